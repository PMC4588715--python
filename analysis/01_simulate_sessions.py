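#!/usr/bin/env python
"""Generate the synthetic study sessions and store their containers.

One session per condition (novel / familiar / no-learning), 4 blocks of 96
trials each, with ground-truth theta coupling and Weibull observers.  The
HDF5 containers go to scratch/sessions/ (regenerable); a ground-truth
summary table goes to results/.
"""

from pathlib import Path

import pandas as pd

import spikefield as sk
from spikefield.io import save_session

OUT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "sessions"
SEED = 2


def main() -> None:
    OUT.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    rows = []
    for cond in ("novel", "familiar", "no_learning"):
        cfg, profiles, observer = sk.make_condition(cond, seed=SEED)
        session = sk.generate_session(cfg, profiles, observer, condition=cond)
        path = SCRATCH / f"{cond}_seed{SEED}.h5"
        save_session(session, path)
        for b, (p, o) in enumerate(zip(profiles, observer), start=1):
            rows.append({"condition": cond, "block": b, "kappa": p.kappa,
                         "base_rate": p.base_rate, "fa": o.fa, "a": o.a,
                         "b": o.b})
        print(f"{cond}: {len(session.trials)} trials -> {path.name}")
    truth = pd.DataFrame(rows)
    truth.to_csv(OUT / "ground_truth_parameters.csv", index=False)
    print(f"ground truth written to {OUT / 'ground_truth_parameters.csv'}")


if __name__ == "__main__":
    main()
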