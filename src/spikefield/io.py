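"""HDF5 session container.

Layout: /trials (one dataset per column), /spikes/unit<i> (concatenated
event times plus per-spike trial index), /lfp/ch<i> (trials × samples, with
rate and t0 attributes), /eye/x and /eye/y, and /ground_truth (coupling
profiles, observer parameters, per-trial oscillator phase offsets).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic_data import (CouplingProfile, ObserverModel, Session,
                             SessionConfig, TrialTiming)


class SchemaError(KeyError):
    """A required group or dataset is missing from the container."""


def save_session(session: Session, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["condition"] = session.condition
        f.attrs["t0"] = session.t0
        f.attrs["config"] = json.dumps({
            **{k: v for k, v in session.config.__dict__.items()
               if k != "timing"},
            "timing": session.config.timing.__dict__,
        })
        g = f.create_group("trials")
        for col in session.trials.columns:
            data = session.trials[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            g.create_dataset(col, data=data)
        g = f.create_group("spikes")
        for u, per_trial in enumerate(session.spikes):
            times = np.concatenate([np.asarray(t) for t in per_trial]) \
                if per_trial else np.array([])
            idx = np.concatenate([np.full(len(t), i)
                                  for i, t in enumerate(per_trial)]) \
                if per_trial else np.array([], int)
            gu = g.create_group(f"unit{u:02d}")
            gu.create_dataset("times", data=times)
            gu.create_dataset("trial", data=idx.astype(np.int32))
        g = f.create_group("lfp")
        for ch in range(session.lfp.shape[0]):
            d = g.create_dataset(f"ch{ch:02d}", data=session.lfp[ch])
            d.attrs["rate"] = session.rate
            d.attrs["t0"] = session.t0
        g = f.create_group("eye")
        g.create_dataset("x", data=session.eye[:, :, 0])
        g.create_dataset("y", data=session.eye[:, :, 1])
        g = f.create_group("ground_truth")
        g.attrs["profiles"] = json.dumps([p.__dict__ for p in session.profiles])
        g.attrs["observer"] = json.dumps([o.__dict__ for o in session.observer])
        g.create_dataset("oscillation_phase0", data=session.oscillation_phase0)


def load_session(path: str | Path) -> Session:
    with h5py.File(path, "r") as f:
        for req in ("trials", "spikes", "lfp", "eye", "ground_truth"):
            if req not in f:
                raise SchemaError(f"missing group /{req} in {path}")
        raw_cfg = json.loads(f.attrs["config"])
        raw_cfg["timing"] = TrialTiming(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw_cfg["timing"].items()})
        for key in ("orientations", "channel_positions_mm",
                    "unit_positions_mm"):
            raw_cfg[key] = tuple(raw_cfg[key])
        config = SessionConfig(**raw_cfg)
        cols = {}
        for col in f["trials"]:
            data = f["trials"][col][()]
            if data.dtype.kind == "S":
                data = data.astype(str)
            cols[col] = data
        trials = pd.DataFrame(cols)
        n_trials = len(trials)
        lfp_keys = sorted(f["lfp"].keys())
        if not lfp_keys:
            raise SchemaError(f"no channels under /lfp in {path}")
        lfp = np.stack([f["lfp"][k][()] for k in lfp_keys])
        rate_ds = f["lfp"][lfp_keys[0]]
        t0 = float(rate_ds.attrs["t0"])
        spikes = []
        for k in sorted(f["spikes"].keys()):
            times = f["spikes"][k]["times"][()]
            idx = f["spikes"][k]["trial"][()]
            per_trial = [times[idx == i] for i in range(n_trials)]
            spikes.append(per_trial)
        eye = np.stack([f["eye"]["x"][()], f["eye"]["y"][()]], axis=-1)
        gt = f["ground_truth"]
        profiles = tuple(CouplingProfile(**{**p, "band": tuple(p["band"])})
                         for p in json.loads(gt.attrs["profiles"]))
        observer = tuple(ObserverModel(**o)
                         for o in json.loads(gt.attrs["observer"]))
        phase0 = gt["oscillation_phase0"][()]
        return Session(config=config, trials=trials, lfp=lfp, spikes=spikes,
                       eye=eye, eye_events=[None] * n_trials,
                       oscillation_phase0=phase0, profiles=profiles,
                       observer=observer,
                       condition=str(f.attrs["condition"]), t0=t0)
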