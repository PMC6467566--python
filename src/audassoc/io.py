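"""On-disk session bundle: events CSV, spike/LFP HDF5 containers, manifest.

A bundle directory holds

* ``events.csv`` -- one row per trial (task, passive and tuning phases)
  with trial-relative event times in seconds and the condition labels;
* ``spikes.h5`` -- per unit, a flat array of spike timestamps plus a
  parallel trial-id array (variable trial lengths without ragged storage);
* ``lfp.h5`` -- a (site x trial x sample) array with the sampling rate and
  per-trial start times as attributes/datasets (absent when no LFP sites
  were recorded);
* ``manifest.json`` -- schema version, seed, config hash and counts.

All times are trial-relative seconds; the S1 onset column is the canonical
alignment anchor for analysis.  Reading validates referential integrity
(every spike/LFP trial id must exist in the events table) before any
analysis can run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["Session", "read_bundle", "write_bundle"]

_EVENT_COLUMNS = [
    "trial_id", "block_id", "phase", "task", "s1_freq", "s2_freq",
    "t_led_on", "t_grasp", "t_s1_on", "t_s2_on", "t_release", "t_reward",
    "tone_duration", "s1_label", "s2_label", "required", "outcome",
]

_STR_COLUMNS = ["phase", "task", "s1_label", "s2_label", "required", "outcome"]


@dataclass
class Session:
    """In-memory session: events table plus spike and LFP containers.

    ``spikes`` maps unit id -> trial id -> sorted trial-relative spike
    times; ``lfp`` is a float32 (site, trial, sample) array whose trial
    axis is described by ``lfp_trial_ids`` and per-trial start times
    ``lfp_t0``.
    """

    SCHEMA_VERSION = "1"

    events: pd.DataFrame
    spikes: dict[int, dict[int, np.ndarray]]
    lfp: np.ndarray | None = None
    lfp_trial_ids: np.ndarray | None = None
    lfp_t0: np.ndarray | None = None
    lfp_sampling_rate: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.spikes)

    @property
    def n_lfp_sites(self) -> int:
        return 0 if self.lfp is None else self.lfp.shape[0]

    def validate(self) -> None:
        """Referential-integrity and schema checks; raises ValidationError."""
        problems: list[str] = []
        if self.events is None or len(self.events) == 0:
            raise ValidationError("events table is empty")
        missing = [c for c in _EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            problems.append(f"events table missing columns: {missing}")
        else:
            ids = set(self.events["trial_id"].astype(int))
            if len(ids) != len(self.events):
                problems.append("duplicate trial_id values in events table")
            for unit_id, trains in self.spikes.items():
                orphans = sorted(set(map(int, trains)) - ids)
                if orphans:
                    problems.append(
                        f"unit {unit_id}: spike trial ids not in events table: {orphans[:5]}"
                    )
            if self.lfp is not None:
                if self.lfp_sampling_rate is None:
                    problems.append("LFP present but sampling rate attribute missing")
                if self.lfp_trial_ids is None or self.lfp_t0 is None:
                    problems.append("LFP present but trial ids / start times missing")
                else:
                    orphans = sorted(set(map(int, self.lfp_trial_ids)) - ids)
                    if orphans:
                        problems.append(f"LFP trial ids not in events table: {orphans[:5]}")
                    if self.lfp.shape[1] != len(self.lfp_trial_ids):
                        problems.append("LFP trial axis does not match lfp_trial_ids")
        version = str(self.meta.get("schema_version", self.SCHEMA_VERSION))
        if version != self.SCHEMA_VERSION:
            problems.append(
                f"schema version {version!r} not supported (expected {self.SCHEMA_VERSION!r})"
            )
        if problems:
            raise ValidationError("; ".join(problems))

    def lfp_traces(self, trial_ids: np.ndarray, site: int) -> tuple[np.ndarray, np.ndarray]:
        """(traces, t0s) for the given trial ids at one site, in request order."""
        index = {int(t): i for i, t in enumerate(self.lfp_trial_ids)}
        rows = [index[int(t)] for t in trial_ids]
        return self.lfp[site, rows].astype(float), self.lfp_t0[rows]


def _config_hash(meta: dict) -> str:
    blob = json.dumps(meta.get("config", {}), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def write_bundle(session: Session, path: str | Path) -> Path:
    """Write a session bundle directory; returns the path.

    The events CSV and manifest are written with stable formatting so that
    write(read(x)) is byte-stable for a fixed schema version.
    """
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    events = session.events.loc[:, _EVENT_COLUMNS].copy()
    events.to_csv(path / "events.csv", index=False, float_format="%.6f", na_rep="")

    with h5py.File(path / "spikes.h5", "w") as f:
        f.attrs["schema_version"] = Session.SCHEMA_VERSION
        for unit_id in sorted(session.spikes):
            trains = session.spikes[unit_id]
            grp = f.create_group(f"unit_{unit_id:04d}")
            trial_ids = sorted(trains)
            counts = np.array([len(trains[t]) for t in trial_ids], dtype=np.int64)
            times = (
                np.concatenate([np.asarray(trains[t], dtype=float) for t in trial_ids])
                if trial_ids else np.empty(0)
            )
            grp.create_dataset("trial_ids", data=np.asarray(trial_ids, dtype=np.int64))
            grp.create_dataset("counts", data=counts)
            grp.create_dataset("times", data=times)
            grp.attrs["unit_id"] = unit_id

    if session.lfp is not None:
        with h5py.File(path / "lfp.h5", "w") as f:
            f.attrs["schema_version"] = Session.SCHEMA_VERSION
            dset = f.create_dataset("data", data=session.lfp.astype(np.float32))
            dset.attrs["sampling_rate"] = float(session.lfp_sampling_rate)
            f.create_dataset("trial_ids", data=np.asarray(session.lfp_trial_ids, dtype=np.int64))
            f.create_dataset("t0", data=np.asarray(session.lfp_t0, dtype=float))

    manifest = {
        "schema_version": Session.SCHEMA_VERSION,
        "seed": session.meta.get("seed"),
        "config_hash": _config_hash(session.meta),
        "n_trials": int(len(session.events)),
        "n_units": session.n_units,
        "n_lfp_sites": session.n_lfp_sites,
        "meta": _jsonable(session.meta),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return path


def read_bundle(path: str | Path) -> Session:
    """Read and validate a session bundle directory."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"no manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    if str(manifest.get("schema_version")) != Session.SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported schema version {manifest.get('schema_version')!r}"
        )

    events = pd.read_csv(path / "events.csv", dtype={c: "string" for c in _STR_COLUMNS})
    for col in _STR_COLUMNS:
        events[col] = events[col].fillna("").astype(str)

    spikes: dict[int, dict[int, np.ndarray]] = {}
    with h5py.File(path / "spikes.h5", "r") as f:
        for name in sorted(f):
            grp = f[name]
            unit_id = int(grp.attrs["unit_id"])
            trial_ids = grp["trial_ids"][...]
            counts = grp["counts"][...]
            times = grp["times"][...]
            offsets = np.concatenate([[0], np.cumsum(counts)])
            spikes[unit_id] = {
                int(t): times[offsets[i]:offsets[i + 1]]
                for i, t in enumerate(trial_ids)
            }

    lfp = lfp_trial_ids = lfp_t0 = None
    sampling_rate = None
    lfp_path = path / "lfp.h5"
    if lfp_path.exists():
        with h5py.File(lfp_path, "r") as f:
            dset = f["data"]
            if "sampling_rate" not in dset.attrs:
                raise ValidationError("lfp.h5 data set lacks the sampling_rate attribute")
            sampling_rate = float(dset.attrs["sampling_rate"])
            lfp = dset[...]
            lfp_trial_ids = f["trial_ids"][...]
            lfp_t0 = f["t0"][...]

    session = Session(
        events=events,
        spikes=spikes,
        lfp=lfp,
        lfp_trial_ids=lfp_trial_ids,
        lfp_t0=lfp_t0,
        lfp_sampling_rate=sampling_rate,
        meta=manifest.get("meta", {}),
    )
    session.validate()
    return session


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
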