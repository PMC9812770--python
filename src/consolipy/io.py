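"""File formats: the HDF5 session container, CSV tables, YAML config.

Container layout::

    /PFC /M1 /HPC          groups, each with dataset ``lfp`` (channels x time,
                           float32), attrs ``rate``, ``t0``, dataset ``channel_ok``
    /spikes/<area>/<unit>  float64 spike times (s)
    /trials                trial table columns as datasets
    /manifest              attrs animal_id, day, block_* bounds
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .types import (AREAS, IntervalSet, Recording, SessionManifest,
                    SpikeTrainSet, make_event_table, validate_event_table,
                    validate_trial_table, _EVENT_COLUMNS, _TRIAL_COLUMNS)

#: serialization precision for timestamps (decimal places = microseconds)
_T_DECIMALS = 6


class FormatError(ValueError):
    """A container or table does not conform to the expected schema."""


# ---------------------------------------------------------------- HDF5

def write_recording(path, rec: Recording) -> None:
    with h5py.File(path, "a") as f:
        if rec.area in f:
            del f[rec.area]
        g = f.create_group(rec.area)
        g.create_dataset("lfp", data=rec.samples.astype(np.float32))
        g.create_dataset("channel_ok", data=rec.channel_ok)
        g.attrs["rate"] = float(rec.rate)
        g.attrs["t0"] = float(rec.t0)


def load_recording(path, area: str) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such container: {path}")
    with h5py.File(path, "r") as f:
        if area not in f:
            raise FormatError(f"container has no group /{area}")
        g = f[area]
        for need in ("lfp", "channel_ok"):
            if need not in g:
                raise FormatError(f"/{area} missing dataset '{need}'")
        if "rate" not in g.attrs:
            raise FormatError(f"/{area} missing attribute 'rate'")
        rate = float(g.attrs["rate"])
        if rate <= 0:
            raise FormatError(f"/{area} rate must be positive, got {rate}")
        return Recording(
            area=area,
            samples=g["lfp"][...],
            rate=rate,
            channel_ok=g["channel_ok"][...],
            t0=float(g.attrs.get("t0", 0.0)),
        )


def write_spikes(path, spikes: SpikeTrainSet) -> None:
    with h5py.File(path, "a") as f:
        if "spikes" in f:
            del f["spikes"]
        g = f.create_group("spikes")
        for unit_id, area, times in spikes.units:
            g.create_dataset(f"{area}/{unit_id}", data=np.asarray(times, dtype=np.float64))


def load_spikes(path, areas=AREAS) -> SpikeTrainSet:
    units = []
    with h5py.File(path, "r") as f:
        if "spikes" not in f:
            return SpikeTrainSet([])
        g = f["spikes"]
        for area in areas:
            if area not in g:
                continue
            for unit_id in sorted(g[area], key=lambda s: (len(s), s)):
                units.append((unit_id, area, g[area][unit_id][...]))
    return SpikeTrainSet(units)


def write_manifest(path, manifest: SessionManifest) -> None:
    with h5py.File(path, "a") as f:
        g = f.require_group("manifest")
        g.attrs["animal_id"] = manifest.animal_id
        g.attrs["day"] = int(manifest.day)
        for name, (s, e) in manifest.blocks.items():
            g.attrs[f"block_{name}"] = (float(s), float(e))


def load_manifest(path) -> SessionManifest:
    with h5py.File(path, "r") as f:
        if "manifest" not in f:
            raise FormatError("container missing /manifest")
        a = f["manifest"].attrs
        blocks = {}
        for name in ("pre_sleep", "training", "post_sleep"):
            key = f"block_{name}"
            if key not in a:
                raise FormatError(f"/manifest missing attribute '{key}'")
            blocks[name] = tuple(map(float, a[key]))
        return SessionManifest(str(a["animal_id"]), int(a["day"]), blocks)


def write_trials(path, trials: pd.DataFrame) -> None:
    trials = validate_trial_table(trials)
    with h5py.File(path, "a") as f:
        if "trials" in f:
            del f["trials"]
        g = f.create_group("trials")
        g.create_dataset("trial_id", data=np.asarray(trials["trial_id"], dtype="S32"))
        g.create_dataset("reach_onset", data=trials["reach_onset"].to_numpy(float))
        g.create_dataset("pellet_touch",
                         data=trials["pellet_touch"].to_numpy(float))
        g.create_dataset("success", data=trials["success"].to_numpy(bool))
        g.create_dataset("hand", data=np.asarray(trials["hand"], dtype="S1"))


def load_trials(path) -> pd.DataFrame:
    with h5py.File(path, "r") as f:
        if "trials" not in f:
            raise FormatError("container missing /trials")
        g = f["trials"]
        df = pd.DataFrame({
            "trial_id": [s.decode() for s in g["trial_id"][...]],
            "reach_onset": g["reach_onset"][...],
            "pellet_touch": g["pellet_touch"][...],
            "success": g["success"][...],
            "hand": [s.decode() for s in g["hand"][...]],
        })
    return validate_trial_table(df)


# ---------------------------------------------------------------- CSV

def write_events(table: pd.DataFrame, path) -> None:
    table = validate_event_table(make_event_table(table) if len(table) else table)
    out = table.copy() if len(table) else make_event_table()
    for c in ("t_onset", "t_peak", "t_end"):
        out[c] = out[c].map(lambda v: f"{v:.{_T_DECIMALS}f}")
    out.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"event CSV missing columns {sorted(missing)}")
    if len(df) == 0:
        return make_event_table()
    return validate_event_table(df[_EVENT_COLUMNS])


def write_intervals(ivs: IntervalSet, path) -> None:
    pd.DataFrame({"start": np.round(ivs.starts, _T_DECIMALS),
                  "end": np.round(ivs.ends, _T_DECIMALS)}).to_csv(path, index=False)


def read_intervals(path) -> IntervalSet:
    df = pd.read_csv(path)
    return IntervalSet(zip(df["start"], df["end"]))


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    out = validate_trial_table(trials).copy()
    out["reach_onset"] = out["reach_onset"].map(lambda v: f"{v:.{_T_DECIMALS}f}")
    out["pellet_touch"] = out["pellet_touch"].map(
        lambda v: "" if pd.isna(v) else f"{v:.{_T_DECIMALS}f}")
    out.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"trial CSV missing columns {sorted(missing)}")
    return validate_trial_table(df)


# ---------------------------------------------------------------- config

DEFAULT_CONFIG = {
    "staging": {
        "epoch_s": 6.0,
        "delta_band": [0.1, 4.0],
        "gamma_band": [30.0, 60.0],
        "min_run_s": 30.0,
        "trace_area": "M1",
        "kmeans_restarts": 10,
    },
    "detection": {
        "artifact_sd": 10.0,
        "so": {"peak_pct": 85.0, "trough_pct": 40.0,
               "dur_min": 0.150, "dur_max": 0.500,
               "hp": [0.1, 2], "lp": [4.0, 5]},
        "spindle": {"upper_sd": 2.5, "lower_sd": 1.5, "min_dur": 0.500,
                    "env_smooth": 0.200, "hp": [10.0, 6], "lp": [15.0, 8]},
        "swr": {"upper_sd": 4.0, "lower_sd": 1.0, "min_dur": 0.050,
                "env_smooth": 0.020, "hp": [150.0, 8], "lp": [250.0, 10],
                "n_channels": 3},
    },
    "coupling": {
        "so_swr_window": [-0.75, 0.75],
        "pfc_m1_window": [-0.2, 0.2],
        "so_spindle_window": [-0.5, 1.0],
        "multi_window": [-1.0, 1.0],
        "swr_so_plus_window": 1.0,
        "null_reps": 1000,
        "subsample_n": 100,
        "subsample_reps": 1000,
        "min_events": 10,
    },
    "dynamics": {
        "kernel_tertiles": 9,
        "pad_days": 2,
        "scan_windows": [3, 4, 5, 6, 7],
        "baseline_days": [1, 4],
        "baseline_sd_mult": 2.0,
    },
    "gpfa": {
        "bin_s": 0.015,
        "window": [-0.2, 0.4],
        "pfc_expand_s": 0.1,
        "latent_dim": 6,
        "top_factors": 3,
        "em_tol": 1e-6,
        "em_max_iter": 500,
        "min_rate_hz": 0.5,
        "gp_noise_frac": 1e-3,
    },
    "reactivation": {
        "bin_s": 0.015,
        "fixed_window_s": 0.195,
        "search_sizes_s": [0.075, 0.405, 0.030],
        "search_lag_step_s": 0.015,
        "search_max_s": 0.405,
        "shuffle_window": [-0.2, 0.4],
        "null_reps": 1000,
        "cca_window_s": 1.0,
    },
}


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Load a YAML config merged over the package defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_update(cfg, user)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
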