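"""Reading and writing signals, tables and cohort manifests.

Signals travel as 1- or 2-column delimited text (time in seconds,
amplitude in arbitrary units); cohort manifests as delimited tables with
``path, label, position, subject_id`` columns.  Writers stamp every table
with the tool version, a config hash and the seed so any artifact can be
traced to the run that produced it.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import CohortDataset, PulseSignal

__all__ = ["read_signal", "write_signal", "write_manifest", "read_manifest",
           "read_cohort", "table_header", "SignalFormatError"]


class SignalFormatError(ValueError):
    """Raised for unparseable or non-uniform signal files."""


def read_signal(path, fs_override: float | None = None) -> PulseSignal:
    """Read a delimited signal file (``time amplitude`` or amplitude only).

    Timestamps must be uniform to 1e-6 relative jitter; rows with
    non-finite entries are dropped with a warning.  Single-column files
    need ``fs_override``.
    """
    try:
        data = np.loadtxt(path, ndmin=2, comments="#", delimiter=None)
    except Exception as exc:
        raise SignalFormatError(f"cannot parse {path}: {exc}") from exc
    if data.size == 0:
        raise SignalFormatError(f"{path} is empty")
    finite = np.all(np.isfinite(data), axis=1)
    dropped = int((~finite).sum())
    if dropped:
        warnings.warn(f"{path}: dropped {dropped} non-finite row(s)",
                      stacklevel=2)
        data = data[finite]
    if data.shape[0] < 2:
        raise SignalFormatError(f"{path}: fewer than 2 usable rows")
    if data.shape[1] == 1:
        if fs_override is None:
            raise SignalFormatError("single-column file needs fs_override")
        return PulseSignal(samples=data[:, 0], fs=fs_override, t0=0.0)
    t, x = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SignalFormatError(f"{path}: non-increasing timestamps")
    base_dt = np.median(dt)
    # gaps from dropped rows are whole multiples of the sampling period;
    # anything else is jitter and rejected at 1e-6 relative tolerance
    mult = dt / base_dt
    if np.max(np.abs(mult - np.round(mult))) > 1e-6 or np.any(
            np.round(mult) < 1):
        raise SignalFormatError(f"{path}: non-uniform sampling")
    fs = fs_override if fs_override is not None else 1.0 / base_dt
    return PulseSignal(samples=x, fs=fs, t0=float(t[0]))


def table_header(config=None, seed=None) -> str:
    from . import __version__

    parts = [f"pulsesst v{__version__}"]
    if config is not None:
        parts.append(f"config={config.config_hash()}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + " ".join(parts)


def write_signal(path, signal: PulseSignal, config=None, seed=None,
                 sidecar: dict | None = None) -> None:
    """Write a 2-column signal file; optional YAML sidecar with metadata."""
    path = Path(path)
    t = signal.t
    with open(path, "w") as fh:
        fh.write(table_header(config, seed) + "\n")
        fh.write("# time_s amplitude\n")
        np.savetxt(fh, np.column_stack([t, signal.samples]), fmt="%.9g")
    if sidecar is not None:
        meta = {"fs": float(signal.fs), "t0": float(signal.t0),
                "n": int(signal.n)}
        meta.update({k: _yamlable(v) for k, v in sidecar.items()})
        with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)


def _yamlable(v):
    if isinstance(v, np.ndarray):
        return [float(x) for x in v.ravel()]
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def write_manifest(path, rows: list[dict], config=None, seed=None) -> None:
    df = pd.DataFrame(rows, columns=["path", "label", "position",
                                     "subject_id"])
    with open(path, "w") as fh:
        fh.write(table_header(config, seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"path", "label"} - set(df.columns)
    if missing:
        raise SignalFormatError(f"manifest lacks columns {sorted(missing)}")
    return df


def read_cohort(manifest_path, fs_override: float | None = None
                ) -> CohortDataset:
    """Load every record referenced by a manifest into a CohortDataset."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    records, meta = [], []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        records.append(read_signal(p, fs_override=fs_override))
        meta.append({k: row[k] for k in df.columns})
    return CohortDataset(records=records,
                         labels=df["label"].to_numpy(int),
                         metadata=meta)
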