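"""Recording container and on-disk formats.

All voltages are held internally in millivolts, times in seconds and
frequencies in hertz.  Two on-disk formats are supported:

``csv``
    Interchange format.  ``#``-prefixed metadata lines (``# key=value``)
    followed by a ``time_s,voltage_mV`` header and one row per sample.
``raw``
    Canonical lossless format: little-endian float64 samples plus a JSON
    sidecar (same path with ``.json`` appended) carrying ``fs``, ``unit``,
    ``t0``, ``modality``, ``labels`` and ``source``.

Acquisition-vendor formats (pCLAMP, CED) are deliberately not parsed;
convert to one of the above first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "read_recording",
    "write_recording",
    "read_table",
    "write_table",
]

MODALITIES = ("lfp", "cell_attached")

#: multiplicative factors converting a declared unit into millivolts
_UNIT_TO_MV = {"mV": 1.0, "V": 1000.0, "uV": 1e-3, "µV": 1e-3}


@dataclass
class Recording:
    """A uniformly sampled single-channel voltage trace.

    Parameters
    ----------
    samples : array-like
        Voltage samples in millivolts.
    fs : float
        Sampling rate in Hz (> 0).
    t0 : float
        Time of the first sample in seconds.
    modality : str
        ``"lfp"`` or ``"cell_attached"``.
    labels : dict
        Free-form experimental labels (genotype, treatment, organoid_id,
        slice_id, batch, electrode_distance_um, ...).
    source : str
        Provenance string (file path, generator spec hash, ...).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    modality: str = "lfp"
    labels: dict[str, Any] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D array with length >= 2")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"fs must be a positive number, got {self.fs!r}")
        bad = np.flatnonzero(~np.isfinite(self.samples))
        if bad.size:
            raise ValueError(f"non-finite sample at index {bad[0]}")
        if self.modality not in MODALITIES:
            raise ValueError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n/fs)."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def with_samples(self, samples: np.ndarray, source_suffix: str = "") -> "Recording":
        """Copy of this recording with new samples (same fs/metadata)."""
        return Recording(
            samples=np.asarray(samples, dtype=np.float64),
            fs=self.fs,
            t0=self.t0,
            modality=self.modality,
            labels=dict(self.labels),
            source=self.source + source_suffix,
        )


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    if path.suffix.lower() == ".csv":
        return "csv"
    return "raw"


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a :class:`Recording` from disk.

    ``format`` may be ``"csv"`` or ``"raw"``; when omitted it is inferred
    from the file suffix.  The declared ``unit`` is converted to mV.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = format or _infer_format(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "raw":
        return _read_raw(path)
    raise ValueError(f"unknown recording format {fmt!r}")


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write ``rec`` to ``path``; returns the path written."""
    path = Path(path)
    fmt = format or _infer_format(path)
    try:
        if fmt == "csv":
            _write_csv(rec, path)
        elif fmt == "raw":
            _write_raw(rec, path)
        else:
            raise ValueError(f"unknown recording format {fmt!r}")
    except OSError as exc:
        raise OSError(f"failed writing recording to {path}: {exc}") from exc
    return path


def _parse_meta(lines: Iterable[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def _read_csv(path: Path) -> Recording:
    header_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line)
            else:
                break
    meta = _parse_meta(header_lines)
    if "fs" not in meta:
        raise ValueError(f"{path}: missing required metadata field 'fs'")
    fs = float(meta["fs"])
    unit = meta.get("unit", "mV")
    if unit not in _UNIT_TO_MV:
        raise ValueError(f"{path}: unknown voltage unit {unit!r}")
    df = pd.read_csv(path, comment="#")
    if "voltage_mV" in df.columns:
        volts = df["voltage_mV"].to_numpy(float)
    elif len(df.columns) >= 2:
        volts = df.iloc[:, 1].to_numpy(float)
    else:
        raise ValueError(f"{path}: expected columns time_s,voltage_mV")
    volts = volts * _UNIT_TO_MV[unit]
    t0 = float(meta.get("t0", 0.0))
    if "time_s" in df.columns and len(df) > 1:
        dt = np.diff(df["time_s"].to_numpy(float))
        fs_implied = 1.0 / np.median(dt)
        if abs(fs_implied - fs) / fs > 1e-3:
            raise ValueError(
                f"{path}: time column implies fs={fs_implied:.6g} Hz, "
                f"inconsistent with declared fs={fs:.6g} Hz (>0.1%)"
            )
        t0 = float(df["time_s"].iloc[0])
    labels = json.loads(meta["labels"]) if "labels" in meta else {}
    return Recording(
        samples=volts,
        fs=fs,
        t0=t0,
        modality=meta.get("modality", "lfp"),
        labels=labels,
        source=str(path),
    )


def _write_csv(rec: Recording, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write("# unit=mV\n")
        fh.write(f"# modality={rec.modality}\n")
        fh.write(f"# t0={rec.t0!r}\n")
        if rec.labels:
            fh.write(f"# labels={json.dumps(rec.labels, sort_keys=True)}\n")
        fh.write("time_s,voltage_mV\n")
        times = rec.times
        for t, v in zip(times, rec.samples):
            fh.write(f"{t:.9g},{v:.9g}\n")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _read_raw(path: Path) -> Recording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar} for raw recording {path}")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise ValueError(f"{sidecar}: missing required metadata field 'fs'")
    unit = meta.get("unit", "mV")
    if unit not in _UNIT_TO_MV:
        raise ValueError(f"{sidecar}: unknown voltage unit {unit!r}")
    samples = np.fromfile(path, dtype="<f8") * _UNIT_TO_MV[unit]
    return Recording(
        samples=samples,
        fs=float(meta["fs"]),
        t0=float(meta.get("t0", 0.0)),
        modality=meta.get("modality", "lfp"),
        labels=meta.get("labels", {}),
        source=str(path),
    )


def _write_raw(rec: Recording, path: Path) -> None:
    rec.samples.astype("<f8").tofile(path)
    meta = {
        "fs": rec.fs,
        "unit": "mV",
        "t0": rec.t0,
        "modality": rec.modality,
        "labels": rec.labels,
        "source": rec.source,
        "n_samples": rec.n_samples,
    }
    _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True, indent=1))


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_table(tbl: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as CSV (NaN -> empty cell)."""
    path = Path(path)
    tbl.to_csv(path, index=False)
    return path


def read_table(path: str | Path, required: Mapping[str, type] | None = None) -> pd.DataFrame:
    """Read a result table; optionally check required columns are present."""
    df = pd.read_csv(path)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df
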