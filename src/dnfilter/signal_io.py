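"""Recordings, run configuration, and delimited-text I/O.

A :class:`Recording` holds the two channels of a compound electrode — the
inner disc (signal + noise) and the outer ring (noise reference) — plus the
sampling rate and optional event markers (oddball or jaw-clench onsets).

On disk a recording is a tab-separated file with a header row naming the
channels, one sample per row; event markers live in a separate two-column
TSV (time_s, code).  Times are seconds from the first sample; sample
indices are 0-based (n = round(t * fs)).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

_FLOAT_FMT = "%.17g"  # full double precision for exact roundtrips


@dataclass
class Recording:
    """Two-channel compound-electrode recording (volts)."""

    inner: np.ndarray
    outer: np.ndarray
    fs: float
    events: np.ndarray = field(default_factory=lambda: np.empty(0))
    label: str = ""

    def __post_init__(self):
        self.inner = np.asarray(self.inner, dtype=float)
        self.outer = np.asarray(self.outer, dtype=float)
        self.events = np.asarray(self.events, dtype=float)
        if self.inner.ndim != 1 or self.outer.ndim != 1:
            raise ValueError("channels must be 1-D")
        if self.inner.size != self.outer.size:
            raise ValueError("inner and outer channels must have equal length")
        if self.inner.size < 1:
            raise ValueError("recording must contain at least one sample")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        dur = self.inner.size / self.fs
        if self.events.size and (self.events.min() < 0 or self.events.max() >= dur):
            raise ValueError("event times must lie within [0, duration)")

    @property
    def n_samples(self) -> int:
        return self.inner.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def as_array(self) -> np.ndarray:
        """(n_samples, 2) array with columns [inner, outer]."""
        return np.column_stack([self.inner, self.outer])


@dataclass
class RunConfig:
    """Flat run configuration shared by all filtering variants.

    ``eta``/``mu`` apply to EMG-noise sessions, ``eta_p300``/``mu_p300`` to
    oddball sessions (the two tasks need different rates because the
    effective learning rate scales with the reference amplitude).  ``mu``
    values of None mean "matched to the corresponding eta".
    """

    fcd: float = 0.5
    fcx: float = 5.0
    gain: float = 1000.0
    ntaps: int = 50
    nlayers: int = 6
    eta: float = 2.5
    eta_p300: float = 10.0
    mu: Optional[float] = None
    mu_p300: Optional[float] = None
    seed: int = 0
    variant: str = "dnf"
    init_scale: object = "fan-in"
    notch_half_width: float = 2.5
    output_delta_derivative: bool = False
    weight_log_every: int = 1

    def __post_init__(self):
        if self.ntaps < 1:
            raise ValueError("ntaps must be >= 1")
        if self.nlayers < 1:
            raise ValueError("nlayers must be >= 1")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.eta < 0 or self.eta_p300 < 0:
            raise ValueError("learning rates must be non-negative")
        if self.variant not in ("dnf", "lms", "laplace", "none"):
            raise ValueError(f"unknown variant {self.variant!r}")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a flat key: value document; keyword overrides win."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def read_recording(path, fs: float, column_map: Optional[dict] = None,
                   events: Optional[Sequence[float]] = None,
                   label: str = "") -> Recording:
    """Read a two-channel TSV recording.

    ``column_map`` maps the roles 'inner'/'outer' to column names in the
    file (default: columns named ``inner`` and ``outer``).
    """
    column_map = column_map or {"inner": "inner", "outer": "outer"}
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    cols = {}
    for role in ("inner", "outer"):
        name = column_map[role]
        if name not in df.columns:
            raise ValueError(f"missing column {name!r} in {path}")
        col = pd.to_numeric(df[name], errors="coerce")
        bad = np.nonzero(~np.isfinite(col.to_numpy(dtype=float)))[0]
        if bad.size:
            raise ValueError(
                f"non-numeric or non-finite value in column {name!r} at row {bad[0]}"
            )
        cols[role] = col.to_numpy(dtype=float)
    ev = np.asarray(events, dtype=float) if events is not None else np.empty(0)
    return Recording(cols["inner"], cols["outer"], fs=fs, events=ev, label=label)


def write_recording(rec: Recording, path) -> None:
    """Write the two channels as TSV (full double precision)."""
    df = pd.DataFrame({"inner": rec.inner, "outer": rec.outer})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_events(path) -> np.ndarray:
    """Read event times (s) from a two-column (time_s, code) TSV."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError(f"missing column 'time_s' in {path}")
    return df["time_s"].to_numpy(dtype=float)


def write_events(times, path, code: int = 1) -> None:
    times = np.asarray(times, dtype=float)
    df = pd.DataFrame({"time_s": times, "code": np.full(times.size, code, dtype=int)})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_results(result, path) -> None:
    """Write a filter result or an SNR report as delimited/flat text.

    Stream-like results (anything with ``e`` and ``y`` attributes) become a
    TSV with one column per signal; report-like results (dataclasses of
    scalars) become a flat key: value document.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"destination directory {path.parent} does not exist")
    if hasattr(result, "e") and hasattr(result, "y"):
        pd.DataFrame({"e": result.e, "y": result.y}).to_csv(
            path, sep="\t", index=False, float_format=_FLOAT_FMT
        )
    elif dataclasses.is_dataclass(result):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(result), fh, sort_keys=False)
    else:
        raise TypeError(f"cannot serialise result of type {type(result)!r}")


def write_weight_distance(wdist, path) -> None:
    """Per-layer weight-distance trace as TSV, one column per layer."""
    wdist = np.asarray(wdist, dtype=float)
    cols = {f"layer{l + 1}": wdist[:, l] for l in range(wdist.shape[1])}
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
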