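"""Core signal containers.

Every signal in the pipeline — RR intervals, binned heart rate, activity
counts, per-channel quality traces — is carried as a :class:`TimestampedSeries`:
a pair of equal-length arrays (time in seconds, value). Missingness is never
represented by NaN; a missing stretch is simply an interval with no samples,
which is what the gap-detection and surrogate-imputation steps operate on.

Beat-level data get the specialised :class:`RRSeries` (beat times + inter-beat
intervals in ms), and the three imputed 30-s signals that feed the coupling
features are bundled into a :class:`TrivariateGrid`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimestampedSeries", "RRSeries", "TrivariateGrid"]


@dataclass(frozen=True)
class TimestampedSeries:
    """Scalar time series with strictly increasing timestamps.

    Parameters
    ----------
    t : array of float
        Sample times in seconds (local clock, 0 = midnight of day 1).
    v : array of float
        Sample values; units depend on the signal (ms for RR, bpm for HR,
        counts for activity, dimensionless for SQI).
    """

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if t.ndim != 1 or v.ndim != 1:
            raise ValueError("t and v must be 1-D arrays")
        if len(t) != len(v):
            raise ValueError(f"length mismatch: len(t)={len(t)} != len(v)={len(v)}")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValueError(f"timestamps not strictly increasing at index {bad}")
        if np.any(np.isnan(v)):
            raise ValueError("NaN values are not allowed; represent missing data as time gaps")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def span(self) -> tuple[float, float]:
        """(first, last) timestamp."""
        if len(self.t) == 0:
            raise ValueError("empty series has no span")
        return float(self.t[0]), float(self.t[-1])

    def crop(self, t0: float, t1: float) -> "TimestampedSeries":
        """Samples with t in the half-open interval [t0, t1)."""
        m = (self.t >= t0) & (self.t < t1)
        return TimestampedSeries(self.t[m], self.v[m])


@dataclass(frozen=True)
class RRSeries:
    """Beat-annotation series: beat times (s) and inter-beat intervals (ms).

    ``rr[i]`` is the interval ending at ``beat_t[i]``; for a gap-free record
    ``rr[i] ~= (beat_t[i] - beat_t[i-1]) * 1000``.
    """

    beat_t: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_t, dtype=float)
        rr = np.asarray(self.rr, dtype=float)
        if len(bt) != len(rr):
            raise ValueError("beat_t and rr must have equal length")
        if len(bt) > 1 and not np.all(np.diff(bt) > 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(rr <= 0):
            raise ValueError("RR intervals must be positive")
        object.__setattr__(self, "beat_t", bt)
        object.__setattr__(self, "rr", rr)

    def __len__(self) -> int:
        return len(self.beat_t)

    def crop(self, t0: float, t1: float) -> "RRSeries":
        m = (self.beat_t >= t0) & (self.beat_t < t1)
        return RRSeries(self.beat_t[m], self.rr[m])

    def as_series(self) -> TimestampedSeries:
        return TimestampedSeries(self.beat_t, self.rr)


@dataclass(frozen=True)
class TrivariateGrid:
    """HR, DC and activity counts aligned on a common uniform grid.

    The nominal configuration is a 30-s grid over 48 h (5760 points) with no
    missing values — the input contract of the multiscale transfer-entropy and
    transition-network features. All three signals must be fully imputed
    before construction.
    """

    t: np.ndarray
    hr: np.ndarray
    dc: np.ndarray
    act: np.ndarray
    step: float = field(default=30.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        arrs = {}
        for name in ("hr", "dc", "act"):
            a = np.asarray(getattr(self, name), dtype=float)
            if len(a) != len(t):
                raise ValueError(f"{name} length {len(a)} != grid length {len(t)}")
            if np.any(np.isnan(a)):
                raise ValueError(f"{name} contains NaN; impute before building the grid")
            arrs[name] = a
        if len(t) > 1:
            dt = np.diff(t)
            if not np.allclose(dt, self.step, atol=1e-6):
                raise ValueError("grid timestamps are not uniform at the declared step")
        object.__setattr__(self, "t", t)
        for name, a in arrs.items():
            object.__setattr__(self, name, a)

    def __len__(self) -> int:
        return len(self.t)

    def signal(self, name: str) -> np.ndarray:
        if name not in ("hr", "dc", "act"):
            raise KeyError(f"unknown grid signal {name!r}")
        return getattr(self, name)
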