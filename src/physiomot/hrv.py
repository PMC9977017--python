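"""Heart-rate-variability features from beat-level RR series.

A pinned set of 24 window metrics is computed on 300-s windows shifted by
30 s, then aggregated (sample mean + sample variance per metric) over the
nocturnal interval 22:00-10:00 of a two-day visit, giving the 48-dimensional
HRV feature block. The same module derives the 30-s heart-rate and
deceleration-capacity grids consumed by the coupling features.

Metric families (24 metrics total):

* time domain (11): nn_mean, nn_median, nn_mode, nn_var, nn_skew, nn_kurt,
  nn_iqr, sdnn, rmssd, pnn50, hr_mean
* frequency domain (6, Lomb-Scargle on irregular beat times): ulf, vlf, lf,
  hf, lf_hf, total_power
* entropy (2): sampen, apen (m=2, r=0.2*SDNN)
* phase-rectified signal averaging (2): prsa_ac, prsa_dc
* non-linear (3): dfa_alpha1, dfa_alpha2, sd1_sd2

Deceleration capacity (prsa_dc) anchors on beats where the RR interval
lengthens (heart rate decelerates) by at most the anchor filter fraction,
aligns +-L-beat windows on the anchors and combines the phase-averaged
signal X(k) as (X(0) + X(1) - X(-1) - X(-2)) / 4. Because only those four
phases enter, the statistic equals the mean of the per-anchor quantity
(rr[a] + rr[a+1] - rr[a-1] - rr[a-2]) / 4, which this module exploits to
slide 300-s DC windows across a 48-h record in linear time.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.signal import lombscargle

from .signals import RRSeries, TimestampedSeries

__all__ = [
    "HRV_METRIC_NAMES",
    "clean_rr",
    "window_rr",
    "compute_window_metrics",
    "prsa_dc",
    "nocturnal_aggregate",
    "hr_dc_grids",
]

HRV_METRIC_NAMES: tuple[str, ...] = (
    "nn_mean", "nn_median", "nn_mode", "nn_var", "nn_skew", "nn_kurt", "nn_iqr",
    "sdnn", "rmssd", "pnn50", "hr_mean",
    "ulf", "vlf", "lf", "hf", "lf_hf", "total_power",
    "sampen", "apen",
    "prsa_ac", "prsa_dc",
    "dfa_alpha1", "dfa_alpha2", "sd1_sd2",
)

_FREQ_BANDS = {"ulf": (0.0, 0.003), "vlf": (0.003, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.4)}


def clean_rr(
    rr: RRSeries,
    lo_ms: float = 300.0,
    hi_ms: float = 2000.0,
    max_rel_change: float = 0.20,
) -> RRSeries:
    """Drop physiologically implausible intervals before feature extraction.

    Intervals outside [lo_ms, hi_ms] or changing more than ``max_rel_change``
    relative to the previous *accepted* beat are excluded.
    """
    keep = np.zeros(len(rr), dtype=bool)
    prev = None
    for i, x in enumerate(rr.rr):
        if not lo_ms <= x <= hi_ms:
            continue
        if prev is not None and abs(x - prev) > max_rel_change * prev:
            continue
        keep[i] = True
        prev = x
    return RRSeries(rr.beat_t[keep], rr.rr[keep])


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def _window_coverage(beat_t: np.ndarray, max_ibi: float = 2.0) -> float:
    """Seconds of the window covered by inter-beat intervals <= max_ibi."""
    if len(beat_t) < 2:
        return 0.0
    dt = np.diff(beat_t)
    return float(np.sum(dt[dt <= max_ibi]))


def window_rr(
    rr: RRSeries,
    win: float = 300.0,
    shift: float = 30.0,
    min_coverage: float = 0.8,
) -> list[tuple[float, RRSeries]]:
    """Slice an RR series into overlapping windows [k*shift, k*shift + win).

    A window is kept only if its beats cover at least ``min_coverage`` of the
    window duration (gap time above 2 s per inter-beat interval does not
    count as covered). Returns (window_start, window RRSeries) pairs.
    """
    if len(rr) == 0:
        return []
    t_lo, t_hi = rr.beat_t[0], rr.beat_t[-1]
    out: list[tuple[float, RRSeries]] = []
    k = int(np.floor(t_lo / shift + 1e-9))
    while k * shift + win <= t_hi + 1e-9:
        start = k * shift
        w = rr.crop(start, start + win)
        if _window_coverage(w.beat_t) >= min_coverage * win:
            out.append((start, w))
        k += 1
    return out


# ---------------------------------------------------------------------------
# PRSA deceleration / acceleration capacity
# ---------------------------------------------------------------------------

def _prsa_anchor_values(
    rr: np.ndarray,
    kind: str,
    anchor_filter: float,
    edge: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(anchor indices, per-anchor (rr[a]+rr[a+1]-rr[a-1]-rr[a-2])/4 values)."""
    n = len(rr)
    lo = max(edge, 2)
    hi = n - max(edge, 2)
    if hi <= lo:
        return np.empty(0, dtype=int), np.empty(0)
    i = np.arange(lo, hi)
    prev = rr[i - 1]
    cur = rr[i]
    if kind == "dc":
        sel = (cur > prev) & (cur <= (1.0 + anchor_filter) * prev)
    else:
        sel = (cur < prev) & (cur >= (1.0 - anchor_filter) * prev)
    a = i[sel]
    vals = (rr[a] + rr[a + 1] - rr[a - 1] - rr[a - 2]) / 4.0
    return a, vals


def prsa_dc(
    rr: RRSeries,
    L: int = 30,
    anchor_filter: float = 0.05,
) -> tuple[float, float]:
    """Phase-rectified deceleration and acceleration capacity, in ms.

    Anchors with fewer than L beats on either side are excluded. Returns
    (DC, AC); either is NaN when no anchors of that kind exist.
    """
    if len(rr) < 2 * L + 2:
        return float("nan"), float("nan")
    _, dc_vals = _prsa_anchor_values(rr.rr, "dc", anchor_filter, edge=L)
    _, ac_vals = _prsa_anchor_values(rr.rr, "ac", anchor_filter, edge=L)
    dc = float(np.mean(dc_vals)) if len(dc_vals) else float("nan")
    ac = float(np.mean(ac_vals)) if len(ac_vals) else float("nan")
    return dc, ac


# ---------------------------------------------------------------------------
# Window metrics
# ---------------------------------------------------------------------------

def _band_powers(beat_t: np.ndarray, rr: np.ndarray) -> dict[str, float]:
    y = rr - rr.mean()
    if np.allclose(y, 0.0):
        return {k: 0.0 for k in _FREQ_BANDS} | {"lf_hf": 0.0, "total_power": 0.0}
    # finer resolution below 0.04 Hz so the ULF/VLF bands are resolved
    freqs = np.concatenate([
        np.arange(0.001, 0.04, 0.001),
        np.arange(0.04, 0.4005, 0.004),
    ])
    pgram = lombscargle(beat_t, y, 2.0 * np.pi * freqs, normalize=False)
    powers: dict[str, float] = {}
    for name, (flo, fhi) in _FREQ_BANDS.items():
        m = (freqs > flo) & (freqs <= fhi)
        powers[name] = float(np.trapezoid(pgram[m], freqs[m])) if m.sum() > 1 else 0.0
    powers["lf_hf"] = powers["lf"] / powers["hf"] if powers["hf"] > 0 else 0.0
    powers["total_power"] = sum(powers[k] for k in _FREQ_BANDS)
    return powers


def _sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> tuple[float, float]:
    """(SampEn, ApEn) with embedding m = 2 and tolerance r = r_frac * SD.

    Both are computed from one shared pairwise Chebyshev-distance matrix:
    d_m[i, j] = max_k |x[i+k] - x[j+k]|, built incrementally from the scalar
    distance matrix.
    """
    n = len(x)
    sd = np.std(x, ddof=1)
    if sd == 0 or n <= m + 1:
        return 0.0, 0.0
    r = r_frac * sd
    d1 = np.abs(x[:, None] - x[None, :])
    d2 = np.maximum(d1[:-1, :-1], d1[1:, 1:])        # templates of length 2
    d3 = np.maximum(d2[:-1, :-1], d1[2:, 2:])        # templates of length 3
    w2 = d2 <= r
    w3 = d3 <= r
    # SampEn: total match counts excluding self-matches, same template range
    nm = n - m  # number of length-(m+1) templates
    b = int(w2[:nm, :nm].sum()) - nm
    a = int(w3.sum()) - nm
    sampen = float(-np.log(a / b)) if a > 0 and b > 0 else 0.0
    # ApEn: per-template log frequencies including self-matches
    cm = w2.sum(axis=1) / (n - m + 1)
    cm1 = w3.sum(axis=1) / (n - m)
    apen = float(np.mean(np.log(cm)) - np.mean(np.log(cm1)))
    return sampen, apen


def _dfa_alpha(x: np.ndarray, lo: int, hi: int) -> float:
    """Detrended-fluctuation scaling exponent over box sizes [lo, hi]."""
    n = len(x)
    hi = min(hi, n // 4)
    if hi < lo:
        return float("nan")
    y = np.cumsum(x - x.mean())
    sizes = np.unique(np.geomspace(lo, hi, num=8).astype(int))
    fs = []
    for s in sizes:
        nseg = n // s
        seg = y[: nseg * s].reshape(nseg, s)
        tt = np.arange(s, dtype=float)
        tm = tt.mean()
        denom = np.sum((tt - tm) ** 2)
        beta = (seg @ (tt - tm)) / denom
        alpha0 = seg.mean(axis=1)
        detr = seg - (alpha0[:, None] + beta[:, None] * (tt - tm))
        fs.append(np.sqrt(np.mean(detr**2)))
    fs = np.asarray(fs)
    ok = fs > 0
    if ok.sum() < 2:
        return 0.0
    slope, _ = np.polyfit(np.log(sizes[ok]), np.log(fs[ok]), 1)
    return float(slope)


def _mode_10ms(rr: np.ndarray) -> float:
    binned = np.round(rr / 10.0) * 10.0
    vals, counts = np.unique(binned, return_counts=True)
    return float(vals[np.argmax(counts)])  # np.unique sorts, so ties -> smallest


def compute_window_metrics(
    w: RRSeries,
    min_beats: int = 30,
    prsa_L: int = 30,
    anchor_filter: float = 0.05,
) -> dict[str, float] | None:
    """All 24 HRV metrics for one RR window; None if too few beats."""
    if len(w) < min_beats:
        return None
    rr = w.rr
    diffs = np.diff(rr)
    out: dict[str, float] = {
        "nn_mean": float(np.mean(rr)),
        "nn_median": float(np.median(rr)),
        "nn_mode": _mode_10ms(rr),
        "nn_var": float(np.var(rr, ddof=1)),
        "nn_skew": float(stats.skew(rr)) if np.std(rr) > 0 else 0.0,
        "nn_kurt": float(stats.kurtosis(rr)) if np.std(rr) > 0 else 0.0,
        "nn_iqr": float(np.percentile(rr, 75) - np.percentile(rr, 25)),
        "sdnn": float(np.std(rr, ddof=1)),
        "rmssd": float(np.sqrt(np.mean(diffs**2))) if len(diffs) else 0.0,
        "pnn50": float(100.0 * np.mean(np.abs(diffs) > 50.0)) if len(diffs) else 0.0,
        "hr_mean": float(np.mean(60000.0 / rr)),
    }
    out.update(_band_powers(w.beat_t, rr))
    sampen, apen = _sample_entropy(rr)
    out["sampen"] = sampen
    out["apen"] = apen
    # within a 300-s window a +-30-beat PRSA exclusion would discard most
    # anchors, so the edge shrinks to what the window supports
    edge = min(prsa_L, max(2, len(w) // 4))
    _, dc_vals = _prsa_anchor_values(rr, "dc", anchor_filter, edge=edge)
    _, ac_vals = _prsa_anchor_values(rr, "ac", anchor_filter, edge=edge)
    out["prsa_dc"] = float(np.mean(dc_vals)) if len(dc_vals) else 0.0
    out["prsa_ac"] = float(np.mean(ac_vals)) if len(ac_vals) else 0.0
    a1 = _dfa_alpha(rr, 4, 16)
    a2 = _dfa_alpha(rr, 16, 64)
    out["dfa_alpha1"] = a1 if np.isfinite(a1) else 0.0
    out["dfa_alpha2"] = a2 if np.isfinite(a2) else 0.0
    sd1_sq = 0.5 * np.var(diffs, ddof=1) if len(diffs) > 1 else 0.0
    sd2_sq = max(2.0 * np.var(rr, ddof=1) - sd1_sq, 0.0)
    out["sd1_sd2"] = float(np.sqrt(sd1_sq / sd2_sq)) if sd2_sq > 0 else 0.0
    assert set(out) == set(HRV_METRIC_NAMES)
    return out


# ---------------------------------------------------------------------------
# Nocturnal aggregation
# ---------------------------------------------------------------------------

def _is_nocturnal(start_sec: float, night: tuple[float, float]) -> bool:
    """Window start falls in the overnight interval [night0, night1) hours."""
    h = (start_sec / 3600.0) % 24.0
    lo, hi = night
    if lo <= hi:
        return lo <= h < hi
    return h >= lo or h < hi


def nocturnal_aggregate(
    windowed_metrics: list[tuple[float, dict[str, float]]],
    night: tuple[float, float] = (22.0, 10.0),
    min_windows: int = 2,
) -> dict[str, float] | None:
    """Mean and sample variance of each metric over nocturnal windows.

    ``windowed_metrics`` pairs each window start (seconds) with its metric
    dict. Windows are assigned by start time to the half-open overnight
    interval (default 22:00-10:00, wrapping midnight). Returns the
    48-feature block ``{metric}_mean`` / ``{metric}_var``, or None when
    fewer than ``min_windows`` nocturnal windows exist (visit flagged
    missing).
    """
    noct = [m for start, m in windowed_metrics if _is_nocturnal(start, night)]
    if len(noct) < min_windows:
        return None
    block: dict[str, float] = {}
    for name in HRV_METRIC_NAMES:
        vals = np.array([m[name] for m in noct if np.isfinite(m[name])])
        if len(vals) < min_windows:
            return None
        block[f"{name}_mean"] = float(np.mean(vals))
        block[f"{name}_var"] = float(np.var(vals, ddof=1))
    return block


# ---------------------------------------------------------------------------
# 30-s HR / DC grids
# ---------------------------------------------------------------------------

def hr_dc_grids(
    rr: RRSeries,
    step: float = 30.0,
    dc_win: float = 300.0,
    span: tuple[float, float] | None = None,
    anchor_filter: float = 0.05,
    min_hr_beats: int = 3,
    min_dc_anchors: int = 3,
) -> tuple[TimestampedSeries, TimestampedSeries]:
    """Mean-HR and sliding-window-DC series on a uniform grid.

    ``hr``: mean instantaneous heart rate (60000/rr, bpm) of the beats in
    each ``step``-second bin. ``dc``: deceleration capacity over a
    ``dc_win``-second window centred on each grid point, computed from
    per-anchor contributions in linear time. Bins with too few beats or
    anchors are absent (gaps, to be surrogate-imputed downstream).
    """
    if len(rr) < 4:
        raise ValueError("RR series too short for grid computation")
    if span is None:
        t0 = float(np.floor(rr.beat_t[0] / step) * step)
        t1 = float(np.ceil(rr.beat_t[-1] / step) * step)
    else:
        t0, t1 = span
    n_bins = int(round((t1 - t0) / step))
    grid = t0 + step * np.arange(n_bins)

    # HR: bin means of instantaneous rate
    bins = np.floor((rr.beat_t - t0) / step).astype(int)
    ok = (bins >= 0) & (bins < n_bins)
    inst_hr = 60000.0 / rr.rr
    counts = np.bincount(bins[ok], minlength=n_bins)
    sums = np.bincount(bins[ok], weights=inst_hr[ok], minlength=n_bins)
    hr_mask = counts >= min_hr_beats
    with np.errstate(invalid="ignore", divide="ignore"):
        hr_vals = sums / counts
    hr = TimestampedSeries(grid[hr_mask], hr_vals[hr_mask])

    # DC: cumulative-sum sliding mean of per-anchor contributions
    a_idx, a_vals = _prsa_anchor_values(rr.rr, "dc", anchor_filter, edge=2)
    a_t = rr.beat_t[a_idx]
    csum = np.concatenate(([0.0], np.cumsum(a_vals)))
    half = dc_win / 2.0
    lo = np.searchsorted(a_t, grid - half, side="left")
    hi = np.searchsorted(a_t, grid + half, side="right")
    n_anchors = hi - lo
    dc_mask = n_anchors >= min_dc_anchors
    with np.errstate(invalid="ignore", divide="ignore"):
        dc_vals = (csum[hi] - csum[lo]) / n_anchors
    dc = TimestampedSeries(grid[dc_mask], dc_vals[dc_mask])
    return hr, dc
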