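"""Missing-data handling for wearable signals.

Three techniques, matched to the three places missingness enters the
pipeline:

1. **SQI-based multi-channel ECG fusion** — when the same window was recorded
   by several chest-patch channels, keep the channel with the highest signal
   quality index, and only if that SQI exceeds 0.75 (strict); otherwise the
   window becomes a gap.
2. **PCHIP hourly activity imputation** — hourly activity-count totals with
   empty interior hours filled by shape-preserving piecewise-cubic
   interpolation.
3. **Stochastic surrogate imputation** — gaps longer than a threshold
   ``th_g`` are filled by copying a donor segment of the same duration from
   the gap's neighbourhood. The donor side is a fair coin toss; the donor
   offset is a folded-normal draw scaled by the gap length, so the search
   neighbourhood widens with gap size; a small Gaussian noise term
   (``noise_frac`` x N(mean, var) of the original series) is added to each
   copied sample. Gaps are processed in increasing length order so that
   freshly filled short gaps can serve as donor material for longer ones.
   Repeating the procedure with different seeds yields a surrogate ensemble
   whose member-to-member spread propagates imputation uncertainty into the
   downstream features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, filtfilt, find_peaks

from .signals import TimestampedSeries

__all__ = [
    "Gap",
    "ChannelWindow",
    "SurrogateEnsemble",
    "fuse_channels_by_sqi",
    "simple_bsqi",
    "detect_gaps",
    "surrogate_impute",
    "generate_surrogate_ensemble",
    "pchip_impute_hourly",
]


@dataclass(frozen=True)
class Gap:
    """A missing interval: last sample before (t_b), first after (t_e)."""

    t_b: float
    t_e: float

    def __post_init__(self) -> None:
        if not self.t_b < self.t_e:
            raise ValueError("gap must have t_b < t_e")

    @property
    def g_l(self) -> float:
        """Gap length in seconds."""
        return self.t_e - self.t_b


@dataclass(frozen=True)
class ChannelWindow:
    """One channel's samples for one fusion window, with its quality index."""

    window_start: float
    channel_id: int
    sqi: float
    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.sqi <= 1.0:
            raise ValueError("SQI must lie in [0, 1]")
        if not 1 <= self.channel_id <= 4:
            raise ValueError("channel_id must be in 1..4")
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))


@dataclass
class SurrogateEnsemble:
    """A set of stochastic imputations of one gappy series."""

    members: list[TimestampedSeries]
    member_seeds: list[int]
    th_g: float
    noise_frac: float = 0.05

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# SQI-based ECG channel fusion
# ---------------------------------------------------------------------------

def fuse_channels_by_sqi(
    windows: list[ChannelWindow],
    threshold: float = 0.75,
) -> tuple[TimestampedSeries, list[dict]]:
    """Fuse up-to-4-channel windowed ECG-derived data by signal quality.

    Per window-start group the channel with the highest SQI wins (ties go to
    the lowest channel id); its samples enter the output only if its SQI is
    *strictly* greater than ``threshold``, otherwise the whole window is
    discarded and becomes a gap.

    Returns the fused series plus a per-window provenance list of dicts with
    keys ``window_start``, ``chosen_channel`` (None if discarded) and ``sqi``.
    """
    by_start: dict[float, list[ChannelWindow]] = {}
    for w in windows:
        by_start.setdefault(float(w.window_start), []).append(w)

    ts: list[np.ndarray] = []
    vs: list[np.ndarray] = []
    provenance: list[dict] = []
    prev_end = -np.inf
    for start in sorted(by_start):
        group = by_start[start]
        if len(group) > 4:
            raise ValueError(f"more than 4 channels at window_start={start}")
        best = min(group, key=lambda w: (-w.sqi, w.channel_id))
        if best.sqi > threshold:
            if len(best.t) and best.t[0] <= prev_end:
                raise ValueError(
                    f"window at {start} overlaps the previous kept window; "
                    "inconsistent window grids"
                )
            ts.append(best.t)
            vs.append(best.v)
            if len(best.t):
                prev_end = best.t[-1]
            provenance.append(
                {"window_start": start, "chosen_channel": best.channel_id, "sqi": best.sqi}
            )
        else:
            provenance.append(
                {"window_start": start, "chosen_channel": None, "sqi": best.sqi}
            )
    if ts:
        fused = TimestampedSeries(np.concatenate(ts), np.concatenate(vs))
    else:
        fused = TimestampedSeries(np.empty(0), np.empty(0))
    return fused, provenance


# ---------------------------------------------------------------------------
# Simplified beat-detector-agreement SQI
# ---------------------------------------------------------------------------

def _detect_amplitude(x: np.ndarray, fs: float) -> np.ndarray:
    """Amplitude-threshold beat detector on a 5-15 Hz band-passed signal."""
    nyq = fs / 2.0
    hi = min(15.0 / nyq, 0.99)
    b, a = butter(2, [5.0 / nyq, hi], btype="band")
    y = filtfilt(b, a, x)
    thr = 0.85 * np.percentile(np.abs(y), 98)
    peaks, _ = find_peaks(np.abs(y), height=thr, distance=max(1, int(0.25 * fs)))
    return peaks / fs


def _detect_slope_energy(x: np.ndarray, fs: float) -> np.ndarray:
    """Slope-energy detector: squared derivative, smoothed, peak-picked."""
    d = np.diff(x, prepend=x[0]) * fs
    e = d * d
    win = max(1, int(0.08 * fs))
    kernel = np.ones(win) / win
    s = np.convolve(e, kernel, mode="same")
    # deliberately permissive: on clean ECG only QRS complexes carry slope
    # energy, while broadband noise triggers densely — which is what makes
    # the two detectors disagree on bad signal
    thr = 0.05 * np.percentile(s, 98)
    peaks, _ = find_peaks(s, height=thr, distance=max(1, int(0.2 * fs)))
    return peaks / fs


def simple_bsqi(ecg_window: np.ndarray, fs: float, match_tol: float = 0.150) -> float:
    """Beat-detector agreement quality index for one ECG window.

    Two dissimilar detectors (amplitude threshold on a band-passed signal;
    slope-energy) are run; the returned fraction is the number of beat pairs
    agreeing within ``match_tol`` seconds divided by the number of beats
    detected by either detector (matched counted once). Returns 0.0 when
    fewer than 3 beats are matched by both.
    """
    x = np.asarray(ecg_window, dtype=float)
    if len(x) < 10 * fs:
        raise ValueError("bSQI window must be at least 10 s long")
    t1 = _detect_amplitude(x, fs)
    t2 = _detect_slope_energy(x, fs)
    if len(t1) == 0 or len(t2) == 0:
        return 0.0
    # greedy one-to-one matching on nearest neighbours
    used = np.zeros(len(t2), dtype=bool)
    matched = 0
    for b in t1:
        j = int(np.argmin(np.abs(t2 - b) + used * 1e9))
        if not used[j] and abs(t2[j] - b) <= match_tol:
            used[j] = True
            matched += 1
    if matched < 3:
        return 0.0
    return matched / (len(t1) + len(t2) - matched)


# ---------------------------------------------------------------------------
# Gap detection and stochastic surrogate imputation
# ---------------------------------------------------------------------------

def detect_gaps(s: TimestampedSeries, th_g: float) -> list[Gap]:
    """Inter-sample spacings greater than ``th_g`` seconds.

    Returned sorted by increasing gap length, ties by gap start time.
    """
    if len(s) < 2:
        return []
    dt = np.diff(s.t)
    idx = np.flatnonzero(dt > th_g)
    gaps = [Gap(float(s.t[i]), float(s.t[i + 1])) for i in idx]
    gaps.sort(key=lambda g: (g.g_l, g.t_b))
    return gaps


def _covered(t: np.ndarray, lo: float, hi: float, th_g: float) -> bool:
    """True iff [lo, hi] lies in the sampled span with no spacing > th_g.

    Boundaries count: the stretch from `lo` to the first interior sample and
    from the last interior sample to `hi` must each be <= th_g, so a donor
    copied from here cannot create a fresh gap at the splice points.
    """
    if len(t) == 0 or lo < t[0] or hi > t[-1]:
        return False
    i0 = int(np.searchsorted(t, lo, side="left"))
    i1 = int(np.searchsorted(t, hi, side="right"))
    seg = t[i0:i1]
    if len(seg) == 0:
        return hi - lo <= th_g
    pts = np.concatenate(([lo], seg, [hi]))
    return bool(np.all(np.diff(pts) <= th_g))


def surrogate_impute(
    s: TimestampedSeries,
    th_g: float,
    noise_frac: float = 0.05,
    seed: int | np.random.Generator = 0,
    align: float | None = None,
    max_tries: int = 50,
) -> TimestampedSeries:
    """Fill every gap longer than ``th_g`` with a stochastic donor segment.

    Per gap (ascending length): a fair coin picks the left or right
    neighbourhood; a folded-normal draw ``|x_r| * g_l`` offsets the donor
    window beyond the admissible boundary (left donors end at
    ``t_b - g_l - offset``, right donors start at ``t_e + offset``); the
    donor's samples are copied into the gap with additive noise
    ``noise_frac * N(mean_S, var_S)`` per sample, where the mean/variance are
    those of the pre-imputation series. The series is updated before the next
    gap, so previously imputed samples may serve as donors.

    ``align`` snaps donor offsets down to a multiple of the given step so
    grid signals stay on-grid after imputation.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    gaps = detect_gaps(s, th_g)
    if not gaps:
        return s
    mu_s = float(np.mean(s.v))
    sd_s = float(np.std(s.v, ddof=0))

    t = s.t.copy()
    v = s.v.copy()
    for gap in gaps:
        g_l = gap.g_l
        filled = False
        first_side = int(rng.integers(2))  # 0 = left, 1 = right
        for side in (first_side, 1 - first_side):
            for _ in range(max_tries):
                offset = abs(float(rng.standard_normal())) * g_l
                if align is not None:
                    offset = np.floor(offset / align) * align
                if side == 0:
                    d_end = gap.t_b - g_l - offset
                    d_start = d_end - g_l
                else:
                    d_start = gap.t_e + offset
                    d_end = d_start + g_l
                if not _covered(t, d_start, d_end, th_g):
                    continue
                i0 = int(np.searchsorted(t, d_start, side="left"))
                i1 = int(np.searchsorted(t, d_end, side="right"))
                donor_t = t[i0:i1]
                donor_v = v[i0:i1].copy()
                new_t = gap.t_b + (donor_t - d_start)
                keep = (new_t > gap.t_b) & (new_t < gap.t_e)
                new_t = new_t[keep]
                new_v = donor_v[keep]
                if len(new_t) == 0:
                    continue
                if noise_frac > 0:
                    new_v = new_v + noise_frac * rng.normal(mu_s, sd_s, size=len(new_v))
                ins = int(np.searchsorted(t, gap.t_b, side="right"))
                t = np.concatenate((t[:ins], new_t, t[ins:]))
                v = np.concatenate((v[:ins], new_v, v[ins:]))
                filled = True
                break
            if filled:
                break
        if not filled:
            raise ValueError(
                f"no donor segment of length {g_l:.1f}s available for gap "
                f"[{gap.t_b:.1f}, {gap.t_e:.1f}]s"
            )
    return TimestampedSeries(t, v)


def generate_surrogate_ensemble(
    s: TimestampedSeries,
    th_g: float,
    m: int = 100,
    noise_frac: float = 0.05,
    base_seed: int = 0,
    align: float | None = None,
) -> SurrogateEnsemble:
    """``m`` independent surrogate imputations, member i seeded base_seed + i."""
    members = []
    seeds = []
    for i in range(m):
        seed = base_seed + i
        members.append(surrogate_impute(s, th_g, noise_frac=noise_frac, seed=seed, align=align))
        seeds.append(seed)
    return SurrogateEnsemble(members=members, member_seeds=seeds, th_g=th_g, noise_frac=noise_frac)


# ---------------------------------------------------------------------------
# PCHIP hourly activity imputation
# ---------------------------------------------------------------------------

def pchip_impute_hourly(
    counts: TimestampedSeries,
    t0: float | None = None,
    n_hours: int | None = None,
) -> TimestampedSeries:
    """Hourly count totals with empty hours filled by PCHIP interpolation.

    Hours with data contribute their sum of counts; empty interior hours are
    filled with shape-preserving piecewise-cubic interpolation over the hour
    index; empty leading/trailing hours take the nearest observed hour's
    value. Output timestamps are hour starts (one value per hour, no missing
    hours).
    """
    if len(counts) == 0:
        raise ValueError("empty count series")
    if t0 is None:
        t0 = float(np.floor(counts.t[0] / 3600.0) * 3600.0)
    if n_hours is None:
        n_hours = int(np.ceil((counts.t[-1] - t0) / 3600.0))
        n_hours = max(n_hours, 1)
    hour_idx = np.floor((counts.t - t0) / 3600.0).astype(int)
    in_range = (hour_idx >= 0) & (hour_idx < n_hours)
    sums = np.bincount(hour_idx[in_range], weights=counts.v[in_range], minlength=n_hours)
    have = np.zeros(n_hours, dtype=bool)
    have[np.unique(hour_idx[in_range])] = True
    n_have = int(have.sum())
    if n_have < 2:
        raise ValueError("need at least 2 non-empty hours for interpolation")

    hours = np.arange(n_hours, dtype=float)
    values = sums.astype(float)
    obs_h = hours[have]
    obs_v = values[have]
    missing = ~have
    if missing.any():
        interior = missing & (hours > obs_h[0]) & (hours < obs_h[-1])
        if interior.any():
            interp = PchipInterpolator(obs_h, obs_v)
            values[interior] = interp(hours[interior])
        edges = missing & ~interior
        if edges.any():
            values[edges & (hours < obs_h[0])] = obs_v[0]
            values[edges & (hours > obs_h[-1])] = obs_v[-1]
    return TimestampedSeries(t0 + hours * 3600.0, values)
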