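"""Activity counts and rest-activity rhythm features.

Acceleration (z-axis of the chest patch) is converted to epoch-wise activity
counts with an Oakley-style procedure: high-pass filter at 0.25 Hz to remove
the gravity component, per-second maximum absolute deviation, a 0.05 g
deadband, and summation of supra-threshold per-second maxima per 30-s epoch.

From 48 h of hourly counts (midnight-to-midnight days, best two consecutive
days, 12 h/day minimum coverage, PCHIP-imputed) eight features are derived:
interdaily stability (IS), intradaily variability (IV), the least-active
5-hour and most-active 10-hour means (L5/M10), relative rest-activity
amplitude RA = (M10 - L5) / (M10 + L5), and the three cosinor-rhythmometry
parameters mesor, amplitude and acrophase of the fitted 24-h cosine.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt

from .signals import TimestampedSeries

__all__ = [
    "ACTIGRAPHY_FEATURE_NAMES",
    "oakley_counts",
    "select_best_two_days",
    "rest_activity_metrics",
    "cosinor_fit",
    "actigraphy_block",
]

ACTIGRAPHY_FEATURE_NAMES: tuple[str, ...] = (
    "is_", "iv", "l5", "m10", "ra", "mesor", "amplitude", "acrophase",
)

_DAY = 86400.0


def oakley_counts(
    accel_z: TimestampedSeries,
    epoch: float = 30.0,
    hp_cutoff: float = 0.25,
    deadband_g: float = 0.05,
) -> TimestampedSeries:
    """Convert a z-axis acceleration signal (g) to per-epoch activity counts.

    Requires a (near-)uniform sampling rate of at least 20 Hz. Gaps in the
    input propagate: epochs without any supra-threshold seconds still appear
    (count 0) if sampled, epochs with no samples at all are absent.
    """
    if len(accel_z) < 2:
        raise ValueError("acceleration series too short")
    dt = np.median(np.diff(accel_z.t))
    fs = 1.0 / dt
    if fs < 20.0:
        raise ValueError(f"sampling rate {fs:.1f} Hz below the 20 Hz minimum")
    nyq = fs / 2.0
    b, a = butter(2, hp_cutoff / nyq, btype="high")
    filtered = filtfilt(b, a, accel_z.v)

    t0 = float(np.floor(accel_z.t[0]))
    sec = np.floor(accel_z.t - t0).astype(int)
    n_sec = sec[-1] + 1
    # per-second max |deviation|
    order = np.argsort(sec, kind="stable")
    sec_max = np.zeros(n_sec)
    np.maximum.at(sec_max, sec[order], np.abs(filtered[order]))
    sampled = np.zeros(n_sec, dtype=bool)
    sampled[sec] = True
    sec_max[sec_max < deadband_g] = 0.0

    ep = int(round(epoch))
    n_ep = int(np.ceil(n_sec / ep))
    epoch_idx = np.arange(n_sec) // ep
    counts = np.bincount(epoch_idx, weights=sec_max, minlength=n_ep)
    has_data = np.bincount(epoch_idx, weights=sampled.astype(float), minlength=n_ep) > 0
    starts = t0 + epoch * np.arange(n_ep)
    return TimestampedSeries(starts[has_data], counts[has_data])


def hourly_coverage(counts: TimestampedSeries, day_start: float, n_days: int) -> np.ndarray:
    """(n_days, 24) boolean array: hour has at least one sampled epoch."""
    cov = np.zeros((n_days, 24), dtype=bool)
    rel = counts.t - day_start
    ok = (rel >= 0) & (rel < n_days * _DAY)
    day = (rel[ok] // _DAY).astype(int)
    hour = ((rel[ok] % _DAY) // 3600.0).astype(int)
    cov[day, hour] = True
    return cov


def select_best_two_days(
    counts: TimestampedSeries,
    day_start: float = 0.0,
) -> tuple[int, int] | None:
    """Pick the consecutive midnight-to-midnight day pair with most coverage.

    Coverage of a day is its number of hours containing any data. Among all
    consecutive pairs the one with the highest total coverage wins (ties go
    to the earliest pair). Returns 0-based day indices, or None (REJECT)
    when the span is shorter than two days or either chosen day has fewer
    than 12 h of data.
    """
    if len(counts) < 2:
        return None
    n_days = int(np.ceil((counts.t[-1] - day_start) / _DAY))
    if n_days < 2:
        return None
    epoch_h = float(np.median(np.diff(counts.t))) / 3600.0
    day = ((counts.t - day_start) // _DAY).astype(int)
    ok = (day >= 0) & (day < n_days)
    cov = np.bincount(day[ok], minlength=n_days) * epoch_h  # sampled hours per day
    totals = cov[:-1] + cov[1:]
    best = int(np.argmax(totals))  # argmax takes the first maximum: earliest pair
    if cov[best] < 12 or cov[best + 1] < 12:
        return None
    return best, best + 1


def rest_activity_metrics(hourly: np.ndarray) -> dict[str, float]:
    """IS, IV, L5, M10 and RA from 48 hourly count values (no missing).

    IS compares the variance of the mean 24-h profile to the total variance;
    IV is the normalized mean square successive difference; L5/M10 are the
    extreme 5-h/10-h moving-average means; RA = (M10-L5)/(M10+L5).
    Constant input makes IS/IV/RA undefined (NaN).
    """
    x = np.asarray(hourly, dtype=float)
    if len(x) != 48:
        raise ValueError(f"expected 48 hourly values, got {len(x)}")
    n = len(x)
    xbar = x.mean()
    total_var = np.sum((x - xbar) ** 2) / n
    profile = x.reshape(2, 24).mean(axis=0)
    if total_var > 0:
        is_ = (np.sum((profile - xbar) ** 2) / 24.0) / total_var
        iv = (n * np.sum(np.diff(x) ** 2)) / ((n - 1) * np.sum((x - xbar) ** 2))
    else:
        is_ = float("nan")
        iv = float("nan")
    win5 = np.convolve(x, np.ones(5) / 5.0, mode="valid")
    win10 = np.convolve(x, np.ones(10) / 10.0, mode="valid")
    l5 = float(win5.min())
    m10 = float(win10.max())
    ra = (m10 - l5) / (m10 + l5) if (m10 + l5) > 0 else float("nan")
    return {"is_": float(is_), "iv": float(iv), "l5": l5, "m10": m10, "ra": float(ra)}


def cosinor_fit(
    hourly_t: np.ndarray,
    hourly_v: np.ndarray,
    period_h: float = 24.0,
) -> dict[str, float]:
    """Least-squares 24-h cosinor: x(t) = M + A*cos(2*pi*(t - phi)/24).

    ``hourly_t`` in hours. Fitted via the linear beta*cos + gamma*sin
    parameterization; amplitude A >= 0, acrophase phi in [0, 24) hours past
    midnight. A constant signal yields A = 0, phi reported as 0 with the
    ``degenerate`` flag set.
    """
    t = np.asarray(hourly_t, dtype=float)
    x = np.asarray(hourly_v, dtype=float)
    if len(t) < 3:
        raise ValueError("cosinor fit needs at least 3 samples")
    if np.ptp(t) == 0:
        raise ValueError("singular design: constant time vector")
    w = 2.0 * np.pi / period_h
    design = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    mesor, beta, gamma = coef
    amplitude = float(np.hypot(beta, gamma))
    degenerate = amplitude < 1e-12 * max(1.0, abs(mesor))
    if degenerate:
        acro = 0.0
    else:
        acro = float((np.arctan2(gamma, beta) / w) % period_h)
    return {
        "mesor": float(mesor),
        "amplitude": amplitude,
        "acrophase": acro,
        "degenerate": bool(degenerate),
    }


def actigraphy_block(
    hourly_two_days: TimestampedSeries,
) -> dict[str, float]:
    """Assemble the 8-feature actigraphy block from 48 imputed hourly values.

    Input must be the PCHIP-imputed hourly series of the selected best two
    consecutive days (exactly 48 samples, hour-start timestamps).
    """
    if len(hourly_two_days) != 48:
        raise ValueError(f"expected 48 hourly samples, got {len(hourly_two_days)}")
    feats = rest_activity_metrics(hourly_two_days.v)
    hours = (hourly_two_days.t - hourly_two_days.t[0]) / 3600.0
    phase0 = (hourly_two_days.t[0] / 3600.0) % 24.0
    cos = cosinor_fit(hours + phase0, hourly_two_days.v)
    feats.update({k: cos[k] for k in ("mesor", "amplitude", "acrophase")})
    assert set(feats) == set(ACTIGRAPHY_FEATURE_NAMES)
    return feats
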