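"""Synthetic patient-visit cohorts with the statistical structure the
analysis assumes.

Each visit emulates a 48-h chest-patch recording at a 30-s base resolution:

* activity counts with a 24-h cosinor profile plus noise,
* a latent heart-rate series with AR(1) dynamics, a circadian component and
  a directional activity -> HR coupling term (activity drives HR one step
  ahead, never the reverse),
* beat-level RR intervals derived from the latent HR by integrating the
  instantaneous rate and adding 3% multiplicative jitter,
* deceleration episodes — short ramps of RR lengthening — injected at a
  Poisson rate with a per-visit amplitude; the amplitude is the generative
  handle on deceleration capacity, lower in high-severity visits,
* per-60-s-window, per-channel Beta-distributed signal-quality traces whose
  mean degrades during high-activity epochs,
* realistic gap patterns: one charging gap per 24 h plus Poisson dropouts.

A discrete VAR(1) companion model provides a closed-form Gaussian transfer
entropy (Lyapunov solve) used as the independent oracle for the adaptive
partitioning TE estimator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .signals import RRSeries, TimestampedSeries

__all__ = [
    "GapModel",
    "VisitParams",
    "CohortConfig",
    "VAR1Params",
    "VisitRecord",
    "CohortDataset",
    "analytic_te_var1",
    "simulate_var1",
    "generate_trivariate_signals",
    "inject_gaps",
    "generate_cohort",
    "write_cohort",
]

_DAY_H = 24.0


@dataclass(frozen=True)
class GapModel:
    """Missingness model: daily charging gap + Poisson dropouts."""

    charging_gap_hours: float = 2.0
    dropout_rate_per_hour: float = 0.5
    dropout_mean_s: float = 300.0

    def __post_init__(self) -> None:
        if self.dropout_rate_per_hour < 0:
            raise ValueError("dropout_rate must be >= 0")


@dataclass(frozen=True)
class VisitParams:
    """Generative parameters for one synthetic patient-visit."""

    patient_id: str
    visit_id: str
    cgis: int
    dc_mean: float = 10.0            # deceleration-episode amplitude, ms
    coupling_gamma: float = 0.15     # activity -> HR coupling, bpm per normalized count
    circadian_amp_counts: float = 40.0
    circadian_amp_bpm: float = 6.0
    acrophase_h: float = 15.0        # activity peak, hours past midnight
    hr_base_bpm: float = 80.0
    hr_ar: float = 0.9               # latent HR AR(1) coefficient
    hr_noise_bpm: float = 2.0
    act_noise: float = 10.0
    rr_jitter: float = 0.03
    dc_episodes_per_hour: float = 200.0
    gap_model: GapModel = field(default_factory=GapModel)
    duration_h: float = 48.0
    n_channels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cgis not in range(1, 8):
            raise ValueError("CGI-S must be an integer in 1..7")
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        if not abs(self.hr_ar) < 1:
            raise ValueError("HR autoregression must be stationary (|a| < 1)")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level structure and group effect sizes.

    ``dc_effect`` separates the low/high-severity deceleration-amplitude
    means by that many between-visit SDs (low-severity higher);
    ``coupling_effect`` widens the high-severity group's coupling spread.
    """

    n_patients: int = 20
    visit_probs: tuple[float, ...] = (0.5, 0.35, 0.15)  # P(1), P(2), P(3) visits
    severity_split: float = 0.5
    dc_effect: float = 2.0
    coupling_effect: float = 0.5
    dc_base_ms: float = 10.0
    dc_visit_sd_ms: float = 1.5
    gamma_base: float = 0.15
    gamma_sd: float = 0.03
    duration_h: float = 48.0
    gap_model: GapModel = field(default_factory=GapModel)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if not 0.0 <= self.severity_split <= 1.0:
            raise ValueError("severity_split must be in [0, 1]")


@dataclass(frozen=True)
class VAR1Params:
    """Bivariate VAR(1): hr_t = a*hr_{t-1} + gamma*act_{t-1} + e1;
    act_t = b*act_{t-1} + e2."""

    a: float
    gamma: float
    b: float
    sigma_hr: float = 1.0
    sigma_act: float = 1.0

    def __post_init__(self) -> None:
        if not (abs(self.a) < 1 and abs(self.b) < 1):
            raise ValueError("non-stationary VAR(1): need |a| < 1 and |b| < 1")


def analytic_te_var1(p: VAR1Params) -> float:
    """Exact Gaussian transfer entropy act -> hr of the VAR(1), in nats.

    TE = 0.5 * ln( Var[hr_t | hr_{t-1}] / Var[hr_t | hr_{t-1}, act_{t-1}] ),
    computed from the stationary covariance (discrete Lyapunov solve).
    """
    a_mat = np.array([[p.a, p.gamma], [0.0, p.b]])
    q = np.diag([p.sigma_hr**2, p.sigma_act**2])
    sigma = solve_discrete_lyapunov(a_mat, q)
    cross = a_mat @ sigma  # Cov(z_t, z_{t-1})
    var_hr = sigma[0, 0]
    # conditioning on hr_{t-1} only
    var_red = var_hr - cross[0, 0] ** 2 / sigma[0, 0]
    # conditioning on (hr_{t-1}, act_{t-1})
    c = cross[0, :]
    var_full = var_hr - c @ np.linalg.solve(sigma, c)
    return float(0.5 * np.log(var_red / var_full))


def simulate_var1(p: VAR1Params, n: int, seed: int = 0, burn: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Sample (act, hr) paths of the VAR(1) after burn-in."""
    rng = np.random.default_rng(seed)
    total = n + burn
    e_hr = rng.normal(0.0, p.sigma_hr, total)
    e_act = rng.normal(0.0, p.sigma_act, total)
    hr = np.zeros(total)
    act = np.zeros(total)
    for i in range(1, total):
        act[i] = p.b * act[i - 1] + e_act[i]
        hr[i] = p.a * hr[i - 1] + p.gamma * act[i - 1] + e_hr[i]
    return act[burn:], hr[burn:]


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _latent_grids(p: VisitParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(t grid, activity counts, latent HR bpm) on the 30-s base grid."""
    n = int(round(p.duration_h * 120))
    t = 30.0 * np.arange(n)
    h = t / 3600.0
    circ = (1.0 + np.cos(2.0 * np.pi * (h - p.acrophase_h) / _DAY_H)) / 2.0
    act = p.circadian_amp_counts * circ + np.abs(rng.normal(0.0, p.act_noise, n))
    act = np.clip(act, 0.0, None)

    act_norm = act / max(act.mean(), 1e-9)
    e = np.zeros(n)
    eps = rng.normal(0.0, p.hr_noise_bpm, n)
    for i in range(1, n):
        e[i] = p.hr_ar * e[i - 1] + eps[i]
    act_lag = np.concatenate(([act_norm[0]], act_norm[:-1]))
    hr = (
        p.hr_base_bpm
        + p.coupling_gamma * p.hr_base_bpm * 0.2 * (act_lag - 1.0)
        + p.circadian_amp_bpm * np.cos(2.0 * np.pi * (h - p.acrophase_h) / _DAY_H)
        + e
    )
    return t, act, np.clip(hr, 35.0, 190.0)


# deceleration episode: RR ramps up over five beats then recovers, the
# consecutive-beat increment equal to the per-visit amplitude (ms), so the
# PRSA deceleration capacity responds linearly to the dc_mean handle.
# Zero-mean so episodes do not inflate total recording time (deceleration
# is followed by a compensatory acceleration, as in baroreflex recovery).
_DC_KERNEL = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
_DC_KERNEL = _DC_KERNEL - _DC_KERNEL.mean()


def _beats_from_hr(
    t: np.ndarray, hr: np.ndarray, p: VisitParams, rng: np.random.Generator
) -> RRSeries:
    """Integrate the latent rate to beat times, jitter, inject decelerations."""
    step = t[1] - t[0] if len(t) > 1 else 30.0
    # cumulative expected beat count at grid edges
    beats_per_bin = hr / 60.0 * step
    cum = np.concatenate(([0.0], np.cumsum(beats_per_bin)))
    edges = np.concatenate((t, [t[-1] + step]))
    n_beats = int(np.floor(cum[-1]))
    base_t = np.interp(np.arange(1, n_beats + 1, dtype=float), cum, edges)
    ibi_ms = np.diff(np.concatenate(([edges[0]], base_t))) * 1000.0
    rr = ibi_ms * (1.0 + p.rr_jitter * rng.standard_normal(n_beats))

    n_ep = rng.poisson(p.dc_episodes_per_hour * p.duration_h)
    if n_ep > 0 and n_beats > len(_DC_KERNEL) + 2:
        starts = rng.integers(1, n_beats - len(_DC_KERNEL) - 1, size=n_ep)
        for s in starts:
            rr[s : s + len(_DC_KERNEL)] += p.dc_mean * _DC_KERNEL
    rr = np.clip(rr, 250.0, 2500.0)
    beat_t = edges[0] + np.cumsum(rr) / 1000.0
    return RRSeries(beat_t, rr)


def _accel_from_act(
    t: np.ndarray, act: np.ndarray, p: VisitParams, rng: np.random.Generator, fs: float
) -> tuple[TimestampedSeries, TimestampedSeries, TimestampedSeries]:
    """Three-axis acceleration (g) whose z-axis burst amplitude tracks counts."""
    step = t[1] - t[0] if len(t) > 1 else 30.0
    n_samp = int(round(len(t) * step * fs))
    ts = t[0] + np.arange(n_samp) / fs
    act_norm = act / max(act.max(), 1e-9)
    amp = 0.02 + 0.4 * np.repeat(act_norm, int(round(step * fs)))[:n_samp]
    carrier = np.sin(2.0 * np.pi * 3.0 * ts + rng.uniform(0, 2 * np.pi))
    noise = rng.normal(0.0, 0.01, n_samp)
    z = amp * carrier + noise
    x = 0.3 * amp * np.sin(2.0 * np.pi * 2.1 * ts) + rng.normal(0.0, 0.01, n_samp)
    y = 0.3 * amp * np.sin(2.0 * np.pi * 1.3 * ts) + rng.normal(0.0, 0.01, n_samp)
    return (
        TimestampedSeries(ts, x),
        TimestampedSeries(ts, y),
        TimestampedSeries(ts, z + 1.0),  # gravity offset on z
    )


def _sqi_traces(
    t: np.ndarray, act: np.ndarray, p: VisitParams, rng: np.random.Generator
) -> np.ndarray:
    """(n_windows, 3) array: window start (s), channel id, SQI value."""
    step = t[1] - t[0] if len(t) > 1 else 30.0
    win = 60.0
    n_win = int(len(t) * step // win)
    act_norm = act / max(act.max(), 1e-9)
    per_win = max(1, int(win // step))
    rows = []
    conc = 30.0
    for w in range(n_win):
        start = t[0] + w * win
        a = act_norm[w * per_win : (w + 1) * per_win].mean()
        for ch in range(1, p.n_channels + 1):
            mu = np.clip(0.95 - 0.5 * a - 0.05 * (ch - 1), 0.05, 0.98)
            sqi = rng.beta(mu * conc, (1.0 - mu) * conc)
            rows.append((start, float(ch), float(sqi)))
    return np.array(rows)


def generate_trivariate_signals(
    p: VisitParams,
    accel_fs: float | None = None,
) -> dict:
    """Gap-free signals for one visit.

    Returns a dict with ``rr`` (RRSeries), ``counts`` (30-s activity counts),
    ``sqi`` ((n, 3) array of window start / channel / SQI) and, when
    ``accel_fs`` is given, ``accel`` = (x, y, z) TimestampedSeries at that
    sampling rate.
    """
    rng = np.random.default_rng(p.seed)
    t, act, hr = _latent_grids(p, rng)
    rr = _beats_from_hr(t, hr, p, rng)
    out = {
        "rr": rr,
        "counts": TimestampedSeries(t, act),
        "sqi": _sqi_traces(t, act, p, rng),
    }
    if accel_fs is not None:
        if accel_fs < 20.0:
            raise ValueError("accelerometer sampling rate must be >= 20 Hz")
        out["accel"] = _accel_from_act(t, act, p, rng, accel_fs)
    return out


def inject_gaps(
    s: TimestampedSeries,
    gap_model: GapModel,
    seed: int = 0,
) -> TimestampedSeries:
    """Apply one charging gap per 24 h plus Poisson dropouts.

    Surviving samples are identical to the input at their timestamps. Warns
    (and proceeds) if the model removes more than 90% of samples.
    """
    if len(s) == 0:
        raise ValueError("cannot inject gaps into an empty series")
    rng = np.random.default_rng(seed)
    t0, t1 = s.span
    duration_h = (t1 - t0) / 3600.0
    intervals: list[tuple[float, float]] = []
    n_days = int(np.ceil(duration_h / _DAY_H - 0.01))
    chg = gap_model.charging_gap_hours
    if chg > 0:
        for d in range(n_days):
            day_start = t0 + d * 86400.0
            hi = min(day_start + (_DAY_H - chg) * 3600.0, t1 - chg * 3600.0)
            if hi <= day_start:
                continue
            start = rng.uniform(day_start, hi)
            intervals.append((start, start + chg * 3600.0))
    if gap_model.dropout_rate_per_hour > 0:
        n_drop = rng.poisson(gap_model.dropout_rate_per_hour * duration_h)
        starts = rng.uniform(t0, t1, n_drop)
        lengths = rng.exponential(gap_model.dropout_mean_s, n_drop)
        intervals.extend(zip(starts, starts + lengths))
    keep = np.ones(len(s), dtype=bool)
    for lo, hi in intervals:
        keep &= ~((s.t > lo) & (s.t < hi))
    if keep.sum() < 0.1 * len(s):
        warnings.warn("gap model removed more than 90% of samples", stacklevel=2)
    return TimestampedSeries(s.t[keep], s.v[keep])


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class VisitRecord:
    params: VisitParams
    rr: RRSeries
    counts: TimestampedSeries
    sqi: np.ndarray

    @property
    def label(self) -> str:
        return "low" if self.params.cgis <= 4 else "high"


@dataclass
class CohortDataset:
    config: CohortConfig
    visits: list[VisitRecord]

    @property
    def n_patients(self) -> int:
        return len({v.params.patient_id for v in self.visits})

    def __len__(self) -> int:
        return len(self.visits)


def generate_cohort(config: CohortConfig, with_gaps: bool = True) -> CohortDataset:
    """Generate a labeled synthetic cohort.

    High-severity visits get a lower deceleration-episode amplitude (the
    group means differ by ``dc_effect`` between-visit SDs) and a wider
    coupling spread. Deterministic given ``master_seed``; rejects any
    severity split that would leave a class empty.
    """
    n_high = int(round(config.severity_split * config.n_patients))
    n_low = config.n_patients - n_high
    if n_high == 0 or n_low == 0:
        raise ValueError(
            f"severity_split={config.severity_split} leaves an empty class "
            f"({n_low} low / {n_high} high patients)"
        )
    ss = np.random.SeedSequence(config.master_seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    groups = np.array(["high"] * n_high + ["low"] * n_low)
    rng.shuffle(groups)

    gap = config.dc_effect * config.dc_visit_sd_ms
    dc_mu = {"low": config.dc_base_ms + gap / 2.0, "high": config.dc_base_ms - gap / 2.0}
    gamma_sd = {
        "low": config.gamma_sd,
        "high": config.gamma_sd * (1.0 + config.coupling_effect),
    }

    visits: list[VisitRecord] = []
    visit_seeds = ss.spawn(config.n_patients + 1)[1:]
    for i, grp in enumerate(groups):
        pid = f"P{i + 1:02d}"
        p_rng = np.random.default_rng(visit_seeds[i])
        n_visits = 1 + int(p_rng.choice(len(config.visit_probs), p=config.visit_probs))
        for j in range(n_visits):
            cgis = int(p_rng.integers(5, 8)) if grp == "high" else int(p_rng.integers(2, 5))
            dc_amp = max(float(p_rng.normal(dc_mu[grp], config.dc_visit_sd_ms)), 1.0)
            gamma = float(p_rng.normal(config.gamma_base, gamma_sd[grp]))
            vseed = int(p_rng.integers(0, 2**31 - 1))
            params = VisitParams(
                patient_id=pid,
                visit_id=f"{pid}V{j + 1}",
                cgis=cgis,
                dc_mean=dc_amp,
                coupling_gamma=gamma,
                gap_model=config.gap_model,
                duration_h=config.duration_h,
                seed=vseed,
            )
            sig = generate_trivariate_signals(params)
            rr, counts = sig["rr"], sig["counts"]
            if with_gaps:
                rr_s = inject_gaps(rr.as_series(), config.gap_model, seed=vseed + 1)
                rr = RRSeries(rr_s.t, rr_s.v)
                counts = inject_gaps(counts, config.gap_model, seed=vseed + 2)
            visits.append(VisitRecord(params=params, rr=rr, counts=counts, sqi=sig["sqi"]))
    labels = {v.label for v in visits}
    if labels != {"low", "high"}:
        raise ValueError("generated cohort lacks a severity class")
    return CohortDataset(config=config, visits=visits)


def write_cohort(cohort: CohortDataset, out_dir: str | Path) -> None:
    """One directory per visit: rr.csv, counts.csv, sqi.csv, meta.json."""
    out = Path(out_dir)
    for v in cohort.visits:
        d = out / v.params.visit_id
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(
            d / "rr.csv",
            np.column_stack([v.rr.beat_t, v.rr.rr]),
            delimiter=",", header="t_sec,rr_ms", comments="", fmt="%.6f",
        )
        np.savetxt(
            d / "counts.csv",
            np.column_stack([v.counts.t, v.counts.v]),
            delimiter=",", header="t_sec,counts", comments="", fmt="%.6f",
        )
        np.savetxt(
            d / "sqi.csv", v.sqi,
            delimiter=",", header="t_start_sec,channel,sqi", comments="", fmt="%.6f",
        )
        meta = {
            "patient_id": v.params.patient_id,
            "visit_id": v.params.visit_id,
            "cgis": v.params.cgis,
            "seed": v.params.seed,
            "dc_mean": v.params.dc_mean,
            "coupling_gamma": v.params.coupling_gamma,
            "duration_h": v.params.duration_h,
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1))
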