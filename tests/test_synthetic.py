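"""Synthetic cohort generator: structure, coupling, determinism, gaps."""

import numpy as np
import pytest
from scipy import stats

from physiomot import (
    CohortConfig,
    GapModel,
    VisitParams,
    clean_rr,
    cosinor_fit,
    detect_gaps,
    generate_cohort,
    generate_trivariate_signals,
    hr_dc_grids,
    inject_gaps,
    pchip_impute_hourly,
    prsa_dc,
)


def visit(seed=0, **kw):
    defaults = dict(patient_id="P", visit_id="V", cgis=3, seed=seed)
    defaults.update(kw)
    return VisitParams(**defaults)


class TestVisitSignals:
    def test_structure_and_span(self, short_visit):
        rr, counts = short_visit["rr"], short_visit["counts"]
        assert len(counts) == 5760
        assert counts.t[0] == 0.0
        assert rr.beat_t[-1] == pytest.approx(172800.0, abs=120.0)
        assert np.all(counts.v >= 0)
        sqi = short_visit["sqi"]
        assert set(np.unique(sqi[:, 1])) == {1.0, 2.0, 3.0}
        assert np.all((sqi[:, 2] >= 0) & (sqi[:, 2] <= 1))

    def test_deterministic_given_seed(self):
        a = generate_trivariate_signals(visit(seed=9))
        b = generate_trivariate_signals(visit(seed=9))
        assert np.array_equal(a["rr"].rr, b["rr"].rr)
        assert np.array_equal(a["counts"].v, b["counts"].v)
        assert np.array_equal(a["sqi"], b["sqi"])

    def test_uncoupled_case_has_no_crosscorrelation(self):
        p = visit(seed=1, coupling_gamma=0.0, circadian_amp_counts=0.0,
                  circadian_amp_bpm=0.0)
        sig = generate_trivariate_signals(p)
        hr, _ = hr_dc_grids(sig["rr"], span=(0.0, 172800.0))
        hr_full = np.interp(sig["counts"].t, hr.t, hr.v)
        r = np.corrcoef(sig["counts"].v, hr_full)[0, 1]
        assert abs(r) < 0.05

    def test_coupling_is_directional(self):
        """Activity drives HR: lagged act->HR correlation dominates."""
        wins = 0
        for seed in range(20):
            p = visit(seed=seed, coupling_gamma=0.5, circadian_amp_bpm=0.0)
            sig = generate_trivariate_signals(p)
            hr, _ = hr_dc_grids(sig["rr"], span=(0.0, 172800.0))
            hr_full = np.interp(sig["counts"].t, hr.t, hr.v)
            act = sig["counts"].v
            fwd = np.corrcoef(act[:-1], hr_full[1:])[0, 1]
            bwd = np.corrcoef(hr_full[:-1], act[1:])[0, 1]
            if fwd > bwd:
                wins += 1
        assert wins >= 16

    def test_cosinor_recovers_acrophase(self):
        p = visit(seed=3, acrophase_h=15.0)
        sig = generate_trivariate_signals(p)
        hourly = pchip_impute_hourly(sig["counts"], t0=0.0, n_hours=48)
        fit = cosinor_fit(hourly.t / 3600.0, hourly.v)
        assert fit["acrophase"] == pytest.approx(15.0, abs=1.0)

    def test_dc_handle_moves_measured_dc(self):
        lo = [prsa_dc(clean_rr(generate_trivariate_signals(visit(seed=s, dc_mean=4.0))["rr"]))[0]
              for s in range(3)]
        hi = [prsa_dc(clean_rr(generate_trivariate_signals(visit(seed=s, dc_mean=14.0))["rr"]))[0]
              for s in range(3)]
        assert min(hi) > max(lo)

    def test_nonstationary_params_rejected(self):
        with pytest.raises(ValueError):
            visit(hr_ar=1.1)


class TestInjectGaps:
    def test_zero_gap_model_is_identity(self, short_visit):
        gm = GapModel(charging_gap_hours=0.0, dropout_rate_per_hour=0.0)
        out = inject_gaps(short_visit["counts"], gm, seed=0)
        assert np.array_equal(out.t, short_visit["counts"].t)
        assert np.array_equal(out.v, short_visit["counts"].v)

    def test_two_charging_gaps_on_48h(self, short_visit):
        gm = GapModel(charging_gap_hours=2.0, dropout_rate_per_hour=0.0)
        out = inject_gaps(short_visit["counts"], gm, seed=1)
        long_gaps = [g for g in detect_gaps(out, 60.0) if g.g_l >= 7200.0 - 60.0]
        assert len(long_gaps) == 2

    def test_deterministic_placement(self, short_visit):
        gm = GapModel()
        a = inject_gaps(short_visit["counts"], gm, seed=4)
        b = inject_gaps(short_visit["counts"], gm, seed=4)
        assert np.array_equal(a.t, b.t)

    def test_surviving_samples_unchanged(self, short_visit):
        out = inject_gaps(short_visit["counts"], GapModel(), seed=5)
        idx = np.searchsorted(short_visit["counts"].t, out.t)
        assert np.allclose(short_visit["counts"].v[idx], out.v)

    def test_extreme_removal_warns(self):
        from conftest import make_series
        s = make_series(np.arange(0.0, 86400.0 * 2, 30.0))
        gm = GapModel(charging_gap_hours=23.0, dropout_rate_per_hour=5.0,
                      dropout_mean_s=3600.0)
        with pytest.warns(UserWarning, match="90%"):
            inject_gaps(s, gm, seed=0)


class TestCohort:
    def test_default_cohort_structure(self):
        cohort = generate_cohort(CohortConfig(master_seed=5), with_gaps=False)
        assert cohort.n_patients == 20
        labels = {v.label for v in cohort.visits}
        assert labels == {"low", "high"}
        for v in cohort.visits:
            assert (v.params.cgis > 4) == (v.label == "high")

    def test_byte_identical_given_seed(self):
        a = generate_cohort(CohortConfig(n_patients=4, master_seed=11))
        b = generate_cohort(CohortConfig(n_patients=4, master_seed=11))
        assert len(a) == len(b)
        for va, vb in zip(a.visits, b.visits):
            assert va.params == vb.params
            assert np.array_equal(va.rr.rr, vb.rr.rr)
            assert np.array_equal(va.counts.t, vb.counts.t)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty class"):
            generate_cohort(CohortConfig(severity_split=0.0))

    def test_high_severity_has_lower_dc_amplitude(self):
        cohort = generate_cohort(CohortConfig(dc_effect=3.0, master_seed=2), with_gaps=False)
        lo = [v.params.dc_mean for v in cohort.visits if v.label == "low"]
        hi = [v.params.dc_mean for v in cohort.visits if v.label == "high"]
        assert np.mean(lo) > np.mean(hi)

    def test_null_effect_groups_indistinguishable(self):
        """Zero effect sizes: DC-proxy distributions match across groups.

        A single 200-visit draw rejects at the 1% level ~1% of the time by
        construction, so the null statement is made on the median p-value
        over three independent cohorts.
        """
        pvals = []
        for seed in (17, 18, 19):
            cfg = CohortConfig(
                n_patients=100, visit_probs=(0.0, 1.0, 0.0),  # 2 visits each
                dc_effect=0.0, coupling_effect=0.0, master_seed=seed,
            )
            cohort = generate_cohort(cfg, with_gaps=False)
            assert len(cohort) == 200
            dc = {"low": [], "high": []}
            for v in cohort.visits:
                dc[v.label].append(prsa_dc(clean_rr(v.rr))[0])
            pvals.append(stats.mannwhitneyu(dc["low"], dc["high"]).pvalue)
        assert np.median(pvals) > 0.01
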