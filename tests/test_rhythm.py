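"""Cosinor fitting, omnibus gating and the two-part rhythmicity call."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qrhythm import (
    DesignSpec,
    GeneSpec,
    classify_rhythmic,
    fit_cosinor,
    generate_expression,
    omnibus_time_test,
    rhythm_screen,
)
from qrhythm.rhythm import CosinorFit, OmnibusResult


def cosine(t, mesor, amplitude, acrophase_h, period_h=24.0):
    w = 2 * math.pi / period_h
    return mesor + amplitude * np.cos(w * np.asarray(t, float) - w * acrophase_h)


def grid_search_sse(t, y, period_h=24.0):
    """Independent brute-force oracle: coarse-to-fine grid over (M, A, phi)
    minimizing the sum of squared errors of M + A*cos(wt - phi)."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    w = 2 * math.pi / period_h

    def sse(m, a, phi):
        return float(np.sum((y - (m + a * np.cos(w * t - phi))) ** 2))

    m0, a0 = y.mean(), max(y.std() * 2, 1e-3)
    centers = (m0, a0, math.pi)
    spans = (max(abs(m0), 1.0) * 1.0 + a0, a0 * 1.5, math.pi)
    best = (math.inf, centers)
    for _ in range(14):  # halve spans until the grid step is < 1e-3
        mc, ac, pc = best[1] if best[0] < math.inf else centers
        ms = np.linspace(mc - spans[0], mc + spans[0], 11)
        As = np.linspace(max(ac - spans[1], 0.0), ac + spans[1], 11)
        ps = np.linspace(pc - spans[2], pc + spans[2], 13)
        for m in ms:
            for a in As:
                for p in ps:
                    s = sse(m, a, p)
                    if s < best[0]:
                        best = (s, (m, a, p))
        spans = tuple(s / 3.5 for s in spans)
    return best[0]


class TestFitCosinor:
    def test_noise_free_exact_recovery(self, design_times):
        y = cosine(design_times, 10.0, 2.0, 16.1)
        fit = fit_cosinor(design_times, y)
        assert fit.mesor == pytest.approx(10.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-9)
        assert fit.acrophase_h == pytest.approx(16.1, abs=1e-9)
        assert fit.p_ns == pytest.approx(0.0, abs=1e-9)
        assert fit.acrophase_h == pytest.approx(fit.phase_rad * 24 / (2 * math.pi))

    def test_constant_series_flat_flag(self, design_times):
        fit = fit_cosinor(design_times, np.full(design_times.size, 7.0))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-12)
        assert fit.mesor == pytest.approx(7.0)
        assert math.isinf(fit.p_ns) and fit.amplitude_zero

    def test_preconditions(self):
        with pytest.raises(ValueError, match=">=4"):
            fit_cosinor([0, 6, 12], [1, 2, 3])
        with pytest.raises(ValueError, match="distinct phases"):
            fit_cosinor([0, 0, 12, 12], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="period"):
            fit_cosinor([0, 3, 6, 9], [1, 2, 3, 4], period_h=0)

    def test_matches_brute_force_grid_oracle(self, design_times):
        # closed-form OLS should reach the same minimum SSE as an
        # independent coarse-to-fine grid search
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = rng.uniform(2, 20)
            a = rng.uniform(0.5, 5)
            phi_h = rng.uniform(0, 24)
            noise = rng.uniform(0.2, 1.5)
            y = cosine(design_times, m, a, phi_h) + rng.normal(0, noise,
                                                               design_times.size)
            fit = fit_cosinor(design_times, y)
            w = 2 * math.pi / 24
            sse_fit = float(np.sum(
                (y - (fit.mesor + fit.amplitude
                      * np.cos(w * design_times - fit.phase_rad))) ** 2))
            sse_grid = grid_search_sse(design_times, y)
            assert sse_fit <= sse_grid + 1e-6

    def test_delta_method_se_matches_monte_carlo(self, design_times):
        # empirical spread of fitted amplitudes vs mean reported SE(A)
        rng = np.random.default_rng(123)
        amps, ses = [], []
        for _ in range(600):
            y = cosine(design_times, 10.0, 1.0, 8.0) + rng.normal(
                0, 1.0, design_times.size)
            fit = fit_cosinor(design_times, y)
            amps.append(fit.amplitude)
            ses.append(fit.se_amplitude)
        assert np.std(amps, ddof=1) == pytest.approx(np.mean(ses), rel=0.10)

    def test_period_parameter(self):
        t = np.arange(0, 12, 1.0)
        y = cosine(t, 5.0, 1.5, 3.0, period_h=12.0)
        fit = fit_cosinor(t, y, period_h=12.0)
        assert fit.amplitude == pytest.approx(1.5, abs=1e-9)
        assert fit.acrophase_h == pytest.approx(3.0, abs=1e-9)


class TestScaleAndShiftEquivariance:
    def test_scale_equivariance(self, design_times):
        rng = np.random.default_rng(1)
        y = cosine(design_times, 10, 2, 5) + rng.normal(0, 0.5, design_times.size)
        f1 = fit_cosinor(design_times, y)
        f2 = fit_cosinor(design_times, 3.7 * y)
        assert f2.mesor == pytest.approx(3.7 * f1.mesor, rel=1e-12)
        assert f2.amplitude == pytest.approx(3.7 * f1.amplitude, rel=1e-12)
        assert f2.se_amplitude == pytest.approx(3.7 * f1.se_amplitude, rel=1e-12)
        assert f2.p_ns == pytest.approx(f1.p_ns, rel=1e-12)
        assert f2.phase_rad == pytest.approx(f1.phase_rad, abs=1e-12)

    def test_time_shift_moves_acrophase(self, design_times):
        rng = np.random.default_rng(2)
        y = cosine(design_times, 10, 2, 5) + rng.normal(0, 0.5, design_times.size)
        f1 = fit_cosinor(design_times, y)
        delta = 7.0
        f2 = fit_cosinor(design_times + delta, y)
        assert (f2.acrophase_h - f1.acrophase_h) % 24 == pytest.approx(delta, abs=1e-9)
        assert f2.amplitude == pytest.approx(f1.amplitude, abs=1e-9)
        assert f2.p_ns == pytest.approx(f1.p_ns, rel=1e-9)

    def test_time_reversal_negates_phase(self, design_times):
        rng = np.random.default_rng(3)
        y = cosine(design_times, 10, 2, 5) + rng.normal(0, 0.5, design_times.size)
        f1 = fit_cosinor(design_times, y)
        f2 = fit_cosinor(-design_times, y)
        assert f2.phase_rad == pytest.approx((-f1.phase_rad) % (2 * math.pi),
                                             abs=1e-9)


class TestOmnibus:
    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        t = np.repeat([0.0, 12.0], 6)
        y = np.concatenate([rng.normal(0, 0.1, 6), rng.normal(10, 0.1, 6)])
        res = omnibus_time_test(t, y)
        assert res.p_value < 1e-6

    def test_identical_constant_groups_fall_to_kruskal_p1(self):
        t = np.repeat([0.0, 12.0, 18.0], 3)
        res = omnibus_time_test(t, np.full(9, 4.2))
        assert res.method == "kruskal_wallis"
        assert res.p_value == 1.0

    def test_small_groups_dropped_with_warning(self, caplog):
        t = np.array([0.0, 3.0, 3.0, 3.0, 6.0, 6.0, 6.0])
        y = np.array([1.0, 2.0, 2.5, 2.2, 3.0, 3.3, 2.9])
        res = omnibus_time_test(t, y)
        assert res.n_groups == 2

    def test_too_few_groups_error(self):
        with pytest.raises(ValueError, match=">=2 groups"):
            omnibus_time_test([0, 0, 0, 3], [1.0, 2.0, 3.0, 4.0])

    def test_null_anova_branch_dominates_and_p_uniform(self, design_times):
        # all groups from one normal distribution: the parametric path
        # should be chosen in most runs and its p-values ~ U(0,1)
        rng = np.random.default_rng(11)
        methods, anova_ps = [], []
        for _ in range(500):
            y = rng.normal(0, 1, design_times.size)
            res = omnibus_time_test(design_times, y)
            methods.append(res.method)
            if res.method == "anova":
                anova_ps.append(res.p_value)
        frac_anova = methods.count("anova") / len(methods)
        assert frac_anova > 0.5
        assert stats.kstest(anova_ps, "uniform").pvalue > 0.01

    def test_skewed_data_takes_nonparametric_path(self, design_times):
        rng = np.random.default_rng(4)
        y = rng.lognormal(0, 1.5, design_times.size)
        res = omnibus_time_test(design_times, y)
        assert res.method == "kruskal_wallis"


class TestClassify:
    @pytest.mark.parametrize(
        "p_ns, omnibus_p, expected",
        [
            (0.01, 0.001, True),   # well-determined oscillation
            (0.41, 0.001, False),  # noisy amplitude
            (0.27, 0.06, False),   # passes P arm, fails omnibus arm
            (0.3, 0.001, False),   # boundary P is non-rhythmic (strict)
            (0.01, 0.05, False),   # boundary alpha is non-rhythmic (strict)
        ],
    )
    def test_two_part_gate(self, p_ns, omnibus_p, expected):
        fit = CosinorFit("g", 1.0, 1.0, 0.0, 0.0, p_ns, p_ns, 54, 51, 24.0)
        omnibus = OmnibusResult(omnibus_p, "anova", 9)
        call = classify_rhythmic(fit, omnibus)
        assert call.rhythmic is expected


class TestRhythmScreen:
    def test_flat_matrix_zero_rhythmic(self, study_design):
        genes = [GeneSpec(f"g{i}", 10.0, 0.0, 0.0, 0.5) for i in range(4)]
        sim = generate_expression(study_design, genes)
        screen = rhythm_screen(sim.expression)
        assert screen.n_rhythmic == 0

    def test_high_snr_genes_detected(self, study_design):
        genes = (
            [GeneSpec(f"osc{i}", 10.0, 3.0, (3 * i) % 24, 1.0) for i in range(8)]
            + [GeneSpec(f"flat{i}", 10.0, 0.0, 0.0, 1.0) for i in range(8)]
        )
        sim = generate_expression(study_design, genes)
        screen = rhythm_screen(sim.expression)
        called = set(screen.rhythmic_genes)
        assert len(called & {f"osc{i}" for i in range(8)}) >= 6
        assert len(called & {f"flat{i}" for i in range(8)}) <= 1

    def test_deterministic_output(self, study_design):
        genes = [GeneSpec("a", 10.0, 2.0, 6.0, 0.8), GeneSpec("b", 10.0, 0.0, 0.0, 0.8)]
        sim = generate_expression(study_design, genes)
        t1 = rhythm_screen(sim.expression).table
        t2 = rhythm_screen(sim.expression).table
        pd.testing.assert_frame_equal(t1, t2)
        assert t1["gene"].tolist() == ["a", "b"]

    def test_unfit_gene_reported_not_fatal(self, study_design):
        genes = [GeneSpec("ok", 10.0, 2.0, 6.0, 0.5)]
        sim = generate_expression(study_design, genes)
        expr = sim.expression
        expr.values.loc["broken"] = np.nan
        expr.values.loc["broken", expr.sample_ids[0]] = 1.0
        screen = rhythm_screen(expr)
        assert "broken" in screen.unfit
        assert "ok" in screen.calls

    def test_collapse_means_mode(self, study_design, clean_gene):
        sim = generate_expression(study_design, [clean_gene])
        screen = rhythm_screen(sim.expression, collapse_means=True)
        fit = screen.fits["g1"]
        assert fit.n_obs == len(study_design.timepoints_h)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-9)
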