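"""Bayes-factor layer: JZS t tests, ANOVA inclusion BFs, regression, K."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from twaves.stats import (bf_linear_regression, extract_level_slopes,
                          jzs_bf_from_t, jzs_ttest_bf, k_capacity,
                          posthoc_pairwise_bf, rm_anova_inclusion_bf,
                          timecourse_bf)


def oracle_jzs_bf(t, n, r=1 / np.sqrt(2), n_grid=200_000):
    """High-resolution fixed-grid quadrature oracle, written independently.

    Substitutes g = r^2 / (2u) so the InverseGamma prior becomes a Gamma
    integral on (0, inf), evaluated by the trapezoid rule in log space.
    """
    nu = n - 1
    u = np.linspace(1e-8, 60.0, n_grid)
    g = r**2 / (2.0 * u)
    log_lik = (-0.5 * np.log1p(n * g)
               - (nu + 1) / 2.0 * np.log1p(t * t / ((1 + n * g) * nu)))
    log_prior = -0.5 * np.log(np.pi) - 0.5 * np.log(u) - u  # Gamma(1/2,1)
    m1 = np.trapezoid(np.exp(log_lik + log_prior), u)
    m0 = (1 + t * t / nu) ** (-(nu + 1) / 2.0)
    return m1 / m0


class TestKCapacity:
    @pytest.mark.parametrize("args,expected", [
        ((4, 0.75, 0.25), 2.0),
        ((6, 1.0, 0.0), 6.0),
        ((3, 0.4, 0.4), 0.0),
    ])
    def test_formula(self, args, expected):
        assert k_capacity(*args) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="hit"):
            k_capacity(4, 1.5, 0.0)
        with pytest.raises(ValueError, match="false_alarm"):
            k_capacity(4, 0.5, -0.1)


class TestJZSTTest:
    @pytest.mark.parametrize("n", [5, 15, 30, 60])
    @pytest.mark.parametrize("t", [0.0, 1.0, 2.0, 3.0, 5.0])
    def test_agrees_with_quadrature_oracle(self, n, t):
        got = jzs_bf_from_t(t, n)
        want = oracle_jzs_bf(t, n)
        assert abs(got - want) / want < 0.005

    @pytest.mark.parametrize("n", [5, 15, 30, 60])
    def test_agrees_with_independent_implementation(self, n):
        pingouin = pytest.importorskip("pingouin")
        for t in (0.0, 2.5, 4.0):
            got = jzs_bf_from_t(t, n)
            want = float(pingouin.bayesfactor_ttest(t, n, paired=True))
            assert abs(got - want) / want < 0.005

    @pytest.mark.parametrize("n", [2, 5, 30, 100])
    def test_null_favored_at_t_zero(self, n):
        assert jzs_bf_from_t(0.0, n) < 1

    def test_monotone_in_t_magnitude(self):
        bfs = [jzs_bf_from_t(t, 20) for t in np.linspace(0, 6, 25)]
        assert np.all(np.diff(bfs) > 0)

    def test_affine_invariance(self, rng):
        d = rng.normal(0.4, 1.0, size=25)
        bf1 = jzs_ttest_bf(d).bf
        bf2 = jzs_ttest_bf(3.7 * d).bf  # scale invariance of t
        assert bf1 == pytest.approx(bf2, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            jzs_ttest_bf(np.zeros(10))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            jzs_ttest_bf(np.array([1.0]))

    @given(st.floats(0.1, 4.0), st.integers(3, 50))
    @settings(derandomize=True, max_examples=25)
    def test_symmetric_in_t_sign(self, t, n):
        assert jzs_bf_from_t(t, n) == pytest.approx(jzs_bf_from_t(-t, n),
                                                    rel=1e-6)


def _anova_cells(rng, n=20, effect=0.0, levels=(2, 4, 6), sigma=1.0):
    rows = []
    for p in range(n):
        intercept = rng.normal(0, 1)
        for i, lv in enumerate(levels):
            rows.append({"participant": f"p{p:02d}", "load": lv,
                         "value": intercept + effect * i + rng.normal(0, sigma)})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_one_factor_reduces_to_pairwise_model_comparison(self, rng):
        # definition collapse: the single-factor inclusion BF equals the BF
        # of "factor + participant" vs "participant", here recomputed from
        # statsmodels OLS BICs as an independent route
        import statsmodels.formula.api as smf

        cells = _anova_cells(rng, n=12, effect=0.4)
        res = rm_anova_inclusion_bf(cells, ["load"])[0]
        full = smf.ols("value ~ C(participant) + C(load)", cells).fit()
        null = smf.ols("value ~ C(participant)", cells).fit()
        want = np.exp((null.bic - full.bic) / 2)
        assert res.bf == pytest.approx(want, rel=1e-6)

    def test_strong_effect_detected(self, rng):
        cells = _anova_cells(rng, n=30, effect=1.0, sigma=1.0)
        res = rm_anova_inclusion_bf(cells, ["load"])[0]
        assert res.bf > 10

    def test_null_effect_favors_null(self):
        bfs = []
        for seed in range(20):
            cells = _anova_cells(np.random.default_rng(seed), n=20)
            bfs.append(rm_anova_inclusion_bf(cells, ["load"])[0].bf)
        assert np.median(bfs) < 1

    def test_two_factor_effects_and_matched_models(self, rng):
        rows = []
        for p in range(24):
            b = rng.normal(0, 1)
            for i, lv in enumerate((2, 4, 6)):
                for j, ax in enumerate(("contra", "ipsi")):
                    rows.append({"participant": f"p{p}", "load": lv,
                                 "axis_role": ax,
                                 "value": b + 0.8 * i + rng.normal(0, 0.8)})
        cells = pd.DataFrame(rows)
        res = {r.effect: r.bf for r in rm_anova_inclusion_bf(
            cells, ["load", "axis_role"])}
        assert set(res) == {"load", "axis_role", "axis_role * load"}
        assert res["load"] > 10
        assert res["axis_role"] < 1

    def test_incomplete_layout_rejected(self, rng):
        cells = _anova_cells(rng, n=5).iloc[:-1]
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova_inclusion_bf(cells, ["load"])

    def test_monte_carlo_reports_error_and_replicates(self, rng):
        cells = _anova_cells(rng, n=15, effect=0.5)
        r1 = rm_anova_inclusion_bf(cells, ["load"], method="monte_carlo",
                                   rng_seed=1)[0]
        r2 = rm_anova_inclusion_bf(cells, ["load"], method="monte_carlo",
                                   rng_seed=2)[0]
        assert r1.error is not None and r1.error > 0
        # seed replicates agree within a few reported MC errors
        tol = 5 * (r1.error + r2.error) / 100
        assert abs(r1.bf - r2.bf) / r1.bf < max(tol, 0.05)

    def test_monte_carlo_tracks_bic_ordering(self, rng):
        strong = _anova_cells(rng, n=20, effect=1.0)
        weak = _anova_cells(rng, n=20, effect=0.0)
        mc_strong = rm_anova_inclusion_bf(strong, ["load"],
                                          method="monte_carlo", rng_seed=0)[0].bf
        mc_weak = rm_anova_inclusion_bf(weak, ["load"],
                                        method="monte_carlo", rng_seed=0)[0].bf
        assert mc_strong > 10 > mc_weak


class TestPosthoc:
    def _cells(self, rng, delta, n=20, sigma=1.0):
        rows = []
        for p in range(n):
            b = rng.normal(0, 1)
            for lv, off in (("l2", 0.0), ("l4", delta)):
                rows.append({"participant": f"p{p}", "load": lv,
                             "value": b + off + rng.normal(0, sigma)})
        return pd.DataFrame(rows)

    def test_no_difference_favors_null(self):
        bfs = [posthoc_pairwise_bf(self._cells(np.random.default_rng(s), 0.0),
                                   "load", ("l2", "l4")).bf
               for s in range(20)]
        assert np.median(bfs) < 1

    def test_level_order_antisymmetry(self, rng):
        cells = self._cells(rng, 0.7)
        r1 = posthoc_pairwise_bf(cells, "load", ("l2", "l4"))
        r2 = posthoc_pairwise_bf(cells, "load", ("l4", "l2"))
        assert r1.bf == pytest.approx(r2.bf, rel=1e-9)
        d1 = dict(r1.extra)["mean_diff"]
        d2 = dict(r2.extra)["mean_diff"]
        assert d1 == pytest.approx(-d2)

    def test_shifted_level_detected(self):
        # shift of one SD of the participant-wise difference, n = 30
        hits = 0
        for seed in range(20):
            cells = self._cells(np.random.default_rng(seed), 1.0, n=30,
                                sigma=2**-0.5)
            if posthoc_pairwise_bf(cells, "load", ("l2", "l4")).bf > 3:
                hits += 1
        assert hits >= 18

    def test_missing_level_rejected(self, rng):
        with pytest.raises(ValueError, match="level"):
            posthoc_pairwise_bf(self._cells(rng, 0.0), "load", ("l2", "l9"))


class TestRegression:
    def test_perfect_linear_relation(self):
        x = np.arange(10, dtype=float)
        y = 0.3 * x - 1.0 + np.linspace(0, 1e-6, 10)  # epsilon noise
        res = bf_linear_regression(x, y)
        assert res.bf > 100

    def test_null_relation_favors_null(self):
        bfs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            bfs.append(bf_linear_regression(r.normal(size=76),
                                            r.normal(size=76)).bf)
        assert np.median(bfs) < 1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bf_linear_regression(np.ones(10), np.arange(10.0))

    def test_slope_extraction_exact(self):
        cells = pd.DataFrame({
            "participant": np.repeat(["a", "b"], 3),
            "load": [2, 4, 6] * 2,
            "value": [1.0, 2.0, 3.0, 5.0, 3.0, 1.0],
        })
        slopes = extract_level_slopes(cells, "load")
        assert slopes["a"] == pytest.approx(0.5, abs=1e-12)
        assert slopes["b"] == pytest.approx(-1.0, abs=1e-12)


class TestTimecourse:
    def _series(self, rng, n_participants=10, effect_times=()):
        rows = []
        times = np.round(np.arange(0.0, 1.0, 0.1), 3)
        for p in range(n_participants):
            for t in times:
                delta = 1.5 if t in effect_times else 0.0
                base = rng.normal(0, 1)
                rows.append({"participant": f"p{p}", "window_time": t,
                             "axis_role": "contra",
                             "db": base + delta + rng.normal(0, 0.5)})
                rows.append({"participant": f"p{p}", "window_time": t,
                             "axis_role": "ipsi",
                             "db": base + rng.normal(0, 0.5)})
        return pd.DataFrame(rows)

    def test_effect_windows_flagged(self, rng):
        effect_times = (0.5, 0.6, 0.7)
        tc = timecourse_bf(self._series(rng, 15, effect_times))
        flagged = set(tc[tc["exceeds_threshold"]]["window_time"])
        assert set(effect_times) <= flagged

    def test_single_participant_rejected(self, rng):
        with pytest.raises(ValueError):
            timecourse_bf(self._series(rng, 1))

    def test_missing_role_rejected(self, rng):
        s = self._series(rng, 5)
        with pytest.raises(ValueError, match="ipsi"):
            timecourse_bf(s[s["axis_role"] == "contra"])
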