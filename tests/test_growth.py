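"""Growth-rate estimation, COD aggregation, phases, correlograms, fits."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microprot.constants import COD_FACTORS
from microprot.growth import (
    GrowthError,
    classify_phase,
    cod_aggregate,
    correlogram,
    growth_rate,
    join_midpoints,
    linear_fit_ci,
    productivity,
    spearman,
)
from microprot.synthetic import SimConfig, simulate_batch
from oracles import brute_spearman


def series(time, od=None, cdw=None, **extra) -> pd.DataFrame:
    data = {"time_h": np.asarray(time, dtype=float)}
    if od is not None:
        data["od600"] = od
    if cdw is not None:
        data["cdw_g_l"] = cdw
    data.update(extra)
    return pd.DataFrame(data)


class TestGrowthRate:
    def test_doubling_in_one_hour_is_ln2(self):
        mu = growth_rate(series([0, 1], od=[0.2, 0.4]))
        assert mu["mu"].iloc[0] == pytest.approx(np.log(2))
        assert mu["time_h"].iloc[0] == 0.5

    def test_constant_od_is_zero(self):
        mu = growth_rate(series([0, 1, 2], od=[0.3, 0.3, 0.3]))
        np.testing.assert_allclose(mu["mu"], 0.0)

    def test_exact_on_pure_exponential_irregular_grid(self):
        t = np.array([0.0, 0.7, 1.1, 2.9, 5.0])
        mu_true = 0.23
        od = 0.1 * np.exp(mu_true * t)
        mu = growth_rate(series(t, od=od))
        np.testing.assert_allclose(mu["mu"], mu_true, rtol=1e-12)

    def test_non_positive_od_is_an_error(self):
        with pytest.raises(GrowthError):
            growth_rate(series([0, 1], od=[0.2, 0.0]))

    def test_recovers_simulator_truth_on_noise_free_run(self):
        cfg = replace(SimConfig(seed=2), noise_cv={"default": 0.0})
        cfg.growth.sample_dt = 0.5
        run = simulate_batch(cfg, "carbon")
        d = run.data
        mu = growth_rate(d)
        truth_mid = np.interp(mu["time_h"], d["time_h"], d["mu_true"])
        abundant = (d["phase_true"] == "abundant").to_numpy()
        fully_abundant = abundant[:-1] & abundant[1:]
        rel = np.abs(mu["mu"].to_numpy() - truth_mid)[fully_abundant] / truth_mid[fully_abundant]
        assert rel.max() < 0.02


class TestCodAggregate:
    def test_eight_gcod_is_one_eeq(self):
        cod, eeq = cod_aggregate({"fructose": 8.0 / COD_FACTORS["fructose"]})
        assert cod == pytest.approx(8.0)
        assert eeq == pytest.approx(1.0)

    def test_zero_concentrations_zero_cod(self):
        cod, eeq = cod_aggregate({"fructose": 0.0, "methanol": 0.0})
        assert cod == 0.0 and eeq == 0.0

    def test_fructose_stoichiometric_factor(self):
        # C6H12O6 + 6 O2 -> 6 CO2 + 6 H2O: 192 g O2 per 180 g sugar
        cod, _ = cod_aggregate({"fructose": 1.0})
        assert cod == pytest.approx(192.0 / 180.0, abs=1e-12)

    def test_methanol_factor(self):
        cod, _ = cod_aggregate({"methanol": 1.0})
        assert cod == pytest.approx(1.5, abs=1e-12)

    def test_missing_factor_names_compound(self):
        with pytest.raises(GrowthError, match="citrate"):
            cod_aggregate({"citrate": 1.0})


class TestProductivity:
    def test_delta_cdw_over_delta_t(self):
        p = productivity(series([0, 2], cdw=[1.0, 2.0]))
        assert p["productivity"].iloc[0] == pytest.approx(0.5)
        assert p["time_h"].iloc[0] == 1.0

    def test_flat_cdw_is_zero(self):
        p = productivity(series([0, 1, 2], cdw=[1.5, 1.5, 1.5]))
        np.testing.assert_allclose(p["productivity"], 0.0)


class TestClassifyPhase:
    def _frame(self):
        return pd.DataFrame(
            {
                "time_h": [0, 1, 2, 3],
                "cod_g_l": [2.0, 2.0, 2.0, 2.0],
                "nh4_g_l": [0.1, 0.1, 0.1, 0.1],
                "mu": [0.3, 0.3, 0.3, 0.3],
            }
        )

    def test_substrate_at_initial_level_is_abundant(self):
        labels = classify_phase(self._frame(), "carbon")
        assert (labels == "abundant").all()

    def test_degenerate_threshold_marks_everything_limiting(self):
        labels = classify_phase(self._frame(), "carbon", frac_initial=1.0, mu_frac=2.0)
        assert (labels == "limiting").all()

    def test_unknown_limitation_is_an_error(self):
        with pytest.raises(GrowthError, match="phosphorus"):
            classify_phase(self._frame(), "phosphorus")

    @pytest.mark.parametrize("limitation", ["carbon", "nitrogen", "dual"])
    def test_agrees_with_generator_truth(self, limitation):
        cfg = replace(SimConfig(seed=2), noise_cv={"default": 0.0})
        cfg.growth.sample_dt = 0.5
        run = simulate_batch(cfg, limitation)
        mu = growth_rate(run.data)
        joined = join_midpoints(run.data, mu).dropna(subset=["mu"])
        labels = classify_phase(joined, limitation)
        agreement = (labels.to_numpy() == joined["phase_true"].to_numpy()).mean()
        assert agreement >= 0.90


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        rho, p, n = spearman(x, 3 * x + 1)
        assert rho == pytest.approx(1.0, abs=1e-12) and n == 4
        rho, _, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = rng.integers(0, 5, size=12).astype(float)  # heavy ties
            y = rng.integers(0, 5, size=12).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            rho, p, _ = spearman(x, y)
            rho_o, p_o = brute_spearman(x, y)
            assert rho == pytest.approx(rho_o, abs=1e-12)
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p, _ = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_constant_variable_undefined_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p, _ = spearman(np.ones(5), np.arange(5.0))
        assert np.isnan(rho)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(14)
        x = rng.random(25)
        y = rng.random(25)
        rho1, _, _ = spearman(x, y)
        rho2, _, _ = spearman(np.exp(3 * x), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)


class TestCorrelogram:
    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        res = correlogram(df)
        np.testing.assert_allclose(np.diag(res.rho), 1.0)
        np.testing.assert_allclose(res.rho, res.rho.T)
        assert not res.significant.to_numpy().diagonal().any()

    def test_pairwise_complete_deletion(self):
        df = pd.DataFrame(
            {
                "a": [1.0, 2, 3, 4, 5, 6],
                "b": [2.0, 4, 6, 8, 10, 12],
                "c": [1.0, np.nan, 2, 5, np.nan, 3],
            }
        )
        res = correlogram(df)
        assert res.n.loc["a", "b"] == 6
        assert res.n.loc["a", "c"] == 4
        assert res.rho.loc["a", "b"] == 1.0

    def test_bh_correction_never_decreases_p(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame(rng.normal(size=(15, 5)), columns=list("abcde"))
        raw = correlogram(df)
        adj = correlogram(df, bh_correct=True)
        off = ~np.eye(5, dtype=bool)
        assert (adj.p.to_numpy()[off] >= raw.p.to_numpy()[off] - 1e-12).all()


class TestLinearFit:
    def test_exact_line_zero_width_band(self):
        x = np.array([0.0, 1, 2, 3, 4])
        fit = linear_fit_ci(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        np.testing.assert_allclose(fit.ci_hi - fit.ci_lo, 0.0, atol=1e-10)

    def test_band_minimal_at_mean_x(self):
        rng = np.random.default_rng(17)
        x = rng.random(30) * 10
        y = 1.5 * x + rng.normal(size=30)
        fit = linear_fit_ci(x, y)
        width = fit.ci_hi - fit.ci_lo
        assert fit.x_grid[np.argmin(width)] == pytest.approx(x.mean(), abs=0.11)

    def test_zero_x_variance_is_an_error(self):
        with pytest.raises(GrowthError):
            linear_fit_ci(np.ones(5), np.arange(5.0))

    def test_band_covers_true_mean_response_95pct(self):
        rng = np.random.default_rng(18)
        beta0, beta1 = 1.0, 2.0
        x = np.linspace(0, 1, 20)
        x0 = 0.25
        covered = 0
        reps = 1000
        for _ in range(reps):
            y = beta0 + beta1 * x + rng.normal(0, 0.5, size=20)
            fit = linear_fit_ci(x, y, x_grid=np.array([x0]))
            truth = beta0 + beta1 * x0
            covered += fit.ci_lo[0] <= truth <= fit.ci_hi[0]
        assert 0.93 <= covered / reps <= 0.97
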