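"""The six validation procedures against analytic and simulation oracles."""

import numpy as np
import pandas as pd
import pytest

import mrdtrack as m

POISSON_LOD = -np.log(0.05)  # smallest rate detected in 95% of samples: 2.996


class TestProbitLoD:
    def _simulate(self, rng, doses, n_per, k=1):
        d = np.repeat(doses, n_per)
        p = 1 - np.exp(-k * d)  # detected iff any of k Poisson draws is >= 1
        return d, rng.random(d.size) < p

    def test_single_sequence_lod_matches_poisson_closed_form(self, rng):
        doses, det = self._simulate(rng, [1.0, 2.0, 3.0, 4.0, 6.0, 9.0], 5000)
        fit = m.fit_probit(doses, det, n_boot=0)
        assert fit.lod == pytest.approx(POISSON_LOD, rel=0.05)

    def test_two_sequences_halve_the_lod(self, rng):
        doses, det = self._simulate(rng, [0.5, 1.0, 1.5, 2.0, 3.0, 4.5], 5000, k=2)
        fit = m.fit_probit(doses, det, n_boot=0)
        assert fit.lod == pytest.approx(POISSON_LOD / 2, rel=0.07)

    def test_complete_separation_is_flagged(self):
        fit = m.fit_probit([1, 2, 3, 4.0], [True, True, True, True], n_boot=0)
        assert fit.separated and np.isnan(fit.lod)

    def test_bootstrap_ci_brackets_the_estimate(self, rng):
        doses, det = self._simulate(rng, [1.0, 2.0, 3.0, 4.5], 300)
        fit = m.fit_probit(doses, det, n_boot=200, seed=0)
        assert fit.ci[0] <= fit.lod <= fit.ci[1]

    def test_fitted_curve_is_monotone_in_dose(self, rng):
        doses, det = self._simulate(rng, [1.0, 2.0, 4.0, 8.0], 1000)
        fit = m.fit_probit(doses, det, n_boot=0)
        assert fit.slope > 0


class TestRelativeTotalError:
    def test_unbiased_poisson_rte_is_inverse_sqrt_lambda(self, rng):
        lam = 4.0
        est = rng.poisson(lam, size=40_000)
        assert m.relative_total_error(est, lam) == pytest.approx(
            1 / np.sqrt(lam), rel=0.03
        )

    def test_perfect_estimator_has_zero_rte(self):
        assert m.relative_total_error([5.0, 5.0, 5.0], 5.0) == 0.0

    def test_pure_doubling_bias_gives_rte_one(self):
        assert m.relative_total_error([10.0, 10.0], 5.0) == 1.0

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(m.InvalidParameterError):
            m.relative_total_error([1.0], 0.0)


class TestSadlerLoQ:
    def test_noiseless_parameter_recovery(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        fit = m.fit_sadler(x, (0.25 + 0.5 * x) ** -0.8)
        assert fit.beta1 == pytest.approx(0.25, rel=1e-6)
        assert fit.beta2 == pytest.approx(0.5, rel=1e-6)
        assert fit.J == pytest.approx(-0.8, rel=1e-6)

    def test_poisson_rte_profile_gives_loq_near_2(self):
        # exact RTE of a Poisson estimator is x**-0.5; 70% crossing at (1/0.7)^2
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        fit = m.fit_sadler(x, x**-0.5)
        assert m.loq_from_profile(fit, 0.70) == pytest.approx((1 / 0.7) ** 2, rel=1e-4)

    def test_threshold_never_reached_raises(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        fit = m.fit_sadler(x, x**-0.5)
        with pytest.raises(m.OutOfRangeError):
            m.loq_from_profile(fit, 2.0)

    def test_too_few_levels_rejected(self):
        with pytest.raises(m.InvalidParameterError):
            m.fit_sadler([1.0, 2.0, 4.0], [1.0, 0.7, 0.5])


class TestLimitOfBlank:
    def test_all_zero_blanks_give_zero(self):
        est = m.estimate_lob(np.zeros(84))
        assert est.value == 0.0

    def test_four_nonzero_of_100_still_zero(self):
        v = np.concatenate([np.zeros(96), np.full(4, 5.0)])
        assert m.estimate_lob(v).value == 0.0

    def test_ten_nonzero_of_100_hits_their_value(self):
        v = np.concatenate([np.zeros(90), np.full(10, 7.0)])
        assert m.estimate_lob(v).value == 7.0

    def test_permutation_invariance(self, rng):
        v = rng.exponential(size=60)
        assert m.estimate_lob(v).value == m.estimate_lob(rng.permutation(v)).value

    def test_monotone_in_each_value(self, rng):
        v = rng.exponential(size=60)
        bumped = v.copy()
        bumped[np.argmax(v)] += 1.0
        assert m.estimate_lob(bumped).value >= m.estimate_lob(v).value

    def test_per_level_percentiles(self):
        v = np.concatenate([np.zeros(50), np.full(50, 2.0)])
        lv = np.repeat([5e5, 2e7], 50)
        est = m.estimate_lob(v, levels=lv)
        assert est.per_level[5e5] == 0.0 and est.per_level[2e7] == 2.0

    def test_empty_input_rejected(self):
        with pytest.raises(m.MissingDataError):
            m.estimate_lob([])


class TestVarianceComponents:
    def test_pure_poisson_attributes_nothing_to_factors(self):
        grid = m.gen_validation_grid(abundances=[612.56], seed=21, n_replicates=420)
        vca = m.variance_components(grid, mode="moments")
        row = vca.table.iloc[0]
        for f in ("operator_set", "instrument_set", "reagent_lot",
                  "day", "run_within_day"):
            assert row[f"{f}_cv"] <= 1.5
        assert row["residual_cv"] == pytest.approx(100 / np.sqrt(612.56), rel=0.15)

    def test_injected_lot_cv_recovered(self):
        recovered = []
        for s in range(10):
            grid = m.gen_validation_grid(
                abundances=[612.56], factor_cvs={"reagent_lot": 0.02},
                seed=100 + s, n_replicates=240,
            )
            vca = m.variance_components(grid, mode="moments")
            recovered.append(vca.table["lot_to_lot_cv"].iloc[0])
        assert np.mean(recovered) == pytest.approx(2.0, abs=0.8)

    def test_moments_components_sum_to_total_variance(self):
        grid = m.gen_validation_grid(
            abundances=[61.26], factor_cvs={"operator_set": 0.05},
            seed=5, n_replicates=120,
        )
        vca = m.variance_components(grid, mode="moments")
        row = vca.table.iloc[0]
        df = grid.data
        total_cv = 100 * df["measurement"].std(ddof=1) / df["measurement"].mean()
        assert row["reproducibility_cv"] == pytest.approx(total_cv, rel=1e-6)

    def test_reproducibility_at_least_repeatability(self):
        grid = m.gen_validation_grid(
            abundances=[21.44, 214.46], factor_cvs={"day": 0.03},
            seed=8, n_replicates=120,
        )
        vca = m.variance_components(grid, mode="moments")
        assert (vca.table["reproducibility_cv"]
                >= vca.table["repeatability_cv"] - 1e-9).all()

    def test_reml_mode_agrees_at_high_abundance(self):
        grid = m.gen_validation_grid(abundances=[612.56], seed=3, n_replicates=120)
        vca = m.variance_components(grid, mode="reml")
        assert vca.table["residual_cv"].iloc[0] == pytest.approx(
            100 / np.sqrt(612.56), rel=0.25
        )

    def test_single_level_factor_raises_confounding(self):
        grid = m.gen_validation_grid(abundances=[21.44], seed=4, n_replicates=24)
        df = grid.data.copy()
        df["reagent_lot"] = 0
        with pytest.raises(m.ConfoundingError) as exc:
            m.variance_components(df, mode="moments")
        assert "reagent_lot" in str(exc.value)

    def test_lod_exclusion_drops_low_strata(self):
        grid = m.gen_validation_grid(abundances=[2.14, 61.26], seed=6,
                                     n_replicates=60)
        vca = m.variance_components(grid, mode="moments", lod=3.0)
        assert vca.table["expected_cells"].tolist() == [61.26]


class TestLinearity:
    LEVELS = np.geomspace(1e-6, 1e-1, 11)

    def test_exact_proportional_data_is_linear_with_unit_slope(self):
        exp_ = np.repeat(self.LEVELS, 3)
        rep = m.assess_linearity(exp_, exp_)
        assert rep.verdict == "linear"
        assert rep.slope == pytest.approx(1.0, abs=1e-9)
        assert rep.accepted_range == (self.LEVELS[0], self.LEVELS[-1])

    def test_constructed_quadratic_violation_reduces_range(self):
        exp_ = np.repeat(self.LEVELS, 3)
        obs = exp_ + 5e4 * exp_**2
        rep = m.assess_linearity(obs, exp_)
        assert rep.verdict != "linear"
        assert rep.dropped_levels  # range was reduced

    def test_replicate_order_invariance(self, rng):
        exp_ = np.repeat(self.LEVELS, 4)
        obs = exp_ * np.exp(rng.normal(0, 0.05, exp_.size))
        a = m.assess_linearity(obs, exp_)
        order = rng.permutation(exp_.size)
        b = m.assess_linearity(obs[order], exp_[order])
        assert a.verdict == b.verdict
        assert a.slope == pytest.approx(b.slope)

    def test_simulated_dilution_series_slope_near_one(self, clone3, profile3_exact):
        # Poisson noise, 8 replicates/level over the observable range
        cells = [6.13, 21.44, 61.26, 214.46, 612.56, 3062.8, 30_627.9]
        total = 2e7 / 6.53
        obs, expd = [], []
        for c in cells:
            for r in range(8):
                s = m.contrive_sample(clone3, None, 2e7, c, seed=31,
                                      sample_id=f"lin-{c}-{r}")
                q = m.quantify(s, profile3_exact)
                if q.consensus_malignant_cells > 0:
                    obs.append(q.mrd_frequency)
                    expd.append(c / total)
        rep = m.assess_linearity(obs, expd)
        assert 0.95 <= rep.slope <= 1.03

    def test_too_few_levels_rejected(self):
        with pytest.raises(m.InvalidParameterError):
            m.assess_linearity([1, 2, 3.0], [1, 2, 3.0])


class TestBootstrapBias:
    @staticmethod
    def _frame(rows):
        return pd.DataFrame(rows, columns=["stratum", "sample_id",
                                           "observed", "expected"])

    def test_perfect_agreement_has_zero_bias(self):
        rows = [(c, f"{c}-{s}", c, c) for c in (10, 100) for s in range(5)]
        rep = m.bootstrap_bias(self._frame(rows), n_boot=200, seed=0)
        assert (rep.table["relative_bias"] == 0).all()
        assert ((rep.table["ci_low"] <= 0) & (rep.table["ci_high"] >= 0)).all()

    def test_constant_25pct_overcall(self):
        rows = [(10, f"s{s}", 12.5, 10.0) for s in range(6)]
        rep = m.bootstrap_bias(self._frame(rows), n_boot=200, seed=0)
        assert rep.table["relative_bias"].iloc[0] == pytest.approx(0.25)
        width = rep.table["ci_high"] - rep.table["ci_low"]
        assert (width < 1e-12).all()

    def test_single_sample_stratum_flagged_degenerate(self):
        rows = [(10, "only", 9.0, 10.0), (10, "only", 11.0, 10.0)]
        rep = m.bootstrap_bias(self._frame(rows), n_boot=100, seed=0)
        assert bool(rep.table["degenerate"].iloc[0])

    def test_ci_contains_point_estimate(self, rng):
        rows = [
            (c, f"{c}-{s}", rng.poisson(c), c)
            for c in (10, 30) for s in range(12) for _ in range(2)
        ]
        rep = m.bootstrap_bias(self._frame(rows), n_boot=500, seed=1)
        t = rep.table
        assert ((t["ci_low"] <= t["relative_bias"])
                & (t["relative_bias"] <= t["ci_high"])).all()

    def test_unbiased_poisson_coverage_of_zero(self, rng):
        # nominal 95% percentile CIs on unbiased data should cover 0 in the
        # vast majority of repetitions
        covered = 0
        n_rep = 60
        for i in range(n_rep):
            rows = [
                (10, f"s{s}", rng.poisson(10), 10.0)
                for s in range(20) for _ in range(2)
            ]
            rep = m.bootstrap_bias(self._frame(rows), n_boot=300, seed=i)
            lo, hi = rep.table[["ci_low", "ci_high"]].iloc[0]
            covered += lo <= 0 <= hi
        assert covered / n_rep >= 0.88

    def test_missing_column_rejected(self):
        with pytest.raises(m.InvalidParameterError):
            m.bootstrap_bias(pd.DataFrame({"stratum": [1], "observed": [1.0]}))
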