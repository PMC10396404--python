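"""Complete-records analysis, FCS/NARFCS imputation, Rubin pooling."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mdagplan.errors import (
    DeltaUnsupportedError,
    ImputationModelError,
    InsufficientDataError,
)
from mdagplan.estimators import (
    AnalysisSpec,
    ImputationSpec,
    delta_adjusted_analysis,
    fcs_impute,
    fit_cra,
    fit_full,
    fit_mi,
    pool_rubin,
)
from mdagplan.evaluation import cra_estimator, mi_estimator, monte_carlo
from mdagplan.simulate import MaskedDataset, pattern_mixture_design


def _toy_masked(records: pd.DataFrame, indicators: dict) -> MaskedDataset:
    return MaskedDataset.from_records(records, indicators)


@pytest.fixture
def simple_spec():
    return AnalysisSpec(outcome="y", exposure="x", covariates=())


class TestCRA:
    def test_no_missingness_equals_full_data_ols(self, simple_spec):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = 1.5 * x + rng.normal(size=200)
        records = pd.DataFrame({"x": x, "y": y, "M_y": np.zeros(200, dtype=int)})
        data = _toy_masked(records, {"M_y": "y"})
        res = fit_cra(data, simple_spec)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.estimate == pytest.approx(ref.params[1])
        assert res.se == pytest.approx(ref.bse[1])
        assert res.n_used == 200

    def test_hand_solved_three_record_design(self, simple_spec):
        # records (x, y): (0,1), (1,3), (2,5) complete; (9, NaN) dropped.
        # normal equations give intercept 1, slope 2 exactly.
        records = pd.DataFrame(
            {
                "x": [0.0, 1.0, 2.0, 9.0],
                "y": [1.0, 3.0, 5.0, np.nan],
                "M_y": [0, 0, 0, 1],
            }
        )
        res = fit_cra(_toy_masked(records, {"M_y": "y"}), simple_spec)
        assert res.estimate == pytest.approx(2.0)
        assert res.n_used == 3

    def test_insufficient_complete_records(self, simple_spec):
        records = pd.DataFrame(
            {"x": [0.0, 1.0, 2.0], "y": [np.nan, np.nan, 1.0], "M_y": [1, 1, 0]}
        )
        with pytest.raises(InsufficientDataError):
            fit_cra(_toy_masked(records, {"M_y": "y"}), simple_spec)


class TestFCSImpute:
    def _gaussian_data(self, n=400, seed=1, p_miss=0.3):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = 2.0 + x + rng.normal(size=n)
        m = (rng.random(n) < p_miss).astype(int)
        y_obs = np.where(m == 1, np.nan, y)
        records = pd.DataFrame({"x": x, "y": y_obs, "M_y": m})
        return _toy_masked(records, {"M_y": "y"})

    def test_zero_missing_cells_returns_identical_copies(self):
        rng = np.random.default_rng(3)
        records = pd.DataFrame(
            {"x": rng.normal(size=50), "y": rng.normal(size=50), "M_y": np.zeros(50, dtype=int)}
        )
        data = _toy_masked(records, {"M_y": "y"})
        ispec = ImputationSpec(variable_models={"y": "gaussian-linear"}, n_imputations=3, seed=5)
        out = fcs_impute(data, ispec)
        assert len(out) == 3
        for frame in out:
            pd.testing.assert_frame_equal(frame, data.records)

    def test_delta_zero_identical_to_no_delta(self):
        data = self._gaussian_data()
        base = ImputationSpec(
            variable_models={"y": "gaussian-linear"}, n_imputations=4, n_cycles=3, seed=11
        )
        with_zero = ImputationSpec(
            variable_models={"y": "gaussian-linear"},
            n_imputations=4,
            n_cycles=3,
            deltas={"y": 0.0},
            seed=11,
        )
        for a, b in zip(fcs_impute(data, base), fcs_impute(data, with_zero)):
            pd.testing.assert_frame_equal(a, b)

    def test_delta_is_exact_additive_offset_on_imputed_cells(self):
        data = self._gaussian_data()
        mk = lambda d: ImputationSpec(
            variable_models={"y": "gaussian-linear"},
            n_imputations=2,
            n_cycles=4,
            deltas={"y": d},
            seed=7,
        )
        miss = data.records["M_y"].to_numpy() == 1
        for f0, f3 in zip(fcs_impute(data, mk(0.0)), fcs_impute(data, mk(3.0))):
            np.testing.assert_allclose(
                f3.loc[miss, "y"].to_numpy() - f0.loc[miss, "y"].to_numpy(), 3.0
            )
            # observed cells untouched in both
            np.testing.assert_array_equal(
                f0.loc[~miss, "y"].to_numpy(), data.records.loc[~miss, "y"].to_numpy()
            )

    def test_observed_cells_never_altered(self):
        design = pattern_mixture_design(d_star=2.0, n=600)
        data = design.sample(seed=21)
        ispec = ImputationSpec(
            variable_models={"Y": "gaussian-linear"}, n_imputations=3, n_cycles=2, seed=2
        )
        miss = data.records["M_Y"].to_numpy() == 1
        for frame in fcs_impute(data, ispec):
            np.testing.assert_array_equal(
                frame.loc[~miss, "Y"].to_numpy(), data.records.loc[~miss, "Y"].to_numpy()
            )
            assert not frame["Y"].isna().any()

    def test_undeclared_incomplete_variable_rejected(self):
        data = self._gaussian_data()
        with pytest.raises(ImputationModelError, match="y"):
            fcs_impute(data, ImputationSpec(variable_models={}, n_imputations=2))

    def test_binary_delta_rejected_with_explanation(self):
        with pytest.raises(DeltaUnsupportedError, match="binary"):
            ImputationSpec(
                variable_models={"x": "bernoulli-logistic"}, deltas={"x": 1.0}
            )

    def test_seed_determinism(self):
        data = self._gaussian_data()
        ispec = ImputationSpec(
            variable_models={"y": "gaussian-linear"}, n_imputations=3, n_cycles=2, seed=19
        )
        for a, b in zip(fcs_impute(data, ispec), fcs_impute(data, ispec)):
            pd.testing.assert_frame_equal(a, b)


class TestRubinPooling:
    def test_direct_arithmetic_example(self):
        pooled = pool_rubin([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert pooled.estimate == pytest.approx(2.0)
        assert pooled.between_variance == pytest.approx(1.0)
        assert pooled.within_variance == pytest.approx(1.0)
        assert pooled.total_variance == pytest.approx(7.0 / 3.0)

    def test_single_imputation_degenerate(self):
        pooled = pool_rubin([4.2], [0.25])
        assert pooled.estimate == 4.2
        assert pooled.between_variance == 0.0
        assert pooled.total_variance == pytest.approx(0.25)

    def test_zero_spread_total_equals_within(self):
        pooled = pool_rubin([1.7, 1.7, 1.7], [0.5, 0.5, 0.5])
        assert pooled.between_variance == 0.0
        assert pooled.total_variance == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_rubin([], [])

    def test_variance_decomposition_invariant(self):
        pooled = pool_rubin([0.3, 0.9, 0.1, 0.5], [0.2, 0.25, 0.22, 0.18], dfcom=100)
        m = pooled.n_imputations_used
        assert pooled.total_variance == pytest.approx(
            pooled.within_variance + (1 + 1 / m) * pooled.between_variance
        )
        assert pooled.ci_low < pooled.estimate < pooled.ci_high

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        ests=st.lists(st.floats(-5, 5), min_size=2, max_size=8),
        var=st.floats(0.01, 2.0),
        seed=st.integers(0, 10_000),
    )
    def test_permutation_invariance(self, ests, var, seed):
        variances = [var] * len(ests)
        perm = list(np.random.default_rng(seed).permutation(len(ests)))
        a = pool_rubin(ests, variances)
        b = pool_rubin([ests[i] for i in perm], [variances[i] for i in perm])
        assert a.estimate == pytest.approx(b.estimate)
        assert a.total_variance == pytest.approx(b.total_variance)


class TestDeltaAdjustedAnalysis:
    def test_zero_grid_equals_standard_mi(self):
        design = pattern_mixture_design(d_star=0.0, n=800)
        data = design.sample(seed=13)
        spec = AnalysisSpec("Y", "X", ("C", "Z"))
        ispec = ImputationSpec(
            variable_models={"Y": "gaussian-linear"}, n_imputations=5, n_cycles=2, seed=3
        )
        grid = delta_adjusted_analysis(data, spec, ispec, [0.0])
        standard = fit_mi(data, spec, ispec)
        assert grid[0].estimate == pytest.approx(standard.estimate)
        assert grid[0].total_variance == pytest.approx(standard.total_variance)

    def test_mean_imputed_outcome_shifts_by_exact_delta_difference(self):
        design = pattern_mixture_design(d_star=0.0, n=800)
        data = design.sample(seed=17)
        miss = data.records["M_Y"].to_numpy() == 1
        mk = lambda d: ImputationSpec(
            variable_models={"Y": "gaussian-linear"},
            n_imputations=3,
            n_cycles=3,
            deltas={"Y": d},
            seed=29,
        )
        d1, d2 = 0.56, 4.92
        means = []
        for d in (d1, d2):
            frames = fcs_impute(data, mk(d))
            means.append(np.mean([f.loc[miss, "Y"].mean() for f in frames]))
        assert means[1] - means[0] == pytest.approx(d2 - d1, abs=1e-10)

    def test_empty_grid_rejected(self):
        design = pattern_mixture_design(d_star=0.0, n=200)
        data = design.sample(seed=1)
        spec = AnalysisSpec("Y", "X", ("C", "Z"))
        ispec = ImputationSpec(variable_models={"Y": "gaussian-linear"}, n_imputations=2)
        with pytest.raises(ValueError):
            delta_adjusted_analysis(data, spec, ispec, [])


class TestMIRecovery:
    def test_mi_unbiased_when_imputation_models_correct(self, design_mar):
        """Proper FCS imputation recovers the exposure effect when missingness
        is driven by the fully observed confounder block."""
        spec = AnalysisSpec("Y", "X", ("C", "Z"))
        ispec = ImputationSpec(
            variable_models={
                "X": "bernoulli-logistic",
                "Y": "gaussian-linear",
                "Z": "gaussian-linear",
            },
            n_imputations=8,
            n_cycles=4,
        )
        report = monte_carlo(
            design_mar, mi_estimator(spec, ispec), n_replicates=60, seed=101, n=2_000
        )
        assert report.failures == 0
        assert not report.significant_bias()

    def test_cra_unbiased_under_same_mechanism(self, design_mar):
        spec = AnalysisSpec("Y", "X", ("C", "Z"))
        report = monte_carlo(design_mar, cra_estimator(spec), n_replicates=100, seed=55, n=2_000)
        assert not report.significant_bias()
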