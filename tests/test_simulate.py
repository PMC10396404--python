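"""Structural-equation generation, missingness mechanisms, calibration, case study."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import norm

from mdagplan.errors import CalibrationError, ModelGraphMismatchError
from mdagplan.mdag import MDag, Node
from mdagplan.simulate import (
    CASE_STUDY_MISSINGNESS,
    Equation,
    GenerativeModel,
    Mechanism,
    calibrate_intercepts,
    case_study_generator,
    draw_masked,
    pattern_mixture_design,
    simulate_complete,
    simulate_missingness,
)


def _single_node_graph():
    return MDag([Node("a")], [])


def _masking_graph():
    return MDag(
        [Node("a"), Node("M_a", kind="missingness", indicator_of="a")],
        [("a", "M_a")],
    )


class TestCompleteData:
    def test_root_gaussian_location(self):
        g = _single_node_graph()
        model = GenerativeModel(
            equations={"a": Equation("gaussian-linear", 5.0, {}, noise_scale=1.0)},
            mechanisms={},
            n=10_000,
            seed=3,
        )
        frame = simulate_complete(g, model)
        assert frame["a"].mean() == pytest.approx(5.0, abs=4 / np.sqrt(10_000))

    def test_zero_noise_scale_rejected(self):
        with pytest.raises(ModelGraphMismatchError, match="noise scale"):
            Equation("gaussian-linear", 0.0, {}, noise_scale=0.0)

    def test_same_seed_gives_identical_tables(self):
        g = _masking_graph()
        model = GenerativeModel(
            equations={"a": Equation("gaussian-linear", 0.0, {}, noise_scale=1.0)},
            mechanisms={"M_a": Mechanism(-1.0, {"a": 0.5})},
            n=500,
            seed=42,
        )
        d1 = draw_masked(g, model, seed=9)
        d2 = draw_masked(g, model, seed=9)
        pd.testing.assert_frame_equal(d1.records, d2.records)
        assert d1.to_csv_string() == d2.to_csv_string()

    def test_coefficient_on_non_parent_rejected(self):
        g = _single_node_graph()
        model = GenerativeModel(
            equations={"a": Equation("gaussian-linear", 0.0, {"b": 1.0}, noise_scale=1.0)},
            mechanisms={},
        )
        with pytest.raises(ModelGraphMismatchError):
            simulate_complete(g, model)

    def test_missing_parent_coefficient_rejected(self):
        g = MDag([Node("a"), Node("b")], [("a", "b")])
        model = GenerativeModel(
            equations={
                "a": Equation("gaussian-linear", 0.0, {}, noise_scale=1.0),
                "b": Equation("gaussian-linear", 0.0, {}, noise_scale=1.0),
            },
            mechanisms={},
        )
        with pytest.raises(ModelGraphMismatchError, match="parents"):
            simulate_complete(g, model)

    def test_bernoulli_prevalence(self):
        g = _single_node_graph()
        model = GenerativeModel(
            equations={"a": Equation("bernoulli-logistic", 1.0, {})},
            mechanisms={},
            n=20_000,
            seed=5,
        )
        frame = simulate_complete(g, model)
        p = expit(1.0)
        assert frame["a"].mean() == pytest.approx(p, abs=4 * np.sqrt(p * (1 - p) / 20_000))


class TestMissingness:
    def _model(self, intercept, coef, n=20_000, seed=0):
        return GenerativeModel(
            equations={"a": Equation("gaussian-linear", 0.0, {}, noise_scale=1.0)},
            mechanisms={"M_a": Mechanism(intercept, {"a": coef})},
            n=n,
            seed=seed,
        )

    def test_null_mechanism_gives_half_missing(self):
        g = _masking_graph()
        model = self._model(0.0, 0.0)
        data = simulate_complete(g, model)
        ind = simulate_missingness(g, model, data)
        assert ind["M_a"].mean() == pytest.approx(0.5, abs=4 * np.sqrt(0.25 / 20_000))

    def test_degenerate_intercept_gives_no_missingness(self):
        g = _masking_graph()
        model = self._model(-30.0, 0.0)
        data = simulate_complete(g, model)
        assert simulate_missingness(g, model, data)["M_a"].sum() == 0

    def test_marginal_rate_matches_quadrature(self):
        # coefficient 1 on a standard-gaussian parent: marginal rate is
        # E[expit(W)], W ~ N(0,1), computed by 1-D quadrature
        g = _masking_graph()
        model = self._model(0.0, 1.0, n=100_000, seed=2)
        data = simulate_complete(g, model)
        ind = simulate_missingness(g, model, data)
        expected, _ = quad(lambda w: expit(w) * norm.pdf(w), -10, 10)
        assert ind["M_a"].mean() == pytest.approx(expected, abs=0.01)

    def test_mechanism_on_non_parent_rejected(self):
        g = _masking_graph()
        model = GenerativeModel(
            equations={"a": Equation("gaussian-linear", 0.0, {}, noise_scale=1.0)},
            mechanisms={"M_a": Mechanism(0.0, {"b": 1.0})},
        )
        data = pd.DataFrame({"a": np.zeros(10)})
        with pytest.raises(ModelGraphMismatchError):
            simulate_missingness(g, model, data)

    def test_masking_conserves_observed_cells(self):
        g = _masking_graph()
        model = self._model(0.0, 1.0, n=5_000, seed=8)
        data = draw_masked(g, model, seed=8)
        assert data.check_conservation()
        # indicator columns are strictly 0/1
        assert set(data.records["M_a"].unique()) <= {0, 1}


class TestCalibration:
    def test_zero_covariate_target_half_gives_zero_intercept(self):
        g = _masking_graph()
        model = GenerativeModel(
            equations={"a": Equation("gaussian-linear", 0.0, {}, noise_scale=1.0)},
            mechanisms={"M_a": Mechanism(5.0, {"a": 0.0})},
        )
        out = calibrate_intercepts(g, model, {"M_a": 0.5}, n=50_000, seed=1)
        assert out.mechanisms["M_a"].intercept == pytest.approx(0.0, abs=0.02)

    def test_nonzero_effect_hits_target(self):
        g = _masking_graph()
        model = GenerativeModel(
            equations={"a": Equation("gaussian-linear", 0.0, {}, noise_scale=1.0)},
            mechanisms={"M_a": Mechanism(0.0, {"a": 1.0})},
        )
        out = calibrate_intercepts(g, model, {"M_a": 0.15}, n=200_000, seed=1)
        data = simulate_complete(g, out, n=200_000, rng=np.random.default_rng(77))
        realized = simulate_missingness(g, out, data, rng=np.random.default_rng(78))
        assert realized["M_a"].mean() == pytest.approx(0.15, abs=0.005)

    def test_boundary_target_rejected(self):
        g = _masking_graph()
        model = GenerativeModel(
            equations={"a": Equation("gaussian-linear", 0.0, {}, noise_scale=1.0)},
            mechanisms={"M_a": Mechanism(0.0, {"a": 1.0})},
        )
        with pytest.raises(CalibrationError):
            calibrate_intercepts(g, model, {"M_a": 0.0})

    def test_recalibration_is_idempotent(self):
        g = _masking_graph()
        model = GenerativeModel(
            equations={"a": Equation("gaussian-linear", 0.0, {}, noise_scale=1.0)},
            mechanisms={"M_a": Mechanism(0.0, {"a": 1.0})},
        )
        once = calibrate_intercepts(g, model, {"M_a": 0.2}, n=100_000, seed=1)
        twice = calibrate_intercepts(g, once, {"M_a": 0.2}, n=100_000, seed=2)
        assert abs(once.mechanisms["M_a"].intercept - twice.mechanisms["M_a"].intercept) < 0.05


class TestCaseStudy:
    def test_missingness_proportions_near_targets(self, design_a):
        data = design_a.sample(seed=4)
        props = data.missing_proportions()
        for ind, target in CASE_STUDY_MISSINGNESS.items():
            assert props[ind] == pytest.approx(target, abs=0.02)

    def test_column_structure(self, design_a):
        data = design_a.sample(seed=4)
        assert sorted(data.records.columns) == ["C", "M_X", "M_Y", "M_Z", "X", "Y", "Z"]
        assert data.check_conservation()

    def test_outcome_stays_on_instrument_scale(self, design_a):
        data = design_a.sample(seed=4, n=20_000)
        y = data.shadow["Y"]
        assert y.min() >= 0.0 and y.max() <= 40.0
        # clipping is a rare-edge phenomenon, not a feature of the bulk
        assert ((y <= 0.0) | (y >= 40.0)).mean() < 0.01

    def test_seed_determinism(self, design_a):
        d1 = design_a.sample(seed=12)
        d2 = design_a.sample(seed=12)
        pd.testing.assert_frame_equal(d1.records, d2.records)

    def test_generator_wrapper_returns_both_graphs(self):
        design, data = case_study_generator(seed=1, n=300)
        assert len(design.mdag_a.edges) + 3 == len(design.mdag_b.edges)
        assert data.n == 300

    def test_outcome_uncorrelated_with_indicators_given_regressors(self, design_a):
        # consequence of d-separation under outcome-independent missingness:
        # partial correlation of Y with each indicator given (X, C, Z) ~ 0
        n = 50_000
        data = design_a.sample(seed=31, n=n)
        shadow = data.shadow
        regressors = np.column_stack(
            [np.ones(n), shadow["X"], shadow["C"], shadow["Z"]]
        )
        resid_y = shadow["Y"] - regressors @ np.linalg.lstsq(regressors, shadow["Y"], rcond=None)[0]
        thr = 4 / np.sqrt(n)
        for ind in ("M_X", "M_Y", "M_Z"):
            m = data.records[ind].to_numpy().astype(float)
            resid_m = m - regressors @ np.linalg.lstsq(regressors, m, rcond=None)[0]
            r = np.corrcoef(resid_y, resid_m)[0, 1]
            assert abs(r) < thr, (ind, r)


class TestPatternMixture:
    def test_truth_has_closed_form(self):
        design = pattern_mixture_design(d_star=4.0, p_miss=(0.15, 0.35))
        assert design.true_beta == pytest.approx(0.6 + 4.0 * 0.20)

    def test_shift_applied_only_to_missing_outcomes(self):
        shifted = pattern_mixture_design(d_star=3.0).sample(seed=5)
        unshifted = pattern_mixture_design(d_star=0.0).sample(seed=5)
        miss = shifted.records["M_Y"].to_numpy() == 1
        # same seed, same underlying draws: observed outcomes identical,
        # missing shadow outcomes shifted by exactly d*
        np.testing.assert_array_equal(
            shifted.shadow["Y"].to_numpy()[~miss], unshifted.shadow["Y"].to_numpy()[~miss]
        )
        np.testing.assert_allclose(
            shifted.shadow["Y"].to_numpy()[miss] - unshifted.shadow["Y"].to_numpy()[miss],
            3.0,
        )

    def test_missingness_rate_depends_on_exposure_alone(self):
        design = pattern_mixture_design(d_star=0.0, p_miss=(0.1, 0.4), n=50_000)
        data = design.sample(seed=9)
        x = data.shadow["X"].to_numpy()
        m = data.records["M_Y"].to_numpy()
        assert m[x == 0].mean() == pytest.approx(0.1, abs=0.01)
        assert m[x == 1].mean() == pytest.approx(0.4, abs=0.01)
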