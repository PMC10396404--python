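"""Structural-equation data generation and logistic missingness mechanisms.

Every quantitative mechanism is tied to an m-DAG: a generative model may only
give a node a nonzero coefficient on an actual graph parent, and must supply
a (possibly zero) coefficient for every graph parent — so simulated data can
never exhibit a dependence the graph does not declare.  Substantive and
latent nodes are generated in topological order as linear-Gaussian or
Bernoulli-logistic equations; each missingness indicator is then drawn
independently per record with a logit-linear probability in its graph
parents, and masking replaces the affected cells with NaN while retaining
the pre-masking "shadow" table for evaluation.

The module also ships the case-study emulator: a point-exposure design with
a binary exposure (~15% missing), a bounded continuous outcome on the 0-40
scale (~23% missing), one complete and one incomplete confounder block
(~19% incomplete), defaulting to n = 4882 records.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import CalibrationError, ModelGraphMismatchError
from .mdag import MDag, Node
from .recoverability import Estimand

FAMILIES = ("gaussian-linear", "bernoulli-logistic")


@dataclass(frozen=True)
class Equation:
    """Structural equation for one substantive or latent node."""

    family: str
    intercept: float
    coefficients: Mapping[str, float] = field(default_factory=dict)
    noise_scale: float | None = None  # gaussian only
    bounds: tuple[float, float] | None = None  # gaussian only: clip range

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ModelGraphMismatchError(f"unknown family {self.family!r}")
        if self.family == "gaussian-linear":
            if self.noise_scale is None or self.noise_scale <= 0:
                raise ModelGraphMismatchError("gaussian noise scale must be > 0")
        object.__setattr__(self, "coefficients", dict(self.coefficients))


@dataclass(frozen=True)
class Mechanism:
    """Logistic missingness mechanism for one indicator: logit-linear in its parents."""

    intercept: float
    coefficients: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", dict(self.coefficients))


@dataclass(frozen=True)
class GenerativeModel:
    """Structural equations plus missingness mechanisms consistent with an m-DAG."""

    equations: Mapping[str, Equation]
    mechanisms: Mapping[str, Mechanism]
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "equations", dict(self.equations))
        object.__setattr__(self, "mechanisms", dict(self.mechanisms))

    def validate_against(self, g: MDag) -> None:
        """Enforce the coefficient/parent correspondence with the graph."""
        for name, eq in self.equations.items():
            node = g.node(name)
            if node.kind == "missingness":
                raise ModelGraphMismatchError(
                    f"{name!r} is a missingness node; use a Mechanism, not an Equation"
                )
            parents = set(g.parents(name))
            got = set(eq.coefficients)
            if got != parents:
                raise ModelGraphMismatchError(
                    f"equation for {name!r}: coefficients {sorted(got)} do not match "
                    f"graph parents {sorted(parents)}"
                )
        for name, mech in self.mechanisms.items():
            node = g.node(name)
            if node.kind != "missingness":
                raise ModelGraphMismatchError(f"{name!r} is not a missingness node")
            parents = set(g.parents(name))
            got = set(mech.coefficients)
            if got != parents:
                raise ModelGraphMismatchError(
                    f"mechanism for {name!r}: coefficients {sorted(got)} do not match "
                    f"graph parents {sorted(parents)}"
                )
        for node in g:
            if node.kind in ("substantive", "latent") and node.name not in self.equations:
                raise ModelGraphMismatchError(f"no equation for node {node.name!r}")


# -- complete-data generation --------------------------------------------


def simulate_complete(
    g: MDag,
    model: GenerativeModel,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate a complete table of substantive and latent variables.

    Nodes are generated in (lexicographic-tie-break) topological order from a
    single pseudo-random stream, so a fixed seed reproduces the table
    byte-for-byte.
    """
    model.validate_against(g)
    n = int(model.n if n is None else n)
    rng = np.random.default_rng(model.seed) if rng is None else rng
    cols: dict[str, np.ndarray] = {}
    for name in g.topological_order():
        if g.node(name).kind == "missingness":
            continue
        eq = model.equations[name]
        eta = np.full(n, float(eq.intercept))
        for parent, coef in sorted(eq.coefficients.items()):
            if coef != 0.0:
                eta += coef * cols[parent]
        if eq.family == "gaussian-linear":
            vals = eta + rng.normal(0.0, eq.noise_scale, size=n)
            if eq.bounds is not None:
                vals = np.clip(vals, eq.bounds[0], eq.bounds[1])
        else:
            vals = (rng.random(n) < expit(eta)).astype(float)
        cols[name] = vals
    order = [nm for nm in g.topological_order() if g.node(nm).kind != "missingness"]
    return pd.DataFrame({nm: cols[nm] for nm in order})


def simulate_missingness(
    g: MDag,
    model: GenerativeModel,
    data: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw each missingness indicator independently per record.

    Indicator probability is expit(intercept + Σ coef·parent value), parents
    restricted to the indicator's m-DAG parents.  Returns a 0/1 integer table
    with one column per missingness node, in sorted node order.
    """
    model.validate_against(g)
    rng = np.random.default_rng(model.seed + 1) if rng is None else rng
    n = len(data)
    out: dict[str, np.ndarray] = {}
    for node in g.missingness_nodes:  # sorted by name
        mech = model.mechanisms.get(node.name)
        if mech is None:
            raise ModelGraphMismatchError(f"no mechanism for missingness node {node.name!r}")
        eta = np.full(n, float(mech.intercept))
        for parent, coef in sorted(mech.coefficients.items()):
            if coef != 0.0:
                if parent not in data.columns:
                    raise ModelGraphMismatchError(
                        f"mechanism for {node.name!r} references {parent!r}, absent from data"
                    )
                eta += coef * data[parent].to_numpy()
        out[node.name] = (rng.random(n) < expit(eta)).astype(np.int64)
    return pd.DataFrame(out, index=data.index)


# -- masked datasets -----------------------------------------------------


@dataclass
class MaskedDataset:
    """A rectangular table with missing cells plus its pre-masking shadow.

    ``records`` holds one column per substantive variable (NaN where masked)
    and one 0/1 column per missingness indicator.  ``shadow`` holds the
    pre-masking substantive values and is retained for evaluation only —
    no estimator may read it.  ``indicator_map`` maps indicator column name
    to the substantive column it masks.
    """

    records: pd.DataFrame
    shadow: pd.DataFrame
    indicator_map: dict[str, str]

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def substantive_columns(self) -> list[str]:
        return list(self.shadow.columns)

    @property
    def indicator_columns(self) -> list[str]:
        return list(self.indicator_map)

    def check_conservation(self) -> bool:
        """Observed cells equal their shadow values; indicators are 0/1."""
        for ind, var in self.indicator_map.items():
            col = self.records[ind]
            if not col.isin((0, 1)).all():
                return False
            obs = col.to_numpy() == 0
            if self.records[var].isna().to_numpy()[obs].any():
                return False
            if not np.array_equal(
                self.records[var].to_numpy()[obs], self.shadow[var].to_numpy()[obs]
            ):
                return False
            if not self.records[var].isna().to_numpy()[~obs].all():
                return False
        return True

    def missing_proportions(self) -> dict[str, float]:
        return {ind: float(self.records[ind].mean()) for ind in self.indicator_map}

    def to_csv(self, path, shadow_path=None) -> None:
        """Write records as CSV (empty cells for missing); optionally the shadow too."""
        self.records.to_csv(path, index=False)
        if shadow_path is not None:
            self.shadow.to_csv(shadow_path, index=False)

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.records.to_csv(buf, index=False)
        return buf.getvalue()

    @classmethod
    def from_records(cls, records: pd.DataFrame, indicator_map: Mapping[str, str]) -> "MaskedDataset":
        """Build from an already-masked table (e.g. read back from CSV).

        The shadow then equals the observed data with NaN in masked cells —
        evaluation against truth is unavailable for such datasets.
        """
        indicator_map = dict(indicator_map)
        shadow = records[[v for v in records.columns if v not in indicator_map]].copy()
        return cls(records=records.copy(), shadow=shadow, indicator_map=indicator_map)


def mask(g: MDag, complete: pd.DataFrame, indicators: pd.DataFrame) -> MaskedDataset:
    """Apply drawn indicators to a complete table, producing a MaskedDataset."""
    subst = [n.name for n in g.substantive_nodes if n.name in complete.columns]
    shadow = complete[subst].copy()
    records = complete[subst].copy()
    indicator_map: dict[str, str] = {}
    for node in g.missingness_nodes:
        target = node.indicator_of
        if target not in records.columns:
            raise ModelGraphMismatchError(
                f"indicator {node.name!r} marks {target!r}, absent from the data"
            )
        ind = indicators[node.name].to_numpy()
        records.loc[ind == 1, target] = np.nan
        records[node.name] = ind
        indicator_map[node.name] = target
    return MaskedDataset(records=records, shadow=shadow, indicator_map=indicator_map)


def draw_masked(
    g: MDag, model: GenerativeModel, n: int | None = None, seed: int | None = None
) -> MaskedDataset:
    """Convenience: complete data + indicators + masking from one seed."""
    rng = np.random.default_rng(model.seed if seed is None else seed)
    complete = simulate_complete(g, model, n=n, rng=rng)
    indicators = simulate_missingness(g, model, complete, rng=rng)
    return mask(g, complete, indicators)


# -- intercept calibration -----------------------------------------------


def calibrate_intercepts(
    g: MDag,
    model: GenerativeModel,
    targets: Mapping[str, float],
    n: int = 200_000,
    seed: int = 0,
    tol: float = 0.005,
) -> GenerativeModel:
    """Adjust mechanism intercepts so realized marginal missingness matches targets.

    For each indicator, the intercept solves
    mean(expit(a + η_i)) = target over a large simulated covariate sample
    (Monte Carlo root-finding via Brent's method; the target function is
    smooth and monotone in ``a``).  The calibrated model is then verified by
    actually drawing indicators: the realized proportion must land within
    ``tol`` of the target, else :class:`CalibrationError` is raised with the
    residual.
    """
    for name, t in targets.items():
        if not (0.0 < t < 1.0):
            raise CalibrationError(f"target for {name!r} must lie strictly in (0, 1), got {t}")
        if name not in model.mechanisms:
            raise CalibrationError(f"no mechanism named {name!r} to calibrate")
    rng = np.random.default_rng(seed)
    complete = simulate_complete(g, model, n=n, rng=rng)
    new_mechs = dict(model.mechanisms)
    for name in sorted(targets):
        mech = model.mechanisms[name]
        target = targets[name]
        eta0 = np.zeros(n)
        for parent, coef in sorted(mech.coefficients.items()):
            if coef != 0.0:
                eta0 += coef * complete[parent].to_numpy()

        def f(a: float) -> float:
            return float(np.mean(expit(a + eta0))) - target

        try:
            a_star = brentq(f, -40.0, 40.0, xtol=1e-10, maxiter=200)
        except ValueError as exc:  # pragma: no cover - requires pathological mechanism
            raise CalibrationError(f"root bracketing failed for {name!r}: {exc}") from None
        new_mechs[name] = replace(mech, intercept=float(a_star))

    calibrated = replace(model, mechanisms=new_mechs)
    indicators = simulate_missingness(g, calibrated, complete, rng=rng)
    for name, target in targets.items():
        realized = float(indicators[name].mean())
        if abs(realized - target) > tol:
            raise CalibrationError(
                f"calibration residual for {name!r}: realized {realized:.4f} vs "
                f"target {target:.4f} (tol {tol})"
            )
    return calibrated


# -- case-study emulation ------------------------------------------------

#: target marginal missingness proportions: exposure, outcome, incomplete confounders
CASE_STUDY_MISSINGNESS = {"M_X": 0.15, "M_Y": 0.23, "M_Z": 0.19}
CASE_STUDY_N = 4882


def case_study_mdag(outcome_arrows: bool = False, confounder_driven: bool = False) -> MDag:
    """The point-exposure study m-DAG (exposure X, outcome Y on the 0-40 scale,
    complete confounder block C, incomplete confounder block Z, indicators
    M_X, M_Y, M_Z).  With ``outcome_arrows=True`` the outcome additionally
    causes all three indicators — the pessimistic alternative graph.  With
    ``confounder_driven=True`` missingness is caused by the complete
    confounder block only (no key arrows; a mechanism under which both CRA
    and standard MI are valid)."""
    nodes = [
        Node("C", role="confounder", group_members=("child_sex", "mat_age")),
        Node(
            "Z",
            role="confounder",
            group_members=("mat_alcohol", "mat_smoking", "child_physical"),
        ),
        Node("X", role="exposure"),
        Node("Y", role="outcome"),
        Node("M_X", kind="missingness", indicator_of="X"),
        Node("M_Y", kind="missingness", indicator_of="Y"),
        Node("M_Z", kind="missingness", indicator_of="Z"),
    ]
    edges = [
        ("C", "Z"),
        ("C", "X"),
        ("C", "Y"),
        ("Z", "X"),
        ("Z", "Y"),
        ("X", "Y"),
    ]
    if confounder_driven:
        edges += [("C", "M_X"), ("C", "M_Y"), ("C", "M_Z")]
    else:
        edges += [
            ("Z", "M_X"),
            ("Z", "M_Y"),
            ("Z", "M_Z"),
            ("X", "M_X"),
            ("X", "M_Y"),
            ("X", "M_Z"),
        ]
    if outcome_arrows:
        edges += [("Y", "M_X"), ("Y", "M_Y"), ("Y", "M_Z")]
    return MDag(nodes, edges)


CASE_STUDY_ROLES = {
    "X": "X",
    "Y": "Y",
    "Z": "Z",
    "C": "C",
    "M_X": "M_X",
    "M_Y": "M_Y",
    "M_Z": "M_Z",
}


@dataclass
class CaseStudyDesign:
    """A fully calibrated case-study emulation: graphs, model, truth, estimand.

    ``mechanism`` selects which graph drives the missingness draws:
    "outcome_independent" (no outcome→indicator arrows; exposure-effect
    estimand recoverable, CRA consistent) or "outcome_dependent" (outcome
    causes all indicators; not recoverable).  ``true_beta`` is the exposure
    coefficient targeted by the estimand.
    """

    mdag_a: MDag
    mdag_b: MDag
    sample_graph: MDag
    model: GenerativeModel
    mechanism: str
    roles: dict[str, str]
    estimand: Estimand
    true_beta: float
    outcome_sd: float
    n: int

    @property
    def graph(self) -> MDag:
        """The m-DAG whose mechanisms actually drive the missingness draws."""
        return self.sample_graph

    @property
    def truth(self) -> float:
        return self.true_beta

    def sample(self, seed: int, n: int | None = None) -> MaskedDataset:
        return draw_masked(self.graph, self.model, n=n or self.n, seed=seed)


def case_study_design(
    mechanism: str = "outcome_independent",
    n: int = CASE_STUDY_N,
    exposure_effect: float = 0.6,
    missingness_log_odds: float = 0.5,
    outcome_log_odds_per_sd: float = 1.0,
    calibration_n: int = 200_000,
    calibration_seed: int = 20230,
) -> CaseStudyDesign:
    """Build the calibrated case-study generative design.

    Structural model: C, Z standard gaussian blocks; X Bernoulli with
    logit = -1.4 + 0.5 C + 0.5 Z (≈20% exposed); Y gaussian with mean
    10 + 0.6 X + C + Z, residual SD 3.5, clipped to the instrument's [0, 40]
    range (clipping touches <1% of draws, so the structural exposure
    coefficient doubles as the full-data regression estimand to well within
    Monte Carlo tolerances).  Missingness: every indicator depends on X and Z
    with log-odds ``missingness_log_odds`` per unit; under the
    outcome-dependent mechanism, additionally on the outcome with
    ``outcome_log_odds_per_sd`` per marginal SD of Y.  Intercepts are
    calibrated to marginal missingness 15% (X), 23% (Y), 19% (Z).
    """
    if mechanism not in ("outcome_independent", "outcome_dependent", "confounder_only"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    mdag_a = case_study_mdag(outcome_arrows=False)
    mdag_b = case_study_mdag(outcome_arrows=True)
    if mechanism == "outcome_independent":
        graph = mdag_a
    elif mechanism == "outcome_dependent":
        graph = mdag_b
    else:
        graph = case_study_mdag(confounder_driven=True)

    equations = {
        "C": Equation("gaussian-linear", 0.0, {}, noise_scale=1.0),
        "Z": Equation("gaussian-linear", 0.0, {"C": 0.3}, noise_scale=1.0),
        "X": Equation("bernoulli-logistic", -1.4, {"C": 0.5, "Z": 0.5}),
        "Y": Equation(
            "gaussian-linear",
            10.0,
            {"X": exposure_effect, "C": 1.0, "Z": 1.0},
            noise_scale=3.5,
            bounds=(0.0, 40.0),
        ),
    }
    # marginal SD of Y, measured on a large structural sample (the outcome enters
    # the missingness mechanisms standardized, so log-odds are per SD of Y)
    probe_model = GenerativeModel(equations=equations, mechanisms={}, n=n, seed=calibration_seed)
    probe = simulate_complete(mdag_a, probe_model, n=calibration_n,
                              rng=np.random.default_rng(calibration_seed))
    outcome_sd = float(probe["Y"].std())
    if mechanism == "confounder_only":
        base = {"C": missingness_log_odds}
    else:
        base = {"X": missingness_log_odds, "Z": missingness_log_odds}
    mechs: dict[str, Mechanism] = {}
    for m in ("M_X", "M_Y", "M_Z"):
        coefs = dict(base)
        if mechanism == "outcome_dependent":
            coefs["Y"] = outcome_log_odds_per_sd / outcome_sd
        mechs[m] = Mechanism(intercept=0.0, coefficients=coefs)

    model = GenerativeModel(equations=equations, mechanisms=mechs, n=n, seed=calibration_seed)
    model = calibrate_intercepts(
        graph, model, CASE_STUDY_MISSINGNESS, n=calibration_n, seed=calibration_seed
    )
    return CaseStudyDesign(
        mdag_a=mdag_a,
        mdag_b=mdag_b,
        sample_graph=graph,
        model=model,
        mechanism=mechanism,
        roles=dict(CASE_STUDY_ROLES),
        estimand=Estimand.regression("Y", "X", {"C", "Z"}),
        true_beta=float(exposure_effect),
        outcome_sd=outcome_sd,
        n=n,
    )


def case_study_generator(
    seed: int, n: int = CASE_STUDY_N, mechanism: str = "outcome_independent"
) -> tuple[CaseStudyDesign, MaskedDataset]:
    """One-call case-study emulation: calibrated design plus one masked dataset."""
    design = case_study_design(mechanism=mechanism, n=n)
    return design, design.sample(seed=seed)


# -- pattern-mixture variant ---------------------------------------------


@dataclass
class PatternMixtureDesign:
    """Outcome-shift pattern-mixture generator for delta-adjustment testing.

    The complete data follow the case-study structural model (without outcome
    clipping); the outcome is the only incomplete variable, its missingness
    depends on the exposure alone (probability ``p_miss_unexposed`` /
    ``p_miss_exposed``), and the *unobserved* outcome values are shifted by
    the constant ``d_star`` — the data-generating counterpart of a
    delta-adjusted imputation model.  Because the missingness probability is
    a function of the binary exposure only, the full-data conditional mean
    stays exactly linear and the true exposure coefficient has the closed
    form  β + d*·(p₁ − p₀).
    """

    mdag: MDag
    model: GenerativeModel
    d_star: float
    p_miss: tuple[float, float]  # (unexposed, exposed)
    beta: float
    estimand: Estimand
    n: int

    @property
    def true_beta(self) -> float:
        return self.beta + self.d_star * (self.p_miss[1] - self.p_miss[0])

    @property
    def truth(self) -> float:
        return self.true_beta

    def sample(self, seed: int, n: int | None = None) -> MaskedDataset:
        n = n or self.n
        rng = np.random.default_rng(seed)
        complete = simulate_complete(self.mdag, self.model, n=n, rng=rng)
        indicators = simulate_missingness(self.mdag, self.model, complete, rng=rng)
        # pattern-mixture shift: the missing outcome values genuinely differ
        shifted = complete.copy()
        miss = indicators["M_Y"].to_numpy() == 1
        shifted.loc[miss, "Y"] = shifted.loc[miss, "Y"] + self.d_star
        return mask(self.mdag, shifted, indicators)


def pattern_mixture_design(
    d_star: float,
    n: int = 5_000,
    beta: float = 0.6,
    p_miss: tuple[float, float] = (0.15, 0.35),
) -> PatternMixtureDesign:
    """Build the outcome-shift pattern-mixture design (closed-form truth)."""
    nodes = [
        Node("C", role="confounder"),
        Node("Z", role="confounder"),
        Node("X", role="exposure"),
        Node("Y", role="outcome"),
        Node("M_Y", kind="missingness", indicator_of="Y"),
    ]
    edges = [
        ("C", "X"),
        ("C", "Y"),
        ("Z", "X"),
        ("Z", "Y"),
        ("X", "Y"),
        ("X", "M_Y"),
    ]
    g = MDag(nodes, edges)
    p0, p1 = p_miss
    logit = lambda p: float(np.log(p / (1.0 - p)))
    equations = {
        "C": Equation("gaussian-linear", 0.0, {}, noise_scale=1.0),
        "Z": Equation("gaussian-linear", 0.0, {}, noise_scale=1.0),
        "X": Equation("bernoulli-logistic", -1.4, {"C": 0.5, "Z": 0.5}),
        "Y": Equation(
            "gaussian-linear", 10.0, {"X": beta, "C": 1.0, "Z": 1.0}, noise_scale=3.5
        ),
    }
    mechanisms = {
        "M_Y": Mechanism(intercept=logit(p0), coefficients={"X": logit(p1) - logit(p0)})
    }
    model = GenerativeModel(equations=equations, mechanisms=mechanisms, n=n, seed=0)
    model.validate_against(g)
    return PatternMixtureDesign(
        mdag=g,
        model=model,
        d_star=float(d_star),
        p_miss=(p0, p1),
        beta=float(beta),
        estimand=Estimand.regression("Y", "X", {"C", "Z"}),
        n=n,
    )
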