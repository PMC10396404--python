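# Methods

## Scope and model

`mdagplan` operationalizes graphical reasoning about multivariable missing
data for point-exposure studies.  The assumption object is an m-DAG: a DAG
over substantive variables (exposure X, outcome Y, complete confounder block
**C**, incomplete confounder block **Z**), optional latent nodes, and one
binary missingness indicator per incomplete variable or collapsed group
(M_X, M_Y, M_Z).  Collapsed blocks are atomic in every algorithm: the
within-block structure does not alter recoverability verdicts for the
catalogued estimands, so no expansion machinery exists.

Three overarching structural assumptions delimit the scope of the canonical
catalogue and are enforced or surfaced by `validate_mdag`:

1. no *unmeasured* common cause of a variable and an indicator (violation
   `ASSUMPTION_I`, detected for declared latent nodes);
2. no *measured* common cause of a variable and an indicator omitted from
   the graph — not machine-checkable, always emitted as a warning requiring
   user attestation, never auto-passed;
3. no arrows out of missingness indicators, including indicator→indicator
   arrows (violation `ASSUMPTION_III`).  Whether an indicator→indicator
   arrow could ever serve as a modelling device is left open in the
   literature; we enforce the prohibition and surface it rather than
   silently dropping the edge.

## d-separation

Queries are answered by the linear-time reachability ("Bayes-ball")
algorithm over (node, travel-direction) states; conditioning blocks chains
and forks, and a collider transmits only when it or one of its descendants
is conditioned on.  The test suite proves the implementation equivalent to
an exhaustive path-enumeration oracle on every DAG with ≤4 nodes and on
1000 random 5–6-node DAGs over all singleton pairs and all conditioning
sets, and cross-checks networkx's `is_d_separator` on random graphs.

## Canonical classification and verdicts

`extract_key_arrows` maps a study graph's arrows into indicators onto the
role grid {X, Y, Z} × {M_X, M_Y, M_Z} under an explicit role assignment
(roles are never inferred from node names; silent misclassification is worse
than an extra input).  Classification is exact-match for the two labels this
package vouches for — "J" (all nine key arrows) and "E" (exposure and
confounder arrows, no outcome arrows) — and `other:<signature>` otherwise,
annotated with the smallest catalogued superset.  "Simplest" is
operationalized as *fewest key arrows among catalogued labels containing the
extracted set*, with the disjunction rule (recoverable in any containing
catalogued graph ⇒ recoverable) as tie-break; this is an interpretation, the
source results do not define "simplest" formally.

The verdict table ships only the cells this package can support: (E,
regression coefficient) → recoverable with CRA consistent, and (J,
regression coefficient) → not recoverable, delta adjustment required.  All
other cells — including every marginal-mean cell — return *undetermined*
with a pointer to the full published catalogue; inventing them would be
provenance laundering.  Non-recoverability never transfers downward through
nesting: a strict subgraph of J may coincide with a smaller canonical type
in which the estimand is recoverable.

CRA validity is additionally decided graph-specifically by the criterion
Y ⫫ {M₁,…,M_k} | X ∪ covariates: complete-record selection that carries no
information about the outcome given the regressors leaves the regression
consistent.  Conditioning is on the regressors only — matching the model a
CRA actually fits — not on auxiliaries.  The criterion is sufficient on its
own, so a graph that is undetermined in the catalogue but satisfies it is
reported recoverable via the CRA route.  Whether the criterion extends to
marginal means is not established; marginal means route through the
catalogue only.

## Synthetic data generator

The generator realizes an m-DAG's arrows as quantitative mechanisms and can
never introduce a dependence the graph lacks: every equation must name
exactly the node's graph parents (zero coefficients allowed).  Substantive
and latent nodes are linear-Gaussian or Bernoulli-logistic, generated in
lexicographic topological order from a single seeded stream; indicators are
drawn independently per record with logit-linear probabilities in their
graph parents (no residual dependence among indicators, consistent with the
prohibition on indicator→indicator arrows).

The case-study emulation targets the structure of a cohort analysis of
maternal mental illness and child behaviour: n = 4882; binary exposure
(logit = −1.4 + 0.5C + 0.5Z, ≈20% exposed, 15% missing); outcome
10 + 0.6X + C + Z + ε, ε ~ N(0, 3.5²), clipped to the instrument's [0, 40]
range (23% missing); standard-gaussian confounder blocks with C→Z
coefficient 0.3 (19% of Z missing).  Design choices worth stating:

* **Clipping.**  The behaviour score is bounded but analysed by linear
  regression, so the outcome is near-gaussian with clipping touching <1% of
  draws.  The structural coefficient 0.6 therefore serves as the evaluation
  truth; at n = 50 000 × 300 replicates the full-data and complete-records
  estimators show bias ≤ 0.001 against it, an order of magnitude below every
  Monte Carlo tolerance used.
* **Mechanism scale.**  The outcome enters missingness mechanisms
  standardized: the "outcome-dependent" variant uses log-odds 1 per marginal
  SD of Y.  A per-unit log-odds of 1 on a variable with SD ≈ 3.9 would
  saturate the mechanism and make the stated marginal rates unreachable.
* **Calibration.**  Mechanism intercepts are found by Brent root-finding on
  the Monte Carlo average expit over a 200 000-row covariate sample, then
  verified by an actual indicator draw (tolerance ±0.5 percentage points).
  Calibration is deterministic given the calibration seed and idempotent to
  <0.05 on the intercept.
* **Mechanism variants.**  `outcome_independent` (X and Z drive all three
  indicators — canonical type E), `outcome_dependent` (adds Y to every
  mechanism — type J), and `confounder_only` (only the fully observed C
  drives missingness — no key arrows).  The last exists because under type E
  the exposure and confounders cause *their own* missingness, which tilts
  the observed-data imputation models away from the population conditionals;
  "correctly specified imputation models" is achievable only when
  missingness depends on fully observed quantities, so the MI-unbiasedness
  property is demonstrated under `confounder_only` while coverage under the
  literal type-E mechanism is verified separately (the self-masking
  perturbation there is far inside the interval noise at the sizes used).

A separate pattern-mixture design makes delta adjustment testable with a
closed-form truth: only Y is incomplete, P(M_Y = 1 | X) is p₀ = 0.15 /
p₁ = 0.35 by exposure group, and unobserved outcomes are shifted by a
constant d*; the full-data conditional mean stays exactly linear with
exposure coefficient β + d*(p₁ − p₀).

What the generator does **not** emulate: longitudinal structure, non-logistic
or dependent missingness mechanisms, within-block confounder structure, the
skewness of real behaviour-score distributions, and the actual cohort's
covariate joint distribution.  Passing tests demonstrate the estimators'
properties under the declared mechanisms, not fidelity to any real cohort.

## Estimators

* **CRA** — OLS on records with all analysis variables observed; model-based
  SE, normal 95% CI.  The dense least-squares kernel is cross-checked
  against statsmodels in the tests.
* **FCS / NARFCS** — chained equations with proper imputation: gaussian
  models draw σ² from its scaled inverse-χ² posterior and β from
  N(β̂, σ²(XᵀX)⁻¹) under the standard noninformative prior; binary models
  draw coefficients from the large-sample normal approximation to the
  logistic posterior and impute by Bernoulli draws (not predictive mean
  matching — the model stays explicit and testable).  Each of m chains is
  initialized by draws from the observed marginals and swept `n_cycles`
  times in column order.  The delta offset is added to gaussian imputed
  values for records whose indicator is 1; δ = 0 is bit-identical to
  standard FCS at a fixed seed, and deltas on binary variables are refused
  (a shift could mean log-odds or probability; we do not guess).  Defaults
  m = 20, 10 cycles — conventional and cheap at these sizes.  Imputed
  outcomes are not re-clipped to the instrument range; the imputation model
  is the declared gaussian.
* **Pooling** — Rubin's rules with total variance W + (1 + 1/m)B and the
  Barnard–Rubin small-sample degrees of freedom when the complete-data df is
  supplied; B = 0 or m = 1 falls back to the complete-data reference.
  Arithmetic saturates rather than overflows for microscopic B.
* **Failure policy** — singular designs and separation raise typed errors;
  the Monte Carlo harness counts and excludes failed replicates (resampling
  would bias error rates) and reports the count.

## Monte Carlo harness and probe

Replicate seeds derive from one master seed via `SeedSequence`; imputation
seeds are further offset so imputation noise is independent across
replicates.  Bias significance uses the conventional 3-Monte-Carlo-SE
threshold (configurable).  The recoverability probe runs CRA and standard MI
at two sample sizes (default 2 000 / 20 000) and declares
"recoverable-by-CRA" when CRA bias is compatible with zero at the larger
size, "not-recoverable-signal" when bias is significant and stable for both
CRA and MI at both sizes, and "inconclusive" otherwise — an explicitly
finite-n heuristic, labelled as such in its output.  The probe never
overrides a graphical verdict; disagreement is flagged.

## Problem sizes

Default verification sizes were chosen as the smallest that give decisive
margins: CRA bias at n = 10 000 × 200 replicates; MI coverage at n = 2 000 ×
200 replicates with m = 10, 5 cycles; delta recovery at n = 5 000 × 100
replicates with m = 20 and d* ≈ one outcome SD; oracle equivalence on all
≤4-node DAGs plus 1000 random 5–6-node DAGs.  The acceptance script uses the
same sizes.

## Known limitations

* Only the E and J catalogue cells are authoritative; other canonical types
  must be supplied by the user from the published catalogue.
* Recoverability with auxiliary variables that themselves cause missingness
  is outside the overarching assumptions and out of scope, as are
  do-calculus search, selection-model MNAR formulations, interactions and
  effect modification, and multilevel/longitudinal imputation.
* Delta elicitation is an input, never a computation; the planner refuses to
  run a delta-adjusted analysis without a user-supplied grid.
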