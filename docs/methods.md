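# Methods

## Setting and threat model

`ldptab` implements *local* differential privacy for per-record clinical
tables: the randomization is applied by the data owner, cell by cell,
before anything leaves the institution. For adjacent inputs `Y₁, Y₂` a
mechanism `κ` is `(ε, δ)`-differentially private when
`P[κ(Y₁) ∈ S] ≤ e^ε · P[κ(Y₂) ∈ S] + δ` for every output set `S`. The
package works with pure DP (`δ = 0`); `δ` is carried in `PrivacyBudget`
for completeness but changes no computation in this release.

The stated `ε` is **per attribute**. A record with `k` perturbed columns
enjoys, under basic composition, a record-level budget of `k·ε`; the CLI
prints this product on every run rather than silently rescaling, because
which composition accounting is appropriate depends on the adversary
model of the release.

## Normalization (schema module)

Continuous columns are affinely mapped from `[lower, upper]` onto
`[-1, 1]`; categorical columns with `m` labels are encoded onto the grid
`g_j = -1 + 2j/(m-1)`. Both maps are exact and exactly invertible, and
all noise is added on the normalized scale, so a single sensitivity
`ΔQ = 2` (the domain width) covers every column, including the
worst-case category swap.

Bounds default to the observed min/max of the supplied table;
`infer_schema` records them in a JSON schema document so that
institutions can instead agree on shared clinical reference ranges —
the synthetic generator does exactly that, emitting hard physiological
bounds (e.g. pH 6.8–7.8) that are stable across seeds. Records with any
missing value are dropped before fitting and perturbation (an explicit
`drop_missing` flag turns this into an error instead); imputation is out
of scope. Category label order is ascending (numeric, else
lexicographic) and is stored in the schema, making the grid encoding
reproducible.

## Bounded Laplace mechanism

Density, normalizing constant `C_q`, CDF and inverse CDF are closed
form (see the README for the formulas). The inverse CDF inverts each
branch of the piecewise CDF analytically; the round-trip error
`|F(F⁻¹(u)) − u|` is below 1e-9 across the unit interval, and draws can
never leave `[l, u]`. A center `q` outside the output domain is an
error, not a clamp: the mechanism is defined for in-domain inputs, and
silently clamping would hide a schema violation.

### Noise-scale modes

* **naive** (default): `b = ΔQ/ε`. With `ΔQ` equal to the domain width
  — the package default of `ΔQ = 2` on `[-1, 1]` — this choice is
  exactly tight: the worst-case density ratio
  `e^{|q₁−q₂|/b} · C_{q₂}/C_{q₁}` is maximized at the endpoint pair
  `(l, u)`, where the normalizing constants cancel, giving
  `ln sup = ΔQ/b = ε` exactly. (Sketch: `∂/∂q₂ [(q₂−l)/b + ln C_{q₂}]
  = 1/b + C′/C ≥ 0` because `C′/C ≥ −1/b` always, so the supremum over
  centers sits on the boundary.) The default also reproduces the
  characteristic binary misclassification of ≈0.49 at `ε = 0.1`.
* **calibrated**: solves `b = ΔQ / (ε − ln ΔC(b))`,
  `ΔC(b) = max_q C_q / min_q C_q`, by fixed-point iteration from the
  naive scale (tolerance 1e-10, ≤200 iterations; infeasibility raises
  with the minimum feasible `ε`). This is the standard sufficient
  condition for the bounded mechanism and is the right choice when
  `ΔQ < u − l`, where renormalization genuinely leaks privacy; on the
  default geometry it is conservative (e.g. `b = 24.95` instead of 20
  at `ε = 0.1`).

`privacy_loss_ratio` evaluates the worst-case ratio in closed form so
either choice can be audited on a grid of center pairs.

## Discretization (randomized rounding)

Perturbed categorical values are mapped to index space
`t = (y + C)(m−1)/(2C) ∈ [0, m−1]`, split into `k = ⌊t⌋` and
`p = t − k`, and released as `k + Bernoulli(p)`. Properties relied on
throughout:

* **closure** — the output is always one of the original `m` labels;
* **unbiasedness** — `E[output] = t` exactly (two-outcome enumeration);
* **identity at zero noise** — grid points map to integral `t`, `p = 0`.

The index space deliberately spans `m − 1` intervals between `m`
attainable integers; a span of `m` intervals would create an
unattainable extra output for binary variables. At the exact top of the
range `t = m−1`, `k = m−1` and `p = 0`, so no tie-break is ever needed.

Because the rounding is stochastic, a vanishingly noisy release still
flips a category with probability `≈ b(m−1)/(2C)` — about 0.001–0.005
at `ε = 10³` — so the misclassification rate converges to zero as
`ε → ∞` but is not exactly zero at finite `ε`. A nearest-grid decode
would be exactly zero there, at the cost of bias; unbiasedness was
chosen because it preserves category frequencies in expectation.
Nominal (unordered) categoricals pass through the same ordinal grid;
order-aware treatment of truly nominal variables (e.g. k-ary randomized
response) is a known limitation, not a goal.

## Fidelity metrics

MSE for continuous columns, misclassification rate for categorical
ones. MSE is reported on the original (denormalized) scale by default
so each column's error is in its own clinical units; a
`normalized_scale` option divides by the squared half-range for
cross-column comparability. `fidelity_sweep` perturbs the table once
per `ε` on the grid, deriving an independent seed substream per `ε`
from the base seed, so curves are reproducible but points are
uncorrelated.

## Utility experiment

Six families — decision tree, KNN, SVM (RBF), logistic regression,
Gaussian naive Bayes, random forest — predict the binary outcome from
original features and from features perturbed at each `ε` (the label is
never perturbed by default: the question is what the *features'*
perturbation costs). Protocol: stratified 80:20 train/test split;
5-fold stratified CV on the training 80 % (fold accuracies and mean
reported) plus accuracy on the held-out 20 % — both are surfaced since
published descriptions of this design are often ambiguous about whether
CV wraps or replaces the holdout. Split and folds depend only on the
seed and labels, so original and perturbed runs score identical rows.

Model settings (recorded in `FAMILY_SETTINGS`): scikit-learn defaults,
except `max_depth=5` for the single tree, `n_neighbors=15` for KNN, and
feature standardization in front of KNN/SVM/logistic regression. The
depth cap and wider neighborhood keep interpolating models from
memorizing pure noise — a fully grown tree fit on uninformative
features scores `p² + (1−p)² ≈ 0.64` on a 24 %-prevalence outcome,
an artifact of overfitting rather than a statement about privacy; the
regularized versions degrade to the majority-class rate (≈0.76), which
is the meaningful chance floor. Standardization is required for
distance- and margin-based models because the feature ranges span four
orders of magnitude (urine output vs pH).

## Synthetic clinical table

`gen_clinical_table` emulates an APACHE-style severity table: binary
intubation/ventilation/dialysis/medication flags, Glasgow coma
components with cardinalities eyes 4, motor 5, verbal 6, sixteen
continuous vitals/labs drawn from truncated normals inside hard
physiological ranges, and a mortality label targeting 24.1 % prevalence
at the reference cohort size n = 4740. (Published per-component GCS
ranges are inconsistent across sources — verbal and motor cardinalities
are sometimes swapped; the generator fixes eyes 4 / motor 5 / verbal 6.)

Mortality follows a logistic model on five schema-normalized severity
markers with fixed coefficients — heart rate +3.5, mean blood pressure
−4.0, creatinine +3.5, motor −4.5, FiO₂ +4.0 — and an intercept
calibrated on the drawn sample to hit the prevalence target (recorded,
with the coefficients, in the schema metadata). The coefficients are
deliberately strong (original-data accuracies 0.84–0.91) so the
privacy–utility curve has visible dynamic range between the chance
floor and the baseline; a weaker, more realistic signal would compress
the curve without changing the mechanism. The generator does **not**
model inter-variable correlation, missingness, measurement artifacts or
survival times — tests passing on it validate the perturbation
machinery and the qualitative shape of the tradeoff curves, not
clinical realism, and accuracy values on real ICU data will differ.

## Problem sizes and numerical choices

Monte-Carlo sizes were chosen so each check's sampling error is well
below its tolerance: 10⁵–10⁶ draws for support and tail-mass checks
(binomial SE ≤ 0.0016), 10⁴ per cardinality for the high-`ε`
misclassification, n = 4740 (the reference cohort size) for the utility
experiment, n = 1000–1200 for routine fixtures. Quadrature oracles
split the integration interval at the density's kink. Fixed-point
iteration and tolerance values are given above; all randomness flows
from `numpy.random.Generator` seeded per column/`ε` via `SeedSequence`
spawning, so every result in the test suite and acceptance script is
bit-reproducible from a single integer seed.
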