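# Methods

## Model

`lpfs` treats biomarker selection as an optimization over a nearest-centroid
classifier. Each class is summarized by its arithmetic-mean profile, and
samples are assigned by L1 distance — a deliberately simple prototype:
training is linear in features and samples, the decision rule is readable,
and the L1 metric is robust to the heavy-tailed single-bin outliers common
in NMR intensity data. The selection variable x ∈ {0,1}ⁿ masks features
inside the distance sums, so "feature subset S classifies sample l
correctly" is a *linear* condition on x: the per-coordinate gap
g_li = |s_li − μ_wrong,i| − |s_li − μ_right,i| must satisfy g_l·x > 0.
Minimizing Σxᵢ (parsimony) together with λ·Σy_l (slack on violated
constraints) scalarizes the two objectives; sweeping λ traces the Pareto
front between panel size and classification error.

Validation structure is built into the constraints rather than wrapped
around the solver. In the default leave-one-out form there is one
constraint per sample, with the held-out sample's own group centroid
recomputed over the remaining m−1 samples and the opposite centroid left
untouched. The resubstitution form (centroids on all samples) is kept for
comparison and is documented as optimistic: each validated sample also
shaped the prototypes it is scored against, so its optimum is provably no
harder than the leave-one-out optimum.

Assumptions worth stating: two classes, each reasonably summarized by a
single centroid (unimodal within group); features commensurable after
row normalization; at least two samples per group (leave-one-out needs one
survivor). Ties in the decision rule go to the control class with a logged
warning — the conservative choice for an effect-detection problem.

## Numerical formulation

* **Margin δ.** The exact model's strict inequalities cannot enter an LP,
  and without a margin x = 0, y = 0 is always feasible and optimal. Each
  constraint is therefore g_l·x + y_l ≥ δ with δ > 0. The margin is
  mandatory, not cosmetic.
* **Row normalization (default on).** Each gap row is divided by its mean
  absolute entry; a row that is identically zero is rejected with an error
  naming the sample. After normalization δ = 1 and the default λ grid
  (25 log-spaced points in [10⁻², 10³]) spans the empty-selection regime
  through the fully separable regime regardless of intensity units —
  multiplying all intensities by any c > 0 provably changes nothing.
* **Bounds.** x is relaxed to [0, 1] by default (the unit box around the
  binary model, keeping scores readable as fractional selections); an
  unbounded mode (x_upper = ∞) is available and is used for the raw
  worked-instance tests.
* **Solver.** `scipy.optimize.linprog` with HiGHS. Non-optimal
  terminations are surfaced in `solver_status`, never swallowed. Feature
  selection reads the strictly positive support of x with tolerance 1e−8;
  no magnitude cutoff is applied beyond numerical zero, because informative
  scores on normalized problems are legitimately small (∼10⁻³–10⁻¹).
  Internal accuracy counts y_l ≤ 1e−6·δ as correct (solver feasibility
  scale).
* **Exact oracle.** For n ≤ 20 the binary problem is solved by enumeration:
  for fixed x the optimal slacks are closed-form, y_l = max(0, δ − g_l·x),
  so each of the 2ⁿ assignments is scored directly (chunked matrix
  products). The LP optimum is verified to lower-bound the enumerated
  optimum, and integral LP solutions to share an optimal support.
* **λ choice.** Among grid points, maximize the *posthoc* leave-one-out
  accuracy of the selected panel — the selected set reused as a plain
  binary mask in the unweighted centroid classifier — with ties broken by
  fewest selected features, then smallest λ. The posthoc accuracy, not the
  LP's slack count, is the reportable accuracy; both are emitted.

## What the reported accuracy does and does not mean

The posthoc leave-one-out accuracy shares data with the selection step:
the LP saw all samples (each as a held-out constraint), so the accuracy of
the chosen panel on those same samples is an optimistic estimate — the
well-known selection bias of feature selection outside the
cross-validation loop. The package makes the consequence measurable: on
null data (no planted effects, 400 features, 20 samples) the λ scan *can*
assemble ~10 noise features that classify every fold, precisely because
400 free columns against 20 linear constraints are almost always
separable. The honest negative control therefore fixes λ on the treatment
run and applies it unchanged to the null run — the protocol mirrored from
control experiments in acupuncture-style designs, where the sham run is
analyzed with the same pipeline, not re-tuned. Under that protocol the
null selection essentially vanishes (mean ≈ 1 feature over seeds) and
permuted-label accuracy sits at chance. Findings on real data should
likewise be validated on held-out subjects or by the control-filter
mechanism in `evaluation`.

A second consequence of parsimony: the LP selects a *minimal cover* of the
validation constraints, not every informative feature. With several strong
markers, one or two of them often satisfy every leave-one-out constraint
alone, and the chosen panel is then a strict subset of the true marker set
(perfect precision, partial recall). Panels should be read as "sufficient
to discriminate", never as "all discriminating molecules"; the recall
trade-off is quantified in `scripts/acceptance.py` output.

## Synthetic data

The generator emulates the structure of a binned ¹H NMR plasma study: 400
bins at 0.01 ppm spacing, 10 subjects per group, per-feature baselines
b_i ~ U(0.5, 1.5) intensity units and noise σ_i ~ U(0.02, 0.1), planted
markers shifting the case mean by a stated multiple of that feature's own
σ_i (so effect sizes are exactly interpretable in sd units), and Gaussian
noise truncated at zero so raw-scale operations (fold change, constant-sum
normalization) stay valid. The baseline/noise defaults keep a 4σ shift far
from the truncation boundary. A lognormal mode adds heavier tails for
realism checks. It does **not** simulate NMR peak shapes, chemical-shift
correlation between bins of one metabolite, or between-batch drift —
passing tests on this generator demonstrate the optimization and its
calibration, not robustness to those real-data features.

## Preprocessing conventions

Pipeline order is exclusion → normalization → log → Pareto (exclusion
first, so solvent signal never contributes to the per-spectrum total; the
operations do not commute and a counterexample is tested). The ppm
exclusion window is closed at both ends — conservative for a solvent
region. Constant-sum total defaults to 1.0, making profiles read as
fractions. Log base 2 with pseudocount 0 by default. Pareto scaling
divides each centered column by the square root of its sd (ddof = 1
throughout — material at n = 10 per group); zero-variance columns map to
zero. The two-sample statistic follows the signal-to-noise form
(mean difference over pooled sd, no √(1/m₁+1/m₂) factor); p-values
computed from it treat the statistic as approximately t-distributed, which
is the convention it pairs with (cutoff 1.73 ↔ one-sided p ≈ 0.05 at
df = 18) but not an exact null distribution. SVM-RFE uses squared weights
of a linear SVM at C = 1.0, eliminating `step` features per round.

## Problem sizes

Tests and the acceptance script run at the design scale the generator
emulates (400 × 20 LPs solve in milliseconds; 20-seed sweeps in seconds)
and verify the oracle at n ≤ 8, where 2ⁿ enumeration is instant.

## Known limitations

Two classes only; single-centroid class geometry; no built-in multiple
-testing correction for the filter baselines (raw cutoffs, as is
conventional in this workflow); external methods (e.g. sparse multinomial
logistic regression tools) enter comparisons via their exported selection
CSVs rather than being reimplemented; the λ grid is a heuristic Pareto
sweep, not an exact parametric-LP path.
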