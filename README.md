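# lpfs — linear-programming feature selection for two-group omics profiles

`lpfs` finds small biomarker panels in high-dimensional two-group intensity
data — the archetype being binned ¹H NMR plasma profiles (hundreds of
chemical-shift bins, ~10 subjects per group), but any samples × features
table with case/control labels works. It is written for metabolomics and
proteomics analysts who need a *few* interpretable markers that support an
accurate classifier, not a long ranked list.

## The method

The classifier is the nearest-centroid rule under the L1 metric: a sample
**s** is assigned to the class whose mean profile **μ** minimizes
‖**s** − **μ**‖₁. Selecting features means choosing a 0/1 indicator vector
**x** over the n features; sample l (validated leave-one-out, with its own
group's centroid recomputed without it) is classified correctly exactly when

  g_l · x > 0, with g_li = |s_li − μ_F,i| − |s_li − μ_T,i|

for a case sample (sign flipped for a control). A slack y_l ≥ 0 per sample
tolerates errors, and parsimony and accuracy are scalarized with a
trade-off λ:

  min Σᵢ xᵢ + λ Σ_l y_l  s.t. g_l·x + y_l ≥ δ, 0 ≤ xᵢ ≤ 1, y_l ≥ 0.

The binary program is relaxed to a linear program (solved with HiGHS); the
optimal fractional xᵢ is the feature's *selection score*, and the strictly
positive support is the selected panel. A positive margin δ replaces the
exact model's strict inequality (otherwise x = 0, y = 0 is trivially
optimal); each constraint row is normalized by its mean absolute entry so
δ = 1 and one λ grid work at any intensity scale. λ is chosen by scanning a
log-spaced grid and keeping the value whose selected panel maximizes
ordinary (unweighted) leave-one-out nearest-centroid accuracy, ties going
to the smallest panel. An exhaustive enumerator over binary x — with the
closed-form optimal slacks y_l = max(0, δ − g_l·x) — provides the exact
optimum for small n and anchors the tests.

Also included: the standard comparison methods (two-sample t-statistic in
its signal-to-noise form (x̄ᵢ − ȳᵢ)/sᵢ with pooled sᵢ, raw fold change
x̄ᵢ′/ȳᵢ′, |log-FC| ranking, SVM-RFE), the binned-NMR preprocessing chain
(ppm-window exclusion, constant-sum normalization, log transform, Pareto
scaling), a seeded planted-biomarker generator, and venn/control-filter/
recovery reporting.

## Worked example

`python examples/01_select_biomarkers.py` generates a study-sized synthetic
dataset — 400 bins, 10 cases vs 10 controls, four markers shifted by four
noise standard deviations — and runs the λ scan:

```
lambda grid: 25 points in [0.01, 1000]
chosen lambda: 0.01
selected bins (score): bin203 (0.0468), bin187 (0.0255)
posthoc leave-one-out accuracy: 100%
planted bins: [187, 203, 301, 380]
precision 1.00, recall 0.50
```

Both selected bins are true planted markers and two of them already
classify every leave-one-out fold correctly, so the LP — which minimizes
the number of features — stops there rather than reporting all four. Small
fractional scores are normal: they only need to cover the margin, and their
ordering is the importance ranking. The other examples walk through
preprocessing (`02`), the baseline comparison with venn overlaps (`03`),
and a sham/null control run with control filtering (`04`). A thin CLI
(`lpfs simulate|preprocess|select|compare|filter-control|evaluate`) wraps
the same API for shell pipelines; every verb writes a JSON run report.

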