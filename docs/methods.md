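# Methods

This note records the statistical models `mirmeta` implements, the choices
made where the design was genuinely open, what the synthetic generators do
and do not emulate, and the numerical conventions.

## Differential screening

The screen is a deliberate simplification of count-model differential
expression: a two-sided Welch t on log2(x + c) per feature, with the log2
fold change computed on raw group means, log2((x̄_case + c)/(x̄_ctrl + c)).
The pseudocount c defaults to 1 (one read per million on the RPM scale),
avoiding log(0) without a variance-stabilizing transform. Retention requires
|log2FC| > 1 AND p < 0.05, both strict inequalities, so a feature sitting
exactly at a twofold change is excluded. BH q-values are always computed;
filtering on q instead of p is a switch (`use_fdr`) because raw-p screening
is the more common convention for this kind of multi-cohort triage, where
the subsequent intersection across cohorts is itself a stringent filter.
Zero-variance features are untestable and get p = 1 rather than an error, so
a screen never aborts on a degenerate feature.

SNR ranking uses sample SDs (ddof = 1) in (x̄₁ − x̄₂)/(s₁ + s₂). The
population-vs-sample SD convention only rescales the denominator by a
per-feature constant factor; since downstream stages consume ranks (top k
per direction), the choice does not affect selection for moderate n.
Zero-denominator features are reported with SNR 0 and flagged rather than
dropped, so the ranking length is stable. The bidirectional top-k cut is
applied before arm collapsing (the ranked lists are per-platform, where arms
are distinct probes); ties at the rank boundary are broken lexicographically
so the selection is deterministic.

Arm collapsing strips the case-insensitive suffixes `-5p`/`-3p` only at the
end of an identifier; interior matches are left alone. Venn region counts
are reported for up to four sets (15 regions); beyond that only per-set
sizes and the full intersection are returned.

## Clinical association

t and F statistics are computable from (n, mean, SD) summaries alone. The
two-sample t defaults to the pooled (equal-variance) form — the convention
under which the shipped case-study table reproduces its published
statistics — with Welch as an option. One-way ANOVA uses
SSB = Σ nᵢ(x̄ᵢ − x̄)² and SSW = Σ (nᵢ−1)sᵢ². Degenerate inputs follow a
"zero over zero is zero" rule: identical constant arms give t = 0, p = 1,
while zero variance with distinct means raises.

ROC AUC is the midrank Mann–Whitney estimator (exactly the tie-corrected
pair-counting probability), with the Hanley–McNeil standard error for the
95% CI, clipped to [0, 1]. Orientation is "higher score ⇒ case"; the
auto-orient flag reports max(AUC, 1 − AUC) for markers whose direction is
unknown a priori.

Survival comparison is Kaplan–Meier plus the two-group log-rank test with
the hypergeometric variance at tied risk sets. The hazard ratio is the
classical O/E estimate (O₁/E₁)/(O₂/E₂) with log-scale CI variance
1/E₁ + 1/E₂ — a Cox model is intentionally out of scope, as the package
targets the single-HR KM comparison reported in biomarker studies. A
`median_split` helper dichotomizes a continuous marker (quantile
configurable; the median is the default because published cut-points are
rarely stated).

## Continuous-outcome meta-analysis

Cohen's d with variance (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)) is the default
flavor: it exactly reproduces the case-study's published pooled values, so
it is what the original software computed. Hedges' g
(J = 1 − 3/(4N − 9)) is available. Pooling is inverse-variance with z-based
95% CIs (not t-based — again matching the reproduced CI widths).
Heterogeneity: Cochran's Q, I² = max(0, (Q − df)/Q), and the
DerSimonian–Laird moment estimator for τ²; REML is not implemented. The
model-selection rule — random effects iff p_Q < 0.1 or I² > 50%, both
strict — is exposed as its own function so reports can show the rule's
inputs. Subgroup pooling applies the rule independently per subgroup;
singleton subgroups pass their study's effect through.

Deeks's funnel-asymmetry test regresses lnDOR on 1/√ESS with weights ESS,
ESS = 4n₁n₂/(n₁+n₂), and tests the slope with k−2 df. Zero cells get a 0.5
continuity correction applied to all four cells of the affected study. When
the regressor or response has no spread (e.g. identical studies), the slope
is defined as 0 with p = 1 instead of a singular fit. Under a symmetric null
the ESS weights are approximately inverse-variance (var(lnDOR) ∝ 1/n), which
is why the t test is close to nominal; the test suite checks the type-I
error over 1000 simulated null meta-analyses of 10 studies each.

## Diagnostic-accuracy meta-analysis

Per-study logit sensitivity/specificity carry within-study variances
1/tp + 1/fn and 1/tn + 1/fp (post-correction). Pooled sensitivity and
specificity use DL random effects on each logit separately, back-transformed
through the inverse logit, so the CI is always inside (0, 1).

The SROC comes from a bivariate normal model on (logit sens, logit spec):
between-study means (μ_s, μ_p), SDs (σ_s, σ_p) and correlation ρ are
estimated by maximizing the marginal Gaussian likelihood with within-study
variances held fixed — a normal-approximation variant of the standard
bivariate approach, chosen over the exact binomial-normal likelihood for
simplicity at desk scale. The optimizer is Nelder–Mead from a moment start
(marginal variances minus mean within-study variance, floored); σ's are kept
positive through a log parameterization and |ρ| ≤ 0.999 through a tanh map,
and the optimum can never be worse than the start. The SROC curve is the
regression of logit sens on logit FPR implied by the fit — slope
−ρσ_s/σ_p through (−μ_p, μ_s) — evaluated on a uniform FPR grid (default
512 points, stable to 1e−3 against 8× refinement), clipped to the unit
square, with AUC by the trapezoid rule. A degenerate σ_p ≈ 0 yields a
vertical-line ROC handled as a step at the summary FPR.

Known limitation: with few studies (k ≲ 15) the between-study correlation is
weakly identified and the estimate often sits at the ±0.999 boundary, which
can distort the SROC slope; parameter recovery is reliable in the regime the
tests exercise (k = 200, per-arm n in the hundreds). The
normal-approximation likelihood also carries a small downward bias in pooled
logits when per-study counts are small and accuracy is high (estimates
correlate with their weights); this is visible but immaterial at the tested
scale. The Moses–Littenberg regression SROC is a possible extension.

## Over-representation and networks

ORA is the hypergeometric upper tail P[X ≥ k] after intersecting both the
study set and each term with the user-supplied universe; the EASE variant
substitutes k − 1 (p = 1 for k ≤ 1). BH FDR is applied across all tested
terms; results sort by p then term name for determinism. Gene symbols are
normalized by uppercasing and whitespace stripping only — no alias
resolution. Vote counting keeps genes supported by ≥ `min_votes` of the
evidence sources (default 6 of up to 12, a literal reading of "more than
five"); the threshold is a parameter because consensus rules vary across
prediction databases. Hubs are nodes with degree ≥ 5 (unique neighbors;
duplicate edges and self-loops are dropped at graph construction).

## Synthetic data

The generators produce every input format the pipeline reads, with the
structure the analysis assumes:

- **Expression cohorts**: per-feature baseline log2 abundance uniform on
  [2, 10]; the first `n_de` features shifted by `lfc_true` log2 units in
  every non-control group; Gaussian log-scale noise (σ default 1.0, a
  realistic per-group spread for log2 expression); values exponentiated so
  the matrix is positive like RPM, with no pseudocount baked in. Paired
  designs add a shared per-subject intercept with within-pair correlation
  0.5 by default. A configurable fraction of names carries -5p/-3p suffixes
  to exercise arm collapsing.
- **Meta-analysis studies**: per-study true SMD from Normal(smd_true, τ²),
  then raw unit-SD normal arms of uniform-random sizes, summarized to
  (n, mean, SD). Default n per arm 20–80, typical of qPCR biomarker studies.
- **Diagnostic studies**: (logit sens, logit spec) from a bivariate normal,
  counts binomial. Calibration tests use k = 200 studies with per-arm n
  300–800 so that within-study noise does not dominate the between-study
  signal being recovered; the Deeks null calibration uses k = 10, n 20–200,
  σ = 0 (a symmetric funnel with no size-effect association).
- **Survival**: exponential event times with rate ratio `hr_true` for the
  group above the marker median, independent exponential censoring.
- **Evidence/network**: i.i.d. Bernoulli source memberships and
  Erdős–Rényi edges.

One integer seed drives all generators; each derives an independent stream
from (seed, stream-id), so outputs are bit-reproducible and adding a
generator does not shift the others.

What the generators do **not** emulate: library-size variation and count
overdispersion of real miRNA-seq, platform-specific microarray noise and
normalization artifacts, batch effects, correlated features (miRNA
clusters), non-proportional hazards, or biologically structured networks.
Passing tests therefore demonstrate that the statistical machinery is
correct under its own model assumptions, not that the pipeline is robust to
the messiness of real cohorts.

## Numerical conventions

- 95% intervals use the normal quantile 1.959963984540054.
- Sorts are stable (mergesort) with lexicographic tie-breaks wherever an
  ordering reaches the output, so all tables are deterministic.
- Validation failures raise a shared `ValidationError`; degenerate-but-
  well-defined inputs (identical arms, empty intersections, flat funnels)
  return defined values with warnings instead of raising.
- Problem sizes in the test-suite simulations (replicate counts, k, n) were
  chosen so each stochastic check is decisively inside its tolerance under
  the generator's own model; they are stated alongside each test.
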