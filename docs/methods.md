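# Methods

## The model and the cascade

The pipeline analyses read counts on a balanced factorial design: two pea
lines with contrasting frost tolerance (Champagne, tolerant; Térèse,
sensitive), two temperature regimes (a low-temperature acclimation
treatment LT and a control N), three sampling times T0 < T1 < T2, and two
biological replicates — 24 samples, 12 line × treatment × time
conditions. The scientific question is a decomposition: which expression
differences are constitutive between the lines (LR), which are a chilling
response common to both (TCR), and which are line-specific temperature
responses (TLSR) — the candidate correlates of freezing tolerance.

Counts for gene *g* in sample *s* are modelled as negative binomial with
mean μ_gs and variance μ_gs + α_g μ_gs², the standard RNA-seq
overdispersion parameterization. The stages are:

1. **Normalization.** Median-of-ratios size factors: each sample's factor
   is the median over zero-free genes of count ÷ per-gene geometric mean.
   Factors are not re-centred. When no zero-free gene exists (tiny
   fixtures), genes with zeros in ≤ 20% of samples are used with zeros
   excluded from their geometric means.
2. **Selection filters.** A gene is *testable* when nonzero in at least
   two samples (the minimal sufficiency condition for a two-group test);
   it passes the *low-count filter* when its summed normalized count over
   all 24 samples exceeds 48 — sums at exactly 48 are discarded. The
   threshold is read as a total (≈ 2 per sample) rather than per-sample;
   both it and all other thresholds are configuration keys.
3. **Contrast tests.** For each of the nine condition contrasts, the log2
   ratio of normalized group means is referred to its delta-method
   standard error: Var(ln q̂) = Σ_s (μ_s + α μ_s²)/(sf_s² n² q²), summed
   over the group's samples, and the Wald statistic uses a standard
   normal reference. Equal group means give statistic 0 and p = 1
   exactly; a gene with zero counts in both groups is untestable for that
   contrast (fold change 0, p = 1). p-values are Benjamini–Hochberg
   adjusted per contrast across genes (nine separate corrections), and a
   gene is a DEG when min over contrasts of the adjusted p is ≤ 0.02 —
   the boundary value is retained. An annotation filter then keeps genes
   whose best database hit has E ≤ 9 × 10⁻⁴ (boundary retained).
4. **ANOVA cascade.** On log2(normalized + 1) values, a fixed-effects
   line × treatment ANOVA is fitted per gene, pooling times and
   replicates as within-cell replication (n = 6 per cell). The partition
   uses the two BH-adjusted factor p-values at α = 0.05: line-only → LR,
   treatment-only → TCR, both → TLSR, neither → NS. This simultaneous
   rule reproduces the arithmetic of the serial subtract-and-retest
   procedure (total − LR feeds the treatment stage, and the remainder
   after TCR is TLSR plus NS) while making every decision auditable from
   one table. The interaction p-value is computed and reported; an
   optional switch additionally requires a significant interaction for
   TLSR, but by default it does not gate the label, because the
   line-specific set is defined by joint line and treatment variation
   rather than by the interaction term alone.
5. **Pattern clustering.** Genes are reduced to their 12 condition means
   (log2 + 1 pseudocount, consistent with the ANOVA stage), standardized
   per gene to zero mean and unit variance, and clustered by average
   linkage (UPGMA) on d = 1 − Pearson correlation. The tree is cut to a
   fixed k per set — 2, 2 and 4 for LR, TCR and TLSR — mirroring the
   known subset structure rather than a height cut. Cluster naming uses
   two signed summaries of the cluster mean profile: Δline = mean(Ch
   conditions) − mean(Te conditions) and Δ_LT = mean(LT at T1, T2) −
   LT at T0 averaged over lines. An exactly zero summary raises an error
   rather than assigning silently.
6. **Functional summary.** Per-subset counts and percentages of kinases,
   transcription factors (with the modal family; ties reported
   alphabetically) and genes carrying any of the three cold GO terms.
   Genes labelled as both kinase and TF count in both tallies, matching
   how independent annotation tools tally. Percentages are recomputed
   from counts at display time (one decimal for kinase/cold columns, two
   for TF, matching the mixed precisions such summaries conventionally
   print) and never cached. GO over-representation is the upper-tail
   hypergeometric probability P(X ≥ overlap) with BH adjustment across
   terms; the background defaults to the annotated DEG universe and is
   configurable, so results are comparable only within a fixed background
   choice.
7. **qPCR corroboration.** Unigene↔EST links come from 12-column tabular
   BLAST hits passing E ≤ 1e-25 AND alignment length ≥ 200 bp AND
   identity ≥ 95% (all boundaries inclusive); "coverage ≥ 200 pb" is
   interpreted as alignment length, the quantity the tabular format
   carries. RNA-seq times T0/T1/T2 pair with qPCR days T0/T6/T10.
   Agreement is the uncentered (cosine) correlation
   R = Σxy/√(Σx²Σy²) — deliberately not Pearson's centred form, which is
   available behind a switch for comparison.

## The synthetic generator

The generator emulates the study conditions: the canonical 24-sample
design and negative-binomial counts with mean
sf_s · base_mean · 2^η_gs. The planted log2 effect η has two components:
a line offset split symmetrically (+offset/2 to Ch, −offset/2 to Te, so
the grand mean and hence the low-count filter are archetype-neutral) and
an LT slope acting only on LT samples with times coded 0, 1, 2. Nine
archetypes cover the null, the two LR directions, the two TCR directions
and the four TLSR quadrants; TLSR archetypes are line-specific, with the
sensitive line's slope scaled by 0.5 so both lines move in the same
direction at different amplitudes — the pattern the TLSR subsets
describe.

Defaults: 1000 null genes plus 100 per non-null archetype, base mean 100
counts, dispersion α = 0.05, offset 1.5 log2 units, slope 1.0 log2 per
step, unit library factors, seed 42. These give stable error-rate
estimates in seconds on one CPU; the dispersion and depth are field-
plausible round numbers, not estimates from any particular dataset.
Annotation sidecars draw a best hit for 80% of genes with E-values
log-uniform across (1e-10, 1e-1) — straddling the 9e-4 threshold so the
annotation filter genuinely bites — plus TF/kinase family labels and
cold GO terms at realistic sparse rates. The qPCR table pairs true
LT-slope-derived log2 ratios with the same ratios plus Gaussian noise
(default sd 0.75 log2 units, a realistic cross-platform discordance).

What the generator does not emulate: sequence content, read-level error,
batch effects beyond library size, gene–gene correlation, dispersion
trends with expression, and partially annotated assemblies' biases.
Passing recovery tests therefore demonstrates that the cascade's decision
logic and clustering recover planted mean structure under NB noise — not
that any particular real dataset would yield the same gene lists.

## Numerical choices

- **Dispersion estimation.** Per-gene method of moments pooled across the
  12 design cells: with cell means m_c and within-cell variances s²_c,
  α̂ = Σ_c(s²_c − m_c)/Σ_c m_c², clipped below at 1e-8. The through-origin
  form stays valid when cell means differ (DE genes). Because this
  estimator has only ~12 degrees of freedom, it is shrunk halfway toward
  the across-gene mean (weight 0.5); without shrinkage, genes whose
  dispersion is underestimated by chance inflate the null rejection rate
  of the Wald test (measured ≈ 0.08 at nominal 0.05, vs ≈ 0.055 with
  shrinkage and ≈ 0.048 at the true dispersion). Empirical-Bayes
  machinery beyond this single shrinkage step is deliberately out of
  scope.
- **Degenerate ANOVA inputs.** A fully constant gene reports p = 1 for
  every factor; zero within-cell variance with a nonzero effect reports
  the machine-minimum p and an infinite F, flagged rather than NaN.
- **Clustering determinism.** Profiles are standardized before the
  correlation distance (making it affine-invariant by construction);
  cluster ids are renumbered by first-row occurrence so output is
  independent of internal linkage numbering. Tie configurations of equal
  merge distances are measure-zero for continuous data; the oracle tests
  use random profiles where minima are unique.
- **BH adjustment** uses the standard step-up with monotonicity
  enforcement (via statsmodels), validated against a literal step-up
  implementation.
- **Seeds.** Every stochastic component takes a seed; the pipeline
  derives stage seeds from one run seed by fixed small offsets, so a run
  is reproducible byte-for-byte.

## Problem sizes

Test and acceptance runs use the generator defaults (1800 genes) and a
2000-gene null-only configuration for calibration checks; these sizes
give Monte-Carlo error small enough for the stated tolerance bands while
keeping the full suite under a minute. The published stage counts (4981
DEGs → 2487 LR / 1403 TCR / 1091 TLSR; subset sizes 906–131) and
annotation tallies enter only as inputs to the summary arithmetic, whose
outputs (2494 remaining after the line stage, 5.52% TFs in the Ch-up
subset, 6.9% cold genes in TLSR c, 193/397/145 tally totals, …) are
recomputed by the package.

## Known limitations

- The Wald test's normal reference is slightly anticonservative at n = 2
  per group (null rejection ≈ 0.055 at nominal 0.05); the acceptance
  band accounts for this, and the ANOVA stage — which drives the final
  partition — is exactly calibrated.
- The cascade thresholds (ANOVA α, adjustment scope) are study
  conventions, not estimated quantities; changing them moves the
  LR/TCR/TLSR boundary.
- With fixed k per set, a degenerate set whose genes all share one
  pattern can yield two clusters with the same subset name; the
  assignment records both clusters and the duplication is visible in
  cluster ids.
- The uncentered R exceeds centred Pearson when both platforms' ratios
  share sign structure; comparisons across studies should state which
  form is used.
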