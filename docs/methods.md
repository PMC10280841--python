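# Methods

This note documents the models, statistical choices and simulation design
behind `dimorphnet`, in the spirit of the methods appendices that
accompany statistical genomics packages.

## Scope and data model

The pipeline consumes a genes × samples matrix of log2-scale abundances
(already normalized; e.g. log2 CPM or FPKM) and a per-sample metadata table
with sex (`F`/`M`), diagnosis (`control`/`AD`/`excluded`), four
ordinal/continuous severity traits (CDR, Braak stage, CERAD category,
plaque mean density), an APOE genotype label, and arbitrary technical
covariates. Samples with an excluded diagnosis (e.g. possible/probable
disease calls) are dropped before any case/control contrast. Gene sets
travel as GMT files with a declared background universe.

## Preprocessing

* **Abundance filter** — keep genes with value ≥ *v* in at least *k*
  samples; a fractional rule uses ⌈f·n⌉ so "at least 10% of samples" is
  never satisfied by fewer samples than the fraction implies.
* **Covariate correction** — per-gene ordinary-least-squares
  residualization on an intercept-plus-covariates design (categoricals
  one-hot expanded, reference level dropped; constant columns are absorbed
  by the intercept and skipped). Residuals are returned with the gene's
  grand mean re-added, so the output remains on the input scale, is
  orthogonal to the covariates to 1e-8, and the operation is idempotent.
  A mixed-effects formulation was deliberately not used: no random-effect
  structure is identifiable from the inputs this package accepts, and the
  fixed-effect residualization is deterministic and directly testable.
  Rank-deficient designs raise with the collinear columns named.
* **Stage groups** — fixed clinical cutoffs (see README). CERAD grouping
  is configuration-driven (an ordered list of category bins) because CERAD
  categories carry no universal numeric scale.

## Differential expression

Expression is already log2, so the log2 fold change is the difference of
group means, tested with the ordinary pooled-variance two-sample *t*
(df = n_A + n_B − 2) and a variance floor of 1e-8 for genes constant
within both groups (flagged). An empirical-Bayes moderated *t* was not
reimplemented: the downstream logic consumes only (log2FC, q) against
explicit thresholds, and the pooled *t* keeps every number reproducible
from first principles. BH adjustment delegates to
`statsmodels.multipletests(method="fdr_bh")` with NaN passthrough.
Signatures take *q* < 0.05 and FC > 1.2 symmetrically (up: FC > 1.2;
down: 1/FC > 1.2). The eight TCG stage contrasts are computed per sex;
a contrast with fewer than two samples in a group is skipped and logged.

## Trend tests

* **Jonckheere–Terpstra** — JT counts cross-group concordant pairs with
  ties worth 1/2. Exact mode enumerates all assignments of the pooled
  values to the observed group sizes (feasible to total n = 10; the
  (3,3,3) layout has 1,680 assignments) and returns the tail fraction.
  Normal mode uses E[JT] = (N² − Σn²)/4 with the standard tie-corrected
  variance and a 0.5 continuity correction; at group sizes (3,3,3) the
  one-sided approximation stays within 0.013 of exact over random data.
  Two-sided p doubles the smaller one-sided tail (capped at 1).
* **Spline trend** — OLS of expression on a smooth basis of the ordinal
  level: an orthogonalized quadratic polynomial when the axis has ≤ 4
  levels (richer bases are not identifiable there), otherwise a natural
  cubic basis with 3 df and knots at quantiles of the levels; the p-value
  is the F-test of the basis against intercept-only. Under a flat null the
  p distribution is uniform; a U-shaped response is caught by the spline
  while the rank test stays null, which is the reason both run.
* **Opposite-trend (DTG) rule** — a gene counts as opposite on an axis iff
  it is significant in *both* sexes (BH q < 0.05 on that axis across
  genes, linear **or** spline — configurable to either alone) with
  opposite nonzero linear directions. TDTA requires this in ≥ 2 clinical
  traits (not necessarily with the same direction pattern across traits);
  ADTA is the APOE-axis set. Joint two-sex significance makes the null
  rate conservative (measured 0 of 200 genes across 20 null cohorts).

## Planar networks and modules

All gene pairs are tested by Spearman correlation with the *t*
approximation and BH-filtered at q < 0.05 (Spearman rather than Pearson
for rank-robustness; switchable). Surviving edges are sorted by |ρ|
descending — ties broken lexicographically so runs are bit-reproducible —
and inserted greedily while the graph stays planar (combinatorial
planarity test each insertion, early stop at the 3(n−2) planar bound).
Networks are built per sex from case samples; the signed ρ is stored on
each edge and |ρ| is used for sorting, connectivity and MDC.

**Module detection.** Connected components of ≥ `min_size` (default 10)
seed the root's children; each module is then recursively split. Candidate
partitions come from Louvain modularity communities on the module's
induced planar subgraph across a resolution sweep (0.3–2.0). Raw
modularity cannot decide whether a split is real: the planar backbone of
even a perfectly homogeneous module is a sparse triangulation on which any
community algorithm scores far above zero, so a modularity-threshold rule
splits everything. Instead, candidate communities are agglomerated until
every remaining inter-community connection is weak — two communities merge
while the mean |weight| of the edges between them is ≥ 0.75× the mean
|weight| inside them, and undersized leftovers are absorbed into their
most attached neighbor. A split is accepted only if ≥ 2 children of
`min_size` survive with a final cut/within weight ratio < 0.75 (plus the
nominal modularity ≥ 0.001 guard). The logic this encodes: distinct
co-expression modules are held together only by weak spurious edges,
whereas splitting a single-factor module would cut edges as strong as the
ones it keeps. Every accepted level is recorded, giving a nested
multiscale hierarchy; the induced subgraph is built in sorted node order
because subgraph views iterate hash-ordered and would otherwise break
seeded determinism.

**Hubs.** Intramodular connectivity k(g) is the sum of |edge weight| to
adjacent co-members on the planar backbone; genes with
k > mean + 1 SD (sample SD) of their module are key network drivers
(KNDs), strict inequality.

## Module scoring

Module summaries are sign-aligned first principal components of the member
submatrix (eigengene convention; the sign is fixed against the members'
mean expression). Summaries are correlated with the four traits by
two-sided Spearman tests over all samples of the network's sex, and module
members are tested against the eight TCG signatures by one-sided Fisher
exact tests (hypergeometric upper tail) over the filtered gene universe.
The combined score S = Σ −log₁₀ max(p, 1e-300) over those 12 slots ranks
modules (descending, ties by id); the top 25% (⌈0.25·m⌉, configurable) are
"disease-associated". Cell-type assignment, when marker GMTs are supplied,
takes the argmax-FE marker set among BH-q < 0.05, FE > 1 grid cells.

## Modular differential connectivity

Module connectivity under a condition is the mean |Spearman ρ| over
unordered member pairs computed on that condition's samples — the full
correlation structure, not the sparse backbone, whose fixed edge budget
would make ratios degenerate for small modules. MDC is the ratio between
conditions; |log MDC| is the permutation statistic so gains and losses are
treated symmetrically. Two nulls are computed with add-one smoothing
((r + 1)/(n_perm + 1), default n_perm = 100): shuffled sample-to-condition
labels, and random equal-size gene sets from the shared universe. Each
null's per-module empirical p is BH-adjusted across modules; the final FDR
is the larger of the two, and calls (GOC/LOC) require it below α = 0.05.
The dual-null FDR is interpreted at module granularity.

## Driver candidates and the 0–1 score

Candidates are KNDs of disease-associated modules passing ≥ 1 of the three
criteria (README). The evidence vector per candidate is its module's four
trait-correlation p-values plus the Fisher-exact p of each of the three
DEG signatures (within-sex case/control ×2, female-case vs male-case)
against the candidate's L-layer neighborhood (default L = 3, candidate
excluded; "neighbors of the 3-layer neighbors" admits L = 3 or 4 — L is a
parameter and the validation path sweeps {2, 3, 4}). The score is the
ascending rank of S = Σ −log₁₀ p divided by the candidate count, ties
broken lexicographically on the gene id: scores are exactly
{1/n, …, 1} with the strongest candidate at 1.0. An alternative
(rank−1)/(n−1) normalization would anchor the weakest at 0; the rank/n
form was chosen so a lone candidate scores 1 rather than being undefined.
External perturbation-target sets (GMT; up/down unioned) are validated by
the same neighborhood enrichment per L with BH across the tested L values.

## The synthetic cohort generator

The generator emulates the statistical skeleton of a two-sex case/control
brain RNA-seq cohort directly on the log2 scale — per-gene baselines
Uniform(2, 8), module factor model x = λ·a + ε with λ ~ |N(1, 0.2)| and
noise SD 0.5, latent module activities shifted in cases by per-module,
per-sex amounts — plus ordinal traits discretized from a noisy severity
latent (controls N(0,1), cases N(2.5,1), trait noise SD 0.3) at empirical
quantiles so no stage group is empty, balanced sex × diagnosis × genotype
cells, e4 dosage 0/0/1 over ε23/ε33/ε34 (optional ε44 = 2), two injected
numeric covariates with global coefficients (0.7, −0.4), and planted
drivers that receive their module's largest loading along with their own
case-by-sex shifts and sex-opposite dosage slopes. Background genes are
unit-variance noise. An optional Poisson count emission
(`counts_from_log2`) exists solely to exercise the abundance filter; no
read-level realism (GC, length, library-size effects) is attempted.

Effect magnitudes are package choices, made once for detectability at the
default cohort size (240 samples): module disease shifts up to 2.0 log2
units, a driver DE shift of 3.0 and dosage slopes of 1.2–1.5. Real
cohorts have weaker effects, more confounding and unbalanced cells, so
passing recovery tests demonstrates the *correctness of the machinery*
— each stage recovers what was planted and stays silent on nulls — not
field performance on human data. The "matched male null twin" used in
driver-recovery checks is an equally loaded hub of a second, equally
disease-associated module: a same-module twin would compete with the
driver for the same planar edge budget, which tests PMFG geometry rather
than the selection logic.

## Numerical and reproducibility choices

* One integer seed drives everything (numpy `default_rng`); community
  sweeps and permutation nulls take explicit seeds; reports serialize with
  sorted keys so identical runs are byte-identical (tested).
* p-floor 1e-300 before logs; variance floor 1e-8 in the pooled *t*;
  constant genes are dropped from edge testing (logged); a constant trait
  correlates as (ρ = 0, p = 1) by convention.
* Tie-breaking is lexicographic on gene/module ids wherever an order
  matters.
* Test-bench problem sizes (cohorts of 80–240 samples, 60–200 genes,
  n_perm = 100, 10–20 replicate seeds) were chosen so each stage's
  recovery and null behavior is measurable with comfortable margins.

## Known limitations

* The pooled *t* loses the shrinkage benefits of moderated statistics for
  very small groups; a moderation hook would slot into
  `differential_expression` without touching downstream code.
* The module-splitting separation ratio (0.75) is calibrated for
  factor-model modules with weak spurious inter-module edges; strongly
  nested correlation structure (sub-modules inside modules) merges back
  into its parent unless the sub-structure's cut is genuinely weak.
* MDC compares two fixed sample sets; paired or covariate-adjusted
  differential connectivity is out of scope.
* The CERAD "definite vs possible" contrast sits uneasily with excluding
  possible/probable-diagnosis samples from case/control work: in a real
  cohort those exclusions can empty the "possible" CERAD group, in which
  case the contrast is skipped and logged. In the synthetic cohorts CERAD
  is a severity discretization over retained samples, so all four
  categories exist and the contrast always computes.
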