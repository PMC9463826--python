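# Methods

## The generative model behind the simulator

The simulator emulates low-coverage whole-genome sequencing of plasma cfDNA
reduced to aligned fragment intervals. One toy chromosome carries `n_genes`
TSSs at jittered multiples of `spacing` (≥ 4000 bp, so ±1000 bp promoter
windows are always disjoint — a deliberate property that makes per-gene
counting unambiguous; real genomes have overlapping promoters, which this
artifact excludes by construction).

Per sample, the fragment count is Poisson with mean
`depth × chrom_length / fragment_length_mean`, so expected sequenced bases
before depletion ≈ `depth × chrom_length`. Fragment midpoints are uniform on
the chromosome; a midpoint falling in gene *g*'s promoter window survives
with probability `1 − d_g`, where the depletion fraction `d_g ∈ [0, 1]`
models nucleosome loss at active promoters (active promoter ⇒ fewer
nucleosome-protected fragments ⇒ lower coverage). Thinning means realized
total bases fall slightly below `depth × chrom_length` when depletion is
nonzero; at the defaults (windows = 40 % of the genome, base depletion 0.2)
the deficit is ~8 %. Fragment lengths are normal(167, 10) bp floored at
50 bp (the floor is ~12 σ from the mean and never binds); fragments sticking
out past a chromosome end are shifted, not truncated, preserving length.

Case/control cohorts share one genome and one planted-promoter set. Cases
get `d_g = base_depletion + effect` at planted genes; everything else (and
all of controls) gets `base_depletion`. Defaults: `base_depletion = 0.2`,
`effect = (1 − base)/3 ≈ 0.267`, chosen so the expected *midpoint* density
ratio control:case at planted promoters is exactly 1.5; because counting is
any-overlap, undepleted edge fragments dilute the realized expected
window-count ratio to ~1.43. `depth = 0.3`, `n = 47 + 47`, and gestational
week (uniform integer 12–27) and fetal sex (fair coin) are attached as
matching covariates. Everything is a pure function of its seed.

What the simulator does **not** model: sequence content and alignment error,
PCR duplicates, GC bias, fragment-length differences between fetal and
maternal DNA, fetal fraction as a separate quantity (group effect sizes
absorb it), overdispersion beyond Poisson, or correlated promoters. Passing
tests therefore demonstrate the pipeline's statistical machinery under a
clean thinned-Poisson law, not performance on real plasma.

## Coverage and normalization

A fragment counts in a promoter window iff the two 0-based half-open
intervals share ≥ 1 bp (any-overlap; a fragment ending where a window starts
does not count). Windows must be disjoint per chromosome, so each fragment
contributes at most once per window; the counting routine is two sorted
searches per window and is checked exactly against a quadratic brute force.
`total_mapped` is the genome-wide fragment count, not the in-window sum.

Normalized coverage is `count / (total_mapped × 2000)` — fragments per
(mapped fragment × bp), kept on its raw ~1e-8 scale with no rescaling so the
stored values match the formula bit for bit. Genes whose window would cross
a chromosome edge are dropped, never clipped, keeping the 2000 bp
denominator constant for every gene. The "primary TSS" of a multi-transcript
gene is the 5′-most TSS in gene orientation, ties broken by transcript id;
windows are ±1000 bp in genomic coordinates regardless of strand (the
depletion being modeled is symmetric about the TSS).

## Discovery

Per gene, a two-sided Wilcoxon rank-sum test on normalized values (exact
permutation null when n₁+n₂ ≤ 12 and tie-free, else the tie-corrected normal
approximation with continuity correction — at the design size of 47+47 the
test is always in the asymptotic regime), Benjamini–Hochberg adjustment
across all tested genes, and a symmetrized fold change of group means
`max(r, 1/r)`, `r = mean_case/mean_control`. Significance requires fold
change ≥ 1.3 **and** FDR ≤ 0.05, both thresholds inclusive and
configurable. Genes with all-zero coverage are excluded before testing (no
rank information); a zero control mean with nonzero case mean yields an
infinite fold change rather than an error.

## Training

Features are the selected genes' normalized values, z-scored per gene with
training moments (re-estimated inside each LOOCV fold — without this, SVM on
1e-8-scale features is numerically degenerate, and with it estimated outside
the fold, the holdout would leak). Models: linear-kernel SVM (C = 1, scores
= signed margin, native cutoff 0) and unpenalized logistic regression
(lbfgs; if separation prevents convergence the fit falls back to a weak
ridge, C = 1000; scores = probability, native cutoff 0.5).

Forward stepwise search over the discovery-stage significant set greedily
adds the candidate maximizing LOOCV AUC, stopping at `max_genes` (default
12) or when the best addition improves AUC by ≤ 1e-4 (floating-point
guard); ties break in candidate order (the discovery sort), making the
search deterministic. LOOCV AUC is the selection objective because AUC is
also the evaluation metric; resubstitution AUC is available as an
alternative objective flag for comparison. The model type with the larger
training LOOCV AUC is the operating classifier; an exact tie goes to the
SVM.

AUC is the Mann–Whitney probability (ties half-credit). Confidence
intervals use DeLong's structural-components variance with a normal
interval truncated to [0, 1] (verified against R pROC to 10 decimals); a
degenerate zero variance falls back to a seeded stratified bootstrap
(2000 resamples, percentile). Paired model comparison on the same samples
uses the correlated-curves DeLong z-test, two-sided.

## Validation and matching

The frozen classifier (training standardization + coefficients, serialized
as JSON + TSV) is applied unchanged to each validation cohort; the training
cohort is reported by LOOCV. The pooled "all" row concatenates per-sample
scores rather than averaging AUCs. Stratification by gestational week sends
a sample at exactly the cutoff (default 17.0) to the late stratum; the
convention is configurable.

Matching draws, for each case in seeded random order (preventing systematic
pool depletion against late cases), `ratio = 4` controls uniformly without
replacement from the pool with the same fetal sex and gestational week
within ±1.0 week (the resolution of the recorded covariate; configurable).
Cases with an insufficient pool are reported as unmatched with their pool
size, never silently dropped and never partially matched.

## Pipeline null path

When a simulation carries no group difference, discovery correctly returns
an empty significant set and stepwise selection has no candidates. So that
a null run still completes and reports calibration AUCs, the pipeline then
fits both models on a label-free fallback panel — the `max_genes`
highest-variance promoters, with **no** stepwise selection — and flags this
in the log and summary. Any label-driven fallback (e.g. top genes by
p-value) would bias the null AUC upward; variance ranking ignores labels
and keeps the null LOOCV AUC centered at 0.5.

## Problem sizes and known statistical limitations

The test suite and the acceptance script run the full analysis at the
study's operating point: 2000 genes on a 10 Mb toy chromosome, 0.3×
coverage, 47 cases vs 47 controls, 50 planted promoters at expected-count
ratio ~1.5 (the acceptance script averages 3 cohort seeds; the deeper
calibration tests use 10 null and 5 planted seeds).

Two consequences of this operating point are worth stating plainly:

* **Per-promoter discovery power is low.** 0.3× coverage puts ~3.2
  fragments in a depleted 2 kb window (Poisson means ≈ 2.2 vs 3.2 at ratio
  1.5 with n = 47+47), giving a per-gene Wilcoxon power of roughly 5–20 %
  at the BH-adjusted threshold across 2000 genes. The discovery stage
  therefore recovers only a small fraction of planted promoters at this
  depth/effect combination — while keeping its false-discovery proportion
  controlled — and the stepwise classifier works with the few promoters
  that do reach significance. Substantially higher recovery requires more
  depth, larger effects or larger cohorts, not a different algorithm.
* **LOOCV AUC is a noisy statistic at n = 94.** Its null sampling sd for a
  fitted multi-gene model is ~0.08–0.11, so individual null runs can land
  outside [0.40, 0.60] without indicating miscalibration; averages over
  seeds center tightly on 0.5. Similarly, the normal-theory DeLong interval
  shows mild undercoverage (~93 %) at 40 per class.

Other limitations: fragments (not reads) are the counting unit; no
mapping-quality, GC or fragment-length filtering; single-chromosome genome;
and the classifier is linear by design — nonlinear kernels and regularized
feature selection are out of scope.
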