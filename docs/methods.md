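# Methods

This note records the models and procedures `uevrna` implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Normalization

**CPM.** CPM = count / effective library size × 10⁶. With plain library
sizes each column sums to 10⁶ exactly (up to float tolerance). log2CPM =
log2(CPM + prior); the prior defaults to 1.0 on the CPM scale and is
configurable — the exact prior used to produce published log2CPM tables is
generally not recoverable from the tables themselves (zero-count entries in
the packaged `table2` print 1.4 ± 0, implying a prior/library-size
interaction we deliberately do not reverse-engineer).

**TMM.** Authored from the published definition. Reference sample: the one
whose 75th-percentile count fraction (type-7 quantile of count/library
size) is closest to the mean of those percentiles; ties break to the lower
sample index for determinism. For each other sample, M = log2 relative
abundance vs the reference and A = mean log2 abundance are computed over
features positive in both; the most extreme 30 % of M and 5 % of A are
trimmed two-sided using average ranks (R tie convention); the factor is
2^(weighted mean of surviving M), weights the inverse asymptotic (delta
method) variances (N−x)/(Nx) summed over the two samples. Factors are
rescaled to unit geometric mean (computed with `math.fsum` so sample order
cannot perturb the constant). Samples whose M-values are all below 1e−6 in
magnitude are exact scalar multiples of the reference and get factor 1
before rescaling, making the scalar-multiple case exact. All-zero samples
are rejected rather than dropped: on four-sample datasets silent sample
loss is worse than failure. The implementation agrees with edgeR's
`calcNormFactors(method="TMM")` to ~1e−12 in the cross-check test.

A note on scale invariance: multiplying one sample's counts by c leaves its
normalized CPM column *exactly* invariant under the unweighted trimmed
mean. The weighted default is only approximately invariant (deviations at
the 1e−3 level), because the inverse-variance weights intentionally depend
on sequencing depth — deeper libraries give more precise M-values. This is
a property of the published estimator, not an implementation artifact.

**Median of ratios.** Pseudo-reference = per-feature geometric mean across
samples over features positive in every sample; size factor = the *linear*
median of count/pseudo-reference ratios. (Taking the median in log space
instead differs whenever an even number of usable features averages the two
middle ratios; the linear form is this package's contract and what its
oracle tests pin.) To keep the CPM > 200 eligibility threshold meaningful
under either method, the effective library size under median-of-ratios is
size factor × mean library size, so CPM stays in per-million units.

Which scaling method a given dataset should use is a parameter (`tmm`,
`median_of_ratios`, `none`) rather than a baked-in choice.

## Detection, loss, and the discordance artifact

A feature is *detected* at (c, f) if at least ⌈f·n⌉-inclusive samples —
"at least", so exactly half qualifies at f = 0.5 — have raw count ≥ c.
Defaults: c = 1 or 5 for miRNA panels, 5 for mRNA, f = 0.5, all settable.
A feature is *lost* in condition A when its raw counts are zero in every A
sample while B observed it at least once — deliberately stronger than
failing the detection filter.

Percent differences between workflows are computed on linear normalized
counts as 100·(mean_A − mean_B)/mean_A with the reference workflow as
denominator; whether such ranges were historically computed on linear or
log2 scale is usually unstated, and linear is this package's documented
choice. Features with mean_A = 0 are undefined (NaN) and excluded from
range summaries.

**Raw-vs-normalized discordance.** The normalized change is the log2 ratio
of group-mean CPM (prior-guarded), not the difference of group means of
log2CPM. The distinction matters: with a common per-sample rescaling the
ordering of group-mean CPM always follows the ordering of group-mean raw
counts, so with method `none` and equal library sizes no feature can be
flagged at any positive thresholds — whereas means of logs can reorder by
Jensen's inequality alone, which would make "discordance" partly an
artifact of the transform rather than of normalization. A feature is
flagged when the normalized change favors one group by ≥ 1 log2 unit
(default) while its mean raw count is lower in that group by ≥ 2×
(default). Both thresholds are conservative defaults, configurable.

## miRNA identifier matching

Identifiers parse case-insensitively into (species prefix, stem, arm).
Numeric variant suffixes stay with the stem (`let-7f-1-3p` → stem
`let-7f-1`, arm 3p). Compound alternations (`miR-200 b/c-3p`) expand by
distributing the shared base and arm; family notations expand through a
packaged, editable table (`miR-30s` → miR-30a…e) because family membership
is biology, not syntax. Common typography in printed tables (`miR323b-5p`,
`628-5p`) is normalized during parsing rather than by editing the shipped
fixture text.

Stem-only identifiers support two policies. Under **precursor** (default
for list-vs-list intersection) a stem-only name denotes the immature miRNA
and matches only stem-level names — the convention stated in the curated
tables' own methods. Under **either-arm** (default for `ids_match` and for
searching count matrices) a stem-only name matches either mature arm,
appropriate when the quantified features are mature arms only. Arm-bearing
names always require equal arms; species prefixes are compared only when
both sides carry one. Matched identifiers are reported by the more specific
member of each pair and deduplicated under a canonical form (lowercase,
prefix-free, arm retained), so stem-only and arm-bearing forms remain
distinct outputs.

On the packaged tables the precursor-policy intersection yields 13
identifiers and the either-arm policy 19. The curated source material is
internally inconsistent about this count (its prose names 12 common
miRNAs, its own table bolds 13 — a different 13 — and one identifier
present verbatim in both tables appears in neither accounting), so the
package reports its computed counts and separately verifies that all 12
prose-named identifiers are contained in the computed intersection — which
they are, under both policies.

## Group separation

Heatmap preparation z-scores each feature row (sample SD, n−1); constant
rows pass through as zeros and are flagged. Clustering defaults are
Euclidean distance with complete linkage — the defaults of the standard
heatmap tooling this workflow mirrors — and row/column orders come from the
dendrogram leaf order. PCA operates on samples-as-rows of the selected
feature submatrix, centered and unscaled by default, via SVD.

Separation at a k = 2 cut is scored by cluster purity — the best fraction
of correctly assigned samples over one-to-one cluster↔group mappings,
found by Hungarian assignment on the contingency table — and the adjusted
Rand index. Bijective purity is invariant to relabeling either side. Note
that it is bounded below by the largest class frequency only for balanced
groups; for unbalanced labels the one-to-one constraint can push it lower,
which is the price of a score that cannot be gamed by merging clusters.
Purity is also upward-biased at small n (the exact null mean for 5+5
balanced samples is ≈ 0.64, approaching 0.5 as n grows), so the null
calibration test uses 15 + 15 samples, where the exact null mean is ≈ 0.56.

## Reference-gene stability search

Per dataset: genes with CPM strictly greater than 200 in *all* samples are
eligible (strict inequality at the boundary); CV = sample SD / mean of
linear CPM (CV on log2CPM would understate relative variability of highly
expressed genes; linear CPM is the scale on which the eligibility threshold
is defined); the k = 100 lowest-CV genes are selected, ties broken
lexicographically. Stages intersect per-dataset top-k lists; every
intermediate set is retained, and the final intersection is the candidate
reference-gene set. Genes absent from a dataset can never enter its top-k
(absence is not stability). Candidate evaluation reports CV per gene per
dataset even where eligibility failed (flagged), plus SD-of-CPM for
presentation ordering, and carries comparison genes (a conventional
reference such as GAPDH, a known high-CV gene such as UPK1A) with explicit
roles. Datasets that were normalized together in the original studies enter
the search pre-merged as a single dataset; the stage structure itself is
configuration, not code.

## Synthetic-data generator

Counts are negative binomial: count_gj ~ NB(mean = L_j·π_g·e_gj, Var =
μ + φ_g μ²). Defaults (all configurable): 2000 genes; baseline abundance
μ_g ~ LogNormal(location 3, scale 2) — heavy-tailed, as small-RNA libraries
are; dispersion φ_g ~ Gamma(2, 0.25); nominal library size L_j ~
LogNormal(ln 2·10⁶, 0.4), a typical depth for these libraries; 40 planted
stable genes with shared abundance LogNormal(7, 0.5) (comfortably above the
CPM > 200 eligibility threshold) and dispersion 0.02 everywhere; degraded
condition e = s·μ/(μ+K) with retention s = 0.1 and half-constant K = 500,
so low-abundance genes are suppressed quadratically while high-abundance
genes shrink toward 10 % retention; 18 workflow-attenuated features with
attenuation drawn from 3–58 %; 20 group-discriminating features with folds
drawn from 2–8×, half down-regulated. Determinism: one PCG64 generator per
dataset, seeded from the config (multi-dataset scenarios spawn independent
child streams from a master `SeedSequence` and share the planted stable
genes' identities and abundances).

**Degraded-condition ground truth.** Zeros are not planted; they emerge
from the count model, which makes "forced to zero" a matter of degree. The
truth therefore records two sets, fixed a priori from the Poisson bound
P(all zero) ≥ exp(−Σ expected): `forced_zero` — total expected degraded
count < 0.1 *and* total expected control count ≥ 8, i.e. genes that are
almost surely all-zero when degraded yet reliably observable in controls —
and the outer `suppressed` bound, per-sample expected count < 0.5. Recovery
is scored as recall of `forced_zero` by the loss analysis, with false
positives counted as lost-calls outside `suppressed`: a borderline gene
that genuinely sampled all zeros is not a false discovery.

**What the generator does not emulate:** sequencing-read-level effects
(no FASTQ, UMI, GC or length bias), fragment-level RNA degradation
chemistry, correlated gene modules, or compositional outliers beyond what
the log-normal tail produces. Passing recovery tests therefore show that
the pipeline's logic is correct under a reasonable count model at realistic
sample sizes — not that real uEV data meet that model.

## Degenerate inputs and numerical choices

All-zero samples: rejected everywhere with a named error. A sample sharing
no positive feature with the TMM reference: error naming the sample. No
feature positive in all samples: median-of-ratios error. Fewer eligible
genes than k: all returned with a warning. Candidate genes absent from a
dataset: flagged, never raised. Clustering ties follow SciPy's
deterministic agglomeration given input order; quantiles are type 7; ranks
average ties. Fixture files are UTF-8 TSV with the Unicode minus normalized
to ASCII during parsing.

## Known limitations

- The curated-table intersection count has no single defensible value (see
  the matching section); the package's computed values are 13 (precursor)
  and 19 (either-arm).
- Weighted TMM is not exactly scale-invariant (by design of the weights).
- The staged search treats top-k lists as sets; it does not model
  between-dataset correlation of CV estimates.
- No dispersion estimation or differential-expression testing: upstream DE
  labels are consumed as data, not recomputed.
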