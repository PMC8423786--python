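# Methods

This note documents the statistical procedures sigshare implements, the
conventions chosen where a procedure admits more than one reading, and
what the synthetic-data generator does and does not emulate.

## Normalization and QC

Raw input is a genes × cells matrix of read counts. Cell QC keeps cells
whose detected-gene count (genes with count > 0) lies inside an inclusive
band; presets reflect common Smart-seq2 nuclear/whole-cell choices
(3000–9000 for adult human adrenal gland, 2000–8000 for neuroblastoma and
mouse adrenal). Gene QC keeps genes expressed in strictly more than
`min_cells` cells (default 5). Normalization scales each cell to 10,000
total counts (CP10K); the log transform is natural log of (CP10K + 1).
Cells with zero total counts cannot be scaled and are dropped with a
warning. Marker tests run on a normalized matrix; the default transform
is log1p-CP10K, but externally standardized expression magnitudes are
accepted unchanged — the Welch machinery is transform-agnostic.

## Marker definitions A and B

For a cluster *c*:

* **A (upregulated)**: gene ∈ A iff mean(c) > mean(all other cells
  pooled) and the BH-adjusted two-sided Welch *p* < 0.01. The BH family
  is all genes tested for that cluster.
* **B (specific signature)**: gene ∈ B iff, for every other cluster *k*,
  mean(c) > mean(k) and the BH-adjusted pairwise Welch *p* < 0.01.

The multiplicity family for B is genuinely open — correction could span
genes, cluster pairs, or both. The default applies BH across all genes
*within each pairwise comparison* and then requires significance in every
comparison, mirroring the per-comparison testing language; a pooled
global family is available (`bh_family="global"`) and can only be more
conservative. B is not constrained to be a subset of A: the two
definitions use different test families.

Welch degenerate cases follow a deterministic convention instead of
propagating NaN: both groups constant with equal means → statistic 0,
p = 1; constant with different means → p = 0. Exact ties in means fail
the strict "higher" requirement.

## Signature sharing and external enrichment

Sharing between two clusterings is an all-pairs one-sided Fisher exact
test on the 2×2 table (in/out of query) × (in/out of reference) over an
explicit universe. The universe is the caller's choice; the natural
default for cross-dataset runs — used by the CLI example and acceptance
path — is the intersection of genes testable in both datasets after
ortholog restriction, since that is the only space both signatures are
drawn from. Pairs sharing fewer than 10 genes are reported with their raw
statistics but flagged and excluded from the BH family and from
significance calls. Tiers: significant (FDR < 0.01), marginal
(FDR in [0.01, 0.05)), ns, excluded. Cross-species comparisons first map
signatures through the 1:1 ortholog subset — a pair survives only if both
genes have mapping degree exactly 1 — dropping everything else and
reporting what was dropped.

## Per-cell signature score

score(cell) = mean over reference genes of (CP10K + 1) − mean over *n*
background genes of (CP10K + 1), with *n* = max(#reference, 50). The
score uses linear CP10K (log transforms are for display only). The
background is drawn once per scoring call, uniformly without replacement
from non-reference genes, from a seeded generator; an expression-binned
draw (background matched to the reference's mean-expression deciles) is
available behind `scheme="binned"` but uniform is the default since
nothing more specific than "randomly selected" is assumed. The score is
invariant to adding a constant to all of a cell's values, and a random
reference set scores ≈ 0 on average.

## Composition tests and deconvolution expectations

Cluster-vs-group composition uses one 2×2 Yates-corrected chi-square per
(cluster, group) pair — {in cluster, not} × {in group, not} — with BH
over all pairs at FDR 0.01 and an over/under direction from observed vs
expected counts. A single R×C variant exists but is not the default. The
deconvolution stand-in is plain non-negative least squares on cluster
mean profiles with proportions renormalized to the simplex; it is
deliberately a generic decomposition, and externally produced proportion
tables can be fed directly into the expectation step. Expected cells per
cluster and risk group are c × mean predicted percentage with
c = (average nuclei per single-nucleus sample in the group) × (number of
bulk samples in the group); group-wise differences in the expected
composition are tested per (cluster, group) against the other groups with
BH-corrected Yates chi-squares on the rounded expected counts.

## CNV clonal enrichment

Segments carry six state probabilities (1 complete loss … 3 neutral … 6
gain of >2 copies). The rearrangement likelihood of a segment is the
summed probability of the five non-neutral states; segments are kept when
the neutral mass is ≤ 0.1 (rearrangement probability > 0.9). Per cell and
region, the mean most-likely state over overlapping kept segments (half-
open coordinate overlap) classifies the cell: gain (> 3), loss (< 3),
neutral (= 3), or no_data when no kept segment overlaps. The per-cell
average includes all overlapping kept segments regardless of direction;
a direction-restricted variant is available behind a flag. Enrichment is
per sample: for each (region, cluster), a one-sided Fisher test of
{call matches the region's expected direction} × {in cluster}, BH across
the sample's region × cluster tests, reported at FDR < 0.05. Neutral and
no_data cells both count as non-rearranged by default (conservative); a
flag excludes no_data cells instead.

## Survival association

The per-sample signature score is the mean of per-gene *z*-scores
(standardized across samples); constant genes are excluded, and
signatures with fewer than three usable genes are not scanned. The scan
evaluates a two-group log-rank test at every midpoint between consecutive
distinct sorted scores, subject to a minimum group size of
max(3, ⌈0.1 n⌉); samples scoring exactly at the cutpoint fall into the
low group, and ties in minimum *p* resolve to the smallest cutpoint. The
minimum over cutpoints is anti-conservative, so the reported adjusted *p*
is Bonferroni over (cutpoints tested) × (signatures tested in the
invocation); the raw minimum is always reported alongside. Under this
correction the null rate of adjusted *p* < 0.01 stays below 0.01, while a
hazard-ratio-3 signature at n = 200 is detected essentially always.

Per-gene screens: one-way ANOVA on log2(RPM + 1) between risk groups
(zero-variance genes get p = 1); Pearson correlation with age at
diagnosis, split into direct/inverse lists; and a per-gene cutpoint scan
whose minima are cutpoint-corrected before BH across genes, split into
worse/better-with-high-expression lists. All lists use FDR < 0.01.
Cluster signatures are then tested for enrichment in these labeled lists
with the same one-sided Fisher + BH machinery.

## Cluster dendrograms with bootstrap support

Cluster-average profiles (arithmetic per-gene means; caller-supplied
exclusion list for e.g. cortex/immune populations; cross-dataset runs
restrict to shared orthologs *before* averaging, since only shared genes
can be compared) are quantile-normalized: each column's sorted values are
replaced by the across-column means at each rank, with tie groups
receiving the mean of their tied positions. Euclidean distances feed a
Ward-2 agglomeration (Lance–Williams update on squared distances, merge
heights on the distance scale, deterministic lowest-index tie-breaking —
the reason this step is implemented directly rather than via a library
whose tie order is unspecified; it is verified against both a brute-force
objective recomputation and library heights).

Branch support is a multiscale bootstrap over genes: at each scale
r ∈ {0.5, 0.6, …, 1.4}, genes are resampled with replacement at sample
size round(r·n), the tree is rebuilt, and each observed branch's
occurrence is counted. BP is the unit-scale occurrence fraction (in %).
AU comes from a weighted least-squares fit of Φ⁻¹(1 − BP_r) against
(√r, 1/√r), evaluated as 1 − Φ(v − c); branches with BP 0 or 1 at every
scale keep their unit-scale BP. AU > 95 is reported as high support. The
default is 1000 replicates per scale; BP estimates are clipped away from
0/1 by half a replicate for the normal-quantile transform.

## Synthetic data: what it emulates, and what it does not

The generator draws counts from a gamma–Poisson (negative binomial)
mixture with var = μ + αμ², α = 0.1 by default, over log-normal baseline
means (log-mean 0, log-sd 1) — the standard overdispersion model for
read counts without UMIs. Defaults mirror the validation conditions used
throughout: 4 clusters × 100 cells × 2000 genes per dataset, 20 unique
markers per cluster at log2FC 2, one 30-gene signature shared between
cluster A1 of dataset 1 and B2 of dataset 2 at the same fold-change, a
5% fraction of 1:many ortholog entries among non-planted genes, a CNV
clone in cluster A1 (state 4 over chr17:25–83 Mb, penetrance 0.6), one
cluster 3× over-represented in "high"-group samples, and a 200-sample
bulk cohort with hazard ratio 3 per unit of latent signature activity
and age correlation 0.5. Risk groups are tertiles of the per-sample
signature average, which intentionally couples composition structure to
outcome. Bulk expression is RPM-like (log2 RPM = 5 + activity + noise).
Survival times are exponential with administrative censoring at 3000
days around a 1200-day baseline median.

All randomness flows through a single seeded generator per operation
(offsets +1 and +2 separate the CNV and bulk streams from the expression
stream), and the truth manifest records every planted quantity, so
recovery can be scored without re-deriving anything.

Not emulated: gene-length and GC biases, dropout curves beyond NB
dispersion, doublets, batch effects, correlated gene modules outside the
planted signatures, subclonal CNV hierarchies, or competing risks in the
survival draw. Passing recovery tests therefore demonstrates that the
statistical machinery detects the structure it is designed for at
realistic effect sizes — not that it is robust to every artifact of real
Smart-seq2 or bulk data.

## Problem sizes used in validation

The acceptance script and test suite run the study conditions above
directly: signature recovery on the full 4 × 100 × 2000 paired bundle;
CNV clone recovery over 50 seeds with 100 clone-cluster cells; scan power
over 100 hazard-ratio-3 cohorts and null calibration over 200
hazard-ratio-1 cohorts of n = 200 (with an 80-gene bulk universe, since
the scan consumes only the signature's scores); and dendrogram support
with 1000 replicates per scale on a 200-gene, 6-cluster profile matrix
with a planted deep split.
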