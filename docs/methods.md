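# Methods

`methconcord` implements a case-control analysis of genome-wide DNA
methylation and gene expression measured on several cell types derived from
the same subjects (induced pluripotent stem cells, olfactory
neurosphere-derived cells, fibroblasts, with an embryonic stem cell line as a
QC comparator). This note records the statistical model, the conventions and
numerical choices the implementation commits to, and what the synthetic-data
generator does and does not emulate.

## Measurement scales

A probe's methylation fraction is the beta value, β = M_int / (M_int +
U_int) ∈ [0, 1], where M_int and U_int are methylated and unmethylated
intensities. Beta is intuitive but heteroscedastic near its boundaries, so
every statistical comparison runs on the M-value, M = log2(β / (1 − β)).
Betas are clipped to [ε, 1 − ε] before the transform; ε defaults to 1e-3
(configurable), chosen so that fully (un)methylated probes map to M ≈ ∓9.97
rather than ±∞ while leaving the (0.001, 0.999) interior untouched. The
inverse transform is exact on the clipped range to 1e-12. For descriptive
state calls, betas are binned hypermethylated (β ≥ 0.70), hypomethylated
(β ≤ 0.30) or mid-methylated (between); boundary values belong to the
extreme bins.

Expression fluorescence is background-floored (floor 1.0; optional
per-sample quantile offset subtraction, off by default), quantile-normalized
to the mean of the sorted sample columns, and log2-transformed. Quantile
normalization is definitional: after it, every sample has the same sorted
value vector.

## QC

Technical replicates are consecutive culture passages of the same line;
their pairwise Pearson r² is reported per (subject, clone, cell type) group
with a mean/min/max summary (the generator's defaults put the mean near
0.99). PCA runs on probe-centered M-values of all detected probes (a probe
is "detected" when its detection p-value is < 0.01 in at least one sample;
without a detection matrix all probes count). Outlier samples are flagged —
never auto-removed — when their Euclidean distance over per-component
robust z-scores (median/MAD, 1.4826 consistency factor) on the first two
components exceeds `k_sd` (default 4). The rule is deliberately simple; the
choice of the first two components and of k_sd = 4 is a design decision, and
removal is an explicit configuration flag.

## Differential testing

Each contrast is a per-probe two-group comparison. Technical replicates are
averaged into one column per biological unit before fitting (the default
policy; a "block" pass-through is exposed for callers who want to model the
replicate structure themselves). iPS clones of a subject remain separate
biological replicates. Per probe: effect = mean(group1) − mean(group2), s²
the pooled within-group variance with df = n1 + n2 − 2.

Variances are moderated empirically: s² is modeled as scaled-inverse-χ²
about a prior (d0, s0²) fitted by moment matching on log variances (mean and
excess variance of log s² relative to χ² sampling noise, inverting the
trigamma function by Newton iteration). The posterior variance is the
precision-weighted blend (d0·s0² + df·s²)/(d0 + df), and the moderated t is
referred to a t distribution with df + d0 degrees of freedom. Degenerate
cases: d0 = 0 recovers the ordinary pooled t exactly (tested to 1e-8);
literally identical variances pass through unchanged; variance spread within
sampling noise pools fully at the bias-corrected log-scale mean (the
uncorrected geometric mean of χ²-noisy variances underestimates s0² by
≈ 16% at df = 6 and visibly inflates the false-discovery proportion). A test
cross-checks the whole moderation path against Bioconductor limma's
lmFit/eBayes on a heteroscedastic fixture and agrees to ~1e-10.

P-values are two-sided; multiplicity is controlled by Benjamini–Hochberg
(step-up, q clipped at 1, monotone). Defaults: q < 1e-4 for cell-type
contrasts (run pairwise, union of significant probes), q < 0.05 for
patient-control contrasts. A probe with zero effect and zero variance is
reported as t = 0, p = 1 (no evidence, rather than 0/0).

## Cross-cell-type overlap test

The k lists of differential loci are intersected requiring a consistent
direction (a locus hypo in one list and hyper in another is excluded). The
null asks how often k unlabeled lists of the observed sizes, drawn uniformly
without replacement from the assayed pool, would share at least the observed
number of loci. The empirical p is the plain proportion #{sim ≥ observed}/
n_sims — "at least", not "more than" — with a conservative (r+1)/(n+1)
estimator behind a flag. Defaults: 10,000 simulations, pool = 27,578 probes.

Sampling: the default sampler draws the running intersection by sequential
hypergeometric conditioning (the intersection after adding list i is
hypergeometric given the intersection so far), which is distributionally
identical to materializing the k lists and orders of magnitude faster; the
explicit-draw sampler is retained and the two are cross-tested within
Monte-Carlo error. A Poisson cross-check uses λ = pool·∏(size_i/pool)
(exact expectation by linearity; the tail is approximate for sizes ≪ pool —
error ≈ 0.005 absolute already at two singleton lists from a pool of 10, far
smaller at survey scale).

## Enrichment statistics

Over-representation is the right-tailed Fisher/hypergeometric test of a
query gene list against each gene set, both intersected with the assayed
universe, BH-corrected across sets; gene symbols match case-insensitively
everywhere. The activation z-score for a set is Σ(signs)/√N over member
genes, sign +1 when a gene's observed direction matches the activating
direction; |z| ≥ 2 is called Increased/Decreased. Unit weights are used
throughout (literature-curated edge weights are not available to an open
pipeline).

The seed PPI network is the induced subgraph on seed genes present in the
interactome plus their first-degree neighbors (absent seeds logged; isolated
seeds retained). Enrichment of a query list in the network uses the binomial
Z statistic

    Z = (O − E) / sqrt((N − 1) p q)

with p = |network| / universe, q = 1 − p, O the observed query genes inside
the network, and E = |query|·p. The (N − 1) factor is reproduced exactly as
stated even though √(n·p·q) is the textbook form. N is deliberately
configurable because the statistic's symbol binding is ambiguous: the
default binds N to the universe size; the alternate binds N to the query
size, which makes Z the standard one-sample proportion z-test (and under
which E = N·p coincides with |query|·p). Under the query binding the normal
tail tracks the exact binomial tail within 0.03 absolute at survey scale
(universe 20,000, query 500, p = 0.1), tightening in the tail; the band is
the usual continuity-correction-sized discrepancy near the center.
Significance is one-tailed normal with critical Z = 1.65 (P < 0.05). The
tail is computed via the complementary error function and is exact down to
~1e-300 (|Z| ≈ 37, the double-precision underflow point).

## Concordance network

Differentially methylated (DM) and differentially expressed (DE) genes are
mapped onto a user-supplied interactome. Edges between two DE genes are kept
outright; a DM–DE edge is kept only when concordant with a repressive
promoter-methylation reading — hypomethylation with up-regulation
(activation) or hypermethylation with down-regulation (inhibition). DM–DM
edges carry no expression evidence to test and are kept with their own
label. Every candidate edge is retained with a kept/rejected annotation and
reason, so the filter is auditable, idempotent and order-independent. A gene
that is both DM and DE acts as DE for classification. Node magnitude is
|effect| (for symbol sizing in downstream plots). Degree summaries report
both E/N ("edges per node") and 2E/N (mean degree), because "average
interactions per node" is ambiguous between the two; neither is asserted as
the right one.

Hierarchical clustering follows the classic microarray convention:
agglomerative, average linkage, uncentered-correlation (cosine) distance.
A zero-norm column's similarity is undefined and its distance is set to 1
with a warning. Leaf ordering is deterministic given input order. Row
clustering is skipped above 5,000 rows (quadratic memory); columns are
always clustered, and the 3-cluster column cut is the cell-type partition
check.

## Synthetic data

The generator reproduces the emulated study design statistically, not
biologically:
27,578 probes; 4 patients and 4 controls, each contributing iPS cells (2
clones, biological replicates), ONS cells and fibroblasts; every line
measured in triplicate (consecutive passages, technical replicates); one ES
comparator line used only for QC. Baseline betas come from a 30/40/30
hypo/mid/hyper Beta-mixture so every methylation state is populated.
Cell-type effects shift 28% of probes by ±2 M-units in one cell type.
Disease effects touch 883/1328/952-of-27,578-scaled fractions of probes per
cell type at Δβ = 0.2 (converted to an M-offset at each probe's own
baseline), including a shared 5-locus core planted in all three cell types
with a common direction (4 hypo, 1 hyper). Noise is Gaussian on the M scale:
biological SD 0.30 per unit, technical SD 0.15 per replicate — which puts
replicate r² near 0.99 against the baseline spread. An optional planted
outlier shifts one sample by +3 M-units for QC-path testing.

Expression is coupled: 80% of each cell type's DM genes receive a ±1 log2
effect whose sign is concordant (hypo→up, hyper→down) with probability 0.9,
plus a 1% independent DE background. The interactome is a
preferential-attachment graph (2,000 genes, m = 3) labeled from the gene
universe; seed genes are sampled with a configurable weight multiplier for
disease-affected genes (0 = null calibration, default 8 plants real
enrichment). Gene sets are 50 random sets of 20–200 genes, 5 of them half-
filled with disease genes.

All randomness derives from one integer seed through spawned child streams;
identical configurations are byte-identical, including written fixtures.

What the generator does **not** emulate: probe-level genomic
autocorrelation, chip/batch/position effects, dye bias, probe
cross-reactivity and SNP artifacts, realistic annotation multiplicity
(default one probe per gene), and the heavy-tailed variance structure of
real arrays (noise is homoscedastic across probes). Passing tests therefore
demonstrate the statistical machinery is correct under the declared model,
not that real-array preprocessing issues are handled.

## Problem sizes used by the test and acceptance suites

Unit and property tests run on scaled-down studies (400–5,000 probes) with
the full design structure; replicate-based calibrations use 25–50
replicate studies. The overlap test is exercised at the full published scale
(lists 883/1328/952 from 27,578, 10,000–100,000 simulations), the moderation
recovery at 10,000 probes, and the end-to-end determinism check at the full
default fixture (27,578 probes, 99 arrays). These sizes were chosen as the
smallest at which each statistical claim is measurable at its stated
tolerance.

## Known limitations

- The two-group fit has no covariates (age/sex/smoking are confounded with
  status in small designs like this one and were not modeled).
- The "block" replicate policy is a pass-through, not a duplicate-correlation
  model.
- Exact k ≥ 3 overlap probabilities are not computed (combinatorially
  intractable at array scale); the Monte-Carlo and Poisson routes are the
  supported answers.
- Activation z-scores use unit weights and flat gene sets (no ontology DAG
  propagation).
- The Eq.-style Z with N bound to the universe is much more conservative
  than the binomial sd; both bindings are exposed and the choice is the
  caller's.
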