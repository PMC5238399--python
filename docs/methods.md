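# Methods

## Design and scope

The package analyses a minimal paired design: one drought-resistant and one
drought-sensitive *B. napus* cultivar, each with a stressed and a
well-watered library (R/RT and S/ST), one library per condition. With no
biological replicates, the differential-expression model is the exact
Poisson tag-count test for two libraries; between-replicate (negative
binomial) overdispersion is deliberately out of scope, and conclusions from
the test are conditional on the single-library design. Read QC, alignment
and transcript assembly are upstream of the package: the input is a table
of uniquely aligned clean-read counts with per-gene lengths and
per-library totals.

## Exact test

Conditional on x tags in library 1, the count y in library 2 follows a
negative binomial with x+1 failures and success probability N₁/(N₁+N₂)
(N₁, N₂ the library totals). The term probability is evaluated in
log-gamma space; tail sums use the regularised incomplete beta identity
P(Y≤y|x) = I_{N₁/(N₁+N₂)}(x+1, y+1), so no truncated series (and hence no
truncation cap) is needed and counts of 10⁴ and beyond are exact to double
precision.

**Sidedness.** Two conventions compete for a two-sided discrete p-value:
doubling the smaller of the two *inclusive* tails, or doubling
min(F(y), 1−F(y)) (equality mass in the lower tail only). The package uses
the latter because it is *exactly* invariant under swapping the two
libraries together with their totals — via the incomplete-beta identity,
{P(Y≤y|x), P(Y>y|x)} maps onto {P(X>x|y), P(X≤x|y)} — whereas the
inclusive form is not (at x=0, y=1, N₁=N₂ it gives 1.0 one way and 0.5
the other). The two conventions differ only by the probability mass of the
observed point, which matters near p≈1 and never near the 0.001 call
threshold. The resulting test is valid: on null simulations the fraction
of raw p < α stays below α (checked at α = 0.05 and 0.01 on 10⁴ genes).

**Thresholds.** A gene is a DEG when the Benjamini–Hochberg adjusted
p-value is ≤ 0.001 *and* |log₂ ratio| ≥ 1. Boundary equality is accepted
at both thresholds. The FDR family is the full gene list of the comparison.
The fold change is the RPKM ratio with a pseudocount of c = 0.001 RPKM on
both sides, so zero-count genes give large but finite ratios; c only
perturbs ratios materially for genes whose RPKM is within an order of
magnitude of c, which are far below any calling threshold.

## Two-round classification

Venn membership is computed *after* the pathway-annotation filter: each
group's DEG set is first intersected with the genes carrying ≥ 1 KEGG
pathway, then the union is partitioned into the 15 masks. Any mask
containing ST-RT (well-watered control vs well-watered control — cultivar
difference, not drought response) is EXCLUDED; the seven remaining masks
map deterministically onto RDR / SDR / CDR. The second-round rules
(README table) are all inclusive ≥ comparisons; a gene whose mask's rule
references a fold change the gene does not carry raises an error rather
than silently failing the rule, since under correct plumbing every mask
member carries exactly the ratios of its member groups.

The fold-change orientation is fixed by the printed rules: group `RT-R`
(RT versus R) carries log₂(R/RT), `S-R` carries log₂(R/S), `ST-S` carries
log₂(S/ST) and `ST-RT` carries log₂(RT/ST) — i.e. the second-named sample
is the ratio numerator.

## Enrichment

One-sided hypergeometric over-representation against a whole-transcriptome
background of N_bg genes. The Bonferroni family is the set of terms
annotating at least one query gene (the tested nodes), not the full term
universe — the convention of term-finder tools that only score touched
nodes; the corrected value is min(1, m·p). The corrected value is named
`p_corrected` with the method recorded, to avoid conflating a Bonferroni
bound with a BH FDR. Under-representation is not tested.

## Networks

The tripartite graph links a gene to each of its processes and pathways,
and a process to a pathway whenever ≥ 1 gene carries both; no intra-layer
edges. Projections are simple weighted graphs (no self-loops or
multi-edges) with weight = shared linking-entity count, and never drop
nodes: isolated nodes are reported (a gene sharing no pathway with any
other gene is itself a result). For the pathway-layer projections linked
through processes, linking via the tripartite process–pathway edges and
linking via genes coincide by construction.

Because published network summaries mix mean-degree conventions, both
2E/N (sum of degrees over nodes) and E/N (edges over nodes) are always
reported side by side; neither is guessed to be "the" convention. The
power-law slope is the least-squares slope of log₁₀(frequency) against
log₁₀(degree) over non-empty positive-degree bins of the integer-degree
histogram — matching how such distributions are usually displayed — not a
maximum-likelihood exponent; fewer than three usable bins returns an
undefined-result signal (`None`) rather than an exception.

## Clustering

Average-linkage (UPGMA) clustering over three distances: Euclidean,
1 − Pearson and 1 − Spearman. Constant rows are rejected for the
correlation metrics (their correlation is undefined) with the offending
row named. Ties in merge order are broken by smallest original index
pair. Expression dendrograms use log₂(RPKM + 0.001); location dendrograms
use a chromosome × position-bin count matrix with a default bin width of
1000 position-code units (the identifier's five-digit locus field is used
as an ordinal position only; no genomic-coordinate semantics are claimed).

## Synthetic-data generator

The generator emulates the study conditions: four libraries (default 10⁶
reads each — a down-scaled stand-in for deep runs, configurable),
log-normal baseline expression (ln-scale mean 3, sd 1, i.e. a median of
~20 expected counts), Poisson counts with per-sample rates
baseline × 2^offset × depth, gene identifiers over A01–A10, C01–C09 and
the unknown-position labels Ann/Cnn/Unn, and annotation universes of 128
pathways and 1200 processes with ~2 pathways and ~6 processes per
annotated gene. A configurable fraction (default 0.4) of *null* genes
lacks pathway annotation, driving the annotation filter; planted genes are
always pathway-annotated so their truth labels survive the filter
deterministically. A few terms are "planted enriched": crucial planted
genes carry each with probability 0.6.

Planted differential expression is parameterised by the per-comparison
effects e₁ = log₂(R/RT), e₂ = log₂(R/S), e₃ = log₂(S/ST). Since each
sample has one expression level, the fourth comparison is determined:
log₂(RT/ST) = −e₁ + e₂ + e₃. A consequence worth stating explicitly: a
gene strongly responsive in exactly one comparison cannot exist at exact
ratios — the identity forces a second comparison past the |log₂| ≥ 1
threshold. Single-group Venn masks are therefore only reachable with
moderate effects (the defaults use |log₂| ∈ [1.2, 1.9] with small
compensating offsets), while crucial-level effects are planted through the
biologically natural multi-group patterns: a resistant-cultivar response
lands in {RT-R, S-R}, a sensitive-cultivar response in {S-R, ST-S}, a
shared response in {RT-R, ST-S} or the triple mask. Ground-truth labels
(mask, category, crucial flag) are always derived from the *realised*
effects with the default thresholds — never from the requested target — so
truth is consistent with the generated counts by construction, and any
recipe spill-over into ST-RT is truthfully labelled EXCLUDED.

What passing tests on synthetic data do and do not show: they validate
the statistical machinery (calibration, recovery, rule arithmetic,
projection algebra) under the stated Poisson model; they do not validate
robustness to overdispersion, mapping artefacts, annotation bias or
length-dependent effects present in real libraries.

Problem sizes used by the validation suite — chosen to make the checks
statistically meaningful at interactive run times — are 10⁴ genes for null
calibration, 400-gene experiments across 20 seeds for parameter recovery
(planted effects one unit beyond each rule cutoff, anchor counts ≥ 50),
and a 169-gene annotation fixture at the 85-pathway scale for network
statistics.

## Numerical and degenerate-input choices

- p-values and hypergeometric tails in log-space / via scipy special
  functions; no overflow up to counts ≥ 10⁴ (tested).
- Empty DEG sets, empty queries, empty networks and empty process files
  flow through every stage without error, returning empty results.
- x = y = 0 gives p = 1: absent genes are never DEGs.
- Identifiers are case-sensitive and stored verbatim; parsing never
  canonicalises.
- Library totals are explicit metadata (a `#library_total` header line),
  not column sums, because the total counts all uniquely aligned reads
  genome-wide, not only the analysed gene set. Gene length is treated as
  an opaque positive integer supplied with the input; no claim is made
  about transcript versus union-exon length.
- TSV (not CSV) throughout, so term descriptions with commas need no
  quoting.

## Known limitations

- No replicate-aware dispersion modelling; the exact test is anti-
  conservative for biological replicates and should not be applied to
  replicated designs.
- The Bonferroni family choice (tested terms) is a convention; correcting
  over the full term universe would be more conservative.
- The power-law slope is a descriptive log-log fit, sensitive to binning
  at the tail; it is not an MLE exponent estimate.
- The generator's planted enrichment uses uniform background annotation
  draws; real annotation is strongly non-uniform (hub pathways), which the
  fixture for network tests mimics only through its degree spread.
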