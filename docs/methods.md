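# Methods

## Data model

A *paired study* is a set of per-tissue expression matrices (genes × units,
FPKM scale) sharing one ordered unit index — here units are pregnancies.
Pairing is by unit identifier, never by column position, so files with
shuffled columns are aligned safely (`align_paired_study` reorders to the
first matrix's order and errors on unit-set mismatches, listing the
symmetric difference).

The expressed-gene filter retains genes with expression **strictly above**
`min_level` (default 1 FPKM) in at least `min_units` (default 4) units.
The inequality is deliberately strict — a gene at exactly 1.0 everywhere is
removed — and the filter is applied per tissue independently, which is why
the per-tissue expressed-gene counts differ.  The filter is idempotent and
order-preserving; an all-removed result is a warning, not an error.

## Cross-tissue correlation

For tissues with j and k expressed genes, the j×k matrix of Pearson
correlations across the paired units is computed by centering and
L2-normalizing each gene's profile and taking a blocked matrix product, so
memory stays bounded at the real-data scale (j, k ~ 10⁴) while each entry
equals the scalar product-moment formula to ≤ 1e-10.  Zero-variance
profiles yield *undefined* entries (NaN); undefined pairs are excluded from
edges and from the eFDR's numerator and denominator on both the observed
and scrambled sides, so both tails stay comparable.  Correlations are
computed on the scale provided (FPKM by default; the generator can emit
log2 matrices, and correlations are scale-equivariant only under monotone
*linear* maps, so the two scales genuinely differ).  Entries are clipped to
[−1, 1] against floating-point overshoot; with n = 5 units the centered
data have rank ≤ 4, so near-±1 values are common even under independence.

Significant edges are all defined pairs with |r| **strictly greater** than
the threshold, annotated with the eFDR at that threshold.

## Scrambled-pairing empirical FDR

The unit order of *one* tissue (the extraembryonic side by convention) is
permuted, which is sufficient to break the pairing of a cross-tissue pair.
B permutations (default 100) are sampled uniformly **without replacement
from the non-identity permutations** — the identity would not break the
pairing, and distinctness maximizes null information when only
n! − 1 = 119 permutations exist at n = 5.  When B equals n! − 1 the
enumeration is exhaustive and seed-independent.

For each permutation the full cross-correlation matrix is recomputed and
the absolute values pooled (or, for large studies, streamed into tail
counts over the threshold grid so memory stays at one matrix).  The eFDR at
threshold t is the smoothed null tail proportion

    eFDR(t) = (#{null |r| ≥ t} + 1) / (pair_count·B + 1),

non-increasing in t with floor 1/(pair_count·B + 1) and eFDR(0) = 1.  This
is a tail proportion of the scrambled distribution, not a ratio of null to
observed exceedances; a classical discoveries-denominated variant
(`ratio_efdr`) is available for users who expect the latter.  The default
grid is 0.00–1.00 in steps of 0.01 plus the operating points 0.95, 0.99,
0.999, 0.9999.

`threshold_for_efdr` returns the smallest grid threshold whose eFDR meets a
target, or None when the target undercuts the smoothing floor.
`reoccurrence_rate` reports, per permutation, the fraction of
observed-significant pairs whose scrambled |r| still exceeds the threshold.
Note that permutations close to the identity (e.g. a single transposition
of 5 indices) break the pairing only weakly, so genuinely coexpressed pairs
reoccur somewhat *more* often than independent null pairs; reoccurrence
should be read as "rare", not as "at the null rate" (see Small-sample
behaviour below).

## Connectivity

A gene's degree is its number of significant partners.  Mean/median degree
are reported both over connected genes (degree ≥ 1; the convention behind
"correlated with N genes on average") and over the full universe.  Degree
sums on the two sides both equal the edge count by construction, and this
is asserted in tests.  Distribution comparisons (observed vs scrambled
correlations, degree distributions) use the two-sample Kolmogorov–Smirnov
test; the choice is recorded in the output metadata.

## Module clustering

Each tissue's genes are clustered by their correlation-profile rows (or
columns) with agglomerative linkage (default: complete) on Euclidean
profile distances; 1 − correlation-of-profiles is available via
`metric="correlation"`.  Undefined entries are imputed as 0 for distance
purposes and the imputation count is logged.  The tree cut (k clusters or a
height) is an explicit user parameter recorded in the output — no automatic
cut-selection is attempted.  Cluster ids are relabelled contiguously from 1
in order of first appearance, making the partition invariant (up to
relabelling) under input gene order; ties in the agglomeration follow
scipy's deterministic lowest-index rule.

Bipartite module summaries count the significant edges crossing two gene
sets and average their r; they inherit the |r|/eFDR operating point from
the edge stage rather than re-thresholding raw correlations.

## Signatures and dendrogram equivalence

The high-coexpression signature of a tissue pair is the set of genes on
each side participating in at least one pair with |r| above a stringent
threshold (0.9999 by default).  Each tissue's units are then given a 5×5
distance matrix d = 1 − Pearson r between unit expression profiles *over
that tissue's own signature genes*, clustered with complete linkage.  Units
are put in lexicographic order first, so scipy's lowest-index tie-break
acts lexicographically; dendrograms are exported as Newick with branch
lengths derived from merge heights.

The Mantel statistic is the Pearson correlation of the two matrices' upper
triangles, tested one-sided (≥) by permuting one matrix's unit labels.
Whenever n! ≤ 5040 all relabelings are enumerated (identity included) and
p = count/n!; at n = 5 this makes 1/120 ≈ 0.0083 the smallest attainable
p — the strongest evidence five pregnancies can provide, and exactly the
value reached when the two tissues' distance structures agree.  Sampled
mode uses the (count + 1)/(B + 1) estimator.  The cophenetic correlation
between the two trees is reported as a secondary descriptor and equals 1
when the trees are built from identical distances.

## Enrichment

Over-representation of a test gene list within a tissue's expressed-gene
background uses the central hypergeometric upper tail
P(X ≥ overlap); sets with empty background intersection are skipped, and
test genes outside the background are a hard error.  When per-gene bias
weights are supplied the Wallenius noncentral variant is used with odds =
mean in-set weight / mean out-of-set weight; without weights no length
model is fabricated.  Raw p-values are BH-adjusted across the sets tested.

The bootstrap validation redraws `n_test` genes uniformly from the
background `rounds` times (default 2,000), reruns enrichment + BH, and
reports per set the proportion of rounds whose FDR is **strictly lower**
than the observed FDR.  A probability of 0.0 means no round beat the
observation and should be read as "< 1/rounds".  The 2-D bootstrap path
uses a vectorized BH implementation verified against statsmodels.

## Synthetic studies

The generator emulates the paired-pregnancy design: 3 tissues × 5 units and
~12,000 genes per tissue by default, of which ~10,000 pass the expression
filter.  Each module owns one latent unit-level factor u_i ~ N(0,1) shared
across tissues; module genes have log2 expression α + βu + ε with
|β| ~ U(loading_range), ε ~ N(0, noise_sd²), and the sign of β flipped in
the non-reference tissues for a configurable fraction of modules.  Null
genes are α + ε.  On the log2 scale the planted correlation of two genes
sharing a factor is exactly β₁β₂/√((β₁²+σ²)(β₂²+σ²)); after
exponentiation to the FPKM-like scale it is approximate, so recovery tests
use the `log2_scale` switch.  A fraction of the *null* genes (so planted
modules stay intact) is generated with baselines in U(−6, −2) log2 units,
well below the FPKM > 1 filter, to exercise filtering.  Defaults:
loading_range (0.5, 1.0) and noise_sd 0.5 give planted correlations from
~0.5 to ~0.8 — the mix of strong and moderate coexpression expected from
bulk RNA-seq across pregnancies; negative_fraction 0.3 plants both signs.
All randomness flows through one numpy PCG64 generator, so a seed fixes
the study byte for byte.

What the generator does **not** emulate: count-level (negative binomial)
noise, library-size and gene-length effects, correlated noise between
tissues of one unit, and overlapping or hierarchical modules.  Passing
tests therefore demonstrate correctness of the statistical machinery under
the latent-factor model, not robustness to RNA-seq technical artifacts.

## Small-sample behaviour (n = 5)

Several honest limits of the five-unit design are worth stating because
they bound what *any* analysis of such data can recover:

- The null distribution of r at n = 5 is the semicircle density
  ∝ √(1 − r²): 10% of independent pairs exceed |r| = 0.8 and 1.3% exceed
  0.95.  The eFDR accounts for this, but absolute correlations are
  individually uninformative.
- The sampling sd of Fisher's z is 1/√(n−3) ≈ 0.71, so even a pair with
  population correlation 0.95 exceeds an observed 0.95 only ~half the
  time.  Planted-pair "recovery" at a threshold equal to the planted
  correlation is therefore ~50–70%, not ~100%.
- Profile-based gene clustering can only isolate planted modules from
  independent genes when √(genes_per_module)·ρ exceeds the noise scale
  √(n_genes)/√(n_units−1); at n = 5 with thousands of null genes the null
  profiles form a cloud whose internal distances exceed module–null
  distances, and no hierarchical cut recovers a "null cluster".  The
  package demonstrates full recovery (ARI ≈ 1) at n_units = 60, and the
  acceptance script reports the honest near-zero ARI at n = 5 alongside
  it.
- The exhaustive Mantel p cannot go below 1/120.

## Pipeline and reproducibility

`run_pipeline` sequences filter → align → correlation → permutation null +
eFDR → edges → connectivity → clustering → signatures → Mantel →
enrichment per configured tissue pair, aborting with the stage name on any
error.  One master seed spawns per-stage sub-seeds via
`numpy.random.SeedSequence`, every artifact directory records the config
hash and seed, outputs are plain TSV/JSON/Newick/SIF with fixed float
formatting, and identical config + seed reproduce every file byte for
byte.  Problem sizes in the test suite and acceptance script (up to
5,000×5,000 null pairs with B = 100, 2,400-gene clustering, 2,000-round
bootstraps) were chosen so the full validation runs in a few minutes on a
single core while keeping Monte-Carlo bands tight enough to be meaningful.
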