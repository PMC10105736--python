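# Methods

`y2hnet` implements the analysis stack of a pooled binary-interactome
mapping campaign: deconvolution scoring of pooled yeast two-hybrid (Y2H)
wells, pairwise-retest calling, network-based link prediction, orthogonal
validation with empirical false-discovery thresholds, reference-network
integration, randomized-network enrichment statistics, and seed-expansion
candidate prioritization. Every stage can be exercised end to end on
synthetic screens produced by the package's own generators, against a known
ground truth.

## Pooled-screen deconvolution (SWIM score)

In the primary screen a single DNA-binding-domain (DB) bait is mated
against a pool of activation-domain (AD) prey ORFs in one well; colonies
from the well are sequenced jointly, so candidate preys must be deconvolved
from read counts. For a bait–prey combination in a well with AD-ORF reads
*x*, DB-ORF reads *y*, well totals *a* and *d*, and per-sequencing-batch
pseudo-counts *M* and *N*, the score is the harmonic mean of the two read
fractions:

    S = 2 / ( (a + M)/x + (d + N)/y )

*S* is defined as 0 when either read channel is empty — a pair absent from
one channel cannot be called — and is bounded by 1 because x ≤ a and
y ≤ d. *S* is symmetric under exchanging the AD and DB channels, strictly
increasing in both read counts, and strictly decreasing in the totals and
pseudo-counts. Pseudo-counts default to M = N = 10 per batch; the real
campaigns' batch values are not published, so these are package defaults,
not estimates.

First-pass pairs (FiPPs) are wells with S at or above a per-batch cutoff.
Screen cutoffs in practice vary by batch and protocol; the package default
is the 95th percentile of the batch's *positive* score distribution, and a
fixed cutoff or per-batch map can be supplied instead.

## Retest calling and auto-activator removal

FiPPs are retested pairwise in quadruplicate on a test plate
(SC-Leu-Trp-His+3AT, selecting for the reporter) and a cycloheximide (CHX)
plate (selecting against the prey plasmid, so growth exposes bait
auto-activation). Growth is modeled as ordinal 0–4 scores per replicate and
classified by medians: strong CHX growth (median ≥ c_max = 3) marks the
pair auto-activator/undetermined; a pair is positive only when the test
median exceeds the CHX median by at least delta = 2 and reaches g_min = 2;
unscorable wells are NA; everything else is negative. The published
protocol's "significantly more growth" is qualitative, so these ordinal
thresholds are package choices. A pair positive in either bait–prey
orientation is positive overall. Baits that grow when mated against an
empty "AD-null" prey plasmid are de novo auto-activators; all their
positives are removed.

## L3 link prediction

Candidate (non-adjacent) pairs are ranked by the degree-normalized number
of length-3 paths joining them:

    p_xy = Σ_{u,v} A_xu A_uv A_vy / sqrt(k_u k_v)

with A the zero-diagonal adjacency matrix and k the degrees. The sqrt
normalization follows the original L3 formulation. The implementation is
the matrix product A·(D^-1/2 A D^-1/2)·A read at non-adjacent pairs, which
for simple graphs equals the constrained walk sum with intermediates
distinct from each other and from the endpoints; an independent brute-force
walk enumerator is kept as the test oracle. Ties are broken by canonical
pair order and zero-score candidates are excluded by default. Precision at
k of retested predictions excludes undetermined retests from the
denominator: precision = positives / (tested − undetermined).

## Orthogonal validation and empirical FDR

Validated pairs get replicate luminescence readings in stimulated and
unstimulated wells plus two negative controls (bait-only, prey-only).
Fold induction is mean(stimulated)/mean(unstimulated); the pair score is
its fold induction divided by the stronger control's. Pairs without a
valid quantitative score (cloning failure, no bait expression) are dropped.
Per batch, the positive/negative threshold is the empirical 99th percentile
of the batch's random-reference-set (RRS) scores — linear interpolation
between order statistics, the common default of the standard quantile
routine — giving a nominal 1% false-discovery rate; a score exactly at the
threshold is negative (ties conservative), and batches with fewer than 20
RRS scores make no calls. Recovery rate of a set is P/(P+N) with standard
error sqrt(rate(1−rate)/(P+N)).

A note on calibration: the exceedance probability of an interpolated
order-statistic threshold is distribution-free with expectation
(n+1−k)/(n+1) ≈ 1.45% at n = 216, slightly above the nominal 1%, and its
per-experiment spread is dominated by order-statistic noise (sd ≈ 1
percentage point for 1000 test pairs). The calibration tests use this
combined Monte-Carlo error.

## Literature classification and reference assembly

Evidence records carry a publication id, a detection-method id, and a
method class from a user-editable lookup in the molecular-interaction (MI)
vocabulary style. A pair is Lit-BM (binary, multiple evidence) when direct
binary evidence supports it in at least two distinct publications or by at
least two distinct direct methods; exactly one distinct line of direct
evidence makes it Lit-BS; duplicated lines (same publication and method) do
not add support. Legacy high-throughput pairs are filtered at an inclusive
confidence cutoff (default 0.7). The reference network is the union of
screen positives, filtered legacy pairs, and Lit-BM, with per-edge source
tags; its node space is the union of edge endpoints.

Dataset overlap uses a two-sided Fisher exact test over an explicit search
space of unordered bait × prey combinations, extended by detected pairs
falling outside the grid. Interolog comparison maps pairs through a
possibly many-to-many ortholog table: a pair is mappable when both
endpoints have an ortholog among the target network's nodes and
overlapping when any ortholog combination is a target edge (counted once).

## Null-network enrichment

The null model is a node-label shuffle: labels are permuted among the
network's own nodes, preserving topology (and the degree sequence) exactly
while destroying label–topology association; an alternative mode draws
labels from a larger universe. Each ensemble replicate uses an independent
substream of the root generator. Empirical p-values use the add-one rule
p = (1 + #{null ≥ observed})/(n_null + 1), so a finite ensemble never
reports 0; both fold (observed/null mean) and a z-score are reported since
either summary is in common use.

Edge statistics: fraction of edges sharing an annotation term (terms with
more than 30 genes dropped by default — broad terms carry little
specificity; the cap is configurable); fraction sharing an organelle
label; per-edge shared-publication counts with publications of ≥ 100 genes
excluded (genome-scale surveys would swamp the signal); and the average
number of cell types in which both endpoints are expressed. Edges with an
unannotated endpoint are excluded from denominators rather than counted as
non-matching. Gene-set enrichment is the upper-tail hypergeometric
probability P(X ≥ overlap). The publication-binned adjacency matrix ranks
genes by publication count (ties by gene id), splits them into
equal-frequency bins, and counts edges per bin pair; the default symmetric
convention double-enters off-diagonal cells to match a mirrored heatmap,
with an upper-triangle mode whose total equals the edge count.

## Seed expansion and RNAi comparison

From a seed list, the first shell is the seeds' direct interactors and the
second shell the first shell's interactors, with shells strictly disjoint,
so combined size is additive (seeds + shell1 + shell2). Seeds absent from
the network contribute no neighbors but stay in the combined list. Because
candidate genes are typically covered by several RNAi lines while random
controls get one line per gene, rate comparison subsamples one line per
gene (uniformly, default five repeats) and averages the per-repeat
modifier rates.

## Synthetic-data generator

The generators define the package's study conditions:

* **Interactome** — Chung–Lu-style edge sampling with power-law weights
  (default degree exponent γ = 2.5, mean degree 4) and planted modules: a
  fraction 1 − mixing of edges is intra-module (default mixing 0.2). The
  annotation bundle ties structure to the modules: one GO-like term per
  namespace per module (covering ~70% of the module), organelles and
  expression cell types assigned by module (with a 10% rate of extra cell
  types), and small publications anchored on true edges — each paper
  "studies" one interaction plus up to three same-module genes, with paper
  choice tilted toward Zipf-distributed gene popularity — plus one
  genome-scale survey that exercises the large-publication filter.
  Publication counts per gene are derived from these papers.
* **Pooled screen** — prey pools of configurable size (default 1000, the
  kilopool; smaller pools for desk-scale runs), two assay versions with
  two replicate screens each, per-version detection sensitivity (default
  0.8). A detected true pair's AD reads are Poisson(λ_sig = 50); all other
  AD rows are Poisson(λ_bg = 0.5); the single DB row per well is
  Poisson(λ_sig), so the well's DB total is the bait's own count. All rate
  and pseudo-count defaults are illustrative — the real screens' read
  depths are unpublished — and live in one configuration block.
  Auto-activating baits (default 5% of baits) grow regardless of prey, so
  the colonies picked from their wells carry an arbitrary subset of the
  pool: each prey reaches signal-level reads with probability
  aa_prey_rate = 0.1. (Giving signal reads to *every* prey in the pool
  would dilute each prey's AD share to ~1/pool_size and no auto-activator
  pair would ever clear a FiPP cutoff, leaving the downstream removal
  machinery untested.)
* **Retests** — true pairs grow on the test plate only (missed with
  probability 0.1); non-pairs grow on neither plate except a 5×10⁻⁴
  spurious rate; auto-activator baits grow on both plates with CHX growth
  strong enough to flag a large fraction, and always grow against AD-null.
* **Validation scores** — measurement tables constructed so the derived
  score is exactly the drawn log-normal variate (negative controls have
  fold induction 1): null pairs and RRS share location μ0 = 0, true pairs
  and PRS use μ1 = 1.5, common scale σ = 0.5; per-batch RRS/PRS blocks
  default to 216/150.
* **RNAi outcomes** — per-line Bernoulli modifier calls at rate 0.5 for
  network-derived genes (1–5 lines each) and 0.25 for random controls (one
  line each), echoing the observed ~2× gap.

What the generators do *not* emulate: sequence-level artifacts (barcode
collisions, alignment error), growth-phenotype gradations beyond the 0–4
ordinal scale, correlated assay failures between versions, batch-to-batch
parameter drift, and the biological correlation structure of real
annotation databases. Passing tests therefore demonstrate that the
algorithms are implemented correctly and behave as designed under the
stated statistical model — not that the model captures every failure mode
of real screens.

## Numerical and design choices

* Homodimers are retained, contribute 1 to degree, appear in neighbor
  sets, and are excluded from L3 path intermediates.
* Canonical pair order is plain string comparison (lexicographic), so
  orientation never matters downstream.
* One root seed; every stage and every null replicate derives an
  independent substream, making runs reproducible and order-independent.
* Unknown configuration keys are rejected at load time.
* Degenerate cases are flagged rather than silently defaulted: empty
  scorable sets raise, constant null ensembles report p = 1 with a
  degeneracy flag, zero-margin overlap tables warn.
* Desk-scale problem sizes used by the test suite and the demo
  configuration (hundreds of genes, pools of ~100, ensembles of a few
  hundred nulls) were chosen so a full run completes in minutes on one
  CPU; all sizes scale up through configuration.

## Known limitations

The FiPP-cutoff default (a within-batch score quantile) is a stand-in for
the screen-specific calibration the original campaigns performed by hand.
The retest growth model is ordinal and symmetric across replicates; real
colony scoring has correlated replicate structure. The validation-score
generator produces exactly log-normal scores, so tail behavior of real
luminescence ratios (occasional saturation) is not represented. Ortholog
mapping treats all ortholog combinations as equally credible, with no
confidence weighting.
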