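# Methods

`nacscan` implements the computational workflow used to ask whether NAC
transcription factors drive leaf-senescence gene expression in a cereal:
select senescence-regulated genes from a one-colour microarray, profile
and cluster senescence time courses measured by qRT-PCR, search gene
promoters for palindromic NAC-binding sites (NACBSs) with a FIMO-style
scanner, test those sites for over-representation in the up- and
down-regulated gene sets, and check whether NACBS-containing genes sit
near the top of NAC genes' co-expression rankings.  Every stage can be
exercised end-to-end on synthetic data with recorded ground truth.

## NACBS motif models

NAC domains bind motifs built around a CGT core, typically preceded by
T at the -2/-3 positions, and the core frequently recurs as an inverted
repeat (CGT ... ACG) with a variable spacer.  Seven letter-probability
models encode this: `NACBS-k` for k = 5..10 with consensus
`ttnCGT(n x k)ACGnnn` (lengths 17-22), and `NACBS-1`, a single core with
conserved upstream T's (`nttnCGTgnnn`, length 11).

A consensus string expands position-wise into probabilities controlled
by a `WeightScheme`: the consensus base gets `core_prob` at upper-case
(core) positions and `minor_prob` at lower-case (weakly conserved)
positions, with the remaining mass split evenly; `n` is uniform.
Defaults are `core_prob = 0.94` and `minor_prob = 0.70` with a 0.001
probability floor.  The exact published weight matrices are not
reproduced here, so the scheme is explicit and configurable rather than
claimed identical to any external matrix.  With symmetric weights the
ACG block is exactly the reverse complement of the CGT block, so the
models are palindromic by construction.  Models serialize to MEME
minimal motif format (nsites written as 20, E-value 0).

## Scanning and exact p-values

Windows are scored by the log-odds sum over positions,
`sum_i log2(p_i(b_i) / bg(b_i))`, against a 0-order background (uniform
by default; a promoter-estimated background is available).  Per-position
scores are discretized to a grid (default granularity 0.01 log2 units)
and the exact null distribution of the window score is computed by
dynamic programming — convolving the per-position score distributions
under the background — giving an exact p-value for every achievable
score.  The granularity is the only approximation knob; the test suite
checks the DP against full 4^L enumeration for models up to L = 6 at
1e-12.

Hits are windows with p <= 1e-4, the conventional scanning threshold.
Both strands are scanned by default (the minus strand via the
reverse-complement model with its own null distribution); windows
containing N are skipped; coordinates are 0-based half-open and
promoter-relative.  p-values are per-window and deliberately not
corrected across windows.  Promoter-level accounting counts a promoter
once per motif no matter how many matches it contains, and the
"Total, non-redundant" row is the per-set union over motifs.

A practical consequence of the default weights worth knowing: at
p <= 1e-4 the accepted word set of these models is essentially the
consensus word alone.  One mismatch at a minor-weight position already
pushes the tail just above 1e-4 (7 x 4^-8 ≈ 1.07e-4 for the k = 8
model), while the consensus word's p-value is 4^-8 ≈ 1.5e-5.

## Enrichment

For a universe of N scanned promoters, K of which carry a motif, a gene
set of size n with k motif-carrying promoters is tested for
over-representation by the exact hypergeometric upper tail
P(X >= k), summed in log space.  Because the statistic is discrete the
plain upper tail is conservative; the report therefore also computes the
mid-p variant P(X > k) + 0.5 P(X = k) and assigns the two-level
significance annotation (** for p <= 0.01, * for p <= 0.05, otherwise
NS) from the mid-p by default.  Cells where the two tails disagree about
the annotation are flagged `borderline`; a two-sided option is exposed.
The per-1000 rate is round(1000 k / n), half-up.  No correction is
applied across the seven motifs, matching how such tables are
conventionally annotated.  The universe is the set of promoters
available for scanning, not all array probes.

## Microarray stage

Background correction is "half": max(signal - background, 0.5), keeping
intensities positive for the log transform.  Quantile normalization maps
every array onto the mean sorted profile, assigning ties the mean of the
reference values they span.  The low-signal filter keeps a probe if its
corrected signal is at least 1.1x background in every array of at least
one condition group (both thresholds configurable; they formalize a
"default settings" pre-filter).

Redundant probes per target are reduced to one representative: among the
two probes with the highest mean signal (all probes if the group has at
most two), the probe closest to the target 3' end wins — labelling
starts from the poly(A) tail, so 3'-proximal probes are the most
reliable.  Distance ties go to the stronger probe, then to the smaller
probe id.  Probe-to-gene assignment, where needed, uses a forward-strand
Hamming scan allowing up to 3 mismatches over the 60-mer, ambiguous
probe bases counting as mismatches to everything.

Differential ranking uses a moderated two-sample t: per-gene pooled
variances are shrunk toward the median gene variance with prior weight
d0 = 4, and two-sided p-values use residual + d0 degrees of freedom,
followed by Benjamini-Hochberg adjustment.  This is a deliberately
simple empirical-Bayes stand-in — reproducing a full limma fit is a
non-goal — and it is calibrated: on null data the raw p-values are
uniform to within binomial sampling error (tested).  Ranking sorts by
adjusted then raw p-value, breaking ties by |log2 fold change| and gene
id.  The top fraction (e.g. 5000 of 24 646 filtered probes, reported as
20%) feeds the downstream gene sets.  An outlier-array screen flags
arrays whose median inter-array Spearman correlation falls more than 3
MADs below the cohort median; exclusion is left to the caller.

## qRT-PCR stage

Triplicate Ct values are averaged; if the replicate range exceeds 1.0
cycle, wells more than 0.5 cycles from the median are dropped and the
measurement flagged (`outlier_removed`) — a mechanical stand-in for
manual curve inspection, thresholds configurable.

Reference-gene stability is the geNorm M value: for each candidate pair
the standard deviation (n-1 denominator) of per-sample log2 expression
ratios, averaged over partners; lower M = more stable.  The single-pass
variant is implemented (not the iterative exclusion loop); M is
invariant to rescaling any gene, and adding noise to a gene increases
its expected M (both tested).  Expression is normalized by delta-Ct,
2^(Ct_ref - Ct_gene).

Samples are ordered by decreasing chlorophyll content as the senescence
axis (ties break by sample id; chlorophyll values are consumed as
given).  Profiles are clustered by k-means with k = round(sqrt(n/2))
(half-up, so 91 profiled genes give k = 7).  Because the object of
interest is the expression *pattern*, profiles are log2-transformed and
z-scored per gene before Lloyd's algorithm with 100 random restarts
(constant genes map to the zero profile); clustering on the log scale
without standardization is available via a flag.  Missing values are
first interpolated linearly over the ordered samples.

## Co-expression rank bias

For each seed gene, every other gene is ranked by Pearson correlation
across samples (descending, ties by gene id; zero-variance genes get
r = 0 with a warning).  Rank histograms over equal-width bins of
[1, universe] are the primary, assumption-free output.  As a formal
statistic — an extension over a purely visual reading — the package
tests "set A ranks above set B" with a one-sided Mann-Whitney U
(U = pairs with rank_A < rank_B, AUC = U/(|A||B|)): exact by full
enumeration when |A| + |B| <= 12, otherwise a normal approximation with
tie and continuity corrections.  A deterministic
uniform sampler provides random control sets (e.g. 500 genes).

## Synthetic data: what it emulates, and what it does not

The generator produces, per seed: 0-order i.i.d. promoters (default
2000 x 1000 bp, a ~1/6 scale of a 12 643-promoter catalogue, with
set sizes 175/210 scaling the 1106 up- / 1329 down-regulated sets);
planted motif instances at per-set frequencies (defaults 30% in the up
set vs 10% elsewhere); a two-group microarray (500 genes, 1-4 probes per
gene with distance-attenuated signal, 25 up- and 25 down-shifted genes
at |log2FC| = 4, lognormal noise sd 0.5 log2, 5% dead probes); a
10-sample senescence panel of 7 archetypes x 13 genes (91 genes, so the
cluster-number rule lands on 7); Ct tables (triplicates, cycle noise sd
0.15, 2% injected outlier wells, four reference genes of graded
stability); and a correlation-structured expression matrix for
co-expression ranking (one latent profile shared by a 40-gene
co-regulated set at noise sd 0.5).

Two generator design points deserve emphasis:

* **Planted instances are near-consensus.**  Words are sampled from a
  sharpened instance scheme (core 0.995, minor 0.99) rather than from
  the reporting matrices.  Since the scanner's accepted set at p <= 1e-4
  is essentially the consensus word, sampling instances from the flatter
  reporting weights would conflate the planted frequency with a ~34%
  detection rate; with the sharp scheme >= 95% of planted words are
  detectable and the planted fraction is the effect size it is meant to
  be.
* **Unstable reference genes drift; they are not merely noisy.**  With
  10 samples, geNorm's pairwise-SD estimator cannot reliably order
  references whose only difference is fine-grained i.i.d. well noise —
  the estimator's sampling error matches the M differences.  Real
  reference-gene instability is dominated by regulation, so the
  synthetic references combine graded well noise (0.05-0.5 cycles) with
  graded systematic log2 drift across the series (0, 0.5, 1.2, 2.5, each
  with a distinct shape so the drifters do not covary).  The most stable
  reference is then recovered in >= 95% of seeds, while the separate
  i.i.d.-noise monotonicity property of M is tested at the operation
  level.

Archetype shapes (very-late extreme riser ~11.6 log2; late riser ~8;
late peak; linear riser of amplitude 2; fast-saturating riser of
amplitude 4; near-flat with a 1.5-log2 mid transient; late decline of 3)
were chosen to be mutually distinguishable after per-gene
standardization: pattern clustering discards amplitude, so the shapes —
not the amplitudes — carry the cluster identity, and the two pinned
amplitudes (2 and 4) distinguish the moderate and early risers only via
their shapes.

What the synthetic data does **not** emulate: real promoter base
composition and repeat structure (0-order background only), probe
thermodynamics and cross-hybridization, dissociation-curve artefacts,
amplification-efficiency differences, and any real co-expression
network topology.  Passing recovery tests therefore demonstrates that
the *pipeline* is correct and calibrated under its stated model, not
that the biological conclusions would replicate on new tissue.

## Numerical choices and degenerate inputs

Score grid granularity 0.01 log2 units (error bounded by L/2
granularity per window score; exactness verified by enumeration at
small L); grids above 10^7 cells are refused with a suggestion to
coarsen.  Probability floor 0.001 keeps log-odds finite.  Hypergeometric
tails are summed in log space (gammaln + logsumexp) and clipped to
[0, 1].  Quantile normalization of a single column is a warned no-op.
A contrast group with a single array downgrades the ranking to fold
change with missing p-values.  Empty probe groups, empty gene sets,
non-positive quantities, out-of-bound hypergeometric quadruples, and
sets outside the scanned universe raise errors naming the offending
item.  K-means is deterministic given the seed; its restarts only ever
improve inertia.

## Reported problem sizes

The bundled tests and the reproduction script run at the scales stated
above (2000-promoter universes, 20-seed recovery studies, 400 null sets,
100 geNorm seeds, 10^6-window calibration checks); these sizes were
chosen as the package's default synthetic study conditions, with the
full 12 643-promoter scale available through `SimConfig`.

## Known limitations

The moderated t is a stand-in, not a limma replica; the geNorm variant
is single-pass; scanning supports 0-order backgrounds only (no
higher-order Markov models, q-values, or gapped motifs); co-expression
uses plain Pearson ranking rather than mutual-rank or network measures;
and the printed-table reproduction inherits one acknowledged discrepancy
— the one-tailed exact test puts the down-regulated union just inside
the 0.05 level (p ≈ 0.043 upper tail, 0.040 mid-p) where the original
table reports it as not significant; the cell is asserted in the tests
as a flagged discrepancy rather than forced to agree.
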