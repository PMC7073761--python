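# Methods

This note documents the models behind `potevo`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Substitution models and distances

Distances are computed from pairwise site-pattern counts after
**complete deletion**: every alignment column containing a gap or `N`
in *any* row is removed once, globally, before any pair is compared.
`N` is treated like a gap — the conservative choice, since an ambiguous
base cannot support a substitution call. Pairwise deletion (per-pair
site removal) is available but is not the default; the two differ
exactly when gapped columns exist.

* **Jukes–Cantor**: `d = -(3/4) ln(1 - 4p/3)` with variance
  `p(1-p) / (n (1 - 4p/3)^2)`.
* **Kimura two-parameter**: with transition proportion `P` and
  transversion proportion `Q`,
  `d = -(1/2) ln((1-2P-Q) sqrt(1-2Q))` and variance
  `[c1^2 P + c3^2 Q - (c1 P + c3 Q)^2] / n`,
  `c1 = 1/(1-2P-Q)`, `c2 = 1/(1-2Q)`, `c3 = (c1+c2)/2`.

Both closed forms are the analytic maximum-likelihood estimators; the
test suite verifies agreement with direct numerical likelihood
maximization to 1e-6 across a grid of (P, Q). The distance standard
error is the analytic (delta-method) one; a site-bootstrap alternative
falls out of the tree-bootstrap machinery but the analytic variance is
what the dating reports propagate, because it is deterministic and
matches the replicate spread to within ~10% in simulation.

Saturated pairs (`p >= 3/4`, or a K2P log argument <= 0) raise an error
rather than returning NaN/infinity: a silent non-finite entry would
corrupt neighbor joining downstream, so the pipeline halts and names
the offending pairs.

## Neighbor joining and support

Standard Saitou–Nei agglomeration on the distance matrix: join the pair
minimizing `Q(i,j) = (r-2) D(i,j) - R_i - R_j`; two-point formulas give
branch lengths; the final three nodes join at a trifurcating
(unrooted) root. Ties in the Q matrix are broken by the lowest (i, j)
index pair in the current node ordering, so runs are bit-reproducible
for a given input order and reproducible up to relabeling under
permutation. Negative branch lengths — an artifact NJ can produce on
noisy matrices — are clamped to zero with the deficit moved to the
sibling branch, a common convention.

**Bootstrap support** resamples alignment columns with replacement,
rebuilds the NJ tree per replicate, and reports, per interior edge of
the full-data tree, the fraction of replicates containing the same
bipartition (internally on [0, 1]; percentages only at presentation).
Replicates in which resampling produces a saturated pair are dropped
and counted; more than 20% dropped aborts the analysis.

**Interior-branch test.** The length of each interior edge is collected
across the bootstrap replicates (zero where the bipartition is absent);
the edge's standard error is the standard deviation of those lengths,
and the confidence probability is the one-sided normal probability
`Phi(length / se)` that the true length exceeds zero. A zero-length
edge with zero SE is reported at 0.5 by convention; a positive edge
with zero SE at 1.0. This is a bootstrap-z formulation of the interior
branch test and is labeled as such in reports.

## Rate constancy and clock dating

**Tajima's relative rate test** counts, over gap-free columns of an
(A, B, outgroup) triple, the sites where only A differs (`m1`) and only
B differs (`m2`); `(m1 - m2)^2/(m1 + m2)` is referred to chi-square
with 1 df (`m1 + m2 = 0` gives p = 1). Monte-Carlo calibration in the
acceptance suite puts the type-I error at the nominal 5% level within
[0.03, 0.07], and power above 0.9 against a threefold rate change
(10,000 sites).

**Calibration.** Each calibration pair (defaults: human–chimpanzee at
6 Myr, human–orangutan at 16 Myr) yields `R_i = K_i / (2 T_i)`. The
headline rate is the **unweighted mean** of the per-calibration rates;
both are retained in the output. The combination is deliberately
simple: with two calibrations there is nothing to estimate a weighting
from, and an unweighted mean keeps the estimator transparent. The rate
standard error combines the delta-method variance of each `R_i` with
the between-calibration spread.

**Dating.** `T = K / (2R)` exactly. The reported `se_T` propagates the
distance variance only (`sqrt(Var K) / 2R`), so the "±" on a date is a
per-event quantity; the version with rate uncertainty added in
quadrature is reported in a separate column rather than folded in. For
an event spanning several paralog pairs, K is the arithmetic mean of
the spanning pair distances and its variance is averaged as if the
pairs were independent (covariance between overlapping pairs is
ignored — a second-order effect at these divergences). Dating a
calibration pair against its own single-point rate returns the
calibration time exactly, which the tests assert as an algebraic
identity. The Tajima outgroup is always named explicitly in the
configuration; there is no automatic outgroup selection.

## LINE-signature classification

Four characters are extracted from a RepeatMasker track plus a gene
model:

* `l1m5_intron1` — any L1M5 hit overlapping intron 1;
* `intron9_cluster` — the ordered names of LINE hits overlapping
  intron 9, with non-LINE hits ignored and consecutive duplicate names
  collapsed (RepeatMasker fragments elements, so two adjacent `L1M5`
  rows are one element);
* `l1pa_invasion` — `L1PA*` hits covering at least 20% of the locus.
  "Massive invasion" has no published operational definition; 20% is a
  configurable default chosen to separate the invaded group-I locus
  (L1PA content well above a third) from the background (a few
  percent);
* `exon6_9_dup_content` — from the gene model: primed extra exons
  (6'–9') on top of the 11 canonical ones.

The rules R1–R4 (see README) are all evaluated; exactly one winning
group is required, otherwise the gene is `ambiguous` with the
conflicting rules listed. Ambiguity is a value, not an error — it is
the correct output for genes with mixed signatures.

Exon numbering follows the canonical 11-exon scheme; paralog-specific
extra exons are annotations, never renumbered, so "intron 9" always
means the intron after canonical exon 9.

## Inverted-repeat (LIR) detection

The detector runs Smith–Waterman local alignment (match +1, mismatch
-1, gap -2) of the sequence against its own reverse complement. Cell
(i, j) pairs base i with base n-1-j complemented; restricting the
matrix to `i + j <= n` removes the mirror-duplicate half of the search
space and forces the end of arm 1 before the start of arm 2. The matrix
is filled along anti-diagonals (each depends only on the previous two),
which vectorizes the O(n^2) fill. Up to 6 kb the full matrix is kept
for traceback; longer sequences get a score-only pass followed by a
windowed traceback behind the best cell (window `4*score + 200`), which
is exact for any arm above ~60% identity — comfortably covering
everything the 80% identity threshold can call.

Thresholds: an arm is a **full** LIR at >= 500 bp and a **half** LIR at
>= 200 bp (both at >= 80% identity), configurable. The full/half
distinction has no published operational definition; these defaults
put the two observed size classes of the family on opposite sides.
The test suite pins the detector to an independently written quadratic
SW oracle (identical scoring and tie-breaks: first maximum in
row-major order, diagonal-preferring traceback) and checks that random
2 kb sequences essentially never contain a 200 bp arm at 80% identity.

## Synthetic data

`synthetic_data` generates the ground truth every stage is tested
against:

* **Event trees**: species splits and duplications at stated times give
  an ultrametric time-tree (branch lengths in Myr). Duplications must
  be younger than the oldest (root) calibration split.
* **Sequences**: a uniform random root sequence evolves down the tree
  under a continuous-time K2P process; a branch of `t` Myr applies
  `d = R t` expected substitutions/site using the exact K2P transition
  probabilities, so the expected distance between lineages separated
  `T` Myr ago is exactly `2RT`. Defaults: `R = 1e-3`
  substitutions/site/Myr (the canonical primate neutral rate, 1e-9 per
  year, which makes the 6-Myr calibration distance ~0.012) and
  `kappa = 2.0` (typical mammalian transition bias — enough to keep K2P
  and JC distinguishable). Sequences are gap-free, so complete deletion
  is a no-op on them; `inject_gaps` exists solely to exercise deletion
  logic.
* **Repeat histories**: insertions stamped on a lineage appear in the
  RepeatMasker-style tracks of all its descendant leaves and nowhere
  else. Insertions are annotation-level only — the classifier consumes
  tracks, and sequence-level transposon insertion would require
  indel-aware alignment, which is out of scope. Per-group insertion
  plans reproduce the diagnostic signatures (including spreading the
  group-I L1PA invasion across introns so it clears the 20% locus-wide
  threshold within the template's intron sizes).
* **Presets**: six single-duplication scenarios with truth times 1.90,
  1.57, 1.07, 1.06, 0.55 and 0.44 Myr, each with chimpanzee (6 Myr) and
  orangutan (16 Myr) calibration lineages, 10,000 sites by default.

What passing these tests shows — and does not. The generator draws from
the very model family the estimators assume (K2P, clocklike, gap-free,
no rate heterogeneity across sites, annotation-level repeats), so the
recovery results demonstrate *internal correctness* of the estimators
at realistic parameter values, not robustness to alignment error, gene
conversion, indels, selection, or rate variation in real loci.
Problem sizes in the tests and acceptance script (10,000 sites, 200
replicates per scenario, 1,000 replicates for test calibration) are the
package's chosen trade-off between statistical resolution and a test
suite that runs in minutes on one CPU.

## Pipeline and reproducibility

All randomness flows from the single configured seed through named
SHA-256-derived substreams (`bootstrap`, `interior-branch`,
`simulate`), so any stage can be re-run in isolation and two runs with
the same config are byte-identical in their tables. Reports embed the
seed, a config hash and a checksum per output file. Stages run in a
fixed order (load, distances, tree + supports, rate tests, calibrate,
date, classify); a failure halts with the stage named, keeping earlier
outputs on disk.

## Known limitations

* No gamma rate heterogeneity, Tamura–Nei/GTR, or codon models; no ML
  or Bayesian topology search; no rate smoothing or Bayesian node
  dating.
* The event-K variance ignores covariance between overlapping paralog
  pairs.
* The K of a multi-pair event assumes the pairs straddle the same node.
* Repeat simulation does not alter sequences; classifier results on
  synthetic data are exact by construction and say nothing about
  RepeatMasker's own calling accuracy.
* The LIR windowed-traceback mode can mis-place coordinates only for
  arms below ~60% identity, which are reported as `none` anyway.
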