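# Methods

This note records the models, numerical choices and open design decisions
behind `o2nseq`, in the spirit of a statistical-software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The duplicate-copy error model

An o2n molecule is `primer(5) + fragment + adaptor(62) + fragment + tail(2)`
with both fragment copies in identical orientation.  Sequencing 2×L from
both ends reads copy 1 on mate 1 and copy 2 (reverse-complemented) on
mate 2.  Under an independent substitution channel with per-base error *e*
(uniform over the three wrong bases), a consensus base supported by both
copies is wrong iff both copies were misread identically:

    P(dual-supported consensus error) = 3 · (e/3)² = e²/3.

This is the quantitative heart of the method and is enforced as a 3σ
property test (`tests/test_consensus.py::TestErrorSuppression`) at e = 0.01,
where ~1.2M dual-supported bases give enough coincident events to resolve
the law.  Requiring *n* distinct consensus contexts multiplies further
suppression on top of this floor; the package only asserts the monotone
nesting of calls across levels, not a closed form for level *n*.

## Simulator

The generator draws, per molecule: fragment length uniform on [60, 120]
(the gel-cut window), start uniform over the reference, strand with
probability ½ (configurable), and — independently per molecule and per
site — the alternate allele of each spiked variant with its allele
fraction.  Errors are substitutions only; the downstream pipeline discards
indel-containing alignments, so indel simulation would add untestable
surface.  Qualities are a constant phred score (default Q30, error 10⁻³);
cycle-dependent decay and GC bias are deliberately out of scope.  Decoy
(non-right-on) pairs are adaptor-free reference fragments sequenced at full
read length — the minimal model that exercises the right-on detector and
the data-utilization denominator.

Two sequences of the molecule anatomy are not public: the 5-base
second-strand primer prefix (a fixed synthetic 5-mer, `GACTG`, stands in)
and the post-nick tail, set to `CT`, the two bases 3′ of the dU nick site in
the printed adaptor oligo.  The 62-base blocking oligo is used as the
canonical intermediate adaptor; the two printed adaptor strands sum to
61 nt, a 1-nt discrepancy we note but do not resolve.

The consensus-level generator (`simulate_consensus_reads`) draws fragments
identically but applies the dual-copy channel directly (per-base error
e²/3, every base dual-supported at Q60).  It exists because very deep
experiments (20,000× consensus) would otherwise need ~2.4M raw reads to be
collapsed pairwise; the raw-read path and the consensus-level path share
the fragment/variant model, and the raw path is exercised end-to-end at
~800× in tests and in the acceptance script.

## Preprocessing

Adaptor matching must handle the dominant case where only a short adaptor
prefix is sequenced at the read end (fragment ≥ 60 bp leaves ≤ 60 adaptor
bases in a 125 bp mate, and ≥ 113 bp fragments leave fewer than the 8-base
minimum overlap — those molecules are unrecoverable by design).  The
matcher scores every end-gap-free placement, tolerating
`ceil(0.1 × overlap)` Hamming mismatches; the best match minimises the
mismatch ratio with ties toward longer overlap, then smaller offset.  Exact
placements are located with C-speed string search; the tolerant scan runs
only when no exact placement exists (a few percent of reads at Q30).
Hamming distance suffices because indels are discarded downstream.

Quality rules follow the stated order — trailing sub-20 trim, 4-base
sliding-window cut, length ≥ 36, mean ≥ 20 — with two refinements.  The
window cut lands on the first individually sub-par base *inside* the
failing window (leading good bases of that window are kept), and the
trailing trim is re-applied after the cut.  The first choice is forced by
the rule's worked behaviour on a read with four Q10 bases at positions
50–53 (the cut must leave 50 bases, not 49); the second makes filtering
idempotent, which the bare rule order is not when the base preceding a
failing window is itself below 20.  Both are enforced against a brute-force
oracle and a hypothesis property test.

When only one mate locates the adaptor, the other mate's target is its full
post-prefix remainder.  Junk (adaptor) bases carried this way end up
single-covered, hence `'#'`-masked, and large junk tails simply fail
mapping; the analytic yield model (below) accounts for this loss.

## Consensus

Copy alignment is an exhaustive end-gap-free offset search maximising exact
matches, with lossless pruning: offsets whose maximum possible overlap
cannot exceed the best match count found so far are skipped, and ties go to
the smallest absolute offset (positive first), so evaluating offset 0 first
makes near-identical copies O(mismatches) instead of O(length²).  "Less
than 2 mismatches" is read literally: at most 1 mismatch in the overlap.

The consensus takes the union of the aligned copies.  Agreeing dual
positions get `min(93, q1+q2)`; single-covered positions get quality 2
(`'#'`).  At the one tolerated disagreeing position the higher-quality base
is kept (ties toward copy 1) but the quality is masked to 2 — the method's
base-quality ≥ 50 filter then automatically excludes it from variant
evidence while preserving read length for mapping.  This disagreement rule
is our choice; the source pipeline does not state one.

## Mapping and calling

The internal mapper is ungapped: candidates come from all exact substring
occurrences on both strands plus tiled 15-mer seed hits; a placement is
scored by its Hamming mismatch count, reads with best > 3 mismatches are
unmapped, and mapq is 60 only when the best placement beats the second best
among the candidate set by ≥ 2 mismatches (else 0, which the mapq ≥ 25
filter then drops).  With *s* tiled seeds any placement carrying < *s*
mismatches shares an exact seed, so for reads ≥ 45 bp (3 seeds) the
candidate set provably contains every placement within 2 mismatches; this
is the deliberate trade against a full Smith-Waterman, which the pipeline's
own indel-discarding filters make pointless.

Post-mapping filters: mapq ≥ 25; bases below quality 50 masked (this
removes every `'#'` base); 3 terminal bases masked each side; and at most
one mismatch counted *over usable bases only* — whether masked-base
mismatches count is not specified upstream; we exclude them, since masked
bases are defined to carry no evidence.  Pileup accumulates strand-resolved
coverage in O(1) per read (interval difference arrays) plus explicit
bookkeeping only for non-reference observations, whose distinct contexts
`(mapped start, length, sequence)`, strand counts and qualities feed the
*n*×CS caller.  Depth conservation (Σ allele counts = column depth = Σ
usable bases) is asserted per run in tests.

The frequency filter is never hard-coded: 0.005 is the conventional choice
for 1%-mixture experiments, and half the theoretical minor AF (0.0345% for
a 1,000:1 mixture of strains differing at a fixed site with minor-strain
AF 0.6888) for ultralow mixtures.

## Evaluation statistics

Error rate at level *n* counts non-reference base *observations* whose
allele has distinct-context support ≥ *n*, over all usable observations at
surveyed positions (gold-standard sites and excluded positions removed from
both sides).  The per-observation (rather than per-allele) numerator is our
resolution of an ambiguity in the level-*n* extension; it makes levels
nest by construction.  Sensitivity matches calls to gold sites by
(position, alternate base); FPR is FP/(TP+FP) over eligible calls.  Depth
CV uses the population standard deviation with 100 bp edge exclusion;
zero-depth sites are excluded from the ln(depth/mean) summary.

## Library sizing

Experiments size libraries analytically, before any pipeline output is
seen: expected usable consensus bases per generated pair ≈ mean over
fragment lengths F of `(F − 6) · P(keep | F)`, where F ≤ 112 is required
for junk-free adaptor location and `P(keep)` is the Poisson(2e(F−3))
probability of ≤ 1 copy mismatch; `n_pairs = depth × genome / yield`.  The
acceptance experiments use a 10 kb reference with 100 spiked 1%-fraction
sites at ~800× (full raw-read pipeline, ~116k pairs, a few minutes on one
CPU) and a 5,386 bp reference with two sites at 6.9×10⁻⁴ / 8.0×10⁻⁴ at
20,000× (consensus-level generator, ~1.28M reads).  These sizes are the
package's desk-scale defaults; megabase genomes at publication depth are
out of scope.

## Amplicon-validation posterior

The typeset source of the posterior is partially unrecoverable (two formula
images), so the channel is a documented reconstruction: given true minor
count `r`, the observed minor count is `Binomial(r, 1−q)` survivals plus
`Binomial(n−r, q/3)` major-to-this-minor errors — q/3 being the standard
symmetric-channel assumption for a specific wrong base.  The prior on θ is
flat (none is stated).  θ is sampled uniformly 1,000 times from
`o/n ± 5·sqrt(max(o/n, 1/n)(1−o/n)/n)` clipped to [0,1]; the 1/n variance
floor keeps the region nonzero at o = 0.  Marginalisation over r is an
exact truncated summation (relative tail 10⁻¹²) in log space rather than
the unavailable iterative scheme; agreement with a deterministic full-grid
(step 10⁻⁵) marginalisation, and 95% ± 3% frequentist coverage over 500
simulated loci, are enforced in tests.  Credible intervals are weighted
2.5/97.5 percentiles of the θ samples (midpoint-interpolated), so the o = 0
lower bound is near but not exactly zero — at most ~1/n in the tested
regimes.

The strand-bias filter is the standard two-sided Fisher exact test on the
major/minor × forward/reverse table, phred-transformed, with a hard cutoff
of 60 and a 500× minimum depth; it is checked against an independent
hypergeometric enumeration oracle.  The neighbor rule uses strict
inequalities on both clauses.

## What passing tests do and do not show

The synthetic generator has uniform coverage, a constant quality score, no
PCR duplicates, no chimeras, no indels and a uniform substitution channel.
Passing the suite therefore demonstrates the *algorithmic* contracts — the
e²/3 law, filter semantics, nesting, posterior calibration under the
model's own channel — not performance on real instrument data, where
context-dependent errors, quality miscalibration and mapping ambiguity in
repetitive genomes all degrade the idealised numbers.  Real-library
headline statistics (error rates to 10⁻⁸, 13.65% utilization, 27.59% depth
CV) require the original deposited sequencing data and are explicitly out
of desk scope.
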