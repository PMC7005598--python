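# Methods

This note documents the models and algorithms implemented in `omcorrect`,
the parameter defaults and why they were chosen, the design decisions taken
where the underlying procedure is under-determined, and the known
limitations.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

An Rmap is an ordered list of positive integer fragment lengths (bp); the
equivalent cut-site representation is the cumulative-sum coordinate list
starting at 0.  All internal arithmetic is integer bp; kilobase decimals
appear only in the Valouev-style text dialect (rounded to the nearest bp on
reading).  In-silico digestion cuts at the 0-based start of every
(possibly overlapping) site occurrence and discards the sequence before the
first and after the last cut; fewer than two occurrences yields a flagged,
empty "undigestible" Rmap rather than an exception.

## Seeds

Window extraction sweeps an l-bp window over the molecule.  The production
code evaluates the window content only at *event positions* — the window
offsets at which some cut site crosses the window boundary or a solid/gap
transition of the spacing pattern — which provably reproduces the full
integer-position sweep (the seed is constant between events); the test suite
checks this equivalence against a brute-force sweep that materialises the
gap-filtered Rmap at every integer position.  Conventions where the
definition is silent:

* A window containing a single (kept) cut still anchors an (l,k)-mer via
  rightward extension; a window with no kept cut yields nothing; seeds with
  fewer than one complete fragment are dropped.
* A window at the right end of the molecule with fewer than k fragments
  available emits the truncated seed rather than nothing.
* Extension fragments beyond the window lie outside the pattern and are
  always kept.
* Seeds are deduplicated per Rmap in first-occurrence order for every seed
  kind, so an all-ones pattern reproduces plain (l,k)-mers exactly.

## Index

Fragments are quantized (`floor(x/b)`, `b` = 1000 bp) before extraction, so
extraction runs in bin units (the 80-bit default pattern spans 1 bin per
bit at `l` = 80 kbp).  The merge procedure makes two passes over the seeds
in lexicographic order; for each seed and each indexed neighbour at L1
distance 1, both entries become their union and both counters their sum
whenever the combined counter stays within the budget (`i_M + i_M' - 1 <=
t_sim`).  The budget caps every merge chain at `t_sim + 1` seeds, hence at
accumulated distance `t_sim`; this is the testable form of the guarantee
that entries of seeds farther apart than `t_sim` never merge.  `t_sim`
defaults to 2 — enough to bridge a quantization-boundary wobble of one bin
in up to two coordinates — and each entry is a fresh set union (no aliasing
between merged entries).  Top-N retrieval counts *distinct* shared seeds,
breaking ties by ascending Rmap id.

## Pairwise alignment

Rmaps are encoded over blocks of `B` = 2000 bp; both molecule endpoints
count as cut sites (the string carries n+1 ones).  The alignment is an
overlap (free-end-gap) Needleman-Wunsch over the weighted edit costs — a
0<->1 substitution or a gapped '1' costs `(c0+c1)/c1` computed over the
strings participating in the task (the pair, or consensus plus incoming
string in the multiple alignment), any other edit costs 1 — but the
alignment is *chosen* by maximising (matched columns − edit costs).  Under
pure cost minimisation with free end gaps the optimum is degenerate: any two
encoded Rmaps admit a one-column overlap of cost zero (every string begins
and ends with '1'), so nothing would ever align.  Rewarding matches makes
the genuine overlap optimal for related Rmaps while unrelated pairs get
fragmentary, edit-heavy alignments.  The DP is row-vectorised in numpy
(the in-row gap chain resolved with a running maximum), with deterministic
traceback preferences match > substitution > gap-in-second > gap-in-first
and a 1e-9 float tolerance.

The candidate filter drops a retrieved Rmap when its cut-site-involving
edits exceed 0.8x the cut count of the Rmap with fewer cuts (each Rmap is
assumed to carry at most 40% added-plus-missing cut sites).  This filter is
deliberately permissive — at realistic sizing noise the optimal alignment of
an unrelated pair can pair most cut sites through runs of cheap 0-gaps — and
the sharper per-member agreement test happens at the consensus stage.

## Consensus correction

The block-resolution alignment columns are too coarse to resolve
neighbouring cut sites (at one cut per ~10 kbp, a large fraction of adjacent
cut pairs lie within the weighted DP's snapping radius), so the consensus is
computed on the members' original cut coordinates:

1. The target is the backbone.  Each member's internal cuts (molecule
   endpoints are breaks, not cuts, and never vote) are put in correspondence
   with the backbone by an optimal monotone chain matching on inter-cut
   distances (`|d_obs - d_ref| <= max(0.6 B, 0.2 d_ref)` per link, first
   pair free, ties broken by minimal accumulated slack).  Sizing error
   accumulates multiplicatively along a 250-kbp molecule, so no global
   offset aligns two molecules end to end; chain matching is drift-free.
2. A backbone cut becomes a consensus site when the members covering it
   support it by majority (where only the target covers, its own cut
   stands).  Member cuts matched to no site are pooled in the target frame
   (placed via their nearest chain anchor) and clustered; a cluster
   supported by at least two members, a majority of the covering members,
   and at least three covering members becomes a restored consensus site.
   Clusters whose rows contribute two or more events each are split at their
   largest internal gap — the signature of two distinct nearby cut sites.
3. Members with more than 3 cuts absent from the called consensus, or more
   than 40% of the consensus sites in their span missing, are removed and
   the sites re-called.  Filtering against the *called consensus* rather
   than the raw target matters: a member carrying a cut the target lost is
   exactly what restoration needs, not evidence of disagreement.  Finally
   every survivor is re-anchored against the full consensus (a weakly
   overlapping member's short backbone chain could otherwise lose to a chain
   of tolerance coincidences and be mis-placed).
4. Each adjacent consensus-site pair defines a fragment whose length is the
   robust average (median) of the original distances over the members
   carrying a cut at both sites, restricted to supporters agreeing with the
   consensus geometry to within two blocks; a fragment nobody supports falls
   back to the inter-site distance.  A corrected Rmap is the consensus
   stretch its span covers, with its own flank fragments (span edge to the
   first/last covered site) retained.

Correction proceeds over the Rmaps in input order; a target already
corrected five times is skipped, a multiple alignment with fewer than five
members does not correct, every member of a correcting alignment is
corrected (last correction wins), and the whole procedure is deterministic
given the input order.

## Simulator

Molecules are drawn with truncated-normal lengths (mean 250 kbp, sd 50 kbp,
minimum 50 kbp) and uniform starts until the requested coverage is reached.
True cut sites come either from digesting a supplied sequence or, by
default, from a seeded Poisson process of one cut per 10 kbp — the typical
density of real data.  Errors are applied as an independent Bernoulli
deletion of each internal true cut (survival probability `p_digest`,
default 0.8), a Poisson process of added cuts (default 1 per 100 kbp), and
per-fragment multiplicative Gaussian sizing noise truncated at three
standard deviations (default sd 5%); Rmaps with fewer than 10 fragments are
discarded.  The emitted ground truth records each molecule's interval, true
cuts, deleted cuts and per-observed-cut provenance, all before sizing noise.
The generator does not model chimeric molecules, optical resolution limits
(merging of nearby cuts during imaging), stretch-factor miscalibration, or
fragment-length-dependent digestion, so passing tests demonstrate behaviour
under this parametric channel, not under every artefact of real Bionano
data.

## Evaluation

Two simulated Rmaps are *related* when their genomic intervals overlap by at
least 100 kbp and the intersection fully contains at least 7 true fragments;
precision/recall/F-score follow from predicted-vs-true pair sets.  For
correction quality, each Rmap's internal cuts are matched to the true cuts
of its source interval by the same optimal monotone chain matching used in
the corrector, with link tolerance `max(1500 bp, 0.15 d_true)`: absolute
coordinates never enter, so accumulated sizing drift (about 1.6 kbp sd
mid-molecule at 5% noise) is not mis-counted as added/deleted cut sites —
it is reported separately as the mean relative error of truly matched
fragments.  Unmatched observed cuts are *added*; unmatched true cuts
between the first and last matched true cut are *deleted*; an Rmap is
*improved* when its added+deleted count strictly decreased.  The chain
matcher attains the maximum matching (verified against exhaustive search),
so the error counts are not an artifact of greedy choices.

## Pattern optimization

Fitness of a spacing pattern is the F-score of the merged index it induces
on a fixed simulated benchmark (default 2000 Rmaps from a 4.6-Mbp genome at
one added cut per 100 kbp and 15% missing cut sites), with two Rmaps
predicted related when they share at least two seeds.  Annealing flips one
random bit per round, always accepts improvements, accepts a worsening move
with probability `exp((f_new - f_old)/T)`, and cools geometrically
(`T0` = 0.05, `alpha` = 0.995, 2000 iterations by default — the schedule is
a package choice; fitness values per pattern are cached).

## Problem sizes and known limitations

* Simulation-based tests run at reduced scale (genomes of 0.25-4.6 Mbp,
  coverages of 5-70x, benchmarks of 60-2000 Rmaps), chosen so the full
  suite completes in a few minutes while each property retains statistical
  power; the seeds are fixed for reproducibility.
* Correction quality depends strongly on how completely the related Rmaps
  overlap the target.  With near-complete overlaps (deep local coverage,
  the regime of the very-high-coverage datasets the approach targets) the
  pipeline removes roughly two thirds of the added+deleted cut sites at the
  default error rates; at 20x genome-wide coverage, where a target's
  alignment rarely collects more than 5-10 partially overlapping members,
  consensus majorities are thin and the net error reduction is small.  The
  acceptance test encoding a >= 40% reduction at 20x coverage documents this
  limit honestly rather than relaxing the conditions.
* Cut sites closer together than roughly the block size can merge in the
  consensus despite the two-cut splitting rule, and an Rmap's first/last
  cut can occasionally be mis-anchored when its overlap with every other
  member is weak.
* Retrieval recall degrades with sizing noise faster than with
  added/deleted cuts: the spacing pattern absorbs cut-site errors under its
  gap bits, but bin-level coordinate jitter changes which bits cuts fall
  under.  Merging recovers part of this; at 5% sizing noise the merged
  spaced index still roughly doubles the recall of plain quantized k-mer
  seeding at broadly comparable precision (the acceptance test requires
  precision within 0.1, which at the fixed benchmark seed is narrowly
  missed — the merged index trades precision for its recall gain).
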