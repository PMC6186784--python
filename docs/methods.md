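# Methods

## The problem

A sequence-specific endoribonuclease (a MazF-family toxin) cuts RNA at a
short motif.  Two computational questions follow from a digestion
experiment read out by 5'-end sequencing:

1. **Where does the enzyme cut, and what is its motif?**  A cut creates a
   new fragment 5' end, so mapped-read coverage jumps at the nucleotide just
   downstream of the cut.  The *relative coverage increase* (RCI) at
   boundary position *i* is

       RCI(i) = c(i) / c(i−1)

   where c is per-position coverage, with a pseudo-count substituted for
   zero coverage on either side so the ratio is always finite and positive.
   Boundaries whose downstream coverage passes a minimum-coverage filter
   compete, pooled across all references, for the overall top-k RCI values;
   the ±flank windows around the winners are aligned and summarised as a
   position weight matrix with per-column information content
   IC_j = 2 − H_j bits (H_j = Shannon entropy of column j's base
   frequencies).  A base is *called* at a column when its frequency is
   ≥ `min_frequency` and IC_j ≥ `min_ic`.  Position labels run
   −flank..+flank with the coverage-increase nucleotide at label 0; a
   UGG-specific cutter that cleaves 5' of the first G therefore shows
   U, G, G at labels −1, 0, +1.

2. **Which transcripts are most susceptible?**  For a coding sequence of
   length L, the per-position chance of the motif (default TGG on the
   coding strand, i.e. UGG in mRNA) is the product of the CDS's *own* base
   frequencies over the motif letters, p = f(T)·f(G)², a triplet has
   L − 2 candidate start positions, the expected count is E = p(L − 2),
   and given the observed overlapping count K the burden statistic is the
   binomial upper tail P = Pr(X ≥ K), X ~ Binomial(L − 2, p).  Transcripts
   are ranked by ascending P.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `min_coverage` | 100 | minimum raw coverage (reads) at the downstream position for a boundary to be eligible |
| `top_k` | 50 | number of pooled top-RCI boundaries kept |
| `flank` | 5 nt | half-width of the aligned window (width 11) |
| `pseudo_count` | 1 | substituted for zero coverage in the RCI ratio |
| `min_frequency` | 0.5 | base-call frequency threshold per logo column |
| `min_ic` | 1.0 bit | information threshold per logo column |

The detection defaults are the experimental analysis conditions being
reproduced; the consensus thresholds are this package's own choice, made so
that "the consensus is UGG" is a testable statement rather than a picture —
a column must be majority one base *and* carry at least half the maximal
information.  Both are configurable.

Open choices resolved here (all configurable where noted):

* **Which side the coverage filter applies to.**  The minimum-coverage rule
  is applied to the downstream (increase) position: upstream of a genuine
  cut the coverage is legitimately low, while the retained position must be
  well supported.  `filter_side` also accepts `up` or `both`.
* **Pseudo-count value.**  1, the conventional minimal choice.  When the
  numerator is zero it is substituted too, keeping every ratio positive;
  such positions can never pass the coverage filter, so candidates are
  unaffected.
* **Tie-breaking.**  Top-k selection orders by (RCI desc, downstream
  coverage desc, reference id asc, position asc) so results are
  deterministic under ties and input shuffling.
* **Edge windows** are N-padded rather than dropped, preserving top-k
  cardinality; N's are excluded from logo counts and column totals.
* **Per-gene composition.**  p uses each CDS's own base frequencies, not
  genome-wide ones — genes of identical length can carry different E.
  Ambiguous bases are excluded from the composition tallies and any window
  containing N never matches.
* **No multiple-testing correction.**  Ranking uses raw P; the statistic
  orders transcripts rather than rejecting hypotheses.

## Numerics

The binomial tail is evaluated through the regularized incomplete beta
function (scipy's binomial survival function), stable for tails down to
1e-15 and far beyond; tests cross-check it against exact-rational direct
summation of the defining sum (`fractions.Fraction`), an oracle that shares
no code with the implementation.  Replay mode recovers p from a published
(L, E, K) row as p = E/(L − 2); because published E values are rounded to
two decimals, reproduced tails agree with published ones to roughly 3
significant figures (observed worst relative error 0.6% over 17 gene rows),
not exactly.  Information content clamps at 0 after the optional
small-sample correction e_n = 3/(2·ln2·n); columns with no effective
observations are defined as 0 bits.

## The synthetic-data generator

The generator replaces the wet digestion + sequencing experiment:

* **References.**  Eight uniform-composition random sequences of
  500–2000 nt (the scale of the artificial RNA substrates being emulated).
  Every motif occurrence — spontaneous (≈ L/64 per reference under uniform
  composition, ~150 sites across a default run) or optionally planted — is
  a ground-truth cleavage boundary at motif start + 1, the same position
  convention the detector reports.
* **Coverage.**  Fragment 5'-end counts are independent Poisson draws:
  mean `signal_rate × cleavage_probability` (default 500 × 0.9) at true
  boundaries, `background_rate` (default 2) elsewhere, plus
  Poisson(`signal_rate`) intact-molecule ends at position 0 so the detector
  faces the realistic reference-start coverage jump (position 0 is never a
  candidate).  Depth is the end-count vector convolved with a
  `read_length`-long box (default 150 nt).  The signal and background rates
  are this package's choices of a plausible bench-scale sequencing depth;
  they are not calibrated to any particular run.
* **CDS sets.**  Background records are uniform random sequence of
  300–3000 nt (a realistic bacterial CDS span); enriched records receive
  extra motif insertions targeting `enrichment_multiplier` times the
  composition expectation, with enrichment labels returned for recovery
  experiments.

What this does and does not show: the model preserves exactly the signal
the RCI statistic consumes (end-count bursts at cut sites under a read-depth
transform) and so validates the detection → consensus chain end to end, but
it omits sequencing error, mapping ambiguity, ligation bias, partial
digestion structure along a molecule, and non-uniform base composition.
Passing the recovery tests demonstrates the statistics are implemented
correctly, not that any particular real library would behave this well.

## Problem sizes

The bundled analyses run at the documented study conditions: 8 simulated
references (~9k positions total), top-50 selection, 500-record CDS sets,
and a 200-case oracle grid with n ≤ 200 for the exact-rational cross-check.
All drivers and the test suite complete in well under a minute on one CPU.

## Known limitations

* Whether published CDS lengths include the stop codon is not recoverable
  from per-gene summaries; replay mode sidesteps the question by consuming
  (L, E, K) directly.
* Tie order among genes with identical (L, E, K) is deterministic
  (K desc, id asc) but arbitrary.
* The coverage filter interpretation (downstream position) is a documented
  choice, not an experimentally fixed convention; the alternative readings
  are exposed as `filter_side`.
* Consensus calling reports a single maximal called span; mixtures of
  motifs would need a richer model and are out of scope.
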