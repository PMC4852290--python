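# Methods

This note documents the models, decision rules and numerical choices behind
`exevol`, and what the synthetic benchmarks do and do not demonstrate.

## The object of study

A gene model is an ordered list of exons (0-based half-open genomic
intervals in transcript orientation), the spliced coding sequence, and the
adjacent noncoding sequence (introns and, by default, 300 bp of flank on
each side). Exon lengths include the stop codon in the terminal exon; this
is configurable in spirit but is the convention used throughout because it
makes exon lengths sum exactly to the CDS length. Frameshifted or
stop-less coding sequences are legal inputs: the CDS is defined by the
annotation, not by an open reading frame.

Curation follows three quantitative rules: coding sequences shorter than
400 bp are removed; within a species, sequences more than 95 % identical
at the CDS level (global alignment, match 1 / mismatch 0 / gap open 10 /
extend 0.5, identity = matches over non-terminal-gap columns) are collapsed
to one representative (longest CDS, ties by id); among isoforms of a locus
the transcript with the fewest structural differences from its nearest
homolog is kept (ties by smaller total difference length, then id).

## Alignment

Two routes produce the codon alignment. When a curated protein alignment
exists it is projected codon-by-codon onto the CDSs (each residue column
becomes a codon triple; a terminal stop is appended ungapped). Otherwise a
built-in progressive aligner merges sequences post-order along the input
tree with affine-gap profile alignment, followed by one leave-one-out
polish pass (each row realigned against the profile of the rest, kept only
if the sum-of-pairs score strictly improves — tie-equivalent
rearrangements would otherwise break the gap agreement between rows that
share an event). This aligner exists so synthetic, desk-scale analyses
need no external tool; it is not a substitute for a production multiple
aligner on deeply diverged data.

Pairwise scoring defaults to match +2, mismatch −3, gap open −5, gap
extend −2 (a gap of length L costs 5 + 2L), with deterministic traceback
(diagonal, then up, then left). The *profile* merges instead use mismatch
−4: with −3, a column of novel sequence against anything scores −1.75 in
expectation, which outscores a gap extension at −2, so gained exons and
insertions would absorb into neighboring blocks instead of gapping out.

Exon boundaries are mapped through each row's column map; boundary columns
shared by a majority of the rows informative there define consensus exon
blocks. Refinement then canonicalises gaps: identical runs are left-aligned
group-wise whenever the sum-of-pairs score does not drop, runs straddling a
consensus boundary are pushed to one side when possible (and flagged
otherwise), and equal-length runs parked a few columns apart are snapped
onto shared columns. Columns are masked (and excluded from export and
classification) when more than 80 % gapped, downstream of an unrepaired
frameshift, or where independent events with disjoint carriers overlap.

## Event classification

Every gap column must end up attributed to an event or to the mask. Within
each consensus block, maximal column intervals with a constant gapped-row
set are classified:

* strictly interior intervals → intraexonic indel (polarity deferred);
* intervals at a block edge, anchored by the ungapped rows' own
  boundaries → boundary events: if the extra sequence matches the gapped
  rows' adjacent intron/UTR end, the event is exonization-class
  (exonization vs pseudoexonization decided later by the tree); otherwise
  it remains an indel;
* rows missing (almost) an entire block → whole-exon change, refined to
  exon gain/loss by the tree; a scan of the partner's noncoding sequence
  distinguishes exonization of pre-existing sequence from true gain;
* boundary columns present in some rows and absent, gap-free, in others →
  intron gain/loss, verified by the perfect-alignment test: the merged
  exon must align to the two partner exons with ≥ 0.9 identity in each
  half and the junction within 3 bp;
* terminal-exon length differences trigger the stop-codon analysis:
  readthrough (the shorter gene's stop is substituted, not gapped, and the
  extension matches its 3' UTR) yields exonization whose length counts the
  new sense codons; a 1–2 bp frameshifting indel followed by a premature
  in-frame stop yields a linked indel + pseudoexonization pair, the
  pseudoexonized length being the reference coding nucleotides beyond the
  new stop.

The anchored homology test for boundary extras is gapless (recruited or
released sequence is contiguous) and graded: a single mismatch is
tolerated up to 6 bp, two up to 12 bp, identity ≥ 0.7 beyond; nothing
below 3 bp is probed, and matches flush with the intron end outrank offset
ones. The unanchored noncoding scan keeps the alignability rule (identity
≥ 0.5 over ≥ 15 columns) plus a significance floor of 2·log₄(m·n) + 12
score points — the best chance local alignment of unrelated sequences
grows logarithmically, and without the floor random backgrounds produce
spurious "homologs".

Post-processing merges fragments of one event (same marker rows within
three columns; staircase fragments whose union gives every involved row
the same gap count) and re-tests drifted boundary gaps at nearby
junctions, since left-alignment can park a boundary gap a few columns
short of the exon end. Boundary extras are read from the partner's own
annotation (exon sequence), not from alignment columns, which makes the
probes immune to residual gap-placement noise.

## Parsimony mapping and ancestral structures

Each event's marker state (gap present / exon merged / exon absent) is a
binary leaf character. Placement minimises state changes; among
equally-parsimonious reconstructions the single-origin scenario is
preferred, then the root-most origin (implemented as a lexicographic
Sankoff over (changes, origins, origin-depth sum)). The root state is the
designated outgroup's state when one exists, else the majority preference
of the two root-adjacent subtrees (ties flagged). Equal-cost single-branch
alternatives are reported, not silently discarded. Events count one step
each regardless of length.

Ancestral structures propagate root estimates: for each consensus exon the
root length is inferred from the leaves' annotation-derived lengths minus
the signed event lengths on their paths (all leaves must agree), and each
node's length adds the deltas on its path — so path conservation holds by
construction and is asserted against the annotations. Intron gain/loss
merges or splits blocks on the affected side of the branch; whole-exon
events toggle presence. Stop-codon events move the stop codon as well as
recruiting/releasing coding sequence, so their exon-length delta exceeds
the event length by the 3-bp stop.

Two bounded repairs run before the hard inconsistency error: a junction
event can be re-attributed to the other exon of its junction (a 3'-side
change of exon *j* and a 5'-side change of exon *j+1* are the same
evidence; the wrong filing puts the delta on the wrong exon), accepted
only if it fully restores consistency; and 1–3 bp single-row indel calls
contradicted by the gene's own annotation are suppressed as alignment
noise (marked, not deleted, in the outputs).

Structural-divergence ranking scores each gene by the events on its
root-to-leaf path, weighting frame-violating events 1 + 2; caller-supplied
thresholds produce nested retained subsets, the analogue of building
progressively stricter alignment matrices.

## The synthetic-data generator

Families emulate MADS-box-like genes: an 8-exon ancestor with template
lengths 185, 79, 62, 100, 42, 42, 137, 85 bp (the inferred ancestral SEP1
configuration; conserved MADS/I/K core, variable terminal exons), random
sense codons ending in TAA, 200-bp introns with GT..AG ends, 300-bp
flanks. Trees are random bifurcations of seven ingroup taxa plus an
outgroup. Per branch, sites substitute with probability 0.01 — a
within-subfamily divergence scale consistent with the ≥ 0.9
perfect-alignment rule — and events arrive Poisson with per-branch rates
(insertion/deletion 0.06 each, exonization/pseudoexonization 0.025 each,
intron gain/loss 0.0125 each, exon gain/loss 0.005 each; ~0.2 events per
branch, ~2.7 per family). Indel lengths are codon multiples with
probability 0.9 (geometric, mean two codons); boundary events recruit or
release whole codons, matching the triplet lengths of observed
exonization/pseudoexonization events, while sub-codon stop-codon
disruption is exercised by the scripted scenarios instead.

Three constraints define the *sparse, non-overlapping regime* the recovery
benchmarks assume: at most one structural event per ancestral exon and per
intron junction family-wide (adjacent boundary events at one junction are
the indel "hot spot" situation, which is irresolvable from pairwise
evidence and is masked rather than classified in real analyses);
intraexonic indels keep a 6-bp margin from exon ends; and the outgroup's
terminal branch carries substitutions only, playing the
ancestral-structure proxy that fixes polarity. The ledger records enough
(event payloads plus per-branch substitutions) to replay every node
byte-for-byte, which the tests assert.

What passing the benchmarks shows — and does not. On these families,
detection recovers ≈ 99 % of events with the correct mechanism class and
exact length, places ≈ 98 % on the true branch, and reconstructs the root
structure exactly in every family of a 200-family sweep, with ≈ 99 %
precision. Real data add everything the generator omits: alternative
splicing, rate heterogeneity, selection and codon bias, splice-site
realism beyond GT..AG, overlapping and recurrent events, annotation error,
and divergence deep enough that alignability itself fails. The benchmarks
therefore validate the logic of the rules and the bookkeeping, not their
error rate on any particular empirical family.

## Fixtures

Six deterministic scenarios reproduce well-studied structural changes:
`brassicaceae_intron_loss` (an 84-bp exon aligning perfectly to 42 + 42 bp
neighbors, identical CDS), `paleoAP1_stop_loss` (two substitutions break
the stop; 15 bp of former UTR become coding), `euAP1_frameshift` (a 1-bp
deletion shifts the frame onto a premature stop, pseudoexonizing the last
8 ancestral coding nucleotides), `capsella_nested_insertions` (a 33-bp
insertion on a three-taxon stem plus an adjacent private 66-bp insertion),
`flc_exon3` (62-bp ancestral exon 3; +3 insertion on one stem, +3
insertion and +3 exonization on another, giving 65 and 68 bp ancestors),
and `flc_exon_loss` (terminal-exon loss leaving seven exons). Their
quantities are recomputed from scratch by `scripts/acceptance.py`.

## Degenerate inputs and edge behaviour

Single-exon genes carry empty boundary lists; annotation-free rows are
flagged and excluded from boundary votes; empty alignment queries raise;
noncoding scans over more than 200 kb truncate with a warning; an
unterminated ORF (no stop within the terminal exon plus 200 bp of flank)
raises in the stop-codon analysis; event rates so high that more drawn
events are discarded than placed raise with advice to lower them. All
randomness flows from a single integer seed per family; identical
configuration and seed reproduce every output file byte-for-byte.
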