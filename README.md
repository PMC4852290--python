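# exevol

Tracing exon–intron structural changes in gene subfamilies.

Plant MADS-box genes (and many other families) evolve not only by point
substitution but by changes to their exon–intron architecture: intraexonic
insertions and deletions, recruitment of intronic/UTR sequence into exons
(*exonization*), loss of coding sequence to noncoding status
(*pseudoexonization*, e.g. when a frameshift creates a premature stop),
intron gain and loss, and gain or loss of whole exons. These changes
confound alignment-based phylogenetics — a frameshift destroys downstream
homology, and independent changes at the same position align together —
but, read correctly, they are also characters that record the history of a
subfamily.

`exevol` implements that reading as a reusable pipeline, for molecular
evolution researchers working with annotated gene families:

1. **Gene models** — read genomic FASTA + CDS FASTA + GFF3/BED exon
   annotations, validate CDS/exon concordance, and apply quantitative
   curation (CDS ≥ 400 bp; same-species sequences > 95 % identical collapse
   to one; least-structurally-diverged transcript per locus).
2. **Boundary-aware codon alignment** — project a protein guide alignment
   onto CDSs codon-by-codon, or progressively align CDSs along the input
   tree; mark each gene's exon boundaries in alignment columns; canonicalise
   gap placement exon by exon; mask nonhomologous columns.
3. **Event classification** — attribute every gap to a mechanism using the
   decision rules of the field: interior gaps → intraexonic indels;
   boundary gaps whose extra sequence matches the partner's adjacent
   intron/UTR → exonization/pseudoexonization; a single exon aligning
   perfectly to two neighboring exons of a homolog → intron gain/loss;
   whole exons with no alignable counterpart anywhere → exon gain/loss;
   stop-codon substitutions and frameshift truncations at the 3' terminus.
4. **Parsimony mapping** — each event is a binary character placed on the
   rooted tree by minimum state changes (Fitch/Sankoff, unit costs), with
   single-origin (Dollo-like) then root-most tie-breaking; the root state —
   fixed by an outgroup when designated — polarises insertion vs deletion,
   gain vs loss, exonization vs pseudoexonization.
5. **Ancestral structures** — per-node exon counts and lengths consistent
   with the placements: for every leaf, leaf length = root length + the
   signed event lengths along its path, exactly.
6. **Synthetic data** — a generator of MADS-like families (8-exon ancestor,
   conserved core, variable terminal exons) with a complete event ledger,
   plus six deterministic fixtures replaying well-studied scenarios
   (Brassicaceae SEP1/2 intron loss, paleoAP1 stop-codon exonization, the
   euAP1 frameshift, nested SEP-clade insertions, FLC exon-3 and exon-loss
   histories).

## Worked example

```python
from exevol import emit_fixture
from exevol.pipeline import analyze_family

fs, tree, _ = emit_fixture("capsella_nested_insertions")
aln, events, placements, structures, ranked, subsets = analyze_family(fs, tree)
for pl in placements:
    print(pl.mechanism, pl.event.length_bp, "bp on", pl.branches)
print("root exon 7:", structures["root"].exon_lengths[6])
print("ingroup exon 7:", structures["ingroup"].exon_lengths[6])
```

prints

```
intraexonic_insertion 66 bp on ['Capsella']
intraexonic_insertion 33 bp on ['ingroup']
root exon 7: 137
ingroup exon 7: 170
```

— the 33-bp insertion shared by the three ingroup taxa is placed on their
stem branch (so the ingroup ancestor's exon 7 is 137 + 33 = 170 bp), while
the adjacent 66-bp insertion, private to one taxon, lands on its terminal
branch.

The same analysis is available from a shell:

```bash
exevol run --fixture capsella_nested_insertions --outdir out/
exevol simulate --n-leaves 8 --seed 7 --outdir sim/
```

Each run writes a report bundle (event table, placements, ancestral
structures, annotated tree, masked alignment, summary) that is
byte-identical when repeated with the same configuration and seed. The
`examples/` directory holds one short narrative script per capability.

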