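"""Gene models: exon coordinates, coding sequence, flanking noncoding sequence.

The unit of analysis is a :class:`GeneModel` — one transcript of one gene with
its exon-intron structure.  Models are read from genomic FASTA + CDS FASTA +
exon annotation (GFF3 or BED6), validated for CDS/exon concordance, and
filtered with the quantitative rules used for subfamily curation: a minimum
CDS length, same-species deduplication at a CDS identity threshold, and
least-structurally-diverged transcript selection among isoforms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

DEFAULT_FLANK_LEN = 300

_COMPL = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


class ValidationError(ValueError):
    """A gene model violates one of its structural invariants."""


@dataclass
class GeneModel:
    """One gene's exon-intron structure and associated sequences.

    ``exons`` are 0-based half-open genomic intervals listed 5'->3' in
    transcript orientation; for '-'-strand genes interval coordinates still
    refer to the forward genomic strand but the list order follows the
    transcript.  ``cds`` is the spliced coding sequence including the stop
    codon (the default length convention; see package docs).  ``introns``
    and flanks may be empty when no genomic sequence is available.
    """

    gene_id: str
    species_id: str
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: str = ""
    introns: list[str] = field(default_factory=list)
    flank_5: str = ""
    flank_3: str = ""
    annotation_source: str = ""

    @property
    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_cds_offsets(self) -> list[int]:
        """Cumulative CDS offsets: position after the last base of each exon."""
        out, total = [], 0
        for ln in self.exon_lengths:
            total += ln
            out.append(total)
        return out

    def exon_seq(self, index: int) -> str:
        """Spliced sequence of exon ``index`` (1-based), from the CDS."""
        offs = [0] + self.exon_cds_offsets()
        return self.cds[offs[index - 1]:offs[index]]

    def intron_before(self, index: int) -> str:
        """Intron upstream of exon ``index`` (1-based, so index >= 2)."""
        if index < 2 or index > self.n_exons:
            raise IndexError(f"no intron upstream of exon {index}")
        return self.introns[index - 2] if self.introns else ""

    def validate(self, genomic: str | None = None) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        lens = self.exon_lengths
        if any(ln <= 0 for ln in lens):
            problems.append("non-positive exon length")
        if self.exons and sum(lens) != len(self.cds):
            problems.append(
                f"exon lengths sum to {sum(lens)} but CDS is {len(self.cds)} bp")
        genomic_order = sorted(self.exons) == (
            self.exons if self.strand == "+" else self.exons[::-1])
        if self.exons and not genomic_order:
            problems.append("exons not ordered in transcript orientation")
        for (_s1, e1), (s2, _e2) in zip(sorted(self.exons),
                                        sorted(self.exons)[1:]):
            if s2 < e1:
                problems.append("overlapping exons")
                break
        if genomic is not None and self.exons:
            parts = [genomic[s:e] for s, e in sorted(self.exons)]
            spliced = "".join(parts)
            if self.strand == "-":
                spliced = revcomp(spliced)
            if spliced.upper() != self.cds.upper():
                problems.append("CDS mismatch with exon concatenation")
        return problems

    def copy(self) -> "GeneModel":
        return GeneModel(self.gene_id, self.species_id, self.strand,
                         list(self.exons), self.cds, list(self.introns),
                         self.flank_5, self.flank_3, self.annotation_source)


@dataclass
class FamilySet:
    """A curated collection of gene models with a provenance log."""

    models: dict[str, GeneModel] = field(default_factory=dict)
    subfamily_labels: dict[str, str] = field(default_factory=dict)
    provenance: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, gm: GeneModel) -> None:
        if gm.gene_id in self.models:
            raise ValueError(f"duplicate gene_id {gm.gene_id!r}")
        self.models[gm.gene_id] = gm

    def log(self, gene_id: str, action: str, reason: str) -> None:
        self.provenance.append((gene_id, action, reason))

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models.values())

    def ids(self) -> list[str]:
        return list(self.models)


# ---------------------------------------------------------------------------
# annotation parsing

def _parse_gff3_exons(path) -> dict[str, dict]:
    """Minimal GFF3 reader for exon features.

    Returns gene_id -> {"seqid", "strand", "intervals" (0-based half-open,
    genomic order), "species"}.  Exon rows are grouped by their ``Parent``
    attribute (falling back to ``ID``).
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            if ftype.lower() not in ("exon", "cds"):
                continue
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            gid = attr.get("Parent") or attr.get("ID")
            if gid is None:
                raise ValueError(f"GFF3 exon without Parent/ID: {line!r}")
            rec = genes.setdefault(gid, {"seqid": seqid, "strand": strand,
                                         "intervals": set(),
                                         "species": attr.get("species")})
            rec["intervals"].add((int(start) - 1, int(end)))
            if attr.get("species"):
                rec["species"] = attr["species"]
    for rec in genes.values():
        rec["intervals"] = sorted(rec["intervals"])
    return genes


def _parse_bed6_exons(path) -> dict[str, dict]:
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"BED6 requires 6 columns: {line!r}")
            seqid, start, end, name, _score, strand = cols[:6]
            rec = genes.setdefault(name, {"seqid": seqid, "strand": strand,
                                          "intervals": [], "species": None})
            rec["intervals"].append((int(start), int(end)))
    for rec in genes.values():
        rec["intervals"] = sorted(set(rec["intervals"]))
    return genes


def _sniff_format(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gff-version"):
                return "gff3"
            if line.strip() and not line.startswith("#"):
                return "gff3" if len(line.split("\t")) == 9 else "bed"
    return "gff3"


def load_gene_models(genomic_fasta, cds_fasta, annotation,
                     flank_len: int = DEFAULT_FLANK_LEN,
                     species_map: dict[str, str] | None = None) -> FamilySet:
    """Assemble a :class:`FamilySet` from standard files.

    ``genomic_fasta`` may be ``None``, in which case models carry the CDS and
    exon lengths only (no introns/flanks).  Genes failing CDS-vs-exon
    concordance are kept out of the set but reported in the provenance log;
    an annotated gene with no sequence at all raises.
    """
    cds_recs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(cds_fasta), "fasta")}
    genomic = {}
    if genomic_fasta is not None:
        genomic = {r.id: str(r.seq).upper()
                   for r in SeqIO.parse(str(genomic_fasta), "fasta")}
    fmt = _sniff_format(annotation)
    ann = (_parse_gff3_exons(annotation) if fmt == "gff3"
           else _parse_bed6_exons(annotation))
    fs = FamilySet()
    for gid, rec in sorted(ann.items()):
        if gid not in cds_recs:
            raise KeyError(f"annotated gene {gid!r} missing from CDS FASTA")
        strand = rec["strand"]
        ivals = rec["intervals"]  # genomic order
        exons = ivals if strand == "+" else ivals[::-1]
        species = rec["species"] or (species_map or {}).get(gid) or gid
        gm = GeneModel(gene_id=gid, species_id=species, strand=strand,
                       exons=list(exons), cds=cds_recs[gid],
                       annotation_source=fmt)
        gseq = None
        if genomic:
            if rec["seqid"] not in genomic:
                raise KeyError(
                    f"genomic record {rec['seqid']!r} for gene {gid!r} missing")
            gseq = genomic[rec["seqid"]]
            _attach_noncoding(gm, gseq, flank_len)
        problems = gm.validate(genomic=gseq)
        if problems:
            fs.log(gid, "rejected", "; ".join(problems))
        else:
            fs.add(gm)
            fs.log(gid, "loaded", fmt)
    return fs


def _attach_noncoding(gm: GeneModel, gseq: str, flank_len: int) -> None:
    ivals = sorted(gm.exons)
    introns = [gseq[e1:s2] for (_, e1), (s2, _) in zip(ivals, ivals[1:])]
    left = gseq[max(0, ivals[0][0] - flank_len):ivals[0][0]]
    right = gseq[ivals[-1][1]:ivals[-1][1] + flank_len]
    if gm.strand == "-":
        introns = [revcomp(i) for i in introns[::-1]]
        left, right = revcomp(right), revcomp(left)
    gm.introns = introns
    gm.flank_5, gm.flank_3 = left, right


# ---------------------------------------------------------------------------
# identity + filtering

def _dedupe_aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "global"
    aln.match_score = 1.0
    aln.mismatch_score = 0.0
    aln.open_gap_score = -10.0
    aln.extend_gap_score = -0.5
    return aln


def cds_identity(a: str, b: str) -> float:
    """Global-alignment CDS identity: matches / non-terminal-gap columns."""
    if not a or not b:
        return 0.0
    alignment = _dedupe_aligner().align(a.upper(), b.upper())[0]
    sa, sb = str(alignment[0]), str(alignment[1])
    lo = 0
    hi = len(sa)
    while lo < hi and (sa[lo] == "-" or sb[lo] == "-"):
        lo += 1
    while hi > lo and (sa[hi - 1] == "-" or sb[hi - 1] == "-"):
        hi -= 1
    cols = hi - lo
    if cols == 0:
        return 0.0
    matches = sum(1 for x, y in zip(sa[lo:hi], sb[lo:hi]) if x == y and x != "-")
    return matches / cols


def filter_models(fs: FamilySet, min_cds: int = 400,
                  dedupe_identity: float = 0.95) -> FamilySet:
    """Apply the curation rules: length floor, then same-species dedup.

    Among a cluster of near-identical same-species genes the longest CDS
    survives (ties broken by lexicographic gene id); removals are logged.
    """
    out = FamilySet(subfamily_labels=dict(fs.subfamily_labels),
                    provenance=list(fs.provenance))
    survivors = []
    for gm in fs:
        if len(gm.cds) < min_cds:
            out.log(gm.gene_id, "removed",
                    f"CDS {len(gm.cds)} bp < {min_cds} bp minimum")
        else:
            survivors.append(gm)
    # same-species near-identical clusters (union-find)
    parent = {gm.gene_id: gm.gene_id for gm in survivors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_species: dict[str, list[GeneModel]] = {}
    for gm in survivors:
        by_species.setdefault(gm.species_id, []).append(gm)
    for group in by_species.values():
        for ga, gb in itertools.combinations(group, 2):
            if cds_identity(ga.cds, gb.cds) > dedupe_identity:
                ra, rb = find(ga.gene_id), find(gb.gene_id)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    clusters: dict[str, list[GeneModel]] = {}
    for gm in survivors:
        clusters.setdefault(find(gm.gene_id), []).append(gm)
    for members in clusters.values():
        keep = sorted(members, key=lambda g: (-len(g.cds), g.gene_id))[0]
        out.add(keep)
        for gm in members:
            if gm is not keep:
                out.log(gm.gene_id, "removed",
                        f"> {dedupe_identity:.0%} identical to {keep.gene_id} "
                        f"(same species)")
    if not out.models:
        import warnings
        warnings.warn("all gene models were filtered out", stacklevel=2)
    for gid in list(out.subfamily_labels):
        if gid not in out.models:
            del out.subfamily_labels[gid]
    return out


def select_transcript(isoforms: list[GeneModel], references: FamilySet) -> GeneModel:
    """Pick the isoform least structurally diverged from its nearest homolog.

    The nearest reference is the one with highest CDS identity; the score is
    the number of pairwise structural events against it, with ties broken by
    smaller total event length, then transcript id.
    """
    from .events import pairwise_structural_events

    if len(isoforms) == 1:
        return isoforms[0]
    if not references.models:
        raise ValueError("unclassifiable locus: no references provided")
    scored = []
    for iso in isoforms:
        best_ref, best_ident = None, -1.0
        for ref in references:
            if ref.gene_id == iso.gene_id:
                continue
            ident = cds_identity(iso.cds, ref.cds)
            if ident > best_ident:
                best_ref, best_ident = ref, ident
        if best_ref is None or best_ident <= 0.0:
            continue
        evs = pairwise_structural_events(iso, best_ref)
        scored.append((len(evs), sum(e[1] for e in evs), iso.gene_id, iso))
    if not scored:
        raise ValueError("unclassifiable locus: no isoform alignable to any reference")
    scored.sort(key=lambda t: t[:3])
    return scored[0][3]


# ---------------------------------------------------------------------------
# writers

def write_family(fs: FamilySet, cds_fasta, gff3, genomic_fasta=None,
                 provenance_tsv=None) -> None:
    """Write a FamilySet as CDS FASTA + GFF3 (+ optional provenance TSV).

    Genomic FASTA output is only possible when models retain their noncoding
    sequence; records are re-assembled as flank + exons/introns + flank on
    the forward strand of each gene's own contig.
    """
    with open(cds_fasta, "w") as fh:
        for gid in sorted(fs.models):
            fh.write(f">{gid}\n{fs.models[gid].cds}\n")
    with open(gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(fs.models):
            gm = fs.models[gid]
            seqid = f"{gid}_locus"
            for k, (s, e) in enumerate(sorted(gm.exons), start=1):
                attrs = f"ID={gid}.exon{k};Parent={gid};species={gm.species_id}"
                fh.write(f"{seqid}\texevol\texon\t{s + 1}\t{e}\t.\t"
                         f"{gm.strand}\t.\t{attrs}\n")
    if genomic_fasta is not None:
        with open(genomic_fasta, "w") as fh:
            for gid in sorted(fs.models):
                fh.write(f">{gid}_locus\n{assemble_locus(fs.models[gid])}\n")
    if provenance_tsv is not None:
        with open(provenance_tsv, "w") as fh:
            fh.write("gene_id\taction\treason\n")
            for gid, action, reason in fs.provenance:
                fh.write(f"{gid}\t{action}\t{reason}\n")


def assemble_locus(gm: GeneModel) -> str:
    """Rebuild the forward-strand genomic span (flank + exons/introns + flank)."""
    exon_seqs = [gm.exon_seq(i) for i in range(1, gm.n_exons + 1)]
    introns = list(gm.introns)
    if gm.strand == "-":
        exon_seqs = [revcomp(s) for s in exon_seqs[::-1]]
        introns = [revcomp(i) for i in introns[::-1]]
        left, right = revcomp(gm.flank_3), revcomp(gm.flank_5)
    else:
        left, right = gm.flank_5, gm.flank_3
    parts = [left]
    for k, ex in enumerate(exon_seqs):
        parts.append(ex)
        if k < len(introns):
            parts.append(introns[k])
    parts.append(right)
    return "".join(parts)


def translate_cds(cds: str) -> str:
    """Translate a CDS (standard code), trimming a terminal stop if present."""
    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot
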