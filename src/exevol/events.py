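"""Classification of exon-intron structural change events.

Every gap in a boundary-marked codon alignment is attributed to a mechanism:

* gaps strictly inside an exon -> intraexonic insertion/deletion;
* gaps abutting an exon boundary -> exonization/pseudoexonization when the
  extra exonic sequence of the longer state aligns to the other state's
  intron/UTR/intergenic flank, exon gain/loss when an entire exon has no
  alignable counterpart anywhere (coding or noncoding);
* equal-length, gap-free rows whose exon counts differ -> intron gain/loss,
  recognised when one gene's exon aligns perfectly to two neighboring exons
  of the other;
* stop-codon changes at the 3' terminus -> readthrough exonization or
  frameshift-driven pseudoexonization.

Insertion-vs-deletion and gain-vs-loss polarity is not decidable from a pair
of sequences, so events are emitted with an *indeterminate* mechanism and a
marker-state row set; :mod:`exevol.parsimony` polarises them against the
tree.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

from . import _dp
from .align import (MIN_COLUMNS, MIN_IDENTITY, PERFECT_IDENTITY,
                    CodonAlignment, PairwiseAlignment, consensus_boundaries,
                    pairwise_flank_align)
from .models import FamilySet, GeneModel

STOP_CODONS = {"TAA", "TAG", "TGA"}

# identity required for the short, positionally anchored boundary checks
# (the >=15-column alignability rule is for unanchored scans)
BOUNDARY_IDENTITY = 0.7
BOUNDARY_ANCHOR_TOL = 3
JUNCTION_TOLERANCE = 3

FINAL_MECHANISMS = {
    "exonization", "pseudoexonization", "exon_gain", "exon_loss",
    "intron_gain", "intron_loss", "intraexonic_insertion",
    "intraexonic_deletion", "indeterminate_indel", "indeterminate_exon_change",
}
PROVISIONAL_MECHANISMS = {"exonization_class", "intron_change",
                          "indeterminate_indel", "indeterminate_exon_change"}


@dataclass
class StructuralEvent:
    """One classified structural change.

    ``state_rows`` hold the marker state used for parsimony polarisation:
    the gapped rows for indel-like events, the merged-exon rows for intron
    changes, the exon-lacking rows for whole-exon events.  ``carrier_genes``
    (the rows exhibiting the *derived* state) is filled in once the event is
    polarised on the tree.
    """

    event_id: str
    mechanism: str
    exon_index: int
    length_bp: int
    column_span: tuple[int, int]
    state_rows: frozenset = frozenset()
    alt_rows: frozenset = frozenset()
    carrier_genes: frozenset = frozenset()
    evidence: str = ""
    detail: dict = field(default_factory=dict)
    linked_to: str | None = None

    @property
    def frame_preserving(self) -> bool:
        return self.length_bp % 3 == 0

    def __post_init__(self):
        if self.mechanism not in FINAL_MECHANISMS | PROVISIONAL_MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.length_bp < 0:
            raise ValueError("negative event length")
        if self.length_bp == 0 and self.evidence != "exon_merge":
            raise ValueError("zero length only allowed for intron changes")


def events_to_tsv(events: list[StructuralEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("event_id\tmechanism\texon_index\tlength_bp\tframe_preserving"
                 "\tcarriers\tevidence\tcolumn_start\tcolumn_end\tlinked_to\n")
        for e in events:
            carriers = ",".join(sorted(e.carrier_genes)) or \
                ",".join(sorted(e.state_rows))
            fh.write(f"{e.event_id}\t{e.mechanism}\t{e.exon_index}\t"
                     f"{e.length_bp}\t{e.frame_preserving}\t{carriers}\t"
                     f"{e.evidence}\t{e.column_span[0]}\t{e.column_span[1]}\t"
                     f"{e.linked_to or ''}\n")


# ---------------------------------------------------------------------------
# low-level helpers

def gap_pattern_intervals(aln: CodonAlignment, lo: int, hi: int,
                          rows: list[str] | None = None
                          ) -> list[tuple[int, int, frozenset]]:
    """Maximal column intervals of [lo, hi) with a constant gapped-row set.

    Only intervals where at least one but not every considered row is gapped
    are returned.  Splitting on the exact row pattern keeps nested or
    adjacent indels from different origins apart (a run shared
    byte-identically by several rows stays one interval).
    """
    rows = list(rows) if rows is not None else list(aln.row_ids)
    out = []
    cur: frozenset | None = None
    start = lo
    for c in range(lo, hi):
        pat = frozenset(g for g in rows if aln.rows[g][c] == "-")
        if pat != cur:
            if cur:
                out.append((start, c, cur))
            cur, start = pat, c
    if cur:
        out.append((start, hi, cur))
    return [(s, e, p) for s, e, p in out if p and len(p) < len(rows)]


def anchored_noncoding_match(extra: str, noncoding: str, side: str,
                             min_identity: float = BOUNDARY_IDENTITY,
                             anchor_tol: int = BOUNDARY_ANCHOR_TOL) -> int:
    """Match count if ``extra`` aligns to the exon-adjacent end of a
    noncoding region, else 0.

    ``side`` names which end of the noncoding sequence abuts the exon:
    ``"end"`` for an upstream intron / 5' flank (its 3' end touches the
    exon), ``"start"`` for a downstream intron / 3' flank.  The extra
    sequence must align with at least ``min_identity`` (a single
    substitution is tolerated for short extras, but nothing shorter than
    3 bp is meaningful) and sit within ``anchor_tol`` bases of the
    adjacent end.
    """
    L = len(extra)
    if L < 3 or not noncoding:
        return 0
    window = L + 2 * anchor_tol
    region = noncoding[-window:] if side == "end" else noncoding[:window]
    if len(region) < max(3, L // 2):
        return 0
    extra = extra.upper()
    region = region.upper()
    if L <= 6:
        need = L - 1
    elif L <= 12:
        need = L - 2
    else:
        need = min_identity * L
    if L <= 12:
        # recruited or released sequence is contiguous: slide a gapless
        # window over the anchored offsets (gapped DP can fabricate short
        # matches out of unrelated sequence); boundary-flush matches are
        # worth more than offset ones, so score = 8*matches - offset
        best = 0
        for j in range(0, len(region) - L + 1):
            dist = (len(region) - L - j) if side == "end" else j
            if dist > anchor_tol:
                continue
            m = sum(1 for x, y in zip(extra, region[j:j + L]) if x == y)
            if m >= need:
                best = max(best, 8 * m - dist)
        return best
    pa = pairwise_flank_align(extra, region, mode="semiglobal")
    matches = sum(1 for x, y in zip(pa.aligned_query, pa.aligned_target)
                  if x != "-" and y != "-" and x == y)
    if matches < need:
        return 0
    if side == "end":
        anchored = len(region) - pa.target_end <= anchor_tol
    else:
        anchored = pa.target_start <= anchor_tol
    return int(matches) if anchored else 0


class NotABoundaryGap(ValueError):
    pass


# ---------------------------------------------------------------------------
# spec operations

@dataclass
class ExonBlock:
    """One homologous exon block of the alignment (consensus numbering).

    ``eff_start``/``eff_end`` trim columns where most rows are gapped (e.g.
    a minority-only gained exon at the block edge), giving the edges of the
    block's shared exonic content.
    """

    aln: CodonAlignment
    index: int  # 1-based consensus exon index
    start: int
    end: int
    eff_start: int = -1
    eff_end: int = -1

    def __post_init__(self):
        if self.eff_start < 0:
            self.eff_start = self.start
        if self.eff_end < 0:
            self.eff_end = self.end


def detect_internal_indels(block: ExonBlock,
                           id_prefix: str = "ev") -> list[StructuralEvent]:
    """Events for gap runs strictly interior to an exon block.

    Rows sharing a byte-identical run become one event's marker group;
    polarity stays indeterminate here.
    """
    aln = block.aln
    events = []
    k = 0
    for s, e, gaps in gap_pattern_intervals(aln, block.start, block.end):
        if s <= block.start or e >= block.end:
            continue
        k += 1
        events.append(StructuralEvent(
            event_id=f"{id_prefix}_b{block.index}_i{k}",
            mechanism="indeterminate_indel",
            exon_index=block.index, length_bp=e - s, column_span=(s, e),
            state_rows=gaps,
            alt_rows=frozenset(aln.row_ids) - gaps,
            evidence="internal_gap"))
    return events


def classify_boundary_gap(block: ExonBlock, row_long: str, row_short: str,
                          side: str, fs: FamilySet,
                          span: tuple[int, int] | None = None,
                          event_id: str = "ev_boundary") -> StructuralEvent:
    """Classify a gap run abutting the 5' or 3' boundary of an exon block.

    ``row_long`` has sequence over the run, ``row_short`` is gapped.  If the
    extra exonic sequence aligns (anchored) to the short row's adjacent
    intron/UTR, the event is exonization-class; if the run covers the whole
    block it is an indeterminate whole-exon change; if noncoding sequence is
    unavailable the call degrades to an indeterminate indel.
    """
    aln = block.aln
    if span is None:
        span = _boundary_run(aln, row_short, block, side)
    s, e = span
    if e <= s:
        raise NotABoundaryGap("zero-length gap run")
    if not (s == block.start or e == block.end):
        raise NotABoundaryGap(
            f"columns [{s},{e}) are not adjacent to a boundary of block "
            f"{block.index}")
    extra = aln.rows[row_long][s:e].replace("-", "")
    whole = all(aln.rows[row_short][c] == "-"
                for c in range(block.start, block.end))
    if whole:
        return StructuralEvent(
            event_id=event_id, mechanism="indeterminate_exon_change",
            exon_index=block.index, length_bp=len(extra), column_span=span,
            state_rows=frozenset({row_short}),
            alt_rows=frozenset({row_long}),
            evidence="whole_exon_unalignable")
    gm = fs.models.get(row_short)
    noncoding, nc_side = _adjacent_noncoding(gm, block.index, side)
    if noncoding is None:
        ev = StructuralEvent(
            event_id=event_id, mechanism="indeterminate_indel",
            exon_index=block.index, length_bp=len(extra), column_span=span,
            state_rows=frozenset({row_short}),
            alt_rows=frozenset({row_long}),
            evidence="internal_gap",
            detail={"note": "no noncoding sequence available for "
                            f"{row_short}; boundary gap left unpolarised"})
        return ev
    if anchored_noncoding_match(extra, noncoding, nc_side):
        return StructuralEvent(
            event_id=event_id, mechanism="exonization_class",
            exon_index=block.index, length_bp=len(extra), column_span=span,
            state_rows=frozenset({row_short}),
            alt_rows=frozenset({row_long}),
            evidence="boundary_gap_noncoding_alignable")
    return StructuralEvent(
        event_id=event_id, mechanism="indeterminate_indel",
        exon_index=block.index, length_bp=len(extra), column_span=span,
        state_rows=frozenset({row_short}), alt_rows=frozenset({row_long}),
        evidence="internal_gap",
        detail={"note": "boundary gap with no noncoding homology"})


def _boundary_run(aln, row_short, block, side):
    row = aln.rows[row_short]
    if side == "5":
        s = block.start
        e = s
        while e < block.end and row[e] == "-":
            e += 1
        return (s, e)
    e = block.end
    s = e
    while s > block.start and row[s - 1] == "-":
        s -= 1
    return (s, e)


def _adjacent_noncoding(gm: GeneModel | None, exon_index: int, side: str):
    """The noncoding sequence touching one side of an exon, plus which of its
    ends abuts the exon ('end' = its 3' end touches the exon)."""
    if gm is None:
        return None, None
    n = gm.n_exons
    idx = min(exon_index, n)
    if side == "5":
        if idx >= 2 and gm.introns:
            return gm.intron_before(idx) or None, "end"
        return (gm.flank_5 or None), "end"
    if idx < n and gm.introns:
        return (gm.introns[idx - 1] if idx - 1 < len(gm.introns) else None), "start"
    return (gm.flank_3 or None), "start"


def detect_intron_change(gene_a: GeneModel, gene_b: GeneModel,
                         junction_tolerance: int = JUNCTION_TOLERANCE,
                         id_prefix: str = "ev") -> list[StructuralEvent]:
    """Intron gain/loss candidates between two annotated genes.

    For each exon of the gene with fewer exons, tests whether it aligns
    perfectly (identity >= 0.9 in each half) to the concatenation of two
    neighboring exons of the other gene, with the junction within
    ``junction_tolerance`` of the partner's boundary.  Swapping the genes
    mirrors the events.  Emits indeterminate ``intron_change`` events
    (length 0, merged length in the detail) for parsimony to polarise.
    """
    if not gene_a.exons or not gene_b.exons:
        raise ValueError("structural annotation required on both genes")
    if gene_a.n_exons == gene_b.n_exons:
        return []
    fewer, more = ((gene_a, gene_b) if gene_a.n_exons < gene_b.n_exons
                   else (gene_b, gene_a))
    events = []
    used = set()
    for k in range(1, fewer.n_exons + 1):
        merged = fewer.exon_seq(k)
        best = None
        for i in range(1, more.n_exons):
            if i in used:
                continue
            la, lb = more.exon_lengths[i - 1], more.exon_lengths[i]
            if abs(len(merged) - (la + lb)) > junction_tolerance:
                continue
            concat = more.exon_seq(i) + more.exon_seq(i + 1)
            pa = pairwise_flank_align(merged, concat, mode="global")
            id_left = pa.segment_identity(0, la)
            id_right = pa.segment_identity(la, la + lb)
            if min(id_left, id_right) >= PERFECT_IDENTITY:
                score = pa.score
                if best is None or score > best[0]:
                    best = (score, i, la, lb)
        if best is not None:
            _, i, la, lb = best
            used.add(i)
            events.append(StructuralEvent(
                event_id=f"{id_prefix}_intron_e{i}",
                mechanism="intron_change", exon_index=i, length_bp=0,
                column_span=(0, 0),
                state_rows=frozenset({fewer.gene_id}),
                alt_rows=frozenset({more.gene_id}),
                evidence="exon_merge",
                detail={"merged_exon_length": len(merged),
                        "partner_exon_lengths": (la, lb),
                        "merged_exon_index_in_carrier": k}))
    return events


def detect_stop_codon_events(gene_a: GeneModel, gene_b: GeneModel,
                             id_prefix: str = "ev") -> list[StructuralEvent]:
    """Stop-codon-driven terminal events between two genes.

    Readthrough: one CDS extends past the other's stop codon, the shorter
    gene's stop columns are substituted (not gapped) in the longer row, and
    the extension matches the start of the shorter gene's 3' noncoding
    sequence -> exonization, length = new sense codons (the extension minus
    its own terminal stop).

    Frameshift: a non-triplet interior indel puts the derived CDS out of
    frame and a premature in-frame stop truncates it -> pseudoexonization of
    the reference coding nucleotides beyond the new stop, linked to the
    causal indel.
    """
    a, b = gene_a.cds.upper(), gene_b.cds.upper()
    _require_stop(gene_a)
    _require_stop(gene_b)
    if a == b or len(a) == len(b):
        return []
    long_gm, short_gm = (gene_a, gene_b) if len(a) > len(b) else (gene_b, gene_a)
    long, short = long_gm.cds.upper(), short_gm.cds.upper()
    d = len(long) - len(short)
    fr = _frameshift_pseudoexonization(long_gm, short_gm, long, short,
                                       id_prefix)
    if fr:
        return fr
    if d < 3 or short[-3:] not in STOP_CODONS:
        return []
    # readthrough hypothesis: long = short-without-stop + substituted codon
    # + exonized extension homologous to short's 3' UTR
    head = len(short) - 3
    mism = sum(1 for x, y in zip(long[:head], short[:head]) if x != y)
    replacement = long[head:head + 3]
    ext = long[len(short):]
    if (mism <= max(1, int(0.1 * head))
            and replacement not in STOP_CODONS
            and anchored_noncoding_match(ext, short_gm.flank_3, "start")):
        length = len(ext) - 3 if ext[-3:] in STOP_CODONS else len(ext)
        return [StructuralEvent(
            event_id=f"{id_prefix}_stop_readthrough",
            mechanism="exonization",
            exon_index=long_gm.n_exons or short_gm.n_exons,
            length_bp=length, column_span=(len(short), len(long)),
            state_rows=frozenset({short_gm.gene_id}),
            alt_rows=frozenset({long_gm.gene_id}),
            carrier_genes=frozenset({long_gm.gene_id}),
            evidence="stop_codon_change",
            detail={"broken_stop": short[-3:], "replacement": replacement,
                    "exon_length_delta": len(ext)})]
    return []


def _require_stop(gm: GeneModel) -> None:
    tail = gm.cds.upper() + gm.flank_3.upper()[:200]
    start = len(gm.cds) - 3
    for pos in range(start, len(tail) - 2, 3):
        if tail[pos:pos + 3] in STOP_CODONS:
            return
    raise ValueError(f"unterminated ORF: no stop codon for {gm.gene_id!r} "
                     "within the terminal exon plus 200 bp of flank")


def _frameshift_pseudoexonization(long_gm, short_gm, long: str, short: str,
                                  id_prefix: str):
    """Test whether the shorter CDS is the longer one truncated by a small
    frameshifting indel followed by a premature in-frame stop."""
    if short[-3:] not in STOP_CODONS:
        return []
    lcp = 0
    for x, y in zip(long, short):
        if x != y:
            break
        lcp += 1
    if lcp >= len(short):
        return []
    m = len(short) - lcp
    best = None
    for delta, kind in ((1, "deletion"), (2, "deletion"),
                        (-1, "insertion"), (-2, "insertion")):
        if m < 3 or lcp + delta < 0:
            continue
        seg_long = long[lcp + delta: lcp + delta + m] if delta > 0 else None
        if delta > 0:
            if len(seg_long) < m:
                continue
            matches = sum(1 for x, y in zip(short[lcp:], seg_long) if x == y)
        else:
            # insertion in the short gene: its extra bases shift the frame
            seg_short = short[lcp - delta:]
            seg_l = long[lcp: lcp + len(seg_short)]
            if len(seg_l) < len(seg_short):
                continue
            matches = sum(1 for x, y in zip(seg_short, seg_l) if x == y)
            m = len(seg_short)
        if m and matches / m >= PERFECT_IDENTITY:
            best = (delta, kind)
            break
    if best is None:
        return []
    delta, kind = best
    # the short gene's final base corresponds to long position
    # len(short) + delta - 1; everything beyond it (minus the long gene's
    # own stop codon) has become noncoding in the short gene
    pseudo_len = (len(long) - 3) - (len(short) + delta)
    if pseudo_len <= 0:
        return []
    mech = ("intraexonic_deletion" if kind == "deletion"
            else "intraexonic_insertion")
    causal = StructuralEvent(
        event_id=f"{id_prefix}_frameshift_indel",
        mechanism=mech, exon_index=short_gm.n_exons or 1,
        length_bp=abs(delta), column_span=(lcp, lcp + abs(delta)),
        state_rows=frozenset({short_gm.gene_id}),
        alt_rows=frozenset({long_gm.gene_id}),
        carrier_genes=frozenset({short_gm.gene_id}),
        evidence="internal_gap")
    pseudo = StructuralEvent(
        event_id=f"{id_prefix}_frameshift_pseudo",
        mechanism="pseudoexonization",
        exon_index=short_gm.n_exons or 1,
        length_bp=pseudo_len,
        column_span=(len(short) + delta, len(long) - 3),
        state_rows=frozenset({short_gm.gene_id}),
        alt_rows=frozenset({long_gm.gene_id}),
        carrier_genes=frozenset({short_gm.gene_id}),
        evidence="stop_codon_change",
        detail={"exon_length_delta": pseudo_len + 3},
        linked_to=causal.event_id)
    return [causal, pseudo]


@dataclass
class ScanHit:
    offset: int
    length: int
    identity: float
    score: float


def scan_noncoding_for_homolog(exon_seq: str, noncoding_seq: str,
                               max_span: int = 200_000) -> ScanHit | None:
    """Best local hit of an exon in a (possibly very long) noncoding region.

    Used to distinguish exonization (a homolog exists in noncoding sequence)
    from exon gain (none does).  Returns ``None`` when no hit reaches the
    alignability threshold (identity >= 0.5 over >= 15 columns).
    """
    if not exon_seq or not noncoding_seq:
        return None
    if len(noncoding_seq) > max_span:
        warnings.warn(f"noncoding sequence truncated to {max_span} bp",
                      stacklevel=2)
        noncoding_seq = noncoding_seq[:max_span]
    score, _bi, bj = _dp.local_best_hit(exon_seq, noncoding_seq)
    if score <= 0:
        return None
    wlo = max(0, bj - 2 * len(exon_seq))
    window = noncoding_seq[wlo:bj]
    if not window:
        return None
    res = _dp.align_seqs(exon_seq, window, mode="local")
    matches, cols = _dp.path_identity(res.path, exon_seq, window)
    if cols < MIN_COLUMNS or (cols and matches / cols < MIN_IDENTITY):
        return None
    # significance floor: the best chance alignment of unrelated sequences
    # scores ~ 2*log4(m*n), so demand a clear margin above it
    import math
    min_score = 2.0 * math.log(max(len(exon_seq) * len(noncoding_seq), 16), 4) + 12
    if score < min_score:
        return None
    return ScanHit(offset=wlo + res.start[1], length=cols,
                   identity=matches / cols, score=res.score)


# ---------------------------------------------------------------------------
# pairwise summary used by transcript selection

def pairwise_structural_events(gm_a: GeneModel, gm_b: GeneModel
                               ) -> list[tuple[str, int]]:
    """Coarse (kind, length) list of structural differences between two genes.

    Counts interior and terminal gap runs of a global CDS alignment plus
    exon-count differences; used to score isoforms by structural divergence.
    """
    out: list[tuple[str, int]] = []
    pa = pairwise_flank_align(gm_a.cds, gm_b.cds, mode="global")
    for row, other in ((pa.aligned_query, pa.aligned_target),
                       (pa.aligned_target, pa.aligned_query)):
        start = None
        for c in range(len(row) + 1):
            gapped = c < len(row) and row[c] == "-"
            if gapped and start is None:
                start = c
            elif not gapped and start is not None:
                out.append(("indel", c - start))
                start = None
    if gm_a.exons and gm_b.exons and gm_a.n_exons != gm_b.n_exons:
        out.append(("exon_count", abs(gm_a.n_exons - gm_b.n_exons) * 0))
        out[-1] = ("exon_count", 0)
    return out


# ---------------------------------------------------------------------------
# whole-alignment orchestrator

def detect_events(aln: CodonAlignment, fs: FamilySet,
                  id_prefix: str = "ev") -> list[StructuralEvent]:
    """Attribute every gap column and exon-count difference to an event.

    Works over a boundary-marked alignment: pattern intervals inside each
    consensus block become indel/boundary/whole-exon events; boundary sites
    present in some rows only are tested for intron changes; non-triplet
    indels in the terminal block trigger the stop-codon analysis.  All
    polarity-dependent mechanisms are emitted indeterminate.
    """
    bounds = consensus_boundaries(aln)
    edges = [0] + bounds + [aln.ncols]
    events: list[StructuralEvent] = []
    counter = itertools.count(1)
    nrows = len(aln.row_ids)
    for bi in range(len(edges) - 1):
        lo, hi = edges[bi], edges[bi + 1]
        content = {g: len(aln.rows[g][lo:hi].replace("-", ""))
                   for g in aln.row_ids}
        filled = sorted(c for c in content.values() if c > 3)
        median_len = filled[len(filled) // 2] if filled else 0
        absent = {g for g, c in content.items() if c == 0}
        if median_len >= MIN_COLUMNS:
            # a handful of stray bases is alignment noise, not an exon
            absent |= {g for g, c in content.items() if 0 < c <= 5}
        absent = frozenset(absent)
        if absent and len(absent) < len(aln.row_ids):
            present = frozenset(aln.row_ids) - absent
            stray = {}
            for g in absent:
                if content[g]:
                    rowseg = aln.rows[g][lo:hi]
                    first = len(rowseg) - len(rowseg.lstrip("-"))
                    stray[g] = (content[g],
                                "next" if first >= (hi - lo) // 2 else "prev")
            ev = StructuralEvent(
                event_id=f"{id_prefix}{next(counter)}",
                mechanism="indeterminate_exon_change",
                exon_index=bi + 1, length_bp=median_len,
                column_span=(lo, hi), state_rows=absent, alt_rows=present,
                evidence="whole_exon_unalignable",
                detail={"column_block": bi + 1, "gained_subblock": False,
                        "stray": stray})
            _attach_scan_evidence(ev, aln, fs, present, absent, bi + 1, lo, hi)
            events.append(ev)
        live = [g for g in aln.row_ids if g not in absent]
        half = max(1, len(live) // 2)
        eff_lo, eff_hi = lo, hi
        for c in range(lo, hi):
            if sum(1 for g in live if aln.rows[g][c] != "-") >= half:
                eff_lo = c
                break
        for c in range(hi - 1, lo - 1, -1):
            if sum(1 for g in live if aln.rows[g][c] != "-") >= half:
                eff_hi = c + 1
                break
        block = ExonBlock(aln, bi + 1, lo, hi, eff_lo, eff_hi)
        for s, e, gaps in gap_pattern_intervals(aln, lo, hi, rows=live):
            present = frozenset(live) - gaps
            eid = f"{id_prefix}{next(counter)}"
            if _is_gained_exon(aln, present, s, e, lo, hi):
                lengths = sorted(len(aln.rows[g][s:e].replace("-", ""))
                                 for g in present)
                ev = StructuralEvent(
                    event_id=eid, mechanism="indeterminate_exon_change",
                    exon_index=bi + 1, length_bp=lengths[len(lengths) // 2],
                    column_span=(s, e), state_rows=gaps, alt_rows=present,
                    evidence="whole_exon_unalignable",
                    detail={"column_block": bi + 1, "gained_subblock": True})
                _attach_scan_evidence(ev, aln, fs, present, gaps, bi + 1, s, e)
                events.append(ev)
            elif (s > lo and e < hi
                    and s not in (eff_lo,) and e not in (eff_hi,)):
                events.append(StructuralEvent(
                    event_id=eid, mechanism="indeterminate_indel",
                    exon_index=bi + 1, length_bp=e - s, column_span=(s, e),
                    state_rows=gaps, alt_rows=present,
                    evidence="internal_gap"))
            else:
                ev = _classify_edge_interval(aln, fs, block, s, e, gaps,
                                             present, eid,
                                             terminal=(bi + 2 == len(edges)))
                if ev is not None:
                    events.append(ev)
    events = _merge_fragmented_events(events)
    events = _merge_staircase_events(events, aln)
    _reclassify_whole_exon_indels(aln, fs, events)
    _reclassify_junction_indels(aln, fs, events, edges)
    events.extend(_detect_boundary_site_changes(aln, fs, bounds, id_prefix,
                                                counter))
    stop_events = _terminal_stop_events(aln, fs, events, id_prefix, counter)
    # a stop-codon analysis explains the same columns as the generic edge
    # classification; keep the mechanistically resolved version
    for sev in stop_events:
        events = [e for e in events
                  if not (e.exon_index == sev.exon_index
                          and e.state_rows == sev.state_rows
                          and e.evidence in ("internal_gap",
                                             "boundary_gap_noncoding_alignable"))]
    events.extend(stop_events)
    del nrows
    return events


def _merge_fragmented_events(events: list[StructuralEvent]
                             ) -> list[StructuralEvent]:
    """Merge indel/boundary fragments that describe one underlying change.

    A single event at an exon junction can surface as several nearby gap
    intervals with the same marker rows when a few bases align by chance
    inside the gap.  Events sharing their state partition, lying within
    three columns of each other and belonging to the same junction
    neighborhood are combined; the boundary-classified fragment, if any,
    names the mechanism and exon.
    """
    mergeable = {"indeterminate_indel", "exonization_class"}
    out: list[StructuralEvent] = []
    for ev in sorted(events, key=lambda e: e.column_span):
        prev = out[-1] if out else None
        if (prev is not None
                and ev.mechanism in mergeable and prev.mechanism in mergeable
                and ev.state_rows == prev.state_rows
                and abs(ev.exon_index - prev.exon_index) <= 1
                and ev.column_span[0] - prev.column_span[1] <= 3):
            lead = max((prev, ev),
                       key=lambda x: (x.mechanism == "exonization_class",
                                      x.length_bp))
            out[-1] = StructuralEvent(
                event_id=prev.event_id, mechanism=lead.mechanism,
                exon_index=lead.exon_index,
                length_bp=prev.length_bp + ev.length_bp,
                column_span=(prev.column_span[0], ev.column_span[1]),
                state_rows=prev.state_rows, alt_rows=prev.alt_rows,
                evidence=lead.evidence, detail=dict(lead.detail))
            continue
        out.append(ev)
    return out


def _merge_staircase_events(events: list[StructuralEvent], aln
                            ) -> list[StructuralEvent]:
    """Merge staircase fragments of one gap run.

    When a base inside a shared gap matches a neighbor by chance, the
    aligner staggers the run across rows, splitting one event into abutting
    intervals with nested marker sets (e.g. {A}, {A,B}, {B}).  If every row
    involved carries the same total gap count over the combined span, and
    that count nearly fills the span, the fragments describe a single event.
    """
    mergeable = {"indeterminate_indel", "exonization_class"}
    out: list[StructuralEvent] = []
    evs = sorted(events, key=lambda e: e.column_span)
    i = 0
    while i < len(evs):
        group = [evs[i]]
        j = i + 1
        while (j < len(evs)
               and evs[j].mechanism in mergeable
               and group[-1].mechanism in mergeable
               and evs[j].column_span[0] - group[-1].column_span[1] <= 1
               and abs(evs[j].exon_index - group[0].exon_index) <= 1):
            group.append(evs[j])
            j += 1
        merged = None
        if len(group) >= 2 and len({g.state_rows for g in group}) >= 2:
            s = group[0].column_span[0]
            e = group[-1].column_span[1]
            union_state = frozenset().union(*(g.state_rows for g in group))
            counts = {r: aln.rows[r][s:e].count("-") for r in union_state}
            L = next(iter(counts.values()))
            others_clean = all(aln.rows[r][s:e].count("-") == 0
                               for r in aln.row_ids if r not in union_state)
            if (len(set(counts.values())) == 1 and L > 0
                    and e - s - L <= 3 and others_clean):
                lead = max(group,
                           key=lambda x: (x.mechanism == "exonization_class",
                                          x.length_bp))
                merged = StructuralEvent(
                    event_id=group[0].event_id, mechanism=lead.mechanism,
                    exon_index=lead.exon_index, length_bp=L,
                    column_span=(s, e), state_rows=union_state,
                    alt_rows=frozenset(aln.row_ids) - union_state,
                    evidence=lead.evidence, detail=dict(lead.detail))
        if merged is not None:
            out.append(merged)
            i = j
        else:
            out.append(evs[i])
            i += 1
    return out


def _is_gained_exon(aln, present, s, e, lo, hi) -> bool:
    """All present rows bound the interval with their own exon boundaries."""
    if not present:
        return False
    for g in present:
        bl = aln.exon_boundaries.get(g)
        if not bl:
            return False
        if s not in bl or e not in bl:
            return False
    return True


def _attach_scan_evidence(ev, aln, fs, present, gaps, exon_index, s, e):
    """Scan an absent row's noncoding region for a homolog of the exon."""
    rep_present = min(present) if present else None
    if rep_present is None:
        return
    exon = aln.rows[rep_present][s:e].replace("-", "")
    for g in sorted(gaps):
        gm = fs.models.get(g)
        if gm is None or not gm.introns:
            continue
        # the merged intron spanning the missing exon's position
        idx = min(exon_index - 1, len(gm.introns))
        candidates = [gm.introns[idx - 1]] if idx >= 1 else []
        candidates += [gm.flank_3, gm.flank_5]
        for nc in candidates:
            if nc and len(exon) >= MIN_COLUMNS:
                hit = scan_noncoding_for_homolog(exon, nc)
                if hit is not None:
                    ev.mechanism = "exonization_class"
                    ev.evidence = "scan_hit"
                    ev.detail["scan_hit"] = (g, hit.offset, round(hit.identity, 3))
                    return
        break


def _classify_edge_interval(aln, fs, block, s, e, gaps, present, eid,
                            terminal: bool):
    """A gap interval touching a block edge: decide which exon the extra
    sequence belongs to (from the ungapped rows' own boundaries), then test
    the gapped rows' adjacent noncoding sequence for homology."""
    rep_long = min(present)
    rep_short = min(gaps)
    bl_long = set(aln.exon_boundaries.get(rep_long, []))
    row_long = aln.rows[rep_long]
    # the long row's exon effectively ends at the interval if nothing but
    # gaps (e.g. a minority gained exon) intervenes before its boundary
    s_anchor = _effective_anchor(row_long, bl_long, s, "left", aln.ncols)
    e_anchor = _effective_anchor(row_long, bl_long, e, "right", aln.ncols)
    at5 = s in (block.start, block.eff_start)
    at3 = e in (block.end, block.eff_end)
    side = exon_idx = None
    if at5:
        if s_anchor and not (e_anchor and not at3):
            side, exon_idx = "5", block.index
        elif e_anchor and block.index > 1:
            side, exon_idx = "3", block.index - 1  # 3' ext of previous exon
    elif at3:
        if e_anchor:
            side, exon_idx = "3", block.index
        elif s_anchor and not terminal:
            side, exon_idx = "5", block.index + 1  # 5' ext of next exon
    if side is None:
        return StructuralEvent(
            event_id=eid, mechanism="indeterminate_indel",
            exon_index=block.index, length_bp=e - s, column_span=(s, e),
            state_rows=gaps, alt_rows=present, evidence="internal_gap",
            detail={"column_block": block.index})
    extra = aln.rows[rep_long][s:e].replace("-", "")
    detail = {"column_block": block.index, "side": side}
    b = s if side == "5" else e
    cands = []
    for rep in sorted(present)[:3]:
        ann = _annotation_extra(aln, fs, rep, b, side, len(extra))
        if ann and ann not in cands:
            cands.append(ann)
    if extra not in cands:
        cands.append(extra)
    status, partner = "unavailable", None
    for cand in cands:
        status, partner, _m = _noncoding_probe(aln, fs, gaps, s, side, cand)
        if status == "hit":
            break
    if status == "hit":
        mech, evid = "exonization_class", "boundary_gap_noncoding_alignable"
        detail["noncoding_partner"] = partner
    elif status == "unavailable":
        mech, evid = "indeterminate_indel", "internal_gap"
        detail["note"] = ("no noncoding sequence available; boundary gap "
                          "left unpolarised")
    else:
        mech, evid = "indeterminate_indel", "internal_gap"
        detail["note"] = "boundary gap with no noncoding homology"
    return StructuralEvent(
        event_id=eid, mechanism=mech, exon_index=exon_idx,
        length_bp=len(extra), column_span=(s, e),
        state_rows=gaps, alt_rows=present, evidence=evid, detail=detail)


def _effective_anchor(row: str, boundaries: set, col: int, direction: str,
                      ncols: int) -> bool:
    if direction == "left":
        if col == 0 or col in boundaries:
            return True
        b = max((x for x in boundaries if x < col), default=0)
        return all(ch == "-" for ch in row[b:col])
    if col == ncols or col in boundaries:
        return True
    b = min((x for x in boundaries if x > col), default=ncols)
    return all(ch == "-" for ch in row[col:b])


def _noncoding_probe(aln, fs, gaps, ref_col, side, extra):
    """Run the anchored homology test against each gapped row's own adjacent
    noncoding sequence, indexed in that row's own exon numbering (rows may
    differ in exon count from the consensus).  Returns
    ``(status, partner, matches)`` with the best match count observed."""
    any_noncoding = 0
    for cand in sorted(gaps):
        if any_noncoding >= 3:
            break  # a real homolog is present in every partner's intron
        gm = fs.models.get(cand)
        if gm is None or not gm.exons:
            continue
        own = aln.exon_boundaries.get(cand, [])
        own_idx = sum(1 for b in own if b <= ref_col) \
            + (1 if side == "5" else 0)
        own_idx = max(1, min(own_idx, gm.n_exons))
        noncoding, nc_side = _adjacent_noncoding(gm, own_idx, side)
        if noncoding is None:
            continue
        any_noncoding += 1
        m = anchored_noncoding_match(extra, noncoding, nc_side)
        if m:
            return "hit", cand, m
    return ("nohit" if any_noncoding else "unavailable"), None, 0


def _reclassify_whole_exon_indels(aln, fs, events,
                                  slack: int = 5) -> None:
    """A long gap bounded by the ungapped rows' own exon boundaries is a
    whole-exon difference, not an intraexonic indel.

    This catches lost exons hiding inside a merged consensus block (the
    absent rows never voted the exon's boundaries into the consensus).
    """
    for ev in events:
        if ev.mechanism != "indeterminate_indel" or ev.length_bp < MIN_COLUMNS:
            continue
        s, e = ev.column_span
        annotated = [g for g in ev.alt_rows if aln.exon_boundaries.get(g)]
        if not annotated:
            continue
        bounded = 0
        for g in annotated:
            bl = aln.exon_boundaries[g]
            near_s = any(abs(x - s) <= slack for x in bl) or s <= slack
            near_e = any(abs(x - e) <= slack for x in bl) \
                or e >= aln.ncols - slack
            if near_s and near_e:
                bounded += 1
        if bounded * 2 < len(annotated):
            continue
        ev.mechanism = "indeterminate_exon_change"
        ev.evidence = "whole_exon_unalignable"
        ev.detail.setdefault("column_block", ev.exon_index)
        ev.detail["gained_subblock"] = True
        # the exon's true length comes from the bounded rows' annotation
        lens = []
        for g in annotated:
            gm = fs.models.get(g)
            bl = aln.exon_boundaries[g]
            starts, ends = [0] + bl, bl + [aln.ncols]
            for idx, (bs, be) in enumerate(zip(starts, ends), start=1):
                if (abs(bs - s) <= slack and abs(be - e) <= slack
                        and gm is not None and idx <= gm.n_exons):
                    lens.append(gm.exon_lengths[idx - 1])
                    break
        if lens:
            lens.sort()
            ev.length_bp = lens[len(lens) // 2]
        _attach_scan_evidence(ev, aln, fs, ev.alt_rows, ev.state_rows,
                              ev.exon_index, s, e)


def _reclassify_junction_indels(aln, fs, events, edges,
                                tolerance: int = 3) -> None:
    """Upgrade drifted boundary gaps from indels to exonization-class.

    Left-aligned canonicalisation (or chance matches inside the gap) can
    park a boundary gap away from the exon edge; re-test the ungapped rows'
    boundary-flush bases against the gapped rows' adjacent noncoding
    sequence.  Short runs are probed only close to a junction; runs of six
    or more columns are probed on both sides of their block (a long drifted
    gap can sit anywhere, and a long chance match is improbable).
    """
    for ev in events:
        if ev.mechanism != "indeterminate_indel" or ev.length_bp < 3:
            continue
        s, e = ev.column_span
        L = ev.length_bp
        rep_long = min(ev.alt_rows) if ev.alt_rows else None
        if rep_long is None:
            continue
        junctions = {b for b in edges[1:-1]
                     if s - 2 * tolerance <= b <= e + 2 * tolerance}
        reps_long = sorted(ev.alt_rows)[:3]
        rep_gap = min(ev.state_rows)
        obs_extra = aln.rows[rep_long][s:e].replace("-", "")
        hit = None
        mid = (s + e) / 2
        for b in sorted(junctions, key=lambda x: abs(x - mid)):
            i = edges.index(b)  # b separates block i (left) and i+1 (right)
            # the two interpretations can test overlapping noncoding
            # sequence; keep the better-supported one.  A side is only
            # considered when the gap sits on the right side of the
            # junction for it, and when parking it flush costs at most two
            # matches (a true interior indel cannot be moved that cheaply).
            candidates = []
            for side in ("3", "5"):
                if side == "5" and not (e >= b - 3 and s - b <= 2 * tolerance):
                    continue
                if side == "3" and not (s <= b + 3 and b - e <= 2 * tolerance):
                    continue
                blk = (edges[i - 1], b) if side == "3" else (b, edges[i + 1])
                exon_idx = i if side == "3" else i + 1
                if not _flush_guard(aln, rep_gap, reps_long[0], blk, L, side):
                    continue
                extras = set()
                for rl in reps_long:
                    ann = _annotation_extra(aln, fs, rl, b, side, L)
                    if ann:
                        extras.add(ann)
                if obs_extra and len(obs_extra) == L:
                    extras.add(obs_extra)
                best_m, best_partner = 0, None
                for extra in sorted(extras):
                    status, partner, m = _noncoding_probe(
                        aln, fs, ev.state_rows, b, side, extra)
                    if status == "hit" and m > best_m:
                        best_m, best_partner = m, partner
                if best_m:
                    candidates.append((best_m, side == "5", side, exon_idx,
                                       best_partner, i))
            if candidates:
                hit = max(candidates)[2:]
                break
        if hit:
            side, exon_idx, partner, i = hit
            ev.mechanism = "exonization_class"
            ev.evidence = "boundary_gap_noncoding_alignable"
            ev.exon_index = exon_idx
            cb = sum(1 for b0 in edges[1:-1] if b0 <= s) + 1
            ev.detail.update({"column_block": cb, "side": side,
                              "noncoding_partner": partner,
                              "drifted": True})


def _annotation_extra(aln, fs, row: str, b: int, side: str, L: int,
                      slack: int = 3) -> str | None:
    """The row's own boundary-flush bases at junction column ``b``.

    Reading the bases from the gene model rather than from alignment
    columns keeps the probe exact even when the row's gap placement has
    drifted around the junction.
    """
    gm = fs.models.get(row)
    if gm is None or not gm.exons:
        return None
    cnt = sum(1 for x in aln.exon_boundaries.get(row, []) if x <= b + slack)
    if side == "5":
        idx = cnt + 1
        if not 1 <= idx <= gm.n_exons:
            return None
        seq = gm.exon_seq(idx)[:L]
    else:
        idx = cnt
        if not 1 <= idx <= gm.n_exons:
            return None
        seq = gm.exon_seq(idx)[-L:]
    return seq if len(seq) == L else None


def _flush_guard(aln, rep_gap: str, rep_long: str, blk: tuple[int, int],
                 L: int, side: str, slack: int = 2) -> bool:
    """Would parking the gap flush at the junction cost real homology?

    Compares the gapped representative's observed matches against the
    ungapped one inside the block with the matches obtained by pairing its
    content boundary-flush (offset by the event length).  A drifted
    boundary gap loses at most a couple of chance matches; an interior
    indel would sacrifice the real alignment of every base between the
    boundary and the indel.
    """
    lo, hi = blk
    rg = aln.rows[rep_gap][lo:hi]
    rl = aln.rows[rep_long][lo:hi]
    observed = sum(1 for x, y in zip(rg, rl)
                   if x != "-" and y != "-" and x == y)
    G = rg.replace("-", "")
    R = rl.replace("-", "")
    if len(R) - len(G) != L:
        return True  # other gaps in play; leave the decision to the probe
    if side == "5":
        flush = sum(1 for i in range(len(G)) if G[i] == R[i + L])
    else:
        flush = sum(1 for i in range(len(G)) if G[i] == R[i])
    return flush >= observed - slack


def _detect_boundary_site_changes(aln, fs, bounds, id_prefix, counter):
    """Intron gain/loss: boundary columns present in some rows, absent and
    gap-free in others, verified by the perfect two-exon alignment test."""
    events = []
    annotated = [g for g in aln.row_ids if aln.exon_boundaries.get(g)]
    all_sites = sorted({c for g in annotated for c in aln.exon_boundaries[g]})
    seen_partitions = set()
    for site in all_sites:
        split = [g for g in annotated if site in aln.exon_boundaries[g]]
        merged = [g for g in annotated
                  if site not in aln.exon_boundaries[g]
                  and aln.rows[g][site - 1] != "-"
                  and site < aln.ncols and aln.rows[g][site] != "-"]
        if not split or not merged:
            continue
        # representatives diverge by substitution, so try several pairs
        # before giving up on the perfect-alignment test
        hit = None
        for s_rep in sorted(split)[:3]:
            for m_rep in sorted(merged)[:3]:
                gm_m, gm_s = fs.models.get(m_rep), fs.models.get(s_rep)
                if gm_m is None or gm_s is None:
                    continue
                try:
                    cands = detect_intron_change(gm_m, gm_s,
                                                 id_prefix=id_prefix)
                except ValueError:
                    continue
                i_split = aln.exon_boundaries[s_rep].index(site) + 1
                for ev in cands:
                    if ev.exon_index == i_split:
                        hit = ev
                        break
                if hit:
                    break
            if hit:
                break
        if hit is None:
            continue
        # the same merge is visible both from the split rows' boundary and
        # from the merged rows' shifted one; keep the first description
        partition = frozenset({frozenset(merged), frozenset(split)})
        if partition in seen_partitions:
            continue
        seen_partitions.add(partition)
        block_index = sum(1 for b in bounds if b < site) + 1
        detail = dict(hit.detail)
        detail["site_col"] = site
        detail["site_in_consensus"] = site in bounds
        events.append(StructuralEvent(
            event_id=f"{id_prefix}{next(counter)}",
            mechanism="intron_change", exon_index=block_index,
            length_bp=0, column_span=(site, site),
            state_rows=frozenset(merged), alt_rows=frozenset(split),
            evidence="exon_merge", detail=detail))
    return events


def _terminal_stop_events(aln, fs, existing, id_prefix, counter):
    """Run the pairwise stop-codon analysis when terminal exons disagree."""
    events = []
    lengths: dict[str, int] = {}
    for g in aln.row_ids:
        gm = fs.models.get(g)
        if gm is not None and gm.exons:
            lengths[g] = gm.exon_lengths[-1]
    if len(set(lengths.values())) < 2:
        return events
    groups: dict[int, list[str]] = {}
    for g, ln in lengths.items():
        groups.setdefault(ln, []).append(g)
    reps = [min(groups[ln]) for ln in sorted(groups)]
    covered = {(e.column_span, e.evidence) for e in existing}
    for ra, rb in itertools.combinations(reps, 2):
        try:
            found = detect_stop_codon_events(fs.models[ra], fs.models[rb],
                                             id_prefix=f"{id_prefix}{next(counter)}")
        except ValueError:
            continue
        for ev in found:
            # generalise the pairwise call to every row sharing each
            # representative's terminal-exon length
            marker_rep = min(ev.state_rows)
            carrier_rep = min(ev.carrier_genes)
            marker_group = frozenset(groups[lengths[marker_rep]])
            carrier_group = frozenset(groups[lengths[carrier_rep]])
            ev.state_rows = marker_group
            ev.alt_rows = frozenset(g for g in lengths
                                    if g not in marker_group)
            ev.carrier_genes = carrier_group
            if (ev.column_span, ev.evidence) not in covered:
                events.append(ev)
    return events
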