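"""Exon-boundary-aware codon alignments.

Two routes produce a :class:`CodonAlignment`:

* projection of a protein guide alignment onto the coding sequences (the
  PAL2NAL-style route used when a curated amino-acid alignment exists), and
* a built-in progressive nucleotide aligner guided by the input tree, used
  for synthetic desk-scale families so no external aligner is required.

Exon boundaries are then mapped into alignment columns, gap placement is
canonicalised exon by exon, and nonhomologous columns are masked before any
matrix is exported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _dp
from ._dp import DEFAULT_SCORING, Scoring
from .models import FamilySet, translate_cds

# Alignability thresholds used across event detection (see package docs):
# a segment is alignable iff a local alignment reaches >= MIN_IDENTITY over
# >= MIN_COLUMNS aligned columns; "perfectly aligned" (the intron-change
# test) requires PERFECT_IDENTITY over each sub-segment.
MIN_IDENTITY = 0.5
MIN_COLUMNS = 15
PERFECT_IDENTITY = 0.9
MAX_GAP_FRACTION = 0.8

# The progressive aligner penalises mismatches more heavily than the
# pairwise default so that novel (non-homologous) sequence gaps out rather
# than absorbing into a neighboring block: with mismatch -3 a random column
# pair (expected -1.75) would outscore a gap extension of -2.
MSA_SCORING = Scoring(match=2.0, mismatch=-4.0, gap_open=5.0, gap_extend=2.0)


@dataclass
class PairwiseAlignment:
    """A scored pairwise alignment with gapped strings and identity."""

    query_id: str
    target_id: str
    aligned_query: str
    aligned_target: str
    score: float
    mode: str
    query_start: int = 0
    query_end: int = 0
    target_start: int = 0
    target_end: int = 0

    @property
    def identity(self) -> float:
        m, c = self._match_cols()
        return m / c if c else 0.0

    @property
    def aligned_columns(self) -> int:
        return self._match_cols()[1]

    def _match_cols(self) -> tuple[int, int]:
        m = c = 0
        for x, y in zip(self.aligned_query, self.aligned_target):
            if x != "-" and y != "-":
                c += 1
                if x.upper() == y.upper():
                    m += 1
        return m, c

    def segment_identity(self, lo: int, hi: int) -> float:
        """Identity over target positions [lo, hi) of the aligned region."""
        m = c = 0
        tpos = self.target_start
        for x, y in zip(self.aligned_query, self.aligned_target):
            if y != "-":
                if lo <= tpos < hi and x != "-":
                    c += 1
                    if x.upper() == y.upper():
                        m += 1
                tpos += 1
        return m / c if c else 0.0

    def is_alignable(self, min_identity: float = MIN_IDENTITY,
                     min_columns: int = MIN_COLUMNS) -> bool:
        return self.aligned_columns >= min_columns and self.identity >= min_identity


def pairwise_flank_align(query: str, target: str, mode: str = "semiglobal",
                         scoring: Scoring = DEFAULT_SCORING,
                         query_id: str = "query",
                         target_id: str = "target") -> PairwiseAlignment:
    """Optimal affine-gap alignment of a focal region against another region.

    ``mode`` is ``global``, ``semiglobal`` (end gaps free) or ``local``.
    Raises on empty input.
    """
    if not query or not target:
        raise ValueError("empty query or target sequence")
    res = _dp.align_seqs(query, target, mode=mode, scoring=scoring)
    sq, st = _dp.path_to_strings(res.path, query, target)
    qpos = [p[0] for p in res.path if p[0] is not None]
    tpos = [p[1] for p in res.path if p[1] is not None]
    return PairwiseAlignment(
        query_id=query_id, target_id=target_id,
        aligned_query=sq, aligned_target=st, score=res.score, mode=mode,
        query_start=min(qpos) if qpos else 0,
        query_end=max(qpos) + 1 if qpos else 0,
        target_start=min(tpos) if tpos else 0,
        target_end=max(tpos) + 1 if tpos else 0)


@dataclass
class CodonAlignment:
    """A multiple nucleotide alignment with per-row exon boundary columns.

    ``rows`` maps gene_id -> gapped string; all rows share a length.
    ``exon_boundaries[gid]`` lists the alignment columns at which each of the
    first n-1 exons of that gene ends (exclusive end column, strictly
    increasing).  ``column_mask`` flags columns excluded from export and
    event classification, with a reason per masked column.
    """

    row_ids: list[str] = field(default_factory=list)
    rows: dict[str, str] = field(default_factory=dict)
    exon_boundaries: dict[str, list[int]] = field(default_factory=dict)
    unannotated: set[str] = field(default_factory=set)
    column_mask: dict[int, str] = field(default_factory=dict)
    length_variant_blocks: list[int] = field(default_factory=list)
    straddling_runs: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def ncols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def degapped(self, gid: str) -> str:
        return self.rows[gid].replace("-", "")

    def column_map(self, gid: str) -> np.ndarray:
        """Per-column CDS position (0-based) or -1 at gap columns."""
        row = np.frombuffer(self.rows[gid].encode(), dtype=np.uint8)
        nongap = row != ord("-")
        out = np.where(nongap, np.cumsum(nongap) - 1, -1)
        return out

    def cds_pos_to_column(self, gid: str, pos: int) -> int:
        """Alignment column holding CDS position ``pos`` (0-based)."""
        cm = self.column_map(gid)
        hits = np.nonzero(cm == pos)[0]
        if len(hits) == 0:
            raise IndexError(f"CDS position {pos} beyond row {gid}")
        return int(hits[0])

    def gap_matrix(self) -> np.ndarray:
        mat = np.stack([np.frombuffer(self.rows[g].encode(), dtype=np.uint8)
                        for g in self.row_ids])
        return mat == ord("-")

    def sum_of_pairs(self, scoring: Scoring = DEFAULT_SCORING,
                     cols: slice | None = None) -> float:
        """Sum-of-pairs score: substitution kernel plus per-run gap costs.

        Gap runs are charged per row pair: each maximal run of columns where
        exactly one of the two rows is gapped costs open + extend * length.
        """
        ids = self.row_ids
        sub = scoring.substitution_kernel()
        total = 0.0
        lo = cols.start if cols else 0
        hi = cols.stop if cols else self.ncols
        enc = {g: _dp.encode(self.rows[g][lo:hi]) for g in ids}
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                ra, rb = enc[ids[a]], enc[ids[b]]
                both = (ra != 5) & (rb != 5)
                total += sub[ra[both], rb[both]].sum()
                single = (ra == 5) ^ (rb == 5)
                run = 0
                for v in single:
                    if v:
                        run += 1
                    elif run:
                        total -= scoring.gap_cost(run)
                        run = 0
                if run:
                    total -= scoring.gap_cost(run)
        return float(total)

    def write_fasta(self, path, masked: bool = False) -> None:
        with open(path, "w") as fh:
            keep = [c for c in range(self.ncols) if c not in self.column_mask] \
                if masked else list(range(self.ncols))
            for gid in self.row_ids:
                row = self.rows[gid]
                fh.write(f">{gid}\n{''.join(row[c] for c in keep)}\n")

    def write_boundary_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\texon_index\tend_column\n")
            for gid in self.row_ids:
                for k, col in enumerate(self.exon_boundaries.get(gid, []), 1):
                    fh.write(f"{gid}\t{k}\t{col}\n")

    def write_mask_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("column\treason\n")
            for col in sorted(self.column_mask):
                fh.write(f"{col}\t{self.column_mask[col]}\n")


def read_alignment_fasta(path) -> CodonAlignment:
    from Bio import SeqIO
    aln = CodonAlignment()
    for rec in SeqIO.parse(str(path), "fasta"):
        aln.row_ids.append(rec.id)
        aln.rows[rec.id] = str(rec.seq).upper()
    lens = {len(r) for r in aln.rows.values()}
    if len(lens) > 1:
        raise ValueError("alignment rows differ in length")
    return aln


# ---------------------------------------------------------------------------
# protein -> codon projection

def project_protein_alignment(protein_aln: dict[str, str],
                              cds_by_id: dict[str, str]) -> CodonAlignment:
    """Expand an aligned protein matrix into its codon-based CDS alignment.

    Every residue column becomes one codon triple, protein gaps become
    ``---``, and a terminal stop codon is appended ungapped for rows whose
    CDS carries one.  Rows must translate exactly to their aligned residues.
    """
    lens = {len(v) for v in protein_aln.values()}
    if len(lens) > 1:
        raise ValueError("protein alignment rows differ in length")
    aln = CodonAlignment()
    any_stop = any(len(cds_by_id[g]) == 3 * len(p.replace("-", "")) + 3
                   for g, p in protein_aln.items())
    for gid, prot in protein_aln.items():
        cds = cds_by_id[gid].upper()
        residues = prot.replace("-", "")
        has_stop = len(cds) == 3 * len(residues) + 3
        if not has_stop and len(cds) != 3 * len(residues):
            raise ValueError(
                f"row {gid!r}: CDS length {len(cds)} does not match "
                f"{len(residues)} aligned residues")
        translated = translate_cds(cds)
        for k, (want, got) in enumerate(zip(residues, translated)):
            if want != got and want != "X":
                raise ValueError(
                    f"row {gid!r}: residue {k} is {want!r} but CDS encodes {got!r}")
        out = []
        pos = 0
        for ch in prot:
            if ch == "-":
                out.append("---")
            else:
                out.append(cds[pos:pos + 3])
                pos += 3
        if any_stop:
            out.append(cds[pos:pos + 3] if has_stop else "---")
        aln.row_ids.append(gid)
        aln.rows[gid] = "".join(out)
    return aln


# ---------------------------------------------------------------------------
# boundary marking

def mark_exon_boundaries(aln: CodonAlignment, fs: FamilySet) -> CodonAlignment:
    """Map each annotated row's cumulative exon lengths into alignment columns.

    A boundary is recorded as the column just after the exon's last base
    (so the exon occupies columns [previous boundary, boundary)).  Rows with
    no structural annotation get an empty list and are flagged.
    """
    for gid in aln.row_ids:
        gm = fs.models.get(gid)
        if gm is None or not gm.exons:
            aln.exon_boundaries[gid] = []
            aln.unannotated.add(gid)
            continue
        offsets = gm.exon_cds_offsets()[:-1]  # internal boundaries only
        cm = aln.column_map(gid)
        cols = []
        for off in offsets:
            hits = np.nonzero(cm == off - 1)[0]
            if len(hits) == 0:
                raise ValueError(
                    f"row {gid!r}: exon lengths exceed the aligned CDS")
            cols.append(int(hits[0]) + 1)
        aln.exon_boundaries[gid] = cols
        aln.unannotated.discard(gid)
    return aln


def consensus_boundaries(aln: CodonAlignment, min_fraction: float = 0.5) -> list[int]:
    """Boundary columns shared by more than ``min_fraction`` of the rows
    informative there (rows with aligned sequence on both sides of the
    column; a row whose gene ends upstream does not get a vote)."""
    counts: dict[int, int] = {}
    annotated = [g for g in aln.row_ids if aln.exon_boundaries.get(g)]
    if not annotated:
        return []
    extents = {}
    for gid in annotated:
        row = aln.rows[gid]
        first = len(row) - len(row.lstrip("-"))
        last = len(row.rstrip("-"))
        extents[gid] = (first, last)
    for gid in annotated:
        for col in aln.exon_boundaries[gid]:
            counts[col] = counts.get(col, 0) + 1
    out = []
    for col, k in counts.items():
        informative = sum(1 for g in annotated
                          if extents[g][0] < col < extents[g][1])
        if informative and k > min_fraction * informative:
            out.append(col)
    return sorted(out)


# ---------------------------------------------------------------------------
# progressive aligner (guide tree = input tree)

def progressive_align(seqs: dict[str, str], tree,
                      scoring: Scoring = MSA_SCORING) -> CodonAlignment:
    """Progressive profile alignment of nucleotide sequences along a tree.

    ``tree`` is a :class:`~exevol.parsimony.PhyloTree`; leaves are merged
    post-order with global affine-gap profile alignment under the package's
    nucleotide scheme.  Intended for desk-scale synthetic families, not as a
    replacement for a production multiple aligner.
    """
    groups: dict[str, tuple[list[str], list[str]]] = {}

    def merge(node) -> tuple[list[str], list[str]]:
        kids = tree.children.get(node, [])
        if not kids:
            if node not in seqs:
                raise KeyError(f"tree leaf {node!r} has no sequence")
            return [node], [seqs[node].upper()]
        ids, rows = merge(kids[0])
        for kid in kids[1:]:
            ids2, rows2 = merge(kid)
            pa = _dp.rows_profile(rows)
            pb = _dp.rows_profile(rows2)
            res = _dp.align_profiles(pa, pb, mode="global", scoring=scoring)
            rows = _expand_rows(rows, [p[0] for p in res.path])
            rows2 = _expand_rows(rows2, [p[1] for p in res.path])
            ids = ids + ids2
            rows = rows + rows2
        groups[node] = (ids, rows)
        return ids, rows

    ids, rows = merge(tree.root)
    aln = CodonAlignment()
    order = [g for g in tree.leaf_ids() if g in seqs]
    rowmap = dict(zip(ids, rows))
    for gid in order:
        aln.row_ids.append(gid)
        aln.rows[gid] = rowmap[gid]
    return aln


def _expand_rows(rows: list[str], col_idx: list[int | None]) -> list[str]:
    out = []
    for r in rows:
        out.append("".join(r[i] if i is not None else "-" for i in col_idx))
    return out


def leave_one_out_refine(aln: CodonAlignment,
                         scoring: Scoring = MSA_SCORING,
                         rounds: int = 1) -> CodonAlignment:
    """Realign each row against the profile of the others.

    Progressive alignment resolves gap-placement ties independently in each
    profile merge, which can leave homologous gaps staggered across subtrees;
    one sequence-to-profile pass with a fixed row order harmonises them.
    All-gap columns left behind are dropped.
    """
    for _ in range(rounds):
        for gid in sorted(aln.rows):
            others = [g for g in aln.row_ids if g != gid]
            if not others:
                continue
            old_rows = dict(aln.rows)
            before = aln.sum_of_pairs(scoring)
            prof = _dp.rows_profile([aln.rows[g] for g in others])
            seq = aln.degapped(gid)
            res = _dp.align_profiles(_dp.seq_profile(seq), prof,
                                     mode="global", scoring=scoring)
            new_others = _expand_rows([aln.rows[g] for g in others],
                                      [p[1] for p in res.path])
            new_row = "".join(seq[p[0]] if p[0] is not None else "-"
                              for p in res.path)
            for g, r in zip(others, new_others):
                aln.rows[g] = r
            aln.rows[gid] = new_row
            _drop_all_gap_columns(aln)
            # a merely tie-equivalent rearrangement may break gap agreement
            # between rows that share an event; keep only strict improvements
            if aln.sum_of_pairs(scoring) <= before + 1e-6:
                aln.rows = old_rows
    return aln


def _drop_all_gap_columns(aln: CodonAlignment) -> None:
    rows = [aln.rows[g] for g in aln.row_ids]
    keep = [c for c in range(len(rows[0]))
            if any(r[c] != "-" for r in rows)]
    if len(keep) != len(rows[0]):
        for g in aln.row_ids:
            aln.rows[g] = "".join(aln.rows[g][c] for c in keep)


# ---------------------------------------------------------------------------
# exon-by-exon refinement

def refine_exon_by_exon(aln: CodonAlignment, fs: FamilySet,
                        scoring: Scoring = DEFAULT_SCORING,
                        max_rounds: int = 4) -> CodonAlignment:
    """Canonicalise gap placement inside homologous exon blocks.

    Within each consensus block, every interior gap run is shifted left one
    column at a time whenever the block's sum-of-pairs score does not
    decrease, which both left-aligns score-equivalent runs and never lowers
    the score.  Runs are not moved across block edges; a run already
    straddling a consensus boundary is kept (the straddling placement can
    only have been produced by a higher-scoring alignment) and flagged.
    Blocks whose per-row ungapped lengths differ are flagged as candidates
    for event detection.
    """
    bounds = consensus_boundaries(aln)
    edges = [0] + bounds + [aln.ncols]
    aln.length_variant_blocks = []
    aln.straddling_runs = []
    for bi in range(len(edges) - 1):
        lo, hi = edges[bi], edges[bi + 1]
        if hi - lo < 2:
            continue
        for _ in range(max_rounds):
            moved = False
            groups: dict[tuple[int, int], list[str]] = {}
            for gid in aln.row_ids:
                for start, end in _gap_runs(aln.rows[gid], lo, hi):
                    if start <= lo or end >= hi:
                        continue  # run touches a block edge: boundary territory
                    groups.setdefault((start, end), []).append(gid)
            # rows sharing a byte-identical run move together; shifting them
            # one at a time would break their mutual agreement and stall
            for (start, end), gids in sorted(groups.items()):
                if _try_shift_left(aln, gids, start, end, lo, scoring):
                    moved = True
            if not moved:
                break
        lens = {len(aln.rows[g][lo:hi].replace("-", "")) for g in aln.row_ids}
        if len(lens) > 1:
            aln.length_variant_blocks.append(bi + 1)
    _resolve_straddles(aln, bounds, scoring)
    _harmonize_runs(aln, scoring)
    for gid in aln.row_ids:
        row = aln.rows[gid]
        for b in bounds:
            for start, end in _gap_runs(row, 0, aln.ncols):
                if start < b < end:
                    aln.straddling_runs.append((gid, start, end))
    return aln


def _resolve_straddles(aln: CodonAlignment, bounds: list[int],
                       scoring: Scoring) -> None:
    """Move gap runs that straddle a consensus boundary to one side of it.

    Tries shifting right until the run starts at the boundary, then left
    until it ends there, one column at a time, accepting only non-decreasing
    sum-of-pairs moves; a run that resists both stays put (and is flagged by
    the caller as a straddling run).
    """
    for gid in aln.row_ids:
        for b in bounds:
            run = next(((s, e) for s, e in
                        _gap_runs(aln.rows[gid], 0, aln.ncols)
                        if s < b < e), None)
            if run is None:
                continue
            for direction in (+1, -1):
                snapshot = aln.rows[gid]
                s, e = run
                ok = True
                while (s < b < e) and ok:
                    ok = _shift_run(aln, gid, s, e, direction, scoring)
                    if ok:
                        s, e = s + direction, e + direction
                if s >= b or e <= b:
                    break
                aln.rows[gid] = snapshot


def _harmonize_runs(aln: CodonAlignment, scoring: Scoring,
                    max_offset: int = 3, rounds: int = 3) -> None:
    """Snap equal-length gap runs lying a few columns apart onto shared
    columns.

    Rows hit by the same event can end up with the run parked at tied but
    different offsets (each profile merge breaks ties independently, and
    one-column shifts stall on non-monotone score paths); jumping a whole
    run to its partner's columns is accepted whenever sum-of-pairs does not
    drop.
    """
    for _ in range(rounds * 8):
        groups: dict[tuple[int, int], list[str]] = {}
        for gid in aln.row_ids:
            for run in _gap_runs(aln.rows[gid], 0, aln.ncols):
                groups.setdefault(run, []).append(gid)
        keys = sorted(groups)
        moved = False
        for i, ka in enumerate(keys):
            if moved:
                break
            for kb in keys[i + 1:]:
                if kb[0] - ka[1] > max_offset:
                    break
                if (kb[1] - kb[0]) != (ka[1] - ka[0]):
                    continue
                if abs(kb[0] - ka[0]) > max_offset:
                    continue
                # move the smaller group onto the larger (ties: later→earlier)
                if len(groups[kb]) <= len(groups[ka]):
                    src, dst = kb, ka
                else:
                    src, dst = ka, kb
                if _jump_runs(aln, groups[src], src, dst, scoring):
                    moved = True
                    break
        if not moved:
            break


def _jump_runs(aln, gids, src, dst, scoring) -> bool:
    (s1, e1), (s2, _e2) = src, dst
    L = e1 - s1
    old = {g: aln.rows[g] for g in gids}

    def rejig(row: str) -> str | None:
        if s2 > s1:  # move right by s2 - s1 (runs may overlap)
            if "-" in row[e1:s2 + L]:
                return None
            return row[:s1] + row[e1:s2 + L] + "-" * L + row[s2 + L:]
        if "-" in row[s2:s1]:
            return None
        return row[:s2] + "-" * L + row[s2:s1] + row[e1:]

    new_rows = {}
    for g in gids:
        nr = rejig(old[g])
        if nr is None:
            return False
        new_rows[g] = nr
    lo, hi = min(s1, s2), max(e1, s2 + L)
    span = slice(lo, hi)
    before = aln.sum_of_pairs(scoring, cols=span)
    aln.rows.update(new_rows)
    after = aln.sum_of_pairs(scoring, cols=span)
    if after + 1e-9 >= before:
        return True
    aln.rows.update(old)
    return False


def _shift_run(aln, gid, s, e, direction, scoring) -> bool:
    row = aln.rows[gid]
    if direction > 0:
        if e >= aln.ncols or row[e] == "-":
            return False
        candidate = row[:s] + row[e] + row[s:e] + row[e + 1:]
        span = slice(s, e + 1)
    else:
        if s <= 0 or row[s - 1] == "-":
            return False
        candidate = row[:s - 1] + row[s:e] + row[s - 1] + row[e:]
        span = slice(s - 1, e)
    before = aln.sum_of_pairs(scoring, cols=span)
    aln.rows[gid] = candidate
    if aln.sum_of_pairs(scoring, cols=span) + 1e-9 >= before:
        return True
    aln.rows[gid] = row
    return False


def _gap_runs(row: str, lo: int, hi: int) -> list[tuple[int, int]]:
    runs = []
    start = None
    for c in range(lo, hi):
        if row[c] == "-":
            if start is None:
                start = c
        elif start is not None:
            runs.append((start, c))
            start = None
    if start is not None:
        runs.append((start, hi))
    return runs


def _try_shift_left(aln: CodonAlignment, gids: list[str], start: int,
                    end: int, lo: int, scoring: Scoring) -> bool:
    """Shift a shared gap run left one column if sum-of-pairs does not drop."""
    if start - 1 < lo:
        return False
    old = {g: aln.rows[g] for g in gids}
    if any(old[g][start - 1] == "-" for g in gids):
        return False
    span = slice(start - 1, end)
    before = aln.sum_of_pairs(scoring, cols=span)
    for g in gids:
        row = old[g]
        aln.rows[g] = (row[:start - 1] + row[start:end] + row[start - 1]
                       + row[end:])
    after = aln.sum_of_pairs(scoring, cols=span)
    if after + 1e-9 >= before:
        return True
    aln.rows.update(old)
    return False


# ---------------------------------------------------------------------------
# masking

def mask_nonhomologous_columns(aln: CodonAlignment, events: list,
                               max_gap_fraction: float = MAX_GAP_FRACTION
                               ) -> CodonAlignment:
    """Mask columns whose homology is not trustworthy.

    Three rules: (1) columns downstream of an unrepaired frameshift (within
    the span where some row's cumulative non-triplet offset is nonzero);
    (2) columns where independent events with disjoint carrier sets overlap;
    (3) columns with more than ``max_gap_fraction`` gaps.
    """
    ncols = aln.ncols
    nrows = len(aln.row_ids)
    gap = aln.gap_matrix()
    gap_frac = gap.sum(axis=0) / max(nrows, 1)
    for c in np.nonzero(gap_frac > max_gap_fraction)[0]:
        aln.column_mask.setdefault(int(c), "gap_fraction")

    # rule 1: unrepaired frameshifts, tracked per carrier row
    frame_events = [e for e in events
                    if not e.frame_preserving and e.length_bp % 3 != 0]
    by_row: dict[str, list] = {}
    for e in frame_events:
        for gid in (e.carrier_genes or e.state_rows):
            by_row.setdefault(gid, []).append(e)
    for gid, evs in by_row.items():
        evs = sorted(evs, key=lambda e: e.column_span[0])
        offset = 0
        open_from = None
        for e in evs:
            sign = 1
            offset = (offset + sign * e.length_bp) % 3
            if offset != 0 and open_from is None:
                open_from = e.column_span[1]
            elif offset == 0 and open_from is not None:
                for c in range(open_from, e.column_span[0]):
                    aln.column_mask.setdefault(c, "frameshift")
                open_from = None
        if open_from is not None:
            for c in range(open_from, ncols):
                aln.column_mask.setdefault(c, "frameshift")

    # rule 2: independent overlapping events
    for i, ea in enumerate(events):
        for eb in events[i + 1:]:
            sa = set(ea.state_rows) if ea.state_rows else set(ea.carrier_genes)
            sb = set(eb.state_rows) if eb.state_rows else set(eb.carrier_genes)
            lo = max(ea.column_span[0], eb.column_span[0])
            hi = min(ea.column_span[1], eb.column_span[1])
            if lo < hi and not (sa & sb):
                for c in range(lo, hi):
                    aln.column_mask.setdefault(c, "independent events")
    return aln
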