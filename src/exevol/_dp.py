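"""Affine-gap dynamic programming over nucleotide sequences and alignment profiles.

A single Gotoh-style engine backs every pairwise comparison in the package:
exon-plus-flank checks, the intron-change "perfect alignment" test, noncoding
homology scans, and the profile merges of the built-in progressive aligner.

Conventions
-----------
* Alphabet ``ACGTN-`` encoded 0..5.  ``N`` and gap score 0 against everything.
* A gap of length L costs ``gap_open + gap_extend * L`` (so a 1-column gap
  costs ``gap_open + gap_extend``).
* Modes: ``global`` (Needleman-Wunsch), ``semiglobal`` (end gaps free on both
  sequences), ``local`` (Smith-Waterman).
* Traceback ties are broken deterministically: diagonal, then up (gap in the
  second sequence), then left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ALPHABET = "ACGTN-"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
NEG = -1e30

DEFAULT_MATCH = 2.0
DEFAULT_MISMATCH = -3.0
DEFAULT_GAP_OPEN = 5.0
DEFAULT_GAP_EXTEND = 2.0


@dataclass(frozen=True)
class Scoring:
    match: float = DEFAULT_MATCH
    mismatch: float = DEFAULT_MISMATCH
    gap_open: float = DEFAULT_GAP_OPEN   # positive penalty
    gap_extend: float = DEFAULT_GAP_EXTEND  # positive penalty

    def substitution_kernel(self) -> np.ndarray:
        """6x6 kernel over ACGTN-; N/gap columns score 0."""
        k = np.zeros((6, 6))
        acgt = slice(0, 4)
        k[acgt, acgt] = self.mismatch
        for i in range(4):
            k[i, i] = self.match
        return k

    def gap_cost(self, length: int) -> float:
        return self.gap_open + self.gap_extend * length if length > 0 else 0.0


DEFAULT_SCORING = Scoring()


def encode(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.uint8)
    for i, c in enumerate(seq.upper()):
        out[i] = _CODE.get(c, 4)  # unknown symbols behave like N
    return out


def seq_profile(seq: str) -> np.ndarray:
    """One-hot count profile (L x 6) for a single ungapped/gapped string."""
    codes = encode(seq)
    prof = np.zeros((len(codes), 6))
    prof[np.arange(len(codes)), codes] = 1.0
    return prof


def rows_profile(rows: list[str]) -> np.ndarray:
    """Column count profile for a set of equal-length gapped strings."""
    if not rows:
        raise ValueError("empty profile")
    mat = np.stack([encode(r) for r in rows])
    prof = np.zeros((mat.shape[1], 6))
    for a in range(6):
        prof[:, a] = (mat == a).sum(axis=0)
    return prof


def _pair_scores(pa: np.ndarray, pb: np.ndarray, sc: Scoring) -> np.ndarray:
    fa = pa / pa.sum(axis=1, keepdims=True)
    fb = pb / pb.sum(axis=1, keepdims=True)
    return fa @ sc.substitution_kernel() @ fb.T


@dataclass
class DPResult:
    score: float
    # pairs of (i, j) indices into the two inputs; None marks a gap
    path: list[tuple[int | None, int | None]]
    start: tuple[int, int]  # 0-based start coordinates of the aligned region
    end: tuple[int, int]    # exclusive end coordinates


def _fill(pa, pb, sc: Scoring, mode: str):
    m, n = pa.shape[0], pb.shape[0]
    S = _pair_scores(pa, pb, sc)
    op, ex = sc.gap_open, sc.gap_extend
    H = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)  # gap in first input (left moves)
    F = np.full((m + 1, n + 1), NEG)  # gap in second input (up moves)
    D = np.full((m + 1, n + 1), NEG)  # best at (i,j) not ending in a left-gap
    H[0, 0] = 0.0
    if mode == "global":
        j = np.arange(1, n + 1)
        E[0, 1:] = -(op + ex * j)
        H[0, 1:] = E[0, 1:]
        i = np.arange(1, m + 1)
        F[1:, 0] = -(op + ex * i)
        H[1:, 0] = F[1:, 0]
    else:
        H[0, :] = 0.0
        H[:, 0] = 0.0
    D[:, 0] = H[:, 0]
    D[0, :] = H[0, :]
    ecoef = ex * np.arange(n + 1)
    for i in range(1, m + 1):
        F[i, 1:] = np.maximum(F[i - 1, 1:] - ex, H[i - 1, 1:] - op - ex)
        drow = np.maximum(H[i - 1, :-1] + S[i - 1, :], F[i, 1:])
        D[i, 1:] = drow
        # E[i,j] = max_{k<j} D[i,k] - op - ex*(j-k): prefix-max trick
        run = np.maximum.accumulate(D[i, :-1] + ecoef[:-1])
        E[i, 1:] = run - op - ecoef[1:]
        H[i, 1:] = np.maximum(D[i, 1:], E[i, 1:])
        if mode == "local":
            H[i, 1:] = np.maximum(H[i, 1:], 0.0)
    return H, E, F, D, S


def _eq(x: float, y: float) -> bool:
    # profile column scores are rational, so equality checks carry a tolerance
    return abs(x - y) <= 1e-6


def _traceback(H, E, F, D, S, sc: Scoring, mode: str, m: int, n: int) -> DPResult:
    op, ex = sc.gap_open, sc.gap_extend
    if mode == "global":
        i, j = m, n
        score = H[m, n]
    elif mode == "semiglobal":
        best = (NEG, -1, -1)
        for jj in range(n, -1, -1):
            if H[m, jj] > best[0]:
                best = (H[m, jj], m, jj)
        for ii in range(m - 1, -1, -1):
            if H[ii, n] > best[0]:
                best = (H[ii, n], ii, n)
        score, i, j = best
        i, j = int(i), int(j)
    else:  # local
        flat = int(np.argmax(H))
        i, j = divmod(flat, H.shape[1])
        score = H[i, j]
    end = (i, j)
    path: list[tuple[int | None, int | None]] = []
    if mode == "semiglobal":
        for jj in range(n - 1, j - 1, -1):
            path.append((None, jj))
        for ii in range(m - 1, i - 1, -1):
            path.append((ii, None))
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if mode == "local" and H[i, j] == 0.0:
                break
            if _eq(H[i, j], D[i, j]):
                state = "D"
            else:
                state = "E"
            continue
        if state == "D":
            if _eq(D[i, j], H[i - 1, j - 1] + S[i - 1, j - 1]):
                path.append((i - 1, j - 1))
                i -= 1
                j -= 1
                state = "H"
            else:
                state = "F"
            continue
        if state == "F":
            path.append((i - 1, None))
            ended = _eq(F[i, j], H[i - 1, j] - op - ex)
            i -= 1
            state = "H" if ended else "F"
            continue
        # state == "E"
        path.append((None, j - 1))
        ended = _eq(E[i, j], D[i, j - 1] - op - ex)
        j -= 1
        state = "D" if ended else "E"
    if mode != "local" and state == "F" and i > 0:
        while i > 0:
            path.append((i - 1, None))
            i -= 1
    if mode != "local" and state == "E" and j > 0:
        while j > 0:
            path.append((None, j - 1))
            j -= 1
    if mode == "global":
        while i > 0:
            path.append((i - 1, None))
            i -= 1
        while j > 0:
            path.append((None, j - 1))
            j -= 1
    elif mode == "semiglobal":
        while i > 0:
            path.append((i - 1, None))
            i -= 1
        while j > 0:
            path.append((None, j - 1))
            j -= 1
    path.reverse()
    return DPResult(score=float(score), path=path, start=(i, j), end=end)


def align_profiles(pa: np.ndarray, pb: np.ndarray, mode: str = "global",
                   scoring: Scoring = DEFAULT_SCORING) -> DPResult:
    if pa.shape[0] == 0 or pb.shape[0] == 0:
        raise ValueError("cannot align an empty sequence or profile")
    if mode not in ("global", "semiglobal", "local"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    H, E, F, D, S = _fill(pa, pb, scoring, mode)
    return _traceback(H, E, F, D, S, scoring, mode, pa.shape[0], pb.shape[0])


def align_seqs(a: str, b: str, mode: str = "global",
               scoring: Scoring = DEFAULT_SCORING) -> DPResult:
    return align_profiles(seq_profile(a), seq_profile(b), mode, scoring)


def local_best_hit(query: str, target: str,
                   scoring: Scoring = DEFAULT_SCORING) -> tuple[float, int, int]:
    """Score-only Smith-Waterman; returns (best score, end_i, end_j).

    Streams one row at a time so targets of hundreds of kilobases stay cheap;
    the caller re-runs :func:`align_seqs` on a window for the traceback.
    """
    pa, pb = seq_profile(query), seq_profile(target)
    m, n = pa.shape[0], pb.shape[0]
    if m == 0 or n == 0:
        return 0.0, 0, 0
    S = _pair_scores(pa, pb, scoring)
    op, ex = scoring.gap_open, scoring.gap_extend
    ecoef = ex * np.arange(n + 1)
    Hprev = np.zeros(n + 1)
    Fprev = np.full(n + 1, NEG)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        F = np.maximum(Fprev[1:] - ex, Hprev[1:] - op - ex)
        drow = np.maximum(Hprev[:-1] + S[i - 1, :], F)
        dfull = np.concatenate(([0.0], drow))
        run = np.maximum.accumulate(dfull[:-1] + ecoef[:-1])
        Erow = run - op - ecoef[1:]
        H = np.concatenate(([0.0], np.maximum(np.maximum(drow, Erow), 0.0)))
        jbest = int(np.argmax(H))
        if H[jbest] > best:
            best, bi, bj = float(H[jbest]), i, jbest
        Hprev = H
        Fprev = np.concatenate(([NEG], F))
    return best, bi, bj


def path_identity(path, a: str, b: str) -> tuple[int, int]:
    """(matches, aligned_columns) over non-gap columns of a DP path."""
    matches = 0
    cols = 0
    for qi, tj in path:
        if qi is not None and tj is not None:
            cols += 1
            if a[qi].upper() == b[tj].upper():
                matches += 1
    return matches, cols


def path_to_strings(path, a: str, b: str) -> tuple[str, str]:
    sa, sb = [], []
    for qi, tj in path:
        sa.append(a[qi] if qi is not None else "-")
        sb.append(b[tj] if tj is not None else "-")
    return "".join(sa), "".join(sb)
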