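"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by brute force or naive
dynamic programming so they stay independent of the package's optimised
implementations.
"""

from __future__ import annotations

import itertools

import pytest

from exevol.models import GeneModel


# ---------------------------------------------------------------------------
# naive affine-gap DP oracle (no Gotoh decomposition, cubic time)

def naive_affine_score(a: str, b: str, mode: str = "global",
                       match: float = 2.0, mismatch: float = -3.0,
                       gap_open: float = 5.0, gap_extend: float = 2.0
                       ) -> float:
    """Optimal affine-gap alignment score by explicit gap-length maximisation.

    ``H[i][j]`` is the best score of an alignment consuming ``a[:i]`` and
    ``b[:j]``; gaps are charged ``gap_open + gap_extend * L`` per run, with
    every run length tried explicitly.
    """
    m, n = len(a), len(b)
    NEG = float("-inf")

    def gap(L):
        return gap_open + gap_extend * L

    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0.0
    free_ends = mode in ("semiglobal", "local")
    for i in range(m + 1):
        for j in range(n + 1):
            best = H[i][j]
            if free_ends and (i == 0 or j == 0):
                best = max(best, 0.0)
            if i > 0 and j > 0:
                s = match if a[i - 1].upper() == b[j - 1].upper() else mismatch
                best = max(best, H[i - 1][j - 1] + s)
            for k in range(1, i + 1):
                best = max(best, H[i - k][j] - gap(k))
            for k in range(1, j + 1):
                best = max(best, H[i][j - k] - gap(k))
            if mode == "local":
                best = max(best, 0.0)
            H[i][j] = best
    if mode == "global":
        return H[m][n]
    if mode == "semiglobal":
        return max(max(H[m]), max(H[i][n] for i in range(m + 1)))
    return max(max(row) for row in H)


# ---------------------------------------------------------------------------
# exhaustive binary-character parsimony oracle

def exhaustive_parsimony_cost(tree, state_of_leaf: dict[str, int]) -> int:
    """Minimum state changes over all assignments of internal node states."""
    internals = [n for n in tree.preorder() if not tree.is_leaf(n)]
    best = 10 ** 9
    for assignment in itertools.product((0, 1), repeat=len(internals)):
        states = dict(zip(internals, assignment))
        states.update(state_of_leaf)
        cost = 0
        for child, parent in tree.parent.items():
            if child in states and parent in states:
                cost += states[child] != states[parent]
        best = min(best, cost)
    return best


# ---------------------------------------------------------------------------
# tiny hand-built gene models

@pytest.fixture
def toy_two_exon_gene():
    """A 2-exon '+'-strand gene: exons of 9 and 6 bp inside a small locus."""
    genomic = "TTTT" + "ATGGCCAAA" + "GTAAG" + "TTTAA" + "CCCC"
    #          flank   exon1(9)      intron(10 total)   exon2? fix below
    genomic = "TTTT" + "ATGGCCAAA" + "GTACGTATAG" + "GGGTAA" + "CCCC"
    gm = GeneModel(gene_id="toy", species_id="toysp", strand="+",
                   exons=[(4, 13), (23, 29)],
                   cds="ATGGCCAAA" + "GGGTAA",
                   introns=["GTACGTATAG"], flank_5="TTTT", flank_3="CCCC")
    return gm, genomic
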