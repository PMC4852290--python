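"""Parsimony placement of events on a rooted tree and ancestral structures.

Each event's marker character (gap present / exon merged / exon absent) is a
binary character on the leaves.  Placement minimises state changes (Fitch /
Sankoff with unit costs); among equally parsimonious reconstructions the
single-origin (Dollo-like) scenario is preferred, then the root-most origin.
The root state — which polarises insertion-vs-deletion, gain-vs-loss and
exonization-vs-pseudoexonization — is fixed by a designated outgroup when
one exists, otherwise by the majority preference of the two root-adjacent
subtrees (ties flagged indeterminate).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy

from .events import StructuralEvent
from .models import FamilySet

INF = (10 ** 9, 10 ** 9, 10 ** 9)


@dataclass
class PhyloTree:
    """A rooted tree as parent/child maps keyed by node ids.

    Leaf ids are gene ids; internal nodes keep their Newick labels (e.g.
    MRCA labels) or receive stable preorder ids ``n1, n2, ...``.
    """

    root: str
    children: dict[str, list[str]] = field(default_factory=dict)
    parent: dict[str, str] = field(default_factory=dict)
    outgroup: str | None = None

    @classmethod
    def from_newick(cls, newick: str, outgroup: str | None = None) -> "PhyloTree":
        t = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True)
        counter = itertools.count(1)
        ids: dict = {}

        def node_id(nd):
            if nd in ids:
                return ids[nd]
            if nd.is_leaf():
                ids[nd] = nd.taxon.label if nd.taxon else f"leaf{next(counter)}"
            else:
                ids[nd] = nd.label or f"n{next(counter)}"
            return ids[nd]

        tree = cls(root="")
        for nd in t.preorder_node_iter():
            nid = node_id(nd)
            if nd.parent_node is None:
                tree.root = nid
            else:
                pid = node_id(nd.parent_node)
                tree.children.setdefault(pid, []).append(nid)
                tree.parent[nid] = pid
            tree.children.setdefault(nid, [])
        tree.outgroup = outgroup
        return tree

    def is_leaf(self, nid: str) -> bool:
        return not self.children.get(nid)

    def leaf_ids(self) -> list[str]:
        return [n for n in self.preorder() if self.is_leaf(n)]

    def preorder(self) -> list[str]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self.children.get(n, [])))
        return out

    def nodes_postorder(self) -> list[str]:
        out = []

        def rec(n):
            for c in self.children.get(n, []):
                rec(c)
            out.append(n)
        rec(self.root)
        return out

    def depth(self, nid: str) -> int:
        d = 0
        while nid in self.parent:
            nid = self.parent[nid]
            d += 1
        return d

    def path_from_root(self, leaf: str) -> list[str]:
        """Node ids from root to ``leaf`` inclusive."""
        path = [leaf]
        while path[-1] in self.parent:
            path.append(self.parent[path[-1]])
        return path[::-1]

    def subtree_leaves(self, nid: str) -> frozenset:
        out = []
        stack = [nid]
        while stack:
            n = stack.pop()
            kids = self.children.get(n, [])
            if not kids:
                out.append(n)
            stack.extend(kids)
        return frozenset(out)

    def mrca(self, leaves) -> str:
        paths = [self.path_from_root(lf) for lf in leaves]
        anc = self.root
        for nodes in zip(*paths):
            if len(set(nodes)) == 1:
                anc = nodes[0]
            else:
                break
        return anc

    def to_newick(self, branch_comments: dict[str, str] | None = None) -> str:
        branch_comments = branch_comments or {}

        def rec(n):
            kids = self.children.get(n, [])
            comment = branch_comments.get(n, "")
            comment = f"[&&NHX:{comment}]" if comment else ""
            if not kids:
                return f"{n}{comment}"
            inner = ",".join(rec(c) for c in kids)
            return f"({inner}){n}{comment}"
        return rec(self.root) + ";"


@dataclass
class EventPlacement:
    event_id: str
    branches: list[str]            # child-node ids of derived-origin branches
    loss_branches: list[str]       # reversions under the chosen scenario
    mechanism: str
    cost: int
    carrier_genes: frozenset
    root_has_marker: bool
    root_ambiguous: bool = False
    alternatives: list[tuple[str, ...]] = field(default_factory=list)
    event: StructuralEvent | None = None
    suppressed: bool = False


def _polarized_mechanism(ev: StructuralEvent, derived_is_marker: bool) -> str:
    if ev.mechanism == "indeterminate_indel":
        return ("intraexonic_deletion" if derived_is_marker
                else "intraexonic_insertion")
    if ev.mechanism == "exonization_class":
        return "pseudoexonization" if derived_is_marker else "exonization"
    if ev.mechanism == "indeterminate_exon_change":
        return "exon_loss" if derived_is_marker else "exon_gain"
    if ev.mechanism == "intron_change":
        return "intron_loss" if derived_is_marker else "intron_gain"
    return ev.mechanism


def map_event(tree: PhyloTree, event: StructuralEvent,
              outgroup: str | None = None) -> EventPlacement:
    """Place one event on the tree by maximum parsimony and polarise it.

    The marker character is 1 for ``event.state_rows`` leaves, 0 for
    ``alt_rows``; leaves in neither set are treated as missing data.  The
    event's ``mechanism`` and ``carrier_genes`` are updated in place.
    """
    leaves = set(tree.leaf_ids())
    missing = (set(event.state_rows) | set(event.alt_rows)) - leaves
    if missing:
        raise ValueError(f"carriers not on tree: {sorted(missing)}")
    outgroup = outgroup or tree.outgroup

    def leaf_state(leaf):
        if leaf in event.state_rows:
            return 1
        if leaf in event.alt_rows:
            return 0
        return None

    # phase 1: minimal change counts per (node, state)
    cost: dict[str, list[int]] = {}
    for n in tree.nodes_postorder():
        if tree.is_leaf(n):
            st = leaf_state(n)
            cost[n] = [0 if st in (None, 0) else 10 ** 9,
                       0 if st in (None, 1) else 10 ** 9]
        else:
            c = [0, 0]
            for kid in tree.children[n]:
                for s in (0, 1):
                    c[s] += min(cost[kid][0] + (s != 0),
                                cost[kid][1] + (s != 1))
            cost[n] = c
    total = min(cost[tree.root])
    root_candidates = [s for s in (0, 1) if cost[tree.root][s] == total]
    root_ambiguous = False
    if len(root_candidates) == 1:
        root_state = root_candidates[0]
    elif outgroup is not None and leaf_state(outgroup) is not None:
        root_state = leaf_state(outgroup)
    else:
        votes = []
        for kid in tree.children[tree.root]:
            pref = [s for s in (0, 1) if cost[kid][s] == min(cost[kid])]
            if len(pref) == 1:
                votes.append(pref[0])
        if votes and len(set(votes)) == 1:
            root_state = votes[0]
        elif votes:
            root_state = max(set(votes), key=votes.count) \
                if votes.count(0) != votes.count(1) else 0
            root_ambiguous = votes.count(0) == votes.count(1)
        else:
            root_state, root_ambiguous = 0, True
    derived = 1 - root_state

    # phase 2: composite DP preferring fewer derived origins, then root-most
    comp: dict[tuple[str, int], tuple] = {}
    choice: dict[tuple[str, int], list[int]] = {}
    for n in tree.nodes_postorder():
        depth = tree.depth(n)
        for s in (0, 1):
            if tree.is_leaf(n):
                st = leaf_state(n)
                comp[(n, s)] = (0, 0, 0) if st in (None, s) else INF
                continue
            tot = (0, 0, 0)
            picks = []
            for kid in tree.children[n]:
                best, best_t = None, None
                for t in (0, 1):
                    base = comp[(kid, t)]
                    if base == INF:
                        continue
                    chg = int(t != s)
                    orig = int(t != s and t == derived)
                    d = (tree.depth(kid)) if orig else 0
                    cand = (base[0] + chg, base[1] + orig, base[2] + d)
                    key = (cand, 0 if t == s else 1, t)
                    if best is None or key < best:
                        best, best_t = key, t
                tot = tuple(a + b for a, b in zip(tot, best[0]))
                # store only the state pick; costs re-derived on descent
                picks.append(best_t)
            comp[(n, s)] = tot
            choice[(n, s)] = picks
        del depth

    # descend from the chosen root state
    state_of: dict[str, int] = {}
    stack = [(tree.root, root_state)]
    while stack:
        n, s = stack.pop()
        state_of[n] = s
        if not tree.is_leaf(n):
            for kid, t in zip(tree.children[n], choice[(n, s)]):
                stack.append((kid, t))
    gains, losses = [], []
    for n, s in state_of.items():
        p = tree.parent.get(n)
        if p is None:
            continue
        if s != state_of[p]:
            (gains if s == derived else losses).append(n)
    gains.sort(key=lambda x: (tree.depth(x), x))
    losses.sort(key=lambda x: (tree.depth(x), x))
    carriers = frozenset(lf for lf in leaves
                         if state_of[lf] == derived and leaf_state(lf) is not None)

    derived_is_marker = derived == 1
    if event.mechanism in ("indeterminate_indel", "exonization_class",
                           "indeterminate_exon_change", "intron_change"):
        event.mechanism = _polarized_mechanism(event, derived_is_marker)
        event.carrier_genes = carriers
    elif not event.carrier_genes:
        event.carrier_genes = carriers

    alternatives = _equal_cost_single_branches(tree, event, derived, total) \
        if len(leaves) <= 16 else []
    alternatives = [a for a in alternatives if a not in [(g,) for g in gains]]
    return EventPlacement(
        event_id=event.event_id, branches=gains, loss_branches=losses,
        mechanism=event.mechanism, cost=total,
        carrier_genes=event.carrier_genes,
        root_has_marker=root_state == 1, root_ambiguous=root_ambiguous,
        alternatives=alternatives, event=event)


def _equal_cost_single_branches(tree, event, derived, total):
    """Other single-origin branches reproducing the carriers at equal cost."""
    if total != 1:
        return []
    out = []
    marker_leaves = frozenset(event.state_rows)
    for n in tree.preorder():
        if n == tree.root:
            continue
        below = tree.subtree_leaves(n)
        informative = frozenset(event.state_rows) | frozenset(event.alt_rows)
        target = marker_leaves if derived == 1 else \
            frozenset(event.alt_rows)
        if (below & informative) == target:
            out.append((n,))
    return out


# ---------------------------------------------------------------------------
# ancestral structures

@dataclass
class AncestralStructure:
    node_id: str
    exon_count: int
    exon_lengths: list[int]
    support: list[str] = field(default_factory=list)  # per exon

    def __post_init__(self):
        assert self.exon_count == len(self.exon_lengths)


class PathInconsistencyError(ValueError):
    def __init__(self, msg, leaf=None, block=None, delta=None):
        super().__init__(msg)
        self.leaf = leaf
        self.block = block
        self.delta = delta


def reconstruct_ancestral_structure(tree: PhyloTree, fs: FamilySet,
                                    placements: list[EventPlacement],
                                    aln=None) -> dict[str, AncestralStructure]:
    """Per-node exon counts and lengths consistent with the placed events.

    Works on the consensus-exon framework of the alignment: every node's
    length for a block is the root length plus the signed lengths of the
    indel-class events placed on the root-to-node path; whole-exon and
    intron-change placements toggle presence and merge/split exons.  A leaf
    whose observed lengths cannot be produced this way raises
    :class:`PathInconsistencyError` naming the offending path — unless the
    conflict traces to a single-row micro-indel call (1-3 bp), which is
    alignment noise by the gene's own annotation and is suppressed.
    """
    active = list(placements)

    def attempt(depth: int, used: frozenset):
        try:
            return _reconstruct_core(tree, fs, active, aln)
        except PathInconsistencyError as err:
            if depth == 0:
                raise
            # a junction event filed under the wrong neighboring exon is
            # re-attributed; compound misattributions are searched to a
            # small depth and kept only if consistency is fully restored
            for pl in _flip_candidates(active, err, used):
                undo = _apply_flip(pl, err.block)
                try:
                    return attempt(depth - 1, used | {pl.event_id})
                except PathInconsistencyError:
                    undo()
            raise

    for _ in range(4):
        try:
            return attempt(3, frozenset())
        except PathInconsistencyError as err:
            drop = _suppression_candidate(active, err)
            if drop is None:
                drop = next(iter(_flip_candidates(active, err, frozenset())),
                            None)
                if drop is None:
                    raise
            drop.suppressed = True
            active.remove(drop)
    return _reconstruct_core(tree, fs, active, aln)


_SUPPRESSIBLE = ("intraexonic_insertion", "intraexonic_deletion",
                 "exonization", "pseudoexonization")


def _flip_candidates(active, err, dead):
    """Junction events whose side attribution may explain the conflict.

    A boundary change at the junction of exons j and j+1 can be described
    as a 3'-side change of j or a 5'-side change of j+1; if it was filed
    under the wrong exon, that exon's bookkeeping is off by exactly the
    event length.
    """
    out = []
    for pl in active:
        ev = pl.event
        if ev is None or ev.event_id in dead:
            continue
        if pl.mechanism not in _SUPPRESSIBLE:
            continue
        if err.block is not None and ev.exon_index != err.block \
                and abs(ev.exon_index - err.block) != 1:
            continue
        if err.block is not None and ev.exon_index == err.block \
                and ev.detail.get("side") not in ("3", "5"):
            continue
        if err.delta is not None and ev.length_bp != err.delta:
            continue
        out.append(pl)
    return out


def _apply_flip(pl, err_block):
    """Move the event's exon attribution across its junction; returns undo."""
    ev = pl.event
    orig = (ev.exon_index, ev.detail.get("side"))
    side = ev.detail.get("side")
    if side == "5":
        ev.exon_index = max(1, ev.exon_index - 1)
        ev.detail["side"] = "3"
    elif side == "3":
        ev.exon_index += 1
        ev.detail["side"] = "5"
    elif err_block is not None:
        ev.exon_index = err_block

    def undo():
        ev.exon_index = orig[0]
        if orig[1] is None:
            ev.detail.pop("side", None)
        else:
            ev.detail["side"] = orig[1]
    return undo


def _suppression_candidate(active, err):
    """The most suspicious placement to drop after an inconsistency:
    single-row micro-indel calls (1-3 bp) near the failing block, which are
    alignment noise by the genes' own annotation."""
    def near(ev):
        return err.block is None or abs(ev.exon_index - err.block) <= 1

    levels = (
        lambda pl, ev: (pl.mechanism in _SUPPRESSIBLE[:2]
                        and ev.length_bp <= 3 and len(ev.state_rows) == 1
                        and near(ev)
                        and (err.leaf is None
                             or err.leaf in (set(ev.state_rows)
                                             | set(ev.carrier_genes)))),
        lambda pl, ev: (pl.mechanism in _SUPPRESSIBLE[:2]
                        and ev.length_bp <= 3 and len(ev.state_rows) == 1
                        and near(ev)),
        lambda pl, ev: (pl.mechanism in _SUPPRESSIBLE[:2]
                        and ev.length_bp <= 2 and near(ev)),
    )
    for pred in levels:
        cands = [pl for pl in active
                 if pl.event is not None and pred(pl, pl.event)]
        if cands:
            cands.sort(key=lambda p: (p.event.length_bp, p.event_id))
            return cands[0]
    return None


def _reconstruct_core(tree: PhyloTree, fs: FamilySet,
                      placements: list[EventPlacement],
                      aln=None) -> dict[str, AncestralStructure]:
    from .align import consensus_boundaries

    if aln is None:
        raise ValueError("an exon-boundary-marked alignment is required")
    bounds = consensus_boundaries(aln)
    edges = [0] + bounds + [aln.ncols]
    nblocks = len(edges) - 1
    leaves = [g for g in tree.leaf_ids() if g in aln.rows]

    leaf_block_len = {
        g: [len(aln.rows[g][edges[b]:edges[b + 1]].replace("-", ""))
            for b in range(nblocks)]
        for g in leaves}
    # a boundary extension sits in the neighboring block's columns but
    # belongs to the owning exon; re-credit its length for the ungapped rows
    for pl in placements:
        ev = pl.event
        if ev is None:
            continue
        cb = ev.detail.get("column_block")
        if cb is None or cb == ev.exon_index:
            continue
        for g in leaves:
            if g in ev.alt_rows:
                amt = len(aln.rows[g][ev.column_span[0]:ev.column_span[1]]
                          .replace("-", ""))
                leaf_block_len[g][cb - 1] -= amt
                leaf_block_len[g][ev.exon_index - 1] += amt

    # signed per-branch deltas and presence toggles per block
    delta: dict[str, dict[int, int]] = {}
    presence_toggle: dict[str, set[int]] = {}
    # (branch, 0-based block, left/right lengths, mechanism, site-in-consensus)
    intron_records: list[tuple[str, int, tuple, str, bool]] = []
    gained_elements: list[tuple[str, int, int, bool]] = []
    ambiguous_blocks: set[int] = set()
    for pl in placements:
        ev = pl.event
        if ev is None:
            continue
        k = ev.exon_index - 1
        if pl.root_ambiguous or pl.alternatives:
            ambiguous_blocks.add(k)
        sign = 0
        if pl.mechanism in ("intraexonic_insertion", "exonization"):
            sign = +1
        elif pl.mechanism in ("intraexonic_deletion", "pseudoexonization"):
            sign = -1
        if sign:
            # stop-codon events move the stop codon as well, so the exon
            # length change can exceed the event's sense-codon length
            amount = ev.detail.get("exon_length_delta", ev.length_bp)
            for b in pl.branches:
                delta.setdefault(b, {})
                delta[b][k] = delta[b].get(k, 0) + sign * amount
            for b in pl.loss_branches:
                delta.setdefault(b, {})
                delta[b][k] = delta[b].get(k, 0) - sign * amount
        elif pl.mechanism in ("exon_gain", "exon_loss"):
            if ev.detail.get("gained_subblock"):
                # an exon occupying part of a neighbor's block: its columns
                # are re-credited and it becomes its own structural element,
                # present below a gain branch or above a loss branch
                for b in pl.branches:
                    gained_elements.append((b, k, ev.length_bp,
                                            pl.mechanism))
                for g in list(ev.alt_rows):
                    if g in leaf_block_len:
                        amt = _element_length(aln, fs, g, ev.column_span)
                        leaf_block_len[g][k] -= amt
            else:
                for b in pl.branches:
                    presence_toggle.setdefault(b, set()).add(k)
                for b in pl.loss_branches:
                    presence_toggle.setdefault(b, set()).add(k)
                # stray bases misaligned into an absent block belong to a
                # neighboring exon
                for g, (cnt, where) in ev.detail.get("stray", {}).items():
                    if g in leaf_block_len:
                        leaf_block_len[g][k] -= cnt
                        nb = k + 1 if where == "next" else k - 1
                        if 0 <= nb < nblocks:
                            leaf_block_len[g][nb] += cnt
        elif pl.mechanism in ("intron_loss", "intron_gain"):
            lens = ev.detail.get("partner_exon_lengths", (0, 0))
            in_cons = bool(ev.detail.get("site_in_consensus"))
            for b in pl.branches:
                intron_records.append((b, k, lens, pl.mechanism, in_cons))

    # where a gene's own exon count matches its present blocks one-to-one,
    # its annotated exon lengths replace the column counts: annotation is
    # exact where gap placement near block edges is only approximate
    gained_alt: set[str] = set()
    for pl in placements:
        if pl.event is not None and pl.event.detail.get("gained_subblock"):
            gained_alt |= set(pl.event.alt_rows)
    for g in leaves:
        gm = fs.models.get(g)
        if gm is None or not gm.exons or g in gained_alt:
            continue
        counts = [len(aln.rows[g][edges[b]:edges[b + 1]].replace("-", ""))
                  for b in range(nblocks)]
        present_idx = [b for b in range(nblocks) if counts[b] > 5]
        if len(present_idx) == gm.n_exons:
            vec = [0] * nblocks
            for b, ln in zip(present_idx, gm.exon_lengths):
                vec[b] = ln
            leaf_block_len[g] = vec

    root_present = [True] * nblocks
    # root presence: block absent at root iff an exon_gain placement exists
    gain_blocks = {pl.event.exon_index - 1 for pl in placements
                   if pl.mechanism == "exon_gain" and pl.event is not None
                   and not pl.event.detail.get("gained_subblock")}
    for k in gain_blocks:
        root_present[k] = False

    # infer root lengths from any event-free leaf per block, verify all
    root_len = [0] * nblocks
    for k in range(nblocks):
        candidates = {}
        for g in leaves:
            path = tree.path_from_root(g)[1:]
            d = sum(delta.get(b, {}).get(k, 0) for b in path)
            toggles = sum(1 for b in path if k in presence_toggle.get(b, set()))
            present = root_present[k] ^ (toggles % 2 == 1)
            obs = leaf_block_len[g][k]
            if not present:
                if obs != 0:
                    raise PathInconsistencyError(
                        f"leaf {g}: block {k + 1} observed {obs} bp but "
                        f"reconstructed absent (path {'>'.join(path)})",
                        leaf=g, block=k + 1, delta=obs)
                continue
            candidates[g] = obs - d
        if candidates:
            vals = sorted(set(candidates.values()))
            if len(vals) > 1:
                bad = min(g for g, v in candidates.items() if v != vals[0])
                raise PathInconsistencyError(
                    f"leaf {bad}: block {k + 1} length inconsistent with "
                    f"placed events (root estimates {vals})",
                    leaf=bad, block=k + 1, delta=max(vals) - min(vals))
            root_len[k] = vals[0]

    out: dict[str, AncestralStructure] = {}
    for node in tree.preorder():
        path = tree.path_from_root(node)[1:]
        lens = []
        support = []
        pres = list(root_present)
        cur = list(root_len)
        for b in path:
            for k, d in delta.get(b, {}).items():
                cur[k] += d
            for k in presence_toggle.get(b, set()):
                pres[k] = not pres[k]
        merged_here: set[int] = set()   # merge block k with k+1 at this node
        split_here: dict[int, tuple] = {}  # show block k as two exons
        for b, k0, lens2, mech, in_cons in intron_records:
            desc = b in path
            if in_cons:
                # blocks are split in the consensus; the merged state shows
                # at intron-loss descendants, or everywhere *except* the
                # descendants of an intron gain
                if (mech == "intron_loss") == desc:
                    merged_here.add(k0)
            else:
                # the consensus block is merged; the split state shows at
                # non-descendants for a loss, at descendants for a gain
                if (mech == "intron_loss") != desc and lens2 != (0, 0):
                    split_here[k0] = lens2
        gained_here = {}
        for b, k0, ln, mech in gained_elements:
            if (b in path) == (mech == "exon_gain"):
                gained_here.setdefault(k0, []).append(ln)
        k = 0
        while k < nblocks:
            for ln in gained_here.get(k, []):
                lens.append(ln)
                support.append("unambiguous")
            if not pres[k]:
                k += 1
                continue
            amb = "ambiguous" if k in ambiguous_blocks else "unambiguous"
            if k in merged_here and k + 1 < nblocks and pres[k + 1]:
                lens.append(cur[k] + cur[k + 1])
                support.append("ambiguous" if (k in ambiguous_blocks or
                                               k + 1 in ambiguous_blocks)
                               else amb)
                k += 2
                continue
            if k in split_here:
                la, lb = split_here[k]
                lens.extend([la, lb])
                support.extend([amb] * 2)
                k += 1
                continue
            lens.append(cur[k])
            support.append(amb)
            k += 1
        out[node] = AncestralStructure(node_id=node, exon_count=len(lens),
                                       exon_lengths=lens, support=support)
    return out


def _element_length(aln, fs, row: str, span: tuple[int, int],
                    slack: int = 5) -> int:
    """Length of the exon a row contributes inside ``span``.

    Prefers the row's own annotation (exact) when one of its exons sits at
    the span within a few columns; falls back to counting its aligned bases.
    """
    s, e = span
    fallback = len(aln.rows[row][s:e].replace("-", ""))
    gm = fs.models.get(row)
    bl = aln.exon_boundaries.get(row) or []
    if gm is None or not gm.exons or not bl:
        return fallback
    starts = [0] + bl
    ends = bl + [aln.ncols]
    for idx, (bs, be) in enumerate(zip(starts, ends), start=1):
        if abs(bs - s) <= slack and abs(be - e) <= slack \
                and idx <= gm.n_exons:
            ln = gm.exon_lengths[idx - 1]
            if abs(ln - (e - s)) <= 2 * slack:
                return ln
    return fallback


def write_ancestral_tsv(structures: dict[str, AncestralStructure], path) -> None:
    with open(path, "w") as fh:
        fh.write("node_id\texon_count\texon_lengths\tsupport\n")
        for nid in sorted(structures):
            st = structures[nid]
            fh.write(f"{nid}\t{st.exon_count}\t"
                     f"{','.join(map(str, st.exon_lengths))}\t"
                     f"{','.join(st.support)}\n")


def write_placements_tsv(placements: list[EventPlacement], path) -> None:
    with open(path, "w") as fh:
        fh.write("event_id\tmechanism\tbranches\tloss_branches\tcost\t"
                 "carriers\troot_ambiguous\talternatives\n")
        for pl in sorted(placements, key=lambda p: p.event_id):
            fh.write(f"{pl.event_id}\t{pl.mechanism}\t"
                     f"{','.join(pl.branches)}\t{','.join(pl.loss_branches)}\t"
                     f"{pl.cost}\t{','.join(sorted(pl.carrier_genes))}\t"
                     f"{pl.root_ambiguous}\t"
                     f"{';'.join('|'.join(a) for a in pl.alternatives)}\n")


# ---------------------------------------------------------------------------
# structural divergence ranking

def rank_structural_divergence(fs: FamilySet, placements: list[EventPlacement],
                               tree: PhyloTree,
                               thresholds: list[float] | None = None,
                               non_triplet_penalty: float = 2.0):
    """Rank genes by path-weighted structural divergence and emit subsets.

    A gene's score sums, over events placed on its root-to-leaf path,
    ``1 + non_triplet_penalty`` for frame-violating events and 1 otherwise.
    ``thresholds`` are maximum retained scores; each yields a nested subset
    (analogous to progressively stricter alignment matrices).
    """
    scores: dict[str, float] = {g: 0.0 for g in tree.leaf_ids()}
    for pl in placements:
        ev = pl.event
        if ev is None:
            continue
        w = 1.0 + (non_triplet_penalty if not ev.frame_preserving else 0.0)
        for b in pl.branches + pl.loss_branches:
            for leaf in tree.subtree_leaves(b):
                if leaf in scores:
                    scores[leaf] += w
    ranked = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    subsets = {}
    for th in (thresholds or []):
        subsets[th] = [g for g, s in ranked if s <= th]
    return ranked, subsets
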