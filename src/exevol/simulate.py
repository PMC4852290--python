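"""Synthetic gene families with known structural-event histories.

Families emulate MADS-box-like genes: an 8-exon ancestor whose core exons
(MADS/K-domain-encoding) have near-fixed lengths and whose terminal exons
vary, evolving by point substitution plus structural events — intraexonic
indels biased to codon multiples, exonization/pseudoexonization at
intron-adjacent exon boundaries, intron gain/loss, and whole-exon gain/loss.

Two entry points:

* :func:`simulate_family` — stochastic families on a random or supplied
  tree, with a :class:`TrueHistory` ledger precise enough to replay every
  leaf byte-for-byte from the ancestral snapshot;
* :func:`emit_fixture` — deterministic scenarios reproducing well-studied
  structural changes in the MADS-box literature (Brassicaceae SEP1/2 intron
  loss, paleoAP1 stop-codon exonization, the euAP1 frameshift, nested
  SEP-clade insertions, FLC exon-3 and exon-loss histories).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .models import FamilySet, GeneModel
from .parsimony import PhyloTree

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")

#: ancestral exon-length template: an eight-exon MADS-like gene (conserved
#: MADS/I/K core, longer variable terminal exons); sums to a codon multiple
ANCESTRAL_EXON_LENGTHS = (185, 79, 62, 100, 42, 42, 137, 85)

#: per-branch event rates (events per ingroup branch, not per site); the
#: defaults put families in the sparse, non-overlapping regime the
#: event-recovery analyses assume (~0.2 events per branch in total)
DEFAULT_EVENT_RATES = {
    "intraexonic_insertion": 0.06,
    "intraexonic_deletion": 0.06,
    "exonization": 0.025,
    "pseudoexonization": 0.025,
    "intron_loss": 0.0125,
    "intron_gain": 0.0125,
    "exon_loss": 0.005,
    "exon_gain": 0.005,
}

FIXTURE_NAMES = ("brassicaceae_intron_loss", "paleoAP1_stop_loss",
                 "euAP1_frameshift", "capsella_nested_insertions",
                 "flc_exon3", "flc_exon_loss")


@dataclass
class SimConfig:
    """Parameters of one simulated family."""

    n_leaves: int = 8
    newick: str | None = None
    ancestral_exon_lengths: tuple = ANCESTRAL_EXON_LENGTHS
    intron_length: int = 200
    flank_length: int = 300
    subs_per_branch: float = 0.01   # substitution probability per site
    event_rates: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_RATES))
    p_frame: float = 0.9            # probability an indel is a codon multiple
    mean_codons: float = 2.0        # geometric mean indel length, in codons
    exon_gain_codons: tuple = (10, 30)
    seed: int = 0

    def validate(self) -> None:
        if any(r < 0 for r in self.event_rates.values()):
            raise ValueError("event rates must be non-negative")
        if not 0.0 <= self.p_frame <= 1.0:
            raise ValueError("p_frame must lie in [0, 1]")
        if any(l <= 0 for l in self.ancestral_exon_lengths):
            raise ValueError("ancestral exon lengths must be positive")


@dataclass
class TrueEvent:
    event_id: str
    branch: str          # child-node id of the branch the event occurred on
    mechanism: str
    exon_label: str      # stable ancestral-exon label ('1'..'8', merges '5+6')
    exon_index: int      # index in the lineage's structure at event time
    length_bp: int
    position: int
    payload: dict = field(default_factory=dict)


@dataclass
class TrueHistory:
    """Ledger of events and substitutions, with per-node snapshots."""

    events: list[TrueEvent] = field(default_factory=list)
    substitutions: dict[str, list[tuple[str, int, int, str]]] = \
        field(default_factory=dict)
    snapshots: dict[str, "GeneState"] = field(default_factory=dict)
    dropped: int = 0
    attempts: int = 0

    def events_on(self, branch: str) -> list[TrueEvent]:
        return [e for e in self.events if e.branch == branch]

    def replay(self, tree: PhyloTree) -> dict[str, "GeneState"]:
        """Re-derive every node state from the root snapshot and the ledger."""
        states = {tree.root: self.snapshots[tree.root].clone()}
        for node in tree.preorder()[1:]:
            st = states[tree.parent[node]].clone()
            for ev in self.events_on(node):
                apply_event(st, ev)
            for region, idx, pos, base in self.substitutions.get(node, []):
                _substitute(st, region, idx, pos, base)
            states[node] = st
        return states

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("event_id\tbranch\tmechanism\texon_label\texon_index\t"
                     "length_bp\tposition\n")
            for e in self.events:
                fh.write(f"{e.event_id}\t{e.branch}\t{e.mechanism}\t"
                         f"{e.exon_label}\t{e.exon_index}\t{e.length_bp}\t"
                         f"{e.position}\n")


@dataclass
class GeneState:
    """Mutable exon/intron/flank decomposition of one gene."""

    exons: list[str]
    introns: list[str]
    flank_5: str
    flank_3: str
    labels: list[str]

    @property
    def cds(self) -> str:
        return "".join(self.exons)

    @property
    def exon_lengths(self) -> list[int]:
        return [len(e) for e in self.exons]

    def clone(self) -> "GeneState":
        return GeneState(list(self.exons), list(self.introns),
                         self.flank_5, self.flank_3, list(self.labels))

    def to_gene_model(self, gene_id: str, flank_length: int) -> GeneModel:
        f5 = self.flank_5[-flank_length:]
        pos = len(f5)
        exons = []
        for k, ex in enumerate(self.exons):
            exons.append((pos, pos + len(ex)))
            pos += len(ex)
            if k < len(self.introns):
                pos += len(self.introns[k])
        return GeneModel(gene_id=gene_id, species_id=gene_id, strand="+",
                         exons=exons, cds=self.cds, introns=list(self.introns),
                         flank_5=f5, flank_3=self.flank_3[:flank_length],
                         annotation_source="simulated")


# ---------------------------------------------------------------------------
# sequence generation

def random_coding(n_codons: int, rng) -> str:
    """Random sense codons (no internal stops)."""
    out = []
    while len(out) < n_codons:
        codon = "".join(rng.choice(list(BASES), size=3))
        if codon not in STOPS:
            out.append(codon)
    return "".join(out)


def random_noncoding(length: int, rng, splice_ends: bool = False) -> str:
    seq = "".join(rng.choice(list(BASES), size=max(length, 0)))
    if splice_ends and length >= 4:
        seq = "GT" + seq[2:-2] + "AG"
    return seq


def ancestral_gene(exon_lengths, intron_length, flank_length, rng) -> GeneState:
    total = sum(exon_lengths)
    if total % 3 != 0:
        raise ValueError("ancestral exon lengths must sum to a codon multiple")
    cds = random_coding(total // 3 - 1, rng) + "TAA"
    exons, pos = [], 0
    for ln in exon_lengths:
        exons.append(cds[pos:pos + ln])
        pos += ln
    introns = [random_noncoding(intron_length, rng, splice_ends=True)
               for _ in range(len(exon_lengths) - 1)]
    return GeneState(exons=exons, introns=introns,
                     flank_5=random_noncoding(flank_length, rng),
                     flank_3=random_noncoding(flank_length, rng),
                     labels=[str(i + 1) for i in range(len(exon_lengths))])


# ---------------------------------------------------------------------------
# event application (shared by the stochastic simulator, the fixtures and
# ledger replay; every operation is fully determined by its payload)

def apply_event(st: GeneState, ev: TrueEvent) -> None:
    k = ev.exon_index - 1
    m = ev.mechanism
    if m == "intraexonic_insertion":
        seq = ev.payload["seq"]
        st.exons[k] = st.exons[k][:ev.position] + seq + st.exons[k][ev.position:]
    elif m == "intraexonic_deletion":
        st.exons[k] = (st.exons[k][:ev.position]
                       + st.exons[k][ev.position + ev.length_bp:])
    elif m == "exonization" and "extension" in ev.payload:
        # stop-codon readthrough: the stop is substituted and translation
        # runs into former 3' UTR up to the next in-frame stop
        repl = ev.payload["replacement"]
        ext = ev.payload["extension"]
        st.exons[k] = st.exons[k][:-3] + repl + ext
        st.flank_3 = st.flank_3[len(ext):]
    elif m == "pseudoexonization" and "to_utr" in ev.payload:
        # frameshift-truncation: the coding tail beyond the premature stop
        # becomes 3' UTR
        n = ev.payload["to_utr"]
        st.flank_3 = st.exons[k][-n:] + st.flank_3
        st.exons[k] = st.exons[k][:-n]
    elif m == "exonization":
        side = ev.payload["side"]
        L = ev.length_bp
        if side == "5":
            donor = st.introns[k - 1]
            st.exons[k] = donor[-L:] + st.exons[k]
            st.introns[k - 1] = donor[:-L]
        else:
            donor = st.introns[k]
            st.exons[k] = st.exons[k] + donor[:L]
            st.introns[k] = donor[L:]
    elif m == "pseudoexonization":
        side = ev.payload["side"]
        L = ev.length_bp
        if side == "5":
            st.introns[k - 1] = st.introns[k - 1] + st.exons[k][:L]
            st.exons[k] = st.exons[k][L:]
        else:
            st.introns[k] = st.exons[k][-L:] + st.introns[k]
            st.exons[k] = st.exons[k][:-L]
    elif m == "intron_loss":
        st.exons[k] = st.exons[k] + st.exons[k + 1]
        st.labels[k] = f"{st.labels[k]}+{st.labels[k + 1]}"
        del st.exons[k + 1], st.labels[k + 1], st.introns[k]
    elif m == "intron_gain":
        seq = ev.payload["intron_seq"]
        p = ev.position
        left, right = st.exons[k][:p], st.exons[k][p:]
        lab = st.labels[k]
        st.exons[k:k + 1] = [left, right]
        st.labels[k:k + 1] = [f"{lab}a", f"{lab}b"]
        st.introns.insert(k, seq)
    elif m == "exon_loss":
        # the exon's sequence disappears; its flanking introns merge
        del st.exons[k], st.labels[k]
        if k < len(st.introns):
            if k > 0:
                st.introns[k - 1] = st.introns[k - 1] + st.introns[k]
                del st.introns[k]
            else:
                st.flank_5 = st.flank_5 + st.introns[k]
                del st.introns[k]
        else:
            st.flank_3 = st.introns[k - 1] + st.flank_3
            del st.introns[k - 1]
    elif m == "exon_gain":
        seq = ev.payload["exon_seq"]
        p = ev.position  # split point inside intron k (after exon k+1... 1-based)
        intron = st.introns[k]
        st.introns[k:k + 1] = [intron[:p], intron[p:]]
        st.exons.insert(k + 1, seq)
        st.labels.insert(k + 1, ev.payload["label"])
    else:
        raise ValueError(f"cannot apply mechanism {m!r}")


def _substitute(st: GeneState, region: str, idx: int, pos: int, base: str):
    if region == "exon":
        s = st.exons[idx]
        st.exons[idx] = s[:pos] + base + s[pos + 1:]
    elif region == "intron":
        s = st.introns[idx]
        st.introns[idx] = s[:pos] + base + s[pos + 1:]
    elif region == "flank_5":
        st.flank_5 = st.flank_5[:pos] + base + st.flank_5[pos + 1:]
    else:
        st.flank_3 = st.flank_3[:pos] + base + st.flank_3[pos + 1:]


# ---------------------------------------------------------------------------
# stochastic simulation

def random_tree(n_leaves: int, rng) -> PhyloTree:
    """Random bifurcating ingroup of n_leaves-1 taxa plus an outgroup."""
    nodes = [f"g{i + 1}" for i in range(n_leaves - 1)]
    counter = itertools.count(1)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        new = f"({a},{b})n{next(counter)}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [new]
    newick = f"(outgroup,{nodes[0]})root;"
    return PhyloTree.from_newick(newick, outgroup="outgroup")


def _indel_length(cfg: SimConfig, rng) -> int:
    codons = 1 + rng.geometric(1.0 / cfg.mean_codons) - 1
    codons = max(int(codons), 1)
    if rng.random() < cfg.p_frame:
        return 3 * codons
    return max(3 * (codons - 1) + int(rng.integers(1, 3)), 1)


def simulate_family(cfg: SimConfig
                    ) -> tuple[FamilySet, PhyloTree, TrueHistory]:
    """Evolve one family along a tree; deterministic under a fixed seed.

    Structural events are drawn per ingroup branch (the outgroup lineage
    evolves by substitution only, anchoring polarity); each ancestral exon
    hosts at most one structural event per family, which keeps events
    non-overlapping and recoverable.  Raises when the configured rates are
    so high that more than half of the event draws cannot be placed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    tree = (PhyloTree.from_newick(cfg.newick) if cfg.newick
            else random_tree(cfg.n_leaves, rng))
    anc = ancestral_gene(cfg.ancestral_exon_lengths, cfg.intron_length,
                         cfg.flank_length, rng)
    hist = TrueHistory()
    hist.snapshots[tree.root] = anc.clone()
    mechs = sorted(cfg.event_rates)
    rates = np.array([cfg.event_rates[m] for m in mechs])
    total_rate = rates.sum()
    probs = rates / total_rate if total_rate > 0 else rates
    used_labels: set[str] = set()
    used_junctions: set[str] = set()
    counter = itertools.count(1)
    states = {tree.root: anc}
    for node in tree.preorder()[1:]:
        st = states[tree.parent[node]].clone()
        eligible = node != tree.outgroup
        if eligible and total_rate > 0:
            n_events = rng.poisson(total_rate)
            for _ in range(n_events):
                placed = False
                for _attempt in range(20):
                    hist.attempts += 1
                    mech = mechs[int(rng.choice(len(mechs), p=probs))]
                    ev = _draw_event(st, mech, cfg, rng, used_labels,
                                     used_junctions, node, counter)
                    if ev is not None:
                        apply_event(st, ev)
                        hist.events.append(ev)
                        placed = True
                        break
                if not placed:
                    hist.dropped += 1
        subs = _draw_substitutions(st, cfg.subs_per_branch, rng)
        for region, idx, pos, base in subs:
            _substitute(st, region, idx, pos, base)
        hist.substitutions[node] = subs
        hist.snapshots[node] = st.clone()
        states[node] = st
    placed = len(hist.events)
    if placed + hist.dropped >= 5 and hist.dropped > placed:
        raise ValueError("event rates too high: events overlap in more than "
                         "half of the placement attempts; lower the rates")
    fs = FamilySet()
    for leaf in tree.leaf_ids():
        fs.add(states[leaf].to_gene_model(leaf, cfg.flank_length))
    return fs, tree, hist


def _locked(st: GeneState, k: int, used: set) -> bool:
    return st.labels[k] in used


def _junction(st: GeneState, i: int) -> str:
    """Stable id of the intron junction between exons i and i+1 (0-based)."""
    return f"{st.labels[i]}|{st.labels[i + 1]}"


def _draw_event(st, mech, cfg, rng, used_labels, used_junctions, branch,
                counter) -> TrueEvent | None:
    n = len(st.exons)
    n = len(st.exons)
    eid = None

    def make(exon_index, label, length, position, payload,
             junctions: tuple = ()):
        used_labels.add(label)
        used_junctions.update(junctions)
        return TrueEvent(event_id=f"true{next(counter)}", branch=branch,
                         mechanism=mech, exon_label=label,
                         exon_index=exon_index, length_bp=length,
                         position=position, payload=payload)

    if mech in ("intraexonic_insertion", "intraexonic_deletion"):
        L = _indel_length(cfg, rng)
        margin = 6
        cands = [k for k in range(n)
                 if not _locked(st, k, used_labels)
                 and len(st.exons[k]) >= (2 * margin + (L if mech ==
                                          "intraexonic_deletion" else 0) + 1)]
        if not cands:
            return None
        k = int(rng.choice(cands))
        hi = len(st.exons[k]) - margin - \
            (L if mech == "intraexonic_deletion" else 0)
        pos = int(rng.integers(margin, hi + 1))
        payload = {}
        if mech == "intraexonic_insertion":
            payload["seq"] = random_noncoding(L, rng)
        return make(k + 1, st.labels[k], L, pos, payload)
    if mech in ("exonization", "pseudoexonization"):
        # boundary events recruit or release whole codons; sub-codon stop
        # disruption is a separate, scripted scenario
        L = 3 * max(1, round(_indel_length(cfg, rng) / 3))
        sides = []
        for k in range(n):
            if _locked(st, k, used_labels):
                continue
            if mech == "pseudoexonization" and len(st.exons[k]) < L + 12:
                continue
            if (k >= 1 and len(st.introns[k - 1]) >= L + 60
                    and _junction(st, k - 1) not in used_junctions):
                sides.append((k, "5"))
            if (k <= n - 2 and len(st.introns[k]) >= L + 60
                    and _junction(st, k) not in used_junctions):
                sides.append((k, "3"))
        if not sides:
            return None
        k, side = sides[int(rng.choice(len(sides)))]
        junc = _junction(st, k - 1 if side == "5" else k)
        return make(k + 1, st.labels[k], L, 0, {"side": side},
                    junctions=(junc,))
    if mech == "intron_loss":
        cands = [i for i in range(n - 1)
                 if not _locked(st, i, used_labels)
                 and not _locked(st, i + 1, used_labels)
                 and _junction(st, i) not in used_junctions
                 and (i == 0 or _junction(st, i - 1) not in used_junctions)
                 and (i == n - 2 or _junction(st, i + 1) not in used_junctions)]
        if not cands:
            return None
        i = int(rng.choice(cands))
        label = f"{st.labels[i]}+{st.labels[i + 1]}"
        used_labels.add(st.labels[i])
        used_labels.add(st.labels[i + 1])
        juncs = tuple(_junction(st, j) for j in (i - 1, i, i + 1)
                      if 0 <= j <= n - 2)
        return make(i + 1, label, 0, 0,
                    {"merged_length": len(st.exons[i]) + len(st.exons[i + 1])},
                    junctions=juncs)
    if mech == "intron_gain":
        cands = [k for k in range(n)
                 if not _locked(st, k, used_labels) and len(st.exons[k]) >= 60]
        if not cands:
            return None
        k = int(rng.choice(cands))
        pos = int(rng.integers(18, len(st.exons[k]) - 18 + 1))
        intron = random_noncoding(cfg.intron_length, rng, splice_ends=True)
        used_labels.add(f"{st.labels[k]}a")
        used_labels.add(f"{st.labels[k]}b")
        return make(k + 1, st.labels[k], 0, pos, {"intron_seq": intron})
    if mech == "exon_loss":
        cands = [k for k in range(1, n - 1)
                 if not _locked(st, k, used_labels)
                 and _junction(st, k - 1) not in used_junctions
                 and _junction(st, k) not in used_junctions]
        if not cands:
            return None
        k = int(rng.choice(cands))
        juncs = (_junction(st, k - 1), _junction(st, k))
        return make(k + 1, st.labels[k], len(st.exons[k]), 0, {},
                    junctions=juncs)
    if mech == "exon_gain":
        cands = [i for i in range(n - 1)
                 if len(st.introns[i]) >= 120
                 and _junction(st, i) not in used_junctions]
        if not cands:
            return None
        i = int(rng.choice(cands))
        codons = int(rng.integers(cfg.exon_gain_codons[0],
                                  cfg.exon_gain_codons[1] + 1))
        seq = random_coding(codons, rng)
        pos = int(rng.integers(30, len(st.introns[i]) - 30 + 1))
        label = f"g{next(counter)}"
        junc = (_junction(st, i),)
        return make(i + 1, label, len(seq), pos,
                    {"exon_seq": seq, "label": label}, junctions=junc)
    del eid
    return None


def _draw_substitutions(st: GeneState, p: float, rng):
    subs = []
    regions = ([("exon", i, s) for i, s in enumerate(st.exons)]
               + [("intron", i, s) for i, s in enumerate(st.introns)]
               + [("flank_5", 0, st.flank_5), ("flank_3", 0, st.flank_3)])
    for region, idx, seq in regions:
        if not seq or p <= 0:
            continue
        hits = np.nonzero(rng.random(len(seq)) < p)[0]
        for pos in hits:
            old = seq[pos]
            alt = [b for b in BASES if b != old.upper()]
            subs.append((region, idx, int(pos),
                         alt[int(rng.integers(0, 3))]))
    return subs


def expected_event_count(cfg: SimConfig, tree: PhyloTree) -> float:
    """Analytic expectation of the ledger size for one family."""
    branches = [n for n in tree.preorder()[1:] if n != tree.outgroup]
    return sum(cfg.event_rates.values()) * len(branches)


# ---------------------------------------------------------------------------
# canned fixtures

def _fixture_family(tree: PhyloTree, anc: GeneState,
                    scripted: dict[str, list[TrueEvent]],
                    flank_length: int = 300
                    ) -> tuple[FamilySet, PhyloTree, TrueHistory]:
    hist = TrueHistory()
    hist.snapshots[tree.root] = anc.clone()
    states = {tree.root: anc}
    for node in tree.preorder()[1:]:
        st = states[tree.parent[node]].clone()
        for ev in scripted.get(node, []):
            apply_event(st, ev)
            hist.events.append(ev)
        hist.substitutions[node] = []
        hist.snapshots[node] = st.clone()
        states[node] = st
    fs = FamilySet()
    for leaf in tree.leaf_ids():
        fs.add(states[leaf].to_gene_model(leaf, flank_length))
    return fs, tree, hist


def emit_fixture(name: str) -> tuple[FamilySet, PhyloTree, TrueHistory]:
    """Deterministic worked-scenario fixtures (see module docstring)."""
    builders = {
        "brassicaceae_intron_loss": _fx_brassicaceae_intron_loss,
        "paleoAP1_stop_loss": _fx_paleoap1_stop_loss,
        "euAP1_frameshift": _fx_euap1_frameshift,
        "capsella_nested_insertions": _fx_capsella_nested,
        "flc_exon3": _fx_flc_exon3,
        "flc_exon_loss": _fx_flc_exon_loss,
    }
    if name not in builders:
        raise ValueError(f"unknown fixture {name!r}; valid names: "
                         + ", ".join(FIXTURE_NAMES))
    return builders[name]()


def _fixture_rng(name: str):
    return np.random.default_rng(abs(hash(name)) % (2 ** 31))


def _fx_brassicaceae_intron_loss():
    """Intron loss merging the 42+42 bp exon pair into one 84 bp exon."""
    rng = np.random.default_rng(101)
    tree = PhyloTree.from_newick("(SEP12_ref,SEP12_brassicaceae)root;",
                                 outgroup="SEP12_ref")
    anc = ancestral_gene(ANCESTRAL_EXON_LENGTHS, 200, 300, rng)
    ev = TrueEvent(event_id="fx_intron_loss", branch="SEP12_brassicaceae",
                   mechanism="intron_loss", exon_label="5+6", exon_index=5,
                   length_bp=0, position=0,
                   payload={"merged_length": 84})
    return _fixture_family(tree, anc, {"SEP12_brassicaceae": [ev]})


_PALEO_TEMPLATE = (185, 79, 65, 100, 42, 42, 113, 106)


def _fx_paleoap1_stop_loss():
    """Two point substitutions break the stop codon; translation reads
    through the next in-frame 15 bp of ancestral 3' UTR."""
    rng = np.random.default_rng(102)
    tree = PhyloTree.from_newick("(SEP_ref,paleoAP1)root;",
                                 outgroup="SEP_ref")
    anc = ancestral_gene(_PALEO_TEMPLATE, 200, 300, rng)
    # ancestral 3' UTR: 15 bp with no in-frame stop, then the next stop
    readthrough = "GACGGTAGTGGTGGC"
    anc.flank_3 = readthrough + "TAA" + anc.flank_3[18:]
    derived = anc.clone()
    old_exon = derived.exons[-1]
    assert old_exon.endswith("TAA")
    derived.exons[-1] = old_exon[:-3] + "CAC" + readthrough + "TAA"
    derived.flank_3 = anc.flank_3[18:]
    tree2, hist = tree, TrueHistory()
    hist.snapshots["root"] = anc.clone()
    hist.snapshots["SEP_ref"] = anc.clone()
    hist.snapshots["paleoAP1"] = derived.clone()
    hist.substitutions = {"SEP_ref": [], "paleoAP1": []}
    hist.events.append(TrueEvent(
        event_id="fx_stop_loss", branch="paleoAP1", mechanism="exonization",
        exon_label="8", exon_index=8, length_bp=15, position=len(old_exon),
        payload={"replacement": "CAC", "extension": readthrough + "TAA",
                 "note": "stop codon TAA -> CAC (T-C, A-C); readthrough to "
                         "the next in-frame stop"}))
    fs = FamilySet()
    fs.add(anc.to_gene_model("SEP_ref", 300))
    fs.add(derived.to_gene_model("paleoAP1", 300))
    return fs, tree2, hist


_EUAP1_TAIL = "GATGTAAAGCAGAAGTAA"  # last six codons of the ancestral CDS


def _fx_euap1_frameshift():
    """A 1-bp deletion in the terminal exon shifts the frame onto a premature
    stop, pseudoexonizing the last 8 ancestral coding nucleotides."""
    rng = np.random.default_rng(103)
    tree = PhyloTree.from_newick("(AP1FUL_ref,euAP1)root;",
                                 outgroup="AP1FUL_ref")
    anc = ancestral_gene(_PALEO_TEMPLATE, 200, 300, rng)
    tail = _EUAP1_TAIL
    anc.exons[-1] = anc.exons[-1][:-len(tail)] + tail
    derived = anc.clone()
    # delete the G of GAT...: frame shifts to ATG TAA, a premature stop
    new_tail = tail[1:]
    stop_at = new_tail.find("TAA", 3)
    coding = new_tail[:stop_at + 3]            # ATGTAA
    remainder = new_tail[stop_at + 3:]         # AGCAGAAGTAA -> now 3' UTR
    derived.exons[-1] = anc.exons[-1][:-len(tail)] + coding
    derived.flank_3 = remainder + anc.flank_3
    hist = TrueHistory()
    hist.snapshots["root"] = anc.clone()
    hist.snapshots["AP1FUL_ref"] = anc.clone()
    hist.snapshots["euAP1"] = derived.clone()
    hist.substitutions = {"AP1FUL_ref": [], "euAP1": []}
    hist.events.append(TrueEvent(
        event_id="fx_frameshift_del", branch="euAP1",
        mechanism="intraexonic_deletion", exon_label="8", exon_index=8,
        length_bp=1, position=len(anc.exons[-1]) - len(tail), payload={}))
    hist.events.append(TrueEvent(
        event_id="fx_pseudo8", branch="euAP1", mechanism="pseudoexonization",
        exon_label="8", exon_index=8, length_bp=8,
        position=len(derived.exons[-1]),
        payload={"to_utr": len(remainder)}))
    fs = FamilySet()
    fs.add(anc.to_gene_model("AP1FUL_ref", 300))
    fs.add(derived.to_gene_model("euAP1", 300))
    return fs, tree, hist


def _fx_capsella_nested():
    """A 33-bp exon-7 insertion shared by three taxa, with an adjacent extra
    66-bp insertion private to Capsella."""
    rng = np.random.default_rng(104)
    tree = PhyloTree.from_newick(
        "(outgroup,(Capsella,(Brassica,Arabidopsis)ba)ingroup)root;",
        outgroup="outgroup")
    anc = ancestral_gene(ANCESTRAL_EXON_LENGTHS, 200, 300, rng)
    pos = 60
    ins33 = random_noncoding(33, rng)
    ins66 = random_noncoding(66, rng)
    shared = TrueEvent(event_id="fx_ins33", branch="ingroup",
                       mechanism="intraexonic_insertion", exon_label="7",
                       exon_index=7, length_bp=33, position=pos,
                       payload={"seq": ins33})
    private = TrueEvent(event_id="fx_ins66", branch="Capsella",
                        mechanism="intraexonic_insertion", exon_label="7",
                        exon_index=7, length_bp=66, position=pos,
                        payload={"seq": ins66})
    return _fixture_family(tree, anc,
                           {"ingroup": [shared], "Capsella": [private]})


def _fx_flc_exon3():
    """Exon 3: 62 bp ancestrally; +3 bp insertion on the AP1/FUL stem (65 bp)
    and an independent 3-bp insertion plus 3-bp exonization on the FLC stem
    (68 bp)."""
    rng = np.random.default_rng(105)
    tree = PhyloTree.from_newick(
        "(SEP_ref,(AGL6_ref,(AP1_ref,(FLC_a,FLC_b)FLC_MRCA)af)core)root;",
        outgroup="SEP_ref")
    anc = ancestral_gene(ANCESTRAL_EXON_LENGTHS, 200, 300, rng)
    ap1_ins = TrueEvent(event_id="fx_ap1_ins3", branch="AP1_ref",
                        mechanism="intraexonic_insertion", exon_label="3",
                        exon_index=3, length_bp=3, position=40,
                        payload={"seq": random_noncoding(3, rng)})
    flc_ins = TrueEvent(event_id="fx_flc_ins3", branch="FLC_MRCA",
                        mechanism="intraexonic_insertion", exon_label="3",
                        exon_index=3, length_bp=3, position=20,
                        payload={"seq": random_noncoding(3, rng)})
    flc_exo = TrueEvent(event_id="fx_flc_exo3", branch="FLC_MRCA",
                        mechanism="exonization", exon_label="3",
                        exon_index=3, length_bp=3, position=0,
                        payload={"side": "5"})
    return _fixture_family(tree, anc, {"AP1_ref": [ap1_ins],
                                       "FLC_MRCA": [flc_ins, flc_exo]})


def _fx_flc_exon_loss():
    """Loss of the terminal (eighth) exon on the FLC stem: seven exons."""
    rng = np.random.default_rng(106)
    tree = PhyloTree.from_newick(
        "(SEP_ref,(AGL6_ref,(FLC_a,FLC_b)FLC_MRCA)core)root;",
        outgroup="SEP_ref")
    anc = ancestral_gene(ANCESTRAL_EXON_LENGTHS, 200, 300, rng)
    loss = TrueEvent(event_id="fx_exon8_loss", branch="FLC_MRCA",
                     mechanism="exon_loss", exon_label="8", exon_index=8,
                     length_bp=ANCESTRAL_EXON_LENGTHS[-1], position=0,
                     payload={})
    return _fixture_family(tree, anc, {"FLC_MRCA": [loss]})


def write_family_files(fs: FamilySet, tree: PhyloTree, hist: TrueHistory,
                       outdir) -> None:
    """Write genomic FASTA, CDS FASTA, GFF3, Newick and TrueHistory TSV."""
    from pathlib import Path

    from .models import write_family
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_family(fs, out / "cds.fasta", out / "annotation.gff3",
                 genomic_fasta=out / "genomic.fasta",
                 provenance_tsv=out / "provenance.tsv")
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")
    hist.write_tsv(out / "true_history.tsv")
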