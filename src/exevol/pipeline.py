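"""End-to-end orchestration: load/simulate -> align -> detect -> map -> report.

The pipeline mirrors the analysis workflow for tracing exon-intron structural
changes in a gene subfamily: curate gene models, build a boundary-marked
codon alignment, attribute every gap to a structural-change event, place
events on the tree by parsimony, reconstruct ancestral exon structures, and
mask nonhomologous columns for downstream phylogenetic use.  A run is fully
deterministic for a given configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .align import (CodonAlignment, leave_one_out_refine,
                    mark_exon_boundaries, mask_nonhomologous_columns,
                    progressive_align, project_protein_alignment,
                    refine_exon_by_exon, read_alignment_fasta)
from .events import StructuralEvent, detect_events, events_to_tsv
from .models import FamilySet, filter_models, load_gene_models, write_family
from .parsimony import (AncestralStructure, EventPlacement, PhyloTree,
                        map_event, rank_structural_divergence,
                        reconstruct_ancestral_structure, write_ancestral_tsv,
                        write_placements_tsv)
from .simulate import SimConfig, emit_fixture, simulate_family


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; every threshold is echoed to the report."""

    # exactly one input route: files, a named fixture, or a simulation
    cds_fasta: str | None = None
    genomic_fasta: str | None = None
    annotation: str | None = None
    tree_newick: str | None = None
    guide_protein_alignment: str | None = None
    fixture: str | None = None
    simulate: bool = False
    n_leaves: int = 8

    outdir: str = "exevol_out"
    seed: int = 0
    outgroup: str | None = None
    min_cds: int = 400
    dedupe_identity: float = 0.95
    flank_len: int = 300
    max_gap_fraction: float = 0.8
    apply_filters: bool = True
    divergence_thresholds: tuple = (0.0, 3.0)
    verbosity: int = 1

    def input_route(self) -> str:
        if self.fixture:
            return "fixture"
        if self.simulate:
            return "simulate"
        if self.cds_fasta and self.annotation and self.tree_newick:
            return "files"
        raise ValueError("config must name a fixture, request a simulation, "
                         "or provide cds_fasta + annotation + tree_newick")


@dataclass
class PipelineResult:
    config: PipelineConfig
    family: FamilySet
    tree: PhyloTree
    alignment: CodonAlignment
    events: list[StructuralEvent]
    placements: list[EventPlacement]
    structures: dict[str, AncestralStructure]
    ranked: list[tuple[str, float]]
    subsets: dict[float, list[str]]
    true_history: object | None = None
    outputs: dict[str, str] = field(default_factory=dict)


def analyze_family(fs: FamilySet, tree: PhyloTree,
                   aln: CodonAlignment | None = None,
                   outgroup: str | None = None,
                   max_gap_fraction: float = 0.8,
                   divergence_thresholds: tuple = (0.0, 3.0)):
    """Core analysis on an in-memory family: align, detect, map, reconstruct.

    Returns ``(aln, events, placements, structures, ranked, subsets)``.
    Used by :func:`run_pipeline` and directly by library callers.
    """
    keep = [g for g in tree.leaf_ids() if g in fs.models]
    if aln is None:
        seqs = {g: fs.models[g].cds for g in keep}
        aln = progressive_align(seqs, tree)
        leave_one_out_refine(aln)
    mark_exon_boundaries(aln, fs)
    refine_exon_by_exon(aln, fs)
    mark_exon_boundaries(aln, fs)
    events = detect_events(aln, fs)
    outgroup = outgroup or tree.outgroup
    placements = [map_event(tree, ev, outgroup=outgroup) for ev in events]
    structures = reconstruct_ancestral_structure(tree, fs, placements, aln=aln)
    mask_nonhomologous_columns(aln, events,
                               max_gap_fraction=max_gap_fraction)
    ranked, subsets = rank_structural_divergence(
        fs, placements, tree, thresholds=list(divergence_thresholds))
    return aln, events, placements, structures, ranked, subsets


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the report bundle to ``cfg.outdir``."""
    route = cfg.input_route()
    hist = None
    if route == "fixture":
        fs, tree, hist = emit_fixture(cfg.fixture)
    elif route == "simulate":
        fs, tree, hist = simulate_family(
            SimConfig(n_leaves=cfg.n_leaves, seed=cfg.seed,
                      flank_length=cfg.flank_len))
    else:
        fs = load_gene_models(cfg.genomic_fasta, cfg.cds_fasta,
                              cfg.annotation, flank_len=cfg.flank_len)
        tree = PhyloTree.from_newick(Path(cfg.tree_newick).read_text(),
                                     outgroup=cfg.outgroup)
    if cfg.apply_filters and route == "files":
        fs = filter_models(fs, min_cds=cfg.min_cds,
                           dedupe_identity=cfg.dedupe_identity)
    guide = None
    if cfg.guide_protein_alignment:
        from Bio import SeqIO
        prot = {r.id: str(r.seq).upper()
                for r in SeqIO.parse(cfg.guide_protein_alignment, "fasta")}
        guide = project_protein_alignment(
            prot, {g: fs.models[g].cds for g in prot})
    aln, events, placements, structures, ranked, subsets = analyze_family(
        fs, tree, aln=guide, outgroup=cfg.outgroup,
        max_gap_fraction=cfg.max_gap_fraction,
        divergence_thresholds=cfg.divergence_thresholds)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = _write_bundle(out, cfg, fs, tree, aln, events, placements,
                            structures, ranked, subsets)
    return PipelineResult(config=cfg, family=fs, tree=tree, alignment=aln,
                          events=events, placements=placements,
                          structures=structures, ranked=ranked,
                          subsets=subsets, true_history=hist, outputs=outputs)


def _config_header(cfg: PipelineConfig) -> str:
    pairs = sorted(asdict(cfg).items())
    body = "; ".join(f"{k}={v}" for k, v in pairs)
    return f"# exevol {__version__}\n# config: {body}\n"


def _write_bundle(out: Path, cfg, fs, tree, aln, events, placements,
                  structures, ranked, subsets) -> dict[str, str]:
    paths = {}

    def p(name):
        paths[name] = str(out / name)
        return out / name

    write_family(fs, p("cds.fasta"), p("annotation.gff3"),
                 provenance_tsv=p("provenance.tsv"))
    aln.write_fasta(p("alignment.fasta"))
    aln.write_fasta(p("alignment_masked.fasta"), masked=True)
    aln.write_boundary_tsv(p("exon_boundaries.tsv"))
    aln.write_mask_tsv(p("column_mask.tsv"))
    events_to_tsv(events, p("events.tsv"))
    write_placements_tsv(placements, p("placements.tsv"))
    write_ancestral_tsv(structures, p("ancestral_structures.tsv"))
    comments = {}
    for pl in placements:
        for b in pl.branches:
            tag = f"{pl.event_id}={pl.mechanism}:{pl.event.length_bp}bp"
            comments[b] = (comments[b] + "+" if b in comments else "") + tag
    p("tree_annotated.nwk").write_text(
        tree.to_newick(branch_comments=comments) + "\n")
    with open(p("divergence.tsv"), "w") as fh:
        fh.write("gene_id\tdivergence_score\n")
        for g, s in ranked:
            fh.write(f"{g}\t{s:g}\n")
    with open(p("summary.txt"), "w") as fh:
        fh.write(_config_header(cfg))
        fh.write(summarize(events, placements, structures, tree))
    return paths


def summarize(events, placements, structures, tree) -> str:
    by_mech: dict[str, int] = {}
    by_exon: dict[int, int] = {}
    for ev in events:
        by_mech[ev.mechanism] = by_mech.get(ev.mechanism, 0) + 1
        by_exon[ev.exon_index] = by_exon.get(ev.exon_index, 0) + 1
    lines = [f"events: {len(events)}"]
    for m in sorted(by_mech):
        lines.append(f"  mechanism {m}: {by_mech[m]}")
    for k in sorted(by_exon):
        lines.append(f"  exon {k}: {by_exon[k]}")
    root = structures.get(tree.root)
    if root is not None:
        lines.append("root structure: "
                     f"{root.exon_count} exons "
                     f"({', '.join(map(str, root.exon_lengths))} bp)")
    for nid in sorted(structures):
        if nid != tree.root and not tree.is_leaf(nid):
            st = structures[nid]
            lines.append(f"node {nid}: {st.exon_count} exons "
                         f"({', '.join(map(str, st.exon_lengths))} bp)")
    return "\n".join(lines) + "\n"


__all__ = ["PipelineConfig", "PipelineResult", "analyze_family",
           "run_pipeline", "summarize", "read_alignment_fasta"]
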