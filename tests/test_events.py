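"""Structural-change event classification."""

import numpy as np
import pytest

from exevol.align import (CodonAlignment, mark_exon_boundaries,
                          consensus_boundaries)
from exevol.events import (ExonBlock, detect_internal_indels,
                           detect_intron_change, detect_stop_codon_events,
                           detect_events, gap_pattern_intervals,
                           scan_noncoding_for_homolog)
from exevol.models import FamilySet, GeneModel
from exevol.simulate import (SimConfig, ancestral_gene, emit_fixture,
                             simulate_family)


def _aln(rows):
    return CodonAlignment(row_ids=sorted(rows), rows=dict(rows))


class TestInternalIndels:
    def test_single_interior_gap_run(self):
        rows = {"a": "ATGGCC---AAATTT", "r1": "ATGGCCGGGAAATTT",
                "r2": "ATGGCCGGGAAATTT", "r3": "ATGGCCGGGAAATTT",
                "r4": "ATGGCCGGGAAATTT"}
        aln = _aln(rows)
        evs = detect_internal_indels(ExonBlock(aln, 1, 0, 15))
        assert len(evs) == 1
        ev = evs[0]
        assert ev.length_bp == 3 and ev.frame_preserving
        assert ev.state_rows == frozenset({"a"})

    def test_shared_run_groups_carriers(self):
        rows = {"a": "ATG------AAATTT", "b": "ATG------AAATTT",
                "r1": "ATGGCCGGGAAATTT", "r2": "ATGGCCGGGAAATTT"}
        evs = detect_internal_indels(ExonBlock(_aln(rows), 1, 0, 15))
        assert len(evs) == 1
        assert evs[0].state_rows == frozenset({"a", "b"})
        assert evs[0].length_bp == 6

    def test_non_triplet_gap_violates_frame(self):
        rows = {"a": "ATGG----AATTTT", "r": "ATGGCCGGAATTTT"}
        evs = detect_internal_indels(ExonBlock(_aln(rows), 1, 0, 14))
        assert evs[0].length_bp == 4
        assert not evs[0].frame_preserving

    def test_nested_runs_stay_separate(self):
        """Adjacent intervals with different marker sets (the nested
        insertion situation) become distinct events."""
        rows = {"out": "AAA---------TTT",
                "c1": "AAACCCGGGGGGTTT",
                "c2": "AAA------GGGTTT",
                "c3": "AAA------GGGTTT"}
        pats = gap_pattern_intervals(_aln(rows), 0, 15)
        spans = {(s, e): p for s, e, p in pats}
        assert spans[(3, 9)] == frozenset({"out", "c2", "c3"})
        assert spans[(9, 12)] == frozenset({"out"})


class TestIntronChange:
    def test_sep_like_merge_recognised(self):
        rng = np.random.default_rng(7)
        anc = ancestral_gene((185, 79, 62, 100, 42, 42, 137, 85), 200, 300,
                             rng)
        split = anc.clone()
        merged = anc.clone()
        merged.exons[4] = merged.exons[4] + merged.exons[5]
        del merged.exons[5], merged.introns[4], merged.labels[5]
        gm_a = split.to_gene_model("split", 300)
        gm_b = merged.to_gene_model("merged", 300)
        evs = detect_intron_change(gm_a, gm_b)
        assert len(evs) == 1
        assert evs[0].exon_index == 5
        assert evs[0].detail["merged_exon_length"] == 84
        # symmetric in its arguments
        evs2 = detect_intron_change(gm_b, gm_a)
        assert evs2[0].detail["merged_exon_length"] == 84

    def test_identical_genes_no_events(self):
        rng = np.random.default_rng(8)
        anc = ancestral_gene((90, 60, 90), 100, 100, rng)
        gm = anc.to_gene_model("x", 100)
        assert detect_intron_change(gm, gm.copy()) == []

    def test_poor_subsegment_identity_rejected(self):
        rng = np.random.default_rng(9)
        anc = ancestral_gene((90, 42, 42, 90), 100, 100, rng)
        merged = anc.clone()
        merged.exons[1] = merged.exons[1] + merged.exons[2]
        del merged.exons[2], merged.introns[1], merged.labels[2]
        # wreck one half of the merged exon
        bad = "".join("A" if c != "A" else "C" for c in merged.exons[1][:21])
        merged.exons[1] = bad + merged.exons[1][21:]
        evs = detect_intron_change(anc.to_gene_model("a", 100),
                                   merged.to_gene_model("b", 100))
        assert evs == []

    def test_annotation_required(self):
        with pytest.raises(ValueError, match="annotation"):
            detect_intron_change(GeneModel("a", "a", cds="ATG"),
                                 GeneModel("b", "b", cds="ATG"))


class TestStopCodonEvents:
    def test_readthrough_exonization_is_15bp(self):
        fs, tree, hist = emit_fixture("paleoAP1_stop_loss")
        evs = detect_stop_codon_events(fs.models["paleoAP1"],
                                       fs.models["SEP_ref"])
        assert [e.mechanism for e in evs] == ["exonization"]
        assert evs[0].length_bp == 15
        assert evs[0].carrier_genes == frozenset({"paleoAP1"})

    def test_frameshift_pseudoexonizes_last_8(self):
        fs, tree, hist = emit_fixture("euAP1_frameshift")
        evs = detect_stop_codon_events(fs.models["euAP1"],
                                       fs.models["AP1FUL_ref"])
        mechs = {e.mechanism: e for e in evs}
        assert mechs["intraexonic_deletion"].length_bp == 1
        assert not mechs["intraexonic_deletion"].frame_preserving
        assert mechs["pseudoexonization"].length_bp == 8
        assert mechs["pseudoexonization"].linked_to == \
            mechs["intraexonic_deletion"].event_id

    def test_identical_terminals_are_silent(self):
        fs, tree, hist = emit_fixture("paleoAP1_stop_loss")
        gm = fs.models["SEP_ref"]
        assert detect_stop_codon_events(gm, gm.copy()) == []

    def test_unterminated_orf_raises(self):
        gm = GeneModel("x", "x", cds="ATGGCCGGG", flank_3="C" * 50,
                       exons=[(0, 9)])
        with pytest.raises(ValueError, match="unterminated ORF"):
            detect_stop_codon_events(gm, gm.copy())


class TestNoncodingScan:
    def test_planted_exon_recovered(self):
        rng = np.random.default_rng(42)
        exon = "".join(rng.choice(list("ACGT"), size=120))
        bg = "".join(rng.choice(list("ACGT"), size=50_000))
        planted = bg[:30_000] + exon + bg[30_000:]
        hit = scan_noncoding_for_homolog(exon, planted)
        assert hit is not None
        assert hit.identity == 1.0
        assert abs(hit.offset - 30_000) <= 2

    def test_random_background_yields_none(self):
        rng = np.random.default_rng(43)
        exon = "".join(rng.choice(list("ACGT"), size=100))
        bg = "".join(rng.choice(list("ACGT"), size=10_000))
        assert scan_noncoding_for_homolog(exon, bg) is None

    def test_empty_noncoding_yields_none(self):
        assert scan_noncoding_for_homolog("ACGTACGT", "") is None

    def test_overlong_background_truncated_with_warning(self):
        rng = np.random.default_rng(44)
        exon = "".join(rng.choice(list("ACGT"), size=50))
        bg = "".join(rng.choice(list("ACGT"), size=2000))
        with pytest.warns(UserWarning, match="truncated"):
            scan_noncoding_for_homolog(exon, bg, max_span=1000)


class TestExhaustiveness:
    @pytest.mark.parametrize("seed", [0, 3, 5])
    def test_every_gap_column_is_explained(self, seed):
        """Each gap column of each row is covered by an event's span, by a
        whole-exon absence, or by the mask."""
        from exevol.pipeline import analyze_family
        fs, tree, hist = simulate_family(SimConfig(seed=seed))
        aln, events, placements, *_ = analyze_family(fs, tree)
        covered = set(aln.column_mask)
        for ev in events:
            covered.update(range(*ev.column_span))
        gap = aln.gap_matrix()
        nrows = len(aln.row_ids)
        for c in range(aln.ncols):
            n_gapped = int(gap[:, c].sum())
            if 0 < n_gapped < nrows:
                assert c in covered, f"column {c} unexplained"

    @pytest.mark.parametrize("seed", range(4))
    def test_frame_flag_matches_length(self, seed):
        fs, tree, hist = simulate_family(SimConfig(seed=seed))
        from exevol.pipeline import analyze_family
        _, events, *_ = analyze_family(fs, tree)
        for ev in events:
            assert ev.frame_preserving == (ev.length_bp % 3 == 0)
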