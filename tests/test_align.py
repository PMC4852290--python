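"""Pairwise DP, codon projection, boundary marking, refinement and masking."""

import numpy as np
import pytest
from conftest import naive_affine_score

from exevol.align import (CodonAlignment, mark_exon_boundaries,
                          mask_nonhomologous_columns, pairwise_flank_align,
                          progressive_align, project_protein_alignment,
                          refine_exon_by_exon)
from exevol.models import FamilySet, GeneModel
from exevol.parsimony import PhyloTree


class TestPairwiseAlign:
    def test_identical_semiglobal(self):
        pa = pairwise_flank_align("ACGTACGTACGT", "ACGTACGTACGT",
                                  mode="semiglobal")
        assert pa.score == 24.0
        assert pa.identity == 1.0

    def test_local_finds_perfect_block(self):
        pa = pairwise_flank_align("ACGTACGT", "ACGTTTTTACGT", mode="local")
        assert pa.identity == 1.0
        assert pa.aligned_columns >= 4

    def test_unrelated_sequences_fail_alignability(self):
        q = "ACGGATCCGTAAGCTTAGGC"
        from exevol.models import revcomp
        pa = pairwise_flank_align(q, revcomp(q), mode="local")
        assert not pa.is_alignable()

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            pairwise_flank_align("", "ACGT")

    @pytest.mark.parametrize("mode", ["global", "semiglobal", "local"])
    def test_matches_naive_dp_oracle(self, mode):
        """Exact score agreement with a cubic DP that tries every gap
        length explicitly, over random and adversarial short pairs."""
        rng = np.random.default_rng(20240917)
        pairs = [("A", "A"), ("A", "C"), ("AAAA", "AA"),
                 ("ACACACAC", "CACACA"), ("GGGGGGGG", "GGG"),
                 ("ACGT" * 5, "TGCA" * 5)]
        for _ in range(60):
            la, lb = rng.integers(1, 21, size=2)
            a = "".join(rng.choice(list("ACGT"), size=la))
            b = "".join(rng.choice(list("ACGT"), size=lb))
            pairs.append((a, b))
        for a, b in pairs:
            got = pairwise_flank_align(a, b, mode=mode).score
            want = naive_affine_score(a, b, mode=mode)
            assert got == pytest.approx(want), (a, b, mode)


class TestProjection:
    def test_malformed_guide_raises(self):
        with pytest.raises(ValueError, match="differ in length"):
            project_protein_alignment({"x": "MK", "y": "M-K"},
                                      {"x": "ATGAAA", "y": "ATGAAA"})

    def test_gap_expansion(self):
        aln = project_protein_alignment({"x": "MK-", "y": "M-K"},
                                        {"x": "ATGAAA", "y": "ATGAAG"})
        assert aln.rows["x"] == "ATGAAA---"
        assert aln.rows["y"] == "ATG---AAG"

    def test_terminal_stop_appended(self):
        cds = "ATGGCCAAAGATCCG" + "TAA"
        prot = "MAKDP"
        aln = project_protein_alignment({"x": prot}, {"x": cds})
        assert len(aln.rows["x"]) == 18
        assert aln.rows["x"].replace("-", "") == cds

    def test_translation_mismatch_names_row_and_residue(self):
        with pytest.raises(ValueError, match="row 'x'.*residue 1"):
            project_protein_alignment({"x": "MQ"}, {"x": "ATGAAA"})


class TestBoundaries:
    def _fs(self, lengths, cds):
        gm = GeneModel(gene_id="g", species_id="g", cds=cds,
                       exons=_intervals(lengths))
        fs = FamilySet()
        fs.add(gm)
        return fs

    def test_single_exon_no_boundaries(self):
        aln = CodonAlignment(row_ids=["g"], rows={"g": "ATGGCCAAA"})
        fs = self._fs([9], "ATGGCCAAA")
        mark_exon_boundaries(aln, fs)
        assert aln.exon_boundaries["g"] == []

    def test_two_exon_boundary_after_first_exon(self):
        cds = "ATGGCCAAAGGGTAA"
        aln = CodonAlignment(row_ids=["g"], rows={"g": cds})
        mark_exon_boundaries(aln, self._fs([9, 6], cds))
        assert aln.exon_boundaries["g"] == [9]

    def test_gap_shifts_boundary_column(self):
        cds = "ATGGCCAAAGGGTAA"
        gapped = cds[:6] + "---" + cds[6:]
        aln = CodonAlignment(row_ids=["g"], rows={"g": gapped})
        mark_exon_boundaries(aln, self._fs([9, 6], cds))
        # the 9th CDS base now sits three columns later
        assert aln.exon_boundaries["g"] == [12]

    def test_unannotated_rows_flagged(self):
        aln = CodonAlignment(row_ids=["g"], rows={"g": "ATG"})
        fs = FamilySet()
        fs.add(GeneModel(gene_id="g", species_id="g", cds="ATG"))
        mark_exon_boundaries(aln, fs)
        assert "g" in aln.unannotated


def _intervals(lengths, gap=100):
    out, pos = [], 0
    for ln in lengths:
        out.append((pos, pos + ln))
        pos += ln + gap
    return out


class TestRefinement:
    def test_identical_rows_unchanged(self):
        rows = {"a": "ATGGCCAAA", "b": "ATGGCCAAA"}
        aln = CodonAlignment(row_ids=["a", "b"], rows=dict(rows))
        fs = FamilySet()
        for g in rows:
            fs.add(GeneModel(gene_id=g, species_id=g, cds=rows[g],
                             exons=_intervals([9])))
        mark_exon_boundaries(aln, fs)
        refine_exon_by_exon(aln, fs)
        assert aln.rows == rows

    def test_gap_runs_left_align_and_score_never_drops(self):
        # a 3-column gap with score-equivalent placements: drifts left
        seqs = {"a": "AAACCCTTTGGG", "b": "AAACCCTTT"}
        rows = {"a": "AAACCCTTTGGG", "b": "AAACCC---TTT"[:9] + "---"}
        rows["b"] = "AAACCCTTT---"  # start from the rightmost placement
        aln = CodonAlignment(row_ids=["a", "b"], rows=dict(rows))
        fs = FamilySet()
        for g, cds in seqs.items():
            fs.add(GeneModel(gene_id=g, species_id=g, cds=cds,
                             exons=_intervals([len(cds)])))
        mark_exon_boundaries(aln, fs)
        before = aln.sum_of_pairs()
        refine_exon_by_exon(aln, fs)
        assert aln.sum_of_pairs() >= before - 1e-9
        for g, cds in seqs.items():
            assert aln.degapped(g) == cds

    def test_degap_invariance_through_pipeline(self):
        from exevol.simulate import SimConfig, simulate_family
        fs, tree, hist = simulate_family(SimConfig(seed=11))
        seqs = {g: fs.models[g].cds for g in tree.leaf_ids()}
        aln = progressive_align(seqs, tree)
        from exevol.align import leave_one_out_refine
        leave_one_out_refine(aln)
        mark_exon_boundaries(aln, fs)
        refine_exon_by_exon(aln, fs)
        for g, cds in seqs.items():
            assert aln.degapped(g) == cds


class TestMasking:
    def test_clean_alignment_unmasked(self):
        aln = CodonAlignment(row_ids=["a", "b"],
                             rows={"a": "ATGGCC", "b": "ATGGCC"})
        mask_nonhomologous_columns(aln, [])
        assert aln.column_mask == {}

    def test_gappy_column_masked(self):
        rows = {f"g{i}": ("A" if i == 0 else "-") + "TGC"
                for i in range(10)}
        aln = CodonAlignment(row_ids=sorted(rows), rows=rows)
        mask_nonhomologous_columns(aln, [])
        assert aln.column_mask.get(0) == "gap_fraction"

    def test_independent_overlapping_events_masked(self):
        from exevol.events import StructuralEvent
        rows = {"a": "ATGGCCAAATTT", "b": "ATGGCCAAATTT",
                "c": "ATGGCCAAATTT", "d": "ATGGCCAAATTT"}
        aln = CodonAlignment(row_ids=sorted(rows), rows=rows)
        e1 = StructuralEvent(event_id="e1", mechanism="indeterminate_indel",
                             exon_index=1, length_bp=3, column_span=(3, 6),
                             state_rows=frozenset({"a"}),
                             alt_rows=frozenset({"b", "c", "d"}),
                             evidence="internal_gap")
        e2 = StructuralEvent(event_id="e2", mechanism="indeterminate_indel",
                             exon_index=1, length_bp=3, column_span=(4, 7),
                             state_rows=frozenset({"d"}),
                             alt_rows=frozenset({"a", "b", "c"}),
                             evidence="internal_gap")
        mask_nonhomologous_columns(aln, [e1, e2])
        assert {4, 5} <= set(aln.column_mask)
        assert aln.column_mask[4] == "independent events"
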