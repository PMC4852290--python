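"""Gene-model loading, validation and filtering."""

import pytest

from exevol.models import (FamilySet, GeneModel, cds_identity, filter_models,
                           load_gene_models, revcomp, select_transcript,
                           write_family)


def test_two_exon_gene_is_consistent(toy_two_exon_gene):
    gm, genomic = toy_two_exon_gene
    assert gm.exon_lengths == [9, 6]
    assert gm.validate(genomic=genomic) == []


def test_cds_mismatch_is_reported(toy_two_exon_gene):
    gm, genomic = toy_two_exon_gene
    gm.cds = gm.cds[:-1] + ("A" if gm.cds[-1] != "A" else "C")
    problems = gm.validate(genomic=genomic)
    assert any("CDS mismatch" in p for p in problems)


def test_minus_strand_concatenation_matches_revcomp_oracle(toy_two_exon_gene):
    gm, genomic = toy_two_exon_gene
    # build the '-'-strand version on the reverse-complemented locus
    rc = revcomp(genomic)
    n = len(genomic)
    # intervals on the forward strand of the new locus, transcript order 5'->3'
    exons_rc = [(n - e, n - s) for s, e in gm.exons]
    gm2 = GeneModel(gene_id="toy_rc", species_id="toysp", strand="-",
                    exons=exons_rc, cds=gm.cds)
    assert gm2.validate(genomic=rc) == []
    # independent oracle: slice, join in genomic order, reverse-complement
    parts = "".join(rc[s:e] for s, e in sorted(exons_rc))
    assert revcomp(parts) == gm.cds


def test_load_round_trip(tmp_path, toy_two_exon_gene):
    gm, genomic = toy_two_exon_gene
    fs = FamilySet()
    fs.add(gm)
    write_family(fs, tmp_path / "cds.fa", tmp_path / "ann.gff3",
                 genomic_fasta=tmp_path / "gen.fa")
    fs2 = load_gene_models(tmp_path / "gen.fa", tmp_path / "cds.fa",
                           tmp_path / "ann.gff3")
    gm2 = fs2.models["toy"]
    assert gm2.cds == gm.cds
    assert gm2.exon_lengths == gm.exon_lengths
    assert gm2.introns == gm.introns


def test_load_reports_missing_sequence(tmp_path, toy_two_exon_gene):
    gm, genomic = toy_two_exon_gene
    (tmp_path / "ann.gff3").write_text(
        "##gff-version 3\nchrX\t.\texon\t5\t13\t.\t+\t.\tParent=ghost\n")
    (tmp_path / "cds.fa").write_text(">other\nATG\n")
    with pytest.raises(KeyError, match="ghost"):
        load_gene_models(None, tmp_path / "cds.fa", tmp_path / "ann.gff3")


def _model(gid, species, cds):
    return GeneModel(gene_id=gid, species_id=species, cds=cds)


def test_filter_rules():
    """Short CDSs go; same-species near-duplicates collapse to one; the
    same similarity across species is kept."""
    base = ("ATGGCC" * 100)[:600]
    similar = base[:300] + "T" * 6 + base[306:]  # ~99% identical
    fs = FamilySet()
    fs.add(_model("short", "spA", base[:399]))
    fs.add(_model("a1", "spA", base))
    fs.add(_model("a2", "spA", similar))
    fs.add(_model("b1", "spB", similar))
    out = filter_models(fs)
    assert "short" not in out.models
    assert ("a1" in out.models) ^ ("a2" in out.models)
    assert "b1" in out.models
    # idempotent
    again = filter_models(out)
    assert set(again.models) == set(out.models)
    removed = {gid for gid, action, _ in out.provenance if action == "removed"}
    assert "short" in removed


def test_identity_agrees_with_naive_oracle():
    """Identity comes from an optimal global alignment under the dedup
    scheme; the alignment's score must equal a naive DP's optimum."""
    from Bio.Align import PairwiseAligner
    from conftest import naive_affine_score

    pairs = [("ACGTACGT", "ACGTCGT"), ("AAAATTTT", "AAATTT"),
             ("ACACACAC", "GTGTGTGT"), ("ATGGCC", "ATGGCC"),
             ("ACGT", "ACGTACGT")]
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    for a, b in pairs:
        score = aligner.score(a, b)
        oracle = naive_affine_score(a, b, mode="global", match=1.0,
                                    mismatch=0.0, gap_open=9.5,
                                    gap_extend=0.5)
        assert score == pytest.approx(oracle)
        ident = cds_identity(a, b)
        assert 0.0 <= ident <= 1.0
        if a == b:
            assert ident == 1.0


def test_select_transcript_prefers_least_diverged():
    base = ("ATGGCAAAG" * 50)[:420]
    ref = _model("ref", "spR", base)
    refs = FamilySet()
    refs.add(ref)
    iso_same = _model("isoA", "spA", base)
    iso_indel = _model("isoB", "spA", base[:200] + base[221:])  # 21 bp gone
    iso_small = _model("isoC", "spA", base[:200] + base[203:])  # 3 bp gone
    assert select_transcript([iso_same, iso_indel], refs) is iso_same
    # tie on event count: the smaller total event length wins
    assert select_transcript([iso_indel, iso_small], refs) is iso_small
    # a single isoform is returned unchanged
    assert select_transcript([iso_indel], refs) is iso_indel
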