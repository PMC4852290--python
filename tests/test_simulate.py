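"""Synthetic-data generator: determinism, ledger completeness, statistics."""

import numpy as np
import pytest

from exevol.simulate import (ANCESTRAL_EXON_LENGTHS, DEFAULT_EVENT_RATES,
                             FIXTURE_NAMES, SimConfig, TrueEvent,
                             apply_event, emit_fixture, expected_event_count,
                             simulate_family)


def _leaf_states(hist, tree):
    return {g: hist.snapshots[g] for g in tree.leaf_ids()}


def test_seed_determinism_is_byte_identical():
    fs1, t1, h1 = simulate_family(SimConfig(seed=77))
    fs2, t2, h2 = simulate_family(SimConfig(seed=77))
    assert t1.to_newick() == t2.to_newick()
    for g in fs1.models:
        assert fs1.models[g].cds == fs2.models[g].cds
        assert fs1.models[g].introns == fs2.models[g].introns
    assert [e.event_id for e in h1.events] == [e.event_id for e in h2.events]


def test_zero_rates_give_ancestral_leaves_and_empty_ledger():
    cfg = SimConfig(seed=1, subs_per_branch=0.0,
                    event_rates={k: 0.0 for k in DEFAULT_EVENT_RATES})
    fs, tree, hist = simulate_family(cfg)
    assert hist.events == []
    for gm in fs:
        assert gm.exon_lengths == list(ANCESTRAL_EXON_LENGTHS)


def test_forced_insertion_bookkeeping():
    from exevol.simulate import ancestral_gene
    rng = np.random.default_rng(0)
    st = ancestral_gene(ANCESTRAL_EXON_LENGTHS, 200, 300, rng)
    before = st.exon_lengths[6]
    apply_event(st, TrueEvent(event_id="t", branch="x",
                              mechanism="intraexonic_insertion",
                              exon_label="7", exon_index=7, length_bp=3,
                              position=10, payload={"seq": "AAA"}))
    assert st.exon_lengths[6] == before + 3


@pytest.mark.parametrize("seed", range(8))
def test_ledger_replay_reproduces_leaves(seed):
    fs, tree, hist = simulate_family(SimConfig(seed=seed))
    states = hist.replay(tree)
    for g in tree.leaf_ids():
        assert states[g].cds == fs.models[g].cds
        assert states[g].introns == fs.models[g].introns
        assert states[g].flank_5 == hist.snapshots[g].flank_5


def test_ledger_completeness_for_exon_lengths():
    """Leaf exon lengths equal ancestral lengths plus the signed event
    lengths along each root-to-leaf path (checked via replay snapshots)."""
    for seed in range(6):
        fs, tree, hist = simulate_family(SimConfig(seed=seed))
        for g in tree.leaf_ids():
            assert hist.snapshots[g].exon_lengths == \
                fs.models[g].exon_lengths


def test_mean_event_count_matches_expectation():
    """Over many families the ledger size tracks the analytic Poisson
    expectation within three standard errors."""
    n_fam = 120
    counts, expect = [], []
    for seed in range(n_fam):
        cfg = SimConfig(seed=seed)
        fs, tree, hist = simulate_family(cfg)
        counts.append(len(hist.events))
        expect.append(expected_event_count(cfg, tree))
    mean, want = np.mean(counts), np.mean(expect)
    se = np.std(counts, ddof=1) / np.sqrt(n_fam)
    assert abs(mean - want) <= 3 * se + 1e-9


def test_non_triplet_fraction_tracks_p_frame():
    lengths = []
    for seed in range(150):
        _, _, hist = simulate_family(SimConfig(seed=seed))
        lengths.extend(e.length_bp for e in hist.events
                       if e.mechanism in ("intraexonic_insertion",
                                          "intraexonic_deletion"))
    frac = np.mean([ln % 3 != 0 for ln in lengths])
    p = 0.1  # 1 - p_frame
    se = np.sqrt(p * (1 - p) / len(lengths))
    assert abs(frac - p) <= 4 * se


def test_excessive_rates_raise():
    rates = {k: 30.0 for k in DEFAULT_EVENT_RATES}
    with pytest.raises(ValueError, match="rates"):
        simulate_family(SimConfig(seed=0, event_rates=rates))


class TestFixtures:
    def test_unknown_name_lists_valid_ones(self):
        with pytest.raises(ValueError, match="brassicaceae_intron_loss"):
            emit_fixture("nope")

    def test_intron_loss_fixture_shape(self):
        fs, tree, hist = emit_fixture("brassicaceae_intron_loss")
        a = fs.models["SEP12_ref"]
        b = fs.models["SEP12_brassicaceae"]
        assert a.cds == b.cds
        assert abs(a.n_exons - b.n_exons) == 1

    def test_capsella_fixture_shape(self):
        fs, tree, hist = emit_fixture("capsella_nested_insertions")
        assert len(fs) == 4
        lens = {g: fs.models[g].exon_lengths[6] for g in fs.models}
        assert lens["outgroup"] == 137
        assert lens["Brassica"] == lens["Arabidopsis"] == 170
        assert lens["Capsella"] == 236

    @pytest.mark.parametrize("name", FIXTURE_NAMES)
    def test_fixture_replay_is_exact(self, name):
        fs, tree, hist = emit_fixture(name)
        states = hist.replay(tree)
        for g in tree.leaf_ids():
            assert states[g].cds == fs.models[g].cds

    @pytest.mark.parametrize("name", FIXTURE_NAMES)
    def test_fixture_is_deterministic(self, name):
        fs1, t1, h1 = emit_fixture(name)
        fs2, t2, h2 = emit_fixture(name)
        for g in fs1.models:
            assert fs1.models[g].cds == fs2.models[g].cds
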