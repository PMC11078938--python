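"""Probe design: isoform choice, k-mer filters, complementarity screens."""

import numpy as np
import pytest

from cycliq import (
    assemble_secondary,
    design_primary_probes,
    enumerate_primary_candidates,
    fab_oligo,
    filter_cross_hybridizing,
    generate_readout_candidates,
    select_longest_isoform,
    validate_primary_set,
    validate_readout_set,
)
from cycliq.probes import PrimaryProbe, PrimaryProbeSet, TranscriptSet, reverse_complement

from _oracles import conflict_pairs, count_occurrences


def _random_transcript(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _random_transcriptome(seed, n_genes=6, lo=1200, hi=2500):
    rng = np.random.default_rng(seed)
    return {
        f"GENE{i}": {"tx1": _random_transcript(rng, int(rng.integers(lo, hi)))}
        for i in range(n_genes)
    }


# ---------------------------------------------------------------------------
# isoform selection


def test_longest_isoform_wins():
    rng = np.random.default_rng(0)
    records = {"G": {"short": _random_transcript(rng, 300),
                     "long": _random_transcript(rng, 500)}}
    ts = select_longest_isoform(records)
    assert len(ts.sequences["G"]) == 500
    assert ts.representative_ids["G"] == "long"


def test_single_isoform_and_tie_determinism():
    rng = np.random.default_rng(1)
    only = _random_transcript(rng, 400)
    assert select_longest_isoform({"G": {"tx": only}}).sequences["G"] == only
    a, b = _random_transcript(rng, 400), _random_transcript(rng, 400)
    records = {"G": {"zzz": a, "aaa": b}}
    for _ in range(3):
        assert select_longest_isoform(records).representative_ids["G"] == "aaa"


# ---------------------------------------------------------------------------
# primary candidates


def _repeat_free_60mer(seed):
    """A 60-nt sequence whose 33 windows are all unique and GC-passing."""
    rng = np.random.default_rng(seed)
    while True:
        seq = _random_transcript(rng, 60)
        wins = [seq[i : i + 28] for i in range(33)]
        gcs = [w.count("G") + w.count("C") for w in wins]
        if len(set(wins)) == 33 and all(13 <= g <= 18 for g in gcs):
            return seq


def test_sixty_nt_repeat_free_transcript_yields_33_candidates():
    seq = _repeat_free_60mer(7)
    ts = TranscriptSet(sequences={"G": seq})
    ps = enumerate_primary_candidates(ts)
    assert len(ps.probes["G"]) == 33  # 60 - 28 + 1


def test_low_gc_window_excluded():
    # 12 G/C out of 28 is ~42.9 %, below the 45 % bound
    core = "A" * 16 + "G" * 12
    assert (core.count("G") + core.count("C")) == 12
    seq = _repeat_free_60mer(3) + core + _repeat_free_60mer(4)
    ts = TranscriptSet(sequences={"G": seq})
    ps = enumerate_primary_candidates(ts)
    assert core not in {p.sequence for p in ps.probes.get("G", [])}


def test_gene_with_23_candidates_dropped():
    rng = np.random.default_rng(11)
    while True:  # 50 nt -> 23 windows; need all of them to survive filters
        seq = _random_transcript(rng, 50)
        wins = [seq[i : i + 28] for i in range(23)]
        gcs = [w.count("G") + w.count("C") for w in wins]
        if len(set(wins)) == 23 and all(13 <= g <= 18 for g in gcs):
            break
    ps = enumerate_primary_candidates(TranscriptSet(sequences={"G": seq}))
    assert "G" not in ps.probes


def test_duplicated_window_across_genes_excluded():
    shared = _repeat_free_60mer(21)[:28]
    a = _repeat_free_60mer(22) + shared
    b = shared + _repeat_free_60mer(23)
    ps = enumerate_primary_candidates(TranscriptSet(sequences={"A": a, "B": b}))
    for plist in ps.probes.values():
        assert shared not in {p.sequence for p in plist}


def test_short_transcript_yields_no_candidates():
    ps = enumerate_primary_candidates(TranscriptSet(sequences={"G": "ACGT" * 5}))
    assert ps.probes == {}


def test_uniqueness_matches_brute_force_counting():
    records = _random_transcriptome(31, n_genes=4, lo=600, hi=900)
    ts = select_longest_isoform(records)
    ps = enumerate_primary_candidates(ts)
    for p in ps.all_probes():
        assert count_occurrences(ts.sequences, p.sequence) == 1


# ---------------------------------------------------------------------------
# cross-hybridisation


def _probe_set(seqs):
    return PrimaryProbeSet(
        probes={"G": [PrimaryProbe("G", i, s) for i, s in enumerate(seqs)]}
    )


def test_ten_mer_complement_flagged_nine_mer_not():
    rng = np.random.default_rng(5)
    a = _random_transcript(rng, 28)
    ten = a[5:15]
    b_conflict = _random_transcript(rng, 9) + reverse_complement(ten) + _random_transcript(rng, 9)
    from cycliq.probes import _conflict_graph

    adj = _conflict_graph([a, b_conflict], 10)
    assert adj[0] == {1} and adj[1] == {0}
    nine = a[5:14]
    b_clean_base = _random_transcript(rng, 10) + reverse_complement(nine) + _random_transcript(rng, 9)
    adj2 = _conflict_graph([a, b_clean_base], 10)
    # only guaranteed when no accidental 10-mer complement arises
    expected = conflict_pairs([a, b_clean_base], 10)
    assert (len(adj2[0]) > 0) == ((0, 1) in expected)


@pytest.mark.parametrize("seed", range(3))
def test_conflict_graph_matches_all_pairs_scan(seed):
    rng = np.random.default_rng(seed)
    seqs = [_random_transcript(rng, 28) for _ in range(60)]
    from cycliq.probes import _conflict_graph

    adj = _conflict_graph(seqs, 10)
    expected = conflict_pairs(seqs, 10)
    got = {(i, j) for i, nbrs in enumerate(adj) for j in nbrs if i < j}
    assert got == expected


def test_surviving_set_is_conflict_free_and_rule_checked():
    records = _random_transcriptome(41, n_genes=3, lo=200, hi=320)
    ps = design_primary_probes(records)
    assert ps.probes, "expected at least one retained gene"
    seqs = [p.sequence for p in ps.all_probes()]
    assert conflict_pairs(seqs, 10) == set()
    ts = select_longest_isoform(records)
    assert validate_primary_set(ps, ts) == []


# ---------------------------------------------------------------------------
# readout probes


def test_readouts_pass_all_filters_and_are_reproducible():
    a = generate_readout_candidates(24, seed=9)
    b = generate_readout_candidates(24, seed=9)
    assert a == b
    assert len(a) == 24
    assert validate_readout_set(a) == []


def test_readout_partial_set_warns_on_attempt_cap(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="cycliq.probes"):
        out = generate_readout_candidates(50, seed=0, max_attempts=40)
    assert len(out) < 50
    assert "only" in caplog.text


# ---------------------------------------------------------------------------
# secondary assembly


def test_secondary_contains_two_readout_binding_units():
    rng = np.random.default_rng(2)
    primary = _random_transcript(rng, 28)
    readout = generate_readout_candidates(1, seed=5)[0]
    sec = assemble_secondary(primary, readout)
    unit = reverse_complement(readout)
    assert sec.count(unit) == 2
    assert reverse_complement(sec[:28]) == primary


def test_fab_oligo_reproduces_documented_layout():
    readout = "ACGTGTCGTTCAACG"  # 15 nt, 5' A, GC 8/15
    oligo = fab_oligo(readout)
    assert oligo == "ACGTTGAACGACACGTAAACGTTGAACGACACGTA"
    assert len(oligo) == 35
    assert oligo.count(reverse_complement(readout)) == 2
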