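"""Hydrogen-bond seed scanner: scoring, site enumeration, counting."""

import random

import numpy as np
import pytest

from helpers import oracle_hbond_score, oracle_scan, random_dna, random_rna
from mutsigmirna.errors import InputError
from mutsigmirna.seedscan import (
    MatureMiRNA,
    SeedWeights,
    UtrRecord,
    count_binding,
    hbond_score,
    scan_region,
    scan_sites,
)


@pytest.mark.parametrize(
    "seed,window,expected",
    [
        ("AAAAAAA", "TTTTTTT", (14, 7)),  # seven A:T pairs at 2 bonds
        ("GGGGGGG", "CCCCCCC", (21, 7)),  # seven G:C pairs at 3 bonds
        ("GGGAAAA", "TTTTCCC", (17, 7)),  # 3x G:C + 4x A:T, antiparallel
        ("GAAAAAA", "TTTTTTT", (14, 7)),  # one G.T wobble (2) + six A:T
        ("UUUUUUU", "AAAAAAA", (14, 7)),  # seven U:A pairs
        ("CCCCCCC", "AAAAAAA", (0, 0)),  # all mismatches
    ],
)
def test_hbond_score_examples(seed, window, expected):
    assert hbond_score(seed, window) == expected


def test_hbond_score_rejects_bad_input():
    with pytest.raises(InputError):
        hbond_score("AAAA", "TTTTTTT")
    with pytest.raises(InputError):
        hbond_score("AAAAAAA", "TTTTTTU")  # U is not DNA
    with pytest.raises(InputError):
        hbond_score("AAAAAAT", "TTTTTTT")  # T is not RNA


def test_hbond_score_matches_oracle_randomised():
    rng = random.Random(101)
    for _ in range(300):
        seed = random_rna(rng, 7)
        window = random_dna(rng, 7)
        assert hbond_score(seed, window) == oracle_hbond_score(seed, window)


def _mirna_with_seed(seed: str) -> MatureMiRNA:
    # pad to a 22-nt mature sequence with the seed at positions 2-8
    return MatureMiRNA("mir-test", "A" + seed + "A" * 14)


def test_scan_threshold_zero_admits_every_window():
    utr = UtrRecord("g", "ACGTACGTACGT")
    sites = scan_sites(_mirna_with_seed("GGGGGGG"), utr, 0, mode="lenient")
    assert len(sites) == len(utr) - 6
    assert [s.offset for s in sites] == list(range(len(utr) - 6))


def test_scan_perfect_site_found_strict():
    utr = UtrRecord("g", "AACCCCCCCAA")
    sites = scan_sites(_mirna_with_seed("GGGGGGG"), utr, 21, mode="strict")
    assert [(s.offset, s.score, s.n_paired) for s in sites] == [(2, 21, 7)]


def test_scan_threshold_above_max_is_empty():
    utr = UtrRecord("g", "CCCCCCCCCC")
    assert scan_sites(_mirna_with_seed("GGGGGGG"), utr, 22) == []


def test_scan_short_utr_yields_no_sites():
    assert scan_sites(_mirna_with_seed("GGGGGGG"), UtrRecord("g", "CCC"), 0) == []


def test_scan_matches_oracle_all_thresholds_both_modes():
    rng = random.Random(7)
    for _ in range(40):
        seed = random_rna(rng, 7)
        utr = random_dna(rng, rng.randint(7, 60))
        mirna = _mirna_with_seed(seed)
        rec = UtrRecord("g", utr)
        for mode in ("lenient", "strict"):
            for t in range(0, 22):
                got = [(s.offset, s.score, s.n_paired) for s in scan_sites(mirna, rec, t, mode=mode)]
                assert got == oracle_scan(seed, utr, t, mode)


def test_threshold_and_mode_monotonicity():
    rng = random.Random(13)
    for _ in range(25):
        mirna = _mirna_with_seed(random_rna(rng, 7))
        rec = UtrRecord("g", random_dna(rng, 50))
        prev = None
        for t in range(0, 22):
            lenient = {s.offset for s in scan_sites(mirna, rec, t, mode="lenient")}
            strict = {s.offset for s in scan_sites(mirna, rec, t, mode="strict")}
            assert strict <= lenient
            if prev is not None:
                assert lenient <= prev  # raising threshold never adds sites
            prev = lenient


def test_c_to_t_substitution_never_raises_score_opposite_seed_g():
    # a C paired with seed G becomes a wobble T: weight 3 -> 2
    rng = random.Random(29)
    for _ in range(50):
        seed = random_rna(rng, 7)
        window = random_dna(rng, 7)
        for j in range(7):
            if window[j] == "C" and seed[6 - j] == "G":
                mutated = window[:j] + "T" + window[j + 1 :]
                assert oracle_hbond_score(seed, mutated)[0] <= oracle_hbond_score(seed, window)[0]
                assert hbond_score(seed, mutated)[0] == hbond_score(seed, window)[0] - 1


def test_equal_weights_collapse_score_to_twice_paired():
    rng = random.Random(31)
    eq = SeedWeights.equal()
    for _ in range(100):
        s, n = hbond_score(random_rna(rng, 7), random_dna(rng, 7), eq)
        assert s == 2 * n


def test_reverse_complement_target_scores_full_watson_crick():
    rng = random.Random(37)
    comp = {"A": "T", "C": "G", "G": "C", "U": "A"}
    for _ in range(50):
        seed = random_rna(rng, 7)
        target = "".join(comp[b] for b in seed)[::-1]  # DNA reverse complement
        score, n = hbond_score(seed, target)
        n_gc = sum(b in "GC" for b in seed)
        assert n == 7
        assert score == 7 * 2 + n_gc * (3 - 2)


def test_scan_region_full_range_equals_scan_sites():
    rng = random.Random(41)
    mirna = _mirna_with_seed(random_rna(rng, 7))
    rec = UtrRecord("g", random_dna(rng, 80))
    assert scan_region(mirna, rec, 10, lo=0, hi=len(rec)) == scan_sites(mirna, rec, 10)


def test_scan_region_outside_sites_is_empty():
    utr = UtrRecord("g", "AACCCCCCCAA" + "A" * 20)
    mirna = _mirna_with_seed("GGGGGGG")
    assert scan_region(mirna, utr, 21, mode="strict", lo=15, hi=25) == []


def test_local_rescan_union_equals_full_rescan():
    """Rescanning only around a mutation reproduces the full mutant scan."""
    rng = random.Random(43)
    for _ in range(100):
        mirna = _mirna_with_seed(random_rna(rng, 7))
        seq = random_dna(rng, 60)
        p = rng.randrange(len(seq))
        alt = rng.choice([b for b in "ACGT" if b != seq[p]])
        mutated = UtrRecord("g", seq[:p] + alt + seq[p + 1 :])
        wt = UtrRecord("g", seq)
        t, mode = rng.choice([(14, "lenient"), (16, "lenient"), (14, "strict")])
        local = scan_region(mirna, mutated, t, mode=mode, lo=p, hi=p + 1)
        outside = [
            s for s in scan_sites(mirna, wt, t, mode=mode) if s.offset + 7 <= p or s.offset > p
        ]
        merged = sorted(local + outside, key=lambda s: s.offset)
        full = scan_sites(mirna, mutated, t, mode=mode)
        assert merged == full


def test_count_binding_aggregates():
    utr = UtrRecord("g1", "CCCCCCC" + "TTTTTTT" + "CCCCCCC" + "TTTTTTT" + "CCCCCCC")
    m_g = _mirna_with_seed("GGGGGGG")
    m_a = MatureMiRNA("mir-a", "A" + "AAAAAAA" + "A" * 14)
    table = count_binding([utr], [m_g, m_a], 21, mode="strict", counting="distinct_mirnas")
    assert table.aggregate_for("g1") == 1  # only the G-seed reaches 21
    table2 = count_binding([utr], [m_g, m_a], 14, mode="strict", counting="total_sites")
    # the G seed fully pairs every C/T window (G:C plus G.T wobble): all 29;
    # the A seed pairs only the two perfect all-T runs
    assert table2.counts[0, 0] == 29 and table2.counts[0, 1] == 2
    assert table2.aggregate_for("g1") == 31
    # at 21 only the three all-C windows survive for the G seed
    t21 = count_binding([utr], [m_g, m_a], 21, mode="strict", counting="total_sites")
    assert t21.counts[0, 0] == 3 and t21.counts[0, 1] == 0


def test_count_binding_rejects_duplicate_genes():
    u = UtrRecord("g1", "ACGTACGT")
    with pytest.raises(InputError):
        count_binding([u, u], [_mirna_with_seed("GGGGGGG")], 0)


def test_count_binding_matches_bruteforce_double_loop():
    rng = random.Random(47)
    utrs = [UtrRecord(f"g{i}", random_dna(rng, 40)) for i in range(5)]
    mirnas = [_mirna_with_seed(random_rna(rng, 7)) for _ in range(4)]
    for t, mode in [(12, "lenient"), (15, "strict")]:
        table = count_binding(utrs, mirnas, t, mode=mode, counting="total_sites")
        for i, u in enumerate(utrs):
            for j, m in enumerate(mirnas):
                assert table.counts[i, j] == len(oracle_scan(m.seed, u.sequence, t, mode))


def test_mirna_seed_is_positions_two_to_eight():
    m = MatureMiRNA("x", "UACGUACGUACGUACGUACGUA")
    assert m.seed == m.sequence[1:8]
    assert len(m.seed) == 7


def test_utr_rejects_bad_alphabet():
    with pytest.raises(InputError):
        UtrRecord("g", "ACGU")
    with pytest.raises(InputError):
        UtrRecord("g", "")
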