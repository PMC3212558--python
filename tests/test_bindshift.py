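"""delta_b sweeps, significance, miRNA ranking and rank aggregation."""

import numpy as np
import pandas as pd
import pytest

from mutsigmirna.bindshift import (
    ImportedPredictions,
    consensus_rank,
    delta_b_sweep,
    per_mirna_delta_b,
    significance,
    subset_mirnas,
    DeltaBRow,
)
from mutsigmirna.errors import InputError
from mutsigmirna.mutmodel import PointMutation
from mutsigmirna.seedscan import MatureMiRNA, UtrRecord


def _mirna(mid, seed):
    return MatureMiRNA(mid, "A" + seed + "A" * 14)


G_MIRNA = _mirna("mir-g", "GGGGGGG")
A_MIRNA = _mirna("mir-a", "AAAAAAA")


def test_empty_mutation_list_gives_zero_delta_b():
    utrs = [UtrRecord("g1", "ACGTACGTACGT")]
    rows = delta_b_sweep(utrs, [], [G_MIRNA], thresholds=[14, 18, 21])
    assert all(r.delta_b == 0 and r.normalized == 0.0 for r in rows)


def test_site_destroying_mutation_gives_positive_delta_b():
    # WT carries a perfect G-seed target; the C>T mutation breaks it
    utrs = [UtrRecord("G1", "AACCCCCCCAA")]
    muts = [PointMutation("G1", 5, "C", "T")]
    (row,) = delta_b_sweep(utrs, muts, [G_MIRNA], thresholds=[21], mode="strict")
    assert (row.n_wt_more, row.n_mut_more, row.n_tied) == (1, 0, 0)
    assert row.delta_b == 1
    assert row.normalized == 1.0


def test_site_creating_mutation_gives_negative_delta_b():
    # the T>C mutation completes the poly-C target in the mutant
    utrs = [UtrRecord("G1", "AACCCCTCCAA")]
    muts = [PointMutation("G1", 6, "T", "C")]
    (row,) = delta_b_sweep(utrs, muts, [G_MIRNA], thresholds=[21], mode="strict")
    assert row.delta_b == -1


def test_delta_b_unknown_gene_is_hard_error():
    with pytest.raises(InputError, match="unknown gene"):
        delta_b_sweep([UtrRecord("g1", "ACGTACG")], [PointMutation("gX", 0, "A", "C")], [G_MIRNA])


def test_delta_b_conservation_invariant():
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    utrs = [UtrRecord(f"g{i}", "".join(rng.choice(bases, 60))) for i in range(12)]
    muts = []
    for u in utrs[:9]:
        off = int(rng.integers(len(u)))
        ref = u.sequence[off]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        muts.append(PointMutation(u.gene_id, off, ref, alt))
    for counting in ("distinct_mirnas", "total_sites"):
        rows = delta_b_sweep(utrs, muts, [G_MIRNA, A_MIRNA], counting=counting)
        for r in rows:
            assert r.n_wt_more + r.n_mut_more + r.n_tied == 9


def test_significance_all_tied():
    rows = [DeltaBRow(t, 3, 3, 10) for t in (14, 15, 16)]
    sig = significance(rows)
    assert sig.p_paired_t == 1.0
    assert sig.all_tied
    assert sig.t_stat == 0.0


def test_sign_test_exact_binomial():
    rows = [DeltaBRow(14, 10, 0, 5), DeltaBRow(15, 5, 5, 5)]
    sig = significance(rows)
    assert sig.sign_p[0] == pytest.approx(2 * 0.5**10)
    assert sig.sign_p[1] == pytest.approx(1.0)


def test_significance_requires_two_thresholds():
    with pytest.raises(InputError):
        significance([DeltaBRow(14, 1, 0, 0)])


def test_per_mirna_ranking_and_conservation():
    utrs = [UtrRecord("G1", "AACCCCCCCAATTTTTTTAA")]
    muts = [PointMutation("G1", 5, "C", "T")]
    c_mirna = _mirna("mir-c", "CCCCCCC")  # no admissible site anywhere
    ranking = per_mirna_delta_b(utrs, muts, [G_MIRNA, A_MIRNA, c_mirna], 21, mode="strict")
    by_id = {r.mirna_id: r for r in ranking}
    assert ranking[0].mirna_id == "mir-g"
    assert by_id["mir-g"].delta_b == 1
    assert by_id["mir-c"].delta_b == 0
    assert by_id["mir-c"].sites_wt == 0
    total = sum(r.delta_b for r in ranking)
    assert total == sum(r.sites_wt for r in ranking) - sum(r.sites_mut for r in ranking)
    assert by_id["mir-g"].rank == 1.0
    assert by_id["mir-a"].rank == by_id["mir-c"].rank == 2.5  # tied at 0


def test_consensus_single_table_is_identity():
    t = pd.DataFrame({"mirna_id": ["a", "b", "c"], "rank": [1.0, 2.0, 3.0]})
    out = consensus_rank([t])
    assert list(out["mirna_id"]) == ["a", "b", "c"]


def test_consensus_reversed_rankings_fully_tie():
    n = 5
    ids = [f"m{i}" for i in range(n)]
    t1 = pd.DataFrame({"mirna_id": ids, "rank": np.arange(1, n + 1, dtype=float)})
    t2 = pd.DataFrame({"mirna_id": ids, "rank": np.arange(n, 0, -1, dtype=float)})
    out = consensus_rank([t1, t2])
    assert (out["consensus_score"] == n + 1).all()
    assert (out["consensus_rank"] == out["consensus_rank"].iloc[0]).all()


def test_consensus_three_tables_hand_computed():
    ids = list("abcde")
    r1 = [1, 2, 3, 4, 5]
    r2 = [2, 1, 4, 3, 5]
    r3 = [1, 3, 2, 5, 4]
    tables = [
        pd.DataFrame({"mirna_id": ids, "rank": list(map(float, r))}) for r in (r1, r2, r3)
    ]
    out = consensus_rank(tables).set_index("mirna_id")
    expected = {i: a + b + c for i, a, b, c in zip(ids, r1, r2, r3)}
    for mid, score in expected.items():
        assert out.loc[mid, "consensus_score"] == score
    assert list(consensus_rank(tables)["mirna_id"])[0] == "a"  # lowest sum (4)


def test_consensus_missing_entries_get_worst_rank_plus_one():
    t1 = pd.DataFrame({"mirna_id": ["a", "b"], "rank": [1.0, 2.0]})
    t2 = pd.DataFrame({"mirna_id": ["a", "b", "c"], "rank": [1.0, 2.0, 3.0]})
    out = consensus_rank([t1, t2]).set_index("mirna_id")
    assert out.loc["c", "rank_0"] == 3.0  # 2 (worst) + 1
    with pytest.raises(InputError):
        consensus_rank([])


def test_subset_mirnas():
    mirnas = [G_MIRNA, A_MIRNA]
    assert subset_mirnas(mirnas, ["mir-g", "mir-a"]) == mirnas
    assert subset_mirnas(mirnas, ["mir-a", "mir-zzz"]) == [A_MIRNA]
    with pytest.raises(InputError):
        subset_mirnas(mirnas, ["nope"])
    with pytest.raises(InputError):
        subset_mirnas(mirnas, [])


def test_imported_predictions_contract():
    df = pd.DataFrame(
        {
            "gene_id": ["g1"] * 4,
            "mirna_id": ["m1", "m1", "m2", "m2"],
            "threshold": [1, 2, 1, 2],
            "sites": [3, 1, 2, 2],
            "sequence": ["wt"] * 4,
        }
    )
    pred = ImportedPredictions("toy", df)
    ranking = pred.mirna_delta_ranking(1)
    assert list(ranking["mirna_id"]) == ["m1", "m2"]  # 3 wt sites beats 2
    bad = df.copy()
    bad.loc[1, "sites"] = 9  # binding grows with stringency: invalid
    with pytest.raises(InputError, match="monotone"):
        ImportedPredictions("toy", bad)


def test_imported_predictions_wt_mut_delta():
    df = pd.DataFrame(
        {
            "gene_id": ["g1"] * 4,
            "mirna_id": ["m1", "m1", "m2", "m2"],
            "threshold": [1] * 4,
            "sites": [5, 1, 2, 2],
            "sequence": ["wt", "mut", "wt", "mut"],
        }
    )
    ranking = ImportedPredictions("toy", df).mirna_delta_ranking(1).set_index("mirna_id")
    assert ranking.loc["m1", "delta_b"] == 4
    assert ranking.loc["m2", "delta_b"] == 0
    assert ranking.loc["m1", "rank"] == 1.0
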