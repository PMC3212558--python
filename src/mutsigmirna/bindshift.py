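"""The delta-b binding-shift statistic and miRNA rankings.

For a set of genes carrying 3'UTR point mutations, each gene's predicted
miRNA binding is computed on the wild-type and on the mutated sequence at a
sweep of binding thresholds.  At each threshold

    delta_b = (# genes with more miRNAs bound to the wild type)
            - (# genes with more miRNAs bound to the mutant),

normalized by the number of mutated genes.  A positive delta_b across the
sweep means the mutation set globally removes predicted binding.  Two
significance summaries are provided: a paired t-test pairing the
(wt_more, mut_more) counts across thresholds, and an exact two-sided
binomial sign test per threshold (ties excluded).  The threshold rows of the
sweep are not independent samples, so the per-threshold sign test is the
more conservative read; both are always reported.

miRNAs are ranked by their own site-count difference (wild-type sites minus
mutant sites, summed over mutated genes), and rankings from independent
prediction programs are aggregated by rank sums into a consensus order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .mutmodel import PointMutation, apply_mutations, group_by_gene
from .seedscan import (
    DEFAULT_WEIGHTS,
    MatureMiRNA,
    SeedWeights,
    UtrRecord,
    site_count_sweep,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = list(range(14, 22))  # fully-paired 7-mer, min..max H-bonds


@dataclass(frozen=True)
class DeltaBRow:
    """Gene-level binding-shift tally at one threshold."""

    threshold: int
    n_wt_more: int
    n_mut_more: int
    n_tied: int

    @property
    def n_genes(self) -> int:
        return self.n_wt_more + self.n_mut_more + self.n_tied

    @property
    def delta_b(self) -> int:
        return self.n_wt_more - self.n_mut_more

    @property
    def normalized(self) -> float:
        if self.n_genes == 0:
            return 0.0
        return self.delta_b / self.n_genes


@dataclass(frozen=True)
class MirnaDeltaB:
    """Per-miRNA site-count difference between wild-type and mutant UTRs."""

    mirna_id: str
    sites_wt: int
    sites_mut: int
    rank: float

    @property
    def delta_b(self) -> int:
        return self.sites_wt - self.sites_mut


def _mutated_pairs(
    utrs: list[UtrRecord], mutations: list[PointMutation]
) -> tuple[list[UtrRecord], list[UtrRecord]]:
    """Wild-type and mutated UtrRecords for every gene carrying a mutation."""
    by_id = {u.gene_id: u for u in utrs}
    wt: list[UtrRecord] = []
    mut: list[UtrRecord] = []
    for gene_id, muts in group_by_gene(mutations).items():
        if gene_id not in by_id:
            raise InputError(f"mutation references unknown gene {gene_id!r}")
        wt.append(by_id[gene_id])
        mut.append(apply_mutations(by_id[gene_id], muts))
    return wt, mut


def _aggregate(counts: np.ndarray, counting: str) -> np.ndarray:
    if counting == "distinct_mirnas":
        return (counts > 0).sum(axis=1)
    if counting == "total_sites":
        return counts.sum(axis=1)
    raise InputError(f"unknown counting mode {counting!r}")


def delta_b_sweep(
    utrs: list[UtrRecord],
    mutations: list[PointMutation],
    mirnas: list[MatureMiRNA],
    thresholds: list[int] | None = None,
    weights: SeedWeights = DEFAULT_WEIGHTS,
    mode: str = "lenient",
    counting: str = "distinct_mirnas",
) -> list[DeltaBRow]:
    """Tally wt_more / mut_more / tied genes at each threshold.

    Only genes carrying at least one mutation enter the tally; a mutated
    gene whose binding is unchanged at a threshold counts as tied.  An
    empty mutation list yields all-zero rows (wild type and mutant are
    identical, so delta_b is 0 by construction).
    """
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    if not thresholds:
        raise InputError("at least one threshold required")
    if not mutations:
        return [DeltaBRow(t, 0, 0, 0) for t in thresholds]
    wt, mut = _mutated_pairs(utrs, mutations)
    wt_counts = site_count_sweep(wt, mirnas, thresholds, weights, mode)
    mut_counts = site_count_sweep(mut, mirnas, thresholds, weights, mode)
    rows = []
    for t in thresholds:
        a = _aggregate(wt_counts[t], counting)
        b = _aggregate(mut_counts[t], counting)
        rows.append(
            DeltaBRow(
                threshold=t,
                n_wt_more=int((a > b).sum()),
                n_mut_more=int((b > a).sum()),
                n_tied=int((a == b).sum()),
            )
        )
    return rows


@dataclass(frozen=True)
class SignificanceResult:
    t_stat: float
    p_paired_t: float
    sign_p: list[float]  # per threshold, ties excluded
    all_tied: bool = False


def significance(rows: list[DeltaBRow]) -> SignificanceResult:
    """Paired t-test across thresholds plus per-threshold exact sign tests.

    The t-test pairs (n_wt_more, n_mut_more) over the sweep.  When every
    gene is tied at every threshold the statistic is undefined and p = 1 is
    returned with ``all_tied`` set.  The sign test at one threshold treats
    each untied gene as a Bernoulli trial with null probability 1/2.
    """
    if len(rows) < 2:
        raise InputError("paired t-test needs at least two thresholds")
    wt = np.array([r.n_wt_more for r in rows], dtype=float)
    mu = np.array([r.n_mut_more for r in rows], dtype=float)
    sign_p = []
    for r in rows:
        n = r.n_wt_more + r.n_mut_more
        if n == 0:
            sign_p.append(1.0)
        else:
            sign_p.append(float(stats.binomtest(r.n_wt_more, n, 0.5).pvalue))
    if np.all(wt == mu):
        return SignificanceResult(0.0, 1.0, sign_p, all_tied=True)
    t_stat, p = stats.ttest_rel(wt, mu)
    if np.isnan(p):  # zero-variance differences
        return SignificanceResult(float(t_stat) if np.isfinite(t_stat) else 0.0, 1.0, sign_p)
    return SignificanceResult(float(t_stat), float(p), sign_p)


def per_mirna_delta_b(
    utrs: list[UtrRecord],
    mutations: list[PointMutation],
    mirnas: list[MatureMiRNA],
    threshold: int,
    weights: SeedWeights = DEFAULT_WEIGHTS,
    mode: str = "lenient",
) -> list[MirnaDeltaB]:
    """Rank miRNAs by lost binding: wild-type sites minus mutant sites.

    Site counts are totals over all mutated genes.  The list is sorted by
    descending delta_b (most wild-type-preferring first); tied values share
    their average 1-based rank.
    """
    if not mutations:
        raise InputError("per-miRNA delta_b requires at least one mutation")
    wt, mut = _mutated_pairs(utrs, mutations)
    wt_counts = site_count_sweep(wt, mirnas, [threshold], weights, mode)[threshold]
    mut_counts = site_count_sweep(mut, mirnas, [threshold], weights, mode)[threshold]
    sites_wt = wt_counts.sum(axis=0)
    sites_mut = mut_counts.sum(axis=0)
    delta = sites_wt - sites_mut
    ranks = pd.Series(delta).rank(ascending=False, method="average")
    rows = [
        MirnaDeltaB(m.id, int(sites_wt[j]), int(sites_mut[j]), float(ranks[j]))
        for j, m in enumerate(mirnas)
    ]
    rows.sort(key=lambda r: (-r.delta_b, r.mirna_id))
    return rows


def _as_rank_series(table) -> pd.Series:
    """Normalize a per-program ranking into a mirna_id -> rank Series."""
    if isinstance(table, pd.DataFrame):
        if not {"mirna_id", "rank"} <= set(table.columns):
            raise InputError("ranking table needs 'mirna_id' and 'rank' columns")
        return table.set_index("mirna_id")["rank"].astype(float)
    # list of MirnaDeltaB (or anything exposing .mirna_id / .rank)
    return pd.Series({r.mirna_id: float(r.rank) for r in table})


def consensus_rank(tables: list) -> pd.DataFrame:
    """Aggregate per-program miRNA rankings by rank sums.

    Tables are joined on the union of miRNA ids; a miRNA missing from one
    table receives that table's worst rank + 1 (logged).  The consensus
    score is the sum of per-table ranks, lowest (most wild-type-preferring)
    first; ties are broken by id for determinism.
    """
    if not tables:
        raise InputError("consensus_rank requires at least one ranking table")
    series = [_as_rank_series(t) for t in tables]
    universe = sorted(set().union(*(s.index for s in series)))
    filled = []
    for i, s in enumerate(series):
        missing = set(universe) - set(s.index)
        if missing:
            logger.info("ranking table %d: %d miRNA(s) missing, assigned worst rank + 1", i, len(missing))
        filled.append(s.reindex(universe).fillna(s.max() + 1.0))
    score = sum(filled)
    out = pd.DataFrame({"mirna_id": universe, "consensus_score": score.values})
    for i, s in enumerate(filled):
        out[f"rank_{i}"] = s.values
    out = out.sort_values(["consensus_score", "mirna_id"]).reset_index(drop=True)
    out["consensus_rank"] = out["consensus_score"].rank(method="average")
    return out


def subset_mirnas(mirnas: list[MatureMiRNA], id_list: list[str]) -> list[MatureMiRNA]:
    """Restrict a miRNA set to the given ids, preserving input order."""
    if not id_list:
        raise InputError("empty miRNA id list")
    wanted = set(id_list)
    kept = [m for m in mirnas if m.id in wanted]
    unknown = wanted - {m.id for m in mirnas}
    if unknown:
        logger.info("subset_mirnas: %d id(s) not in the miRNA set", len(unknown))
    if not kept:
        raise InputError("miRNA id list has no overlap with the miRNA set")
    return kept


@dataclass
class ImportedPredictions:
    """Normalized external-program prediction table.

    One row per (gene_id, mirna_id, threshold) with a ``sites`` count (a
    ``bound`` 0/1 indicator is accepted and treated as a count) and an
    optional ``sequence`` column in {wt, mut} distinguishing predictions on
    wild-type vs mutated inputs.  External programs are consumed through
    this interface only, never re-run here.
    """

    program: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        cols = set(self.table.columns)
        if "sites" not in cols and "bound" in cols:
            self.table = self.table.rename(columns={"bound": "sites"})
            cols = set(self.table.columns)
        if not {"gene_id", "mirna_id", "threshold", "sites"} <= cols:
            raise InputError(
                f"{self.program}: prediction table needs gene_id, mirna_id, threshold, sites/bound"
            )
        if "sequence" not in cols:
            self.table = self.table.assign(sequence="wt")
        # stringency check: the bound set must shrink as threshold grows
        tot = self.table.groupby("threshold")["sites"].sum().sort_index()
        if not tot.is_monotonic_decreasing:
            raise InputError(f"{self.program}: site totals not monotone in threshold")

    def mirna_delta_ranking(self, threshold: int) -> pd.DataFrame:
        """Per-miRNA (wt - mut) site difference and rank at one threshold."""
        sub = self.table[self.table["threshold"] == threshold]
        if sub.empty:
            raise InputError(f"{self.program}: no predictions at threshold {threshold}")
        pivot = (
            sub.groupby(["mirna_id", "sequence"])["sites"].sum().unstack(fill_value=0)
        )
        wt = pivot.get("wt", pd.Series(0, index=pivot.index))
        mut = pivot.get("mut", pd.Series(0, index=pivot.index))
        delta = (wt - mut).astype(float)
        out = pd.DataFrame({"mirna_id": delta.index, "delta_b": delta.values})
        out["rank"] = out["delta_b"].rank(ascending=False, method="average")
        return out.sort_values(["rank", "mirna_id"]).reset_index(drop=True)
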