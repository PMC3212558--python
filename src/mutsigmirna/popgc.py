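"""GC/AT composition of alleles called at SNP sites, compared across populations.

Every diploid genotype call contributes its two alleles, each classified as
Strong (G/C) or Weak (A/T).  Calls are filtered by a minimum read depth (DP)
and optionally restricted to genomic intervals (e.g. 3'UTRs, or predicted
miRNA target sites partitioned into a focal miRNA set vs the rest).  Two
populations are compared with a Pearson chi-square test on the 2x2
Strong/Weak allele-count table; a common-SNP mode restricts both populations
to the sites segregating in both.

The per-call-allele tally is the default ("%GC" over contributed alleles);
an alternative per-site mode counts each distinct allele observed at a site
once, for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)

STRONG_BASES = frozenset("GC")

CALL_COLUMNS = ["chrom", "pos", "sample", "allele1", "allele2", "dp"]


@dataclass
class SnpCallSet:
    """Per-individual genotype calls with read depth for one population.

    ``calls`` columns: chrom, pos (1-based), sample, allele1, allele2,
    dp (supporting read depth, >= 0).
    """

    population: str
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(CALL_COLUMNS) - set(self.calls.columns)
        if missing:
            raise InputError(f"{self.population}: call table missing columns {sorted(missing)}")
        for col in ("allele1", "allele2"):
            bad = ~self.calls[col].isin(list("ACGT"))
            if bad.any():
                raise InputError(f"{self.population}: invalid base in column {col}")
        if (self.calls["dp"] < 0).any():
            raise InputError(f"{self.population}: negative read depth")

    @property
    def sites(self) -> pd.DataFrame:
        return self.calls[["chrom", "pos"]].drop_duplicates()

    def restrict_sites(self, keep: pd.DataFrame) -> "SnpCallSet":
        """Return a copy keeping only calls at the given (chrom, pos) sites."""
        merged = self.calls.merge(keep[["chrom", "pos"]].drop_duplicates(), on=["chrom", "pos"])
        return SnpCallSet(self.population, merged.reset_index(drop=True))


@dataclass(frozen=True)
class GcCompositionResult:
    """Strong/Weak allele tallies for one population under one filter."""

    population: str
    dp_min: int
    n_snps: int
    n_calls: int
    gc_alleles: int
    at_alleles: int

    @property
    def n_alleles(self) -> int:
        return self.gc_alleles + self.at_alleles

    @property
    def pct_gc(self) -> float:
        return 100.0 * self.gc_alleles / self.n_alleles

    @property
    def pct_at(self) -> float:
        return 100.0 * self.at_alleles / self.n_alleles


@dataclass
class TargetIntervalSet:
    """BED-style intervals (0-based half-open) annotated with a miRNA id."""

    intervals: pd.DataFrame  # columns: chrom, start, end, mirna_id

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "mirna_id"}
        if not need <= set(self.intervals.columns):
            raise InputError(f"target intervals need columns {sorted(need)}")
        if (self.intervals["start"] >= self.intervals["end"]).any():
            raise InputError("target interval with start >= end")


def _interval_trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in intervals.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), d) for s, e, d in zip(sub["start"], sub["end"], sub.get("mirna_id", sub["start"]))
        )
    return trees


def _in_regions(calls: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Boolean mask of calls whose site lies in any region (pos is 1-based)."""
    trees = _interval_trees(regions)
    mask = np.zeros(len(calls), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(calls["chrom"].values, calls["pos"].values)):
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps(int(pos) - 1):
            mask[i] = True
    return mask


def gc_composition(
    calls: SnpCallSet,
    dp_min: int = 0,
    regions: pd.DataFrame | None = None,
    allele_mode: str = "per-call",
) -> GcCompositionResult:
    """Tally Strong (G/C) vs Weak (A/T) alleles over passing genotype calls.

    A call passes when its DP >= ``dp_min``; with ``regions`` given, only
    sites inside an interval count.  In the default ``per-call`` mode each
    passing call contributes both genotype alleles; ``per-site`` counts each
    distinct allele observed at a site once.
    """
    if dp_min < 0:
        raise InputError("dp_min must be >= 0")
    df = calls.calls
    passing = df[df["dp"] >= dp_min]
    if regions is not None:
        passing = passing[_in_regions(passing, regions)]
    if passing.empty:
        raise InputError(
            f"{calls.population}: no calls pass dp_min={dp_min}"
            + ("" if regions is None else " within the given regions")
        )
    n_snps = len(passing[["chrom", "pos"]].drop_duplicates())
    n_calls = len(passing)
    if allele_mode == "per-call":
        alleles = pd.concat([passing["allele1"], passing["allele2"]])
        gc = int(alleles.isin(list(STRONG_BASES)).sum())
        total = len(alleles)
    elif allele_mode == "per-site":
        long = pd.concat(
            [
                passing[["chrom", "pos", "allele1"]].rename(columns={"allele1": "allele"}),
                passing[["chrom", "pos", "allele2"]].rename(columns={"allele2": "allele"}),
            ]
        ).drop_duplicates()
        gc = int(long["allele"].isin(list(STRONG_BASES)).sum())
        total = len(long)
    else:
        raise InputError(f"unknown allele mode {allele_mode!r}")
    return GcCompositionResult(
        population=calls.population,
        dp_min=dp_min,
        n_snps=n_snps,
        n_calls=n_calls,
        gc_alleles=gc,
        at_alleles=total - gc,
    )


def partition_by_targets(
    calls: SnpCallSet,
    targets: TargetIntervalSet,
    melanoma_ids: list[str],
) -> tuple[SnpCallSet, SnpCallSet]:
    """Split calls into (focal-miRNA target sites, other-miRNA target sites).

    A SNP inside at least one interval of a listed (focal) miRNA goes to the
    first set; SNPs only inside other miRNAs' intervals go to the second;
    SNPs in no target interval are excluded.  Focal membership takes
    precedence when a SNP lies in both kinds of interval (counted, logged).
    """
    if targets.intervals.empty:
        raise InputError("empty target interval set")
    if not melanoma_ids:
        raise InputError("focal miRNA id list is empty")
    focal = set(melanoma_ids)
    trees = _interval_trees(targets.intervals)
    sites = calls.sites
    mel_rows, other_rows = [], []
    n_both = 0
    for chrom, pos in zip(sites["chrom"].values, sites["pos"].values):
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = {iv.data for iv in tree.at(int(pos) - 1)}
        if not hits:
            continue
        in_focal = bool(hits & focal)
        in_other = bool(hits - focal)
        if in_focal and in_other:
            n_both += 1
        (mel_rows if in_focal else other_rows).append((chrom, pos))
    if n_both:
        logger.info("partition_by_targets: %d site(s) in both focal and other intervals (focal wins)", n_both)
    mel = pd.DataFrame(mel_rows, columns=["chrom", "pos"])
    oth = pd.DataFrame(other_rows, columns=["chrom", "pos"])
    return calls.restrict_sites(mel), calls.restrict_sites(oth)


def common_snps(a: SnpCallSet, b: SnpCallSet) -> tuple[SnpCallSet, SnpCallSet]:
    """Restrict both populations to SNP sites present in both."""
    shared = a.sites.merge(b.sites, on=["chrom", "pos"])
    if shared.empty:
        raise InputError("no SNP sites shared between the two populations")
    return a.restrict_sites(shared), b.restrict_sites(shared)


@dataclass(frozen=True)
class PopulationComparison:
    chi2: float
    p_value: float
    test: str  # "chi-square" or "fisher-exact"


def compare_populations(
    r1: GcCompositionResult, r2: GcCompositionResult
) -> PopulationComparison:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2
    Strong/Weak allele table; falls back to Fisher's exact test when a cell
    is zero."""
    table = np.array(
        [[r1.gc_alleles, r1.at_alleles], [r2.gc_alleles, r2.at_alleles]], dtype=np.int64
    )
    if (table == 0).any():
        _, p = stats.fisher_exact(table)
        logger.warning("zero cell in 2x2 table; Fisher's exact test used")
        return PopulationComparison(float("nan"), float(p), "fisher-exact")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return PopulationComparison(float(chi2), float(p), "chi-square")


def sequence_composition(seqs: list[str], region: str = "full") -> dict[str, float]:
    """Pooled base fractions of a sequence set (T and U tallied together).

    ``region='seed'`` restricts each sequence to nucleotides 2-8 (1-based),
    the miRNA seed.  Returns fractions for A, C, G, T/U plus the pooled GC
    fraction.
    """
    if not seqs:
        raise InputError("empty sequence set")
    if region not in ("full", "seed"):
        raise InputError(f"unknown region {region!r}")
    counts = {"A": 0, "C": 0, "G": 0, "T/U": 0}
    for s in seqs:
        s = s[1:8] if region == "seed" else s
        for b in s:
            if b in "TU":
                counts["T/U"] += 1
            elif b in counts:
                counts[b] += 1
            else:
                raise InputError(f"invalid base {b!r} in sequence")
    total = sum(counts.values())
    if total == 0:
        raise InputError("sequence set contains no bases in the requested region")
    out = {k: v / total for k, v in counts.items()}
    out["GC"] = out["C"] + out["G"]
    return out
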