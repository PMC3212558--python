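"""Seed-match scanning by counted hydrogen bonds.

A mature miRNA recognises a target mainly through its seed (nucleotides 2-8,
1-based, of the mature sequence).  This module scores every 7-nt window of a
3'UTR against a seed by summing the hydrogen bonds of the base pairs the
antiparallel RNA:mRNA duplex would form: a Watson-Crick G:C pair contributes
3 bonds, A:U(T) contributes 2, and the G-U wobble (seed G over UTR T, or seed
U over UTR G) contributes 2.  Positions that form no legal pair contribute
nothing.  A window is a predicted binding site when its summed bonds reach a
threshold; *strict* mode additionally requires all 7 positions to pair.

Scoring is table-driven so the weights can be altered, e.g. the equal-weight
ablation (``wc_gc = 2``) that removes the thermodynamic advantage of G:C
pairs while leaving the pairing geometry untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

logger = logging.getLogger(__name__)

SEED_LENGTH = 7

_DNA_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_RNA_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def encode_dna(seq: str) -> np.ndarray:
    """Encode a DNA string (A,C,G,T) as uint8 codes 0..3."""
    try:
        return np.array([_DNA_CODE[b] for b in seq], dtype=np.uint8)
    except KeyError as exc:
        raise InputError(f"invalid DNA base {exc.args[0]!r} in sequence") from None


def encode_rna(seq: str) -> np.ndarray:
    """Encode an RNA string (A,C,G,U) as uint8 codes 0..3."""
    try:
        return np.array([_RNA_CODE[b] for b in seq], dtype=np.uint8)
    except KeyError as exc:
        raise InputError(f"invalid RNA base {exc.args[0]!r} in sequence") from None


@dataclass(frozen=True)
class SeedWeights:
    """Hydrogen-bond weights per base-pair class.

    ``wc_gc`` is the weight of a Watson-Crick G:C pair (3 H-bonds), ``wc_au``
    of an A:U(T) pair (2 H-bonds), ``wobble`` of the G-U wobble pair (2
    H-bonds chemically).  Mismatched positions always score 0.
    """

    wc_gc: int = 3
    wc_au: int = 2
    wobble: int = 2

    def __post_init__(self) -> None:
        if min(self.wc_gc, self.wc_au, self.wobble) < 0:
            raise InputError("seed weights must be non-negative")

    @classmethod
    def equal(cls) -> "SeedWeights":
        """The GC-ablation weighting: every legal pair counts 2 bonds."""
        return cls(wc_gc=2, wc_au=2, wobble=2)

    def matrix(self) -> np.ndarray:
        """4x4 weight lookup, rows = seed (RNA) base, cols = UTR (DNA) base."""
        w = np.zeros((4, 4), dtype=np.int64)
        w[_RNA_CODE["G"], _DNA_CODE["C"]] = self.wc_gc
        w[_RNA_CODE["C"], _DNA_CODE["G"]] = self.wc_gc
        w[_RNA_CODE["A"], _DNA_CODE["T"]] = self.wc_au
        w[_RNA_CODE["U"], _DNA_CODE["A"]] = self.wc_au
        w[_RNA_CODE["G"], _DNA_CODE["T"]] = self.wobble
        w[_RNA_CODE["U"], _DNA_CODE["G"]] = self.wobble
        return w

    @property
    def max_score(self) -> int:
        return SEED_LENGTH * max(self.wc_gc, self.wc_au, self.wobble)


# Legal-pair indicator (independent of weights): WC pairs plus the G-U wobble.
_PAIRED = np.zeros((4, 4), dtype=np.int64)
_PAIRED[_RNA_CODE["G"], _DNA_CODE["C"]] = 1
_PAIRED[_RNA_CODE["C"], _DNA_CODE["G"]] = 1
_PAIRED[_RNA_CODE["A"], _DNA_CODE["T"]] = 1
_PAIRED[_RNA_CODE["U"], _DNA_CODE["A"]] = 1
_PAIRED[_RNA_CODE["G"], _DNA_CODE["T"]] = 1
_PAIRED[_RNA_CODE["U"], _DNA_CODE["G"]] = 1

DEFAULT_WEIGHTS = SeedWeights()


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence (RNA alphabet, 5'->3') with its seed."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 8:
            raise InputError(f"miRNA {self.id!r}: sequence shorter than 8 nt")
        if set(self.sequence) - set("ACGU"):
            raise InputError(f"miRNA {self.id!r}: non-RNA characters in sequence")

    @property
    def seed(self) -> str:
        """Nucleotides 2-8 (1-based) of the mature sequence."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class UtrRecord:
    """A gene's 3'UTR sequence (DNA, sense strand of the mRNA, 5'->3')."""

    gene_id: str
    sequence: str
    chrom: str | None = None
    start: int | None = None  # 0-based genomic anchor
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"UTR {self.gene_id!r}: empty sequence")
        if set(self.sequence) - set("ACGT"):
            raise InputError(f"UTR {self.gene_id!r}: non-ACGT characters in sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingSite:
    """One predicted seed-match site: a 7-nt UTR window [offset, offset+7)."""

    gene_id: str
    mirna_id: str
    offset: int
    score: int
    n_paired: int


def hbond_score(
    seed: str, window: str, weights: SeedWeights = DEFAULT_WEIGHTS
) -> tuple[int, int]:
    """Score one seed against one 7-nt UTR window.

    The duplex is antiparallel: seed position i (0-based, 5'->3') pairs with
    window position 6-i.  Returns ``(score, n_paired)`` where score is the
    summed hydrogen bonds and n_paired the number of positions forming a
    legal (WC or wobble) pair.
    """
    if len(seed) != SEED_LENGTH or len(window) != SEED_LENGTH:
        raise InputError("seed and window must both be 7 nt")
    s = encode_rna(seed)
    w = encode_dna(window)
    wrev = w[::-1]
    wm = weights.matrix()
    score = int(wm[s, wrev].sum())
    n_paired = int(_PAIRED[s, wrev].sum())
    return score, n_paired


def score_profile(
    seed_codes: np.ndarray, utr_codes: np.ndarray, weights: SeedWeights
) -> tuple[np.ndarray, np.ndarray]:
    """Score every 7-nt window of a UTR against one or more seeds.

    ``seed_codes`` is (n_seeds, 7) RNA codes, ``utr_codes`` (L,) DNA codes.
    Returns ``(scores, n_paired)``, each (n_seeds, L-6).  The core loop runs
    over the 7 seed positions only; windows and seeds are vectorised.
    """
    if seed_codes.ndim == 1:
        seed_codes = seed_codes[None, :]
    n_windows = utr_codes.size - SEED_LENGTH + 1
    if n_windows <= 0:
        return (
            np.zeros((seed_codes.shape[0], 0), dtype=np.int64),
            np.zeros((seed_codes.shape[0], 0), dtype=np.int64),
        )
    wm = weights.matrix()
    scores = np.zeros((seed_codes.shape[0], n_windows), dtype=np.int64)
    paired = np.zeros_like(scores)
    for i in range(SEED_LENGTH):
        utr_slice = utr_codes[SEED_LENGTH - 1 - i : SEED_LENGTH - 1 - i + n_windows]
        scores += wm[seed_codes[:, i]][:, utr_slice]
        paired += _PAIRED[seed_codes[:, i]][:, utr_slice]
    return scores, paired


def _admissible(scores: np.ndarray, paired: np.ndarray, threshold: int, mode: str) -> np.ndarray:
    if mode not in ("strict", "lenient"):
        raise InputError(f"unknown scan mode {mode!r}")
    ok = scores >= threshold
    if mode == "strict":
        ok &= paired == SEED_LENGTH
    return ok


def scan_sites(
    mirna: MatureMiRNA,
    utr: UtrRecord,
    threshold: int,
    weights: SeedWeights = DEFAULT_WEIGHTS,
    mode: str = "lenient",
) -> list[BindingSite]:
    """Enumerate admissible seed-match sites on a UTR, sorted by offset.

    A site is reported when its summed H-bonds reach ``threshold``; strict
    mode additionally requires all 7 positions to pair.  UTRs shorter than
    7 nt yield no sites.
    """
    if threshold < 0:
        raise InputError("threshold must be >= 0")
    if len(utr) < SEED_LENGTH:
        logger.info("UTR %s shorter than 7 nt; no windows to scan", utr.gene_id)
        return []
    scores, paired = score_profile(encode_rna(mirna.seed), encode_dna(utr.sequence), weights)
    ok = _admissible(scores, paired, threshold, mode)[0]
    return [
        BindingSite(utr.gene_id, mirna.id, int(o), int(scores[0, o]), int(paired[0, o]))
        for o in np.nonzero(ok)[0]
    ]


def scan_region(
    mirna: MatureMiRNA,
    utr: UtrRecord,
    threshold: int,
    weights: SeedWeights = DEFAULT_WEIGHTS,
    mode: str = "lenient",
    lo: int = 0,
    hi: int | None = None,
) -> list[BindingSite]:
    """``scan_sites`` restricted to windows overlapping ``[lo, hi)``.

    Used to rescan locally around a mutation: only windows touching the
    changed bases can change.
    """
    if hi is None:
        hi = len(utr)
    if not (0 <= lo <= hi <= len(utr)):
        raise InputError(f"invalid region [{lo}, {hi}) for UTR of length {len(utr)}")
    first = max(0, lo - SEED_LENGTH + 1)
    last = min(len(utr) - SEED_LENGTH, hi - 1)  # inclusive window start bound
    if last < first:
        return []
    sub = UtrRecord(utr.gene_id, utr.sequence[first : last + SEED_LENGTH])
    return [
        BindingSite(s.gene_id, s.mirna_id, s.offset + first, s.score, s.n_paired)
        for s in scan_sites(mirna, sub, threshold, weights, mode)
    ]


@dataclass
class BindingTable:
    """Per-gene, per-miRNA admissible-site counts at one threshold.

    ``counts[i, j]`` is the number of sites of miRNA j on gene i.  The
    per-gene aggregate is either the number of distinct miRNAs with at least
    one site (``distinct_mirnas``) or the summed site count (``total_sites``).
    """

    gene_ids: list[str]
    mirna_ids: list[str]
    counts: np.ndarray
    threshold: int
    counting: str = "distinct_mirnas"
    aggregate: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.counting == "distinct_mirnas":
            self.aggregate = (self.counts > 0).sum(axis=1)
        elif self.counting == "total_sites":
            self.aggregate = self.counts.sum(axis=1)
        else:
            raise InputError(f"unknown counting mode {self.counting!r}")

    def aggregate_for(self, gene_id: str) -> int:
        return int(self.aggregate[self.gene_ids.index(gene_id)])


def site_count_sweep(
    utrs: list[UtrRecord],
    mirnas: list[MatureMiRNA],
    thresholds: list[int],
    weights: SeedWeights = DEFAULT_WEIGHTS,
    mode: str = "lenient",
) -> dict[int, np.ndarray]:
    """Per-(gene, miRNA) site counts at each threshold in one pass.

    Score profiles are computed once per (UTR, miRNA set) pair and reused
    across thresholds, which makes threshold sweeps linear in sequence
    length rather than in sweep size.
    Returns a mapping threshold -> (n_genes, n_mirnas) count matrix.
    """
    if not utrs or not mirnas:
        raise InputError("count_binding requires non-empty UTR and miRNA sets")
    gene_ids = [u.gene_id for u in utrs]
    if len(set(gene_ids)) != len(gene_ids):
        raise InputError("duplicate gene_id in UTR set")
    seed_codes = np.stack([encode_rna(m.seed) for m in mirnas])
    out = {t: np.zeros((len(utrs), len(mirnas)), dtype=np.int64) for t in thresholds}
    for i, utr in enumerate(utrs):
        if len(utr) < SEED_LENGTH:
            logger.info("UTR %s shorter than 7 nt; zero counts", utr.gene_id)
            continue
        scores, paired = score_profile(seed_codes, encode_dna(utr.sequence), weights)
        strict_ok = paired == SEED_LENGTH if mode == "strict" else None
        for t in thresholds:
            ok = scores >= t
            if strict_ok is not None:
                ok = ok & strict_ok
            out[t][i] = ok.sum(axis=1)
    return out


def count_binding(
    utrs: list[UtrRecord],
    mirnas: list[MatureMiRNA],
    threshold: int,
    weights: SeedWeights = DEFAULT_WEIGHTS,
    mode: str = "lenient",
    counting: str = "distinct_mirnas",
) -> BindingTable:
    """Count admissible sites for every (gene, miRNA) pair at one threshold."""
    counts = site_count_sweep(utrs, mirnas, [threshold], weights, mode)[threshold]
    return BindingTable(
        gene_ids=[u.gene_id for u in utrs],
        mirna_ids=[m.id for m in mirnas],
        counts=counts,
        threshold=threshold,
        counting=counting,
    )
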