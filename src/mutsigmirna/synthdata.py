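"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate the real data sources end to end: 3'UTR sets with a
controllable GC content (default 42.4%, the typical 3'UTR composition),
mature miRNA sets whose seeds are GC-enriched (default 50.9% with a 1.2:1
G:C skew, matching the G-over-C excess of real mature miRNAs), somatic
mutation sets drawn from parameterized strand-collapsed substitution
spectra (a UV-like preset with 75% Strong-to-Weak substitutions, and a
balanced preset resembling non-UV malignancies), and two-population diploid
genotype tables with per-call read depths for the SNP composition analysis.

Everything is driven by one integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .mutmodel import COLLAPSED_TYPES, PointMutation, TYPE_CLASS
from .popgc import SnpCallSet
from .seedscan import MatureMiRNA, UtrRecord

import pandas as pd


@dataclass(frozen=True)
class SpectrumPreset:
    """A named probability vector over the six strand-collapsed types."""

    name: str
    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.probabilities) != set(COLLAPSED_TYPES):
            raise InputError(f"preset {self.name!r}: must cover all six collapsed types")
        if abs(sum(self.probabilities.values()) - 1.0) > 1e-9:
            raise InputError(f"preset {self.name!r}: probabilities must sum to 1")

    def class_fractions(self) -> dict[str, float]:
        out = {"S2W": 0.0, "W2S": 0.0, "S2S": 0.0, "W2W": 0.0}
        for k, p in self.probabilities.items():
            out[TYPE_CLASS[k]] += p
        return out


#: UV-like spectrum: 64.5% C>T|G>A and 75% Strong-to-Weak overall, 13.9%
#: Weak-to-Strong.  The split of the remaining mass across minor types is a
#: modelling choice consistent with those aggregates.
MELANOMA_UV = SpectrumPreset(
    "melanoma_uv",
    {
        "C>T|G>A": 0.645,
        "C>A|G>T": 0.105,
        "C>G|G>C": 0.055,
        "T>C|A>G": 0.100,
        "T>G|A>C": 0.039,
        "T>A|A>T": 0.056,
    },
)

#: Balanced spectrum resembling non-UV cancers (lung, AML): 48%
#: Strong-to-Weak, 32% Weak-to-Strong.
BALANCED = SpectrumPreset(
    "balanced",
    {
        "C>T|G>A": 0.24,
        "C>A|G>T": 0.24,
        "C>G|G>C": 0.10,
        "T>C|A>G": 0.16,
        "T>G|A>C": 0.16,
        "T>A|A>T": 0.10,
    },
)

PRESETS = {p.name: p for p in (MELANOMA_UV, BALANCED)}


@dataclass(frozen=True)
class PopulationConfig:
    """One simulated population for the SNP genotype generator."""

    name: str
    s_allele_freq: float
    n_individuals: int = 100
    n_sites: int = 5000
    dp_mean: float = 6.0  # Poisson mean; DP filters at 5/8/11 all bite

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_allele_freq <= 1.0:
            raise InputError(f"{self.name}: s_allele_freq outside [0, 1]")


@dataclass
class SimConfig:
    """Default study conditions for the end-to-end synthetic analysis."""

    n_genes: int = 200
    utr_length: int = 1000
    utr_gc: float = 0.424
    n_mirnas: int = 100
    mirna_length: int = 22
    seed_gc: float = 0.509
    body_gc: float = 0.486  # chosen so whole-miRNA GC ~ 49.3%
    g_to_c_ratio: float = 1.2  # G excess over C among miRNA Strong bases
    n_mutations: int = 300
    spectrum: SpectrumPreset = MELANOMA_UV
    populations: tuple[PopulationConfig, ...] = (
        PopulationConfig("YRI_like", 0.57),
        PopulationConfig("CEU_like", 0.55),
    )
    site_overlap: float = 0.8  # fraction of the site pool each pop reports
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("utr_gc", "seed_gc", "body_gc", "site_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} outside [0, 1]")


def _draw_bases(rng: np.random.Generator, n: int, gc: float, g_to_c: float = 1.0, rna: bool = False) -> np.ndarray:
    """i.i.d. bases with GC fraction ``gc``; G:C ratio ``g_to_c``, A:T(U) even."""
    p_g = gc * g_to_c / (1.0 + g_to_c)
    p_c = gc / (1.0 + g_to_c)
    p_a = p_t = (1.0 - gc) / 2.0
    alphabet = np.array(list("ACGU" if rna else "ACGT"))
    return alphabet[rng.choice(4, size=n, p=[p_a, p_c, p_g, p_t])]


def gen_utrs(config: SimConfig, rng_seed: int | None = None) -> list[UtrRecord]:
    """Generate ``n_genes`` UTRs of i.i.d. bases at the configured GC content."""
    if config.n_genes < 1:
        raise InputError("n_genes must be >= 1")
    rng = np.random.default_rng(config.rng_seed if rng_seed is None else rng_seed)
    out = []
    for i in range(config.n_genes):
        seq = "".join(_draw_bases(rng, config.utr_length, config.utr_gc))
        out.append(UtrRecord(f"gene{i + 1:04d}", seq))
    return out


def gen_mirnas(config: SimConfig, rng_seed: int | None = None) -> list[MatureMiRNA]:
    """Generate mature miRNAs with GC-enriched, G-skewed seeds.

    Seed positions (nt 2-8) are drawn at ``seed_gc`` GC with the configured
    G:C skew; the remaining positions at ``body_gc`` with the same skew.
    """
    if config.n_mirnas < 1:
        raise InputError("n_mirnas must be >= 1")
    if config.mirna_length < 8:
        raise InputError("miRNAs must be at least 8 nt")
    rng = np.random.default_rng(config.rng_seed if rng_seed is None else rng_seed)
    out = []
    for i in range(config.n_mirnas):
        bases = _draw_bases(rng, config.mirna_length, config.body_gc, config.g_to_c_ratio, rna=True)
        bases[1:8] = _draw_bases(rng, 7, config.seed_gc, config.g_to_c_ratio, rna=True)
        out.append(MatureMiRNA(f"mir-{i + 1:04d}", "".join(bases)))
    return out


_TYPE_REPS = {
    key: ((key[0], key[2]), (key[4], key[6]))  # e.g. "C>T|G>A" -> (C,T), (G,A)
    for key in COLLAPSED_TYPES
}


def gen_mutations(
    utrs: list[UtrRecord],
    n: int,
    preset: SpectrumPreset = MELANOMA_UV,
    rng_seed: int = 0,
) -> list[PointMutation]:
    """Draw ``n`` point mutations from a substitution-spectrum preset.

    Each draw picks a collapsed type from the preset, then a uniform
    position among all UTR positions carrying either strand representative
    of that type (e.g. C>T|G>A applies at a C, mutating to T, or at a G,
    mutating to A).  Positions are unique within a gene.
    """
    rng = np.random.default_rng(rng_seed)
    pos_by_base: dict[str, list[tuple[int, int]]] = {b: [] for b in "ACGT"}
    for gi, u in enumerate(utrs):
        for off, b in enumerate(u.sequence):
            pos_by_base[b].append((gi, off))
    used: set[tuple[int, int]] = set()
    type_keys = list(preset.probabilities)
    type_p = np.array([preset.probabilities[k] for k in type_keys])
    out: list[PointMutation] = []
    for _ in range(n):
        key = type_keys[rng.choice(len(type_keys), p=type_p)]
        (ref1, alt1), (ref2, alt2) = _TYPE_REPS[key]
        pool1, pool2 = pos_by_base[ref1], pos_by_base[ref2]
        total = len(pool1) + len(pool2)
        if total == 0:
            raise InputError(f"no eligible positions for type {key}; use longer UTRs")
        for _attempt in range(1000):
            j = int(rng.integers(total))
            gi, off = pool1[j] if j < len(pool1) else pool2[j - len(pool1)]
            if (gi, off) not in used:
                break
        else:
            raise InputError(f"eligible positions exhausted for type {key}; use longer UTRs")
        used.add((gi, off))
        ref, alt = (ref1, alt1) if j < len(pool1) else (ref2, alt2)
        out.append(PointMutation(utrs[gi].gene_id, off, ref, alt))
    return out


def gen_genotypes(
    config: SimConfig, rng_seed: int | None = None
) -> tuple[SnpCallSet, SnpCallSet]:
    """Simulate diploid genotype tables with read depths for two populations.

    Every SNP site has one fixed Strong (G/C) and one fixed Weak (A/T)
    allele; each individual's two alleles are i.i.d. Strong with the
    population's S-allele frequency.  Read depth is Poisson around
    ``dp_mean``.  Each population reports a random subset of a shared site
    pool, so the common-SNP restriction is non-trivial.
    """
    if len(config.populations) != 2:
        raise InputError("exactly two populations expected")
    rng = np.random.default_rng(config.rng_seed if rng_seed is None else rng_seed)
    n_pool = max(p.n_sites for p in config.populations)
    if config.site_overlap < 1.0:
        n_pool = int(np.ceil(n_pool / config.site_overlap))
    pool_pos = np.arange(1, n_pool + 1) * 997  # deterministic spaced coordinates
    strong = rng.choice(np.array(list("GC")), size=n_pool)
    weak = rng.choice(np.array(list("AT")), size=n_pool)

    sets = []
    for pop in config.populations:
        idx = np.sort(rng.choice(n_pool, size=min(pop.n_sites, n_pool), replace=False))
        n_sites, n_ind = idx.size, pop.n_individuals
        is_strong = rng.random((n_sites, n_ind, 2)) < pop.s_allele_freq
        s_bases = np.broadcast_to(strong[idx][:, None, None], is_strong.shape)
        w_bases = np.broadcast_to(weak[idx][:, None, None], is_strong.shape)
        alleles = np.where(is_strong, s_bases, w_bases)
        dp = rng.poisson(pop.dp_mean, size=(n_sites, n_ind))
        calls = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.repeat(pool_pos[idx], n_ind),
                "sample": np.tile([f"{pop.name}_{k:03d}" for k in range(n_ind)], n_sites),
                "allele1": alleles[:, :, 0].reshape(-1),
                "allele2": alleles[:, :, 1].reshape(-1),
                "dp": dp.reshape(-1),
            }
        )
        sets.append(SnpCallSet(pop.name, calls))
    return sets[0], sets[1]


def gen_target_intervals(
    snp_positions,
    mirnas: list[MatureMiRNA],
    rng_seed: int = 0,
    sites_per_mirna: int = 3,
    site_length: int = 7,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Random miRNA target intervals overlapping simulated SNP sites.

    Each miRNA gets ``sites_per_mirna`` 7-nt intervals, each centred on a
    randomly chosen SNP position (1-based), so a subset of SNPs falls within
    predicted target sites — the input the target-partition analysis needs.
    """
    rng = np.random.default_rng(rng_seed)
    positions = np.asarray(sorted(set(int(p) for p in snp_positions)))
    if positions.size == 0:
        raise InputError("no SNP positions to anchor target intervals on")
    rows = []
    for m in mirnas:
        for _ in range(sites_per_mirna):
            pos0 = int(positions[rng.integers(positions.size)]) - 1  # 0-based
            start = max(0, pos0 - int(rng.integers(site_length)))
            rows.append((chrom, start, start + site_length, m.id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mirna_id"])
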