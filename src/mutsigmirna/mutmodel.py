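"""Somatic point mutations: classification, spectra, application, nulls.

Substitutions are classified thermodynamically by the hydrogen-bond count of
the bases involved: G and C are Strong (3 H-bonds in a Watson-Crick pair),
A and T Weak (2).  A C>T transition — the canonical UV lesion — is therefore
Strong-to-Weak (S2W).  Spectra are tallied over the six strand-collapsed
substitution types (C>T counted together with its reverse-complement G>A,
and so on), the standard convention for mutation signatures.

Three *in silico* randomization schemes generate null mutation sets against
which the observed binding shift is compared:

``random_any``
    new uniform position within the same gene's UTR, uniform alt allele —
    destroys both position and substitution type.
``same_type``
    keeps each (ref, alt) pair but relocates it to a uniform position in the
    same UTR carrying the ref base — preserves the spectrum exactly.
``same_position``
    keeps each position but redraws the alt allele uniformly from the three
    non-reference bases — preserves positions exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import InputError
from .seedscan import UtrRecord

logger = logging.getLogger(__name__)

STRONG = frozenset("GC")
WEAK = frozenset("AT")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The six strand-collapsed substitution types, pyrimidine representative first.
COLLAPSED_TYPES = (
    "C>T|G>A",
    "C>A|G>T",
    "C>G|G>C",
    "T>C|A>G",
    "T>A|A>T",
    "T>G|A>C",
)

#: Strong/Weak transition class of each collapsed type.
TYPE_CLASS = {
    "C>T|G>A": "S2W",
    "C>A|G>T": "S2W",
    "C>G|G>C": "S2S",
    "T>C|A>G": "W2S",
    "T>A|A>T": "W2W",
    "T>G|A>C": "W2S",
}


class SubstitutionClass(str, Enum):
    S2W = "S2W"
    W2S = "W2S"
    S2S = "S2S"
    W2W = "W2W"


@dataclass(frozen=True)
class PointMutation:
    """A single-nucleotide substitution addressed in UTR space (0-based)."""

    gene_id: str
    offset: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in "ACGT" or self.alt not in "ACGT" or len(self.ref) != 1 or len(self.alt) != 1:
            raise InputError(f"{self.gene_id}@{self.offset}: bases must be single A/C/G/T")
        if self.ref == self.alt:
            raise InputError(f"{self.gene_id}@{self.offset}: ref and alt are identical")
        if self.offset < 0:
            raise InputError(f"{self.gene_id}: negative offset {self.offset}")


def classify_substitution(ref: str, alt: str) -> SubstitutionClass:
    """Classify a substitution as S2W/W2S/S2S/W2W by base strength."""
    if ref not in "ACGT" or alt not in "ACGT":
        raise InputError(f"invalid bases {ref!r}>{alt!r}")
    if ref == alt:
        raise InputError("ref and alt are identical")
    a = "S" if ref in STRONG else "W"
    b = "S" if alt in STRONG else "W"
    return SubstitutionClass(f"{a}2{b}")


def collapse_type(ref: str, alt: str) -> str:
    """Map (ref, alt) to its strand-collapsed type key.

    Substitutions whose reference base is a purine are re-expressed on the
    opposite strand (complementing both alleles) so every substitution falls
    in one of the six pyrimidine-first classes.
    """
    if ref in "GA":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    key_head = f"{ref}>{alt}"
    for key in COLLAPSED_TYPES:
        if key.startswith(key_head):
            return key
    raise InputError(f"cannot collapse substitution {ref}>{alt}")


@dataclass
class MutationSpectrum:
    """Counts and fractions over the six strand-collapsed substitution types."""

    counts: dict[str, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        total = self.n
        return {k: self.counts.get(k, 0) / total for k in COLLAPSED_TYPES}

    @property
    def class_fractions(self) -> dict[str, float]:
        """Fractions of the four S/W transition classes (sum to 1)."""
        out = {"S2W": 0.0, "W2S": 0.0, "S2S": 0.0, "W2W": 0.0}
        for key, frac in self.fractions.items():
            out[TYPE_CLASS[key]] += frac
        return out


def spectrum(mutations: list[PointMutation]) -> MutationSpectrum:
    """Tally a mutation list into a strand-collapsed spectrum."""
    if not mutations:
        raise InputError("cannot compute a spectrum of zero mutations")
    counts = {k: 0 for k in COLLAPSED_TYPES}
    for m in mutations:
        counts[collapse_type(m.ref, m.alt)] += 1
    return MutationSpectrum(counts)


def apply_mutations(utr: UtrRecord, muts: list[PointMutation]) -> UtrRecord:
    """Return a copy of the UTR with every mutation applied.

    Each mutation's ref allele is checked against the sequence; offsets must
    be unique so the result is order-independent.
    """
    seq = list(utr.sequence)
    seen: set[int] = set()
    for m in muts:
        if m.gene_id != utr.gene_id:
            raise InputError(f"mutation gene {m.gene_id!r} does not match UTR {utr.gene_id!r}")
        if m.offset >= len(seq):
            raise InputError(f"{utr.gene_id}@{m.offset}: offset beyond UTR of length {len(seq)}")
        if m.offset in seen:
            raise InputError(f"{utr.gene_id}@{m.offset}: duplicate mutation offset")
        if seq[m.offset] != m.ref:
            raise InputError(
                f"{utr.gene_id}@{m.offset}: ref mismatch (expected {m.ref}, sequence has {seq[m.offset]})"
            )
        seq[m.offset] = m.alt
        seen.add(m.offset)
    return UtrRecord(utr.gene_id, "".join(seq), utr.chrom, utr.start, utr.strand)


RANDOMIZE_MODES = ("random_any", "same_type", "same_position")


def randomize_mutations(
    utrs: list[UtrRecord],
    muts: list[PointMutation],
    mode: str,
    rng_seed: int,
) -> list[PointMutation]:
    """Generate one randomized null mutation set (see module docstring).

    Positions are drawn within the same gene's UTR.  Within a gene, drawn
    positions are kept distinct (and distinct from other randomized
    positions of that gene) so the set remains jointly applicable.  In
    ``same_type`` mode, a mutation whose ref base has no free occurrence in
    its UTR keeps its original position, with a counted warning.
    """
    if mode not in RANDOMIZE_MODES:
        raise InputError(f"unknown randomization mode {mode!r}")
    rng = np.random.default_rng(rng_seed)
    by_id = {u.gene_id: u for u in utrs}
    used: dict[str, set[int]] = {}
    kept_in_place = 0
    out: list[PointMutation] = []

    for m in muts:
        if m.gene_id not in by_id:
            raise InputError(f"mutation references unknown gene {m.gene_id!r}")
        seq = by_id[m.gene_id].sequence
        taken = used.setdefault(m.gene_id, set())

        if mode == "same_position":
            alts = [b for b in "ACGT" if b != m.ref]
            out.append(PointMutation(m.gene_id, m.offset, m.ref, alts[rng.integers(3)]))
            continue

        if mode == "same_type":
            candidates = [i for i, b in enumerate(seq) if b == m.ref and i not in taken]
            if not candidates:
                logger.warning(
                    "same_type: no free %s position in %s; keeping original offset %d",
                    m.ref, m.gene_id, m.offset,
                )
                kept_in_place += 1
                pos = m.offset
            else:
                pos = candidates[rng.integers(len(candidates))]
            taken.add(pos)
            out.append(PointMutation(m.gene_id, pos, m.ref, m.alt))
            continue

        # random_any
        candidates = [i for i in range(len(seq)) if i not in taken]
        if not candidates:
            raise InputError(f"random_any: UTR {m.gene_id} exhausted of positions")
        pos = candidates[rng.integers(len(candidates))]
        taken.add(pos)
        ref = seq[pos]
        alts = [b for b in "ACGT" if b != ref]
        out.append(PointMutation(m.gene_id, pos, ref, alts[rng.integers(3)]))

    if kept_in_place:
        logger.warning("same_type: %d mutation(s) kept in place", kept_in_place)
    return out


def group_by_gene(muts: list[PointMutation]) -> dict[str, list[PointMutation]]:
    """Group mutations by gene_id, preserving order."""
    out: dict[str, list[PointMutation]] = {}
    for m in muts:
        out.setdefault(m.gene_id, []).append(m)
    return out
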