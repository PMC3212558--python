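"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: per-position dictionary lookups and full enumeration,
sharing no code with the vectorised scanner they validate.
"""

from __future__ import annotations

import random


def oracle_hbond_score(seed: str, window: str, wc_gc=3, wc_au=2, wobble=2):
    """Per-position score of an antiparallel seed:window duplex."""
    pair_weight = {
        ("G", "C"): wc_gc,
        ("C", "G"): wc_gc,
        ("A", "T"): wc_au,
        ("U", "A"): wc_au,
        ("G", "T"): wobble,
        ("U", "G"): wobble,
    }
    score = 0
    n_paired = 0
    for i in range(7):
        w = pair_weight.get((seed[i], window[6 - i]))
        if w is not None:
            score += w
            n_paired += 1
    return score, n_paired


def oracle_scan(seed: str, utr: str, threshold: int, mode: str, wc_gc=3, wc_au=2, wobble=2):
    """All admissible window offsets by exhaustive enumeration."""
    out = []
    for off in range(len(utr) - 6):
        s, n = oracle_hbond_score(seed, utr[off : off + 7], wc_gc, wc_au, wobble)
        if s >= threshold and (mode == "lenient" or n == 7):
            out.append((off, s, n))
    return out


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def random_rna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(n))
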