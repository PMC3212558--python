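"""Randomization null sets: is it the substitution type or the position?

Compares the observed UV-like mutation set's binding shift against three
in-silico null constructions on the same UTRs: fully random mutations
(position and type redrawn), same-type (spectrum preserved, positions
random) and same-position (positions preserved, alt redrawn).  Writes
results/null_models.tsv.
"""

import pathlib

import numpy as np
import pandas as pd

from mutsigmirna import bindshift, io, mutmodel

ROOT = pathlib.Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "sim_inputs"
OUT = ROOT / "results" / "null_models.tsv"

N_REPLICATES = 5

if __name__ == "__main__":
    utrs = io.load_utrs(SIM / "utrs.fa")
    mirnas = io.load_mirnas(SIM / "mirnas.fa")
    muts = io.read_mutations(SIM / "muts.tsv", utrs)

    records = []
    rows = bindshift.delta_b_sweep(utrs, muts, mirnas)
    for r in rows:
        records.append({"set": "observed", "replicate": 0, "threshold": r.threshold,
                        "delta_b": r.delta_b, "normalized": round(r.normalized, 4)})
    obs_mean = np.mean([r.normalized for r in rows])
    print(f"observed UV-like set: mean normalized delta_b = {obs_mean:.4f}")

    mode_means = {}
    for mode in ("random_any", "same_type", "same_position"):
        means = []
        for rep in range(N_REPLICATES):
            null = mutmodel.randomize_mutations(utrs, muts, mode, rng_seed=1000 + rep)
            nrows = bindshift.delta_b_sweep(utrs, null, mirnas)
            means.append(np.mean([r.normalized for r in nrows]))
            for r in nrows:
                records.append({"set": mode, "replicate": rep, "threshold": r.threshold,
                                "delta_b": r.delta_b, "normalized": round(r.normalized, 4)})
        mode_means[mode] = np.mean(means)
        print(f"{mode:>14}: mean normalized delta_b = {np.mean(means):+.4f} "
              f"(range {min(means):+.4f} .. {max(means):+.4f}) over {N_REPLICATES} replicates")

    closest = min(mode_means, key=lambda m: abs(mode_means[m] - obs_mean))
    print(f"null closest to the observed shift: {closest}")
    if closest == "same_type":
        print("preserving the substitution spectrum preserves the effect: the type "
              "of substitution, not its position, drives the binding loss")
    OUT.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(records).to_csv(OUT, sep="\t", index=False)
    print(f"table -> {OUT}")
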