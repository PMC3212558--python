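"""Wild-type vs mutant binding shift across the hydrogen-bond threshold sweep.

Reads the simulated inputs from results/sim_inputs/, computes the per-
threshold delta_b tallies under default GC-weighted scoring and under the
equal-weight ablation, and contrasts the UV-like mutation set with a
balanced-spectrum set drawn on the same UTRs.  Writes
results/binding_shift.tsv and prints the headline numbers.
"""

import pathlib

import pandas as pd

from mutsigmirna import bindshift, io, synthdata
from mutsigmirna.seedscan import SeedWeights

ROOT = pathlib.Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "sim_inputs"
OUT = ROOT / "results" / "binding_shift.tsv"


def sweep_to_frame(rows, sig, label):
    return pd.DataFrame(
        [
            {
                "analysis": label,
                "threshold": r.threshold,
                "n_wt_more": r.n_wt_more,
                "n_mut_more": r.n_mut_more,
                "n_tied": r.n_tied,
                "delta_b": r.delta_b,
                "normalized": round(r.normalized, 4),
                "sign_p": p,
            }
            for r, p in zip(rows, sig.sign_p)
        ]
    )


if __name__ == "__main__":
    utrs = io.load_utrs(SIM / "utrs.fa")
    mirnas = io.load_mirnas(SIM / "mirnas.fa")
    muts = io.read_mutations(SIM / "muts.tsv", utrs)

    frames = []
    rows = bindshift.delta_b_sweep(utrs, muts, mirnas)
    sig = bindshift.significance(rows)
    frames.append(sweep_to_frame(rows, sig, "uv_default_weights"))
    print(f"UV-like mutations, GC-weighted scoring: paired-t p = {sig.p_paired_t:.3g}, "
          f"min per-threshold sign p = {min(sig.sign_p):.3g}")
    best = max(rows, key=lambda r: r.normalized)
    print(f"  strongest wild-type preference at threshold {best.threshold}: "
          f"{best.n_wt_more} genes wt-preferring vs {best.n_mut_more} mutant-preferring "
          f"(normalized delta_b = {best.normalized:.3f})")

    rows_eq = bindshift.delta_b_sweep(utrs, muts, mirnas, weights=SeedWeights.equal())
    sig_eq = bindshift.significance(rows_eq)
    frames.append(sweep_to_frame(rows_eq, sig_eq, "uv_equal_weights"))
    mean_eq = sum(r.normalized for r in rows_eq) / len(rows_eq)
    print(f"equal-weight ablation (G:C = A:T = 2 bonds): mean normalized delta_b = {mean_eq:.4f} "
          "- the wild-type preference disappears when GC pairs lose their extra bond")

    bal = synthdata.gen_mutations(utrs, len(muts), synthdata.BALANCED, 4242)
    rows_bal = bindshift.delta_b_sweep(utrs, bal, mirnas)
    sig_bal = bindshift.significance(rows_bal)
    frames.append(sweep_to_frame(rows_bal, sig_bal, "balanced_default_weights"))
    mean_bal = sum(r.normalized for r in rows_bal) / len(rows_bal)
    mean_uv = sum(r.normalized for r in rows)/len(rows)
    print(f"balanced spectrum on the same UTRs: mean normalized delta_b = {mean_bal:.4f} "
          f"(vs {mean_uv:.4f} for the UV-like set)")

    OUT.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(OUT, sep="\t", index=False)
    print(f"table -> {OUT}")
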