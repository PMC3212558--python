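# mutsigmirna

How a mutagen's substitution signature reshapes global microRNA binding.

UV radiation leaves a characteristic fingerprint in melanoma genomes:
C→T (with its opposite-strand twin G→A) dominates the somatic substitution
spectrum, so roughly three quarters of all point mutations replace a
Strong base (G/C, three hydrogen bonds in a Watson–Crick pair) with a Weak
one (A/T, two bonds). Because miRNA seed regions are GC-enriched, such
Strong→Weak mutations in 3′UTRs preferentially weaken miRNA:mRNA duplexes —
a global erosion of post-transcriptional regulation that a balanced
(non-UV) mutation spectrum does not produce. This package implements that
analysis end to end on synthetic data: a hydrogen-bond seed-match scanner,
the Δb binding-shift statistic with randomization nulls and a GC-weight
ablation, mutation-spectrum classification, per-miRNA rankings with
consensus aggregation, and a two-population comparison of GC/AT composition
at SNP sites.

## The statistic

A seed (nucleotides 2–8 of a mature miRNA) is scored against every 7-nt
window of a 3′UTR by summing the hydrogen bonds of the antiparallel duplex:
G:C = 3, A:U(T) = 2, G·U wobble = 2, mismatch = 0. A window is a predicted
site when its sum reaches a threshold *t* (swept over 14–21, the score
range of a fully paired 7-mer). For the set *M* of genes carrying 3′UTR
mutations,

    Δb(t) = #{g ∈ M : b_wt(g,t) > b_mut(g,t)} − #{g ∈ M : b_mut(g,t) > b_wt(g,t)}

where b(g,t) is the gene's binding aggregate (distinct miRNAs bound, or
total sites) on the wild-type vs the mutated sequence; the normalized form
divides by |M|. Significance is assessed with a paired t-test across the
threshold sweep and an exact binomial sign test per threshold (ties
excluded). Three null constructions separate the role of substitution type
from position: fully random, *same type* (spectrum preserved, positions
random) and *same position* (positions preserved, substitution redrawn).
Setting the G:C weight to 2 (the equal-weight ablation) removes the
thermodynamic asymmetry and, with it, the wild-type preference.

## Worked example

Generate the default synthetic inputs (200 genes × 1 kb UTRs at 42.4% GC,
100 miRNAs with GC-enriched G-skewed seeds, 300 UV-like mutations,
two genotyped populations) and run the binding-shift analysis:

```
python analysis/01_simulate.py 1
python analysis/02_binding_shift.py
```

which prints (seed 1):

```
UV-like mutations, GC-weighted scoring: paired-t p = 0.25, min per-threshold sign p = 0.000277
  strongest wild-type preference at threshold 18: 21 genes wt-preferring vs 3 mutant-preferring (normalized delta_b = 0.115)
equal-weight ablation (G:C = A:T = 2 bonds): mean normalized delta_b = -0.0008 - the wild-type preference disappears when GC pairs lose their extra bond
balanced spectrum on the same UTRs: mean normalized delta_b = 0.0000 (vs 0.0239 for the UV-like set)
```

At the most informative thresholds the UV-like mutation set leaves far more
genes with better predicted binding to the wild-type sequence (21 vs 3;
sign-test p ≈ 2.8×10⁻⁴), the effect disappears when G:C pairs are
artificially weighted like A:T, and a balanced substitution spectrum on the
same sequences produces no systematic shift. The remaining drivers —
`03_null_models.py`, `04_rank_mirnas.py` (GC-rich seeds dominate the most
affected miRNAs: mean seed G+C 4.55 in the top 20 vs 3.00 in the bottom
20), and `05_population_gc.py` (57.0% vs 55.0% GC at SNP sites, χ² p ≈
10⁻¹²⁷, robust to depth filters 5/8/11 and to the common-SNP restriction) —
each write their tables under `results/`.

The same computations are scriptable through the umbrella CLI
(`mutsigmirna scan | deltab | spectrum | randomize | rank | popgc |
simulate`), every command writing a JSON run manifest next to its output.

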