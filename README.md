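# bottleload

Mutational-load trajectories through population bottlenecks: per-individual
diversity, ROH-based inbreeding, conservation-score-weighted relative load,
coding total/realised load, and the R_xy derived-allele frequency-ratio
statistic — with a forward Wright–Fisher cohort simulator to exercise the
whole pipeline end to end.

The package is aimed at conservation genomicists analysing resequenced
cohorts that span a severe demographic crash: museum-era ("historical")
genomes plus one or more modern populations descended from very few
founders, e.g. after a rescue translocation. It answers the questions such
studies ask: how much heterozygosity was lost, how much of each genome is in
runs of homozygosity, whether the burden of deleterious variation changed,
and whether inbreeding purged the most damaging variants.

## Statistics implemented

Given a polarized callset (per-site derived-allele dosages `g ∈ {0,1,2}`
relative to an outgroup ancestral allele, complete-case across all
individuals):

* **Heterozygosity** — heterozygous sites per 1,000 callable bp, per sample.
* **Nucleotide diversity** — windowed π: per site `2p(1−p)·n/(n−1)`, summed
  per 10-kb window and divided by the window length.
* **ROH / F_ROH** — PLINK-style sliding-window detection (window of
  `window_snp` SNPs, at most `window_het` hets; SNP eligible when ≥ 5% of
  its windows are homozygous; segment-level minimum SNPs/span, density and
  gap constraints). `F_ROH` = fraction of the autosomal genome in ROH above
  a length threshold (100 kb and 2 Mb by default). The three published
  window presets ship as `PRESETS["window100" | "window250" | "main"]`.
* **Relative load (GERP)** — per score category, `Σ score·g / Σ g` over a
  sample's derived alleles (hom sites count twice); categories 0–1, 1–3,
  3–5, >5, and the top-percentile bin >5.88.
* **Coding load** — per SnpEff-style impact category (LOW / MODERATE /
  HIGH): *total load* (sites or alleles carrying derived variants) and
  *realised load* (`n_hom / 2S`, with `S` the category's segregating sites).
* **R_xy** — with `f` the per-site derived frequency,
  `Freq_x(C) = Σ_i f_x(1−f_y)` and `R_xy = Freq_x/Freq_y`; values below 1
  mean the category's derived alleles are relatively rarer in `x` than `y`.
  Uncertainty via delete-one jack-knife across chromosomes; plus a sharing
  summary (shared / unique / fixed / frequency-increased / -decreased).
* **Group contrasts** — Tukey HSD on per-sample statistics.

The simulator (`bottleload.simulate`) produces cohorts with the structure
this analysis assumes: standing variation drawn from the neutral 1/i
frequency spectrum, effect classes with selection and dominance
coefficients, conservation scores correlated with deleteriousness, and a
demography template of decline → crash to a single breeding pair →
recovery → translocation split, with historical samples taken pre-crash.

## Worked example

```python
import pandas as pd
from bottleload import (SimulationConfig, simulate_cohort, het_per_kb,
                        froh_table, PRESETS, annotate_sites, load_annotations)
from bottleload.rxy import FreqTable, rxy_jackknife

cfg = SimulationConfig(seed=1)                 # default crash-and-split cohort
callset, ann_table, truth = simulate_cohort(cfg)
pops = pd.Series({s: callset.populations[s] for s in callset.samples})

print(het_per_kb(callset).groupby(pops).mean().round(3))
# historical    0.184
# popA          0.057
# popB          0.049

froh = froh_table(callset, PRESETS["desk"], cfg.genome_bp,
                  min_lengths_bp=(10_000.0, 100_000.0))
print(froh.groupby("population")[["froh_10kb", "froh_100kb"]].mean().round(3))
#             froh_10kb  froh_100kb
# historical      0.063       0.016
# popA            0.722       0.562
# popB            0.770       0.583

ann = annotate_sites(callset, load_annotations(
    gerp_source=ann_table[["chrom", "pos", "gerp"]],
    impact_source=ann_table[["chrom", "pos", "impact"]]))
freqs = FreqTable.from_callset(callset, ann["impact"].to_numpy())
s = rxy_jackknife(freqs, "popA", "historical", "HIGH")
print(f"R_xy = {s.rxy:.3f} ± {s.jackknife_se:.3f} ({s.n_sites} sites)")
# R_xy = 0.422 ± 0.141 (75 sites)
```

Reading: the two modern populations have lost roughly two thirds of their
heterozygosity, carry most of their genomes in ROH (F_ROH ≈ 0.7 vs ≈ 0.06
historically), and HIGH-impact derived alleles sit at less than half their
historical relative frequency — the signature of drift plus purging through
the bottleneck.

The same analysis runs from the shell on a VCF or a simulated cohort:

```sh
bottleload run-all --config run.yaml --seed 1
bottleload report --outdir out/
```

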