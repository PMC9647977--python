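# Methods

This note documents the models, conventions and design choices behind
`bottleload`, in the order data flows through the pipeline.

## Cohort simulator

**Model.** Discrete-generation diploid Wright–Fisher with viability
selection. Each individual is two haplotypes; a haplotype is the set of
variant sites at which it carries the derived allele. Fitness is
multiplicative across sites with factors `1`, `1 + hs`, `1 + s` for 0/1/2
derived copies (`s ≤ 0` deleterious). Offspring are formed by drawing two
distinct parents uniformly, making one recombinant gamete from each, and
accepting the offspring with probability `w / w_max`, where `w_max` is the
highest fitness among the current parents — i.e. survival proportional to
relative fitness. A generation that cannot produce enough surviving
offspring (all-zero fitness, or acceptance below 1/200 per slot) raises a
simulation error naming the generation.

**Recombination and mutation.** Crossovers are Poisson per chromosome per
meiosis (`rec_rate` per bp, default 1e-6 at desk scale) with free assortment
across chromosomes — this is what makes chromosomes exchangeable jack-knife
units downstream. New mutations are Poisson with the avian-scale rate
2.3e-9 per bp per generation at new uniform-random positions (infinite
sites on a finite grid; collisions redrawn).

**Standing variation instead of burn-in.** Variation segregating in a real
cohort is overwhelmingly much older than the few simulated decades, and at a
realistic mutation rate a forward simulation cannot burn that history in.
The founding population is therefore initialised with `n_standing_sites`
(default 3,000) variant sites whose derived-allele counts are drawn from the
neutral equilibrium frequency spectrum, P(count = i) ∝ 1/i at the founding
size. Two consequences matter for interpretation: (i) under neutrality the
expected per-individual derived-allele count is then stationary across the
simulated timeline (new mutations contribute < 1% at the default rate), so
drift-conservation checks are meaningful; (ii) deleterious classes start on
a neutral spectrum, so the first simulated epoch re-equilibrates them —
selection responses measured across the timeline are conservative.

**Effect classes.** Each site belongs to one of four classes drawn once at
creation; defaults:

| class    | prob | s      | h    | conservation score |
|----------|------|--------|------|--------------------|
| neutral  | 0.70 | 0      | 0.5  | U(−2, 1)           |
| low      | 0.15 | −0.005 | 0.3  | U(1, 3)            |
| moderate | 0.10 | −0.02  | 0.25 | U(3, 5.88)         |
| high     | 0.05 | −0.10  | 0.05 | U(5.88, 12)        |

Scores are deliberately class-separated so that score bins act as a clean
proxy for deleteriousness; the high class is partially recessive, which is
what makes purging through inbreeding possible. Classes map to impact
annotations as neutral→MODIFIER, low→LOW, moderate→MODERATE, high→HIGH.

**Default demography** (desk-scale template for a crash-to-pair history,
not a calibrated estimate — census numbers for the recovery phase are not
translatable into Ne without data we do not model): 40 generations at
N = 500; historical sample of 13; 10 generations at N = 50; crash to one
randomly chosen breeding pair; geometric recovery to 60 over 10
generations; translocation of 20 founders into a second population; 15
generations of separation; modern samples of 9 and 20. The genome is 8
chromosomes × 250 kb. All sizes, epochs and samples are configurable as an
ordered stage list.

**Emission.** Every site carrying at least one derived allele among the
sampled individuals becomes a callset site (sites fixed-derived within one
or both modern populations are thereby retained — the sharing analysis
counts them). Genotypes are emitted directly; optional uniform genotype
missingness is available, but no read-level error model. Identical
(config, seed) gives byte-identical VCF/TSV output from a single
`numpy` PCG64 stream.

**What the generator does not emulate:** sequencing depth and error,
reference bias, linked-selection realism, a realistic avian karyotype
(macro/micro-chromosomes), or calibrated absolute census sizes. Passing
tests therefore demonstrate the correctness and qualitative behaviour of
the statistics, not quantitative reproduction of any real cohort.

## Callset handling

Coordinates are 1-based inclusive internally (VCF convention); BED masks
are read as 0-based half-open and converted at the boundary. Only biallelic
SNPs are analysed; indel records are consumed solely to drive the
indel-proximity filter. Filters follow resequencing practice: QUAL ≥ 30;
SNPs within 5 bp of an indel removed; per-genotype depth outside
[mean/3, 2×mean] set missing (per genotype, not per site, so one
low-coverage sample does not delete a site before the complete-case
restriction); heterozygotes with REF-read fraction outside (0.2, 0.8) set
missing. Polarization replaces REF with the outgroup base: dosage `d → 2−d`
where the outgroup matches ALT, and sites matching neither allele are
dropped and counted. Every drop reason is tallied separately in the run
manifest. All statistics run on the complete-case callset (zero missing
genotypes).

## Diversity

Heterozygosity is direct counting from filtered genotypes (het sites per
1,000 callable bp). True callable length is rarely available for synthetic
data, so `callable_bp` defaults to the stored per-sample value (the genome
length, for simulated cohorts) or the callset site count; both modes are
explicit arguments. π uses non-overlapping 10-kb tiles by default (step
configurable), with per-site correction `n/(n−1)` over non-missing
haplotypes and sites with fewer than two called haplotypes skipped. π is
computed per population by default, since pooling across strongly
differentiated groups conflates divergence with diversity. Group contrasts
use Tukey HSD via `statsmodels`.

## ROH dialect

The detector implements the sliding-window scan with explicit, testable
semantics: only full windows of `window_snp` SNPs are scored; a SNP's
eligibility fraction is taken over however many full windows contain it
(SNPs on chromosomes shorter than one window are ineligible); eligible runs
are split at inter-SNP gaps above `gap_kb`; segment span is measured
between first and last SNP positions. Reference implementations of this
scan differ in undocumented edge details, so an exhaustive rule-enumeration
oracle in the test suite defines the authoritative behaviour here, and the
detector is required to match it exactly on randomized instances. The
published parameter sets ship as presets (`window100`, `window250`,
`main` = 500-SNP windows with ≤ 5 hets), plus a `desk` preset
(25-SNP windows, 10-kb minimum) scaled to the sparse maps of the synthetic
cohorts. `F_ROH` divides summed segment length above a threshold (100 kb
and 2 Mb reported) by the configured autosomal genome length.
`window_missing` defaults to 0 because the analysis callset is
complete-case.

## Load statistics

Score categories use half-open bins [lo, hi); the boundary score 5 falls in
">5", and the top-percentile bin ">5.88" overrides ">5" for exclusive
labelling while remaining its subset for category-level analyses. Negative
scores are treated as unconstrained and excluded from every load
computation. Relative load is the dosage-weighted mean score of a sample's
derived alleles (hets one allele, homs two); it is undefined (NaN, distinct
from 0) when the sample carries no derived allele in the category.

Total load counts sites with a derived allele by default, with an
allele-count mode alongside, since "number of variants" is ambiguous
between the two; both appear in the output table. Realised load is
`n_hom / 2S` with `S` the category's segregating sites in the complete-case
cohort callset (cohort-wide so that values are comparable across
individuals; a population-wise scope is an option). The homozygote count is
restricted to those same segregating sites — counting homozygotes at
cohort-fixed sites would break the bound realised ≤ 0.5 that makes the
statistic a proportion of expressible load.

## R_xy

Implemented exactly as `Freq_x(C) = Σ f_x(1−f_y)`, `R_xy = Freq_x/Freq_y`,
on complete-case frequencies (so `n` is constant per population). The
default site-inclusion rule requires at least one derived allele in the
pooled x∪y sample; the stricter "≥1 in each population" reading is available
but excludes exactly the population-unique variants that the sharing
analysis counts, so it is not the default. `Freq_y = 0` yields +inf (or NaN
when both sums are zero) rather than an exception. The jack-knife deletes
one chromosome at a time over chromosomes that contribute included sites
(≥ 2 required), and reports leave-one-out estimates, pseudo-values
(`m·R − (m−1)·R₋c`), their mean, and the standard error
`sqrt((m−1)/m · Σ(R₋c − R̄₋)²)`; both leave-one-out values and
pseudo-values are emitted since either may be wanted for plotting.
Pipeline output orients each population pair as (descendant, ancestor) so
that R_xy < 1 reads as a frequency reduction in the later cohort.

## Validation experiment sizes

The test bench and `scripts/acceptance.py` use: 20 replicates of the
default neutral crash demography (drift conservation of derived-allele
counts to within 5%, F_ROH and heterozygosity direction in ≥ 18/20
replicates); 20 replicates of a purging scenario (N = 50, 20 generations,
s = −0.5, h = 0.5 on the high class, R_xy(descendant, ancestral) < 1);
200 randomized ROH instances up to 2,000 SNPs checked exactly against the
enumeration oracle; and 100 random frequency tables for the reciprocity
identity `R_xy·R_yx = 1` (tolerance 1e-12). These sizes were chosen so the
whole bench runs in a few minutes on one core while keeping the directional
checks far from their decision boundaries.

## Known limitations

* Heterozygosity is counted directly from genotypes; no likelihood-based
  θ estimation from read pileups.
* The simulator's viability selection ignores fertility differences, and
  its per-generation RNG is a single sequential stream (reproducible, but
  not parallelisable across chromosomes).
* GERP scores and impact categories are consumed, never computed; the
  simulator's class-separated score distributions are idealised.
* No dominance-aware fitness modelling of *observed* genotypes: realised
  load treats homozygosity as the expressed fraction without estimating h.
* π windows require the chromosome's variant span only; windows beyond the
  last variant are not emitted.
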