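# clonetrace

Clonal lineage tracing of human hematopoiesis from somatic mutations:
Bayesian quantification of mutant cell fractions from droplet digital PCR
(ddPCR), classification of hematopoietic stem cell (HSC) clones by their
output across the five major blood lineages, phylogenetic dating of clonal
mutation acquisition, and statistics for whether sibling clones inherit
their lineage programs.

The package is aimed at analyses of clonal hematopoiesis (CH) in elderly
donors, where expanded HSC clones are marked either by CH driver mutations
(e.g. *DNMT3A*, *TET2*) or by neutral passenger mutations (CH-US). Because
such donor data are typically under controlled access, the package ships a
first-class synthetic-cohort generator that reproduces the statistical
structure the analysis assumes — Poisson-partitioned droplet assays,
clones with balanced (PEMBT), PEMB- and PEM-restricted or -biased lineage
output, and somatic phylogenies with constant lifelong mutation
accumulation — together with ground truth, so every inference stage is
testable end to end.

## The models

**ddPCR mutant cell fraction.** A duplex well partitions template into
~14,000 droplets read as double-negative, mutant-only, wild-type-only or
double-positive. With λ_m, λ_w the expected mutant and wild-type molecules
per droplet, quadrant probabilities are the Poisson-occupancy closed form
(e^{−λ_m−λ_w}, (1−e^{−λ_m})e^{−λ_w}, e^{−λ_m}(1−e^{−λ_w}),
(1−e^{−λ_m})(1−e^{−λ_w})). The rates are tied to the mutant cell fraction
θ and an extraction efficiency *e* by

    λ_m = n_cells · θ · m_c · e / n_droplets
    λ_w = n_cells · (p − θ·m_c) · e / n_droplets

with ploidy p (2 on autosomes and the female X, 1 on the male X/Y) and
m_c = 1 mutant copies per cell (heterozygous). The posterior over (θ, e)
under θ ~ Beta(1,1) and e ~ Exponential(1) is integrated on a
deterministic 2-D grid and marginalised; positivity of a sample against a
wild-type control is called from the overlap of the two θ posteriors
(<5% positive, 5–20% likely positive, 20–40% inconclusive, ≥40%
negative). Bulk DNA uses the 60 ng = 9,090 cells convention (6.6 pg per
diploid cell), and MCF = 2×VAF (MCF = VAF on the male X).

**Lineage patterns.** Each clone's MCFs in the platelet (MkP), erythroid
(EP), myeloid, B and T compartments are sorted and nearest-neighbour
ratios computed; a >5-fold gap at a canonical boundary defines PEMB- or
PEM-bias, absence of lineages defines restriction, and a balanced
multilineage call requires max/min < 10. Clones qualify for tracing at
bulk MCF ≥ 2% (driver) or ≥ 1% (CH-US).

**Phylogenetic dating.** Colony genotype matrices (positive: VAF ≥ 0.15
and ≥2 mutant reads; negative: 0 mutant reads at depth ≥ 5) yield a
perfect phylogeny whose branch lengths are mutation counts. Assuming a
constant lifelong mutation rate, node age = span × (root-to-node count) /
(mean root-to-tip count below the node), with the timeline starting at
conception (birth at 40 gestational weeks) and tips fixed at the sampling
age. Acquisition is dated at the distal end of the marker branch
(midpoint/proximal variants available), with 95% CIs built from exact
Poisson bounds on branch counts (upstream branches lowered and downstream
raised for the lower age bound, and vice versa).

**Concordance statistics.** Within each clade of ≥2 terminal clones, the
lineage concordance score is the fraction showing the modal pattern
(all-positive / T-negative / B&T-negative); significance comes from
resampling clade-sized draws from the pooled clones of all donors (10,000
permutations). Moran's I on HSC-normalised lineage MCFs uses weights
1/(1 + phylogenetic age distance), zero across donors and on the
diagonal, tested one-sided (greater).

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort and write tables under `results/`:

```
$ python analysis/01_simulate_cohort.py --seed 1
12 donors, 216 ddPCR wells -> results/cohort

$ python analysis/02_estimate_mcf.py --seed 1
216 wells: |err| 0.31% (bias +0.11%); 95% CI coverage 96.0% on mutant wells;
100.0% of zero-MCF wells called negative

$ python analysis/03_classify_patterns.py --seed 1
29 clones: PEMBT 4, PEMB pooled 7, PEM pooled 4, unique 14; exact-label accuracy 62.1%

$ python analysis/04_date_clones.py --seed 1
112 clones dated: CI coverage 100.0%, |err| 0.67 y, r = 0.999

$ python analysis/05_concordance_moran.py --seed 1
concordance: observed 0.875, p = 9.999e-05 (10000 permutations)
Moran's I [B]: I = +0.697, one-sided p = 8.74e-06
Moran's I [EP]: I = +0.058, one-sided p = 0.325
Moran's I [MkP]: I = -0.216, one-sided p = 0.884
Moran's I [Myeloid]: I = +0.428, one-sided p = 0.00372
Moran's I [T]: I = +0.682, one-sided p = 1.31e-05
```

Reading the output: per-well posterior means recover simulated MCFs to a
few tenths of a percent with nominal credible-interval coverage; clone
acquisition ages are recovered almost exactly (r = 0.999) with honest
CIs; and when sibling clones inherit a family lineage program, both the
concordance test and Moran's I detect it — positive autocorrelation
appears exactly in the lineages that discriminate the patterns (B, T,
myeloid) and not in those shared by all patterns (MkP, EP). The
classification census shows the expected sensitivity limit: suppressed
lineages of biased clones sit near the ddPCR detection floor, so some
biased clones are read as restricted or unique, while the pooled
PEMB/PEM families remain stable.

The same functionality is exposed as a CLI (`clonetrace simulate | mcf |
classify | date | concordance | moran`), each subcommand taking
`--config`, `--seed` and `--out`.

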