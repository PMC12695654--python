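# Methods

This note documents the models implemented in `clonetrace`, the choices
made where the design was genuinely open, what the synthetic cohort does
and does not emulate, and the numerical conventions. No empirical claim
is made here beyond what the test suite and `scripts/acceptance.py`
compute.

## Bayesian ddPCR quantification

A duplex ddPCR well is summarised by four quadrant counts
(double-negative, mutant-only, wild-type-only, double-positive). Template
molecules are assumed Poisson-distributed over droplets, giving the
closed-form quadrant probabilities in (λ_m, λ_w); the rates are linked to
the mutant cell fraction θ ∈ [0,1] and an extraction efficiency e > 0 via
λ_m = n·θ·m_c·e/D and λ_w = n·(p − θ·m_c)·e/D (n sorted cells, D
droplets, ploidy p, m_c mutant copies per mutant cell). Assumptions:
heterozygosity (m_c = 1; copy-number-altered loci are out of scope),
independent droplets, and a single well per estimate.

Priors are weakly informative: θ ~ Beta(1,1) and e ~ Exponential(mean 1)
on (0, ∞). Efficiency is deliberately not truncated at 1: sorted-cell DNA
is whole-genome amplified before partitioning, so the well can contain
more template than input genome equivalents. For bulk DNA the cell-number
parameter follows the 60 ng convention (6.6 pg per diploid cell → 9,090
cells).

Inference is a deterministic 2-D grid integration (default 401 θ-points ×
201 e-points) rather than MCMC: it is reproducible to the bit, fast
(~10 ms per well), and the joint posterior is smooth. Numerical choices:

* the θ grid is quadratically spaced (θ_i = (i/(N−1))²), concentrating
  points near zero where rare-clone posteriors live (single-droplet
  resolution is ~1/(n·e) ≈ 10⁻⁴–10⁻³); prior mass per point is the Beta
  density times the trapezoid cell width;
* the e grid uses exponential-quantile midpoints, giving every point
  equal prior mass and covering (0, ~6) at the default resolution;
* the multinomial log likelihood uses `xlogy`, so structurally impossible
  counts (e.g. mutant-positive droplets at θ = 0) contribute −∞ rather
  than NaN;
* the credible interval is equal-tailed (2.5/97.5% of the interpolated
  grid CDF). An equal-tailed interval cannot cover a boundary truth of
  exactly θ = 0; wells with true MCF 0 are therefore assessed by their
  negativity call, not by CI coverage.

Positivity against a control is the overlap Σ min(mass) of the two θ
posteriors on a shared grid, with cuts at 5/20/40% (positive / likely
positive / inconclusive / negative); likely-positive collapses to
positive downstream and inconclusive wells are excluded from pattern
calling. The overlap is computed on θ marginals (the joint would mix in
efficiency, a nuisance). When no measured wild-type well is supplied, the
control is a synthetic null with the same droplet and cell numbers and
all mutant-positive droplets reassigned mutant-negative.

## Lineage-pattern classification

Profiles carry per-lineage posterior-mean MCFs and resolved positivity;
negative lineages contribute exactly 0. Positive lineages are sorted
descending (ties broken by the fixed precedence P>E>M>B>T; zero
denominators give +∞ ratios) and nearest-neighbour ratios computed.
Labels are assigned deterministically: balanced PEMBT (all five positive,
no ratio >5, max/min <10); PEMB/PEM restricted (exactly that involved
set, max/min <10); PEMB/PEM biased (all five positive, a unique >5-fold
gap isolating the canonical top group, top max/min <10); anything else is
reported as a unique pattern. Only the two canonical splits receive
names, mirroring the empirical observation that no other restriction
pattern recurs. Strict inequalities are used at both fold thresholds.

## Synthetic cohort

The generator encodes the study conditions: donors aged 70–84, >8,000
droplets per well (default 14,000), 2,000 sorted cells per population,
clone HSC MCFs log-normal with median 2% and σ = 0.9 (mean ≈ 3%, matching
the reported cohort mean), per-well efficiency truths uniform on
(0.1, 0.9), pattern frequencies defaulting to the observed 15 balanced /
25 PEMB / 13 PEM / 4 unique of 57 clones, and acquisition ages uniform
between 5 years after conception and 10 years before sampling. Effect
sizes are rule-forced: positive-group lineage factors are log-uniform on
[0.5, 2] (spread ≤ 4), suppressed lineages in biased clones sit a shared
6–50-fold below the smallest positive-group MCF with <1.1× jitter, so
the >5-fold boundary gap and <10-fold top-group spread hold by
construction and classification is exact whenever positivity calls are.

Phylogenies place each clone with ≥2 assigned colonies (binomial in its
HSC MCF) as a clade whose MRCA sits exactly at the acquisition age, with
background lineages and clade stems coalescing in a developmental window
(<0.9 y post-conception) and branch counts Poisson(rate × duration). The
default rate, 17 mutations/year, is an order-of-magnitude adult HSC
figure; only self-consistency is claimed. Colony reads are
Poisson(depth) totals with Binomial(total, 0.5) mutant reads for carriers
(error rate otherwise).

What the generator does **not** emulate: amplification chimeras and
fluorescence-level artifacts (quadrant counts are the entry point),
copy-number changes, nested subclones sharing droplet wells, T-cell-only
long-lived clones, serial time points, and selection-driven tree shapes
beyond a single expansion per clone. Passing tests therefore demonstrate
correctness of the inference machinery under the stated generative
assumptions, not robustness to these real-data complications.

A note on the detection floor: with partition efficiencies below 1 a well
holding 2,000 cells at MCF 0.12% contains only ~1–2 mutant molecules, and
no method can call it positive reliably. The study protocol amplifies
sorted-cell DNA to the 60 ng ddPCR input (~9,090 genome equivalents), so
the sensitivity property is exercised at efficiency 9090/2000 ≈ 4.5
(template per sorted cell), while the cohort default keeps the
conservative sub-unity efficiencies.

## Ultrametric scaling and dating

The timeline runs from conception (t = 0) to the sampling age plus 40
gestational weeks (365.25-day years). Node age = span × (root-to-node
mutation count) / (mean root-to-tip count over tips below the node) —
chosen among several consistent schemes because it reduces to exact
proportionality for equal tip counts; tips are forced to the span, and
Poisson noise that would locally invert nested node ages is resolved by
clamping children to their parent's age. Acquisition is dated at the
distal end of the marker branch by default (driver mutations concentrate
toward the ends of long branches); midpoint and proximal conventions are
provided for sensitivity analyses of passenger-marked clones.

The 95% CI uses exact (Garwood) Poisson bounds on each branch count
(0 → [0, 3.689]). The lower age bound lowers all root-to-node branches
and raises all branches below the node, re-ultrametricises, and reads off
the node age; the upper bound reverses the substitution. Because
per-branch bounds are combined conservatively, realised coverage is above
nominal (the acceptance suite requires ≥90%; observed ≈100% under the
generator). An alternative reading — deriving the interval from the
average per-colony rate × duration — is left unimplemented as it is
strictly less conservative and ambiguous in its normalisation.

Genotype matrices use the positive / negative / unknown thresholds stated
above. Unknown entries are imputed before the four-gamete check by clade
vouching: an unknown colony joins a mutation's carriers only when the
augmented set equals the carrier set of some fully resolved mutation
(i.e. other mutations on the same branch vouch for membership); remaining
unknowns count as negative. At the depths used (≥20×) unknowns are rare
and this is the operative form of clade-majority imputation. The perfect
phylogeny is the unique laminar tree of carrier sets; conflicts raise an
error naming the offending mutation pair. Branches carrying zero
mutations are unobservable, so "exact recovery" is defined on the carrier
structure (topology up to collapsing zero-count edges plus per-branch
counts). Externally reconstructed trees enter through newick and bypass
the builder.

## Concordance and Moran's I

The observed concordance statistic is the unweighted mean of per-clade
modal-pattern fractions (a clade-size-weighted variant is available
behind a flag; the aggregation is the one genuinely open choice and both
are reported by the result object). Null draws sample each clade's size
without replacement from the pooled clone labels of all donors,
independently across clades; the empirical p uses the +1 convention, so
p ≥ 1/(B+1) and the test is exact-level under exchangeability. Modal
ties score identically under either tied label and are flagged.

Moran's I uses raw weights w_ij = 1/(1 + age distance) within donors,
exactly zero across donors and on the diagonal. The default p-value is
the one-sided (greater) normality approximation; the randomization
(kurtosis-corrected) variance and a permutation p are available. The
implementation is cross-checked in the tests against R's `ape::Moran.I`
on a frozen fixture (ape row-standardises its weight matrix, which the
test replicates explicitly). Clone values are per-lineage MCFs normalised
by the clone's HSC MCF; distances are differences in acquisition age.

## Problem sizes and determinism

Default analysis sizes — 12–15 donors × 3–4 clones for ddPCR/census runs,
60–100 donors × 2 clones × 25 colonies for dating, 2,000 null cohorts for
calibration checks — were chosen so each stage completes in seconds to a
couple of minutes on one core while keeping Monte-Carlo error well below
the decision thresholds. Every stochastic routine takes an explicit seed
and is bitwise reproducible; reports embed the package version, seed and
configuration echo.

## Known limitations

* Posterior-mean MCFs feed the ratio rules; near the detection floor the
  mean overestimates tiny truths, inflating spreads and occasionally
  pushing balanced clones into unique labels (visible as reduced
  exact-label accuracy in the worked example).
* The grid posterior's θ resolution near zero (~10⁻⁵) limits overlap
  discrimination for clones far below one mutant molecule per well.
* The dating CI is conservative by construction; interval widths should
  not be compared across methods as if nominal.
* The concordance test conditions on the observed clade sizes; with few,
  small clades its discreteness makes it mildly conservative.
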