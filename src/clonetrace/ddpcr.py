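"""Bayesian mutant-cell-fraction (MCF) estimation from droplet digital PCR.

A duplex ddPCR well partitions amplified template into ~14,000 droplets and
reads each droplet as double-negative (NN), mutant-only, wild-type-only, or
double-positive. Molecule counts per droplet are Poisson, so the four
quadrant probabilities have a closed form in the expected mutant and
wild-type molecules per droplet (lambda_m, lambda_w). Those rates are tied
to the latent mutant cell fraction theta and an extraction efficiency e
(template molecules successfully partitioned per input genome equivalent):

    lambda_m = n_cells * theta * m_c * e / n_droplets
    lambda_w = n_cells * (p - theta * m_c) * e / n_droplets

with ploidy p (2 for autosomes and the female X, 1 for the male X/Y) and
m_c mutant copies per mutant cell (1, heterozygous). The posterior over
(theta, e) under a Beta prior on theta and an exponential prior on e is
integrated on a deterministic 2-D grid and marginalised over e; positivity
of a sample against a wild-type control is called from the overlap of the
two theta posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .config import DEFAULT_CONFIG, RunConfig

__all__ = [
    "GeneticContext",
    "DropletAssay",
    "PosteriorMCF",
    "PositivityCall",
    "quadrant_probs",
    "lambdas_from_state",
    "posterior_mcf",
    "null_control_assay",
    "positivity",
    "binary_positive",
    "vaf_to_mcf",
    "cells_from_dna_mass",
    "tracing_eligible",
]

QUADRANTS = ("nn", "mut_only", "wt_only", "double_pos")


@dataclass(frozen=True)
class GeneticContext:
    """Ploidy and mutant copy number at the assayed locus."""

    ploidy: int = 2
    mutant_copies: int = 1

    def __post_init__(self):
        if self.ploidy not in (1, 2):
            raise ValueError(f"ploidy must be 1 or 2, got {self.ploidy}")
        if not 1 <= self.mutant_copies <= self.ploidy:
            raise ValueError("mutant_copies must be in [1, ploidy]")

    @classmethod
    def from_sample(cls, chrom_class: str, sex: str) -> "GeneticContext":
        """Resolve ploidy from chromosome class and donor sex.

        Autosomes and the female X are diploid; the male X and the Y are
        haploid.
        """
        chrom_class = chrom_class.lower()
        sex = sex.upper()
        if chrom_class == "autosome":
            return cls(ploidy=2)
        if chrom_class == "x":
            return cls(ploidy=2 if sex == "F" else 1)
        if chrom_class == "y":
            if sex != "M":
                raise ValueError("Y-chromosome assay requires a male donor")
            return cls(ploidy=1)
        raise ValueError(f"unknown chrom_class {chrom_class!r}")


@dataclass(frozen=True)
class DropletAssay:
    """One ddPCR well: quadrant droplet counts plus the cell input."""

    nn: int
    mut_only: int
    wt_only: int
    double_pos: int
    n_cells: int
    chrom_class: str = "autosome"
    sex: str = "F"

    def __post_init__(self):
        for q in QUADRANTS:
            if getattr(self, q) < 0:
                raise ValueError(f"negative droplet count in quadrant {q}")
        if self.n_droplets == 0:
            raise ValueError("assay has zero droplets")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")

    @property
    def n_droplets(self) -> int:
        return self.nn + self.mut_only + self.wt_only + self.double_pos

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.nn, self.mut_only, self.wt_only, self.double_pos])

    def context(self) -> GeneticContext:
        return GeneticContext.from_sample(self.chrom_class, self.sex)


@dataclass
class PosteriorMCF:
    """Grid posterior over the mutant cell fraction theta in [0, 1]."""

    grid: np.ndarray
    mass: np.ndarray
    mean: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if abs(float(self.mass.sum()) - 1.0) > 1e-9:
            raise ValueError("posterior mass must sum to 1")
        if not (0 <= self.ci_low <= self.ci_high <= 1):
            raise ValueError("credible interval out of [0,1] or inverted")

    def quantile(self, q: float) -> float:
        return _grid_quantile(self.grid, self.mass, q)


@dataclass(frozen=True)
class PositivityCall:
    """Posterior-overlap positivity decision for one well."""

    overlap: float
    label: str  # positive | likely_positive | inconclusive | negative


def quadrant_probs(lambda_m: float, lambda_w: float) -> np.ndarray:
    """Closed-form Poisson-occupancy quadrant probabilities.

    Returns (NN, mutant-only, wild-type-only, double-positive); the vector
    sums to 1 for any non-negative rates.
    """
    lm = np.asarray(lambda_m, dtype=float)
    lw = np.asarray(lambda_w, dtype=float)
    if np.any(~np.isfinite(lm)) or np.any(~np.isfinite(lw)) or np.any(lm < 0) or np.any(lw < 0):
        raise ValueError("lambda parameters must be finite and non-negative")
    em = np.exp(-lm)
    ew = np.exp(-lw)
    return np.stack(
        [em * ew, (1.0 - em) * ew, em * (1.0 - ew), (1.0 - em) * (1.0 - ew)],
        axis=-1,
    )


def lambdas_from_state(
    theta,
    efficiency,
    n_cells: int,
    n_droplets: int,
    ctx: GeneticContext,
) -> tuple:
    """Expected mutant / wild-type molecules per droplet for a given state."""
    theta = np.asarray(theta, dtype=float)
    efficiency = np.asarray(efficiency, dtype=float)
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValueError("theta must lie in [0, 1]")
    if np.any(efficiency <= 0):
        raise ValueError("efficiency must be positive")
    if np.any(theta * ctx.mutant_copies > ctx.ploidy + 1e-12):
        raise ValueError("theta * mutant_copies exceeds ploidy")
    scale = n_cells * efficiency / n_droplets
    lam_m = scale * theta * ctx.mutant_copies
    lam_w = scale * np.clip(ctx.ploidy - theta * ctx.mutant_copies, 0.0, None)
    return lam_m, lam_w


def _theta_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Quadratically spaced theta grid on [0, 1] with trapezoid cell widths.

    Quadratic spacing concentrates points near zero, where posteriors for
    rare clones live (single-droplet resolution is ~1/(n_cells*e), i.e.
    1e-4..1e-3 for typical wells), while keeping coverage up to 1.
    """
    base = np.linspace(0.0, 1.0, n)
    grid = base**2
    widths = np.empty(n)
    widths[1:-1] = (grid[2:] - grid[:-2]) / 2.0
    widths[0] = (grid[1] - grid[0]) / 2.0
    widths[-1] = (grid[-1] - grid[-2]) / 2.0
    return grid, widths


def _efficiency_grid(n: int, mean: float) -> np.ndarray:
    """Equal-prior-mass grid on (0, inf): exponential quantiles at bin midpoints."""
    u = (np.arange(n) + 0.5) / n
    return -mean * np.log1p(-u)


def _grid_quantile(grid: np.ndarray, mass: np.ndarray, q: float) -> float:
    cdf = np.cumsum(mass)
    i = int(np.searchsorted(cdf, q))
    if i <= 0:
        return float(grid[0])
    if i >= len(grid):
        return float(grid[-1])
    c0, c1 = cdf[i - 1], cdf[i]
    if c1 <= c0:
        return float(grid[i])
    frac = (q - c0) / (c1 - c0)
    return float(grid[i - 1] + frac * (grid[i] - grid[i - 1]))


def posterior_mcf(
    assay: DropletAssay,
    ctx: GeneticContext | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> PosteriorMCF:
    """Posterior over theta by deterministic 2-D grid integration.

    The joint posterior over (theta, efficiency) is proportional to
    multinomial(quadrant counts | quadrant_probs) x Beta(theta) x Exp(e);
    it is evaluated on a theta grid (prior weighted by Beta pdf times cell
    width) crossed with an equal-prior-mass efficiency grid, then
    marginalised over efficiency. Deterministic given the configuration.
    """
    ctx = ctx if ctx is not None else assay.context()
    counts = assay.counts
    if counts.sum() == 0:
        raise ValueError("all four quadrant counts are zero")
    theta, widths = _theta_grid(config.theta_points)
    eff = _efficiency_grid(config.efficiency_points, config.efficiency_prior_mean)

    lam_m, lam_w = lambdas_from_state(
        theta[:, None], eff[None, :], assay.n_cells, assay.n_droplets, ctx
    )
    probs = quadrant_probs(lam_m, lam_w)  # (T, E, 4)
    loglik = xlogy(counts, probs).sum(axis=-1)

    # Beta prior as point mass: pdf * cell width (flat for Beta(1,1)).
    from scipy.stats import beta as beta_dist

    eps = 1e-12
    log_prior = beta_dist.logpdf(np.clip(theta, eps, 1 - eps), config.beta_a, config.beta_b)
    log_prior = log_prior + np.log(widths)

    logpost = loglik + log_prior[:, None]
    logpost -= logpost.max()
    joint = np.exp(logpost)
    mass = joint.sum(axis=1)
    mass /= mass.sum()

    mean = float(np.dot(theta, mass))
    lo = _grid_quantile(theta, mass, 0.025)
    hi = _grid_quantile(theta, mass, 0.975)
    lo = min(lo, mean)
    hi = max(hi, mean)
    return PosteriorMCF(grid=theta, mass=mass, mean=mean, ci_low=lo, ci_high=hi)


def null_control_assay(assay: DropletAssay) -> DropletAssay:
    """Synthetic wild-type control matched on droplet and cell numbers.

    Used when no measured negative-control well is available: all
    mutant-positive droplets are reassigned to their mutant-negative
    quadrant, preserving wild-type occupancy.
    """
    return DropletAssay(
        nn=assay.nn + assay.mut_only,
        mut_only=0,
        wt_only=assay.wt_only + assay.double_pos,
        double_pos=0,
        n_cells=assay.n_cells,
        chrom_class=assay.chrom_class,
        sex=assay.sex,
    )


def _common_grid_mass(p: PosteriorMCF, grid: np.ndarray) -> np.ndarray:
    if len(p.grid) == len(grid) and np.allclose(p.grid, grid):
        return p.mass
    # Re-grid via the interpolated CDF so total mass is conserved.
    cdf = np.concatenate([[0.0], np.cumsum(p.mass)])
    knots = np.concatenate([[p.grid[0]], p.grid])
    edges = np.concatenate([[grid[0]], (grid[1:] + grid[:-1]) / 2.0, [grid[-1]]])
    cdf_at = np.interp(edges, knots, cdf)
    mass = np.diff(cdf_at)
    s = mass.sum()
    if s <= 0:
        raise ValueError("posterior supports cannot be re-gridded onto a common grid")
    return mass / s


def positivity(
    sample: PosteriorMCF,
    control: PosteriorMCF,
    thresholds: tuple[float, float, float] = DEFAULT_CONFIG.positivity_thresholds,
) -> PositivityCall:
    """Call positivity from the overlap of sample and control posteriors.

    overlap = sum_i min(sample mass_i, control mass_i) on a shared theta
    grid. Labels: overlap < t1 positive; [t1, t2) likely_positive;
    [t2, t3) inconclusive; >= t3 negative (defaults 5/20/40%). Symmetric
    in its two arguments.
    """
    t1, t2, t3 = thresholds
    grid = sample.grid
    m_s = _common_grid_mass(sample, grid)
    m_c = _common_grid_mass(control, grid)
    overlap = float(np.minimum(m_s, m_c).sum())
    if overlap < t1:
        label = "positive"
    elif overlap < t2:
        label = "likely_positive"
    elif overlap < t3:
        label = "inconclusive"
    else:
        label = "negative"
    return PositivityCall(overlap=overlap, label=label)


def binary_positive(call: PositivityCall) -> bool:
    """Collapse the four-way call to the binary treatment used downstream."""
    return call.label in ("positive", "likely_positive")


def vaf_to_mcf(vaf: float, ctx: GeneticContext) -> float:
    """Convert a variant allele frequency to a mutant cell fraction.

    MCF = 2*VAF at diploid loci (heterozygous), capped at 1; MCF = VAF at
    haploid loci (male X / Y).
    """
    if not 0 <= vaf <= 1:
        raise ValueError("vaf must lie in [0, 1]")
    if ctx.ploidy == 1:
        return float(vaf)
    return float(min(2.0 * vaf, 1.0))


# one human diploid genome: 3e9 bp (haploid) x 2 x 660 Da/bp x 1.67e-12 pg/Da,
# rounded to one decimal -> 6.6 pg
PG_PER_CELL = round(3e9 * 2 * 660 * 1.67e-12, 1)


def cells_from_dna_mass(mass_ng: float) -> int:
    """Number of diploid cells represented by a bulk DNA mass in ng."""
    if mass_ng <= 0:
        raise ValueError("DNA mass must be positive")
    return int(mass_ng * 1000.0 / PG_PER_CELL)


def tracing_eligible(
    mcf_bulk: float, driver_flag: bool, config: RunConfig = DEFAULT_CONFIG
) -> bool:
    """Bulk-MCF eligibility for clonal lineage tracing.

    Driver-marked clones qualify at MCF >= 2%, CH-US-marked clones at
    >= 1% (defaults; configurable).
    """
    if not 0 <= mcf_bulk <= 1:
        raise ValueError("mcf must lie in [0, 1]")
    cut = config.tracing_mcf_driver if driver_flag else config.tracing_mcf_chus
    return mcf_bulk >= cut
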