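"""Run-wide configuration: grid resolutions, priors, classification thresholds.

All fractions (MCF, VAF, positivity thresholds) are stored as values in
[0, 1]; reports multiply by 100 for display.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Constants shared across the pipeline.

    Parameters
    ----------
    theta_points, efficiency_points
        Resolution of the deterministic 2-D posterior grid over mutant
        cell fraction (theta) and extraction efficiency.
    beta_a, beta_b
        Beta prior hyperparameters on theta (default flat).
    efficiency_prior_mean
        Mean of the exponential prior on extraction efficiency. Support is
        (0, inf): whole-genome amplification can yield more template than
        input genome equivalents, so efficiency is not truncated at 1.
    positivity_thresholds
        Posterior-overlap cut points (positive / likely-positive /
        inconclusive / negative), strictly increasing.
    bias_fold
        A clone is lineage-biased only when nearest-neighbour MCF ratios
        exceed this fold change (strict >).
    balance_fold
        Max/min MCF ratio within the involved lineage group must be below
        this for a balanced/restricted call (strict <).
    tracing_mcf_driver, tracing_mcf_chus
        Bulk-MCF eligibility cuts for lineage tracing (driver vs CH-US
        marker mutations).
    n_permutations
        Resamples for the clade concordance null distribution.
    gestation_weeks
        Weeks from conception to birth used when converting trees to an
        age scale starting at conception.
    min_droplets
        Minimum accepted ddPCR events per well.
    """

    theta_points: int = 401
    efficiency_points: int = 201
    beta_a: float = 1.0
    beta_b: float = 1.0
    efficiency_prior_mean: float = 1.0
    positivity_thresholds: tuple[float, float, float] = (0.05, 0.20, 0.40)
    bias_fold: float = 5.0
    balance_fold: float = 10.0
    tracing_mcf_driver: float = 0.02
    tracing_mcf_chus: float = 0.01
    n_permutations: int = 10_000
    gestation_weeks: float = 40.0
    min_droplets: int = 8000
    seed: int = 0

    def __post_init__(self) -> None:
        t = self.positivity_thresholds
        if len(t) != 3 or not (0 < t[0] < t[1] < t[2] < 1):
            raise ValueError(
                f"positivity thresholds must be strictly increasing in (0,1), got {t}"
            )
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.theta_points < 3 or self.efficiency_points < 3:
            raise ValueError("grid resolution must be >= 3 points per axis")
        if self.efficiency_prior_mean <= 0:
            raise ValueError("efficiency_prior_mean must be positive")
        if not (self.bias_fold > 1 and self.balance_fold > 1):
            raise ValueError("fold thresholds must exceed 1")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "positivity_thresholds" in raw:
            raw["positivity_thresholds"] = tuple(raw["positivity_thresholds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["positivity_thresholds"] = list(d["positivity_thresholds"])
        return d


DEFAULT_CONFIG = RunConfig()
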