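"""Clade-level concordance and phylogenetic spatial autocorrelation.

Two complementary tests of whether sibling clones within a phylogenetic
clade share lineage output:

* a permutation test on the lineage concordance score — within each clade
  of >= 2 terminal clones whose pattern is one of {positive in all
  lineages, T-negative, B-and-T-negative}, the proportion showing the
  modal pattern; the null resamples clade-sized draws from the pooled
  clone labels of all donors;
* Moran's I on HSC-normalised lineage MCFs with weights
  w_ij = 1/(1 + phylogenetic age distance), zero across donors and on the
  diagonal, tested one-sided (greater) under the normality approximation.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

CANONICAL_CLADE_PATTERNS = ("all_positive", "T_negative", "BT_negative")


@dataclass(frozen=True)
class CladePatternSet:
    """Terminal-clone pattern labels for one clade of one donor."""

    clade_id: str
    donor_id: str
    patterns: tuple

    def __post_init__(self):
        bad = [p for p in self.patterns if p not in CANONICAL_CLADE_PATTERNS]
        if bad:
            raise ValueError(f"non-canonical clade patterns: {bad}")

    @property
    def size(self) -> int:
        return len(self.patterns)


@dataclass
class ConcordanceResult:
    per_clade: dict  # clade_id -> score
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    n_permutations: int
    tied_clades: tuple = ()


@dataclass
class MoranResult:
    lineage: str
    i: float
    expectation: float
    variance: float
    p_value: float
    n: int


def concordance_score(clade: CladePatternSet) -> tuple[float, bool]:
    """Proportion of clones showing the clade's modal pattern.

    Returns (score, tied); ``tied`` marks clades where two patterns share
    the modal count (the score itself is unambiguous).
    """
    if clade.size < 2:
        raise ValueError("concordance needs >= 2 terminal clones")
    counts = Counter(clade.patterns)
    top = counts.most_common()
    tied = len(top) > 1 and top[0][1] == top[1][1]
    return top[0][1] / clade.size, tied


def _max_frequency(labels: np.ndarray, sizes, starts) -> float:
    """Mean over clades of the modal-pattern fraction of a sampled set."""
    scores = []
    for s, st in zip(sizes, starts):
        chunk = labels[st : st + s]
        _, counts = np.unique(chunk, return_counts=True)
        scores.append(counts.max() / s)
    return float(np.mean(scores))


def concordance_test(
    clades,
    n_permutations: int = 10_000,
    seed=None,
    weight_by_size: bool = False,
) -> ConcordanceResult:
    """Permutation test for within-clade lineage concordance.

    The observed statistic is the (unweighted by default) mean of
    per-clade concordance scores. Each null draw samples, for every
    clade, that clade's number of clones without replacement from the
    pooled clone labels of all donors and records the modal-pattern
    fraction; the empirical p-value uses the (1 + #{null >= observed}) /
    (B + 1) convention.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    eligible = [c for c in clades if c.size >= 2]
    if not eligible:
        raise ValueError("no clade with >= 2 terminal clones")
    pool = np.array(
        [CANONICAL_CLADE_PATTERNS.index(p) for c in eligible for p in c.patterns]
    )
    sizes = np.array([c.size for c in eligible])
    if sizes.max() > len(pool):
        raise ValueError("largest clade exceeds pooled clone count")

    per_clade, tied = {}, []
    for c in eligible:
        score, is_tied = concordance_score(c)
        per_clade[c.clade_id] = score
        if is_tied:
            tied.append(c.clade_id)
    weights = sizes / sizes.sum() if weight_by_size else None
    observed = float(np.average(list(per_clade.values()), weights=weights))

    rng = np.random.default_rng(seed)
    n = len(pool)
    null = np.empty(n_permutations)
    scores = np.empty(len(sizes))
    for b in range(n_permutations):
        for j, s in enumerate(sizes):
            idx = rng.choice(n, size=s, replace=False)
            _, counts = np.unique(pool[idx], return_counts=True)
            scores[j] = counts.max() / s
        null[b] = np.average(scores, weights=weights)

    p = (1.0 + np.sum(null >= observed - 1e-12)) / (n_permutations + 1.0)
    return ConcordanceResult(
        per_clade=per_clade,
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_permutations > 1 else float("nan"),
        p_value=float(p),
        n_permutations=n_permutations,
        tied_clades=tuple(tied),
    )


def phylo_weight_matrix(distances: np.ndarray, donor_ids) -> np.ndarray:
    """Weights 1/(1+d) within donor, zero across donors and on the diagonal."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    donors = np.asarray(donor_ids)
    same = donors[:, None] == donors[None, :]
    w = np.where(same, 1.0 / (1.0 + d), 0.0)
    np.fill_diagonal(w, 0.0)
    return w


def morans_i(
    values: np.ndarray,
    weights: np.ndarray,
    lineage: str = "",
    alternative: str = "greater",
    assumption: str = "normality",
) -> MoranResult:
    """Moran's I with an arbitrary weight matrix.

    I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    with expectation -1/(n-1); the variance uses the standard
    normality-assumption formula (default) or the randomization formula
    with the sample kurtosis (``assumption='randomization'``). One-sided
    (greater) by default.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = len(x)
    if w.shape != (n, n):
        raise ValueError("weight matrix shape mismatch")
    if n < 3:
        raise ValueError("need >= 3 observations")
    s0 = w.sum()
    if s0 <= 0:
        raise ValueError("weight graph is fully disconnected")
    z = x - x.mean()
    denom = float(z @ z)
    if denom <= 0:
        raise ValueError("constant values: Moran's I undefined")
    i_obs = float(n / s0 * (z @ w @ z) / denom)

    e_i = -1.0 / (n - 1)
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    if assumption == "normality":
        var = (n * n * s1 - n * s2 + 3.0 * s0 * s0) / ((n * n - 1.0) * s0 * s0) - e_i**2
    elif assumption == "randomization":
        k = n * np.sum(z**4) / denom**2
        var = (
            n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
            - k * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0)
        ) / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i**2
    else:
        raise ValueError(f"unknown assumption {assumption!r}")
    sd = math.sqrt(max(var, 0.0))
    zscore = (i_obs - e_i) / sd if sd > 0 else math.inf * np.sign(i_obs - e_i)
    if alternative == "greater":
        p = float(norm.sf(zscore))
    elif alternative == "less":
        p = float(norm.cdf(zscore))
    elif alternative == "two-sided":
        p = float(2 * norm.sf(abs(zscore)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return MoranResult(lineage=lineage, i=i_obs, expectation=e_i, variance=float(var), p_value=p, n=n)


def morans_i_permutation_p(
    values: np.ndarray,
    weights: np.ndarray,
    n_permutations: int = 999,
    seed=None,
) -> float:
    """Optional permutation p (label shuffling) for Moran's I, greater-tail."""
    x = np.asarray(values, dtype=float)
    obs = morans_i(x, weights).i
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(x)
        hits += morans_i(perm, weights).i >= obs - 1e-12
    return (1.0 + hits) / (n_permutations + 1.0)
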