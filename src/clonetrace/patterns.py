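"""Classification of clonal lineage-output patterns across five blood lineages.

Each HSC-derived clone is profiled by its mutant cell fraction (MCF) in the
platelet (P, via MkP), erythroid (E, via EP), myeloid (M), B and T lineages.
Clones are classified by ratio rules on the positive lineages sorted from
highest to lowest MCF:

* balanced multilineage (PEMBT): all five positive, no nearest-neighbour
  ratio above the bias fold (5), max/min below the balance fold (10);
* PEMB / PEM restricted: exactly {P,E,M,B} / {P,E,M} positive with max/min
  below 10;
* PEMB / PEM biased: all five positive with a unique >5-fold gap isolating
  {P,E,M,B} over {T}, or {P,E,M} over {B,T}, top-group max/min below 10;
* anything else is a unique pattern (reported, not named).

Negative lineages contribute MCF 0 and sort below every positive lineage.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .config import DEFAULT_CONFIG, RunConfig

LINEAGES = ("P", "E", "M", "B", "T")
_PRECEDENCE = {l: i for i, l in enumerate(LINEAGES)}

PATTERN_LABELS = (
    "PEMBT_balanced",
    "PEMB_restricted",
    "PEMB_biased",
    "PEM_restricted",
    "PEM_biased",
    "other_unique",
    "no_output",
)


@dataclass(frozen=True)
class LineageProfile:
    """Per-clone five-lineage MCFs with resolved positivity calls."""

    clone_id: str
    mcf: dict  # lineage -> fraction in [0, 1]
    positive: dict  # lineage -> bool
    hsc_mcf: float = float("nan")

    def __post_init__(self):
        for lin in LINEAGES:
            if lin not in self.mcf or lin not in self.positive:
                raise ValueError(f"profile {self.clone_id}: missing lineage {lin}")
            if not 0 <= self.mcf[lin] <= 1:
                raise ValueError(f"profile {self.clone_id}: MCF out of [0,1] for {lin}")

    def effective_mcf(self, lineage: str) -> float:
        """MCF used in ratio computations: negatives contribute exactly 0."""
        return self.mcf[lineage] if self.positive[lineage] else 0.0


@dataclass(frozen=True)
class PatternCall:
    clone_id: str
    label: str
    involved: frozenset
    gap_ratios: tuple
    spread: float  # max/min over the involved (top-group) lineages


def gap_structure(profile: LineageProfile):
    """Sort positive lineages by MCF and compute nearest-neighbour ratios.

    Returns (ordered lineage list, tuple of consecutive ratios). Ties are
    broken by the fixed precedence P > E > M > B > T; a zero denominator
    yields +inf. Returns (None, None) for a clone with no positive lineage.
    """
    pos = [l for l in LINEAGES if profile.positive[l]]
    if not pos:
        return None, None
    order = sorted(pos, key=lambda l: (-profile.effective_mcf(l), _PRECEDENCE[l]))
    ratios = []
    for a, b in zip(order, order[1:]):
        num = profile.effective_mcf(a)
        den = profile.effective_mcf(b)
        ratios.append(num / den if den > 0 else math.inf)
    return order, tuple(ratios)


def _spread(values) -> float:
    lo = min(values)
    hi = max(values)
    return hi / lo if lo > 0 else math.inf


def classify_pattern(
    profile: LineageProfile, config: RunConfig = DEFAULT_CONFIG
) -> PatternCall:
    """Deterministic pattern label for one clone profile."""
    fold = config.bias_fold
    bal = config.balance_fold
    order, ratios = gap_structure(profile)
    if order is None:
        return PatternCall(profile.clone_id, "no_output", frozenset(), (), math.nan)
    involved = frozenset(order)
    vals = [profile.effective_mcf(l) for l in order]
    label = "other_unique"
    spread = _spread(vals)

    if involved == frozenset(LINEAGES):
        big = [i for i, r in enumerate(ratios) if r > fold]
        if not big and spread < bal:
            label = "PEMBT_balanced"
        elif len(big) == 1:
            top = frozenset(order[: big[0] + 1])
            top_spread = _spread(vals[: big[0] + 1])
            if top == frozenset("PEMB") and top_spread < bal:
                label = "PEMB_biased"
                spread = top_spread
            elif top == frozenset("PEM") and top_spread < bal:
                label = "PEM_biased"
                spread = top_spread
    elif involved == frozenset("PEMB") and spread < bal:
        label = "PEMB_restricted"
    elif involved == frozenset("PEM") and spread < bal:
        label = "PEM_restricted"

    return PatternCall(profile.clone_id, label, involved, ratios, spread)


def pattern_census(calls) -> dict:
    """Tabulate pattern labels; restricted and biased PEMB/PEM are pooled.

    Returns a dict with one count per label plus pooled subtotals
    ('PEMB_pooled', 'PEM_pooled') and the total number of classified
    clones ('total', excluding no-output sentinels).
    """
    counts = Counter(c.label for c in calls)
    out = {label: counts.get(label, 0) for label in PATTERN_LABELS}
    out["PEMB_pooled"] = out["PEMB_restricted"] + out["PEMB_biased"]
    out["PEM_pooled"] = out["PEM_restricted"] + out["PEM_biased"]
    out["total"] = sum(counts.values()) - out["no_output"]
    return out
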