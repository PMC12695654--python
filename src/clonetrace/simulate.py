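"""Synthetic cohort generator: donors, clones, ddPCR wells, phylogenies and
colony read counts with the statistical structure the analysis assumes.

The generator emulates elderly donors carrying expanded HSC clones whose
lineage output follows the recurrently observed patterns (balanced PEMBT,
PEMB- and PEM-restricted or -biased), droplet assays produced by Poisson
partitioning of amplified template, and somatic phylogenies in which each
expanded clone forms a clade whose stem carries the clone-defining
mutation, with mutations accumulating at a constant lifelong rate.
Every simulation emits its ground truth so inference can be scored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .ddpcr import DropletAssay, GeneticContext, quadrant_probs
from .patterns import LINEAGES

__all__ = [
    "SimClone",
    "SimDonor",
    "simulate_donor",
    "simulate_ddpcr",
    "simulate_phylogeny",
    "simulate_colony_reads",
    "tree_mutation_carriers",
]

PATTERNS = (
    "PEMBT_balanced",
    "PEMB_restricted",
    "PEMB_biased",
    "PEM_restricted",
    "PEM_biased",
    "other",
)

# defaults calibrated to the study's reported summaries (median ~2,000
# sorted cells per population, >8,000 accepted droplets, mean clone
# HSC MCF ~3%); the background rate is an order-of-magnitude adult HSC
# accumulation figure and only self-consistency is claimed.
DEFAULT_DROPLETS = 14_000
DEFAULT_CELLS = 2_000
DEFAULT_MUTATION_RATE = 17.0  # somatic mutations / year
_MCF_LOG_MEDIAN = math.log(0.02)
_MCF_LOG_SIGMA = 0.9


@dataclass(frozen=True)
class SimClone:
    mutation_id: str
    driver_flag: bool
    true_mcf_hsc: float
    pattern: str
    lineage_mcf: dict  # P,E,M,B,T -> true MCF
    acquisition_age: float  # years from conception

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        for lin in LINEAGES:
            if lin not in self.lineage_mcf:
                raise ValueError(f"clone {self.mutation_id}: missing lineage {lin}")


@dataclass(frozen=True)
class SimDonor:
    donor_id: str
    age_at_sampling: float
    sex: str
    clones: tuple
    mutation_rate: float = DEFAULT_MUTATION_RATE


def _clone_lineages(pattern: str, hsc_mcf: float, rng: np.random.Generator) -> dict:
    """Per-lineage true MCFs realising a declared pattern by construction.

    Positive-group factors are log-uniform on [0.5, 2] (spread <= 4, so no
    spurious >5-fold gap and max/min < 10); suppressed lineages in biased
    patterns sit a shared 6-50-fold below the smallest positive-group MCF
    with a small (<1.1x) jitter, guaranteeing the >5-fold boundary gap.
    """
    def factors(k):
        return np.exp(rng.uniform(math.log(0.5), math.log(2.0), size=k))

    out = {l: 0.0 for l in LINEAGES}
    if pattern == "PEMBT_balanced":
        for l, f in zip(LINEAGES, factors(5)):
            out[l] = hsc_mcf * f
    elif pattern in ("PEMB_restricted", "PEMB_biased"):
        top = ("P", "E", "M", "B")
        for l, f in zip(top, factors(4)):
            out[l] = hsc_mcf * f
        if pattern == "PEMB_biased":
            gap = rng.uniform(6.0, 50.0)
            base = min(out[l] for l in top) / gap
            out["T"] = base * rng.uniform(1 / 1.1, 1.1)
    elif pattern in ("PEM_restricted", "PEM_biased"):
        top = ("P", "E", "M")
        for l, f in zip(top, factors(3)):
            out[l] = hsc_mcf * f
        if pattern == "PEM_biased":
            gap = rng.uniform(6.0, 50.0)
            base = min(out[l] for l in top) / gap
            out["B"] = base * rng.uniform(1 / 1.1, 1.1)
            out["T"] = base * rng.uniform(1 / 1.1, 1.1)
    elif pattern == "other":
        # a non-canonical output observed at most once in real cohorts:
        # platelet/erythroid only
        for l, f in zip(("P", "E"), factors(2)):
            out[l] = hsc_mcf * f
    return out


def simulate_donor(
    age: float,
    n_clones: int,
    pattern_mix,
    seed,
    donor_id: str = "D01",
    sex: str | None = None,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    acquisition_window: tuple[float, float] | None = None,
    hsc_mcf_range: tuple[float, float] | None = None,
    max_attempts: int = 50,
) -> SimDonor:
    """Draw a donor with ``n_clones`` expanded HSC clones.

    ``pattern_mix`` gives probabilities over :data:`PATTERNS`. HSC MCFs
    are log-normal (median 2%, sigma 0.9, mean ~3%) unless
    ``hsc_mcf_range`` restricts them to a uniform window (useful for
    phylogeny studies, which only admit clones above the 2% HSC-MCF
    tracing cut); acquisition ages are uniform on ``acquisition_window``
    (default 5 years after conception to 10 years before sampling).
    Redraws a clone set whose summed MCF exceeds 1 in any lineage,
    erroring after ``max_attempts``.
    """
    if age <= 18:
        raise ValueError("donor age must exceed 18 years")
    mix = np.asarray(pattern_mix, dtype=float)
    if len(mix) != len(PATTERNS) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValueError("pattern_mix must be a probability vector over the six patterns")
    rng = np.random.default_rng(seed)
    sex = sex or ("F" if rng.random() < 0.5 else "M")
    lo, hi = acquisition_window or (5.0, max(age - 10.0, 6.0))

    for _ in range(max_attempts):
        clones = []
        for i in range(n_clones):
            pattern = PATTERNS[rng.choice(len(PATTERNS), p=mix)]
            if hsc_mcf_range is not None:
                hsc = float(rng.uniform(*hsc_mcf_range))
            else:
                hsc = float(np.clip(rng.lognormal(_MCF_LOG_MEDIAN, _MCF_LOG_SIGMA), 1e-4, 0.4))
            clones.append(
                SimClone(
                    mutation_id=f"{donor_id}_clone{i:02d}",
                    driver_flag=bool(rng.random() < 0.8),
                    true_mcf_hsc=hsc,
                    pattern=pattern,
                    lineage_mcf=_clone_lineages(pattern, hsc, rng),
                    acquisition_age=float(rng.uniform(lo, hi)),
                )
            )
        totals = {
            lin: sum(c.lineage_mcf[lin] for c in clones) for lin in LINEAGES
        }
        totals["HSC"] = sum(c.true_mcf_hsc for c in clones)
        if all(v <= 1.0 for v in totals.values()):
            return SimDonor(donor_id, float(age), sex, tuple(clones), mutation_rate)
    raise RuntimeError(
        f"could not draw {n_clones} clones with total MCF <= 1 in every lineage"
    )


def simulate_ddpcr(
    true_mcf: float,
    n_cells: int = DEFAULT_CELLS,
    n_droplets: int = DEFAULT_DROPLETS,
    efficiency: float = 0.5,
    chrom_class: str = "autosome",
    sex: str = "F",
    seed=None,
    method: str = "molecules",
) -> DropletAssay:
    """Simulate one ddPCR well at a known mutant cell fraction.

    ``method='molecules'`` draws Poisson totals of mutant and wild-type
    template molecules and scatters them uniformly over droplets;
    ``method='multinomial'`` draws quadrant counts directly from the
    closed-form Poisson-occupancy probabilities. The two are identical in
    distribution (Poisson totals thinned uniformly are independent Poisson
    per droplet).
    """
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    if efficiency <= 0:
        raise ValueError("efficiency must be positive")
    if not 0 <= true_mcf <= 1:
        raise ValueError("true_mcf must lie in [0, 1]")
    ctx = GeneticContext.from_sample(chrom_class, sex)
    rng = np.random.default_rng(seed)
    mean_mut = n_cells * true_mcf * ctx.mutant_copies * efficiency
    mean_wt = n_cells * (ctx.ploidy - true_mcf * ctx.mutant_copies) * efficiency

    if method == "multinomial":
        probs = quadrant_probs(mean_mut / n_droplets, mean_wt / n_droplets)
        nn, m, w, dp = rng.multinomial(n_droplets, probs)
    elif method == "molecules":
        n_mut = rng.poisson(mean_mut)
        n_wt = rng.poisson(mean_wt)
        mut_occ = np.zeros(n_droplets, dtype=bool)
        wt_occ = np.zeros(n_droplets, dtype=bool)
        if n_mut:
            mut_occ[np.unique(rng.integers(0, n_droplets, size=n_mut))] = True
        if n_wt:
            wt_occ[np.unique(rng.integers(0, n_droplets, size=n_wt))] = True
        nn = int(np.sum(~mut_occ & ~wt_occ))
        m = int(np.sum(mut_occ & ~wt_occ))
        w = int(np.sum(~mut_occ & wt_occ))
        dp = int(np.sum(mut_occ & wt_occ))
    else:
        raise ValueError(f"unknown method {method!r}")
    return DropletAssay(
        nn=int(nn), mut_only=int(m), wt_only=int(w), double_pos=int(dp),
        n_cells=n_cells, chrom_class=chrom_class, sex=sex,
    )


class _Unit:
    """A pre-built subtree (tip or clone clade) awaiting attachment."""

    __slots__ = ("node", "time")

    def __init__(self, node, time):
        self.node = node
        self.time = time


def _leaf(tns, label, time):
    node = dendropy.Node()
    node.taxon = tns.require_taxon(label=label)
    node.sim_time = time
    return _Unit(node, time)


def _random_clade(tns, labels, t0, span, rng):
    """Random binary subtree over ``labels`` with its root at time t0."""
    def build(lbls, lo):
        if len(lbls) == 1:
            return _leaf(tns, lbls[0], span).node, span
        t = rng.uniform(lo, span) if lo < span else lo
        k = rng.integers(1, len(lbls))
        idx = rng.permutation(len(lbls))
        left = [lbls[i] for i in idx[:k]]
        right = [lbls[i] for i in idx[k:]]
        node = dendropy.Node()
        node.sim_time = t
        for part in (left, right):
            child, _ = build(part, t)
            node.add_child(child)
        return node, t

    if len(labels) == 1:
        return _leaf(tns, labels[0], span)
    node = dendropy.Node()
    node.sim_time = t0
    k = rng.integers(1, len(labels))
    idx = rng.permutation(len(labels))
    for part in ([labels[i] for i in idx[:k]], [labels[i] for i in idx[k:]]):
        child, _ = build(part, t0)
        node.add_child(child)
    return _Unit(node, t0)


def simulate_phylogeny(
    donor: SimDonor,
    n_colonies: int,
    seed,
    gestation_weeks: float = 40.0,
):
    """Simulate a colony phylogeny with expanded clades for each clone.

    Colonies are assigned to clones with probabilities equal to the clone
    HSC MCFs (the remainder is polyclonal background). Each clone with
    >= 2 assigned colonies becomes a clade whose most recent common
    ancestor sits exactly at the clone's acquisition age and whose stem
    carries the clone-defining mutation; background lineages and clade
    stems coalesce in a developmental window shortly after conception.
    Branch mutation counts are Poisson(rate x branch duration in years).

    Returns ``(tree, truth)`` where ``truth`` records clone acquisition
    ages, clone tip sets, undetectable clones and per-branch expectations.
    """
    if n_colonies < 2:
        raise ValueError("n_colonies must be >= 2")
    rng = np.random.default_rng(seed)
    span = donor.age_at_sampling + gestation_weeks * 7.0 / 365.25
    probs = [c.true_mcf_hsc for c in donor.clones]
    p_bg = 1.0 - sum(probs)
    assign = rng.choice(len(probs) + 1, size=n_colonies, p=probs + [p_bg])

    tns = dendropy.TaxonNamespace()
    units = []
    clone_tips: dict[str, list] = {}
    undetectable = []
    labels = [f"{donor.donor_id}_c{i:03d}" for i in range(n_colonies)]
    clone_nodes: dict[str, dendropy.Node] = {}
    for ci, clone in enumerate(donor.clones):
        tips = [labels[i] for i in np.flatnonzero(assign == ci)]
        if len(tips) < 2:
            undetectable.append(clone.mutation_id)
            # too small to form a clade; its tips rejoin the background
            for t in tips:
                units.append(_leaf(tns, t, span))
            continue
        clade = _random_clade(tns, tips, clone.acquisition_age, span, rng)
        clade.node.clone_id = clone.mutation_id
        clone_tips[clone.mutation_id] = tips
        clone_nodes[clone.mutation_id] = clade.node
        units.append(clade)
    for i in np.flatnonzero(assign == len(probs)):
        units.append(_leaf(tns, labels[i], span))
    if undetectable:
        warnings.warn(
            f"clones with <2 colonies marked undetectable: {undetectable}",
            stacklevel=2,
        )

    # developmental coalescence of background tips and clade stems; the
    # root is conception (time 0), splits before 0.9 years post-conception
    def join(us, lo, hi):
        if len(us) == 1:
            return us[0]
        t = lo if lo >= hi else rng.uniform(lo, hi)
        node = dendropy.Node()
        node.sim_time = t
        k = rng.integers(1, len(us))
        idx = rng.permutation(len(us))
        for part in ([us[i] for i in idx[:k]], [us[i] for i in idx[k:]]):
            sub = join(part, t + 1e-3, hi) if len(part) > 1 else part[0]
            node.add_child(sub.node)
        return _Unit(node, t)

    if len(units) == 1:
        root_unit = units[0]
        root = dendropy.Node()
        root.sim_time = 0.0
        root.add_child(root_unit.node)
    else:
        top = join(units, 0.0, 0.9)
        root = top.node
        root.sim_time = 0.0

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True

    # Poisson mutation counts on each branch; clone stems get the defining
    # mutation appended (acquired at the distal end of the stem).
    mut_serial = 0
    truth_branches = []
    for node in tree.preorder_node_iter():
        node.mutation_ids = []
        if node.parent_node is None:
            node.edge.length = 0
            continue
        duration = node.sim_time - node.parent_node.sim_time
        if duration < -1e-9:
            raise RuntimeError("non-monotone node times in simulated tree")
        count = int(rng.poisson(donor.mutation_rate * max(duration, 0.0)))
        ids = []
        for _ in range(count):
            ids.append(f"{donor.donor_id}_m{mut_serial:05d}")
            mut_serial += 1
        if getattr(node, "clone_id", None) is not None:
            ids.append(node.clone_id)
        node.edge.length = len(ids)
        node.mutation_ids = ids
        truth_branches.append(
            {"duration": duration, "count": len(ids), "expected": donor.mutation_rate * duration}
        )

    truth = {
        "span": span,
        "clone_ages": {c.mutation_id: c.acquisition_age for c in donor.clones},
        "clone_tips": {k: sorted(v) for k, v in clone_tips.items()},
        "clone_nodes": clone_nodes,
        "undetectable": undetectable,
        "tip_labels": labels,
        "branches": truth_branches,
    }
    return tree, truth


def tree_mutation_carriers(tree: dendropy.Tree) -> dict[str, frozenset]:
    """Map every mutation id on the tree to its carrier tip-label set."""
    carriers: dict[str, frozenset] = {}
    for node in tree.preorder_node_iter():
        ids = getattr(node, "mutation_ids", [])
        if not ids:
            continue
        tips = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        for m in ids:
            carriers[m] = tips
    return carriers


def simulate_colony_reads(
    tree: dendropy.Tree,
    mean_depth: float,
    error_rate: float,
    seed,
) -> pd.DataFrame:
    """Per colony x mutation read counts for genotype-matrix construction.

    Total reads are Poisson(mean_depth); mutant reads are
    Binomial(total, 0.5) for carried heterozygous autosomal mutations and
    Binomial(total, error_rate) otherwise.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    carriers = tree_mutation_carriers(tree)
    colonies = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    muts = sorted(carriers)
    n = len(colonies) * len(muts)
    total = rng.poisson(mean_depth, size=n)
    carried = np.array(
        [c in carriers[m] for c in colonies for m in muts], dtype=bool
    )
    p = np.where(carried, 0.5, error_rate)
    mut_reads = rng.binomial(total, p)
    return pd.DataFrame(
        {
            "colony": np.repeat(colonies, len(muts)),
            "mutation": np.tile(muts, len(colonies)),
            "mut_reads": mut_reads,
            "total_reads": total,
        }
    )
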