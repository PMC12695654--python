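"""Somatic phylogenies: genotype matrices, perfect phylogeny, ultrametric
age scaling and Poisson-bounded dating of mutation acquisition.

Trees are dendropy objects whose edge lengths carry integer somatic
mutation counts. Age scaling assumes a constant lifelong mutation rate and
a timeline starting at conception (birth at a configurable gestation, 40
weeks by default): after `make_ultrametric` every node carries `.age` in
years from conception and every tip sits at the donor's sampling age.

The perfect-phylogeny builder is intended for clean, near-complete
genotype matrices such as those produced by the synthetic cohort;
externally reconstructed trees (parsimony pipelines) enter through newick
instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import chi2

DAYS_PER_YEAR = 365.25

POSITIVE, NEGATIVE, UNKNOWN = 1, 0, -1


@dataclass(frozen=True)
class ColonyQC:
    colony: str
    median_vaf: float
    mean_depth: float
    passed: bool


@dataclass
class BranchDating:
    branch: str  # label of the node subtending the dated branch
    convention: str  # distal | midpoint | proximal
    age: float  # years from conception
    ci_low: float
    ci_high: float


def build_genotype_matrix(reads: pd.DataFrame) -> pd.DataFrame:
    """Binary genotype matrix (colonies x mutations) from read counts.

    ``reads`` must have columns colony, mutation, mut_reads, total_reads.
    Entry rules: positive iff VAF >= 0.15 and mutant reads >= 2; negative
    iff mutant reads = 0 and total reads >= 5; otherwise unknown.
    Values are 1 / 0 / -1 for positive / negative / unknown.
    """
    required = {"colony", "mutation", "mut_reads", "total_reads"}
    missing = required - set(reads.columns)
    if missing:
        raise ValueError(f"read table lacks columns: {sorted(missing)}")
    if (reads["mut_reads"] > reads["total_reads"]).any():
        bad = reads[reads["mut_reads"] > reads["total_reads"]].iloc[0]
        raise ValueError(
            f"mutant reads exceed total reads for colony {bad['colony']}, "
            f"mutation {bad['mutation']}"
        )
    if (reads[["mut_reads", "total_reads"]] < 0).any().any():
        raise ValueError("negative read counts")

    mut = reads["mut_reads"].to_numpy(float)
    tot = reads["total_reads"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(tot > 0, mut / np.where(tot > 0, tot, 1), 0.0)
    state = np.full(len(reads), UNKNOWN, dtype=int)
    state[(vaf >= 0.15) & (mut >= 2)] = POSITIVE
    state[(mut == 0) & (tot >= 5)] = NEGATIVE

    out = reads.assign(_state=state).pivot_table(
        index="colony", columns="mutation", values="_state", aggfunc="first"
    )
    return out.fillna(UNKNOWN).astype(int)


def colony_purity(
    matrix: pd.DataFrame,
    reads: pd.DataFrame,
    window: tuple[float, float] = (0.35, 0.65),
    depth_floor: float = 8.0,
) -> list[ColonyQC]:
    """Single-cell-origin QC: carried-mutation VAFs should centre on 0.5.

    A colony fails when the median VAF over its positive entries falls
    outside ``window`` (doublets and contaminated colonies skew low) or
    its mean depth is below ``depth_floor``.
    """
    reads = reads.copy()
    reads["vaf"] = np.where(
        reads["total_reads"] > 0, reads["mut_reads"] / reads["total_reads"].clip(lower=1), 0.0
    )
    out = []
    for colony, sub in reads.groupby("colony", sort=True):
        if str(colony) not in matrix.index.astype(str):
            continue
        row = matrix.loc[colony]
        carried = row[row == POSITIVE].index
        sub_c = sub[sub["mutation"].isin(carried)]
        med = float(sub_c["vaf"].median()) if len(sub_c) else math.nan
        depth = float(sub["total_reads"].mean())
        passed = (
            len(sub_c) > 0
            and window[0] <= med <= window[1]
            and depth >= depth_floor
        )
        out.append(ColonyQC(str(colony), med, depth, passed))
    return out


def _impute_unknowns(matrix: pd.DataFrame) -> dict[str, frozenset]:
    """Carrier sets per mutation with clade-based imputation of unknowns.

    An unknown entry (colony i, mutation m) is imputed positive when the
    resolved carriers of m plus i coincide with the carrier set of some
    fully resolved mutation (i.e. i's clade membership is vouched for by
    other mutations on the same branch); otherwise it is left negative.
    """
    colonies = list(matrix.index)
    carriers: dict[str, set] = {}
    unknowns: dict[str, list] = {}
    for m in matrix.columns:
        col = matrix[m]
        carriers[m] = set(col.index[col == POSITIVE])
        unk = list(col.index[col == UNKNOWN])
        if unk:
            unknowns[m] = unk
    resolved_sets = {
        frozenset(carriers[m]) for m in matrix.columns if m not in unknowns
    }
    final = {}
    for m in matrix.columns:
        base = set(carriers[m])
        for i in unknowns.get(m, []):
            if frozenset(base | {i}) in resolved_sets and frozenset(base) not in resolved_sets:
                base.add(i)
            elif frozenset(base | {i}) in resolved_sets and not base:
                # a private mutation whose only carrier dropped out
                base.add(i)
        final[m] = frozenset(base)
    return final


def perfect_phylogeny(matrix: pd.DataFrame) -> dendropy.Tree:
    """Build the unique perfect phylogeny of a conflict-free genotype matrix.

    Clades are exactly the distinct mutation carrier sets; each branch
    length is the number of mutations whose carrier set equals its clade,
    and those mutation ids are stored on ``node.mutation_ids``. Raises if
    two mutations violate the four-gamete condition (overlapping,
    non-nested carrier sets).
    """
    colonies = [str(c) for c in matrix.index]
    if len(set(colonies)) != len(colonies):
        raise ValueError("duplicate colony ids")
    matrix = matrix.copy()
    matrix.index = colonies
    carrier = _impute_unknowns(matrix)

    sets: dict[frozenset, list] = {}
    for m, s in carrier.items():
        if s:
            sets.setdefault(s, []).append(str(m))

    # laminar-family check == pairwise four-gamete test on carrier sets
    uniq = sorted(sets, key=len, reverse=True)
    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            if a & b and not (b <= a):
                ma, mb = sets[a][0], sets[b][0]
                raise ValueError(
                    f"four-gamete conflict between mutations {ma} and {mb}"
                )

    root_set = frozenset(colonies)
    children: dict[frozenset, list] = {root_set: []}
    order = [s for s in uniq if s != root_set]
    # insert sets from largest to smallest under their tightest superset
    placed = [root_set]
    for s in order:
        parent = min((p for p in placed if s <= p), key=len)
        children.setdefault(parent, [])
        children[parent].append(s)
        children.setdefault(s, [])
        placed.append(s)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True

    def covered(s: frozenset) -> set:
        return set().union(*children[s]) if children[s] else set()

    def build(s: frozenset, node: dendropy.Node):
        node.mutation_ids = sets.get(s, [])
        node.edge.length = len(sets.get(s, [])) if s != root_set else 0
        for c in sorted(children[s], key=lambda x: sorted(x)[0]):
            child = dendropy.Node()
            node.add_child(child)
            build(c, child)
        for colony in sorted(s - covered(s)):
            if len(s) == 1 and not children[s]:
                # s itself is a tip clade
                continue
            leaf = dendropy.Node()
            leaf.taxon = tns.require_taxon(label=colony)
            leaf.edge.length = 0
            leaf.mutation_ids = []
            node.add_child(leaf)
        if len(s) == 1 and not children[s]:
            node.taxon = tns.require_taxon(label=sorted(s)[0])

    build(root_set, tree.seed_node)
    tree.seed_node.edge.length = len(sets.get(root_set, []))
    tree.seed_node.mutation_ids = sets.get(root_set, [])
    return tree


def timeline_span(age_years: float, gestation_weeks: float = 40.0) -> float:
    """Years from conception to sampling."""
    return age_years + gestation_weeks * 7.0 / DAYS_PER_YEAR


def make_ultrametric(
    tree: dendropy.Tree, age_years: float, gestation_weeks: float = 40.0
) -> dendropy.Tree:
    """Annotate every node with an age (years from conception).

    Assuming a constant lifelong mutation rate, a node's age is the
    timeline span S times its root-to-node mutation count divided by the
    mean root-to-tip count over the tips below it; tips are forced to S
    exactly. The input tree is annotated in place and returned.
    """
    span = timeline_span(age_years, gestation_weeks)
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0
        if edge < 0:
            raise ValueError("negative branch mutation count")
        node._root_count = (parent._root_count if parent is not None else 0) + (
            edge if parent is not None else 0
        )
    leaves = list(tree.leaf_node_iter())
    if not leaves:
        raise ValueError("tree has no tips")
    for leaf in leaves:
        if leaf._root_count <= 0:
            raise ValueError(f"zero root-to-tip mutation count at {leaf.taxon}")
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tip_counts = [node._root_count]
        else:
            node._tip_counts = [c for ch in node.child_nodes() for c in ch._tip_counts]
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.age = span
        else:
            mean_tip = float(np.mean(node._tip_counts))
            node.age = span * node._root_count / mean_tip
            # Poisson noise can locally invert ages between nested nodes;
            # ages are clamped to keep the root-to-tip ordering monotone
            if node.parent_node is not None and node.age < node.parent_node.age:
                node.age = node.parent_node.age
    tree.timeline_span = span
    return tree


def _find_node(tree: dendropy.Tree, branch) -> dendropy.Node:
    if isinstance(branch, dendropy.Node):
        return branch
    for node in tree.preorder_node_iter():
        if node.taxon is not None and node.taxon.label == branch:
            return node
        if getattr(node, "label", None) == branch:
            return node
        if branch in getattr(node, "mutation_ids", []):
            return node
    raise KeyError(f"branch {branch!r} not found")


def date_mutation(tree: dendropy.Tree, branch, convention: str = "distal") -> float:
    """Acquisition-age point estimate for a mutation on a given branch.

    distal: age of the branch's child node (default; expansion-driving
    mutations sit toward the distal end of long branches); proximal: age
    of the parent node (conception, 0, for the root branch); midpoint:
    mean of the two.
    """
    node = _find_node(tree, branch)
    if not hasattr(node, "age"):
        raise ValueError("tree must be made ultrametric first")
    distal = node.age
    proximal = node.parent_node.age if node.parent_node is not None else 0.0
    if convention == "distal":
        return float(distal)
    if convention == "proximal":
        return float(proximal)
    if convention == "midpoint":
        return float((distal + proximal) / 2.0)
    raise ValueError(f"unknown convention {convention!r}")


def poisson_ci(count: float, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence bounds on a Poisson mean from one count."""
    if count < 0:
        raise ValueError("count must be non-negative")
    alpha = 1.0 - level
    lo = 0.0 if count == 0 else 0.5 * chi2.ppf(alpha / 2.0, 2 * count)
    hi = 0.5 * chi2.ppf(1.0 - alpha / 2.0, 2 * count + 2)
    return float(lo), float(hi)


def _clone_with_counts(tree: dendropy.Tree, counts: dict) -> dendropy.Tree:
    clone = tree.clone(depth=1)
    for node, cnode in zip(tree.preorder_node_iter(), clone.preorder_node_iter()):
        cnode.edge.length = counts.get(id(node), node.edge.length)
    return clone


def dating_ci(
    tree: dendropy.Tree,
    branch,
    age_years: float,
    gestation_weeks: float = 40.0,
    convention: str = "distal",
    level: float = 0.95,
) -> BranchDating:
    """95% CI on a mutation's acquisition age from per-branch Poisson bounds.

    For the lower age bound, branches on the root-to-node path (upstream,
    including the dated branch) take their Poisson lower bounds while
    branches below the node (downstream) take their upper bounds; the
    perturbed tree is re-scaled to ultrametric before reading off the node
    age. The upper bound reverses the substitution. Branches outside the
    path and subtree keep their observed counts.
    """
    tree = make_ultrametric(tree, age_years, gestation_weeks)
    node = _find_node(tree, branch)
    point = date_mutation(tree, node, convention)

    path = set()
    anc = node
    while anc is not None:
        path.add(id(anc))
        anc = anc.parent_node
    below = {id(n) for n in node.preorder_iter()} - {id(node)}

    lo_counts, hi_counts = {}, {}
    for n in tree.preorder_node_iter():
        if n.parent_node is None:
            continue
        k = n.edge.length or 0
        lo_k, hi_k = poisson_ci(k, level)
        if id(n) in path:
            lo_counts[id(n)], hi_counts[id(n)] = lo_k, hi_k
        elif id(n) in below:
            lo_counts[id(n)], hi_counts[id(n)] = hi_k, lo_k
    # map the perturbed trees through the same ultrametric scaling
    def node_age(counts):
        t = _clone_with_counts(tree, counts)
        t = make_ultrametric(t, age_years, gestation_weeks)
        for orig, copy in zip(tree.preorder_node_iter(), t.preorder_node_iter()):
            if orig is node:
                return date_mutation(t, copy, convention)
        raise RuntimeError("node lost during cloning")

    lo_age = node_age(lo_counts)
    hi_age = node_age(hi_counts)
    lo_age, hi_age = min(lo_age, hi_age), max(lo_age, hi_age)
    span = timeline_span(age_years, gestation_weeks)
    lo_age = max(0.0, min(lo_age, point))
    hi_age = min(span, max(hi_age, point))
    label = branch if isinstance(branch, str) else (
        node.taxon.label if node.taxon else (node.label or "internal")
    )
    return BranchDating(str(label), convention, float(point), lo_age, hi_age)


def clade_filter_for_tracing(
    clade_hsc_mcf: dict, threshold: float = 0.02
) -> dict:
    """Keep clades whose clone shows >= 2% MCF in HSCs (default threshold)."""
    kept = {k: v for k, v in clade_hsc_mcf.items() if v >= threshold}
    dropped = sorted(set(clade_hsc_mcf) - set(kept))
    if dropped:
        warnings.warn(
            f"{len(dropped)} clade(s) below HSC-MCF threshold dropped: {dropped}",
            stacklevel=2,
        )
    return kept
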