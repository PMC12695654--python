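"""Readers and writers for assay tables, genotype read counts, newick trees
and machine-readable result reports.

CSV is the default interchange dialect (comma-separated, UTF-8, '.'
decimal); tab-separated files are accepted via ``sep='\\t'`` or a ``.tsv``
extension. Dates are ISO-8601. Percentages are stored as fractions
internally and rendered x100 only in reports.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .config import DEFAULT_CONFIG, RunConfig

log = logging.getLogger("clonetrace")

ASSAY_COLUMNS = {
    "donor_id": str,
    "sample_date": str,
    "mutation_id": str,
    "lineage": str,
    "n_cells": int,
    "sex": str,
    "chrom_class": str,
    "nn": int,
    "mut_only": int,
    "wt_only": int,
    "double_pos": int,
    "is_control": bool,
}
LINEAGE_VALUES = {"HSC", "MkP", "EP", "Myeloid", "B", "T", "proB", "other"}
COUNT_COLUMNS = ("n_cells", "nn", "mut_only", "wt_only", "double_pos")


class FormatError(ValueError):
    """Structural problem with an input file (missing column, bad header)."""


def _sep_for(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_assay_table(
    path,
    sep: str | None = None,
    min_droplets: int = DEFAULT_CONFIG.min_droplets,
) -> pd.DataFrame:
    """Read and validate a ddPCR assay table.

    Returns a typed DataFrame with a ``total_droplets`` column and a
    ``rejected`` flag for wells below the accepted-droplet minimum
    (default 8,000; override with ``min_droplets``). Malformed rows are
    reported with their line numbers.
    """
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    missing = set(ASSAY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"assay table lacks required column(s): {sorted(missing)}")

    errors = []
    for col in COUNT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0) | (vals % 1 != 0)]
        for i in bad:
            errors.append(f"line {i + 2}: column {col!r} has invalid count {df.at[i, col]!r}")
        df[col] = vals
    bad_lin = df.index[~df["lineage"].isin(LINEAGE_VALUES)]
    for i in bad_lin:
        errors.append(f"line {i + 2}: unknown lineage {df.at[i, 'lineage']!r}")
    bad_sex = df.index[~df["sex"].isin(["M", "F"])]
    for i in bad_sex:
        errors.append(f"line {i + 2}: sex must be M or F")
    bad_chrom = df.index[~df["chrom_class"].str.lower().isin(["autosome", "x", "y"])]
    for i in bad_chrom:
        errors.append(f"line {i + 2}: chrom_class must be autosome/X/Y")
    try:
        pd.to_datetime(df["sample_date"], format="ISO8601")
    except (ValueError, TypeError):
        errors.append("sample_date column contains non-ISO-8601 dates")
    if errors:
        raise ValueError("invalid assay rows:\n" + "\n".join(errors))

    df = df.astype({c: int for c in COUNT_COLUMNS})
    df["is_control"] = df["is_control"].astype(bool)
    df["total_droplets"] = df[["nn", "mut_only", "wt_only", "double_pos"]].sum(axis=1)
    df["rejected"] = df["total_droplets"] < min_droplets
    n_rej = int(df["rejected"].sum())
    if n_rej:
        log.warning("%d well(s) below %d accepted droplets flagged rejected", n_rej, min_droplets)

    key = ["donor_id", "mutation_id", "lineage", "sample_date", "is_control"]
    dupes = df[df.duplicated(subset=key, keep=False)]
    if len(dupes):
        raise ValueError(
            f"duplicate assay keys (donor, mutation, lineage, date, control): "
            f"{dupes[key].drop_duplicates().to_dict('records')}"
        )
    # serial samples ordered by date; ties keep file order
    df = df.sort_values(["donor_id", "mutation_id", "sample_date"], kind="stable")
    return df.reset_index(drop=True)


def read_genotype_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a colony x mutation read-count table (colony, mutation,
    mut_reads, total_reads)."""
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    missing = {"colony", "mutation", "mut_reads", "total_reads"} - set(df.columns)
    if missing:
        raise FormatError(f"genotype table lacks column(s): {sorted(missing)}")
    return df


def read_tree(path) -> dendropy.Tree:
    """Read a single rooted newick tree whose branch lengths are mutation counts."""
    from dendropy.dataio.newickreader import NewickReader

    try:
        trees = dendropy.TreeList.get(path=str(path), schema="newick")
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip names in tree file: {exc}") from exc
    if len(trees) != 1:
        raise FormatError(f"expected exactly one tree, found {len(trees)}")
    tree = trees[0]
    tree.is_rooted = True
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    dup = [l for l, c in Counter(labels).items() if c > 1]
    if dup:
        raise ValueError(f"duplicate tip names: {dup}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length (mutation counts must be >= 0)")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict("records")
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj


def write_report(
    results: dict,
    path,
    config: RunConfig = DEFAULT_CONFIG,
    seed=None,
    tables: dict | None = None,
) -> None:
    """Emit a JSON report (plus optional TSV tables alongside).

    The JSON embeds a version stamp and an echo of the configuration and
    seed; given identical inputs it is byte-identical across reruns.
    """
    path = Path(path)
    payload = {
        "clonetrace_version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "results": _jsonable(results),
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for name, table in (tables or {}).items():
        tpath = path.with_name(f"{path.stem}_{name}.tsv")
        table.to_csv(tpath, sep="\t", index=False)
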