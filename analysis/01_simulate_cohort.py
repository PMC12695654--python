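"""Simulate the synthetic donor cohort and write its raw data + truth.

Emulates elderly donors (70-84 y) carrying expanded HSC clones with
balanced, PEMB- and PEM-restricted/biased lineage output, one duplex ddPCR
well per clone x sorted population, one colony phylogeny per donor, and
the corresponding truth tables.

Writes under results/cohort/: assays.csv, truth.tsv, HD*.nwk,
HD*_reads.tsv.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np

from clonetrace import pipeline
from clonetrace.io import write_report, write_tree
from clonetrace.simulate import simulate_colony_reads, simulate_phylogeny


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-donors", type=int, default=12)
    ap.add_argument("--outdir", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    assays, truth, donors = pipeline.simulate_cohort(
        n_donors=args.n_donors, seed=args.seed, clones_per_donor=3,
        within_donor_concordance=0.75,
    )
    assays.to_csv(args.outdir / "assays.csv", index=False)
    truth.to_csv(args.outdir / "truth.tsv", sep="\t", index=False)

    rng = np.random.default_rng(args.seed + 1)
    for donor in donors:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree, _ = simulate_phylogeny(donor, 25, seed=int(rng.integers(2**31)))
        write_tree(tree, args.outdir / f"{donor.donor_id}.nwk")
    write_report(
        {"n_donors": args.n_donors, "n_wells": len(assays),
         "n_clones": int(truth[["donor_id", "mutation_id"]].drop_duplicates().shape[0])},
        args.outdir / "cohort.json", seed=args.seed,
    )
    print(f"{args.n_donors} donors, {len(assays)} ddPCR wells -> {args.outdir}")


if __name__ == "__main__":
    main()
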