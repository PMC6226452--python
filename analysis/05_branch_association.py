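#!/usr/bin/env python
"""Independent-loss screen: phylogeny-aware branch association.

For traits lost several times independently (the subterranean-mammal
setting), the clade-based Z-score screen is replaced by a phylogenetic
GLS of per-species seqId on the loss phenotype with Brownian-motion
covariance.  This script simulates a 14-leaf tree with four scattered
loss lineages, relaxes 10% of CNEs 20-fold on the loss branches, runs
the association, and reports recovery at BH-adjusted p < 0.005.

Writes results/branch/.
"""

import pathlib

import pandas as pd

import cnescreen as cs

OUT = pathlib.Path("results/branch")
SEED = 24


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tree = cs.generate_fixture_tree(10, 4, 0.9, seed=3, scattered=True)
    print(f"tree: {len(tree.species)} leaves, loss lineages "
          f"{list(tree.loss_species)} placed in independent clades")
    alns, truths, roots = cs.evolve_cnes(
        tree, 1000, constrained_rate=0.15, relaxed_fraction=0.10,
        relaxation_factor=20.0, seed=SEED, _return_roots=True,
    )
    config = cs.ScreenConfig(loss_species=tuple(tree.loss_species))
    records = cs.compute_divergence_records(alns, tree, config, ancestors=roots)
    seqids = records.set_index("cne_id")[
        [c for c in records.columns if c.startswith("seqid_")]
    ]
    phenotype = {
        s: ("loss" if s in tree.loss_species else "intact") for s in tree.species
    }
    res = cs.branch_association(seqids, tree, phenotype)
    res.to_csv(OUT / "branch_association.tsv", sep="\t", index=False,
               float_format="%.4g")

    relaxed = {t.cne_id for t in truths if t.sim_class == "relaxed_in_loss"}
    called = set(res.loc[res["adjusted_p"] < 0.005, "cne_id"])
    tp = len(called & relaxed)
    fp = len(called - relaxed)
    print(f"{len(res)} CNEs tested; {len(called)} significant at "
          f"BH-adjusted p < 0.005")
    print(f"recovered {tp}/{len(relaxed)} planted relaxed CNEs; "
          f"{fp} constrained CNEs called "
          f"(empirical FDR {fp / max(1, len(called)):.1%})")
    print(f"wrote {OUT}/branch_association.tsv")


if __name__ == "__main__":
    main()
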