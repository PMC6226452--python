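#!/usr/bin/env python
"""Associate CNEs with candidate target genes and test enrichment.

Builds GREAT-style regulatory domains (5 kb/1 kb basal, <= 300 kb
extension), merges CNEs closer than 50 bp, maps diverged vs non-diverged
CNEs to genes, and asks (i) whether diverged CNEs are enriched near the
genes targeted by the planted relaxed CNEs (one-sided Fisher + BH), and
(ii) whether diverged CNEs are enriched within a limb-like peak set built
over the planted relaxed CNEs (Fisher + 10,000x subsampling Z-score),
with the uniform simulated peak set as a no-enrichment control.

Reads results/sim/ and results/screen/, writes results/enrichment/.
"""

import pathlib

import pandas as pd

import cnescreen as cs
from cnescreen.association import enrichment_table

SIM = pathlib.Path("results/sim")
SCREEN = pathlib.Path("results/screen")
OUT = pathlib.Path("results/enrichment")
SEED = 22


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cnes = cs.read_bed(SIM / "cnes.bed")
    genes = pd.read_csv(SIM / "genes.tsv", sep="\t")
    peaks = cs.read_bed(SIM / "peaks.bed")
    truth = pd.read_csv(SIM / "truth.tsv", sep="\t")
    diverged_ids = set((SCREEN / "diverged_ids.txt").read_text().split())

    domains = cs.build_regulatory_domains(genes)
    merged = cs.merge_close(cnes, 50)
    assoc = cs.associate_cnes(merged, domains)
    print(f"{len(cnes)} CNEs -> {len(merged)} after 50-bp merging; "
          f"{sum(bool(v) for v in assoc.values())} lie in a regulatory domain")

    # merged CNE is "diverged" if it contains a called source CNE
    def contains_any(m, ids):
        return any(
            c.name in ids and c.start < m.end and m.start < c.end
            for c in cnes
            if c.chrom == m.chrom
        )

    fg = [m for m in merged if contains_any(m, diverged_ids)]
    bg = [m for m in merged if m not in fg]

    # gene set: targets of the planted relaxed CNEs (ground truth)
    relaxed_ids = set(truth.loc[truth["class"] == "relaxed_in_loss", "cne_id"])
    relaxed_cnes = [c for c in cnes if c.name in relaxed_ids]
    relaxed_assoc = cs.associate_cnes(relaxed_cnes, domains)
    target_genes = set().union(*relaxed_assoc.values())
    print(f"gene set: {len(target_genes)} genes whose domains contain "
          f"planted relaxed CNEs")

    name_to_genes = assoc
    def in_gene_set(m):
        key = m.name or f"{m.chrom}:{m.start}-{m.end}"
        return bool(name_to_genes.get(key, set()) & target_genes)

    results = [cs.fisher_enrichment(fg, bg, in_gene_set, "relaxed_target_genes")]

    # limb-like peaks: regulatory elements over 80% of the relaxed CNEs,
    # plus decoys elsewhere; the uniform peak set is the negative control
    relaxed_df = pd.DataFrame(
        [(c.chrom, c.start, c.end, c.name) for c in relaxed_cnes],
        columns=["chrom", "start", "end", "name"],
    )
    limb_peaks_df = cs.generate_peaks(
        relaxed_df, 0.8, 60, seed=SEED, chrom_length=int(max(c.end for c in cnes))
    )
    limb_peaks = [
        cs.GenomicInterval(r.chrom, r.start, r.end, r.name)
        for r in limb_peaks_df.itertuples()
    ]
    results.append(
        cs.overlap_enrichment(
            fg, bg, limb_peaks, "limb_like_peaks", n_subsamples=10_000, seed=SEED
        )
    )
    results.append(
        cs.overlap_enrichment(
            fg, bg, peaks, "uniform_peaks", n_subsamples=10_000, seed=SEED
        )
    )
    cs.adjust_enrichments(results)
    table = enrichment_table(results)
    table.to_csv(OUT / "enrichment.tsv", sep="\t", index=False, float_format="%.4g")
    for r in results:
        z = f", subsample Z = {r.subsample_z:.2f}" if r.subsample_z is not None else ""
        print(f"{r.set_name}: {r.a}/{r.a + r.b} diverged vs "
              f"{r.c}/{r.c + r.d} background in set; one-sided Fisher "
              f"p = {r.p_value:.3g} (BH-adjusted {r.adjusted_p:.3g}){z}")
    print(f"wrote {OUT}/enrichment.tsv")


if __name__ == "__main__":
    main()
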