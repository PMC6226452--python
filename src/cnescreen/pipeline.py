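"""Stage orchestration: simulate -> screen -> associate -> enrich -> motifs
-> report, with per-stage manifests and seeded reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import zlib

import numpy as np
import pandas as pd

from . import simulate as sim
from .alignment import read_alignment_dir, write_alignment_dir
from .association import (
    adjust_enrichments,
    associate_cnes,
    build_regulatory_domains,
    enrichment_table,
    overlap_enrichment,
)
from .config import PipelineConfig
from .intervals import GenomicInterval, merge_close, read_bed, write_bed
from .motifs import (
    compute_motif_scores,
    excess_score,
    gc_content,
    gc_cutoffs,
    read_meme,
)
from .screen import (
    ScreenConfig,
    compute_divergence_records,
    reconstruct_ancestral,
    screen_cnes,
    simulation_fdr,
    write_records_tsv,
)
from .trees import PhyloTree

log = logging.getLogger("cnescreen")

STAGES = ["simulate", "screen", "associate", "enrich", "motifs", "report"]


class PipelineError(RuntimeError):
    pass


def derive_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed: master seed mixed with the stage name's CRC32."""
    return (master_seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(config, stage, params, inputs, outputs) -> None:
    mdir = os.path.join(config.outdir, "manifests")
    os.makedirs(mdir, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": derive_seed(config.seed, stage),
        "master_seed": config.seed,
        "parameters": params,
        "input_checksums": {p: _sha256(p) for p in inputs if os.path.exists(p)},
        "outputs": sorted(outputs),
    }
    with open(os.path.join(mdir, f"{stage}.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _path(config: PipelineConfig, key: str, default_rel: str) -> str:
    p = getattr(config.paths, key)
    return p if p else os.path.join(config.outdir, default_rel)


def _require(path: str, stage: str, needed_by: str) -> str:
    if not os.path.exists(path):
        raise PipelineError(
            f"stage '{needed_by}' needs {path!r}; run stage '{stage}' first"
        )
    return path


def _load_tree(config: PipelineConfig) -> PhyloTree:
    path = _require(_path(config, "tree", "tree.nwk"), "simulate", "screen")
    meta_path = os.path.join(config.outdir, "tree_meta.json")
    loss, local = (), ()
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = json.load(fh)
        loss, local = tuple(meta["loss_species"]), tuple(meta["local_species"])
    return PhyloTree.from_newick_file(path, loss, local)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: PipelineConfig) -> list[str]:
    p = config.simulate
    seed = derive_seed(config.seed, "simulate")
    tree = sim.generate_fixture_tree(
        p.n_other_species, p.n_loss_species, p.depth, seed, scattered=p.scattered
    )
    out = config.outdir
    tree.write_newick(os.path.join(out, "tree.nwk"))
    with open(os.path.join(out, "tree_meta.json"), "w") as fh:
        json.dump(
            {
                "loss_species": list(tree.loss_species),
                "local_species": list(tree.local_comparison_species),
            },
            fh,
        )
    alns, truths = sim.evolve_cnes(
        tree,
        p.n_cnes,
        length_mean=p.length_mean,
        constrained_rate=p.constrained_rate,
        relaxed_fraction=p.relaxed_fraction,
        relaxation_factor=p.relaxation_factor,
        seed=seed + 1,
        spacing=p.spacing,
    )
    write_alignment_dir(alns, os.path.join(out, "alignments"))
    cnes = [GenomicInterval(a.chrom, a.start, a.end, a.cne_id) for a in alns]
    write_bed(cnes, os.path.join(out, "cnes.bed"))
    sim.write_truth_table(truths, os.path.join(out, "truth.tsv"))
    chrom_length = max(a.end for a in alns) + 100000
    genes = sim.generate_gene_annotation(p.n_genes, chrom_length, seed + 2)
    genes.to_csv(os.path.join(out, "genes.tsv"), sep="\t", index=False)
    cne_df = pd.DataFrame(
        [(c.chrom, c.start, c.end, c.name) for c in cnes],
        columns=["chrom", "start", "end", "name"],
    )
    peaks = sim.generate_peaks(
        cne_df, p.peak_overlap_fraction, p.n_decoy_peaks, seed + 3,
        chrom_length=chrom_length,
    )
    peaks_iv = [
        GenomicInterval(r.chrom, r.start, r.end, r.name) for r in peaks.itertuples()
    ]
    write_bed(peaks_iv, os.path.join(out, "peaks.bed"))
    library = sim.generate_motif_library(p.n_motifs, seed=seed + 4)
    from .motifs import write_meme

    write_meme(library, os.path.join(out, "motifs.meme"))
    return [
        os.path.join(out, f)
        for f in ["tree.nwk", "cnes.bed", "truth.tsv", "genes.tsv", "peaks.bed", "motifs.meme"]
    ]


def _stage_screen(config: PipelineConfig) -> list[str]:
    out = config.outdir
    tree = _load_tree(config)
    aln_dir = _require(
        _path(config, "alignments_dir", "alignments"), "simulate", "screen"
    )
    alns = read_alignment_dir(aln_dir)
    sp = config.screen
    sconf = ScreenConfig.from_tree(
        tree,
        z_cutoff=sp.z_cutoff,
        min_additional_species=sp.min_additional_species,
        min_nongap_frac=sp.min_nongap_frac,
        **(
            {"required_species": tuple(sp.required_species)}
            if sp.required_species
            else {}
        ),
    )
    records = compute_divergence_records(alns, tree, sconf)
    diverged = screen_cnes(records, sconf)
    write_records_tsv(records, diverged, os.path.join(out, "records.tsv"))
    with open(os.path.join(out, "diverged_ids.txt"), "w") as fh:
        fh.write("\n".join(diverged) + ("\n" if diverged else ""))
    # simulation FDR from an in-stage constrained-only null
    seed = derive_seed(config.seed, "screen")
    null_alns, _ = sim.evolve_cnes(
        tree,
        sp.n_null_cnes,
        length_mean=config.simulate.length_mean,
        constrained_rate=config.simulate.constrained_rate,
        relaxed_fraction=0.0,
        seed=seed,
    )
    null_records = compute_divergence_records(null_alns, tree, sconf)
    null_pass = len(screen_cnes(null_records, sconf))
    fdr = (
        simulation_fdr(null_pass, sp.n_null_cnes, len(records), len(diverged))
        if diverged
        else None
    )
    with open(os.path.join(out, "fdr.json"), "w") as fh:
        json.dump(
            {
                "n_screened": len(records),
                "n_called": len(diverged),
                "n_null_pass": null_pass,
                "n_null_total": sp.n_null_cnes,
                "false_positive_rate": fdr.false_positive_rate if fdr else None,
                "expected_false_positives": fdr.expected_false_positives if fdr else None,
                "fdr": fdr.fdr if fdr else None,
            },
            fh,
            indent=2,
        )
    return [os.path.join(out, f) for f in ["records.tsv", "diverged_ids.txt", "fdr.json"]]


def _stage_associate(config: PipelineConfig) -> list[str]:
    out = config.outdir
    cnes = read_bed(_require(_path(config, "cnes_bed", "cnes.bed"), "simulate", "associate"))
    genes = pd.read_csv(
        _require(_path(config, "genes_tsv", "genes.tsv"), "simulate", "associate"),
        sep="\t",
    )
    e = config.enrich
    domains = build_regulatory_domains(
        genes, e.basal_up, e.basal_down, e.max_extension
    )
    merged = merge_close(cnes, e.merge_gap)
    assoc = associate_cnes(merged, domains)
    rows = [
        (name, ",".join(sorted(genes_)) if genes_ else "")
        for name, genes_ in sorted(assoc.items())
    ]
    pd.DataFrame(rows, columns=["cne", "genes"]).to_csv(
        os.path.join(out, "associations.tsv"), sep="\t", index=False
    )
    dom_rows = [
        (d.gene_id, d.chrom, d.start, d.end, d.basal_start, d.basal_end)
        for d in domains
    ]
    pd.DataFrame(
        dom_rows,
        columns=["gene_id", "chrom", "start", "end", "basal_start", "basal_end"],
    ).to_csv(os.path.join(out, "domains.tsv"), sep="\t", index=False)
    return [os.path.join(out, "associations.tsv"), os.path.join(out, "domains.tsv")]


def _diverged_merged_sets(config: PipelineConfig):
    out = config.outdir
    cnes = read_bed(_require(_path(config, "cnes_bed", "cnes.bed"), "simulate", "enrich"))
    div_path = _require(os.path.join(out, "diverged_ids.txt"), "screen", "enrich")
    with open(div_path) as fh:
        diverged_ids = {line.strip() for line in fh if line.strip()}
    merged = merge_close(cnes, config.enrich.merge_gap)
    # a merged CNE is diverged if it contains any diverged source CNE
    by_chrom: dict[str, list] = {}
    for c in cnes:
        by_chrom.setdefault(c.chrom, []).append(c)
    fg, bg = [], []
    for m in merged:
        hit = any(
            c.name in diverged_ids and c.start < m.end and m.start < c.end
            for c in by_chrom.get(m.chrom, [])
        )
        (fg if hit else bg).append(m)
    return fg, bg


def _stage_enrich(config: PipelineConfig) -> list[str]:
    out = config.outdir
    fg, bg = _diverged_merged_sets(config)
    if not fg or not bg:
        raise PipelineError(
            "stage 'enrich' needs non-empty diverged and background CNE sets; "
            "run stage 'screen' first"
        )
    peaks = read_bed(_require(_path(config, "peaks_bed", "peaks.bed"), "simulate", "enrich"))
    seed = derive_seed(config.seed, "enrich")
    res = overlap_enrichment(
        fg, bg, peaks, "peaks", n_subsamples=config.enrich.n_subsamples, seed=seed
    )
    adjust_enrichments([res])
    enrichment_table([res]).to_csv(
        os.path.join(out, "enrichment.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    return [os.path.join(out, "enrichment.tsv")]


def _stage_motifs(config: PipelineConfig) -> list[str]:
    out = config.outdir
    tree = _load_tree(config)
    alns = read_alignment_dir(
        _require(_path(config, "alignments_dir", "alignments"), "simulate", "motifs")
    )
    library = read_meme(
        _require(_path(config, "motifs_meme", "motifs.meme"), "simulate", "motifs")
    )
    div_path = _require(os.path.join(out, "diverged_ids.txt"), "screen", "motifs")
    with open(div_path) as fh:
        diverged_ids = {line.strip() for line in fh if line.strip()}
    mp = config.motifs
    seed = derive_seed(config.seed, "motifs")
    ancestors = {a.cne_id: reconstruct_ancestral(a, tree) for a in alns}
    cne_gc = {cid: gc_content(anc.replace("-", "")) for cid, anc in ancestors.items()}
    excess_rows = []
    cutoff_rows = []
    for pwm in library[: mp.n_motifs_scored]:
        cuts = gc_cutoffs(
            pwm, mp.n_gc_bins, mp.n_seqs, mp.seq_len, mp.quantile, seed
        )
        for bi, cut in enumerate(cuts):
            cutoff_rows.append((pwm.motif_id, bi / (mp.n_gc_bins - 1), cut))
        records = compute_motif_scores(alns, ancestors, pwm)
        from .motifs import select_ancestral_pairs

        kept = select_ancestral_pairs(records, {pwm.motif_id: cuts}, cne_gc)
        fg_scores = {
            sp: [r.species_scores[sp] for r in kept if r.cne_id in diverged_ids]
            for sp in tree.species
        }
        bg_scores = {
            sp: [r.species_scores[sp] for r in kept if r.cne_id not in diverged_ids]
            for sp in tree.species
        }
        if not any(fg_scores.values()) or not any(bg_scores.values()):
            log.warning("motif %s: empty foreground or background", pwm.motif_id)
            continue
        for r in excess_score(fg_scores, bg_scores, mp.direction):
            excess_rows.append(
                (
                    pwm.motif_id, r.species, r.median_foreground,
                    r.median_background, r.excess, r.p_value, r.adjusted_p,
                )
            )
    pd.DataFrame(
        cutoff_rows, columns=["motif_id", "gc", "cutoff"]
    ).to_csv(os.path.join(out, "cutoffs.tsv"), sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        excess_rows,
        columns=[
            "motif_id", "species", "median_fg", "median_bg",
            "excess", "p_value", "adjusted_p",
        ],
    ).to_csv(os.path.join(out, "excess.tsv"), sep="\t", index=False, float_format="%.6g")
    return [os.path.join(out, "cutoffs.tsv"), os.path.join(out, "excess.tsv")]


def _stage_report(config: PipelineConfig) -> list[str]:
    out = config.outdir
    summary: dict = {}
    fdr_path = _require(os.path.join(out, "fdr.json"), "screen", "report")
    with open(fdr_path) as fh:
        summary["screen"] = json.load(fh)
    enr_path = os.path.join(out, "enrichment.tsv")
    if os.path.exists(enr_path):
        df = pd.read_csv(enr_path, sep="\t")
        summary["top_enrichments"] = df.head(5).to_dict("records")
    exc_path = os.path.join(out, "excess.tsv")
    if os.path.exists(exc_path):
        df = pd.read_csv(exc_path, sep="\t")
        summary["excess_scores"] = df.to_dict("records")
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return [os.path.join(out, "summary.json")]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "screen": _stage_screen,
    "associate": _stage_associate,
    "enrich": _stage_enrich,
    "motifs": _stage_motifs,
    "report": _stage_report,
}


def run_stage(stage: str, config: PipelineConfig) -> list[str]:
    """Run one pipeline stage; returns the paths it wrote.

    Each stage writes a manifest (parameters, derived seed, input
    checksums) under ``<outdir>/manifests/``.
    """
    if stage not in _STAGE_FN:
        raise PipelineError(f"unknown stage {stage!r}; choose from {STAGES}")
    os.makedirs(config.outdir, exist_ok=True)
    log.info("running stage %s", stage)
    inputs = [
        p
        for p in [
            _path(config, "tree", "tree.nwk"),
            _path(config, "cnes_bed", "cnes.bed"),
            _path(config, "genes_tsv", "genes.tsv"),
            _path(config, "peaks_bed", "peaks.bed"),
            _path(config, "motifs_meme", "motifs.meme"),
        ]
        if stage != "simulate"
    ]
    outputs = _STAGE_FN[stage](config)
    params = {
        "simulate": dataclasses.asdict(config.simulate),
        "screen": dataclasses.asdict(config.screen),
        "enrich": dataclasses.asdict(config.enrich),
        "motifs": dataclasses.asdict(config.motifs),
    }
    _write_manifest(config, stage, params.get(stage, params), inputs, outputs)
    return outputs


def run_all(config: PipelineConfig) -> list[str]:
    out = []
    for stage in STAGES:
        out.extend(run_stage(stage, config))
    return out
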