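"""Synthetic data with known ground truth.

Everything the screen consumes can be generated here at small scale:
a phylogeny with designated trait-loss lineages, CNE alignments evolved
under purifying selection with a planted fraction relaxed on the branches
private to the loss lineages, a gene/TSS annotation, regulatory peak sets
overlapping chosen CNEs, and a random motif library.

The sequence model is Jukes–Cantor: per branch the expected number of
substitutions per site is ``branch_length × constrained_rate``, multiplied
by ``relaxation_factor`` on branches whose entire leaf-descendant set lies
within the loss lineages when the CNE is labelled ``relaxed_in_loss``.
Constraint is a uniform per-CNE rate scaling; alignments are gap-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import CNEAlignment
from .trees import PhyloTree

_BASES = np.array(list("ACGT"))

CONSTRAINED = "constrained"
RELAXED = "relaxed_in_loss"


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth label for one simulated CNE."""

    cne_id: str
    sim_class: str  # "constrained" or "relaxed_in_loss"
    relaxation_factor: float

    def __post_init__(self) -> None:
        if self.sim_class not in (CONSTRAINED, RELAXED):
            raise ValueError(f"unknown class {self.sim_class}")
        if self.sim_class == CONSTRAINED and self.relaxation_factor != 1.0:
            raise ValueError("constrained CNEs must have relaxation_factor 1")
        if self.relaxation_factor < 1.0:
            raise ValueError("relaxation_factor must be >= 1")


# ---------------------------------------------------------------------------
# fixture phylogenies


def _join_ultrametric(clades, t_lo, t_hi, rng):
    """Randomly join (newick, height) clades into one ultrametric clade.

    Join times are drawn uniformly in (t_lo, t_hi) with the final join
    forced to t_hi, so the returned clade has height exactly t_hi.
    """
    clades = list(clades)
    if len(clades) == 1:
        return clades[0]
    times = np.sort(rng.uniform(t_lo, t_hi, size=len(clades) - 1))
    times[-1] = t_hi
    for t in times:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        (nwk_j, h_j) = clades.pop(j)
        (nwk_i, h_i) = clades.pop(i)
        merged = f"({nwk_i}:{t - h_i:.6f},{nwk_j}:{t - h_j:.6f})"
        clades.append((merged, t))
    return clades[0]


def generate_fixture_tree(
    n_other_species: int,
    n_loss_species: int,
    depth: float,
    seed: int,
    scattered: bool = False,
) -> PhyloTree:
    """Random ultrametric binary fixture tree with trait-loss leaves.

    By default the loss species form a single clade nested inside a small
    "near" group of close relatives (single-origin loss, snake-style); the
    near group becomes ``local_comparison_species``.  With ``scattered=True``
    each loss leaf is grafted as the sister of a distinct non-loss leaf, so
    the losses are phylogenetically independent (subterranean-style).

    ``depth`` is the root-to-tip path length in substitutions/site; the
    tree is ultrametric so every leaf has the same distance to the root.
    """
    if n_other_species < 3 or n_loss_species < 1 or depth <= 0:
        raise ValueError("need n_other_species >= 3, n_loss_species >= 1, depth > 0")
    if scattered and n_loss_species > n_other_species:
        raise ValueError("scattered mode needs n_other_species >= n_loss_species")
    rng = np.random.default_rng(seed)
    others = [f"sp{i + 1:02d}" for i in range(n_other_species)]
    losses = [f"loss{i + 1}" for i in range(n_loss_species)]

    if scattered:
        hosts = list(rng.choice(n_other_species, size=n_loss_species, replace=False))
        cherry_h = 0.25 * depth
        clades = []
        for i, sp in enumerate(others):
            if i in hosts:
                lf = losses[hosts.index(i)]
                clades.append(
                    (f"({sp}:{cherry_h:.6f},{lf}:{cherry_h:.6f})", cherry_h)
                )
            else:
                clades.append((sp, 0.0))
        nwk, _ = _join_ultrametric(clades, 0.3 * depth, depth, rng)
        return PhyloTree(nwk + ";", tuple(losses), ())

    n_near = max(1, min(3, n_other_species - 2))
    near, far = others[:n_near], others[n_near:]
    loss_clade = _join_ultrametric(
        [(s, 0.0) for s in losses], 0.05 * depth, 0.35 * depth, rng
    ) if n_loss_species > 1 else (losses[0], 0.0)
    near_clades = [(s, 0.0) for s in near]
    if len(near_clades) > 1:
        near_clade = _join_ultrametric(near_clades, 0.05 * depth, 0.5 * depth, rng)
    else:
        near_clade = near_clades[0]
    ingroup = _join_ultrametric([loss_clade, near_clade], 0.55 * depth, 0.6 * depth, rng)
    far_clade = _join_ultrametric([(s, 0.0) for s in far], 0.3 * depth, 0.8 * depth, rng)
    root, _ = _join_ultrametric([ingroup, far_clade], 0.9 * depth, depth, rng)
    return PhyloTree(root + ";", tuple(losses), tuple(near))


# ---------------------------------------------------------------------------
# sequence evolution


def _truncated_geometric_lengths(n, mean, lo, hi, rng):
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = rng.geometric(1.0 / mean, size=max(8, 2 * (n - filled)))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def _evolve_branch(parent_seq, d_sub, rng):
    """JC69: substitute each site with prob 3/4(1 - exp(-4d/3))."""
    p = 0.75 * (1.0 - np.exp(-4.0 * d_sub / 3.0))
    mask = rng.random(parent_seq.size) < p
    child = parent_seq.copy()
    n = int(mask.sum())
    if n:
        child[mask] = (child[mask] + rng.integers(1, 4, size=n)) % 4
    return child


def _evolve_tree(tree: PhyloTree, root_seq, rate_for_edge, rng):
    """Evolve root_seq down the tree; returns {species: int array}."""
    seqs = {}
    node_seq = {id(tree.tree.seed_node): root_seq}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = node_seq[id(node.parent_node)]
        child = _evolve_branch(parent, rate_for_edge(node.edge), rng)
        node_seq[id(node)] = child
        if node.is_leaf():
            seqs[node.taxon.label] = child
    return seqs


def evolve_cnes(
    tree: PhyloTree,
    n_cnes: int,
    length_mean: float = 200.0,
    constrained_rate: float = 0.15,
    relaxed_fraction: float = 0.0,
    relaxation_factor: float = 1.0,
    seed: int = 0,
    base_composition=(0.25, 0.25, 0.25, 0.25),
    length_range=(30, 1000),
    chrom: str = "chr1",
    spacing: int = 1000,
    _return_roots: bool = False,
):
    """Simulate gap-free CNE alignments along ``tree`` with planted relaxation.

    CNE lengths are geometric with the given mean, truncated to
    ``length_range`` (default [30, 1000] bp).  A fraction
    ``relaxed_fraction`` of CNEs is labelled ``relaxed_in_loss``: on branches
    private to the loss lineages their substitution rate is multiplied by
    ``relaxation_factor``.  Returns ``(alignments, truths)``; CNEs are placed
    end to end on one chromosome with ``spacing`` bp between them.
    """
    if not (0.0 <= relaxed_fraction <= 1.0):
        raise ValueError("relaxed_fraction must be in [0, 1]")
    if relaxed_fraction > 0 and not tree.loss_species:
        raise ValueError("relaxed_fraction > 0 requires loss_species on the tree")
    if not (0.0 < constrained_rate <= 1.0):
        raise ValueError("constrained_rate must be in (0, 1]")
    if relaxation_factor < 1.0:
        raise ValueError("relaxation_factor must be >= 1")
    rng = np.random.default_rng(seed)
    base = np.asarray(base_composition, dtype=float)
    base = base / base.sum()
    lengths = _truncated_geometric_lengths(
        n_cnes, length_mean, length_range[0], length_range[1], rng
    )
    n_relaxed = int(round(relaxed_fraction * n_cnes))
    relaxed_idx = set(
        rng.choice(n_cnes, size=n_relaxed, replace=False).tolist()
    ) if n_relaxed else set()
    loss_edges = {id(e) for e in tree.loss_exclusive_edges()}

    alignments, truths, roots = [], [], {}
    pos = 0
    for i in range(n_cnes):
        L = int(lengths[i])
        relaxed = i in relaxed_idx
        factor = relaxation_factor if relaxed else 1.0

        def rate_for_edge(edge, _factor=factor):
            r = (edge.length or 0.0) * constrained_rate
            if _factor != 1.0 and id(edge) in loss_edges:
                r *= _factor
            return r

        root_seq = rng.choice(4, size=L, p=base)
        seqs = _evolve_tree(tree, root_seq, rate_for_edge, rng)
        cne_id = f"cne{i:05d}"
        alignments.append(
            CNEAlignment(
                cne_id,
                chrom,
                pos,
                pos + L,
                {sp: "".join(_BASES[s]) for sp, s in seqs.items()},
            )
        )
        truths.append(SimTruth(cne_id, RELAXED if relaxed else CONSTRAINED, factor))
        roots[cne_id] = "".join(_BASES[root_seq])
        pos += L + spacing
    if _return_roots:
        return alignments, truths, roots
    return alignments, truths


# ---------------------------------------------------------------------------
# annotation fixtures


def generate_gene_annotation(
    n_genes: int, chrom_length: int, seed: int, chrom: str = "chr1"
) -> pd.DataFrame:
    """Random gene/TSS table: columns chrom, tss, strand, gene_id.

    TSS positions are unique and strictly increasing; strands random.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_genes > chrom_length:
        raise ValueError("cannot place genes without TSS collision")
    rng = np.random.default_rng(seed)
    tss: set[int] = set()
    tries = 0
    while len(tss) < n_genes:
        tss.update(rng.integers(0, chrom_length, size=n_genes - len(tss)).tolist())
        tries += 1
        if tries > 1000:
            raise ValueError("infeasible TSS placement")
    positions = np.array(sorted(tss))
    strands = rng.choice(["+", "-"], size=n_genes)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "tss": positions,
            "strand": strands,
            "gene_id": [f"gene{i:04d}" for i in range(n_genes)],
        }
    )


def generate_peaks(
    cnes: pd.DataFrame,
    overlap_fraction: float,
    n_decoys: int,
    seed: int,
    chrom_length: int | None = None,
    peak_length: int = 300,
) -> pd.DataFrame:
    """Peak BED fixture: a chosen fraction of CNEs each get one overlapping
    peak (>= 1 bp intersection); decoy peaks intersect no CNE.

    ``cnes`` is a BED-like frame with chrom/start/end[/name].
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cnes = cnes.sort_values(["chrom", "start"]).reset_index(drop=True)
    if chrom_length is None:
        chrom_length = int(cnes["end"].max()) + 100 * peak_length
    k = int(np.floor(overlap_fraction * len(cnes)))
    chosen = rng.choice(len(cnes), size=k, replace=False) if k else np.array([], int)
    rows = []
    for j, i in enumerate(sorted(chosen.tolist())):
        row = cnes.iloc[i]
        lo = max(0, int(row.start) - peak_length + 1)
        hi = int(row.end) - 1  # start <= end-1 guarantees >=1 bp overlap
        start = int(rng.integers(lo, hi + 1))
        rows.append((row.chrom, start, start + peak_length, f"peak{j:04d}"))
    # decoys by rejection sampling against the CNE intervals
    by_chrom = {
        c: sub[["start", "end"]].to_numpy()
        for c, sub in cnes.groupby("chrom")
    }
    chroms = sorted(by_chrom)
    placed, tries = 0, 0
    while placed < n_decoys:
        tries += 1
        if tries > 200 * max(1, n_decoys):
            raise ValueError("not enough CNE-free space for decoy peaks")
        c = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max(1, chrom_length - peak_length)))
        iv = by_chrom[c]
        if np.any((iv[:, 0] < start + peak_length) & (iv[:, 1] > start)):
            continue
        rows.append((c, start, start + peak_length, f"decoy{placed:04d}"))
        placed += 1
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def generate_motif_library(n_motifs: int, length_range=(6, 12), seed: int = 0):
    """Random PWM library with per-column Dirichlet concentrations spanning
    a wide information-content range."""
    from .motifs import PWM

    lo, hi = length_range
    if lo < 4 or hi < lo:
        raise ValueError("motif lengths must satisfy 4 <= lo <= hi")
    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(n_motifs):
        L = int(rng.integers(lo, hi + 1))
        cols = []
        for _ in range(L):
            alpha = float(rng.uniform(0.08, 2.0))
            cols.append(rng.dirichlet([alpha] * 4))
        pwms.append(PWM(f"motif{i:02d}", np.array(cols)))
    return pwms


# ---------------------------------------------------------------------------
# motif-decay fixture


def plant_motif_decay_dataset(
    tree: PhyloTree,
    pwm,
    n_foreground: int,
    n_background: int,
    length: int = 200,
    constrained_rate: float = 0.05,
    seed: int = 0,
    gc: float = 0.5,
):
    """CNEs whose ancestor carries one planted consensus binding site.

    Foreground CNEs get the site at a random position in the root sequence;
    all species then evolve under constraint, and afterwards the site
    positions of every trait-loss species are overwritten with random bases
    (site turnover after trait loss).  Background CNEs carry no site.
    Returns ``(fg_alignments, bg_alignments, ancestors)`` where ``ancestors``
    maps cne_id to the true root sequence.
    """
    rng = np.random.default_rng(seed)
    consensus = np.argmax(pwm.matrix, axis=1)
    L_site = consensus.size
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    loss = set(tree.loss_species)

    def one(cne_id, planted, pos0):
        root = rng.choice(4, size=length, p=base)
        site_at = None
        if planted:
            site_at = int(rng.integers(0, length - L_site + 1))
            root[site_at : site_at + L_site] = consensus
        seqs = _evolve_tree(
            tree, root, lambda e: (e.length or 0.0) * constrained_rate, rng
        )
        if planted:
            for sp in seqs:
                if sp in loss:
                    seqs[sp] = seqs[sp].copy()
                    seqs[sp][site_at : site_at + L_site] = rng.choice(
                        4, size=L_site, p=base
                    )
        aln = CNEAlignment(
            cne_id, "chr1", pos0, pos0 + length,
            {sp: "".join(_BASES[s]) for sp, s in seqs.items()},
        )
        return aln, "".join(_BASES[root])

    fg, bg, ancestors = [], [], {}
    pos = 0
    for i in range(n_foreground):
        aln, root = one(f"fg{i:04d}", True, pos)
        fg.append(aln)
        ancestors[aln.cne_id] = root
        pos += length + 500
    for i in range(n_background):
        aln, root = one(f"bg{i:04d}", False, pos)
        bg.append(aln)
        ancestors[aln.cne_id] = root
        pos += length + 500
    return fg, bg, ancestors


def write_truth_table(truths, path) -> None:
    pd.DataFrame(
        [(t.cne_id, t.sim_class, t.relaxation_factor) for t in truths],
        columns=["cne_id", "class", "relaxation_factor"],
    ).to_csv(path, sep="\t", index=False)
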