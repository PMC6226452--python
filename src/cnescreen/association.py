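"""GREAT-style gene association and region-set enrichment.

Each gene gets a basal regulatory domain (5 kb upstream / 1 kb downstream
of the TSS, strand-aware) extended on both sides up to 300 kb or until the
nearest other gene's basal domain, whichever comes first.  A CNE is a
candidate target of every gene whose domain it overlaps by at least 1 bp.

Enrichment of diverged (foreground) CNEs in a gene set or peak set is
tested two ways: a one-sided Fisher's exact test on the 2x2 table against
the non-diverged background, and a Z-score from repeatedly drawing
same-sized random subsets of the full CNE universe and counting their
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .intervals import GenomicInterval
from .screen import bh_adjust


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    chrom: str
    basal_start: int
    basal_end: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (self.start <= self.basal_start < self.basal_end <= self.end):
            raise ValueError(f"{self.gene_id}: basal not contained in domain")


def build_regulatory_domains(
    genes: pd.DataFrame,
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_extension: int = 300000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains from a TSS table.

    ``genes`` needs columns chrom, tss, strand, gene_id.  The basal domain
    is [tss - basal_up, tss + basal_down) on the + strand and mirrored on
    the - strand; each side then extends outward up to ``max_extension`` bp
    beyond the basal edge, stopping earlier at the nearest other gene's
    basal domain or the chromosome boundary.  Extensions never invade a
    foreign basal domain, but basal domains themselves may overlap.
    """
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids")
    out = []
    for chrom, sub in genes.groupby("chrom", sort=True):
        sub = sub.sort_values("tss")
        size = None if chrom_sizes is None else chrom_sizes.get(chrom)
        basals = []
        for _, g in sub.iterrows():
            if g.strand == "+":
                b0, b1 = g.tss - basal_up, g.tss + basal_down
            else:
                b0, b1 = g.tss - basal_down, g.tss + basal_up
            b0 = max(0, int(b0))
            b1 = int(b1) if size is None else min(size, int(b1))
            basals.append((b0, b1, g.gene_id))
        for i, (b0, b1, gid) in enumerate(basals):
            # each side extends until the nearest foreign basal edge: any
            # foreign basal reaching left of b0 stops the left extension at
            # its end (clipped to b0); mirrored on the right
            left_stop = 0
            right_stop = size if size is not None else None
            for j, b in enumerate(basals):
                if j == i:
                    continue
                if b[0] < b0:
                    left_stop = max(left_stop, min(b[1], b0))
                if b[1] > b1:
                    edge = max(b[0], b1)
                    right_stop = edge if right_stop is None else min(right_stop, edge)
            start = min(max(b0 - max_extension, left_stop), b0)
            end = b1 + max_extension
            if right_stop is not None:
                end = min(end, right_stop)
            end = max(end, b1)
            if size is not None:
                end = min(end, size)
                start = max(0, start)
            out.append(RegulatoryDomain(gid, chrom, b0, b1, start, end))
    return out


def associate_cnes(
    cnes, domains: list[RegulatoryDomain]
) -> dict[str, set[str]]:
    """Map CNE name -> gene ids whose regulatory domain it overlaps (>=1 bp)."""
    trees: dict[str, IntervalTree] = {}
    for d in domains:
        trees.setdefault(d.chrom, IntervalTree()).addi(d.start, d.end, d.gene_id)
    out: dict[str, set[str]] = {}
    for cne in cnes:
        name = cne.name or f"{cne.chrom}:{cne.start}-{cne.end}"
        hits = trees.get(cne.chrom, IntervalTree()).overlap(cne.start, cne.end)
        out[name] = {h.data for h in hits}
    return out


# ---------------------------------------------------------------------------
# enrichment statistics


@dataclass
class EnrichmentResult:
    set_name: str
    a: int  # foreground in set
    b: int  # foreground not in set
    c: int  # background in set
    d: int  # background not in set
    odds_ratio: float | None
    p_value: float
    adjusted_p: float | None = None
    subsample_z: float | None = None
    n_subsamples: int = 0


def fisher_enrichment(
    foreground, background, in_set_predicate, set_name: str
) -> EnrichmentResult:
    """One-sided (enrichment) Fisher's exact test for a CNE property.

    Builds the 2x2 table of foreground/background CNEs satisfying the
    predicate and returns the hypergeometric upper-tail p-value together
    with the sample odds ratio ad/bc (None on a zero margin).
    """
    fg = list(foreground)
    bg = list(background)
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    try:
        if set(fg) & set(bg):
            raise ValueError("foreground and background must be disjoint")
    except TypeError:
        pass  # unhashable items: disjointness is the caller's contract
    a = sum(bool(in_set_predicate(x)) for x in fg)
    b = len(fg) - a
    c = sum(bool(in_set_predicate(x)) for x in bg)
    d = len(bg) - c
    if (a + c) == 0 or (b + d) == 0:
        return EnrichmentResult(set_name, a, b, c, d, None, 1.0)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    odds = (a * d) / (b * c) if b * c > 0 else None
    return EnrichmentResult(set_name, a, b, c, d, odds, float(p))


def adjust_enrichments(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """BH-adjust p-values across a batch of enrichment tests, in place."""
    if results:
        adj = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, adj):
            r.adjusted_p = float(q)
    return results


def subsample_z(
    observed: int,
    universe,
    sample_size: int,
    in_set_predicate,
    n_subsamples: int = 10000,
    seed: int = 0,
) -> float:
    """Overlap Z-score against same-sized random subsets of the universe.

    Draws ``n_subsamples`` without-replacement subsets of ``sample_size``
    CNEs from the universe, counts how many satisfy the predicate, and
    standardizes the observed count against that null (sample sd, n-1).
    """
    universe = list(universe)
    if sample_size > len(universe):
        raise ValueError("sample_size exceeds universe")
    if n_subsamples < 100:
        raise ValueError("n_subsamples must be >= 100")
    flags = np.fromiter(
        (bool(in_set_predicate(x)) for x in universe), dtype=bool, count=len(universe)
    )
    if flags.all() or not flags.any():
        raise ValueError("predicate constant over the universe; Z undefined")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_subsamples, dtype=np.int64)
    n = len(universe)
    for i in range(n_subsamples):
        idx = rng.choice(n, size=sample_size, replace=False)
        counts[i] = int(flags[idx].sum())
    sd = counts.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate subsample distribution")
    return float((observed - counts.mean()) / sd)


def peak_overlap_predicate(peaks):
    """Predicate factory: does a CNE intersect any peak by >= 1 bp?"""
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)

    def pred(cne: GenomicInterval) -> bool:
        t = trees.get(cne.chrom)
        return bool(t and t.overlaps(cne.start, cne.end))

    return pred


def overlap_enrichment(
    foreground,
    background,
    peaks,
    set_name: str,
    n_subsamples: int = 10000,
    seed: int = 0,
) -> EnrichmentResult:
    """Enrichment of foreground CNEs within a peak set.

    Fisher's exact test against the background plus a subsampling Z-score
    drawn from the full universe (foreground + background).
    """
    fg = list(foreground)
    bg = list(background)
    pred = peak_overlap_predicate(list(peaks))
    res = fisher_enrichment(fg, bg, pred, set_name)
    universe = fg + bg
    try:
        res.subsample_z = subsample_z(
            res.a, universe, len(fg), pred, n_subsamples=n_subsamples, seed=seed
        )
        res.n_subsamples = n_subsamples
    except ValueError:
        res.subsample_z = None
    return res


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            (
                r.set_name, r.a, r.b, r.c, r.d,
                r.odds_ratio, r.p_value, r.adjusted_p, r.subsample_z,
            )
            for r in results
        ],
        columns=[
            "set_name", "a", "b", "c", "d",
            "odds_ratio", "p_value", "adjusted_p", "subsample_z",
        ],
    )
    return df.sort_values(
        "adjusted_p" if df["adjusted_p"].notna().any() else "p_value"
    ).reset_index(drop=True)
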