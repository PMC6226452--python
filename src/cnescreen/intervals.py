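"""Interval arithmetic turning conserved-element calls into CNEs.

Coordinates are 0-based half-open (BED). Two rules matter and both carry
strict boundaries: coding sequence is expanded by a 50 bp flank before
subtraction and remainders shorter than 30 bp are dropped; for enrichment
testing, CNEs separated by a gap strictly smaller than 50 bp are merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                iv = GenomicInterval(
                    parts[0],
                    int(parts[1]),
                    int(parts[2]),
                    parts[3] if len(parts) > 3 else None,
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
            out.append(iv)
    return out


def write_bed(intervals, path) -> None:
    rows = [
        (iv.chrom, iv.start, iv.end, iv.name if iv.name else ".")
        for iv in sorted(intervals)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def _merge_touching(ivs):
    """Union of intervals (overlapping or bookended) per chromosome."""
    out = []
    for iv in sorted(ivs, key=lambda i: (i.chrom, i.start, i.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def derive_cnes(
    conserved,
    coding,
    flank: int = 50,
    min_length: int = 30,
) -> list[GenomicInterval]:
    """Subtract flank-expanded coding regions from conserved elements.

    Every coding interval is widened by ``flank`` bp on both sides (clipped
    at 0); the widened set is subtracted from each conserved interval and
    remainders of at least ``min_length`` bp are kept.  Output is sorted
    and non-overlapping, named after the source element.
    """
    if flank < 0 or min_length < 0:
        raise ValueError("flank and min_length must be >= 0")
    expanded = _merge_touching(
        GenomicInterval(c.chrom, max(0, c.start - flank), c.end + flank)
        for c in coding
    )
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in expanded:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    out = []
    for cons in sorted(conserved):
        cursor = cons.start
        pieces = []
        for mask in by_chrom.get(cons.chrom, []):
            if mask.end <= cursor or mask.start >= cons.end:
                continue
            if mask.start > cursor:
                pieces.append((cursor, mask.start))
            cursor = max(cursor, mask.end)
        if cursor < cons.end:
            pieces.append((cursor, cons.end))
        for k, (s, e) in enumerate(pieces):
            if e - s >= min_length:
                name = cons.name or f"{cons.chrom}:{cons.start}-{cons.end}"
                out.append(
                    GenomicInterval(cons.chrom, s, e, f"{name}.{k}" if len(pieces) > 1 else name)
                )
    return sorted(out)


def merge_close(cnes, max_gap: int = 50) -> list[GenomicInterval]:
    """Merge CNEs whose gap is strictly smaller than ``max_gap`` bp.

    Chains of close CNEs collapse into one interval spanning the chain;
    merging never crosses chromosomes.  Idempotent: a second application
    changes nothing (merged intervals are separated by gaps >= max_gap).
    """
    merged: list[GenomicInterval] = []
    group_sizes: list[int] = []
    for iv in sorted(cnes, key=lambda i: (i.chrom, i.start, i.end)):
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end < max_gap
        ):
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(
                    iv.chrom, merged[-1].start, iv.end, merged[-1].name
                )
            group_sizes[-1] += 1
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end, iv.name))
            group_sizes.append(1)
    # renumber merged groups for traceability
    out = []
    for iv, n in zip(merged, group_sizes):
        name = iv.name if n == 1 and iv.name else f"{iv.chrom}:{iv.start}-{iv.end}"
        out.append(GenomicInterval(iv.chrom, iv.start, iv.end, name))
    return out
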