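"""Per-CNE multiple sequence alignments and FASTA I/O."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN-")


@dataclass
class CNEAlignment:
    """One conserved non-coding element's gapped per-species sequences.

    Coordinates are 0-based half-open on the reference assembly; sequences
    are uppercase over the alphabet ``ACGTN-`` and all have equal gapped
    length.
    """

    cne_id: str
    chrom: str
    start: int
    end: int
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.cne_id}: unequal gapped sequence lengths")
        for sp, s in self.sequences.items():
            bad = set(s) - _VALID
            if bad:
                raise ValueError(f"{self.cne_id}/{sp}: invalid characters {bad}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.cne_id}: bad coordinates {self.start}..{self.end}")

    @property
    def aligned_length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=sp, description="")
            for sp, s in self.sequences.items()
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def read_fasta(cls, path, cne_id=None, chrom="chr1", start=0, end=None):
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(path, "fasta")
        }
        if cne_id is None:
            cne_id = os.path.splitext(os.path.basename(path))[0]
        if end is None:
            end = start + (len(next(iter(seqs.values()))) if seqs else 1)
        return cls(cne_id, chrom, start, end, seqs)


def write_alignment_dir(alignments, directory) -> None:
    os.makedirs(directory, exist_ok=True)
    for aln in alignments:
        aln.write_fasta(os.path.join(directory, f"{aln.cne_id}.fa"))


def read_alignment_dir(directory) -> list[CNEAlignment]:
    out = []
    for name in sorted(os.listdir(directory)):
        if name.endswith((".fa", ".fasta")):
            out.append(CNEAlignment.read_fasta(os.path.join(directory, name)))
    return out
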