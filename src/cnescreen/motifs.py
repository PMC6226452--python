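"""Transcription-factor motif scoring and decay statistics.

A CNE's motif content is summarized by a position-agnostic occupancy
score: every possible binding position on both strands contributes
softplus2(llr) = log2(1 + 2^llr), where llr is the log2 likelihood ratio
of the site under the PWM versus a GC-matched background.  Strong sites
dominate but many weak sites also add up, and no assumption is made about
where in the element the site sits.  Long sequences are scored in 200-bp
windows (the maximum window score is reported) so that local site clusters
are not diluted.

Motif-presence cutoffs are calibrated per GC content: for each of 21 GC
bins, random 200-bp sequences with one inserted sampled site are scored
and the 90% quantile becomes the bin's cutoff, so that ~10% of GC-matched
random sequences with a site still score at or above it.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import motifs as bio_motifs
from scipy import stats

from .screen import bh_adjust

_BASE_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PWM:
    """Position probability matrix (columns of base probabilities)."""

    motif_id: str
    matrix: np.ndarray  # shape (L, 4), rows sum to 1
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 4:
            raise ValueError("PWM must be L x 4 with L >= 4")
        if np.any(m < 0):
            raise ValueError("PWM probabilities must be >= 0")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def column_ics(self) -> np.ndarray:
        return np.array([column_ic(c) for c in self.matrix])

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.matrix, axis=1))


def column_ic(column) -> float:
    """Information content of one PWM column: 2 + sum p*log2 p, in bits."""
    p = np.asarray(column, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
        raise ValueError("column must be a probability distribution")
    nz = p[p > 0]
    return float(2.0 + np.sum(nz * np.log2(nz)))


# ---------------------------------------------------------------------------
# MEME-minimal text I/O


def write_meme(pwms, path_or_handle) -> None:
    import os

    own = isinstance(path_or_handle, (str, bytes, os.PathLike))
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.length} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in p.matrix:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
    finally:
        if own:
            fh.close()


def read_meme(path) -> list[PWM]:
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        mat = np.array(
            [[m.pwm[b][i] for b in "ACGT"] for i in range(m.length)]
        )
        mat = mat / mat.sum(axis=1, keepdims=True)
        out.append(PWM(m.name, mat))
    return out


# ---------------------------------------------------------------------------
# occupancy scoring


def _encode(seq: str) -> np.ndarray:
    return np.fromiter(
        (_BASE_TO_INT.get(c, 4) for c in seq.upper()), dtype=np.int8, count=len(seq)
    )


def _position_scores(s: np.ndarray, logodds: np.ndarray):
    L = logodds.shape[0]
    m = s.size - L + 1
    scores = np.zeros(m)
    valid = np.ones(m, dtype=bool)
    for i in range(L):
        b = s[i : i + m]
        ok = b < 4
        valid &= ok
        scores += logodds[i, np.where(ok, b, 0)]
    return scores, valid


def _window_starts(n: int, window: int, step: int) -> list[int]:
    if n <= window:
        return [0]
    span = n - window
    k = int(np.ceil(span / step)) + 1
    starts = {int(round(x)) for x in np.linspace(0, span, k)}
    starts |= {span - s for s in starts}  # strand-symmetric coverage
    return sorted(starts)


def score_sequence(
    seq: str,
    pwm: PWM,
    gc_background: float = 0.5,
    pseudocount: float | None = None,
    window: int = 200,
    step: int = 100,
) -> float:
    """Occupancy score of a sequence for one motif.

    O(w) = sum over all positions and both strands of log2(1 + 2^llr)
    within each window; the sequence score is the maximum over windows.
    Positions containing N contribute nothing; a sequence shorter than the
    motif scores 0.  The background is the GC-matched i.i.d. model
    bg = {A,T: (1-gc)/2; C,G: gc/2}.
    """
    pc = pwm.pseudocount if pseudocount is None else pseudocount
    gc = min(max(gc_background, 0.01), 0.99)
    s = _encode(seq)
    if s.size < pwm.length:
        warnings.warn(f"sequence shorter than motif {pwm.motif_id}; score 0")
        return 0.0
    bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    logodds = np.log2((pwm.matrix + pc) / bg)
    best = 0.0
    for start in _window_starts(s.size, window, step):
        w = s[start : start + window]
        rc = np.where(w < 4, 3 - w, 4)[::-1]
        total = 0.0
        for strand_seq in (w, rc):
            sc, valid = _position_scores(strand_seq, logodds)
            if sc.size:
                total += float(np.logaddexp2(0.0, sc[valid]).sum())
        best = max(best, total) if start else total
    return best


def gc_content(seq: str) -> float:
    s = _encode(seq)
    bases = s[s < 4]
    if bases.size == 0:
        return 0.5
    return float(np.isin(bases, (1, 2)).mean())


def random_gc_sequence(length: int, gc: float, rng) -> np.ndarray:
    g = min(max(gc, 0.01), 0.99)
    p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    return rng.choice(4, size=length, p=p)


def sample_site(pwm: PWM, rng) -> np.ndarray:
    """Draw one binding site column-wise from the PWM probabilities."""
    return np.array(
        [rng.choice(4, p=col / col.sum()) for col in pwm.matrix], dtype=np.int8
    )


_INT_TO_BASE = np.array(list("ACGT"))


def with_site_sequence(pwm: PWM, seq_len: int, gc: float, rng) -> str:
    """Random GC-matched sequence with one sampled site inserted."""
    s = random_gc_sequence(seq_len, gc, rng)
    site = sample_site(pwm, rng)
    pos = int(rng.integers(0, seq_len - pwm.length + 1))
    s[pos : pos + pwm.length] = site
    return "".join(_INT_TO_BASE[s])


def gc_bin_centers(n_bins: int = 21) -> np.ndarray:
    return np.linspace(0.0, 1.0, n_bins)


def gc_cutoffs(
    pwm: PWM,
    n_bins: int = 21,
    n_seqs: int = 100,
    seq_len: int = 200,
    quantile: float = 0.9,
    seed: int = 0,
) -> np.ndarray:
    """GC-dependent motif score cutoffs.

    For each GC bin (0, 5, ..., 100%; generation clamped to [1%, 99%]),
    ``n_seqs`` random sequences each receive one sampled binding site at a
    uniform random position and are scored against a background of the
    bin's GC.  The cutoff is the empirical ``quantile`` order statistic
    chosen so that a fresh with-site sequence exceeds it with probability
    ~1 - quantile: the ceil(q*(n+1))-th smallest score.
    """
    if n_seqs < 10:
        raise ValueError("n_seqs must be >= 10")
    rng = np.random.default_rng(seed)
    k = min(n_seqs, int(np.ceil(quantile * (n_seqs + 1))))
    out = np.empty(n_bins)
    for bi, g in enumerate(gc_bin_centers(n_bins)):
        scores = np.sort(
            [
                score_sequence(with_site_sequence(pwm, seq_len, g, rng), pwm, g)
                for _ in range(n_seqs)
            ]
        )
        out[bi] = scores[k - 1]
    return out


def nearest_gc_bin(gc: float, n_bins: int = 21) -> int:
    """Index of the nearest GC bin; ties go to the lower bin."""
    idx = int(np.ceil(gc * (n_bins - 1) - 0.5))
    return min(max(idx, 0), n_bins - 1)


# ---------------------------------------------------------------------------
# CNE-motif pair selection and decay statistics


@dataclass
class MotifScoreRecord:
    cne_id: str
    motif_id: str
    ancestral_score: float
    species_scores: dict[str, float]


def compute_motif_scores(
    alignments, ancestors: dict[str, str], pwm: PWM
) -> list[MotifScoreRecord]:
    """Score the ancestral and every species sequence of each CNE.

    Gaps are stripped before scoring; the background GC is the ancestral
    sequence's GC so that species scores are comparable within a CNE.
    """
    out = []
    for aln in alignments:
        anc = ancestors[aln.cne_id].replace("-", "")
        gc = gc_content(anc)
        rec = MotifScoreRecord(
            aln.cne_id,
            pwm.motif_id,
            score_sequence(anc, pwm, gc),
            {
                sp: score_sequence(seq.replace("-", ""), pwm, gc)
                for sp, seq in aln.sequences.items()
            },
        )
        out.append(rec)
    return out


def select_ancestral_pairs(
    records: list[MotifScoreRecord],
    cutoffs: dict[str, np.ndarray],
    cne_gc: dict[str, float],
) -> list[MotifScoreRecord]:
    """Keep CNE-motif pairs whose ancestral sequence scores strictly above
    the cutoff of the CNE's nearest GC bin (ancestral motif presence)."""
    out = []
    for rec in records:
        if rec.cne_id not in cne_gc:
            raise KeyError(f"no GC value for {rec.cne_id}")
        table = cutoffs[rec.motif_id]
        cut = table[nearest_gc_bin(cne_gc[rec.cne_id], len(table))]
        if rec.ancestral_score > cut:
            out.append(rec)
    return out


@dataclass
class ExcessScoreResult:
    species: str
    median_foreground: float
    median_background: float
    excess: float
    p_value: float
    adjusted_p: float | None = None


def excess_score(
    foreground_scores: dict[str, list],
    background_scores: dict[str, list],
    direction: str = "greater",
) -> list[ExcessScoreResult]:
    """Per-species excess motif score of foreground over background CNEs.

    excess = median(foreground) - median(background); the p-value is a
    one-sided Wilcoxon rank-sum test (normal approximation with tie and
    continuity correction) in the configured direction, BH-adjusted across
    species.  Sensible power needs >= 20 values per group.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    results = []
    for sp in foreground_scores:
        fg = np.asarray(foreground_scores[sp], dtype=float)
        bg = np.asarray(background_scores[sp], dtype=float)
        if fg.size == 0 or bg.size == 0:
            raise ValueError(f"empty score list for {sp}")
        _, p = stats.mannwhitneyu(
            fg, bg, alternative=direction, use_continuity=True, method="asymptotic"
        )
        results.append(
            ExcessScoreResult(
                sp,
                float(np.median(fg)),
                float(np.median(bg)),
                float(np.median(fg) - np.median(bg)),
                float(p),
            )
        )
    adj = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, adj):
        r.adjusted_p = float(q)
    return results


# ---------------------------------------------------------------------------
# IC-binned motif randomization control


def randomize_motifs(
    library: list[PWM], n_ic_bins: int = 20, seed: int = 0
) -> list[PWM]:
    """Shuffle motif columns within information-content bins.

    All columns of the library are pooled, ranked by IC and split into
    ``n_ic_bins`` equal-frequency bins; every column of every motif is then
    replaced by a uniformly drawn column from its own bin.  Motif lengths
    are preserved, and the randomized motifs keep the IC profile of the
    originals while losing their base preferences.
    """
    pool = [col for p in library for col in p.matrix]
    if len(pool) < n_ic_bins:
        raise ValueError("library has fewer columns than IC bins")
    ics = np.array([column_ic(c) for c in pool])
    order = np.argsort(ics, kind="mergesort")
    bin_of = np.empty(len(pool), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_ic_bins)):
        bin_of[chunk] = b
    members = [np.flatnonzero(bin_of == b) for b in range(n_ic_bins)]
    rng = np.random.default_rng(seed)
    out = []
    i = 0
    for p in library:
        cols = []
        for _ in range(p.length):
            b = bin_of[i]
            j = members[b][int(rng.integers(0, members[b].size))]
            cols.append(pool[j])
            i += 1
        out.append(PWM(p.motif_id + "_rand", np.array(cols), p.pseudocount))
    return out
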