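"""Screen CNEs for lineage-specific sequence divergence.

The screen measures, for every conserved non-coding element, how far each
species' sequence has drifted from the reconstructed ancestral sequence,
normalizes that divergence by the species' evolutionary distance to the
ancestor, and asks whether the trait-loss lineages are outliers:

    seqId = (fractional identity to the ancestor - 1) / distance to ancestor
    Z     = (max over loss species of seqId - mean(seqId of others))
            / sd(seqId of others)

seqId is <= 0, with 0 meaning perfect identity; Z uses the LEAST diverged
loss species so that a CNE is only called when every loss lineage is
diverged.  A CNE passes when both the global Z (all non-loss species) and
the local Z (a designated close-relative subset) fall strictly below the
cutoff (default -3).  The false discovery rate is estimated by running the
identical screen on a constrained-only simulation (null pass rate scaled to
the screened set) or bounded from above with a sister-lineage control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alignment import CNEAlignment
from .trees import PhyloTree

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
_GAP = 5
_N = 4


@dataclass
class ScreenConfig:
    """Species requirements and cutoff for the divergence screen.

    ``required_species`` must all have a computable seqId for a CNE to be
    screened; beyond those, at least ``min_additional_species`` other
    species must be non-missing.  ``min_nongap_frac`` is the fraction of
    non-gap columns below which a species' identity is treated as missing.
    """

    loss_species: tuple[str, ...]
    local_comparison_species: tuple[str, ...] = ()
    required_species: tuple[str, ...] = ()
    min_additional_species: int = 3
    z_cutoff: float = -3.0
    min_nongap_frac: float = 0.3

    def __post_init__(self) -> None:
        if self.z_cutoff >= 0:
            raise ValueError("z_cutoff must be negative")
        if not self.loss_species:
            raise ValueError("loss_species must be non-empty")

    @classmethod
    def from_tree(cls, tree: PhyloTree, **kw) -> "ScreenConfig":
        kw.setdefault("loss_species", tuple(tree.loss_species))
        kw.setdefault(
            "local_comparison_species", tuple(tree.local_comparison_species)
        )
        kw.setdefault(
            "required_species",
            tuple(tree.loss_species) + tuple(tree.local_comparison_species),
        )
        return cls(**kw)


# ---------------------------------------------------------------------------
# ancestral reconstruction (JC69 marginal ML at the root)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - validated upstream
        raise ValueError(f"invalid character {exc}") from exc


def _jc_probs(d: float) -> tuple[float, float]:
    """JC69 stay/change probabilities for branch length d (subs/site)."""
    e = np.exp(-4.0 * d / 3.0)
    return 0.25 + 0.75 * e, 0.25 - 0.25 * e


def reconstruct_ancestral(
    alignment: CNEAlignment, tree: PhyloTree, ancestor_node: str | None = None
) -> str:
    """Marginal maximum-likelihood root sequence under Jukes–Cantor.

    Per column, Felsenstein pruning over the four bases yields the marginal
    posterior at the root (uniform prior); the reported state is the argmax
    with ties broken in the fixed order A < C < G < T.  Gaps are handled as
    a fifth, presence/absence character under Fitch parsimony: a column is
    reconstructed as a gap only when parsimony supports absence at the root
    (an all-gap column is always a gap); N counts as present but contributes
    no base information.

    ``ancestor_node`` selects an internal node by label; the default (and
    the screen's convention) is the root of the input tree.
    """
    dtree = tree.tree
    if ancestor_node is not None:
        target = None
        for node in dtree.preorder_node_iter():
            if node.label == ancestor_node:
                target = node
                break
        if target is None:
            raise ValueError(f"internal node {ancestor_node!r} not found")
        if target is not dtree.seed_node:
            dtree = dtree.clone(depth=1)
            for node in dtree.preorder_node_iter():
                if node.label == ancestor_node:
                    dtree.reroot_at_node(node, update_bipartitions=False)
                    break

    leaf_labels = {lf.taxon.label for lf in dtree.leaf_node_iter()}
    missing = set(alignment.sequences) - leaf_labels
    if missing:
        raise ValueError(f"alignment species not on tree: {sorted(missing)}")

    L = alignment.aligned_length
    coded = {sp: _encode(s) for sp, s in alignment.sequences.items()}

    # --- gap presence/absence by Fitch parsimony (bit 1 = present) --------
    PRESENT, ABSENT = 1, 2
    fitch: dict[int, np.ndarray] = {}
    # --- base likelihoods by pruning --------------------------------------
    partial: dict[int, np.ndarray] = {}

    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            if lab in coded:
                s = coded[lab]
                lik = np.zeros((L, 4))
                known = s < _N
                lik[known, s[known]] = 1.0
                lik[s >= _N] = 1.0  # N or gap: uninformative for the base
                fitch[id(node)] = np.where(s == _GAP, ABSENT, PRESENT)
            else:  # species absent from this alignment: fully missing
                lik = np.ones((L, 4))
                fitch[id(node)] = np.full(L, PRESENT | ABSENT)
            partial[id(node)] = lik
            continue
        lik = np.ones((L, 4))
        sets = None
        for child in node.child_nodes():
            p_same, p_diff = _jc_probs(child.edge.length or 0.0)
            cp = partial[id(child)]
            tot = cp.sum(axis=1, keepdims=True)
            lik *= p_diff * tot + (p_same - p_diff) * cp
            cs = fitch[id(child)]
            sets = cs if sets is None else np.where(
                sets & cs, sets & cs, sets | cs
            )
        partial[id(node)] = lik
        fitch[id(node)] = sets

    root_lik = partial[id(dtree.seed_node)] * 0.25
    best = np.argmax(root_lik, axis=1)  # ties -> first index -> A<C<G<T
    root_fitch = fitch[id(dtree.seed_node)]
    # parsimony supports a base whenever "present" is in the root state set
    is_gap = root_fitch == ABSENT
    # a column where no species has a base cannot be reconstructed
    any_base = np.zeros(L, dtype=bool)
    for s in coded.values():
        any_base |= s < _N
    out = np.array(list("ACGT"))[best]
    out[is_gap | ~any_base] = "-"
    return "".join(out)


# ---------------------------------------------------------------------------
# identity and Z statistics


def percent_identity(
    species_seq: str,
    ancestral_seq: str,
    min_nongap_frac: float = 0.3,
) -> float | None:
    """Fractional identity of a species sequence to the ancestor.

    Columns where the ancestor has a gap are excluded from the denominator;
    a species gap (or N) opposite an ancestral base counts as a mismatch.
    Returns None (missing) when the species has fewer than
    ``min_nongap_frac`` non-gap columns over the ancestral-base columns.
    A value of 0 corresponds to complete loss of the element.
    """
    if len(species_seq) != len(ancestral_seq):
        raise ValueError("gapped lengths differ")
    sp = _encode(species_seq)
    anc = _encode(ancestral_seq)
    cols = anc < _N  # ancestral base present
    n_cols = int(cols.sum())
    if n_cols == 0:
        return None
    sp_cols = sp[cols]
    if (sp_cols < _N).sum() < min_nongap_frac * n_cols:
        return None
    matches = int((sp_cols == anc[cols]).sum())
    return matches / n_cols


def normalized_identity(pid: float, distance: float) -> float:
    """seqId = (fractional identity - 1) / evolutionary distance to ancestor.

    Always <= 0; equals 0 only for perfect identity, and -1/distance for
    complete loss (identity 0).
    """
    if distance <= 0:
        raise ValueError("distance to ancestor must be > 0")
    if not (0.0 <= pid <= 1.0):
        raise ValueError("pid must be a fraction in [0, 1]")
    return (pid - 1.0) / distance


def z_score(loss_values, other_values) -> float:
    """Standardized divergence of the least-diverged trait-loss species.

    Z = (max(seqId over loss species) - mean(seqId of comparison species))
        / sample sd(seqId of comparison species).
    """
    loss = np.asarray([v for v in loss_values if v is not None and np.isfinite(v)])
    other = np.asarray([v for v in other_values if v is not None and np.isfinite(v)])
    if loss.size == 0:
        raise ValueError("no finite loss-species values")
    if other.size < 2:
        raise ValueError("need >= 2 finite comparison values")
    sd = other.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(other).max())):
        raise ValueError("zero standard deviation among comparison species")
    return float((loss.max() - other.mean()) / sd)


def compute_divergence_records(
    alignments,
    tree: PhyloTree,
    config: ScreenConfig,
    ancestors: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-CNE identity, seqId and Z-score table.

    Ancestral sequences are reconstructed at the root unless supplied in
    ``ancestors`` (useful for simulations where the truth is known).
    Columns: cne_id, chrom, start, end, pid_<sp>, seqid_<sp>, z_global,
    z_local, n_species.  Z columns are NaN where the statistic is undefined
    (missing loss species, < 2 comparison values, or zero spread).
    """
    dist = tree.distance_to_root
    loss = list(config.loss_species)
    global_comp = [s for s in tree.species if s not in set(loss)]
    local_comp = [s for s in config.local_comparison_species if s not in set(loss)]
    rows = []
    for aln in alignments:
        anc = (
            ancestors[aln.cne_id]
            if ancestors is not None
            else reconstruct_ancestral(aln, tree)
        )
        pid: dict[str, float | None] = {}
        sid: dict[str, float | None] = {}
        for sp in tree.species:
            seq = aln.sequences.get(sp)
            p = (
                percent_identity(seq, anc, config.min_nongap_frac)
                if seq is not None
                else None
            )
            pid[sp] = p
            sid[sp] = (
                normalized_identity(p, dist[sp])
                if p is not None and dist[sp] > 0
                else None
            )
        row = {
            "cne_id": aln.cne_id,
            "chrom": aln.chrom,
            "start": aln.start,
            "end": aln.end,
        }
        for sp in tree.species:
            row[f"pid_{sp}"] = np.nan if pid[sp] is None else pid[sp]
            row[f"seqid_{sp}"] = np.nan if sid[sp] is None else sid[sp]
        for name, comp in (("z_global", global_comp), ("z_local", local_comp)):
            try:
                row[name] = z_score(
                    [sid[s] for s in loss], [sid[s] for s in comp]
                )
            except ValueError:
                row[name] = np.nan
        row["n_species"] = sum(v is not None for v in sid.values())
        rows.append(row)
    return pd.DataFrame(rows)


def screen_cnes(records: pd.DataFrame, config: ScreenConfig) -> list[str]:
    """IDs of CNEs diverged in the loss lineages, sorted by global Z.

    A CNE passes when (i) seqId is non-missing for every required species
    and for at least ``min_additional_species`` others, and (ii) both Z
    scores lie strictly below the cutoff.
    """
    if records.empty:
        return []
    required = list(config.required_species)
    keep = pd.Series(True, index=records.index)
    for sp in required:
        keep &= records[f"seqid_{sp}"].notna()
    other_cols = [
        c
        for c in records.columns
        if c.startswith("seqid_") and c[len("seqid_"):] not in set(required)
    ]
    if other_cols:
        keep &= records[other_cols].notna().sum(axis=1) >= config.min_additional_species
    elif config.min_additional_species > 0:
        keep &= False
    keep &= records["z_global"] < config.z_cutoff
    if config.local_comparison_species:
        keep &= records["z_local"] < config.z_cutoff
    passed = records[keep].sort_values("z_global", kind="mergesort")
    return passed["cne_id"].tolist()


# ---------------------------------------------------------------------------
# FDR estimation


@dataclass(frozen=True)
class FDREstimate:
    """Simulation-based FDR: null pass rate scaled to the screened set."""

    false_positive_rate: float
    expected_false_positives: float
    fdr: float


def simulation_fdr(
    n_null_pass: int, n_null_total: int, n_screened: int, n_called: int
) -> FDREstimate:
    """FDR from a constrained-only simulation null.

    fpr = n_null_pass / n_null_total; the expected number of false
    positives among n_screened real CNEs is fpr * n_screened, and the FDR
    is that count divided by the number of called CNEs.
    """
    if n_null_total <= 0 or n_called <= 0:
        raise ValueError("n_null_total and n_called must be positive")
    fpr = n_null_pass / n_null_total
    expected = fpr * n_screened
    return FDREstimate(fpr, expected, expected / n_called)


def sister_bound_fdr(n_control_called: int, n_called: int) -> float:
    """Upper FDR bound: CNEs called in a sister-lineage control screen,
    all conservatively assumed to be false positives, over calls."""
    if n_called <= 0:
        raise ValueError("n_called must be positive")
    return n_control_called / n_called


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# phylogeny-aware branch association (independent losses)


@dataclass(frozen=True)
class BranchAssociationResult:
    cne_id: str
    statistic: float
    p_value: float
    adjusted_p: float


def branch_association(
    seq_ids: pd.DataFrame,
    tree: PhyloTree,
    phenotype: dict[str, str],
) -> pd.DataFrame:
    """Phylogeny-aware association of per-species seqId with trait loss.

    For each CNE, generalized least squares regresses seqId on a loss
    indicator with a Brownian-motion covariance derived from the tree
    (shared root-to-MRCA path length); the one-sided p-value tests whether
    the loss coefficient is negative, i.e. loss species more diverged.
    CNEs missing any loss species are excluded; missing intact species are
    dropped per CNE (>= 4 required).  p-values are BH-adjusted across CNEs.

    ``seq_ids`` is indexed by cne_id with one seqid column per species
    (``seqid_<sp>`` or plain species names); ``phenotype`` maps species to
    "loss" or "intact".

    This is a species-level approximation to per-branch "Forward Genomics"
    association; it shares the same logic (divergence co-varies with the
    phenotype across independent loss lineages, correcting for shared
    ancestry) without mapping substitutions onto individual branches.
    """
    cols = {}
    for c in seq_ids.columns:
        sp = c[len("seqid_"):] if c.startswith("seqid_") else c
        if sp in phenotype:
            cols[sp] = c
    loss = [s for s, v in phenotype.items() if v == "loss" and s in cols]
    intact = [s for s, v in phenotype.items() if v == "intact" and s in cols]
    if len(loss) < 2:
        raise ValueError("need >= 2 loss species")
    order, cov = tree.bm_covariance
    pos = {s: i for i, s in enumerate(order)}

    rows = []
    for cne_id, row in seq_ids.iterrows():
        y_loss = row[[cols[s] for s in loss]].to_numpy(dtype=float)
        if np.any(~np.isfinite(y_loss)):
            continue  # all loss species must be measurable
        use_intact = [s for s in intact if np.isfinite(row[cols[s]])]
        if len(use_intact) < 4:
            continue
        spp = loss + use_intact
        y = np.array([row[cols[s]] for s in spp], dtype=float)
        X = np.column_stack(
            [np.ones(len(spp)), [1.0 if s in set(loss) else 0.0 for s in spp]]
        )
        C = cov[np.ix_([pos[s] for s in spp], [pos[s] for s in spp])]
        try:
            Ci_X = np.linalg.solve(C, X)
            Ci_y = np.linalg.solve(C, y)
            XtCiX = X.T @ Ci_X
            beta = np.linalg.solve(XtCiX, X.T @ Ci_y)
            resid = y - X @ beta
            df = len(spp) - 2
            sigma2 = float(resid @ np.linalg.solve(C, resid)) / df
            se = np.sqrt(sigma2 * np.linalg.inv(XtCiX)[1, 1])
        except np.linalg.LinAlgError:
            warnings.warn(f"singular covariance for {cne_id}; skipped")
            continue
        if se == 0 or not np.isfinite(se):
            continue
        t = beta[1] / se
        p = float(stats.t.cdf(t, df))  # one-sided: loss more diverged
        rows.append((cne_id, float(t), p))
    out = pd.DataFrame(rows, columns=["cne_id", "statistic", "p_value"])
    out["adjusted_p"] = bh_adjust(out["p_value"]) if len(out) else []
    return out


def write_records_tsv(records: pd.DataFrame, diverged_ids, path) -> None:
    df = records.copy()
    df["pass"] = df["cne_id"].isin(set(diverged_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
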