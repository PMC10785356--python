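"""Gene-set (non-topology) pathway activity schemes.

Four single-sample schemes that treat a pathway as an unordered gene set:

* ``combiner_activity`` — signed-z mean over the pathway's top differentially
  expressed genes, a(Pj) = sum z(gi) * sign(t(gi)) / sqrt(j).
* ``pac_activity`` — plain z-score aggregation over all members,
  a(Pj) = sum z(gij) / sqrt(k) (the variance-stabilised mean).
* ``plage_activity`` — SVD of the member-gene z sub-matrix; the first right
  singular vector is the per-sample pathway summary.
* ``gsva_activity`` — KS-like running-sum enrichment of the set in each
  sample's gene ranking, ESdiff = |ES+| - |ES-|.

All four are deterministic; ties anywhere are broken lexicographically by
gene id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .expression import (
    ExpressionDataset,
    GeneStatistics,
    ValidationError,
    ZMatrix,
)
from .profiles import PathwayActivityProfile
from .resources import GeneSetCollection

__all__ = [
    "combiner_activity",
    "pac_activity",
    "plage_activity",
    "gsva_activity",
    "PlageFactors",
    "GsvaScores",
]


@dataclass
class PlageFactors:
    """SVD factors of one pathway's z sub-matrix (U diag(D) Vt)."""

    left_vectors: np.ndarray
    singular_values: np.ndarray
    right_vectors: np.ndarray  # rows of Vt; row 0 is the activity direction


@dataclass
class GsvaScores:
    """Enrichment-walk summaries: ES+ , ES-, ESdiff per (pathway, sample).

    ``walks`` (optional, kept only on request — the full deviation sequences
    are large) maps pathway id -> (genes x samples) deviation matrix v(l).
    """

    es_pos: pd.DataFrame
    es_neg: pd.DataFrame
    es_diff: pd.DataFrame
    tau: float
    walks: dict[str, np.ndarray] = field(default_factory=dict)


def combiner_activity(
    z: ZMatrix,
    stats: GeneStatistics,
    sets: GeneSetCollection,
    p_threshold: float = 0.05,
    max_genes: int = 20,
) -> PathwayActivityProfile:
    """Signed-z activity over each pathway's top differentially expressed genes.

    Member genes with p <= ``p_threshold`` are ranked by descending \\|t\\|
    (ties by gene id) and capped at ``max_genes``; the activity of a sample is
    sum z(gi)*sign(t(gi)) / sqrt(j) over the j genes kept.  Pathways with no
    qualifying gene are dropped and recorded.
    """
    zdf = z.values
    z_np = zdf.to_numpy()
    gidx = {g: i for i, g in enumerate(zdf.index)}
    pval = stats.pvalue.to_dict()
    tsc = stats.tscore.to_dict()
    sgn = stats.sign.to_dict()
    rows: dict[str, np.ndarray] = {}
    provenance: dict[str, dict] = {}
    dropped: dict[str, str] = {}
    for pid, members in sets.sets.items():
        degs = [
            g for g in members if g in gidx and pval.get(g, 1.0) <= p_threshold
        ]
        degs.sort(key=lambda g: (-abs(tsc[g]), g))
        degs = degs[:max_genes]
        if not degs:
            dropped[pid] = "no member genes pass the DEG filter"
            continue
        signs = np.array([sgn[g] for g in degs])
        rows[pid] = z_np[[gidx[g] for g in degs]].T @ signs / np.sqrt(len(degs))
        provenance[pid] = {"genes": degs, "degs_used": len(degs)}
    activity = pd.DataFrame(rows, index=zdf.columns).T
    activity.index.name = "pathway"
    return PathwayActivityProfile(
        activity,
        "combiner",
        provenance,
        dropped,
        {"p_threshold": p_threshold, "max_genes": max_genes},
    )


def pac_activity(z: ZMatrix, sets: GeneSetCollection) -> PathwayActivityProfile:
    """Variance-stabilised z-score aggregation over all member genes.

    a(Pj) per sample = sum over the k measured members of z(gij) / sqrt(k).
    """
    zdf = z.values
    z_np = zdf.to_numpy()
    gidx = {g: i for i, g in enumerate(zdf.index)}
    rows: dict[str, np.ndarray] = {}
    provenance: dict[str, dict] = {}
    dropped: dict[str, str] = {}
    for pid, members in sets.sets.items():
        used = [g for g in members if g in gidx]
        if not used:
            dropped[pid] = "no member genes measured"
            continue
        rows[pid] = z_np[[gidx[g] for g in used]].sum(axis=0) / np.sqrt(len(used))
        provenance[pid] = {"genes": used, "degs_used": len(used)}
    activity = pd.DataFrame(rows, index=zdf.columns).T
    activity.index.name = "pathway"
    return PathwayActivityProfile(activity, "pac", provenance, dropped, {})


def plage_activity(
    z: ZMatrix,
    sets: GeneSetCollection,
    return_factors: bool = False,
) -> PathwayActivityProfile | tuple[PathwayActivityProfile, dict[str, PlageFactors]]:
    """First right singular vector of each pathway's z sub-matrix.

    The SVD sign is arbitrary, so the activity vector is oriented to correlate
    non-negatively with the mean member z profile — the orientation matters
    when t-scores of activities are compared across data splits.
    """
    zdf = z.values
    z_np = zdf.to_numpy()
    gidx = {g: i for i, g in enumerate(zdf.index)}
    rows: dict[str, np.ndarray] = {}
    provenance: dict[str, dict] = {}
    dropped: dict[str, str] = {}
    factors: dict[str, PlageFactors] = {}
    for pid, members in sets.sets.items():
        used = [g for g in members if g in gidx]
        if len(used) < 2:
            dropped[pid] = "fewer than 2 measured member genes"
            continue
        sub = z_np[[gidx[g] for g in used]]
        if not np.any(sub):
            dropped[pid] = "all-zero member sub-matrix"
            continue
        u, d, vt = np.linalg.svd(sub, full_matrices=False)
        act = vt[0]
        mean_profile = sub.mean(axis=0)
        if float(act @ mean_profile) < 0:
            act = -act
            u = u.copy()
            vt = vt.copy()
            u[:, 0] *= -1
            vt[0] *= -1
        rows[pid] = act
        provenance[pid] = {"genes": used, "degs_used": len(used)}
        if return_factors:
            factors[pid] = PlageFactors(u, d, vt)
    activity = pd.DataFrame(rows, index=zdf.columns).T
    activity.index.name = "pathway"
    profile = PathwayActivityProfile(activity, "plage", provenance, dropped, {})
    if return_factors:
        return profile, factors
    return profile


# ---------------------------------------------------------------------------
# GSVA


def _cdf_scores(x: np.ndarray, kcdf: str) -> np.ndarray:
    """Per-gene cumulative-density score of each sample's value.

    ecdf: fraction of samples at or below the value.  gaussian: mean normal
    CDF with per-gene bandwidth sd/4 (n-1 sd); constant rows score 0.5.
    """
    g, n = x.shape
    if kcdf == "ecdf":
        # fraction of samples at or below the value == max-rank / n
        return _sstats.rankdata(x, axis=1, method="max") / n
    if kcdf == "gaussian":
        sd = x.std(axis=1, ddof=1)
        h = sd / 4.0
        out = np.empty_like(x)
        for i in range(g):
            if h[i] == 0.0:
                out[i] = 0.5
                continue
            out[i] = _sstats.norm.cdf((x[i][:, None] - x[i][None, :]) / h[i]).mean(axis=1)
        return out
    raise ValidationError(f"unknown kcdf {kcdf!r} (expected 'ecdf' or 'gaussian')")


def gsva_activity(
    dataset: ExpressionDataset,
    sets: GeneSetCollection,
    tau: float = 1.0,
    kcdf: str = "ecdf",
    keep_walks: bool = False,
) -> tuple[PathwayActivityProfile, GsvaScores]:
    """Sample-wise KS-like enrichment score of each gene set.

    Per gene the expression value of each sample is converted to a
    cumulative-density score across samples; per sample, genes are ordered by
    decreasing score (ties by gene id) and the gene at position l carries the
    symmetric rank weight \\|p - l + 1 - p/2\\|.  The running sum accumulates
    in-set weight share minus out-of-set count share; ES+ / ES- are its
    largest positive / negative excursions and the activity is
    ESdiff = \\|ES+\\| - \\|ES-\\|.  Label-free and rank-based: any monotone
    per-sample transform leaves the ecdf result unchanged.
    """
    if dataset.n_genes < 2 or dataset.n_samples < 2:
        raise ValidationError("GSVA needs >= 2 genes and >= 2 samples")
    x = dataset.values.to_numpy(float)
    genes = list(dataset.values.index)
    p, n = x.shape
    scores = _cdf_scores(x, kcdf)

    # per-sample walk order: decreasing CDF score, ties by gene id (index order
    # is made lexicographic first so a stable sort on -score settles ties)
    lex = np.argsort(np.array(genes), kind="stable")
    order = lex[np.argsort(-scores[lex], axis=0, kind="stable")]

    # symmetric rank weights by walk position (position 1 <-> rank p)
    ranks = np.arange(p, 0, -1, dtype=float)
    w_pos = np.abs(ranks - p / 2.0) ** tau  # shape (p,), same for every sample

    # inverse permutation: position of each gene in each sample's walk order
    inv = np.empty_like(order)
    np.put_along_axis(inv, order, np.arange(p)[:, None], axis=0)

    gene_idx = {g: i for i, g in enumerate(genes)}
    es_pos: dict[str, np.ndarray] = {}
    es_neg: dict[str, np.ndarray] = {}
    walks: dict[str, np.ndarray] = {}
    provenance: dict[str, dict] = {}
    dropped: dict[str, str] = {}
    for pid, members in sets.sets.items():
        used = [g for g in members if g in gene_idx]
        if not used:
            dropped[pid] = "no member genes measured"
            continue
        k = len(used)
        if k >= p:
            raise ValidationError(
                f"gene set {pid!r} covers the whole gene universe; complement is empty"
            )
        sidx = np.array([gene_idx[g] for g in used])
        if keep_walks:
            # full deviation sequence (O(p) per sample)
            inset = np.zeros(p, dtype=bool)
            inset[sidx] = True
            inset_sorted = inset[order]
            w_in = w_pos[:, None] * inset_sorted
            denom_in = w_in.sum(axis=0)
            pos_term = np.cumsum(w_in, axis=0) / np.where(denom_in == 0, 1.0, denom_in)
            neg_term = np.cumsum(~inset_sorted, axis=0) / (p - k)
            v = pos_term - neg_term
            es_pos[pid] = np.maximum(0.0, v.max(axis=0))
            es_neg[pid] = np.minimum(0.0, v.min(axis=0))
            walks[pid] = v
        else:
            # the walk only rises at in-set positions, so its extrema occur
            # just after (max) or just before (min) an in-set gene; evaluate
            # v there only (O(k) per sample)
            pos = np.sort(inv[sidx, :], axis=0)  # (k, n), 0-based positions
            wk = w_pos[pos]  # w_pos already carries the tau exponent
            cumw = np.cumsum(wk, axis=0)
            denom = cumw[-1].copy()
            denom[denom == 0.0] = 1.0
            out_before = pos - np.arange(k)[:, None]
            v_at = cumw / denom - out_before / (p - k)
            v_before = np.vstack([np.zeros((1, n)), cumw[:-1]]) / denom - out_before / (
                p - k
            )
            es_pos[pid] = np.maximum(0.0, v_at.max(axis=0))
            es_neg[pid] = np.minimum(0.0, v_before.min(axis=0))
        provenance[pid] = {"genes": used, "degs_used": k}
    samples = list(dataset.values.columns)
    pos_df = pd.DataFrame(es_pos, index=samples).T
    neg_df = pd.DataFrame(es_neg, index=samples).T
    diff_df = pos_df.abs() - neg_df.abs()
    diff_df.index.name = "pathway"
    profile = PathwayActivityProfile(
        diff_df.copy(), "gsva", provenance, dropped, {"tau": tau, "kcdf": kcdf}
    )
    return profile, GsvaScores(pos_df, neg_df, diff_df, tau, walks)
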