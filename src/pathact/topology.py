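"""Pathway-topology methods: random walk with restart and DRW-family scoring.

The walk engine iterates W_{t+1} = (1-r) M^T W_t + r W_0 on the row-normalised
transition matrix M until the L1 change falls below tolerance.  Mass leaving
through dangling nodes (no out-edges) is redistributed to the restart
distribution each step, which keeps the iterate on the probability simplex and
guarantees a unique fixed point; the converged vector then satisfies the
closed form w = r (I - (1-r) Mt^T)^{-1} w0 with Mt the transition matrix whose
dangling rows are replaced by w0.

Three activity schemes build on the converged weights:

* DRW — walk seeded with normalised \\|t\\|-scores; pathway activity is the
  W-weighted signed-z sum over member DEGs, normalised by sqrt(sum W^2).
* sDRW — same, but edge weights are first replaced by the mean of the two
  endpoint node weights (raw \\|t\\|), strengthening connectivity around
  discriminative genes, and the matrix re-row-normalised.
* e-DRW — walk seeded with per-gene expression entropy; the numerator weights
  each member DEG by H_inf * PCTscore (PBC + t, signed), and the denominator is
  the L2 norm of the normalised complement-entropy weights over members.  One
  walk per input network; profiles from several networks are concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import linalg as splinalg

from .expression import GeneStatistics, ValidationError, ZMatrix
from .profiles import PathwayActivityProfile
from .resources import DirectedPathwayNetwork, GeneSetCollection

__all__ = [
    "WalkConfig",
    "WalkResult",
    "EdrwWeights",
    "initial_weight_vector",
    "write_walk_tsv",
    "random_walk_restart",
    "closed_form_walk",
    "sdrw_reweight",
    "drw_activity",
    "edrw_activity",
    "entropy_weights",
]


class ConvergenceError(RuntimeError):
    """The walk did not reach tolerance within max_iter iterations."""


@dataclass
class WalkConfig:
    """Restart probability, convergence tolerance and iteration cap."""

    restart: float = 0.7
    tolerance: float = 1e-10
    max_iter: int = 100_000
    dangling_policy: str = "redistribute_to_restart"

    def __post_init__(self) -> None:
        if not 0.0 < self.restart <= 1.0:
            raise ValidationError("restart probability must lie in (0, 1]")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")
        if self.dangling_policy != "redistribute_to_restart":
            raise ValidationError(f"unknown dangling policy {self.dangling_policy!r}")


@dataclass
class WalkResult:
    """Initial and converged node-probability vectors, indexed by gene id."""

    w0: pd.Series
    w_inf: pd.Series
    iterations: int
    residual: float
    closed_form_residual: float | None = None
    mass_history: list[float] = field(default_factory=list)  # sum(w) per iteration

    def weight(self, gene: str) -> float:
        return float(self.w_inf.get(gene, 0.0))


@dataclass
class EdrwWeights:
    """Converged entropy walk plus per-pathway complement-entropy weights."""

    h_inf: pd.Series
    entropy_weight: dict[str, pd.Series] = field(default_factory=dict)


def write_walk_tsv(result: WalkResult, stream) -> None:
    """Export a converged walk vector as two-column TSV (gene, weight)."""
    stream.write("gene\tweight\n")
    for gene, weight in result.w_inf.items():
        stream.write(f"{gene}\t{weight:.12g}\n")


def initial_weight_vector(
    stats: GeneStatistics, network: DirectedPathwayNetwork, mode: str = "abs_t"
) -> pd.Series:
    """L1-normalised seed distribution over network nodes.

    ``abs_t`` seeds with \\|t\\|, ``entropy`` with the per-gene histogram
    entropy; nodes not measured in the dataset get zero.  Raises if nothing
    is measured or every seed weight is zero.
    """
    if mode == "abs_t":
        base = stats.tscore.abs()
    elif mode == "entropy":
        base = stats.entropy
    else:
        raise ValidationError(f"unknown seed mode {mode!r}")
    w = pd.Series(0.0, index=pd.Index(network.nodes, name="gene"))
    measured = [g for g in network.nodes if g in base.index and g not in network.unmeasured]
    if not measured:
        raise ValidationError("network shares no measured genes with the dataset")
    w[measured] = base[measured].to_numpy()
    total = float(w.sum())
    if total <= 0.0:
        raise ValidationError("all seed weights are zero; cannot normalise")
    return w / total


def _dangling_mask(network: DirectedPathwayNetwork) -> np.ndarray:
    dang = set(network.dangling)
    return np.array([g in dang for g in network.nodes])


def random_walk_restart(
    network: DirectedPathwayNetwork,
    w0: pd.Series,
    config: WalkConfig | None = None,
    check_closed_form: bool = False,
) -> WalkResult:
    """Iterate the restart walk to its stationary distribution.

    Each step computes (1-r) * [M^T w + (dangling mass) * w0] + r * w0, i.e.
    mass sitting on nodes without out-edges restarts instead of vanishing, so
    sum(w) stays 1 throughout.  Convergence is L1: \\|w_{t+1} - w_t\\|_1 <
    tolerance.  With ``check_closed_form`` the result also carries its
    residual against the direct linear solve.
    """
    config = config or WalkConfig()
    if network.transition is None:
        raise ValidationError("network has no transition matrix; call row_normalize")
    if list(w0.index) != list(network.nodes):
        w0 = w0.reindex(network.nodes, fill_value=0.0)
    v0 = w0.to_numpy(float)
    if not np.isclose(v0.sum(), 1.0, atol=1e-9):
        raise ValidationError("w0 must sum to 1")
    r = config.restart
    mt = network.transition.T.tocsr()
    dang = _dangling_mask(network)
    w = v0.copy()
    if r == 1.0:
        return WalkResult(
            pd.Series(v0, index=w0.index),
            pd.Series(v0, index=w0.index),
            iterations=1,
            residual=0.0,
            closed_form_residual=0.0 if check_closed_form else None,
        )
    mass_history: list[float] = []
    for it in range(1, config.max_iter + 1):
        dangling_mass = w[dang].sum() if dang.any() else 0.0
        w_next = (1.0 - r) * (mt @ w + dangling_mass * v0) + r * v0
        residual = float(np.abs(w_next - w).sum())
        w = w_next
        mass_history.append(float(w.sum()))
        if residual < config.tolerance:
            break
    else:
        raise ConvergenceError(
            f"walk did not converge in {config.max_iter} iterations "
            f"(residual {residual:.3e})"
        )
    cf_res = None
    if check_closed_form:
        exact = closed_form_walk(network, pd.Series(v0, index=w0.index), r)
        cf_res = float(np.abs(w - exact.to_numpy()).max())
    return WalkResult(
        pd.Series(v0, index=w0.index),
        pd.Series(w, index=w0.index),
        iterations=it,
        residual=residual,
        closed_form_residual=cf_res,
        mass_history=mass_history,
    )


def closed_form_walk(
    network: DirectedPathwayNetwork, w0: pd.Series, restart: float
) -> pd.Series:
    """Direct linear solve w = r (I - (1-r) Mt^T)^{-1} w0.

    Mt is the transition matrix with each dangling row replaced by w0, the
    matrix the iterative scheme implicitly walks on.  Used as the independent
    oracle for the power iteration.
    """
    if network.transition is None:
        raise ValidationError("network has no transition matrix; call row_normalize")
    v0 = w0.reindex(network.nodes, fill_value=0.0).to_numpy(float)
    n = len(network.nodes)
    dang = _dangling_mask(network).astype(float)
    mt = network.transition.T.tocsr()
    # M~^T w = M^T w + w0 (d . w); build densely only for modest n
    a = sparse.eye(n, format="csr") - (1.0 - restart) * (
        mt + sparse.csr_matrix(np.outer(v0, dang))
    )
    sol = splinalg.spsolve(a.tocsc(), restart * v0)
    return pd.Series(sol, index=pd.Index(network.nodes, name="gene"))


def sdrw_reweight(
    network: DirectedPathwayNetwork, node_weight: pd.Series
) -> DirectedPathwayNetwork:
    """Replace each edge weight by the mean of its endpoint node weights.

    Node weights are the raw (pre-normalisation) seed scores, e.g. \\|t\\|.
    Edges whose endpoints both carry zero weight get weight zero; a node whose
    out-edges all drop to zero becomes dangling.  The returned network is
    re-row-normalised and walks with the standard restart iteration.
    """
    nw = node_weight.reindex(network.nodes, fill_value=0.0)
    if (nw < 0).any():
        raise ValidationError("node weights must be non-negative")
    nmap = nw.to_dict()
    new_weights = np.array(
        [(nmap[s] + nmap[t]) / 2.0 for s, t, _ in network.edges], dtype=float
    )
    out = DirectedPathwayNetwork(
        list(network.nodes), list(network.edges), new_weights, unmeasured=set(network.unmeasured)
    )
    from .resources import row_normalize

    return row_normalize(out)


def drw_activity(
    z: ZMatrix,
    stats: GeneStatistics,
    walk: WalkResult,
    sets: GeneSetCollection,
    p_threshold: float = 0.05,
) -> PathwayActivityProfile:
    """Walk-weighted signed-z pathway activity.

    Per pathway, member genes that are DEGs (p < ``p_threshold``, strict) and
    sit on the network with positive converged weight contribute
    W_inf(gi) * sign(t(gi)) * z(gi); the sum is scaled by
    1 / sqrt(sum W_inf(gi)^2).  Pathways with no qualifying gene (or zero
    denominator) are dropped and recorded.
    """
    zdf = z.values
    z_np = zdf.to_numpy()
    gidx = {g: i for i, g in enumerate(zdf.index)}
    wmap = walk.w_inf.to_dict()
    pval = stats.pvalue.to_dict()
    sgn = stats.sign.to_dict()
    rows: dict[str, np.ndarray] = {}
    provenance: dict[str, dict] = {}
    dropped: dict[str, str] = {}
    for pid, members in sets.sets.items():
        used = [
            g
            for g in members
            if g in gidx and pval.get(g, 1.0) < p_threshold and wmap.get(g, 0.0) > 0.0
        ]
        if not used:
            dropped[pid] = "no member DEG carries walk weight"
            continue
        wv = np.array([wmap[g] for g in used])
        denom = float(np.sqrt((wv**2).sum()))
        signs = np.array([sgn[g] for g in used])
        rows[pid] = z_np[[gidx[g] for g in used]].T @ (wv * signs) / denom
        provenance[pid] = {"genes": used, "degs_used": len(used)}
    activity = pd.DataFrame(rows, index=zdf.columns).T
    activity.index.name = "pathway"
    return PathwayActivityProfile(
        activity, "drw", provenance, dropped, {"p_threshold": p_threshold}
    )


def entropy_weights(h_inf: pd.Series, members: list[str]) -> pd.Series:
    """Normalised complement of converged entropy probabilities over members.

    weight(gi) = (1 - H_inf(gi)) / sum_members (1 - H_inf(gj)); sums to 1 when
    every complement is non-negative (H_inf lives on the simplex so each entry
    is <= 1 and the complements are non-negative for networks of > 1 node).
    """
    comp = 1.0 - h_inf.reindex(members, fill_value=0.0)
    total = float(comp.sum())
    if total == 0.0:
        raise ValidationError("complement-entropy weights sum to zero")
    return comp / total


def edrw_activity(
    z: ZMatrix,
    stats: GeneStatistics,
    walks: dict[str, WalkResult],
    sets_by_network: dict[str, GeneSetCollection],
    p_threshold: float = 0.05,
) -> tuple[PathwayActivityProfile, EdrwWeights]:
    """Entropy-walk pathway activity over one or more networks.

    Each pathway collection is tagged with the network whose converged entropy
    walk H_inf scores it.  Member DEGs (p < threshold) on that network
    contribute H_inf(gi) * PCTscore(gi) * z(gi) to the numerator; the
    denominator is sqrt(sum entropy_weight(gi)^2) with the complement-entropy
    weights of :func:`entropy_weights`.  Profiles from the networks are
    concatenated; a pathway id occurring under several networks is suffixed
    with its network tag.
    """
    if set(walks) != set(sets_by_network):
        raise ValidationError("walks and gene-set collections must share network tags")
    zdf = z.values
    rows: dict[str, np.ndarray] = {}
    provenance: dict[str, dict] = {}
    dropped: dict[str, str] = {}
    all_pids: dict[str, int] = {}
    for col in sets_by_network.values():
        for pid in col.sets:
            all_pids[pid] = all_pids.get(pid, 0) + 1
    z_np = zdf.to_numpy()
    gidx = {g: i for i, g in enumerate(zdf.index)}
    pval = stats.pvalue.to_dict()
    pct_map = stats.pct.to_dict()
    ew_store: dict[str, pd.Series] = {}
    h_concat: list[pd.Series] = []
    for tag, collection in sets_by_network.items():
        walk = walks[tag]
        h_concat.append(walk.w_inf)
        wmap = walk.w_inf.to_dict()
        for pid, members in collection.sets.items():
            out_id = pid if all_pids[pid] == 1 else f"{pid}|{tag}"
            used = [
                g
                for g in members
                if g in gidx and pval.get(g, 1.0) < p_threshold and wmap.get(g, 0.0) > 0.0
            ]
            if not used:
                dropped[out_id] = "no member DEG carries walk weight"
                continue
            hv = np.array([wmap[g] for g in used])
            comp = 1.0 - hv
            total = comp.sum()
            if total == 0.0:
                dropped[out_id] = "zero entropy-weight denominator"
                continue
            ew = comp / total
            denom = float(np.sqrt((ew**2).sum()))
            if denom == 0.0:
                dropped[out_id] = "zero entropy-weight denominator"
                continue
            pct = np.array([pct_map[g] for g in used])
            rows[out_id] = z_np[[gidx[g] for g in used]].T @ (hv * pct) / denom
            provenance[out_id] = {"genes": used, "degs_used": len(used), "network": tag}
            ew_store[out_id] = pd.Series(ew, index=used)
    activity = pd.DataFrame(rows, index=zdf.columns).T
    activity.index.name = "pathway"
    profile = PathwayActivityProfile(
        activity, "edrw", provenance, dropped, {"p_threshold": p_threshold}
    )
    h_all = pd.concat(h_concat) if h_concat else pd.Series(dtype=float)
    return profile, EdrwWeights(h_all, ew_store)
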