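"""Gene-set collections (GMT) and directed pathway networks (SIF / edge TSV).

Gene identifiers are case-normalised to uppercase at parse time so that sets,
networks and expression matrices share a namespace.  Directed networks are
simple: parallel duplicate edges collapse to one; self-loops are kept (the
random-walk formalism tolerates them).  Interaction-type strings are carried
through but never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .expression import ExpressionDataset, FormatError, ValidationError

__all__ = [
    "GeneSetCollection",
    "DirectedPathwayNetwork",
    "parse_gmt",
    "write_gmt",
    "parse_network",
    "write_sif",
    "restrict_to_dataset",
    "row_normalize",
    "generate_synthetic_network",
]


@dataclass
class GeneSetCollection:
    """Ordered mapping pathway id -> member gene list (deduplicated)."""

    sets: dict[str, list[str]]
    source: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {pid!r} is empty")
            self.sets[pid] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def pathway_ids(self) -> list[str]:
        return list(self.sets)


@dataclass
class DirectedPathwayNetwork:
    """Simple directed gene graph with per-edge weights and a transition matrix.

    ``transition`` is the row-normalised adjacency M (rows sum to 1 where the
    node has out-edges, 0 where dangling); walks iterate with its transpose.
    ``unmeasured`` marks nodes absent from the expression matrix after
    :func:`restrict_to_dataset` (they receive zero initial walk weight).
    """

    nodes: list[str]
    edges: list[tuple[str, str, str]]
    edge_weight: np.ndarray | None = None
    transition: sparse.csr_matrix | None = None
    dangling: list[str] = field(default_factory=list)
    unmeasured: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise ValidationError("duplicate nodes")
        for s, t, _ in self.edges:
            if s not in self._index or t not in self._index:
                raise ValidationError(f"edge endpoint {s!r}->{t!r} not in node set")
        if self.edge_weight is None:
            self.edge_weight = np.ones(len(self.edges))
        if np.any(self.edge_weight < 0):
            raise ValidationError("edge weights must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, gene: str) -> int:
        return self._index[gene]

    def adjacency(self) -> sparse.csr_matrix:
        """Weighted adjacency with parallel edges already collapsed."""
        n = self.n_nodes
        if not self.edges:
            return sparse.csr_matrix((n, n))
        rows = [self._index[s] for s, _, _ in self.edges]
        cols = [self._index[t] for _, t, _ in self.edges]
        return sparse.csr_matrix(
            (self.edge_weight, (rows, cols)), shape=(n, n)
        )


# ---------------------------------------------------------------------------
# parsing / writing


def _read_lines(stream) -> list[str]:
    text = stream.read()
    lines = [ln.rstrip("\r") for ln in text.split("\n")]
    while lines and not lines[-1].strip():
        lines.pop()
    return lines


def parse_gmt(stream, source: str = "") -> GeneSetCollection:
    """Parse a GMT stream: one set per line, tab-separated name/desc/genes.

    Duplicate members within a set are dropped (first occurrence kept); sets
    left empty are dropped.  Lines with fewer than three fields raise a
    :class:`FormatError` naming the line.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(_read_lines(stream), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
        name, desc, *genes = fields
        genes = [g.strip().upper() for g in genes if g.strip()]
        if not genes:
            continue
        if name in sets:
            raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
        sets[name] = list(dict.fromkeys(genes))
        descriptions[name] = desc
    return GeneSetCollection(sets, source=source, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, stream) -> None:
    for pid, members in collection.sets.items():
        desc = collection.descriptions.get(pid, "na") or "na"
        stream.write("\t".join([pid, desc, *members]) + "\n")


def parse_network(stream, source: str = "") -> DirectedPathwayNetwork:
    """Parse a SIF or three-column edge TSV into a directed network.

    SIF lines read ``source interaction target`` (whitespace separated); the
    TSV dialect has a header ``source\\ttarget\\ttype``.  Single-token lines
    declare isolated nodes.  Parallel duplicate edges collapse to one.
    """
    lines = [ln for ln in _read_lines(stream) if ln.strip()]
    if not lines:
        raise ValidationError("empty network stream")
    tsv_mode = lines[0].lower().replace(" ", "").startswith("source\ttarget")
    if tsv_mode:
        lines = lines[1:]
    nodes: dict[str, None] = {}
    edges: dict[tuple[str, str], str] = {}
    for line in lines:
        toks = line.split("\t") if "\t" in line else line.split()
        toks = [t.strip() for t in toks if t.strip()]
        if len(toks) == 1:
            nodes.setdefault(toks[0].upper())
            continue
        if tsv_mode:
            if len(toks) < 2:
                raise FormatError(f"bad edge line: {line!r}")
            s, t = toks[0].upper(), toks[1].upper()
            kind = toks[2] if len(toks) > 2 else "interacts"
        else:
            if len(toks) != 3:
                raise FormatError(f"bad SIF line (need 3 tokens): {line!r}")
            s, kind, t = toks[0].upper(), toks[1], toks[2].upper()
        nodes.setdefault(s)
        nodes.setdefault(t)
        edges.setdefault((s, t), kind)
    edge_list = [(s, t, k) for (s, t), k in edges.items()]
    net = DirectedPathwayNetwork(list(nodes), edge_list)
    return row_normalize(net)


def write_sif(network: DirectedPathwayNetwork, stream) -> None:
    """Write SIF with deterministic lexicographic edge order; isolated nodes
    appear as single-token lines."""
    touched = set()
    for s, t, kind in sorted(network.edges):
        stream.write(f"{s}\t{kind}\t{t}\n")
        touched.update((s, t))
    for node in sorted(set(network.nodes) - touched):
        stream.write(node + "\n")


# ---------------------------------------------------------------------------
# restriction and normalisation


def restrict_to_dataset(obj, dataset: ExpressionDataset, min_size: int = 2):
    """Restrict a collection or network to the dataset's measured genes.

    Gene sets are intersected with the measured genes and dropped when they
    fall below ``min_size``.  Networks keep their full node set but mark
    unmeasured nodes, which later receive zero initial walk weight.
    """
    measured = set(dataset.gene_ids)
    if isinstance(obj, GeneSetCollection):
        kept: dict[str, list[str]] = {}
        for pid, members in obj.sets.items():
            inter = [g for g in members if g in measured]
            if len(inter) >= min_size:
                kept[pid] = inter
        return GeneSetCollection(kept, source=obj.source, descriptions=dict(obj.descriptions))
    if isinstance(obj, DirectedPathwayNetwork):
        out = DirectedPathwayNetwork(
            list(obj.nodes),
            list(obj.edges),
            None if obj.edge_weight is None else obj.edge_weight.copy(),
            transition=obj.transition,
            dangling=list(obj.dangling),
        )
        out.unmeasured = {g for g in obj.nodes if g not in measured}
        return out
    raise TypeError(f"cannot restrict object of type {type(obj).__name__}")


def row_normalize(network: DirectedPathwayNetwork) -> DirectedPathwayNetwork:
    """Attach the row-normalised transition matrix M.

    transition[u, v] = weight(u->v) / sum of u's out-weights; nodes without
    positive out-weight become dangling (all-zero rows) and are listed.
    """
    adj = network.adjacency().tocsr()
    out_sum = np.asarray(adj.sum(axis=1)).ravel()
    inv = np.zeros_like(out_sum)
    positive = out_sum > 0
    inv[positive] = 1.0 / out_sum[positive]
    network.transition = sparse.diags(inv) @ adj
    network.dangling = [g for g, ok in zip(network.nodes, positive) if not ok]
    return network


# ---------------------------------------------------------------------------
# synthetic networks


def generate_synthetic_network(
    n_nodes: int,
    n_edges: int,
    seed: int,
    node_ids: list[str] | None = None,
    hub_bias: np.ndarray | None = None,
) -> DirectedPathwayNetwork:
    """Directed preferential-attachment graph with exact node/edge counts.

    A spanning arborescence over a random node order guarantees weak
    connectivity; remaining edges attach preferentially to high-degree nodes
    (optionally biased by ``hub_bias`` per node, used to hub differentially
    expressed genes in the synthetic benchmark).  Deterministic per seed.
    """
    if n_nodes < 1:
        raise ValidationError("need at least one node")
    if n_edges < n_nodes - 1:
        raise ValidationError(
            f"need >= n_nodes-1 edges for weak connectivity ({n_edges} < {n_nodes - 1})"
        )
    if n_edges > n_nodes * n_nodes:
        raise ValidationError("more edges requested than a simple digraph admits")
    rng = np.random.default_rng(seed)
    if node_ids is None:
        width = len(str(n_nodes))
        node_ids = [f"G{i + 1:0{width}d}" for i in range(n_nodes)]
    if len(node_ids) != n_nodes:
        raise ValidationError("node_ids length must equal n_nodes")
    bias = np.ones(n_nodes) if hub_bias is None else np.asarray(hub_bias, float)

    order = rng.permutation(n_nodes)
    edges: set[tuple[int, int]] = set()
    degree = np.zeros(n_nodes)
    # spanning tree over the random order, direction randomised
    for k in range(1, n_nodes):
        child = order[k]
        weights = degree[order[:k]] + bias[order[:k]]
        parent = order[rng.choice(k, p=weights / weights.sum())]
        e = (parent, child) if rng.random() < 0.5 else (child, parent)
        edges.add(e)
        degree[parent] += 1
        degree[child] += 1
    while len(edges) < n_edges:
        p = degree + bias
        p = p / p.sum()
        u, v = rng.choice(n_nodes, size=2, p=p)
        if (u, v) in edges:
            continue
        edges.add((u, v))
        degree[u] += 1
        degree[v] += 1
    edge_list = sorted(
        (node_ids[u], node_ids[v], "interacts") for u, v in edges
    )
    net = DirectedPathwayNetwork(list(node_ids), edge_list)
    return row_normalize(net)
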