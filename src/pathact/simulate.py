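"""Synthetic two-class expression benchmarks with planted risk pathways.

The generator emulates the structure of a cancer-vs-normal expression study:
a genes x samples Gaussian matrix in z-space, a gene-set collection whose
neighbouring sets overlap mildly (as real curated collections do), a directed
gene network in which differentially expressed genes are preferentially
hubbed, and a ground-truth record of which pathways carry signal.  Both
robustness assessments run end-to-end on its output with no downloads.

Differential expression is a mean shift of +/- delta standard deviations in
the tumour class, applied to a fraction of each risk pathway's members with a
50/50 up/down sign mixture (so signed aggregation schemes are exercised in
both directions).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionDataset, NORMAL, TUMOUR, ValidationError
from .markers import LiteratureIndex
from .profiles import PathwayActivityProfile
from .resources import (
    DirectedPathwayNetwork,
    GeneSetCollection,
    generate_synthetic_network,
)

__all__ = [
    "SyntheticDesign",
    "SyntheticTruth",
    "generate_dataset",
    "generate_literature_index",
    "generate_signal_profiles",
    "permute_labels",
    "write_truth",
    "read_truth",
]


@dataclass
class SyntheticDesign:
    """Generating parameters of one synthetic benchmark.

    Defaults are the benchmark's study conditions: 2000 genes, 50 samples per
    class, 100 pathways of 20-60 genes (sizes like curated canonical-pathway
    collections; large enough that most pathways keep >= 1 member gene after
    a p < 0.05 DEG filter, so top-50 selections stay well defined) with ~0.1
    neighbour Jaccard overlap,
    10 risk pathways in which half the members shift by delta = 1.5 sd, and a
    directed network of 3 edges per gene with DE genes preferentially hubbed.
    """

    n_genes: int = 2000
    n_samples: tuple[int, int] = (50, 50)  # (normal, tumour)
    n_pathways: int = 100
    pathway_size: tuple[int, int] = (20, 60)
    n_risk_pathways: int = 10
    effect_size: float = 1.5
    de_fraction: float = 0.5
    noise_sd: float = 1.0
    edges_per_gene: float = 3.0
    overlap: float = 0.1  # target neighbour Jaccard
    hub_bias: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_pathways, self.n_risk_pathways) < 1:
            raise ValidationError("counts must be positive")
        if min(self.n_samples) < 2:
            raise ValidationError("each class needs >= 2 samples")
        if not 0.0 < self.de_fraction <= 1.0:
            raise ValidationError("de_fraction must lie in (0, 1]")
        if self.n_risk_pathways > self.n_pathways:
            raise ValidationError("risk pathways cannot exceed pathways")
        if self.pathway_size[1] > self.n_genes:
            raise ValidationError("pathway sizes exceed the gene count")
        if self.noise_sd <= 0 or self.effect_size < 0:
            raise ValidationError("noise sd must be positive, effect size non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth: risk pathway ids, planted DE genes with directions."""

    risk_pathways: list[str]
    de_genes: dict[str, int]  # gene -> +1 (up in tumour) or -1
    design: dict = field(default_factory=dict)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def generate_dataset(
    design: SyntheticDesign,
) -> tuple[ExpressionDataset, GeneSetCollection, DirectedPathwayNetwork, SyntheticTruth]:
    """Draw one benchmark: expression, gene sets, network, and truth.

    Deterministic per ``design.seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    genes = _gene_ids(design.n_genes)
    n0, n1 = design.n_samples
    samples = [f"N{i + 1:03d}" for i in range(n0)] + [f"T{i + 1:03d}" for i in range(n1)]
    labels = pd.Series([NORMAL] * n0 + [TUMOUR] * n1, index=samples, name="label")

    # gene sets: sizes uniform in range; each set shares ~overlap Jaccard with
    # its predecessor, remaining members drawn fresh
    lo, hi = design.pathway_size
    sizes = rng.integers(lo, hi + 1, size=design.n_pathways)
    width = len(str(design.n_pathways))
    sets: dict[str, list[str]] = {}
    prev: list[str] = []
    share_frac = design.overlap / (1.0 + design.overlap) * 2.0  # Jaccard -> share
    for j, size in enumerate(sizes):
        pid = f"PWY{j + 1:0{width}d}"
        members: list[str] = []
        if prev:
            k = min(len(prev), max(1, round(share_frac * size)))
            members.extend(map(str, rng.choice(prev, size=k, replace=False)))
        pool = rng.permutation(design.n_genes)
        for gi in pool:
            if len(members) >= size:
                break
            g = genes[gi]
            if g not in members:
                members.append(g)
        sets[pid] = sorted(members)
        prev = sets[pid]
    collection = GeneSetCollection(sets, source=f"synthetic(seed={design.seed})")

    # risk pathways and planted DE genes
    risk_ids = sorted(
        str(p)
        for p in rng.choice(
            collection.pathway_ids(), size=design.n_risk_pathways, replace=False
        )
    )
    de_genes: dict[str, int] = {}
    for pid in risk_ids:
        members = collection.sets[pid]
        n_de = max(1, round(design.de_fraction * len(members)))
        chosen = rng.choice(members, size=n_de, replace=False)
        for g in map(str, chosen):
            if g not in de_genes:
                de_genes[g] = 1 if rng.random() < 0.5 else -1

    # expression: Gaussian baseline, tumour mean shifted for DE genes
    x = rng.normal(0.0, design.noise_sd, size=(design.n_genes, n0 + n1))
    gidx = {g: i for i, g in enumerate(genes)}
    shift = design.effect_size * design.noise_sd
    for g, direction in de_genes.items():
        x[gidx[g], n0:] += direction * shift
    dataset = ExpressionDataset(pd.DataFrame(x, index=genes, columns=samples), labels)

    # network: DE genes preferentially hubbed
    bias = np.ones(design.n_genes)
    for g in de_genes:
        bias[gidx[g]] = design.hub_bias
    n_edges = int(round(design.edges_per_gene * design.n_genes))
    network = generate_synthetic_network(
        design.n_genes,
        n_edges,
        seed=int(rng.integers(0, 2**31 - 1)),
        node_ids=genes,
        hub_bias=bias,
    )

    truth = SyntheticTruth(
        risk_pathways=list(risk_ids),
        de_genes=dict(sorted(de_genes.items())),
        design=asdict(design),
    )
    return dataset, collection, network, truth


def permute_labels(dataset: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Return the dataset with its labels randomly permuted (null benchmark)."""
    rng = np.random.default_rng(seed)
    shuffled = dataset.labels.to_numpy().copy()
    rng.shuffle(shuffled)
    return ExpressionDataset(
        dataset.values.copy(), pd.Series(shuffled, index=dataset.labels.index)
    )


def generate_literature_index(
    truth: SyntheticTruth, coverage: float, seed: int
) -> LiteratureIndex:
    """Index a deterministic fraction of the truth's marker terms.

    Exactly round(coverage * n) terms per category (risk pathways; DE genes)
    receive synthetic PMIDs; selection and PMIDs are drawn per seed.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValidationError("coverage must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    terms: dict[str, list[int]] = {}
    for category in (truth.risk_pathways, sorted(truth.de_genes)):
        n_pick = int(np.floor(coverage * len(category) + 0.5))
        if n_pick == 0:
            continue
        chosen = rng.choice(category, size=n_pick, replace=False)
        for term in sorted(map(str, chosen)):
            n_pmids = int(rng.integers(1, 4))
            terms[term] = sorted(int(p) for p in rng.integers(1, 10**8, size=n_pmids))
    return LiteratureIndex(terms, cancer_keyword="Synthetic Cancer")


def generate_signal_profiles(
    n_pathways: int = 20,
    n_signal: int = 3,
    n_train: tuple[int, int] = (30, 30),
    n_val: tuple[int, int] = (10, 10),
    effect_size: float = 1.5,
    seed: int = 0,
) -> dict:
    """Directly drawn activity profiles where only a few pathways carry signal.

    Pathway activities are unit Gaussians; the first ``n_signal`` pathways
    gain an ``effect_size`` mean shift in the tumour class of both portions.
    Used to exercise forward selection in isolation from the inference
    methods.  Returns train/val profiles, labels and the signal pathway ids.
    """
    rng = np.random.default_rng(seed)
    width = len(str(n_pathways))
    pids = [f"PWY{j + 1:0{width}d}" for j in range(n_pathways)]
    signal = pids[:n_signal]

    def draw(n0: int, n1: int, prefix: str) -> tuple[PathwayActivityProfile, pd.Series]:
        samples = [f"{prefix}N{i + 1:03d}" for i in range(n0)] + [
            f"{prefix}T{i + 1:03d}" for i in range(n1)
        ]
        x = rng.normal(size=(n_pathways, n0 + n1))
        x[:n_signal, n0:] += effect_size
        labels = pd.Series([NORMAL] * n0 + [TUMOUR] * n1, index=samples)
        df = pd.DataFrame(x, index=pids, columns=samples)
        prof = PathwayActivityProfile(
            df, "synthetic", {p: {"genes": [], "degs_used": 0} for p in pids}
        )
        return prof, labels

    train_prof, train_labels = draw(*n_train, "tr")
    val_prof, val_labels = draw(*n_val, "va")
    return {
        "train_profile": train_prof,
        "val_profile": val_prof,
        "train_labels": train_labels,
        "val_labels": val_labels,
        "signal": signal,
    }


def write_truth(truth: SyntheticTruth, stream) -> None:
    json.dump(
        {
            "risk_pathways": truth.risk_pathways,
            "de_genes": truth.de_genes,
            "design": truth.design,
        },
        stream,
        indent=1,
        sort_keys=True,
    )


def read_truth(stream) -> SyntheticTruth:
    data = json.load(stream)
    return SyntheticTruth(
        risk_pathways=list(data["risk_pathways"]),
        de_genes={g: int(d) for g, d in data["de_genes"].items()},
        design=dict(data.get("design", {})),
    )
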