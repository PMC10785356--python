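"""Uniform fit/score wrappers around the seven activity schemes.

The robustness assessments repeatedly (i) fit method parameters — gene
statistics, DEG membership, walk vectors, edge re-weightings — on a training
portion, then (ii) score training and held-out portions with those frozen
parameters, z-scoring each portion separately.  ``make_scorer`` builds the
wrapper for a method tag; every wrapper is deterministic.

GSVA and PAC/PLAGE carry no fitted parameters (label-free / per-portion
decompositions) and simply recompute per portion; COMBINER and the walk
methods freeze their training-derived state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .expression import ExpressionDataset, GeneStatistics, ValidationError, zscore_rows
from .geneset import combiner_activity, gsva_activity, pac_activity, plage_activity
from .profiles import PathwayActivityProfile
from .resources import DirectedPathwayNetwork, GeneSetCollection
from .topology import (
    WalkConfig,
    WalkResult,
    drw_activity,
    edrw_activity,
    initial_weight_vector,
    random_walk_restart,
    sdrw_reweight,
)

__all__ = ["PathwayScorer", "make_scorer", "METHOD_TAGS"]

METHOD_TAGS = ("combiner", "pac", "plage", "gsva", "drw", "sdrw", "edrw")


@dataclass
class PathwayScorer:
    """One activity method bound to its pathway resources.

    ``fit`` derives all label-dependent parameters from a training dataset;
    ``score`` turns any dataset over the same gene namespace into a pathway
    activity profile using those parameters.
    """

    method: str
    sets: GeneSetCollection | None = None
    network: DirectedPathwayNetwork | None = None
    sets_by_network: dict[str, GeneSetCollection] | None = None
    networks: dict[str, DirectedPathwayNetwork] | None = None
    p_threshold: float | None = None
    max_genes: int = 20
    tau: float = 1.0
    kcdf: str = "ecdf"
    walk_config: WalkConfig = field(default_factory=WalkConfig)

    stats_: GeneStatistics | None = None
    walk_: WalkResult | None = None
    walks_: dict[str, WalkResult] | None = None

    def __post_init__(self) -> None:
        if self.method not in METHOD_TAGS:
            raise ValidationError(f"unknown method {self.method!r}")
        if self.method in ("drw", "sdrw") and self.network is None:
            raise ValidationError(f"{self.method} needs a directed network")
        if self.method == "edrw":
            if self.networks is None and self.network is not None:
                self.networks = {"net": self.network}
                if self.sets_by_network is None and self.sets is not None:
                    self.sets_by_network = {"net": self.sets}
            if not self.networks or not self.sets_by_network:
                raise ValidationError("edrw needs networks and per-network gene sets")
        elif self.sets is None:
            raise ValidationError(f"{self.method} needs a gene-set collection")
        if self.p_threshold is None:
            self.p_threshold = 0.05

    # -- fitting -----------------------------------------------------------

    def fit(self, dataset: ExpressionDataset) -> "PathwayScorer":
        if self.method in ("gsva", "pac", "plage"):
            self.stats_ = None  # label-free / per-portion; nothing to freeze
            return self
        from .expression import gene_statistics

        self.stats_ = gene_statistics(dataset)
        if self.method == "drw":
            w0 = initial_weight_vector(self.stats_, self.network, mode="abs_t")
            self.walk_ = random_walk_restart(self.network, w0, self.walk_config)
        elif self.method == "sdrw":
            raw = self.stats_.tscore.abs()
            reweighted = sdrw_reweight(self.network, raw)
            w0 = initial_weight_vector(self.stats_, reweighted, mode="abs_t")
            self.walk_ = random_walk_restart(reweighted, w0, self.walk_config)
        elif self.method == "edrw":
            self.walks_ = {}
            for tag, net in self.networks.items():
                h0 = initial_weight_vector(self.stats_, net, mode="entropy")
                self.walks_[tag] = random_walk_restart(net, h0, self.walk_config)
        return self

    # -- scoring -----------------------------------------------------------

    def score(self, dataset: ExpressionDataset) -> PathwayActivityProfile:
        if self.method == "gsva":
            profile, _ = gsva_activity(dataset, self.sets, tau=self.tau, kcdf=self.kcdf)
            return profile
        z = zscore_rows(dataset)
        if self.method == "pac":
            return pac_activity(z, self.sets)
        if self.method == "plage":
            return plage_activity(z, self.sets)
        if self.stats_ is None:
            raise ValidationError(f"{self.method} scorer must be fit before scoring")
        if self.method == "combiner":
            return combiner_activity(
                z, self.stats_, self.sets, self.p_threshold, self.max_genes
            )
        if self.method == "drw" or self.method == "sdrw":
            profile = drw_activity(z, self.stats_, self.walk_, self.sets, self.p_threshold)
            profile.method = self.method
            return profile
        profile, _ = edrw_activity(
            z, self.stats_, self.walks_, self.sets_by_network, self.p_threshold
        )
        return profile

    def fit_score(self, dataset: ExpressionDataset) -> PathwayActivityProfile:
        return self.fit(dataset).score(dataset)


def make_scorer(
    method: str,
    sets: GeneSetCollection | None = None,
    network: DirectedPathwayNetwork | None = None,
    **params,
) -> PathwayScorer:
    """Build a :class:`PathwayScorer` for a method tag.

    Gene-set methods need ``sets``; drw/sdrw need ``sets`` and ``network``;
    edrw accepts either a single ``network`` (used for all sets) or
    ``networks=`` / ``sets_by_network=`` dicts keyed by network tag.
    """
    return PathwayScorer(method=method, sets=sets, network=network, **params)
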