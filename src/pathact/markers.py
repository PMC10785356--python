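"""Classification-driven pathway-marker identification (Assessment 2).

Workflow per experiment: split samples 60/20/20 (train/validation/test,
stratified), infer pathway activities with training-derived parameters, rank
the training pathways by absolute t-score, and run AUC-gated greedy forward
selection over the top candidates with a chosen classifier (Gaussian naive
Bayes, k-nearest neighbours, or L2 logistic regression).  A candidate stays
in the feature set only if it strictly increases the validation AUC; the
optimised feature set is then evaluated for accuracy on the test portion.
Repeating the experiment with fresh splits yields per-pathway selection
frequencies; the most frequently selected markers are checked against an
offline literature index (term -> PMIDs) to count informative markers.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from .expression import ExpressionDataset, TUMOUR, ValidationError
from .methods import PathwayScorer
from .profiles import PathwayActivityProfile
from .reproducibility import pathway_tscores

__all__ = [
    "SelectionResult",
    "MarkerSummary",
    "LiteratureIndex",
    "split_dataset",
    "rank_auc",
    "evaluate_classifier",
    "make_classifier",
    "forward_select",
    "assessment2",
    "marker_frequency",
    "build_pubmed_query",
    "count_informative",
    "normalise_term",
    "read_literature_index",
]

CLASSIFIER_TAGS = ("nb", "knn", "lr")


@dataclass
class SelectionResult:
    """Outcome of one forward-selection experiment with one classifier."""

    experiment: int
    classifier: str
    selected: list[str]
    auc_trajectory: list[float]  # validation AUC after each kept candidate
    test_auc: float | None
    test_accuracy: float
    confusion: dict[str, int]  # tp / tn / fp / fn at the 0.5 score threshold
    skipped: list[str] = field(default_factory=list)


@dataclass
class MarkerSummary:
    """Selection frequencies, top markers, and literature-index validation."""

    frequency: dict[str, int]
    mean_rank: dict[str, float]
    top_markers: list[str]
    pmids: dict[str, list[int]] = field(default_factory=dict)
    informative_pathways: int = 0
    informative_genes: int = 0
    gene_pmids: dict[str, list[int]] = field(default_factory=dict)


@dataclass
class LiteratureIndex:
    """Offline marker-term -> PMID mapping for one cancer-type keyword."""

    terms: dict[str, list[int]]
    cancer_keyword: str = ""

    def __post_init__(self) -> None:
        normalised: dict[str, list[int]] = {}
        for term, pmids in self.terms.items():
            pmids = sorted({int(p) for p in pmids})
            if any(p <= 0 for p in pmids):
                raise ValidationError(f"non-positive PMID under term {term!r}")
            normalised.setdefault(normalise_term(term), []).extend(pmids)
        self.terms = {t: sorted(set(v)) for t, v in normalised.items()}

    def lookup(self, term: str) -> list[int]:
        return self.terms.get(normalise_term(term), [])


def normalise_term(term: str) -> str:
    """Case-fold, strip punctuation, collapse whitespace."""
    cleaned = re.sub(r"[^\w\s]", " ", term.casefold())
    return re.sub(r"\s+", " ", cleaned).strip()


def read_literature_index(stream, cancer_keyword: str = "") -> LiteratureIndex:
    """Read a ``term\\tpmid`` TSV (one PMID per line) or a JSON term->PMIDs map."""
    text = stream.read()
    stripped = text.lstrip()
    terms: dict[str, list[int]] = {}
    if stripped.startswith("{"):
        for term, pmids in json.loads(text).items():
            terms.setdefault(term, []).extend(int(p) for p in pmids)
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\r").split("\t")
            if len(parts) != 2:
                raise ValidationError(f"literature TSV line {lineno}: expected 2 columns")
            terms.setdefault(parts[0], []).append(int(parts[1]))
    return LiteratureIndex(terms, cancer_keyword)


# ---------------------------------------------------------------------------
# splitting, classification, AUC


def split_dataset(
    dataset: ExpressionDataset,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[ExpressionDataset, ExpressionDataset, ExpressionDataset]:
    """Stratified, disjoint, exhaustive train/validation/test split.

    Within each class the shuffled samples are cut at the cumulative
    fractions (largest-remainder rounding, so the split is exhaustive).
    Raises when any portion would hold fewer than 2 samples of a class.
    """
    if len(fractions) != 3 or not np.isclose(sum(fractions), 1.0):
        raise ValidationError("fractions must be three numbers summing to 1")
    rng = np.random.default_rng(seed)
    portions: list[list[str]] = [[], [], []]
    for cls in sorted(dataset.labels.unique()):
        ids = np.array(sorted(dataset.labels.index[dataset.labels == cls]))
        rng.shuffle(ids)
        n = len(ids)
        counts = np.floor(np.asarray(fractions) * n).astype(int)
        remainders = np.asarray(fractions) * n - counts
        for _ in range(n - counts.sum()):
            i = int(np.argmax(remainders))
            counts[i] += 1
            remainders[i] = -1
        if (counts < 2).any():
            raise ValidationError(
                f"class {cls!r}: portions {counts.tolist()} need >= 2 samples each"
            )
        start = 0
        for i, c in enumerate(counts):
            portions[i].extend(str(s) for s in ids[start : start + c])
            start += c
    return tuple(dataset.subset_samples(p) for p in portions)  # type: ignore[return-value]


def rank_auc(scores: np.ndarray, y: np.ndarray) -> float | None:
    """AUC as the Mann-Whitney rank statistic; ties count half.

    Returns None (undefined) when only one class is present.
    """
    y = np.asarray(y, bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    r = rankdata(np.asarray(scores, float))
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def make_classifier(tag: str):
    """Instantiate one of the three reference classifiers.

    Gaussian NB; KNN with k = 5 and Euclidean distance; logistic regression
    with a mild L2 ridge so separable activity features stay estimable.
    """
    if tag == "nb":
        return GaussianNB()
    if tag == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if tag == "lr":
        return LogisticRegression(C=1.0, max_iter=1000)  # default L2 ridge
    raise ValidationError(f"unknown classifier tag {tag!r} (expected nb/knn/lr)")


def evaluate_classifier(
    model, features: np.ndarray, y: np.ndarray
) -> tuple[float | None, float, dict[str, int]]:
    """Score a fitted model: (AUC, accuracy, confusion counts).

    AUC comes from the rank statistic over the model's continuous scores;
    accuracy and the confusion counts use the 0.5 score threshold.  AUC is
    None (flagged undefined) when the evaluation labels are single-class.
    """
    scores = model.predict_proba(features)[:, 1]
    y = np.asarray(y, bool)
    auc = rank_auc(scores, y)
    pred = scores >= 0.5
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    accuracy = (tp + tn) / len(y)
    return auc, accuracy, {"tp": tp, "tn": tn, "fp": fp, "fn": fn}


# ---------------------------------------------------------------------------
# forward selection


def candidate_ranking(
    train_profile: PathwayActivityProfile, train_labels: pd.Series, n_candidates: int
) -> list[str]:
    """Top pathways by descending training activity \\|t\\| (ties by id)."""
    t = pathway_tscores(train_profile, train_labels)
    ranked = sorted(t.index, key=lambda p: (-abs(t[p]), p))
    return ranked[:n_candidates]


def forward_select(
    train_profile: PathwayActivityProfile,
    val_profile: PathwayActivityProfile,
    train_labels: pd.Series,
    val_labels: pd.Series,
    classifier: str,
    n_candidates: int = 50,
    candidates: list[str] | None = None,
    experiment: int = 0,
) -> SelectionResult:
    """AUC-gated greedy forward selection over the top-ranked candidates.

    Starting from an empty feature set with baseline AUC 0.5, each candidate
    (in training-rank order) is added, the classifier refit on the training
    portion, and the validation AUC computed; the candidate is kept iff the
    AUC strictly increases.  A classifier failure on a step skips that
    candidate and records it.
    """
    if candidates is None:
        candidates = candidate_ranking(train_profile, train_labels, n_candidates)
    if not candidates:
        raise ValidationError("no candidate pathways to select from")
    candidates = [
        p for p in candidates if p in val_profile.activity.index
    ]
    if not candidates:
        raise ValidationError("no candidate pathway is present in the validation profile")
    y_train = (train_labels.reindex(train_profile.sample_ids) == TUMOUR).to_numpy()
    y_val = (val_labels.reindex(val_profile.sample_ids) == TUMOUR).to_numpy()
    x_train = train_profile.activity.T  # samples x pathways
    x_val = val_profile.activity.T
    kept: list[str] = []
    trajectory: list[float] = []
    skipped: list[str] = []
    best_auc = 0.5
    for cand in candidates:
        trial = kept + [cand]
        try:
            model = make_classifier(classifier)
            model.fit(x_train[trial].to_numpy(), y_train)
            auc, _, _ = evaluate_classifier(model, x_val[trial].to_numpy(), y_val)
        except Exception:
            skipped.append(cand)
            continue
        if auc is None:
            raise ValidationError("validation labels are single-class; AUC undefined")
        if auc > best_auc:
            kept.append(cand)
            trajectory.append(auc)
            best_auc = auc
    return SelectionResult(
        experiment=experiment,
        classifier=classifier,
        selected=kept,
        auc_trajectory=trajectory,
        test_auc=None,
        test_accuracy=float("nan"),
        confusion={},
        skipped=skipped,
    )


def assessment2(
    dataset: ExpressionDataset,
    scorer: PathwayScorer,
    classifiers: tuple[str, ...] = CLASSIFIER_TAGS,
    repeats: int = 10,
    n_candidates: int = 50,
    seed: int = 0,
) -> dict:
    """Repeated split / select / test evaluation of one method.

    Per repeat a fresh stratified 60/20/20 split is drawn, the method fit on
    the training portion, and every classifier runs forward selection on the
    validation AUC; the optimised feature set is refit on training and scored
    for accuracy on the test portion (an empty selection falls back to the
    majority-class rate).  Returns per-classifier SelectionResults and mean
    accuracies plus the best classifier — highest mean accuracy, ties broken
    toward the classifier selecting more pathways.
    """
    children = np.random.SeedSequence(seed).spawn(repeats)
    results: dict[str, list[SelectionResult]] = {c: [] for c in classifiers}
    for rep, child in enumerate(children):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        train, val, test = split_dataset(dataset, seed=rep_seed)
        scorer.fit(train)
        prof_train = scorer.score(train)
        prof_val = scorer.score(val)
        prof_test = scorer.score(test)
        candidates = candidate_ranking(prof_train, train.labels, n_candidates)
        y_train = (train.labels.reindex(prof_train.sample_ids) == TUMOUR).to_numpy()
        y_test = (test.labels.reindex(prof_test.sample_ids) == TUMOUR).to_numpy()
        for tag in classifiers:
            sel = forward_select(
                prof_train,
                prof_val,
                train.labels,
                val.labels,
                tag,
                n_candidates=n_candidates,
                candidates=candidates,
                experiment=rep,
            )
            usable = [p for p in sel.selected if p in prof_test.activity.index]
            if usable:
                model = make_classifier(tag)
                model.fit(prof_train.activity.T[usable].to_numpy(), y_train)
                auc, acc, conf = evaluate_classifier(
                    model, prof_test.activity.T[usable].to_numpy(), y_test
                )
                sel.test_auc = auc
                sel.test_accuracy = acc
                sel.confusion = conf
            else:
                majority = max(y_test.mean(), 1.0 - y_test.mean())
                sel.test_auc = None
                sel.test_accuracy = float(majority)
                sel.confusion = {}
            results[tag].append(sel)
    mean_accuracy = {
        tag: float(np.mean([r.test_accuracy for r in results[tag]]))
        for tag in classifiers
    }
    totals = {tag: sum(len(r.selected) for r in results[tag]) for tag in classifiers}
    best = max(classifiers, key=lambda tag: (mean_accuracy[tag], totals[tag]))
    return {
        "results": results,
        "mean_accuracy": mean_accuracy,
        "selected_counts": totals,
        "best_classifier": best,
    }


# ---------------------------------------------------------------------------
# marker summaries and literature validation


def marker_frequency(results: list[SelectionResult], top_k: int = 6) -> MarkerSummary:
    """Rank pathways by selection frequency across experiments.

    Ties break toward the lower mean selection rank (earlier in the greedy
    order on average), then pathway id.
    """
    if not results:
        raise ValidationError("no selection results")
    freq: dict[str, int] = {}
    ranks: dict[str, list[int]] = {}
    for res in results:
        for pos, pid in enumerate(res.selected, start=1):
            freq[pid] = freq.get(pid, 0) + 1
            ranks.setdefault(pid, []).append(pos)
    mean_rank = {p: float(np.mean(r)) for p, r in ranks.items()}
    ordered = sorted(freq, key=lambda p: (-freq[p], mean_rank[p], p))
    return MarkerSummary(
        frequency=freq, mean_rank=mean_rank, top_markers=ordered[:top_k]
    )


def build_pubmed_query(marker: str, marker_kind: str, cancer_keyword: str) -> str:
    """Deterministic PubMed query string: marker AND prognostic AND "cancer type"."""
    if not marker.strip():
        raise ValidationError("empty marker term")
    if not cancer_keyword.strip():
        raise ValidationError("empty cancer keyword")
    if marker_kind not in ("pathway", "gene"):
        raise ValidationError(f"marker_kind must be 'pathway' or 'gene', got {marker_kind!r}")
    return f'{marker.strip()} AND prognostic AND "{cancer_keyword.strip()}"'


def count_informative(
    markers: list[str],
    genes_per_marker: dict[str, list[str]],
    index: LiteratureIndex,
) -> MarkerSummary:
    """Count markers and member genes with literature support.

    A marker (or gene) is informative iff its normalised term has at least
    one PMID in the index.  Returns the per-marker and per-gene PMID lists
    alongside the two counts.
    """
    pmids = {m: index.lookup(m) for m in markers}
    genes = sorted({g for m in markers for g in genes_per_marker.get(m, [])})
    gene_pmids = {g: index.lookup(g) for g in genes}
    return MarkerSummary(
        frequency={},
        mean_rank={},
        top_markers=list(markers),
        pmids=pmids,
        informative_pathways=sum(1 for m in markers if pmids[m]),
        informative_genes=sum(1 for g in genes if gene_pmids[g]),
        gene_pmids=gene_pmids,
    )
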