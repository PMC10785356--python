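"""Cross-validated reproducibility power of pathway activities (Assessment 1).

A method is reproducible when pathways that discriminate the classes on a
training portion also discriminate on held-out samples.  The reproducibility
power of a selection of N pathways is

    Cscore(N) = (1/N) * sum_i t_train(P_i) * t_test(P_i)

over the N pathways with the largest training \\|t\\|; concordant
discrimination in both portions yields positive products, so higher Cscore
means more robust pathway activity.  The assessment repeats a stratified
k-fold partition many times, fitting method parameters on each training
portion only, and reports the mean Cscore per top-k selection together with
its coefficient of variation across experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionDataset, ValidationError, pooled_tscores
from .methods import PathwayScorer
from .profiles import PathwayActivityProfile

__all__ = [
    "ReproducibilityRecord",
    "CvSummary",
    "pathway_tscores",
    "cscore",
    "stratified_folds",
    "assessment1",
    "coefficient_of_variation",
]


@dataclass
class ReproducibilityRecord:
    """One Cscore measurement: (method, partition, fold, top-k)."""

    method: str
    partition: int
    fold: int
    top_k: int
    cscore: float
    pairs: list[tuple[str, float, float]]  # (pathway, t_train, t_test), by |t_train| desc


@dataclass
class CvSummary:
    """Dispersion of Cscores: cv = sd / mean, in percent.

    ``cv`` is None (flagged undefined) when the mean is not positive.
    """

    method: str
    mean: float
    sd: float
    cv: float | None


def pathway_tscores(profile: PathwayActivityProfile, labels: pd.Series) -> pd.Series:
    """Pooled-variance two-sample t per pathway activity row (tumour - normal)."""
    labels = labels.reindex(profile.sample_ids)
    if labels.isna().any():
        raise ValidationError("labels do not cover all profile samples")
    mask = (labels == "tumour").to_numpy()
    x = profile.activity.to_numpy(float)
    t, _, _ = pooled_tscores(x, mask)
    return pd.Series(t, index=profile.activity.index, name="tscore")


def cscore(
    train_t: pd.Series,
    test_t: pd.Series,
    top_k: int,
    method: str = "",
    partition: int = 0,
    fold: int = 0,
) -> ReproducibilityRecord:
    """Mean product of training and test t-scores over the training top-k.

    Pathways are ranked by descending training \\|t\\| (ties by pathway id);
    both vectors must be indexed by the same pathways.
    """
    common = train_t.index.intersection(test_t.index)
    if top_k > len(common):
        raise ValidationError(
            f"top_k={top_k} exceeds the {len(common)} pathways shared by both portions"
        )
    ranked = sorted(common, key=lambda p: (-abs(train_t[p]), p))[:top_k]
    products = [float(train_t[p]) * float(test_t[p]) for p in ranked]
    return ReproducibilityRecord(
        method=method,
        partition=partition,
        fold=fold,
        top_k=top_k,
        cscore=float(np.mean(products)),
        pairs=[(p, float(train_t[p]), float(test_t[p])) for p in ranked],
    )


def stratified_folds(
    labels: pd.Series, folds: int, rng: np.random.Generator
) -> list[list[str]]:
    """Random class-stratified partition of sample ids into ``folds`` subsets.

    Each class is shuffled and dealt round-robin, so fold class proportions
    match the dataset within one sample.  Raises when some fold would hold
    fewer than 2 samples of a class.
    """
    fold_members: list[list[str]] = [[] for _ in range(folds)]
    for cls in sorted(labels.unique()):
        ids = np.array(sorted(labels.index[labels == cls]))
        if len(ids) < 2 * folds:
            raise ValidationError(
                f"class {cls!r} has {len(ids)} samples; needs >= 2 per fold x {folds} folds"
            )
        rng.shuffle(ids)
        for i, sid in enumerate(ids):
            fold_members[i % folds].append(str(sid))
    return fold_members


def assessment1(
    dataset: ExpressionDataset,
    scorer: PathwayScorer,
    folds: int = 5,
    repeats: int = 100,
    top_k_list: tuple[int, ...] = (50, 40, 30, 20, 10),
    seed: int = 0,
) -> tuple[list[ReproducibilityRecord], dict[int, float]]:
    """Repeated stratified k-fold reproducibility evaluation of one method.

    Per random partition, each fold in turn is the held-out portion: the
    method is fit on the remaining folds, both portions are scored with the
    training-derived parameters (each portion z-scored separately), pathway
    t-scores are computed per portion, and one Cscore record is produced per
    requested top-k.  Returns all folds x repeats records per top-k and the
    mean Cscore per top-k.  Deterministic per master seed (per-partition
    child seeds are fanned out with SeedSequence).
    """
    dataset.require_two_classes(min_per_class=2)
    children = np.random.SeedSequence(seed).spawn(repeats)
    records: list[ReproducibilityRecord] = []
    for part, child in enumerate(children):
        rng = np.random.default_rng(child)
        fold_members = stratified_folds(dataset.labels, folds, rng)
        for fold_id, test_ids in enumerate(fold_members):
            train_ids = [
                sid for f, members in enumerate(fold_members) if f != fold_id
                for sid in members
            ]
            train = dataset.subset_samples(train_ids)
            test = dataset.subset_samples(test_ids)
            scorer.fit(train)
            prof_train = scorer.score(train)
            prof_test = scorer.score(test)
            t_train = pathway_tscores(prof_train, train.labels)
            t_test = pathway_tscores(prof_test, test.labels)
            for k in top_k_list:
                records.append(
                    cscore(t_train, t_test, k, scorer.method, part, fold_id)
                )
    means = {
        k: float(np.mean([r.cscore for r in records if r.top_k == k]))
        for k in top_k_list
    }
    return records, means


def coefficient_of_variation(
    scores, method: str = ""
) -> CvSummary:
    """Sample sd over mean of a collection of Cscores, in percent."""
    values = np.asarray(
        [r.cscore if isinstance(r, ReproducibilityRecord) else float(r) for r in scores]
    )
    if values.size < 2:
        raise ValidationError("coefficient of variation needs >= 2 scores")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    cv = (sd / mean) * 100.0 if mean > 0 else None
    return CvSummary(method=method, mean=mean, sd=sd, cv=cv)
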