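"""Whole-pipeline synthetic benchmark harness.

Bundles the evaluations that exercise every method end-to-end on the default
synthetic study (2000 genes, 50+50 samples, 100 pathways, 10 risk pathways,
delta = 1.5):

* ``trend_and_recovery`` — per seed and method, the mean reproducibility
  power at top-10 vs top-50 (the headline trend: fewer, stronger selections
  reproduce better) and how many planted risk pathways appear in the
  method's top-20 activity \\|t\\| ranking.
* ``null_cscore`` — the same reproducibility machinery on label-permuted
  data, whose mean Cscore should be statistically indistinguishable from 0.
* ``selection_recovery`` — forward selection on directly drawn 3-signal
  activity profiles, counting full-signal recoveries and false positives.

Used by both the test suite and the acceptance script; everything is
deterministic per master seed.
"""

from __future__ import annotations

import numpy as np

from .markers import candidate_ranking, forward_select
from .methods import METHOD_TAGS, make_scorer
from .reproducibility import assessment1, pathway_tscores
from .resources import restrict_to_dataset
from .simulate import (
    SyntheticDesign,
    generate_dataset,
    generate_signal_profiles,
    permute_labels,
)

__all__ = ["trend_and_recovery", "null_cscore", "selection_recovery"]


def _child_seeds(master_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def _scorer_for(tag: str, sets, network):
    return make_scorer(tag, sets=sets, network=network)


def trend_and_recovery(
    master_seed: int,
    n_seeds: int = 20,
    methods: tuple[str, ...] = METHOD_TAGS,
    repeats: int = 10,
    folds: int = 5,
    top_k_pair: tuple[int, int] = (10, 50),
    recovery_top: int = 20,
    design_kwargs: dict | None = None,
) -> dict:
    """Per-seed trend and planted-pathway recovery for every method.

    For each of ``n_seeds`` independently generated benchmarks: run the
    repeated stratified-fold reproducibility evaluation (``repeats``
    partitions x ``folds``) and record the mean Cscore at the small and large
    top-k; additionally fit each method on the full dataset and count how
    many of the planted risk pathways sit in its top ``recovery_top``
    pathways by absolute activity t-score.
    """
    k_small, k_large = top_k_pair
    out: dict = {tag: {"mean_small": [], "mean_large": [], "hits": []} for tag in methods}
    out["seeds"] = _child_seeds(master_seed, n_seeds)
    for seed in out["seeds"]:
        design = SyntheticDesign(seed=seed, **(design_kwargs or {}))
        dataset, sets, network, truth = generate_dataset(design)
        sets = restrict_to_dataset(sets, dataset)
        risk = set(truth.risk_pathways)
        for tag in methods:
            scorer = _scorer_for(tag, sets, network)
            _, means = assessment1(
                dataset, scorer, folds=folds, repeats=repeats,
                top_k_list=(k_small, k_large), seed=seed,
            )
            out[tag]["mean_small"].append(means[k_small])
            out[tag]["mean_large"].append(means[k_large])
            profile = _scorer_for(tag, sets, network).fit_score(dataset)
            t = pathway_tscores(profile, dataset.labels)
            top = sorted(t.index, key=lambda p: (-abs(t[p]), p))[:recovery_top]
            out[tag]["hits"].append(len(risk & {p.split("|")[0] for p in top}))
    for tag in methods:
        rec = out[tag]
        rec["trend_fraction"] = float(
            np.mean(
                [s >= l for s, l in zip(rec["mean_small"], rec["mean_large"])]
            )
        )
        rec["recovery_fraction"] = float(np.mean([h >= 8 for h in rec["hits"]]))
    return out


def null_cscore(
    master_seed: int,
    methods: tuple[str, ...] = METHOD_TAGS,
    repeats: int = 20,
    folds: int = 5,
    top_k: int = 10,
    design_kwargs: dict | None = None,
) -> dict:
    """Mean Cscore and its standard error on label-permuted data.

    Each of ``repeats`` partitions draws a fresh benchmark with freshly
    permuted labels, so training and held-out t-scores are genuinely
    independent and the expected Cscore is exactly 0.  (Repeated partitions
    of a single fixed dataset would not do: its chance gene-label
    associations are shared between complementary portions and bias the
    product of t-scores.)
    """
    seeds = _child_seeds(master_seed, repeats)
    values: dict[str, list[float]] = {tag: [] for tag in methods}
    part_means: dict[str, list[float]] = {tag: [] for tag in methods}
    for seed in seeds:
        design = SyntheticDesign(seed=seed, **(design_kwargs or {}))
        dataset, sets, network, _ = generate_dataset(design)
        dataset = permute_labels(dataset, seed=seed + 1)
        sets_r = restrict_to_dataset(sets, dataset)
        for tag in methods:
            scorer = _scorer_for(tag, sets_r, network)
            records, _ = assessment1(
                dataset, scorer, folds=folds, repeats=1,
                top_k_list=(top_k,), seed=seed,
            )
            scores = [r.cscore for r in records]
            values[tag].extend(scores)
            part_means[tag].append(float(np.mean(scores)))
    out = {}
    for tag in methods:
        arr = np.array(values[tag])
        # folds within a partition share a dataset, so the standard error of
        # the mean is clustered at the partition level
        pm = np.array(part_means[tag])
        out[tag] = {
            "mean": float(arr.mean()),
            "se": float(pm.std(ddof=1) / np.sqrt(len(pm))),
            "n": len(arr),
        }
    return out


def selection_recovery(
    master_seed: int,
    runs: int = 50,
    classifier: str = "lr",
    n_pathways: int = 20,
    n_signal: int = 3,
) -> dict:
    """Forward-selection recovery of planted signal pathways.

    ``runs`` independent 3-signal activity-profile draws; each run counts as
    a full recovery when all planted signals are selected with at most two
    false positives.
    """
    seeds = _child_seeds(master_seed, runs)
    full = 0
    found_counts = []
    fp_counts = []
    for seed in seeds:
        sim = generate_signal_profiles(
            n_pathways=n_pathways, n_signal=n_signal, seed=seed
        )
        cands = candidate_ranking(
            sim["train_profile"], sim["train_labels"], n_pathways
        )
        res = forward_select(
            sim["train_profile"], sim["val_profile"],
            sim["train_labels"], sim["val_labels"], classifier,
            candidates=cands,
        )
        signal = set(sim["signal"])
        found = len(set(res.selected) & signal)
        fp = len(set(res.selected) - signal)
        found_counts.append(found)
        fp_counts.append(fp)
        full += found == n_signal and fp <= 2
    return {
        "runs": runs,
        "full_recovery_fraction": full / runs,
        "mean_signals_found": float(np.mean(found_counts)),
        "mean_false_positives": float(np.mean(fp_counts)),
    }
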