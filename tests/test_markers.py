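import io

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import pathact as pa
from pathact import markers as mk
from pathact.expression import NORMAL, TUMOUR, ValidationError


def brute_force_auc(scores, y):
    """All-pairs concordance count: ties contribute one half."""
    pos = [s for s, t in zip(scores, y) if t]
    neg = [s for s, t in zip(scores, y) if not t]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestSplit:
    def _dataset(self, n0, n1):
        rng = np.random.default_rng(0)
        samples = [f"N{i}" for i in range(n0)] + [f"T{i}" for i in range(n1)]
        values = pd.DataFrame(
            rng.normal(size=(5, n0 + n1)), index=[f"G{i}" for i in range(5)], columns=samples
        )
        return pa.ExpressionDataset(
            values, pd.Series([NORMAL] * n0 + [TUMOUR] * n1, index=samples)
        )

    def test_balanced_hundred_gives_30_10_10_per_class(self):
        ds = self._dataset(50, 50)
        train, val, test = pa.split_dataset(ds, seed=1)
        for part, expect in ((train, 30), (val, 10), (test, 10)):
            counts = part.labels.value_counts()
            assert counts[NORMAL] == expect and counts[TUMOUR] == expect

    def test_partition_identity(self):
        ds = self._dataset(23, 31)
        parts = pa.split_dataset(ds, seed=2)
        ids = [set(p.sample_ids) for p in parts]
        assert ids[0] | ids[1] | ids[2] == set(ds.sample_ids)
        assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])

    def test_deterministic(self):
        ds = self._dataset(20, 20)
        a = pa.split_dataset(ds, seed=3)
        b = pa.split_dataset(ds, seed=3)
        assert all(x.sample_ids == y.sample_ids for x, y in zip(a, b))

    def test_infeasible_split_rejected(self):
        ds = self._dataset(4, 4)
        with pytest.raises(ValidationError):
            pa.split_dataset(ds, seed=0)


class TestAuc:
    def test_hand_four_sample_example(self):
        auc = pa.rank_auc(np.array([0.9, 0.8, 0.4, 0.1]), np.array([1, 1, 0, 0]))
        assert auc == 1.0

    def test_constant_scores_give_chance(self):
        assert pa.rank_auc(np.zeros(10), np.array([1] * 5 + [0] * 5)) == 0.5

    def test_single_class_undefined(self):
        assert pa.rank_auc(np.array([0.1, 0.2]), np.array([1, 1])) is None

    def test_brute_force_concordance_exact(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            n = int(rng.integers(4, 31))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, size=int(rng.integers(2, n - 1)), replace=False)] = 1
            if y.sum() in (0, n):
                continue
            assert pa.rank_auc(scores, y) == pytest.approx(
                brute_force_auc(scores, y), abs=1e-12
            )

    def test_sklearn_oracle(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(int)
        if 0 < y.sum() < 40:
            assert pa.rank_auc(scores, y) == pytest.approx(
                roc_auc_score(y, scores), abs=1e-12
            )

    def test_evaluate_classifier_perfect(self):
        x = np.array([[0.0], [0.1], [5.0], [6.0]])
        y = np.array([False, False, True, True])
        model = mk.make_classifier("lr").fit(x, y)
        auc, acc, conf = pa.evaluate_classifier(model, x, y)
        assert auc == 1.0 and acc == 1.0
        assert conf == {"tp": 2, "tn": 2, "fp": 0, "fn": 0}
        assert (conf["tp"] + conf["tn"]) / 4 == acc


class TestForwardSelect:
    def _profiles(self, pids, n=8):
        rng = np.random.default_rng(12)
        samples_t = [f"tr{i}" for i in range(n)]
        samples_v = [f"va{i}" for i in range(n)]
        prov = {p: {"genes": [], "degs_used": 0} for p in pids}
        tr = pa.PathwayActivityProfile(
            pd.DataFrame(rng.normal(size=(len(pids), n)), index=pids, columns=samples_t),
            "test", prov)
        va = pa.PathwayActivityProfile(
            pd.DataFrame(rng.normal(size=(len(pids), n)), index=pids, columns=samples_v),
            "test", prov)
        labels_t = pd.Series([NORMAL] * (n // 2) + [TUMOUR] * (n - n // 2), index=samples_t)
        labels_v = pd.Series([NORMAL] * (n // 2) + [TUMOUR] * (n - n // 2), index=samples_v)
        return tr, va, labels_t, labels_v

    def test_greedy_rule_keeps_strict_improvers(self, monkeypatch):
        # scripted validation AUCs per candidate: 0.9, 0.6, 0.95 -> keep 1st and 3rd
        tr, va, lt, lv = self._profiles(["P1", "P2", "P3"])
        scripted = iter([0.9, 0.6, 0.95])

        class StubModel:
            def fit(self, x, y):
                return self

        monkeypatch.setattr(mk, "make_classifier", lambda tag: StubModel())
        monkeypatch.setattr(
            mk, "evaluate_classifier", lambda model, x, y: (next(scripted), 0.0, {})
        )
        res = mk.forward_select(tr, va, lt, lv, "nb", candidates=["P1", "P2", "P3"])
        assert res.selected == ["P1", "P3"]
        assert res.auc_trajectory == [0.9, 0.95]

    def test_perfect_first_candidate_blocks_rest(self):
        # P1 separates validation perfectly; later candidates cannot improve
        pids = ["P1", "P2", "P3"]
        n = 12
        samples_t = [f"tr{i}" for i in range(n)]
        samples_v = [f"va{i}" for i in range(n)]
        rng = np.random.default_rng(13)
        xt = rng.normal(size=(3, n))
        xv = rng.normal(size=(3, n))
        xt[0, n // 2 :] += 10.0
        xv[0, n // 2 :] += 10.0
        prov = {p: {"genes": [], "degs_used": 0} for p in pids}
        tr = pa.PathwayActivityProfile(pd.DataFrame(xt, index=pids, columns=samples_t), "t", prov)
        va = pa.PathwayActivityProfile(pd.DataFrame(xv, index=pids, columns=samples_v), "t", prov)
        lt = pd.Series([NORMAL] * (n // 2) + [TUMOUR] * (n // 2), index=samples_t)
        lv = pd.Series([NORMAL] * (n // 2) + [TUMOUR] * (n // 2), index=samples_v)
        res = pa.forward_select(tr, va, lt, lv, "lr", candidates=pids)
        assert res.selected == ["P1"]
        assert res.auc_trajectory == [1.0]

    def test_no_candidates_rejected(self):
        tr, va, lt, lv = self._profiles(["P1"])
        with pytest.raises(ValidationError):
            pa.forward_select(tr, va, lt, lv, "nb", candidates=[])

    def test_trajectory_strictly_increasing(self, small_benchmark):
        ds, sets = small_benchmark["dataset"], small_benchmark["sets"]
        train, val, _ = pa.split_dataset(ds, seed=4)
        scorer = pa.make_scorer("combiner", sets=sets).fit(train)
        res = pa.forward_select(
            scorer.score(train), scorer.score(val), train.labels, val.labels, "nb",
            n_candidates=20,
        )
        assert all(b > a for a, b in zip(res.auc_trajectory, res.auc_trajectory[1:]))

    def test_signal_pathways_dominate_selection(self):
        # the greedy picker should lock onto the planted signals: the first
        # kept feature is always one of them, and at least two of the three
        # survive in most runs (full 3-of-3 recovery is limited by the
        # strict-increase rule saturating a 20-sample validation AUC)
        runs = 15
        first_is_signal = 0
        two_or_more = 0
        for seed in range(runs):
            sim = pa.generate_signal_profiles(seed=seed)
            res = pa.forward_select(
                sim["train_profile"], sim["val_profile"],
                sim["train_labels"], sim["val_labels"], "lr",
                candidates=mk.candidate_ranking(sim["train_profile"], sim["train_labels"], 20),
            )
            signal = set(sim["signal"])
            first_is_signal += bool(res.selected) and res.selected[0] in signal
            two_or_more += len(set(res.selected) & signal) >= 2
        assert first_is_signal == runs
        assert two_or_more >= 0.8 * runs


class TestAssessment2:
    def test_bookkeeping_and_determinism(self, small_benchmark):
        ds, sets = small_benchmark["dataset"], small_benchmark["sets"]
        scorer = pa.make_scorer("pac", sets=sets)
        out1 = pa.assessment2(ds, scorer, classifiers=("nb", "lr"), repeats=3,
                              n_candidates=10, seed=9)
        assert {len(v) for v in out1["results"].values()} == {3}
        for tag in ("nb", "lr"):
            accs = [r.test_accuracy for r in out1["results"][tag]]
            assert out1["mean_accuracy"][tag] == pytest.approx(float(np.mean(accs)))
        out2 = pa.assessment2(ds, scorer, classifiers=("nb", "lr"), repeats=3,
                              n_candidates=10, seed=9)
        for tag in ("nb", "lr"):
            assert [r.selected for r in out1["results"][tag]] == [
                r.selected for r in out2["results"][tag]
            ]
        assert out1["best_classifier"] == out2["best_classifier"]


class TestMarkerFrequency:
    def _result(self, exp, selected):
        return mk.SelectionResult(exp, "nb", selected, [0.9] * len(selected),
                                  None, 1.0, {})

    def test_always_selected_ranks_first(self):
        results = [self._result(i, ["A", "B"] if i % 2 else ["A"]) for i in range(10)]
        summary = pa.marker_frequency(results, top_k=2)
        assert summary.top_markers[0] == "A"
        assert summary.frequency["A"] == 10

    def test_tie_broken_by_mean_selection_rank(self):
        results = [
            self._result(0, ["X", "Y"]),
            self._result(1, ["Y", "X"]),
            self._result(2, ["X", "Y"]),
        ]
        summary = pa.marker_frequency(results, top_k=2)
        # both selected 3 times; X has mean rank (1+2+1)/3 < Y's (2+1+2)/3
        assert summary.top_markers == ["X", "Y"]

    def test_frequency_bound(self):
        results = [self._result(i, ["A", "B", "C"]) for i in range(7)]
        summary = pa.marker_frequency(results)
        assert sum(summary.frequency.values()) <= 7 * 3
        assert all(v <= 7 for v in summary.frequency.values())


class TestLiterature:
    def test_query_template(self):
        q = pa.build_pubmed_query("TP53", "gene", "Breast Cancer")
        assert q == 'TP53 AND prognostic AND "Breast Cancer"'
        assert q == pa.build_pubmed_query("TP53", "gene", "Breast Cancer")

    def test_empty_marker_rejected(self):
        with pytest.raises(ValidationError):
            pa.build_pubmed_query("  ", "gene", "Breast Cancer")

    def test_tsv_and_json_round_trip(self):
        tsv = "Wnt signaling\t123\nWnt signaling\t456\nTP53\t789\n"
        idx = mk.read_literature_index(io.StringIO(tsv))
        assert idx.lookup("wnt  SIGNALING!") == [123, 456]
        idx2 = mk.read_literature_index(
            io.StringIO('{"Wnt signaling": [123, 456], "TP53": [789]}')
        )
        assert idx.terms == idx2.terms

    def test_count_informative(self):
        idx = pa.LiteratureIndex({"P1": [11], "G1": [22]}, "Synthetic Cancer")
        out = pa.count_informative(
            ["P1", "P2", "P3"], {"P1": ["G1", "G2"], "P2": ["G3"]}, idx
        )
        assert out.informative_pathways == 1
        assert out.informative_genes == 1
        assert out.pmids["P1"] == [11] and out.pmids["P2"] == []
        assert out.informative_pathways <= 3

    def test_empty_index_vacuous(self):
        idx = pa.LiteratureIndex({}, "")
        out = pa.count_informative(["A", "B"], {}, idx)
        assert out.informative_pathways == 0 and out.informative_genes == 0
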