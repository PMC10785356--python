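import numpy as np
import pandas as pd
import pytest

import pathact as pa
from pathact.expression import NORMAL, TUMOUR, ValidationError


def make_z(values, genes, samples=None):
    samples = samples or [f"S{i}" for i in range(np.asarray(values).shape[1])]
    return pa.ZMatrix(pd.DataFrame(values, index=genes, columns=samples))


def make_stats(genes, t, p):
    t = pd.Series(t, index=genes, dtype=float)
    p = pd.Series(p, index=genes, dtype=float)
    sign = pd.Series(np.where(t >= 0, 1.0, -1.0), index=genes)
    zero = pd.Series(0.0, index=genes)
    return pa.GeneStatistics(t, p, sign, zero, zero + t, zero)


def brute_force_gsva(x, genes, members, tau=1.0):
    """Independent O(p^2 n) enrichment walk: explicit loops, no shortcuts."""
    p, n = x.shape
    es_pos, es_neg, walks = [], [], []
    for j in range(n):
        sc = [sum(1 for k in range(n) if x[i, k] <= x[i, j]) / n for i in range(p)]
        order = sorted(range(p), key=lambda i: (-sc[i], genes[i]))
        weight = [abs((p - l) - p / 2.0) ** tau for l in range(p)]
        total_in = sum(
            w for l, w in zip(range(p), weight) if genes[order[l]] in members
        )
        cum_in = cum_out = 0.0
        vs = []
        for l in range(p):
            if genes[order[l]] in members:
                cum_in += weight[l]
            else:
                cum_out += 1
            vs.append(cum_in / total_in - cum_out / (p - len(members)))
        es_pos.append(max(0.0, max(vs)))
        es_neg.append(min(0.0, min(vs)))
        walks.append(vs)
    return np.array(es_pos), np.array(es_neg), np.array(walks).T


class TestCombiner:
    def test_deg_cap_at_max_genes(self):
        genes = [f"G{i:02d}" for i in range(25)]
        z = make_z(np.ones((25, 4)), genes)
        stats = make_stats(genes, np.arange(1, 26, dtype=float), [0.01] * 25)
        prof = pa.combiner_activity(z, stats, pa.GeneSetCollection({"P": genes}))
        assert prof.provenance["P"]["degs_used"] == 20
        # the 20 largest |t| survive
        assert set(prof.provenance["P"]["genes"]) == set(genes[5:])

    def test_single_deg_identity(self):
        z = make_z([[0.3, -1.2, 2.0]], ["G1"])
        stats = make_stats(["G1"], [2.5], [0.01])
        prof = pa.combiner_activity(z, stats, pa.GeneSetCollection({"P": ["G1"]}))
        assert np.allclose(prof.activity.loc["P"], [0.3, -1.2, 2.0])

    def test_hand_two_gene_value(self):
        z = make_z([[1.0], [2.0]], ["G1", "G2"], samples=["S"])
        stats = make_stats(["G1", "G2"], [3.0, -3.0], [0.01, 0.01])
        prof = pa.combiner_activity(z, stats, pa.GeneSetCollection({"P": ["G1", "G2"]}))
        assert prof.activity.loc["P", "S"] == pytest.approx(-1.0 / np.sqrt(2), abs=1e-12)

    def test_non_deg_pathway_dropped(self):
        z = make_z([[1.0, 2.0]], ["G1"])
        stats = make_stats(["G1"], [0.5], [0.8])
        prof = pa.combiner_activity(z, stats, pa.GeneSetCollection({"P": ["G1"]}))
        assert prof.activity.empty and "P" in prof.dropped

    def test_linearity_in_z(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(10)]
        zv = rng.normal(size=(10, 6))
        stats = make_stats(genes, rng.normal(size=10) * 3, [0.01] * 10)
        sets = pa.GeneSetCollection({"P": genes[:5], "Q": genes[3:]})
        a1 = pa.combiner_activity(make_z(zv, genes), stats, sets).activity
        a2 = pa.combiner_activity(make_z(3.0 * zv, genes), stats, sets).activity
        assert np.allclose(a2, 3.0 * a1, atol=1e-12)


class TestPac:
    def test_single_gene_set_equals_z_row(self):
        z = make_z([[0.1, -0.5, 2.0]], ["G1"])
        prof = pa.pac_activity(z, pa.GeneSetCollection({"P": ["G1"]}))
        assert np.allclose(prof.activity.loc["P"], z.values.loc["G1"])

    def test_hand_four_gene_value(self):
        z = make_z(np.full((4, 1), 0.5), [f"G{i}" for i in range(4)], samples=["S"])
        prof = pa.pac_activity(z, pa.GeneSetCollection({"P": [f"G{i}" for i in range(4)]}))
        assert prof.activity.loc["P", "S"] == pytest.approx(1.0, abs=1e-12)

    def test_unit_variance_under_independent_members(self):
        rng = np.random.default_rng(1)
        k, n = 8, 10_000
        genes = [f"G{i}" for i in range(k)]
        z = make_z(rng.normal(size=(k, n)), genes)
        prof = pa.pac_activity(z, pa.GeneSetCollection({"P": genes}))
        assert prof.activity.loc["P"].std(ddof=1) == pytest.approx(1.0, abs=0.05)


class TestPlage:
    def test_activity_unit_norm(self, random_dataset):
        z = pa.zscore_rows(random_dataset)
        sets = pa.GeneSetCollection({"P": random_dataset.gene_ids[:7]})
        prof = pa.plage_activity(z, sets)
        assert np.linalg.norm(prof.activity.loc["P"]) == pytest.approx(1.0, abs=1e-9)

    def test_rank_one_recovery(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=6)
        v = rng.normal(size=9)
        genes = [f"G{i}" for i in range(6)]
        z = make_z(np.outer(u, v), genes)
        prof = pa.plage_activity(z, pa.GeneSetCollection({"P": genes}))
        act = prof.activity.loc["P"].to_numpy()
        corr = np.corrcoef(act, v / np.linalg.norm(v))[0, 1]
        assert abs(corr) > 0.999

    def test_member_order_irrelevant(self, random_dataset):
        z = pa.zscore_rows(random_dataset)
        members = random_dataset.gene_ids[:8]
        a = pa.plage_activity(z, pa.GeneSetCollection({"P": members})).activity
        b = pa.plage_activity(z, pa.GeneSetCollection({"P": members[::-1]})).activity
        assert np.allclose(a, b, atol=1e-8)

    def test_duplicated_rows_keep_direction(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(4)]
        zv = rng.normal(size=(4, 7))
        a = pa.plage_activity(make_z(zv, genes), pa.GeneSetCollection({"P": genes})).activity
        dup_genes = genes + [f"H{i}" for i in range(4)]
        b = pa.plage_activity(
            make_z(np.vstack([zv, zv]), dup_genes),
            pa.GeneSetCollection({"P": dup_genes}),
        ).activity
        corr = np.corrcoef(a.loc["P"], b.loc["P"])[0, 1]
        assert abs(abs(corr) - 1.0) < 1e-9

    def test_reconstruction_and_factor_invariants(self, random_dataset):
        z = pa.zscore_rows(random_dataset)
        sets = pa.GeneSetCollection({"P": random_dataset.gene_ids[:6]})
        prof, factors = pa.plage_activity(z, sets, return_factors=True)
        f = factors["P"]
        sub = z.values.loc[sets.sets["P"]].to_numpy()
        recon = f.left_vectors @ np.diag(f.singular_values) @ f.right_vectors
        assert np.max(np.abs(recon - sub)) < 1e-8
        assert np.all(np.diff(f.singular_values) <= 1e-12)
        assert np.allclose(np.linalg.norm(f.right_vectors, axis=1), 1.0, atol=1e-9)


class TestGsva:
    def _dataset(self, x, genes):
        n = x.shape[1]
        samples = [f"S{i}" for i in range(n)]
        labels = pd.Series([NORMAL] * (n // 2) + [TUMOUR] * (n - n // 2), index=samples)
        return pa.ExpressionDataset(pd.DataFrame(x, index=genes, columns=samples), labels)

    def test_single_top_gene_closed_form_walk(self):
        # G1 is the strict top of sample S0; a singleton set walks v(l) = 1 - (l-1)/(p-1)
        rng = np.random.default_rng(4)
        p = 6
        genes = [f"G{i}" for i in range(p)]
        x = rng.normal(size=(p, 4))
        x[0, 0] = 10.0  # ecdf score 1.0, unique top in sample 0
        ds = self._dataset(x, genes)
        prof, scores = pa.gsva_activity(ds, pa.GeneSetCollection({"P": ["G0"]}), keep_walks=True)
        v = scores.walks["P"][:, 0]
        expected = 1.0 - np.arange(p) / (p - 1)
        assert np.allclose(v, expected, atol=1e-12)
        assert prof.activity.loc["P", "S0"] == pytest.approx(1.0, abs=1e-12)

    def test_esdiff_identity(self, random_dataset):
        sets = pa.GeneSetCollection(
            {"A": random_dataset.gene_ids[:5], "B": random_dataset.gene_ids[10:18]}
        )
        _, scores = pa.gsva_activity(random_dataset, sets)
        assert np.allclose(
            scores.es_diff, scores.es_pos.abs() - scores.es_neg.abs(), atol=1e-15
        )

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(8)]
        x = rng.normal(size=(8, 4))
        ds = self._dataset(x, genes)
        sets = pa.GeneSetCollection({"A": genes[:3], "B": [genes[1], genes[5], genes[7]]})
        prof, scores = pa.gsva_activity(ds, sets, keep_walks=True)
        prof_fast, _ = pa.gsva_activity(ds, sets, keep_walks=False)
        for pid in sets.sets:
            bp, bn, bw = brute_force_gsva(x, genes, set(sets.sets[pid]))
            assert np.allclose(scores.es_pos.loc[pid], bp, atol=1e-12)
            assert np.allclose(scores.es_neg.loc[pid], bn, atol=1e-12)
            assert np.allclose(scores.walks[pid], bw, atol=1e-12)
            assert np.allclose(prof.activity.loc[pid], np.abs(bp) - np.abs(bn), atol=1e-12)
            # the sparse-extrema path agrees with the full walk
            assert np.allclose(prof_fast.activity.loc[pid], prof.activity.loc[pid], atol=1e-12)

    def test_monotone_transform_invariance(self, random_dataset):
        sets = pa.GeneSetCollection({"A": random_dataset.gene_ids[:6]})
        a, _ = pa.gsva_activity(random_dataset, sets)
        warped = pa.ExpressionDataset(
            np.exp(random_dataset.values / 2.0), random_dataset.labels.copy()
        )
        b, _ = pa.gsva_activity(warped, sets)
        assert np.allclose(a.activity, b.activity, atol=1e-12)

    def test_esdiff_bounded(self, random_dataset):
        sets = pa.GeneSetCollection(
            {f"P{j}": list(np.random.default_rng(j).choice(random_dataset.gene_ids, 6, replace=False)) for j in range(10)}
        )
        prof, _ = pa.gsva_activity(random_dataset, sets)
        assert (prof.activity.to_numpy() <= 1.0 + 1e-12).all()
        assert (prof.activity.to_numpy() >= -1.0 - 1e-12).all()

    def test_whole_universe_set_rejected(self, random_dataset):
        with pytest.raises(ValidationError):
            pa.gsva_activity(
                random_dataset, pa.GeneSetCollection({"ALL": random_dataset.gene_ids})
            )


def test_all_methods_deterministic(small_benchmark):
    ds, sets, net = (small_benchmark[k] for k in ("dataset", "sets", "network"))
    for tag in pa.METHOD_TAGS:
        a = pa.make_scorer(tag, sets=sets, network=net).fit_score(ds)
        b = pa.make_scorer(tag, sets=sets, network=net).fit_score(ds)
        assert a.activity.to_csv() == b.activity.to_csv()
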