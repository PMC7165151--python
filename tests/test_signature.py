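"""Derivation-stage tests: filtering, clustering, labelling, DE, Venn, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codsig import (CohortAnnotation, ExpressionMatrix, StageError,
                    ValidationError, derive_signature,
                    derive_signature_detailed, differential_genes,
                    hierarchical_cluster, label_clusters, variance_filter,
                    venn_partition, simulate_cohort)

from conftest import small_config


def matrix(rows, genes=None, samples=None):
    rows = np.asarray(rows, float)
    genes = genes or [f"g{i + 1}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(rows.shape[1])]
    return ExpressionMatrix(genes, samples, rows)


class TestVarianceFilter:
    def test_hand_computed_sds_strict_threshold(self):
        # per-row sample SDs: 1.2, 0.9, 0.3, 2.0, 0.0 by construction
        base = np.array([-1.0, 0.0, 1.0]) / np.std([-1.0, 0.0, 1.0], ddof=1)
        expr = matrix(np.outer([1.2, 0.9, 0.3, 2.0, 0.0], base))
        sds = expr.values.std(axis=1, ddof=1)
        np.testing.assert_allclose(sds, [1.2, 0.9, 0.3, 2.0, 0.0], atol=1e-12)
        assert variance_filter(expr, 0.9) == ["g1", "g4"]

    def test_constant_gene_always_excluded(self):
        expr = matrix([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        assert "g1" not in variance_filter(expr, 0.0001)
        assert "g2" in variance_filter(expr, 0.0)

    def test_threshold_monotonicity(self, rng):
        expr = matrix(rng.normal(size=(50, 10)) * rng.uniform(0, 2, (50, 1)))
        previous = set(variance_filter(expr, 0.0))
        for thr in (0.2, 0.5, 1.0, 1.5):
            current = set(variance_filter(expr, thr))
            assert current <= previous
            previous = current

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            variance_filter(matrix([[1.0]]), 0.5)


class TestHierarchicalCluster:
    def _point_masses(self):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        cols = np.repeat(centers, 4, axis=0).T  # 2 genes x 12 samples
        noise = np.random.default_rng(0).normal(0, 0.01, cols.shape)
        return matrix(cols + noise)

    def test_separated_groups_recovered(self):
        expr = self._point_masses()
        model = hierarchical_cluster(expr, expr.gene_ids, k=3,
                                     distance="euclidean")
        groups = [set(model.members(c)) for c in (1, 2, 3)]
        expected = [set(expr.sample_ids[i:i + 4]) for i in (0, 4, 8)]
        assert set(map(frozenset, groups)) == set(map(frozenset, expected))

    def test_k_equals_n(self):
        expr = matrix(np.random.default_rng(1).normal(size=(5, 6)))
        model = hierarchical_cluster(expr, expr.gene_ids, k=6)
        assert len(set(model.labels)) == 6

    def test_sample_permutation_invariance_up_to_relabeling(self, rng):
        expr, _, _, _ = simulate_cohort(small_config(seed=21, n_genes=200,
                                                     n_int_module=30,
                                                     n_cod_module=40))
        perm = rng.permutation(expr.n_samples)
        shuffled = ExpressionMatrix(
            expr.gene_ids, [expr.sample_ids[i] for i in perm],
            expr.values[:, perm])
        m1 = hierarchical_cluster(expr, expr.gene_ids, k=3)
        m2 = hierarchical_cluster(shuffled, shuffled.gene_ids, k=3)
        part1 = {frozenset(m1.members(c)) for c in (1, 2, 3)}
        part2 = {frozenset(m2.members(c)) for c in (1, 2, 3)}
        assert part1 == part2

    def test_zero_variance_sample_named(self):
        expr = matrix([[1.0, 2.0, 7.0], [2.0, 3.0, 7.0], [3.0, 1.0, 7.0]])
        with pytest.raises(ValidationError, match="s3"):
            hierarchical_cluster(expr, expr.gene_ids, k=2)

    def test_merge_tree_shape(self):
        expr = self._point_masses()
        model = hierarchical_cluster(expr, expr.gene_ids, k=3,
                                     distance="euclidean")
        assert model.merge_tree.shape == (expr.n_samples - 1, 4)
        heights = model.merge_tree[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)  # monotone for average linkage


def _annotations(histologies):
    return [CohortAnnotation(f"s{i + 1}", histology=h)
            for i, h in enumerate(histologies)]


class TestLabelClusters:
    def _model(self, labels):
        n = len(labels)
        tree = np.zeros((n - 1, 4))
        tree[:, 2] = np.arange(1, n)
        return hierarchical_cluster  # placeholder, unused

    def _make(self, labels):
        from codsig.signature import ClusterModel
        n = len(labels)
        tree = np.column_stack([np.arange(n - 1), np.arange(1, n),
                                np.arange(1, n, dtype=float), np.arange(2, n + 1)])
        return ClusterModel(distance="euclidean", linkage="average", k=3,
                            sample_ids=[f"s{i + 1}" for i in range(n)],
                            labels=np.array(labels), merge_tree=tree)

    def test_pure_clusters(self):
        model = self._make([1, 1, 2, 2, 3, 3])
        ann = _annotations(["normal", "normal", "intestinal", "intestinal",
                            "diffuse", "diffuse"])
        assert label_clusters(model, ann) == {1: "N", 2: "INT", 3: "COD"}

    def test_majority_normal_cluster_is_n(self):
        # 19-of-20 normal composition labels the cluster N
        labels = [1] * 20 + [2] * 10 + [3] * 10
        hist = ["normal"] * 19 + ["diffuse"] + ["intestinal"] * 8 + \
            ["diffuse"] * 2 + ["diffuse"] * 10
        assert label_clusters(self._make(labels), _annotations(hist))[1] == "N"

    def test_double_tie_refused(self):
        labels = [1, 1, 2, 2, 3, 3]
        hist = ["diffuse"] * 6  # all fractions identical
        with pytest.raises(ValidationError, match="manual"):
            label_clusters(self._make(labels), _annotations(hist))


class TestDifferentialGenes:
    def test_null_pass_rate_near_threshold(self, rng):
        expr = matrix(rng.normal(size=(4000, 40)))
        hits = differential_genes(expr, expr.sample_ids[:20],
                                  expr.sample_ids[20:], p_threshold=0.05)
        assert 0.02 <= len(hits) / 4000 <= 0.08

    def test_strongly_shifted_gene_found(self, rng):
        vals = rng.normal(size=(10, 40))
        vals[3, 20:] += 10.0
        expr = matrix(vals)
        hits = differential_genes(expr, expr.sample_ids[:20],
                                  expr.sample_ids[20:], p_threshold=0.001)
        assert "g4" in hits

    def test_zero_threshold_empty(self, rng):
        expr = matrix(rng.normal(size=(10, 8)))
        assert differential_genes(expr, expr.sample_ids[:4],
                                  expr.sample_ids[4:], 0.0) == []

    def test_overlapping_groups_rejected(self, rng):
        expr = matrix(rng.normal(size=(5, 6)))
        with pytest.raises(ValidationError, match="overlap"):
            differential_genes(expr, expr.sample_ids[:3],
                               expr.sample_ids[2:], 0.05)


class TestVennPartition:
    def test_published_worked_example(self):
        # |A| = 737, |B| = 2069, overlap 147 -> 590 / 147 / 1922
        a = {f"a{i}" for i in range(590)} | {f"c{i}" for i in range(147)}
        b = {f"b{i}" for i in range(1922)} | {f"c{i}" for i in range(147)}
        part = venn_partition(a, b)
        assert part.counts() == {"a": 737, "b": 2069, "only_a": 590,
                                 "a_and_b": 147, "only_b": 1922}

    def test_equal_sets(self):
        part = venn_partition({"x", "y"}, {"x", "y"})
        assert part.only_a == part.only_b == frozenset()
        assert part.a_and_b == {"x", "y"}

    def test_disjoint_sets(self):
        part = venn_partition({"x"}, {"y", "z"})
        assert part.a_and_b == frozenset()
        assert part.only_a == {"x"} and part.only_b == {"y", "z"}

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.sets(st.integers(0, 60)), st.sets(st.integers(0, 60)))
    def test_count_identities(self, a, b):
        a = {str(x) for x in a}
        b = {str(x) for x in b}
        part = venn_partition(a, b)
        c = part.counts()
        assert c["only_a"] + c["a_and_b"] == c["a"]
        assert c["only_b"] + c["a_and_b"] == c["b"]
        assert not (part.only_a & part.only_b)
        assert not (part.only_a & part.a_and_b)
        assert not (part.only_b & part.a_and_b)


class TestDeriveSignature:
    def test_recovers_planted_cod_module(self):
        expr, ann, _, truth = simulate_cohort(small_config(seed=31))
        res = derive_signature_detailed(expr, ann)
        cod = set(truth.cod_module_genes)
        nulls = (set(expr.gene_ids) - cod - set(truth.int_module_genes))
        tpr = len(cod & res.partition.only_b) / len(cod)
        fpr = len(nulls & res.partition.only_b) / len(nulls)
        assert tpr >= 0.9
        assert fpr <= 0.05
        # directions: planted genes go up in COD
        dm = res.signature.direction_map
        up = [dm[g] for g in cod & set(res.signature.gene_ids)]
        assert np.mean(np.array(up) == 1) > 0.95

    def test_rerun_is_identical(self):
        expr, ann, _, _ = simulate_cohort(small_config(seed=32))
        s1 = derive_signature(expr, ann)
        s2 = derive_signature(expr, ann)
        assert s1.gene_ids == s2.gene_ids
        assert s1.directions == s2.directions

    def test_no_diffuse_samples_fails_at_de_stage(self):
        cfg = small_config(seed=33, n_normal=30, n_intestinal=30, n_diffuse=1)
        expr, ann, _, _ = simulate_cohort(cfg)
        with pytest.raises(StageError, match="differential_expression"):
            derive_signature(expr, ann)

    def test_signature_round_trip(self, tmp_path):
        expr, ann, _, _ = simulate_cohort(small_config(seed=34))
        sig = derive_signature(expr, ann)
        path = tmp_path / "sig.json"
        sig.save(path)
        from codsig import Signature
        back = Signature.load(path)
        assert back.gene_ids == sig.gene_ids
        assert back.directions == sig.directions
        assert back.sd_threshold == sig.sd_threshold
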