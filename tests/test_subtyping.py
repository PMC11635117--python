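"""ssGSEA running-sum oracle, consensus clustering, subtype mapping."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from deeppath.subtyping import (
    SUBTYPE_MAP,
    SubtypeConfig,
    assign_subtype,
    consensus_cluster,
    read_gmt,
    ssgsea,
    subtype_cohort,
    write_gmt,
)


def _ssgsea_oracle(expr_col, gene_ids, gene_set, alpha):
    """Independent loop-based running-sum implementation."""
    order = sorted(range(len(expr_col)), key=lambda i: (-expr_col[i], i))
    N = len(order)
    in_set = [gene_ids[i] in gene_set for i in order]
    weights = [(N - pos) ** alpha for pos in range(N)]
    sum_w = sum(w for w, s in zip(weights, in_set) if s)
    n_out = N - sum(in_set)
    p_in = p_out = 0.0
    es = 0.0
    for pos in range(N):
        if in_set[pos]:
            p_in += weights[pos] / sum_w
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es


class TestSSGSEA:
    def test_top_genes_score_higher_than_bottom_genes(self):
        expr = pd.DataFrame({"s1": np.arange(10, 0, -1.0)},
                            index=[f"g{i}" for i in range(10)])
        sets = {"top": ["g0", "g1", "g2"], "bottom": ["g7", "g8", "g9"]}
        res = ssgsea(expr, sets, alpha=0.25, normalize=False)
        assert res.scores.loc["top", "s1"] > 0
        assert res.scores.loc["top", "s1"] > res.scores.loc["bottom", "s1"]

    def test_matches_loop_oracle_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_genes = int(rng.integers(5, 20))
            genes = [f"g{i}" for i in range(n_genes)]
            expr = pd.DataFrame(rng.standard_normal((n_genes, 2)),
                                index=genes, columns=["a", "b"])
            k = int(rng.integers(1, n_genes - 1))
            gene_set = set(rng.choice(genes, size=k, replace=False).tolist())
            alpha = float(rng.choice([0.0, 0.25, 1.0]))
            res = ssgsea(expr, {"s": sorted(gene_set)}, alpha=alpha,
                         normalize=False)
            for col in ("a", "b"):
                ref = _ssgsea_oracle(expr[col].to_list(), genes, gene_set, alpha)
                assert np.isclose(res.scores.loc["s", col], ref, atol=1e-9)

    def test_running_sum_returns_to_zero_for_proper_subsets(self):
        # final increments and decrements cancel: P_in(N) = P_out(N) = 1
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(12)]
        expr_col = rng.standard_normal(12).tolist()
        gene_set = {"g1", "g5", "g9"}
        order = sorted(range(12), key=lambda i: (-expr_col[i], i))
        in_set = [genes[i] in gene_set for i in order]
        weights = [(12 - p) ** 0.25 for p in range(12)]
        sw = sum(w for w, s in zip(weights, in_set) if s)
        p_in = sum(w / sw for w, s in zip(weights, in_set) if s)
        p_out = sum(1 / 9 for s in in_set if not s)
        assert np.isclose(p_in, 1.0) and np.isclose(p_out, 1.0)

    def test_invariant_under_monotone_transform_per_sample(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(15)]
        X = rng.standard_normal((15, 3))
        expr = pd.DataFrame(X, index=genes, columns=list("abc"))
        warped = pd.DataFrame(np.exp(2 * X) + 1, index=genes, columns=list("abc"))
        sets = {"s1": genes[:4], "s2": genes[8:]}
        r1 = ssgsea(expr, sets, normalize=False).scores
        r2 = ssgsea(warped, sets, normalize=False).scores
        assert np.allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-12)

    def test_zero_overlap_set_named_in_error(self):
        expr = pd.DataFrame(np.ones((3, 1)), index=list("abc"), columns=["s"])
        with pytest.raises(ValueError, match="phantom"):
            ssgsea(expr, {"phantom": ["zz"]})

    def test_duplicate_genes_rejected(self):
        expr = pd.DataFrame(np.ones((2, 1)), index=["a", "a"], columns=["s"])
        with pytest.raises(ValueError, match="duplicate"):
            ssgsea(expr, {"s": ["a"]})


class TestConsensusCluster:
    def _blobs(self, n_per=20, k=3, sep=6.0, seed=0):
        rng = np.random.default_rng(seed)
        X = np.concatenate([rng.standard_normal((n_per, 4)) + sep * i
                            for i in range(k)])
        labels = np.repeat(np.arange(k), n_per)
        return X, labels

    def test_recovers_well_separated_clusters_exactly(self):
        X, truth = self._blobs()
        res = consensus_cluster(X, k_range=[3], n_iter=50, seed=1)
        assert adjusted_rand_score(truth, res.assignments[3]) == 1.0

    def test_degenerate_single_full_resample_gives_binary_consensus(self):
        X, _ = self._blobs(n_per=8)
        res = consensus_cluster(X, k_range=[3], n_iter=1, resample_frac=1.0,
                                seed=2)
        M = res.consensus[3]
        assert set(np.unique(M)) <= {0.0, 1.0}
        from scipy.cluster.hierarchy import fcluster, linkage

        ref = fcluster(linkage(X, "average"), 3, "maxclust")
        assert np.array_equal(M, (ref[:, None] == ref[None, :]).astype(float))

    def test_consensus_symmetric_in_unit_interval(self):
        X, _ = self._blobs(n_per=10, sep=1.0)
        res = consensus_cluster(X, k_range=[2, 3], n_iter=30, seed=3)
        for k, M in res.consensus.items():
            assert np.allclose(M, M.T, equal_nan=True)
            finite = M[~np.isnan(M)]
            assert (finite >= 0).all() and (finite <= 1).all()

    def test_more_iterations_reduce_consensus_variance(self):
        X, _ = self._blobs(n_per=10, sep=1.5)
        def spread(n_iter):
            vals = []
            for seed in range(6):
                M = consensus_cluster(X, k_range=[2], n_iter=n_iter,
                                      seed=seed).consensus[2]
                vals.append(M[np.triu_indices(len(X), 1)])
            return np.nanvar(np.stack(vals), axis=0).mean()

        assert spread(100) < spread(10)

    def test_chosen_k_prefers_true_cluster_count(self):
        X, _ = self._blobs(n_per=15, k=3, sep=8.0)
        res = consensus_cluster(X, k_range=[2, 3, 4], n_iter=100, seed=4)
        assert res.chosen_k == 3

    def test_invalid_parameters_rejected(self):
        X, _ = self._blobs(n_per=5)
        with pytest.raises(ValueError):
            consensus_cluster(X, k_range=[2], n_iter=0)
        with pytest.raises(ValueError):
            consensus_cluster(X, k_range=[2], resample_frac=1.5)
        with pytest.raises(ValueError):
            consensus_cluster(X, k_range=[1])


class TestAssignSubtype:
    @pytest.mark.parametrize("pair,expected", sorted(SUBTYPE_MAP.items()))
    def test_golden_mapping_table(self, pair, expected):
        assert assign_subtype(*pair) == expected

    def test_mapping_is_total_over_six_pairs(self):
        labels = {assign_subtype(l, i) for l in (1, 2, 3) for i in (1, 2)}
        assert labels == {"iFA", "iAA", "iGlu", "iFolate"}

    @pytest.mark.parametrize("pair", [(0, 1), (4, 1), (1, 3), (1, 0)])
    def test_out_of_range_rejected(self, pair):
        with pytest.raises(ValueError):
            assign_subtype(*pair)


class TestSubtypeCohort:
    def test_recovers_planted_subtypes(self, expression_cohort):
        c = expression_cohort
        out = subtype_cohort(c.expr, c.panel, c.immune_sets,
                             SubtypeConfig(n_iter=60, seed=0))
        acc = (out["subtype"].to_numpy() == c.truth["subtype"].to_numpy()).mean()
        assert acc >= 0.95

    def test_deterministic_under_fixed_seed(self, expression_cohort):
        c = expression_cohort
        cfg = SubtypeConfig(n_iter=25, seed=3)
        o1 = subtype_cohort(c.expr, c.panel, c.immune_sets, cfg)
        o2 = subtype_cohort(c.expr, c.panel, c.immune_sets, cfg)
        pd.testing.assert_frame_equal(o1, o2)

    def test_low_panel_coverage_reports_missing_genes(self, expression_cohort):
        c = expression_cohort
        panel = c.panel + [f"MISSING{i}" for i in range(len(c.panel))]
        with pytest.raises(ValueError, match="MISSING"):
            subtype_cohort(c.expr, panel, c.immune_sets,
                           SubtypeConfig(n_iter=5, seed=0))


def test_gmt_round_trip(tmp_path):
    sets = {"setA": ["g1", "g2"], "setB": ["g3"]}
    path = tmp_path / "sets.gmt"
    write_gmt(sets, path)
    assert read_gmt(path) == sets
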