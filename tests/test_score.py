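import numpy as np
import pandas as pd
import pytest

from iciscope.io import ExpressionMatrix
from iciscope.score import (
    SignaturePartition,
    assign_signatures,
    boruta_select,
    compute_ici_score,
    pc1_score,
)

from conftest import expr_matrix


def _labeled_expr(x, labels):
    m = expr_matrix(x, scale="log2")
    return m, pd.Series(labels, index=m.sample_ids)


class TestAssignSignatures:
    def test_monotone_gene_lands_in_signature_a(self):
        # clusters ordered worst->best by immune score; gene rises with it
        x = np.array([[1.0, 1.1, 2.0, 2.1, 3.0, 3.1],
                      [3.0, 3.1, 2.0, 2.1, 1.0, 1.1],
                      [1.0, 1.0, 1.0, 1.0, 1.0, 1.0]])
        m, labels = _labeled_expr(x, ["c1", "c1", "c2", "c2", "c3", "c3"])
        immune = pd.Series([0, 0, 5, 5, 10, 10], index=m.sample_ids)
        part = assign_signatures(m, labels, immune)
        assert "g0" in part.genes_A
        assert "g1" in part.genes_B
        assert "g2" not in part.genes_A + part.genes_B  # constant: excluded

    def test_missing_labels_rejected(self):
        x = np.ones((2, 4))
        m, labels = _labeled_expr(x, ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="missing"):
            assign_signatures(m, labels.iloc[:2], pd.Series(0.0, index=m.sample_ids))

    def test_planted_activation_genes_recovered(self, rng):
        # genes 0..19 increase along the cluster axis, 20..39 decrease
        n_per = 30
        axis = np.repeat([0.0, 1.0, 2.0], n_per)
        x = rng.normal(scale=0.5, size=(40, 3 * n_per))
        x[:20] += axis
        x[20:] -= axis
        m, labels = _labeled_expr(x, np.repeat(["lo", "mid", "hi"], n_per))
        immune = pd.Series(axis, index=m.sample_ids)
        part = assign_signatures(m, labels, immune)
        up = {f"g{i}" for i in range(20)}
        down = {f"g{i}" for i in range(20, 40)}
        acc_a = len(up & set(part.genes_A)) / 20
        acc_b = len(down & set(part.genes_B)) / 20
        assert acc_a >= 0.9 and acc_b >= 0.9

    def test_partition_disjointness_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            SignaturePartition(["g1"], ["g1"])


class TestBorutaSelect:
    def test_planted_informative_features_confirmed(self):
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            n = 200
            y = rng.choice(["A", "B"], size=n)
            informative = np.where(y == "A", 1.0, -1.0)[None, :] + rng.normal(
                scale=0.5, size=(5, n)
            )
            noise = rng.normal(size=(50, n))
            m = expr_matrix(np.vstack([informative, noise]), scale="log2")
            labels = pd.Series(y, index=m.sample_ids)
            out = boruta_select(m, labels, n_iter=40, seed=seed)
            assert set(f"g{i}" for i in range(5)) <= set(out["confirmed"])
            noise_confirmed = set(out["confirmed"]) - {f"g{i}" for i in range(5)}
            assert len(noise_confirmed) <= 2

    def test_label_copy_feature_confirmed(self, rng):
        n = 100
        y = rng.choice(["A", "B"], size=n)
        x = np.vstack([(y == "A").astype(float), rng.normal(size=(10, n))])
        m = expr_matrix(x, scale="log2")
        out = boruta_select(m, pd.Series(y, index=m.sample_ids), n_iter=30, seed=1)
        assert "g0" in out["confirmed"]

    def test_single_iteration_everything_tentative(self, rng):
        x = rng.normal(size=(8, 40))
        y = pd.Series(rng.choice(["A", "B"], size=40), index=[f"s{j}" for j in range(40)])
        out = boruta_select(expr_matrix(x, scale="log2"), y, n_iter=1, seed=0)
        assert out["confirmed"] == [] and out["rejected"] == []
        assert len(out["tentative"]) == 8

    def test_single_class_target_rejected(self, rng):
        x = rng.normal(size=(5, 30))
        y = pd.Series(["A"] * 30, index=[f"s{j}" for j in range(30)])
        with pytest.raises(ValueError, match="two classes"):
            boruta_select(expr_matrix(x, scale="log2"), y)


class TestPc1Score:
    def test_two_correlated_genes_recover_common_profile(self, rng):
        profile = rng.normal(size=20)
        x = np.vstack([2.0 * profile + 5.0, -3.0 * profile + 1.0])
        m = expr_matrix(x, scale="log2")
        s = pc1_score(m)
        # score must align with the common z-profile up to sign anchoring
        assert abs(np.corrcoef(s, profile)[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_sign_anchored_to_mean_expression(self, rng):
        x = rng.normal(size=(10, 15))
        x[0] += np.linspace(0, 3, 15)
        m = expr_matrix(x, scale="log2")
        s = pc1_score(m)
        z = (m.data.sub(m.data.mean(axis=1), axis=0)
             .div(m.data.std(axis=1, ddof=1), axis=0))
        assert np.corrcoef(s, z.mean(axis=0))[0, 1] > 0

    def test_rank_one_plus_noise_dominant_component(self, rng):
        profile = rng.normal(size=30)
        loadings = rng.uniform(0.5, 2.0, size=25)
        x = np.outer(loadings, profile) + rng.normal(scale=0.05, size=(25, 30))
        m = expr_matrix(x, scale="log2")
        z = (m.data.sub(m.data.mean(axis=1), axis=0)
             .div(m.data.std(axis=1, ddof=1), axis=0))
        svals = np.linalg.svd(z.to_numpy(), compute_uv=False)
        assert svals[0] ** 2 / (svals**2).sum() >= 0.9
        s = pc1_score(m)
        assert abs(np.corrcoef(s, profile)[0, 1]) > 0.99

    def test_zero_variance_genes_dropped(self, rng):
        x = np.vstack([np.ones(8), rng.normal(size=(3, 8))])
        s = pc1_score(expr_matrix(x, scale="log2"))
        assert len(s) == 8
        with pytest.raises(ValueError, match="non-constant"):
            pc1_score(expr_matrix(np.ones((3, 8)), scale="log2"))


class TestComputeIciScore:
    def test_missing_signature_b_reduces_to_pc1a(self, rng):
        x = rng.normal(size=(6, 12))
        m = expr_matrix(x, scale="log2")
        part = SignaturePartition([f"g{i}" for i in range(3)], ["absent1", "absent2"])
        table = compute_ici_score(m, part)
        np.testing.assert_allclose(table.data["ici_score"], table.data["pc1a"])
        np.testing.assert_allclose(table.data["pc1b"], 0.0)

    def test_swapping_signatures_negates_score(self, rng):
        x = rng.normal(size=(10, 15))
        m = expr_matrix(x, scale="log2")
        a = [f"g{i}" for i in range(4)]
        b = [f"g{i}" for i in range(5, 9)]
        s_ab = compute_ici_score(m, SignaturePartition(a, b))
        s_ba = compute_ici_score(m, SignaturePartition(b, a))
        np.testing.assert_allclose(
            s_ab.data["ici_score"], -s_ba.data["ici_score"], atol=1e-9
        )

    def test_per_gene_affine_invariance(self, rng):
        x = rng.normal(size=(8, 12))
        m1 = expr_matrix(x, scale="log2")
        scales = rng.uniform(0.5, 3.0, size=(8, 1))
        offsets = rng.normal(size=(8, 1))
        m2 = expr_matrix(x * scales + offsets, scale="log2")
        part = SignaturePartition([f"g{i}" for i in range(4)],
                                  [f"g{i}" for i in range(4, 8)])
        np.testing.assert_allclose(
            compute_ici_score(m1, part).data["ici_score"],
            compute_ici_score(m2, part).data["ici_score"],
            atol=1e-9,
        )

    def test_noise_gene_barely_perturbs_ranking(self, rng):
        profile = np.linspace(-1, 1, 40)
        x = np.outer(rng.uniform(0.8, 1.2, size=12), profile)
        x += rng.normal(scale=0.05, size=x.shape)
        m1 = expr_matrix(x, scale="log2")
        part1 = SignaturePartition([f"g{i}" for i in range(12)], [])
        x2 = np.vstack([x, rng.normal(size=(1, 40))])
        m2 = expr_matrix(x2, scale="log2")
        part2 = SignaturePartition([f"g{i}" for i in range(13)], [])
        s1 = compute_ici_score(m1, part1).data["ici_score"]
        s2 = compute_ici_score(m2, part2).data["ici_score"]
        assert s1.corr(s2, method="spearman") >= 0.99

    def test_group_assignment_consistent_with_cutoff(self, rng):
        x = rng.normal(size=(6, 20))
        m = expr_matrix(x, scale="log2")
        part = SignaturePartition([f"g{i}" for i in range(3)],
                                  [f"g{i}" for i in range(3, 6)])
        table = compute_ici_score(m, part).with_cutoff(0.0)
        high = table.data.loc[table.data["group"] == "high", "ici_score"]
        assert (high > 0).all()

    def test_no_genes_present_rejected(self, rng):
        m = expr_matrix(rng.normal(size=(3, 5)), scale="log2")
        with pytest.raises(ValueError, match="no signature genes"):
            compute_ici_score(m, SignaturePartition(["x1"], ["x2"]))
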