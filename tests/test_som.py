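"""Batch SOM training, classification, similarity and contingency tests."""

import numpy as np
import pandas as pd
import pytest

from zfseizure import som, synth
from zfseizure.profiles import get_profile
from zfseizure.som import FeatureSet, SOMParams


def _features(X, larvae, groups, bins):
    meta = pd.DataFrame({"larva": larvae, "group": groups, "bin": bins})
    return FeatureSet(X=np.asarray(X, float), meta=meta,
                      outputs=[f"f{i}" for i in range(X.shape[1])],
                      means=np.zeros(X.shape[1]), sds=np.ones(X.shape[1]))


class TestBuildFeatures:
    def test_standardization_and_shape(self):
        mat = synth.generate_behavior([get_profile("TL")], 4, seed=0)
        fs = som.build_features(mat)
        assert fs.X.shape == (4 * 60, 8)
        assert np.allclose(fs.X.mean(axis=0), 0.0, atol=1e-9)
        nontrivial = fs.X.std(axis=0) > 0
        assert np.allclose(fs.X.std(axis=0)[nontrivial], 1.0, atol=1e-9)

    def test_constant_output_guarded_to_zeros(self):
        mat = synth.generate_behavior([get_profile("TL")], 3, seed=1)
        mat.loc[mat["output"] == "activity", "value"] = 4.2
        fs = som.build_features(mat)
        col = fs.outputs.index("activity")
        assert np.allclose(fs.X[:, col], 0.0)

    def test_standardization_invertible(self):
        mat = synth.generate_behavior([get_profile("TL")], 3, seed=2)
        fs = som.build_features(mat)
        orig = fs.destandardize()
        assert np.all(orig[:, fs.outputs.index("activity")] >= 0.0)


class TestTraining:
    def test_identical_samples_collapse_all_weights(self):
        X = np.tile([1.0, -2.0, 0.5], (50, 1))
        model = som.train_som(X, SOMParams(n_iterations=50))
        assert np.allclose(model.weights, [1.0, -2.0, 0.5], atol=1e-9)

    def test_separated_blobs_occupy_disjoint_nodes(self):
        rng = np.random.default_rng(0)
        a = rng.normal(-5.0, 0.3, size=(200, 4))
        b = rng.normal(+5.0, 0.3, size=(200, 4))
        model = som.train_som(np.vstack([a, b]))
        nodes_a = set(som.bmu(model.weights, a))
        nodes_b = set(som.bmu(model.weights, b))
        assert nodes_a.isdisjoint(nodes_b)

    def test_quantization_error_non_increasing(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            X = rng.standard_normal((rng.integers(100, 800), rng.integers(2, 9)))
            model = som.train_som(X)
            qe = np.asarray(model.quantization_errors)
            assert np.all(np.diff(qe) <= 1e-9)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            som.train_som(np.empty((0, 8)))

    def test_training_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((300, 5))
        m1 = som.train_som(X)
        m2 = som.train_som(X)
        assert np.array_equal(m1.weights, m2.weights)


class TestClassification:
    def _model(self):
        rng = np.random.default_rng(1)
        return som.train_som(rng.standard_normal((200, 2)))

    def test_modal_assignment_and_tie_break(self):
        model = self._model()
        # larva A: all bins at the node of weights[7]; larva B: 30/30 split
        w = model.weights
        X = np.vstack([np.tile(w[7], (60, 1)),
                       np.tile(w[2], (30, 1)), np.tile(w[5], (30, 1))])
        fs = _features(X, ["A"] * 60 + ["B"] * 60, ["g"] * 120,
                       list(range(60)) * 2)
        asg = som.classify_larvae(model, fs).set_index("larva")["node"]
        assert asg["A"] == 7
        assert asg["B"] == 2  # tie between 2 and 5 -> lowest index

    def test_majority_wins(self):
        model = self._model()
        w = model.weights
        X = np.vstack([np.tile(w[2], (31, 1)), np.tile(w[9], (29, 1))])
        fs = _features(X, ["A"] * 60, ["g"] * 60, range(60))
        assert som.classify_larvae(model, fs)["node"].iloc[0] == 2

    def test_project_reproduces_training_assignments(self):
        mat = synth.generate_behavior([get_profile("TL")], 8, seed=4)
        fs = som.build_features(mat)
        model = som.train_som(fs.X)
        a1 = som.classify_larvae(model, fs)
        a2 = som.project(model, fs)
        pd.testing.assert_frame_equal(a1, a2)

    def test_project_empty_group(self):
        model = self._model()
        fs = _features(np.empty((0, 2)), [], [], [])
        assert som.project(model, fs).empty


class TestSimilarity:
    def _assignments(self, nodes1, nodes2, g1="A", g2="B"):
        rows = [{"larva": f"{g1}{i}", "group": g1, "node": n}
                for i, n in enumerate(nodes1)]
        rows += [{"larva": f"{g2}{i}", "group": g2, "node": n}
                 for i, n in enumerate(nodes2)]
        return pd.DataFrame(rows)

    def test_identical_assignments_score_zero(self):
        asg = self._assignments([3] * 10 + [7] * 26, [3] * 10 + [7] * 26)
        assert som.similarity(asg, "A", "B") == 0.0

    def test_disjoint_single_nodes_score_4_5(self):
        asg = self._assignments([1] * 36, [2] * 36)
        assert som.similarity(asg, "A", "B") == pytest.approx(4.5)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(5)
        asg = self._assignments(rng.integers(0, 16, 36), rng.integers(0, 16, 36))
        assert som.similarity(asg, "A", "B") == som.similarity(asg, "B", "A")
        assert som.similarity(asg, "A", "A") == 0.0

    def test_invariant_under_consistent_node_relabeling(self):
        rng = np.random.default_rng(6)
        n1 = rng.integers(0, 16, 36)
        n2 = rng.integers(0, 16, 36)
        perm = rng.permutation(16)
        s1 = som.similarity(self._assignments(n1, n2), "A", "B")
        s2 = som.similarity(self._assignments(perm[n1], perm[n2]), "A", "B")
        assert s1 == s2


class TestContingency:
    def _assignments(self, nodes1, nodes2):
        rows = [{"larva": f"A{i}", "group": "A", "node": int(n)}
                for i, n in enumerate(nodes1)]
        rows += [{"larva": f"B{i}", "group": "B", "node": int(n)}
                 for i, n in enumerate(nodes2)]
        return pd.DataFrame(rows)

    def test_identical_distributions_p_near_one(self):
        asg = self._assignments([0] * 18 + [5] * 18, [0] * 18 + [5] * 18)
        p = som.cluster_contingency_test(asg, "A", "B", n_permutations=2000, seed=0)
        assert p > 0.99

    def test_disjoint_occupancy_tiny_p(self):
        asg = self._assignments([1] * 36, [9] * 36)
        p = som.cluster_contingency_test(asg, "A", "B",
                                         n_permutations=20_000, seed=0)
        assert p < 1e-4

    def test_monte_carlo_matches_exhaustive_enumeration_toy(self):
        asg = self._assignments([0, 0, 1, 2], [1, 2, 3, 3])
        p_exact = som.cluster_contingency_test(asg, "A", "B", exact=True)
        p_mc = som.cluster_contingency_test(asg, "A", "B", exact=False,
                                            n_permutations=40_000, seed=1)
        se = np.sqrt(p_exact * (1 - p_exact) / 40_000)
        assert p_mc == pytest.approx(p_exact, abs=4 * se + 1e-4)


def test_same_template_groups_rank_more_similar():
    """End-to-end ordering on a small seed sweep (full sweep in acceptance)."""
    tl = get_profile("TL")
    tl2 = tl.with_(name="TL-rep")
    other = get_profile("panx1b")
    wins = 0
    for seed in range(10):
        mat = synth.generate_behavior([tl, tl2, other], 36, seed=500 + seed)
        fs = som.build_features(mat)
        model = som.train_som(fs.X)
        asg = som.classify_larvae(model, fs)
        same = som.similarity(asg, "TL", "TL-rep")
        diff = min(som.similarity(asg, "TL", "panx1b-/-"),
                   som.similarity(asg, "TL-rep", "panx1b-/-"))
        wins += same < diff
    assert wins >= 9
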