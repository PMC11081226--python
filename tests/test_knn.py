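"""Distances, neighbourhoods, KNN prediction and the k-scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gafs.data import LabeledDataset
from gafs.knn import (
    DistanceSpec,
    distance,
    evaluate_knn,
    knn_predict,
    misclassification_rate,
    neighborhood,
    scan_k,
)

finite_vec = st.lists(
    st.floats(-10, 10, allow_nan=False, allow_infinity=False),
    min_size=1, max_size=6)


def _reference_knn(train: LabeledDataset, query, k: int, spec: DistanceSpec):
    """Independent oracle: exhaustive sort + explicit vote with the documented
    tie rules (lower index on distance ties; closest member then smallest
    label on vote ties)."""
    pairs = sorted(
        (distance(query, train.matrix[i], spec), i) for i in range(train.n_samples))
    top = pairs[:k]
    votes: dict[str, list] = {}
    for d, i in top:
        votes.setdefault(train.labels[i], []).append(d)
    most = max(len(v) for v in votes.values())
    tied = {lab: min(v) for lab, v in votes.items() if len(v) == most}
    return min(tied, key=lambda lab: (tied[lab], lab))


class TestDistance:
    def test_identity_of_indiscernibles(self):
        x = np.array([1.0, -2.0, 3.0])
        for spec in (DistanceSpec("chebyshev"), DistanceSpec("minkowski", 1),
                     DistanceSpec("minkowski", 3.5)):
            assert distance(x, x, spec) == 0.0

    def test_hand_values(self):
        assert distance([0, 0], [1, 1], DistanceSpec("minkowski", 1)) == 2.0
        assert distance([0, 0], [3, 4], DistanceSpec("minkowski", 2)) == pytest.approx(5.0)
        assert distance([0, 0], [3, 4], DistanceSpec("chebyshev")) == 4.0

    def test_weights_scale_coordinates(self):
        spec = DistanceSpec("minkowski", 1, weights=np.array([2.0, 0.0]))
        assert distance([0, 0], [1, 5], spec) == 2.0

    def test_length_mismatch_and_nonfinite_error(self):
        with pytest.raises(ValueError):
            distance([0, 0], [1], DistanceSpec())
        with pytest.raises(ValueError):
            distance([0, np.nan], [1, 1], DistanceSpec())

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DistanceSpec("minkowski", 0.5)
        with pytest.raises(ValueError):
            DistanceSpec(weights=np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            DistanceSpec("euclideanish")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(finite_vec, finite_vec, finite_vec,
           st.floats(1, 8, allow_nan=False))
    def test_metric_axioms(self, x, y, z, p):
        n = min(len(x), len(y), len(z))
        x, y, z = np.array(x[:n]), np.array(y[:n]), np.array(z[:n])
        spec = DistanceSpec("minkowski", p)
        dxy, dyx = distance(x, y, spec), distance(y, x, spec)
        assert dxy == dyx  # symmetry, exact
        assert distance(x, z, spec) <= dxy + distance(y, z, spec) + 1e-9

    def test_chebyshev_is_large_p_limit(self):
        rng = np.random.default_rng(0)
        d = 5
        bound = d ** (1 / 64) - 1  # exact: L_inf <= L_64 <= d^(1/64) L_inf
        for _ in range(20):
            x, y = rng.random(d), rng.random(d)
            cheb = distance(x, y, DistanceSpec("chebyshev"))
            p8 = distance(x, y, DistanceSpec("minkowski", 8))
            p64 = distance(x, y, DistanceSpec("minkowski", 64))
            assert cheb - 1e-12 <= p64 <= cheb * (1 + bound) + 1e-12
            assert p64 - cheb <= p8 - cheb + 1e-12  # convergence from above
        # with a dominant coordinate the limit is reached to 1e-6
        x = np.array([0.0, 0.1, 0.2, 0.1, 0.0])
        y = np.array([0.9, 0.2, 0.1, 0.0, 0.1])
        cheb = distance(x, y, DistanceSpec("chebyshev"))
        assert abs(distance(x, y, DistanceSpec("minkowski", 64)) - cheb) < 1e-6


class TestNeighborhood:
    def test_k_equals_n_returns_all(self, tiny_dataset):
        nb = neighborhood(tiny_dataset, [0.0, 0.0], 3, DistanceSpec())
        assert sorted(nb.indices.tolist()) == [0, 1, 2]
        assert np.all(np.diff(nb.distances) >= 0)

    def test_single_point(self):
        ds = LabeledDataset(np.array([[1.0]]), np.array(["A", "A"], dtype=object)[:1])
        nb = neighborhood(ds, [0.0], 1, DistanceSpec())
        assert nb.indices.tolist() == [0]

    def test_line_tie_break_keeps_lower_index(self):
        # points at |x| = 1,1,2,2,3 from the origin: ties at 1 and at 2
        X = np.array([[1.0], [-1.0], [2.0], [-2.0], [3.0]])
        ds = LabeledDataset(X, np.array(list("ABABA"), dtype=object))
        nb = neighborhood(ds, [0.0], 3, DistanceSpec())
        assert nb.indices.tolist() == [0, 1, 2]

    def test_k_out_of_range(self, tiny_dataset):
        for k in (0, 4):
            with pytest.raises(ValueError):
                neighborhood(tiny_dataset, [0.0, 0.0], k, DistanceSpec())


class TestPredict:
    def test_k1_nearest_label(self, tiny_dataset):
        assert knn_predict(tiny_dataset, [1.0, 2.0], 1, DistanceSpec()) == "A"
        assert knn_predict(tiny_dataset, [3.0, 4.0], 1, DistanceSpec()) == "B"

    def test_strict_majority(self):
        X = np.array([[0.0], [1.0], [2.0]])
        ds = LabeledDataset(X, np.array(["A", "A", "B"], dtype=object))
        assert knn_predict(ds, [0.0], 3, DistanceSpec()) == "A"

    def test_vote_tie_goes_to_closer_class(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        ds = LabeledDataset(X, np.array(["B", "A", "B", "A"], dtype=object))
        # k=4: 2 votes each; B's nearest member (d=1) beats A's (d=2)
        assert knn_predict(ds, [0.0], 4, DistanceSpec()) == "B"

    def test_oracle_equivalence_random_points(self):
        rng = np.random.default_rng(7)
        ds = LabeledDataset(rng.normal(size=(20, 2)),
                            rng.choice(np.array(["a", "b", "c"], dtype=object), 20))
        for q in rng.normal(size=(10, 2)):
            for k in (1, 3, 5, 20):
                assert knn_predict(ds, q, k, DistanceSpec()) == \
                    _reference_knn(ds, q, k, DistanceSpec())

    def test_k_equals_n_predicts_global_majority(self):
        rng = np.random.default_rng(1)
        ds = LabeledDataset(rng.normal(size=(15, 3)),
                            np.array(["A"] * 9 + ["B"] * 6, dtype=object))
        for q in rng.normal(size=(5, 3)):
            assert knn_predict(ds, q, 15, DistanceSpec()) == "A"

    def test_agrees_with_sklearn_on_unambiguous_data(self):
        # independent library oracle, restricted to queries without vote ties
        from sklearn.neighbors import KNeighborsClassifier
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 3))
        y = rng.choice(np.array(["a", "b"], dtype=object), 40)
        ds = LabeledDataset(X, y)
        clf = KNeighborsClassifier(n_neighbors=3).fit(X, y.astype(str))
        Q = rng.normal(size=(25, 3))
        proba = clf.predict_proba(Q)
        sk = clf.predict(Q)
        for i, q in enumerate(Q):
            if np.isclose(proba[i].max(), 2 / 3):  # unambiguous 2-1 vote
                assert knn_predict(ds, q, 3, DistanceSpec()) == sk[i]


class TestMisclassification:
    def test_complement_identity(self, tiny_dataset):
        nb = neighborhood(tiny_dataset, [0.0, 0.0], 3, DistanceSpec())
        pred = knn_predict(tiny_dataset, [0.0, 0.0], 3, DistanceSpec())
        rate = misclassification_rate(nb, pred)
        agree = float(np.mean(nb.labels == pred))
        assert rate + agree == 1.0

    def test_counts(self):
        X = np.array([[0.0], [1.0], [2.0]])
        ds = LabeledDataset(X, np.array(["A", "A", "B"], dtype=object))
        nb = neighborhood(ds, [0.0], 3, DistanceSpec())
        assert misclassification_rate(nb, "A") == pytest.approx(1 / 3)
        assert misclassification_rate(nb, "B") == pytest.approx(2 / 3)


class TestScanK:
    def test_separable_gaussians_high_rate(self, separable_gaussians):
        from gafs.data import stratified_split
        tr, va = stratified_split(separable_gaussians, 0.7, seed=0)
        rates = dict(scan_k(tr, va, spec=DistanceSpec()))
        assert set(rates) == {1, 3, 5, 7, 9, 11, 13, 15}
        assert rates[1] >= 0.95

    def test_memorization_at_k1(self, tiny_dataset):
        rates = scan_k(tiny_dataset, tiny_dataset, k_values=[1],
                       spec=DistanceSpec())
        assert rates == [(1, 1.0)]

    def test_single_k(self, separable_gaussians):
        out = scan_k(separable_gaussians, separable_gaussians, k_values=[3])
        assert len(out) == 1 and out[0][0] == 3

    def test_matches_evaluate_knn(self, separable_gaussians):
        from gafs.data import stratified_split
        tr, va = stratified_split(separable_gaussians, 0.7, seed=1)
        spec = DistanceSpec("chebyshev")
        (k, rate), = scan_k(tr, va, k_values=[5], spec=spec)
        assert rate == evaluate_knn(tr, va, 5, spec)
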