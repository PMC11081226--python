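"""GA-KNN wrapper: encodings, decode, fitness, evolution."""

import numpy as np
import pytest

from gafs.data import stratified_split
from gafs.ga_knn import (
    SCHEMES,
    WeightChromosome,
    decode,
    fitness,
    report,
    select_features,
)
from gafs.knn import DistanceSpec, evaluate_knn
from gafs.mga import GAConfig
from gafs.synthetic import GeneratorSpec, make_dataset


def _split(ds, seed=0):
    return stratified_split(ds, 0.7, seed=seed)


class TestDecode:
    def test_binary_bits(self):
        chrom = WeightChromosome("binary", np.array([1.0, 0.0, 1.0]))
        assert decode(chrom) == {0, 2}

    def test_all_zero_empty(self):
        chrom = WeightChromosome("real", np.zeros(4))
        assert decode(chrom) == set()

    def test_strict_inequality(self):
        chrom = WeightChromosome("real", np.array([0.2, 0.6, 0.61]), threshold=0.6)
        assert decode(chrom) == {2}

    def test_decode_encode_identity_binary(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            bits = rng.integers(0, 2, 8).astype(float)
            chrom = WeightChromosome("binary", bits)
            sel = decode(chrom)
            rebuilt = np.zeros(8)
            rebuilt[sorted(sel)] = 1.0
            np.testing.assert_array_equal(rebuilt, bits)

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            WeightChromosome("binary", np.array([0.5]))
        with pytest.raises(ValueError):
            WeightChromosome("decimal", np.array([0.55]))
        with pytest.raises(ValueError):
            WeightChromosome("nope", np.array([1.0]))


class TestFitness:
    def test_all_ones_on_separable_data(self, separable_gaussians):
        tr, va = _split(separable_gaussians)
        chrom = WeightChromosome("binary", np.ones(2))
        assert fitness(chrom, tr, va, k=7) >= 0.95

    def test_empty_decode_zero(self, separable_gaussians):
        tr, va = _split(separable_gaussians)
        chrom = WeightChromosome("binary", np.zeros(2))
        assert fitness(chrom, tr, va, k=7) == 0.0

    def test_masking_informative_feature_lowers_fitness(self):
        # one informative feature among noise: dropping it must hurt on average
        keep_acc, drop_acc = [], []
        for seed in range(20):
            spec = GeneratorSpec(n_samples=80, n_features=10, n_informative=1,
                                 n_redundant=0, n_classes=2, effect_size=1.5,
                                 seed=seed)
            ds, truth = make_dataset(spec)
            tr, va = _split(ds, seed=seed)
            w = np.ones(10)
            keep_acc.append(fitness(WeightChromosome("binary", w), tr, va, k=7))
            w2 = w.copy()
            w2[truth.informative[0]] = 0.0
            drop_acc.append(fitness(WeightChromosome("binary", w2), tr, va, k=7))
        assert np.mean(keep_acc) > np.mean(drop_acc)

    def test_weights_shape_the_geometry(self, separable_gaussians):
        # up-weighting the separating coordinates cannot be mimicked by the
        # unweighted metric when a junk column is appended
        rng = np.random.default_rng(0)
        ds = separable_gaussians.copy()
        junk = rng.normal(scale=20.0, size=(ds.n_samples, 1))
        ds.matrix = np.hstack([ds.matrix, junk])
        ds.feature_names = ["f0", "f1", "junk"]
        tr, va = _split(ds)
        flat = WeightChromosome("real", np.array([1.0, 1.0, 1.0]), threshold=0.0)
        tuned = WeightChromosome("real", np.array([1.0, 1.0, 0.01]), threshold=0.0)
        assert fitness(tuned, tr, va, k=7) >= fitness(flat, tr, va, k=7)


class TestSelectFeatures:
    def test_zero_generations_returns_initial_best(self, separable_gaussians):
        cfg = GAConfig(generations=0, seed=0)
        res = select_features(separable_gaussians, "binary", cfg, k=3)
        assert len(res.history) == 1
        assert res.n_after <= res.n_before == 2

    def test_history_accuracy_non_decreasing(self):
        spec = GeneratorSpec(n_samples=60, n_features=30, n_informative=3,
                             n_redundant=0, n_classes=2, effect_size=1.0, seed=0)
        ds, _ = make_dataset(spec)
        res = select_features(ds, "binary", GAConfig(generations=15, seed=0), k=5)
        assert np.all(np.diff(res.history) >= -1e-15)

    def test_determinism(self):
        spec = GeneratorSpec(n_samples=40, n_features=20, n_informative=2,
                             n_redundant=0, n_classes=2, seed=1)
        ds, _ = make_dataset(spec)
        cfg = GAConfig(generations=10, seed=4)
        r1 = select_features(ds, "real", cfg, k=3)
        r2 = select_features(ds, "real", cfg, k=3)
        assert r1.selected == r2.selected and r1.history == r2.history

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_every_scheme_runs_and_decodes(self, scheme):
        spec = GeneratorSpec(n_samples=40, n_features=15, n_informative=2,
                             n_redundant=0, n_classes=2, seed=2)
        ds, _ = make_dataset(spec)
        res = select_features(ds, scheme, GAConfig(generations=5, seed=2), k=3)
        assert res.selected == decode(res.best_chromosome)
        assert res.n_after == len(res.selected) <= res.n_before
        if scheme == "binary":
            assert set(np.unique(res.best_chromosome.weights)) <= {0.0, 1.0}
        if scheme == "decimal":
            w = res.best_chromosome.weights
            np.testing.assert_allclose(w * 10, np.round(w * 10), atol=1e-12)

    def test_noise_only_no_hallucinated_signal_held_out(self):
        # labels independent of features: held-out accuracy after selection
        # must track the majority rate (internal-validation accuracy is
        # selection-biased upward and is not the quantity checked here)
        diffs = []
        for seed in range(10):
            spec = GeneratorSpec(n_samples=80, n_features=60, n_informative=0,
                                 n_redundant=0, n_classes=2, seed=seed)
            ds, _ = make_dataset(spec)
            tr, te = _split(ds, seed=seed)
            res = select_features(tr, "binary", GAConfig(generations=10, seed=seed), k=7)
            sel = sorted(res.selected)
            acc = (evaluate_knn(tr.take_features(sel), te.take_features(sel),
                                7, DistanceSpec()) if sel else 0.0)
            majority = max(np.mean(te.labels == c) for c in te.classes)
            diffs.append(acc - majority)
        assert abs(np.mean(diffs)) <= 0.15

    def test_missing_matrix_rejected(self):
        ds, _ = make_dataset(GeneratorSpec(n_samples=20, n_features=10,
                                           n_informative=1, n_redundant=0,
                                           missing_rate=0.1, seed=0))
        with pytest.raises(ValueError, match="impute"):
            select_features(ds, "binary", GAConfig(generations=1, seed=0), k=3)


class TestReport:
    def _result(self, scheme="binary"):
        spec = GeneratorSpec(n_samples=40, n_features=10, n_informative=2,
                             n_redundant=0, n_classes=2, seed=0)
        ds, _ = make_dataset(spec)
        return select_features(ds, scheme, GAConfig(generations=3, seed=0), k=3)

    def test_single_row_shape(self):
        df = report(self._result())
        assert df.shape == (1, 5)
        assert list(df.columns) == ["scheme", "n_before", "acc_before",
                                    "n_after", "acc_after"]

    def test_batch_of_schemes(self):
        results = [self._result(s) for s in SCHEMES]
        df = report(results)
        assert df.shape == (5, 5)
        assert df["scheme"].tolist() == list(SCHEMES)

    def test_four_decimal_precision(self):
        df = report(self._result())
        for col in ("acc_before", "acc_after"):
            v = float(df[col].iloc[0])
            assert round(v, 4) == v
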