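"""Seeded generators for microarray-like labelled matrices with planted structure.

High-dimensional expression classification data is characterized by many
features, high redundancy among them, few samples, and class imbalance.  The
generator emulates exactly that statistical shape: a handful of informative
features whose class-conditional means are separated by a stated number of
standard deviations, noisy affine copies of them (redundancy), and a bulk of
label-independent Gaussian noise features.  Ground truth (which features are
informative, which are copies of which) is returned with every dataset so
planted-recovery assertions are possible without any download.

Presets named after classic microarray benchmark shapes (colon-like,
srbct-like, …) generate matrices of matching dimensions, not matching content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LabeledDataset

__all__ = [
    "GeneratorSpec",
    "make_dataset",
    "inject_missingness",
    "make_lowrank_dataset",
    "make_xor_dataset",
    "PRESETS",
]

#: Matrix shapes of well-known microarray benchmarks (features, samples, classes).
PRESETS: dict[str, tuple[int, int, int]] = {
    "colon-like": (1800, 70, 3),
    "srbct-like": (2200, 80, 5),
    "lymphoma-like": (7100, 60, 4),
    "leukemia-like": (7100, 70, 3),
    "cns-like": (7100, 50, 3),
    "mll-like": (12500, 70, 2),
    "ovarian-like": (15100, 260, 4),
}


@dataclass
class GeneratorSpec:
    """Shape and planted-signal parameters of one synthetic dataset.

    ``effect_size`` is the separation between adjacent class means on each
    informative feature, in units of the within-class SD.  ``class_weights``
    (summing to 1) control imbalance; None means uniform.  Redundant features
    are their source plus N(0, redundant_noise_sd·noise_sd) noise, which at
    the default 0.3 keeps their correlation with the source above 0.9.
    """

    n_samples: int = 70
    n_features: int = 1800
    n_informative: int = 10
    n_redundant: int = 20
    n_classes: int = 2
    class_weights: tuple[float, ...] | None = None
    effect_size: float = 2.0
    noise_sd: float = 1.0
    redundant_noise_sd: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValueError("n_informative + n_redundant exceeds n_features")
        if self.n_classes < 2:
            raise ValueError("need >= 2 classes")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
            if len(w) != self.n_classes or abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
                raise ValueError("class_weights must be n_classes probabilities summing to 1")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "GeneratorSpec":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        d, n, k = PRESETS[name]
        kw = dict(n_samples=n, n_features=d, n_classes=k)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class PlantedTruth:
    """Ground truth returned with every generated dataset."""

    informative: list[int]
    redundant: dict[int, int] = field(default_factory=dict)  # copy index -> source index


def make_dataset(spec: GeneratorSpec) -> tuple[LabeledDataset, PlantedTruth]:
    """Draw one labelled matrix with planted informative/redundant features.

    Informative feature j: class-conditional Gaussian whose class-c mean is
    sign_j · c · effect_size · noise_sd (adjacent classes separated by
    effect_size SDs).  Redundant features are noisy copies of random
    informative ones.  Everything else is label-independent noise.
    Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    weights = (np.full(spec.n_classes, 1.0 / spec.n_classes)
               if spec.class_weights is None
               else np.asarray(spec.class_weights, dtype=float))
    y = rng.choice(spec.n_classes, size=n, p=weights)

    X = rng.normal(0.0, spec.noise_sd, size=(n, d))
    positions = rng.permutation(d)[: spec.n_informative + spec.n_redundant]
    informative = sorted(int(p) for p in positions[: spec.n_informative])
    redundant_pos = sorted(int(p) for p in positions[spec.n_informative:])

    for j in informative:
        sign = rng.choice([-1.0, 1.0])
        X[:, j] += sign * spec.effect_size * spec.noise_sd * y

    redundant: dict[int, int] = {}
    for j in redundant_pos:
        src = int(rng.choice(informative)) if informative else int(rng.integers(d))
        X[:, j] = X[:, src] + rng.normal(
            0.0, spec.redundant_noise_sd * spec.noise_sd, size=n)
        redundant[j] = src

    labels = np.array([f"c{c}" for c in y], dtype=object)
    ds = LabeledDataset(X, labels)
    if spec.missing_rate > 0:
        ds, _ = inject_missingness(ds, spec.missing_rate, seed=spec.seed + 1)
    return ds, PlantedTruth(informative, redundant)


def inject_missingness(ds: LabeledDataset, rate: float, seed: int = 0
                       ) -> tuple[LabeledDataset, np.ndarray]:
    """Mask each entry independently with probability ``rate`` (MCAR).

    Guarantees every row and every feature keeps at least one observed entry
    by re-drawing the whole mask (bounded attempts); errors if the rate makes
    the guarantee practically infeasible.  Returns the masked dataset and the
    binary observation indicator Z.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n, d = ds.matrix.shape
    if rate == 0.0:
        return ds.copy(), np.ones((n, d), dtype=np.int8)
    for _ in range(100):
        observed = rng.random((n, d)) >= rate
        if observed.any(axis=1).all() and observed.any(axis=0).all():
            out = ds.copy()
            out.matrix[~observed] = np.nan
            return out, observed.astype(np.int8)
    raise ValueError(f"missing rate {rate} cannot keep every row/feature observed")


def make_lowrank_dataset(n_samples: int = 200, n_features: int = 50,
                         rank: int = 2, noise_sd: float = 0.1, seed: int = 0
                         ) -> tuple[LabeledDataset, np.ndarray]:
    """Low-rank latent-structure matrix for imputation benchmarking.

    X = U V + noise with U (n×rank), V (rank×d) standard normal.  Returns the
    dataset (with alternating dummy labels) and the noiseless ground-truth
    matrix used for RMSE scoring.
    """
    rng = np.random.default_rng(seed)
    U = rng.normal(size=(n_samples, rank))
    V = rng.normal(size=(rank, n_features))
    truth = U @ V
    X = truth + rng.normal(0.0, noise_sd, size=truth.shape)
    labels = np.array(["a" if i % 2 == 0 else "b" for i in range(n_samples)],
                      dtype=object)
    return LabeledDataset(X, labels), truth


def make_xor_dataset(n_samples: int = 150, n_noise: int = 10,
                     label_noise_sd: float = 0.1, seed: int = 0
                     ) -> tuple[LabeledDataset, PlantedTruth]:
    """Two-feature interaction ("XOR") data for feature-construction tests.

    The signal features f0, f1 take values sign·(0.5 + U(0, 1)) — continuous
    but bimodal around ±1 — and the label is the sign of f0·f1 plus a small
    Gaussian perturbation, so no single feature carries any marginal signal;
    only the product does.  ``n_noise`` standard-normal distractor features
    are appended so that a plain distance-based classifier degrades without
    the constructed interaction.
    """
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_samples, 2))
    f = signs * (0.5 + rng.random((n_samples, 2)))
    score = f[:, 0] * f[:, 1] + rng.normal(0.0, label_noise_sd, size=n_samples)
    labels = np.where(score > 0, "pos", "neg").astype(object)
    noise = rng.normal(size=(n_samples, n_noise))
    X = np.hstack([f, noise])
    return LabeledDataset(X, labels), PlantedTruth([0, 1])
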