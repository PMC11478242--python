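"""Autoscaling with stored parameters and venetian-blinds cross-validation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: columns whose sample standard deviation falls below this are treated as
#: constant and dropped from the scaled representation
VARIANCE_FLOOR = 1e-12


@dataclass
class ScalingModel:
    """Per-column mean/std learned on a training matrix.

    Columns with (numerically) zero variance are excluded via ``kept_mask``
    rather than epsilon-padded; prediction data are reduced identically so
    train and test live in the same column space.
    """

    means: np.ndarray
    stds: np.ndarray
    kept_mask: np.ndarray

    @property
    def n_variables(self) -> int:
        return len(self.means)

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "stds": self.stds.tolist(),
            "kept_mask": self.kept_mask.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingModel":
        return cls(
            means=np.asarray(d["means"], dtype=float),
            stds=np.asarray(d["stds"], dtype=float),
            kept_mask=np.asarray(d["kept_mask"], dtype=bool),
        )


def autoscale_fit(X: np.ndarray) -> ScalingModel:
    """Fit column means and sample standard deviations (n-1 denominator)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("autoscaling requires a matrix with at least 2 rows")
    means = X.mean(axis=0)
    stds = X.std(axis=0, ddof=1)
    kept = stds >= VARIANCE_FLOOR
    return ScalingModel(means=means, stds=stds, kept_mask=kept)


def autoscale_apply(model: ScalingModel, X: np.ndarray) -> np.ndarray:
    """Standardize with stored training parameters; dropped columns removed.

    Accepts a matrix or a single row vector.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_variables:
        raise ValueError(
            f"column mismatch: data has {X.shape[1]}, model expects {model.n_variables}"
        )
    k = model.kept_mask
    return (X[:, k] - model.means[k]) / model.stds[k]


def autoscale_inverse(model: ScalingModel, Z: np.ndarray) -> np.ndarray:
    """Map standardized data back to the original scale and column layout.

    Dropped (constant) columns are restored at their training means.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != model.n_kept:
        raise ValueError("column mismatch in inverse transform")
    k = model.kept_mask
    X = np.tile(model.means, (Z.shape[0], 1))
    X[:, k] = Z * model.stds[k] + model.means[k]
    return X


@dataclass
class CvFolds:
    """Cross-validation fold assignment over n samples."""

    k: int
    assignments: np.ndarray

    def __post_init__(self):
        self.assignments = np.asarray(self.assignments, dtype=int)

    @property
    def n(self) -> int:
        return len(self.assignments)

    def iter_folds(self):
        """Yield (train_idx, test_idx) per fold, in fold order."""
        idx = np.arange(self.n)
        for j in range(self.k):
            test = self.assignments == j
            yield idx[~test], idx[test]


def venetian_blinds(n: int, k: int = 10) -> CvFolds:
    """Interleaved ("venetian blinds") fold assignment: sample i -> fold i mod k.

    Deterministic given (n, k, sample order); fold sizes differ by at most 1.
    """
    if k < 2:
        raise ValueError("venetian blinds requires k >= 2")
    if n < k:
        raise ValueError(f"venetian blinds requires n >= k (got n={n}, k={k})")
    return CvFolds(k=k, assignments=np.arange(n) % k)
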