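"""PLS regression core (NIPALS), PLS-DA classification, and exploratory PCA/HCA.

The discriminant model is PLS1 regression of autoscaled spectra onto a coded
class variable (+1 positive / -1 negative), with a scalar decision threshold
on the predicted score. Latent-variable (LV) weights over the m/z axis expose
which fragment ions drive each separation.

Sign indeterminacy of the latent vectors is fixed by forcing the largest-
magnitude element of each x-loading vector positive, so scores, weights and
loadings are reproducible; the regression vector is invariant to the choice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PLS (NIPALS, single response)
# ---------------------------------------------------------------------------

def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_lv: int):
    """NIPALS decomposition for a single centered response.

    Returns (W, P, q, T, used) with weights W (p x A), x-loadings P (p x A),
    y-loadings q (A,), orthogonal scores T (n x A). ``used`` may fall short
    of n_lv if the residual collapses first.
    """
    n, p = X.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    Xa = X.copy()
    ya = y.astype(float).copy()
    used = 0
    for a in range(n_lv):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xa @ w
        tt = t @ t
        if tt < 1e-12:
            break
        pa = Xa.T @ t / tt
        qa = (ya @ t) / tt
        # fixed sign convention: largest-|loading| element positive
        j = int(np.argmax(np.abs(pa)))
        if pa[j] < 0:
            w, t, pa, qa = -w, -t, -pa, -qa
        Xa -= np.outer(t, pa)
        ya -= qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
        used += 1
    return W[:, :used], P[:, :used], q[:used], T[:, :used], used


def _pls_reg_coef(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Regression vector b with yhat = X b (centered scales)."""
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


@dataclass
class PlsModel:
    """Fitted PLS1 model on (possibly variable-selected) autoscaled data."""

    n_lv: int
    weights: np.ndarray        # p_sel x A
    x_loadings: np.ndarray     # p_sel x A
    y_loadings: np.ndarray     # A
    scores: np.ndarray         # n x A (training scores)
    reg_coef: np.ndarray       # p_sel
    y_mean: float
    variable_mask: np.ndarray  # p_sel bools (all True unless a mask was applied upstream)
    mz_axis: np.ndarray | None = None  # m/z value of each retained column
    algorithm: str = "nipals"

    @property
    def n_variables(self) -> int:
        return len(self.reg_coef)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_variables:
            raise ValueError(
                f"column mismatch: data has {X.shape[1]}, model expects {self.n_variables}"
            )
        return X @ self.reg_coef + self.y_mean

    def to_dict(self) -> dict:
        return {
            "n_lv": int(self.n_lv),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "reg_coef": self.reg_coef.tolist(),
            "y_mean": float(self.y_mean),
            "variable_mask": self.variable_mask.astype(int).tolist(),
            "mz_axis": None if self.mz_axis is None else np.asarray(self.mz_axis).tolist(),
            "algorithm": self.algorithm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlsModel":
        return cls(
            n_lv=d["n_lv"],
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            scores=np.zeros((0, d["n_lv"])),
            reg_coef=np.asarray(d["reg_coef"], dtype=float),
            y_mean=d["y_mean"],
            variable_mask=np.asarray(d["variable_mask"], dtype=bool),
            mz_axis=None if d["mz_axis"] is None else np.asarray(d["mz_axis"]),
            algorithm=d.get("algorithm", "nipals"),
        )


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    mz_axis: np.ndarray | None = None,
) -> PlsModel:
    """Fit a PLS1 model to autoscaled X and a coded class vector y.

    y is centered internally (its mean is stored and added back at
    prediction). Requires 1 <= n_lv <= min(n-1, p).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    if np.std(y) < 1e-12:
        raise ValueError("y has zero variance: both classes must be present")
    if not (1 <= n_lv <= min(n - 1, p)):
        raise ValueError(f"n_lv must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    y_mean = float(y.mean())
    W, P, q, T, used = _nipals_pls1(X, y - y_mean, n_lv)
    if used < n_lv:
        logger.warning("PLS residual collapsed after %d of %d components", used, n_lv)
    return PlsModel(
        n_lv=used,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        reg_coef=_pls_reg_coef(W, P, q),
        y_mean=y_mean,
        variable_mask=np.ones(p, dtype=bool),
        mz_axis=None if mz_axis is None else np.asarray(mz_axis),
    )


# ---------------------------------------------------------------------------
# Decision threshold and classification
# ---------------------------------------------------------------------------

def fit_threshold(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Decision threshold between two classes of predicted scores.

    Fits a Gaussian to each class's scores and places the threshold at the
    equal-density crossing under equal priors (the Bayes boundary). Falls
    back to the midpoint of the class means when either variance is
    numerically zero or no crossing lies between the means.
    """
    sp = np.asarray(scores_pos, dtype=float)
    sn = np.asarray(scores_neg, dtype=float)
    if sp.size == 0 or sn.size == 0:
        raise ValueError("both classes need at least one score")
    m1, m0 = sp.mean(), sn.mean()
    v1 = sp.var(ddof=1) if sp.size > 1 else 0.0
    v0 = sn.var(ddof=1) if sn.size > 1 else 0.0
    mid = 0.5 * (m1 + m0)
    if m1 == m0 and v1 == v0:
        warnings.warn("identical class score distributions; threshold at midpoint")
        return mid
    if v1 < 1e-12 or v0 < 1e-12:
        return mid
    # equal-density: (x-m1)^2/(2 v1) + ln(s1) = (x-m0)^2/(2 v0) + ln(s0)
    A = 0.5 * (1.0 / v1 - 1.0 / v0)
    B = m0 / v0 - m1 / v1
    C = m1 ** 2 / (2 * v1) - m0 ** 2 / (2 * v0) + 0.5 * np.log(v1 / v0)
    lo, hi = min(m0, m1), max(m0, m1)
    if abs(A) < 1e-14:
        if abs(B) < 1e-14:
            warnings.warn("degenerate Gaussian crossing; threshold at midpoint")
            return mid
        x = -C / B
        return float(x) if lo <= x <= hi else mid
    disc = B * B - 4 * A * C
    if disc < 0:
        warnings.warn("no real Gaussian crossing; threshold at midpoint")
        return mid
    r = np.sqrt(disc)
    roots = [(-B - r) / (2 * A), (-B + r) / (2 * A)]
    between = [x for x in roots if lo <= x <= hi]
    if not between:
        warnings.warn("no Gaussian crossing between class means; threshold at midpoint")
        return mid
    return float(between[0] if len(between) == 1 else min(between, key=lambda x: abs(x - mid)))


@dataclass
class PlsdaClassifier:
    """PLS-DA: a PLS1 model plus a decision threshold and class labels.

    A score greater than or equal to the threshold is assigned the positive
    label (ties go to the positive class by documented convention).
    """

    pls: PlsModel
    threshold: float
    positive_label: str = "positive"
    negative_label: str = "negative"

    def to_dict(self) -> dict:
        return {
            "pls": self.pls.to_dict(),
            "threshold": float(self.threshold),
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlsdaClassifier":
        return cls(
            pls=PlsModel.from_dict(d["pls"]),
            threshold=d["threshold"],
            positive_label=d["positive_label"],
            negative_label=d["negative_label"],
        )


def classify(c: PlsdaClassifier, X_new: np.ndarray):
    """Predict labels and discrimination scores for preprocessed rows.

    X_new must already be scaled with the classifier's stored scaling and
    reduced to its variable mask.
    """
    scores = c.pls.predict(X_new)
    labels = [c.positive_label if s >= c.threshold else c.negative_label for s in scores]
    return labels, scores


def lv_weight_report(m: PlsModel, lv_index: int, top_k: int):
    """Top-|weight| m/z values of one latent variable, sign retained.

    ``lv_index`` is 1-based. Positive/negative weight signs indicate which
    class a strong peak at that m/z pushes a sample toward.
    """
    if not (1 <= lv_index <= m.n_lv):
        raise ValueError(f"lv_index must lie in [1, {m.n_lv}]")
    w = m.weights[:, lv_index - 1]
    mz = m.mz_axis if m.mz_axis is not None else np.arange(len(w))
    order = np.argsort(-np.abs(w), kind="stable")[: min(top_k, len(w))]
    return [(mz[i], float(w[i])) for i in order]


# ---------------------------------------------------------------------------
# Exploratory analysis: PCA and Ward HCA
# ---------------------------------------------------------------------------

def pca_scores(X: np.ndarray, k: int):
    """Scores and explained-variance fractions of the top-k principal components.

    Deterministic: component signs fixed by the largest-|loading| convention.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not (1 <= k <= min(n - 1, p)):
        raise ValueError(f"k must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U[:, :k] * s[:k]
    total = float((s ** 2).sum())
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return scores, frac


def ward_hca(X: np.ndarray) -> np.ndarray:
    """Agglomerative clustering under Ward's minimum-variance criterion.

    Returns a scipy-format linkage matrix (Lance-Williams recursion); merge
    heights are non-decreasing.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("Ward HCA requires at least 2 samples")
    return linkage(X, method="ward")
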