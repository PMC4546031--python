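"""PLS1 calibration with Monte Carlo cross-validation factor selection.

The regression core is classical NIPALS PLS1 on mean-centered data (X
columns are centered, never variance-scaled — per-spectrum normalization
already conditions the data).  Per factor:

    w = X'y / ||X'y||          (weight)
    t = X w                    (score)
    p = X't / (t't)            (x-loading)
    q = y't / (t't)            (y-loading)
    X <- X - t p',  y <- y - q t   (deflation of X and y)

The regression vector for k factors is b = W (P'W)^-1 q with intercept
b0 = y_mean - x_mean . b, so prediction is affine: yhat = b0 + x . b.

The number of factors is chosen by repeated Monte Carlo cross-validation:
the calibration set is split uniformly at random into training and
validation subsets (default 67/66), models with k = 1..k_max (default 30)
factors are fit on the training part, squared validation errors are pooled
over all repeats (default 10,000), and

    RMMCCV(k) = sqrt( pooled squared error / (n_repeats * n_validation) ).

The chosen k minimizes RMMCCV (ties broken toward the smallest k), after
which a final model is refit on the entire calibration set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PLS1Model",
    "MCCVResult",
    "fit_pls1",
    "predict",
    "mccv_select_factors",
    "fit_final_model",
]

# deflation stops early when the residual covariance collapses (rank reached)
_RANK_TOL = 1e-12


@dataclass(frozen=True)
class PLS1Model:
    """Fitted single-response PLS regression state."""

    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # W, (p, k), unit-norm columns
    x_loadings: np.ndarray   # P, (p, k)
    y_loadings: np.ndarray   # q, (k,)
    coef: np.ndarray         # b, (p,), mg/dL per AU
    intercept: float         # b0, mg/dL
    scores: np.ndarray = field(repr=False, default=None)  # T, (n, k), training scores
    meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.x_mean.size

    def to_json(self, destination=None) -> str:
        doc = {
            "n_factors": self.n_factors,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "meta": self.meta,
        }
        text = json.dumps(doc, sort_keys=True)
        if destination is not None:
            Path(destination).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PLS1Model":
        path = Path(source)
        doc = json.loads(path.read_text()) if path.exists() else json.loads(str(source))
        return cls(
            n_factors=int(doc["n_factors"]),
            x_mean=np.asarray(doc["x_mean"], float),
            y_mean=float(doc["y_mean"]),
            weights=np.asarray(doc["weights"], float).reshape(len(doc["x_mean"]), -1),
            x_loadings=np.asarray(doc["x_loadings"], float).reshape(len(doc["x_mean"]), -1),
            y_loadings=np.asarray(doc["y_loadings"], float),
            coef=np.asarray(doc["coef"], float),
            intercept=float(doc["intercept"]),
            meta=doc.get("meta", {}),
        )


@dataclass(frozen=True)
class MCCVResult:
    """RMMCCV-versus-factor-count curve and the selected factor count."""

    rmmccv: np.ndarray
    chosen_k: int
    k_max: int
    n_repeats: int
    train_size: int
    validation_size: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": np.arange(1, self.k_max + 1), "rmmccv": self.rmmccv}
        )


def _nipals(Xc: np.ndarray, yc: np.ndarray, k: int):
    """NIPALS PLS1 on centered data; returns (W, P, q, T, n_extracted)."""
    n, p = Xc.shape
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    q = np.zeros(k)
    T = np.zeros((n, k))
    X = Xc.copy()
    y = yc.copy()
    scale = np.linalg.norm(Xc.T @ yc)
    extracted = 0
    for a in range(k):
        cov = X.T @ y
        norm = np.linalg.norm(cov)
        if not np.isfinite(norm) or norm <= _RANK_TOL * max(scale, 1.0):
            break
        w = cov / norm
        t = X @ w
        tt = t @ t
        if tt <= _RANK_TOL * max(scale, 1.0):
            break
        pa = (X.T @ t) / tt
        qa = (y @ t) / tt
        X -= np.outer(t, pa)
        y = y - qa * t
        W[:, a] = w
        P[:, a] = pa
        q[a] = qa
        T[:, a] = t
        extracted += 1
    return W, P, q, T, extracted


def _coef_path(W: np.ndarray, P: np.ndarray, q: np.ndarray, extracted: int, k_max: int) -> np.ndarray:
    """Regression vectors b_k for k = 1..k_max as columns of a (p, k_max) matrix.

    Factors beyond the extracted rank reuse the last available vector (the
    fit cannot improve past the rank of the centered data).
    """
    p = W.shape[0]
    B = np.zeros((p, k_max))
    b_prev = np.zeros(p)
    for k in range(1, k_max + 1):
        if k <= extracted:
            PtW = P[:, :k].T @ W[:, :k]
            r = np.linalg.solve(PtW, q[:k])
            b_prev = W[:, :k] @ r
        B[:, k - 1] = b_prev
    return B


def fit_pls1(X: np.ndarray, y: np.ndarray, k: int, meta: dict | None = None) -> PLS1Model:
    """Fit a k-factor PLS1 model (k = 0 gives the mean-only model).

    At k equal to the rank of centered X the training predictions coincide
    with the minimum-norm least-squares solution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match X rows")
    if n < 2:
        raise ValueError("need at least 2 training samples")
    if not 0 <= k <= min(n - 1, p):
        raise ValueError(f"k must be in [0, min(n-1, p)] = [0, {min(n - 1, p)}]")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    if k > 0 and np.allclose(y, y_mean):
        raise ValueError("y is constant; PLS factors are undefined")
    Xc = X - x_mean
    yc = y - y_mean
    W, P, q, T, extracted = _nipals(Xc, yc, k)
    if extracted == 0:
        coef = np.zeros(p)
    else:
        PtW = P[:, :extracted].T @ W[:, :extracted]
        coef = W[:, :extracted] @ np.linalg.solve(PtW, q[:extracted])
    intercept = y_mean - float(x_mean @ coef)
    return PLS1Model(
        n_factors=k,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W[:, :extracted],
        x_loadings=P[:, :extracted],
        y_loadings=q[:extracted],
        coef=coef,
        intercept=intercept,
        scores=T[:, :extracted],
        meta=dict(meta or {}),
    )


def predict(model: PLS1Model, X: np.ndarray) -> np.ndarray:
    """Predict IgG (mg/dL): yhat = b0 + X . b (affine in X)."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} features, model expects {model.n_features}"
        )
    yhat = model.intercept + X @ model.coef
    return yhat[0] if single else yhat


def mccv_select_factors(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    k_max: int = 30,
    n_repeats: int = 10_000,
    train_size: int | None = None,
    seed: int = 0,
) -> MCCVResult:
    """Monte Carlo cross-validation over random train/validation splits.

    ``train_size`` defaults to ceil(n/2) (67 of a 133-sample calibration
    set).  Centering statistics are recomputed on each training split.
    Squared validation errors are pooled over repeats:
    RMMCCV(k) = sqrt(sum / (n_repeats * validation_size)).
    """
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float)
    n, p = X.shape
    if train_size is None:
        train_size = -(-n // 2)
    if not 2 <= train_size < n:
        raise ValueError("train_size must be in [2, n_cal)")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if not 1 <= k_max <= min(train_size - 1, p):
        raise ValueError(f"k_max must be in [1, min(train_size-1, p)] = [1, {min(train_size - 1, p)}]")
    val_size = n - train_size
    rng = np.random.default_rng(seed)
    sse = np.zeros(k_max)
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        tr, va = perm[:train_size], perm[train_size:]
        x_mean = X[tr].mean(axis=0)
        y_mean = y[tr].mean()
        W, P, q, _, extracted = _nipals(X[tr] - x_mean, y[tr] - y_mean, k_max)
        B = _coef_path(W, P, q, extracted, k_max)
        resid = ((X[va] - x_mean) @ B + y_mean) - y[va][:, None]
        sse += np.einsum("ij,ij->j", resid, resid)
    rmmccv = np.sqrt(sse / (n_repeats * val_size))
    chosen_k = int(np.argmin(rmmccv)) + 1  # argmin returns the smallest tied k
    return MCCVResult(
        rmmccv=rmmccv,
        chosen_k=chosen_k,
        k_max=k_max,
        n_repeats=n_repeats,
        train_size=train_size,
        validation_size=val_size,
        seed=seed,
    )


def fit_final_model(
    X_cal: np.ndarray, y_cal: np.ndarray, chosen_k: int, meta: dict | None = None
) -> PLS1Model:
    """Refit on the full calibration set with the MCCV-selected factor count."""
    return fit_pls1(X_cal, y_cal, chosen_k, meta=meta)
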