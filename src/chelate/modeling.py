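"""Enantioselectivity modeling: Eyring conversion, Bayesian ridge regression
(BRR), leave-one-out scoring and capped forward feature selection.

Model
-----
ddG = w . z + b + eps, with z the standardized predictors, an isotropic
zero-mean Gaussian prior N(0, 1/alpha) on w, Gaussian noise of precision
beta, and an unpenalized intercept b (the training mean of y).  alpha and
beta are set by type-II maximum likelihood (MacKay fixed-point updates,
relative tolerance 1e-6 on both precisions, at most 300 iterations) unless
frozen by the caller.  Predictions carry a calibrated standard deviation
sigma^2 = 1/beta + z' S z with S the weight posterior covariance.

Selection
---------
Forward stepwise search capped at three features: stage one scores every
single feature, later stages extend the top-`beam` survivors by one unseen
feature; candidates of every size are retained and the final ranking is by
the adjusted R^2 of pooled leave-one-out predictions (ties: fewer features,
then lower LOO MAE, then name order).  Standardization is refit inside each
LOO fold, so no information leaks from the held-out sample.

The per-fold refits are vectorized: fold-wise means, variances, Gram
matrices and moment vectors are obtained by rank-one downdates of the full
data moments, and the evidence iterations run batched over folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ee_to_ddg",
    "ddg_to_ee",
    "read_screening_table",
    "BRRModel",
    "brr_fit",
    "adjusted_r2",
    "loo_scores",
    "ModelReport",
    "forward_select",
]

#: gas constant in kcal mol^-1 K^-1
GAS_CONSTANT_KCAL = 1.98720425e-3

MAX_ITER = 300
TOL = 1e-6


# ---------------------------------------------------------------------------
# Eyring conversion


def ee_to_ddg(ee, temperature):
    """ddG (kcal/mol) between diastereomeric transition states from ee at T.

    ddG = R T ln((1 + ee) / (1 - ee)); positive ee gives positive ddG.
    """
    ee = np.asarray(ee, dtype=float)
    T = np.asarray(temperature, dtype=float)
    if np.any(np.abs(ee) >= 1):
        raise ValueError("enantiomeric excess must satisfy |ee| < 1")
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (K)")
    out = GAS_CONSTANT_KCAL * T * np.log((1 + ee) / (1 - ee))
    return float(out) if out.ndim == 0 else out


def ddg_to_ee(ddg, temperature):
    """Inverse Eyring relation: ee = tanh(ddG / (2 R T))."""
    ddg = np.asarray(ddg, dtype=float)
    T = np.asarray(temperature, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (K)")
    out = np.tanh(ddg / (2.0 * GAS_CONSTANT_KCAL * T))
    return float(out) if out.ndim == 0 else out


def read_screening_table(path) -> pd.DataFrame:
    """Read a screening table and return (ligand_id-indexed) records with ddG.

    Accepts either columns (ligand_id, ee, temperature_K) or
    (ligand_id, ddg_kcal_mol); delimited text, '#' comments allowed.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip() for c in df.columns]
    if "ligand_id" not in df.columns:
        raise ValueError("screening table needs a ligand_id column")
    df = df.set_index("ligand_id")
    if "ddg_kcal_mol" in df.columns:
        df["ddg"] = df["ddg_kcal_mol"].astype(float)
    elif {"ee", "temperature_K"} <= set(df.columns):
        df["ddg"] = ee_to_ddg(df["ee"].to_numpy(), df["temperature_K"].to_numpy())
    else:
        raise ValueError(
            "screening table needs either (ee, temperature_K) or ddg_kcal_mol"
        )
    return df


# ---------------------------------------------------------------------------
# Bayesian ridge regression


@dataclass
class BRRModel:
    """Fitted BRR posterior in standardized predictor units."""

    feature_names: list[str]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    weights: np.ndarray            # posterior mean, standardized units
    weight_cov: np.ndarray         # posterior covariance, standardized units
    alpha: float                   # prior precision
    beta: float                    # noise precision
    n_iter: int
    converged: bool

    @property
    def weights_raw(self) -> np.ndarray:
        return self.weights / self.x_std

    @property
    def intercept_raw(self) -> float:
        return self.y_mean - float(np.dot(self.weights_raw, self.x_mean))

    @property
    def normalized_weights(self) -> np.ndarray:
        """|w|/sum|w| on standardized predictors (importance shares)."""
        a = np.abs(self.weights)
        s = a.sum()
        return a / s if s > 0 else a

    def predict(self, X, return_std: bool = False):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} predictors, got {X.shape[1]}"
            )
        Z = (X - self.x_mean) / self.x_std
        mu = Z @ self.weights + self.y_mean
        if not return_std:
            return mu
        var = 1.0 / self.beta + np.einsum("ij,jk,ik->i", Z, self.weight_cov, Z)
        return mu, np.sqrt(np.maximum(var, 0.0))

    def equation(self) -> str:
        terms = " ".join(
            f"{w:+.4f}*z({n})" for w, n in zip(self.weights, self.feature_names)
        )
        return f"ddG = {self.y_mean:.4f} {terms}  [standardized predictors]"


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    if np.any(std <= 0):
        raise ValueError("constant predictor column cannot be standardized")
    return (X - mean) / std, mean, std


def _evidence_iterate(s, q, yy, n, alpha0, beta0, fixed):
    """MacKay fixed-point updates, batched over leading axes of s/q/yy.

    s: eigenvalues of Z'Z (..., p); q: V' Z'y in the eigenbasis (..., p);
    yy: centered sum of squares (...,); n: samples per problem (scalar or
    (...,)).  Returns (alpha, beta, m_eig, n_iter, converged).
    """
    alpha = np.broadcast_to(np.asarray(alpha0, dtype=float), yy.shape).copy()
    beta = np.broadcast_to(np.asarray(beta0, dtype=float), yy.shape).copy()
    n = np.broadcast_to(np.asarray(n, dtype=float), yy.shape)
    it = 0
    converged = np.zeros(yy.shape, dtype=bool)
    for it in range(1, MAX_ITER + 1):
        denom = alpha[..., None] + beta[..., None] * s
        m = beta[..., None] * q / denom
        if fixed:
            converged[...] = True
            break
        gamma = (beta[..., None] * s / denom).sum(axis=-1)
        mm = (m * m).sum(axis=-1)
        rss = yy - 2.0 * (m * q).sum(axis=-1) + (m * m * s).sum(axis=-1)
        rss = np.maximum(rss, 1e-12)
        new_alpha = np.clip(gamma / np.maximum(mm, 1e-12), 1e-9, 1e9)
        new_beta = np.clip(np.maximum(n - gamma, 1e-3) / rss, 1e-9, 1e12)
        # geometric damping: same fixed point, suppresses the period-2
        # oscillation of the raw updates on irrelevant-predictor problems
        new_alpha = np.sqrt(alpha * new_alpha)
        new_beta = np.sqrt(beta * new_beta)
        converged = (np.abs(new_alpha - alpha) <= TOL * np.abs(alpha)) & (
            np.abs(new_beta - beta) <= TOL * np.abs(beta)
        )
        alpha, beta = new_alpha, new_beta
        if converged.all():
            break
    denom = alpha[..., None] + beta[..., None] * s
    m = beta[..., None] * q / denom
    return alpha, beta, m, it, converged


def brr_fit(
    X,
    y,
    feature_names: Sequence[str] | None = None,
    alpha: float | None = None,
    beta: float | None = None,
    require_convergence: bool = False,
) -> BRRModel:
    """Fit BRR on raw predictors (standardized internally).

    If ``alpha`` and ``beta`` are given, the precisions are frozen and the
    posterior mean equals the ridge closed form m = beta A^-1 Z'y with
    A = alpha I + beta Z'Z.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y have different lengths")
    if n < 2:
        raise ValueError("need at least 2 samples")
    names = list(feature_names) if feature_names is not None else [f"x{i}" for i in range(p)]
    Z, x_mean, x_std = _standardize(X)
    y_mean = float(y.mean())
    yc = y - y_mean

    svals, V = np.linalg.eigh(Z.T @ Z)
    svals = np.maximum(svals, 0.0)
    q = V.T @ (Z.T @ yc)
    yy = float(yc @ yc)

    fixed = alpha is not None and beta is not None
    if (alpha is None) != (beta is None):
        raise ValueError("freeze both precisions or neither")
    a0 = alpha if fixed else 1.0
    b0 = beta if fixed else 1.0 / max(np.var(yc), 1e-9)
    al, be, m_eig, n_iter, conv = _evidence_iterate(
        svals[None, :], q[None, :], np.array([yy]), n, a0, b0, fixed
    )
    al, be = float(al[0]), float(be[0])
    if require_convergence and not bool(conv[0]):
        raise RuntimeError(
            f"BRR evidence maximization did not converge in {MAX_ITER} iterations "
            f"(alpha={al:.3e}, beta={be:.3e})"
        )
    w = V @ m_eig[0]
    cov = V @ np.diag(1.0 / (al + be * svals)) @ V.T
    return BRRModel(
        feature_names=names,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        weights=w,
        weight_cov=cov,
        alpha=al,
        beta=be,
        n_iter=n_iter,
        converged=bool(conv[0]),
    )


# ---------------------------------------------------------------------------
# scoring


def adjusted_r2(y, yhat, p: int) -> float:
    """1 - (1 - R^2) (n - 1) / (n - p - 1)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = len(y)
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 needs n > p + 1 (n={n}, p={p})")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 0:
        raise ValueError("response has zero variance")
    r2 = 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1.0) / (n - p - 1.0)


def _loo_predict_batch(Xc: np.ndarray, y: np.ndarray, strict: bool = True) -> np.ndarray:
    """Pooled LOO BRR predictions for a batch of candidate designs.

    ``Xc`` has shape (C, n, p): C candidate feature subsets over the same n
    samples.  Each fold of each candidate re-standardizes its own training
    rows (rank-one downdates of the full moments) and re-runs the evidence
    maximization from scratch; results match a naive per-fold loop to
    within the convergence tolerance.  Returns (C, n) predictions.
    """
    C, n, p = Xc.shape
    m = n - 1

    sx = Xc.sum(axis=1)                                     # (C, p)
    sy = y.sum()
    G0 = np.einsum("cnp,cnq->cpq", Xc, Xc)                  # (C, p, p)
    xy0 = np.einsum("cnp,n->cp", Xc, y)
    yy0 = float(y @ y)

    mu = (sx[:, None, :] - Xc) / m                          # (C, n, p)
    diag = np.einsum("cpp->cp", G0)
    ex2 = (diag[:, None, :] - Xc * Xc) / m
    var = np.maximum(ex2 - mu * mu, 0.0)
    bad = (var <= 1e-24).any(axis=(1, 2))                   # (C,)
    if bad.any():
        if strict:
            raise ValueError("a predictor is constant within a LOO fold")
        var = np.where(var <= 1e-24, 1.0, var)              # placeholder; masked below
    sd = np.sqrt(var)
    ybar = (sy - y[None, :]) / m                            # (C, n) broadcast of (n,)
    ybar = np.broadcast_to((sy - y) / m, (C, n))
    # centered, standardized fold Gram and moment vectors via downdates
    G = G0[:, None, :, :] - Xc[:, :, :, None] * Xc[:, :, None, :]
    G = G - m * mu[:, :, :, None] * mu[:, :, None, :]
    G = G / (sd[:, :, :, None] * sd[:, :, None, :])         # (C, n, p, p)
    b = xy0[:, None, :] - Xc * y[None, :, None]
    b = (b - m * mu * ybar[:, :, None]) / sd                # (C, n, p)
    yy = (yy0 - y * y)[None, :] - m * ybar * ybar           # (C, n)

    svals, V = np.linalg.eigh(G.reshape(C * n, p, p))
    svals = np.maximum(svals, 0.0)
    q = np.einsum("kij,ki->kj", V, b.reshape(C * n, p))
    yyf = yy.reshape(C * n)
    b0 = 1.0 / np.maximum(yyf / m, 1e-9)
    _, _, m_eig, _, _ = _evidence_iterate(svals, q, yyf, m, 1.0, b0, False)
    w = np.einsum("kij,kj->ki", V, m_eig).reshape(C, n, p)
    z_out = (Xc - mu) / sd
    pred = (z_out * w).sum(axis=2) + ybar
    if not strict and bad.any():
        pred[bad] = np.nan
    return pred


def loo_predictions(X, y) -> np.ndarray:
    """Pooled leave-one-out BRR predictions, one refit per fold (vectorized).

    Each fold re-standardizes its own training rows and re-runs the
    evidence maximization from scratch; results match a naive loop up to
    the convergence tolerance of the evidence updates.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y have different lengths")
    if n < 3:
        raise ValueError("LOO needs at least 3 samples")
    return _loo_predict_batch(X[None, :, :], y)[0]


def loo_scores(X, y, p: int | None = None) -> tuple[float, float]:
    """(adjusted R^2, MAE) of pooled leave-one-out predictions."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if p is None:
        p = X.shape[1]
    yhat = loo_predictions(X, y)
    return adjusted_r2(y, yhat, p), float(np.mean(np.abs(y - yhat)))


# ---------------------------------------------------------------------------
# forward selection


@dataclass
class ModelReport:
    """One candidate model from the selection pipeline."""

    features: list[str]
    n: int
    weights: np.ndarray
    weight_variances: np.ndarray
    normalized_weights: np.ndarray
    weights_raw: np.ndarray
    intercept_raw: float
    alpha: float
    beta: float
    r2_adj: float
    mae: float
    r2_adj_loo: float
    mae_loo: float
    model: BRRModel = field(repr=False)

    def __post_init__(self):
        assert len(self.features) <= 3, "model complexity cap exceeded"

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "n": self.n,
            "weights_standardized": [float(w) for w in self.weights],
            "weight_variances": [float(v) for v in self.weight_variances],
            "normalized_weights": [float(w) for w in self.normalized_weights],
            "weights_raw": [float(w) for w in self.weights_raw],
            "intercept_raw": float(self.intercept_raw),
            "prior_precision": float(self.alpha),
            "noise_precision": float(self.beta),
            "r2_adj": float(self.r2_adj),
            "mae": float(self.mae),
            "r2_adj_loo": float(self.r2_adj_loo),
            "mae_loo": float(self.mae_loo),
            "equation": self.model.equation(),
        }


def _evaluate_subset(frame: pd.DataFrame, y: np.ndarray, subset: tuple[str, ...]) -> ModelReport | None:
    X = frame[list(subset)].to_numpy()
    scores = _loo_only(X, y, len(subset))
    if scores is None:
        return None
    return _full_report(X, y, subset, scores)


def _loo_only(X: np.ndarray, y: np.ndarray, p: int) -> tuple[float, float] | None:
    try:
        return loo_scores(X, y, p=p)
    except (ValueError, np.linalg.LinAlgError, RuntimeError):
        return None


def _full_report(
    X: np.ndarray, y: np.ndarray, subset: tuple[str, ...], scores: tuple[float, float]
) -> ModelReport | None:
    r2_loo, mae_loo = scores
    try:
        model = brr_fit(X, y, feature_names=list(subset))
    except (ValueError, np.linalg.LinAlgError, RuntimeError):
        return None
    yhat = model.predict(X)
    try:
        r2 = adjusted_r2(y, yhat, len(subset))
    except ValueError:
        return None
    mae = float(np.mean(np.abs(y - yhat)))
    return ModelReport(
        features=list(subset),
        n=len(y),
        weights=model.weights,
        weight_variances=np.diag(model.weight_cov).copy(),
        normalized_weights=model.normalized_weights,
        weights_raw=model.weights_raw,
        intercept_raw=model.intercept_raw,
        alpha=model.alpha,
        beta=model.beta,
        r2_adj=r2,
        mae=mae,
        r2_adj_loo=r2_loo,
        mae_loo=mae_loo,
        model=model,
    )


def _rank_key(r: ModelReport):
    return (-r.r2_adj_loo, len(r.features), r.mae_loo, tuple(sorted(r.features)))


def forward_select(
    table,
    y,
    max_features: int = 3,
    beam: int = 10,
    candidate_features: Sequence[str] | None = None,
    allow_small: bool = False,
    top_k: int | None = 10,
) -> list[ModelReport]:
    """Capped forward-stepwise BRR selection ranked by LOO adjusted R^2.

    ``table`` is a FeatureTable or DataFrame (rows aligned with ``y``).
    Candidates of every size 1..max_features are retained in the ranking;
    the ``top_k`` best (all if None) are returned as full ModelReports.
    """
    frame = table.frame if hasattr(table, "frame") else table
    y = np.asarray(y, dtype=float)
    if len(y) != len(frame):
        raise ValueError("y length does not match the feature table")
    if len(y) < 6 and not allow_small:
        raise ValueError("forward selection needs at least 6 samples")
    max_features = min(max_features, max(1, len(y) - 2))

    cols = list(candidate_features) if candidate_features is not None else list(frame.columns)
    X_all = frame[cols].to_numpy(dtype=float)
    col_ix = {c: k for k, c in enumerate(cols)}
    std = X_all.std(axis=0)
    usable = [c for c in cols if std[col_ix[c]] > 1e-12]
    if not usable:
        raise ValueError("no usable (non-constant) candidate features")
    Zc = (X_all - X_all.mean(axis=0)) / np.where(std > 0, std, 1.0)
    corr = np.abs(Zc.T @ Zc) / len(y)

    # LOO scores per subset during the search; full posteriors only at the end
    scored: dict[frozenset, tuple[float, float, tuple[str, ...]]] = {}

    n = len(y)
    ss_tot = float(((y - y.mean()) ** 2).sum())

    def score(subsets: Iterable[tuple[str, ...]]) -> list[tuple[float, float, tuple[str, ...]]]:
        uniq, seen = [], set()
        for sub in subsets:
            key = frozenset(sub)
            if key not in scored and key not in seen:
                seen.add(key)
                uniq.append(sub)
        if not uniq:
            return []
        p = len(uniq[0])
        Xc = np.stack([X_all[:, [col_ix[c] for c in sub]] for sub in uniq])
        pred = _loo_predict_batch(Xc, y, strict=False)
        resid = y[None, :] - pred
        r2 = 1.0 - (resid**2).sum(axis=1) / ss_tot
        adj = 1.0 - (1.0 - r2) * (n - 1.0) / (n - p - 1.0)
        mae = np.abs(resid).mean(axis=1)
        new = []
        for k, sub in enumerate(uniq):
            if not np.isfinite(adj[k]):
                continue
            entry = (float(adj[k]), float(mae[k]), sub)
            scored[frozenset(sub)] = entry
            new.append(entry)
        return new

    def stage_key(e):
        return (-e[0], len(e[2]), e[1], tuple(sorted(e[2])))

    stage = score([(c,) for c in usable])
    for _size in range(2, max_features + 1):
        if not stage:
            break
        survivors = sorted(stage, key=stage_key)[:beam]
        ext = []
        for _, _, sub in survivors:
            for c in usable:
                if c in sub:
                    continue
                # never extend with a near-duplicate of a selected feature
                if any(corr[col_ix[c], col_ix[f]] > 0.999 for f in sub):
                    continue
                ext.append(sub + (c,))
        stage = score(ext)

    if not scored:
        raise RuntimeError("every candidate model failed to fit")
    ranked = sorted(scored.values(), key=stage_key)
    if top_k is not None:
        ranked = ranked[: max(top_k * 2, top_k + 4)]  # headroom for fit failures
    reports = []
    for r2_loo, mae_loo, sub in ranked:
        rep = _full_report(
            X_all[:, [col_ix[c] for c in sub]], y, sub, (r2_loo, mae_loo)
        )
        if rep is not None:
            reports.append(rep)
        if top_k is not None and len(reports) >= top_k:
            break
    if not reports:
        raise RuntimeError("every candidate model failed to fit")
    return reports
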