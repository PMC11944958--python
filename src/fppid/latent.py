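"""Latent-variable models: UV-scaled PCA and NIPALS PLS2 with diagnostics.

The process model at the heart of the design framework is a two-response
partial least squares regression (PLS2), fitted by the classical NIPALS
algorithm on mean-centered, unit-variance (UV) scaled data. The module
provides:

* :class:`PCAUV` / :class:`PLSNipals` - scikit-learn style estimators
  (``fit`` / ``transform`` / ``predict``, fitted attributes with trailing
  underscores) that compose with sklearn model selection;
* cumulative R2X / R2Y, cross-validated Q2, RMSEE and RMSECV metrics with
  deterministic interleaved 7-fold assignment;
* variable importance in projection (VIP) and one-pass VIP pruning;
* Hotelling T2 with its F-distribution limit, and squared prediction error
  (SPE) with Jackson-Mudholkar or chi-square moment-matching limits.

Model components follow the usual chemometrics notation: X-weights W,
X-loadings P, Y-loadings C, scores T, with regression coefficients
B = W (P'W)^-1 C' on the scaled spaces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

__all__ = [
    "UVScaler",
    "PCAUV",
    "PLSNipals",
    "ModelMetrics",
    "fit_pca",
    "fit_pls",
    "metrics",
    "vip",
    "refine_by_vip",
    "hotelling_t2",
    "t2_limit",
    "spe",
    "spe_limit",
    "save_model",
    "load_model",
]


class ScalingError(ValueError):
    """Raised when UV scaling is impossible (zero-variance column)."""


class ConvergenceError(RuntimeError):
    """NIPALS failed to converge within the iteration budget."""


class UVScaler:
    """Column-wise mean centering and unit-variance scaling (ddof=1)."""

    def fit(self, X: np.ndarray, names=None) -> "UVScaler":
        X = np.asarray(X, float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_ == 0):
            j = int(np.flatnonzero(self.scale_ == 0)[0])
            label = names[j] if names is not None else f"column {j}"
            raise ScalingError(f"zero-variance column cannot be UV scaled: {label}")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean_) / self.scale_

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, float) * self.scale_ + self.mean_


def _as_2d(M) -> np.ndarray:
    M = np.asarray(M, float)
    if M.ndim == 1:
        M = M[:, None]
    if M.ndim != 2:
        raise ValueError("expected a 2-D array")
    if not np.isfinite(M).all():
        raise ValueError("input contains non-finite values")
    return M


def _sign_fix(v: np.ndarray) -> float:
    """Sign convention: the largest-magnitude element of v is positive."""
    return 1.0 if v[np.argmax(np.abs(v))] >= 0 else -1.0


class PCAUV(BaseEstimator, TransformerMixin):
    """Principal component analysis on UV-scaled data via SVD.

    Parameters
    ----------
    n_components : int
        Number of components to retain.
    scale : bool
        Divide by column standard deviations after centering (UV scaling).

    Attributes
    ----------
    loadings_ : (p, A) array; columns sign-fixed so the largest-magnitude
        element of each loading is positive.
    scores_ : (n, A) training scores.
    explained_variance_ratio_ : (A,) fractions of total variance.
    """

    def __init__(self, n_components: int = 2, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y=None, feature_names=None):
        X = _as_2d(X)
        n, p = X.shape
        if not 1 <= self.n_components <= min(n - 1, p):
            raise ValueError(
                f"n_components={self.n_components} out of range for {n}x{p} data"
            )
        self.feature_names_ = list(feature_names) if feature_names is not None else None
        self.scaler_ = UVScaler() if self.scale else _CenterOnly()
        Z = self.scaler_.fit(X, names=self.feature_names_).transform(X)
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        A = self.n_components
        signs = np.array([_sign_fix(Vt[a]) for a in range(A)])
        self.loadings_ = (Vt[:A].T * signs)
        self.scores_ = U[:, :A] * s[:A] * signs
        total = float((s**2).sum())
        self.explained_variance_ratio_ = s[:A] ** 2 / total
        self.singular_values_ = s[:A]
        self.n_samples_ = n
        return self

    def transform(self, X) -> np.ndarray:
        X = _as_2d(X)
        return self.scaler_.transform(X) @ self.loadings_

    def inverse_transform(self, T) -> np.ndarray:
        return self.scaler_.inverse_transform(np.asarray(T, float) @ self.loadings_.T)


class _CenterOnly(UVScaler):
    def fit(self, X, names=None):
        X = np.asarray(X, float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.ones(X.shape[1])
        return self


class PLSNipals(BaseEstimator, RegressorMixin):
    """NIPALS PLS2 regression on UV-scaled X and Y.

    Components are extracted sequentially with X deflation; the sign of
    each weight vector is fixed so its largest-magnitude element is
    positive, making the decomposition deterministic.

    Attributes
    ----------
    x_weights_ : (p, A) W, unit-norm columns.
    x_loadings_ : (p, A) P.
    y_loadings_ : (q, A) C.
    x_scores_ : (n, A) training scores T.
    coef_scaled_ : (p, q) regression coefficients on the scaled spaces.
    x_scaler_, y_scaler_ : fitted :class:`UVScaler` instances.
    """

    def __init__(self, n_components: int = 2, scale: bool = True,
                 max_iter: int = 5000, tol: float = 1e-12):
        self.n_components = n_components
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, Y, feature_names=None, response_names=None):
        X = _as_2d(X)
        Y = _as_2d(Y)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        n, p = X.shape
        q = Y.shape[1]
        A = self.n_components
        if not 1 <= A <= min(n - 1, p):
            raise ValueError(f"n_components={A} out of range for {n}x{p} data")
        self.feature_names_ = list(feature_names) if feature_names is not None else None
        self.response_names_ = list(response_names) if response_names is not None else None
        cls = UVScaler if self.scale else _CenterOnly
        self.x_scaler_ = cls().fit(X, names=self.feature_names_)
        self.y_scaler_ = cls().fit(Y, names=self.response_names_)
        Z = self.x_scaler_.transform(X)
        V = self.y_scaler_.transform(Y)
        self._ssx_total_ = float((Z**2).sum())
        self._ssy_total_ = float((V**2).sum())

        W = np.zeros((p, A))
        P = np.zeros((p, A))
        C = np.zeros((q, A))
        T = np.zeros((n, A))
        Zd, Vd = Z.copy(), V.copy()
        for a in range(A):
            if float((Zd**2).sum()) <= 1e-24 * max(1.0, self._ssx_total_):
                raise ConvergenceError(
                    f"X exhausted before component {a + 1}; reduce n_components"
                )
            u = Vd[:, int(np.argmax((Vd**2).sum(axis=0)))].copy()
            t_old = np.zeros(n)
            for _ in range(self.max_iter):
                w = Zd.T @ u
                nw = np.linalg.norm(w)
                if nw == 0:
                    raise ConvergenceError(f"zero weight vector at component {a + 1}")
                w /= nw
                t = Zd @ w
                tt = float(t @ t)
                c = Vd.T @ t / tt
                if float(c @ c) == 0:
                    break
                u = Vd @ c / float(c @ c)
                if np.linalg.norm(t - t_old) <= self.tol * np.sqrt(tt):
                    break
                t_old = t
            else:
                raise ConvergenceError(
                    f"NIPALS did not converge at component {a + 1}"
                )
            s = _sign_fix(w)
            w, t, c = s * w, s * t, s * c
            tt = float(t @ t)
            pvec = Zd.T @ t / tt
            Zd = Zd - np.outer(t, pvec)
            Vd = Vd - np.outer(t, c)
            W[:, a], P[:, a], C[:, a], T[:, a] = w, pvec, c, t

        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = C
        self.x_scores_ = T
        self._rotation_ = W @ np.linalg.solve(P.T @ W, np.eye(A))
        self.coef_scaled_ = self._rotation_ @ C.T
        self.n_train_ = n
        self.score_variance_ = T.var(axis=0, ddof=1)
        # training residuals in scaled X space, for SPE limits
        self._x_residual_train_ = Z - T @ P.T
        return self

    # -- projection and prediction ---------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "x_weights_"):
            raise RuntimeError("model is not fitted")

    def transform(self, X) -> np.ndarray:
        """Scores of new observations, T = Z W (P'W)^-1."""
        self._check_fitted()
        Z = self.x_scaler_.transform(_as_2d(X))
        return Z @ self._rotation_

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        Z = self.x_scaler_.transform(_as_2d(X))
        return self.y_scaler_.inverse_transform(Z @ self.coef_scaled_)

    def reconstruct_x(self, X) -> np.ndarray:
        """Model-plane reconstruction of X in the scaled space."""
        return self.transform(X) @ self.x_loadings_.T

    # -- diagnostics ------------------------------------------------------

    def hotelling_t2(self, X=None, scores=None) -> np.ndarray:
        """Per-row Hotelling T2 = sum_a t_ia^2 / var(t_a) (training
        score variances, n-1 denominator)."""
        self._check_fitted()
        if scores is None:
            scores = self.x_scores_ if X is None else self.transform(X)
        scores = np.asarray(scores, float)
        return (scores**2 / self.score_variance_).sum(axis=1)

    def spe(self, X) -> np.ndarray:
        """Squared prediction error sum_j (z_ij - zhat_ij)^2 on the scaled
        X space."""
        self._check_fitted()
        Z = self.x_scaler_.transform(_as_2d(X))
        E = Z - Z @ self._rotation_ @ self.x_loadings_.T
        return (E**2).sum(axis=1)


@dataclass
class ModelMetrics:
    """Goodness-of-fit and cross-validation metrics of a PLS model."""

    r2x_cum: float
    r2y_cum: float
    q2_cum: float
    rmsee: dict[str, float]
    rmsecv: dict[str, float]
    n_components: int
    folds: int


def fit_pca(X, n_components: int = 2, scale: bool = True,
            feature_names=None) -> PCAUV:
    return PCAUV(n_components=n_components, scale=scale).fit(
        X, feature_names=feature_names)


def fit_pls(X, Y, n_components: int, scale: bool = True,
            feature_names=None, response_names=None) -> PLSNipals:
    return PLSNipals(n_components=n_components, scale=scale).fit(
        X, Y, feature_names=feature_names, response_names=response_names)


def _fold_assignment(n: int, folds: int, method: str,
                     seed: int | None) -> np.ndarray:
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError(f"folds={folds} exceeds {n} rows")
    if method == "interleaved":
        return np.arange(n) % folds
    if method == "random":
        rng = np.random.default_rng(seed)
        return rng.permutation(np.arange(n) % folds)
    raise ValueError(f"unknown fold assignment {method!r}")


def metrics(model: PLSNipals, X, Y, folds: int = 7,
            assignment: str = "interleaved",
            seed: int | None = None) -> ModelMetrics:
    """Cumulative R2X/R2Y on the scaled training data, pooled Q2 from
    cross-validation, and per-response RMSEE / RMSECV in original units.

    Q2 = 1 - PRESS/SS is pooled over responses on the full-sample UV scale
    of Y, so responses with different units contribute comparably. Fold
    assignment defaults to deterministic interleaving (row i -> fold
    i mod folds); ``assignment='random'`` uses a seeded permutation.
    """
    model._check_fitted()
    X = _as_2d(X)
    Y = _as_2d(Y)
    n, q = Y.shape
    rnames = model.response_names_ or [f"y{k}" for k in range(q)]

    Z = model.x_scaler_.transform(X)
    V = model.y_scaler_.transform(Y)
    T = Z @ model._rotation_
    Ex = Z - T @ model.x_loadings_.T
    r2x = 1.0 - float((Ex**2).sum()) / float((Z**2).sum())
    Vhat = Z @ model.coef_scaled_
    r2y = 1.0 - float(((V - Vhat) ** 2).sum()) / float((V**2).sum())

    Yhat_train = model.predict(X)
    rmsee = {
        rnames[k]: float(np.sqrt(((Y[:, k] - Yhat_train[:, k]) ** 2).mean()))
        for k in range(q)
    }

    fold_of = _fold_assignment(n, folds, assignment, seed)
    Ycv = np.empty_like(Y)
    for f in range(folds):
        test = fold_of == f
        sub = PLSNipals(n_components=model.n_components, scale=model.scale,
                        max_iter=model.max_iter, tol=model.tol)
        sub.fit(X[~test], Y[~test])
        Ycv[test] = sub.predict(X[test])

    sd = Y.std(axis=0, ddof=1)
    mu = Y.mean(axis=0)
    press = float((((Y - Ycv) / sd) ** 2).sum())
    ss = float((((Y - mu) / sd) ** 2).sum())
    q2 = 1.0 - press / ss
    rmsecv = {
        rnames[k]: float(np.sqrt(((Y[:, k] - Ycv[:, k]) ** 2).mean()))
        for k in range(q)
    }
    return ModelMetrics(r2x_cum=r2x, r2y_cum=r2y, q2_cum=q2,
                        rmsee=rmsee, rmsecv=rmsecv,
                        n_components=model.n_components, folds=folds)


def choose_components(X, Y, max_components: int, folds: int = 7,
                      tol: float = 0.01, assignment: str = "interleaved",
                      seed: int | None = None) -> tuple[int, list[float]]:
    """Pick the number of latent variables by cross-validation.

    Fits models with 1..max_components components and returns the smallest
    A whose Q2 is within ``tol`` of the maximum (the usual parsimony rule:
    beyond the true dimensionality the Q2 curve is flat, so the raw argmax
    overfits), together with the full Q2 curve.
    """
    q2s = []
    for a in range(1, max_components + 1):
        m = fit_pls(X, Y, a)
        q2s.append(metrics(m, X, Y, folds=folds, assignment=assignment,
                           seed=seed).q2_cum)
    best = max(q2s)
    chosen = next(i + 1 for i, q in enumerate(q2s) if q >= best - tol)
    return chosen, q2s


def vip(model: PLSNipals) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ) with
    SSY_a = ||t_a||^2 ||c_a||^2 the Y-variance captured by component a.
    Satisfies mean(VIP^2) = 1.
    """
    model._check_fitted()
    W = model.x_weights_
    ssy = (model.x_scores_**2).sum(axis=0) * (model.y_loadings_**2).sum(axis=0)
    p = W.shape[0]
    wnorm2 = (W**2).sum(axis=0)
    contrib = (W**2 / wnorm2) @ ssy
    return np.sqrt(p * contrib / ssy.sum())


def refine_by_vip(X, Y, n_components: int, threshold: float = 1.0,
                  feature_names=None, response_names=None,
                  ) -> tuple[PLSNipals, list[str], PLSNipals]:
    """One-pass VIP pruning: fit, drop features with VIP < threshold, refit.

    Returns ``(refined_model, dropped_feature_names, full_model)``. The
    refined model keeps the same number of components (capped at the
    remaining feature count).
    """
    X = _as_2d(X)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    full = fit_pls(X, Y, n_components, feature_names=list(feature_names),
                   response_names=response_names)
    scores = vip(full)
    keep = scores >= threshold
    if not keep.any():
        raise ValueError("VIP pruning would drop every feature; refusing")
    dropped = [feature_names[j] for j in range(len(feature_names)) if not keep[j]]
    A = min(n_components, int(keep.sum()))
    refined = fit_pls(X[:, keep], Y, A,
                      feature_names=[f for f, k in zip(feature_names, keep) if k],
                      response_names=response_names)
    return refined, dropped, full


def t2_limit(n_components: int, n_train: int, alpha: float = 0.05) -> float:
    """Hotelling T2 control limit A(n-1)/(n-A) * F(A, n-A; 1-alpha)."""
    A, n = n_components, n_train
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n <= A or A < 1:
        raise ValueError("require n_train > n_components >= 1")
    return A * (n - 1) / (n - A) * float(stats.f.ppf(1 - alpha, A, n - A))


def hotelling_t2(model: PLSNipals, X=None, scores=None) -> np.ndarray:
    return model.hotelling_t2(X=X, scores=scores)


def spe(model: PLSNipals, X) -> np.ndarray:
    return model.spe(X)


def spe_limit(residuals: np.ndarray, alpha: float = 0.05,
              method: str = "jackson-mudholkar") -> float:
    """SPE control limit from a training residual matrix (scaled space).

    ``jackson-mudholkar``: the classical approximation from the residual
    covariance eigenvalues. ``chi2``: moment matching of the SPE sample to
    g*chi2_h (g = v/2m, h = 2m^2/v from the SPE mean m and variance v).
    """
    E = _as_2d(residuals)
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if method == "chi2":
        q = (E**2).sum(axis=1)
        m, v = float(q.mean()), float(q.var(ddof=1))
        if v == 0:
            return m
        g, h = v / (2 * m), 2 * m**2 / v
        return g * float(stats.chi2.ppf(1 - alpha, h))
    if method != "jackson-mudholkar":
        raise ValueError(f"unknown SPE limit method {method!r}")
    lam = np.linalg.eigvalsh(E.T @ E / (E.shape[0] - 1))
    lam = lam[lam > max(1e-12 * lam.max(), 0.0)]
    th1, th2, th3 = (float((lam**k).sum()) for k in (1, 2, 3))
    if th1 == 0:
        return 0.0
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    if h0 <= 0:
        h0 = 1e-4
    z = float(stats.norm.ppf(1 - alpha))
    term = (z * np.sqrt(2.0 * th2 * h0**2) / th1
            + 1.0 + th2 * h0 * (h0 - 1.0) / th1**2)
    return th1 * term ** (1.0 / h0)


# -- serialization --------------------------------------------------------

def save_model(model: PLSNipals, path) -> None:
    """Serialize a fitted PLS model (scalers, W/P/C, scores metadata) to JSON."""
    model._check_fitted()
    payload = {
        "n_components": model.n_components,
        "scale": model.scale,
        "n_train": model.n_train_,
        "feature_names": model.feature_names_,
        "response_names": model.response_names_,
        "x_mean": model.x_scaler_.mean_.tolist(),
        "x_scale": model.x_scaler_.scale_.tolist(),
        "y_mean": model.y_scaler_.mean_.tolist(),
        "y_scale": model.y_scaler_.scale_.tolist(),
        "x_weights": model.x_weights_.tolist(),
        "x_loadings": model.x_loadings_.tolist(),
        "y_loadings": model.y_loadings_.tolist(),
        "score_variance": model.score_variance_.tolist(),
        "x_residual_train": model._x_residual_train_.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> PLSNipals:
    with open(path) as fh:
        d = json.load(fh)
    model = PLSNipals(n_components=d["n_components"], scale=d["scale"])
    model.feature_names_ = d["feature_names"]
    model.response_names_ = d["response_names"]
    for attr, key in (("x_scaler_", "x"), ("y_scaler_", "y")):
        sc = UVScaler()
        sc.mean_ = np.array(d[f"{key}_mean"])
        sc.scale_ = np.array(d[f"{key}_scale"])
        setattr(model, attr, sc)
    model.x_weights_ = np.array(d["x_weights"])
    model.x_loadings_ = np.array(d["x_loadings"])
    model.y_loadings_ = np.array(d["y_loadings"])
    model.score_variance_ = np.array(d["score_variance"])
    model._x_residual_train_ = np.array(d["x_residual_train"])
    model.n_train_ = d["n_train"]
    A = model.n_components
    model._rotation_ = model.x_weights_ @ np.linalg.solve(
        model.x_loadings_.T @ model.x_weights_, np.eye(A))
    model.coef_scaled_ = model._rotation_ @ model.y_loadings_.T
    model.x_scores_ = np.zeros((0, A))
    return model
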