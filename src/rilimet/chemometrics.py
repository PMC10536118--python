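"""Multivariate engine: scaling, NIPALS PLS/PLS-DA, VIP, orthogonal
signal correction, kernel PLS, cross-validated Q2 and the response
permutation test.

The estimators follow the statsmodels convention: a Model object is
built from data and ``fit()`` returns a Results object carrying scores,
loadings, explained variance, prediction and ``summary()``.

Conventions fixed here (the classic SIMCA-style defaults):

* unit-variance (autoscaling) of X by default; pareto and center-only
  available; Y is centered, not scaled;
* NIPALS with deflation, convergence tolerance 1e-10 on the score
  direction, at most 2000 inner iterations, deterministic initialization
  from the first Y column;
* PLS-DA encodes classes as one-hot Y; predicted class = argmax of the
  predicted indicator columns;
* VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ) with
  SSY_a = (t_a' t_a) ||q_a||^2, so mean(VIP^2) = 1 identically;
* OSC is Wold's iterative variant: per component the leading principal
  score is made exactly orthogonal to Y, re-estimated through a PLS
  inner relation until stable, then deflated from X;
* the Gaussian kernel width defaults to the median-distance heuristic,
  gamma = 1 / median(pairwise squared Euclidean distances);
* Q2 = 1 - PRESS/SS from venetian-blind cross-validation (7 folds by
  default) with the blind assignment drawn from a seed.

Missing cells are mean-imputed inside multivariate fits only (flagged on
the results); univariate statistics elsewhere never impute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# scaling

def impute_mean(X):
    """Column-mean imputation for multivariate fits. Returns the imputed
    matrix and whether anything was imputed."""
    X = np.array(X, dtype=float)
    nan = np.isnan(X)
    if not nan.any():
        return X, False
    col_mean = np.nanmean(X, axis=0)
    X[nan] = np.take(col_mean, np.nonzero(nan)[1])
    return X, True


def scale_matrix(X, method: str = "uv"):
    """Center/scale columns. ``uv``: (x-mean)/SD; ``pareto``:
    (x-mean)/sqrt(SD); ``center_only``: x-mean. Returns
    (X_scaled, center, scale); the stored vectors invert the transform
    exactly. SD uses the n-1 denominator."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).all(axis=0).any():
        raise ValueError("all-missing column")
    center = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    if method == "uv":
        if np.any(sd == 0):
            cols = np.flatnonzero(sd == 0).tolist()
            raise ValueError(f"zero-variance column(s) {cols} under uv "
                             "scaling")
        scale = sd
    elif method == "pareto":
        scale = np.sqrt(np.where(sd > 0, sd, 1.0))
    elif method == "center_only":
        scale = np.ones_like(sd)
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    return (X - center) / scale, center, scale


def unscale_matrix(Xs, center, scale):
    return np.asarray(Xs) * scale + center


def one_hot(labels):
    """Class labels -> (indicator matrix, ordered class list)."""
    classes = sorted(set(labels))
    Y = np.zeros((len(labels), len(classes)))
    pos = {c: j for j, c in enumerate(classes)}
    for i, lab in enumerate(labels):
        Y[i, pos[lab]] = 1.0
    return Y, classes


# ---------------------------------------------------------------------------
# NIPALS PLS


@dataclass
class PLSResults:
    """Fitted PLS factorization. T: scores (n x A); W: weights (p x A,
    unit columns); P: X loadings; Q: Y loadings (c x A); ssy: explained
    Y sum of squares per component."""

    n_components: int
    T: np.ndarray
    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    ssy: np.ndarray
    r2x: float
    r2y: float
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray
    classes: list = None
    imputed: bool = False
    q2: float = None

    @property
    def coef(self) -> np.ndarray:
        """Regression coefficients in scaled-X / centered-Y space."""
        return self.W @ np.linalg.solve(self.P.T @ self.W, self.Q.T)

    def predict(self, X_new) -> np.ndarray:
        X_new, _ = impute_mean(X_new)
        Xs = (X_new - self.x_center) / self.x_scale
        return Xs @ self.coef + self.y_center

    def predict_class(self, X_new):
        if self.classes is None:
            raise ValueError("model was not fitted on class labels")
        Yhat = self.predict(X_new)
        return [self.classes[j] for j in np.argmax(Yhat, axis=1)]

    def vip(self) -> np.ndarray:
        """Variable importance in projection; mean(VIP^2) = 1."""
        ssy = self.ssy
        if not np.any(ssy > 0):
            raise ValueError("degenerate model: no explained Y variance")
        wn = self.W / np.linalg.norm(self.W, axis=0, keepdims=True)
        p = self.W.shape[0]
        return np.sqrt(p * (wn ** 2 @ ssy) / ssy.sum())

    def summary(self) -> str:
        lines = [f"PLS model: {self.n_components} components, "
                 f"p={self.W.shape[0]}, n={self.T.shape[0]}",
                 f"R2X={self.r2x:.4f}  R2Y={self.r2y:.4f}"
                 + (f"  Q2={self.q2:.4f}" if self.q2 is not None else ""),
                 "component  SSY_explained"]
        for a, s in enumerate(self.ssy, 1):
            lines.append(f"{a:>9d}  {s:.4f}")
        if self.imputed:
            lines.append("note: missing cells were mean-imputed")
        return "\n".join(lines)


class PLSModel:
    """Two-block PLS regression / PLS-DA via NIPALS.

    Parameters
    ----------
    X : (n, p) matrix; missing cells are mean-imputed (flagged).
    y : (n,) or (n, c) responses, or a sequence of class labels when
        ``classes=True`` (one-hot encoded, centered).
    scale : X scaling, ``uv`` (default) | ``pareto`` | ``center_only``.
    """

    def __init__(self, X, y, scale: str = "uv", classes: bool = False):
        X, self.imputed = impute_mean(X)
        if classes:
            Y, self.class_list = one_hot(y)
        else:
            Y = np.asarray(y, dtype=float)
            if Y.ndim == 1:
                Y = Y[:, None]
            self.class_list = None
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        self.Xs, self.x_center, self.x_scale = scale_matrix(X, scale)
        self.y_center = Y.mean(axis=0)
        self.Yc = Y - self.y_center

    def fit(self, n_components: int, tol: float = 1e-10,
            max_iter: int = 2000) -> PLSResults:
        X = self.Xs.copy()
        Y = self.Yc.copy()
        n, p = X.shape
        c = Y.shape[1]
        if not (1 <= n_components <= min(n - 1, p)):
            raise ValueError("n_components must lie in [1, min(n-1, p)]")
        ssx0 = (X ** 2).sum()
        ssy0 = (Y ** 2).sum()
        T = np.zeros((n, n_components))
        W = np.zeros((p, n_components))
        P = np.zeros((p, n_components))
        Q = np.zeros((c, n_components))
        ssy = np.zeros(n_components)
        for a in range(n_components):
            u = Y[:, 0].copy()
            if (u ** 2).sum() == 0:
                nz = np.flatnonzero((Y ** 2).sum(axis=0))
                if nz.size == 0:
                    raise ValueError(f"Y fully deflated before component "
                                     f"{a + 1}")
                u = Y[:, nz[0]].copy()
            d_old = None
            x_norm = np.linalg.norm(X)
            for _ in range(max_iter):
                w = X.T @ u
                nw = np.linalg.norm(w)
                if nw <= 1e-12 * x_norm * np.linalg.norm(u):
                    # Y has (numerically) no covariance with X: the
                    # weight is rounding noise. Take the leading PC
                    # direction deterministically; q will be ~0 and the
                    # component explains nothing of Y.
                    w = np.linalg.svd(X, full_matrices=False)[2][0]
                    t = X @ w
                    q = Y.T @ t / (t @ t)
                    break
                w = w / nw
                t = X @ w
                q = Y.T @ t / (t @ t)
                # convergence on the score direction (sign-aligned)
                d = t / np.linalg.norm(t)
                if d_old is not None and min(
                        np.linalg.norm(d - d_old),
                        np.linalg.norm(d + d_old)) <= tol:
                    break
                d_old = d
                qq = q @ q
                if qq == 0:  # no Y structure left; t is stationary
                    break
                u = Y @ q
                u = u / np.linalg.norm(u)  # scale-free: avoids cancellation
            else:
                raise RuntimeError(f"NIPALS failed to converge at component "
                                   f"{a + 1}")
            pvec = X.T @ t / (t @ t)
            X -= np.outer(t, pvec)
            Y -= np.outer(t, q)
            T[:, a], W[:, a], P[:, a], Q[:, a] = t, w, pvec, q
            ssy[a] = (t @ t) * (q @ q)
        r2x = 1.0 - (X ** 2).sum() / ssx0 if ssx0 > 0 else 0.0
        r2y = 1.0 - (Y ** 2).sum() / ssy0 if ssy0 > 0 else 0.0
        return PLSResults(n_components=n_components, T=T, W=W, P=P, Q=Q,
                          ssy=ssy, r2x=r2x, r2y=r2y,
                          x_center=self.x_center, x_scale=self.x_scale,
                          y_center=self.y_center, classes=self.class_list,
                          imputed=self.imputed)


def fit_pls(X, Y, n_components: int, scale: str = "uv") -> PLSResults:
    """Functional wrapper: fit an ``n_components`` NIPALS PLS model."""
    return PLSModel(X, Y, scale=scale).fit(n_components)


def vip(results: PLSResults) -> np.ndarray:
    return results.vip()


# ---------------------------------------------------------------------------
# orthogonal signal correction


@dataclass
class OSCResult:
    """Wold-style OSC filter. ``weights``/``loadings`` reproduce the
    correction on new data: t = X w; X <- X - t p', per component."""

    X_filtered: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    weights: np.ndarray
    removed_variance_fraction: float

    def apply(self, X_new) -> np.ndarray:
        X = np.array(X_new, dtype=float)
        for a in range(self.weights.shape[1]):
            t = X @ self.weights[:, a]
            X -= np.outer(t, self.loadings[:, a])
        return X


def osc_filter(X, Y, n_osc: int = 1, tol: float = 1e-6,
               max_iter: int = 500) -> OSCResult:
    """Remove ``n_osc`` components of X-variation orthogonal to Y.

    X must already be centered/scaled. Per component the weight vector
    solves the constrained problem that the classic iterative scheme
    (orthogonalize the leading score against Y, regress it back onto X,
    repeat) seeks a fixed point of: maximize the removed X-variance
    w'X'Xw subject to the removed score t = Xw being exactly orthogonal
    to every response column (w in the null space of Y'X) and
    ``||w|| = 1``. Solving it directly by eigendecomposition is
    deterministic, keeps |corr(t, Y)| at rounding level, and — because
    Y'Xw = 0 makes the score vanish on the Y-structure itself — applying
    the stored (w, p) correction to held-out samples cannot strip their
    Y-related variation. X is deflated by t p' per component.
    """
    X = np.array(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Yc = Y - Y.mean(axis=0)
    # projector onto the orthogonal complement of span(Yc)
    G = Yc.T @ Yc
    Ginv = np.linalg.pinv(G)

    def orth(v):
        return v - Yc @ (Ginv @ (Yc.T @ v))

    ssx0 = (X ** 2).sum()
    n, p = X.shape
    scores = np.zeros((n, n_osc))
    loadings = np.zeros((p, n_osc))
    weights = np.zeros((p, n_osc))
    for a in range(n_osc):
        # orthonormal basis N of null(Yc'X): any w = N v yields a score
        # Xw exactly orthogonal to the responses
        C = Yc.T @ X
        _, s, Vt = np.linalg.svd(C, full_matrices=True)
        rank = int(np.sum(s > max(C.shape) * np.finfo(float).eps
                          * (s[0] if s.size else 0.0)))
        N = Vt[rank:].T
        if N.shape[1] == 0:
            raise RuntimeError("OSC: Y'X has full rank, no orthogonal "
                               "direction left to remove")
        # maximal removed variance within the constraint subspace
        Z = X @ N
        S = Z.T @ Z
        evals, evecs = np.linalg.eigh((S + S.T) / 2.0)
        w = N @ evecs[:, -1]
        w = w / np.linalg.norm(w)
        t = X @ w
        t = orth(t)  # exact at rounding level already; belt and braces
        if (t @ t) == 0:
            raise RuntimeError("OSC score collapsed to zero")
        pvec = X.T @ t / (t @ t)
        X -= np.outer(t, pvec)
        scores[:, a], loadings[:, a], weights[:, a] = t, pvec, w
    removed = 1.0 - (X ** 2).sum() / ssx0 if ssx0 > 0 else 0.0
    return OSCResult(X_filtered=X, scores=scores, loadings=loadings,
                     weights=weights, removed_variance_fraction=removed)


# ---------------------------------------------------------------------------
# kernel PLS


def gaussian_gamma(X) -> float:
    """Median-distance heuristic: 1 / median(pairwise squared Euclidean
    distances)."""
    X = np.asarray(X, dtype=float)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    iu = np.triu_indices_from(sq, k=1)
    med = np.median(sq[iu])
    if med <= 0:
        return 1.0
    return 1.0 / med


def _kernel(Xa, Xb, kernel: str, gamma: float) -> np.ndarray:
    if kernel == "linear":
        return Xa @ Xb.T
    if kernel == "gaussian":
        sq = ((Xa[:, None, :] - Xb[None, :, :]) ** 2).sum(-1)
        return np.exp(-gamma * sq)
    raise ValueError(f"unknown kernel {kernel!r}")


@dataclass
class KPLSResults:
    kernel: str
    gamma: float
    n_components: int
    T: np.ndarray
    U: np.ndarray
    dual_coef: np.ndarray          # B so that Yhat = Kc_new @ B + y_center
    X_train: np.ndarray            # scaled training inputs
    K_train: np.ndarray            # uncentered training kernel
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray
    r2y: float
    classes: list = None
    imputed: bool = False

    def _center_cross(self, K_new):
        n = self.K_train.shape[0]
        H = np.eye(n) - np.ones((n, n)) / n
        return (K_new - np.ones((K_new.shape[0], n)) / n @ self.K_train) @ H

    def predict(self, X_new) -> np.ndarray:
        X_new, _ = impute_mean(X_new)
        Xs = (np.asarray(X_new, dtype=float) - self.x_center) / self.x_scale
        K_new = _kernel(Xs, self.X_train, self.kernel, self.gamma)
        return self._center_cross(K_new) @ self.dual_coef + self.y_center

    def predict_class(self, X_new):
        if self.classes is None:
            raise ValueError("model was not fitted on class labels")
        Yhat = self.predict(X_new)
        return [self.classes[j] for j in np.argmax(Yhat, axis=1)]

    def summary(self) -> str:
        return (f"KPLS model: kernel={self.kernel}, gamma={self.gamma:.4g}, "
                f"{self.n_components} components, n={self.T.shape[0]}, "
                f"R2Y={self.r2y:.4f}")


class KPLSModel:
    """Kernel PLS (NIPALS in feature space with double-centered kernel).

    ``kernel='linear'`` reproduces ordinary PLS predictions; the Gaussian
    kernel uses K_ij = exp(-gamma ||xi - xj||^2) with the median-distance
    heuristic for gamma when not supplied.
    """

    def __init__(self, X, y, kernel: str = "gaussian", gamma: float = None,
                 scale: str = "uv", classes: bool = False):
        X, self.imputed = impute_mean(X)
        if classes:
            Y, self.class_list = one_hot(y)
        else:
            Y = np.asarray(y, dtype=float)
            if Y.ndim == 1:
                Y = Y[:, None]
            self.class_list = None
        self.Xs, self.x_center, self.x_scale = scale_matrix(X, scale)
        self.y_center = Y.mean(axis=0)
        self.Yc = Y - self.y_center
        self.kernel = kernel
        if kernel == "gaussian":
            gamma = gaussian_gamma(self.Xs) if gamma is None else gamma
            if gamma <= 0:
                raise ValueError("gamma must be positive")
        self.gamma = gamma

    def fit(self, n_components: int, tol: float = 1e-10,
            max_iter: int = 2000) -> KPLSResults:
        n = self.Xs.shape[0]
        K = _kernel(self.Xs, self.Xs, self.kernel, self.gamma)
        H = np.eye(n) - np.ones((n, n)) / n
        Kc = H @ K @ H
        Kw = Kc.copy()
        Y = self.Yc.copy()
        ssy0 = (Y ** 2).sum()
        T = np.zeros((n, n_components))
        U = np.zeros((n, n_components))
        for a in range(n_components):
            u = Y[:, 0].copy()
            if (u ** 2).sum() == 0:
                nz = np.flatnonzero((Y ** 2).sum(axis=0))
                if nz.size == 0:
                    raise ValueError(f"Y fully deflated before component "
                                     f"{a + 1}")
                u = Y[:, nz[0]].copy()
            t_old = None
            for _ in range(max_iter):
                t = Kw @ u
                nt = np.linalg.norm(t)
                if nt == 0 or not np.isfinite(nt):
                    raise RuntimeError("degenerate KPLS score at component "
                                       f"{a + 1}")
                t = t / nt
                if t_old is not None and min(
                        np.linalg.norm(t - t_old),
                        np.linalg.norm(t + t_old)) <= tol:
                    break
                t_old = t
                c = Y.T @ t
                cc = c @ c
                if cc == 0:  # Y exhausted; keep the stationary score
                    break
                u = Y @ c
                u = u / np.linalg.norm(u)
            else:
                raise RuntimeError(f"KPLS failed to converge at component "
                                   f"{a + 1}")
            T[:, a], U[:, a] = t, u
            D = np.eye(n) - np.outer(t, t)
            Kw = D @ Kw @ D
            Y = Y - np.outer(t, t @ Y)
        M = T.T @ Kc @ U
        dual = U @ np.linalg.solve(M, T.T @ self.Yc)
        Yhat = Kc @ dual
        r2y = (1.0 - ((self.Yc - Yhat) ** 2).sum() / ssy0
               if ssy0 > 0 else 0.0)
        return KPLSResults(kernel=self.kernel, gamma=self.gamma,
                           n_components=n_components, T=T, U=U,
                           dual_coef=dual, X_train=self.Xs, K_train=K,
                           x_center=self.x_center, x_scale=self.x_scale,
                           y_center=self.y_center, r2y=r2y,
                           classes=self.class_list, imputed=self.imputed)


def fit_kpls(X, Y, n_components: int, kernel: str = "gaussian",
             gamma: float = None, scale: str = "uv") -> KPLSResults:
    return KPLSModel(X, Y, kernel=kernel, gamma=gamma, scale=scale) \
        .fit(n_components)


# ---------------------------------------------------------------------------
# cross-validation and permutation test


def venetian_folds(n: int, folds: int, seed: int) -> np.ndarray:
    """Venetian-blind fold assignment on a seed-permuted sample order."""
    if folds < 2 or folds > n:
        raise ValueError("folds must lie in [2, n]")
    order = np.random.default_rng(seed).permutation(n)
    assign = np.empty(n, dtype=int)
    assign[order] = np.arange(n) % folds
    return assign


def cross_validate_q2(X, Y, n_components: int, folds: int = 7,
                      seed: int = 0, scale: str = "uv") -> float:
    """Q2 = 1 - PRESS/SS with SS about the training-fold means of Y."""
    X, _ = impute_mean(X)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    assign = venetian_folds(n, folds, seed)
    press = 0.0
    ss = 0.0
    for f in range(folds):
        test = assign == f
        train = ~test
        res = PLSModel(X[train], Y[train], scale=scale).fit(
            min(n_components, train.sum() - 1, X.shape[1]))
        Yhat = res.predict(X[test])
        press += ((Y[test] - Yhat) ** 2).sum()
        ss += ((Y[test] - Y[train].mean(axis=0)) ** 2).sum()
    return 1.0 - press / ss


@dataclass
class PermutationReport:
    n_perm: int
    observed_r2y: float
    observed_q2: float
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray

    @property
    def empirical_p_q2(self) -> float:
        return (1.0 + np.sum(self.permuted_q2 >= self.observed_q2)) \
            / (self.n_perm + 1.0)

    def to_dict(self) -> dict:
        return {"n_perm": self.n_perm,
                "observed_R2Y": self.observed_r2y,
                "observed_Q2": self.observed_q2,
                "permuted_R2Y": list(map(float, self.permuted_r2y)),
                "permuted_Q2": list(map(float, self.permuted_q2)),
                "empirical_p_Q2": self.empirical_p_q2}


def permutation_test(X, Y, n_components: int, n_perm: int = 200,
                     seed: int = 0, folds: int = 7,
                     scale: str = "uv") -> PermutationReport:
    """Response permutation test: refit R2Y and Q2 under ``n_perm`` row
    permutations of Y; empirical p = (1 + #{Q2_perm >= Q2_obs}) /
    (n_perm + 1)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, _ = impute_mean(X)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    rng = np.random.default_rng(seed)
    obs_r2y = PLSModel(X, Y).fit(n_components).r2y
    obs_q2 = cross_validate_q2(X, Y, n_components, folds=folds, seed=seed)
    perm_r2y = np.empty(n_perm)
    perm_q2 = np.empty(n_perm)
    for i in range(n_perm):
        Yp = Y[rng.permutation(Y.shape[0])]
        perm_r2y[i] = PLSModel(X, Yp).fit(n_components).r2y
        perm_q2[i] = cross_validate_q2(X, Yp, n_components, folds=folds,
                                       seed=int(rng.integers(2 ** 31)))
    return PermutationReport(n_perm=n_perm, observed_r2y=obs_r2y,
                             observed_q2=obs_q2, permuted_r2y=perm_r2y,
                             permuted_q2=perm_q2)
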