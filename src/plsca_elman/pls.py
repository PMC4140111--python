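"""Partial least squares feature reduction via NIPALS, with PRESS-based
cross-validated choice of the number of latent components, and the PCA
baseline used by the PCA-variant classifier.

The decomposition is the classical one: X = T P' + E and Y = U Q' + F,
with the inner regression u = b t linking the score pairs, and the
regression coefficient matrix B = W (P'W)^{-1} Q' mapping (standardized)
X to (standardized) Y.  NIPALS extracts one component pair at a time and
deflates both blocks, which is what lets the method operate on n < p
(singular-covariance, "small sample") data where ordinary least squares
cannot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "PCAModel",
    "nipals_fit",
    "select_components_cv",
    "pls_transform",
    "pls_predict",
    "pca_fit",
    "pca_transform",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PLSModel:
    """Fitted PLS factor model.

    T, U are (n, l) score matrices; P (p, l) and Q (q, l) loadings; W (p, l)
    weights; ``inner_coefs`` the per-component inner regression coefficients
    b_k (regression of u on t).  ``l`` is the retained component count,
    ``achieved`` how many components NIPALS could extract before the X
    residual was exhausted.  Centering/scaling vectors for both blocks are
    stored so new data can be transformed and predictions de-standardized.
    """

    T: np.ndarray
    P: np.ndarray
    U: np.ndarray
    Q: np.ndarray
    W: np.ndarray
    inner_coefs: np.ndarray
    l: int
    achieved: int
    x_means: np.ndarray
    x_scales: np.ndarray
    y_means: np.ndarray
    y_scales: np.ndarray
    press: np.ndarray | None = None
    residual_x_norms: np.ndarray = field(default_factory=lambda: np.empty(0))
    residual_y_norms: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def B(self) -> np.ndarray:
        """Coefficient matrix W (P'W)^{-1} Q' for the first ``l`` components."""
        return _coef_matrix(self.W, self.P, self.Q, self.l)

    def rotation(self, l: int | None = None) -> np.ndarray:
        l = self.l if l is None else l
        Wl, Pl = self.W[:, :l], self.P[:, :l]
        return Wl @ np.linalg.inv(Pl.T @ Wl)

    def to_json(self, path) -> None:
        payload = {
            k: getattr(self, k).tolist()
            for k in (
                "T", "P", "U", "Q", "W", "inner_coefs",
                "x_means", "x_scales", "y_means", "y_scales",
                "residual_x_norms", "residual_y_norms",
            )
        }
        payload["l"] = self.l
        payload["achieved"] = self.achieved
        payload["press"] = None if self.press is None else self.press.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PLSModel":
        with open(path) as fh:
            payload = json.load(fh)
        arrays = {
            k: np.asarray(v, dtype=float)
            for k, v in payload.items()
            if k not in ("l", "achieved", "press")
        }
        press = payload["press"]
        return cls(
            l=int(payload["l"]),
            achieved=int(payload["achieved"]),
            press=None if press is None else np.asarray(press, dtype=float),
            **arrays,
        )


def _coef_matrix(W: np.ndarray, P: np.ndarray, Q: np.ndarray, l: int) -> np.ndarray:
    Wl, Pl, Ql = W[:, :l], P[:, :l], Q[:, :l]
    return Wl @ np.linalg.inv(Pl.T @ Wl) @ Ql.T


def _standardize_block(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = M.mean(axis=0)
    scales = M.std(axis=0)
    scales = np.where(scales > 0, scales, 1.0)  # constant block column: center only
    return (M - means) / scales, means, scales


def nipals_fit(
    X: np.ndarray,
    Y: np.ndarray,
    max_components: int | None = None,
    tol: float = 1e-10,
    max_iter: int = 500,
    l: int | None = None,
) -> PLSModel:
    """Extract latent components by the NIPALS alternating iteration.

    Per component: iterate w ∝ E'u, t = Ew, q = F't/(t't), u = Fq/(q'q)
    until the score t stabilizes, then deflate E by t p' and F by the
    regression of F on t.  Extraction stops early, recording the achieved
    count, when the X residual is numerically exhausted (rank reached).

    ``l`` fixes the retained component count (≤ achieved); by default all
    extracted components are retained.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    cap = min(n - 1, p)
    if max_components is None:
        max_components = cap
    max_components = min(max_components, cap)
    if max_components < 1:
        raise ValueError("need at least one extractable component (n ≥ 2)")

    E, xm, xs = _standardize_block(X)
    F, ym, ys = _standardize_block(Y)
    x_norm0 = np.linalg.norm(E)

    Ts, Ps, Us, Qs, Ws, bs = [], [], [], [], [], []
    rx, ry = [], []
    for a in range(max_components):
        if np.linalg.norm(E) < 1e-12 * max(x_norm0, 1.0):
            break  # X-rank exhausted
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        if np.linalg.norm(u) < 1e-300:
            u = E[:, int(np.argmax(E.var(axis=0)))].copy()
        t_old = np.zeros(n)
        converged = False
        if F.shape[1] == 1:
            # univariate Y: the alternation is closed-form in one pass
            w = E.T @ u
            wn = np.linalg.norm(w)
            if wn < 1e-300:
                break
            w /= wn
            t = E @ w
            if t @ t < 1e-300:
                break
            converged = True
        else:
            for it in range(max_iter):
                w = E.T @ u
                wn = np.linalg.norm(w)
                if wn < 1e-300:
                    break
                w /= wn
                t = E @ w
                tt = t @ t
                if tt < 1e-300:
                    break
                q = F.T @ t / tt
                qq = q @ q
                u = F @ q / qq if qq > 1e-300 else t.copy()
                if np.linalg.norm(t - t_old) < tol * max(np.linalg.norm(t), 1e-300):
                    converged = True
                    break
                t_old = t
            else:
                raise ConvergenceError(
                    f"NIPALS failed to converge for component {a + 1} "
                    f"within {max_iter} iterations"
                )
        if not converged:
            break  # degenerate residual: nothing left to extract
        tt = t @ t
        p_load = E.T @ t / tt
        c = F.T @ t / tt  # Y-loading used for deflation (regression of F on t)
        b = (u @ t) / tt
        E = E - np.outer(t, p_load)
        F = F - np.outer(t, c)
        Ts.append(t)
        Ps.append(p_load)
        Us.append(u)
        Qs.append(c)
        Ws.append(w)
        bs.append(b)
        rx.append(np.linalg.norm(E))
        ry.append(np.linalg.norm(F))

    if not Ts:
        raise ValueError("no components could be extracted (zero-variance X)")
    achieved = len(Ts)
    keep = achieved if l is None else min(l, achieved)
    return PLSModel(
        T=np.column_stack(Ts),
        P=np.column_stack(Ps),
        U=np.column_stack(Us),
        Q=np.column_stack(Qs),
        W=np.column_stack(Ws),
        inner_coefs=np.asarray(bs),
        l=keep,
        achieved=achieved,
        x_means=xm,
        x_scales=xs,
        y_means=ym,
        y_scales=ys,
        residual_x_norms=np.asarray(rx),
        residual_y_norms=np.asarray(ry),
    )


def pls_transform(model: PLSModel, X_new: np.ndarray, l: int | None = None) -> np.ndarray:
    """Project new rows onto the latent scores (deflation-consistent).

    Uses the rotation R = W (P'W)^{-1}, so transforming the training matrix
    reproduces the stored score matrix T.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_means.shape[0]:
        raise ValueError(
            f"feature count {X_new.shape[1]} != model input dim {model.x_means.shape[0]}"
        )
    Xc = (X_new - model.x_means) / model.x_scales
    return Xc @ model.rotation(l)


def pls_predict(model: PLSModel, X_new: np.ndarray, l: int | None = None) -> np.ndarray:
    """Predict Y for new rows through the coefficient matrix B, de-standardized."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_means.shape[0]:
        raise ValueError("feature count mismatch")
    l = model.l if l is None else min(l, model.achieved)
    Xc = (X_new - model.x_means) / model.x_scales
    B = _coef_matrix(model.W, model.P, model.Q, l)
    return (Xc @ B) * model.y_scales + model.y_means


def _fold_slices(n: int, k_folds: int, seed: int | None, shuffle: bool):
    idx = np.arange(n)
    if shuffle:
        idx = np.random.default_rng(seed).permutation(n)
    return [idx[part] for part in np.array_split(np.arange(n), k_folds)]


def select_components_cv(
    X: np.ndarray,
    Y: np.ndarray,
    k_folds: int = 10,
    max_components: int | None = None,
    seed: int | None = None,
    shuffle: bool = False,
    rule: str = "min",
) -> tuple[int, np.ndarray]:
    """Choose the component count minimizing K-fold PRESS.

    PRESS(l) = Σ_folds Σ_held-out (y − ŷ_{−fold, l})².  Folds are contiguous
    blocks by default (deterministic; suits chronologically ordered data);
    ``shuffle=True`` permutes sample order under ``seed`` first.  Ties break
    to the smallest l; ``rule="first_local_min"`` stops at the first local
    PRESS minimum instead of the global one.  Returns (l, PRESS vector).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if k_folds < 2:
        raise ValueError("k_folds must be ≥ 2")
    if n < k_folds:
        raise ValueError(f"cannot make {k_folds} folds from {n} samples")
    folds = _fold_slices(n, k_folds, seed, shuffle)
    if min(len(f) for f in folds) < 2:
        raise ValueError("every fold needs at least 2 samples")

    models = []
    for hold in folds:
        mask = np.ones(n, dtype=bool)
        mask[hold] = False
        models.append(nipals_fit(X[mask], Y[mask], max_components=max_components))
    n_cand = min(m.achieved for m in models)
    press = np.zeros(n_cand)
    for l in range(1, n_cand + 1):
        for hold, m in zip(folds, models):
            resid = Y[hold] - pls_predict(m, X[hold], l=l)
            press[l - 1] += float(np.sum(resid**2))
    if rule == "first_local_min":
        best = n_cand
        for i in range(n_cand - 1):
            if press[i] <= press[i + 1]:
                best = i + 1
                break
        return best, press
    return int(np.argmin(press)) + 1, press


@dataclass
class PCAModel:
    components: np.ndarray  # (p, k) orthonormal loading columns
    explained_variance_ratio: np.ndarray
    k: int
    means: np.ndarray
    scales: np.ndarray


def pca_fit(X: np.ndarray, variance_threshold: float = 0.8) -> PCAModel:
    """Eigendecomposition of the correlation matrix of X; retain the smallest
    number of components whose cumulative explained-variance ratio reaches
    the threshold."""
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    X = np.asarray(X, dtype=float)
    Xs, means, scales = _standardize_block(X)
    cov = np.cov(Xs, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    ratios = evals / total if total > 0 else evals
    cum = np.cumsum(ratios)
    # components with numerically-zero variance never count toward k
    nonzero = evals > 1e-12 * max(total, 1.0)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, int(nonzero.sum()))
    return PCAModel(
        components=evecs,
        explained_variance_ratio=ratios,
        k=max(k, 1),
        means=means,
        scales=scales,
    )


def pca_transform(model: PCAModel, X_new: np.ndarray, k: int | None = None) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.means.shape[0]:
        raise ValueError("feature count mismatch")
    k = model.k if k is None else k
    Xc = (X_new - model.means) / model.scales
    return Xc @ model.components[:, :k]
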