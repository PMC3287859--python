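"""Gaussian LASSO with per-coefficient penalty factors, by coordinate descent.

Objective, on the standardized design (columns of X and Z mean 0,
1/n-variance 1; y centered):

    (1/2n) ||y - X beta - Z gamma||^2 + lambda ||beta||_1

SNP coefficients beta are penalized; covariate coefficients gamma carry
penalty factor 0, so Sex/Age/Smoke are always free to be nonzero.  This
scaling convention makes lambda values directly comparable to the usual
penalized-regression software for this model family.

The solver is cyclical coordinate descent with an active-set/KKT
screening accelerator: it iterates over the current nonzero set, then
scans the full gradient for Karush-Kuhn-Tucker violations and admits the
violators.  Semantics are pinned by the plain full-sweep algorithm — a
final full sweep must move no coefficient by more than ``tol`` before a
fit is declared converged — so the accelerator changes speed, never the
solution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from snplasso.preprocess import StandardizedDesign, standardize_arrays

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 100_000


def soft_threshold(z: float, gamma: float) -> float:
    """sign(z) * max(|z| - gamma, 0): the scalar L1-penalized update."""
    if gamma < 0:
        raise ValueError("threshold must be nonnegative")
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


@dataclass
class LassoFit:
    """One solution of the penalized problem at a single lambda."""

    lam: float
    coef_penalized: dict[str, float]
    coef_unpenalized: dict[str, float]
    intercept: float
    n_iterations: int
    converged: bool
    objective_value: float
    beta: np.ndarray = field(repr=False, default=None)  # full penalized vector
    gamma: np.ndarray = field(repr=False, default=None)

    @property
    def support(self) -> set[str]:
        return set(self.coef_penalized)


@dataclass
class LassoPath:
    """Warm-started solutions along a strictly decreasing lambda grid."""

    lambdas: np.ndarray
    fits: list[LassoFit]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lambdas) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")


@dataclass
class CvResult:
    """Cross-validation curve and the lambda_min / lambda_1se rules.

    With ``n_repeats > 1`` the stored ``lambda_min``/``lambda_1se`` are the
    medians of the per-repeat choices (the curve is averaged over repeats
    for reporting).
    """

    lambdas: np.ndarray
    cvm: np.ndarray
    cvse: np.ndarray
    lambda_min: float
    lambda_1se: float
    seed: int
    per_repeat_min: list[float] = field(default_factory=list)
    per_repeat_1se: list[float] = field(default_factory=list)


def _objective(r: np.ndarray, beta: np.ndarray, lam: float, n: int) -> float:
    return float(r @ r) / (2.0 * n) + lam * float(np.abs(beta).sum())


def lambda_max(d: StandardizedDesign) -> float:
    """Smallest penalty at which every penalized coefficient is zero.

    The covariates absorb y first (they are unpenalized), then
    lambda_max = max_j |<x_j, r0>| / n over SNP columns.
    """
    if d.q:
        gamma0, *_ = np.linalg.lstsq(d.Z, d.y, rcond=None)
        r0 = d.y - d.Z @ gamma0
    else:
        r0 = d.y
    if d.p == 0:
        return 0.0
    return float(np.max(np.abs(d.X.T @ r0)) / d.n)


def _sweep_numpy(
    W: np.ndarray,
    r: np.ndarray,
    b: np.ndarray,
    idx: np.ndarray,
    thresh: np.ndarray,
    n: int,
) -> float:
    """One cyclical pass over columns ``idx``; returns max coefficient change."""
    max_delta = 0.0
    for j in idx:
        wj = W[:, j]
        bj = b[j]
        zj = bj + (wj @ r) / n
        t = thresh[j]
        if zj > t:
            bn = zj - t
        elif zj < -t:
            bn = zj + t
        else:
            bn = 0.0
        if bn != bj:
            r += wj * (bj - bn)
            b[j] = bn
            delta = abs(bn - bj)
            if delta > max_delta:
                max_delta = delta
    return max_delta


try:  # compiled kernel: same algorithm, same update order
    from numba import njit

    @njit(cache=True)
    def _sweep_nb(W, r, b, idx, thresh, n):  # pragma: no cover - numba
        max_delta = 0.0
        rows = W.shape[0]
        for t in range(idx.shape[0]):
            j = idx[t]
            bj = b[j]
            g = 0.0
            for i in range(rows):
                g += W[i, j] * r[i]
            zj = bj + g / n
            th = thresh[j]
            if zj > th:
                bn = zj - th
            elif zj < -th:
                bn = zj + th
            else:
                bn = 0.0
            if bn != bj:
                diff = bj - bn
                for i in range(rows):
                    r[i] += W[i, j] * diff
                b[j] = bn
                d = bn - bj
                if d < 0.0:
                    d = -d
                if d > max_delta:
                    max_delta = d
        return max_delta

    def _sweep(W, r, b, idx, thresh, n):
        return _sweep_nb(W, r, b, np.asarray(idx, dtype=np.int64), thresh, float(n))

except ImportError:  # pragma: no cover
    _sweep = _sweep_numpy


def fit_lasso(
    d: StandardizedDesign,
    lam: float,
    init: LassoFit | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    _W: np.ndarray | None = None,
) -> LassoFit:
    """Solve the penalized problem at one lambda by coordinate descent.

    ``init`` supplies a warm start (typically the previous path point).
    Non-convergence within ``max_iter`` full-equivalent sweeps returns the
    current iterate with ``converged=False`` and a warning.  ``_W`` lets a
    path fit reuse the assembled [X Z] design (column-major for the sweep
    kernel) instead of rebuilding it per lambda.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if tol <= 0:
        raise ValueError("tol must be positive")
    n, p, q = d.n, d.p, d.q
    m = p + q
    if _W is not None:
        W = _W
    else:
        W = np.asfortranarray(
            np.concatenate([d.X, d.Z], axis=1) if q else d.X
        )
    thresh = np.concatenate([np.full(p, lam), np.zeros(q)])

    b = np.zeros(m)
    if init is not None:
        if init.beta is not None:
            b[:p] = init.beta
        if q and init.gamma is not None:
            b[p:] = init.gamma
    elif q:
        # exact unpenalized start: keeps the all-null solution exact at
        # lambda >= lambda_max (the X gradient then matches its definition
        # to machine precision)
        b[p:] = np.linalg.lstsq(d.Z, d.y, rcond=None)[0]
    r = d.y - W @ b

    all_idx = np.arange(m)
    sweeps = 0
    converged = False
    prev_obj = _objective(r, b[:p], lam, n)
    in_active = np.zeros(m, dtype=bool)
    in_active[p:] = True  # unpenalized coordinates always active
    in_active[:p] = b[:p] != 0.0
    while sweeps < max_iter:
        active = np.flatnonzero(in_active)
        # inner loop on the active set
        while sweeps < max_iter:
            delta = _sweep(W, r, b, active, thresh, n)
            sweeps += 1
            obj = _objective(r, b[:p], lam, n)
            if obj > prev_obj + 1e-10 * max(1.0, abs(prev_obj)):  # descent guard
                warnings.warn(f"objective increased by {obj - prev_obj:.3g} in a sweep")
            prev_obj = obj
            if delta < tol:
                break
        if sweeps >= max_iter:
            break
        # full KKT screen: admit penalized coordinates whose gradient
        # exceeds the penalty; if none, confirm with a full sweep
        g = (W.T @ r) / n
        viol = np.flatnonzero((b[:p] == 0.0) & (np.abs(g[:p]) > lam + 1e-12))
        if viol.size:
            in_active[viol] = True
            continue
        delta = _sweep(W, r, b, all_idx, thresh, n)
        sweeps += 1
        prev_obj = _objective(r, b[:p], lam, n)
        if delta < tol:
            converged = True
            break
        in_active[:p] |= b[:p] != 0.0
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge at lambda={lam:.4g} "
            f"after {sweeps} sweeps"
        )

    if lam > 0:
        # numerically-zero coefficients (gradient overshoot at the order of
        # the KKT screen epsilon) are exact zeros of the solution
        tiny = (b[:p] != 0.0) & (np.abs(b[:p]) < 1e-11)
        if tiny.any():
            r += W[:, :p][:, tiny] @ b[:p][tiny]
            b[:p][tiny] = 0.0

    beta, gam = b[:p].copy(), b[p:].copy()
    # raw-scale intercept via back-transformation of standardized slopes
    intercept = d.y_mean
    if p:
        intercept -= float((beta / d.x_scale) @ d.x_mean)
    if q:
        intercept -= float((gam / d.z_scale) @ d.z_mean)
    return LassoFit(
        lam=lam,
        coef_penalized={
            d.snp_ids[j]: float(beta[j]) for j in np.flatnonzero(beta != 0.0)
        },
        coef_unpenalized={name: float(g_) for name, g_ in zip(d.covariate_names, gam)},
        intercept=intercept,
        n_iterations=sweeps,
        converged=converged,
        objective_value=_objective(r, beta, lam, n),
        beta=beta,
        gamma=gam,
    )


def check_kkt(fit: LassoFit, d: StandardizedDesign, tol: float = 1e-6) -> dict:
    """Verify the stationarity conditions of a fit; returns the worst violation.

    Zero penalized coefficients need |<x_j, r>/n| <= lambda; nonzero ones
    need <x_j, r>/n = lambda * sign(beta_j); unpenalized gradients vanish.
    """
    r = d.y - d.X @ fit.beta
    if d.q:
        r = r - d.Z @ fit.gamma
    g = (d.X.T @ r) / d.n
    nz = fit.beta != 0.0
    viol_zero = float(np.max(np.abs(g[~nz]) - fit.lam, initial=0.0))
    viol_nonzero = float(
        np.max(np.abs(g[nz] - fit.lam * np.sign(fit.beta[nz])), initial=0.0)
    )
    viol_unpen = float(np.max(np.abs(d.Z.T @ r) / d.n, initial=0.0)) if d.q else 0.0
    worst = max(viol_zero, viol_nonzero, viol_unpen)
    return {
        "worst": worst,
        "zero_bound": viol_zero,
        "nonzero_stationarity": viol_nonzero,
        "unpenalized_gradient": viol_unpen,
        "ok": worst <= tol,
    }


def default_lambda_grid(
    d: StandardizedDesign,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
) -> np.ndarray:
    """Log-spaced grid from lambda_max down to lambda_max * ratio.

    Ratio defaults to 0.01 when p >= n (the high-dimensional case needs
    to stop earlier) and 1e-4 otherwise.
    """
    lam_max = lambda_max(d)
    if lam_max <= 0.0:
        lam_max = 1.0  # degenerate: y already explained; grid is arbitrary
    if lambda_min_ratio is None:
        lambda_min_ratio = 0.01 if d.n < d.p else 1e-4
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def fit_path(
    d: StandardizedDesign,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    lambdas: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    dev_ratio_max: float = 0.999,
    dev_change_min: float = 1e-5,
    dfmax: int | None = None,
) -> LassoPath:
    """Fit the path, warm-starting each lambda from the previous.

    On an auto-generated grid the path stops early — the standard
    convention for this model family — once the training deviance ratio
    1 - RSS/TSS exceeds ``dev_ratio_max`` (the fit is essentially
    interpolating, which with p > n the deep end of the grid always
    reaches), once its per-step relative increase falls below
    ``dev_change_min`` (the fit has saturated), or once the support
    exceeds ``dfmax`` nonzero SNPs.  An explicitly supplied ``lambdas``
    grid is fitted in full (only ``dfmax`` still applies), so
    cross-validation folds cover a common grid.  The returned
    ``lambdas`` are exactly those fitted.
    """
    auto_grid = lambdas is None
    if auto_grid:
        lambdas = default_lambda_grid(d, n_lambda, lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    W = np.asfortranarray(np.concatenate([d.X, d.Z], axis=1) if d.q else d.X)
    tss = float(d.y @ d.y)
    fits: list[LassoFit] = []
    prev: LassoFit | None = None
    prev_dev = 0.0
    n_fitted = 0
    for lam in lambdas:
        prev = fit_lasso(d, lam, init=prev, tol=tol, max_iter=max_iter, _W=W)
        fits.append(prev)
        n_fitted += 1
        if dfmax is not None and len(prev.coef_penalized) > dfmax:
            break
        if auto_grid and tss > 0:
            b = np.concatenate([prev.beta, prev.gamma]) if d.q else prev.beta
            rss = float(np.sum((d.y - W @ b) ** 2))
            dev = 1.0 - rss / tss
            if dev > dev_ratio_max or (
                n_fitted > 1 and dev - prev_dev < dev_change_min * max(dev, 1e-12)
            ):
                break
            prev_dev = dev
    return LassoPath(lambdas=lambdas[:n_fitted], fits=fits)


def _predict_raw(fit: LassoFit, d_train: StandardizedDesign, X_raw, Z_raw) -> np.ndarray:
    """Predict raw-scale responses for new rows using a fold-trained fit."""
    eta = np.full(X_raw.shape[0], fit.intercept)
    if d_train.p:
        eta += X_raw @ (fit.beta / d_train.x_scale)
    if d_train.q:
        eta += Z_raw @ (fit.gamma / d_train.z_scale)
    return eta


def _fold_assignment(n: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation split into K near-equal folds."""
    folds = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    for k, chunk in enumerate(np.array_split(perm, K)):
        folds[chunk] = k
    return folds


def cross_validate(
    d: StandardizedDesign,
    K: int = 10,
    n_repeats: int = 1,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    tol: float = DEFAULT_TOL,
    dfmax: int | None = None,
) -> CvResult:
    """K-fold cross-validation of the penalty on a common lambda grid.

    The grid is the portion of the auto grid the full-data path actually
    fits (early stopping and the default support cap of max(100, n/2)
    SNPs keep it out of the near-interpolation zone, where the penalty
    could never be chosen anyway).  Each fold re-standardizes its
    training rows (columns constant within the fold are dropped for that
    fold, with a warning) and scores mean squared prediction error on the
    held-out rows.  ``cvm`` is the mean of fold means; ``cvse`` their
    standard deviation over sqrt(K).  lambda_min minimizes cvm;
    lambda_1se is the largest lambda with cvm within one standard error
    of the minimum.  Repeats re-randomize the folds; the median
    lambda_min and median lambda_1se across repeats are reported.
    """
    if d.n < 2 * K:
        raise ValueError(f"need n >= 2K for {K}-fold CV, have n={d.n}")
    if d.X_raw is None or d.y_raw is None:
        raise ValueError("design lacks raw arrays; build it with standardize()")
    if dfmax is None:
        dfmax = min(d.p, max(100, d.n // 2))
    base = fit_path(
        d, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio, tol=tol, dfmax=dfmax
    )
    grid = base.lambdas
    n = d.n

    cvm_rep = np.zeros((n_repeats, grid.size))
    cvse_rep = np.zeros((n_repeats, grid.size))
    n_common = grid.size  # fold paths may stop early; compare where all reach
    mins, ones = [], []
    for rep in range(n_repeats):
        rng = np.random.default_rng([seed, rep])
        folds = _fold_assignment(n, K, rng)
        fold_mse = np.full((K, grid.size), np.nan)
        for k in range(K):
            tr = folds != k
            te = ~tr
            if d.p - (d.X_raw[tr].std(axis=0) > 0).sum():
                warnings.warn(f"fold {k}: constant SNP column(s) dropped")
            d_tr = standardize_arrays(
                d.X_raw[tr],
                d.Z_raw[tr] if d.q else np.empty((int(tr.sum()), 0)),
                d.y_raw[tr],
                d.snp_ids,
                d.covariate_names,
                drop_constant=True,
            )
            path = fit_path(d_tr, lambdas=grid, tol=tol, dfmax=dfmax)
            if d_tr.p != d.p:
                col = {s: j for j, s in enumerate(d.snp_ids)}
                X_te = d.X_raw[te][:, [col[s] for s in d_tr.snp_ids]]
            else:
                X_te = d.X_raw[te]
            Z_te = d.Z_raw[te] if d.q else np.empty((int(te.sum()), 0))
            for i, fit in enumerate(path.fits):
                pred = _predict_raw(fit, d_tr, X_te, Z_te)
                fold_mse[k, i] = float(np.mean((d.y_raw[te] - pred) ** 2))
            n_common = min(n_common, len(path.fits))
        use = fold_mse[:, :n_common]
        cvm = use.mean(axis=0)
        cvse = use.std(axis=0, ddof=1) / np.sqrt(K)
        i_min = int(np.argmin(cvm))
        lam_min = float(grid[i_min])
        within = np.flatnonzero(cvm <= cvm[i_min] + cvse[i_min])
        lam_1se = float(grid[within.min()])  # grid is decreasing: first = largest
        cvm_rep[rep, :n_common] = cvm
        cvse_rep[rep, :n_common] = cvse
        mins.append(lam_min)
        ones.append(lam_1se)

    return CvResult(
        lambdas=grid[:n_common],
        cvm=cvm_rep[:, :n_common].mean(axis=0),
        cvse=cvse_rep[:, :n_common].mean(axis=0),
        lambda_min=float(np.median(mins)),
        lambda_1se=float(np.median(ones)),
        seed=seed,
        per_repeat_min=mins,
        per_repeat_1se=ones,
    )


def select_at(d: StandardizedDesign, lam: float, tol: float = DEFAULT_TOL) -> set[str]:
    """Refit on the full data at ``lam``; SNPs with nonzero coefficients."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    return fit_lasso(d, lam, tol=tol).support
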