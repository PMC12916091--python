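"""Nested cross-validated L1 composite tapping score + partial correlation.

For one cognitive outcome, a composite tapping score is a weighted linear
combination of the 15 standardized tapping features with weights chosen by
LASSO.  To keep the score strictly out-of-sample, a 5-fold outer
cross-validation loop fits the model on each training set — with feature
standardization computed from training-fold statistics only and the
penalty chosen by an inner 5-fold cross-validation over a log-spaced grid
— and predicts the held-out fold.  Every participant thus receives exactly
one composite value from a model that never saw them.  The composite is
validated against the outcome by partial correlation adjusting for age,
sex and education.

The L1 solver is cyclic coordinate descent on the Gram matrix for the
objective

    (1 / 2n) * ||y - b0 - X beta||^2 + lambda * ||beta||_1

with an unpenalized intercept.  (Some toolkits call this penalty "alpha";
here it is ``lam`` to avoid clashing with the significance level.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateInputError(ValueError):
    """Residual variance (numerically) zero in a partial correlation."""


@dataclass
class LassoFit:
    coef: np.ndarray
    intercept: float
    lam: float
    n_iter: int
    objective_path: np.ndarray  # objective value after each full sweep

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coef


@dataclass
class CompositeResult:
    """Out-of-fold composite scores and the per-fold fitted models."""

    composite: np.ndarray
    fold_assignment: np.ndarray
    fold_lambdas: list[float]
    fold_coefs: list[np.ndarray]
    fold_intercepts: list[float]
    index: pd.Index | None = None

    @property
    def n_nonzero(self) -> list[int]:
        return [int(np.sum(c != 0)) for c in self.fold_coefs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fold": self.fold_assignment, "composite": self.composite},
            index=self.index if self.index is not None else pd.RangeIndex(len(self.composite)),
        )


def soft_threshold(z: float, t: float) -> float:
    """S(z, t) = sign(z) * max(|z| - t, 0)."""
    return float(np.sign(z) * max(abs(z) - t, 0.0))


def _validate_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) and y length n")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    return X, y


def l1_fit(
    X,
    y,
    lam: float,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    coef_init: np.ndarray | None = None,
    record_objective: bool = True,
) -> LassoFit:
    """LASSO by cyclic coordinate descent (Gram form).

    Minimizes ``(1/2n)||y - b0 - X beta||^2 + lam * ||beta||_1`` with an
    unpenalized intercept.  Convergence when the largest coefficient
    update in a sweep falls below ``tol``.  Each coordinate update is an
    exact one-dimensional minimization, so the objective is
    non-increasing sweep over sweep; with ``record_objective`` the value
    after every sweep is kept in ``objective_path`` (the cross-validation
    paths switch this off — it costs a Gram product per sweep).
    """
    X, y = _validate_xy(X, y)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    n, p = X.shape
    xm = X.mean(axis=0)
    ym = float(y.mean())
    Xc = X - xm
    yc = y - ym
    G = (Xc.T @ Xc) / n
    c = (Xc.T @ yc) / n
    var_y = float(yc @ yc) / n

    beta = np.zeros(p) if coef_init is None else np.asarray(coef_init, dtype=float).copy()

    def objective(b: np.ndarray) -> float:
        return 0.5 * (var_y - 2.0 * float(c @ b) + float(b @ G @ b)) + lam * float(
            np.abs(b).sum()
        )

    # hot loop on plain Python floats/lists: p is ~15, numpy per-call
    # overhead would dominate
    Gl = G.tolist()
    cl = c.tolist()
    bl = beta.tolist()
    rng_p = range(p)
    all_coords = list(rng_p)
    path = [objective(beta)] if record_objective else []

    def sweep(coords) -> float:
        delta = 0.0
        for j in coords:
            gj = Gl[j]
            den = gj[j]
            if den <= 0.0:
                bl[j] = 0.0
                continue
            s = 0.0
            for k in rng_p:
                s += gj[k] * bl[k]
            rho = cl[j] - s + den * bl[j]
            if rho > lam:
                new = (rho - lam) / den
            elif rho < -lam:
                new = (rho + lam) / den
            else:
                new = 0.0
            d = new - bl[j]
            if d < 0.0:
                d = -d
            if d > delta:
                delta = d
            bl[j] = new
        if record_objective:
            path.append(objective(np.asarray(bl)))
        return delta

    # glmnet-style active-set iteration: converge on the nonzero set,
    # then confirm with a full sweep
    n_iter = 0
    while n_iter < max_iter:
        n_iter += 1
        if sweep(all_coords) < tol:
            break
        active = [j for j in all_coords if bl[j] != 0.0]
        while n_iter < max_iter:
            n_iter += 1
            if sweep(active) < tol:
                break
    beta = np.asarray(bl)
    intercept = ym - float(xm @ beta)
    return LassoFit(beta, intercept, float(lam), n_iter, np.asarray(path))


def kkt_max_violation(X, y, fit: LassoFit) -> float:
    """Largest violation of the LASSO stationarity conditions at ``fit``:
    for beta_j = 0, |grad_j| <= lam; else grad_j = -lam * sign(beta_j)."""
    X, y = _validate_xy(X, y)
    n = X.shape[0]
    r = y - fit.predict(X)
    grad = -(X - X.mean(axis=0)).T @ (r - r.mean()) / n
    viol = np.where(
        fit.coef == 0,
        np.maximum(np.abs(grad) - fit.lam, 0.0),
        np.abs(grad + fit.lam * np.sign(fit.coef)),
    )
    return float(viol.max())


def lambda_grid(X, y, n_lambdas: int = 100, eps: float = 1e-4) -> np.ndarray:
    """Log-spaced descending grid from lambda_max (smallest penalty with
    an all-zero solution) down to ``eps * lambda_max``."""
    X, y = _validate_xy(X, y)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    lam_max = float(np.abs(Xc.T @ yc).max() / n)
    if lam_max <= 0:
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * eps, n_lambdas)


def lasso_path(X, y, lambdas, tol: float = 1e-5, max_iter: int = 300) -> np.ndarray:
    """Warm-started coefficient path over a descending lambda grid;
    returns an array of shape (len(lambdas), p).

    Defaults favour speed over final-digit precision: the path is used to
    compare out-of-fold prediction errors across penalties, where 1e-5
    coefficient accuracy is far below the Monte-Carlo noise of the error
    estimate.  The model refit at the selected penalty uses the tight
    :func:`l1_fit` defaults.
    """
    X, y = _validate_xy(X, y)
    coefs = np.zeros((len(lambdas), X.shape[1]))
    warm = None
    for i, lam in enumerate(lambdas):
        fit = l1_fit(
            X, y, lam, tol=tol, max_iter=max_iter, coef_init=warm,
            record_objective=False,
        )
        coefs[i] = fit.coef
        warm = fit.coef
    return coefs


def _folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded random partition into k folds with sizes differing by <= 1."""
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def inner_cv_select(
    X, y, k: int = 5, lambdas: np.ndarray | None = None, seed: int = 0
) -> float:
    """Penalty minimizing the mean out-of-fold squared error over the grid.

    Ties go to the larger lambda (sparser model); the grid is descending
    so the first minimum wins.
    """
    X, y = _validate_xy(X, y)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    if lambdas is None:
        lambdas = lambda_grid(X, y)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty lambda grid")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 23)))
    folds = _folds(n, k, rng)
    errors = np.zeros((lambdas.size, k))
    for f, test_idx in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test_idx)
        coefs = lasso_path(X[train], y[train], lambdas)
        xm = X[train].mean(axis=0)
        ym = y[train].mean()
        preds = ym + (X[test_idx] - xm) @ coefs.T
        errors[:, f] = np.mean((preds - y[test_idx, None]) ** 2, axis=0)
    mean_err = errors.mean(axis=1)
    return float(lambdas[int(np.argmin(mean_err))])


def nested_cv_composite(
    X,
    y,
    outer_k: int = 5,
    inner_k: int = 5,
    seed: int = 0,
    n_lambdas: int = 100,
) -> CompositeResult:
    """Out-of-fold composite scores via nested cross-validation.

    Within each outer training fold the features are z-standardized with
    training-fold mean/SD only (a constant training column gets SD 1 and
    a zero coefficient), the penalty is selected by inner k-fold CV, and
    the refitted model scores the held-out fold.  Neither standardization
    nor penalty selection ever touches held-out rows.

    The composite is the weighted combination of the features alone,
    ``X_heldout @ coef`` — the unpenalized training intercept is reported
    in the result but not added.  Including it would shift each fold by
    its training-fold outcome mean, which under the null is
    anti-correlated with the held-out outcomes and would leak a spurious
    negative association into the pooled scores.
    """
    index = X.index if isinstance(X, pd.DataFrame) else None
    X, y = _validate_xy(X, y)
    n = X.shape[0]
    if n < outer_k:
        raise ValueError(f"need at least outer_k={outer_k} rows, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 17)))
    folds = _folds(n, outer_k, rng)

    composite = np.full(n, np.nan)
    assignment = np.full(n, -1)
    lams: list[float] = []
    coefs: list[np.ndarray] = []
    intercepts: list[float] = []
    for f, test_idx in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test_idx)
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr = (X[train] - mu) / sd
        Xte = (X[test_idx] - mu) / sd
        grid = lambda_grid(Xtr, y[train], n_lambdas=n_lambdas)
        inner_seed = int(
            np.random.SeedSequence((int(seed), 101, f)).generate_state(1)[0] % (2**31)
        )
        lam = inner_cv_select(Xtr, y[train], k=inner_k, lambdas=grid, seed=inner_seed)
        fit = l1_fit(Xtr, y[train], lam, tol=1e-9)
        composite[test_idx] = Xte @ fit.coef
        assignment[test_idx] = f
        lams.append(lam)
        coefs.append(fit.coef)
        intercepts.append(fit.intercept)
    return CompositeResult(composite, assignment, lams, coefs, intercepts, index=index)


def partial_correlation(x, y, covariates: pd.DataFrame | np.ndarray | None = None) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on the covariates plus an intercept by
    OLS and the residuals correlated; the p-value uses the t distribution
    with ``n - n_covariates - 2`` degrees of freedom.  With no covariates
    this reduces to the plain Pearson correlation.  The result is
    invariant under any invertible affine transform of the covariate
    columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        C = np.empty((x.size, 0))
    else:
        C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(
            covariates, dtype=float
        )
        if C.ndim == 1:
            C = C[:, None]
    n, k = x.size, C.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} rows for {k} covariates, got {n}")
    A = np.column_stack([np.ones(n), C])
    rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
    ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    scale = max(float(x @ x), float(y @ y), 1.0)
    if float(rx @ rx) <= 1e-12 * scale or float(ry @ ry) <= 1e-12 * scale:
        raise DegenerateInputError("residual variance is (numerically) zero")
    r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    dof = n - k - 2
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * np.sqrt(dof / (1.0 - r_clip**2))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return r, p


def composite_with_validation(
    feature_z: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    outer_k: int = 5,
    inner_k: int = 5,
    seed: int = 0,
) -> dict:
    """End-to-end composite for one outcome on complete cases.

    ``covariates`` must contain ``age``, ``sex`` and ``education`` (raw
    categorical); education is dummy-coded internally.  Returns the
    :class:`CompositeResult` plus the partial r and p of the out-of-fold
    composite against the outcome.
    """
    idx = feature_z.index.intersection(outcome.index).intersection(covariates.index)
    cov = pd.DataFrame(index=idx)
    cov["age"] = covariates.loc[idx, "age"].astype(float)
    cov["sex_female"] = (covariates.loc[idx, "sex"] == "F").astype(float)
    for level in ("high_school", "some_college"):
        cov[f"education_{level}"] = (covariates.loc[idx, "education"] == level).astype(float)

    data = feature_z.loc[idx].join(outcome.loc[idx].rename("__y__")).join(cov)
    data = data.dropna()
    Xdf = data[feature_z.columns]
    yv = data["__y__"].to_numpy()
    result = nested_cv_composite(Xdf, yv, outer_k=outer_k, inner_k=inner_k, seed=seed)
    r, p = partial_correlation(result.composite, yv, data[cov.columns])
    return {"composite": result, "partial_r": r, "partial_p": p, "n": len(data)}
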