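"""Weighted least squares and weighted permutation inference.

The closed-form WLS estimator is ``(X'WX)^{-1} X'WY`` with
``W = diag(w_1..w_n)``; with unit weights it reduces exactly to OLS.  Under
the working model that the weights are inverse error variances, the
coefficient covariance is ``sigma2 * (X'WX)^{-1}`` with
``sigma2 = sum_i w_i r_i^2 / (n - p)``.

Because the weights are themselves estimated (from the atlas bootstrap),
p-values for the predictor of interest come from permutation procedures
rather than the t reference distribution:

* Collins–Dekker (primary): residualize the predictor of interest against
  the nuisance covariates by WLS, permute those residuals to build new
  predictor vectors, and re-fit the full weighted model for each
  permutation.  With unit weights this is the standard (unweighted)
  Collins–Dekker / Smith procedure.
* Freedman–Lane (secondary): permute the residuals of the response under
  the reduced (nuisance-only) weighted fit, add back the fitted values,
  and re-fit.

Both pool the observed statistic with the permuted ones, so the two-sided
p-value is ``(#{|t*| >= |t_obs|} + 1) / (n_perm + 1)`` and can never be 0.

Permutation fits are vectorized through the Frisch–Waugh–Lovell identity
in the sqrt(w)-transformed coordinates, which reproduces the full-model
t-statistic exactly.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _all_permutations
from math import factorial

import numpy as np

__all__ = [
    "WLSFit",
    "PermutationResult",
    "wls_fit",
    "collins_dekker_test",
    "freedman_lane_test",
]


@dataclass(frozen=True)
class WLSFit:
    """Result of a weighted least-squares fit."""

    beta: np.ndarray
    sigma2: float
    cov: np.ndarray
    t_stats: np.ndarray
    residuals: np.ndarray
    df: int
    column_names: tuple[str, ...] | None = None


@dataclass(frozen=True)
class PermutationResult:
    """Observed t, permutation t's and the pooled two-sided p-value."""

    t_observed: float
    t_permuted: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None


def _validate_weights(w: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights must have shape ({n},), got {w.shape}")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("all weights must be positive and finite")
    return w


def wls_fit(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    column_names: tuple[str, ...] | None = None,
) -> WLSFit:
    """Closed-form weighted least squares: beta = (X'WX)^{-1} X'Wy.

    Raises ``numpy.linalg.LinAlgError`` if the weighted design is rank
    deficient and ``ValueError`` on dimension/weight problems.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2D")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"y must have shape ({n},), got {y.shape}")
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    w = _validate_weights(w, n)

    sw = np.sqrt(w)
    Xt = X * sw[:, None]
    yt = y * sw
    beta, _, rank, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient under the weights")
    residuals = y - X @ beta
    df = n - p
    sigma2 = float(w @ residuals**2) / df
    xtwx_inv = np.linalg.inv(Xt.T @ Xt)
    cov = sigma2 * xtwx_inv
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = beta / np.sqrt(np.diag(cov))
    return WLSFit(
        beta=beta,
        sigma2=sigma2,
        cov=cov,
        t_stats=t_stats,
        residuals=residuals,
        df=df,
        column_names=column_names,
    )


def _check_nuisance(Z: np.ndarray, n: int) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != n:
        raise ValueError(f"nuisance matrix must have {n} rows")
    col_range = np.ptp(Z, axis=0)
    if not np.any((col_range == 0) & (Z[0] != 0)):
        raise ValueError("nuisance matrix must include an explicit intercept column")
    return Z


def _fwl_t_stats(
    X_rows: np.ndarray,
    y_perp: np.ndarray,
    Q: np.ndarray,
    sw: np.ndarray,
    df: int,
) -> np.ndarray:
    """t-statistics of each row of ``X_rows`` as predictor of interest.

    ``X_rows`` holds candidate predictors on the original scale (one per
    row); ``Q`` is an orthonormal basis of the sqrt(w)-scaled nuisance
    columns and ``y_perp`` the response residualized against it.  The
    returned t equals the full-model WLS t exactly (Frisch–Waugh–Lovell),
    with ``df = n - p`` of the full model.
    """
    Xt = X_rows * sw[None, :]
    X_perp = Xt - (Xt @ Q) @ Q.T
    xnorm2 = np.einsum("ij,ij->i", X_perp, X_perp)
    if np.any(xnorm2 <= 1e-12 * np.einsum("ij,ij->i", Xt, Xt)):
        raise ValueError("predictor of interest is constant after residualization")
    beta = (X_perp @ y_perp) / xnorm2
    rss = float(y_perp @ y_perp) - beta**2 * xnorm2
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta * np.sqrt(xnorm2) / np.sqrt(sigma2)
    return t


def _pooled_p(t_obs: float, t_perm: np.ndarray, counting: str) -> float:
    if counting == "pooled":
        exceed = int(np.count_nonzero(np.abs(t_perm) >= abs(t_obs)))
        return (exceed + 1) / (t_perm.size + 1)
    if counting == "strict":
        exceed = int(np.count_nonzero(np.abs(t_perm) > abs(t_obs)))
        return exceed / t_perm.size
    raise ValueError(f"unknown counting rule {counting!r}")


def _permutation_matrix(
    n: int, n_perm: int, rng: np.random.Generator, exhaustive: bool
) -> np.ndarray:
    if exhaustive:
        if factorial(n) > 50_000:
            raise ValueError(f"exhaustive enumeration infeasible for n={n}")
        return np.array(list(_all_permutations(range(n))), dtype=np.intp)
    base = np.tile(np.arange(n), (n_perm, 1))
    return rng.permuted(base, axis=1)


def _prepare(y, x_interest, Z_nuisance, w):
    y = np.asarray(y, dtype=float)
    x = np.asarray(x_interest, dtype=float)
    n = y.shape[0]
    if x.shape != (n,):
        raise ValueError("x_interest must be a length-n vector")
    Z = _check_nuisance(Z_nuisance, n)
    w = _validate_weights(w, n)
    sw = np.sqrt(w)
    Q, _ = np.linalg.qr(Z * sw[:, None])
    df = n - (Z.shape[1] + 1)
    if df <= 0:
        raise ValueError("not enough observations for the full model")
    y_perp = y * sw - Q @ (Q.T @ (y * sw))
    return y, x, Z, w, sw, Q, df, y_perp


def collins_dekker_test(
    y: np.ndarray,
    x_interest: np.ndarray,
    Z_nuisance: np.ndarray,
    w: np.ndarray,
    n_perm: int = 999,
    seed: int | None = 0,
    counting: str = "pooled",
    exhaustive: bool = False,
) -> PermutationResult:
    """Weighted Collins–Dekker permutation test of the predictor of interest.

    Residuals of the weighted regression of ``x_interest`` on the nuisance
    covariates are permuted to form surrogate predictors; each surrogate is
    refit in the full weighted model and its t-statistic recorded.  With
    ``exhaustive=True`` all n! permutations are enumerated (small n only)
    and the p-value is the exact proportion ``#{|t*| >= |t_obs|} / n!``
    (the identity permutation supplies the pooled observed statistic).
    """
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    y, x, Z, w, sw, Q, df, y_perp = _prepare(y, x_interest, Z_nuisance, w)

    e = wls_fit(Z, x, w).residuals
    if np.allclose(e, 0):
        raise ValueError("x_interest is constant after residualization on the nuisance")

    rng = np.random.default_rng(seed)
    perms = _permutation_matrix(y.size, n_perm, rng, exhaustive)
    t_obs = float(_fwl_t_stats(x[None, :], y_perp, Q, sw, df)[0])
    t_perm = _fwl_t_stats(e[perms], y_perp, Q, sw, df)

    if exhaustive:
        p = float(np.count_nonzero(np.abs(t_perm) >= abs(t_obs))) / t_perm.size
    else:
        p = _pooled_p(t_obs, t_perm, counting)
    return PermutationResult(
        t_observed=t_obs, t_permuted=t_perm, p_value=p, n_perm=t_perm.size, seed=seed
    )


def freedman_lane_test(
    y: np.ndarray,
    x_interest: np.ndarray,
    Z_nuisance: np.ndarray,
    w: np.ndarray,
    n_perm: int = 999,
    seed: int | None = 0,
    counting: str = "pooled",
    exhaustive: bool = False,
) -> PermutationResult:
    """Weighted Freedman–Lane permutation test of the predictor of interest.

    The response residuals under the reduced (nuisance-only) weighted fit
    are permuted and added back to the reduced-model fitted values to form
    surrogate responses, each refit in the full weighted model.
    """
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    y, x, Z, w, sw, Q, df, y_perp = _prepare(y, x_interest, Z_nuisance, w)

    reduced = wls_fit(Z, y, w)
    fitted = y - reduced.residuals

    rng = np.random.default_rng(seed)
    perms = _permutation_matrix(y.size, n_perm, rng, exhaustive)
    t_obs = float(_fwl_t_stats(x[None, :], y_perp, Q, sw, df)[0])

    # surrogate responses y* = fitted + permuted residuals, residualized
    # against the nuisance in sqrt(w) coordinates; the predictor is fixed
    sw_mat = sw[None, :]
    Ystar = (fitted[None, :] + reduced.residuals[perms]) * sw_mat
    Ystar_perp = Ystar - (Ystar @ Q) @ Q.T

    xt = x * sw
    x_perp = xt - Q @ (Q.T @ xt)
    xnorm2 = float(x_perp @ x_perp)
    if xnorm2 <= 1e-12 * float(xt @ xt):
        raise ValueError("x_interest is constant after residualization on the nuisance")
    beta = (Ystar_perp @ x_perp) / xnorm2
    rss = np.einsum("ij,ij->i", Ystar_perp, Ystar_perp) - beta**2 * xnorm2
    rss = np.maximum(rss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = beta * np.sqrt(xnorm2) / np.sqrt(rss / df)

    if exhaustive:
        p = float(np.count_nonzero(np.abs(t_perm) >= abs(t_obs))) / t_perm.size
    else:
        p = _pooled_p(t_obs, t_perm, counting)
    return PermutationResult(
        t_observed=t_obs, t_permuted=t_perm, p_value=p, n_perm=t_perm.size, seed=seed
    )
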