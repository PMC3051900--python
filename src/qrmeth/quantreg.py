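"""Quantile regression by check-loss minimisation.

The conditional :math:`\\tau`-quantile model is fitted by minimising the
check loss

.. math::

    \\sum_i \\rho_\\tau(y_i - x_i'\\beta), \\qquad
    \\rho_\\tau(u) = u\\,(\\tau - \\mathbf{1}\\{u < 0\\}),

which is a linear program.  The workhorse here is a primal-dual
interior-point solver (Frisch-Newton scheme) on the bounded dual

.. math::

    \\max_a \\; y'a \\quad \\text{s.t.} \\quad X'a = (1-\\tau) X'e,
    \\qquad a \\in [0, 1]^n,

whose equality multipliers are the regression coefficients.  The
interior-point solution is then "polished" onto a vertex — a quantile
regression solution interpolates ``k`` observations exactly — so the
residual sign-count properties of the LP optimum hold exactly.  A sparse
``scipy.optimize.linprog`` (HiGHS) formulation serves as a fallback when
the interior point fails to converge.

``oracle_fit`` solves tiny instances by exhaustive enumeration of all
interpolating bases; it exists so the LP path can be checked against an
independent brute-force minimum.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.optimize import linprog
from scipy.stats import norm

__all__ = [
    "QuantRegFit",
    "CoefficientInference",
    "check_loss",
    "fit_quantreg",
    "oracle_fit",
    "infer_pvalues",
]


@dataclass
class QuantRegFit:
    """Result of a single check-loss fit.

    Attributes
    ----------
    tau : float
        Quantile level of the fit.
    coefficients : ndarray, shape (k,)
        Minimising coefficient vector.
    objective : float
        Check loss evaluated at ``coefficients`` (recomputed, not the
        solver's internal value).
    residuals : ndarray, shape (n,)
        ``y - X @ coefficients``.
    converged : bool
        Whether the interior point reached its duality-gap tolerance
        (a HiGHS fallback solution also sets this to True).
    n_iter : int
        Interior-point iterations used.
    """

    tau: float
    coefficients: np.ndarray
    objective: float
    residuals: np.ndarray
    converged: bool
    n_iter: int = 0


@dataclass
class CoefficientInference:
    """Per-coefficient estimates and p-values.

    ``p_values[j]`` tests the null that coefficient ``j`` is zero;
    with ``alternative='greater'`` small values indicate a coefficient
    significantly above zero.
    """

    estimates: np.ndarray
    p_values: np.ndarray
    std_errors: np.ndarray
    method: str
    n_boot: int
    seed: int
    alternative: str = "greater"
    boot_estimates: np.ndarray | None = field(default=None, repr=False)


def _validate_tau(tau: float) -> float:
    tau = float(tau)
    if not 0.0 < tau < 1.0:
        raise ValueError(f"quantile level tau must lie in (0, 1), got {tau}")
    return tau


def check_loss(residuals, tau: float) -> float:
    """Check (pinball) loss ``sum_i rho_tau(u_i)``.

    ``rho_tau(u) = u * (tau - 1{u < 0})`` weights positive residuals by
    ``tau`` and negative residuals by ``1 - tau``; its location
    minimiser is the empirical ``tau``-quantile.
    """
    tau = _validate_tau(tau)
    u = np.asarray(residuals, dtype=float)
    return float(np.sum(u * (tau - (u < 0.0))))


def _check_design(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]} entries")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("design matrix and response must be finite (no missing values)")
    if n <= k:
        raise ValueError(f"need more observations than parameters (n={n}, k={k})")
    # column-pivoted QR exposes any dependent columns by name
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(n, k) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < k:
        dependent = sorted(int(j) for j in piv[rank:])
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {k}); "
            f"dependent columns: {dependent}"
        )
    return X, y


def _ip_dual(X, y, tau, max_iter=80, tol=1e-11):
    """Frisch-Newton interior point on the bounded dual LP.

    Returns (beta, converged, n_iter).  The iterate stays primal- and
    dual-feasible throughout; only complementarity is driven to zero
    with a Mehrotra predictor-corrector step.
    """
    n, k = X.shape
    A = X.T  # k x n
    c = -y
    e = np.ones(n)

    def amul(v):  # X @ v, length n
        return X @ v

    def atmul(u):  # X' @ u, length k
        return A @ u

    x = np.full(n, 1.0 - tau)
    s = np.full(n, tau)

    M0 = A @ A.T
    try:
        yd = scipy.linalg.solve(M0, atmul(c), assume_a="pos")
    except scipy.linalg.LinAlgError:
        yd = np.linalg.lstsq(M0, atmul(c), rcond=None)[0]
    d = c - amul(yd)
    z = np.maximum(d, 0.0) + 1e-6
    w = z - d  # keeps dual feasibility exact: z - w = c - X yd

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gap = x @ z + s @ w
        obj = c @ x
        if gap < tol * (1.0 + abs(obj)):
            converged = True
            break
        q = 1.0 / (z / x + w / s)

        def newton(r):
            rhs = -atmul(q * r)
            Mq = (A * q) @ A.T
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
                try:
                    dy = scipy.linalg.solve(Mq, rhs, assume_a="pos")
                except scipy.linalg.LinAlgError:
                    Mq = Mq + 1e-12 * np.trace(Mq) / k * np.eye(k)
                    dy = scipy.linalg.solve(Mq, rhs)
            dx = q * (amul(dy) + r)
            return dy, dx

        # predictor (affine) direction
        r1 = w - z
        dy_a, dx_a = newton(r1)
        dz_a = -z - z * dx_a / x
        dw_a = -w + w * dx_a / s
        ap = _step_length(x, dx_a, s)
        ad = _step_length_dual(z, dz_a, w, dw_a)
        mu = gap / (2.0 * n)
        mu_aff = (
            (x + ap * dx_a) @ (z + ad * dz_a) + (s - ap * dx_a) @ (w + ad * dw_a)
        ) / (2.0 * n)
        sigma = min(0.99, max((mu_aff / mu) ** 3, 1e-8)) if mu > 0 else 0.1
        mut = sigma * mu

        # corrector
        r2 = (mut - dx_a * dz_a) / x - z - (mut + dx_a * dw_a) / s + w
        dy, dx = newton(r2)
        dz = (mut - dx_a * dz_a) / x - z - z * dx / x
        dw = (mut + dx_a * dw_a) / s - w + w * dx / s

        ap = _step_length(x, dx, s)
        ad = _step_length_dual(z, dz, w, dw)
        x = x + ap * dx
        s = s - ap * dx
        yd = yd + ad * dy
        z = z + ad * dz
        w = w + ad * dw
        np.clip(x, 1e-14, None, out=x)
        np.clip(s, 1e-14, None, out=s)
        np.clip(z, 1e-14, None, out=z)
        np.clip(w, 1e-14, None, out=w)

    return -yd, converged, it


def _step_length(x, dx, s, scale=0.9995):
    a = 1.0
    neg = dx < 0
    if np.any(neg):
        a = min(a, scale * np.min(-x[neg] / dx[neg]))
    pos = dx > 0
    if np.any(pos):
        a = min(a, scale * np.min(s[pos] / dx[pos]))
    return a


def _step_length_dual(z, dz, w, dw, scale=0.9995):
    a = 1.0
    neg = dz < 0
    if np.any(neg):
        a = min(a, scale * np.min(-z[neg] / dz[neg]))
    neg = dw < 0
    if np.any(neg):
        a = min(a, scale * np.min(-w[neg] / dw[neg]))
    return a


def _polish(X, y, tau, beta):
    """Snap an interior-point solution onto the best nearby vertex.

    An optimal basic solution interpolates ``k`` observations.  The
    ``k`` rows with the smallest absolute residuals (plus a few spares
    in case of near-collinearity) are searched for an invertible basis;
    the exact-fit solution through it is kept if it does not increase
    the check loss.
    """
    n, k = X.shape
    r = y - X @ beta
    order = np.argsort(np.abs(r), kind="stable")
    m = min(n, k + 8)
    cand = order[:m]
    Xm = X[cand]
    # pivoted QR on Xm' selects k independent rows among the candidates
    _, R, piv = scipy.linalg.qr(Xm.T, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(m, k) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    if int(np.sum(diag > tol)) < k:
        return beta
    rows = cand[piv[:k]]
    try:
        beta_v = scipy.linalg.solve(X[rows], y[rows])
    except scipy.linalg.LinAlgError:
        return beta
    if not np.all(np.isfinite(beta_v)):
        return beta
    if check_loss(y - X @ beta_v, tau) <= check_loss(r, tau) + 1e-12:
        return beta_v
    return beta


def _linprog_fit(X, y, tau):
    """Sparse HiGHS formulation of the primal LP (fallback path)."""
    n, k = X.shape
    eye = scipy.sparse.identity(n, format="csc")
    A_eq = scipy.sparse.hstack([scipy.sparse.csc_matrix(X), eye, -eye], format="csc")
    c = np.concatenate([np.zeros(k), np.full(n, tau), np.full(n, 1.0 - tau)])
    bounds = [(None, None)] * k + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"LP solver failed: {res.message}")
    return res.x[:k]


def fit_quantreg(X, y, tau: float, method: str = "lp") -> QuantRegFit:
    """Fit the linear ``tau``-quantile regression of ``y`` on ``X``.

    Parameters
    ----------
    X : array-like, shape (n, k)
        Design matrix; must be full column rank with ``n > k`` and no
        missing entries.
    y : array-like, shape (n,)
        Response vector.
    tau : float
        Quantile level in ``(0, 1)``.
    method : {"lp", "ip"}
        ``"lp"`` (default) solves the check-loss linear program with the
        HiGHS simplex, which returns a basic (vertex) solution — at
        least ``k`` residuals are exactly zero.  ``"ip"`` runs the
        interior-point path (faster on repeated refits); its solution is
        polished toward a vertex but may stop short of one when the
        optimal basis is ambiguous.

    Returns
    -------
    QuantRegFit
    """
    tau = _validate_tau(tau)
    X, y = _check_design(X, y)
    if method == "lp":
        beta = _linprog_fit(X, y, tau)
        converged, it = True, 0
    elif method == "ip":
        beta, converged, it = _ip_dual(X, y, tau)
        beta = _polish(X, y, tau, beta)
        if not converged:
            beta_lp = _polish(X, y, tau, _linprog_fit(X, y, tau))
            if check_loss(y - X @ beta_lp, tau) < check_loss(y - X @ beta, tau):
                beta = beta_lp
            converged = True
    else:
        raise ValueError(f"unknown method {method!r}")
    resid = y - X @ beta
    return QuantRegFit(
        tau=tau,
        coefficients=beta,
        objective=check_loss(resid, tau),
        residuals=resid,
        converged=converged,
        n_iter=it,
    )


def oracle_fit(X, y, tau: float, max_n: int = 12, max_k: int = 3) -> float:
    """Brute-force minimal check loss on a tiny instance.

    A quantile-regression optimum interpolates ``k`` observations, so on
    small problems the global minimum can be found by enumerating every
    size-``k`` observation subset with an invertible subdesign, solving
    each exactly and evaluating the loss.  Intended purely as an
    independent cross-check of the LP path.
    """
    tau = _validate_tau(tau)
    X, y = _check_design(X, y)
    n, k = X.shape
    if n > max_n or k > max_k:
        raise ValueError(
            f"oracle_fit only handles instances with n <= {max_n} and k <= {max_k} "
            f"(got n={n}, k={k})"
        )
    best = np.inf
    for rows in itertools.combinations(range(n), k):
        sub = X[list(rows)]
        if abs(np.linalg.det(sub)) < 1e-12:
            continue
        beta = np.linalg.solve(sub, y[list(rows)])
        loss = check_loss(y - X @ beta, tau)
        if loss < best:
            best = loss
    if not np.isfinite(best):
        raise ValueError("no invertible interpolating subset found")
    return float(best)


def _pvalues_from_normal(est, se, alternative):
    est = np.asarray(est, float)
    se = np.asarray(se, float)
    p = np.empty_like(est)
    degenerate = se <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(degenerate, 0.0, est / np.where(degenerate, 1.0, se))
    if alternative == "greater":
        p = norm.sf(z)
        p[degenerate] = np.where(est[degenerate] > 0, 0.0, 1.0)
    elif alternative == "two_sided":
        p = 2.0 * norm.sf(np.abs(z))
        p[degenerate] = np.where(est[degenerate] != 0, 0.0, 1.0)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return np.clip(p, 0.0, 1.0)


def infer_pvalues(
    X,
    y,
    tau: float,
    method: str = "bootstrap",
    n_boot: int = 200,
    seed: int | None = None,
    alternative: str = "greater",
) -> CoefficientInference:
    """Per-coefficient p-values for a quantile-regression fit.

    The default is the xy-pair bootstrap: observation rows are resampled
    with replacement, the model is refitted, and a normal approximation
    with the bootstrap standard error gives each coefficient a p-value
    for the null that it equals zero.  ``alternative='greater'`` is the
    one-sided test appropriate for hypermethylation (signal above zero).

    Rank-deficient resamples (e.g. a factor level that was never drawn)
    are rejected and redrawn, up to ``10 * n_boot`` attempts.
    """
    tau = _validate_tau(tau)
    X, y = _check_design(X, y)
    if method == "rank":
        raise NotImplementedError(
            "rank-score inference is a reserved method slot; use method='bootstrap'"
        )
    if method != "bootstrap":
        raise ValueError(f"unknown inference method {method!r}")
    if seed is None:
        raise ValueError("bootstrap inference requires an explicit seed")
    if n_boot < 50:
        warnings.warn(
            f"n_boot={n_boot} is small; bootstrap standard errors may be unstable",
            UserWarning,
            stacklevel=2,
        )
    n, k = X.shape
    fit = fit_quantreg(X, y, tau)
    rng = np.random.default_rng(int(seed))
    boot = np.empty((n_boot, k))
    got = 0
    attempts = 0
    while got < n_boot:
        if attempts >= 10 * n_boot:
            raise RuntimeError(
                "bootstrap failed: too many rank-deficient resamples "
                f"({attempts} attempts for {n_boot} replicates)"
            )
        idx = rng.integers(0, n, size=n)
        attempts += 1
        Xb = X[idx]
        if np.linalg.matrix_rank(Xb) < k:
            continue
        bfit, ok, _ = _ip_dual(Xb, y[idx], tau)
        if not ok:
            try:
                bfit = _linprog_fit(Xb, y[idx], tau)
            except RuntimeError:
                continue
        boot[got] = bfit
        got += 1
    se = boot.std(axis=0, ddof=1)
    p = _pvalues_from_normal(fit.coefficients, se, alternative)
    return CoefficientInference(
        estimates=fit.coefficients,
        p_values=p,
        std_errors=se,
        method="bootstrap",
        n_boot=n_boot,
        seed=int(seed),
        alternative=alternative,
        boot_estimates=boot,
    )
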