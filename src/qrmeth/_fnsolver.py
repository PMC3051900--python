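"""Structure-exploiting interior-point solver for the per-CGI model.

The per-CGI design is a two-way layout: one dummy column per sample (no
intercept) plus sum-to-zero probe contrasts.  Every design row therefore
has one sample indicator and one probe-contrast row, so all the linear
algebra inside the Frisch-Newton interior point — design matvecs and the
weighted normal matrix ``X' diag(q) X`` — collapses to grouped sums and
a tiny Schur complement on the probe block.  That makes a single fit
cheap enough to run the xy-pair bootstrap (hundreds of refits per CGI
per quantile level) at full study scale.

Probe coding: probes ``0 .. P-2`` map to unit contrast columns, probe
``P-1`` is the reference level whose contrast row is all ``-1``; with
``P == 1`` there is no probe block at all.

These kernels only return coefficient estimates (the bootstrap needs
nothing else); vertex-exact main fits live in :mod:`qrmeth.quantreg`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["fit_structured", "bootstrap_sample_effects"]


@njit(cache=True, nogil=True)
def _amul(v, si, pi, N, kp, out):
    """out = X @ v for the structured design."""
    n = si.shape[0]
    psum = 0.0
    for j in range(kp):
        psum += v[N + j]
    for i in range(n):
        t = v[si[i]]
        if kp > 0:
            if pi[i] < kp:
                t += v[N + pi[i]]
            else:
                t -= psum
        out[i] = t


@njit(cache=True, nogil=True)
def _atmul(u, si, pi, N, kp, out):
    """out = X' @ u for the structured design."""
    n = si.shape[0]
    for j in range(N + kp):
        out[j] = 0.0
    ref = 0.0
    for i in range(n):
        out[si[i]] += u[i]
        if kp > 0:
            if pi[i] < kp:
                out[N + pi[i]] += u[i]
            else:
                ref += u[i]
    for j in range(kp):
        out[N + j] -= ref


@njit(cache=True, nogil=True)
def _chol_solve(S, rhs, sol):
    """Cholesky solve of a small SPD system; returns False on failure."""
    m = S.shape[0]
    L = np.zeros((m, m))
    for j in range(m):
        d = S[j, j]
        for t in range(j):
            d -= L[j, t] * L[j, t]
        if d <= 0.0:
            return False
        L[j, j] = np.sqrt(d)
        for i in range(j + 1, m):
            v = S[i, j]
            for t in range(j):
                v -= L[i, t] * L[j, t]
            L[i, j] = v / L[j, j]
    # forward then backward substitution
    for i in range(m):
        v = rhs[i]
        for t in range(i):
            v -= L[i, t] * sol[t]
        sol[i] = v / L[i, i]
    for i in range(m - 1, -1, -1):
        v = sol[i]
        for t in range(i + 1, m):
            v -= L[t, i] * sol[t]
        sol[i] = v / L[i, i]
    return True


@njit(cache=True, nogil=True)
def _solve_normal(q, r, si, pi, N, kp, out, ridge):
    """Solve (X' diag(q) X) out = r via a Schur complement on probes."""
    n = si.shape[0]
    Ds = np.zeros(N)
    G = np.zeros((N, kp))  # per-(sample, non-ref probe) q sums
    R = np.zeros(N)  # per-sample q sum over reference-probe rows
    Dp = np.zeros(kp)
    qref = 0.0
    qtot = 0.0
    for i in range(n):
        qi = q[i]
        qtot += qi
        Ds[si[i]] += qi
        if kp > 0:
            if pi[i] < kp:
                G[si[i], pi[i]] += qi
                Dp[pi[i]] += qi
            else:
                R[si[i]] += qi
                qref += qi
    floor = 1e-12 * (qtot / n + 1e-300)
    for s_ in range(N):
        if Ds[s_] < floor:
            Ds[s_] = floor
    if kp == 0:
        for s_ in range(N):
            out[s_] = r[s_] / Ds[s_]
        return True
    # Msp[s, j] = G[s, j] - R[s];  Mpp = diag(Dp) + qref * ones
    S = np.empty((kp, kp))
    for j in range(kp):
        for l in range(kp):
            S[j, l] = qref
        S[j, j] += Dp[j]
    rhs_p = np.empty(kp)
    for j in range(kp):
        rhs_p[j] = r[N + j]
    for s_ in range(N):
        inv = 1.0 / Ds[s_]
        for j in range(kp):
            msj = G[s_, j] - R[s_]
            rhs_p[j] -= msj * r[s_] * inv
            for l in range(kp):
                S[j, l] -= msj * (G[s_, l] - R[s_]) * inv
    # ridge keeps the factorisation alive near convergence / at degeneracy
    dmax = 0.0
    for j in range(kp):
        if S[j, j] > dmax:
            dmax = S[j, j]
    if dmax <= 0.0:
        dmax = qtot / n + 1e-300
    for j in range(kp):
        S[j, j] += ridge * dmax
    up = np.empty(kp)
    if not _chol_solve(S, rhs_p, up):
        return False
    for j in range(kp):
        out[N + j] = up[j]
    for s_ in range(N):
        acc = r[s_]
        for j in range(kp):
            acc -= (G[s_, j] - R[s_]) * up[j]
        out[s_] = acc / Ds[s_]
    return True


@njit(cache=True, nogil=True)
def _solve_normal_robust(q, r, si, pi, N, kp, out):
    if _solve_normal(q, r, si, pi, N, kp, out, 1e-13):
        return True
    if _solve_normal(q, r, si, pi, N, kp, out, 1e-7):
        return True
    return _solve_normal(q, r, si, pi, N, kp, out, 1e-3)


@njit(cache=True, nogil=True)
def _fit_fn(si, pi, y, N, P, tau, max_iter, tol):
    """Frisch-Newton interior point on the structured design.

    Returns (beta, ok, iterations).  When the Newton system breaks down
    (near-degenerate optimum) the current iterate is accepted as long as
    the complementarity gap is already small; the objective is then
    accurate even though coefficients on a flat optimal face may carry
    a small residual wobble."""
    n = y.shape[0]
    kp = P - 1 if P > 1 else 0
    k = N + kp
    c = -y

    x = np.full(n, 1.0 - tau)
    s = np.full(n, tau)
    ones = np.ones(n)

    yd = np.zeros(k)
    rhs0 = np.empty(k)
    _atmul(c, si, pi, N, kp, rhs0)
    if not _solve_normal_robust(ones, rhs0, si, pi, N, kp, yd):
        return -yd, False, 0
    d = np.empty(n)
    _amul(yd, si, pi, N, kp, d)
    z = np.empty(n)
    w = np.empty(n)
    for i in range(n):
        di = c[i] - d[i]
        zi = di if di > 0.0 else 0.0
        z[i] = zi + 1e-6
        w[i] = z[i] - di

    dy = np.empty(k)
    dy_a = np.empty(k)
    dx = np.empty(n)
    dz = np.empty(n)
    dw = np.empty(n)
    r_vec = np.empty(n)
    qr_vec = np.empty(n)
    rhs = np.empty(k)
    xv = np.empty(n)
    q = np.empty(n)

    ok = False
    it = 0
    gap = np.inf
    loose = 1e-6
    for it in range(1, max_iter + 1):
        gap = 0.0
        obj = 0.0
        for i in range(n):
            gap += x[i] * z[i] + s[i] * w[i]
            obj += c[i] * x[i]
        if gap < tol * (1.0 + abs(obj)):
            ok = True
            break
        scale = 1.0 + abs(obj)
        for i in range(n):
            q[i] = 1.0 / (z[i] / x[i] + w[i] / s[i])

        # --- affine predictor ---
        for i in range(n):
            r_vec[i] = w[i] - z[i]
            qr_vec[i] = q[i] * r_vec[i]
        _atmul(qr_vec, si, pi, N, kp, rhs)
        for j in range(k):
            rhs[j] = -rhs[j]
        if not _solve_normal_robust(q, rhs, si, pi, N, kp, dy_a):
            return -yd, gap < loose * scale, it
        _amul(dy_a, si, pi, N, kp, xv)
        for i in range(n):
            dx[i] = q[i] * (xv[i] + r_vec[i])
            dz[i] = -z[i] - z[i] * dx[i] / x[i]
            dw[i] = -w[i] + w[i] * dx[i] / s[i]
        ap = 1.0
        ad = 1.0
        for i in range(n):
            if dx[i] < 0.0:
                a = -0.9995 * x[i] / dx[i]
                if a < ap:
                    ap = a
            elif dx[i] > 0.0:
                a = 0.9995 * s[i] / dx[i]
                if a < ap:
                    ap = a
            if dz[i] < 0.0:
                a = -0.9995 * z[i] / dz[i]
                if a < ad:
                    ad = a
            if dw[i] < 0.0:
                a = -0.9995 * w[i] / dw[i]
                if a < ad:
                    ad = a
        mu = gap / (2.0 * n)
        mu_aff = 0.0
        for i in range(n):
            mu_aff += (x[i] + ap * dx[i]) * (z[i] + ad * dz[i])
            mu_aff += (s[i] - ap * dx[i]) * (w[i] + ad * dw[i])
        mu_aff /= 2.0 * n
        sigma = (mu_aff / mu) ** 3 if mu > 0.0 else 0.1
        if sigma > 0.99:
            sigma = 0.99
        if sigma < 1e-8:
            sigma = 1e-8
        mut = sigma * mu

        # --- corrector; dx/dz/dw currently hold the affine direction ---
        for i in range(n):
            r_vec[i] = (mut - dx[i] * dz[i]) / x[i] - z[i] - (
                mut + dx[i] * dw[i]
            ) / s[i] + w[i]
            qr_vec[i] = q[i] * r_vec[i]
        _atmul(qr_vec, si, pi, N, kp, rhs)
        for j in range(k):
            rhs[j] = -rhs[j]
        if not _solve_normal_robust(q, rhs, si, pi, N, kp, dy):
            return -yd, gap < loose * scale, it
        _amul(dy, si, pi, N, kp, xv)
        for i in range(n):
            corr_z = (mut - dx[i] * dz[i]) / x[i]
            corr_w = (mut + dx[i] * dw[i]) / s[i]
            dxi = q[i] * (xv[i] + r_vec[i])
            dz[i] = corr_z - z[i] - z[i] * dxi / x[i]
            dw[i] = corr_w - w[i] + w[i] * dxi / s[i]
            dx[i] = dxi
        ap = 1.0
        ad = 1.0
        for i in range(n):
            if dx[i] < 0.0:
                a = -0.9995 * x[i] / dx[i]
                if a < ap:
                    ap = a
            elif dx[i] > 0.0:
                a = 0.9995 * s[i] / dx[i]
                if a < ap:
                    ap = a
            if dz[i] < 0.0:
                a = -0.9995 * z[i] / dz[i]
                if a < ad:
                    ad = a
            if dw[i] < 0.0:
                a = -0.9995 * w[i] / dw[i]
                if a < ad:
                    ad = a
        for i in range(n):
            x[i] += ap * dx[i]
            if x[i] < 1e-14:
                x[i] = 1e-14
            s[i] -= ap * dx[i]
            if s[i] < 1e-14:
                s[i] = 1e-14
            z[i] += ad * dz[i]
            if z[i] < 1e-14:
                z[i] = 1e-14
            w[i] += ad * dw[i]
            if w[i] < 1e-14:
                w[i] = 1e-14
        for j in range(k):
            yd[j] += ad * dy[j]

    if not ok:
        # max_iter exhausted: accept if effectively converged
        obj = 0.0
        gap = 0.0
        for i in range(n):
            gap += x[i] * z[i] + s[i] * w[i]
            obj += c[i] * x[i]
        ok = gap < loose * (1.0 + abs(obj))
    beta = np.empty(k)
    for j in range(k):
        beta[j] = -yd[j]
    return beta, ok, it


@njit(cache=True, nogil=True)
def _boot_fn(si, pi, y, N, P, tau, idx, out_eff, valid):
    """Refit on each resample of rows; store sample effects per replicate."""
    B, n = idx.shape
    sib = np.empty(n, np.int64)
    pib = np.empty(n, np.int64)
    yb = np.empty(n)
    scount = np.empty(N, np.int64)
    pcount = np.empty(P, np.int64)
    for b in range(B):
        for s_ in range(N):
            scount[s_] = 0
        for p_ in range(P):
            pcount[p_] = 0
        for t in range(n):
            i = idx[b, t]
            sib[t] = si[i]
            pib[t] = pi[i]
            yb[t] = y[i]
            scount[si[i]] += 1
            pcount[pi[i]] += 1
        ok = True
        for s_ in range(N):
            if scount[s_] == 0:
                ok = False
        nmiss = 0
        for p_ in range(P):
            if pcount[p_] == 0:
                nmiss += 1
        if nmiss > 1:
            ok = False
        if ok:
            beta, fok, _ = _fit_fn(sib, pib, yb, N, P, tau, 50, 1e-9)
            if fok:
                for s_ in range(N):
                    out_eff[b, s_] = beta[s_]
                valid[b] = True
                continue
        valid[b] = False


def fit_structured(sample_idx, probe_idx, y, n_samples, n_probes, tau,
                   max_iter=60, tol=1e-10):
    """Fit the two-way quantile-regression layout; returns (beta, ok, iters).

    ``beta`` stacks the ``n_samples`` sample effects followed by the
    ``n_probes - 1`` probe contrast coefficients.
    """
    si = np.ascontiguousarray(sample_idx, dtype=np.int64)
    pi = np.ascontiguousarray(probe_idx, dtype=np.int64)
    yv = np.ascontiguousarray(y, dtype=np.float64)
    return _fit_fn(si, pi, yv, int(n_samples), int(n_probes), float(tau),
                   int(max_iter), float(tol))


def bootstrap_sample_effects(sample_idx, probe_idx, y, n_samples, n_probes,
                             tau, n_boot, rng):
    """xy-pair bootstrap of the sample effects on the structured design.

    Resamples design rows with replacement and refits; resamples that
    lose a sample (or are otherwise degenerate) are redrawn, up to
    ``10 * n_boot`` attempts.  Returns an ``(n_boot, n_samples)`` array
    of bootstrap sample-effect estimates.
    """
    si = np.ascontiguousarray(sample_idx, dtype=np.int64)
    pi = np.ascontiguousarray(probe_idx, dtype=np.int64)
    yv = np.ascontiguousarray(y, dtype=np.float64)
    n = yv.shape[0]
    N = int(n_samples)
    P = int(n_probes)
    collected = np.empty((n_boot, N))
    got = 0
    attempts = 0
    while got < n_boot:
        if attempts >= 10 * n_boot:
            raise RuntimeError(
                f"bootstrap failed: {attempts} resampling attempts produced "
                f"only {got}/{n_boot} valid replicates"
            )
        need = n_boot - got
        draw = min(need, 10 * n_boot - attempts)
        idx = rng.integers(0, n, size=(draw, n)).astype(np.int64)
        out_eff = np.empty((draw, N))
        valid = np.zeros(draw, dtype=np.bool_)
        _boot_fn(si, pi, yv, N, P, float(tau), idx, out_eff, valid)
        nv = int(valid.sum())
        if nv:
            collected[got:got + nv] = out_eff[valid]
            got += nv
        attempts += draw
    return collected
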