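"""Exact Gaussian-process marginal likelihood for the trajectory models.

All trajectory models in this package are GPs with Gaussian observation
noise, so the marginal likelihood is available in closed form (it equals the
optimal ELBO a variational treatment would reach) and is maximised directly
with analytic gradients. Constant mean functions are profiled out by
generalised least squares at every evaluation; the envelope theorem makes
the profiled gradient equal to the partial gradient at the GLS optimum.

Two-output ("coregionalized") models couple the F0 and F1 trajectories with
a covariance ``C[(a,i),(b,j)] = B[a,b] * k(|t_i - t_j|) + noise``, where B is
a 2x2 PSD coregionalization matrix (parameterised through its Cholesky
factor, so positive semi-definiteness is maintained throughout optimisation)
and k is a Matern-3/2 kernel on pseudotime. Rank-1 B with equal loadings
makes the two outputs share a single latent function (pure-cis structure); a
constant kernel removes all dynamics.

Observation noise per bin is ``exp(u_out) * mean_depth_out / depth_i`` —
inversely proportional to the allelic read support of the bin, with one free
log-scale per output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

_SQRT3 = np.sqrt(3.0)
_LOG2PI = np.log(2.0 * np.pi)

VARIANTS = ("M_const", "M_cis_only", "M_persistent_trans", "M_dynamic_trans")


def matern32(dist, lengthscale):
    s = _SQRT3 * dist / lengthscale
    return (1.0 + s) * np.exp(-s)


def matern32_dlogls(dist, lengthscale):
    """d k / d log(lengthscale) for the unit-variance Matern-3/2."""
    s = _SQRT3 * dist / lengthscale
    return s * s * np.exp(-s)


def rbf(dist, lengthscale):
    return np.exp(-0.5 * (dist / lengthscale) ** 2)


@dataclass
class GPFit:
    variant: str
    theta: np.ndarray
    objective: float          # maximised log marginal likelihood
    lengthscale: float
    B: np.ndarray             # 2x2 coregionalization matrix (or 1x1)
    noise_scale: np.ndarray   # per-output noise variance at average depth
    means: np.ndarray         # profiled constant mean(s)
    converged: bool = True


class _CoregProblem:
    """One gene's stacked two-output GP problem at fixed bin grid."""

    def __init__(self, t, y, out, depth, variant):
        out = np.asarray(out, dtype=int)
        order = np.argsort(out, kind="stable")  # contiguous output blocks
        self.t = np.asarray(t, dtype=float)[order]
        self.y = np.asarray(y, dtype=float)[order]
        self.out = out[order]
        self.variant = variant
        self.n = self.y.size
        self.n0 = int(np.sum(self.out == 0))
        self.dist = np.abs(self.t[:, None] - self.t[None, :])
        depth = np.asarray(depth, dtype=float)[order]
        # relative inverse depth per output: noise_i = exp(u_out) * mbar/depth_i
        self.inv_depth = np.empty(self.n)
        for a in (0, 1):
            sel = self.out == a
            if sel.any():
                self.inv_depth[sel] = np.mean(depth[sel]) / np.maximum(depth[sel], 1e-12)
        if variant == "M_cis_only" or variant == "M_const":
            self.X = np.ones((self.n, 1))
        else:
            self.X = np.column_stack([(self.out == 0).astype(float),
                                      (self.out == 1).astype(float)])

    # --- parameter layout ---------------------------------------------------
    # M_const:            [b0, u0, u1]
    # M_cis_only:         [log_ls, b0, u0, u1]
    # M_persistent_trans: [log_ls, b0, u0, u1]
    # M_dynamic_trans:    [log_ls, b0, b1, b2, u0, u1]   L = [[e^b0,0],[b1,e^b2]]

    def n_params(self):
        return {"M_const": 3, "M_cis_only": 4,
                "M_persistent_trans": 4, "M_dynamic_trans": 6}[self.variant]

    def bounds(self):
        ls = (np.log(1e-3), np.log(1e3))
        amp = (-15.0, 5.0)
        off = (-20.0, 20.0)
        u = (-30.0, 5.0)
        v = self.variant
        if v == "M_const":
            return [amp, u, u]
        if v in ("M_cis_only", "M_persistent_trans"):
            return [ls, amp, u, u]
        return [ls, amp, off, amp, u, u]

    def unpack(self, theta):
        v = self.variant
        if v == "M_const":
            log_ls, b = None, theta[:1]
            u = theta[1:3]
        elif v in ("M_cis_only", "M_persistent_trans"):
            log_ls, b = theta[0], theta[1:2]
            u = theta[2:4]
        else:
            log_ls, b = theta[0], theta[1:4]
            u = theta[4:6]
        return log_ls, b, u

    def _B_and_grads(self, b):
        if self.variant == "M_dynamic_trans":
            L = np.array([[np.exp(b[0]), 0.0], [b[1], np.exp(b[2])]])
            B = L @ L.T
            dLs = [np.array([[L[0, 0], 0.0], [0.0, 0.0]]),
                   np.array([[0.0, 0.0], [1.0, 0.0]]),
                   np.array([[0.0, 0.0], [0.0, L[1, 1]]])]
            dBs = [dL @ L.T + L @ dL.T for dL in dLs]
            return B, dBs
        amp = np.exp(2.0 * b[0])
        B = amp * np.ones((2, 2))
        return B, [2.0 * B]

    def _scale_blocks(self, M, B):
        """In-place multiply M's output blocks by the entries of B."""
        n0 = self.n0
        M[:n0, :n0] *= B[0, 0]
        M[:n0, n0:] *= B[0, 1]
        M[n0:, :n0] *= B[1, 0]
        M[n0:, n0:] *= B[1, 1]
        return M

    def _block_quadforms(self, M, alpha):
        """q[a,b] = alpha_a . M_ab . alpha_b for the 2x2 output blocks."""
        n0 = self.n0
        v0 = M[:, :n0] @ alpha[:n0]
        v1 = M[:, n0:] @ alpha[n0:]
        return np.array([
            [alpha[:n0] @ v0[:n0], alpha[:n0] @ v1[:n0]],
            [alpha[n0:] @ v0[n0:], alpha[n0:] @ v1[n0:]],
        ])

    def _block_sums(self, M):
        n0 = self.n0
        return np.array([
            [M[:n0, :n0].sum(), M[:n0, n0:].sum()],
            [M[n0:, :n0].sum(), M[n0:, n0:].sum()],
        ])

    def neg_loglik_grad(self, theta):
        from scipy.linalg.lapack import dpotrf, dpotri

        log_ls, b, u = self.unpack(theta)
        B, dBs = self._B_and_grads(b)
        if self.variant == "M_const":
            K = np.ones((self.n, self.n))
            dK = None
        else:
            # shared exponential for the kernel and its lengthscale derivative
            s = (_SQRT3 / np.exp(log_ls)) * self.dist
            es = np.exp(-s)
            K = (1.0 + s) * es
            dK = s * s * es
        noise = np.where(self.out == 0, np.exp(u[0]), np.exp(u[1])) * self.inv_depth
        C = self._scale_blocks(K.copy(), B)
        C[np.diag_indices(self.n)] += noise + 1e-8
        if not np.all(np.isfinite(C)):
            return 1e10, np.zeros_like(theta)
        L, info = dpotrf(C, lower=1)
        if info != 0:
            return 1e10, np.zeros_like(theta)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        Ci, info = dpotri(L, lower=1)
        if info != 0:
            return 1e10, np.zeros_like(theta)
        d = Ci.diagonal().copy()
        Ci = Ci + Ci.T
        np.fill_diagonal(Ci, d)
        CiX = Ci @ self.X
        A = self.X.T @ CiX
        m = np.linalg.solve(A, CiX.T @ self.y)
        r = self.y - self.X @ m
        alpha = Ci @ r
        ll = -0.5 * float(r @ alpha) - 0.5 * logdet - 0.5 * self.n * _LOG2PI

        grads = np.zeros_like(theta)
        idx = 0
        if dK is not None:
            q = self._block_quadforms(dK, alpha)
            tr = self._block_sums(Ci * dK)
            grads[idx] = float(np.sum(B * (0.5 * q - 0.5 * tr)))
            idx += 1
        qK = self._block_quadforms(K, alpha)
        trK = self._block_sums(Ci * K)
        for dB in dBs:
            grads[idx] = float(np.sum(dB * (0.5 * qK - 0.5 * trK)))
            idx += 1
        diag_ci = np.diag(Ci)
        for a in (0, 1):
            sel = self.out == a
            grads[idx] = 0.5 * float(np.sum((alpha[sel] ** 2 - diag_ci[sel]) * noise[sel]))
            idx += 1
        return -ll, -grads

    def loglik(self, theta):
        return -self.neg_loglik_grad(theta)[0]

    def gls_means(self, theta):
        log_ls, b, u = self.unpack(theta)
        B, _ = self._B_and_grads(b)
        Bix = B[self.out[:, None], self.out[None, :]]
        if self.variant == "M_const":
            K = np.ones((self.n, self.n))
        else:
            K = matern32(self.dist, np.exp(log_ls))
        noise = np.where(self.out == 0, np.exp(u[0]), np.exp(u[1])) * self.inv_depth
        C = Bix * K
        C[np.diag_indices(self.n)] += noise + 1e-8
        cf = cho_factor(C, lower=True)
        CiX = cho_solve(cf, self.X)
        A = self.X.T @ CiX
        return np.linalg.solve(A, CiX.T @ self.y)


def _default_theta(problem: _CoregProblem):
    y = problem.y
    var_y = max(float(np.var(y)), 1e-6)
    log_sig = 0.5 * np.log(0.5 * var_y)
    log_noise = np.log(0.5 * var_y + 1e-8)
    t_range = max(problem.t.max() - problem.t.min(), 1e-6)
    log_ls = np.log(0.25 * t_range)
    v = problem.variant
    if v == "M_const":
        return np.array([log_sig, log_noise, log_noise])
    if v in ("M_cis_only", "M_persistent_trans"):
        return np.array([log_ls, log_sig, log_noise, log_noise])
    return np.array([log_ls, log_sig, 0.5 * np.exp(log_sig), log_sig - 4.0,
                     log_noise, log_noise])


def embed_warm_start(variant, warm: GPFit):
    """Map a simpler fitted variant's parameters into a richer variant."""
    if warm is None:
        return None
    log_ls = np.log(max(warm.lengthscale, 1e-6))
    u = np.log(np.maximum(warm.noise_scale, 1e-10))
    if variant in ("M_cis_only", "M_persistent_trans"):
        amp = max(float(warm.B[0, 0]), 1e-10)
        return np.array([log_ls, 0.5 * np.log(amp), u[0], u[1]])
    if variant == "M_dynamic_trans":
        # rank-1 equal-loading B = a^2 * ones -> L ~ [[a,0],[a,eps]]
        a = np.sqrt(max(float(warm.B[0, 0]), 1e-10))
        return np.array([log_ls, np.log(a), a, np.log(a) - 6.0, u[0], u[1]])
    return None


def fit_variant(t, y, out, depth, variant, warm=None, n_restarts=1, seed=0,
                maxiter=150) -> GPFit:
    """Maximise the exact log marginal likelihood of one model variant.

    ``warm`` is an already-fitted simpler variant whose optimum is embedded
    as an extra initialisation, which guarantees the nested-model objective
    ordering up to optimiser tolerance. ``n_restarts`` adds jittered
    restarts (seeded) beyond the deterministic initialisation.
    """
    problem = _CoregProblem(t, y, out, depth, variant)
    theta0 = _default_theta(problem)
    warm_theta = embed_warm_start(variant, warm)
    # the embedded warm start sits at (or above) the simpler model's optimum,
    # so it both speeds up convergence and guarantees the nested objective
    # ordering; the cold default is used when no warm start exists
    inits = [warm_theta] if warm_theta is not None else [theta0]
    rng = np.random.default_rng(seed)
    for _ in range(max(n_restarts - 1, 0)):
        inits.append(theta0 + rng.normal(0.0, 0.5, size=theta0.size))

    best = None
    converged = False
    for x0 in inits:
        bounds = problem.bounds()
        x0 = np.array([np.clip(x, lo, hi) for x, (lo, hi) in zip(x0, bounds)])
        res = optimize.minimize(
            problem.neg_loglik_grad, x0, jac=True, method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-4},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success) or converged
    log_ls, b, u = problem.unpack(best.x)
    B, _ = problem._B_and_grads(b)
    fit = GPFit(
        variant=variant,
        theta=best.x,
        objective=-float(best.fun),
        lengthscale=float(np.exp(log_ls)) if log_ls is not None else np.inf,
        B=B,
        noise_scale=np.exp(u),
        means=problem.gls_means(best.x),
        converged=converged,
    )
    return fit


# ---------------------------------------------------------------------------
# generic single-output GP regression (used for latent allelic trajectories)


def gp_log_marginal(C, y, X=None):
    """Exact log N(y; X m_gls, C) with the constant mean profiled out.

    Dense closed form; independent callers use this as the reference
    objective for any Gaussian-noise GP in the package.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    cf = cho_factor(C, lower=True)
    if X is None:
        X = np.ones((n, 1))
    CiX = cho_solve(cf, X)
    A = X.T @ CiX
    m = np.linalg.solve(A, CiX.T @ y)
    r = y - X @ m
    alpha = cho_solve(cf, r)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return -0.5 * float(r @ alpha) - 0.5 * logdet - 0.5 * n * _LOG2PI


def gp_regression_rbf(t, y, noise_var, grid, lengthscale=None, signal_var=None,
                      optimize_hypers=True):
    """Weighted RBF-kernel GP regression with posterior mean/sd on a grid.

    noise_var : per-observation Gaussian noise variances (typically
        inversely proportional to allelic depth).
    Hyperparameters (lengthscale, signal variance, noise scale multiplier)
    are fitted by marginal likelihood unless given; on optimiser failure the
    median-heuristic lengthscale is used as a fallback.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    noise_var = np.maximum(np.asarray(noise_var, dtype=float), 1e-10)
    dist = np.abs(t[:, None] - t[None, :])
    med_ls = max(np.median(dist), 1e-3)
    var_y = max(float(np.var(y)), 1e-8)

    def build(theta):
        ls, sig, nsc = np.exp(np.clip(theta, -25.0, 25.0))
        C = sig * rbf(dist, ls)
        C[np.diag_indices(t.size)] += nsc * noise_var + 1e-10
        return C, ls, sig, nsc

    if lengthscale is not None and signal_var is not None:
        theta = np.log([lengthscale, signal_var, 1.0])
    elif optimize_hypers:
        def nll(theta):
            try:
                C, *_ = build(theta)
                return -gp_log_marginal(C, y)
            except np.linalg.LinAlgError:
                return 1e10
        x0 = np.log([med_ls, var_y, 1.0])
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200})
        theta = res.x if np.isfinite(res.fun) else x0
    else:
        theta = np.log([med_ls, var_y, 1.0])

    C, ls, sig, nsc = build(theta)
    cf = cho_factor(C, lower=True)
    ones = np.ones((t.size, 1))
    CiX = cho_solve(cf, ones)
    m = float((CiX[:, 0] @ y) / CiX.sum())
    alpha = cho_solve(cf, y - m)
    Ks = sig * rbf(np.abs(np.asarray(grid)[:, None] - t[None, :]), ls)
    mean = m + Ks @ alpha
    V = cho_solve(cf, Ks.T)
    var = sig - np.sum(Ks * V.T, axis=1)
    sd = np.sqrt(np.maximum(var, 1e-12))
    return mean, sd, {"lengthscale": ls, "signal_var": sig, "noise_scale": nsc, "mean": m}
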