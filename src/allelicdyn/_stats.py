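"""Shared statistical primitives.

Log-likelihoods for the two count distributions the pipeline is built on —
the negative binomial (per-allele totals across replicate libraries, mean/
dispersion parameterisation ``var = mu + phi * mu**2``) and the beta-binomial
(allelic counts, rate/correlation parameterisation where ``rho`` is the
intra-class correlation, ``var = n p (1-p) (1 + (n-1) rho)``) — together with
their per-gene maximum-likelihood estimators and the tail probability of a
weighted sum of chi-square(1) variables used by the variance-component score
test.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import chi2

# dispersion bounds shared by all estimators
PHI_FLOOR = 1e-8
PHI_CAP = 10.0
RHO_FLOOR = 1e-8
RHO_CAP = 0.99

_EPS = 1e-12


# ---------------------------------------------------------------------------
# log-pmfs


def nb_logpmf(k, mu, phi):
    """Negative-binomial log-pmf with mean ``mu`` and dispersion ``phi``.

    ``var = mu + phi mu^2``; ``phi -> 0`` recovers the Poisson limit, which is
    used directly below a small threshold for numerical stability.
    """
    k = np.asarray(k, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _EPS)
    phi = float(phi)
    if phi < 1e-10:
        return k * np.log(mu) - mu - gammaln(k + 1.0)
    r = 1.0 / phi
    return (
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1.0)
        + r * np.log(r / (r + mu))
        + k * np.log(mu / (r + mu))
    )


def bb_logpmf(k, n, p, rho):
    """Beta-binomial log-pmf with success rate ``p`` and correlation ``rho``.

    ``rho -> 0`` recovers the binomial, evaluated directly below a small
    threshold.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.clip(p, _EPS, 1.0 - _EPS)
    rho = float(rho)
    binom_coef = gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
    if rho < 1e-10:
        return binom_coef + k * np.log(p) + (n - k) * np.log1p(-p)
    s = (1.0 - rho) / rho  # concentration
    a = p * s
    b = (1.0 - p) * s
    return (
        binom_coef
        + gammaln(k + a)
        + gammaln(n - k + b)
        - gammaln(n + s)
        + gammaln(s)
        - gammaln(a)
        - gammaln(b)
    )


# ---------------------------------------------------------------------------
# maximum-likelihood estimators


def bb_loglik(k, n, p, rho):
    return float(np.sum(bb_logpmf(k, n, p, rho)))


def bb_mle(k, n, fix_p=None, fix_rho=None):
    """Beta-binomial MLE over observations ``(k, n)``.

    Returns ``(p_hat, rho_hat, loglik)``. Either parameter may be held fixed.
    rho is bounded to [RHO_FLOOR, RHO_CAP].
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    keep = n > 0
    k, n = k[keep], n[keep]
    if k.size == 0:
        raise ValueError("beta-binomial MLE requires at least one observation with n > 0")

    p0 = float(np.clip(k.sum() / n.sum(), 1e-4, 1 - 1e-4))

    if fix_p is not None and fix_rho is not None:
        return float(fix_p), float(fix_rho), bb_loglik(k, n, fix_p, fix_rho)

    if fix_rho is not None:
        res = optimize.minimize_scalar(
            lambda lp: -bb_loglik(k, n, 1.0 / (1.0 + np.exp(-lp)), fix_rho),
            bounds=(-12.0, 12.0),
            method="bounded",
            options={"xatol": 1e-8},
        )
        p = 1.0 / (1.0 + np.exp(-res.x))
        return float(p), float(fix_rho), -float(res.fun)

    if fix_p is not None:
        res = optimize.minimize_scalar(
            lambda lr: -bb_loglik(k, n, fix_p, _expit_rho(lr)),
            bounds=(-20.0, 6.0),
            method="bounded",
            options={"xatol": 1e-8},
        )
        rho = _expit_rho(res.x)
        return float(fix_p), float(rho), bb_loglik(k, n, fix_p, rho)

    # free (p, rho): L-BFGS-B on (logit p, log concentration) with the
    # analytic digamma gradient; concentration s = (1 - rho) / rho
    from scipy.special import digamma

    def nll_grad(theta):
        p = 1.0 / (1.0 + np.exp(-theta[0]))
        s = np.exp(theta[1])
        a, b = p * s, (1.0 - p) * s
        ll = float(np.sum(
            gammaln(k + a) - gammaln(a) + gammaln(n - k + b) - gammaln(b)
            - gammaln(n + s) + gammaln(s)
        ))
        dla = float(np.sum(digamma(k + a) - digamma(a) - digamma(n + s) + digamma(s)))
        dlb = float(np.sum(digamma(n - k + b) - digamma(b) - digamma(n + s) + digamma(s)))
        g1 = (dla - dlb) * s * p * (1.0 - p)
        g2 = dla * a + dlb * b
        return -ll, -np.array([g1, g2])

    # bounds on log s keep rho within [RHO_FLOOR, RHO_CAP]
    ls_lo = np.log((1.0 - RHO_CAP) / RHO_CAP)
    ls_hi = np.log((1.0 - RHO_FLOOR) / RHO_FLOOR)
    x0 = np.array([np.log(p0 / (1 - p0)), np.clip(4.0, ls_lo, ls_hi)])
    res = optimize.minimize(nll_grad, x0, jac=True, method="L-BFGS-B",
                            bounds=[(-12.0, 12.0), (ls_lo, ls_hi)],
                            options={"maxiter": 200, "ftol": 1e-12})
    p = 1.0 / (1.0 + np.exp(-res.x[0]))
    rho = float(np.clip(1.0 / (1.0 + np.exp(res.x[1])), RHO_FLOOR, RHO_CAP))
    binom_coef = float(np.sum(gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)))
    return float(p), rho, -float(res.fun) + binom_coef


def _expit_rho(x):
    return np.clip(1.0 / (1.0 + np.exp(-x)), RHO_FLOOR, RHO_CAP)


def bb_rho_apl(k, n):
    """Adjusted-profile-likelihood estimate of the BB correlation rho.

    Profiles the rate p out at each rho and subtracts half the log observed
    information for p (Cox-Reid), correcting the downward bias of the plain
    rho MLE when p is estimated from few replicates.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    keep = n > 0
    k, n = k[keep], n[keep]
    if k.size < 2:
        raise ValueError("rho estimation requires >= 2 observations with n > 0")

    def neg_apl(lr):
        rho = _expit_rho(lr)
        p_hat, _, ll = bb_mle(k, n, fix_rho=rho)
        h = 1e-4
        d2 = (bb_loglik(k, n, min(p_hat + h, 1 - _EPS), rho)
              - 2.0 * ll + bb_loglik(k, n, max(p_hat - h, _EPS), rho)) / h**2
        return -(ll - 0.5 * np.log(max(-d2, _EPS)))

    res = optimize.minimize_scalar(neg_apl, bounds=(-20.0, 6.0), method="bounded",
                                   options={"xatol": 1e-6})
    return float(_expit_rho(res.x))


def nb_mle(counts, groups=None, exposure=None, cr_adjust=False):
    """NB MLE with a shared dispersion and (optionally) group-specific means.

    counts : 1-D array of nonnegative integers.
    groups : optional integer labels; a separate mean is fitted per group and
        the dispersion ``phi`` is shared.
    exposure : optional positive per-observation size factors; the mean of
        observation i is ``exposure_i * mu_group``.
    cr_adjust : maximise the Cox-Reid adjusted profile likelihood instead of
        the plain profile likelihood. The adjustment
        ``-0.5 log det(X^T W X)`` (W the NB working weights) corrects the
        downward bias of the dispersion MLE caused by estimating the group
        means — the estimator underlying edgeR's estimateDisp.

    Returns ``(means, phi, loglik)`` where means maps group label -> fitted
    mean (per unit exposure) and loglik is the unadjusted log-likelihood at
    the optimum. For fixed phi each group mean is estimated by the
    exposure-weighted ratio ``sum(k) / sum(exposure)`` (the exact MLE when
    exposures are equal, exact Poisson MLE otherwise).
    """
    counts = np.asarray(counts, dtype=float)
    if groups is None:
        groups = np.zeros(counts.size, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if counts.size < 2:
        raise ValueError("NB MLE requires at least two observations")
    if exposure is None:
        exposure = np.ones(counts.size)
    exposure = np.asarray(exposure, dtype=float)
    mu = {g: max(counts[groups == g].sum() / exposure[groups == g].sum(), _EPS)
          for g in labels}
    muvec = np.array([mu[g] for g in groups]) * exposure

    def nll_logphi(lphi):
        phi = np.exp(lphi)
        ll = float(np.sum(nb_logpmf(counts, muvec, phi)))
        if cr_adjust:
            w = muvec / (1.0 + phi * muvec)  # working weights
            for g in labels:
                ll -= 0.5 * np.log(max(w[groups == g].sum(), _EPS))
        return -ll

    res = optimize.minimize_scalar(
        nll_logphi, bounds=(np.log(PHI_FLOOR), np.log(PHI_CAP)),
        method="bounded", options={"xatol": 1e-8},
    )
    phi = float(np.clip(np.exp(res.x), PHI_FLOOR, PHI_CAP))
    loglik = float(np.sum(nb_logpmf(counts, muvec, phi)))
    return mu, phi, loglik


# ---------------------------------------------------------------------------
# weighted chi-square tail


def wchi2_sf(q, weights):
    """P(sum_i w_i Z_i^2 > q) for independent chi-square(1) variables Z_i^2.

    Evaluated by numerical inversion of the characteristic function (Imhof's
    integral); falls back to Satterthwaite moment matching if the integral
    misbehaves. Weights that are zero or negligible are dropped.
    """
    w = np.asarray(weights, dtype=float)
    wmax = np.abs(w).max(initial=0.0)
    if wmax <= 0:
        return 1.0
    w = w[np.abs(w) > 1e-7 * wmax]
    q = float(q)
    if q <= 0:
        return 1.0
    # rescale so the largest weight is 1 (distribution of Q/wmax)
    w = w / wmax
    q = q / wmax
    if w.size == 1:
        return float(chi2.sf(q / w[0], 1))

    p = _imhof_sf(q, w)
    if p is None:
        return max(_satterthwaite_sf(q, w), 1e-300)
    if p < 1e-8:
        # below the absolute precision of the inversion; use the
        # moment-matched tail for a smooth (approximate) tiny p-value
        return max(_satterthwaite_sf(q, w), 1e-300)
    return float(min(p, 1.0))


def _imhof_sf(q, w, points_per_period=32, chunk=4096, max_chunks=96):
    """Gil-Pelaez / Imhof inversion by vectorised midpoint quadrature.

    The step resolves both the q-driven oscillation (period 4 pi / q) and
    the arctan phase scale of the weights (order one after rescaling).
    Integration stops once the integrand envelope
    ``1 / (u prod(1 + w^2 u^2)^{1/4})`` certifies that the remaining tail —
    bounded by envelope times one oscillation period (cancellation) or by
    the direct envelope integral, whichever is smaller — is below the
    precision target. The target is 1e-9 in the upper tail (small p, where
    relative precision matters) and 1e-6 otherwise. Returns None if the
    budget is exhausted before the bound is met.
    """
    m = w.size
    period = 4.0 * np.pi / max(q, 1e-3)
    step = min(period, 2.0 * np.pi) / points_per_period
    tol = 1e-9 if q > np.sum(w) else 1e-6
    total = 0.0
    u0 = 0.0
    for _ in range(max_chunks):
        u = u0 + step * (np.arange(chunk) + 0.5)
        uw = np.outer(u, w)
        theta = 0.5 * np.arctan(uw).sum(axis=1) - 0.5 * q * u
        rho = np.prod((1.0 + uw**2) ** 0.25, axis=1)
        total += float(np.sum(np.sin(theta) / (u * rho)) * step)
        u0 += chunk * step
        envelope = 1.0 / (u0 * np.prod(np.maximum(u0 * np.abs(w), 1.0) ** 0.5))
        remainder = envelope * min(period, 2.0 * u0 / m)
        if remainder < tol:
            return 0.5 + total / np.pi
    return None


def _satterthwaite_sf(q, w):
    s1, s2 = np.sum(w), np.sum(w**2)
    if s2 <= 0:
        return 1.0
    scale = s2 / s1
    df = s1**2 / s2
    return float(chi2.sf(q / scale, df))


def holm_bonferroni(pvalues):
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
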