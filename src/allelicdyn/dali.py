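"""Persistent and dynamic allelic imbalance along the trajectory.

Per gene, F1 allelic counts (k B6 reads out of n allelic reads per cell) are
modelled as beta-binomial. Two complementary tests:

* ``persistent_ai_test`` — likelihood-ratio test of a free global allelic
  rate against the balanced null p = 0.5 (chi-square(1) reference), i.e.
  imbalance irrespective of cell state.
* ``dynamic_ai_score_test`` — variance-component score test for a
  cell-state-dependent deviation of the allelic rate, with a cell-state
  kernel given by an inhomogeneous degree-3 polynomial on standardised
  pseudotime. The score statistic is a quadratic form in the null-model
  residuals and its null distribution is a weighted sum of chi-square(1)
  variables (exact tail by characteristic-function inversion, moment-matched
  fallback).

Genes significant in the score test are "dynamic"; genes significant only in
the LRT are "persistent". Latent allelic trajectories for dynamic genes are
estimated by depth-weighted RBF-kernel GP regression and clustered (Ward on
z-scored profiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import comb
from scipy.stats import chi2

from ._gp import gp_regression_rbf
from ._stats import bb_mle, holm_bonferroni, wchi2_sf

DEFAULT_GRID = np.linspace(0.0, 1.0, 100)
POLY_DEGREE = 3


@dataclass
class CisTestResult:
    gene: str
    p_persistent: float
    p_dynamic: float
    p_adj_persistent: float
    p_adj_dynamic: float
    ai_class: str       # dynamic / persistent_only / none
    p_hat: float
    rho_hat: float
    depth: float


@dataclass
class LatentTrajectory:
    gene: str
    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    @property
    def z(self):
        s = self.mean.std()
        if s < 1e-12:
            return np.zeros_like(self.mean)
        return (self.mean - self.mean.mean()) / s


# ---------------------------------------------------------------------------
# tests


def persistent_ai_test(k, n, rho):
    """Beta-binomial LRT of a free allelic rate against p = 0.5.

    Returns (p_value, p_hat). Dispersion rho is a plug-in from the null fit.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    keep = n > 0
    k, n = k[keep], n[keep]
    if k.size == 0:
        raise ValueError("persistent test requires positive allelic depth")
    p_hat, _, ll_free = bb_mle(k, n, fix_rho=rho)
    _, _, ll_null = bb_mle(k, n, fix_p=0.5, fix_rho=rho)
    stat = max(2.0 * (ll_free - ll_null), 0.0)
    return float(chi2.sf(stat, 1)), float(p_hat)


def _poly_features(t, degree=POLY_DEGREE):
    """Feature map of the inhomogeneous polynomial kernel (1 + t t')^degree
    on standardised pseudotime; Phi Phi^T reproduces the kernel exactly."""
    t = np.asarray(t, dtype=float)
    sd = t.std()
    if sd < 1e-12:
        raise ValueError("constant pseudotime: cell-state kernel is degenerate")
    z = (t - t.mean()) / sd
    cols = [np.sqrt(comb(degree, j)) * z**j for j in range(degree + 1)]
    return np.column_stack(cols)


def _score_test_components(k, n, t, rho, degree=POLY_DEGREE):
    """Score statistic and null mixture weights for the dynamic test.

    The working rate estimate solves the quasi-score equation with
    beta-binomial variance weights; residuals are projected accordingly so
    the estimation of the rate is accounted for in the null distribution.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    t = np.asarray(t, dtype=float)
    keep = n > 0
    k, n, t = k[keep], n[keep], t[keep]
    phi = _poly_features(t, degree)

    # quasi-score estimate of the global rate under BB variance
    p = np.clip(k.sum() / n.sum(), 1e-6, 1 - 1e-6)
    for _ in range(25):
        w = n * p * (1 - p) * (1 + (n - 1) * rho)
        a = n / np.maximum(w, 1e-12)
        p_new = np.clip((a * k).sum() / (a * n).sum(), 1e-6, 1 - 1e-6)
        if abs(p_new - p) < 1e-12:
            p = p_new
            break
        p = p_new
    w = n * p * (1 - p) * (1 + (n - 1) * rho)
    e = k - n * p
    a = n / np.maximum(w, 1e-12)
    c = a / (a * n).sum()

    # r = M e with M = I - n c^T (residual after rate estimation)
    r = e - n * (c @ e)
    u = phi.T @ r
    q = float(u @ u)

    # null weights: eigenvalues of Phi^T M W M^T Phi  (rank <= degree+1)
    A = phi.T - np.outer(phi.T @ n, c)           # Phi^T M
    S = (A * w[None, :]) @ A.T
    lam = np.linalg.eigvalsh(S)
    return q, lam, float(p)


def dynamic_ai_score_test(k, n, t, rho, degree=POLY_DEGREE):
    """P-value of the variance-component score test for dynamic AI."""
    q, lam, _ = _score_test_components(k, n, t, rho, degree)
    return wchi2_sf(q, lam)


def cis_test_genes(acm, cells, min_allelic_reads=1000, alpha=0.01,
                   genes=None) -> pd.DataFrame:
    """Run both cis tests over all (or the given) genes on F1 cells.

    Genes below ``min_allelic_reads`` total F1 allelic depth are skipped.
    Holm-Bonferroni adjustment is applied separately to each test across the
    tested genes; classes follow the partition dynamic / persistent_only /
    none at adjusted p < ``alpha``.
    """
    is_f1 = (cells["genotype"] == "F1").to_numpy()
    ok_pt = cells["pseudotime"].notna().to_numpy()
    sub = acm.subset_cells(is_f1 & ok_pt)
    t_all = cells.loc[is_f1 & ok_pt, "pseudotime"].to_numpy()
    b6 = sub.layer_b6.tocsr()
    cast = sub.layer_cast.tocsr()
    gene_idx = range(sub.shape[0]) if genes is None else sub.genes.get_indexer(pd.Index(genes))

    rows = []
    for g in gene_idx:
        kk = np.asarray(b6[g].todense()).ravel().astype(float)
        nn = kk + np.asarray(cast[g].todense()).ravel().astype(float)
        depth = nn.sum()
        if depth < min_allelic_reads:
            continue
        p_hat, rho_hat, _ = bb_mle(kk, nn)
        p_pers, _ = persistent_ai_test(kk, nn, rho_hat)
        p_dyn = dynamic_ai_score_test(kk, nn, t_all, rho_hat)
        rows.append({"gene": str(sub.genes[g]), "p_persistent": p_pers,
                     "p_dynamic": p_dyn, "p_hat": p_hat, "rho_hat": rho_hat,
                     "depth": depth})
    if not rows:
        return pd.DataFrame(columns=["gene", "p_persistent", "p_dynamic",
                                     "p_adj_persistent", "p_adj_dynamic",
                                     "ai_class", "p_hat", "rho_hat", "depth"])
    out = pd.DataFrame(rows)
    out["p_adj_persistent"] = holm_bonferroni(out["p_persistent"].to_numpy())
    out["p_adj_dynamic"] = holm_bonferroni(out["p_dynamic"].to_numpy())
    dynamic = out["p_adj_dynamic"] < alpha
    persistent_only = ~dynamic & (out["p_adj_persistent"] < alpha)
    out["ai_class"] = np.where(dynamic, "dynamic",
                               np.where(persistent_only, "persistent_only", "none"))
    return out


# ---------------------------------------------------------------------------
# latent trajectories


def fit_latent_trajectory(k, n, t, gene="gene", grid=None, max_points=800,
                          n_agg_bins=200) -> LatentTrajectory:
    """Depth-weighted GP regression of the allelic ratio on pseudotime.

    Observation noise for a cell with depth n is sigma^2 / n (binomial-style
    shrinkage), so deep cells anchor the fit. For datasets larger than
    ``max_points`` cells, observations are pooled into ``n_agg_bins``
    pseudotime bins first — under the 1/depth noise model pooling cells at
    nearly equal pseudotime is equivalent and keeps the cubic solve small.
    Posterior mean and sd are evaluated on a 100-point grid.
    """
    if grid is None:
        grid = DEFAULT_GRID
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    t = np.asarray(t, dtype=float)
    keep = n > 0
    k, n, t = k[keep], n[keep], t[keep]
    if k.size < 50:
        raise ValueError("latent trajectory requires >= 50 cells with allelic depth")
    if k.size > max_points:
        edges = np.linspace(t.min(), t.max() + 1e-9, n_agg_bins + 1)
        which = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_agg_bins - 1)
        ksum = np.bincount(which, weights=k, minlength=n_agg_bins)
        nsum = np.bincount(which, weights=n, minlength=n_agg_bins)
        tsum = np.bincount(which, weights=t * n, minlength=n_agg_bins)
        nz = nsum > 0
        k, n, t = ksum[nz], nsum[nz], tsum[nz] / nsum[nz]
    y = k / n
    mean, sd, _ = gp_regression_rbf(t, y, noise_var=1.0 / n, grid=grid)
    return LatentTrajectory(gene=str(gene), grid=np.asarray(grid), mean=mean, sd=sd)


def cluster_trajectories(trajectories, n_clusters: int = 7):
    """Ward hierarchical clustering of z-scored latent trajectories.

    Returns (labels, cluster_means) where labels are 0-based and
    cluster_means is a (n_clusters x grid) array of mean z-profiles.
    """
    trajs = list(trajectories)
    if n_clusters > len(trajs):
        raise ValueError("more clusters requested than trajectories")
    grid0 = trajs[0].grid
    for tr in trajs:
        if tr.grid.shape != grid0.shape or not np.allclose(tr.grid, grid0):
            raise ValueError("all trajectories must share one grid")
    Z = np.vstack([tr.z for tr in trajs])
    link = linkage(Z, method="ward", metric="euclidean")
    labels = fcluster(link, t=n_clusters, criterion="maxclust") - 1
    means = np.vstack([Z[labels == c].mean(axis=0) for c in range(labels.max() + 1)])
    return labels, means


# ---------------------------------------------------------------------------
# allelic imbalance across up- and down-regulation


def updown_ai_profile(acm, cells, genes=None, n_intervals=100, n_segments=5,
                      lowess_frac=0.3) -> pd.DataFrame:
    """AI across the rise and fall of expression for transiently expressed genes.

    Per gene, a local-regression smooth of log total counts versus pseudotime
    is evaluated on ``n_intervals`` points; genes whose smoothed expression
    peaks in the first or last interval (monotone profiles) are excluded.
    For retained genes the expressed trajectory (cells with nonzero total,
    ordered by pseudotime) is split into ``n_segments`` equal-cell quantile
    segments; pooled AI is reported per segment together with the segment of
    maximal |AI - 0.5|.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    is_f1 = (cells["genotype"] == "F1").to_numpy()
    ok_pt = cells["pseudotime"].notna().to_numpy()
    sub = acm.subset_cells(is_f1 & ok_pt)
    t = cells.loc[is_f1 & ok_pt, "pseudotime"].to_numpy()
    gene_idx = range(sub.shape[0]) if genes is None else sub.genes.get_indexer(pd.Index(genes))

    rows = []
    for g in gene_idx:
        tot = np.asarray(sub.layer_total[g].todense()).ravel().astype(float)
        expressed = tot > 0
        if expressed.sum() < 5 * n_segments:
            continue
        te, ye = t[expressed], np.log1p(tot[expressed])
        grid = np.linspace(te.min(), te.max(), n_intervals)
        smooth = lowess(ye, te, frac=lowess_frac, xvals=grid)
        peak = int(np.argmax(smooth))
        included = 0 < peak < n_intervals - 1
        row = {"gene": str(sub.genes[g]), "included": included, "peak_interval": peak}
        if included:
            b6 = np.asarray(sub.layer_b6[g].todense()).ravel()[expressed]
            cast = np.asarray(sub.layer_cast[g].todense()).ravel()[expressed]
            order = np.argsort(te, kind="stable")
            seg_edges = np.array_split(order, n_segments)
            ais = []
            for s, idx in enumerate(seg_edges):
                depth = b6[idx].sum() + cast[idx].sum()
                ai = b6[idx].sum() / depth if depth > 0 else np.nan
                row[f"ai_seg{s + 1}"] = ai
                ais.append(ai)
            ais = np.asarray(ais, dtype=float)
            with np.errstate(invalid="ignore"):
                row["peak_ai_segment"] = int(np.nanargmax(np.abs(ais - 0.5))) + 1
        rows.append(row)
    return pd.DataFrame(rows)
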