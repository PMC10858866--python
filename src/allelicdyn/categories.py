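"""Regulatory-category assignment and differential allelic imbalance.

The F0/F1 decomposition: a cis-acting variant changes expression of the
allele it sits on, so it shifts both the parental (F0) expression ratio and
the allelic ratio inside F1 hybrids by the same amount; a trans-acting
difference affects both alleles in the shared F1 nucleus equally, so it
shifts the F0 ratio but leaves the F1 allelic ratio at 0.5. Per gene we fit
four models — parental per-sample totals as negative binomial, F1 allelic
counts as beta-binomial — that constrain the F0 log2 mean ratio tau and the
F1 B6-allele rate p:

    conserved   tau = 0,            p = 0.5
    cis         tau = logit2(p),    p free      (shared shift)
    trans       tau free,           p = 0.5
    cis+trans   tau free,           p free

Nuisance dispersions (NB phi, BB rho) are estimated once per gene under the
fullest model and held fixed, so BIC differences reflect only the regulatory
parameters (k = 1, 2, 2, 3 free parameters; N = number of F0 + F1 samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from scipy import optimize

from ._stats import (
    PHI_CAP, PHI_FLOOR, RHO_CAP, RHO_FLOOR,
    bb_logpmf, bb_mle, bb_rho_apl, holm_bonferroni, nb_logpmf, nb_mle,
)
from .ase import _afc

MODELS = ("conserved", "cis", "trans", "cis+trans")
MODEL_K = {"conserved": 1, "cis": 2, "trans": 2, "cis+trans": 3}


@dataclass
class CategoryFit:
    gene: str
    scope: str
    phi: float
    rho: float
    params: dict          # per model: {mu_b, mu_c, tau, p}
    loglik: dict          # per model
    bic: dict             # per model
    assigned_category: str
    delta_bic_vs_conserved: float  # BIC(conserved) - BIC(assigned); >= 0 unless conserved wins
    converged: bool = True

    @property
    def stringent_category(self):
        """The stringent classification: a gene leaves 'conserved' only with
        a BIC advantage of at least 4 over the conserved model."""
        if self.assigned_category == "unassigned":
            return "unassigned"
        if self.delta_bic_vs_conserved >= 4.0:
            return self.assigned_category
        return "conserved"

    def as_row(self):
        row = {"gene": self.gene, "scope": self.scope, "phi": self.phi, "rho": self.rho,
               "assigned_category": self.assigned_category,
               "stringent_category": self.stringent_category,
               "delta_bic_vs_conserved": self.delta_bic_vs_conserved}
        for m in MODELS:
            row[f"bic_{m.replace('+', '_')}"] = self.bic[m]
        return row


def _logit2(p):
    return np.log2(p / (1.0 - p))


def estimate_dispersions(f0_counts, f0_genotype, f1_k, f1_n, f0_size_factors=None):
    """Per-gene nuisance dispersions under the fullest (cis+trans) model.

    f0_counts : (genes x F0 samples) allelic totals
    f0_genotype : length-n_samples labels ("F0_B6" / "F0_CAST")
    f1_k, f1_n : (genes x F1 samples) B6 counts and allelic totals
    f0_size_factors : optional per-F0-sample library-size factors entering
        the NB means as exposures

    Returns (phi, rho) arrays: phi by Cox-Reid adjusted NB profile
    likelihood with genotype-specific means, rho by adjusted profile
    likelihood with a free rate — both corrections for the downward bias of
    plain MLE at few replicates. phi in [1e-8, 10], rho in [1e-8, 0.99].
    """
    f0_counts = np.atleast_2d(np.asarray(f0_counts, dtype=float))
    f1_k = np.atleast_2d(np.asarray(f1_k, dtype=float))
    f1_n = np.atleast_2d(np.asarray(f1_n, dtype=float))
    geno = np.asarray(f0_genotype)
    for label in np.unique(geno):
        if np.sum(geno == label) < 2:
            raise ValueError("dispersion estimation requires >= 2 replicates per genotype")
    if f1_k.shape[1] < 2:
        raise ValueError("dispersion estimation requires >= 2 F1 samples")
    groups = (geno == geno[0]).astype(int)
    n_genes = f0_counts.shape[0]
    phi = np.empty(n_genes)
    rho = np.empty(n_genes)
    for g in range(n_genes):
        _, phi[g], _ = nb_mle(f0_counts[g], groups, exposure=f0_size_factors,
                              cr_adjust=True)
        rho[g] = bb_rho_apl(f1_k[g], f1_n[g])
    return np.clip(phi, PHI_FLOOR, PHI_CAP), np.clip(rho, RHO_FLOOR, RHO_CAP)


def fit_category_models(f0_b6_counts, f0_cast_counts, f1_k, f1_n,
                        phi=None, rho=None, gene="gene", scope="all",
                        f0_b6_sf=None, f0_cast_sf=None) -> CategoryFit:
    """Fit the four constrained models for one gene and assign by BIC.

    f0_b6_counts / f0_cast_counts : per-sample allelic totals of the two
        parental strains; f1_k, f1_n : per-F1-sample (B6 count, allelic total).
    phi / rho : optional precomputed dispersions; estimated under the fullest
        model (with bias adjustment) when omitted.
    f0_b6_sf / f0_cast_sf : optional library-size factors; the NB mean of
        sample j is ``sf_j * mu`` so that tau compares depth-normalised
        expression. Defaults to 1 (no correction).
    """
    xb = np.asarray(f0_b6_counts, dtype=float)
    xc = np.asarray(f0_cast_counts, dtype=float)
    k = np.asarray(f1_k, dtype=float)
    n = np.asarray(f1_n, dtype=float)
    sfb = np.ones(xb.size) if f0_b6_sf is None else np.asarray(f0_b6_sf, dtype=float)
    sfc = np.ones(xc.size) if f0_cast_sf is None else np.asarray(f0_cast_sf, dtype=float)
    if n.sum() <= 0:
        raise ValueError(f"gene {gene}: zero F1 allelic depth")
    if xb.size < 2 or xc.size < 2 or k.size < 2:
        raise ValueError("need >= 2 replicates per F0 genotype and >= 2 F1 samples")

    x_all = np.concatenate([xb, xc])
    sf_all = np.concatenate([sfb, sfc])
    groups = np.concatenate([np.zeros(xb.size, int), np.ones(xc.size, int)])
    if phi is None:
        _, phi, _ = nb_mle(x_all, groups, exposure=sf_all, cr_adjust=True)
    if rho is None:
        rho = bb_rho_apl(k, n)
    converged = True

    def nb_ll(mu_b, mu_c):
        return float(np.sum(nb_logpmf(xb, mu_b * sfb, phi))
                     + np.sum(nb_logpmf(xc, mu_c * sfc, phi)))

    def bb_ll(p):
        return float(np.sum(bb_logpmf(k, n, p, rho)))

    mean_b = max(xb.sum() / sfb.sum(), 1e-8)
    mean_c = max(xc.sum() / sfc.sum(), 1e-8)
    loglik, params = {}, {}

    # conserved: shared NB mean (exposure-weighted estimate), p = 0.5
    mu0 = max(x_all.sum() / sf_all.sum(), 1e-8)
    loglik["conserved"] = nb_ll(mu0, mu0) + bb_ll(0.5)
    params["conserved"] = {"mu_b": mu0, "mu_c": mu0, "tau": 0.0, "p": 0.5}

    # trans: free genotype means (MLE = group means), p = 0.5
    loglik["trans"] = nb_ll(mean_b, mean_c) + bb_ll(0.5)
    params["trans"] = {"mu_b": mean_b, "mu_c": mean_c,
                       "tau": float(np.log2(mean_b / mean_c)), "p": 0.5}

    # cis+trans: free means and free p (independent 1-d BB MLE)
    p_free, _, bb_free = bb_mle(k, n, fix_rho=rho)
    loglik["cis+trans"] = nb_ll(mean_b, mean_c) + bb_free
    params["cis+trans"] = {"mu_b": mean_b, "mu_c": mean_c,
                           "tau": float(np.log2(mean_b / mean_c)), "p": p_free}

    # cis: tau tied to logit2(p). For fixed p the scale mu has the same
    # exposure-weighted estimate as the other models (the allele shift acts
    # as an extra exposure 2^{+-tau/2}), so only p is profiled numerically.
    def nll_cis_logitp(lp):
        p = 1.0 / (1.0 + np.exp(-lp))
        a = np.exp2(0.5 * _logit2(np.clip(p, 1e-9, 1 - 1e-9)))
        mu = max((xb.sum() + xc.sum()) / (a * sfb.sum() + sfc.sum() / a), 1e-8)
        return -(nb_ll(mu * a, mu / a) + bb_ll(p))

    res = optimize.minimize_scalar(nll_cis_logitp, bounds=(-12.0, 12.0),
                                   method="bounded", options={"xatol": 1e-9})
    if not np.isfinite(res.fun):
        converged = False
        loglik["cis"] = -np.inf
        params["cis"] = {"mu_b": np.nan, "mu_c": np.nan, "tau": np.nan, "p": np.nan}
    else:
        p_cis = float(1.0 / (1.0 + np.exp(-res.x)))
        tau_cis = float(_logit2(np.clip(p_cis, 1e-9, 1 - 1e-9)))
        a = 2.0 ** (0.5 * tau_cis)
        mu = float(max((xb.sum() + xc.sum()) / (a * sfb.sum() + sfc.sum() / a), 1e-8))
        loglik["cis"] = -float(res.fun)
        params["cis"] = {"mu_b": mu * a, "mu_c": mu / a, "tau": tau_cis, "p": p_cis}

    n_obs = xb.size + xc.size + k.size
    bic = {m: -2.0 * loglik[m] + MODEL_K[m] * np.log(n_obs) for m in MODELS}
    if converged:
        assigned = min(MODELS, key=lambda m: bic[m])
    else:
        assigned = "unassigned"
    delta = bic["conserved"] - (bic[assigned] if assigned in bic else np.nan)
    return CategoryFit(gene, scope, float(phi), float(rho), params, loglik, bic,
                       assigned, float(delta), converged)


def pooled_dispersions(f0_b6, f0_cast, f1_k, f1_n, f0_b6_sf=None, f0_cast_sf=None):
    """Shared (phi, rho) maximising the summed adjusted profile likelihood.

    One NB dispersion and one BB correlation across all genes, each with a
    Cox-Reid-style correction for the per-gene mean/rate parameters. With
    hundreds of genes the plug-in noise of per-gene dispersion estimates
    disappears, which keeps the constrained-model likelihood-ratio geometry
    chi-square calibrated; gene-specific estimates remain available through
    :func:`estimate_dispersions`.
    """
    from scipy import optimize

    xb = np.atleast_2d(np.asarray(f0_b6, dtype=float))
    xc = np.atleast_2d(np.asarray(f0_cast, dtype=float))
    k = np.atleast_2d(np.asarray(f1_k, dtype=float))
    n = np.atleast_2d(np.asarray(f1_n, dtype=float))
    sfb = np.ones(xb.shape[1]) if f0_b6_sf is None else np.asarray(f0_b6_sf, float)
    sfc = np.ones(xc.shape[1]) if f0_cast_sf is None else np.asarray(f0_cast_sf, float)

    # NB: per-gene genotype means are exposure-weighted ratios (phi-free)
    mu_b = np.maximum(xb.sum(axis=1) / sfb.sum(), 1e-8)
    mu_c = np.maximum(xc.sum(axis=1) / sfc.sum(), 1e-8)
    muvec = np.concatenate([mu_b[:, None] * sfb[None, :],
                            mu_c[:, None] * sfc[None, :]], axis=1)
    x_all = np.concatenate([xb, xc], axis=1)
    n_b = sfb.size

    def neg_apl_phi(lphi):
        phi = float(np.exp(lphi))
        ll = float(np.sum(nb_logpmf(x_all, muvec, phi)))
        w = muvec / (1.0 + phi * muvec)
        ll -= 0.5 * float(np.sum(np.log(np.maximum(w[:, :n_b].sum(axis=1), 1e-12))))
        ll -= 0.5 * float(np.sum(np.log(np.maximum(w[:, n_b:].sum(axis=1), 1e-12))))
        return -ll

    res = optimize.minimize_scalar(neg_apl_phi, bounds=(np.log(PHI_FLOOR), np.log(PHI_CAP)),
                                   method="bounded", options={"xatol": 1e-8})
    phi = float(np.clip(np.exp(res.x), PHI_FLOOR, PHI_CAP))

    # BB: per-gene rates profiled by quasi-score iteration at each rho
    nsafe = np.maximum(n, 1e-12)

    def _p_hat(rho):
        p = np.clip(k.sum(axis=1) / np.maximum(n.sum(axis=1), 1e-12), 1e-6, 1 - 1e-6)
        for _ in range(4):
            w = nsafe * (p * (1 - p))[:, None] * (1.0 + (nsafe - 1.0) * rho)
            a = nsafe / np.maximum(w, 1e-12)
            p = np.clip((a * k).sum(axis=1) / np.maximum((a * n).sum(axis=1), 1e-12),
                        1e-6, 1 - 1e-6)
        return p

    def neg_apl_rho(lr):
        rho = float(np.clip(1.0 / (1.0 + np.exp(-lr)), RHO_FLOOR, RHO_CAP))
        p = _p_hat(rho)
        h = 1e-4
        ll0 = np.sum(bb_logpmf(k, n, p[:, None], rho), axis=1)
        llp = np.sum(bb_logpmf(k, n, np.minimum(p + h, 1 - 1e-9)[:, None], rho), axis=1)
        llm = np.sum(bb_logpmf(k, n, np.maximum(p - h, 1e-9)[:, None], rho), axis=1)
        d2 = (llp - 2 * ll0 + llm) / h**2
        return -(float(ll0.sum()) - 0.5 * float(np.sum(np.log(np.maximum(-d2, 1e-12)))))

    res = optimize.minimize_scalar(neg_apl_rho, bounds=(-20.0, 6.0), method="bounded",
                                   options={"xatol": 1e-6})
    rho = float(np.clip(1.0 / (1.0 + np.exp(-res.x)), RHO_FLOOR, RHO_CAP))
    return phi, rho


def f0_size_factors(f0_b6, f0_cast):
    """Library-size factors for the F0 samples from their allelic totals.

    Total allelic reads per sample across genes, scaled to mean 1 over all
    F0 samples (B6 and CAST jointly, so the two strains share one scale).
    Valid under the genome-wide assumption that most genes are not
    differentially expressed between the strains.
    """
    f0_b6 = np.atleast_2d(f0_b6)
    f0_cast = np.atleast_2d(f0_cast)
    totals = np.concatenate([f0_b6.sum(axis=0), f0_cast.sum(axis=0)]).astype(float)
    sf = totals / totals.mean()
    return sf[: f0_b6.shape[1]], sf[f0_b6.shape[1]:]


def categorize_genes(f0_b6, f0_cast, f1_k, f1_n, genes=None, scope="all",
                     phi=None, rho=None, size_factors=True,
                     dispersion="pooled") -> pd.DataFrame:
    """Vectorised driver: fit the four models for every gene (rows).

    With ``size_factors`` (default) the F0 means include library-size
    exposures computed from the summed allelic totals, so a depth imbalance
    between the parental libraries is not mistaken for a global
    trans-effect. ``dispersion`` selects the nuisance estimates when phi/rho
    are not supplied: "pooled" (default) shares one adjusted-profile (phi,
    rho) across the gene set, "per-gene" estimates them gene by gene.
    Returns one row per gene with BICs, assigned category and delta-BIC
    versus the conserved model.
    """
    f0_b6 = np.atleast_2d(f0_b6)
    f0_cast = np.atleast_2d(f0_cast)
    f1_k = np.atleast_2d(f1_k)
    f1_n = np.atleast_2d(f1_n)
    n_genes = f0_b6.shape[0]
    if genes is None:
        genes = [f"gene{i}" for i in range(n_genes)]
    if size_factors:
        sfb, sfc = f0_size_factors(f0_b6, f0_cast)
    else:
        sfb = sfc = None
    if phi is None and dispersion == "pooled" and n_genes > 1:
        phi_shared, rho_shared = pooled_dispersions(f0_b6, f0_cast, f1_k, f1_n,
                                                    sfb, sfc)
        phi = np.full(n_genes, phi_shared)
        if rho is None:
            rho = np.full(n_genes, rho_shared)
    rows = []
    for g in range(n_genes):
        rn = f1_n[g]
        if rn.sum() <= 0:
            continue
        fit = fit_category_models(
            f0_b6[g], f0_cast[g], f1_k[g], rn,
            phi=None if phi is None else phi[g],
            rho=None if rho is None else rho[g],
            gene=str(genes[g]), scope=scope,
            f0_b6_sf=sfb, f0_cast_sf=sfc,
        )
        rows.append(fit.as_row())
    return pd.DataFrame(rows)


def pseudobulk_tables(acm, cells, cell_mask=None):
    """Per-sample allelic pseudo-bulk for the category models.

    Returns a dict with F0 B6-sample totals, F0 CAST-sample totals and F1
    (k, n) pairs, each genes x samples, plus the sample labels. An optional
    boolean ``cell_mask`` restricts to a cell subset (e.g. one cell type).
    """
    mask = np.ones(len(cells), dtype=bool) if cell_mask is None else np.asarray(cell_mask)

    def _per_sample(layer, genotype):
        sel = mask & (cells["genotype"] == genotype).to_numpy()
        labels = pd.unique(cells.loc[sel, "sample"])
        out = np.zeros((acm.shape[0], len(labels)))
        samples = cells["sample"].to_numpy()
        for j, s in enumerate(labels):
            cols = np.flatnonzero(sel & (samples == s))
            out[:, j] = np.asarray(layer[:, cols].sum(axis=1)).ravel()
        return out, list(labels)

    f0_b6, b6_samples = _per_sample(acm.layer_b6, "F0_B6")
    f0_cast, cast_samples = _per_sample(acm.layer_cast, "F0_CAST")
    f1_k, f1_samples = _per_sample(acm.layer_b6, "F1")
    f1_cast, _ = _per_sample(acm.layer_cast, "F1")
    return {
        "f0_b6": f0_b6, "f0_cast": f0_cast,
        "f1_k": f1_k, "f1_n": f1_k + f1_cast,
        "b6_samples": b6_samples, "cast_samples": cast_samples,
        "f1_samples": f1_samples,
    }


# ---------------------------------------------------------------------------
# differential allelic imbalance between discrete cell types


@dataclass
class DifferentialAIResult:
    gene: str
    cell_type_pair: tuple
    afc_a: float
    afc_b: float
    delta_afc: float
    lrt: float
    df: int
    p: float
    p_adj: float = np.nan
    significant: bool = False
    separation_flag: bool = False


def differential_ai_glm(acm, cells, cell_type_pair, genes=None,
                        alpha: float = 0.1, min_delta_afc: float = 0.5) -> pd.DataFrame:
    """Binomial GLM test for cell-type differences in allelic imbalance.

    Per gene, each cell is one binomial observation (B6 count out of allelic
    total); the full model is ``logit(p) ~ intercept + cell_type + library``
    and is compared by likelihood-ratio test to the reduced model without the
    cell-type term (df = 1 for a pair). p-values are Holm-Bonferroni adjusted
    across tested genes; a gene is called significant when the adjusted p is
    below ``alpha`` AND the absolute difference in log2 aFC between the two
    cell types exceeds ``min_delta_afc``.
    """
    ct_a, ct_b = cell_type_pair
    sel = cells["cell_type"].isin(cell_type_pair).to_numpy()
    sub = acm.subset_cells(sel)
    meta = cells.loc[sel].reset_index(drop=True)
    for ct in cell_type_pair:
        libs = meta.loc[meta["cell_type"] == ct, "sample"].nunique()
        if libs < 2:
            raise ValueError(f"cell type '{ct}' present in fewer than 2 libraries")

    b6 = np.asarray(sub.layer_b6.todense(), dtype=float)
    cast = np.asarray(sub.layer_cast.todense(), dtype=float)
    ntot = b6 + cast
    is_a = (meta["cell_type"] == ct_a).to_numpy()
    lib_dummies = pd.get_dummies(meta["sample"], drop_first=True, dtype=float).to_numpy()

    gene_idx = range(sub.shape[0]) if genes is None else sub.genes.get_indexer(pd.Index(genes))
    results = []
    for g in gene_idx:
        use = ntot[g] > 0
        if use.sum() < 4 or len(np.unique(is_a[use])) < 2:
            continue
        kk, nn = b6[g, use], ntot[g, use]
        x_ct = is_a[use].astype(float)
        exog_full = np.column_stack([np.ones(use.sum()), x_ct, lib_dummies[use]])
        exog_red = np.column_stack([np.ones(use.sum()), lib_dummies[use]])
        endog = np.column_stack([kk, nn - kk])
        sep = (kk.sum() == 0) or (kk.sum() == nn.sum()) \
            or (kk[x_ct == 1].sum() in (0, nn[x_ct == 1].sum())) \
            or (kk[x_ct == 0].sum() in (0, nn[x_ct == 0].sum()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                full = sm.GLM(endog, exog_full, family=sm.families.Binomial()).fit(maxiter=100)
                red = sm.GLM(endog, exog_red, family=sm.families.Binomial()).fit(maxiter=100)
            except Exception:
                continue
        lrt = max(2.0 * (full.llf - red.llf), 0.0)
        from scipy.stats import chi2
        p = float(chi2.sf(lrt, 1))
        afc_a_val = float(_afc(np.array([kk[x_ct == 1].sum()]), np.array([(nn - kk)[x_ct == 1].sum()]))[0])
        afc_b_val = float(_afc(np.array([kk[x_ct == 0].sum()]), np.array([(nn - kk)[x_ct == 0].sum()]))[0])
        results.append(DifferentialAIResult(
            gene=str(sub.genes[g]), cell_type_pair=(ct_a, ct_b),
            afc_a=afc_a_val, afc_b=afc_b_val, delta_afc=afc_a_val - afc_b_val,
            lrt=float(lrt), df=1, p=p, separation_flag=bool(sep),
        ))
    if not results:
        return pd.DataFrame(columns=[f.name for f in DifferentialAIResult.__dataclass_fields__.values()])
    out = pd.DataFrame([r.__dict__ for r in results])
    out["p_adj"] = holm_bonferroni(out["p"].to_numpy())
    out["significant"] = (out["p_adj"] < alpha) & (out["delta_afc"].abs() > min_delta_afc)
    return out
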