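import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from allelicdyn import estimate_dispersions, fit_category_models
from allelicdyn.categories import (
    MODELS, categorize_genes, differential_ai_glm, pseudobulk_tables,
)
from allelicdyn._stats import bb_logpmf, nb_logpmf

from conftest import make_acm


def bb_logpmf_direct(k, n, p, rho):
    """Direct product-form beta-binomial pmf (independent oracle).

    P(k) = C(n,k) * prod_{j<k}(a+j) prod_{j<n-k}(b+j) / prod_{j<n}(a+b+j)
    """
    s = (1 - rho) / rho
    a, b = p * s, (1 - p) * s
    num = sum(np.log(a + j) for j in range(int(k)))
    num += sum(np.log(b + j) for j in range(int(n - k)))
    den = sum(np.log(a + b + j) for j in range(int(n)))
    coef = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return coef + num - den


def nb_logpmf_direct(k, mu, phi):
    """NB pmf as a gamma-Poisson product form (independent oracle)."""
    r = 1 / phi
    p = r / (r + mu)
    num = sum(np.log(r + j) for j in range(int(k)))
    return num - gammaln(k + 1) + r * np.log(p) + k * np.log(1 - p)


def test_likelihoods_match_direct_summation_oracles():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(1, 30))
        k = int(rng.integers(0, n + 1))
        p = rng.uniform(0.05, 0.95)
        rho = rng.uniform(0.005, 0.5)
        assert bb_logpmf(k, n, p, rho) == pytest.approx(
            bb_logpmf_direct(k, n, p, rho), abs=1e-8)
        mu = rng.uniform(0.5, 25)
        phi = rng.uniform(0.02, 2.0)
        assert nb_logpmf(k, mu, phi) == pytest.approx(
            nb_logpmf_direct(k, mu, phi), abs=1e-8)


class TestDispersionEstimation:
    def test_poisson_counts_give_vanishing_phi(self):
        rng = np.random.default_rng(1)
        f0 = rng.poisson(10_000, (20, 12)).astype(float)
        geno = np.array(["F0_B6"] * 6 + ["F0_CAST"] * 6)
        n = rng.poisson(5_000, (20, 6))
        k = rng.binomial(n, 0.5)
        phi, rho = estimate_dispersions(f0, geno, k, n)
        assert np.median(phi) <= 0.01
        assert np.median(rho) <= 0.01  # binomial allelic counts -> rho -> 0

    def test_phi_parameter_recovery(self):
        rng = np.random.default_rng(2)
        phi0 = 0.5
        n_genes = 500
        lam = rng.gamma(1 / phi0, phi0 * 1000, size=(n_genes, 12))
        f0 = rng.poisson(lam).astype(float)
        geno = np.array(["F0_B6"] * 6 + ["F0_CAST"] * 6)
        n = rng.poisson(1000, (n_genes, 6))
        k = rng.binomial(n, 0.5)
        phi, _ = estimate_dispersions(f0, geno, k, n)
        assert 0.3 <= np.median(phi) <= 0.7

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            estimate_dispersions(np.ones((3, 2)), ["F0_B6", "F0_CAST"],
                                 np.ones((3, 2)), np.ones((3, 2)))


class TestCategoryFits:
    def _gene(self, rng, c=0.0, delta=0.0, depth=3000, n_samples=6):
        mu = depth
        shift = 2.0 ** (0.5 * (c + delta))
        xb = rng.poisson(mu * shift, n_samples)
        xc = rng.poisson(mu / shift, n_samples)
        n = rng.poisson(depth, n_samples)
        p1 = 1 / (1 + 2.0 ** (-c))
        k = rng.binomial(n, p1)
        return xb, xc, k, n

    def test_deep_conserved_gene(self):
        rng = np.random.default_rng(3)
        fit = fit_category_models(*self._gene(rng))
        assert fit.assigned_category == "conserved"

    def test_pure_cis_gene_wins_with_strong_evidence(self):
        rng = np.random.default_rng(4)
        fit = fit_category_models(*self._gene(rng, c=1.0))
        assert fit.assigned_category == "cis"
        assert fit.delta_bic_vs_conserved >= 4
        assert fit.params["cis"]["p"] == pytest.approx(2 / 3, abs=0.05)
        assert fit.params["cis"]["tau"] == pytest.approx(1.0, abs=0.3)

    def test_pure_trans_gene(self):
        rng = np.random.default_rng(5)
        fit = fit_category_models(*self._gene(rng, delta=1.0))
        assert fit.assigned_category == "trans"
        assert fit.params["trans"]["tau"] == pytest.approx(1.0, abs=0.3)

    def test_cis_plus_trans_gene(self):
        rng = np.random.default_rng(6)
        # F0 ratio 2 log2 units, F1 allelic shift only 1 -> needs both terms
        fit = fit_category_models(*self._gene(rng, c=1.0, delta=1.0))
        assert fit.assigned_category == "cis+trans"

    def test_allele_relabelling_symmetry(self):
        rng = np.random.default_rng(7)
        xb, xc, k, n = self._gene(rng, c=1.0)
        fwd = fit_category_models(xb, xc, k, n)
        rev = fit_category_models(xc, xb, n - k, n)
        assert fwd.assigned_category == rev.assigned_category == "cis"
        assert rev.params["cis"]["tau"] == pytest.approx(
            -fwd.params["cis"]["tau"], abs=0.05)
        assert rev.params["cis"]["p"] == pytest.approx(
            1 - fwd.params["cis"]["p"], abs=0.01)

    def test_bic_counts_free_parameters(self):
        rng = np.random.default_rng(8)
        fit = fit_category_models(*self._gene(rng))
        n_obs = 6 + 6 + 6
        ks = {"conserved": 1, "cis": 2, "trans": 2, "cis+trans": 3}
        for m in MODELS:
            assert fit.bic[m] == pytest.approx(
                -2 * fit.loglik[m] + ks[m] * np.log(n_obs))

    def test_zero_f1_depth_is_an_error(self):
        with pytest.raises(ValueError, match="depth"):
            fit_category_models([10, 10], [10, 10], [0, 0], [0, 0])


class TestDifferentialAiGlm:
    def _dataset(self, rates_by_ct, n_genes=20, n_libs=4, cells_per_lib=100,
                 depth=10, seed=0, lib_shift=None):
        rng = np.random.default_rng(seed)
        cells, cts, libs = [], [], []
        for lib in range(n_libs):
            for j in range(cells_per_lib):
                cells.append(f"l{lib}c{j}")
                cts.append("A" if j < cells_per_lib // 2 else "B")
                libs.append(f"s{lib}")
        cts = np.array(cts)
        table = pd.DataFrame({"cell": cells, "sample": libs, "genotype": "F1",
                              "replicate": 1, "cell_type": cts, "pseudotime": 0.5})
        n = rng.poisson(depth, (n_genes, len(cells)))
        k = np.empty_like(n)
        for g in range(n_genes):
            p = np.where(cts == "A", rates_by_ct[0], rates_by_ct[1]).astype(float)
            if lib_shift is not None:
                shifted = np.isin(table["sample"], lib_shift)
                p = np.where(shifted, 0.75, p)
            k[g] = rng.binomial(n[g], p)
        return make_acm(k, n - k, cells=cells), table

    def test_power_and_effect_size(self):
        acm, cells = self._dataset((0.5, 0.75), n_genes=20, cells_per_lib=200)
        res = differential_ai_glm(acm, cells, ("A", "B"))
        assert res["significant"].mean() >= 0.9
        assert res["delta_afc"].abs().median() == pytest.approx(np.log2(3), abs=0.35)

    def test_library_confounded_shift_not_called(self):
        # allelic shift in two whole libraries, same in both cell types:
        # the library covariate absorbs it
        acm, cells = self._dataset((0.5, 0.5), n_genes=20, lib_shift=["s0", "s1"])
        res = differential_ai_glm(acm, cells, ("A", "B"))
        assert res["significant"].sum() == 0

    def test_single_library_cell_type_rejected(self):
        acm, cells = self._dataset((0.5, 0.5), n_genes=2, n_libs=1)
        with pytest.raises(ValueError, match="libraries"):
            differential_ai_glm(acm, cells, ("A", "B"))


def test_categorize_genes_on_simulated_pseudobulk(small_experiment):
    acm, cells, genes, truth = small_experiment
    pb = pseudobulk_tables(acm, cells)
    out = categorize_genes(pb["f0_b6"], pb["f0_cast"], pb["f1_k"], pb["f1_n"],
                           genes=acm.genes)
    assert len(out) == acm.shape[0]
    assert set(out["assigned_category"]) <= set(MODELS) | {"unassigned"}
    # strong-evidence genes should match the simulated truth most of the time
    merged = out.merge(truth.table[["gene", "category"]], on="gene")
    strong = merged[merged["delta_bic_vs_conserved"] >= 4]
    if len(strong) >= 5:
        assert (strong["assigned_category"] == strong["category"]).mean() > 0.6
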