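import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from allelicdyn import bin_trajectories, fit_gp_variant, trans_bayes_factors
from allelicdyn.transgp import BinnedTrajectoryPair, dynamic_de_test
from allelicdyn._gp import VARIANTS, _CoregProblem, matern32

from conftest import make_acm


def make_pair(y0, y1, depth=60.0, gene="g"):
    nb = y0.size
    t = (np.arange(nb) + 0.5) / nb
    d = np.full(nb, float(depth))
    return BinnedTrajectoryPair(gene, t, y0, y1, d, d,
                                np.ones(nb, bool), np.ones(nb, bool))


class TestBinning:
    def _experiment(self, depth_scale_by_sample, n_genes=30, cells_per_sample=300,
                    seed=0):
        rng = np.random.default_rng(seed)
        cells, names = [], []
        for geno in ("F0_B6", "F0_CAST", "F1"):
            for rep in (1, 2):
                s = f"{geno}_rep{rep}"
                for j in range(cells_per_sample):
                    names.append(f"{s}c{j}")
                    cells.append((f"{s}c{j}", s, geno, rep, "SC",
                                  rng.uniform(0, 1)))
        table = pd.DataFrame(cells, columns=["cell", "sample", "genotype",
                                             "replicate", "cell_type", "pseudotime"])
        scale = table["sample"].map(depth_scale_by_sample).fillna(1.0).to_numpy()
        n = rng.poisson(10 * scale, (n_genes, len(table)))
        b6 = np.zeros_like(n)
        cast = np.zeros_like(n)
        geno = table["genotype"].to_numpy()
        b6[:, geno == "F0_B6"] = n[:, geno == "F0_B6"]
        cast[:, geno == "F0_CAST"] = n[:, geno == "F0_CAST"]
        kk = rng.binomial(n[:, geno == "F1"], 0.5)
        b6[:, geno == "F1"] = kk
        cast[:, geno == "F1"] = n[:, geno == "F1"] - kk
        return make_acm(b6, cast, cells=names), table

    def test_equal_depth_conserved_genes_are_balanced(self):
        acm, cells = self._experiment({})
        pairs, centers = bin_trajectories(acm, cells, n_bins=20)
        y0 = np.vstack([p.y_f0 for p in pairs])
        assert abs(np.nanmean(y0) - 0.5) < 0.01
        assert centers.size == 20

    def test_depth_imbalance_removed_by_normalisation(self):
        # B6 libraries at twice the depth: raw ratio ~ 2/3, normalised ~ 1/2
        acm, cells = self._experiment({"F0_B6_rep1": 2.0, "F0_B6_rep2": 2.0})
        pairs, _ = bin_trajectories(acm, cells, n_bins=20)
        y0 = np.vstack([p.y_f0 for p in pairs])
        assert abs(np.nanmean(y0) - 0.5) < 0.01
        raw_b6 = sum(p.depth_f0.sum() for p in pairs)
        assert raw_b6 > 0

    def test_bin_boundary_is_right_open_except_last(self):
        names = ["a", "b", "c"]
        cells = pd.DataFrame({
            "cell": names, "sample": "F1_rep1", "genotype": "F1", "replicate": 1,
            "cell_type": "SC", "pseudotime": [0.0, 0.5, 1.0],
        })
        b6 = np.array([[1, 2, 4]])
        acm = make_acm(b6, np.zeros_like(b6), cells=names)
        pairs, _ = bin_trajectories(acm, cells, n_bins=2)
        # pseudotime 0.5 sits on the boundary -> second (right-open) interval;
        # pseudotime 1.0 is the closed end of the last interval
        assert pairs[0].depth_f1[0] == 1
        assert pairs[0].depth_f1[1] == 6

    def test_too_few_bins_rejected(self, small_experiment):
        acm, cells, _, _ = small_experiment
        with pytest.raises(ValueError):
            bin_trajectories(acm, cells, n_bins=1)


class TestGpFits:
    def test_objective_matches_dense_mvn_oracle(self):
        rng = np.random.default_rng(0)
        nb = 100
        t = (np.arange(nb) + 0.5) / nb
        y = np.concatenate([0.5 + rng.normal(0, 0.05, nb),
                            0.55 + rng.normal(0, 0.05, nb)])
        tt = np.concatenate([t, t])
        out = np.concatenate([np.zeros(nb, int), np.ones(nb, int)])
        depth = np.full(2 * nb, 50.0)
        for variant in VARIANTS:
            prob = _CoregProblem(tt, y, out, depth, variant)
            theta = np.array([np.clip(x, lo, hi) for x, (lo, hi) in zip(
                np.random.default_rng(1).normal(-2, 0.5, prob.n_params()),
                prob.bounds())])
            ll = -prob.neg_loglik_grad(theta)[0]
            log_ls, b, u = prob.unpack(theta)
            B, _ = prob._B_and_grads(b)
            K = np.ones((prob.n, prob.n)) if variant == "M_const" else \
                matern32(prob.dist, np.exp(log_ls))
            C = prob._scale_blocks(K.copy(), B)
            noise = np.where(prob.out == 0, np.exp(u[0]), np.exp(u[1])) * prob.inv_depth
            C[np.diag_indices(prob.n)] += noise + 1e-8
            mu = prob.X @ prob.gls_means(theta)
            oracle = multivariate_normal.logpdf(prob.y, mu, C)
            assert ll == pytest.approx(oracle, abs=1e-6)

    def test_nested_objective_ordering(self):
        rng = np.random.default_rng(2)
        nb = 100
        t = (np.arange(nb) + 0.5) / nb
        for trial in range(3):
            f = 0.5 + 0.1 * np.sin(2 * np.pi * t + trial)
            noise = lambda: rng.normal(0, 0.06, nb)
            pair = make_pair(f + 0.1 * trial + noise(), f + noise())
            fits = {}
            warm = None
            for v in VARIANTS:
                fits[v] = fit_gp_variant(pair, v, warm=warm)
                warm = fits[v] if v != "M_const" else None
            assert fits["M_dynamic_trans"].objective >= \
                fits["M_persistent_trans"].objective - 0.1
            assert fits["M_persistent_trans"].objective >= \
                fits["M_cis_only"].objective - 0.1

    def test_persistent_offset_recovered_in_means(self):
        rng = np.random.default_rng(3)
        nb = 100
        t = (np.arange(nb) + 0.5) / nb
        f = 0.5 + 0.08 * np.sin(2 * np.pi * t)
        pair = make_pair(f + 0.2 + rng.normal(0, 0.04, nb),
                         f + rng.normal(0, 0.04, nb))
        fit = fit_gp_variant(pair, "M_persistent_trans",
                             warm=fit_gp_variant(pair, "M_cis_only"))
        offset = fit.means[0] - fit.means[1]
        assert offset == pytest.approx(0.2, abs=0.05)

    def test_white_noise_pair_has_no_dynamic_evidence(self):
        rng = np.random.default_rng(4)
        objs_diff = []
        for trial in range(5):
            nb = 100
            y0 = 0.5 + rng.normal(0, 0.06, nb)
            y1 = 0.5 + rng.normal(0, 0.06, nb)
            pair = make_pair(y0, y1)
            const = fit_gp_variant(pair, "M_const")
            cis = fit_gp_variant(pair, "M_cis_only")
            objs_diff.append(cis.objective - const.objective)
        assert np.median(objs_diff) < 2.0

    def test_psd_coregionalization_maintained(self):
        rng = np.random.default_rng(5)
        nb = 60
        t = (np.arange(nb) + 0.5) / nb
        pair = make_pair(0.5 + 0.1 * np.sin(6 * t) + rng.normal(0, 0.05, nb),
                         0.5 - 0.1 * np.sin(6 * t) + rng.normal(0, 0.05, nb))
        fit = fit_gp_variant(pair, "M_dynamic_trans")
        eigs = np.linalg.eigvalsh(fit.B)
        assert (eigs >= -1e-12).all()

    def test_too_few_observed_bins_rejected(self):
        nb = 30
        pair = make_pair(np.full(nb, 0.5), np.full(nb, 0.5))
        pair.mask_f0[:] = False
        pair.mask_f0[:10] = True
        with pytest.raises(ValueError, match="bins"):
            fit_gp_variant(pair, "M_cis_only")


class TestBayesFactors:
    def test_model_selection_on_planted_structures(self):
        rng = np.random.default_rng(6)
        nb = 100
        t = (np.arange(nb) + 0.5) / nb
        f = 0.5 + 0.1 * np.sin(2 * np.pi * t)
        noise = lambda: rng.normal(0, np.sqrt(0.25 / 60), nb)

        conserved = trans_bayes_factors(make_pair(0.5 + noise(), 0.5 + noise()),
                                        with_de=False)
        assert not (conserved.call_persistent_trans or conserved.call_dynamic_trans
                    or conserved.call_dynamic_cis)

        pers = trans_bayes_factors(make_pair(f + 0.2 + noise(), f + noise()),
                                   with_de=False)
        assert pers.call_persistent_trans and not pers.call_dynamic_trans

        dyn = trans_bayes_factors(
            make_pair(0.5 + 0.15 * np.sin(2 * np.pi * t) + noise(), 0.5 + noise()),
            with_de=False)
        assert dyn.call_dynamic_trans

        cis = trans_bayes_factors(make_pair(f + noise(), f + noise()), with_de=False)
        assert cis.call_dynamic_cis and not cis.call_dynamic_trans


class TestDynamicDe:
    def test_step_divergence_called_flat_and_offset_not(self):
        rng = np.random.default_rng(7)
        nb = 100
        t = (np.arange(nb) + 0.5) / nb
        noise = lambda: rng.normal(0, np.sqrt(0.25 / 60), nb)
        flat = make_pair(0.5 + noise(), 0.5 + noise())
        step = make_pair(0.5 + 0.15 * (t > 0.5) + noise(), 0.5 + noise())
        offset = make_pair(0.65 + noise(), 0.5 + noise())
        assert dynamic_de_test(step) > 10
        assert dynamic_de_test(flat) <= 10
        # constant displacement is persistent DE; the dynamic kernel earns
        # no evidence for it
        assert dynamic_de_test(offset) <= 10

    def test_read_filter_returns_nan(self):
        pair = make_pair(np.full(100, 0.5), np.full(100, 0.5), depth=2)
        assert np.isnan(dynamic_de_test(pair, min_reads=1000))
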