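import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from allelicdyn import (
    cluster_trajectories,
    dynamic_ai_score_test,
    fit_latent_trajectory,
    persistent_ai_test,
    updown_ai_profile,
)
from allelicdyn.dali import (
    LatentTrajectory, _poly_features, _score_test_components, cis_test_genes,
)
from allelicdyn._stats import bb_mle

from conftest import make_acm


class TestPersistentTest:
    def test_single_bernoulli_observation_is_uninformative(self):
        # one cell with k = n = 1: the LRT statistic is 2*(0 - log 0.5) =
        # 2 log 2, p = chi2.sf(1.386, 1) ~ 0.24 >= ... enumeration gives the
        # same for k=0, so p is bounded well away from significance
        p, _ = persistent_ai_test([1], [1], rho=0.01)
        assert p >= 0.2

    def test_power_at_strong_imbalance(self):
        rng = np.random.default_rng(0)
        hits = 0
        for i in range(20):
            n = rng.poisson(10, 500)
            k = rng.binomial(n, 0.7)
            _, rho, _ = bb_mle(k, n)
            p, p_hat = persistent_ai_test(k, n, rho)
            hits += p < 1e-6
            assert abs(p_hat - 0.7) < 0.05
        assert hits >= 19

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            persistent_ai_test([0], [0], rho=0.01)


class TestScoreTest:
    def test_statistic_equals_brute_force_kernel_quadratic_form(self):
        # the feature expansion must reproduce Q = r^T K r with
        # K = (1 + z z')^3 on standardised pseudotime, r the projected
        # null residuals
        rng = np.random.default_rng(1)
        for trial in range(5):
            ncells = 150
            n = rng.poisson(8, ncells)
            t = rng.uniform(0, 1, ncells)
            k = rng.binomial(n, 0.55)
            rho = 0.02
            q, lam, p_hat = _score_test_components(k, n, t, rho)
            keep = n > 0
            kk, nn, tt = k[keep], n[keep], t[keep]
            z = (tt - tt.mean()) / tt.std()
            K = (1 + np.outer(z, z)) ** 3
            w = nn * p_hat * (1 - p_hat) * (1 + (nn - 1) * rho)
            e = kk - nn * p_hat
            a = nn / w
            c = a / (a * nn).sum()
            r = e - nn * (c @ e)
            assert q == pytest.approx(float(r @ K @ r), abs=1e-8 * max(1, abs(q)))

    def test_constant_pseudotime_rejected(self):
        with pytest.raises(ValueError, match="pseudotime"):
            dynamic_ai_score_test([3, 4], [6, 7], [0.5, 0.5], rho=0.01)

    def test_detects_dynamic_signal_and_ignores_permuted(self):
        rng = np.random.default_rng(2)
        ncells = 800
        n = rng.poisson(10, ncells)
        t = rng.uniform(0, 1, ncells)
        p_true = 0.5 + 0.15 * np.sin(2 * np.pi * t)
        k = rng.binomial(n, p_true)
        _, rho, _ = bb_mle(k, n)
        assert dynamic_ai_score_test(k, n, t, rho) < 1e-6
        t_perm = rng.permutation(t)
        assert dynamic_ai_score_test(k, n, t_perm, rho) > 1e-3

    def test_feature_map_reproduces_polynomial_kernel(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(0, 1, 40)
        phi = _poly_features(t)
        z = (t - t.mean()) / t.std()
        np.testing.assert_allclose(phi @ phi.T, (1 + np.outer(z, z)) ** 3,
                                   atol=1e-10)


class TestLatentTrajectory:
    def test_constant_rate_recovery(self):
        rng = np.random.default_rng(4)
        n = rng.poisson(10, 1000)
        t = rng.uniform(0, 1, 1000)
        k = rng.binomial(n, 0.7)
        tr = fit_latent_trajectory(k, n, t)
        assert np.max(np.abs(tr.mean - 0.7)) <= 0.05

    def test_step_profile_recovery_away_from_step(self):
        rng = np.random.default_rng(5)
        n = rng.poisson(15, 1500)
        t = rng.uniform(0, 1, 1500)
        p_true = np.where(t < 0.5, 0.35, 0.65)
        k = rng.binomial(n, p_true)
        tr = fit_latent_trajectory(k, n, t)
        away = (tr.grid < 0.4) | (tr.grid > 0.6)
        truth = np.where(tr.grid < 0.5, 0.35, 0.65)
        assert np.max(np.abs(tr.mean[away] - truth[away])) < 0.06

    def test_zero_depth_cells_are_ignored(self):
        rng = np.random.default_rng(6)
        n = rng.poisson(10, 200)
        t = rng.uniform(0, 1, 200)
        k = rng.binomial(n, 0.6)
        tr1 = fit_latent_trajectory(k, n, t)
        # append zero-depth cells: identical output
        n2 = np.concatenate([n, np.zeros(50, int)])
        k2 = np.concatenate([k, np.zeros(50, int)])
        t2 = np.concatenate([t, rng.uniform(0, 1, 50)])
        tr2 = fit_latent_trajectory(k2, n2, t2)
        np.testing.assert_allclose(tr1.mean, tr2.mean, atol=1e-10)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            fit_latent_trajectory(np.ones(10), np.ones(10), np.linspace(0, 1, 10))

    def test_z_profile_is_standardised(self):
        grid = np.linspace(0, 1, 100)
        tr = LatentTrajectory("g", grid, np.sin(grid * 6), np.ones(100))
        assert tr.z.mean() == pytest.approx(0, abs=1e-12)
        assert tr.z.std() == pytest.approx(1, abs=1e-12)


class TestClustering:
    def _trajs(self, shapes, n_each=20, noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        grid = np.linspace(0, 1, 100)
        out, labels = [], []
        for i, f in enumerate(shapes):
            for j in range(n_each):
                y = f(grid) + rng.normal(0, noise, 100)
                out.append(LatentTrajectory(f"s{i}g{j}", grid, y, np.ones(100)))
                labels.append(i)
        return out, np.array(labels)

    def test_two_shape_families_perfectly_separated(self):
        trajs, truth = self._trajs([np.sin, lambda t: (t > 0.5).astype(float)])
        labels, means = cluster_trajectories(trajs, n_clusters=2)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert means.shape == (2, 100)

    def test_duplicated_trajectories_co_cluster(self):
        trajs, _ = self._trajs([np.sin], n_each=3, noise=0.0)
        doubled = trajs + trajs
        labels, _ = cluster_trajectories(doubled + self._trajs(
            [lambda t: -t], n_each=3, seed=1)[0], n_clusters=2)
        assert len(set(labels[:6])) == 1

    def test_more_clusters_than_genes_rejected(self):
        trajs, _ = self._trajs([np.sin], n_each=3)
        with pytest.raises(ValueError):
            cluster_trajectories(trajs, n_clusters=10)

    def test_within_cluster_ss_invariant_to_input_order(self):
        trajs, _ = self._trajs([np.sin, np.cos], n_each=10, seed=2)
        labels1, _ = cluster_trajectories(trajs, 2)
        order = np.random.default_rng(0).permutation(len(trajs))
        labels2, _ = cluster_trajectories([trajs[i] for i in order], 2)
        Z = np.vstack([tr.z for tr in trajs])

        def wss(lbl, Zm):
            return sum(((Zm[lbl == c] - Zm[lbl == c].mean(0)) ** 2).sum()
                       for c in np.unique(lbl))

        assert wss(labels1, Z) == pytest.approx(wss(labels2[np.argsort(order)], Z))


class TestUpdownProfile:
    def _experiment(self, expr_profile, ai_profile, n_cells=1200, seed=0):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0, 1, n_cells)
        lam = expr_profile(t) * 20
        tot = rng.poisson(lam)
        n_allelic = rng.binomial(tot, 0.5)
        k = rng.binomial(n_allelic, ai_profile(t))
        acm = make_acm(k[None, :], (n_allelic - k)[None, :], total=tot[None, :])
        cells = pd.DataFrame({"cell": [f"c{j}" for j in range(n_cells)],
                              "sample": "F1_rep1", "genotype": "F1", "replicate": 1,
                              "cell_type": "SC", "pseudotime": t})
        return acm, cells

    def test_monotone_gene_excluded(self):
        acm, cells = self._experiment(lambda t: 0.2 + 2 * t, lambda t: 0.5)
        out = updown_ai_profile(acm, cells)
        assert not out.loc[0, "included"]

    def test_bump_gene_with_early_ai_deviation(self):
        expr = lambda t: 0.3 + 2 * np.exp(-0.5 * ((t - 0.5) / 0.15) ** 2)
        ai = lambda t: np.where(t < 0.35, 0.75, 0.5)  # deviation during up-regulation
        acm, cells = self._experiment(expr, ai, seed=3)
        out = updown_ai_profile(acm, cells)
        assert out.loc[0, "included"]
        assert out.loc[0, "peak_ai_segment"] in (1, 2)


def test_cis_test_classes_partition_significant_genes(small_experiment):
    acm, cells, genes, truth = small_experiment
    res = cis_test_genes(acm, cells, min_allelic_reads=500)
    assert not res.empty
    assert set(res["ai_class"]) <= {"dynamic", "persistent_only", "none"}
    dyn = res["ai_class"] == "dynamic"
    pers = res["ai_class"] == "persistent_only"
    # partition logic
    assert ((res.loc[dyn, "p_adj_dynamic"] < 0.01).all())
    assert ((res.loc[pers, "p_adj_persistent"] < 0.01).all())
    assert ((res.loc[pers, "p_adj_dynamic"] >= 0.01).all())
    # persistent-cis genes in the simulation should mostly be recovered
    merged = res.merge(truth.table[["gene", "has_cis", "cis_dynamic"]], on="gene")
    pers_cis = merged[merged["has_cis"] & ~merged["cis_dynamic"]]
    if len(pers_cis) >= 5:
        assert (pers_cis["ai_class"] != "none").mean() >= 0.8
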