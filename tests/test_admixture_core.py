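import numpy as np
import pytest

from admixkit import (
    AlleleFreqMatrix,
    FitOptions,
    ReferencePanel,
    em_step,
    fit_supervised,
    fit_unsupervised,
    fit_with_frequencies,
    loglikelihood,
    simulate_genotypes,
)
from admixkit.admixture_core import _em_step_ll, _em_update, _split_observed, _loglik_arrays
from conftest import make_matrix


class TestLoglikelihood:
    def test_single_het_single_pop(self):
        G = make_matrix([[1]])
        F = AlleleFreqMatrix(["P"], [[0.5]])
        assert loglikelihood(G, np.array([[1.0]]), F) == pytest.approx(
            np.log(0.5) + np.log(0.5), abs=1e-12
        )
        assert loglikelihood(G, np.array([[1.0]]), F) == pytest.approx(-1.38629, abs=1e-5)

    def test_hom_alt(self):
        G = make_matrix([[2]])
        F = AlleleFreqMatrix(["P"], [[0.9]])
        assert loglikelihood(G, np.array([[1.0]]), F) == pytest.approx(-0.21072, abs=1e-5)

    def test_two_snp_mixture_hand_value(self):
        # q=(0.5,0.5), f col1=(0.2,0.8), col2=(0.1,0.3), g=(1,0)
        # p = (0.5, 0.2); LL = ln 0.5 + ln 0.5 + 2 ln 0.8 = -1.83258
        G = make_matrix([[1, 0]])
        F = AlleleFreqMatrix(["A", "B"], [[0.2, 0.1], [0.8, 0.3]])
        Q = np.array([[0.5, 0.5]])
        assert loglikelihood(G, Q, F) == pytest.approx(-1.83258, abs=1e-5)
        # brute-force cross-check
        p = Q @ F.F
        expected = sum(
            g * np.log(pj) + (2 - g) * np.log(1 - pj)
            for g, pj in zip([1, 0], p[0])
        )
        assert loglikelihood(G, Q, F) == pytest.approx(expected, abs=1e-12)

    def test_missing_contributes_zero(self):
        G = make_matrix([[1, -1]])
        F = AlleleFreqMatrix(["P"], [[0.5, 0.5]])
        assert loglikelihood(G, np.array([[1.0]]), F) == pytest.approx(
            2 * np.log(0.5), abs=1e-12
        )

    def test_dimension_mismatch(self):
        G = make_matrix([[1, 0]])
        F = AlleleFreqMatrix(["P"], [[0.5, 0.5]])
        with pytest.raises(Exception):
            loglikelihood(G, np.array([[0.5, 0.5]]), F)


class TestEMStep:
    def test_k1_trivial_simplex(self):
        G = make_matrix([[0, 1], [2, 1]])
        F = AlleleFreqMatrix(["P"], [[0.3, 0.7]])
        Q = np.array([[1.0], [1.0]])
        Q2, _ = em_step(G, Q, F)
        np.testing.assert_allclose(Q2, 1.0)

    def test_pure_f_update_reaches_sample_frequency(self):
        # one population, fully supervised: the MLE for f is the sample freq
        G = make_matrix([[0], [1], [2]])
        F = AlleleFreqMatrix(["P"], [[0.2]])
        Q = np.ones((3, 1))
        for _ in range(200):
            _, F = em_step(G, Q, F, fixed_q_rows=[0, 1, 2])
        assert F.F[0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_monotone_loglikelihood_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n, J, K = 2, 3, 2
            G = make_matrix(rng.integers(0, 3, size=(n, J)))
            Q = rng.dirichlet(np.ones(K), size=n)
            F = AlleleFreqMatrix(["A", "B"], rng.uniform(0.05, 0.95, size=(K, J)))
            ll0 = loglikelihood(G, Q, F)
            Q2, F2 = em_step(G, Q, F)
            assert loglikelihood(G, Q2, F2) >= ll0 - 1e-9
            assert np.abs(Q2.sum(1) - 1.0).max() < 1e-9

    def test_kernel_matches_reference_update(self):
        """The fused kernel and the plain numpy update agree bit-tightly."""
        rng = np.random.default_rng(1)
        G = rng.integers(0, 3, size=(6, 15)).astype(np.int16)
        G[2, 4] = -1
        Q = rng.dirichlet(np.ones(3), size=6)
        F = rng.uniform(0.1, 0.9, size=(3, 15))
        fixed = np.array([0, 1], dtype=int)
        Qk, Fk, llk = _em_step_ll(G, Q, F, fixed, True)
        Gm, Hm, obs = _split_observed(G)
        Qn, Fn = _em_update(Gm, Hm, obs.sum(1), Q, F, fixed, True)
        lln = _loglik_arrays(Gm, Hm, Q, F)
        np.testing.assert_allclose(Qk, Qn, atol=1e-12)
        np.testing.assert_allclose(Fk, Fn, atol=1e-12)
        assert llk == pytest.approx(lln, abs=1e-8)


class TestSupervisedFit:
    def test_k1_all_targets_unit(self):
        G = make_matrix([[0, 1], [2, 1], [1, 1]])
        panel = ReferencePanel(G.take_samples([0, 1]), ["P", "P"], ["P"])
        targets = G.take_samples([2])
        est, freqs = fit_supervised(panel, targets)
        np.testing.assert_allclose(est.Q, 1.0)

    def test_reference_copies_recover_own_population(self, small_panel_sim):
        spec, F, panel, _, _ = small_panel_sim
        # verbatim copies of PopA reference members as targets
        idxA = panel.members_of("PopA")[:10]
        targets = panel.genotypes.take_samples(idxA)
        targets = type(targets)(
            [f"t{i}" for i in range(targets.n)], targets.variants, targets.G
        )
        est, _ = fit_supervised(panel, targets)
        a = est.populations.index("PopA")
        assert est.Q[:, a].mean() > 0.95

    def test_half_half_targets_recovered(self, small_panel_sim):
        spec, F, panel, targets, Qtrue = small_panel_sim
        est, _ = fit_supervised(panel, targets)
        assert est.converged
        np.testing.assert_allclose(est.Q.mean(0), [0.5, 0.5], atol=0.03)

    def test_variant_mismatch_error(self, small_panel_sim):
        _, _, panel, targets, _ = small_panel_sim
        bad = targets.take_variants(range(targets.J - 1))
        with pytest.raises(Exception):
            fit_supervised(panel, bad)

    def test_grid_search_oracle_single_target(self):
        """EM optimum matches a 1-D likelihood grid search for K=2, fixed F."""
        rng = np.random.default_rng(9)
        for trial in range(5):
            J = 20
            F = AlleleFreqMatrix(["A", "B"], rng.uniform(0.05, 0.95, size=(2, J)))
            q_true = rng.uniform(0.1, 0.9)
            G = simulate_genotypes(
                np.array([[q_true, 1 - q_true]]), F, seed=100 + trial
            )
            est = fit_with_frequencies(G, F, FitOptions(tol=1e-12, max_iter=20000))
            grid = np.arange(0.0, 1.0 + 1e-9, 1e-4)
            g = G.G[0].astype(float)
            P = grid[:, None] * F.F[0] + (1 - grid[:, None]) * F.F[1]
            ll = (g * np.log(P) + (2 - g) * np.log(1 - P)).sum(1)
            q_grid = grid[np.argmax(ll)]
            assert abs(est.Q[0, 0] - q_grid) < 1e-3

    def test_label_permutation_invariance(self, small_panel_sim):
        _, _, panel, targets, _ = small_panel_sim
        est, _ = fit_supervised(panel, targets)
        flipped = ReferencePanel(
            panel.genotypes, list(panel.labels), list(reversed(panel.populations))
        )
        est2, _ = fit_supervised(flipped, targets)
        np.testing.assert_allclose(est.Q, est2.Q[:, ::-1], atol=1e-6)
        assert est.loglik == pytest.approx(est2.loglik, abs=1e-4)

    def test_unbiased_with_known_frequencies(self):
        """With true F fixed, q-hat is unbiased within Monte-Carlo error."""
        rng = np.random.default_rng(17)
        F = AlleleFreqMatrix(["A", "B"], rng.uniform(0.1, 0.9, size=(2, 2000)))
        n = 60
        Q = np.tile([0.3, 0.7], (n, 1))
        G = simulate_genotypes(Q, F, seed=5)
        est = fit_with_frequencies(G, F)
        err = est.Q[:, 0] - 0.3
        bias = err.mean()
        sd = err.std(ddof=1)
        assert abs(bias) < 2 * sd / np.sqrt(n)


class TestUnsupervisedFit:
    def test_k1_pooled_frequencies(self):
        G = make_matrix([[0, 2], [2, 0], [1, 1]])
        est, freqs = fit_unsupervised(G, K=1, opts=FitOptions(max_iter=500))
        np.testing.assert_allclose(est.Q, 1.0)
        np.testing.assert_allclose(freqs.F[0], [0.5, 0.5], atol=1e-3)

    def test_two_populations_recovered_up_to_permutation(self, small_panel_sim):
        _, _, panel, _, _ = small_panel_sim
        est, _ = fit_unsupervised(panel.genotypes, K=2, opts=FitOptions(seed=3))
        hard = est.Q.argmax(1)
        truth = np.array([0] * 40 + [1] * 40)
        agreement = max((hard == truth).mean(), (hard != truth).mean())
        assert agreement >= 0.98

    def test_seed_stability_small(self, small_panel_sim):
        """Different seeds land on the same optimum up to label permutation."""
        _, _, panel, _, _ = small_panel_sim
        est1, _ = fit_unsupervised(panel.genotypes, K=2, opts=FitOptions(seed=1))
        est2, _ = fit_unsupervised(panel.genotypes, K=2, opts=FitOptions(seed=2))
        direct = np.abs(est1.Q - est2.Q).mean()
        swapped = np.abs(est1.Q - est2.Q[:, ::-1]).mean()
        assert min(direct, swapped) < 0.01
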