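import numpy as np
import pytest

from admixkit import (
    DistanceMatrix,
    FitOptions,
    ReferencePanel,
    distance_variance_test,
    ibs_distance_matrix,
    leave_one_out,
    pairwise_fst,
    pcoa,
    se_vs_marker_count,
    simulate_frequencies,
    simulate_genotypes,
    simulate_reference_panel,
    SimulationSpec,
    trio_deviation,
)
from conftest import make_matrix


class TestIBSDistance:
    def test_identical_rows_zero(self):
        M = make_matrix([[0, 1, 2], [0, 1, 2]])
        D = ibs_distance_matrix(M)
        assert D.D[0, 1] == 0.0

    def test_opposite_homozygotes_one(self):
        M = make_matrix([[0, 0, 0], [2, 2, 2]])
        assert ibs_distance_matrix(M).D[0, 1] == 1.0

    def test_het_vs_hom_half(self):
        M = make_matrix([[0, 0], [1, 1]])
        assert ibs_distance_matrix(M).D[0, 1] == 0.5

    def test_missing_restricts_to_joint_sites(self):
        M = make_matrix([[0, 2, -1], [0, -1, 2]])
        assert ibs_distance_matrix(M).D[0, 1] == 0.0  # only site 1 shared

    def test_no_overlap_errors(self):
        M = make_matrix([[0, -1], [-1, 2]])
        with pytest.raises(Exception):
            ibs_distance_matrix(M)

    def test_triangle_inequality_random(self):
        rng = np.random.default_rng(4)
        M = make_matrix(rng.integers(0, 3, size=(12, 200)))
        D = ibs_distance_matrix(M).D
        for _ in range(200):
            i, j, k = rng.choice(12, 3, replace=False)
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


class TestPCoA:
    def test_two_points_exact(self):
        D = DistanceMatrix(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        res = pcoa(D, m=1)
        assert abs(res.coords[0, 0] - res.coords[1, 0]) == pytest.approx(3.0, abs=1e-10)
        np.testing.assert_allclose(res.varexp, [1.0], atol=1e-10)

    def test_equilateral_triangle_split_variance(self):
        D = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        res = pcoa(D, m=2)
        np.testing.assert_allclose(res.varexp, [0.5, 0.5], atol=1e-10)

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(15, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(DistanceMatrix([str(i) for i in range(15)], D), m=2)
        D2 = np.linalg.norm(res.coords[:, None] - res.coords[None, :], axis=-1)
        np.testing.assert_allclose(D2, D, atol=1e-8)

    def test_matches_skbio_oracle(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        mine = pcoa(DistanceMatrix([str(i) for i in range(10)], D), m=3)
        ref = skbio_pcoa(D, number_of_dimensions=3)
        np.testing.assert_allclose(
            np.abs(mine.coords), np.abs(ref.samples.values[:, :3]), atol=1e-6
        )
        np.testing.assert_allclose(
            mine.varexp, ref.proportion_explained.values[:3], atol=1e-6
        )

    def test_varexp_non_increasing(self):
        rng = np.random.default_rng(2)
        M = make_matrix(rng.integers(0, 3, size=(20, 100)))
        res = pcoa(ibs_distance_matrix(M), m=5)
        assert (np.diff(res.varexp) <= 1e-12).all()


class TestFst:
    def _panel(self, G, labels):
        return ReferencePanel(make_matrix(G), labels)

    def test_identical_compositions_near_zero(self):
        rng = np.random.default_rng(3)
        block = rng.integers(0, 3, size=(20, 400))
        panel = self._panel(np.vstack([block, block]), ["A"] * 20 + ["B"] * 20)
        fst = pairwise_fst(panel)
        assert abs(fst[0, 1]) < 2 / np.sqrt(400)

    def test_fixed_difference_is_one(self):
        G = np.vstack([np.zeros((5, 50)), np.full((5, 50), 2)]).astype(np.int16)
        panel = self._panel(G, ["A"] * 5 + ["B"] * 5)
        assert pairwise_fst(panel)[0, 1] == pytest.approx(1.0)

    def test_balding_nichols_recovery_across_target_range(self):
        """Hudson estimates recover the simulated differentiation within
        +/- 0.01 across the continental Fst range."""
        for target in (0.03, 0.15, 0.3):
            spec = SimulationSpec(
                populations=["A", "B"], fst=[target, target],
                J=10_000, n_ref=100, seed=int(target * 1000),
            )
            F = simulate_frequencies(spec)
            panel = simulate_reference_panel(spec, F)
            est = pairwise_fst(panel)[0, 1]
            # under the star model the expected pairwise Fst is about
            # (F_a + F_b) / 2 relative to the shared ancestral pool
            assert est == pytest.approx(target, abs=0.01)

    def test_singleton_population_error(self):
        panel = self._panel(np.array([[0, 1], [1, 2], [2, 0]]), ["A", "A", "B"])
        with pytest.raises(Exception):
            pairwise_fst(panel)


class TestDistanceVarianceTest:
    def test_single_group_errors(self):
        D = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(Exception):
            distance_variance_test(D, ["x", "x"], n_perm=99)

    def test_separated_clusters_minimal_p(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 0.05, (10, 2)), rng.normal(5, 0.05, (10, 2))])
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = ["a"] * 10 + ["b"] * 10
        r2, p = distance_variance_test(
            DistanceMatrix([str(i) for i in range(20)], D), labels, n_perm=199, seed=0
        )
        # a permutation can reproduce the same partition (label complement),
        # tying with the observed statistic, so allow one tie above the
        # theoretical minimum of 1/(n_perm+1)
        assert p <= 2 / 200
        assert r2 > 0.9

    def test_matches_skbio_permanova(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova

        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 1, (12, 2)), rng.normal(1.5, 1, (12, 2))])
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = ["a"] * 12 + ["b"] * 12
        r2, p = distance_variance_test(
            DistanceMatrix([str(i) for i in range(24)], D), labels, n_perm=999, seed=1
        )
        ref = permanova(SkbioDM(D), grouping=labels, permutations=999)
        # same pseudo-F statistic up to float noise; p-values within
        # permutation Monte-Carlo error of each other
        f_mine = (r2 / 1) / ((1 - r2) / 22)
        assert f_mine == pytest.approx(ref["test statistic"], rel=1e-9)
        assert p == pytest.approx(ref["p-value"], abs=0.05)

    def test_null_p_values_roughly_uniform(self):
        """Random labels on structureless data: p approximately U(0,1)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(11)
        ps = []
        for rep in range(120):
            pts = rng.normal(size=(14, 2))
            D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            labels = ["a"] * 7 + ["b"] * 7
            _, p = distance_variance_test(
                DistanceMatrix([str(i) for i in range(14)], D), labels,
                n_perm=99, seed=int(rng.integers(2**31 - 1)),
            )
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestLeaveOneOut:
    def test_six_pop_panel_diagonal_property(self):
        spec = SimulationSpec(
            fst=[0.1, 0.15, 0.2, 0.25, 0.3, 0.35],
            J=5000, n_ref=50, seed=41,
        )
        panel = simulate_reference_panel(spec)
        est = leave_one_out(panel)
        own = est.Q[np.arange(panel.genotypes.n), panel.label_indices()]
        assert (own > 0.9).mean() >= 0.95

    def test_identical_frequencies_uninformative(self):
        rng = np.random.default_rng(13)
        G = rng.binomial(2, 0.4, size=(30, 600)).astype(np.int16)
        panel = ReferencePanel(make_matrix(G), ["A"] * 15 + ["B"] * 15)
        est = leave_one_out(panel)
        own = est.Q[np.arange(30), panel.label_indices()]
        assert abs(own.mean() - 0.5) < 0.1

    def test_admixed_spike_in_flagged(self):
        spec = SimulationSpec(
            populations=["A", "B"], fst=[0.2, 0.2], J=3000, n_ref=30, seed=43,
            targets=[(1, [0.5, 0.5])],
        )
        from admixkit import simulate_admixed_targets
        from admixkit.io import GenotypeMatrix

        F = simulate_frequencies(spec)
        panel = simulate_reference_panel(spec, F)
        mixed, _ = simulate_admixed_targets(spec, F)
        G = GenotypeMatrix(
            panel.genotypes.samples + mixed.samples,
            panel.genotypes.variants,
            np.vstack([panel.genotypes.G, mixed.G]),
        )
        spiked = ReferencePanel(G, list(panel.labels) + ["A"], ["A", "B"])
        est = leave_one_out(spiked)
        own = est.Q[np.arange(G.n), spiked.label_indices()]
        assert own[-1] < 0.9  # the admixed member fails to recapitulate
        assert (own[:-1] > 0.9).mean() > 0.95

    def test_singleton_population_error(self):
        rng = np.random.default_rng(1)
        G = make_matrix(rng.integers(0, 3, size=(3, 50)))
        panel = ReferencePanel(G, ["A", "A", "B"])
        with pytest.raises(Exception):
            leave_one_out(panel)


class TestSECurve:
    def test_full_count_matches_direct_bootstrap(self, small_panel_sim):
        _, _, panel, targets, _ = small_panel_sim
        few = targets.take_samples(range(4))
        table = se_vs_marker_count(panel, few, [targets.J], n_reps=12, seed=3)
        assert table.shape == (1, 2)
        assert (table.values >= 0).all()

    def test_count_above_J_errors(self, small_panel_sim):
        _, _, panel, targets, _ = small_panel_sim
        with pytest.raises(Exception):
            se_vs_marker_count(panel, targets, [targets.J + 1], n_reps=5)

    def test_inverse_sqrt_scaling_fixed_F(self):
        """Under fixed true frequencies and unlinked markers the mean SE
        falls like J^(-1/2): log-log slope -0.5 within +/- 0.1."""
        rng = np.random.default_rng(19)
        Jmax = 6400
        spec = SimulationSpec(populations=["A", "B"], fst=[0.2, 0.2],
                              J=Jmax, n_ref=80, seed=23,
                              targets=[(6, [0.5, 0.5])])
        F = simulate_frequencies(spec)
        panel = simulate_reference_panel(spec, F)
        from admixkit import simulate_admixed_targets

        targets, _ = simulate_admixed_targets(spec, F)
        counts = [400, 1600, 6400]
        table = se_vs_marker_count(
            panel, targets, counts, FitOptions(fixed_F=True), n_reps=60, seed=29
        )
        mean_se = table.mean(axis=1).values
        slope = np.polyfit(np.log(counts), np.log(mean_se), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)


class TestTrioDeviation:
    def test_exact_parental_mean_zero(self):
        assert trio_deviation([0.5, 0.5], [0.4, 0.6], [0.6, 0.4]).tolist() == [0, 0]

    def test_hand_arithmetic(self):
        np.testing.assert_allclose(
            trio_deviation([0.6, 0.4], [0.5, 0.5], [0.5, 0.5]), [0.1, 0.1]
        )

    def test_dimension_mismatch(self):
        with pytest.raises(Exception):
            trio_deviation([0.5, 0.5], [1.0], [1.0])

    def test_simulated_trios_small_deviation(self):
        """Mendelian offspring of admixed parents: estimated deviations on
        the order of 1e-2, as estimation error predicts."""
        from admixkit import fit_with_frequencies, simulate_offspring
        from admixkit.io import GenotypeMatrix

        spec = SimulationSpec(
            populations=["Europe", "Africa", "America", "EastAsia"],
            fst=[0.15, 0.25, 0.25, 0.15], J=4000, n_ref=1, seed=47,
        )
        F = simulate_frequencies(spec)
        q_parent = np.array([0.46, 0.05, 0.46, 0.03])
        devs = []
        for t in range(6):
            parents = simulate_genotypes(
                np.tile(q_parent, (2, 1)), F, seed=200 + t, sample_prefix=f"p{t}_"
            )
            child_vec = simulate_offspring(parents.G[0], parents.G[1], seed=300 + t)
            trio = GenotypeMatrix(
                parents.samples + [f"c{t}"], parents.variants,
                np.vstack([parents.G, child_vec[None, :]]),
            )
            est = fit_with_frequencies(trio, F)
            devs.append(trio_deviation(est.Q[2], est.Q[0], est.Q[1]))
        mean_dev = np.mean(devs, axis=0)
        assert (mean_dev < 0.05).all()
        assert mean_dev.mean() < 0.03
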