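import numpy as np
import pytest

from metachain import (
    SiteAtlas,
    TrainConfig,
    build_initial_matrix,
    generate_generic,
    generate_support,
    generate_target,
    perturb_initial,
    residual,
    stationary_distribution,
    train,
    uniform_distribution,
    validate,
)
from metachain.training import rank_two_noise

from conftest import dist


@pytest.fixture(scope="module")
def small_problem():
    """2-site problem with a known stationary target."""
    atlas = SiteAtlas(("alpha", "beta"))
    target = dist(atlas, 0.75, 0.25)
    generic = uniform_distribution(atlas)
    return atlas, target, generic


class TestInitialMatrix:
    def test_rank_two_when_rows_differ(self, small_problem):
        atlas, target, generic = small_problem
        a0 = build_initial_matrix(target, generic, primary_site=1)
        assert np.linalg.matrix_rank(a0.a) == 2
        assert np.allclose(a0.a[0], target.p)
        assert np.allclose(a0.a[1], generic.p)

    def test_rank_one_when_target_equals_generic(self, small_problem):
        atlas, target, _ = small_problem
        a0 = build_initial_matrix(target, target, primary_site=1)
        assert np.linalg.matrix_rank(a0.a) == 1

    def test_rows_are_probability_vectors(self, atlas50):
        target = generate_target(atlas50, generate_support(atlas50, 27, seed=0),
                                 seed=1)
        generic = generate_generic(atlas50, generate_support(atlas50, 30, seed=2),
                                   seed=3)
        a0 = build_initial_matrix(target, generic, primary_site=23)
        assert validate(a0) == []
        assert np.linalg.matrix_rank(a0.a) == 2


class TestResidual:
    def test_zero_residual_at_own_stationary(self):
        atlas = SiteAtlas.numbered(2)
        from metachain import TransitionMatrix

        m = TransitionMatrix(atlas, np.array([[0.75, 0.25], [0.75, 0.25]]))
        r, norm = residual(m, stationary_distribution(m))
        assert norm < 1e-10

    def test_known_two_site_residual(self):
        atlas = SiteAtlas.numbered(2)
        from metachain import TransitionMatrix

        m = TransitionMatrix(atlas, np.full((2, 2), 0.5))
        r, norm = residual(m, dist(atlas, 0.75, 0.25))
        assert np.allclose(r, [-0.25, 0.25], atol=1e-10)
        assert norm == pytest.approx(np.sqrt(2 * 0.25**2), abs=1e-10)

    def test_invariant_under_joint_relabeling(self, atlas50):
        support = generate_support(atlas50, 10, seed=4)
        target = generate_target(atlas50, support, seed=5)
        generic = generate_generic(atlas50, support, seed=6)
        a0 = build_initial_matrix(target, generic, primary_site=sorted(support)[0])
        _, norm = residual(a0, target)

        perm = np.random.default_rng(7).permutation(50)
        from metachain import SiteDistribution, TransitionMatrix

        a_perm = TransitionMatrix(atlas50, a0.a[np.ix_(perm, perm)])
        t_perm = SiteDistribution(atlas50, target.p[perm])
        _, norm_perm = residual(a_perm, t_perm)
        assert norm_perm == pytest.approx(norm, abs=1e-9)


class TestTrain:
    def test_two_site_training_reaches_target(self, small_problem):
        atlas, target, generic = small_problem
        a0 = build_initial_matrix(target, generic, primary_site=1)
        cfg = TrainConfig(epsilon=1e-3, seed=0)
        m, trace = train(a0, target, cfg)
        assert trace.converged
        assert validate(m) == []
        pi = stationary_distribution(m)
        assert np.linalg.norm(pi.p - target.p) <= 1e-3

    @pytest.mark.parametrize("support_size", [5, 10, 27])
    def test_parameter_recovery_across_supports(self, atlas50, support_size):
        """Training recovers synthetic targets over supports of 5, 10, 27 sites."""
        support = generate_support(atlas50, support_size, seed=support_size)
        target = generate_target(atlas50, support, seed=support_size + 100)
        generic = generate_generic(atlas50, support, seed=support_size + 200)
        primary = sorted(support)[0]
        a0 = build_initial_matrix(target, generic, primary)
        m, trace = train(a0, target, TrainConfig(epsilon=1e-3, seed=support_size))
        assert trace.converged
        assert trace.residual_norms[-1] <= 1e-3
        pi = stationary_distribution(m)
        assert np.linalg.norm(pi.p - target.p) <= 1e-3

    def test_effective_rank_matches_support_when_generic_shares_it(self, atlas50):
        """Trained matrices have as many non-negligible singular values as
        there are sites receiving probability mass (here: the shared support)."""
        from metachain import singular_spectrum

        for size in (5, 10):
            support = generate_support(atlas50, size, seed=size + 50)
            target = generate_target(atlas50, support, seed=size + 60)
            generic = generate_generic(atlas50, support, seed=size + 70)
            a0 = build_initial_matrix(target, generic, sorted(support)[0])
            m, trace = train(a0, target, TrainConfig(seed=size))
            assert trace.converged
            summary = singular_spectrum([m])
            assert abs(summary.effective_rank - size) <= 1

    def test_seed_determinism_bit_identical(self, small_problem):
        atlas, target, generic = small_problem
        a0 = build_initial_matrix(target, generic, primary_site=1)
        cfg = TrainConfig(epsilon=1e-4, seed=1234)
        m1, t1 = train(a0, target, cfg)
        m2, t2 = train(a0, target, cfg)
        assert np.array_equal(m1.a, m2.a)
        assert np.array_equal(t1.residual_norms, t2.residual_norms)

    def test_trace_final_residual_consistent_with_convergence(self, atlas50):
        support = generate_support(atlas50, 5, seed=8)
        target = generate_target(atlas50, support, seed=9)
        generic = generate_generic(atlas50, support, seed=10)
        a0 = build_initial_matrix(target, generic, sorted(support)[0])
        m, trace = train(a0, target, TrainConfig(epsilon=1e-3, seed=2))
        assert trace.converged == (trace.residual_norms[-1] <= 1e-3)

    def test_smoothed_residual_trend_non_increasing(self, atlas50):
        """Raw residuals fluctuate (randomized updates) but the 50-iteration
        block means decay monotonically on converged runs."""
        support = generate_support(atlas50, 10, seed=20)
        target = generate_target(atlas50, support, seed=21)
        generic = generate_generic(atlas50, support, seed=22)
        a0 = build_initial_matrix(target, generic, sorted(support)[0])
        _, trace = train(a0, target, TrainConfig(epsilon=1e-3, seed=3))
        assert trace.converged
        norms = trace.residual_norms
        blocks = [norms[i : i + 50].mean() for i in range(0, len(norms) - 49, 50)]
        assert all(b2 <= b1 for b1, b2 in zip(blocks, blocks[1:]))

    def test_clamp_mode_also_converges(self, small_problem):
        atlas, target, generic = small_problem
        a0 = build_initial_matrix(target, generic, primary_site=1)
        m, trace = train(a0, target, TrainConfig(seed=5, clip_mode="clamp"))
        assert trace.converged
        assert validate(m) == []

    def test_iteration_budget_returns_best_not_raises(self, atlas50):
        support = generate_support(atlas50, 10, seed=30)
        target = generate_target(atlas50, support, seed=31)
        generic = generate_generic(atlas50, support, seed=32)
        a0 = build_initial_matrix(target, generic, sorted(support)[0])
        m, trace = train(a0, target, TrainConfig(max_iterations=10, seed=4))
        assert not trace.converged
        assert trace.iterations == 10
        assert validate(m) == []


class TestPerturbation:
    def test_noise_matrix_has_rank_two(self, atlas50):
        e = rank_two_noise(atlas50, primary_site=23, seed=0)
        assert np.linalg.matrix_rank(e) == 2

    def test_perturbation_magnitude_tracks_rel_size(self, atlas50):
        support = generate_support(atlas50, 27, seed=40)
        target = generate_target(atlas50, support, seed=41)
        generic = generate_generic(atlas50, support, seed=42)
        a0 = build_initial_matrix(target, generic, 23 if 23 in support else sorted(support)[0])
        e = rank_two_noise(a0.atlas, 23, seed=1)
        scale = 0.05 * a0.a.mean() / np.abs(e).mean()
        # mean absolute perturbation before clamping is 5% of the mean entry
        assert np.abs(scale * e).mean() == pytest.approx(0.05 * a0.a.mean(), rel=1e-12)

    def test_zero_rel_size_is_identity(self, atlas50):
        support = generate_support(atlas50, 10, seed=43)
        target = generate_target(atlas50, support, seed=44)
        generic = generate_generic(atlas50, support, seed=45)
        a0 = build_initial_matrix(target, generic, sorted(support)[0])
        assert np.array_equal(perturb_initial(a0, 0.0).a, a0.a)

    def test_perturbed_matrix_is_valid(self, atlas50):
        support = generate_support(atlas50, 10, seed=46)
        target = generate_target(atlas50, support, seed=47)
        generic = generate_generic(atlas50, support, seed=48)
        a0 = build_initial_matrix(target, generic, sorted(support)[0])
        p = perturb_initial(a0, 0.05, primary_site=sorted(support)[0], seed=2)
        assert validate(p) == []
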