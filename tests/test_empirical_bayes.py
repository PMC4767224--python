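import numpy as np
import pytest

from pebkit.gaussian_core import GaussianBelief, ParameterSpace, _sym, spd_inverse
from pebkit.empirical_bayes import (
    PEBOptions,
    SecondLevelModel,
    apply_shrinkage,
    peb_invert,
    peb_recursive,
    second_level_as_subject,
    second_level_free_energy,
)
from pebkit.model_space import bpa

from conftest import gaussian_evidence, make_linear_subject, space


def _group(rng, N=6, M=3, D=10, prior_var=0.5, s2=0.05, sigma_eps=0.04, X=None,
           beta_true=None):
    sp = space(M)
    prior = GaussianBelief.diagonal(sp, 0.0, prior_var)
    if X is None:
        X = np.column_stack([np.ones(N), np.r_[-np.ones(N // 2), np.ones(N - N // 2)]])
    if beta_true is None:
        beta_true = rng.normal(0, 0.3, (X.shape[1], M))
    thetas = X @ beta_true + rng.normal(0, np.sqrt(s2), (N, M))
    subjects, As = [], []
    for i in range(N):
        A = rng.standard_normal((D, M))
        subjects.append(make_linear_subject(rng, A, prior, sigma_eps, theta=thetas[i]))
        As.append(A)
    return subjects, As, X, beta_true, prior


def _pin_gamma(slm, s2):
    """Fix gamma so the between-subject covariance equals s2 * I exactly."""
    q0 = slm.Q0[0, 0]
    g0 = -np.log(1.0 / s2 - q0)
    slm.gamma_prior = GaussianBelief(
        slm.gamma_prior.space, np.array([g0]), np.zeros((1, 1)), np.zeros(1, dtype=bool)
    )
    return slm


class TestSecondLevelModel:
    def test_constant_column_enforced(self, rng):
        subjects, *_ = _group(rng, N=4)
        X = rng.standard_normal((4, 2))
        with pytest.raises(ValueError, match="constant"):
            SecondLevelModel.from_subjects(subjects, X)

    def test_rank_deficiency_rejected(self, rng):
        subjects, *_ = _group(rng, N=4)
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError, match="rank"):
            SecondLevelModel.from_subjects(subjects, X)

    def test_defaults(self, rng):
        subjects, _, X, _, prior = _group(rng, N=4, M=3, prior_var=0.5)
        slm = SecondLevelModel.from_subjects(subjects, X)
        assert slm.W.shape == (3, 3)
        assert len(slm.Q) == 1
        np.testing.assert_allclose(slm.Q0, 2.0**-4 * np.eye(3) / 0.5)
        # beta prior variances = first-level prior variances tiled over B
        np.testing.assert_allclose(np.diag(slm.beta_prior.cov), 0.5)
        np.testing.assert_allclose(np.diag(slm.gamma_prior.cov), 1.0)

    def test_column_subset_switches_beta_blocks(self, rng):
        subjects, _, X, _, _ = _group(rng, N=4, M=3)
        slm = SecondLevelModel.from_subjects(subjects, X)
        sub = slm.with_column_subset([0])
        assert sub.beta_prior.support[:3].all()
        assert not sub.beta_prior.support[3:].any()
        with pytest.raises(ValueError, match="constant"):
            slm.with_column_subset([1])


class TestSecondLevelFreeEnergy:
    def test_identity_reduction_recovers_subject_F(self, rng):
        """N=1, X=[1], beta pinned at the subject's full prior mean and
        gamma pinned so the between-subject covariance equals the full
        prior covariance: the empirical prior IS the full prior, the
        reduction is the identity and F2 = F_full exactly (no active
        second-level dimensions remain)."""
        sp = space(2)
        prior_var = 0.5
        prior = GaussianBelief.diagonal(sp, 0.3 * np.ones(2), prior_var)
        X = np.ones((1, 1))
        subj = make_linear_subject(rng, rng.standard_normal((8, 2)), prior, 0.1)
        slm = SecondLevelModel.from_subjects([subj], X, effect_names=("mean",))
        slm = _pin_gamma(slm, prior_var)
        slm.beta_prior = GaussianBelief(
            slm.beta_prior.space, prior.mean.copy(), np.zeros((2, 2)),
            np.zeros(2, dtype=bool),
        )
        mu2 = np.concatenate([prior.mean, slm.gamma_prior.mean])
        F2 = second_level_free_energy([subj], slm, mu2)
        assert F2 == pytest.approx(subj.evidence.F, abs=1e-9)

    def test_linear_optimum_matches_collapsed_evidence(self, rng):
        """F2 at the PEB optimum equals the exact log evidence of the
        collapsed hierarchical linear model (gamma pinned at truth)."""
        s2 = 0.05
        sigma_eps = 0.04
        subjects, As, X, beta_true, prior = _group(rng, s2=s2, sigma_eps=sigma_eps)
        N, M, D = len(subjects), 3, 10
        slm = SecondLevelModel.from_subjects(subjects, X, effect_names=("mean", "group"))
        slm = _pin_gamma(slm, s2)
        slp = peb_invert(subjects, slm)
        assert slp.converged
        # collapsed evidence: y ~ N(AK eta_b, AK Sb AK' + blkdiag(A s2 A' + Se))
        K = [np.kron(X[i], np.eye(M)) for i in range(N)]
        AK = np.vstack([As[i] @ K[i] for i in range(N)])
        C = AK @ slm.beta_prior.cov @ AK.T
        for i in range(N):
            blk = As[i] @ (s2 * np.eye(M)) @ As[i].T + sigma_eps * np.eye(D)
            C[i * D : (i + 1) * D, i * D : (i + 1) * D] += blk
        ystack = np.concatenate([s.data for s in subjects])
        logev = gaussian_evidence(ystack, AK @ slm.beta_prior.mean, C)
        assert slp.F2 == pytest.approx(logev, abs=1e-4)
        # the point-evaluation route agrees at the optimum
        mu2 = np.concatenate([slp.beta.mean, slp.gamma.mean])
        assert second_level_free_energy(subjects, slm, mu2) == pytest.approx(
            logev, abs=1e-4
        )

    def test_tighter_shrinkage_lowers_F2_on_spread_data(self, rng):
        """Subjects far apart: forcing a tight between-subject prior
        (more negative gamma under the exp(-gamma) convention) must lower
        F2 on a grid of gamma values."""
        sp = space(2)
        prior = GaussianBelief.diagonal(sp, 0.0, 4.0)
        subjects = []
        for m in (-4.0, 4.0):  # huge between-subject spread
            subjects.append(
                make_linear_subject(
                    rng,
                    np.eye(2),
                    prior,
                    0.01,
                    theta=np.full(2, m),
                )
            )
        X = np.ones((2, 1))
        slm = SecondLevelModel.from_subjects(subjects, X, effect_names=("mean",))
        vals = []
        for g in (1.0, 0.0, -2.0, -4.0):
            mu2 = np.concatenate([np.zeros(2), [g]])
            vals.append(second_level_free_energy(subjects, slm, mu2))
        # tightening the between-subject prior (decreasing gamma under the
        # exp(-gamma) convention) monotonically lowers F2 on spread data
        assert vals == sorted(vals, reverse=True)


class TestPEBInvert:
    def test_identical_subjects_pool_to_common_mean(self, rng):
        sp = space(2)
        prior = GaussianBelief.diagonal(sp, 0.0, 1.0)
        A = rng.standard_normal((10, 2))
        base = make_linear_subject(rng, A, prior, 0.05, theta=np.array([0.8, -0.4]))
        subjects = [base] * 5
        X = np.ones((5, 1))
        slm = SecondLevelModel.from_subjects(subjects, X, effect_names=("mean",))
        # near-flat beta prior so the group mean is data-driven
        slm.beta_prior = GaussianBelief.diagonal(slm.beta_prior.space, 0.0, 100.0)
        slp = peb_invert(subjects, slm)
        np.testing.assert_allclose(
            slp.beta.mean, base.full_posterior.mean, atol=5e-2
        )

    def test_matches_gls_oracle(self, rng):
        """Two-group linear study: beta means equal the collapsed-model GLS
        estimate with gamma profiled at the PEB value."""
        subjects, As, X, beta_true, prior = _group(rng, N=16, M=3, D=12)
        slm = SecondLevelModel.from_subjects(subjects, X, effect_names=("mean", "group"))
        slp = peb_invert(subjects, slm)
        assert slp.converged
        Sigma2 = spd_inverse(slm.within_precision(slp.gamma.mean))
        P = spd_inverse(slm.beta_prior.cov)
        h = P @ slm.beta_prior.mean
        for i, s in enumerate(subjects):
            AK = As[i] @ np.kron(X[i], np.eye(3))
            V = As[i] @ Sigma2 @ As[i].T + 0.04 * np.eye(As[i].shape[0])
            Vi = spd_inverse(_sym(V))
            P = P + AK.T @ Vi @ AK
            h = h + AK.T @ Vi @ s.data
        beta_gls = spd_inverse(_sym(P)) @ h
        assert np.abs(slp.beta.mean - beta_gls).max() <= 1e-3

    def test_trace_monotone_and_posterior_spd(self, rng):
        subjects, _, X, _, _ = _group(rng, N=8)
        slm = SecondLevelModel.from_subjects(subjects, X)
        slp = peb_invert(subjects, slm)
        assert np.all(np.diff(slp.trace) >= -1e-9)
        w = np.linalg.eigvalsh(slp.joint.sub_cov())
        assert w.min() > 0

    def test_hessian_paper_mode_runs(self, rng):
        subjects, _, X, _, _ = _group(rng, N=6)
        slm = SecondLevelModel.from_subjects(subjects, X)
        slp_c = peb_invert(subjects, slm, PEBOptions(hessian="consistent"))
        slp_p = peb_invert(subjects, slm, PEBOptions(hessian="paper"))
        # same mode, different covariance convention
        np.testing.assert_allclose(slp_c.beta.mean, slp_p.beta.mean, atol=1e-8)
        assert not np.allclose(slp_c.joint.cov, slp_p.joint.cov)
        with pytest.raises(ValueError, match="hessian"):
            peb_invert(subjects, slm, PEBOptions(hessian="bogus"))

    def test_fixed_effects_keep_full_priors(self, rng):
        """Parameters outside the random-effect mask keep their first-level
        priors in the empirical prior."""
        M = 3
        mask = np.array([True, True, False])
        sp = ParameterSpace(tuple(f"p{i}" for i in range(M)), mask)
        prior = GaussianBelief.diagonal(sp, 0.0, 0.5)
        subjects = [
            make_linear_subject(rng, rng.standard_normal((10, M)), prior, 0.05)
            for _ in range(4)
        ]
        X = np.ones((4, 1))
        slm = SecondLevelModel.from_subjects(subjects, X, effect_names=("mean",))
        assert slm.M_r == 2
        slp = peb_invert(subjects, slm)
        for ep in slp.empirical_priors:
            assert ep.cov[2, 2] == pytest.approx(0.5)
            assert ep.mean[2] == pytest.approx(0.0)


class TestShrinkage:
    def test_identity_empirical_prior_is_noop(self, rng):
        sp = space(2)
        prior = GaussianBelief.diagonal(sp, 0.0, 1.0)
        subj = make_linear_subject(rng, rng.standard_normal((8, 2)), prior, 0.1)
        out = apply_shrinkage(subj, prior)
        np.testing.assert_allclose(out.mean, subj.full_posterior.mean, atol=1e-9)
        np.testing.assert_allclose(out.cov, subj.full_posterior.cov, atol=1e-9)

    def test_tiny_variance_pins_to_group_mean(self, rng):
        sp = space(2)
        prior = GaussianBelief.diagonal(sp, 0.0, 1.0)
        subj = make_linear_subject(rng, rng.standard_normal((8, 2)), prior, 0.1)
        group_mean = np.array([0.5, -0.2])
        ep = GaussianBelief.diagonal(sp, group_mean, 1e-10)
        out = apply_shrinkage(subj, ep)
        np.testing.assert_allclose(out.mean, group_mean, atol=1e-4)

    def test_1d_intermediate_precision_strictly_between(self, rng):
        sp = space(1)
        prior = GaussianBelief.diagonal(sp, 0.0, 1.0)
        subj = make_linear_subject(
            rng, np.array([[1.0]]), prior, 0.2, theta=np.array([1.0])
        )
        mu_map = subj.full_posterior.mean[0]
        group_mean = 0.1
        ep = GaussianBelief.diagonal(sp, group_mean, 0.3)
        out = apply_shrinkage(subj, ep)
        lo, hi = sorted([group_mean, mu_map])
        assert lo < out.mean[0] < hi

    def test_shrinkage_moves_toward_empirical_mean(self, rng):
        """Mahalanobis distance to the empirical prior mean never grows."""
        subjects, _, X, _, _ = _group(rng, N=8)
        slm = SecondLevelModel.from_subjects(subjects, X)
        slp = peb_invert(subjects, slm)
        for subj, ep, shrunk in zip(
            subjects, slp.empirical_priors, slp.shrunk_posteriors
        ):
            Pi = ep.precision()
            d_before = subj.full_posterior.mean - ep.mean
            d_after = shrunk.mean - ep.mean
            assert d_after @ Pi @ d_after <= d_before @ Pi @ d_before + 1e-9


class TestRecursion:
    def test_identity_third_level_leaves_beta(self, rng):
        """A third level that exactly reproduces the second-level prior
        (beta3 pinned at the original prior mean, between-level covariance
        equal to the original beta prior) is a no-op: the shrunk posterior
        equals the second-level posterior to 1e-6 and dF3 = 0."""
        subjects, _, X, _, _ = _group(rng, N=6)
        slm = SecondLevelModel.from_subjects(subjects, X, effect_names=("mean", "group"))
        slp = peb_invert(subjects, slm)
        pseudo = second_level_as_subject(slp)
        X3 = np.ones((1, 1))
        slm3 = SecondLevelModel.from_subjects([pseudo], X3, effect_names=("mean",))
        nb = slp.slm.B * slp.slm.C
        # pin beta3 at the original prior mean
        slm3.beta_prior = GaussianBelief(
            slm3.beta_prior.space,
            slm.beta_prior.mean.copy(),
            np.zeros((nb, nb)),
            np.zeros(nb, dtype=bool),
        )
        # pin gamma3 so Sigma3 == the original (iid) beta prior variance
        v = slm.beta_prior.cov[0, 0]
        q0 = slm3.Q0[0, 0]
        g3 = -np.log(1.0 / v - q0)
        slm3.gamma_prior = GaussianBelief(
            slm3.gamma_prior.space, np.array([g3]), np.zeros((1, 1)),
            np.zeros(1, dtype=bool),
        )
        slp3 = peb_recursive(slp, slm3)
        shrunk = slp3.shrunk_posteriors[0]
        np.testing.assert_allclose(shrunk.mean[:nb], slp.joint.mean[:nb], atol=1e-6)
        assert slp3.F2 == pytest.approx(slp.F2, abs=1e-6)

    def test_two_posteriors_pool_like_bpa(self, rng):
        """Two second-level posteriors, X = [1; 1], near-zero third-level
        variance: the pooled beta matches the Bayesian parameter average."""
        slps = []
        for k in range(2):
            subjects, _, X, _, _ = _group(rng, N=6)
            slm = SecondLevelModel.from_subjects(subjects, X, effect_names=("mean", "group"))
            slps.append(peb_invert(subjects, slm))
        pseudos = [second_level_as_subject(s, random_effects="all") for s in slps]
        # shared prior across "subjects" (same second-level model family)
        pseudos[1].full_prior = pseudos[0].full_prior
        X3 = np.ones((2, 1))
        slm3 = SecondLevelModel.from_subjects(pseudos, X3, effect_names=("mean",))
        # the fused-parameter oracle counts the shared prior once: use it as
        # the beta3 prior, and make the between-posterior variance a delta
        shared = pseudos[0].full_prior
        slm3.beta_prior = GaussianBelief(
            slm3.beta_prior.space, shared.mean.copy(), shared.cov.copy()
        )
        slm3.gamma_prior = GaussianBelief(
            slm3.gamma_prior.space, np.array([-20.0]), np.zeros((1, 1)),
            np.zeros(1, dtype=bool),
        )
        slp3 = peb_invert(pseudos, slm3)
        fused = bpa(
            [p.full_posterior for p in pseudos], pseudos[0].full_prior
        )
        nb = slps[0].slm.B * slps[0].slm.C
        np.testing.assert_allclose(
            slp3.beta.mean, fused.mean[: slm3.B * slm3.C], atol=1e-3
        )
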