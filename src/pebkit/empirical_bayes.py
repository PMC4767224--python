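"""Parametric empirical Bayes over first-level posteriors.

The second (between-subject) level is linear in group effects ``beta`` via
the Kronecker design ``X (x) W`` and parameterises the between-subject
precision with log-precision weights ``gamma``:

    empirical prior mean for subject i :  (x_i (x) W) beta   (random effects)
    empirical prior precision         :  Q0 + sum_j exp(-gamma_j) Q_j

Fixed-effect parameters keep their full (first-level) priors.  The second
level is inverted from the subjects' full posteriors alone, using the
closed-form reduction of each subject under its empirical prior.  At the
Laplace fixed point (C2 = (Pi2 - H)^-1 with H the summed curvature of the
reduced free energies):

    F2 = sum_i dF_i + sum_i F_i - 1/2 dmu' Pi2 dmu + 1/2 ln|Pi2 C2|

The curvature of dF_i is analytic in beta (dF_i is quadratic in the
empirical prior mean) and obtained by central finite differences in gamma.
Vectorisation convention: beta is ordered with the within-subject index
fast, so ``np.kron(x_i, W) @ beta`` yields the subject's random-effect
block directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .gaussian_core import (
    GaussianBelief,
    ParameterSpace,
    _sym,
    logdet_psd,
    spd_inverse,
    spd_solve,
)
from .model_reduction import reduce as bmr_reduce
from .variational_laplace import SubjectInversion

__all__ = [
    "SecondLevelModel",
    "SecondLevelPosterior",
    "PEBOptions",
    "second_level_free_energy",
    "peb_invert",
    "apply_shrinkage",
    "peb_recursive",
    "random_effect_indices",
]

logger = logging.getLogger(__name__)

GAMMA_BOUND = 32.0


def random_effect_indices(subject: SubjectInversion) -> np.ndarray:
    """Dimensions treated as random effects: flagged in the space AND
    supported by the subject's full prior."""
    mask = subject.full_prior.space.random_effect_mask & subject.full_prior.support
    return np.flatnonzero(mask)


@dataclass
class SecondLevelModel:
    """Design and priors of the between-subject level."""

    X: np.ndarray
    W: np.ndarray
    Q0: np.ndarray
    Q: list[np.ndarray]
    beta_prior: GaussianBelief
    gamma_prior: GaussianBelief
    effect_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.Q0 = np.asarray(self.Q0, dtype=float)
        self.Q = [np.asarray(Qj, dtype=float) for Qj in self.Q]
        if not self.effect_names:
            self.effect_names = tuple(f"effect_{b}" for b in range(self.B))
        if len(self.effect_names) != self.B:
            raise ValueError("one effect name per design column required")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first column of the design matrix must be constant (ones)")
        if np.linalg.matrix_rank(self.X) < self.B:
            raise ValueError("design matrix is rank deficient")
        if not self.Q:
            raise ValueError("at least one precision component Q_j is required")
        if self.beta_prior.M != self.B * self.C:
            raise ValueError("beta prior dimension must be B*C")
        if self.gamma_prior.M != len(self.Q):
            raise ValueError("one gamma per precision component required")

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def B(self) -> int:
        return self.X.shape[1]

    @property
    def C(self) -> int:
        return self.W.shape[1]

    @property
    def M_r(self) -> int:
        return self.W.shape[0]

    def within_precision(self, gamma: np.ndarray) -> np.ndarray:
        """Between-subject precision Q0 + sum_j exp(-gamma_j) Q_j."""
        gamma = np.clip(np.atleast_1d(gamma), -GAMMA_BOUND, GAMMA_BOUND)
        Pi = self.Q0.copy()
        for gj, Qj in zip(gamma, self.Q):
            Pi = Pi + np.exp(-gj) * Qj
        return _sym(Pi)

    @classmethod
    def from_subjects(
        cls,
        subjects: Sequence[SubjectInversion],
        X: np.ndarray,
        effect_names: Sequence[str] | None = None,
        W: np.ndarray | str = "identity",
        Q0_scale: float = 2.0**-4,
        gamma_prior_var: float = 1.0,
    ) -> "SecondLevelModel":
        """Default second-level model for a group of inverted subjects.

        W = identity over random effects; a single iid precision component
        Q1 = I; precision floor Q0 = 2^-4 * diag(first-level prior
        precisions); gamma ~ N(0, 1); beta prior variances are the
        first-level full prior variances tiled over design columns.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ref = subjects[0]
        re_idx = random_effect_indices(ref)
        M_r = re_idx.size
        prior_var = np.diag(ref.full_prior.cov)[re_idx]
        if isinstance(W, str):
            if W != "identity":
                raise ValueError("W must be a matrix or 'identity'")
            W = np.eye(M_r)
        W = np.atleast_2d(np.asarray(W, dtype=float))
        if W.shape[0] != M_r:
            raise ValueError("W must have one row per random-effect parameter")
        C = W.shape[1]
        B = X.shape[1]
        Q0 = Q0_scale * np.diag(1.0 / prior_var)
        Q = [np.eye(M_r)]
        if effect_names is None:
            effect_names = tuple(f"effect_{b}" for b in range(B))
        re_names = tuple(ref.full_prior.space.names[i] for i in re_idx)
        if W.shape == (M_r, M_r) and np.allclose(W, np.eye(M_r)):
            col_names = re_names
            col_var = prior_var
        else:
            col_names = tuple(f"w{c}" for c in range(C))
            w2 = W**2
            col_var = (w2 * prior_var[:, None]).sum(axis=0) / w2.sum(axis=0)
        beta_names = tuple(
            f"{e}:{c}" for e in effect_names for c in col_names
        )
        beta_space = ParameterSpace(beta_names)
        beta_prior = GaussianBelief.diagonal(
            beta_space, 0.0, np.tile(col_var, B)
        )
        gamma_space = ParameterSpace(tuple(f"gamma_{j}" for j in range(len(Q))))
        gamma_prior = GaussianBelief.diagonal(gamma_space, 0.0, gamma_prior_var)
        return cls(X, W, Q0, Q, beta_prior, gamma_prior, tuple(effect_names))

    def with_beta_support(self, active: np.ndarray) -> "SecondLevelModel":
        """Copy with off-``active`` beta dimensions switched off (pinned at 0)."""
        active = np.asarray(active, dtype=bool)
        cov = self.beta_prior.cov.copy()
        off = ~active
        cov[off, :] = 0.0
        cov[:, off] = 0.0
        mean = self.beta_prior.mean.copy()
        mean[off] = 0.0
        bp = GaussianBelief(self.beta_prior.space, mean, cov, active)
        return replace(self, beta_prior=bp)

    def with_column_subset(self, columns: Sequence[int]) -> "SecondLevelModel":
        """Switch off all beta blocks of design columns not in ``columns``."""
        columns = sorted(set(int(c) for c in columns))
        if 0 not in columns:
            raise ValueError("the constant column must be retained")
        active = np.zeros(self.B * self.C, dtype=bool)
        for b in columns:
            active[b * self.C : (b + 1) * self.C] = True
        return self.with_beta_support(active & self.beta_prior.support)


@dataclass
class SecondLevelPosterior:
    """Joint Gaussian posterior over (beta, gamma) plus per-subject output."""

    beta: GaussianBelief
    gamma: GaussianBelief
    joint: GaussianBelief
    F2: float
    empirical_priors: list[GaussianBelief]
    shrunk_posteriors: list[GaussianBelief]
    slm: SecondLevelModel
    converged: bool = True
    trace: list = field(default_factory=list)

    @property
    def mu2(self) -> np.ndarray:
        return self.joint.mean


@dataclass
class PEBOptions:
    max_iter: int = 64
    tol: float = 1e-4
    n_converged: int = 4
    lm_init: float = 1.0 / 64.0
    lm_up: float = 8.0
    lm_down: float = 0.5
    gamma_step: float = 1e-3
    hessian: str = "consistent"  # "paper" omits the prior-precision term


class _SubjectCache:
    """Support-subspace sufficient statistics of one subject."""

    def __init__(self, subject: SubjectInversion):
        prior = subject.full_prior
        post = subject.full_posterior
        if np.any(post.support != prior.support):
            raise ValueError("subject posterior support must match its prior support")
        self.idx = np.flatnonzero(prior.support)
        self.eta_F = prior.mean[self.idx]
        Sigma_F = prior.sub_cov()
        self.Pi_F = spd_inverse(Sigma_F)
        self.mu_F = post.mean[self.idx]
        self.C_F = post.sub_cov()
        self.P_F = spd_inverse(self.C_F)
        self.a = self.P_F @ self.mu_F - self.Pi_F @ self.eta_F
        self.ld_Pi_F = logdet_psd(self.Pi_F)
        self.ld_P_F = logdet_psd(self.P_F)
        self.b_const = float(
            self.mu_F @ self.P_F @ self.mu_F - self.eta_F @ self.Pi_F @ self.eta_F
        )
        # positions of random-effect dims within the support subspace
        self.re_pos = np.flatnonzero(prior.space.random_effect_mask[self.idx])
        self.fe_pos = np.setdiff1d(np.arange(self.idx.size), self.re_pos)
        Sigma_FE = Sigma_F[np.ix_(self.fe_pos, self.fe_pos)]
        self.Pi_FE = spd_inverse(Sigma_FE) if self.fe_pos.size else np.zeros((0, 0))
        self.F = subject.evidence.F


class _GammaCache:
    """Per-gamma quantities shared by all beta evaluations."""

    def __init__(self, sc: _SubjectCache, Pi_w: np.ndarray):
        n = sc.idx.size
        Pi_R = np.zeros((n, n))
        Pi_R[np.ix_(sc.re_pos, sc.re_pos)] = Pi_w
        Pi_R[np.ix_(sc.fe_pos, sc.fe_pos)] = sc.Pi_FE
        self.Pi_R = Pi_R
        P_R = _sym(sc.P_F + Pi_R - sc.Pi_F)
        w = np.linalg.eigvalsh(P_R) if P_R.size else np.array([1.0])
        if w[0] <= 1e-12 * max(abs(w[-1]), 1.0):
            raise ValueError("empirical-prior reduced precision not positive definite")
        self.P_R = P_R
        self.C_R = spd_inverse(P_R)
        self.ld = 0.5 * (
            logdet_psd(Pi_R) - sc.ld_Pi_F + sc.ld_P_F - logdet_psd(P_R)
        )
        # curvature of dF w.r.t. the empirical prior mean
        self.Hess_eta = _sym(Pi_R @ self.C_R @ Pi_R - Pi_R)

    def delta_F(self, sc: _SubjectCache, eta_R: np.ndarray) -> float:
        u = sc.a + self.Pi_R @ eta_R
        mu_R = self.C_R @ u
        quad = sc.b_const + eta_R @ self.Pi_R @ eta_R - mu_R @ self.P_R @ mu_R
        return float(self.ld - 0.5 * quad)

    def grad_eta(self, sc: _SubjectCache, eta_R: np.ndarray) -> np.ndarray:
        mu_R = self.C_R @ (sc.a + self.Pi_R @ eta_R)
        return self.Pi_R @ (mu_R - eta_R)


def _build_eta_R(sc: _SubjectCache, K_beta: np.ndarray) -> np.ndarray:
    eta_R = sc.eta_F.copy()
    eta_R[sc.re_pos] = K_beta
    return eta_R


class _PEBProblem:
    """Evaluates sum_i dF_i and its derivatives as a function of (beta, gamma)."""

    def __init__(self, subjects: Sequence[SubjectInversion], slm: SecondLevelModel):
        if slm.X.shape[0] != len(subjects):
            raise ValueError("design matrix rows must match the number of subjects")
        self.slm = slm
        self.caches = [_SubjectCache(s) for s in subjects]
        M_r = self.caches[0].re_pos.size
        if slm.W.shape[0] != M_r:
            raise ValueError(
                f"W has {slm.W.shape[0]} rows but subjects expose {M_r} random effects"
            )
        self.K = [np.kron(slm.X[i], slm.W) for i in range(len(subjects))]

    def gamma_caches(self, gamma: np.ndarray) -> list[_GammaCache]:
        Pi_w = self.slm.within_precision(gamma)
        return [_GammaCache(sc, Pi_w) for sc in self.caches]

    def sum_dF(self, beta: np.ndarray, gcs: list[_GammaCache]) -> float:
        total = 0.0
        for sc, gc, K in zip(self.caches, gcs, self.K):
            total += gc.delta_F(sc, _build_eta_R(sc, K @ beta))
        return total

    def dF_list(self, beta: np.ndarray, gcs: list[_GammaCache]) -> np.ndarray:
        return np.array(
            [
                gc.delta_F(sc, _build_eta_R(sc, K @ beta))
                for sc, gc, K in zip(self.caches, gcs, self.K)
            ]
        )

    def grad_hess_beta(
        self, beta: np.ndarray, gcs: list[_GammaCache]
    ) -> tuple[np.ndarray, np.ndarray]:
        nb = beta.size
        g = np.zeros(nb)
        H = np.zeros((nb, nb))
        for sc, gc, K in zip(self.caches, gcs, self.K):
            eta_R = _build_eta_R(sc, K @ beta)
            ge = gc.grad_eta(sc, eta_R)
            g += K.T @ ge[sc.re_pos]
            H += K.T @ gc.Hess_eta[np.ix_(sc.re_pos, sc.re_pos)] @ K
        return g, _sym(H)


def _objective_terms(
    problem: _PEBProblem,
    slm: SecondLevelModel,
    beta: np.ndarray,
    gamma: np.ndarray,
    gcs: list[_GammaCache] | None = None,
) -> float:
    """sum_i dF_i - 1/2 (mu2 - eta2)' Pi2 (mu2 - eta2) on active dims."""
    gcs = gcs if gcs is not None else problem.gamma_caches(gamma)
    total = problem.sum_dF(beta, gcs)
    sb = slm.beta_prior.support
    sg = slm.gamma_prior.support
    db = (beta - slm.beta_prior.mean)[sb]
    dg = (gamma - slm.gamma_prior.mean)[sg]
    Pib = spd_inverse(slm.beta_prior.sub_cov()) if sb.any() else np.zeros((0, 0))
    Pig = spd_inverse(slm.gamma_prior.sub_cov()) if sg.any() else np.zeros((0, 0))
    total -= 0.5 * float(db @ Pib @ db) + 0.5 * float(dg @ Pig @ dg)
    return float(total)


def _full_grad_hess(
    problem: _PEBProblem,
    slm: SecondLevelModel,
    beta: np.ndarray,
    gamma: np.ndarray,
    h: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Objective, gradient and Hessian over active (beta, gamma) dims.

    Analytic in beta; central finite differences (step ``h``) in gamma,
    including the beta-gamma cross block.
    """
    sb = slm.beta_prior.support
    sg = slm.gamma_prior.support
    bi = np.flatnonzero(sb)
    gi = np.flatnonzero(sg)
    nb, ng = bi.size, gi.size

    gcs0 = problem.gamma_caches(gamma)
    f0 = problem.sum_dF(beta, gcs0)
    gb_full, Hb_full = problem.grad_hess_beta(beta, gcs0)
    gb = gb_full[bi]
    Hbb = Hb_full[np.ix_(bi, bi)]

    gg = np.zeros(ng)
    Hgg = np.zeros((ng, ng))
    Hbg = np.zeros((nb, ng))
    fp = np.zeros(ng)
    fm = np.zeros(ng)
    for a, j in enumerate(gi):
        gp = gamma.copy(); gp[j] += h
        gm = gamma.copy(); gm[j] -= h
        gcs_p = problem.gamma_caches(gp)
        gcs_m = problem.gamma_caches(gm)
        fp[a] = problem.sum_dF(beta, gcs_p)
        fm[a] = problem.sum_dF(beta, gcs_m)
        gg[a] = (fp[a] - fm[a]) / (2 * h)
        Hgg[a, a] = (fp[a] - 2 * f0 + fm[a]) / h**2
        gbp, _ = problem.grad_hess_beta(beta, gcs_p)
        gbm, _ = problem.grad_hess_beta(beta, gcs_m)
        Hbg[:, a] = (gbp[bi] - gbm[bi]) / (2 * h)
    for a in range(ng):
        for c in range(a + 1, ng):
            gpp = gamma.copy(); gpp[[gi[a], gi[c]]] += h
            gmm = gamma.copy(); gmm[[gi[a], gi[c]]] -= h
            gpm = gamma.copy(); gpm[gi[a]] += h; gpm[gi[c]] -= h
            gmp = gamma.copy(); gmp[gi[a]] -= h; gmp[gi[c]] += h
            val = (
                problem.sum_dF(beta, problem.gamma_caches(gpp))
                - problem.sum_dF(beta, problem.gamma_caches(gpm))
                - problem.sum_dF(beta, problem.gamma_caches(gmp))
                + problem.sum_dF(beta, problem.gamma_caches(gmm))
            ) / (4 * h**2)
            Hgg[a, c] = Hgg[c, a] = val

    # prior terms
    Pib = spd_inverse(slm.beta_prior.sub_cov()) if nb else np.zeros((0, 0))
    Pig = spd_inverse(slm.gamma_prior.sub_cov()) if ng else np.zeros((0, 0))
    db = (beta - slm.beta_prior.mean)[bi]
    dg = (gamma - slm.gamma_prior.mean)[gi]
    obj = f0 - 0.5 * float(db @ Pib @ db) - 0.5 * float(dg @ Pig @ dg)
    g = np.concatenate([gb - Pib @ db, gg - Pig @ dg])
    H = np.zeros((nb + ng, nb + ng))
    H[:nb, :nb] = Hbb - Pib
    H[nb:, nb:] = Hgg - Pig
    H[:nb, nb:] = Hbg
    H[nb:, :nb] = Hbg.T
    return obj, g, _sym(H)


def _prior_precision_active(slm: SecondLevelModel) -> np.ndarray:
    sb = slm.beta_prior.support
    sg = slm.gamma_prior.support
    nb, ng = int(sb.sum()), int(sg.sum())
    Pi = np.zeros((nb + ng, nb + ng))
    if nb:
        Pi[:nb, :nb] = spd_inverse(slm.beta_prior.sub_cov())
    if ng:
        Pi[nb:, nb:] = spd_inverse(slm.gamma_prior.sub_cov())
    return Pi


def empirical_prior_for(
    subject: SubjectInversion,
    slm: SecondLevelModel,
    mean_re: np.ndarray,
    Sigma_re: np.ndarray,
) -> GaussianBelief:
    """Subject's empirical prior: RE block replaced, FE priors unchanged.

    Cross-covariance between random- and fixed-effect dimensions is zeroed.
    """
    prior = subject.full_prior
    re_idx = random_effect_indices(subject)
    mean = prior.mean.copy()
    mean[re_idx] = mean_re
    cov = prior.cov.copy()
    cov[re_idx, :] = 0.0
    cov[:, re_idx] = 0.0
    cov[np.ix_(re_idx, re_idx)] = Sigma_re
    return GaussianBelief(prior.space, mean, _sym(cov), prior.support.copy())


def second_level_free_energy(
    subjects: Sequence[SubjectInversion],
    slm: SecondLevelModel,
    mu2: np.ndarray,
    opts: PEBOptions | None = None,
) -> float:
    """F2 at the given second-level means (beta then gamma, active dims full).

    Includes the Laplace normalisation 1/2 ln|Pi2 C2| with C2 from the local
    curvature (falling back to the prior covariance where the curvature is
    not negative definite).
    """
    opts = opts or PEBOptions()
    nb = slm.B * slm.C
    mu2 = np.asarray(mu2, dtype=float).reshape(-1)
    beta, gamma = mu2[:nb], mu2[nb:]
    problem = _PEBProblem(subjects, slm)
    obj, _, H = _full_grad_hess(problem, slm, beta, gamma, opts.gamma_step)
    Pi2 = _prior_precision_active(slm)
    P2 = _sym(-H)  # H already carries the prior curvature
    w = np.linalg.eigvalsh(P2) if P2.size else np.array([1.0])
    if P2.size and w[0] <= 0:
        P2 = Pi2  # fall back to the prior curvature
    sumF = float(sum(s.evidence.F for s in subjects))
    ld = 0.5 * (logdet_psd(Pi2) - logdet_psd(P2)) if P2.size else 0.0
    return float(obj + sumF + ld)


def peb_invert(
    subjects: Sequence[SubjectInversion],
    slm: SecondLevelModel,
    opts: PEBOptions | None = None,
) -> SecondLevelPosterior:
    """Invert the second level by LM-damped Newton ascent on (beta, gamma)."""
    opts = opts or PEBOptions()
    if opts.hessian not in ("consistent", "paper"):
        raise ValueError("hessian mode must be 'consistent' or 'paper'")
    problem = _PEBProblem(subjects, slm)
    nb_full = slm.B * slm.C
    sb = slm.beta_prior.support
    sg = slm.gamma_prior.support
    bi = np.flatnonzero(sb)
    gi = np.flatnonzero(sg)
    nb, ng = bi.size, gi.size

    # initialise beta by OLS of subject posterior means on the design
    beta = slm.beta_prior.mean.copy()
    if nb:
        Y = np.stack([sc.mu_F[sc.re_pos] for sc in problem.caches])  # N x M_r
        XtX = slm.X.T @ slm.X
        Bhat = np.linalg.solve(XtX, slm.X.T @ Y)  # B x M_r
        Wpinv = np.linalg.pinv(slm.W)
        ols = (Bhat @ Wpinv.T).reshape(-1)  # beta blocks, within-subject fast
        beta[bi] = ols[bi]
    gamma = slm.gamma_prior.mean.copy()

    obj, g, H = _full_grad_hess(problem, slm, beta, gamma, opts.gamma_step)
    trace = [obj]
    lm = opts.lm_init
    n_small = 0
    converged = False
    for _ in range(opts.max_iter):
        prev = obj
        negH = _sym(-H)
        w = np.linalg.eigvalsh(negH) if negH.size else np.array([1.0])
        accepted = False
        # inner Levenberg-Marquardt loop: damp until the step ascends (the
        # gamma surface can be locally convex far from the optimum)
        while lm < 1e9:
            shift = max(0.0, -w[0]) + lm if negH.size else 0.0
            if negH.size:
                step = spd_solve(negH + shift * np.eye(negH.shape[0]), g)
            else:
                step = np.zeros(0)
            cand_b = beta.copy()
            cand_g = gamma.copy()
            cand_b[bi] = beta[bi] + step[:nb]
            cand_g[gi] = np.clip(gamma[gi] + step[nb:], -GAMMA_BOUND, GAMMA_BOUND)
            cand_obj = _objective_terms(problem, slm, cand_b, cand_g)
            if cand_obj > obj - 1e-12:
                beta, gamma = cand_b, cand_g
                obj = cand_obj
                lm = max(lm * opts.lm_down, 1e-8)
                accepted = True
                break
            lm *= opts.lm_up
        if accepted:
            obj, g, H = _full_grad_hess(problem, slm, beta, gamma, opts.gamma_step)
        trace.append(obj)
        if abs(obj - prev) < opts.tol:
            n_small += 1
            if n_small >= opts.n_converged:
                converged = True
                break
        else:
            n_small = 0
    if not converged:
        logger.warning("peb_invert: no convergence after %d iterations", opts.max_iter)

    # posterior precision over active (beta, gamma)
    Pi2 = _prior_precision_active(slm)
    H_curv = H + Pi2  # summed dF curvature alone (prior added back)
    if opts.hessian == "consistent":
        P2 = _sym(Pi2 - H_curv)
    else:
        P2 = _sym(-H_curv)
    if P2.size:
        w = np.linalg.eigvalsh(P2)
        if w[0] <= 0:
            P2 = P2 + (1e-8 + abs(w[0])) * np.eye(P2.shape[0])
        C2 = spd_inverse(P2)
    else:
        C2 = P2

    # assemble full-dimension joint belief over (beta, gamma)
    act = np.concatenate([bi, nb_full + gi])
    M2 = nb_full + slm.gamma_prior.M
    mean2 = np.concatenate([beta, gamma])
    cov2 = np.zeros((M2, M2))
    cov2[np.ix_(act, act)] = C2
    support2 = np.zeros(M2, dtype=bool)
    support2[act] = True
    joint_space = ParameterSpace(
        tuple(slm.beta_prior.space.names) + tuple(slm.gamma_prior.space.names),
        np.concatenate(
            [np.ones(nb_full, dtype=bool), np.zeros(slm.gamma_prior.M, dtype=bool)]
        ),
    )
    joint = GaussianBelief(joint_space, mean2, cov2, support2)
    beta_belief = joint.marginal(np.arange(nb_full))
    gamma_belief = joint.marginal(np.arange(nb_full, M2))

    # F2 at the optimum: obj + sum_i F_i + 1/2 ln|Pi2 C2| (consistent C2)
    P2c = _sym(Pi2 - H_curv)
    wc = np.linalg.eigvalsh(P2c) if P2c.size else np.array([1.0])
    ldC2 = -logdet_psd(P2c) if (P2c.size and wc[0] > 0) else (
        -logdet_psd(Pi2) if Pi2.size else 0.0
    )
    sumF = float(sum(s.evidence.F for s in subjects))
    F2 = float(obj + sumF + 0.5 * ((logdet_psd(Pi2) if Pi2.size else 0.0) + ldC2))

    Sigma_re = spd_inverse(slm.within_precision(gamma))
    empirical_priors = []
    shrunk = []
    for i, subj in enumerate(subjects):
        mean_re = problem.K[i] @ beta
        ep = empirical_prior_for(subj, slm, mean_re, Sigma_re)
        empirical_priors.append(ep)
        shrunk.append(apply_shrinkage(subj, ep))

    return SecondLevelPosterior(
        beta=beta_belief,
        gamma=gamma_belief,
        joint=joint,
        F2=F2,
        empirical_priors=empirical_priors,
        shrunk_posteriors=shrunk,
        slm=slm,
        converged=converged,
        trace=trace,
    )


def apply_shrinkage(
    subject: SubjectInversion, empirical_prior: GaussianBelief
) -> GaussianBelief:
    """Subject posterior under the empirical (shrinkage) prior."""
    res = bmr_reduce(
        subject.full_prior, subject.full_posterior, empirical_prior, subject.evidence.F
    )
    return res.reduced_posterior


def peb_recursive(
    slp: SecondLevelPosterior, higher_slm: SecondLevelModel, opts: PEBOptions | None = None
) -> SecondLevelPosterior:
    """Apply PEB again, treating a second-level posterior as a single subject."""
    return peb_invert([second_level_as_subject(slp)], higher_slm, opts)


def second_level_as_subject(
    slp: SecondLevelPosterior, random_effects: str = "beta"
) -> SubjectInversion:
    """Package (beta, gamma) posterior as a pseudo-subject for recursion.

    The joint prior over (beta, gamma) plays the role of the full prior and
    F2 the role of the subject free energy.  ``random_effects`` selects
    which joint dimensions the next level may shrink ("beta" or "all").
    """
    slm = slp.slm
    nb = slm.B * slm.C
    M2 = nb + slm.gamma_prior.M
    mean = np.concatenate([slm.beta_prior.mean, slm.gamma_prior.mean])
    cov = np.zeros((M2, M2))
    cov[:nb, :nb] = slm.beta_prior.cov
    cov[nb:, nb:] = slm.gamma_prior.cov
    support = np.concatenate([slm.beta_prior.support, slm.gamma_prior.support])
    if random_effects == "all":
        re_mask = np.ones(M2, dtype=bool)
    elif random_effects == "beta":
        re_mask = np.concatenate(
            [np.ones(nb, dtype=bool), np.zeros(slm.gamma_prior.M, dtype=bool)]
        )
    else:
        raise ValueError("random_effects must be 'beta' or 'all'")
    joint_space = ParameterSpace(slp.joint.space.names, re_mask)
    prior = GaussianBelief(joint_space, mean, cov, support)
    posterior = GaussianBelief(
        joint_space, slp.joint.mean, slp.joint.cov, slp.joint.support
    )
    from .gaussian_core import EvidenceRecord

    return SubjectInversion(
        data=np.zeros(0),
        full_prior=prior,
        full_posterior=posterior,
        hyper_posterior=GaussianBelief.diagonal(ParameterSpace(("none",)), 0.0, 1.0),
        evidence=EvidenceRecord(slp.F2, slp.F2, 0.0),
        trace=[slp.F2],
    )
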