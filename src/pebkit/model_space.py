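"""Operators over the subjects x models array.

Fixed- and random-effects model comparison, Bayesian model/parameter
averaging, the exhaustive/greedy search over second-level parameter subsets,
and the joint first x second level comparison.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma

from .empirical_bayes import (
    PEBOptions,
    SecondLevelModel,
    SecondLevelPosterior,
    peb_invert,
)
from .gaussian_core import GaussianBelief, _sym, spd_inverse
from .model_reduction import ModelDefinition, ReductionResult, reduce, score_model_set
from .variational_laplace import SubjectInversion

__all__ = [
    "ModelArray",
    "ffx_bmc",
    "rfx_bmc",
    "bma",
    "bpa",
    "peb_bmc_search",
    "joint_bmc_peb",
    "softmax",
]

logger = logging.getLogger(__name__)

DEFAULT_OCCAM_WINDOW = 8.0


def softmax(F: np.ndarray, axis: int | None = None) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    z = F - F.max(axis=axis, keepdims=axis is not None)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=axis is not None)


@dataclass
class ModelArray:
    """Free energies and posteriors over N subjects x K models.

    The full model occupies the first column by convention.
    """

    subjects: list[SubjectInversion]
    models: list[ModelDefinition]
    F: np.ndarray
    posteriors: list[list[GaussianBelief]]

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if not np.all(np.isfinite(self.F)):
            raise ValueError("free-energy matrix contains non-finite entries")

    @classmethod
    def from_reduction(
        cls, subjects: Sequence[SubjectInversion], models: Sequence[ModelDefinition]
    ) -> "ModelArray":
        """Score every model for every subject by Bayesian model reduction."""
        F = np.zeros((len(subjects), len(models)))
        posteriors: list[list[GaussianBelief]] = []
        for i, subj in enumerate(subjects):
            row = score_model_set(
                subj.full_prior, subj.full_posterior, models, subj.evidence.F
            )
            posteriors.append([res.reduced_posterior for _, res in row])
            F[i] = [res.F_R for _, res in row]
        return cls(list(subjects), list(models), F, posteriors)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (subject, model, F, prob) table; prob is FFX per subject."""
        rows = []
        for i in range(self.F.shape[0]):
            probs = softmax(self.F[i])
            for k, model in enumerate(self.models):
                rows.append(
                    {"subject": i, "model": model.name, "F": self.F[i, k], "prob": probs[k]}
                )
        return pd.DataFrame(rows)


def ffx_bmc(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-effects comparison: sum free energies over subjects, softmax."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    group_F = F.sum(axis=0)
    return group_F, softmax(group_F)


def rfx_bmc(
    F: np.ndarray,
    alpha0: float = 1.0,
    n_samples: int = 100_000,
    seed: int = 0,
    max_iter: int = 256,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random-effects comparison via variational Dirichlet updates.

    Returns (alpha, expected frequencies, exceedance probabilities); the
    exceedance probabilities are estimated by seeded Dirichlet sampling.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    N, K = F.shape
    alpha = np.full(K, alpha0)
    for _ in range(max_iter):
        logu = F + (digamma(alpha) - digamma(alpha.sum()))
        g = softmax(logu, axis=1)
        new_alpha = alpha0 + g.sum(axis=0)
        if np.abs(new_alpha - alpha).max() < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    else:
        logger.warning("rfx_bmc: Dirichlet updates did not converge")
    freq = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=K) / n_samples
    return alpha, freq, xp


@dataclass
class BMAResult:
    """Mixture-of-posteriors summary for one subject."""

    mean: np.ndarray
    cov: np.ndarray
    weights: np.ndarray
    samples: np.ndarray
    members: np.ndarray  # indices of models inside the Occam window


def bma(
    posteriors: Sequence[GaussianBelief],
    F: np.ndarray,
    window: float = DEFAULT_OCCAM_WINDOW,
    n_samples: int = 10_000,
    seed: int = 0,
) -> BMAResult:
    """Bayesian model average: softmax-weighted mixture of posteriors.

    Models further than ``window`` nats below the best are excluded (the
    best model is always included).  Returns analytic mixture moments and
    seeded samples from the mixture.
    """
    F = np.asarray(F, dtype=float)
    keep = np.flatnonzero(F >= F.max() - window)
    w = softmax(F[keep])
    mean = np.zeros(posteriors[0].M)
    for wk, k in zip(w, keep):
        mean += wk * posteriors[k].mean
    cov = np.zeros((mean.size, mean.size))
    for wk, k in zip(w, keep):
        d = posteriors[k].mean - mean
        cov += wk * (posteriors[k].cov + np.outer(d, d))
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_samples, w)
    chunks = [
        posteriors[k].sample(rng, int(c)) for k, c in zip(keep, counts) if c > 0
    ]
    samples = np.concatenate(chunks, axis=0) if chunks else np.zeros((0, mean.size))
    rng.shuffle(samples, axis=0)
    return BMAResult(mean, _sym(cov), w, samples, keep)


def bpa(
    posteriors: Sequence[GaussianBelief], prior: GaussianBelief
) -> GaussianBelief:
    """Bayesian parameter average: fuse one model's posteriors over subjects.

    P = sum_i P_i - (N-1) Pi_prior;  mean = P^-1 (sum_i P_i mu_i - (N-1) Pi eta)
    """
    N = len(posteriors)
    s = prior.support
    idx = np.flatnonzero(s)
    Pi = spd_inverse(prior.sub_cov())
    P = -(N - 1) * Pi
    h = -(N - 1) * (Pi @ prior.mean[idx])
    for q in posteriors:
        if q.space.names != prior.space.names:
            raise ValueError("posterior space mismatch in bpa")
        Pq = spd_inverse(q.cov[np.ix_(idx, idx)])
        P = P + Pq
        h = h + Pq @ q.mean[idx]
    P = _sym(P)
    w = np.linalg.eigvalsh(P)
    if w[0] <= 0:
        raise ValueError("fused posterior precision is not positive definite")
    C = spd_inverse(P)
    mean = prior.mean.copy()
    mean[idx] = C @ h
    cov = np.zeros_like(prior.cov)
    cov[np.ix_(idx, idx)] = C
    return GaussianBelief(prior.space, mean, cov, s.copy())


# -- second-level model search ---------------------------------------------


@dataclass
class PEBSearchResult:
    table: pd.DataFrame
    best_subset: tuple[int, ...]
    bma_mean: np.ndarray
    bma_cov: np.ndarray
    candidates: tuple[int, ...]
    exhaustive: bool


def _second_level_prior(slp: SecondLevelPosterior) -> GaussianBelief:
    slm = slp.slm
    nb = slm.B * slm.C
    M2 = nb + slm.gamma_prior.M
    mean = np.concatenate([slm.beta_prior.mean, slm.gamma_prior.mean])
    cov = np.zeros((M2, M2))
    cov[:nb, :nb] = slm.beta_prior.cov
    cov[nb:, nb:] = slm.gamma_prior.cov
    support = np.concatenate([slm.beta_prior.support, slm.gamma_prior.support])
    return GaussianBelief(slp.joint.space, mean, cov, support)


def _subset_reduction(
    slp: SecondLevelPosterior,
    prior: GaussianBelief,
    candidates: np.ndarray,
    subset: tuple[int, ...],
) -> ReductionResult:
    off = np.setdiff1d(candidates, np.asarray(subset, dtype=int))
    reduced_support = prior.support.copy()
    reduced_support[off] = False
    mean = prior.mean.copy()
    mean[off] = 0.0
    cov = prior.cov.copy()
    cov[off, :] = 0.0
    cov[:, off] = 0.0
    reduced_prior = GaussianBelief(prior.space, mean, cov, reduced_support)
    return reduce(prior, slp.joint, reduced_prior, slp.F2)


def peb_bmc_search(
    slp: SecondLevelPosterior,
    candidates: Sequence[int] | None = None,
    window: float = DEFAULT_OCCAM_WINDOW,
    max_exhaustive: int = 16,
) -> PEBSearchResult:
    """Score combinations of second-level (beta) parameters by reduction.

    Candidates default to all beta entries of non-constant design columns;
    the constant-column block is always retained.  Exhaustive over the
    subset lattice when there are at most ``max_exhaustive`` candidates,
    otherwise greedy backward elimination (remove the candidate with the
    largest free-energy gain until no single removal raises F; ties broken
    by lowest parameter index).  Returns the subset table and a
    Bayesian-model-average of beta over retained models.
    """
    slm = slp.slm
    nb = slm.B * slm.C
    prior = _second_level_prior(slp)
    if candidates is None:
        candidates = [
            b * slm.C + c
            for b in range(1, slm.B)
            for c in range(slm.C)
            if prior.support[b * slm.C + c]
        ]
    candidates = np.asarray(sorted(set(int(c) for c in candidates)), dtype=int)
    if np.any(candidates >= nb):
        raise ValueError("candidates must index beta dimensions")

    results: dict[tuple[int, ...], ReductionResult] = {}
    exhaustive = candidates.size <= max_exhaustive
    if exhaustive:
        for r in range(candidates.size + 1):
            for comb in itertools.combinations(candidates.tolist(), r):
                results[comb] = _subset_reduction(slp, prior, candidates, comb)
    else:
        current = tuple(candidates.tolist())
        results[current] = _subset_reduction(slp, prior, candidates, current)
        improved = True
        while improved and current:
            improved = False
            best_gain, best_sub = 0.0, None
            for c in current:  # ascending index order; ties keep the first
                sub = tuple(x for x in current if x != c)
                if sub not in results:
                    results[sub] = _subset_reduction(slp, prior, candidates, sub)
                gain = results[sub].F_R - results[current].F_R
                if gain > best_gain + 1e-12:
                    best_gain, best_sub = gain, sub
            if best_sub is not None:
                current = best_sub
                improved = True

    subsets = list(results.keys())
    Fs = np.array([results[s].F_R for s in subsets])
    order = np.argsort(-Fs)
    table = pd.DataFrame(
        {
            "subset": [subsets[i] for i in order],
            "n_on": [len(subsets[i]) for i in order],
            "F": Fs[order],
            "prob": softmax(Fs)[order],
        }
    )
    best_subset = subsets[int(np.argmax(Fs))]

    keep = np.flatnonzero(Fs >= Fs.max() - window)
    w = softmax(Fs[keep])
    mean = np.zeros(nb)
    cov = np.zeros((nb, nb))
    for wk, i in zip(w, keep):
        mu = results[subsets[i]].reduced_posterior.mean[:nb]
        mean += wk * mu
    for wk, i in zip(w, keep):
        post = results[subsets[i]].reduced_posterior
        d = post.mean[:nb] - mean
        cov += wk * (post.cov[:nb, :nb] + np.outer(d, d))
    return PEBSearchResult(table, tuple(best_subset), mean, _sym(cov), tuple(candidates.tolist()), exhaustive)


# -- joint first x second level comparison ---------------------------------


@dataclass
class JointComparisonResult:
    F: np.ndarray  # K1 x K2 grid of second-level free energies
    prob: np.ndarray  # joint posterior probabilities (softmax over the grid)
    first_marginal: np.ndarray
    second_marginal: np.ndarray
    first_models: list[ModelDefinition]
    second_models: list[tuple[int, ...]]
    posteriors: list = field(default_factory=list)


def _reduced_subjects(
    subjects: Sequence[SubjectInversion], model: ModelDefinition
) -> list[SubjectInversion]:
    out = []
    for subj in subjects:
        res = reduce(
            subj.full_prior, subj.full_posterior, model.reduced_prior, subj.evidence.F
        )
        from .gaussian_core import EvidenceRecord

        out.append(
            SubjectInversion(
                data=subj.data,
                full_prior=model.reduced_prior,
                full_posterior=res.reduced_posterior,
                hyper_posterior=subj.hyper_posterior,
                evidence=EvidenceRecord(res.F_R, res.F_R, 0.0),
                trace=[res.F_R],
                converged=subj.converged,
            )
        )
    return out


def joint_bmc_peb(
    subjects: Sequence[SubjectInversion],
    first_models: Sequence[ModelDefinition],
    X: np.ndarray,
    second_models: Sequence[Sequence[int]] | None = None,
    effect_names: Sequence[str] | None = None,
    opts: PEBOptions | None = None,
) -> JointComparisonResult:
    """Score every (first-level model, design-column subset) pair by PEB.

    Each first-level model is applied to the subjects by Bayesian model
    reduction; the second level is then inverted under each column subset
    (the constant column is mandatory).  All resulting free energies are
    functions of the same data, hence directly comparable; marginal model
    probabilities are row/column sums of the softmax over the grid.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B = X.shape[1]
    if second_models is None:
        second_models = [
            (0,) + comb
            for r in range(B)
            for comb in itertools.combinations(range(1, B), r)
        ]
    second_models = [tuple(sorted(set(int(c) for c in sm))) for sm in second_models]
    for sm in second_models:
        if 0 not in sm:
            raise ValueError("every second-level model must include the constant column")

    K1, K2 = len(first_models), len(second_models)
    F = np.zeros((K1, K2))
    posteriors: list[list[SecondLevelPosterior]] = []
    for k1, fm in enumerate(first_models):
        red = _reduced_subjects(subjects, fm)
        re_mask = red[0].full_prior.space.random_effect_mask & red[0].full_prior.support
        row = []
        if not np.any(re_mask):
            # no random effects survive this first-level model: the second
            # level is empty and every column subset scores the same
            F[k1, :] = sum(s.evidence.F for s in red)
            posteriors.append([None] * K2)
            continue
        slm_full = SecondLevelModel.from_subjects(red, X, effect_names=effect_names)
        for k2, cols in enumerate(second_models):
            slm = slm_full.with_column_subset(cols)
            slp = peb_invert(red, slm, opts)
            F[k1, k2] = slp.F2
            row.append(slp)
        posteriors.append(row)

    prob = softmax(F)
    return JointComparisonResult(
        F=F,
        prob=prob,
        first_marginal=prob.sum(axis=1),
        second_marginal=prob.sum(axis=0),
        first_models=list(first_models),
        second_models=second_models,
        posteriors=posteriors,
    )
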