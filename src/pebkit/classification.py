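"""Predictive inference on unknown design-matrix entries for test subjects.

The roles of design entries and group effects are swapped: with trained
expectations (beta~, gamma~), the empirical prior mean of a test subject is
(x (x) W) beta~, an explicit linear function of the subject's design row x.
Maximising the subject's reduced free energy over the unknown entries of x
(with tight priors pinning the known ones) yields a Gaussian posterior over
the unknown explanatory variables; point reductions at categorical values
then give Savage-Dickey label probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .empirical_bayes import (
    PEBOptions,
    SecondLevelModel,
    SecondLevelPosterior,
    _GammaCache,
    _SubjectCache,
    _build_eta_R,
    peb_invert,
)
from .gaussian_core import GaussianBelief, ParameterSpace, _sym, spd_inverse, spd_solve
from .model_reduction import reduce_point
from .model_space import softmax
from .variational_laplace import SubjectInversion

__all__ = [
    "PredictiveTask",
    "posterior_predictive",
    "categorical_probability",
    "loo_cross_validation",
]

logger = logging.getLogger(__name__)

TIGHT_VARIANCE = 1e-8
UNKNOWN_PRIOR_VARIANCE = 1.0


@dataclass
class PredictiveTask:
    """A trained second level, a test subject and the known/unknown split."""

    trained: SecondLevelPosterior
    test: SubjectInversion
    known: Mapping[int, float]
    unknown: Sequence[int]
    unknown_prior_var: float = UNKNOWN_PRIOR_VARIANCE
    tight_var: float = TIGHT_VARIANCE

    def __post_init__(self) -> None:
        B = self.trained.slm.B
        cols = set(self.known) | set(self.unknown)
        if cols != set(range(B)):
            raise ValueError("known and unknown must cover all design columns")
        if set(self.known) & set(self.unknown):
            raise ValueError("a column cannot be both known and unknown")
        if 0 in self.unknown:
            raise ValueError("the constant column is always known (value 1)")
        if not np.isclose(self.known.get(0, 1.0), 1.0):
            raise ValueError("the constant column must be fixed at 1")

    def design_prior(self) -> GaussianBelief:
        """Prior over the full design row x (tight on known entries)."""
        slm = self.trained.slm
        space = ParameterSpace(tuple(f"x:{e}" for e in slm.effect_names))
        mean = np.zeros(slm.B)
        var = np.full(slm.B, self.unknown_prior_var)
        for b, v in self.known.items():
            mean[b] = v
            var[b] = self.tight_var
        return GaussianBelief.diagonal(space, mean, var)


@dataclass
class PredictivePosterior:
    unknown: GaussianBelief
    joint: GaussianBelief  # over the full design row
    prior: GaussianBelief
    delta_F: float


def _design_map(slp: SecondLevelPosterior) -> np.ndarray:
    """T with T[:, b] = W @ beta_block_b, so that eta_RE = T @ x."""
    slm = slp.slm
    beta = slp.beta.mean
    T = np.zeros((slm.M_r, slm.B))
    for b in range(slm.B):
        T[:, b] = slm.W @ beta[b * slm.C : (b + 1) * slm.C]
    return T


def posterior_predictive(task: PredictiveTask, opts: PEBOptions | None = None) -> PredictivePosterior:
    """Gaussian posterior over the unknown design entries of the test subject.

    The reduced free energy is an explicit quadratic in the design row x
    (the empirical prior mean is linear in x and the covariance is fixed at
    the trained gamma expectation), so the Laplace ascent is an exact
    Newton solve.
    """
    if not task.unknown:
        slm = task.trained.slm
        space = ParameterSpace(())
        empty = GaussianBelief(space, np.zeros(0), np.zeros((0, 0)), np.zeros(0, dtype=bool))
        prior = task.design_prior()
        return PredictivePosterior(empty, prior, prior, 0.0)

    slm = task.trained.slm
    prior_x = task.design_prior()
    sc = _SubjectCache(task.test)
    if sc.re_pos.size != slm.M_r:
        raise ValueError("test subject does not expose the trained random effects")
    gamma = task.trained.gamma.mean
    gc = _GammaCache(sc, slm.within_precision(gamma))
    T = _design_map(task.trained)

    Pi_x = spd_inverse(prior_x.cov)
    eta_x = prior_x.mean

    # dF(x) is quadratic: Newton from the prior mean is exact; iterate twice
    # to wash out rounding.
    x = eta_x.copy()
    for _ in range(2):
        eta_R = _build_eta_R(sc, T @ x)
        ge = gc.grad_eta(sc, eta_R)[sc.re_pos]
        g = T.T @ ge - Pi_x @ (x - eta_x)
        H = _sym(T.T @ gc.Hess_eta[np.ix_(sc.re_pos, sc.re_pos)] @ T - Pi_x)
        x = x + spd_solve(-H, g)
    P_post = _sym(Pi_x - T.T @ gc.Hess_eta[np.ix_(sc.re_pos, sc.re_pos)] @ T)
    C_post = spd_inverse(P_post)
    joint = GaussianBelief(prior_x.space, x, C_post)
    dF = gc.delta_F(sc, _build_eta_R(sc, T @ x))
    unknown_idx = np.asarray(sorted(task.unknown), dtype=int)
    return PredictivePosterior(
        unknown=joint.marginal(unknown_idx),
        joint=joint,
        prior=prior_x,
        delta_F=float(dF),
    )


def categorical_probability(
    task: PredictiveTask,
    labels: Sequence[float] | Sequence[Sequence[float]],
    predictive: PredictivePosterior | None = None,
) -> np.ndarray:
    """Probability of each categorical assignment of the unknown entries.

    Each label pins the unknown design entries exactly (zero reduced
    variance); the reduced free energies are Savage-Dickey log density
    ratios and the probabilities their softmax.
    """
    pp = predictive if predictive is not None else posterior_predictive(task)
    unknown_idx = np.asarray(sorted(task.unknown), dtype=int)
    logF = []
    for lab in labels:
        values = np.atleast_1d(np.asarray(lab, dtype=float))
        if values.size != unknown_idx.size:
            raise ValueError("label dimension must match the number of unknown columns")
        dF, _ = reduce_point(pp.prior, pp.joint, unknown_idx, values)
        logF.append(dF)
    return softmax(np.asarray(logF))


def loo_cross_validation(
    subjects: Sequence[SubjectInversion],
    X: np.ndarray,
    unknown_column: int,
    labels: Sequence[float] | None = None,
    effect_names: Sequence[str] | None = None,
    opts: PEBOptions | None = None,
) -> pd.DataFrame:
    """Leave-one-out predictive classification over a group.

    For each held-out subject, the second level is re-estimated on the
    remaining subjects and the unknown design entry predicted from the
    trained expectations.  Returns one row per fold with the predictive
    mean/sd and the categorical probability of each label.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N, B = X.shape
    if N < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    if unknown_column == 0:
        raise ValueError("cannot leave out the constant column")
    if labels is None:
        labels = sorted(set(np.round(X[:, unknown_column], 12).tolist()))
    labels = [float(l) for l in labels]

    rows = []
    for i in range(N):
        train_idx = [j for j in range(N) if j != i]
        X_train = X[train_idx]
        train_subjects = [subjects[j] for j in train_idx]
        slm = SecondLevelModel.from_subjects(train_subjects, X_train, effect_names=effect_names)
        slp = peb_invert(train_subjects, slm, opts)
        known = {
            b: float(X[i, b]) for b in range(B) if b != unknown_column
        }
        task = PredictiveTask(slp, subjects[i], known, [unknown_column])
        pp = posterior_predictive(task)
        probs = categorical_probability(task, labels, predictive=pp)
        truth = float(X[i, unknown_column])
        pred_label = labels[int(np.argmax(probs))]
        row = {
            "subject": i,
            "truth": truth,
            "posterior_mean": float(pp.unknown.mean[0]),
            "posterior_sd": float(np.sqrt(pp.unknown.cov[0, 0])),
            "predicted": pred_label,
            "correct": bool(np.isclose(pred_label, truth)),
            "converged": bool(slp.converged),
        }
        for lab, p in zip(labels, probs):
            row[f"P({lab:g})"] = float(p)
        row["P(correct)"] = float(probs[labels.index(truth)]) if truth in labels else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
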