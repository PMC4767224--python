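"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from pebkit.gaussian_core import (
    LOG2PI,
    EvidenceRecord,
    GaussianBelief,
    ParameterSpace,
    _sym,
    logdet_psd,
    spd_inverse,
)
from pebkit.variational_laplace import SubjectInversion


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_spd(rng, n, scale=1.0):
    """Random symmetric positive-definite matrix."""
    A = rng.standard_normal((n, n))
    return _sym(A @ A.T / n + 0.1 * np.eye(n)) * scale


def space(n, prefix="p", re_mask=None):
    return ParameterSpace(tuple(f"{prefix}{i}" for i in range(n)), re_mask)


def gaussian_evidence(y, mean, cov):
    """ln N(y; mean, cov) — plain dense evaluation (oracle side)."""
    y = np.asarray(y, float)
    r = y - mean
    Ci = spd_inverse(_sym(np.asarray(cov, float)))
    return float(-0.5 * (y.size * LOG2PI + logdet_psd(cov) + r @ Ci @ r))


def conjugate_linear(A, y, prior: GaussianBelief, Sigma_eps):
    """Independent conjugate linear-Gaussian oracle (support-aware).

    Returns (posterior mean full-size, posterior cov full-size, log evidence).
    Written against the standard normal-equations, not the package's Eq.-8
    machinery.
    """
    idx = np.flatnonzero(prior.support)
    As = A[:, idx]
    off = (
        A[:, ~prior.support] @ prior.mean[~prior.support]
        if np.any(~prior.support)
        else 0.0
    )
    Pi = spd_inverse(prior.sub_cov())
    Se_i = spd_inverse(_sym(np.asarray(Sigma_eps, float)))
    P = _sym(As.T @ Se_i @ As + Pi)
    C = spd_inverse(P)
    mu = C @ (As.T @ Se_i @ (y - off) + Pi @ prior.mean[idx])
    mean = prior.mean.copy()
    mean[idx] = mu
    cov = np.zeros_like(prior.cov)
    cov[np.ix_(idx, idx)] = C
    ev = gaussian_evidence(y, As @ prior.mean[idx] + off, As @ prior.sub_cov() @ As.T + Sigma_eps)
    return mean, cov, ev


def make_linear_subject(rng, A, prior, sigma_eps, theta=None):
    """SubjectInversion backed by the conjugate oracle (no iterative scheme)."""
    D, M = A.shape
    if theta is None:
        theta = prior.sample(rng)[0]
    y = A @ theta + np.sqrt(sigma_eps) * rng.standard_normal(D)
    mean, cov, ev = conjugate_linear(A, y, prior, sigma_eps * np.eye(D))
    post = GaussianBelief(prior.space, mean, cov, prior.support.copy())
    hyper = GaussianBelief.diagonal(ParameterSpace(("lambda_0",)), 0.0, 1.0)
    return SubjectInversion(
        data=y,
        full_prior=prior,
        full_posterior=post,
        hyper_posterior=hyper,
        evidence=EvidenceRecord(ev, ev, 0.0),
        trace=[ev],
    )
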