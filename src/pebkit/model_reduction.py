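"""Closed-form posteriors and evidence for nested-prior (reduced) models.

Given the posterior of a *full* model, the posterior and free energy of any
model with a more constrained prior (same likelihood) follow in closed form:

    P_R  = P_F + Pi_R - Pi_F
    mu_R = C_R (P_F mu_F + Pi_R eta_R - Pi_F eta_F)
    dF   = 1/2 [ logdet Pi_R - logdet Pi_F + logdet P_F - logdet P_R ]
         - 1/2 [ mu_F' P_F mu_F + eta_R' Pi_R eta_R
                 - eta_F' Pi_F eta_F - mu_R' P_R mu_R ]

with (eta, Sigma/Pi) prior moments/precisions and (mu, C/P) posterior ones.
The determinant term is computed in the split form above (algebraically
identical to the printed product determinant, but each factor is symmetric
PD so Cholesky log-determinants apply).

Dimensions switched off in the reduced prior (zero variance) are handled by
the exact limit: they contribute a Savage-Dickey density-ratio term
ln q_s(eta_s) - ln p_s(eta_s), and the remaining dimensions are reduced
after conditioning the full prior and posterior on the pinned values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gaussian_core import (
    GaussianBelief,
    _sym,
    gaussian_log_density,
    logdet_psd,
    spd_inverse,
)

__all__ = [
    "ModelDefinition",
    "ReductionResult",
    "reduce",
    "reduce_point",
    "score_model_set",
]


@dataclass(frozen=True)
class ModelDefinition:
    """A nested model: a (possibly support-reduced) prior on the full space."""

    name: str
    reduced_prior: GaussianBelief

    def validate_against(self, full_prior: GaussianBelief) -> None:
        if self.reduced_prior.space.names != full_prior.space.names:
            raise ValueError(f"model {self.name!r}: parameter space mismatch")
        if np.any(self.reduced_prior.support & ~full_prior.support):
            raise ValueError(
                f"model {self.name!r}: reduced prior has mass where the full prior has none"
            )


@dataclass
class ReductionResult:
    """Outcome of reducing one model from the full-model posterior."""

    reduced_posterior: GaussianBelief
    delta_F: float
    F_R: float


def _reduce_on_support(
    eta_F: np.ndarray,
    Sigma_F: np.ndarray,
    mu_F: np.ndarray,
    C_F: np.ndarray,
    eta_R: np.ndarray,
    Sigma_R: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-form reduction core on a common, fully supported subspace.

    All means are translated so the reduced prior mean sits at the origin
    (the free-energy change is translation invariant); this avoids
    catastrophic cancellation when the reduced precision is extreme.
    """
    if eta_F.size == 0:
        return mu_F.copy(), C_F.copy(), 0.0
    shift = eta_R
    eta_F = eta_F - shift
    mu_F = mu_F - shift
    eta_R = np.zeros_like(eta_R)
    Pi_F = spd_inverse(Sigma_F)
    P_F = spd_inverse(C_F)
    Pi_R = spd_inverse(Sigma_R)
    P_R = _sym(P_F + Pi_R - Pi_F)
    w = np.linalg.eigvalsh(P_R)
    # sign test only: the spectrum may legitimately span ~12 decades when a
    # dimension is being pinned by a near-zero reduced variance
    if w[0] <= 0.0:
        vecs = np.linalg.eigh(P_R)[1]
        raise ValueError(
            "reduced posterior precision is not positive definite; "
            f"offending eigen-direction {vecs[:, 0].round(4).tolist()} "
            f"(eigenvalue {w[0]:.3e}) — incompatible reduction"
        )
    C_R = spd_inverse(P_R)
    mu_R = C_R @ (P_F @ mu_F + Pi_R @ eta_R - Pi_F @ eta_F)
    logdet_term = 0.5 * (
        logdet_psd(Pi_R) - logdet_psd(Pi_F) + logdet_psd(P_F) - logdet_psd(P_R)
    )
    quad_term = 0.5 * (
        mu_F @ P_F @ mu_F
        + eta_R @ Pi_R @ eta_R
        - eta_F @ Pi_F @ eta_F
        - mu_R @ P_R @ mu_R
    )
    return mu_R + shift, C_R, float(logdet_term - quad_term)


def reduce(
    full_prior: GaussianBelief,
    full_posterior: GaussianBelief,
    reduced_prior: GaussianBelief,
    F_full: float = 0.0,
) -> ReductionResult:
    """Posterior and evidence of the reduced model, from the full posterior.

    Dimensions outside the full prior's support are ignored entirely (fixed
    constants).  Dimensions inside the full support but switched off in the
    reduced prior are pinned at the reduced prior mean and contribute the
    exact Savage-Dickey limit term.
    """
    if full_prior.space.names != full_posterior.space.names:
        raise ValueError("full prior and posterior live on different spaces")
    if reduced_prior.space.names != full_prior.space.names:
        raise ValueError("reduced prior lives on a different space")
    if np.any(reduced_prior.support & ~full_prior.support):
        raise ValueError("nesting violated: reduced prior has mass where full prior has none")
    if np.any(full_posterior.support != full_prior.support):
        raise ValueError("full posterior support must match full prior support")

    sF = full_prior.support
    r = reduced_prior.support
    pin = sF & ~r  # supported in the full model, removed in the reduced one

    delta_F = 0.0
    if np.any(pin):
        pin_idx = np.flatnonzero(pin)
        eta_s = reduced_prior.mean[pin_idx]
        q_marg = full_posterior.marginal(pin_idx)
        p_marg = full_prior.marginal(pin_idx)
        delta_F += gaussian_log_density(eta_s, q_marg) - gaussian_log_density(
            eta_s, p_marg
        )
        # condition remaining dims on the pinned values; recurse on the rest
        q_c = full_posterior.condition(pin_idx, eta_s)
        p_c = full_prior.condition(pin_idx, eta_s)
        keep = np.setdiff1d(np.arange(full_prior.M), pin_idx)
        # on the kept dims, the conditioned full support equals the reduced
        # support (pin removed exactly the sF & ~r dims)
        mu_R_s, C_R_s, dF8 = _reduce_on_support(
            p_c.mean[p_c.support],
            p_c.sub_cov(),
            q_c.mean[q_c.support],
            q_c.sub_cov(),
            reduced_prior.mean[keep][p_c.support],
            reduced_prior.cov[np.ix_(keep, keep)][np.ix_(p_c.support, p_c.support)],
        )
        delta_F += dF8
        mean = reduced_prior.mean.copy()
        mean[~sF] = full_prior.mean[~sF]
        cov = np.zeros_like(full_prior.cov)
        on_idx = keep[p_c.support]
        mean[on_idx] = mu_R_s
        cov[np.ix_(on_idx, on_idx)] = C_R_s
        reduced_posterior = GaussianBelief(full_prior.space, mean, cov, r)
    else:
        idx = np.flatnonzero(sF)
        mu_R_s, C_R_s, dF8 = _reduce_on_support(
            full_prior.mean[idx],
            full_prior.sub_cov(),
            full_posterior.mean[idx],
            full_posterior.sub_cov(),
            reduced_prior.mean[idx],
            reduced_prior.cov[np.ix_(idx, idx)],
        )
        delta_F += dF8
        mean = full_prior.mean.copy()
        mean[idx] = mu_R_s
        cov = np.zeros_like(full_prior.cov)
        cov[np.ix_(idx, idx)] = C_R_s
        reduced_posterior = GaussianBelief(full_prior.space, mean, cov, sF.copy())

    if not np.isfinite(delta_F):
        raise ValueError("reduced free energy is not finite")
    return ReductionResult(reduced_posterior, float(delta_F), float(F_full + delta_F))


def reduce_point(
    full_prior: GaussianBelief,
    full_posterior: GaussianBelief,
    indices: Sequence[int],
    values: np.ndarray,
) -> tuple[float, GaussianBelief]:
    """Savage-Dickey point reduction: pin ``indices`` to ``values`` exactly.

    Returns the log evidence ratio (reduced minus full, in nats) and the
    conditioned posterior over the remaining parameters.  This is the limit
    of :func:`reduce` as the reduced variance at the pinned values goes to
    zero, with the remaining prior left at its full-model conditional.
    """
    indices = np.asarray(indices, dtype=int)
    values = np.asarray(values, dtype=float).reshape(-1)
    if indices.size != values.size:
        raise ValueError("indices and values must have the same length")
    if np.any(~full_prior.support[indices]):
        raise ValueError("values are off the full-prior support")
    q_marg = full_posterior.marginal(indices)
    p_marg = full_prior.marginal(indices)
    delta_F = gaussian_log_density(values, q_marg) - gaussian_log_density(values, p_marg)
    conditioned = full_posterior.condition(indices, values)
    return float(delta_F), conditioned


def score_model_set(
    full_prior: GaussianBelief,
    full_posterior: GaussianBelief,
    models: Sequence[ModelDefinition],
    F_full: float = 0.0,
) -> list[tuple[ModelDefinition, ReductionResult]]:
    """Reduce every model in a set against one full-model inversion."""
    out = []
    for model in models:
        model.validate_against(full_prior)
        out.append(
            (model, reduce(full_prior, full_posterior, model.reduced_prior, F_full))
        )
    return out


def full_model(full_prior: GaussianBelief, name: str = "full") -> ModelDefinition:
    """The identity reduction (the full model itself)."""
    return ModelDefinition(name, full_prior)
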