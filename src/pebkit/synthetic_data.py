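"""Hierarchical group-study simulator.

Generates two groups of subjects whose parameters are group means plus
Gaussian random effects (between-subject variance a fixed fraction of the
prior variance), observed through per-subject random mixing matrices with
smoothed additive noise scaled to a fraction of the signal SD.  Surrogate
first-level families are linear (exactness oracles apply) or weakly
nonlinear (tanh); three disjoint parameter blocks span an 8-model on/off
lattice for model-comparison experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gaussian_core import GaussianBelief, ParameterSpace
from .model_reduction import ModelDefinition
from .variational_laplace import (
    MODEL_REGISTRY,
    NonlinearModel,
    register_model,
)

__all__ = [
    "SimulationConfig",
    "GroupStudy",
    "simulate_group_study",
    "make_model_space",
    "default_blocks",
]

BLOCK_LABELS = ("forward", "backward", "intrinsic")

#: Table-style lattice: model 1 = everything on ... model 8 = nothing.
#: Rows are (forward, backward, intrinsic) flags.
MODEL_LATTICE = (
    (True, True, True),     # 1: intrinsic + forward + backward
    (False, True, True),    # 2: intrinsic + backward
    (True, False, True),    # 3: intrinsic + forward
    (False, False, True),   # 4: intrinsic
    (True, True, False),    # 5: forward + backward
    (False, True, False),   # 6: backward
    (True, False, False),   # 7: forward
    (False, False, False),  # 8: none
)


@dataclass
class SimulationConfig:
    n_per_group: int = 8
    M_r: int = 6
    D: int = 32
    model_family: str = "linear"  # or "sigmoid"
    prior_var: float = 0.25
    between_var_ratio: float = 1.0 / 16.0
    group_diff_sd_units: float = 2.0
    effect_range: tuple[float, float] = (0.1, 0.4)
    noise_sd_ratio: float = 1.0 / 8.0
    noise_smoothing_bins: int = 8
    generating_model: int = 3  # index into the 8-model lattice (1-based)
    group_diff_model: int = 4  # blocks carrying group differences
    confound: bool = True
    mixing: bool = True
    mixing_rank: int = 3  # rank of the per-subject mixing matrix; each
    # subject then informs only a random parameter subspace (random
    # lead-field analogue)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M_r % 3 != 0:
            raise ValueError("M_r must be divisible into 3 equal blocks")
        for name in ("prior_var", "between_var_ratio", "noise_sd_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.model_family not in ("linear", "sigmoid"):
            raise ValueError("model_family must be 'linear' or 'sigmoid'")

    @property
    def between_var(self) -> float:
        return self.prior_var * self.between_var_ratio


@dataclass
class GroupStudy:
    config: SimulationConfig
    space: ParameterSpace
    prior: GaussianBelief
    X: np.ndarray
    effect_names: tuple[str, ...]
    beta_true: np.ndarray  # B x M_r (row per design column)
    theta_true: np.ndarray  # N x M_r
    data: list[np.ndarray]
    models: list[NonlinearModel]
    blocks: list[np.ndarray] = field(default_factory=list)
    group_labels: np.ndarray | None = None


def default_blocks(M_r: int) -> list[np.ndarray]:
    """Three equal, disjoint parameter blocks (forward/backward/intrinsic)."""
    k = M_r // 3
    return [np.arange(i * k, (i + 1) * k) for i in range(3)]


def _parameter_space(M_r: int) -> ParameterSpace:
    blocks = default_blocks(M_r)
    names = []
    for label, idx in zip(BLOCK_LABELS, blocks):
        names.extend(f"{label}_{j}" for j in range(idx.size))
    return ParameterSpace(tuple(names))


def _smoothed_noise(rng: np.random.Generator, D: int, bins: int) -> np.ndarray:
    e = rng.standard_normal(D + bins)
    kernel = np.ones(bins) / bins
    return np.convolve(e, kernel, mode="valid")[:D]


@register_model("linear_mixing")
def _linear_model(space: ParameterSpace, A: np.ndarray) -> NonlinearModel:
    A = np.asarray(A, dtype=float)
    return NonlinearModel(
        space=space,
        predict=lambda th: A @ th,
        noise_components=[np.eye(A.shape[0])],
        jacobian=lambda th: A,
    )


@register_model("sigmoid_mixing")
def _sigmoid_model(space: ParameterSpace, A: np.ndarray) -> NonlinearModel:
    A = np.asarray(A, dtype=float)
    return NonlinearModel(
        space=space,
        predict=lambda th: A @ np.tanh(th),
        noise_components=[np.eye(A.shape[0])],
        jacobian=lambda th: A * (1.0 - np.tanh(th) ** 2)[None, :],
    )


def simulate_group_study(config: SimulationConfig) -> GroupStudy:
    """Simulate a two-group study; bit-identical for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    M_r = config.M_r
    N = 2 * config.n_per_group
    space = _parameter_space(M_r)
    prior = GaussianBelief.diagonal(space, 0.0, config.prior_var)
    blocks = default_blocks(M_r)

    # design: constant, group (+/-1), optional standard-normal confound
    group = np.concatenate(
        [-np.ones(config.n_per_group), np.ones(config.n_per_group)]
    )
    cols = [np.ones(N), group]
    effect_names = ["mean", "group"]
    if config.confound:
        cols.append(rng.standard_normal(N))
        effect_names.append("age")
    X = np.column_stack(cols)
    B = X.shape[1]

    # group-level effects: condition effects on the generating model's
    # retained blocks; group differences on the difference model's blocks
    beta_true = np.zeros((B, M_r))
    gen_flags = MODEL_LATTICE[config.generating_model - 1]
    for on, idx in zip(gen_flags, blocks):
        if on:
            lo, hi = config.effect_range
            beta_true[0, idx] = rng.uniform(lo, hi, size=idx.size)
    sd_between = np.sqrt(config.between_var)
    diff_flags = MODEL_LATTICE[config.group_diff_model - 1]
    for on, idx in zip(diff_flags, blocks):
        if on:
            # +/-1 coding: between-group difference = 2 * beta_group
            beta_true[1, idx] = -config.group_diff_sd_units * sd_between / 2.0

    theta_true = X @ beta_true + np.sqrt(config.between_var) * rng.standard_normal(
        (N, M_r)
    )

    data: list[np.ndarray] = []
    models: list[NonlinearModel] = []
    family = "linear_mixing" if config.model_family == "linear" else "sigmoid_mixing"
    for i in range(N):
        if config.mixing:
            r = min(config.mixing_rank, M_r)
            A = (
                rng.standard_normal((config.D, r))
                @ rng.standard_normal((r, M_r))
            ) / np.sqrt(r * M_r)
        else:
            A = np.eye(config.D, M_r)
        model = MODEL_REGISTRY[family](space, A)
        signal = np.asarray(model.predict(theta_true[i]), dtype=float)
        sd_sig = float(signal.std())
        noise = _smoothed_noise(rng, config.D, config.noise_smoothing_bins)
        if sd_sig > 0 and noise.std() > 0:
            noise = noise * (sd_sig * config.noise_sd_ratio / noise.std())
        else:
            noise = np.zeros(config.D)
        y = signal + noise
        # noise component scaled to the nominal post-averaging level so the
        # log-precision hyperparameter operates near zero
        nominal = float(y.var()) / 64.0 if y.var() > 0 else 1.0
        model = MODEL_REGISTRY[family](space, A)
        model.noise_components = [nominal * np.eye(config.D)]
        data.append(y)
        models.append(model)

    return GroupStudy(
        config=config,
        space=space,
        prior=prior,
        X=X,
        effect_names=tuple(effect_names),
        beta_true=beta_true,
        theta_true=theta_true,
        data=data,
        models=models,
        blocks=blocks,
        group_labels=group,
    )


def make_model_space(
    blocks: Sequence[np.ndarray],
    full_prior: GaussianBelief,
) -> list[ModelDefinition]:
    """The 8-model on/off lattice over three disjoint parameter blocks.

    Model 1 retains every block; model 8 switches all three off ("off"
    means a zero-mean, zero-variance reduced prior).  Ordering follows the
    conventional lattice (see MODEL_LATTICE).
    """
    blocks = [np.asarray(b, dtype=int) for b in blocks]
    if len(blocks) != 3:
        raise ValueError("exactly three parameter blocks are required")
    flat = np.concatenate(blocks)
    if np.unique(flat).size != flat.size:
        raise ValueError("parameter blocks must be disjoint")

    models = []
    for m, flags in enumerate(MODEL_LATTICE, start=1):
        support = full_prior.support.copy()
        mean = full_prior.mean.copy()
        cov = full_prior.cov.copy()
        off_label = [lab for lab, on in zip(BLOCK_LABELS, flags) if not on]
        for on, idx in zip(flags, blocks):
            if not on:
                support[idx] = False
                mean[idx] = 0.0
                cov[idx, :] = 0.0
                cov[:, idx] = 0.0
        name = f"m{m}:" + ("+".join(
            lab for lab, on in zip(BLOCK_LABELS, flags) if on
        ) or "none")
        reduced = GaussianBelief(full_prior.space, mean, cov, support)
        models.append(ModelDefinition(name, reduced))
    return models
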