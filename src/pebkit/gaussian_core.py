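"""Multivariate-Gaussian algebra on named parameter spaces.

Everything downstream (model reduction, empirical Bayes, classification)
manipulates Gaussian beliefs whose dimensions may be *switched off*: a boolean
support mask marks dimensions with nonzero variance, and off-support
dimensions are pinned exactly to their mean.  All determinant and quadratic
forms are evaluated on the support subspace, which keeps the zero-variance
limit exact instead of relying on tiny variances.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ParameterSpace",
    "GaussianBelief",
    "EvidenceRecord",
    "kl_gaussian",
    "logdet_psd",
    "gaussian_log_density",
    "LOG2PI",
]

LOG2PI = float(np.log(2.0 * np.pi))

#: jitter ladder used when a Cholesky factorisation fails
_JITTERS = (0.0, 1e-12, 1e-10, 1e-8, 1e-6)

#: precision used by the large-precision fallback for switched-off dimensions
HUGE_PRECISION = 2.0**32


def _sym(a: np.ndarray) -> np.ndarray:
    """Symmetrise before any factorisation (guards against float drift)."""
    return 0.5 * (a + a.T)


def _chol(a: np.ndarray) -> np.ndarray:
    """Cholesky factor with a jitter ladder fallback."""
    a = _sym(a)
    scale = max(float(np.abs(np.diag(a)).max()), 1.0) if a.size else 1.0
    for jit in _JITTERS:
        try:
            return np.linalg.cholesky(a + jit * scale * np.eye(a.shape[0]))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("matrix not positive definite (jitter ladder exhausted)")


def spd_inverse(a: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric positive-definite matrix via Cholesky."""
    if a.size == 0:
        return a.copy()
    L = _chol(a)
    eye = np.eye(a.shape[0])
    y = np.linalg.solve(L, eye)
    return _sym(np.linalg.solve(L.T, y))


def spd_solve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve ``a @ x = b`` for SPD ``a``."""
    if a.size == 0:
        return np.zeros_like(b)
    L = _chol(a)
    return np.linalg.solve(L.T, np.linalg.solve(L, b))


def logdet_psd(a: np.ndarray, support: np.ndarray | None = None) -> float:
    """Log pseudo-determinant of a PSD matrix over ``support`` dimensions.

    Uses Cholesky when the supported block is PD, falling back to an
    eigendecomposition where eigenvalues below a relative tolerance are
    treated as exact zeros (pseudo-determinant).  A negative eigenvalue
    beyond tolerance raises ``ValueError``.
    """
    a = np.asarray(a, dtype=float)
    if support is not None:
        support = np.asarray(support, dtype=bool)
        a = a[np.ix_(support, support)]
    if a.size == 0:
        return 0.0
    a = _sym(a)
    try:
        L = np.linalg.cholesky(a)
        return float(2.0 * np.sum(np.log(np.diag(L))))
    except np.linalg.LinAlgError:
        pass
    w = np.linalg.eigvalsh(a)
    tol = max(abs(w[-1]), 1.0) * 1e-12
    if w[0] < -max(np.abs(w).max(), 1.0) * 1e-10:
        raise ValueError(f"matrix has negative eigenvalue {w[0]:.3e} beyond tolerance")
    w = w[w > tol]
    return float(np.sum(np.log(w)))


@dataclass(frozen=True)
class ParameterSpace:
    """An ordered, named parameter space of dimension ``M``.

    ``random_effect_mask`` flags which parameters may express between-subject
    random effects (i.e. which rows of the within-subject design ``W`` they
    select); the remainder are treated as fixed effects by the second level.
    """

    names: tuple[str, ...]
    random_effect_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        mask = self.random_effect_mask
        if mask is None:
            mask = np.ones(len(names), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (len(names),):
            raise ValueError("random_effect_mask length must equal the number of names")
        mask.setflags(write=False)
        object.__setattr__(self, "random_effect_mask", mask)

    @property
    def M(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def indices(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    def subspace(self, mask: np.ndarray) -> "ParameterSpace":
        mask = np.asarray(mask, dtype=bool)
        return ParameterSpace(
            tuple(n for n, m in zip(self.names, mask) if m),
            self.random_effect_mask[mask],
        )


@dataclass
class GaussianBelief:
    """Gaussian density N(mean, cov) over a :class:`ParameterSpace`.

    Serves as prior, posterior and empirical prior alike.  Off-support
    rows/columns of ``cov`` are exactly zero and the corresponding mean
    entries are fixed values (a point mass in those dimensions).
    """

    space: ParameterSpace
    mean: np.ndarray
    cov: np.ndarray
    support: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(-1).copy()
        self.cov = np.asarray(self.cov, dtype=float).copy()
        M = self.space.M
        if self.mean.shape != (M,):
            raise ValueError(f"mean has shape {self.mean.shape}, expected ({M},)")
        if self.cov.shape != (M, M):
            raise ValueError(f"cov has shape {self.cov.shape}, expected ({M}, {M})")
        if self.cov.size:
            scale = max(float(np.abs(self.cov).max()), 1.0)
            if np.abs(self.cov - self.cov.T).max() > 1e-10 * scale:
                raise ValueError("covariance is not symmetric to 1e-10 relative")
        self.cov = _sym(self.cov)
        if self.support is None:
            self.support = np.abs(np.diag(self.cov)) > 0
        self.support = np.asarray(self.support, dtype=bool).copy()
        if self.support.shape != (M,):
            raise ValueError("support mask length must equal M")
        # enforce exact zeros off support
        off = ~self.support
        self.cov[off, :] = 0.0
        self.cov[:, off] = 0.0
        if np.any(self.support):
            sub = self.cov[np.ix_(self.support, self.support)]
            w = np.linalg.eigvalsh(_sym(sub))
            if w.size and w[0] < -1e-10 * max(np.abs(w).max(), 1.0):
                raise ValueError(f"covariance has negative eigenvalue {w[0]:.3e}")
        self._precision: np.ndarray | None = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def diagonal(
        cls,
        space: ParameterSpace,
        mean: np.ndarray | float = 0.0,
        var: np.ndarray | float = 1.0,
    ) -> "GaussianBelief":
        M = space.M
        mean = np.broadcast_to(np.asarray(mean, dtype=float), (M,)).copy()
        var = np.broadcast_to(np.asarray(var, dtype=float), (M,)).copy()
        return cls(space, mean, np.diag(var))

    # -- basic properties ---------------------------------------------------

    @property
    def M(self) -> int:
        return self.space.M

    @property
    def dim_support(self) -> int:
        return int(self.support.sum())

    def precision(self) -> np.ndarray:
        """Precision on the support subspace, embedded at full size (cached).

        Off-support rows/columns are zero; this is the natural pairing with
        quadratic forms evaluated on the support subspace only.
        """
        if self._precision is None:
            P = np.zeros_like(self.cov)
            s = self.support
            if np.any(s):
                P[np.ix_(s, s)] = spd_inverse(self.cov[np.ix_(s, s)])
            self._precision = P
        return self._precision

    def sub_mean(self) -> np.ndarray:
        return self.mean[self.support]

    def sub_cov(self) -> np.ndarray:
        return self.cov[np.ix_(self.support, self.support)]

    # -- Gaussian operations ------------------------------------------------

    def marginal(self, idx: Sequence[int]) -> "GaussianBelief":
        """Marginal belief over the given dimensions (new anonymous space)."""
        idx = np.asarray(idx, dtype=int)
        space = ParameterSpace(
            tuple(self.space.names[i] for i in idx),
            self.space.random_effect_mask[idx],
        )
        return GaussianBelief(
            space, self.mean[idx], self.cov[np.ix_(idx, idx)], self.support[idx]
        )

    def condition(self, idx: Sequence[int], values: np.ndarray) -> "GaussianBelief":
        """Condition on dimensions ``idx`` taking ``values``; returns the
        belief over the remaining dimensions."""
        idx = np.asarray(idx, dtype=int)
        values = np.asarray(values, dtype=float).reshape(-1)
        keep = np.setdiff1d(np.arange(self.M), idx)
        if not np.all(self.support[idx]):
            raise ValueError("cannot condition on off-support dimensions")
        S_ss = self.cov[np.ix_(idx, idx)]
        S_rs = self.cov[np.ix_(keep, idx)]
        gain = np.linalg.solve(_sym(S_ss), S_rs.T).T if idx.size else np.zeros((keep.size, 0))
        mean = self.mean[keep] + gain @ (values - self.mean[idx])
        cov = self.cov[np.ix_(keep, keep)] - gain @ S_rs.T
        space = ParameterSpace(
            tuple(self.space.names[i] for i in keep),
            self.space.random_effect_mask[keep],
        )
        return GaussianBelief(space, mean, _sym(cov), self.support[keep])

    def logpdf(self, x: np.ndarray) -> float:
        return gaussian_log_density(x, self)

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Draw ``n`` samples; off-support dimensions are pinned to the mean."""
        out = np.tile(self.mean, (n, 1))
        s = self.support
        if np.any(s):
            L = _chol(self.cov[np.ix_(s, s)])
            out[:, s] += rng.standard_normal((n, int(s.sum()))) @ L.T
        return out

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "names": list(self.space.names),
            "random_effect_mask": self.space.random_effect_mask.astype(int).tolist(),
            "mean": self.mean.tolist(),
            "cov": self.cov.reshape(-1).tolist(),
            "support": self.support.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianBelief":
        names = tuple(d["names"])
        M = len(names)
        space = ParameterSpace(names, np.asarray(d["random_effect_mask"], dtype=bool))
        return cls(
            space,
            np.asarray(d["mean"], dtype=float),
            np.asarray(d["cov"], dtype=float).reshape(M, M),
            np.asarray(d["support"], dtype=bool),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "GaussianBelief":
        return cls.from_dict(json.loads(s))

    def to_hdf5(self, group) -> None:
        group.create_dataset("mean", data=self.mean)
        group.create_dataset("cov", data=self.cov)
        group.create_dataset("support", data=self.support.astype(np.uint8))
        group.create_dataset("random_effect_mask", data=self.space.random_effect_mask.astype(np.uint8))
        group.attrs["names"] = json.dumps(list(self.space.names))

    @classmethod
    def from_hdf5(cls, group) -> "GaussianBelief":
        names = tuple(json.loads(group.attrs["names"]))
        space = ParameterSpace(names, np.asarray(group["random_effect_mask"][...], dtype=bool))
        return cls(
            space,
            group["mean"][...],
            group["cov"][...],
            np.asarray(group["support"][...], dtype=bool),
        )

    # -- zero-variance fallback --------------------------------------------

    def with_precision_floor(self) -> "GaussianBelief":
        """Replace switched-off dimensions by variance ``2**-32``.

        Large-precision fallback for the exact subspace path; unit tests
        check the two agree to 1e-6.
        """
        cov = self.cov.copy()
        off = ~self.support
        cov[off, off] = 1.0 / HUGE_PRECISION
        return GaussianBelief(self.space, self.mean, cov, np.ones(self.M, dtype=bool))


@dataclass(frozen=True)
class EvidenceRecord:
    """Free energy in nats, decomposed as accuracy minus complexity."""

    F: float
    accuracy: float
    complexity: float

    def __post_init__(self) -> None:
        if abs(self.F - (self.accuracy - self.complexity)) > 1e-8 * max(
            1.0, abs(self.F)
        ):
            raise ValueError("F must equal accuracy - complexity")


def _check_same_space(q: GaussianBelief, p: GaussianBelief) -> None:
    if q.space.names != p.space.names:
        raise ValueError("beliefs are defined on different parameter spaces")


def kl_gaussian(q: GaussianBelief, p: GaussianBelief) -> float:
    """KL(q ‖ p) in nats, on the joint support subspace.

    Requires support(q) ⊆ support(p): q may not place mass where p has none.
    Dimensions where p has support but q does not are point masses under q
    and are excluded (the subspace-restriction convention used throughout).
    """
    _check_same_space(q, p)
    if np.any(q.support & ~p.support):
        raise ValueError("support violation: q has mass where p has none")
    if (
        q is p
        or (
            np.array_equal(q.mean, p.mean)
            and np.array_equal(q.cov, p.cov)
            and np.array_equal(q.support, p.support)
        )
    ):
        return 0.0  # exact identity case
    s = q.support
    k = int(s.sum())
    if k == 0:
        return 0.0
    idx = np.flatnonzero(s)
    Sq = q.cov[np.ix_(idx, idx)]
    Sp = p.cov[np.ix_(idx, idx)]
    dm = p.mean[idx] - q.mean[idx]
    Pp = spd_inverse(Sp)
    tr = float(np.trace(Pp @ Sq))
    quad = float(dm @ Pp @ dm)
    ld = logdet_psd(Sp) - logdet_psd(Sq)
    return 0.5 * (tr + quad - k + ld)


def gaussian_log_density(x: np.ndarray, b: GaussianBelief) -> float:
    """log N(x; mean, cov) evaluated on the support subspace of ``b``.

    ``x`` must match the pinned values on off-support dimensions.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.shape != (b.M,):
        raise ValueError(f"x has shape {x.shape}, expected ({b.M},)")
    off = ~b.support
    if np.any(off) and np.abs(x[off] - b.mean[off]).max() > 1e-8:
        raise ValueError("x is off the support of the belief")
    s = b.support
    k = int(s.sum())
    if k == 0:
        return 0.0
    idx = np.flatnonzero(s)
    S = b.cov[np.ix_(idx, idx)]
    r = x[idx] - b.mean[idx]
    alpha = spd_solve(_sym(S), r)
    return float(-0.5 * (k * LOG2PI + logdet_psd(S) + r @ alpha))
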