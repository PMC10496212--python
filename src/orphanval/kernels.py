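"""Samplers used by the Monte Carlo layers.

Four primitives:

* **PERT** — the project-management three-point distribution: a Beta
  distribution scaled to [min, max] with shape parameters
  ``alpha = 1 + 4 (mode - min)/(max - min)`` and
  ``beta = 1 + 4 (max - mode)/(max - min)`` (the classical lambda = 4
  parameterization). Mean ``(min + 4 mode + max) / 6``; variance
  ``(mean - min)(max - mean) / 7``.
* **CI-calibrated normal** — a normal pinned by its central 95% confidence
  interval, ``sd = (hi - lo) / (2 * 1.959964)``.
* **Sequential Bernoulli phase chain** — a phase is attempted iff all prior
  phases succeeded; success is Bernoulli(PoS).
* **Gaussian copula** — correlate latent standard normals, push each margin
  through the standard-normal CDF to a uniform, then through the margin's
  inverse CDF. Bernoulli margins realize success iff the uniform falls below
  the success probability.

All samplers accept either an integer seed or a ``numpy.random.Generator``;
identical seeds give identical draw sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import stats

from .scenario import PhasePlan

#: two-sided 95% standard-normal quantile used for CI calibration
Z95 = 1.959964

RngLike = Union[int, np.random.Generator, np.random.SeedSequence]


def as_generator(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# PERT
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PertParams:
    """Three-point (min, mode, max) estimate; units follow the quantity."""

    minimum: float
    mode: float
    maximum: float

    def __post_init__(self) -> None:
        if not self.minimum <= self.mode <= self.maximum:
            raise ValueError(
                f"PERT requires minimum <= mode <= maximum, got "
                f"({self.minimum}, {self.mode}, {self.maximum})"
            )

    @property
    def degenerate(self) -> bool:
        return self.maximum == self.minimum

    def shape(self) -> tuple[float, float]:
        span = self.maximum - self.minimum
        a = 1.0 + 4.0 * (self.mode - self.minimum) / span
        b = 1.0 + 4.0 * (self.maximum - self.mode) / span
        return a, b

    def mean(self) -> float:
        return (self.minimum + 4.0 * self.mode + self.maximum) / 6.0

    def variance(self) -> float:
        if self.degenerate:
            return 0.0
        m = self.mean()
        return (m - self.minimum) * (self.maximum - m) / 7.0


def pert_ppf(u: np.ndarray, params: PertParams) -> np.ndarray:
    """Inverse CDF of the PERT distribution (vectorized over ``u``)."""
    u = np.asarray(u, dtype=float)
    if params.degenerate:
        return np.full_like(u, params.minimum)
    a, b = params.shape()
    return params.minimum + (params.maximum - params.minimum) * stats.beta.ppf(u, a, b)


def sample_pert(params: PertParams, n: int, rng: RngLike) -> np.ndarray:
    """Draw ``n`` PERT variates; a degenerate triple returns the constant."""
    if n < 1:
        raise ValueError("n must be >= 1")
    gen = as_generator(rng)
    u = gen.random(n)
    return pert_ppf(u, params)


# ---------------------------------------------------------------------------
# CI-calibrated normal
# ---------------------------------------------------------------------------


def normal_from_ci(
    center: float, lo: float, hi: float, *, rtol: float = 1e-6
) -> tuple[float, float]:
    """(mean, sd) of a normal whose central 95% CI is [lo, hi].

    The CI must be symmetric about ``center``; an asymmetric interval raises
    with instructions to re-center it, since a normal cannot match one.
    """
    if not (lo < center < hi):
        raise ValueError(f"require lo < center < hi, got ({lo}, {center}, {hi})")
    if abs((lo + hi) - 2.0 * center) > rtol * (hi - lo):
        raise ValueError(
            f"CI [{lo}, {hi}] is not symmetric about {center}; a normal "
            "distribution cannot match an asymmetric interval — center it "
            "(or switch to a skewed marginal) before calibrating"
        )
    return center, (hi - lo) / (2.0 * Z95)


def sample_truncated_normal(
    mean: float,
    sd: float,
    n: int,
    rng: RngLike,
    *,
    lower: float = 0.0,
    upper: float = np.inf,
) -> np.ndarray:
    """Normal draws truncated to (lower, upper) by rejection.

    Used for price (> 0) and adoption (in (0, 1]); at the calibrated CIs the
    rejection probability is negligible, so resampling is cheap.
    """
    gen = as_generator(rng)
    x = gen.normal(mean, sd, n)
    bad = (x <= lower) | (x > upper)
    while bad.any():
        x[bad] = gen.normal(mean, sd, int(bad.sum()))
        bad = (x <= lower) | (x > upper)
    return x


# ---------------------------------------------------------------------------
# Gaussian copula
# ---------------------------------------------------------------------------


class Marginal:
    """A marginal distribution descriptor: maps uniforms to draws."""

    def from_uniform(self, u: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class PertMarginal(Marginal):
    params: PertParams

    def from_uniform(self, u: np.ndarray) -> np.ndarray:
        return pert_ppf(u, self.params)


@dataclass(frozen=True)
class NormalMarginal(Marginal):
    mean: float
    sd: float

    def from_uniform(self, u: np.ndarray) -> np.ndarray:
        return self.mean + self.sd * stats.norm.ppf(u)


@dataclass(frozen=True)
class BernoulliMarginal(Marginal):
    """Success (1.0) iff the copula uniform falls below ``pos``."""

    pos: float

    def from_uniform(self, u: np.ndarray) -> np.ndarray:
        return (u < self.pos).astype(float)


@dataclass(frozen=True)
class LognormalMarginal(Marginal):
    """Log-scale parameterization: exp(mu + sigma * z)."""

    mu: float
    sigma: float

    def from_uniform(self, u: np.ndarray) -> np.ndarray:
        return np.exp(self.mu + self.sigma * stats.norm.ppf(u))


@dataclass(frozen=True)
class CopulaSpec:
    corr: np.ndarray
    marginals: Sequence[Marginal]

    def __post_init__(self) -> None:
        corr = np.asarray(self.corr, dtype=float)
        object.__setattr__(self, "corr", corr)
        k = corr.shape[0]
        if corr.shape != (k, k):
            raise ValueError("corr must be square")
        if len(self.marginals) != k:
            raise ValueError(
                f"{len(self.marginals)} marginals for a {k}x{k} matrix"
            )
        if not np.allclose(corr, corr.T):
            raise ValueError("corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("corr must have a unit diagonal")
        w = np.linalg.eigvalsh(corr)
        if w.min() < -1e-10:
            raise ValueError(
                f"corr is not positive semi-definite: smallest eigenvalue "
                f"{w.min():.6g}"
            )


def _psd_factor(corr: np.ndarray) -> np.ndarray:
    """A factor L with L L' = corr, tolerating semi-definite matrices."""
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def copula_uniforms(corr: np.ndarray, n: int, rng: RngLike) -> np.ndarray:
    """n x k uniforms with Gaussian-copula dependence ``corr``."""
    gen = as_generator(rng)
    L = _psd_factor(np.asarray(corr, dtype=float))
    z = gen.standard_normal((n, corr.shape[0])) @ L.T
    return stats.norm.cdf(z)


def copula_sample(spec: CopulaSpec, n: int, rng: RngLike) -> np.ndarray:
    """Joint draws: n rows, one column per marginal."""
    u = copula_uniforms(spec.corr, n, rng)
    cols = [m.from_uniform(u[:, j]) for j, m in enumerate(spec.marginals)]
    return np.column_stack(cols)


def gaussian_rank_correlation(rho: float) -> float:
    """Spearman rank correlation implied by a Gaussian copula with
    latent correlation ``rho``: (6/pi) * arcsin(rho / 2)."""
    return 6.0 / np.pi * np.arcsin(rho / 2.0)


# ---------------------------------------------------------------------------
# Phase chain
# ---------------------------------------------------------------------------


def sample_phase_chain(
    plan: PhasePlan, n: int, rng: RngLike
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential Bernoulli development outcomes.

    Returns boolean arrays ``(attempted, succeeded)`` of shape
    ``(n, n_phases)``: a phase is attempted iff every prior phase succeeded,
    and succeeds with its PoS.
    """
    gen = as_generator(rng)
    u = gen.random((n, plan.n_phases))
    return phase_chain_from_uniforms(u, plan.pos_vector())


def phase_chain_from_uniforms(
    u: np.ndarray, pos: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a chain from pre-drawn per-phase uniforms (copula-friendly)."""
    n, k = u.shape
    hit = u < pos[None, :]
    attempted = np.ones((n, k), dtype=bool)
    for j in range(1, k):
        attempted[:, j] = attempted[:, j - 1] & hit[:, j - 1]
    succeeded = attempted & hit
    return attempted, succeeded
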