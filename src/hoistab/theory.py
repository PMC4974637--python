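"""Analytic stability theory: effective pairwise matrix, Girko criterion,
order-n conditions, and diversity bounds.

Around a coexistence fixed point with total abundance 1 the abundances scale
as ``x_i ~ 1/N``, and the high-order terms fold into an effective pairwise
matrix: ``A_eff_ij = A_ij + sum_k (B_ijk + B_ikj) x_k + sum_{kl} (C_ijkl +
C_ikjl + C_iklj) x_k x_l``.  Its entries are sums of independent zero-mean
coefficients, so their variances add: with strengths read as coefficient
variances and strictly ordered trailing indices, the random part of
``A_eff`` has entry variance ``alpha + beta/N + gamma/N**2``.  By Girko's
circular law the eigenvalues of such an ``N x N`` matrix fill a disc of
radius ``sqrt(N * variance)`` which, shifted by the ``-1`` self-limitation,
yields the stability criterion

    N * alpha + beta + gamma / N < 1.

With unrestricted index sums the two high-order terms pick up constant
combinatorial factors (2 and 3) without changing the scaling.  Viewing the
margin as a quadratic in N, ``alpha N**2 - (1 - beta) N + gamma < 0``, its
roots bound the feasible community sizes from below and above; the interval
closes when the discriminant ``(1 - beta)**2 - 4 alpha gamma`` vanishes, at
the optimal size ``N* = sqrt(gamma / alpha)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .interactions import ScaledInteractions, TensorOptions, scaled_community

__all__ = [
    "StabilityReport",
    "DiversityBounds",
    "effective_pairwise",
    "girko_margin",
    "order_n_condition",
    "diversity_bounds",
    "sample_effective_spectrum",
    "spectral_radii",
]


@dataclass(frozen=True)
class StabilityReport:
    n_species: int
    alpha: float
    beta: float
    gamma: float
    criterion_margin: float  # squared Girko radius; stable iff < 1
    predicted_stable: bool
    eigenvalues: np.ndarray | None = None
    spectral_radius_offset: float | None = None


@dataclass(frozen=True)
class DiversityBounds:
    """Lower/upper bounds on species number and the optimal size N*.

    Bounds may be non-integer (callers round inward for integer counts);
    ``n_lower = n_upper = None`` means no community size is stable.
    """

    n_lower: float | None
    n_upper: float | None
    n_star: float | None
    discriminant: float

    @property
    def is_empty(self) -> bool:
        return self.n_lower is None


def effective_pairwise(interactions: ScaledInteractions, x: np.ndarray | None = None) -> np.ndarray:
    """Effective pairwise matrix ``A_eff`` at state ``x`` (default uniform 1/N).

    This is the linearization of the per-capita growth rates with the
    ``-x_i`` self-term excluded: ``A_eff = df/dx + I``.
    """
    from .dynamics import growth_rate_gradient

    n = interactions.n_species
    if x is None:
        x = np.full(n, 1.0 / n)
    return growth_rate_gradient(x, interactions) + np.eye(n)


def girko_margin(
    n_species: int,
    alpha: float,
    beta: float,
    gamma: float,
    strict_order_factors: bool = True,
) -> StabilityReport:
    """Squared Girko disc radius of ``A_eff`` against the unit stability margin.

    ``margin = N alpha + beta + gamma / N`` under the strictly-ordered
    trailing-index convention; with unrestricted sums the high-order terms
    carry constant factors (2, 3) that leave the scaling untouched.  The
    boundary ``margin == 1`` is classified unstable (the disc must lie
    strictly inside the unit circle around -1).
    """
    if n_species < 1:
        raise ValueError("n_species must be positive")
    if min(alpha, beta, gamma) < 0:
        raise ValueError("strengths must be non-negative")
    f3, f4 = (1.0, 1.0) if strict_order_factors else (2.0, 3.0)
    margin = n_species * alpha + f3 * beta + f4 * gamma / n_species
    return StabilityReport(
        n_species=n_species,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        criterion_margin=margin,
        predicted_stable=margin < 1.0,
    )


def order_n_condition(n_order: int, strength: float, n_species: int) -> bool:
    """Single-order stability condition ``strength < N**(n_order - 3)``.

    Recovers ``alpha < 1/N`` for pairwise, ``beta < 1`` for three-way and
    ``gamma < N`` for four-way interactions.
    """
    if n_order < 2:
        raise ValueError("interaction order must be at least 2")
    return strength < float(n_species) ** (n_order - 3)


def diversity_bounds(alpha: float, beta: float, gamma: float) -> DiversityBounds:
    """Roots of ``alpha N**2 - (1 - beta) N + gamma = 0`` and the optimal N*.

    ``n_star = sqrt(gamma / alpha)`` wherever both strengths are positive
    (the location of the minimum margin, independent of beta).  For
    ``alpha == 0`` the upper bound is unbounded and the lower bound is
    ``gamma / (1 - beta)``; for ``beta >= 1`` no community size is stable.
    """
    if min(alpha, beta, gamma) < 0:
        raise ValueError("strengths must be non-negative")
    one_minus_beta = 1.0 - beta
    disc = one_minus_beta**2 - 4.0 * alpha * gamma
    n_star = math.sqrt(gamma / alpha) if alpha > 0 and gamma > 0 else None
    if beta >= 1.0:
        return DiversityBounds(None, None, n_star, disc)
    if alpha == 0.0:
        return DiversityBounds(gamma / one_minus_beta, math.inf, n_star, disc)
    if disc < 0.0:
        return DiversityBounds(None, None, n_star, disc)
    # cancellation-free quadratic roots: larger root from the sum, smaller
    # from the product gamma / (alpha * n_upper)
    q = 0.5 * (one_minus_beta + math.sqrt(disc))
    return DiversityBounds(
        n_lower=gamma / q if q > 0 else 0.0,
        n_upper=q / alpha,
        n_star=n_star,
        discriminant=disc,
    )


def sample_effective_spectrum(
    n_species: int,
    alpha: float,
    beta: float,
    gamma: float,
    n_samples: int,
    seed: int,
    options: TensorOptions | None = None,
    x: np.ndarray | None = None,
) -> np.ndarray:
    """Eigenvalues of sampled ``A_eff`` matrices, shape ``(n_samples, N)``.

    Each sample draws a fresh seeded community, scales it, and evaluates
    ``A_eff`` at ``x`` (default uniform 1/N).
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31, size=n_samples)
    eigs = np.empty((n_samples, n_species), dtype=complex)
    for s, sub in enumerate(sub_seeds):
        inter = scaled_community(n_species, int(sub), alpha, beta, gamma, options)
        eigs[s] = np.linalg.eigvals(effective_pairwise(inter, x))
    return eigs


def spectral_radii(eigenvalues: np.ndarray) -> np.ndarray:
    """Per-sample spectral radius ``max |lambda|`` of a (samples, N) array."""
    return np.abs(np.atleast_2d(eigenvalues)).max(axis=1)
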