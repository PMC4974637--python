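"""Community dynamics: growth rates, replicator / Lotka-Volterra RHS, Jacobians.

The per-capita growth rate of species ``i`` is

    f_i(x) = -x_i + sum_j A_ij x_j + sum_{jk} B_ijk x_j x_k
             + sum_{jkl} C_ijkl x_j x_k x_l

where the leading ``-x_i`` encodes self-limitation of an inherently stable
community and the sums run over all index tuples (structural restrictions
live in the tensors themselves).  The replicator model subtracts the
abundance-weighted mean growth rate ``phi = sum_j x_j f_j`` from each
species, which keeps the total abundance constant on the simplex:

    dx_i/dt = x_i (f_i - phi).

The Lotka-Volterra variant drops the normalization, ``dx_i/dt = x_i f_i``.
Its published form is not fully specified here, so it is a labelled
reconstruction kept out of the quantitative reproduction targets.

Tensor contractions are matricized so the dominant cost is a dense
matrix-vector product (``N**4`` multiply-adds for the four-way term).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .interactions import ScaledInteractions

__all__ = [
    "ModelSpec",
    "growth_rates",
    "growth_rate_gradient",
    "replicator_rhs",
    "lotka_volterra_rhs",
    "jacobian",
    "make_rhs",
]

VARIANTS = ("replicator", "lotka_volterra")


@dataclass(frozen=True)
class ModelSpec:
    """A dynamical model: variant plus the scaled interaction tensors."""

    interactions: ScaledInteractions
    variant: str = "replicator"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")

    @property
    def n_species(self) -> int:
        return self.interactions.n_species


def _check_state(x: np.ndarray, n: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (n,):
        raise ValueError(f"state has shape {x.shape}, expected ({n},)")
    return x


def growth_rates(x: np.ndarray, interactions: ScaledInteractions) -> np.ndarray:
    """Per-capita growth rates ``f(x)`` including the ``-x`` self-limitation."""
    n = interactions.n_species
    x = _check_state(x, n)
    f = -x
    a, b, c = interactions.a, interactions.b, interactions.c
    if a is not None:
        f = f + a @ x
    if b is not None:
        f = f + (b.reshape(n * n, n) @ x).reshape(n, n) @ x
    if c is not None:
        f = f + ((c.reshape(n**3, n) @ x).reshape(n * n, n) @ x).reshape(n, n) @ x
    return f


def growth_rate_gradient(x: np.ndarray, interactions: ScaledInteractions) -> np.ndarray:
    """Exact gradient ``df_i/dx_j`` of the per-capita growth rates.

    ``df_i/dx_j = -delta_ij + A_ij + sum_k (B_ijk + B_ikj) x_k
    + sum_{kl} (C_ijkl + C_ikjl + C_iklj) x_k x_l``.
    """
    n = interactions.n_species
    x = _check_state(x, n)
    g = -np.eye(n)
    a, b, c = interactions.a, interactions.b, interactions.c
    if a is not None:
        g = g + a
    if b is not None:
        g = g + np.tensordot(b, x, axes=(2, 0)) + np.tensordot(b, x, axes=(1, 0))
    if c is not None:
        d_l = np.tensordot(c, x, axes=(3, 0))  # (i, j, k): sum_l C_ijkl x_l
        g = g + np.tensordot(d_l, x, axes=(2, 0))  # wrt index at position 1
        g = g + np.tensordot(d_l, x, axes=(1, 0))  # wrt index at position 2
        e_j = np.tensordot(c, x, axes=(1, 0))  # (i, k, l): sum_j C_ijkl x_j
        g = g + np.tensordot(e_j, x, axes=(1, 0))  # wrt index at position 3
    return g


def replicator_rhs(x: np.ndarray, interactions: ScaledInteractions) -> np.ndarray:
    """Abundance-conserving replicator right-hand side ``x_i (f_i - phi)``.

    The returned vector sums to ``phi * (1 - sum x)``, i.e. to zero (up to
    floating point) on the simplex; faces ``x_i = 0`` are invariant.
    """
    f = growth_rates(x, interactions)
    x = np.asarray(x, dtype=float)
    phi = float(x @ f)
    return x * (f - phi)


def lotka_volterra_rhs(x: np.ndarray, interactions: ScaledInteractions) -> np.ndarray:
    """Lotka-Volterra variant ``x_i f_i`` (no normalization term)."""
    return np.asarray(x, dtype=float) * growth_rates(x, interactions)


def jacobian(
    x: np.ndarray, interactions: ScaledInteractions, variant: str = "replicator"
) -> np.ndarray:
    """Exact analytic Jacobian of the chosen right-hand side.

    For the replicator variant the normalization derivatives are included:
    ``J_ij = delta_ij (f_i - phi) + x_i (df_i/dx_j - dphi/dx_j)`` with
    ``dphi/dx_j = f_j + sum_m x_m df_m/dx_j``.  On the simplex every column
    of ``J`` sums to ``-phi`` (the derivative of the conserved total
    abundance rate).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    n = interactions.n_species
    x = _check_state(x, n)
    f = growth_rates(x, interactions)
    g = growth_rate_gradient(x, interactions)
    if variant == "lotka_volterra":
        return np.diag(f) + x[:, None] * g
    phi = float(x @ f)
    dphi = f + x @ g
    return np.diag(f - phi) + x[:, None] * (g - dphi[None, :])


def make_rhs(model: ModelSpec) -> Callable[[float, np.ndarray], np.ndarray]:
    """Integrator-ready ``(t, x) -> dx/dt`` closure for a model.

    Overflow warnings are suppressed: diverging trajectories (strong
    interactions outside the simplex) are detected by the integration
    driver from non-finite states instead.
    """
    inter = model.interactions
    rhs = replicator_rhs if model.variant == "replicator" else lotka_volterra_rhs

    def f(t: float, x: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore", invalid="ignore", under="ignore"):
            return rhs(x, inter)

    return f
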