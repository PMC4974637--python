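"""Random interaction tensors for pairwise and higher-order community models.

A community of ``N`` species carries a pairwise interaction matrix ``A``
(``N x N``), a three-way tensor ``B`` (``N x N x N``) and a four-way tensor
``C`` (``N x N x N x N``).  Entry ``A[i, j]`` is the effect of species ``j``
on the per-capita growth of species ``i``; ``B[i, j, k]`` is the joint effect
of species ``j`` and ``k`` on species ``i``, modelling one species modulating
the interaction between two others (e.g. degradation of an antibiotic that
mediates a pairwise inhibition), and similarly for ``C``.

Unscaled ("tilde") tensors hold standardized random entries: mean 0 and unit
variance over the nonzero support, for every supported distribution.  The
interaction strengths ``alpha``, ``beta``, ``gamma`` are the *variances* of
the scaled coefficients, so scaling multiplies a standardized tensor by the
square root of the strength.

Tensors are regenerated from an integer seed rather than stored; each order
draws from an independent child stream of the seed, so a pairwise-only
simulation never materializes the ``N**4`` tensor yet all orders reproduce
exactly when requested together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TensorOptions",
    "InteractionEnsemble",
    "ScaledInteractions",
    "generate_ensemble",
    "scale",
    "scaled_community",
    "structural_mask",
]

_DISTRIBUTIONS = ("gaussian", "uniform", "laplace")


@dataclass(frozen=True)
class TensorOptions:
    """Structural options for random interaction tensors.

    Parameters
    ----------
    distribution
        Marginal law of the nonzero entries; all choices are standardized to
        mean 0 and variance 1 (``uniform`` is on ``[-sqrt(3), sqrt(3)]``).
    connectance
        Probability in ``(0, 1]`` that an entry is nonzero; masked entries
        are exactly zero and the surviving entries keep unit variance.
    exclude_focal
        When set (the default), order-3 and order-4 entries involving the
        focal species among their trailing indices are zero
        (``B[i, j, k] != 0`` only when ``j != i`` and ``k != i``), so
        high-order terms are pure modulations of the focal species by
        *other* species, matching the definition of a high-order
        interaction; repeated trailing indices are still allowed.
    exclude_diagonal
        When set, order-3 and order-4 entries are nonzero only for pairwise
        distinct indices (``B[i, j, k] != 0`` only when ``i != j != k != i``).
        Implies ``exclude_focal``.
    strict_order
        When set, only entries whose trailing indices are strictly
        decreasing (``j > k`` for order 3, ``j > k > l`` for order 4) are
        kept.  Implies ``exclude_diagonal``.
    """

    distribution: str = "gaussian"
    connectance: float = 1.0
    exclude_focal: bool = True
    exclude_diagonal: bool = False
    strict_order: bool = False

    def __post_init__(self) -> None:
        if self.distribution not in _DISTRIBUTIONS:
            raise ValueError(
                f"unknown distribution {self.distribution!r}; choose from {_DISTRIBUTIONS}"
            )
        if not (0.0 < float(self.connectance) <= 1.0):
            raise ValueError("connectance must lie in (0, 1]")
        if self.strict_order and not self.exclude_diagonal:
            # strict trailing-index ordering only makes sense off-diagonal
            object.__setattr__(self, "exclude_diagonal", True)
        if self.exclude_diagonal and not self.exclude_focal:
            object.__setattr__(self, "exclude_focal", True)


@dataclass(frozen=True)
class InteractionEnsemble:
    """One community draw of standardized (unit-variance) interaction tensors."""

    n_species: int
    a_tilde: np.ndarray
    b_tilde: np.ndarray
    c_tilde: np.ndarray
    seed: int
    options: TensorOptions = field(default_factory=TensorOptions)


@dataclass(frozen=True)
class ScaledInteractions:
    """Interaction tensors after strength scaling.

    ``None`` for an order means the tensor is structurally zero (the
    corresponding strength was exactly 0); consumers treat it as a zero
    tensor without allocating it.
    """

    n_species: int
    a: np.ndarray | None
    b: np.ndarray | None
    c: np.ndarray | None

    def tensor(self, order: int) -> np.ndarray | None:
        return {2: self.a, 3: self.b, 4: self.c}[order]


def _standardized_sample(rng: np.random.Generator, shape, distribution: str) -> np.ndarray:
    if distribution == "gaussian":
        return rng.standard_normal(shape)
    if distribution == "uniform":
        r = math.sqrt(3.0)  # variance of U(-r, r) is r**2 / 3 = 1
        return rng.uniform(-r, r, shape)
    if distribution == "laplace":
        return rng.laplace(0.0, 1.0 / math.sqrt(2.0), shape)
    raise ValueError(f"unknown distribution {distribution!r}")


def structural_mask(n_species: int, order: int, options: TensorOptions) -> np.ndarray | None:
    """Boolean keep-mask implied by the structural flags, or None if trivial.

    Order 2 is never masked structurally (the explicit ``-x_i``
    self-limitation is separate from ``A`` and the pairwise diagonal stays
    random, as in the baseline model).
    """
    if order < 3 or not options.exclude_focal:
        return None
    idx = np.indices((n_species,) * order)
    keep = np.ones((n_species,) * order, dtype=bool)
    if options.exclude_diagonal:
        for a in range(order):
            for b in range(a + 1, order):
                keep &= idx[a] != idx[b]
    else:  # focal species only: trailing indices differ from the first
        for a in range(1, order):
            keep &= idx[a] != idx[0]
    if options.strict_order:
        for a in range(1, order - 1):
            keep &= idx[a] > idx[a + 1]
    return keep


def _draw_tensor(n_species: int, seed: int, order: int, options: TensorOptions) -> np.ndarray:
    # independent child stream per order keyed on (seed, order)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(order,)))
    t = _standardized_sample(rng, (n_species,) * order, options.distribution)
    if options.connectance < 1.0:
        t = np.where(rng.random(t.shape) < options.connectance, t, 0.0)
    keep = structural_mask(n_species, order, options)
    if keep is not None:
        t = np.where(keep, t, 0.0)
    return t


def generate_ensemble(
    n_species: int, seed: int, options: TensorOptions | None = None
) -> InteractionEnsemble:
    """Draw standardized pairwise, three-way and four-way tensors.

    Deterministic in ``(n_species, seed, options)``.
    """
    if n_species < 2:
        raise ValueError("n_species must be at least 2")
    options = options or TensorOptions()
    return InteractionEnsemble(
        n_species=n_species,
        a_tilde=_draw_tensor(n_species, seed, 2, options),
        b_tilde=_draw_tensor(n_species, seed, 3, options),
        c_tilde=_draw_tensor(n_species, seed, 4, options),
        seed=int(seed),
        options=options,
    )


def _check_strengths(alpha: float, beta: float, gamma: float) -> None:
    for name, s in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        if s < 0:
            raise ValueError(f"{name} must be non-negative, got {s}")


def scale(
    ensemble: InteractionEnsemble, alpha: float, beta: float, gamma: float
) -> ScaledInteractions:
    """Scale standardized tensors so entry variances equal the strengths.

    ``A = sqrt(alpha) * A~`` and likewise for the higher orders: strengths
    are coefficient variances, not standard deviations.
    """
    _check_strengths(alpha, beta, gamma)
    return ScaledInteractions(
        n_species=ensemble.n_species,
        a=math.sqrt(alpha) * ensemble.a_tilde,
        b=math.sqrt(beta) * ensemble.b_tilde,
        c=math.sqrt(gamma) * ensemble.c_tilde,
    )


def scaled_community(
    n_species: int,
    seed: int,
    alpha: float,
    beta: float,
    gamma: float,
    options: TensorOptions | None = None,
) -> ScaledInteractions:
    """Scaled tensors for one community draw, skipping zero-strength orders.

    Equivalent to ``scale(generate_ensemble(n_species, seed, options), ...)``
    except that orders with exactly zero strength are returned as ``None``
    (structurally zero) and never drawn; the per-order seed streams make the
    generated orders bit-identical either way.
    """
    if n_species < 2:
        raise ValueError("n_species must be at least 2")
    _check_strengths(alpha, beta, gamma)
    options = options or TensorOptions()

    def _maybe(order: int, strength: float) -> np.ndarray | None:
        if strength == 0.0:
            return None
        return math.sqrt(strength) * _draw_tensor(n_species, seed, order, options)

    return ScaledInteractions(
        n_species=n_species,
        a=_maybe(2, alpha),
        b=_maybe(3, beta),
        c=_maybe(4, gamma),
    )
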