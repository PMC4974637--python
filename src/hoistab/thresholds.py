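"""Feasibility probabilities and critical interaction strengths.

The probability that a random community is feasible is estimated as the
fraction of feasible runs over a *fixed collection* of R seeded communities
(common random numbers), so that infeasibility is monotone in strength in
practice and quantile crossings are well defined.  The critical strength of
an interaction order is the strength at which 5% of the collection loses
feasibility; the 2% and 10% crossings bracket it (error-bar range).

Strength searches use a multiplicative coarse scan (factor 1.3 per step)
followed by bisection in log-strength; replicate evaluation stops early as
soon as the quantile comparison is decided, which leaves the result
identical to exhaustive evaluation because replicates are independently
seeded and visited in a fixed order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dynamics import ModelSpec
from .integrate import IntegrationControls, SimulationOutcome, run_to_persistence
from .interactions import TensorOptions, scaled_community

__all__ = [
    "MatrixCollection",
    "FeasibilityEstimate",
    "CriticalThreshold",
    "RadialBoundaryPoint",
    "ORDERS",
    "simulate_replicate",
    "feasibility_probability",
    "find_critical_strength",
    "radial_scan",
]

ORDERS = ("pairwise", "three_way", "four_way")


@dataclass(frozen=True)
class MatrixCollection:
    """A fixed, regenerable collection of R community seeds at one N."""

    n_species: int
    seeds: tuple[int, ...]
    options: TensorOptions = field(default_factory=TensorOptions)

    def __post_init__(self) -> None:
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("collection seeds must be distinct")

    @property
    def n_replicates(self) -> int:
        return len(self.seeds)

    @classmethod
    def from_master_seed(
        cls,
        n_species: int,
        n_replicates: int = 300,
        master_seed: int = 0,
        options: TensorOptions | None = None,
    ) -> "MatrixCollection":
        """Derive ``n_replicates`` distinct sub-2^31 seeds from one master seed."""
        ss = np.random.SeedSequence(master_seed, spawn_key=(n_species,))
        raw = ss.generate_state(4 * n_replicates, np.uint64) % np.uint64(2**31)
        seeds: list[int] = []
        seen: set[int] = set()
        for s in raw:
            s = int(s)
            if s not in seen:
                seen.add(s)
                seeds.append(s)
            if len(seeds) == n_replicates:
                break
        if len(seeds) < n_replicates:
            raise RuntimeError("could not derive enough distinct seeds")
        return cls(n_species, tuple(seeds), options or TensorOptions())


@dataclass(frozen=True)
class FeasibilityEstimate:
    alpha: float
    beta: float
    gamma: float
    fraction_feasible: float
    fraction_feasible_conservative: float
    n_replicates: int
    n_timeouts: int
    n_integrator_failures: int


@dataclass(frozen=True)
class CriticalThreshold:
    """Interaction strength at the quantile crossing, with its bracket."""

    order: str
    n_species: int
    value: float
    bracket_low: float
    bracket_high: float
    quantile: float
    bracket_quantiles: tuple[float, float]
    n_replicates: int
    n_simulations: int


@dataclass(frozen=True)
class RadialBoundaryPoint:
    theta: float
    r: float
    alpha: float
    gamma: float
    unbounded: bool


def simulate_replicate(
    collection: MatrixCollection,
    index: int,
    alpha: float,
    beta: float,
    gamma: float,
    controls: IntegrationControls | None = None,
    variant: str = "replicator",
    keep_trace: bool = False,
) -> SimulationOutcome:
    """Run one seeded community of the collection at the given strengths."""
    inter = scaled_community(
        collection.n_species, collection.seeds[index], alpha, beta, gamma, collection.options
    )
    return run_to_persistence(
        ModelSpec(interactions=inter, variant=variant), controls, keep_trace=keep_trace
    )


def feasibility_probability(
    collection: MatrixCollection,
    alpha: float,
    beta: float,
    gamma: float,
    controls: IntegrationControls | None = None,
    variant: str = "replicator",
) -> FeasibilityEstimate:
    """Fraction of feasible communities over the full fixed collection.

    Integrator failures are excluded from the denominator (and counted).
    """
    n_feas = n_cons = n_timeout = n_fail = 0
    for i in range(collection.n_replicates):
        out = simulate_replicate(collection, i, alpha, beta, gamma, controls, variant)
        if out.status == "failed":
            n_fail += 1
            continue
        if out.status == "timeout":
            n_timeout += 1
        n_feas += out.feasible
        n_cons += out.feasible_conservative
    denom = max(collection.n_replicates - n_fail, 1)
    return FeasibilityEstimate(
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        fraction_feasible=n_feas / denom,
        fraction_feasible_conservative=n_cons / denom,
        n_replicates=collection.n_replicates,
        n_timeouts=n_timeout,
        n_integrator_failures=n_fail,
    )


class _ScanEvaluator:
    """Lazily evaluated per-replicate verdicts along a 1-parameter strength path.

    Verdicts are cached per strength and extended replicate-by-replicate in a
    fixed order, so early-stopped quantile comparisons are decided exactly as
    they would be by exhaustive evaluation.
    """

    def __init__(
        self,
        collection: MatrixCollection,
        strengths_of: Callable[[float], tuple[float, float, float]],
        controls: IntegrationControls | None,
        variant: str = "replicator",
    ) -> None:
        self.collection = collection
        self.strengths_of = strengths_of
        self.controls = controls
        self.variant = variant
        self._cache: dict[float, list[str]] = {}
        self.n_simulations = 0

    def _extend_one(self, s: float, verdicts: list[str]) -> None:
        a, b, g = self.strengths_of(s)
        out = simulate_replicate(
            self.collection, len(verdicts), a, b, g, self.controls, self.variant
        )
        self.n_simulations += 1
        if out.status == "failed":
            verdicts.append("failed")
        else:
            verdicts.append("feasible" if out.feasible else "infeasible")

    def infeasible_fraction_ge(self, s: float, q: float) -> bool:
        """Whether the infeasible fraction at strength ``s`` is >= ``q``."""
        R = self.collection.n_replicates
        v = self._cache.setdefault(float(s), [])
        while True:
            n_inf = v.count("infeasible")
            n_fail = v.count("failed")
            rem = R - len(v)
            # certain bounds on the final fraction (failures shrink the denominator)
            f_lo = n_inf / max(R - n_fail, 1)
            f_hi = max(
                (n_inf + rem) / max(R - n_fail, 1),
                n_inf / max(R - n_fail - rem, 1) if R - n_fail - rem > 0 else 0.0,
            )
            if f_lo >= q - 1e-12:
                return True
            if f_hi < q - 1e-12:
                return False
            self._extend_one(s, v)


def _strength_direction(order: str) -> Callable[[float], tuple[float, float, float]]:
    if order == "pairwise":
        return lambda s: (s, 0.0, 0.0)
    if order == "three_way":
        return lambda s: (0.0, s, 0.0)
    if order == "four_way":
        return lambda s: (0.0, 0.0, s)
    raise ValueError(f"unknown order {order!r}; choose from {ORDERS}")


def margin_factor(order: str, n_species: int, options: TensorOptions) -> float:
    """Analytic squared-Girko-radius margin per unit strength of one order.

    Counts the tensor entries contributing to an effective pairwise
    coefficient under the structural flags; at strength ``1/factor`` the
    Girko disc radius of the effective matrix reaches 1.
    """
    n = n_species
    if order == "pairwise":
        return float(n)
    if order == "three_way":
        if options.strict_order:
            count = n - 2  # unordered pairs {j, k} containing j, k != i
        elif options.exclude_diagonal:
            count = 2 * (n - 2)
        elif options.exclude_focal:
            count = 2 * (n - 1)
        else:
            count = 2 * n
        return count / n
    if order == "four_way":
        if options.strict_order:
            count = (n - 2) * (n - 3) // 2  # triples {j,k,l} containing j
        elif options.exclude_diagonal:
            count = 3 * (n - 2) * (n - 3)
        elif options.exclude_focal:
            count = 3 * (n - 1) ** 2
        else:
            count = 3 * n * n
        return count / n**3
    raise ValueError(f"unknown order {order!r}; choose from {ORDERS}")


def _default_guess(order: str, n_species: int, options: TensorOptions) -> float:
    # start well below the analytic margin-1 strength of each order
    factor = margin_factor(order, n_species, options)
    if factor <= 0:  # degenerate small-N structural masks
        factor = 1.0 / n_species
    return 1.0 / (6.0 * factor)


def find_critical_strength(
    collection: MatrixCollection,
    order: str,
    quantile: float = 0.05,
    bracket_quantiles: tuple[float, float] = (0.02, 0.10),
    controls: IntegrationControls | None = None,
    initial_strength: float | None = None,
    growth: float = 1.3,
    rel_width: float = 0.05,
    max_scan_steps: int = 80,
    variant: str = "replicator",
) -> CriticalThreshold:
    """Strength at which the infeasible fraction first reaches the quantile.

    Scans a geometric ladder (factor ``growth``) on the fixed collection
    until the upper bracket quantile is crossed, then bisects each quantile
    crossing in log-strength down to ``rel_width`` relative width.  The
    first crossing is taken should the fraction be non-monotone.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    q_lo, q_hi = bracket_quantiles
    if not (0.0 < q_lo <= quantile <= q_hi < 1.0):
        raise ValueError("bracket quantiles must straddle the quantile")
    ev = _ScanEvaluator(collection, _strength_direction(order), controls, variant)

    s0 = (
        initial_strength
        if initial_strength is not None
        else _default_guess(order, collection.n_species, collection.options)
    )
    steps = 0
    while ev.infeasible_fraction_ge(s0, q_lo):
        s0 /= growth
        steps += 1
        if steps > max_scan_steps:
            raise RuntimeError(
                f"{order}: infeasible fraction still >= {q_lo} at strength {s0:.3g}"
            )
    ladder = [s0]
    while not ev.infeasible_fraction_ge(ladder[-1], q_hi):
        if len(ladder) > max_scan_steps:
            raise RuntimeError(
                f"{order}: quantile {q_hi} not crossed in scanned interval "
                f"[{ladder[0]:.3g}, {ladder[-1]:.3g}]"
            )
        ladder.append(ladder[-1] * growth)

    def crossing(q: float) -> float:
        lo = ladder[0]
        hi = None
        for s in ladder[1:]:
            if ev.infeasible_fraction_ge(s, q):
                hi = s
                break
            lo = s
        assert hi is not None  # guaranteed: ladder top crossed q_hi >= q
        while hi / lo > 1.0 + rel_width:
            mid = math.sqrt(lo * hi)
            if ev.infeasible_fraction_ge(mid, q):
                hi = mid
            else:
                lo = mid
        return math.sqrt(lo * hi)

    value = crossing(quantile)
    v_lo = crossing(q_lo)
    v_hi = crossing(q_hi)
    return CriticalThreshold(
        order=order,
        n_species=collection.n_species,
        value=value,
        bracket_low=min(v_lo, value),
        bracket_high=max(v_hi, value),
        quantile=quantile,
        bracket_quantiles=bracket_quantiles,
        n_replicates=collection.n_replicates,
        n_simulations=ev.n_simulations,
    )


def radial_scan(
    collection: MatrixCollection,
    thetas: Sequence[float] | None = None,
    controls: IntegrationControls | None = None,
    quantile: float = 0.05,
    r_step: float = 0.5,
    r_max: float = 60.0,
    r_width: float = 0.05,
    alpha_anchor: float = 0.001,
    alpha_base: float = 1.2,
    gamma_anchor: float = 0.05,
    gamma_base: float = 1.3,
    variant: str = "replicator",
) -> list[RadialBoundaryPoint]:
    """Feasibility boundary in (alpha, gamma) space along radial lines.

    Along the ray at angle ``theta``, strengths grow as
    ``alpha = alpha_anchor * alpha_base ** (r cos theta)`` and
    ``gamma = gamma_anchor * gamma_base ** (r sin theta)``; ``r`` increases
    from 0 in steps of ``r_step`` until the infeasible fraction reaches the
    quantile, then the crossing is bisected to width ``r_width``.
    """
    if thetas is None:
        thetas = np.linspace(0.0, math.pi / 2.0, 17)
    points: list[RadialBoundaryPoint] = []
    for theta in thetas:
        ct, st = math.cos(theta), math.sin(theta)

        def strengths(r: float, ct: float = ct, st: float = st):
            return (alpha_anchor * alpha_base ** (r * ct), 0.0, gamma_anchor * gamma_base ** (r * st))

        ev = _ScanEvaluator(collection, strengths, controls, variant)
        if ev.infeasible_fraction_ge(0.0, quantile):
            r_cross, unbounded = 0.0, False
        else:
            lo, hi, unbounded = 0.0, None, False
            r = r_step
            while r <= r_max:
                if ev.infeasible_fraction_ge(r, quantile):
                    hi = r
                    break
                lo = r
                r += r_step
            if hi is None:
                r_cross, unbounded = r_max, True
            else:
                while hi - lo > r_width:
                    mid = 0.5 * (lo + hi)
                    if ev.infeasible_fraction_ge(mid, quantile):
                        hi = mid
                    else:
                        lo = mid
                r_cross = 0.5 * (lo + hi)
        a, _, g = strengths(r_cross)
        points.append(
            RadialBoundaryPoint(theta=float(theta), r=r_cross, alpha=a, gamma=g, unbounded=unbounded)
        )
    return points
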