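import math

import numpy as np
import pytest

from hoistab.dynamics import growth_rates, jacobian
from hoistab.integrate import IntegrationControls, run_to_persistence
from hoistab.dynamics import ModelSpec
from hoistab.interactions import generate_ensemble, scale, scaled_community
from hoistab.theory import (
    diversity_bounds,
    effective_pairwise,
    girko_margin,
    order_n_condition,
    sample_effective_spectrum,
    spectral_radii,
)

from conftest import brute_effective_pairwise, finite_difference_jacobian


def test_effective_pairwise_reduces_to_a_for_pairwise_only():
    inter = scale(generate_ensemble(5, seed=1), 0.3, 0.0, 0.0)
    assert np.allclose(effective_pairwise(inter), inter.a)
    # at x = 0 every high-order term vanishes too
    full = scale(generate_ensemble(5, seed=1), 0.3, 0.2, 0.1)
    assert np.allclose(effective_pairwise(full, np.zeros(5)), full.a)


def test_effective_pairwise_matches_nested_loop_oracle():
    inter = scale(generate_ensemble(4, seed=12), 0.4, 0.3, 0.2)
    x = np.random.default_rng(2).dirichlet(np.ones(4))
    eff = effective_pairwise(inter, x)
    assert np.allclose(eff, brute_effective_pairwise(x, inter.a, inter.b, inter.c), rtol=1e-12)
    # it is also the linearization of f with the self-term removed
    J_f = finite_difference_jacobian(lambda y: growth_rates(y, inter), x)
    assert np.allclose(eff, J_f + np.eye(4), rtol=1e-5, atol=1e-6)


def test_girko_margin_values_and_boundary_convention():
    assert girko_margin(10, 0.0, 0.0, 0.0).criterion_margin == 0.0
    assert girko_margin(10, 0.0, 0.0, 0.0).predicted_stable
    boundary = girko_margin(20, 1.0 / 20.0, 0.0, 0.0)
    assert boundary.criterion_margin == pytest.approx(1.0)
    assert not boundary.predicted_stable  # margin == 1 counts unstable
    mixed = girko_margin(10, 0.02, 0.3, 2.0)
    assert mixed.criterion_margin == pytest.approx(10 * 0.02 + 0.3 + 2.0 / 10)
    loose = girko_margin(10, 0.02, 0.3, 2.0, strict_order_factors=False)
    assert loose.criterion_margin == pytest.approx(10 * 0.02 + 2 * 0.3 + 3 * 2.0 / 10)


@pytest.mark.parametrize(
    "n_order,strength,n,expected",
    [
        (2, 1.0 / 40.0, 20, True),  # alpha < 1/N
        (2, 1.0 / 10.0, 20, False),
        (3, 2.0, 50, False),  # beta < 1
        (3, 0.5, 50, True),
        (4, 10.0, 20, True),  # gamma < N
        (4, 40.0, 20, False),
    ],
)
def test_order_n_condition(n_order, strength, n, expected):
    assert order_n_condition(n_order, strength, n) is expected


def test_diversity_bounds_closed_forms():
    b = diversity_bounds(0.01, 0.0, 0.0)
    assert b.n_lower == pytest.approx(0.0)
    assert b.n_upper == pytest.approx(100.0)
    # vanishing discriminant: both bounds collapse onto N*
    alpha = 0.02
    closed = diversity_bounds(alpha, 0.0, 1.0 / (4 * alpha))
    assert closed.discriminant == pytest.approx(0.0, abs=1e-15)
    assert closed.n_lower == pytest.approx(1.0 / (2 * alpha))
    assert closed.n_star == pytest.approx(1.0 / (2 * alpha))
    # the fixed gamma = 1e3 * alpha ratio gives N* = sqrt(1000)
    r = diversity_bounds(1e-6, 0.0, 1e-3)
    assert r.n_star == pytest.approx(math.sqrt(1000.0))
    # degenerate regimes
    assert diversity_bounds(0.1, 1.2, 0.1).is_empty
    free = diversity_bounds(0.0, 0.5, 2.0)
    assert free.n_lower == pytest.approx(4.0) and math.isinf(free.n_upper)
    assert diversity_bounds(0.1, 0.0, 10.0).is_empty  # discriminant < 0


def test_margin_and_bounds_are_dual():
    rng = np.random.default_rng(0)
    for _ in range(200):
        alpha = 10 ** rng.uniform(-4, -1)
        beta = rng.uniform(0.0, 0.9)
        gamma = 10 ** rng.uniform(-2, 1)
        n = int(rng.integers(2, 200))
        b = diversity_bounds(alpha, beta, gamma)
        stable = girko_margin(n, alpha, beta, gamma).predicted_stable
        inside = (not b.is_empty) and b.n_lower < n < b.n_upper
        assert stable == inside


def test_girko_radius_concentrates_at_sqrt_margin():
    # pairwise-only at margin m: spectral radius -> sqrt(m) as N grows
    for margin in (0.5, 1.0):
        eigs = sample_effective_spectrum(100, margin / 100.0, 0.0, 0.0, n_samples=8, seed=5)
        radii = spectral_radii(eigs)
        assert abs(radii.mean() - math.sqrt(margin)) < 0.1


def test_neglected_normalization_terms_preserve_leading_sign():
    """At weak-interaction fixed points, the exact replicator Jacobian and
    the effective-pairwise approximation diag(x)(A_eff - I) agree on the
    sign of the leading eigenvalue in nearly all seeded instances."""
    agree = 0
    n = 10
    for seed in range(12):
        inter = scaled_community(n, seed, 0.02, 0.0, 0.1)
        out = run_to_persistence(ModelSpec(interactions=inter), IntegrationControls())
        x_star = np.clip(out.final_x, 0.0, None)
        x_star = x_star / x_star.sum()
        exact = np.linalg.eigvals(jacobian(x_star, inter, "replicator"))
        approx = np.linalg.eigvals(
            np.diag(x_star) @ (effective_pairwise(inter, x_star) - np.eye(n))
        )
        # leading nonzero mode (the conservation mode sits at ~0)
        lead_exact = np.sort(exact.real)[-2]
        lead_approx = np.sort(approx.real)[-2]
        agree += (lead_exact < 0) == (lead_approx < 0)
    assert agree >= 11


def test_invalid_theory_arguments():
    with pytest.raises(ValueError):
        girko_margin(0, 0.1, 0.0, 0.0)
    with pytest.raises(ValueError):
        girko_margin(5, -0.1, 0.0, 0.0)
    with pytest.raises(ValueError):
        order_n_condition(1, 0.5, 10)
    with pytest.raises(ValueError):
        diversity_bounds(-0.1, 0.0, 0.0)
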