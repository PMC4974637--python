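import numpy as np
import pytest

from hoistab.interactions import generate_ensemble, scale


@pytest.fixture
def small_interactions():
    """Scaled tensors for a 4-species community with all orders present."""
    ens = generate_ensemble(4, seed=123)
    return scale(ens, 0.3, 0.2, 0.1)


def brute_growth_rates(x, a, b, c):
    """Nested-loop oracle for the per-capita growth rates."""
    n = len(x)
    f = np.empty(n)
    for i in range(n):
        v = -x[i]
        for j in range(n):
            v += a[i, j] * x[j]
            for k in range(n):
                v += b[i, j, k] * x[j] * x[k]
                for l in range(n):
                    v += c[i, j, k, l] * x[j] * x[k] * x[l]
        f[i] = v
    return f


def brute_effective_pairwise(x, a, b, c):
    """Nested-loop oracle for the effective pairwise matrix."""
    n = len(x)
    eff = np.array(a, dtype=float, copy=True)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                eff[i, j] += (b[i, j, k] + b[i, k, j]) * x[k]
                for l in range(n):
                    eff[i, j] += (c[i, j, k, l] + c[i, k, j, l] + c[i, k, l, j]) * x[k] * x[l]
    return eff


def finite_difference_jacobian(fun, x, h=1e-6):
    """Central-difference Jacobian of a vector field."""
    n = len(x)
    J = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (fun(x + e) - fun(x - e)) / (2 * h)
    return J
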