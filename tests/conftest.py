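import math

import numpy as np
import pytest

import squarecycle as sq


@pytest.fixture(scope="session")
def unit_rates():
    return sq.fixture_rate_set("unit")


@pytest.fixture(scope="session")
def plausible():
    """Shipped default: detailed balanced, violates the monotonicity criterion."""
    return sq.fixture_rate_set("plausible")


@pytest.fixture(scope="session")
def diffusion_limited():
    """Detailed balanced with k_x_xp == k_sp: the criterion holds."""
    return sq.fixture_rate_set("diffusion_limited")


@pytest.fixture(scope="session")
def asym_potencies():
    """Potencies breaking the S<->P, X<->XP symmetry of the unit rate set."""
    return sq.Potencies(0.0, 0.0, 1.0, 2.0)


def grid_concavity_oracle(coeffs, n=100001, umax=36.0):
    """Independent inflection count: extended-precision dense-grid differencing.

    Evaluates the leakiness-shifted response on a log grid in 80-bit floats,
    normalizes to unit range, and counts sign changes of the second finite
    difference above a fixed noise threshold.  Cannot resolve features whose
    curvature signal falls below ~1e-16 of the range (marginal curves right
    at a phase boundary).
    """
    L = np.longdouble
    A, B, C, D, E, F = [L(v) for v in coeffs.as_tuple()]
    r0 = A / D
    n1, n2 = B - r0 * E, C - r0 * F
    u = np.linspace(-float(umax), float(umax), n, dtype=np.longdouble)
    x = np.exp(u) * np.sqrt(D / F)
    rr = (x * (n1 + x * n2)) / (D + x * (E + x * F))
    rng = rr.max() - rr.min()
    if rng == 0:
        return None
    g = (rr - rr.min()) / rng
    d2 = np.diff(g, 2)
    s = np.sign(d2)
    s[np.abs(d2) <= np.longdouble(1e-16)] = 0
    s = s[s != 0]
    return int((s[:-1] * s[1:] < 0).sum())


def rates_matrix(rate_sets):
    return np.array([rs.as_tuple() for rs in rate_sets])


def assert_close(a, b, rtol=1e-9, atol=0.0, msg=""):
    assert math.isclose(a, b, rel_tol=rtol, abs_tol=atol), f"{a} != {b} {msg}"
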