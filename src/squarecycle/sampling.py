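"""Seeded rate-set samplers and named fixture rate sets.

The wide sampler draws each of the eight rates log-uniformly over a window of
``decades`` decades centered on 1 (default 8, i.e. 1e-4..1e4 in units of the
reference timescale) -- wide enough to probe per-edge-pair drives up to
~e^+-18 while staying within plausible kinetic magnitudes.  The equilibrium
sampler draws the four forward (binding) rates the same way and four state
free energies uniformly over +-4 kBT, fixing the unbinding rates by detailed
balance; binding free energies of a few kBT are typical of TF- and
polymerase-promoter interactions.

Fixtures
--------
``unit``
    All eight rates equal to 1; the fully symmetric equilibrium point.
``plausible``
    The shipped default: detailed balanced, built from state energies
    (0, -2, -1, -5) kBT and forward rates (10, 0.1, 1, 5) /s spanning the
    orders of magnitude typical of transcription.  It deliberately violates
    both equalities of the kinetic monotonicity criterion (k_x_xp > k_sp and
    k_xp_x > k_ps), so drive scans starting here can reach nonmonotonic
    responses.
``diffusion_limited``
    Same energies, but the TF leaves the polymerase binding rate untouched
    (k_x_xp = k_sp): the classical diffusion-limited-binding scenario.  The
    monotonicity criterion holds, so no amount of drive along non-criterion
    edges can produce a nonmonotonic response.
"""

from __future__ import annotations

import math

import numpy as np

from .graph_model import EDGE_NAMES, Potencies, RateSet

__all__ = [
    "DEFAULT_POTENCIES",
    "FIXTURE_NAMES",
    "fixture_rate_set",
    "sample_rate_array",
    "sample_rate_sets",
    "sample_equilibrium_rate_array",
    "sample_equilibrium_rate_sets",
]

DEFAULT_POTENCIES = Potencies()

_PLAUSIBLE_ENERGIES = (0.0, -2.0, -1.0, -5.0)  # E_S, E_X, E_P, E_XP in kBT

_FIXTURES = {
    "unit": lambda: RateSet(*([1.0] * 8)),
    "plausible": lambda: RateSet.from_energies(
        *_PLAUSIBLE_ENERGIES, k_sx=10.0, k_sp=0.1, k_x_xp=1.0, k_p_xp=5.0
    ),
    "diffusion_limited": lambda: RateSet.from_energies(
        *_PLAUSIBLE_ENERGIES, k_sx=10.0, k_sp=0.1, k_x_xp=0.1, k_p_xp=5.0
    ),
}

FIXTURE_NAMES = tuple(_FIXTURES)


def fixture_rate_set(name: str) -> RateSet:
    """Return a named canonical rate set (see module docstring)."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {FIXTURE_NAMES}"
        ) from None


def sample_rate_array(n: int, seed: int, decades: float = 8.0) -> np.ndarray:
    """``(n, 8)`` array of log-uniform rates over ``decades`` decades."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not decades > 0:
        raise ValueError("decades must be positive")
    rng = np.random.default_rng(seed)
    half = decades / 2.0
    return 10.0 ** rng.uniform(-half, half, size=(n, len(EDGE_NAMES)))


def sample_rate_sets(n: int, seed: int, decades: float = 8.0) -> list:
    """Seeded list of :class:`RateSet`, each rate log-uniform over the window."""
    arr = sample_rate_array(n, seed, decades)
    return [RateSet(*row) for row in arr]


def sample_equilibrium_rate_array(
    n: int, seed: int, decades: float = 8.0, energy_scale: float = 4.0
) -> np.ndarray:
    """``(n, 8)`` detailed-balanced rate sets from random state energies.

    Forward rates (k_sx, k_sp, k_x_xp, k_p_xp) are log-uniform over the
    window; state free energies are uniform over ``+-energy_scale`` kBT and
    set each reverse rate via ``k_ji = k_ij * exp(E_j - E_i)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    half = decades / 2.0
    fwd = 10.0 ** rng.uniform(-half, half, size=(n, 4))  # k_sx, k_sp, k_x_xp, k_p_xp
    e = rng.uniform(-energy_scale, energy_scale, size=(n, 4))  # E_S, E_X, E_P, E_XP
    e_s, e_x, e_p, e_xp = e.T
    out = np.empty((n, len(EDGE_NAMES)))
    cols = {name: i for i, name in enumerate(EDGE_NAMES)}
    out[:, cols["k_sx"]] = fwd[:, 0]
    out[:, cols["k_xs"]] = fwd[:, 0] * np.exp(e_x - e_s)
    out[:, cols["k_sp"]] = fwd[:, 1]
    out[:, cols["k_ps"]] = fwd[:, 1] * np.exp(e_p - e_s)
    out[:, cols["k_x_xp"]] = fwd[:, 2]
    out[:, cols["k_xp_x"]] = fwd[:, 2] * np.exp(e_xp - e_x)
    out[:, cols["k_p_xp"]] = fwd[:, 3]
    out[:, cols["k_xp_p"]] = fwd[:, 3] * np.exp(e_xp - e_p)
    return out


def sample_equilibrium_rate_sets(
    n: int, seed: int, decades: float = 8.0, energy_scale: float = 4.0
) -> list:
    arr = sample_equilibrium_rate_array(n, seed, decades, energy_scale)
    return [RateSet(*row) for row in arr]
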