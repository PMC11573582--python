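"""Systematic detailed-balance breaking along single edges and edge pairs.

Starting from a detailed-balanced base rate set, spending a free energy
``dmu`` (in kBT) on a named transition scales that rate by ``exp(dmu)``.
Within a conservative biological budget of |dmu| <= 40 kBT per edge (about
two ATP hydrolyses), these scans map which regulatory shape phenotypes each
edge or edge pair can reach, the minimum net drive at which the response
turns nonmonotonic, and where in the permissible rate box the raw slope of
the response is maximized.

The *net drive* of a modified set is its cycle affinity; for a single
modified edge it equals +-dmu according to the edge's orientation in the
cycle.  The *rate-space distance* D = sqrt(dmu1^2 + dmu2^2) measures how far
the pair moved from its starting point in log-rate space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .graph_model import (
    CRITERION_RATES,
    CYCLE_ORIENTATION,
    EDGE_NAMES,
    Potencies,
    RateSet,
    cycle_drive,
    is_detailed_balanced,
)
from .response_shape import DegenerateResponseError, classify_phenotype
from .sensitivity import _core_sensitivity
from .response_shape import _shape_core
from .steady_state import RationalResponse, square_coefficient_arrays

__all__ = [
    "DEFAULT_BUDGET",
    "DriveSpec",
    "ScanResult",
    "apply_drive",
    "scan_single_edge",
    "scan_edge_pair",
    "min_drive_to_nonmonotonicity",
    "optimize_pair_slope",
    "rate_distance",
    "all_edge_pairs",
    "pairs_containing_criterion_rate",
    "plot_phase_map",
]

#: Default per-edge free-energy budget, kBT (two ATP hydrolyses' worth).
DEFAULT_BUDGET = 40.0


@dataclass(frozen=True)
class DriveSpec:
    """One or two named edges and the free energy spent on each (kBT)."""

    edges: tuple
    dmus: tuple
    budget: float = DEFAULT_BUDGET

    def __post_init__(self) -> None:
        edges = tuple(self.edges)
        dmus = tuple(float(d) for d in self.dmus)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "dmus", dmus)
        if len(edges) not in (1, 2) or len(edges) != len(dmus):
            raise ValueError("DriveSpec needs 1 or 2 edges with matching dmus")
        if len(set(edges)) != len(edges):
            raise ValueError("edges must be distinct")
        for e in edges:
            if e not in EDGE_NAMES:
                raise ValueError(f"unknown edge {e!r}; expected one of {EDGE_NAMES}")
        if not self.budget >= 0:
            raise ValueError("budget must be nonnegative")
        for e, d in zip(edges, dmus):
            if abs(d) > self.budget + 1e-12:
                raise ValueError(
                    f"|dmu| = {abs(d):.3f} kBT on edge {e!r} exceeds the "
                    f"budget of {self.budget:.3f} kBT"
                )


@dataclass
class ScanResult:
    """Tabular scan output plus refined phenotype boundaries."""

    rows: pd.DataFrame
    boundaries: list = field(default_factory=list)
    params: dict = field(default_factory=dict)


def apply_drive(base: RateSet, spec: DriveSpec) -> RateSet:
    """Scale each named edge of ``base`` by exp(dmu); other rates unchanged."""
    out = base
    for e, d in zip(spec.edges, spec.dmus):
        out = out.scaled(e, math.exp(d))
    return out


def rate_distance(dmu1: float, dmu2: float = 0.0) -> float:
    """Euclidean distance moved in log-rate space, sqrt(dmu1^2 + dmu2^2)."""
    return math.hypot(dmu1, dmu2)


def all_edge_pairs() -> list:
    """The 28 unordered pairs of the eight edge names, in canonical order."""
    return [
        (EDGE_NAMES[i], EDGE_NAMES[j])
        for i in range(len(EDGE_NAMES))
        for j in range(i + 1, len(EDGE_NAMES))
    ]


def pairs_containing_criterion_rate() -> list:
    """Pairs with at least one of the four monotonicity-criterion rates (22)."""
    crit = set(CRITERION_RATES)
    return [p for p in all_edge_pairs() if crit & set(p)]


# ---------------------------------------------------------------------------
# scan internals
# ---------------------------------------------------------------------------


def _modified_matrix(base: RateSet, edges, dmu_cols) -> np.ndarray:
    """Rate matrix (n, 8) with the named edges scaled by exp(dmu) per row."""
    n = len(dmu_cols[0])
    mat = np.tile(np.array(base.as_tuple()), (n, 1))
    for e, col in zip(edges, dmu_cols):
        mat[:, EDGE_NAMES.index(e)] *= np.exp(np.asarray(col, dtype=float))
    return mat


def _scan_rows(
    base: RateSet, edges, dmu_cols, potencies: Potencies | None
) -> pd.DataFrame:
    mat = _modified_matrix(base, edges, dmu_cols)
    A, B, C, D, E, F = square_coefficient_arrays(mat, potencies)
    base_drive = cycle_drive(base)
    signs = [CYCLE_ORIENTATION[e] for e in edges]
    records = []
    for i in range(len(mat)):
        rec = {}
        if len(edges) == 1:
            rec["dmu"] = float(dmu_cols[0][i])
            dist = rate_distance(dmu_cols[0][i])
            net = base_drive + signs[0] * dmu_cols[0][i]
        else:
            rec["dmu1"] = float(dmu_cols[0][i])
            rec["dmu2"] = float(dmu_cols[1][i])
            dist = rate_distance(dmu_cols[0][i], dmu_cols[1][i])
            net = base_drive + signs[0] * dmu_cols[0][i] + signs[1] * dmu_cols[1][i]
        try:
            coeffs = RationalResponse(A[i], B[i], C[i], D[i], E[i], F[i])
            rep = classify_phenotype(coeffs)
            sens = _core_sensitivity(_shape_core(coeffs))
            rec.update(rep.to_csv_row())
            rec["s_max"] = sens.s_max
            rec["raw_slope_max"] = sens.raw_sharpness_max
        except DegenerateResponseError:
            rec.update(
                {k: math.nan for k in (
                    "u1", "u2", "u3", "s1", "s2", "s3",
                    "r0", "r_inf", "r_min", "r_max", "r_star",
                    "s_max", "raw_slope_max",
                )}
            )
            rec["n_inflections"] = 0
            rec["monotonic"] = True
        rec["net_drive"] = float(net)
        rec["distance"] = float(dist)
        records.append(rec)
    return pd.DataFrame.from_records(records)


def _count_for(base: RateSet, edges, dmus, potencies) -> int:
    mat = _modified_matrix(base, edges, [[d] for d in dmus])
    A, B, C, D, E, F = square_coefficient_arrays(mat, potencies)
    try:
        core = _shape_core(RationalResponse(A[0], B[0], C[0], D[0], E[0], F[0]))
        return core.n_inflections
    except DegenerateResponseError:
        return 0


def _nonmono_for(base: RateSet, edges, dmus, potencies) -> bool:
    """Nonmonotonicity from interior extrema (a quadratic root problem),
    which is numerically sturdier than the inflection count."""
    mat = _modified_matrix(base, edges, [[d] for d in dmus])
    A, B, C, D, E, F = square_coefficient_arrays(mat, potencies)
    try:
        core = _shape_core(RationalResponse(A[0], B[0], C[0], D[0], E[0], F[0]))
        return not core.monotonic
    except DegenerateResponseError:
        return False


def scan_single_edge(
    base: RateSet,
    edge: str,
    dmu_grid,
    potencies: Potencies | None = None,
    budget: float = DEFAULT_BUDGET,
    resolution: float = 1e-3,
) -> ScanResult:
    """Phenotype and sensitivity along a one-edge drive grid.

    Phenotype boundaries between adjacent grid points are refined by
    bisection to ``resolution`` kBT and reported in ``boundaries``.
    """
    dmu_grid = np.asarray(dmu_grid, dtype=float)
    DriveSpec(edges=(edge,), dmus=(float(np.abs(dmu_grid).max()),), budget=budget)
    rows = _scan_rows(base, (edge,), [dmu_grid], potencies)
    boundaries = []
    counts = rows["n_inflections"].to_numpy()
    for i in range(len(dmu_grid) - 1):
        if counts[i] != counts[i + 1]:
            lo, hi = dmu_grid[i], dmu_grid[i + 1]
            c_lo = counts[i]
            while hi - lo > resolution:
                mid = 0.5 * (lo + hi)
                if _count_for(base, (edge,), (mid,), potencies) == c_lo:
                    lo = mid
                else:
                    hi = mid
            boundaries.append(0.5 * (lo + hi))
    return ScanResult(
        rows=rows,
        boundaries=boundaries,
        params={
            "edge": edge,
            "base": base.to_dict(),
            "budget": budget,
            "resolution": resolution,
        },
    )


def scan_edge_pair(
    base: RateSet,
    pair,
    dmu1_grid,
    dmu2_grid=None,
    potencies: Potencies | None = None,
    budget: float = DEFAULT_BUDGET,
) -> ScanResult:
    """Full 2D phenotype/sensitivity table over a pair-drive grid.

    Rows are in row-major order (dmu1 outer, dmu2 inner); each carries the
    net cycle drive of the modified set and the rate-space distance D.
    """
    e1, e2 = pair
    dmu1_grid = np.asarray(dmu1_grid, dtype=float)
    dmu2_grid = dmu1_grid if dmu2_grid is None else np.asarray(dmu2_grid, dtype=float)
    DriveSpec(
        edges=(e1, e2),
        dmus=(float(np.abs(dmu1_grid).max()), float(np.abs(dmu2_grid).max())),
        budget=budget,
    )
    g1, g2 = np.meshgrid(dmu1_grid, dmu2_grid, indexing="ij")
    rows = _scan_rows(base, (e1, e2), [g1.ravel(), g2.ravel()], potencies)
    return ScanResult(
        rows=rows,
        params={
            "pair": list(pair),
            "base": base.to_dict(),
            "budget": budget,
            "grid_shape": [len(dmu1_grid), len(dmu2_grid)],
        },
    )


def min_drive_to_nonmonotonicity(
    base: RateSet,
    edges,
    resolution: float = 1e-3,
    budget: float = DEFAULT_BUDGET,
    grid_points: int = 81,
    potencies: Potencies | None = None,
) -> float:
    """Minimum |net drive| (kBT) at which the response becomes nonmonotonic.

    ``edges`` is one or two edge names.  The base set must be detailed
    balanced so the net drive is attributable to the modification.  Returns
    ``math.inf`` when no nonmonotonic response exists within the budget.

    Single edges use a grid scan plus bisection toward zero drive; pairs use
    a deterministic zooming grid over the 2D budget box, minimizing the net
    cycle affinity over the nonmonotonic region.
    """
    if isinstance(edges, str):
        edges = (edges,)
    edges = tuple(edges)
    if not is_detailed_balanced(base, tol=1e-6):
        raise ValueError(
            "base rate set must be detailed balanced; measured drive = "
            f"{cycle_drive(base):.3g} kBT"
        )
    grid = np.linspace(-budget, budget, grid_points)

    if len(edges) == 1:
        flags = np.array([_nonmono_for(base, edges, (d,), potencies) for d in grid])
        nonmono = np.where(flags)[0]
        if len(nonmono) == 0:
            return math.inf
        best = math.inf
        for side in (nonmono[grid[nonmono] >= 0], nonmono[grid[nonmono] < 0]):
            if len(side) == 0:
                continue
            # grid point of smallest |dmu| that is nonmonotonic on this side
            j = side[np.argmin(np.abs(grid[side]))]
            hi = grid[j]
            lo = 0.0 if not _nonmono_for(base, edges, (0.0,), potencies) else hi
            while abs(hi - lo) > resolution:
                mid = 0.5 * (lo + hi)
                if _nonmono_for(base, edges, (mid,), potencies):
                    hi = mid
                else:
                    lo = mid
            best = min(best, abs(hi))
        return best

    if len(edges) != 2:
        raise ValueError("edges must name one or two rates")
    s1, s2 = (CYCLE_ORIENTATION[e] for e in edges)
    base_drive = cycle_drive(base)

    def refine_box(lo1, hi1, lo2, hi2, n):
        d1 = np.linspace(lo1, hi1, n)
        d2 = np.linspace(lo2, hi2, n)
        g1, g2 = np.meshgrid(d1, d2, indexing="ij")
        mat = _modified_matrix(base, edges, [g1.ravel(), g2.ravel()])
        A, B, C, D, E, F = square_coefficient_arrays(mat, potencies)
        best_net, best_at = math.inf, None
        for i in range(len(mat)):
            try:
                core = _shape_core(RationalResponse(A[i], B[i], C[i], D[i], E[i], F[i]))
            except DegenerateResponseError:
                continue
            if not core.monotonic:
                net = abs(base_drive + s1 * g1.ravel()[i] + s2 * g2.ravel()[i])
                if net < best_net:
                    best_net, best_at = net, (g1.ravel()[i], g2.ravel()[i])
        return best_net, best_at, (d1[1] - d1[0], d2[1] - d2[0])

    n = max(grid_points, 21)
    lo1, hi1, lo2, hi2 = -budget, budget, -budget, budget
    best_overall = math.inf
    for _ in range(64):
        best_net, best_at, (h1, h2) = refine_box(lo1, hi1, lo2, hi2, n)
        if best_at is None:
            return best_overall  # inf on first pass; else keep best found
        best_overall = min(best_overall, best_net)
        if max(h1, h2) <= resolution or best_overall <= resolution:
            break
        c1, c2 = best_at
        w1, w2 = 2.0 * h1, 2.0 * h2
        lo1, hi1 = max(-budget, c1 - w1), min(budget, c1 + w1)
        lo2, hi2 = max(-budget, c2 - w2), min(budget, c2 + w2)
        n = 21
    return best_overall


def optimize_pair_slope(
    base: RateSet,
    pair,
    budget: float = DEFAULT_BUDGET,
    potencies: Potencies | None = None,
    coarse: int = 41,
    n_starts: int = 5,
) -> dict:
    """Maximize the raw log-axis slope over the closed pair-drive box.

    Deterministic: a coarse interior grid seeds Nelder-Mead refinements, and
    the four boundary slices (one drive pinned at +-budget) are maximized by
    bounded 1D search.  The slope surface often plateaus toward extreme
    drives, so when a boundary point matches the best interior value the
    boundary point is reported (the supremum is attained there).  The record
    carries the optimum location, slope, phenotype, net drive, distance D,
    the best slopes attainable along each single edge alone
    (``axis1_slope_max``/``axis2_slope_max``), and ``on_boundary``.
    """
    e1, e2 = pair

    def slope_at(d1, d2):
        mat1 = _modified_matrix(base, (e1, e2), [[d1], [d2]])
        a, b_, c, dd, e_, f = square_coefficient_arrays(mat1, potencies)
        try:
            core = _shape_core(RationalResponse(a[0], b_[0], c[0], dd[0], e_[0], f[0]))
            if len(core.inflection_slopes) == 0:
                return -math.inf
            return float(np.abs(core.inflection_slopes).max())
        except DegenerateResponseError:
            return -math.inf

    # interior: coarse grid + Nelder-Mead from the best cells
    grid = np.linspace(-budget, budget, coarse)
    g1, g2 = np.meshgrid(grid, grid, indexing="ij")
    mat = _modified_matrix(base, (e1, e2), [g1.ravel(), g2.ravel()])
    A, B, C, D, E, F = square_coefficient_arrays(mat, potencies)
    vals = np.empty(len(mat))
    for i in range(len(mat)):
        try:
            core = _shape_core(RationalResponse(A[i], B[i], C[i], D[i], E[i], F[i]))
            vals[i] = (
                float(np.abs(core.inflection_slopes).max())
                if len(core.inflection_slopes)
                else -math.inf
            )
        except DegenerateResponseError:
            vals[i] = -math.inf
    order = np.argsort(vals)[::-1][:n_starts]
    best_interior, best_at = -math.inf, (0.0, 0.0)
    for i in order:
        res = scipy.optimize.minimize(
            lambda d: -slope_at(d[0], d[1]),
            x0=[g1.ravel()[i], g2.ravel()[i]],
            method="Nelder-Mead",
            bounds=[(-budget, budget), (-budget, budget)],
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
        )
        if -res.fun > best_interior:
            best_interior, best_at = -res.fun, (float(res.x[0]), float(res.x[1]))

    # boundary slices: pin one coordinate at +-budget, 1D maximize the other
    def line_max(fun):
        t = np.linspace(-budget, budget, 161)
        v = np.array([fun(ti) for ti in t])
        j = int(np.argmax(v))
        lo = t[max(0, j - 1)]
        hi = t[min(len(t) - 1, j + 1)]
        res = scipy.optimize.minimize_scalar(
            lambda s: -fun(s), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        return max(v[j], -res.fun), (t[j] if v[j] >= -res.fun else float(res.x))

    best_boundary, boundary_at = -math.inf, None
    for pinned, which in ((budget, 0), (-budget, 0), (budget, 1), (-budget, 1)):
        if which == 0:
            v, s = line_max(lambda t: slope_at(pinned, t))
            at = (pinned, s)
        else:
            v, s = line_max(lambda t: slope_at(t, pinned))
            at = (s, pinned)
        if v > best_boundary:
            best_boundary, boundary_at = v, at

    if best_boundary >= best_interior * (1.0 - 1e-9):
        d1, d2 = boundary_at
        on_boundary = True
    else:
        d1, d2 = best_at
        on_boundary = max(abs(d1), abs(d2)) >= budget - 1e-4
    row = _scan_rows(base, (e1, e2), [[d1], [d2]], potencies).iloc[0].to_dict()
    row["on_boundary"] = bool(on_boundary)
    row["pair"] = (e1, e2)
    row["axis1_slope_max"] = line_max(lambda t: slope_at(t, 0.0))[0]
    row["axis2_slope_max"] = line_max(lambda t: slope_at(0.0, t))[0]
    return row


def plot_phase_map(result: ScanResult, path: str) -> None:
    """Export a 2D phenotype phase map (PNG) from a pair-scan result."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = result.rows
    n1, n2 = result.params["grid_shape"]
    z = rows["n_inflections"].to_numpy().reshape(n1, n2)
    d1 = rows["dmu1"].to_numpy().reshape(n1, n2)
    d2 = rows["dmu2"].to_numpy().reshape(n1, n2)
    fig, ax = plt.subplots(figsize=(5, 4))
    pc = ax.pcolormesh(d1, d2, z, cmap="viridis", vmin=0, vmax=3, shading="auto")
    fig.colorbar(pc, ax=ax, label="number of inflections")
    pair = result.params.get("pair", ["dmu1", "dmu2"])
    ax.set_xlabel(f"dmu on {pair[0]} (kBT)")
    ax.set_ylabel(f"dmu on {pair[1]} (kBT)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
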