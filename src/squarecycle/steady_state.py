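"""Stationary distributions via the Matrix Tree Theorem.

For a continuous-time Markov chain on a strongly connected graph, the
steady-state weight of a state equals the sum, over all spanning trees rooted
in that state, of the product of the tree's edge rates (the Matrix Tree /
Markov Chain Tree theorem).  Because each rooted spanning tree of the square
promoter cycle contains 0, 1 or 2 TF-binding edges, every steady-state
observable is a ratio of quadratic polynomials in the TF concentration x:

    <r>(x) = (A + B x + C x^2) / (D + E x + F x^2)

with D, E, F collecting tree weights by their power of x over all roots (the
nonequilibrium partition function) and A, B, C the same sums weighted by the
root state's potency.

Trees are enumerated by brute force over (N-1)-edge subsets -- exhaustive and
transparent for the small graphs (N <= ~10) this package targets.  An
independent linear-algebra route (null space of the rate matrix) is provided
as a cross-validation oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .graph_model import (
    EDGE_NAMES,
    SQUARE_STATES,
    ControlledGraph,
    Potencies,
    RateSet,
    build_square_graph,
)

__all__ = [
    "SpanningTree",
    "RationalResponse",
    "NotSquareEquivalentError",
    "enumerate_rooted_spanning_trees",
    "steady_state_probabilities",
    "stationary_nullspace_oracle",
    "response_coefficients",
    "square_response_coefficients",
    "square_coefficient_arrays",
]


class NotSquareEquivalentError(ValueError):
    """Raised when a graph's spanning trees exceed quadratic x-dependence.

    Such graphs fall outside the quadratic-ratio response family; evaluate
    their observables pointwise with :func:`steady_state_probabilities`
    instead.
    """


@dataclass(frozen=True)
class SpanningTree:
    """A directed spanning tree rooted in ``root``.

    Every non-root state has exactly one outgoing edge and the root has none;
    following outgoing edges from any state leads to the root.
    """

    root: str
    edges: tuple  # tuple of (source, target) pairs
    weight_base: float  # product of base rates over the tree's edges
    x_degree: int  # number of TF-dependent edges in the tree

    def weight_at(self, x: float) -> float:
        return self.weight_base * x**self.x_degree


@dataclass(frozen=True)
class RationalResponse:
    """Coefficients of the quadratic-ratio response in x.

    For positive rates on the square cycle, D and F are strictly positive
    (trees with zero and with two TF-binding edges exist for every root).
    Square-equivalent graphs with fewer TF-dependent tree classes may leave
    D, C/F, or other coefficients exactly zero; the limits below handle
    those reduced degrees.
    """

    A: float
    B: float
    C: float
    D: float
    E: float
    F: float

    def __post_init__(self) -> None:
        den = (self.D, self.E, self.F)
        if any(c < 0 for c in den) or not sum(den) > 0:
            raise ValueError(
                "denominator coefficients must be nonnegative with a positive sum"
            )

    @property
    def r0(self) -> float:
        """Leakiness: the limit of the response as x -> 0+."""
        num = (self.A, self.B, self.C)
        den = (self.D, self.E, self.F)
        i = next(k for k in range(3) if den[k] > 0)
        return num[i] / den[i]

    @property
    def r_inf(self) -> float:
        """Saturation: the response in the limit x -> infinity."""
        num = (self.A, self.B, self.C)
        den = (self.D, self.E, self.F)
        i = next(k for k in (2, 1, 0) if den[k] > 0)
        return num[i] / den[i]

    def as_tuple(self) -> tuple:
        return (self.A, self.B, self.C, self.D, self.E, self.F)

    def evaluate(self, x):
        """Evaluate the response; accepts scalars or arrays, x = 0 and inf."""
        x = np.asarray(x, dtype=float)
        isinf = np.isinf(x)
        iszero = x == 0.0
        xf = np.where(isinf, 1.0, x)
        num = self.A + xf * (self.B + xf * self.C)
        den = self.D + xf * (self.E + xf * self.F)
        out = np.where(
            isinf, self.r_inf,
            np.where(iszero, self.r0, num / np.where(den == 0.0, 1.0, den)),
        )
        return float(out) if out.ndim == 0 else out

    __call__ = evaluate


def enumerate_rooted_spanning_trees(graph: ControlledGraph, root: str) -> list:
    """All spanning trees of ``graph`` rooted in ``root``, by exhaustive search.

    Every (N-1)-subset of the directed edges is tested for the rooted-tree
    property.  The result is ordered lexicographically by edge list, so the
    enumeration is deterministic.
    """
    graph.state_index(root)  # validates the root label
    n = len(graph.states)
    trees = []
    candidates = [e for e in graph.edges if e.source != root]
    for subset in itertools.combinations(candidates, n - 1):
        sources = [e.source for e in subset]
        if len(set(sources)) != n - 1:
            continue  # some non-root state has 0 or 2 outgoing edges
        out_edge = {e.source: e.target for e in subset}
        # unique out-edges: following them must reach the root from everywhere
        ok = True
        for s in out_edge:
            seen = set()
            cur = s
            while cur != root:
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
                cur = out_edge[cur]
            if not ok:
                break
        if not ok:
            continue
        edge_pairs = tuple(sorted((e.source, e.target) for e in subset))
        weight = 1.0
        for e in subset:
            weight *= e.base_rate
        xdeg = sum(e.x_exponent for e in subset)
        trees.append(SpanningTree(root=root, edges=edge_pairs, weight_base=weight, x_degree=xdeg))
    trees.sort(key=lambda t: t.edges)
    return trees


def steady_state_probabilities(graph: ControlledGraph, x: float) -> np.ndarray:
    """Stationary probabilities at TF concentration ``x`` via tree weights.

    ``p_i`` is proportional to the sum of ``weight_base * x**x_degree`` over
    spanning trees rooted in state i.  Valid for any strongly connected graph,
    regardless of the x-dependence pattern.
    """
    if not x > 0:
        raise ValueError(f"x must be positive, got {x!r}")
    rho = np.array(
        [
            sum(t.weight_at(x) for t in enumerate_rooted_spanning_trees(graph, s))
            for s in graph.states
        ]
    )
    return rho / rho.sum()


def stationary_nullspace_oracle(graph: ControlledGraph, x: float) -> np.ndarray:
    """Stationary probabilities from the null space of the rate matrix.

    Builds the column-sum-zero transition matrix L (off-diagonal ``L[j, i]``
    holds the i -> j rate; diagonal entries are minus the column sums) and
    solves ``L p = 0`` with ``sum(p) = 1``.  Used as an independent check on
    the tree-based route.
    """
    if not x > 0:
        raise ValueError(f"x must be positive, got {x!r}")
    n = len(graph.states)
    idx = {s: i for i, s in enumerate(graph.states)}
    L = np.zeros((n, n))
    for e in graph.edges:
        L[idx[e.target], idx[e.source]] += e.rate_at(x)
    L -= np.diag(L.sum(axis=0))
    ns = scipy.linalg.null_space(L, rcond=1e-12)
    if ns.shape[1] != 1:
        raise np.linalg.LinAlgError(
            f"rate matrix null space has dimension {ns.shape[1]}, expected 1 "
            "(is the graph strongly connected?)"
        )
    p = ns[:, 0]
    p = p / p.sum()
    if np.any(p <= 0):
        raise np.linalg.LinAlgError("null-space vector is not single-signed")
    return p


def response_coefficients(graph: ControlledGraph) -> RationalResponse:
    """Collect the quadratic-ratio coefficients from rooted spanning trees.

    Requires every spanning tree to carry at most two TF-dependent edges
    ("square-equivalent" graphs); otherwise a
    :class:`NotSquareEquivalentError` is raised.
    """
    pot = graph.potency_vector()
    num = [0.0, 0.0, 0.0]
    den = [0.0, 0.0, 0.0]
    for s, r in zip(graph.states, pot):
        for t in enumerate_rooted_spanning_trees(graph, s):
            if t.x_degree > 2:
                raise NotSquareEquivalentError(
                    f"a spanning tree rooted in {s!r} carries x-degree "
                    f"{t.x_degree} > 2; the response is not a quadratic ratio. "
                    "Evaluate pointwise with steady_state_probabilities instead."
                )
            den[t.x_degree] += t.weight_base
            num[t.x_degree] += r * t.weight_base
    return RationalResponse(A=num[0], B=num[1], C=num[2], D=den[0], E=den[1], F=den[2])


# ---------------------------------------------------------------------------
# Fast batch path for the square cycle
# ---------------------------------------------------------------------------

_SQUARE_TREE_TABLE = None


def _square_tree_table():
    """(root_potency_index, edge_index_triple, x_degree) for all 16 trees.

    Computed once from the brute-force enumeration on the unit-rate square
    graph; edge indices refer to the canonical EDGE_NAMES ordering.
    """
    global _SQUARE_TREE_TABLE
    if _SQUARE_TREE_TABLE is None:
        unit = RateSet(*([1.0] * 8))
        g = build_square_graph(unit)
        pair_to_idx = {
            (e.source, e.target): i
            for i, e in enumerate(g.edges)
        }
        roots, eidx, xdeg = [], [], []
        for si, s in enumerate(SQUARE_STATES):
            for t in enumerate_rooted_spanning_trees(g, s):
                roots.append(si)
                eidx.append([pair_to_idx[p] for p in t.edges])
                xdeg.append(t.x_degree)
        _SQUARE_TREE_TABLE = (
            np.array(roots),
            np.array(eidx),
            np.array(xdeg),
        )
    return _SQUARE_TREE_TABLE


def square_coefficient_arrays(rates: np.ndarray, potencies: Potencies | None = None):
    """Vectorized response coefficients for a batch of square-cycle rate sets.

    Parameters
    ----------
    rates
        Array of shape ``(n, 8)`` with columns in the canonical
        :data:`~squarecycle.graph_model.EDGE_NAMES` order.
    potencies
        Shared observable weights (default: transcriptional).

    Returns
    -------
    Six arrays ``(A, B, C, D, E, F)`` of shape ``(n,)``.
    """
    potencies = potencies if potencies is not None else Potencies()
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    if rates.shape[1] != len(EDGE_NAMES):
        raise ValueError(f"rates must have {len(EDGE_NAMES)} columns")
    roots, eidx, xdeg = _square_tree_table()
    pot = np.asarray(potencies.as_tuple())
    w = rates[:, eidx].prod(axis=2)  # (n, 16) tree weights
    coeffs = []
    for weighted in (pot[roots] * w, w):
        for d in (0, 1, 2):
            coeffs.append((weighted * (xdeg == d)).sum(axis=1))
    A, B, C, D, E, F = coeffs
    return A, B, C, D, E, F


def square_response_coefficients(
    rates: RateSet, potencies: Potencies | None = None
) -> RationalResponse:
    """Response coefficients of a single square-cycle rate set (fast path)."""
    A, B, C, D, E, F = square_coefficient_arrays(
        np.array(rates.as_tuple())[None, :], potencies
    )
    return RationalResponse(
        A=float(A[0]), B=float(B[0]), C=float(C[0]),
        D=float(D[0]), E=float(E[0]), F=float(F[0]),
    )
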