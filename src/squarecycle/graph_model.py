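"""Four-state promoter cycle and generic controlled graphs.

A promoter that can bind one transcription factor (TF) molecule and one RNA
polymerase molecule occupies four states -- empty (``S``), TF-bound (``X``),
polymerase-bound (``P``), and doubly bound (``XP``) -- connected in a square
cycle by eight binding/unbinding transitions.  Two of those transitions are
TF-binding steps whose propensity is proportional to the TF concentration
``x``; the other six are concentration-independent.

This module holds the rate-constant container for that motif, a generic
small-graph representation for square-equivalent variants, the cycle affinity
(thermodynamic drive, in units of kBT) and the detailed-balance test.

Conventions
-----------
* ``x`` is dimensionless: the TF concentration measured in units of a
  reference scale (1 nM).  All rate constants then carry units of 1/time.
* Polymerase concentration is held fixed and folded into the polymerase
  binding rates ``k_sp`` and ``k_x_xp``.
* Edge names are ``k_{from,to}`` in lower case, e.g. ``k_xp_p`` for the
  XP -> P transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import networkx as nx

__all__ = [
    "EDGE_NAMES",
    "EDGE_ENDPOINTS",
    "X_DEPENDENT_EDGES",
    "CYCLE_ORIENTATION",
    "CRITERION_RATES",
    "SQUARE_STATES",
    "RateSet",
    "Potencies",
    "Edge",
    "ControlledGraph",
    "build_square_graph",
    "cycle_drive",
    "is_detailed_balanced",
]

#: Canonical ordering of the eight square-cycle rate constants.
EDGE_NAMES = (
    "k_sx", "k_xs", "k_sp", "k_ps",
    "k_x_xp", "k_xp_x", "k_p_xp", "k_xp_p",
)

#: Directed endpoints of each named edge.
EDGE_ENDPOINTS = {
    "k_sx": ("S", "X"),
    "k_xs": ("X", "S"),
    "k_sp": ("S", "P"),
    "k_ps": ("P", "S"),
    "k_x_xp": ("X", "XP"),
    "k_xp_x": ("XP", "X"),
    "k_p_xp": ("P", "XP"),
    "k_xp_p": ("XP", "P"),
}

#: The TF-binding edges; their rates are multiplied by the concentration x.
X_DEPENDENT_EDGES = ("k_sx", "k_p_xp")

#: Sign of each edge in the directed cycle S -> X -> XP -> P -> S.  The cycle
#: affinity is the signed sum of log rates with these orientations.
CYCLE_ORIENTATION = {
    "k_sx": +1, "k_x_xp": +1, "k_xp_p": +1, "k_ps": +1,
    "k_xs": -1, "k_xp_x": -1, "k_p_xp": -1, "k_sp": -1,
}

#: The four rates entering the kinetic monotonicity criterion (the polymerase
#: binding/unbinding rates with and without the TF present).
CRITERION_RATES = ("k_x_xp", "k_sp", "k_xp_x", "k_ps")

SQUARE_STATES = ("S", "X", "P", "XP")


@dataclass(frozen=True)
class RateSet:
    """The eight rate constants of the square cycle (units 1/time).

    ``k_sx`` and ``k_p_xp`` are per unit dimensionless TF concentration; the
    polymerase concentration is folded into ``k_sp`` and ``k_x_xp``.
    """

    k_sx: float
    k_xs: float
    k_sp: float
    k_ps: float
    k_x_xp: float
    k_xp_x: float
    k_p_xp: float
    k_xp_p: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(
                    f"rate {f.name!r} must be strictly positive and finite, got {v!r}"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "RateSet":
        missing = [k for k in EDGE_NAMES if k not in d]
        if missing:
            raise ValueError(f"missing rate(s): {missing}")
        return cls(**{k: float(d[k]) for k in EDGE_NAMES})

    @classmethod
    def from_energies(
        cls,
        e_s: float,
        e_x: float,
        e_p: float,
        e_xp: float,
        k_sx: float = 1.0,
        k_sp: float = 1.0,
        k_x_xp: float = 1.0,
        k_p_xp: float = 1.0,
    ) -> "RateSet":
        """Detailed-balanced rate set from state free energies (kBT).

        Each reverse rate is fixed by the forward rate and the energy drop,
        ``k_ji = k_ij * exp(E_j - E_i)``, so every cycle affinity vanishes by
        construction.
        """
        return cls(
            k_sx=k_sx,
            k_xs=k_sx * math.exp(e_x - e_s),
            k_sp=k_sp,
            k_ps=k_sp * math.exp(e_p - e_s),
            k_x_xp=k_x_xp,
            k_xp_x=k_x_xp * math.exp(e_xp - e_x),
            k_p_xp=k_p_xp,
            k_xp_p=k_p_xp * math.exp(e_xp - e_p),
        )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in EDGE_NAMES}

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, k) for k in EDGE_NAMES)

    def scaled(self, edge: str, factor: float) -> "RateSet":
        """Return a copy with one named rate multiplied by ``factor``."""
        if edge not in EDGE_NAMES:
            raise ValueError(f"unknown edge {edge!r}; expected one of {EDGE_NAMES}")
        return replace(self, **{edge: getattr(self, edge) * factor})


@dataclass(frozen=True)
class Potencies:
    """Observable weight of each state: ``<r> = sum_i r_i p_i``.

    Defaults are the transcriptional choice -- polymerase-bound states
    produce, others do not.
    """

    r_s: float = 0.0
    r_x: float = 0.0
    r_p: float = 1.0
    r_xp: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"potency {f.name!r} must be finite and >= 0, got {v!r}")

    @property
    def degenerate(self) -> bool:
        """True when all states have equal potency (constant observable)."""
        vals = self.as_tuple()
        return max(vals) == min(vals)

    def as_tuple(self) -> tuple:
        """Potencies ordered as the square states (S, X, P, XP)."""
        return (self.r_s, self.r_x, self.r_p, self.r_xp)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_state_dict(self) -> dict:
        return dict(zip(SQUARE_STATES, self.as_tuple()))


@dataclass(frozen=True)
class Edge:
    """A directed transition with rate ``base_rate * x**x_exponent``."""

    source: str
    target: str
    base_rate: float
    x_exponent: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.base_rate) and self.base_rate > 0):
            raise ValueError(
                f"edge {self.source}->{self.target}: base_rate must be positive "
                f"and finite, got {self.base_rate!r}"
            )
        if self.x_exponent not in (0, 1):
            raise ValueError(
                f"edge {self.source}->{self.target}: x_exponent must be 0 or 1"
            )

    def rate_at(self, x: float) -> float:
        return self.base_rate * (x if self.x_exponent else 1.0)


@dataclass(frozen=True)
class ControlledGraph:
    """A strongly connected directed graph with concentration-annotated rates.

    ``potencies`` maps each state label to its observable weight.
    """

    states: tuple
    edges: tuple
    potencies: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "edges", tuple(self.edges))
        state_set = set(self.states)
        if len(state_set) != len(self.states):
            raise ValueError("duplicate state labels")
        seen = set()
        for e in self.edges:
            if e.source not in state_set or e.target not in state_set:
                raise ValueError(f"edge {e.source}->{e.target} references unknown state")
            if e.source == e.target:
                raise ValueError(f"self-loop on state {e.source!r}")
            if (e.source, e.target) in seen:
                raise ValueError(f"duplicate edge {e.source}->{e.target}")
            seen.add((e.source, e.target))
        if self.potencies:
            extra = set(self.potencies) - state_set
            if extra:
                raise ValueError(f"potencies reference unknown states: {sorted(extra)}")
        if not nx.is_strongly_connected(self.to_networkx()):
            raise ValueError("graph must be strongly connected for a unique steady state")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.states)
        for e in self.edges:
            g.add_edge(e.source, e.target, base_rate=e.base_rate, x_exponent=e.x_exponent)
        return g

    def potency_vector(self) -> tuple:
        return tuple(float(self.potencies.get(s, 0.0)) for s in self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ValueError(f"unknown state {state!r}; graph states are {self.states}") from None


def build_square_graph(rates: RateSet, potencies: Potencies | None = None) -> ControlledGraph:
    """Assemble the four-state square cycle as a :class:`ControlledGraph`.

    The TF-binding edges S -> X and P -> XP carry ``x_exponent = 1``; the six
    remaining edges are concentration independent.
    """
    potencies = potencies if potencies is not None else Potencies()
    edges = tuple(
        Edge(
            source=EDGE_ENDPOINTS[name][0],
            target=EDGE_ENDPOINTS[name][1],
            base_rate=getattr(rates, name),
            x_exponent=1 if name in X_DEPENDENT_EDGES else 0,
        )
        for name in EDGE_NAMES
    )
    return ControlledGraph(
        states=SQUARE_STATES, edges=edges, potencies=potencies.as_state_dict()
    )


def cycle_drive(rates: RateSet) -> float:
    """Cycle affinity of the square cycle, in units of kBT.

    ``ln[(k_sx * k_x_xp * k_xp_p * k_ps) / (k_sp * k_p_xp * k_xp_x * k_xs)]``,
    the free energy dissipated per completed cycle at steady state.  The TF
    concentration does not enter: each cycle direction contains exactly one
    TF-binding edge, so the factors of x cancel.
    """
    return sum(s * math.log(getattr(rates, name)) for name, s in CYCLE_ORIENTATION.items())


def is_detailed_balanced(rates: RateSet, tol: float = 1e-9) -> bool:
    """True when the cycle affinity vanishes to within ``tol`` (kBT)."""
    if not tol > 0:
        raise ValueError("tol must be positive")
    return abs(cycle_drive(rates)) <= tol
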