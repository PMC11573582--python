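"""Shape analysis of quadratic-ratio induction curves.

The steady-state observable of the square promoter cycle is a ratio of
quadratic polynomials in the TF concentration x.  Subtracting the leakiness
and rescaling x by the characteristic concentration ``sqrt(D/F)`` collapses
the six coefficients to two emergent shape parameters (a, b):

    (<r> - <r>_0) / (<r>_inf - <r>_0) = (a*y + y^2) / (1 + b*y + y^2),
    y = x / sqrt(D/F).

All shape questions are posed on the logarithmic concentration axis
u = ln y.  Inflection points are the odd-multiplicity positive roots of a
quartic obtained by clearing denominators from d^2<r>/du^2; interior extrema
come from the quadratic numerator of d<r>/du.  Roots are found via companion
matrices (no derivative-free searching) and sign changes are confirmed by
direct evaluation between roots, so tangencies (even multiplicity) never
count as concavity changes.

Every response of this family falls into one of three shape phenotypes:
monotonic with a single inflection (the equilibrium-like curve), nonmonotonic
with two inflections, or monotonic with three inflections.  The latter two
require broken detailed balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph_model import Potencies, RateSet, cycle_drive, is_detailed_balanced
from .steady_state import RationalResponse

__all__ = [
    "DegenerateResponseError",
    "NotDetailedBalancedError",
    "ShapeParams",
    "EquilibriumLinearForm",
    "PhenotypeReport",
    "evaluate_response",
    "leakiness",
    "saturation",
    "collapse_shape",
    "equilibrium_linear_form",
    "count_inflections",
    "classify_phenotype",
    "monotonicity_criterion",
]

# relative tolerance for clustering nearly coincident polynomial roots
_ROOT_CLUSTER_RTOL = 1e-8
# |imag|/(1+|z|) below this counts as a real root
_IMAG_RTOL = 1e-7

_EPS = float(np.finfo(float).eps)


def _fmul(u, fu, v, fv):
    """Product with propagated rounding floor."""
    return u * v, abs(u) * fv + fu * abs(v) + _EPS * abs(u * v)


def _fsub(u, fu, v, fv):
    """Difference with propagated rounding floor (tracks cancellation)."""
    return u - v, fu + fv + _EPS * (abs(u) + abs(v))


class DegenerateResponseError(ValueError):
    """The response is constant in x; shape analysis is undefined."""


class NotDetailedBalancedError(ValueError):
    """Raised when an equilibrium-only reduction is requested off equilibrium."""

    def __init__(self, drive: float):
        self.drive = drive
        super().__init__(
            f"rate set is not detailed balanced: cycle drive = {drive:.6g} kBT"
        )


# ---------------------------------------------------------------------------
# internal shape core
# ---------------------------------------------------------------------------


@dataclass
class _ShapeCore:
    """Everything shape-related for one response, in rescaled y coordinates."""

    x_scale: float           # y = x / x_scale
    r0: float
    r_inf: float
    cshift: float            # value shift applied to the numerator
    ncoef: np.ndarray        # shifted numerator coefficients in y (len 3)
    dcoef: np.ndarray        # denominator coefficients in y: (1, b, 1)
    mcoef: np.ndarray        # slope numerator (quadratic in y)
    qcoef: np.ndarray        # curvature numerator (quartic in y)
    mfloor: np.ndarray       # rounding floors of mcoef
    qfloor: np.ndarray       # rounding floors of qcoef
    inflection_y: np.ndarray
    inflection_slopes: np.ndarray  # d<r>/du at each inflection
    extrema_y: np.ndarray
    extrema_values: np.ndarray
    monotonic: bool
    boundary_case: bool

    @property
    def n_inflections(self) -> int:
        return len(self.inflection_y)

    def value_at_y(self, y):
        y = np.asarray(y, dtype=float)
        n = self.ncoef
        d = self.dcoef
        return self.cshift + (n[0] + y * (n[1] + y * n[2])) / (
            d[0] + y * (d[1] + y * d[2])
        )

    def slope_at_y(self, y):
        """d<r>/du at y (u = ln y); shift-invariant, original response units."""
        y = np.asarray(y, dtype=float)
        m = self.mcoef
        d = self.dcoef
        den = d[0] + y * (d[1] + y * d[2])
        return y * (m[0] + y * (m[1] + y * m[2])) / den**2

    def curvature_sign_at_y(self, y):
        """Quantity with the sign of d^2<r>/du^2 at y > 0."""
        y = np.asarray(y, dtype=float)
        q = self.qcoef
        return q[0] + y * (q[1] + y * (q[2] + y * (q[3] + y * q[4])))

    def extrema_and_limits(self):
        """(values, x positions) of r over {0, interior extrema, infinity}."""
        vals = [self.r0, *self.extrema_values.tolist(), self.r_inf]
        xs = [0.0, *(self.x_scale * self.extrema_y).tolist(), math.inf]
        return np.array(vals), np.array(xs)

    @property
    def r_range(self) -> float:
        vals, _ = self.extrema_and_limits()
        return float(vals.max() - vals.min())


def _polish_roots(coef_ascending: np.ndarray, roots: np.ndarray) -> np.ndarray:
    """Newton-refine real roots; keep a step only while it improves |p|."""
    pv = np.polynomial.polynomial
    dcoef = pv.polyder(coef_ascending)
    out = roots.astype(float).copy()
    for _ in range(8):
        f = pv.polyval(out, coef_ascending)
        fp = pv.polyval(out, dcoef)
        step = np.where(fp != 0.0, f / np.where(fp == 0.0, 1.0, fp), 0.0)
        cand = out - step
        better = (np.abs(pv.polyval(cand, coef_ascending)) <= np.abs(f)) & (cand > 0)
        out = np.where(better, cand, out)
    return np.sort(out)


def _positive_real_roots(coef_ascending: np.ndarray, floor: np.ndarray) -> np.ndarray:
    """Distinct positive real roots of a polynomial, ascending.

    ``floor`` is a per-coefficient rounding floor: leading coefficients that
    are indistinguishable from zero at their own floor are dropped (they only
    encode cancellation noise), while small-but-genuine leading coefficients
    are kept -- their far-out roots are real features of the curve.  Nearly
    coincident roots are merged, so a double root that the companion matrix
    splits into a close pair is reported once.
    """
    c = np.asarray(coef_ascending, dtype=float)
    fl = np.asarray(floor, dtype=float)
    deg = len(c) - 1
    while deg >= 0 and abs(c[deg]) <= 16.0 * fl[deg]:
        deg -= 1
    if deg < 1:
        return np.array([])
    desc = c[deg::-1]
    roots = np.roots(desc / np.abs(desc).max())
    real = roots[np.abs(roots.imag) <= _IMAG_RTOL * (1.0 + np.abs(roots))].real
    real = np.sort(real[real > 0.0])
    if len(real) == 0:
        return real
    # companion eigenvalues of polynomials whose roots span many decades can
    # be off by factors of 2; a few Newton steps restore full accuracy
    real = _polish_roots(c[: deg + 1], real)
    merged = [real[0]]
    for r in real[1:]:
        if r - merged[-1] <= _ROOT_CLUSTER_RTOL * max(abs(r), 1e-300):
            merged[-1] = 0.5 * (merged[-1] + r)
        else:
            merged.append(r)
    return np.array(merged)


def _sign_change_roots(
    coef_ascending: np.ndarray, floor: np.ndarray, candidates: np.ndarray
) -> np.ndarray:
    """Subset of candidate roots across which the polynomial changes sign.

    Sign probes between roots are compared against the evaluated rounding
    floor, so a probe value lost in noise never manufactures a sign change.
    """
    if len(candidates) == 0:
        return candidates
    c = np.asarray(coef_ascending, dtype=float)
    probes = [candidates[0] / 2.0]
    probes += list(np.sqrt(candidates[:-1] * candidates[1:]))
    probes += [candidates[-1] * 2.0]
    probes = np.array(probes)
    vals = np.polynomial.polynomial.polyval(probes, c)
    noise = np.polynomial.polynomial.polyval(probes, np.asarray(floor, dtype=float))
    signs = np.sign(vals)
    signs[np.abs(vals) <= 16.0 * noise] = 0.0
    keep = signs[:-1] * signs[1:] < 0
    return candidates[keep]


def _shape_core(coeffs: RationalResponse) -> _ShapeCore:
    A, B, C, D, E, F = coeffs.as_tuple()
    # Reduced degrees (possible for square-equivalent graphs that are not the
    # square cycle itself): strip a common factor of x, then re-embed a
    # linear fraction as a quadratic ratio by multiplying numerator and
    # denominator by (1 + x/xc).  The factor's root is negative, so it adds
    # no positive roots to the slope or curvature numerators.
    if D == 0.0:
        A, B, C = B, C, 0.0
        D, E, F = E, F, 0.0
    if F == 0.0 or D == 0.0:
        if D == 0.0 or E == 0.0:
            raise DegenerateResponseError("response is constant in x")
        if C != 0.0:
            raise ValueError("unbounded response: C > 0 with F = 0")
        xc = D / E
        A, B, C = A, B + A / xc, B / xc
        D, E, F = D, E + D / xc, E / xc
    x0 = math.sqrt(D / F)
    # rescale x = x0*y and divide numerator and denominator by D: the
    # denominator becomes (1, b, 1), the numerator (r0, n1, r_inf).
    b = E / math.sqrt(D * F)
    r0 = A / D
    r_inf = C / F
    n = np.array([r0, B * x0 / D, r_inf])
    d = np.array([1.0, b, 1.0])

    # subtract a constant (exact shape invariance) to kill cancellation when
    # the response rides on a large offset; pick the endpoint that leaves the
    # larger residual.
    shifted0 = n - r0 * d
    shifted_inf = n - r_inf * d
    if np.abs(shifted0).max() >= np.abs(shifted_inf).max():
        cshift, nn = r0, shifted0
    else:
        cshift, nn = r_inf, shifted_inf
    ref = max(np.abs(n).max(), abs(r0), abs(r_inf), 1e-300)
    if np.abs(nn).max() <= 1e-12 * ref:
        raise DegenerateResponseError(
            "response is constant in x (numerator proportional to denominator)"
        )

    # slope numerator M (d<r>/du = y*M/den^2) and curvature numerator q
    # (d^2<r>/du^2 = y*q/den^3); closed forms for quadratic/quadratic ratios.
    # Rounding floors are propagated through every product and difference so
    # cancellation noise can be told apart from genuinely small coefficients.
    fn = _EPS * (np.abs(n) + abs(cshift) * np.abs(d))  # floor of nn
    fd = _EPS * np.abs(d)

    def mk(i, j, scale):
        u, fu = _fmul(nn[i], fn[i], d[j], fd[j])
        v, fv = _fmul(nn[j], fn[j], d[i], fd[i])
        w, fw = _fsub(u, fu, v, fv)
        return scale * w, scale * fw

    m = np.empty(3)
    fm = np.empty(3)
    (m[0], fm[0]) = mk(1, 0, 1.0)
    (m[1], fm[1]) = mk(2, 0, 2.0)
    (m[2], fm[2]) = mk(2, 1, 1.0)

    def qk(terms):
        tot, ftot = 0.0, 0.0
        for scale, (u, fu), (v, fv) in terms:
            w, fw = _fmul(u, fu, v, fv)
            tot, ftot = tot + scale * w, ftot + abs(scale) * fw + _EPS * abs(scale * w)
        return tot, ftot

    mf = [(m[i], fm[i]) for i in range(3)]
    df = [(d[i], fd[i]) for i in range(3)]
    q = np.empty(5)
    fq = np.empty(5)
    (q[0], fq[0]) = qk([(1.0, mf[0], df[0])])
    (q[1], fq[1]) = qk([(2.0, mf[1], df[0]), (-1.0, mf[0], df[1])])
    (q[2], fq[2]) = qk([(3.0, mf[2], df[0]), (-3.0, mf[0], df[2])])
    (q[3], fq[3]) = qk([(1.0, mf[2], df[1]), (-2.0, mf[1], df[2])])
    (q[4], fq[4]) = qk([(-1.0, mf[2], df[2])])

    infl = _sign_change_roots(q, fq, _positive_real_roots(q, fq))
    extr = _sign_change_roots(m, fm, _positive_real_roots(m, fm))

    core = _ShapeCore(
        x_scale=x0,
        r0=r0,
        r_inf=r_inf,
        cshift=cshift,
        ncoef=nn,
        dcoef=d,
        mcoef=m,
        qcoef=q,
        mfloor=fm,
        qfloor=fq,
        inflection_y=infl,
        inflection_slopes=np.array([]),
        extrema_y=extr,
        extrema_values=np.array([]),
        monotonic=len(extr) == 0,
        boundary_case=False,
    )

    # a saturating rational curve has slope -> 0 at both ends, forcing the
    # parity relation (#inflections + #extrema) odd; a violation means the
    # root finder straddled a phase boundary -- settle it on a dense grid.
    if (len(infl) + len(extr)) % 2 == 0 or len(infl) == 0:
        core.boundary_case = True
        _dense_recount(core)

    core.inflection_slopes = np.asarray(core.slope_at_y(core.inflection_y), dtype=float)
    core.extrema_values = np.asarray(core.value_at_y(core.extrema_y), dtype=float)
    core.monotonic = len(core.extrema_y) == 0
    return core


def _dense_recount(core: _ShapeCore, n_grid: int = 40001) -> None:
    """Settle inflection/extremum counts by sign evaluation on a log grid.

    Values are compared against the evaluated per-point rounding floor, so
    noise-dominated stretches of the polynomial contribute no sign changes.
    """
    anchors = [core.inflection_y, core.extrema_y, np.array([1.0])]
    # adjacent-coefficient ratios bracket the decades where roots can live
    for coef, floor in ((core.qcoef, core.qfloor), (core.mcoef, core.mfloor)):
        keep = np.abs(coef) > 16.0 * floor
        c = np.abs(coef[keep])
        if len(c) > 1:
            anchors.append(c[:-1] / c[1:])
    anchors = np.concatenate(anchors)
    anchors = anchors[(anchors > 0) & np.isfinite(anchors)]
    lo = min(1e-10, anchors.min() / 1e3)
    hi = max(1e10, anchors.max() * 1e3)
    y = np.exp(np.linspace(math.log(lo), math.log(hi), n_grid))

    def grid_roots(coef, floor):
        vals = np.polynomial.polynomial.polyval(y, coef)
        noise = np.polynomial.polynomial.polyval(y, floor)
        s = np.sign(vals)
        s[np.abs(vals) <= 16.0 * noise] = 0.0
        idx = np.where(s != 0)[0]
        nz = s[idx]
        flips = np.where(nz[:-1] * nz[1:] < 0)[0]
        return np.sqrt(y[idx[flips]] * y[idx[flips + 1]])

    core.inflection_y = grid_roots(core.qcoef, core.qfloor)
    core.extrema_y = grid_roots(core.mcoef, core.mfloor)


# ---------------------------------------------------------------------------
# public types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShapeParams:
    """Two-parameter collapsed representation of a response curve.

    The normalized curve ``(a*y + y^2)/(1 + b*y + y^2)`` with
    ``y = x/x_scale`` runs from 0 (at x = 0) to 1 (as x -> infinity) and
    carries all shape information.  Detailed-balanced responses satisfy
    ``b = a + 1/a`` exactly, collapsing further to a Hill-type curve.
    """

    a: float
    b: float
    x_scale: float
    r0: float
    r_inf: float
    degenerate: bool = False

    def normalized_curve(self, y):
        if self.degenerate:
            raise DegenerateResponseError("no shape parameters: r0 == r_inf")
        y = np.asarray(y, dtype=float)
        return (self.a * y + y**2) / (1.0 + self.b * y + y**2)


@dataclass(frozen=True)
class EquilibriumLinearForm:
    """Linear-fraction response ``(A' + B' x)/(C' + D' x)`` at detailed balance."""

    A_p: float
    B_p: float
    C_p: float
    D_p: float

    def evaluate(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(
            np.isinf(x),
            self.B_p / self.D_p,
            (self.A_p + self.B_p * x) / (self.C_p + self.D_p * x),
        )
        return float(out) if out.ndim == 0 else out

    __call__ = evaluate


@dataclass(frozen=True)
class PhenotypeReport:
    """Classification of one response curve on the log-concentration axis.

    Positions are in log units ``u = ln(x/x_scale)``; slopes are d<r>/du in
    the observable's own units.  ``r_star`` is the plateau value at the
    middle (slope-minimal) inflection of a three-inflection curve.
    ``boundary_case`` flags curves within root-finding tolerance of a phase
    boundary (e.g. an inflection coinciding with an extremum).
    """

    n_inflections: int
    inflection_positions: tuple
    inflection_slopes: tuple
    monotonic: bool
    r0: float
    r_inf: float
    r_min: float
    r_max: float
    argmin_x: float
    argmax_x: float
    r_star: float | None
    x_scale: float
    boundary_case: bool = False

    def to_dict(self) -> dict:
        d = {
            "n_inflections": self.n_inflections,
            "monotonic": self.monotonic,
            "r0": self.r0,
            "r_inf": self.r_inf,
            "r_min": self.r_min,
            "r_max": self.r_max,
            "argmin_x": self.argmin_x,
            "argmax_x": self.argmax_x,
            "r_star": self.r_star,
            "x_scale": self.x_scale,
            "boundary_case": self.boundary_case,
            "inflection_positions": list(self.inflection_positions),
            "inflection_slopes": list(self.inflection_slopes),
        }
        return d

    def to_csv_row(self) -> dict:
        row = {"n_inflections": self.n_inflections}
        for i in range(3):
            row[f"u{i + 1}"] = (
                self.inflection_positions[i] if i < len(self.inflection_positions) else math.nan
            )
            row[f"s{i + 1}"] = (
                self.inflection_slopes[i] if i < len(self.inflection_slopes) else math.nan
            )
        row.update(
            monotonic=self.monotonic,
            r0=self.r0,
            r_inf=self.r_inf,
            r_min=self.r_min,
            r_max=self.r_max,
            r_star=math.nan if self.r_star is None else self.r_star,
        )
        return row


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def evaluate_response(coeffs: RationalResponse, x):
    """Evaluate ``(A + Bx + Cx^2)/(D + Ex + Fx^2)``; handles x = 0 and inf."""
    return coeffs.evaluate(x)


def leakiness(rates: RateSet, potencies: Potencies | None = None) -> float:
    """Response at x = 0: the two-state S/P balance.

    Without TF the system reduces to the acyclic pair {S, P}, which is always
    detailed balanced, so the leakiness is set purely by the S<->P rates.
    """
    p = potencies if potencies is not None else Potencies()
    return (p.r_s * rates.k_ps + p.r_p * rates.k_sp) / (rates.k_sp + rates.k_ps)


def saturation(rates: RateSet, potencies: Potencies | None = None) -> float:
    """Response as x -> infinity: the two-state X/XP balance."""
    p = potencies if potencies is not None else Potencies()
    return (p.r_x * rates.k_xp_x + p.r_xp * rates.k_x_xp) / (
        rates.k_x_xp + rates.k_xp_x
    )


def collapse_shape(coeffs: RationalResponse) -> ShapeParams:
    """Collapse six coefficients to the two shape parameters (a, b).

    ``x_scale = sqrt(D/F)``, ``b = E/sqrt(D F)`` and
    ``a = (BD - AE)/(CD - AF) * sqrt(F/D)``.  When the leakiness equals the
    saturation (C*D == A*F) the normalization divides by zero; the result is
    flagged degenerate and carries no (a, b).
    """
    A, B, C, D, E, F = coeffs.as_tuple()
    x0 = math.sqrt(D / F)
    b = E / math.sqrt(D * F)
    r0, r_inf = A / D, C / F
    denom = C * D - A * F
    if abs(denom) <= 1e-13 * max(abs(C * D), abs(A * F), 1e-300):
        return ShapeParams(
            a=math.nan, b=b, x_scale=x0, r0=r0, r_inf=r_inf, degenerate=True
        )
    a = (B * D - A * E) / denom * math.sqrt(F / D)
    return ShapeParams(a=a, b=b, x_scale=x0, r0=r0, r_inf=r_inf)


def equilibrium_linear_form(
    rates: RateSet, potencies: Potencies | None = None, tol: float = 1e-9
) -> EquilibriumLinearForm:
    """Reduce a detailed-balanced response to its linear-fraction form.

    At equilibrium the state weights are Boltzmann factors built from the
    association constants K_x = k_sx/k_xs, K_p = k_sp/k_ps and
    K_xp = k_x_xp/k_xp_x, and the quadratic ratio cancels down to
    ``(A' + B' x)/(C' + D' x)`` -- the Hill/Langmuir/MWC family.
    """
    p = potencies if potencies is not None else Potencies()
    if not is_detailed_balanced(rates, tol=tol):
        raise NotDetailedBalancedError(cycle_drive(rates))
    K_x = rates.k_sx / rates.k_xs
    K_p = rates.k_sp / rates.k_ps
    K_xp = rates.k_x_xp / rates.k_xp_x
    return EquilibriumLinearForm(
        A_p=p.r_s + p.r_p * K_p,
        B_p=K_x * (p.r_x + p.r_xp * K_xp),
        C_p=1.0 + K_p,
        D_p=K_x * (1.0 + K_xp),
    )


def count_inflections(coeffs: RationalResponse) -> int:
    """Number of inflection points of <r> vs ln x over x in (0, inf).

    Counts sign changes of the second derivative on the log axis; for this
    response family the count is always 1, 2 or 3.
    """
    return _shape_core(coeffs).n_inflections


def classify_phenotype(coeffs: RationalResponse) -> PhenotypeReport:
    """Full shape-phenotype report for one response curve."""
    core = _shape_core(coeffs)
    vals, xs = core.extrema_and_limits()
    imin, imax = int(np.argmin(vals)), int(np.argmax(vals))
    r_star = None
    if core.n_inflections == 3:
        r_star = float(core.value_at_y(core.inflection_y[1]))
    return PhenotypeReport(
        n_inflections=core.n_inflections,
        inflection_positions=tuple(np.log(core.inflection_y)),
        inflection_slopes=tuple(core.inflection_slopes),
        monotonic=core.monotonic,
        r0=core.r0,
        r_inf=core.r_inf,
        r_min=float(vals[imin]),
        r_max=float(vals[imax]),
        argmin_x=float(xs[imin]),
        argmax_x=float(xs[imax]),
        r_star=r_star,
        x_scale=core.x_scale,
        boundary_case=core.boundary_case,
    )


def monotonicity_criterion(rates: RateSet) -> bool:
    """Kinetic condition guaranteeing a monotonic response at any drive.

    True when the TF changes the polymerase's binding and unbinding rates in
    opposite senses (or leaves either unchanged):
    ``(k_x_xp >= k_sp and k_xp_x <= k_ps) or (k_x_xp <= k_sp and k_xp_x >= k_ps)``.
    Rate sets satisfying this can never produce a nonmonotonic response,
    however strongly detailed balance is broken; nonmonotonicity requires the
    TF to change both rates coherently.
    """
    up = rates.k_x_xp >= rates.k_sp and rates.k_xp_x <= rates.k_ps
    down = rates.k_x_xp <= rates.k_sp and rates.k_xp_x >= rates.k_ps
    return up or down
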