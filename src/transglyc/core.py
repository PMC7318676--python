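"""Equilibrium model of nucleoside-phosphorylase-catalyzed transglycosylation.

A transglycosylation couples two reversible phosphorolysis half-reactions:

    I.   N1 + P  <->  B1 + P1P      (sugar donor cleaved,   constant K1)
    II.  N2 + P  <->  B2 + P1P      (product formed in reverse, constant K2)

where N1/N2 are the donor and product nucleosides, B1/B2 the corresponding
nucleobases, P inorganic phosphate and P1P the pentose-1-phosphate
intermediate. The apparent equilibrium constants are

    K1 = [B1][P1P] / ([N1][P]),     K2 = [B2][P1P] / ([N2][P])

and their ratio K_N = K1/K2 is the net-reaction constant of the overall
sugar transfer N1 + B2 <-> B1 + N2. Phosphate acts catalytically: it is
consumed in step I and released in step II, but any phosphate present at
equilibrium sequesters sugar as P1P and phosphorolyzes product, lowering the
yield below the ideal (vanishing-phosphate) value.

This module provides the closed-form ideal yield (quadratic in the amount of
product formed), a full numerical equilibrium solver parametrized by the two
reaction extents (so all mass balances hold exactly by construction), and
yield-versus-phosphate summaries. All concentrations are in mM; "equiv"
denotes multiples of the starting acceptor-base concentration B2_0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

from .errors import ConvergenceError, DomainError

__all__ = [
    "PhosphorolysisEntry",
    "TransglycosylationSystem",
    "EquilibriumState",
    "IdealYield",
    "YieldPrediction",
    "apparent_constant",
    "ideal_yield",
    "solve_equilibrium",
    "yield_vs_phosphate",
    "phosphate_gap",
]

#: |K_N - 1| below which the ideal-yield quadratic degenerates to linear.
_KN_LINEAR_EPS = 1e-9


def _require_finite_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise DomainError(f"{name} must be finite and > 0, got {value!r}")


def _require_nonnegative(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise DomainError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class PhosphorolysisEntry:
    """One nucleoside's apparent equilibrium constant of phosphorolysis.

    The constant is condition-specific (apparent), so temperature and pH are
    carried alongside it.
    """

    species_id: str
    K: float
    temperature_C: float = float("nan")
    pH: float = float("nan")
    source: str = ""

    def __post_init__(self) -> None:
        if not self.species_id:
            raise DomainError("species_id must be a non-empty label")
        _require_finite_positive(f"K for {self.species_id!r}", self.K)


@dataclass(frozen=True)
class TransglycosylationSystem:
    """Constants plus initial composition: the full input of the solver.

    Parameters
    ----------
    K1, K2
        Apparent equilibrium constants of phosphorolysis of the sugar donor
        and of the product nucleoside (dimensionless, > 0).
    N1_0, B1_0, N2_0, B2_0, P_0, P1P_0
        Initial concentrations in mM of donor nucleoside, donor base,
        product nucleoside, acceptor base, inorganic phosphate and
        pentose-1-phosphate. B2_0 must be > 0 because yield is defined
        relative to it. B1_0, N2_0 and P1P_0 default to 0, matching the
        usual synthetic setup (donor + base + phosphate only).
    """

    K1: float
    K2: float
    N1_0: float
    B2_0: float
    P_0: float
    B1_0: float = 0.0
    N2_0: float = 0.0
    P1P_0: float = 0.0

    def __post_init__(self) -> None:
        _require_finite_positive("K1", self.K1)
        _require_finite_positive("K2", self.K2)
        _require_nonnegative("N1_0", self.N1_0)
        _require_finite_positive("B2_0", self.B2_0)
        _require_nonnegative("P_0", self.P_0)
        _require_nonnegative("B1_0", self.B1_0)
        _require_nonnegative("N2_0", self.N2_0)
        _require_nonnegative("P1P_0", self.P1P_0)
        _require_finite_positive("K_N = K1/K2", self.K1 / self.K2)

    @property
    def K_N(self) -> float:
        """Net-reaction equilibrium constant K1/K2."""
        return self.K1 / self.K2

    def with_phosphate(self, P_0: float) -> "TransglycosylationSystem":
        """Copy of this system with a different initial phosphate level."""
        return replace(self, P_0=P_0)


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium composition (mM) and the product yield it implies.

    ``yield_fraction`` is the product nucleoside *formed* (relative to the
    initial state) divided by the initial acceptor base B2_0.
    """

    N1: float
    B1: float
    N2: float
    B2: float
    P: float
    P1P: float
    yield_fraction: float


class IdealYield(NamedTuple):
    """Closed-form zero-phosphate equilibrium: product formed and yield."""

    N2_mM: float
    yield_fraction: float


@dataclass(frozen=True)
class YieldPrediction:
    """Ideal yield together with phosphate-adjusted yields.

    ``yields_at_phosphate`` pairs each phosphate loading (in equivalents of
    B2_0) with the corresponding full-equilibrium yield fraction. Phosphate
    can only diminish yield, so every entry is <= ``ideal_yield``.
    """

    ideal_yield: float
    yields_at_phosphate: tuple[tuple[float, float], ...]
    settings: TransglycosylationSystem


def apparent_constant(
    nucleoside: float, base: float, p1p: float, phosphate: float
) -> float:
    """Apparent equilibrium constant of phosphorolysis from a composition.

    K = [base] * [pentose-1-phosphate] / ([nucleoside] * [phosphate]),
    all concentrations at equilibrium and in the same unit (K is
    dimensionless, so the unit cancels).

    Raises
    ------
    DomainError
        If the nucleoside or phosphate concentration is zero or negative
        (the quotient is undefined), or any input is negative.
    """
    if not math.isfinite(nucleoside) or nucleoside <= 0:
        raise DomainError(
            f"nucleoside concentration must be > 0 to define K, got {nucleoside!r}"
        )
    if not math.isfinite(phosphate) or phosphate <= 0:
        raise DomainError(
            f"phosphate concentration must be > 0 to define K, got {phosphate!r}"
        )
    _require_nonnegative("base concentration", base)
    _require_nonnegative("pentose-1-phosphate concentration", p1p)
    return (base * p1p) / (nucleoside * phosphate)


def ideal_yield(K_N: float, N1_0: float, B2_0: float) -> IdealYield:
    """Ideal (vanishing-phosphate) transglycosylation yield, in closed form.

    In the zero-phosphate limit no sugar is sequestered as pentose-1-phosphate
    and the net reaction N1 + B2 <-> B1 + N2 alone fixes the equilibrium.
    With x the product formed, K_N = x^2 / ((N1_0 - x)(B2_0 - x)), i.e.

        (K_N - 1) x^2 - K_N (N1_0 + B2_0) x + K_N N1_0 B2_0 = 0,

    which has exactly one root in the feasible interval [0, min(N1_0, B2_0)].
    When K_N is numerically 1 the quadratic degenerates and the exact linear
    solution x = N1_0 B2_0 / (N1_0 + B2_0) is used.

    Returns
    -------
    IdealYield
        Product formed (mM) and yield fraction x / B2_0.
    """
    _require_finite_positive("K_N", K_N)
    _require_nonnegative("N1_0", N1_0)
    _require_finite_positive("B2_0", B2_0)
    if N1_0 == 0.0:
        return IdealYield(0.0, 0.0)

    s = N1_0 + B2_0
    if abs(K_N - 1.0) < _KN_LINEAR_EPS:
        x = N1_0 * B2_0 / s
        return IdealYield(x, x / B2_0)

    # discriminant = K_N * (K_N (N1_0 - B2_0)^2 + 4 N1_0 B2_0)  >= 0 always
    disc = K_N * (K_N * (N1_0 - B2_0) ** 2 + 4.0 * N1_0 * B2_0)
    q = 0.5 * (K_N * s + math.sqrt(disc))
    # of the two roots q/(K_N-1) and c/q, the feasible one is always c/q,
    # which is also free of subtractive cancellation for extreme K_N
    x = K_N * N1_0 * B2_0 / q
    upper = min(N1_0, B2_0)
    x = min(max(x, 0.0), upper)
    return IdealYield(x, x / B2_0)


# ---------------------------------------------------------------------------
# Full equilibrium solver
# ---------------------------------------------------------------------------
#
# Parametrize the state by reaction extents:
#   xi1 = net donor phosphorolysis   (N1 + P -> B1 + P1P)
#   xi2 = net product synthesis      (B2 + P1P -> N2 + P)
# so that
#   N1 = N1_0 - xi1        B1  = B1_0  + xi1
#   N2 = N2_0 + xi2        B2  = B2_0  - xi2
#   P1P = P1P_0 + xi1 - xi2
#   P   = P_0   - xi1 + xi2
# All four conservation laws (donor pool, acceptor pool, ribose, phosphorus)
# hold exactly for any (xi1, xi2); the solver only has to satisfy the two
# equilibrium quotients. For fixed xi2 the K1 constraint
#   (B1_0+xi1)(P1P_0+xi1-xi2) - K1 (N1_0-xi1)(P_0-xi1+xi2) = 0
# is a quadratic in xi1 whose left side is strictly increasing on the
# feasible bracket, so it has a unique feasible root (solved in closed form,
# with a bisection fallback for degenerate coefficients). The outer K2
# residual is then a monotone function of xi2, bracketed on
# [-N2_0, B2_0] with opposite signs at the ends, and is solved by Brent's
# bracketed method. Extents may be negative when product or P1P is present
# initially (the net reaction then runs in reverse).


# For numerical stability the inner problem is solved for delta = xi1 - xi2,
# the net pentose-1-phosphate formed, so that P1P = P1P_0 + delta and
# P = P_0 - delta are computed directly: near the zero-phosphate limit both
# are tiny while xi1 and xi2 are O(1), and forming them as xi1 - xi2 would
# lose all significant digits to cancellation.


def _k1_residual(sys_: TransglycosylationSystem, delta: float, xi2: float) -> float:
    b1 = sys_.B1_0 + xi2 + delta
    p1p = sys_.P1P_0 + delta
    n1 = sys_.N1_0 - xi2 - delta
    p = sys_.P_0 - delta
    return b1 * p1p - sys_.K1 * n1 * p


def _solve_delta(sys_: TransglycosylationSystem, xi2: float, max_iter: int) -> float:
    """Unique net-P1P amount satisfying the K1 constraint at the given xi2."""
    lo = max(-sys_.P1P_0, -sys_.B1_0 - xi2)
    hi = min(sys_.P_0, sys_.N1_0 - xi2)
    if hi <= lo:
        return lo
    # quadratic coefficients of the residual in delta; the residual is
    # strictly increasing on the feasible bracket, so at most one root lies
    # inside it
    k1 = sys_.K1
    a = 1.0 - k1
    b = (sys_.B1_0 + xi2 + sys_.P1P_0) + k1 * (sys_.N1_0 - xi2 + sys_.P_0)
    c = (sys_.B1_0 + xi2) * sys_.P1P_0 - k1 * (sys_.N1_0 - xi2) * sys_.P_0
    roots: list[float] = []
    if abs(a) < 1e-14 * max(abs(b), 1.0):
        if b != 0.0:
            roots.append(-c / b)
    else:
        disc = b * b - 4.0 * a * c
        if disc >= 0.0:
            # numerically stable quadratic roots
            q = -0.5 * (b + math.copysign(math.sqrt(disc), b))
            roots.append(q / a)
            if q != 0.0:
                roots.append(c / q)
    span = hi - lo
    tol = 1e-9 * max(span, 1.0)
    in_bracket = [r for r in roots if lo - tol <= r <= hi + tol]
    if in_bracket:
        return min(max(in_bracket[0], lo), hi)
    # fallback: bisection on the monotone residual
    if _k1_residual(sys_, lo, xi2) > 0.0:
        return lo
    if _k1_residual(sys_, hi, xi2) < 0.0:
        return hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if _k1_residual(sys_, mid, xi2) < 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-17 * max(1.0, abs(hi)):
            break
    return 0.5 * (lo + hi)


def _state_from_extents(
    sys_: TransglycosylationSystem, delta: float, xi2: float
) -> EquilibriumState:
    clip = lambda v: v if v > 0.0 else 0.0
    return EquilibriumState(
        N1=clip(sys_.N1_0 - xi2 - delta),
        B1=clip(sys_.B1_0 + xi2 + delta),
        N2=clip(sys_.N2_0 + xi2),
        B2=clip(sys_.B2_0 - xi2),
        P=clip(sys_.P_0 - delta),
        P1P=clip(sys_.P1P_0 + delta),
        yield_fraction=xi2 / sys_.B2_0,
    )


def _relative_residuals(
    sys_: TransglycosylationSystem, st: EquilibriumState
) -> tuple[float, float]:
    t1a, t1b = st.B1 * st.P1P, sys_.K1 * st.N1 * st.P
    t2a, t2b = st.B2 * st.P1P, sys_.K2 * st.N2 * st.P
    scale1 = max(abs(t1a), abs(t1b), 1e-300)
    scale2 = max(abs(t2a), abs(t2b), 1e-300)
    return abs(t1a - t1b) / scale1, abs(t2a - t2b) / scale2


def _polish_extended(
    sys_: TransglycosylationSystem, delta: float, xi2: float
) -> tuple[EquilibriumState, tuple[float, float]]:
    """Newton-polish (delta, xi2) in extended precision.

    The bracketed solve resolves the extents to float64 ulps, but when one
    equilibrium constant is very small the corresponding quotient residual,
    measured relative to its own (tiny) terms, can sit a couple of orders of
    magnitude above the target tolerance at that resolution. A few Newton
    steps on the 2x2 system in ``numpy.longdouble`` remove that limitation;
    the returned state is the nearest-float64 image of the polished
    solution, and the reported residuals are evaluated at extended
    precision.
    """
    import numpy as np

    ld = np.longdouble
    k1, k2 = ld(sys_.K1), ld(sys_.K2)
    n1_0, b1_0 = ld(sys_.N1_0), ld(sys_.B1_0)
    n2_0, b2_0 = ld(sys_.N2_0), ld(sys_.B2_0)
    p_0, p1p_0 = ld(sys_.P_0), ld(sys_.P1P_0)
    d, x = ld(delta), ld(xi2)

    def terms(d, x):
        b1, p1p = b1_0 + x + d, p1p_0 + d
        n1, p = n1_0 - x - d, p_0 - d
        n2, b2 = n2_0 + x, b2_0 - x
        return b1, p1p, n1, p, n2, b2

    floor = ld(1e-300)

    def residuals(d, x):
        b1, p1p, n1, p, n2, b2 = terms(d, x)
        r1 = abs(b1 * p1p - k1 * n1 * p) / max(abs(b1 * p1p), abs(k1 * n1 * p), floor)
        r2 = abs(b2 * p1p - k2 * n2 * p) / max(abs(b2 * p1p), abs(k2 * n2 * p), floor)
        return float(r1), float(r2)

    def clamp(d, x):
        x = min(max(x, -n2_0), b2_0)
        d = min(max(d, max(-p1p_0, -b1_0 - x)), min(p_0, n1_0 - x))
        return d, x

    best = (clamp(d, x), residuals(*clamp(d, x)))
    for _ in range(8):
        b1, p1p, n1, p, n2, b2 = terms(d, x)
        f1 = b1 * p1p - k1 * n1 * p
        f2 = b2 * p1p - k2 * n2 * p
        j11 = p1p + b1 + k1 * (p + n1)
        j12 = p1p + k1 * p
        j21 = b2 + k2 * n2
        j22 = -p1p - k2 * p
        det = j11 * j22 - j12 * j21
        if det == 0:
            break
        d = d - (f1 * j22 - f2 * j12) / det
        x = x - (j11 * f2 - j21 * f1) / det
        d, x = clamp(d, x)
        r = residuals(d, x)
        if max(r) < max(best[1]):
            best = ((d, x), r)
        if max(r) < 1e-16:
            break
    (d, x), (r1, r2) = best
    state = _state_from_extents(sys_, float(d), float(x))
    return state, (r1, r2)


def solve_equilibrium(
    system: TransglycosylationSystem,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> EquilibriumState:
    """Solve both equilibrium constraints with complete mass balance.

    The state is parametrized by the two reaction extents, so the donor-pool,
    acceptor-pool, ribose and phosphorus balances hold exactly by
    construction; root finding only enforces the two equilibrium quotients,
    each to relative residual below ``tol``.

    If the system contains no phosphorus at all (P_0 = P1P_0 = 0) neither
    half-reaction can proceed and the initial state is returned unchanged:
    phosphate is catalytic, and the ideal yield is the limit P_0 -> 0+, not
    the frozen P_0 = 0 state.

    Raises
    ------
    ConvergenceError
        If the residual tolerance is not met within the iteration budget.
    DomainError
        If ``tol`` is not positive.
    """
    if not (tol > 0.0):
        raise DomainError(f"tol must be > 0, got {tol!r}")
    if system.P_0 + system.P1P_0 == 0.0:
        return _state_from_extents(system, 0.0, 0.0)

    def outer(xi2: float) -> float:
        delta = _solve_delta(system, xi2, max_iter)
        st = _state_from_extents(system, delta, xi2)
        return st.B2 * st.P1P - system.K2 * st.N2 * st.P

    lo, hi = -system.N2_0, system.B2_0
    flo, fhi = outer(lo), outer(hi)
    # outer residual decreases from >=0 at xi2 = -N2_0 (N2 = 0) to <=0 at
    # xi2 = B2_0 (B2 = 0); endpoint roots short-circuit the search
    if flo == 0.0:
        xi2 = lo
    elif fhi == 0.0:
        xi2 = hi
    else:
        from scipy.optimize import brentq

        xi2 = brentq(
            outer, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=max_iter, disp=False
        )
    delta = _solve_delta(system, xi2, max_iter)
    state, (r1, r2) = _polish_extended(system, delta, xi2)
    if r1 > tol or r2 > tol:
        raise ConvergenceError(
            f"equilibrium residuals ({r1:.3e}, {r2:.3e}) exceed tol={tol:.3e}",
            residuals=(r1, r2),
        )
    return state


def yield_vs_phosphate(
    K1: float,
    K2: float,
    N1_0: float,
    B2_0: float,
    phosphate_equivs: Sequence[float],
    tol: float = 1e-12,
) -> YieldPrediction:
    """Ideal yield plus full-equilibrium yields over a phosphate ladder.

    Each entry of ``phosphate_equivs`` is a phosphate loading in equivalents
    of the starting base (P_0 = equiv * B2_0). The returned list preserves
    the input order. A loading of exactly 0 is reported as the catalytic
    limit P_0 -> 0+, i.e. the ideal yield (with literally no phosphorus the
    reaction cannot start at all).
    """
    for eq in phosphate_equivs:
        _require_nonnegative("phosphate equivalents", eq)
    base_system = TransglycosylationSystem(
        K1=K1, K2=K2, N1_0=N1_0, B2_0=B2_0, P_0=0.0
    )
    ideal = ideal_yield(base_system.K_N, N1_0, B2_0).yield_fraction
    pairs = []
    for eq in phosphate_equivs:
        if eq == 0.0:
            pairs.append((0.0, ideal))
            continue
        state = solve_equilibrium(base_system.with_phosphate(eq * B2_0), tol=tol)
        pairs.append((float(eq), state.yield_fraction))
    return YieldPrediction(
        ideal_yield=ideal,
        yields_at_phosphate=tuple(pairs),
        settings=base_system,
    )


def phosphate_gap(
    K1: float,
    K2: float,
    N1_0: float,
    B2_0: float,
    phosphate_equiv: float,
    tol: float = 1e-12,
) -> float:
    """Yield lost to phosphate, in percentage points.

    100 * (ideal yield - full-equilibrium yield at the given phosphate
    loading). Zero phosphate gives a zero gap; more phosphate can only widen
    it.
    """
    _require_nonnegative("phosphate equivalents", phosphate_equiv)
    if phosphate_equiv == 0.0:
        return 0.0
    pred = yield_vs_phosphate(K1, K2, N1_0, B2_0, [phosphate_equiv], tol=tol)
    gap = 100.0 * (pred.ideal_yield - pred.yields_at_phosphate[0][1])
    return max(gap, 0.0)
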