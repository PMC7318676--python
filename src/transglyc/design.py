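"""Inverse problems for transglycosylation planning.

The forward model (``transglyc.core``) maps reaction conditions to yield.
Planning a synthesis asks the reverse questions: how much sugar-donor excess
buys a target yield, and how much phosphate can be tolerated before the
yield drops more than an acceptable number of percentage points. The maps
being inverted are monotone (yield increases with donor, decreases with
phosphate), so every numeric inversion here is a bracketed bisection with
explicit feasibility checks at the bracket ends.
"""

from __future__ import annotations

import itertools
import math
from typing import NamedTuple, Sequence

import pandas as pd

from .core import (
    TransglycosylationSystem,
    ideal_yield,
    phosphate_gap,
    solve_equilibrium,
)
from .errors import DomainError, InfeasibleTargetError

__all__ = [
    "donor_for_target_yield",
    "donor_for_target_yield_with_phosphate",
    "max_phosphate_for_deviation",
    "PhosphateBudget",
    "yield_landscape",
]

#: Donor excess (equivalents of B2_0) treated as "effectively infinite" when
#: probing the asymptotic yield at a fixed phosphate level.
_ASYMPTOTIC_DONOR_EQUIV = 1e4


def donor_for_target_yield(K_N: float, target_yield: float, B2_0: float) -> float:
    """Donor concentration achieving a target ideal yield, analytically.

    Inverts the net-reaction equilibrium K_N = x^2 / ((N1_0 - x)(B2_0 - x))
    for the initial donor concentration, with x = target_yield * B2_0:

        N1_0 = x + x^2 / (K_N * (B2_0 - x))

    Low K_N systems require large donor excess for yields above 50 %; a
    yield of 1 is unreachable at any finite donor concentration.

    Returns
    -------
    float
        Required initial donor concentration N1_0 in mM.
    """
    if not (0.0 < target_yield < 1.0):
        raise DomainError(
            f"target_yield must be in (0, 1); yield 1 is only reached in the "
            f"infinite-donor limit (got {target_yield!r})"
        )
    if not (K_N > 0.0 and math.isfinite(K_N)):
        raise DomainError(f"K_N must be finite and > 0, got {K_N!r}")
    if not (B2_0 > 0.0):
        raise DomainError(f"B2_0 must be > 0, got {B2_0!r}")
    x = target_yield * B2_0
    return x + x * x / (K_N * (B2_0 - x))


def donor_for_target_yield_with_phosphate(
    K1: float,
    K2: float,
    target_yield: float,
    B2_0: float,
    P_0: float,
    xtol: float = 1e-9,
) -> float:
    """Smallest donor concentration reaching a target yield at finite phosphate.

    Unlike :func:`donor_for_target_yield`, which works in the zero-phosphate
    limit, this accounts for sugar sequestered as pentose-1-phosphate and
    product phosphorolysis by solving the full equilibrium at each trial
    donor level. Yield is monotone increasing in donor, so the smallest
    sufficient N1_0 is found by bisection to within ``xtol`` mM.

    In this model the yield tends to 1 as the donor excess grows without
    bound (donor phosphorolysis keeps producing pentose-1-phosphate), so any
    target below 1 is reachable *eventually*; the search is therefore capped
    at 1e4 donor equivalents, far beyond any synthetically sensible excess.

    Raises
    ------
    InfeasibleTargetError
        If the target is not reached within the donor cap at this phosphate
        level; the error reports the yield observed at the cap.
    """
    if not (0.0 < target_yield < 1.0):
        raise DomainError(f"target_yield must be in (0, 1), got {target_yield!r}")
    if P_0 < 0.0:
        raise DomainError(f"P_0 must be >= 0, got {P_0!r}")

    def yield_at(n1_0: float) -> float:
        sys_ = TransglycosylationSystem(K1=K1, K2=K2, N1_0=n1_0, B2_0=B2_0, P_0=P_0)
        if P_0 == 0.0:
            return ideal_yield(sys_.K_N, n1_0, B2_0).yield_fraction
        return solve_equilibrium(sys_).yield_fraction

    hi = _ASYMPTOTIC_DONOR_EQUIV * B2_0
    asymptotic = yield_at(hi)
    if asymptotic < target_yield:
        raise InfeasibleTargetError(
            f"target yield {target_yield:.4f} unreachable at P_0={P_0} mM: "
            f"yield at {_ASYMPTOTIC_DONOR_EQUIV:g} donor equivalents is only "
            f"{asymptotic:.4f}",
            asymptotic_yield=asymptotic,
        )
    lo = 0.0
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if yield_at(mid) >= target_yield:
            hi = mid
        else:
            lo = mid
    return hi


class PhosphateBudget(NamedTuple):
    """Largest tolerable phosphate loading, in mM and in equivalents of B2_0."""

    P_0_mM: float
    equiv: float


def max_phosphate_for_deviation(
    K1: float,
    K2: float,
    N1_0: float,
    B2_0: float,
    max_gap: float,
    xtol: float = 1e-9,
) -> PhosphateBudget:
    """Largest phosphate loading keeping the yield loss within ``max_gap``.

    ``max_gap`` is in percentage points of yield relative to the ideal
    (zero-phosphate) value. The phosphate gap grows monotonically with
    phosphate but saturates: in the large-phosphate limit essentially all
    nucleoside is phosphorolyzed, bounding the gap by 100 * ideal_yield. If
    ``max_gap`` exceeds that bound, no finite phosphate amount violates it
    and an infinite budget is returned (a comparable sentinel rather than an
    error, so planning tables stay well-defined).
    """
    if not (max_gap > 0.0):
        raise DomainError(f"max_gap must be > 0 percentage points, got {max_gap!r}")

    def gap_at(equiv: float) -> float:
        return phosphate_gap(K1, K2, N1_0, B2_0, equiv)

    # bracket the crossing in equivalents; the gap saturates, so if a huge
    # loading stays within budget the budget is practically unbounded
    hi = 1.0
    while gap_at(hi) <= max_gap:
        hi *= 10.0
        if hi > 1e6:
            return PhosphateBudget(math.inf, math.inf)
    lo = 0.0
    xtol_equiv = xtol / B2_0
    while hi - lo > xtol_equiv:
        mid = 0.5 * (lo + hi)
        if gap_at(mid) <= max_gap:
            lo = mid
        else:
            hi = mid
    return PhosphateBudget(lo * B2_0, lo)


def yield_landscape(
    K1_values: Sequence[float],
    K2_values: Sequence[float],
    donor_equivs: Sequence[float],
    phosphate_equivs: Sequence[float],
    B2_0: float,
) -> pd.DataFrame:
    """Yields over a grid of constants, donor excesses and phosphate levels.

    For every combination of K1, K2 and donor excess, one row reports the
    ideal (zero-phosphate) yield and one row each phosphate level. Rows are
    emitted in lexicographic order over the input grids, ideal first within
    each cell, making the output deterministic and directly serializable.

    Returns
    -------
    pandas.DataFrame
        Long-format table with columns ``K1``, ``K2``, ``donor_equiv``,
        ``kind`` ("ideal" or "equilibrium"), ``phosphate_equiv`` (NaN for
        ideal rows) and ``yield_fraction``.
    """
    for name, grid in (
        ("K1_values", K1_values),
        ("K2_values", K2_values),
        ("donor_equivs", donor_equivs),
    ):
        if len(grid) == 0:
            raise DomainError(f"{name} must be non-empty")
        if any(v <= 0 for v in grid):
            raise DomainError(f"{name} entries must be > 0")
    if any(v < 0 for v in phosphate_equivs):
        raise DomainError("phosphate_equivs entries must be >= 0")

    rows = []
    for k1, k2, d_eq in itertools.product(K1_values, K2_values, donor_equivs):
        n1_0 = d_eq * B2_0
        ideal = ideal_yield(k1 / k2, n1_0, B2_0).yield_fraction
        rows.append(
            dict(
                K1=k1, K2=k2, donor_equiv=d_eq, kind="ideal",
                phosphate_equiv=math.nan, yield_fraction=ideal,
            )
        )
        for p_eq in phosphate_equivs:
            sys_ = TransglycosylationSystem(
                K1=k1, K2=k2, N1_0=n1_0, B2_0=B2_0, P_0=p_eq * B2_0
            )
            y = solve_equilibrium(sys_).yield_fraction if p_eq > 0 else ideal
            rows.append(
                dict(
                    K1=k1, K2=k2, donor_equiv=d_eq, kind="equilibrium",
                    phosphate_equiv=float(p_eq), yield_fraction=y,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["K1", "K2", "donor_equiv", "kind", "phosphate_equiv", "yield_fraction"],
    )
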