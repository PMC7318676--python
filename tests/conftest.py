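"""Shared fixtures and the independent grid-refinement oracle.

The oracle solves the coupled equilibrium by brute-force residual
minimization over the two reaction extents (nested 1-D grid refinement),
sharing no code path with the package's bracketed root-finding solver.
"""

from __future__ import annotations

import numpy as np
import pytest

from transglyc import TransglycosylationSystem


def grid_refine_equilibrium(
    K1: float,
    K2: float,
    N1_0: float,
    B2_0: float,
    P_0: float,
    B1_0: float = 0.0,
    N2_0: float = 0.0,
    P1P_0: float = 0.0,
    outer_rounds: int = 6,
    inner_rounds: int = 5,
    n_grid: int = 64,
) -> dict:
    """Residual-minimizing search over (xi1, xi2) by nested grid refinement.

    xi1 is the donor-phosphorolysis extent, xi2 the product-synthesis
    extent. Each equilibrium quotient residual is normalized by its largest
    term; the score is the sum of the two squared normalized residuals.
    """

    def inner_best(xi2: float) -> tuple[float, float]:
        lo = max(-B1_0, xi2 - P1P_0)
        hi = min(N1_0, P_0 + xi2)
        if hi <= lo:
            return _score(lo, xi2), lo
        for _ in range(inner_rounds):
            x1 = np.linspace(lo, hi, n_grid)
            sc = _score(x1, xi2)
            j = int(np.argmin(sc))
            step = (hi - lo) / (n_grid - 1)
            lo_new, hi_new = x1[j] - 2 * step, x1[j] + 2 * step
            lo = max(max(-B1_0, xi2 - P1P_0), lo_new)
            hi = min(min(N1_0, P_0 + xi2), hi_new)
        return float(np.min(sc)), float(x1[j])

    def _score(x1, xi2):
        n1 = N1_0 - x1
        b1 = B1_0 + x1
        p1p = P1P_0 + x1 - xi2
        p = P_0 - x1 + xi2
        n2 = N2_0 + xi2
        b2 = B2_0 - xi2
        t1a, t1b = b1 * p1p, K1 * n1 * p
        t2a, t2b = b2 * p1p, K2 * n2 * p
        s1 = np.maximum(np.maximum(np.abs(t1a), np.abs(t1b)), 1e-300)
        s2 = np.maximum(np.maximum(np.abs(t2a), np.abs(t2b)), 1e-300)
        return ((t1a - t1b) / s1) ** 2 + ((t2a - t2b) / s2) ** 2

    lo2, hi2 = -N2_0, B2_0
    best = None
    for _ in range(outer_rounds):
        x2 = np.linspace(lo2, hi2, n_grid)
        results = [inner_best(float(v)) for v in x2]
        scores = [r[0] for r in results]
        j = int(np.argmin(scores))
        best = (scores[j], results[j][1], float(x2[j]))
        step = (hi2 - lo2) / (n_grid - 1)
        lo2 = max(-N2_0, x2[j] - 2 * step)
        hi2 = min(B2_0, x2[j] + 2 * step)
    _, xi1, xi2 = best
    return dict(
        xi1=xi1,
        xi2=xi2,
        N1=N1_0 - xi1,
        B1=B1_0 + xi1,
        N2=N2_0 + xi2,
        B2=B2_0 - xi2,
        P=P_0 - xi1 + xi2,
        P1P=P1P_0 + xi1 - xi2,
        yield_fraction=xi2 / B2_0,
    )


def random_systems(n: int, seed: int, k_range=(1e-3, 10.0), c_range=(1e-2, 10.0)):
    """Sample n random well-posed transglycosylation systems."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        k1, k2 = np.exp(rng.uniform(np.log(k_range[0]), np.log(k_range[1]), 2))
        n1, b2, p = rng.uniform(c_range[0], c_range[1], 3)
        out.append(
            TransglycosylationSystem(K1=k1, K2=k2, N1_0=n1, B2_0=b2, P_0=p)
        )
    return out


@pytest.fixture(scope="session")
def uridine_adenine_system() -> TransglycosylationSystem:
    """Adenosine synthesis from adenine with uridine donor, 10 equiv phosphate."""
    return TransglycosylationSystem(K1=0.16, K2=0.01, N1_0=1.0, B2_0=0.5, P_0=5.0)


@pytest.fixture(scope="session")
def uridine_ethynyluracil_system() -> TransglycosylationSystem:
    """5-ethynyluridine synthesis with uridine donor, 10 equiv phosphate."""
    return TransglycosylationSystem(K1=0.16, K2=0.35, N1_0=1.0, B2_0=0.5, P_0=5.0)
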