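"""Fixed points, stability and invasion analysis of the prevalence recursion.

The one-generation map step(p) is a rational function of p; clearing its
denominator turns the fixed-point condition step(p) = p into a polynomial
whose real roots in [0, 1] are the equilibria.  Each is classified by the
finite-difference derivative of the map: |dp'/dp| < 1 stable, > 1 unstable.

Invasion from rare is governed by the linearisation at p = 0,

    lambda = (1 + w)(1 - mu) F,

which is independent of H because cytoplasmic incompatibility only acts at
second order in p.  With CI and no horizontal transmission the interior
unstable equilibrium is the classical invasion threshold; horizontal
transmission lowers or removes it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as P

from .dynamics import step
from .params import ModelParams

__all__ = [
    "FixedPoint",
    "fixed_points",
    "stability_of",
    "invasion_growth_factor",
    "ci_threshold",
    "equilibrium_sweep",
]

_FD_STEP = 1e-6          # central finite-difference step for the derivative
_NEUTRAL_TOL = 1e-6      # |derivative| within this of 1 counts as neutral
_MERGE_TOL = 1e-8        # fixed points closer than this are merged
_RESIDUAL_TOL = 1e-10    # |step(p*) - p*| accepted as a fixed point


@dataclass(frozen=True)
class FixedPoint:
    """An equilibrium prevalence with its local stability classification."""

    p_star: float
    stability: str  # stable | unstable | neutral | degenerate
    derivative: float


def _map_derivative(p_star: float, params: ModelParams) -> float:
    """Central finite-difference d step/dp, clamped to [0, 1] near the edges."""
    lo = max(0.0, p_star - _FD_STEP)
    hi = min(1.0, p_star + _FD_STEP)
    return (step(hi, params) - step(lo, params)) / (hi - lo)


def _classify(deriv: float) -> str:
    if abs(abs(deriv) - 1.0) <= _NEUTRAL_TOL:
        return "neutral"
    return "stable" if abs(deriv) < 1.0 else "unstable"


def stability_of(p_star: float, params: ModelParams) -> FixedPoint:
    """Classify a point that is already (numerically) a fixed point of step.

    Raises ValueError if ``p_star`` does not satisfy step(p*) = p* within
    tolerance.
    """
    if not 0.0 <= p_star <= 1.0:
        raise ValueError(f"p_star must lie in [0, 1], got {p_star}")
    residual = abs(step(p_star, params) - p_star)
    if residual > 1e-8:
        raise ValueError(
            f"p={p_star} is not a fixed point (|step(p)-p| = {residual:.3g})"
        )
    deriv = _map_derivative(p_star, params)
    return FixedPoint(p_star=float(p_star), stability=_classify(deriv), derivative=deriv)


def _fixed_point_polynomial(params: ModelParams) -> np.ndarray:
    """Coefficients (ascending) of the cleared fixed-point condition.

    With k(p) = N(p)/D(p) the condition k + w k (1 - k) = p becomes

        N D + w N (D - N) - p D^2 = 0.
    """
    mu, F, w = params.mu, params.F, params.w
    s_f, s_h = params.s_f, params.s_h
    N = np.array([0.0, (1.0 - mu) * F])
    D = np.array([1.0, -(s_f + s_h), s_h * (1.0 - mu * F)])
    poly = P.polyadd(P.polymul(N, D), w * P.polymul(N, P.polysub(D, N)))
    poly = P.polysub(poly, P.polymul([0.0, 1.0], P.polymul(D, D)))
    return P.polytrim(poly, tol=1e-14)


def _polish_root(p: float, poly: np.ndarray) -> float:
    """A few Newton steps on the cleared polynomial to tighten a root."""
    dpoly = P.polyder(poly)
    for _ in range(6):
        f = P.polyval(p, poly)
        df = P.polyval(p, dpoly)
        if df == 0.0:
            break
        p_new = p - f / df
        if not -1e-6 <= p_new <= 1.0 + 1e-6:
            break
        p = p_new
    return min(max(p, 0.0), 1.0)


def _bisection_scan(params: ModelParams, n_grid: int = 10_000) -> list[float]:
    """Fallback: bracket sign changes of step(p) - p on a fine grid."""
    from scipy.optimize import brentq

    grid = np.linspace(0.0, 1.0, n_grid + 1)
    g = np.array([step(p, params) - p for p in grid])
    roots = [float(grid[i]) for i in np.nonzero(np.abs(g) < _RESIDUAL_TOL)[0]]
    for i in range(n_grid):
        if g[i] == 0.0 or g[i + 1] == 0.0:
            continue
        if np.sign(g[i]) != np.sign(g[i + 1]):
            roots.append(
                float(brentq(lambda p: step(p, params) - p, grid[i], grid[i + 1],
                             xtol=1e-14))
            )
    return roots


def fixed_points(params: ModelParams) -> list[FixedPoint]:
    """All equilibria of the one-generation map in [0, 1], classified.

    The degenerate identity map (mu=0, F=1, H=1, w=0) fixes every point;
    a single FixedPoint with stability ``"degenerate"`` is returned rather
    than an infinite set.
    """
    poly = _fixed_point_polynomial(params)
    if poly.size == 0 or np.all(np.abs(poly) < 1e-14):
        return [FixedPoint(p_star=0.0, stability="degenerate", derivative=1.0)]

    candidates = {0.0}  # p = 0 is always absorbing
    roots = P.polyroots(poly)
    for r in roots:
        if abs(r.imag) > 1e-9:
            continue
        p = float(r.real)
        if -1e-9 <= p <= 1.0 + 1e-9:
            candidates.add(_polish_root(min(max(p, 0.0), 1.0), poly))

    verified = [
        p for p in candidates if abs(step(p, params) - p) <= _RESIDUAL_TOL
    ]
    if not verified:  # ill-conditioned polynomial: fall back to bracketing
        verified = _bisection_scan(params)

    merged: list[float] = []
    for p in sorted(verified):
        if not merged or p - merged[-1] > _MERGE_TOL:
            merged.append(p)
    return [
        FixedPoint(p_star=p, stability=_classify(_map_derivative(p, params)),
                   derivative=_map_derivative(p, params))
        for p in merged
    ]


def invasion_growth_factor(params: ModelParams) -> float:
    """Per-generation growth factor of a rare infection, (1+w)(1-mu)F.

    The infection invades from low prevalence iff the factor exceeds 1.
    Independent of H: incompatibility affects only terms of order p^2.
    """
    return (1.0 + params.w) * (1.0 - params.mu) * params.F


def ci_threshold(params: ModelParams) -> float | None:
    """Invasion threshold prevalence for a CI strain without horizontal transmission.

    Solves the interior fixed-point quadratic obtained by cancelling p in
    k(p) = p,

        s_h (1 - mu F) p^2 - (s_f + s_h) p + 1 - (1 - mu) F = 0,

    and returns its smaller root — the unstable equilibrium a CI strain must
    exceed to invade — when it lies in [0, 1); returns None when no interior
    threshold exists.  Requires w = 0 (with horizontal transmission use
    :func:`fixed_points`) and s_h > 0.
    """
    if params.w != 0.0:
        raise ValueError(
            "ci_threshold is defined for w = 0 only; use fixed_points for w > 0"
        )
    if params.s_h <= 0.0:
        raise ValueError("ci_threshold requires cytoplasmic incompatibility (H < 1)")
    a = params.s_h * (1.0 - params.mu * params.F)
    b = -(params.s_f + params.s_h)
    c = 1.0 - (1.0 - params.mu) * params.F
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        return None
    sqrt_disc = float(np.sqrt(disc))
    roots = sorted(((-b - sqrt_disc) / (2.0 * a), (-b + sqrt_disc) / (2.0 * a)))
    for p in roots:
        if -1e-12 <= p < 1.0:
            return max(p, 0.0)
    return None


def equilibrium_sweep(
    mu: float, F: float, H: float, w_values
) -> "pd.DataFrame":
    """Tabulate equilibria over a sweep of horizontal-transmission rates.

    Returns a tidy DataFrame with columns (mu, F, H, w, p_star, stability)
    suitable for bifurcation-style plots over w.
    """
    import pandas as pd

    rows = []
    for w in w_values:
        params = ModelParams(mu=mu, F=F, H=H, w=float(w))
        for fp in fixed_points(params):
            rows.append(
                {"mu": mu, "F": F, "H": H, "w": float(w),
                 "p_star": fp.p_star, "stability": fp.stability}
            )
    return pd.DataFrame(rows)
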