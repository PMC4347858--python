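"""Deterministic one-generation prevalence recursion and trajectory iteration.

Each generation is a composition of two maps.  First, vertical (maternal)
transmission with cytoplasmic incompatibility and relative fecundity gives
the prevalence among offspring,

    k = p (1 - mu)(1 - s_f)
        / [1 - s_f p - s_h p (1 - p) - mu s_h p^2 (1 - s_f)],

then a phoretic-vector step adds horizontal transmission among the new
cohort,

    p' = k + w k (1 - k).

Zero prevalence is absorbing; the horizontal step can only increase
prevalence.  For biologically plausible parameters both maps send [0, 1]
into itself; p' is clipped (with a warning) if a very large w pushes it
above one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import ModelParams, ParameterDomainError

__all__ = [
    "Trajectory",
    "vertical_step",
    "horizontal_step",
    "step",
    "simulate_trajectory",
    "scenario_fig6",
    "FIG6_PANELS",
    "FIG6_W_VALUES",
    "LOSS_THRESHOLD",
    "CONVERGENCE_TOL",
]

#: prevalence below which an infection is declared lost
LOSS_THRESHOLD = 1e-6
#: successive-iterate distance below which a trajectory is declared converged
CONVERGENCE_TOL = 1e-10

#: (H, F) for the three published scenario panels: A — neutral symbiont,
#: B — cytoplasmic incompatibility, C — host fitness benefit.
FIG6_PANELS = {"A": (1.0, 1.0), "B": (0.1, 1.0), "C": (1.0, 1.05)}
#: horizontal-transmission rates compared in each panel
FIG6_W_VALUES = (0.0, 0.01, 0.06)


def _check_prevalence(p: float, name: str = "p") -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be a prevalence in [0, 1], got {p}")


def vertical_step(p: float, params: ModelParams) -> float:
    """Prevalence among offspring after maternal transmission and CI.

    Parameters
    ----------
    p : prevalence of infected adults in the parental generation.
    params : model parameters (w is not used by this map).

    Returns
    -------
    k, the offspring prevalence before any horizontal transmission.
    """
    _check_prevalence(p)
    mu, s_f, s_h = params.mu, params.s_f, params.s_h
    F = params.F
    numerator = p * (1.0 - mu) * F
    denominator = (
        1.0 - s_f * p - s_h * p * (1.0 - p) - mu * s_h * p * p * F
    )
    if denominator <= 0.0:
        raise ParameterDomainError(
            "non-positive denominator in the vertical-transmission map for "
            f"p={p}, mu={mu}, F={F}, H={params.H}"
        )
    k = numerator / denominator
    # guard floating-point overshoot; the map is bounded on the valid domain
    return min(max(k, 0.0), 1.0)


def horizontal_step(k: float, params: ModelParams) -> float:
    """Add vector-borne horizontal transmission to the offspring cohort."""
    _check_prevalence(k, "k")
    p_next = k + params.w * k * (1.0 - k)
    if p_next > 1.0:
        warnings.warn(
            f"horizontal transmission rate w={params.w} pushed prevalence to "
            f"{p_next:.6g}; clipping to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        p_next = 1.0
    return p_next


def step(p: float, params: ModelParams) -> float:
    """One full generation: vertical transmission then horizontal transmission."""
    return horizontal_step(vertical_step(p, params), params)


@dataclass(frozen=True)
class Trajectory:
    """Per-generation prevalence sequence p_0 ... p_T under fixed parameters."""

    params: ModelParams
    p: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        if self.p.ndim != 1 or self.p.size < 1:
            raise ValueError("trajectory must be a non-empty 1-D sequence")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("all prevalences must lie in [0, 1]")

    @property
    def generations(self) -> int:
        return self.p.size - 1

    @property
    def final(self) -> float:
        return float(self.p[-1])

    @property
    def lost(self) -> bool:
        """Infection declared lost (final prevalence below threshold)."""
        return self.final < LOSS_THRESHOLD

    @property
    def converged(self) -> bool:
        """Last two iterates within the convergence tolerance."""
        if self.p.size < 2:
            return False
        return abs(float(self.p[-1]) - float(self.p[-2])) < CONVERGENCE_TOL

    def to_csv(self, path: str | Path, sidecar: bool = True) -> Path:
        """Write generation/prevalence columns; parameters go to a JSON sidecar."""
        import pandas as pd

        path = Path(path)
        pd.DataFrame(
            {"generation": np.arange(self.p.size), "prevalence": self.p}
        ).to_csv(path, index=False)
        if sidecar:
            meta = {
                "mu": self.params.mu,
                "F": self.params.F,
                "H": self.params.H,
                "w": self.params.w,
                "generations": self.generations,
            }
            path.with_suffix(".params.json").write_text(
                json.dumps(meta, indent=2) + "\n"
            )
        return path


def simulate_trajectory(
    p0: float, params: ModelParams, generations: int
) -> Trajectory:
    """Iterate the one-generation map from p0 for the given number of generations.

    Purely deterministic; the returned trajectory has ``generations + 1``
    entries including p0.
    """
    _check_prevalence(p0, "p0")
    if generations < 0:
        raise ValueError("generations must be non-negative")
    out = np.empty(generations + 1)
    out[0] = p0
    p = p0
    for t in range(generations):
        p = step(p, params)
        out[t + 1] = p
    return Trajectory(params=params, p=out)


def scenario_fig6(
    panel: str, generations: int = 1000, p0: float = 0.01, mu: float = 0.03
) -> dict[float, Trajectory]:
    """Run the three published horizontal-transmission scenarios for one panel.

    Panel A is a neutral symbiont (H=1, F=1), panel B a CI-inducing strain
    (H=0.1, F=1) and panel C a beneficial strain (H=1, F=1.05).  Each panel
    compares w = 0, 0.01 and 0.06 from a starting prevalence of 0.01 with
    imperfect maternal transmission mu = 0.03.

    Returns a mapping from w to its Trajectory.
    """
    key = str(panel).upper()
    if key not in FIG6_PANELS:
        raise ValueError(
            f"unknown panel {panel!r}; expected one of {sorted(FIG6_PANELS)}"
        )
    H, F = FIG6_PANELS[key]
    return {
        w: simulate_trajectory(
            p0, ModelParams(mu=mu, F=F, H=H, w=w), generations
        )
        for w in FIG6_W_VALUES
    }
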