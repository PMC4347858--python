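"""Individual-based "dirty needle" simulation of parasitoid-vectored transmission.

A single effective wasp probes hosts in a random order each generation.
Probing an infected host contaminates its mouthparts/ovipositor; the
contamination survives for a fixed number of subsequent visits (one, by
default) and is lost when the wasp probes an uninfected host.  A
contaminated probe of an uninfected host establishes a new infection with
probability tau, and only hosts that survive probing (probability sigma)
contribute to the next generation.

By default the vector never kills its host: survival is folded into
establishment, so a contaminated probe infects a reproducing host with
probability tau * sigma.  In ``kill_hosts`` mode probed non-survivors are
instead removed from the reproducing pool.

Hosts infected during a transmission phase carry too few bacteria to
contaminate the wasp within the same phase; only hosts infected before the
phase are contagious.  This makes the expected number of new cases from a
single infected host in an otherwise uninfected population

    E[w] = v * tau * sigma

for the next-visit-only contamination scheme, which is the quantity the
deterministic recursion's w summarises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import vertical_step
from .params import ModelParams

__all__ = [
    "VectorParams",
    "ABMResult",
    "WEstimate",
    "PlausibilityBand",
    "simulate_abm",
    "estimate_w",
    "plausibility_band_for_w",
]


@dataclass(frozen=True)
class VectorParams:
    """Mechanistic parameters of the phoretic vector.

    n_hosts : host population size per generation.
    visit_prob : probability v that a host is probed in a generation.
    infect_prob : probability tau that a contaminated probe establishes
        infection in an uninfected host.
    survive_prob : probability sigma that a probed host survives to reproduce.
    infectious_visits : number of subsequent visits for which contamination
        persists (the published mechanism assumes 1: only the next host).
    kill_hosts : if True, probed non-survivors are removed before
        reproduction instead of survival being folded into establishment.
    seed : default random seed for simulations using these parameters.
    """

    n_hosts: int
    visit_prob: float
    infect_prob: float
    survive_prob: float
    infectious_visits: int = 1
    kill_hosts: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_hosts < 2:
            raise ValueError("n_hosts must be at least 2")
        for name in ("visit_prob", "infect_prob", "survive_prob"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be a probability, got {val}")
        if self.infectious_visits < 1:
            raise ValueError("infectious_visits must be >= 1")


@dataclass(frozen=True)
class ABMResult:
    """Replicate-by-generation prevalences from the individual-based model."""

    prevalence: np.ndarray  # shape (replicates, generations + 1)
    seeds: tuple[int, ...]

    @property
    def replicates(self) -> int:
        return self.prevalence.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.prevalence.mean(axis=0)

    @property
    def se(self) -> np.ndarray:
        """Monte-Carlo standard error of the mean trajectory."""
        n = self.replicates
        if n < 2:
            return np.full(self.prevalence.shape[1], np.nan)
        return self.prevalence.std(axis=0, ddof=1) / np.sqrt(n)

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        reps, gens = self.prevalence.shape
        return pd.DataFrame(
            {
                "replicate": np.repeat(np.arange(reps), gens),
                "generation": np.tile(np.arange(gens), reps),
                "prevalence": self.prevalence.ravel(),
            }
        )


@dataclass(frozen=True)
class WEstimate:
    """Monte-Carlo estimate of the horizontal-transmission rate w."""

    w: float
    se: float
    n_reps: int


@dataclass(frozen=True)
class PlausibilityBand:
    """Verbal-argument bounds on w from observed visit-outcome fractions."""

    point: float
    lower: float
    upper: float


def _transmission_phase(
    infected: np.ndarray, vp: VectorParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One wasp visit sequence; returns (updated infection status, probed mask).

    ``infected`` is a boolean array over hosts; it is not modified in place.
    """
    n = infected.size
    probed = rng.random(n) < vp.visit_prob
    visited_idx = np.flatnonzero(probed)
    if visited_idx.size == 0:
        return infected.copy(), probed
    order = rng.permutation(visited_idx)
    seq_infected = infected[order]

    # wasp contaminated at visit i iff any of the previous `infectious_visits`
    # visits probed an (already) infected host
    m = vp.infectious_visits
    window = np.convolve(seq_infected.astype(float), np.ones(m))[: seq_infected.size]
    contaminated = np.zeros(seq_infected.size, dtype=bool)
    contaminated[1:] = window[:-1] > 0.0

    establish_prob = vp.infect_prob if vp.kill_hosts else vp.infect_prob * vp.survive_prob
    hit = contaminated & ~seq_infected & (rng.random(seq_infected.size) < establish_prob)

    new_infected = infected.copy()
    new_infected[order[hit]] = True
    return new_infected, probed


def simulate_abm(
    p0: float,
    vector_params: VectorParams,
    model_params: ModelParams,
    generations: int,
    replicates: int = 1,
    seed: int | None = None,
) -> ABMResult:
    """Stochastic counterpart of the deterministic recursion.

    Each generation the current adults reproduce — offspring infection is a
    binomial draw around the vertical-transmission expectation using mu, F
    and H — and the new cohort is then exposed to the wasp's transmission
    phase, mirroring the deterministic composition horizontal(vertical(p)).
    Recorded prevalences are those of adults at the start of each generation.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    if generations < 0 or replicates < 1:
        raise ValueError("generations must be >= 0 and replicates >= 1")
    if generations * vector_params.n_hosts > 10**10:
        raise ValueError("generations * n_hosts too large")
    if seed is None:
        seed = vector_params.seed if vector_params.seed is not None else 0

    n = vector_params.n_hosts
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(replicates)]
    out = np.empty((replicates, generations + 1))

    for r, child_seed in enumerate(child_seeds):
        rng = np.random.default_rng(child_seed)
        infected = rng.random(n) < p0
        alive = np.ones(n, dtype=bool)
        out[r, 0] = infected[alive].mean() if alive.any() else 0.0
        for t in range(generations):
            p_adult = infected[alive].mean() if alive.any() else 0.0
            k = vertical_step(p_adult, model_params)
            infected = rng.random(n) < k  # new cohort of n offspring
            infected, probed = _transmission_phase(infected, vector_params, rng)
            if vector_params.kill_hosts:
                died = probed & (rng.random(n) < 1.0 - vector_params.survive_prob)
                alive = ~died
            else:
                alive = np.ones(n, dtype=bool)
            out[r, t + 1] = infected[alive].mean() if alive.any() else 0.0

    return ABMResult(prevalence=out, seeds=tuple(child_seeds))


def estimate_w(
    vector_params: VectorParams, n_reps: int, seed: int | None = None
) -> WEstimate:
    """Monte-Carlo estimate of w: new cases from one infected host.

    Seeds a single infected host among otherwise uninfected hosts, runs one
    transmission phase and counts new infections; repeated ``n_reps`` times.
    For the next-visit-only scheme the expectation is v * tau * sigma.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if seed is None:
        seed = vector_params.seed if vector_params.seed is not None else 0
    rng = np.random.default_rng(seed)
    n = vector_params.n_hosts
    counts = np.empty(n_reps)
    base = np.zeros(n, dtype=bool)
    base[0] = True
    for i in range(n_reps):
        after, _ = _transmission_phase(base, vector_params, rng)
        counts[i] = int(after.sum()) - 1
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else float("nan")
    return WEstimate(w=mean, se=se, n_reps=n_reps)


def plausibility_band_for_w(
    parasitism_rate: float, survive_frac: float, infect_frac: float
) -> PlausibilityBand:
    """Reporting helper: w lies below the parasitism (visit) rate.

    The point estimate multiplies the visit rate by the fraction of probed
    hosts that survive and the fraction of survivors that become infected.
    """
    for name, val in (
        ("parasitism_rate", parasitism_rate),
        ("survive_frac", survive_frac),
        ("infect_frac", infect_frac),
    ):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {val}")
    return PlausibilityBand(
        point=parasitism_rate * survive_frac * infect_frac,
        lower=0.0,
        upper=parasitism_rate,
    )
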