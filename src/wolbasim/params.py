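"""Parameters of the discrete-generation endosymbiont prevalence model.

The model tracks the prevalence p_t (proportion of infected adults) of a
maternally inherited symbiont such as *Wolbachia* in a host population with
non-overlapping generations.  Four parameters govern one generation:

mu : imperfect maternal transmission — the fraction of uninfected ova
     produced by infected mothers.
F  : fecundity of infected females relative to uninfected females
     (F > 1 is a fitness benefit).
H  : relative hatch rate of incompatible crosses (infected male ×
     uninfected female) under cytoplasmic incompatibility; H = 1 means
     no CI, H = 0 complete incompatibility.
w  : horizontal-transmission rate — the expected number of new cases
     generated by one infected host in an otherwise uninfected population
     per generation (here via a phoretic parasitoid vector), discounted
     by any reduction in vertical transmission among the newly infected.

The selection coefficients s_f = 1 - F and s_h = 1 - H are derived, never
stored, so a fitness benefit (F > 1, s_f < 0) is handled uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ModelParams", "ParameterDomainError"]


class ParameterDomainError(ValueError):
    """Parameter combination outside the model's valid domain."""


@dataclass(frozen=True)
class ModelParams:
    mu: float = 0.0
    F: float = 1.0
    H: float = 1.0
    w: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu < 1.0:
            raise ParameterDomainError(f"mu must be in [0, 1), got {self.mu}")
        if not 0.0 <= self.H <= 1.0:
            raise ParameterDomainError(f"H must be in [0, 1], got {self.H}")
        if not self.F > 0.0:
            raise ParameterDomainError(f"F must be positive, got {self.F}")
        if self.w < 0.0:
            raise ParameterDomainError(f"w must be non-negative, got {self.w}")

    @property
    def s_f(self) -> float:
        """Fecundity cost 1 - F (negative when infection is beneficial)."""
        return 1.0 - self.F

    @property
    def s_h(self) -> float:
        """Incompatibility strength 1 - H."""
        return 1.0 - self.H

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        fields = {"mu": self.mu, "F": self.F, "H": self.H, "w": self.w}
        fields.update(kwargs)
        return ModelParams(**fields)
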