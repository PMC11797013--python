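"""Parameterization of a single gene drive release scenario.

The seven biological variables (conversion efficiency, resistance level,
resistance frequency, fitness cost, exposure rate, dominance, inbreeding)
plus the run settings (population size, generations, initial drive
frequency, module timing, stochastic/deterministic mode, seed) fully
determine a simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Optional

import numpy as np

from .core import AlleleSet
from .errors import ParameterError

__all__ = ["DriveScenario", "TIMINGS", "MODES"]

TIMINGS = ("prezygotic", "postzygotic")
MODES = ("stochastic", "deterministic")

#: admissible range of each rate parameter, used for validation messages
_BOUNDS = {
    "conversion": (0.0, 1.0),
    "resistance_level": (0.0, 1.0),
    "resistance_frequency": (0.0, 0.4),
    "fitness_cost": (0.0, 1.0),
    "exposure": (0.0, 1.0),
    "dominance": (0.0, 1.0),
    "inbreeding": (0.0, 1.0),
}


@dataclass(frozen=True)
class DriveScenario:
    """A complete simulation scenario.

    Parameters
    ----------
    conversion : float
        Probability ``c`` that the drive converts a wild-type allele in a
        heterozygote, per generation.
    resistance_level : float
        Conversion rate of the drive acting on the resistant allele
        (quantitative resistance); must not exceed ``conversion``.
        0 means a fully immune resistant allele.
    resistance_frequency : float
        Initial frequency of the resistant allele, in [0, 0.4] — resistant
        alleles are modelled as minor alleles.
    fitness_cost : float
        Selection coefficient ``s`` against drive carriers.
    exposure : float
        Fraction ``e`` of the population exposed to selection each
        generation.
    dominance : float
        Dominance ``d`` of the fitness cost in drive heterozygotes
        (0 recessive, 0.5 additive, 1 dominant).
    inbreeding : float
        Inbreeding coefficient ``F``: excess homozygosity at zygote
        formation relative to Hardy-Weinberg.
    population_size : int
        Constant population size ``n`` (default one million).
    generations : int
        Number of generations to simulate (default 500).
    initial_drive_frequency : float
        Drive allele frequency at generation 0 (default 0.001).
    timing : {"prezygotic", "postzygotic"}
        Whether homing happens during gametogenesis (after selection on the
        parents) or in the newly formed zygote (before selection).
    mode : {"stochastic", "deterministic"}
        Binomial sampling at size ``n`` versus expectation propagation.
    seed : int, optional
        Seed for the stochastic mode.
    drift_method : {"binomial", "multinomial"}
        Per-allele binomial resampling with renormalization (default) or a
        single joint multinomial gamete draw.
    """

    conversion: float
    resistance_level: float = 0.0
    resistance_frequency: float = 0.0
    fitness_cost: float = 0.0
    exposure: float = 1.0
    dominance: float = 0.5
    inbreeding: float = 0.0
    population_size: int = 1_000_000
    generations: int = 500
    initial_drive_frequency: float = 0.001
    timing: str = "prezygotic"
    mode: str = "stochastic"
    seed: Optional[int] = None
    drift_method: str = "binomial"

    def __post_init__(self):
        for name, (lo, hi) in _BOUNDS.items():
            val = getattr(self, name)
            if not (np.isfinite(val) and lo <= val <= hi):
                raise ParameterError(
                    f"{name} must lie in [{lo}, {hi}], got {val!r}"
                )
        if self.resistance_level > self.conversion:
            raise ParameterError(
                "resistance_level cannot exceed conversion "
                f"({self.resistance_level!r} > {self.conversion!r})"
            )
        if not 0.0 < self.initial_drive_frequency < 1.0:
            raise ParameterError(
                "initial_drive_frequency must lie in (0, 1), "
                f"got {self.initial_drive_frequency!r}"
            )
        if self.initial_drive_frequency + self.resistance_frequency >= 1.0:
            raise ParameterError(
                "initial_drive_frequency + resistance_frequency must be < 1"
            )
        if int(self.population_size) < 1 or self.population_size != int(self.population_size):
            raise ParameterError("population_size must be a positive integer")
        if int(self.generations) < 1 or self.generations != int(self.generations):
            raise ParameterError("generations must be a positive integer")
        if self.timing not in TIMINGS:
            raise ParameterError(f"timing must be one of {TIMINGS}, got {self.timing!r}")
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.drift_method not in ("binomial", "multinomial"):
            raise ParameterError("drift_method must be 'binomial' or 'multinomial'")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_ratio(cls, conversion: float, resistance_ratio: float, **kwargs) -> "DriveScenario":
        """Build a scenario giving resistance as a fraction of ``conversion``.

        ``resistance_level = resistance_ratio * conversion``, the form used
        when sampling the variable space (the ratio is uniform on [0, 1], so
        resistance can never exceed conversion).
        """
        if not 0.0 <= resistance_ratio <= 1.0:
            raise ParameterError("resistance_ratio must lie in [0, 1]")
        return cls(conversion=conversion, resistance_level=resistance_ratio * conversion, **kwargs)

    # -- derived views -----------------------------------------------------

    @property
    def resistance_ratio(self) -> float:
        """Resistance level as a fraction of the conversion efficiency."""
        if self.conversion == 0.0:
            return 0.0
        return self.resistance_level / self.conversion

    @property
    def selection_pressure(self) -> float:
        """Composite selection intensity: fitness cost times exposure."""
        return self.fitness_cost * self.exposure

    def allele_set(self) -> AlleleSet:
        """Drive / wild-type / resistant alleles with their susceptibilities."""
        return AlleleSet.standard(self.conversion, self.resistance_level)

    def initial_frequencies(self) -> np.ndarray:
        """Generation-0 allele frequencies (drive, wild-type, resistant)."""
        p0 = self.initial_drive_frequency
        pr = self.resistance_frequency
        return np.array([p0, 1.0 - p0 - pr, pr])

    def replace(self, **changes) -> "DriveScenario":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)
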