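"""Named fixture scenarios.

Each preset fixes the variables that are not the focus of an analysis at a
reference point in the variable space:

- ``equilibrium``: an efficient (c = 0.95) pre-zygotic drive with a strong
  but recessive, half-exposed fitness cost and a weakly convertible
  resistant allele — the drive climbs and plateaus at an intermediate
  frequency.
- ``temporary``: same backbone, but the resistant allele is fully immune
  (resistance level 0) and the cost is additive — the drive peaks and then
  crashes as immune alleles take over.
- ``dominance-switch``: a post-zygotic variant with resistance level 0.3
  where dominance is the free variable; sweeping d from 0 to 1 walks the
  outcome from equilibrium through to temporary.
"""

from __future__ import annotations

from .scenario import DriveScenario

__all__ = ["PRESETS", "load_preset"]

PRESETS = {
    "equilibrium": DriveScenario(
        conversion=0.95,
        resistance_level=0.1,
        resistance_frequency=0.1,
        fitness_cost=0.8,
        exposure=0.5,
        dominance=0.0,
        inbreeding=0.0,
        timing="prezygotic",
    ),
    "temporary": DriveScenario(
        conversion=0.95,
        resistance_level=0.0,
        resistance_frequency=0.1,
        fitness_cost=0.8,
        exposure=0.5,
        dominance=0.5,
        inbreeding=0.0,
        timing="prezygotic",
    ),
    "dominance-switch": DriveScenario(
        conversion=0.95,
        resistance_level=0.3,
        resistance_frequency=0.1,
        fitness_cost=0.8,
        exposure=0.5,
        dominance=0.0,
        inbreeding=0.0,
        timing="postzygotic",
    ),
}


def load_preset(name: str, **overrides) -> DriveScenario:
    """Return a preset scenario, optionally with fields overridden."""
    try:
        preset = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {sorted(PRESETS)}"
        ) from None
    return preset.replace(**overrides) if overrides else preset
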