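"""Single-locus dynamics of a CRISPR homing gene drive.

The model tracks the frequencies of a drive allele, a wild-type allele and
(optionally) conversion-resistant alleles through discrete, non-overlapping
generations in a population of constant size ``n``.  Each generation cycles
through four modules simulating the life cycle of a sexually reproducing
organism:

1. **Zygote formation** from the gamete pool, at Hardy-Weinberg proportions
   except for excess homozygosity controlled by an inbreeding coefficient
   ``F``.
2. **Homing conversion**: drive/non-drive heterozygotes become drive
   homozygotes at an allele-specific rate — the conversion efficiency ``c``
   for the wild-type allele, the (lower) resistance level for resistant
   alleles.
3. **Selection** against drive carriers, controlled by a fitness cost ``s``,
   the fraction ``e`` of the population exposed to selection, and the
   dominance ``d`` of the cost in heterozygotes (drive homozygotes always
   pay the full cost).
4. **Wright-Fisher drift**: binomial resampling of the gamete pool.

Pre- and post-zygotic drives differ only in module order: a post-zygotic
drive converts the newly formed zygotes *before* selection acts on them,
while a pre-zygotic drive converts during gametogenesis, i.e. *after*
selection on the parents.  Every stochastic module also has a deterministic
flavour that propagates expectations, which is useful for closed-form
validation and for isolating drift effects.

Genotype frequencies are stored as a symmetric matrix in which an
off-diagonal entry carries the *full* mass of the unordered heterozygote,
so total mass counts each heterozygote once::

    sum_i G[i, i] + 1/2 * sum_{i != j} G[i, j] == 1

Allele order convention throughout: index 0 = drive, index 1 = wild-type,
further indices = resistant alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

from .errors import ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .scenario import DriveScenario

__all__ = [
    "AlleleSet",
    "GenotypeState",
    "Trajectory",
    "form_zygotes",
    "convert_heterozygotes",
    "apply_selection",
    "genotypes_to_alleles",
    "apply_drift",
    "step_generation",
    "simulate",
]

#: tolerance for frequency-conservation checks
MASS_TOL = 1e-9

STOCHASTIC = "stochastic"
DETERMINISTIC = "deterministic"
_MODES = (STOCHASTIC, DETERMINISTIC)


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise ParameterError(f"mode must be one of {_MODES}, got {mode!r}")


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlleleSet:
    """Labelled alleles at the drive locus with per-allele susceptibility.

    ``susceptibility[j]`` is the per-generation rate at which the drive
    converts allele ``j`` in a drive/``j`` heterozygote: 0 for the drive
    allele itself, the conversion efficiency ``c`` for the wild-type allele
    and the resistance level for resistant alleles.
    """

    labels: tuple
    susceptibility: np.ndarray
    drive_index: int = 0
    wild_index: int = 1

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        sus = np.asarray(self.susceptibility, dtype=float)
        object.__setattr__(self, "susceptibility", sus)
        k = len(self.labels)
        if sus.shape != (k,):
            raise ParameterError("one susceptibility per allele is required")
        if k < 2:
            raise ParameterError("need the drive allele and at least one other allele")
        if not (0 <= self.drive_index < k and 0 <= self.wild_index < k):
            raise ParameterError("drive/wild indices out of range")
        if self.drive_index == self.wild_index:
            raise ParameterError("drive and wild-type must be distinct alleles")
        if sus[self.drive_index] != 0.0:
            raise ParameterError("the drive allele cannot convert itself")
        if np.any(sus < 0) or np.any(sus > 1):
            raise ParameterError("susceptibilities must lie in [0, 1]")

    @property
    def n_alleles(self) -> int:
        return len(self.labels)

    @classmethod
    def standard(cls, conversion: float, resistance_level: float) -> "AlleleSet":
        """Drive / wild-type / resistant trio used by :class:`DriveScenario`."""
        return cls(
            labels=("drive", "wild-type", "resistant"),
            susceptibility=np.array([0.0, conversion, resistance_level]),
        )


def _validate_frequencies(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ParameterError("allele frequencies must be a 1-d vector of length >= 2")
    if np.any(p < -MASS_TOL) or np.any(p > 1 + MASS_TOL):
        raise ParameterError("allele frequencies must lie in [0, 1]")
    if abs(p.sum() - 1.0) > MASS_TOL:
        raise ParameterError(f"allele frequencies must sum to 1 (got {p.sum()!r})")
    return p


class GenotypeState:
    """Symmetric matrix of diploid genotype frequencies.

    Off-diagonal entry ``G[i, j] == G[j, i]`` holds the full frequency of the
    unordered heterozygote {i, j}; :meth:`total` therefore counts each
    heterozygote once.
    """

    __slots__ = ("G",)

    def __init__(self, G: np.ndarray, validate: bool = True):
        G = np.asarray(G, dtype=float)
        if validate:
            if G.ndim != 2 or G.shape[0] != G.shape[1]:
                raise ParameterError("genotype frequencies must form a square matrix")
            if not np.allclose(G, G.T, atol=MASS_TOL):
                raise ParameterError("genotype matrix must be symmetric")
            if np.any(G < -MASS_TOL):
                raise ParameterError("genotype frequencies must be non-negative")
            tot = np.trace(G) + 0.5 * (G.sum() - np.trace(G))
            if abs(tot - 1.0) > MASS_TOL:
                raise ParameterError(f"genotype mass must sum to 1 (got {tot!r})")
        self.G = G

    @property
    def n_alleles(self) -> int:
        return self.G.shape[0]

    @property
    def total(self) -> float:
        """Total genotype mass, counting each heterozygote once."""
        tr = np.trace(self.G)
        return tr + 0.5 * (self.G.sum() - tr)

    def allele_frequencies(self) -> np.ndarray:
        """Marginal allele frequencies (see :func:`genotypes_to_alleles`)."""
        return np.diag(self.G) + 0.5 * (self.G.sum(axis=1) - np.diag(self.G))

    def copy(self) -> "GenotypeState":
        return GenotypeState(self.G.copy(), validate=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeState(n_alleles={self.n_alleles}, total={self.total:.6f})"


@dataclass
class Trajectory:
    """Per-generation drive-allele frequency of a single simulation.

    ``drive_frequency[0]`` is the initial state, so the array has length
    ``generations + 1``.  ``allele_frequencies`` optionally carries the full
    per-generation frequency vector of every allele (same leading length).
    """

    drive_frequency: np.ndarray
    allele_frequencies: Optional[np.ndarray] = None
    scenario: Optional["DriveScenario"] = None

    def __post_init__(self):
        self.drive_frequency = np.asarray(self.drive_frequency, dtype=float)

    def __len__(self) -> int:
        return self.drive_frequency.size

    @property
    def generations(self) -> int:
        return len(self) - 1


# ---------------------------------------------------------------------------
# life-cycle operations
# ---------------------------------------------------------------------------


def form_zygotes(p: Sequence[float], F: float) -> GenotypeState:
    """Form diploid zygotes from gamete frequencies ``p`` with inbreeding ``F``.

    Homozygote frequency is ``p_i**2 + F * p_i * (1 - p_i)`` and heterozygote
    frequency is ``2 * (1 - F) * p_i * p_j`` — Hardy-Weinberg proportions with
    heterozygosity reduced by the factor ``1 - F``.  For two alleles this is
    the classical inbreeding correction; for more alleles the homozygote
    excess is ``F * p_i * (1 - p_i)``, which preserves the marginal allele
    frequencies exactly.
    """
    p = _validate_frequencies(p)
    if not 0.0 <= F <= 1.0:
        raise ParameterError(f"inbreeding coefficient must lie in [0, 1], got {F!r}")
    G = 2.0 * (1.0 - F) * np.outer(p, p)
    np.fill_diagonal(G, p**2 + F * p * (1.0 - p))
    return GenotypeState(G, validate=False)


def convert_heterozygotes(
    G: GenotypeState,
    alleles: AlleleSet,
    n: int,
    mode: str = STOCHASTIC,
    rng=None,
) -> GenotypeState:
    """Homing conversion of drive heterozygotes into drive homozygotes.

    For each heterozygote pairing the drive with a susceptible allele ``j``
    (susceptibility ``c_j > 0``), the converted mass is ``x / n`` with
    ``x ~ Binomial(n, c_j * G[drive, j])`` in stochastic mode, or its
    expectation ``c_j * G[drive, j]`` in deterministic mode.  The converted
    mass moves from the heterozygote to the drive homozygote; binomial
    overshoot beyond the available heterozygote mass is clamped.
    """
    _check_mode(mode)
    if n < 1:
        raise ParameterError("population size must be >= 1")
    out = G.G.copy()
    d = alleles.drive_index
    if mode == STOCHASTIC:
        rng = _as_rng(rng)
    for j in range(alleles.n_alleles):
        c_j = alleles.susceptibility[j]
        if j == d or c_j == 0.0:
            continue
        mass = out[d, j]
        if mode == STOCHASTIC:
            x = rng.binomial(n, min(c_j * mass, 1.0))
            delta = min(x / n, mass)
        else:
            delta = c_j * mass
        out[d, j] -= delta
        out[j, d] -= delta
        out[d, d] += delta
    return GenotypeState(out, validate=False)


def apply_selection(
    G: GenotypeState,
    s: float,
    e: float,
    d: float,
    alleles: AlleleSet,
    n: int,
    mode: str = STOCHASTIC,
    rng=None,
) -> GenotypeState:
    """Viability selection against drive-carrying genotypes.

    Genotypes without a drive allele have fitness 1 and are untouched before
    rescaling.  For each drive-carrying genotype the effective cost is
    ``d_eff * s`` where ``d_eff`` is the dominance ``d`` for heterozygotes
    and 1 for the drive homozygote.  Only the exposed fraction ``e`` of the
    genotype's carriers is at risk: the killed mass is ``x / n`` with
    ``x ~ Binomial(round(e * G_ij * n), d_eff * s)`` in stochastic mode, or
    ``e * G_ij * d_eff * s`` in deterministic mode.  After removal the whole
    genotype distribution is rescaled to sum to 1.
    """
    _check_mode(mode)
    for name, val in (("fitness cost", s), ("exposure rate", e), ("dominance", d)):
        if not 0.0 <= val <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1], got {val!r}")
    if n < 1:
        raise ParameterError("population size must be >= 1")
    out = G.G.copy()
    di = alleles.drive_index
    if mode == STOCHASTIC:
        rng = _as_rng(rng)
    removed_total = 0.0
    removals = []
    for j in range(alleles.n_alleles):
        d_eff = 1.0 if j == di else d
        mass = out[di, j]
        if mode == STOCHASTIC:
            trials = int(np.rint(e * mass * n))
            x = rng.binomial(trials, d_eff * s)
            killed = min(x / n, mass)
        else:
            killed = e * mass * d_eff * s
        removals.append((j, killed))
        removed_total += killed
    total = 1.0 - removed_total
    if total <= MASS_TOL:
        # selection would wipe out the whole population (drive fixed under a
        # fully exposed lethal cost); survivor frequencies are undefined, so
        # the state is left unchanged.
        return GenotypeState(out, validate=False)
    for j, killed in removals:
        out[di, j] -= killed
        if j != di:
            out[j, di] -= killed
    out /= total
    return GenotypeState(out, validate=False)


def genotypes_to_alleles(G: GenotypeState) -> np.ndarray:
    """Collapse genotype frequencies to marginal allele frequencies.

    ``p_i = G_ii + 1/2 * sum_{j != i} G_ij``, renormalized so the returned
    vector sums to exactly 1.  (Without renormalization the quadratic
    zygote-formation step amplifies rounding error in the total mass from
    one generation to the next.)
    """
    p = np.clip(G.allele_frequencies(), 0.0, None)
    return p / p.sum()


def apply_drift(
    p: Sequence[float],
    n: int,
    mode: str = STOCHASTIC,
    rng=None,
    method: str = "binomial",
    renormalize: bool = True,
) -> np.ndarray:
    """Wright-Fisher genetic drift on the gamete pool.

    In stochastic mode each allele is independently resampled as
    ``x_i / (2n)`` with ``x_i ~ Binomial(2n, p_i)``, and the drawn vector is
    renormalized to sum to 1 (independent per-allele draws do not conserve
    mass exactly); each raw draw has mean ``p_i`` and variance
    ``p_i (1 - p_i) / 2n``, and ``renormalize=False`` returns the raw
    ``x_i / 2n`` for inspecting those moments.  ``method="multinomial"``
    instead draws the ``2n`` gametes jointly from one multinomial, which
    conserves mass by construction.  Deterministic mode is the identity.
    Frequencies of exactly 0 or 1 are absorbing.
    """
    _check_mode(mode)
    p = _validate_frequencies(p)
    if n < 1:
        raise ParameterError("population size must be >= 1")
    if mode == DETERMINISTIC:
        return p.copy()
    rng = _as_rng(rng)
    two_n = 2 * int(n)
    if method == "binomial":
        x = rng.binomial(two_n, np.clip(p, 0.0, 1.0))
        if not renormalize:
            return x / two_n
        tot = x.sum()
        if tot == 0:
            # all draws empty (only possible at tiny n); keep the input pool
            return p.copy()
        return x / tot
    elif method == "multinomial":
        pv = np.clip(p, 0.0, None)
        pv = pv / pv.sum()
        x = rng.multinomial(two_n, pv)
        return x / two_n
    raise ParameterError(f"unknown drift method {method!r}")


def step_generation(p: Sequence[float], scenario: "DriveScenario", rng=None) -> np.ndarray:
    """Advance the allele-frequency vector by one full generation.

    Module order is zygote formation -> (post-zygotic: conversion) ->
    selection -> (pre-zygotic: conversion) -> collapse to alleles -> drift.
    """
    alleles = scenario.allele_set()
    n = scenario.population_size
    mode = scenario.mode
    post = scenario.timing == "postzygotic"
    G = form_zygotes(p, scenario.inbreeding)
    if post:
        G = convert_heterozygotes(G, alleles, n, mode, rng)
    G = apply_selection(
        G,
        scenario.fitness_cost,
        scenario.exposure,
        scenario.dominance,
        alleles,
        n,
        mode,
        rng,
    )
    if not post:
        G = convert_heterozygotes(G, alleles, n, mode, rng)
    p_next = genotypes_to_alleles(G)
    return apply_drift(p_next, n, mode, rng, method=scenario.drift_method)


def simulate(
    scenario: "DriveScenario",
    rng=None,
    record_alleles: bool = False,
    method: str = "fast",
) -> Trajectory:
    """Run a scenario for ``scenario.generations`` generations.

    Generation 0 is the initial allele-frequency state (drive at
    ``initial_drive_frequency``, resistant allele at
    ``resistance_frequency``, wild-type at the remainder).  Once the drive
    frequency hits exactly 0 the state is frozen for the remaining
    generations — with no mutation there is no way back.  The same seed and
    scenario always produce the same trajectory.

    ``method="fast"`` uses the vectorized batch engine; ``method="reference"``
    loops over the per-module operations above.  The two are algebraically
    identical and agree exactly in deterministic mode.
    """
    from .scenario import DriveScenario  # noqa: F401  (validation done there)

    if rng is None:
        rng = scenario.seed
    if method == "fast":
        from ._engine import ScenarioBatch, simulate_batch

        batch = ScenarioBatch.from_scenarios([scenario])
        traj, alle = simulate_batch(batch, rng=rng, record_alleles=record_alleles)
        return Trajectory(
            drive_frequency=traj[:, 0],
            allele_frequencies=alle[:, 0, :] if record_alleles else None,
            scenario=scenario,
        )
    if method != "reference":
        raise ParameterError(f"unknown simulate method {method!r}")
    rng = _as_rng(rng) if scenario.mode == STOCHASTIC else None
    p = scenario.initial_frequencies()
    T = scenario.generations
    drive = np.empty(T + 1)
    drive[0] = p[0]
    alle = np.empty((T + 1, p.size)) if record_alleles else None
    if record_alleles:
        alle[0] = p
    for t in range(1, T + 1):
        if p[0] == 0.0 or p[0] == 1.0:
            drive[t:] = p[0]
            if record_alleles:
                alle[t:] = p
            break
        p = step_generation(p, scenario, rng)
        drive[t] = p[0]
        if record_alleles:
            alle[t] = p
    return Trajectory(drive_frequency=drive, allele_frequencies=alle, scenario=scenario)
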