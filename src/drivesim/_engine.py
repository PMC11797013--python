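"""Vectorized batch engine for the drive / wild-type / resistant trio.

Simulates many scenarios simultaneously, one array element per scenario,
with the same per-generation semantics as the module-level operations in
:mod:`drivesim.core`.  Because conversion and selection only ever touch
genotypes that carry the drive allele, the engine tracks just the three
drive-carrying genotype frequencies (DD, DW, DR) plus the wild-type and
resistant marginal mass locked up in the drive-free block — the internal
composition of that block is irrelevant to the dynamics within one
generation.

Simulations whose drive frequency has hit an absorbing state (exactly 0 or
exactly 1) are frozen and dropped from the active set, which makes large
Monte Carlo batches cheap once most drives have been lost or fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np

from .errors import ParameterError

__all__ = ["ScenarioBatch", "simulate_batch"]

_FLOAT = np.float64


@dataclass
class ScenarioBatch:
    """Structure-of-arrays representation of a set of scenarios.

    The seven biological variables are arrays of shape ``(m,)``; run
    settings (population size, generations, initial drive frequency,
    timing, mode) are shared by the whole batch.
    """

    conversion: np.ndarray
    resistance_level: np.ndarray
    resistance_frequency: np.ndarray
    fitness_cost: np.ndarray
    exposure: np.ndarray
    dominance: np.ndarray
    inbreeding: np.ndarray
    population_size: int = 1_000_000
    generations: int = 500
    initial_drive_frequency: float = 0.001
    timing: str = "prezygotic"
    mode: str = "stochastic"
    drift_method: str = "binomial"

    def __post_init__(self):
        arrays = {}
        size = None
        for name in (
            "conversion",
            "resistance_level",
            "resistance_frequency",
            "fitness_cost",
            "exposure",
            "dominance",
            "inbreeding",
        ):
            a = np.atleast_1d(np.asarray(getattr(self, name), dtype=_FLOAT))
            arrays[name] = a
            if size is None:
                size = a.size
            elif a.size != size and a.size != 1:
                raise ParameterError("batch variable arrays must share one length")
        for name, a in arrays.items():
            setattr(self, name, np.broadcast_to(a, (size,)).copy() if a.size == 1 else a)
        if np.any(self.resistance_level > self.conversion + 1e-12):
            raise ParameterError("resistance_level cannot exceed conversion")
        if self.timing not in ("prezygotic", "postzygotic"):
            raise ParameterError(f"unknown timing {self.timing!r}")
        if self.mode not in ("stochastic", "deterministic"):
            raise ParameterError(f"unknown mode {self.mode!r}")

    @property
    def size(self) -> int:
        return self.conversion.size

    @classmethod
    def from_scenarios(cls, scenarios: Iterable) -> "ScenarioBatch":
        """Build a batch from DriveScenario objects sharing run settings."""
        scenarios = list(scenarios)
        if not scenarios:
            raise ParameterError("need at least one scenario")
        first = scenarios[0]
        for sc in scenarios[1:]:
            for attr in (
                "population_size",
                "generations",
                "initial_drive_frequency",
                "timing",
                "mode",
                "drift_method",
            ):
                if getattr(sc, attr) != getattr(first, attr):
                    raise ParameterError(
                        f"scenarios in one batch must share {attr}"
                    )
        get = lambda name: np.array([getattr(sc, name) for sc in scenarios], dtype=_FLOAT)
        return cls(
            conversion=get("conversion"),
            resistance_level=get("resistance_level"),
            resistance_frequency=get("resistance_frequency"),
            fitness_cost=get("fitness_cost"),
            exposure=get("exposure"),
            dominance=get("dominance"),
            inbreeding=get("inbreeding"),
            population_size=first.population_size,
            generations=first.generations,
            initial_drive_frequency=first.initial_drive_frequency,
            timing=first.timing,
            mode=first.mode,
            drift_method=first.drift_method,
        )


def _convert(Gdd, Ghet, rate, n, stochastic, rng):
    """Move converted mass from a drive heterozygote into DD (in place)."""
    if stochastic:
        x = rng.binomial(n, np.clip(rate * Ghet, 0.0, 1.0))
        delta = np.minimum(x / n, Ghet)
    else:
        delta = rate * Ghet
    return Gdd + delta, Ghet - delta


def simulate_batch(
    batch: ScenarioBatch,
    rng=None,
    record_alleles: bool = False,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Simulate every scenario in ``batch``.

    Returns ``(drive, alleles)`` where ``drive`` has shape
    ``(generations + 1, m)`` holding the drive allele frequency of every
    simulation at every generation, and ``alleles`` (if requested) has shape
    ``(generations + 1, m, 3)`` with the full drive/wild/resistant vectors.
    """
    m = batch.size
    stochastic = batch.mode == "stochastic"
    if stochastic and not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = int(batch.population_size)
    two_n = 2 * n
    T = int(batch.generations)
    post = batch.timing == "postzygotic"
    multinomial_drift = batch.drift_method == "multinomial"

    c = batch.conversion
    R = batch.resistance_level
    s = batch.fitness_cost
    e = batch.exposure
    dom = batch.dominance
    F = batch.inbreeding

    pd = np.full(m, batch.initial_drive_frequency, dtype=_FLOAT)
    pr = batch.resistance_frequency.astype(_FLOAT).copy()
    pw = 1.0 - pd - pr

    drive = np.empty((T + 1, m), dtype=_FLOAT)
    drive[0] = pd
    alle = None
    if record_alleles:
        alle = np.empty((T + 1, m, 3), dtype=_FLOAT)
        alle[0] = np.stack([pd, pw, pr], axis=1)

    active = (pd > 0.0) & (pd < 1.0)

    for t in range(1, T + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            drive[t:] = pd
            if record_alleles:
                alle[t:] = np.stack([pd, pw, pr], axis=1)
            break
        d_ = pd[idx]
        w_ = pw[idx]
        r_ = pr[idx]
        Fi = F[idx]
        ci = c[idx]
        Ri = R[idx]
        si = s[idx]
        ei = e[idx]
        domi = dom[idx]

        # zygote formation (only the drive-carrying genotypes are needed)
        het = 2.0 * (1.0 - Fi) * d_
        Gdd = d_ * d_ + Fi * d_ * (1.0 - d_)
        Gdw = het * w_
        Gdr = het * r_
        w_rest = w_ - 0.5 * Gdw
        r_rest = r_ - 0.5 * Gdr

        if post:
            Gdd, Gdw = _convert(Gdd, Gdw, ci, n, stochastic, rng)
            Gdd, Gdr = _convert(Gdd, Gdr, Ri, n, stochastic, rng)

        # selection: killed mass per drive genotype, then global rescale
        kill_het = domi * si
        if stochastic:
            t_dd = np.rint(ei * Gdd * n).astype(np.int64)
            t_dw = np.rint(ei * Gdw * n).astype(np.int64)
            t_dr = np.rint(ei * Gdr * n).astype(np.int64)
            k_dd = np.minimum(rng.binomial(t_dd, si) / n, Gdd)
            k_dw = np.minimum(rng.binomial(t_dw, kill_het) / n, Gdw)
            k_dr = np.minimum(rng.binomial(t_dr, kill_het) / n, Gdr)
        else:
            k_dd = ei * Gdd * si
            k_dw = ei * Gdw * kill_het
            k_dr = ei * Gdr * kill_het
        tot = 1.0 - (k_dd + k_dw + k_dr)
        wiped = tot <= 1e-12
        if wiped.any():
            # whole-population removal: leave those states unchanged
            k_dd = np.where(wiped, 0.0, k_dd)
            k_dw = np.where(wiped, 0.0, k_dw)
            k_dr = np.where(wiped, 0.0, k_dr)
            tot = np.where(wiped, 1.0, tot)
        Gdd = (Gdd - k_dd) / tot
        Gdw = (Gdw - k_dw) / tot
        Gdr = (Gdr - k_dr) / tot
        w_rest = w_rest / tot
        r_rest = r_rest / tot

        if not post:
            Gdd, Gdw = _convert(Gdd, Gdw, ci, n, stochastic, rng)
            Gdd, Gdr = _convert(Gdd, Gdr, Ri, n, stochastic, rng)

        # collapse to allele frequencies; renormalize so the vector sums to
        # exactly 1 (the quadratic zygote step otherwise amplifies rounding
        # error in the total mass exponentially)
        d_ = np.clip(Gdd + 0.5 * (Gdw + Gdr), 0.0, None)
        w_ = np.clip(w_rest + 0.5 * Gdw, 0.0, None)
        r_ = np.clip(r_rest + 0.5 * Gdr, 0.0, None)
        mass = d_ + w_ + r_
        d_ = d_ / mass
        w_ = w_ / mass
        r_ = r_ / mass

        if stochastic:
            if multinomial_drift:
                P = np.stack([d_, w_, r_], axis=1)
                P = np.clip(P, 0.0, None)
                P /= P.sum(axis=1, keepdims=True)
                counts = rng.multinomial(two_n, P)
                d_ = counts[:, 0] / two_n
                w_ = counts[:, 1] / two_n
                r_ = counts[:, 2] / two_n
            else:
                x_d = rng.binomial(two_n, np.clip(d_, 0.0, 1.0))
                x_w = rng.binomial(two_n, np.clip(w_, 0.0, 1.0))
                x_r = rng.binomial(two_n, np.clip(r_, 0.0, 1.0))
                tot_x = x_d + x_w + x_r
                empty = tot_x == 0
                if empty.any():
                    tot_x = np.where(empty, 1, tot_x)
                    nd = x_d / tot_x
                    nw = x_w / tot_x
                    nr = x_r / tot_x
                    d_ = np.where(empty, d_, nd)
                    w_ = np.where(empty, w_, nw)
                    r_ = np.where(empty, r_, nr)
                else:
                    d_ = x_d / tot_x
                    w_ = x_w / tot_x
                    r_ = x_r / tot_x
        pd[idx] = d_
        pw[idx] = w_
        pr[idx] = r_
        drive[t] = pd
        if record_alleles:
            alle[t] = np.stack([pd, pw, pr], axis=1)

        frozen = (d_ <= 0.0) | (d_ >= 1.0)
        if frozen.any():
            active[idx[frozen]] = False

    return drive, alle
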