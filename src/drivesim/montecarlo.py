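"""Monte Carlo sensitivity analysis over the seven-variable space.

Scenarios are drawn uniformly from the variable space (conversion, fitness
cost, exposure, dominance and inbreeding on [0, 1]; resistance frequency on
[0, 0.4]; resistance level as a uniform fraction of the drawn conversion),
simulated for 500 generations at population size one million, classified,
and tabulated.  Balanced per-outcome datasets support within-outcome
ordinary-least-squares regressions of the dynamics metrics (time to
maximum, final frequency, maximum frequency) on the seven variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterator, Optional

import numpy as np
import pandas as pd

from ._engine import ScenarioBatch, simulate_batch
from .errors import BudgetExceededError, CollinearityError, ParameterError
from .outcomes import CLASSIFIED_OUTCOMES, classify_batch, summarize_batch
from .scenario import DriveScenario, TIMINGS

__all__ = [
    "VARIABLES",
    "OutcomeTable",
    "sample_scenario",
    "run_monte_carlo",
    "outcome_frequencies",
    "balanced_sample",
    "regress_within_outcome",
    "RECORD_COLUMNS",
]

logger = logging.getLogger(__name__)

#: the seven sampled variables, in sampling order
VARIABLES = [
    "conversion",
    "resistance_level",
    "resistance_frequency",
    "fitness_cost",
    "exposure",
    "dominance",
    "inbreeding",
]

#: fixed column order of the records table / CSV export
RECORD_COLUMNS = [
    "conversion",
    "resistance_level",
    "resistance_ratio",
    "resistance_frequency",
    "fitness_cost",
    "exposure",
    "dominance",
    "inbreeding",
    "selection_pressure",
    "timing",
    "seed",
    "sim_index",
    "max_frequency",
    "time_to_max",
    "final_frequency",
    "gradient",
    "outcome",
]

DEFAULT_CHUNK_SIZE = 4096

_TIMING_CODE = {"prezygotic": 0, "postzygotic": 1}


def _check_timing(timing: str) -> None:
    if timing not in TIMINGS:
        raise ParameterError(f"timing must be one of {TIMINGS}, got {timing!r}")


def _draw_variables(rng: np.random.Generator, m: int, fixed: Optional[dict]) -> dict:
    """Uniform draws of the seven variables (plus the resistance ratio)."""
    draws = {
        "conversion": rng.uniform(0.0, 1.0, m),
        "resistance_ratio": rng.uniform(0.0, 1.0, m),
        "resistance_frequency": rng.uniform(0.0, 0.4, m),
        "fitness_cost": rng.uniform(0.0, 1.0, m),
        "exposure": rng.uniform(0.0, 1.0, m),
        "dominance": rng.uniform(0.0, 1.0, m),
        "inbreeding": rng.uniform(0.0, 1.0, m),
    }
    if fixed:
        for name, value in fixed.items():
            if name not in draws and name != "resistance_level":
                raise ParameterError(f"unknown variable {name!r}")
            draws[name] = np.full(m, float(value))
    draws["resistance_level"] = fixed.get("resistance_level") if fixed else None
    if draws["resistance_level"] is None:
        draws["resistance_level"] = draws["resistance_ratio"] * draws["conversion"]
    else:
        draws["resistance_level"] = np.full(m, float(draws["resistance_level"]))
    return draws


def sample_scenario(rng, timing: str = "prezygotic") -> DriveScenario:
    """Draw a single scenario from the variable-space distributions."""
    _check_timing(timing)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    d = _draw_variables(rng, 1, None)
    return DriveScenario(
        conversion=float(d["conversion"][0]),
        resistance_level=float(d["resistance_level"][0]),
        resistance_frequency=float(d["resistance_frequency"][0]),
        fitness_cost=float(d["fitness_cost"][0]),
        exposure=float(d["exposure"][0]),
        dominance=float(d["dominance"][0]),
        inbreeding=float(d["inbreeding"][0]),
        timing=timing,
    )


def _run_chunk(
    chunk_index: int,
    m: int,
    timing: str,
    root_seed: int,
    mode: str,
    fixed: Optional[dict],
    population_size: int,
    generations: int,
    initial_drive_frequency: float,
    gradient_method: str,
) -> pd.DataFrame:
    code = _TIMING_CODE[timing]
    sample_rng = np.random.default_rng(
        np.random.SeedSequence([root_seed, code, chunk_index, 0])
    )
    sim_rng = np.random.default_rng(
        np.random.SeedSequence([root_seed, code, chunk_index, 1])
    )
    draws = _draw_variables(sample_rng, m, fixed)
    batch = ScenarioBatch(
        conversion=draws["conversion"],
        resistance_level=draws["resistance_level"],
        resistance_frequency=draws["resistance_frequency"],
        fitness_cost=draws["fitness_cost"],
        exposure=draws["exposure"],
        dominance=draws["dominance"],
        inbreeding=draws["inbreeding"],
        population_size=population_size,
        generations=generations,
        initial_drive_frequency=initial_drive_frequency,
        timing=timing,
        mode=mode,
    )
    drive, _ = simulate_batch(batch, rng=sim_rng)
    stats = summarize_batch(drive, gradient_method=gradient_method)
    records = pd.DataFrame({name: draws[name] for name in VARIABLES})
    records["resistance_ratio"] = draws["resistance_ratio"]
    records["selection_pressure"] = records["fitness_cost"] * records["exposure"]
    records["timing"] = timing
    records["seed"] = root_seed
    records["sim_index"] = chunk_index * m + np.arange(m)
    for col in stats.columns:
        records[col] = stats[col].to_numpy()
    records["outcome"] = classify_batch(stats)
    return records[RECORD_COLUMNS]


def _chunk_stream(
    timing: str,
    root_seed: int,
    mode: str,
    chunk_size: int,
    fixed: Optional[dict],
    population_size: int,
    generations: int,
    initial_drive_frequency: float,
    gradient_method: str,
) -> Iterator[pd.DataFrame]:
    chunk_index = 0
    while True:
        yield _run_chunk(
            chunk_index,
            chunk_size,
            timing,
            root_seed,
            mode,
            fixed,
            population_size,
            generations,
            initial_drive_frequency,
            gradient_method,
        )
        chunk_index += 1


def run_monte_carlo(
    n_sims: int,
    timing: str = "prezygotic",
    root_seed: int = 0,
    *,
    mode: str = "stochastic",
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    fixed: Optional[dict] = None,
    population_size: int = 1_000_000,
    generations: int = 500,
    initial_drive_frequency: float = 0.001,
    gradient_method: str = "difference",
) -> pd.DataFrame:
    """Run ``n_sims`` independent sampled simulations and classify each.

    Simulation is vectorized in chunks of ``chunk_size`` scenarios; each
    chunk draws its variables and its binomial noise from generators seeded
    by ``(root_seed, timing, chunk_index)``, so a given seed always yields
    the same records.  ``fixed`` pins any subset of the seven variables to a
    constant instead of sampling it.
    """
    if n_sims < 1:
        raise ParameterError("n_sims must be >= 1")
    _check_timing(timing)
    chunks = []
    collected = 0
    stream = _chunk_stream(
        timing,
        root_seed,
        mode,
        chunk_size,
        fixed,
        population_size,
        generations,
        initial_drive_frequency,
        gradient_method,
    )
    for chunk in stream:
        chunks.append(chunk)
        collected += len(chunk)
        logger.info(
            "monte carlo %s: %d/%d simulations done", timing, min(collected, n_sims), n_sims
        )
        if collected >= n_sims:
            break
    records = pd.concat(chunks, ignore_index=True).iloc[:n_sims].copy()
    return records


@dataclass(frozen=True)
class OutcomeTable:
    """Percentage of simulations per outcome (0-100 scale).

    ``total`` is the sum of the four classified categories; the remainder up
    to 100% is unclassified.
    """

    loss: float
    fixation: float
    temporary: float
    equilibrium: float
    n_simulations: int

    @property
    def total(self) -> float:
        return self.loss + self.fixation + self.temporary + self.equilibrium

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "Loss": self.loss,
                "Fixation": self.fixation,
                "Temporary": self.temporary,
                "Equilibrium": self.equilibrium,
                "Total": self.total,
            },
            name="outcome frequency (%)",
        )

    def to_dict(self) -> dict:
        d = self.as_series().to_dict()
        d["n_simulations"] = self.n_simulations
        return d


def outcome_frequencies(records: pd.DataFrame) -> OutcomeTable:
    """Tabulate outcome percentages over a records table.

    Unclassified simulations stay in the denominator, so the classified
    total is below 100%.
    """
    if len(records) == 0:
        raise ParameterError("cannot tabulate outcome frequencies of zero records")
    counts = records["outcome"].value_counts()
    n = len(records)
    pct = {k: 100.0 * counts.get(k, 0) / n for k in CLASSIFIED_OUTCOMES}
    return OutcomeTable(
        loss=pct["loss"],
        fixation=pct["fixation"],
        temporary=pct["temporary"],
        equilibrium=pct["equilibrium"],
        n_simulations=n,
    )


def balanced_sample(
    n_per_outcome: int,
    timing: str = "prezygotic",
    root_seed: int = 0,
    max_attempts: Optional[int] = None,
    *,
    mode: str = "stochastic",
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    population_size: int = 1_000_000,
    generations: int = 500,
    initial_drive_frequency: float = 0.001,
    gradient_method: str = "difference",
) -> pd.DataFrame:
    """Sample until every classified outcome has ``n_per_outcome`` records.

    Keeps drawing fresh scenarios (in the same chunked, seeded way as
    :func:`run_monte_carlo`) and retains the first ``n_per_outcome`` records
    of each of the four classified outcomes; unclassified simulations are
    discarded.  Raises :class:`BudgetExceededError` naming the lagging
    outcome if the quota cannot be filled within ``max_attempts``
    simulations (default ``1000 * n_per_outcome``) — equilibrium, the rarest
    outcome by far, is the usual culprit.
    """
    if n_per_outcome < 1:
        raise ParameterError("n_per_outcome must be >= 1")
    _check_timing(timing)
    if max_attempts is None:
        max_attempts = 1000 * n_per_outcome
    kept: Dict[str, list] = {k: [] for k in CLASSIFIED_OUTCOMES}
    counts = {k: 0 for k in CLASSIFIED_OUTCOMES}
    attempts = 0
    stream = _chunk_stream(
        timing,
        root_seed,
        mode,
        chunk_size,
        None,
        population_size,
        generations,
        initial_drive_frequency,
        gradient_method,
    )
    for chunk in stream:
        attempts += len(chunk)
        for outcome in CLASSIFIED_OUTCOMES:
            need = n_per_outcome - counts[outcome]
            if need <= 0:
                continue
            sub = chunk[chunk["outcome"] == outcome].iloc[:need]
            if len(sub):
                kept[outcome].append(sub)
                counts[outcome] += len(sub)
        logger.info(
            "balanced sampling %s: %s after %d simulations", timing, counts, attempts
        )
        if all(counts[k] >= n_per_outcome for k in CLASSIFIED_OUTCOMES):
            break
        if attempts >= max_attempts:
            lagging = min(counts, key=counts.get)
            raise BudgetExceededError(
                f"could not collect {n_per_outcome} records per outcome within "
                f"{max_attempts} simulations; lagging outcome: {lagging!r} "
                f"({counts[lagging]}/{n_per_outcome})",
                lagging_outcome=lagging,
                counts=counts,
            )
    frames = [pd.concat(kept[k], ignore_index=True) for k in CLASSIFIED_OUTCOMES]
    return pd.concat(frames, ignore_index=True)


def regress_within_outcome(
    records: pd.DataFrame,
    outcome: str,
    response: str,
) -> pd.DataFrame:
    """OLS regression of a dynamics metric on the seven variables.

    Fits ``response ~ intercept + conversion + resistance_level +
    resistance_frequency + fitness_cost + exposure + dominance + inbreeding``
    on the records of one outcome (raw, unstandardized variable scales).
    Returns a table with the coefficient, standard error and p-value per
    variable.
    """
    import statsmodels.api as sm

    if response not in ("time_to_max", "final_frequency", "max_frequency"):
        raise ParameterError(f"unsupported response {response!r}")
    sub = records[records["outcome"] == outcome]
    if len(sub) < 100:
        raise ParameterError(
            f"need >= 100 records of outcome {outcome!r} to regress, got {len(sub)}"
        )
    X = sub[VARIABLES].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(sub)), X]))
    if rank < len(VARIABLES) + 1:
        constant = [v for v in VARIABLES if np.ptp(sub[v].to_numpy()) == 0.0]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (VARIABLES[i], VARIABLES[j])
            for i in range(len(VARIABLES))
            for j in range(i + 1, len(VARIABLES))
            if np.isfinite(corr[i, j]) and abs(corr[i, j]) > 1 - 1e-10
        ]
        raise CollinearityError(
            "design matrix is rank deficient; "
            f"constant variables: {constant or 'none'}, "
            f"perfectly correlated pairs: {pairs or 'none'}"
        )
    exog = sm.add_constant(sub[VARIABLES].astype(float))
    fit = sm.OLS(sub[response].astype(float), exog).fit()
    return pd.DataFrame(
        {
            "coefficient": fit.params,
            "std_error": fit.bse,
            "p_value": fit.pvalues,
        }
    )
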