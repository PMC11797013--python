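"""Trajectory summary statistics and categorical outcome assignment.

A 500-generation drive-frequency trajectory is reduced to four numbers —
maximum frequency, time to maximum, final frequency, and the gradient (mean
per-generation change over the last 20 generations) — and those numbers map
to one of five categories:

- ``fixation``     final frequency > 0.90
- ``loss``         maximum frequency < 0.10
- ``temporary``    maximum frequency > 0.30 and final frequency < 0.10
- ``equilibrium``  final frequency in [0.10, 0.90) and |gradient| < 1e-4
- ``unclassified`` anything else (e.g. a maximum between 0.10 and 0.30, or
  a drive still climbing at generation 500)

The rules are mutually exclusive by construction: fixation and equilibrium
are separated at 0.90, loss/temporary demand a final below 0.10 while
equilibrium demands at least 0.10, and loss/temporary are separated by the
maximum.  Threshold comparisons are strict except the lower equilibrium
bound, so values exactly on a threshold fall to ``unclassified``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Trajectory
from .errors import ParameterError

__all__ = [
    "SummaryStats",
    "OUTCOMES",
    "GRADIENT_WINDOW",
    "summarize",
    "classify",
    "classify_trajectory",
    "summarize_batch",
    "classify_batch",
]

#: categorical outcomes, the four classified ones first
OUTCOMES = ("loss", "fixation", "temporary", "equilibrium", "unclassified")
CLASSIFIED_OUTCOMES = OUTCOMES[:4]

GRADIENT_WINDOW = 20

FIXATION_FINAL = 0.90
LOSS_MAX = 0.10
TEMPORARY_MAX = 0.30
TEMPORARY_FINAL = 0.10
EQUILIBRIUM_FINAL_LOW = 0.10
EQUILIBRIUM_FINAL_HIGH = 0.90
EQUILIBRIUM_GRADIENT = 1e-4


@dataclass(frozen=True)
class SummaryStats:
    """Summary of one drive-frequency trajectory."""

    max_frequency: float
    time_to_max: int
    final_frequency: float
    gradient: float

    def __post_init__(self):
        if self.final_frequency > self.max_frequency + 1e-12:
            raise ParameterError("final frequency cannot exceed the maximum")
        if self.time_to_max < 0:
            raise ParameterError("time_to_max must be a non-negative generation index")


def _drive_series(traj) -> np.ndarray:
    if isinstance(traj, Trajectory):
        return traj.drive_frequency
    return np.asarray(traj, dtype=float)


def summarize(traj, gradient_method: str = "difference") -> SummaryStats:
    """Compute the summary statistics of a trajectory.

    The gradient is the mean per-generation change over the final
    ``GRADIENT_WINDOW`` generations, ``(p_T - p_{T-20}) / 20``
    (``gradient_method="difference"``), or alternatively the least-squares
    slope over the last 21 points (``gradient_method="slope"``).  Both
    estimators agree for a linear tail; the difference form is the default.
    """
    p = _drive_series(traj)
    if p.size < GRADIENT_WINDOW + 1:
        raise ParameterError(
            f"trajectory must span at least {GRADIENT_WINDOW} generations "
            f"({GRADIENT_WINDOW + 1} entries), got {p.size}"
        )
    max_f = float(p.max())
    ttm = int(p.argmax())
    final = float(p[-1])
    tail = p[-(GRADIENT_WINDOW + 1):]
    if gradient_method == "difference":
        grad = (tail[-1] - tail[0]) / GRADIENT_WINDOW
    elif gradient_method == "slope":
        x = np.arange(tail.size, dtype=float)
        grad = float(np.polyfit(x, tail, 1)[0])
    else:
        raise ParameterError(f"unknown gradient method {gradient_method!r}")
    return SummaryStats(max_f, ttm, final, float(grad))


def classify(stats: SummaryStats) -> str:
    """Assign the categorical outcome for one set of summary statistics."""
    if stats.final_frequency > FIXATION_FINAL:
        return "fixation"
    if stats.max_frequency < LOSS_MAX:
        return "loss"
    if stats.max_frequency > TEMPORARY_MAX and stats.final_frequency < TEMPORARY_FINAL:
        return "temporary"
    if (
        EQUILIBRIUM_FINAL_LOW <= stats.final_frequency < EQUILIBRIUM_FINAL_HIGH
        and abs(stats.gradient) < EQUILIBRIUM_GRADIENT
    ):
        return "equilibrium"
    return "unclassified"


def classify_trajectory(traj, gradient_method: str = "difference") -> str:
    """Convenience wrapper: summarize then classify."""
    return classify(summarize(traj, gradient_method=gradient_method))


# ---------------------------------------------------------------------------
# vectorized versions for Monte Carlo batches
# ---------------------------------------------------------------------------


def summarize_batch(drive: np.ndarray, gradient_method: str = "difference") -> pd.DataFrame:
    """Summaries of a ``(generations + 1, m)`` trajectory matrix, one row per column."""
    drive = np.asarray(drive, dtype=float)
    if drive.ndim != 2 or drive.shape[0] < GRADIENT_WINDOW + 1:
        raise ParameterError(
            "expected a (generations + 1, m) matrix spanning >= "
            f"{GRADIENT_WINDOW} generations"
        )
    tail = drive[-(GRADIENT_WINDOW + 1):]
    if gradient_method == "difference":
        grad = (tail[-1] - tail[0]) / GRADIENT_WINDOW
    elif gradient_method == "slope":
        x = np.arange(tail.shape[0], dtype=float)
        xc = x - x.mean()
        grad = xc @ (tail - tail.mean(axis=0)) / (xc @ xc)
    else:
        raise ParameterError(f"unknown gradient method {gradient_method!r}")
    return pd.DataFrame(
        {
            "max_frequency": drive.max(axis=0),
            "time_to_max": drive.argmax(axis=0),
            "final_frequency": drive[-1],
            "gradient": grad,
        }
    )


def classify_batch(stats: pd.DataFrame) -> np.ndarray:
    """Vectorized outcome assignment on the output of :func:`summarize_batch`."""
    max_f = stats["max_frequency"].to_numpy()
    final = stats["final_frequency"].to_numpy()
    grad = stats["gradient"].to_numpy()
    conditions = [
        final > FIXATION_FINAL,
        max_f < LOSS_MAX,
        (max_f > TEMPORARY_MAX) & (final < TEMPORARY_FINAL),
        (final >= EQUILIBRIUM_FINAL_LOW)
        & (final < EQUILIBRIUM_FINAL_HIGH)
        & (np.abs(grad) < EQUILIBRIUM_GRADIENT),
    ]
    choices = ["fixation", "loss", "temporary", "equilibrium"]
    return np.select(conditions, choices, default="unclassified")
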