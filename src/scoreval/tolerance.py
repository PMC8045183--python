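"""Noise-injection tolerance simulation.

How much extra score noise can the classifier absorb before its decision
performance degrades?  The simulation answers this in two separable stages:

1. *noise generation* — i.i.d. Gaussian noise of a given SD is added to every
   patient score of a labelled validation cohort (one draw per patient per
   replicate);
2. *metric computation* — the noisy scores are re-classified and diagnostic
   metrics are computed against the zero-noise baseline calls.

The two stages repeat ``n_reps`` times per noise SD on a grid spanning
0.01-10 score units; the median of each metric across replicates forms the
tolerance curve.  The *maximum allowable SD* is the largest noise SD at which
every product requirement (default: PPV of intermediate-to-high
up-classification >= 50%) still holds on the median metrics, refined between
grid points by bisection on freshly simulated medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import derive_seed, substream
from .domain import (
    DecisionPolicy,
    PerformanceMetrics,
    classify_scores,
    fraction_of_range,
    metrics_matrix,
)
from .errors import ConfigError, DataError

__all__ = [
    "NoiseGrid",
    "Requirement",
    "ToleranceCurve",
    "DEFAULT_REQUIREMENTS",
    "run_noise_injection",
    "max_allowable_sd",
    "first_failure_mode",
    "NO_TOLERANCE",
    "NO_FAILURE",
]

NO_TOLERANCE = "no tolerance"
NO_FAILURE = "no failure"


@dataclass(frozen=True)
class NoiseGrid:
    """Grid of injected-noise SDs with a replicate count per grid point."""

    sd_values: Tuple[float, ...] = tuple(np.logspace(np.log10(0.01), np.log10(10.0), 40))
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        sd = np.asarray(self.sd_values, dtype=float)
        if sd.size < 1 or np.any(sd <= 0) or np.any(np.diff(sd) <= 0):
            raise DataError("sd_values must be strictly increasing and positive")
        if self.n_reps < 1:
            raise DataError("n_reps must be >= 1")


@dataclass(frozen=True)
class Requirement:
    """A named lower bound on one median performance metric."""

    metric: str
    bound: float

    def holds(self, value: float) -> bool:
        # an undefined (NaN) median is a failure, never a silent pass
        return bool(np.isfinite(value) and value >= self.bound)


DEFAULT_REQUIREMENTS: Tuple[Requirement, ...] = (
    Requirement("ppv_intermediate_up", 0.50),
)


@dataclass
class ToleranceCurve:
    """Median metrics per injected-noise SD, plus the inputs to refine them.

    ``table`` has one row per grid SD with a column per metric (NaN where the
    metric was undefined in more than half the replicates) and
    ``<metric>_n_defined`` columns counting the defined replicates.
    """

    table: pd.DataFrame
    requirements: Tuple[Requirement, ...]
    policy: DecisionPolicy
    grid: NoiseGrid
    scores: np.ndarray = field(repr=False)
    pre_level: np.ndarray = field(repr=False)
    malignant: np.ndarray = field(repr=False)
    baseline_calls: np.ndarray = field(repr=False)
    pooled_arms: bool = True
    max_allowable: Optional[float] = None
    max_allowable_pct_of_range: Optional[float] = None
    first_failure: Optional[str] = None

    def passes_at(self, row: Mapping[str, float]) -> bool:
        return all(req.holds(row[req.metric]) for req in self.requirements)

    def summary(self) -> dict:
        return {
            "max_allowable_sd": self.max_allowable,
            "max_allowable_pct_of_range": self.max_allowable_pct_of_range,
            "first_failure": self.first_failure,
            "requirements": {r.metric: r.bound for r in self.requirements},
            "n_reps": self.grid.n_reps,
            "n_patients": int(self.pre_level.size),
        }


def _simulate_medians(
    scores: np.ndarray,
    pre_level: np.ndarray,
    malignant: np.ndarray,
    baseline: np.ndarray,
    policy: DecisionPolicy,
    sd: float,
    n_reps: int,
    rng: np.random.Generator,
    pooled_arms: bool = True,
) -> dict:
    """Stage 1 + stage 2 at one noise SD: medians of each metric over reps."""
    noisy = scores[None, :] + rng.normal(0.0, sd, (n_reps, scores.size))
    calls = classify_scores(noisy, pre_level[None, :], policy)
    m = metrics_matrix(calls, pre_level, malignant, baseline, pooled_arms=pooled_arms)
    out = {}
    for k, v in m.items():
        defined = np.isfinite(v)
        out[k + "_n_defined"] = int(defined.sum())
        # median over defined replicates; all-undefined => NaN (a requirement
        # failure at this grid point, not an exception)
        out[k] = float(np.nanmedian(v)) if defined.any() else float("nan")
    return out


def _cohort_arrays(cohort: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    for col in ("pre_test", "truth", "score"):
        if col not in cohort.columns:
            raise DataError(f"cohort table missing column {col!r}")
    level_map = {"low": 1, "intermediate": 2, "high": 3}
    try:
        pre = cohort["pre_test"].map(level_map).to_numpy(dtype=int)
    except (TypeError, ValueError) as exc:
        raise DataError(f"unknown pre-test group in cohort: {exc}") from exc
    mal = (cohort["truth"] == "malignant").to_numpy()
    scores = cohort["score"].to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        raise DataError("cohort scores must be finite")
    return scores, pre, mal


def run_noise_injection(
    cohort: pd.DataFrame,
    policy: DecisionPolicy,
    grid: NoiseGrid = NoiseGrid(),
    requirements: Sequence[Requirement] = DEFAULT_REQUIREMENTS,
    pooled_arms: bool = True,
) -> ToleranceCurve:
    """Tolerance curve of median metrics across the noise grid.

    Baseline calls are computed once at zero noise; each grid point draws
    ``grid.n_reps`` noisy replicates of the cohort from its own seeded
    substream, so the curve is deterministic given (cohort, policy, grid).
    """
    if len(cohort) == 0:
        raise DataError("cohort is empty")
    names = set(PerformanceMetrics.metric_names())
    for req in requirements:
        if req.metric not in names:
            raise ConfigError(f"requirement references unknown metric {req.metric!r}")
    scores, pre, mal = _cohort_arrays(cohort)
    baseline = classify_scores(scores, pre, policy)
    rows = []
    for i, sd in enumerate(grid.sd_values):
        rng = substream(grid.seed, "noise", f"{i}")
        row = _simulate_medians(
            scores, pre, mal, baseline, policy, sd, grid.n_reps, rng, pooled_arms
        )
        row["sd"] = float(sd)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("sd", drop=False)
    curve = ToleranceCurve(
        table=table,
        requirements=tuple(requirements),
        policy=policy,
        grid=grid,
        scores=scores,
        pre_level=pre,
        malignant=mal,
        baseline_calls=baseline,
        pooled_arms=pooled_arms,
    )
    return curve


def max_allowable_sd(
    curve: ToleranceCurve,
    requirements: Optional[Sequence[Requirement]] = None,
    tol: float = 1e-3,
) -> Tuple["float | str", Optional[float]]:
    """Largest noise SD at which all requirements hold on median metrics.

    Scans the grid for the last passing point; when a later grid point fails,
    the pass/fail boundary is refined by bisection on freshly simulated
    medians (fixed derived seed, same replicate count).  Returns
    ``(sd, pct_of_range)``, or ``(NO_TOLERANCE, None)`` when the requirements
    already fail at the smallest grid SD.

    The result is stored on the curve (``max_allowable``,
    ``max_allowable_pct_of_range``).
    """
    reqs = tuple(requirements) if requirements is not None else curve.requirements
    tab = curve.table
    passing = np.array(
        [all(r.holds(row[r.metric]) for r in reqs) for _, row in tab.iterrows()]
    )
    sds = tab["sd"].to_numpy()
    if not passing[0]:
        curve.max_allowable = None
        curve.max_allowable_pct_of_range = None
        return NO_TOLERANCE, None
    if passing.all():
        sd = float(sds[-1])
        pct = fraction_of_range(sd, curve.policy)
        curve.max_allowable, curve.max_allowable_pct_of_range = sd, pct
        return sd, pct

    first_fail = int(np.argmin(passing))  # first False
    lo, hi = float(sds[first_fail - 1]), float(sds[first_fail])
    rng_seed = derive_seed(curve.grid.seed, "refine")
    it = 0
    while hi - lo > tol and it < 60:
        mid = 0.5 * (lo + hi)
        rng = np.random.default_rng(derive_seed(rng_seed, f"{it}"))
        row = _simulate_medians(
            curve.scores,
            curve.pre_level,
            curve.malignant,
            curve.baseline_calls,
            curve.policy,
            mid,
            curve.grid.n_reps,
            rng,
            curve.pooled_arms,
        )
        if all(r.holds(row[r.metric]) for r in reqs):
            lo = mid
        else:
            hi = mid
        it += 1
    pct = fraction_of_range(lo, curve.policy)
    curve.max_allowable, curve.max_allowable_pct_of_range = lo, pct
    return lo, pct


def first_failure_mode(
    curve: ToleranceCurve, requirements: Optional[Sequence[Requirement]] = None
) -> str:
    """Name of the requirement that fails at the smallest grid SD.

    Ties at the same grid point break by requirement declaration order;
    returns :data:`NO_FAILURE` when every requirement holds over the whole
    grid.  Stored on the curve (``first_failure``).
    """
    reqs = tuple(requirements) if requirements is not None else curve.requirements
    best: Optional[Tuple[int, int]] = None  # (grid index, declaration index)
    for j, req in enumerate(reqs):
        fails = ~np.array([req.holds(v) for v in curve.table[req.metric]])
        if fails.any():
            i = int(np.argmax(fails))
            if best is None or (i, j) < best:
                best = (i, j)
    result = NO_FAILURE if best is None else reqs[best[1]].metric
    curve.first_failure = None if best is None else result
    return result
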