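"""Core score-domain model.

A continuous classifier score refines a physician-assessed pre-test risk of
malignancy (low < 10%, intermediate 10-60%, high > 60%) into a post-test risk
category (very low / low / intermediate / high / very high).  Each pre-test
group can move at most one level down or up, so the decision policy is a small
set of per-group score cuts on a score scale whose nominal training-set span
is 4.57 units.

This module houses the record types, the reclassification decision policy,
diagnostic performance metrics over a labelled cohort, and score-range
arithmetic.  Everything here is deterministic; the vectorised entry points
(:func:`classify_scores`, :func:`metrics_matrix`) are what the noise-injection
simulation calls in its inner loop.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "PreTestGroup",
    "PostTestCategory",
    "DecisionPolicy",
    "ScoreRecord",
    "CohortRecord",
    "PerformanceMetrics",
    "REACHABLE",
    "classify",
    "classify_scores",
    "reclassification_direction",
    "compute_performance_metrics",
    "metrics_matrix",
    "fraction_of_range",
    "round_percent",
    "pre_levels",
]

#: Default nominal classifier score span (training-set range).
DEFAULT_SCORE_RANGE = 4.57


class PreTestGroup(enum.Enum):
    """Physician pre-test malignancy-risk group.

    ``level`` places the group on the common 0-4 risk ladder shared with
    :class:`PostTestCategory`, so the reclassification direction is simply
    the level difference.  ``risk_interval`` is the malignancy-probability
    interval (%, half-open) the group represents.
    """

    LOW = ("low", 1, (0.0, 10.0))
    INTERMEDIATE = ("intermediate", 2, (10.0, 60.0))
    HIGH = ("high", 3, (60.0, 100.0))

    def __init__(self, label: str, level: int, risk_interval: tuple):
        self.label = label
        self.level = level
        self.risk_interval = risk_interval

    @classmethod
    def from_label(cls, label: "str | PreTestGroup") -> "PreTestGroup":
        if isinstance(label, cls):
            return label
        for g in cls:
            if g.label == str(label).strip().lower():
                return g
        raise DataError(f"unknown pre-test group {label!r}")


class PostTestCategory(enum.Enum):
    """Post-test risk category on the 0-4 ladder."""

    VERY_LOW = ("very_low", 0)
    LOW = ("low", 1)
    INTERMEDIATE = ("intermediate", 2)
    HIGH = ("high", 3)
    VERY_HIGH = ("very_high", 4)

    def __init__(self, label: str, level: int):
        self.label = label
        self.level = level

    @classmethod
    def from_level(cls, level: int) -> "PostTestCategory":
        for c in cls:
            if c.level == level:
                return c
        raise DataError(f"no post-test category at level {level}")

    @classmethod
    def from_label(cls, label: "str | PostTestCategory") -> "PostTestCategory":
        if isinstance(label, cls):
            return label
        for c in cls:
            if c.label == str(label).strip().lower():
                return c
        raise DataError(f"unknown post-test category {label!r}")


#: Post-test categories reachable from each pre-test group (one level down,
#: stay, or one level up; low/high groups have a single boundary each).
REACHABLE: Mapping[PreTestGroup, tuple] = {
    PreTestGroup.LOW: (PostTestCategory.VERY_LOW, PostTestCategory.LOW),
    PreTestGroup.INTERMEDIATE: (
        PostTestCategory.LOW,
        PostTestCategory.INTERMEDIATE,
        PostTestCategory.HIGH,
    ),
    PreTestGroup.HIGH: (PostTestCategory.HIGH, PostTestCategory.VERY_HIGH),
}


@dataclass(frozen=True)
class DecisionPolicy:
    """Per-group score cuts mapping a continuous score to a post-test category.

    The published assay does not disclose its decision boundaries; these
    defaults are a surrogate policy on a zero-centred scale spanning
    ``score_range`` units, and every cut is overridable (including from a
    YAML/JSON config, see :mod:`scoreval.io`).

    ``boundary_rule`` resolves a score falling exactly on a cut:
    ``"stay"`` (default) keeps the un-reclassified category, ``"reclassify"``
    moves it.
    """

    score_range: float = DEFAULT_SCORE_RANGE
    low_down_cut: float = -0.5
    intermediate_down_cut: float = -0.3
    intermediate_up_cut: float = 0.9
    high_up_cut: float = 1.2
    boundary_rule: str = "stay"

    def __post_init__(self):
        if self.score_range <= 0:
            raise ConfigError("score_range must be positive")
        if not self.intermediate_down_cut < self.intermediate_up_cut:
            raise ConfigError(
                "intermediate down cut must lie below the intermediate up cut"
            )
        if self.boundary_rule not in ("stay", "reclassify"):
            raise ConfigError(
                f"boundary_rule must be 'stay' or 'reclassify', got {self.boundary_rule!r}"
            )

    def cuts_for(self, group: PreTestGroup) -> Mapping[str, float]:
        """Decision boundaries relevant to one pre-test group."""
        if group is PreTestGroup.LOW:
            return {"down": self.low_down_cut}
        if group is PreTestGroup.INTERMEDIATE:
            return {"down": self.intermediate_down_cut, "up": self.intermediate_up_cut}
        return {"up": self.high_up_cut}

    # -- config (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "score_range": self.score_range,
            "thresholds": {
                "low": {"down": self.low_down_cut},
                "intermediate": {
                    "down": self.intermediate_down_cut,
                    "up": self.intermediate_up_cut,
                },
                "high": {"up": self.high_up_cut},
            },
            "boundary_rule": self.boundary_rule,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DecisionPolicy":
        try:
            th = d.get("thresholds", {})
            return cls(
                score_range=float(d.get("score_range", DEFAULT_SCORE_RANGE)),
                low_down_cut=float(th.get("low", {}).get("down", cls.low_down_cut)),
                intermediate_down_cut=float(
                    th.get("intermediate", {}).get("down", cls.intermediate_down_cut)
                ),
                intermediate_up_cut=float(
                    th.get("intermediate", {}).get("up", cls.intermediate_up_cut)
                ),
                high_up_cut=float(th.get("high", {}).get("up", cls.high_up_cut)),
                boundary_rule=str(d.get("boundary_rule", "stay")),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid decision-policy config: {exc}") from exc


@dataclass(frozen=True)
class ScoreRecord:
    """One classifier-score measurement with its design coordinates."""

    sample_id: str
    lab_id: str
    run_id: str
    replicate_id: str
    condition: str
    score: float

    def __post_init__(self):
        if not math.isfinite(self.score):
            raise DataError(
                f"non-finite score {self.score!r} for sample {self.sample_id!r}"
            )

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.lab_id, self.run_id, self.replicate_id, self.condition)


@dataclass(frozen=True)
class CohortRecord:
    """One validation patient: pre-test group, truth label, score."""

    patient_id: str
    pre_test: PreTestGroup
    truth: str  # "malignant" | "benign"
    score: float

    def __post_init__(self):
        if self.truth not in ("malignant", "benign"):
            raise DataError(f"truth must be 'malignant' or 'benign', got {self.truth!r}")
        if not math.isfinite(self.score):
            raise DataError(f"non-finite score for patient {self.patient_id!r}")


@dataclass(frozen=True)
class PerformanceMetrics:
    """Diagnostic performance of the reclassification calls on a cohort.

    Down-classification is the "test-negative" event over the pooled low and
    intermediate pre-test arms: sensitivity = P(not down | malignant),
    specificity = P(down | benign), NPV = P(benign | down).  The two PPVs
    condition on the up-classified calls of the intermediate and high arms.
    A metric whose denominator is empty is ``None`` (flagged undefined), never
    silently 0.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    npv: Optional[float]
    ppv_intermediate_up: Optional[float]
    ppv_high_up: Optional[float]
    pct_down_classified: Optional[float]
    pct_up_classified: Optional[float]
    flip_rate: Optional[float]

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def metric_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify(score: float, pre_test: PreTestGroup, policy: DecisionPolicy) -> PostTestCategory:
    """Map one score to its post-test category under the policy.

    Monotone within each group: a higher score never yields a lower-risk
    category.  A score exactly on a cut follows ``policy.boundary_rule``.
    """
    if not math.isfinite(score):
        raise DataError(f"cannot classify non-finite score {score!r}")
    pre_test = PreTestGroup.from_label(pre_test)
    level = int(
        classify_scores(np.array([score]), np.array([pre_test.level]), policy)[0]
    )
    return PostTestCategory.from_level(level)


def classify_scores(
    scores: np.ndarray, pre_level: np.ndarray, policy: DecisionPolicy
) -> np.ndarray:
    """Vectorised :func:`classify` on category levels.

    Parameters
    ----------
    scores
        Array of scores, any shape.
    pre_level
        Integer array broadcastable against ``scores`` holding pre-test group
        levels (low=1, intermediate=2, high=3).

    Returns
    -------
    Integer array of post-test levels (very_low=0 ... very_high=4).
    """
    scores = np.asarray(scores, dtype=float)
    pre_level = np.asarray(pre_level)
    if not np.all(np.isfinite(scores)):
        raise DataError("cannot classify non-finite scores")
    strict = policy.boundary_rule == "stay"
    below = np.less if strict else np.less_equal
    above = np.greater if strict else np.greater_equal

    post = np.broadcast_to(pre_level, np.broadcast_shapes(scores.shape, pre_level.shape)).copy()
    scores = np.broadcast_to(scores, post.shape)

    low = pre_level == PreTestGroup.LOW.level
    post = np.where(low & below(scores, policy.low_down_cut), 0, post)
    inter = pre_level == PreTestGroup.INTERMEDIATE.level
    post = np.where(inter & below(scores, policy.intermediate_down_cut), 1, post)
    post = np.where(inter & above(scores, policy.intermediate_up_cut), 3, post)
    high = pre_level == PreTestGroup.HIGH.level
    post = np.where(high & above(scores, policy.high_up_cut), 4, post)
    return post


def reclassification_direction(
    pre_test: PreTestGroup, post_test: PostTestCategory
) -> str:
    """Direction of the call relative to pre-test risk: 'down', 'none' or 'up'."""
    pre_test = PreTestGroup.from_label(pre_test)
    post_test = PostTestCategory.from_label(post_test)
    if post_test not in REACHABLE[pre_test]:
        raise DataError(
            f"post-test {post_test.label!r} is not reachable from pre-test {pre_test.label!r}"
        )
    delta = post_test.level - pre_test.level
    return {-1: "down", 0: "none", 1: "up"}[delta]


# ---------------------------------------------------------------------------
# performance metrics
# ---------------------------------------------------------------------------

def pre_levels(cohort: Sequence[CohortRecord]) -> np.ndarray:
    return np.array([r.pre_test.level for r in cohort], dtype=int)


def metrics_matrix(
    calls: np.ndarray,
    pre_level: np.ndarray,
    malignant: np.ndarray,
    baseline_calls: np.ndarray,
    pooled_arms: bool = True,
) -> dict:
    """Per-replicate metrics for a (n_reps, n_patients) matrix of calls.

    The workhorse of the noise-injection simulation: each row of ``calls`` is
    one simulated replicate of the whole cohort.  Undefined metrics (empty
    denominator) are NaN.

    ``pooled_arms=True`` evaluates sensitivity/specificity/NPV on the pooled
    low+intermediate arm (the down-classification arm); ``False`` restricts
    them to the intermediate arm alone.
    """
    calls = np.atleast_2d(np.asarray(calls))
    baseline = np.asarray(baseline_calls)
    pre = np.asarray(pre_level)
    mal = np.asarray(malignant, dtype=bool)
    if calls.shape[-1] != pre.shape[0] or baseline.shape[-1] != pre.shape[0]:
        raise DataError(
            f"calls ({calls.shape[-1]}), baseline ({baseline.shape[-1]}) and cohort "
            f"({pre.shape[0]}) lengths must match"
        )

    down = calls < pre
    up = calls > pre
    if pooled_arms:
        arm = pre <= PreTestGroup.INTERMEDIATE.level
    else:
        arm = pre == PreTestGroup.INTERMEDIATE.level

    def ratio(num, den):
        num = num.astype(float)
        den = den.astype(float)
        return np.where(den > 0, num / np.maximum(den, 1), np.nan)

    mal_arm = mal & arm
    ben_arm = ~mal & arm
    sens = ratio((~down & mal_arm).sum(-1), np.broadcast_to(mal_arm.sum(), calls.shape[:-1]))
    spec = ratio((down & ben_arm).sum(-1), np.broadcast_to(ben_arm.sum(), calls.shape[:-1]))
    npv = ratio((down & ben_arm).sum(-1), (down & arm).sum(-1))

    int_up = (pre == PreTestGroup.INTERMEDIATE.level) & (calls == PostTestCategory.HIGH.level)
    high_up = (pre == PreTestGroup.HIGH.level) & (calls == PostTestCategory.VERY_HIGH.level)
    ppv_int = ratio((int_up & mal).sum(-1), int_up.sum(-1))
    ppv_high = ratio((high_up & mal).sum(-1), high_up.sum(-1))

    n = pre.shape[0]
    return {
        "sensitivity": sens,
        "specificity": spec,
        "npv": npv,
        "ppv_intermediate_up": ppv_int,
        "ppv_high_up": ppv_high,
        "pct_down_classified": down.sum(-1) / n,
        "pct_up_classified": up.sum(-1) / n,
        "flip_rate": (calls != baseline).sum(-1) / n,
    }


def compute_performance_metrics(
    cohort: Sequence[CohortRecord],
    calls: Sequence[PostTestCategory],
    baseline_calls: Sequence[PostTestCategory],
    pooled_arms: bool = True,
) -> PerformanceMetrics:
    """Diagnostic metrics of one set of calls against a labelled cohort.

    ``calls`` and ``baseline_calls`` must align with ``cohort``; the baseline
    is the zero-noise reference used for the flip rate.
    """
    if len(calls) != len(cohort) or len(baseline_calls) != len(cohort):
        raise DataError(
            f"cohort ({len(cohort)}), calls ({len(calls)}) and baseline "
            f"({len(baseline_calls)}) must have equal length"
        )
    pre = pre_levels(cohort)
    for c, rec in zip(calls, cohort):
        reclassification_direction(rec.pre_test, c)  # validates reachability
    call_lv = np.array([PostTestCategory.from_label(c).level for c in calls])
    base_lv = np.array([PostTestCategory.from_label(c).level for c in baseline_calls])
    mal = np.array([r.truth == "malignant" for r in cohort])
    m = metrics_matrix(call_lv[None, :], pre, mal, base_lv, pooled_arms=pooled_arms)
    vals = {k: (None if np.isnan(v[0]) else float(v[0])) for k, v in m.items()}
    return PerformanceMetrics(**vals)


# ---------------------------------------------------------------------------
# score-range arithmetic
# ---------------------------------------------------------------------------

def fraction_of_range(sd: float, policy: "DecisionPolicy | float" = None) -> float:
    """Express a score SD as a percentage of the classifier score range.

    ``policy`` may be a :class:`DecisionPolicy` or the numeric range itself
    (default: the nominal 4.57-unit span).
    """
    if sd < 0:
        raise DataError(f"sd must be non-negative, got {sd}")
    if policy is None:
        rng = DEFAULT_SCORE_RANGE
    elif isinstance(policy, DecisionPolicy):
        rng = policy.score_range
    else:
        rng = float(policy)
    if rng <= 0:
        raise ConfigError("score range must be positive")
    return 100.0 * sd / rng


def round_percent(pct: float, ndigits: int = 1) -> float:
    """Round a percentage half away from zero (so 9.923 -> 9.9, 3.85 -> 3.9)."""
    q = 10.0 ** ndigits
    return math.copysign(math.floor(abs(pct) * q + 0.5) / q, pct)
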