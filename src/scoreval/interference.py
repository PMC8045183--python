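"""Interference analysis: fixed-effect condition testing and admixture curves.

Two ways a contaminant or protocol deviation can disturb the classifier:

* a *condition effect* — a fixed per-level shift ``b_j`` shared by all
  samples (RNA input amount, %gDNA by mass), tested by a blocked two-way
  ANOVA on the model ``score = mu_i + b_j + residual`` (no sample:condition
  interaction term; the residual pools within-cell and sample x level
  variation, classical balanced-design degrees of freedom);

* an *admixture dose-response* — a contaminant (blood RNA scores in the
  high/malignant region) pulls the score of a mixed sample monotonically
  towards its own score as its proportion grows.  A monotone curve is fitted
  through the dilution-series scores and inverted against the decision
  boundaries of the sample's pre-test group to find the smallest contaminant
  proportion that alters the classifier call ("flip threshold"); a boundary
  the curve never crosses on [0, 1] reports "no call change".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .domain import DecisionPolicy, PostTestCategory, PreTestGroup, classify
from .errors import ComputationError, DataError

__all__ = [
    "InterferenceTestResult",
    "AdmixtureSeries",
    "FittedCurve",
    "FlipThreshold",
    "FlipThresholdReport",
    "test_condition_effect",
    "fit_admixture_curve",
    "invert_threshold",
]

NO_CALL_CHANGE = "no call change"


# ---------------------------------------------------------------------------
# condition-effect ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InterferenceTestResult:
    """Blocked-ANOVA test of a fixed condition effect on classifier scores."""

    f_statistic: float
    df_numerator: int
    df_denominator: int
    p_value: float
    significant: bool
    alpha: float
    level_effects: Mapping[str, float]  # sum-to-zero deviations per level
    n_obs: int = 0

    def as_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "df_numerator": self.df_numerator,
            "df_denominator": self.df_denominator,
            "p_value": self.p_value,
            "significant": self.significant,
            "alpha": self.alpha,
            "level_effects": dict(self.level_effects),
            "n_obs": self.n_obs,
        }


def test_condition_effect(records: pd.DataFrame, alpha: float = 0.05) -> InterferenceTestResult:
    """F-test of the condition effect in ``score = mu_i + b_j + residual``.

    ``records`` needs columns ``sample_id``, ``condition`` and ``score`` and
    must be balanced: every sample measured at every level with a common
    replicate count (balance makes the sample and condition sums of squares
    orthogonal, so the blocked decomposition is exact).
    """
    df = records
    for col in ("sample_id", "condition", "score"):
        if col not in df.columns:
            raise DataError(f"missing required column {col!r}")
    counts = df.groupby(["sample_id", "condition"], sort=True).size()
    samples = df["sample_id"].unique()
    levels = df["condition"].unique()
    if len(levels) < 2:
        raise DataError("at least two condition levels are required")
    expected = len(samples) * len(levels)
    if len(counts) != expected:
        present = set(counts.index)
        missing = [
            (s, l) for s in samples for l in levels if (s, l) not in present
        ]
        raise DataError(f"missing sample x condition cells: {missing[:5]}")
    if counts.nunique() != 1:
        raise DataError(
            "unbalanced replicate counts per sample x condition cell: "
            f"{sorted(counts.unique())}"
        )

    y = df["score"].to_numpy(dtype=float)
    grand = y.mean()
    n = y.size
    lvl_means = df.groupby("condition", sort=True)["score"].mean()
    smp_means = df.groupby("sample_id", sort=True)["score"].mean()
    n_per_level = n // len(levels)
    n_per_sample = n // len(samples)

    ss_cond = n_per_level * ((lvl_means - grand) ** 2).sum()
    ss_sample = n_per_sample * ((smp_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_resid = ss_total - ss_cond - ss_sample

    df_num = len(levels) - 1
    df_den = n - len(samples) - len(levels) + 1
    ms_resid = ss_resid / df_den
    if ms_resid == 0.0:
        f = 0.0 if ss_cond == 0.0 else np.inf
    else:
        f = (ss_cond / df_num) / ms_resid
    p = float(stats.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0
    effects = {str(k): float(v - grand) for k, v in lvl_means.items()}
    return InterferenceTestResult(
        f_statistic=float(f),
        df_numerator=df_num,
        df_denominator=df_den,
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
        level_effects=effects,
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# admixture series and monotone curve fit
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureSeries:
    """Dilution series of one base sample mixed with one contaminant.

    ``points`` holds (proportion, replicate scores) pairs with proportions in
    [0, 1]; the fitted curve (attached by :func:`fit_admixture_curve`) is a
    monotone function of the contaminant proportion.
    """

    base_id: str
    contaminant_id: str
    pre_test: PreTestGroup
    points: List[Tuple[float, np.ndarray]]
    fitted_curve: Optional["FittedCurve"] = None
    fit_residual_sd: Optional[float] = None

    def proportions(self) -> np.ndarray:
        return np.array([p for p, _ in self.points], dtype=float)

    def mean_scores(self) -> np.ndarray:
        return np.array([np.mean(s) for _, s in self.points], dtype=float)

    def flat(self) -> Tuple[np.ndarray, np.ndarray]:
        ps, ys = [], []
        for p, scores in self.points:
            scores = np.atleast_1d(scores)
            ps.extend([p] * len(scores))
            ys.extend(scores)
        return np.array(ps, dtype=float), np.array(ys, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, scores in self.points:
            for k, s in enumerate(np.atleast_1d(scores)):
                rows.append(
                    {
                        "base_id": self.base_id,
                        "contaminant_id": self.contaminant_id,
                        "pre_test": self.pre_test.label,
                        "proportion": p,
                        "replicate_id": f"rep_{k + 1}",
                        "score": float(s),
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class FittedCurve:
    """Monotone fitted dose-response curve on the proportion domain [0, 1].

    ``family`` is ``"4pl"`` (four-parameter logistic in the proportion:
    ``f(p) = a + (d - a) / (1 + exp(-k (p - m)))``, inherently monotone),
    ``"linear"``, or ``"interp"`` (monotone piecewise-linear interpolation of
    per-proportion means, the fallback for sparse designs).
    """

    family: str
    params: tuple
    fit_residual_sd: float
    _fn: Callable[[np.ndarray], np.ndarray] = field(repr=False, compare=False, default=None)

    def __call__(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self._fn(p)


def _fourpl(p, a, d, k, m):
    z = np.clip(-k * (np.asarray(p, dtype=float) - m), -700.0, 700.0)
    return a + (d - a) / (1.0 + np.exp(z))


def fit_admixture_curve(
    series: "AdmixtureSeries | Sequence[Tuple[float, np.ndarray]]",
    monotone_tolerance: float = 0.25,
) -> FittedCurve:
    """Least-squares monotone curve through a dilution series.

    Fits the four-parameter logistic family (multi-start on the slope) and a
    straight line, keeping whichever has the lower residual sum of squares
    (ties prefer the line, so exactly linear data reproduces the line with
    zero residual).  With fewer than four distinct proportions the fit falls
    back to monotone piecewise-linear interpolation of per-proportion means.

    Per-proportion means that reverse direction by more than
    ``monotone_tolerance`` times the observed span raise a warning; the fit
    then proceeds on the per-proportion means.
    """
    if isinstance(series, AdmixtureSeries):
        points = series.points
    else:
        points = [(float(p), np.atleast_1d(s)) for p, s in series]
    if len(points) < 3:
        raise DataError("at least three distinct proportions are required")
    props = np.array([p for p, _ in points])
    if np.unique(props).size != props.size:
        raise DataError("duplicate proportions in series")
    order = np.argsort(props)
    points = [points[i] for i in order]
    props = props[order]
    means = np.array([np.mean(s) for _, s in points])

    span = means.max() - means.min()
    direction = np.sign(means[-1] - means[0]) or 1.0
    reversals = -direction * np.diff(means)
    fit_on_means = False
    if span > 0 and np.any(reversals > monotone_tolerance * span):
        warnings.warn(
            "admixture series is non-monotone beyond tolerance; "
            "fitting on per-proportion means",
            stacklevel=2,
        )
        fit_on_means = True

    if fit_on_means:
        ps, ys = props, means
    else:
        ps, ys = AdmixtureSeries("", "", PreTestGroup.LOW, points).flat()

    if np.unique(props).size < 4:
        # isotone piecewise-linear interpolation of per-proportion means
        mono = np.maximum.accumulate(means) if direction > 0 else np.minimum.accumulate(means)
        fn = lambda p, xp=props, fp=mono: np.interp(np.asarray(p, dtype=float), xp, fp)
        resid = ys - fn(ps)
        return FittedCurve("interp", tuple(mono), float(np.sqrt(np.mean(resid**2))), fn)

    # linear candidate
    lin = np.polynomial.Polynomial.fit(ps, ys, 1).convert()
    sse_lin = float(((ys - lin(ps)) ** 2).sum())

    # 4PL candidates, multi-start on slope magnitude
    a0, d0 = means[0], means[-1]
    best = None
    for k0 in (1.0, 4.0, 10.0, 30.0):
        try:
            res = optimize.least_squares(
                lambda th: _fourpl(ps, *th) - ys,
                x0=[a0, d0, direction * k0, 0.5],
                method="lm" if len(ys) >= 4 else "trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=20000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    sse_4pl = 2 * best.cost if best is not None else np.inf

    dof = max(len(ys) - 2, 1)
    if best is None or sse_lin <= sse_4pl + 1e-12:
        fn = lambda p, c=lin: c(np.asarray(p, dtype=float))
        return FittedCurve(
            "linear", tuple(lin.coef), float(np.sqrt(sse_lin / dof)), fn
        )
    a, d, k, m = best.x
    dof = max(len(ys) - 4, 1)
    fn = lambda p, th=(a, d, k, m): _fourpl(np.asarray(p, dtype=float), *th)
    return FittedCurve("4pl", (float(a), float(d), float(k), float(m)),
                       float(np.sqrt(sse_4pl / dof)), fn)


# ---------------------------------------------------------------------------
# threshold inversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlipThreshold:
    """Flip threshold for one decision boundary of one pre-test group."""

    pre_test: str
    boundary: str            # "down" or "up"
    cut: float
    post_test: str           # category reached once the boundary is crossed
    threshold_proportion: Optional[float]  # None => no call change on [0, 1]
    direction: Optional[str]  # induced call change: "up" / "down"

    @property
    def threshold_pct(self) -> Optional[float]:
        if self.threshold_proportion is None:
            return None
        return 100.0 * self.threshold_proportion

    def describe(self) -> str:
        if self.threshold_proportion is None:
            return NO_CALL_CHANGE
        return f"{round(self.threshold_pct):d}%"


@dataclass(frozen=True)
class FlipThresholdReport:
    """Per-boundary flip thresholds estimated from a fitted admixture curve."""

    base_id: str
    contaminant_id: str
    pre_test: str
    baseline_call: str
    thresholds: Tuple[FlipThreshold, ...]

    def as_dict(self) -> dict:
        return {
            "base_id": self.base_id,
            "contaminant_id": self.contaminant_id,
            "pre_test": self.pre_test,
            "baseline_call": self.baseline_call,
            "thresholds": [
                {
                    "boundary": t.boundary,
                    "cut": t.cut,
                    "post_test": t.post_test,
                    "threshold_proportion": t.threshold_proportion,
                    "threshold_pct": t.threshold_pct,
                    "direction": t.direction,
                    "display": t.describe(),
                }
                for t in self.thresholds
            ],
        }


def _crossing(curve: FittedCurve, cut: float, tol: float = 1e-6) -> Optional[float]:
    """Smallest p in [0, 1] at which the monotone curve crosses ``cut``."""
    f0, f1 = float(curve(0.0)) - cut, float(curve(1.0)) - cut
    if f0 == 0.0:
        return 0.0
    if f0 * f1 > 0:
        return None
    if f1 == 0.0 and f0 * f1 == 0.0 and f0 != 0.0:
        return 1.0
    root = optimize.brentq(lambda p: float(curve(p)) - cut, 0.0, 1.0, xtol=tol)
    return float(root)


def invert_threshold(
    curve: FittedCurve,
    policy: DecisionPolicy,
    pre_test: PreTestGroup,
    base_id: str = "base",
    contaminant_id: str = "contaminant",
) -> FlipThresholdReport:
    """Contaminant proportion needed to alter the call, per decision boundary.

    For each boundary of the pre-test group, the smallest p in [0, 1] at
    which the noise-free fitted curve crosses the cut (bisection to 1e-6); a
    boundary never crossed reports "no call change".
    """
    if curve is None:
        raise DataError("curve must be fitted before inversion")
    pre_test = PreTestGroup.from_label(pre_test)
    base_call = classify(float(curve(0.0)), pre_test, policy)
    out = []
    for boundary, cut in policy.cuts_for(pre_test).items():
        p_star = _crossing(curve, cut)
        # crossing at the baseline itself is not a call change
        if p_star is not None and p_star == 0.0:
            p_star = _crossing(curve, cut, tol=1e-9) or None
        if p_star is None:
            post, direction = None, None
        else:
            rising = float(curve(1.0)) >= float(curve(0.0))
            below = PostTestCategory.from_level(
                pre_test.level - 1 if boundary == "down" else pre_test.level
            )
            above = PostTestCategory.from_level(
                pre_test.level if boundary == "down" else pre_test.level + 1
            )
            post = above if rising else below
            direction = "up" if post.level > base_call.level else "down"
            post = post.label
        out.append(
            FlipThreshold(
                pre_test=pre_test.label,
                boundary=boundary,
                cut=cut,
                post_test=post if post else NO_CALL_CHANGE,
                threshold_proportion=p_star,
                direction=direction,
            )
        )
    return FlipThresholdReport(
        base_id=base_id,
        contaminant_id=contaminant_id,
        pre_test=pre_test.label,
        baseline_call=base_call.label,
        thresholds=tuple(out),
    )
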