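"""Variance-component estimation for reproducibility and inter-lab studies.

Reproducibility tables follow the crossed mixed model
``score = mu_i + run_j + (sample:run)_ij + residual_ijk`` with fixed sample
means and random run, interaction and residual effects.  On the balanced
samples x runs x replicates layout the components are estimated in closed
form by equating observed mean squares to their expectations
(method of moments / expected mean squares):

    sigma2_residual    = MS_within
    sigma2_interaction = (MS_interaction - MS_within) / r
    sigma2_run         = (MS_run - MS_interaction) / (r * n_samples)

Between-run variability is reported as the composition
``sigma_inter = sqrt(sigma2_run + sigma2_interaction)`` and the total as
``sigma_total = sqrt(sigma2_residual + sigma2_inter)``; negative moment
solutions are truncated to zero and flagged.  Confidence intervals come from
a residual bootstrap: the model's residual terms at every level (run and
interaction predictions, within-cell residuals), reflated to their estimated
variances, are resampled with replacement, re-added to the fitted sample
means, and the components re-estimated (percentile interval).

The inter-laboratory study uses the one-way model ``score = mu_i + eps`` on
samples paired across two labs; its residual SD pools over labs with
``N_obs - n_samples`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .domain import fraction_of_range
from .errors import ComputationError, DataError

__all__ = [
    "VarianceDecomposition",
    "InterlabResult",
    "ConcordanceResult",
    "compose_sd",
    "decompose_variance",
    "bootstrap_ci",
    "interlab_sd",
    "concordance",
]

COMPONENTS = ("intra", "run", "interaction", "inter", "total")


def compose_sd(*sds: float) -> float:
    """Orthogonal composition of independent SDs: sqrt(sum of squares)."""
    return float(np.sqrt(np.sum(np.square(np.asarray(sds, dtype=float)))))


@dataclass(frozen=True)
class VarianceDecomposition:
    """Estimated intra-run, run, interaction, inter-run and total score SDs.

    ``sigma_inter**2 = sigma_run**2 + sigma_interaction**2`` and
    ``sigma_total**2 = sigma_intra**2 + sigma_inter**2`` hold exactly by
    construction.  ``truncated`` lists components whose moment estimate was
    negative and was clipped to zero.
    """

    sigma_intra: float
    sigma_run: float
    sigma_interaction: float
    n_samples: int
    n_runs: int
    n_replicates: int
    truncated: Tuple[str, ...] = ()
    ci: Optional[Mapping[str, Tuple[float, float]]] = None
    n_boot: int = 0

    @property
    def sigma_inter(self) -> float:
        return compose_sd(self.sigma_run, self.sigma_interaction)

    @property
    def sigma_total(self) -> float:
        return compose_sd(self.sigma_intra, self.sigma_inter)

    def sigma(self, component: str) -> float:
        return {
            "intra": self.sigma_intra,
            "run": self.sigma_run,
            "interaction": self.sigma_interaction,
            "inter": self.sigma_inter,
            "total": self.sigma_total,
        }[component]

    def as_dict(self, score_range: Optional[float] = None) -> dict:
        out = {
            "components": {c: self.sigma(c) for c in COMPONENTS},
            "design": {
                "n_samples": self.n_samples,
                "n_runs": self.n_runs,
                "n_replicates": self.n_replicates,
            },
            "flags": {"truncated": list(self.truncated)},
            "n_boot": self.n_boot,
        }
        if self.ci is not None:
            out["ci"] = {k: list(v) for k, v in self.ci.items()}
        if score_range is not None:
            out["pct_of_range"] = {
                c: fraction_of_range(self.sigma(c), score_range) for c in COMPONENTS
            }
        return out


# ---------------------------------------------------------------------------
# balanced-table plumbing
# ---------------------------------------------------------------------------

def _to_array(records: pd.DataFrame) -> Tuple[np.ndarray, list, list]:
    """Pivot a balanced score table to an (a, b, r) array, sorted by ids.

    Raises :class:`DataError` naming the violated design requirement when the
    table is unbalanced, incomplete or single-replicate.
    """
    df = records
    for col in ("sample_id", "run_id", "score"):
        if col not in df.columns:
            raise DataError(f"missing required column {col!r}")
    counts = df.groupby(["sample_id", "run_id"], sort=True).size()
    samples = sorted(df["sample_id"].unique())
    runs = sorted(df["run_id"].unique())
    if len(samples) < 2 or len(runs) < 2:
        raise DataError("the crossed design needs >= 2 samples and >= 2 runs")
    if len(counts) != len(samples) * len(runs):
        present = set(counts.index)
        missing = [(s, r) for s in samples for r in runs if (s, r) not in present][:5]
        raise DataError(f"incomplete design, missing sample x run cells: {missing}")
    if counts.nunique() != 1:
        raise DataError(
            f"unbalanced replicate counts per cell: {sorted(counts.unique())}"
        )
    r = int(counts.iloc[0])
    if r < 2:
        raise DataError(
            "within-cell replication (>= 2 replicates per sample x run cell) "
            "is required to separate intra-run from interaction variance"
        )
    ordered = df.sort_values(["sample_id", "run_id", "replicate_id"] if "replicate_id" in df else ["sample_id", "run_id"])
    y = ordered["score"].to_numpy(dtype=float).reshape(len(samples), len(runs), r)
    return y, samples, runs


def _components_from_array(y: np.ndarray) -> dict:
    """EMS variance components for arrays of shape (..., a, b, r).

    Vectorised over leading dimensions; returns variance-scale arrays plus
    truncation masks.
    """
    a, b, r = y.shape[-3:]
    cell = y.mean(-1)
    samp = cell.mean(-1)
    run = cell.mean(-2)
    grand = cell.mean((-1, -2))
    ms_within = ((y - cell[..., None]) ** 2).sum((-1, -2, -3)) / (a * b * (r - 1))
    ms_run = a * r * ((run - grand[..., None]) ** 2).sum(-1) / (b - 1)
    inter = cell - samp[..., :, None] - run[..., None, :] + grand[..., None, None]
    ms_int = r * (inter**2).sum((-1, -2)) / ((a - 1) * (b - 1))
    v_res = ms_within
    v_int_raw = (ms_int - ms_within) / r
    v_run_raw = (ms_run - ms_int) / (r * a)
    return {
        "v_res": v_res,
        "v_int": np.maximum(v_int_raw, 0.0),
        "v_run": np.maximum(v_run_raw, 0.0),
        "trunc_int": v_int_raw < 0,
        "trunc_run": v_run_raw < 0,
    }


def decompose_variance(
    records: pd.DataFrame,
    n_boot: int = 0,
    level: float = 0.95,
    seed: int = 0,
) -> VarianceDecomposition:
    """Estimate the variance decomposition of a balanced reproducibility table.

    With ``n_boot > 0`` a residual bootstrap attaches percentile confidence
    intervals for every reported component (including the composed inter-run
    and total SDs, bootstrapped on the composed statistic).
    """
    y, samples, runs = _to_array(records)
    comp = _components_from_array(y)
    trunc = tuple(
        name for name, flag in (("interaction", comp["trunc_int"]), ("run", comp["trunc_run"]))
        if bool(flag)
    )
    vd = VarianceDecomposition(
        sigma_intra=float(np.sqrt(comp["v_res"])),
        sigma_run=float(np.sqrt(comp["v_run"])),
        sigma_interaction=float(np.sqrt(comp["v_int"])),
        n_samples=len(samples),
        n_runs=len(runs),
        n_replicates=y.shape[-1],
        truncated=trunc,
    )
    if n_boot:
        ci = bootstrap_ci(records, "varcomp", n_boot=n_boot, level=level, seed=seed)
        vd = VarianceDecomposition(
            **{
                **{f: getattr(vd, f) for f in (
                    "sigma_intra", "sigma_run", "sigma_interaction",
                    "n_samples", "n_runs", "n_replicates", "truncated",
                )},
                "ci": ci,
                "n_boot": n_boot,
            }
        )
    return vd


# ---------------------------------------------------------------------------
# residual bootstrap
# ---------------------------------------------------------------------------

def _resample_crossed(y: np.ndarray, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Bootstrap tables from the crossed model by level-wise residual resampling.

    The fitted decomposition splits the table into fixed sample means plus
    three residual sets (run deviations, interaction deviations, within-cell
    residuals).  Each set is reflated to its variance-component estimate,
    sorted into canonical order (record order therefore never matters), and
    resampled with replacement independently per bootstrap replicate.
    """
    a, b, r = y.shape
    comp = _components_from_array(y)
    samp = y.mean((1, 2))
    grand = y.mean()
    run_dev = y.mean((0, 2)) - grand
    inter_dev = (y.mean(-1) - samp[:, None] - y.mean((0, 2))[None, :] + grand).ravel()
    resid = (y - y.mean(-1, keepdims=True)).ravel()

    def reflate(x, target):
        m2 = float((x**2).mean())
        if m2 == 0.0 or target == 0.0:
            return np.zeros_like(x)
        return np.sort(x * np.sqrt(target / m2))

    bd = reflate(run_dev, float(comp["v_run"]))
    wd = reflate(inter_dev, float(comp["v_int"]))
    ed = reflate(resid, float(comp["v_res"]))
    bs = bd[rng.integers(0, b, (n_boot, 1, b, 1))]
    ws = wd[rng.integers(0, a * b, (n_boot, a, b, 1))]
    es = ed[rng.integers(0, a * b * r, (n_boot, a, b, r))]
    return samp[None, :, None, None] + bs + ws + es


def _percentile_interval(draws: np.ndarray, level: float) -> Tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def bootstrap_ci(
    records: pd.DataFrame,
    estimator: "str | Callable[[np.ndarray], Mapping[str, float]]" = "varcomp",
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> Mapping[str, Tuple[float, float]]:
    """Residual-bootstrap percentile CIs for the variance components.

    For the crossed model every random term is a model residual at its own
    level: the run-effect predictions, the interaction predictions, and the
    within-cell residuals.  Each set is reflated so its resampling second
    moment equals the corresponding variance-component estimate (a residual
    set drawn from a fitted mean under-disperses; reflation keeps the
    bootstrap distribution centred on the point estimates), then each is
    resampled with replacement and re-added to the fixed sample means, and
    the estimator re-run on each of the ``n_boot`` synthetic tables.  The
    one-way inter-lab model has a single residual level, rescaled by the
    usual leverage factor ``sqrt(m / (m - 1))``.

    ``estimator`` is ``"varcomp"`` (vectorised fast path), ``"interlab"``, or
    a callable mapping an (a, b, r) score array to named statistics.
    """
    if n_boot < 100:
        raise DataError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)

    if estimator == "interlab":
        y, samples = _interlab_array(records)
        fitted = y.mean(-1, keepdims=True)
        m = y.shape[-1]
        # residuals from an m-observation mean have variance sigma^2 (1 - 1/m)
        resid = np.sort(((y - fitted) * np.sqrt(m / (m - 1))).ravel())
        idx = rng.integers(0, resid.size, (n_boot,) + y.shape)
        yb = fitted[None] + resid[idx]
        n_obs = y.size
        sig = np.sqrt(((yb - yb.mean(-1, keepdims=True)) ** 2).sum((-1, -2)) / (n_obs - len(samples)))
        return {"interlab": _percentile_interval(sig, level)}

    y, _, _ = _to_array(records)
    yb = _resample_crossed(y, n_boot, rng)

    if estimator == "varcomp":
        comp = _components_from_array(yb)
        draws = {
            "intra": np.sqrt(comp["v_res"]),
            "run": np.sqrt(comp["v_run"]),
            "interaction": np.sqrt(comp["v_int"]),
            "inter": np.sqrt(comp["v_run"] + comp["v_int"]),
            "total": np.sqrt(comp["v_res"] + comp["v_run"] + comp["v_int"]),
        }
        return {k: _percentile_interval(v, level) for k, v in draws.items()}

    # generic callable path
    rows: dict = {}
    failures = 0
    for bidx in range(n_boot):
        try:
            est = estimator(yb[bidx])
        except Exception:
            failures += 1
            continue
        for k, v in est.items():
            rows.setdefault(k, []).append(v)
    if failures > 0.01 * n_boot:
        raise ComputationError(
            f"estimator failed on {failures}/{n_boot} bootstrap replicates"
        )
    return {k: _percentile_interval(np.asarray(v), level) for k, v in rows.items()}


# ---------------------------------------------------------------------------
# inter-laboratory model
# ---------------------------------------------------------------------------

def _interlab_array(records: pd.DataFrame) -> Tuple[np.ndarray, list]:
    df = records
    for col in ("sample_id", "lab_id", "score"):
        if col not in df.columns:
            raise DataError(f"missing required column {col!r}")
    labs = sorted(df["lab_id"].unique())
    if len(labs) != 2:
        raise DataError(f"exactly two labs are required, found {labs}")
    per_sample = df.groupby("sample_id")["lab_id"].nunique()
    missing = sorted(per_sample[per_sample < 2].index.tolist())
    if missing:
        raise DataError(f"samples measured in only one lab: {missing[:10]}")
    counts = df.groupby(["sample_id", "lab_id"], sort=True).size()
    if counts.nunique() != 1:
        raise DataError(
            f"unbalanced replicate counts per sample x lab: {sorted(counts.unique())}"
        )
    r = int(counts.iloc[0])
    samples = sorted(df["sample_id"].unique())
    ordered = df.sort_values(
        ["sample_id", "lab_id", "replicate_id"] if "replicate_id" in df else ["sample_id", "lab_id"]
    )
    y = ordered["score"].to_numpy(dtype=float).reshape(len(samples), 2 * r)
    return y, samples


@dataclass(frozen=True)
class InterlabResult:
    """Pooled residual SD of the paired-laboratory one-way model."""

    sigma: float
    df: int
    n_samples: int
    n_obs: int
    ci: Optional[Tuple[float, float]] = None

    def as_dict(self, score_range: Optional[float] = None) -> dict:
        out = {
            "sigma_interlab": self.sigma,
            "df": self.df,
            "n_samples": self.n_samples,
            "n_obs": self.n_obs,
        }
        if self.ci is not None:
            out["ci"] = list(self.ci)
        if score_range is not None:
            out["pct_of_range"] = fraction_of_range(self.sigma, score_range)
        return out


def interlab_sd(
    records: pd.DataFrame,
    n_boot: int = 0,
    level: float = 0.95,
    seed: int = 0,
) -> InterlabResult:
    """Residual SD of ``score = mu_i + eps`` pooled across two laboratories.

    Degrees of freedom are ``N_obs - n_samples``; the CI (``n_boot > 0``) is a
    residual bootstrap.
    """
    y, samples = _interlab_array(records)
    n_obs = y.size
    dfree = n_obs - len(samples)
    ss = ((y - y.mean(-1, keepdims=True)) ** 2).sum()
    sigma = float(np.sqrt(ss / dfree))
    ci = None
    if n_boot:
        ci = bootstrap_ci(records, "interlab", n_boot=n_boot, level=level, seed=seed)["interlab"]
    return InterlabResult(sigma=sigma, df=dfree, n_samples=len(samples), n_obs=n_obs, ci=ci)


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceResult:
    """Between-laboratory call concordance and score correlation."""

    n_calls: int
    n_discordant: int
    discordance_rate: float
    acceptance_bound: float
    passed: bool
    r_squared: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "n_calls": self.n_calls,
            "n_discordant": self.n_discordant,
            "discordance_rate": self.discordance_rate,
            "acceptance_bound": self.acceptance_bound,
            "pass": self.passed,
            "r_squared": self.r_squared,
        }


def concordance(
    calls_a: Sequence,
    calls_b: Sequence,
    scores_a: Optional[Sequence[float]] = None,
    scores_b: Optional[Sequence[float]] = None,
    acceptance_bound: float = 0.15,
) -> ConcordanceResult:
    """Call discordance rate between two laboratories, vs. an acceptance bound.

    ``r_squared`` is the squared Pearson correlation of the paired scores when
    both score vectors are supplied.
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape:
        raise DataError(f"call vectors differ in length: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise DataError("empty call vectors")
    n_disc = int((a != b).sum())
    rate = n_disc / a.size
    r2 = None
    if scores_a is not None and scores_b is not None:
        sa = np.asarray(scores_a, dtype=float)
        sb = np.asarray(scores_b, dtype=float)
        if sa.shape != sb.shape:
            raise DataError(f"score vectors differ in length: {sa.shape} vs {sb.shape}")
        r2 = float(np.corrcoef(sa, sb)[0, 1] ** 2)
    return ConcordanceResult(
        n_calls=int(a.size),
        n_discordant=n_disc,
        discordance_rate=rate,
        acceptance_bound=acceptance_bound,
        passed=bool(rate < acceptance_bound),
        r_squared=r2,
    )
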