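"""Synthetic score-table generators with known ground truth.

The validation studies consume classifier scores, not reads or genes; these
generators emulate each study's data-generating process at the score level so
every estimator in the pipeline can be exercised against known parameters:

* reproducibility tables — additive sample / run / sample:run / residual
  effects on a balanced samples x runs x replicates layout,
* two-laboratory paired tables — per-sample means plus measurement noise,
* condition-effect tables — per-level fixed shifts (RNA input, %gDNA),
* admixture dilution series — a monotone blend from a pure bronchial sample
  towards a contaminant that scores in the high (malignant) region,
* labelled validation cohorts spanning the three pre-test risk groups.

All generators are pure functions of (design, seed): identical inputs give
byte-identical tables.  Defaults reproduce the regimes the validation studies
report (residual SD 0.117, between-run SD 0.136 split 0.11/0.08 between run
and interaction, inter-laboratory SD 0.169, 33- and 95-sample panels).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import substream
from .domain import DEFAULT_SCORE_RANGE, PreTestGroup
from .errors import DataError
from .interference import AdmixtureSeries

__all__ = [
    "ReproDesign",
    "CohortDesign",
    "AdmixtureDesign",
    "default_sample_means",
    "generate_reproducibility_scores",
    "generate_interlab_scores",
    "generate_condition_scores",
    "generate_admixture_series",
    "generate_validation_cohort",
    "SCORE_COLUMNS",
    "COHORT_COLUMNS",
]

SCORE_COLUMNS = ["sample_id", "lab_id", "run_id", "replicate_id", "condition", "score"]
COHORT_COLUMNS = ["patient_id", "pre_test", "truth", "score"]


def default_sample_means(
    n_samples: int, n_controls: int = 0, score_range: float = DEFAULT_SCORE_RANGE
) -> np.ndarray:
    """Sample means evenly dividing the score space.

    Non-control samples span 90% of the zero-centred range (evenly divided
    between high, medium and low scoring samples); controls sit at fixed
    interior positions.
    """
    if not 0 <= n_controls <= n_samples:
        raise DataError("n_controls must be between 0 and n_samples")
    n_reg = n_samples - n_controls
    reg = np.linspace(-0.45 * score_range, 0.45 * score_range, n_reg) if n_reg else np.array([])
    ctl = np.linspace(-0.33 * score_range, 0.33 * score_range, n_controls) if n_controls else np.array([])
    return np.concatenate([ctl, reg])


@dataclass(frozen=True)
class ReproDesign:
    """Design of a reproducibility (or inter-laboratory) score study.

    Default layout mirrors the single-laboratory precision study: 33 samples
    (six of them controls) in triplicate across three runs, with run,
    sample:run interaction and residual SDs sitting at the estimated regime
    (0.11, 0.08, 0.117; between-run SD hypot(0.11, 0.08) = 0.136).
    """

    n_samples: int = 33
    n_controls: int = 6
    n_runs: int = 3
    n_replicates_per_run: int = 3
    sample_means: Optional[np.ndarray] = None
    sigma_run: float = 0.11
    sigma_interaction: float = 0.08
    sigma_residual: float = 0.117
    score_range: float = DEFAULT_SCORE_RANGE
    seed: int = 0

    def __post_init__(self):
        if min(self.n_samples, self.n_runs, self.n_replicates_per_run) < 1:
            raise DataError("counts must be >= 1")
        if min(self.sigma_run, self.sigma_interaction, self.sigma_residual) < 0:
            raise DataError("SDs must be >= 0")
        if self.sample_means is not None and len(self.sample_means) != self.n_samples:
            raise DataError(
                f"sample_means has {len(self.sample_means)} entries for "
                f"{self.n_samples} samples"
            )

    @property
    def means(self) -> np.ndarray:
        if self.sample_means is not None:
            return np.asarray(self.sample_means, dtype=float)
        return default_sample_means(self.n_samples, self.n_controls, self.score_range)

    @property
    def sample_ids(self) -> list:
        ctl = [f"control_{i + 1:02d}" for i in range(self.n_controls)]
        reg = [f"sample_{i + 1:03d}" for i in range(self.n_samples - self.n_controls)]
        return ctl + reg

    @classmethod
    def interlab_default(cls, seed: int = 0) -> "ReproDesign":
        """95-sample two-laboratory panel with per-measurement SD 0.169."""
        return cls(
            n_samples=95,
            n_controls=6,
            n_runs=1,
            n_replicates_per_run=1,
            sigma_run=0.0,
            sigma_interaction=0.0,
            sigma_residual=0.169,
            seed=seed,
        )


def generate_reproducibility_scores(design: ReproDesign) -> pd.DataFrame:
    """Balanced samples x runs x replicates score table.

    score(i, j, k) = mu_i + run_j + (sample:run)_ij + residual_ijk, every
    random effect Gaussian with the design SDs.
    """
    a, b, r = design.n_samples, design.n_runs, design.n_replicates_per_run
    rng = substream(design.seed, "reproducibility")
    mu = design.means
    y = (
        mu[:, None, None]
        + rng.normal(0.0, design.sigma_run, (1, b, 1))
        + rng.normal(0.0, design.sigma_interaction, (a, b, 1))
        + rng.normal(0.0, design.sigma_residual, (a, b, r))
    )
    ids = design.sample_ids
    rows = pd.MultiIndex.from_product(
        [ids, [f"run_{j + 1}" for j in range(b)], [f"rep_{k + 1}" for k in range(r)]],
        names=["sample_id", "run_id", "replicate_id"],
    ).to_frame(index=False)
    rows.insert(1, "lab_id", "lab_A")
    rows["condition"] = "nominal"
    rows["score"] = y.ravel()
    return rows[SCORE_COLUMNS]


def generate_interlab_scores(
    design: ReproDesign,
    lab_ids: Tuple[str, str] = ("lab_A", "lab_B"),
    replicates_per_lab: int = 1,
) -> pd.DataFrame:
    """Paired two-laboratory table: score = mu_i + residual noise.

    ``replicates_per_lab`` exposes how many calls each sample contributes per
    laboratory (the concordance denominator is not fixed by the study design).
    """
    if len(set(lab_ids)) != 2:
        raise DataError("exactly two distinct lab_ids are required")
    rng = substream(design.seed, "interlab")
    mu = design.means
    a = design.n_samples
    y = mu[:, None, None] + rng.normal(
        0.0, design.sigma_residual, (a, 2, replicates_per_lab)
    )
    rows = pd.MultiIndex.from_product(
        [design.sample_ids, list(lab_ids), [f"rep_{k + 1}" for k in range(replicates_per_lab)]],
        names=["sample_id", "lab_id", "replicate_id"],
    ).to_frame(index=False)
    rows["run_id"] = "run_1"
    rows["condition"] = "nominal"
    rows["score"] = y.ravel()
    return rows[SCORE_COLUMNS]


def generate_condition_scores(
    sample_means: Sequence[float],
    condition_levels: Sequence,
    condition_effects: Sequence[float],
    sigma_residual: float = 0.117,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced condition-effect table: score = mu_i + b_j + residual.

    One fixed effect ``b_j`` per condition level (e.g. RNA input in ng, or
    %gDNA by mass), balanced across samples x levels x replicates.
    """
    if len(condition_levels) != len(condition_effects):
        raise DataError("one condition effect is required per level")
    mu = np.asarray(sample_means, dtype=float)
    b = np.asarray(condition_effects, dtype=float)
    rng = substream(seed, "condition")
    y = mu[:, None, None] + b[None, :, None] + rng.normal(
        0.0, sigma_residual, (len(mu), len(b), replicates)
    )
    rows = pd.MultiIndex.from_product(
        [
            [f"sample_{i + 1:03d}" for i in range(len(mu))],
            [str(l) for l in condition_levels],
            [f"rep_{k + 1}" for k in range(replicates)],
        ],
        names=["sample_id", "condition", "replicate_id"],
    ).to_frame(index=False)
    rows["lab_id"] = "lab_A"
    rows["run_id"] = "run_1"
    rows["score"] = y.ravel()
    return rows[SCORE_COLUMNS]


# ---------------------------------------------------------------------------
# admixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdmixtureDesign:
    """Contaminant dilution series for one base sample.

    The contaminant (e.g. whole-blood RNA) scores in the high/malignant score
    region, so mixing pulls the base score towards ``contaminant_score``
    monotonically.  ``mixing`` selects the blend: ``"logistic"`` (shape
    ``mixing_k``; the ``k -> 0`` limit is linear) or ``"linear"``.

    Default proportions follow the dilution layout of the blood study (pure
    base, 5/10/20/50/75% contaminant, pure contaminant), run in triplicate at
    the lower proportions and duplicate at 50/75%.
    """

    base_score: float = -0.8
    contaminant_score: float = 1.6
    proportions: Tuple[float, ...] = (0.0, 0.05, 0.10, 0.20, 0.50, 0.75, 1.0)
    mixing: str = "logistic"
    mixing_k: float = 4.0
    replicate_noise_sd: float = 0.117
    pre_test: PreTestGroup = PreTestGroup.INTERMEDIATE
    base_id: str = "base"
    contaminant_id: str = "contaminant"
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if p.size < 1 or p.min() < 0 or p.max() > 1 or not np.all(np.diff(p) > 0):
            raise DataError("proportions must be sorted, distinct and within [0, 1]")
        if p[0] != 0.0:
            raise DataError("proportions must include 0 (pure base sample)")
        if self.replicate_noise_sd < 0:
            raise DataError("replicate_noise_sd must be >= 0")
        if self.mixing not in ("logistic", "linear"):
            raise DataError(f"unknown mixing shape {self.mixing!r}")

    def replicates_at(self, p: float) -> int:
        return 2 if 0.2 < p < 1.0 else 3

    def mixing_weight(self, p) -> np.ndarray:
        """Monotone blend weight w(p) with w(0) = 0 and w(1) = 1."""
        p = np.asarray(p, dtype=float)
        if self.mixing == "linear" or abs(self.mixing_k) < 1e-8:
            return p
        k = self.mixing_k

        def logistic(x):
            return 1.0 / (1.0 + np.exp(-k * (x - 0.5)))

        lo, hi = logistic(0.0), logistic(1.0)
        return (logistic(p) - lo) / (hi - lo)

    def noise_free_score(self, p) -> np.ndarray:
        w = self.mixing_weight(p)
        return self.base_score + (self.contaminant_score - self.base_score) * w


def generate_admixture_series(design: AdmixtureDesign) -> AdmixtureSeries:
    """Replicate scores along the dilution series of one (base, contaminant) pair."""
    rng = substream(design.seed, "admixture", design.base_id, design.contaminant_id)
    points = []
    for p in design.proportions:
        n = design.replicates_at(p)
        scores = design.noise_free_score(p) + rng.normal(0.0, design.replicate_noise_sd, n)
        points.append((float(p), scores))
    return AdmixtureSeries(
        base_id=design.base_id,
        contaminant_id=design.contaminant_id,
        pre_test=design.pre_test,
        points=points,
    )


# ---------------------------------------------------------------------------
# validation cohort
# ---------------------------------------------------------------------------

def _default_score_params() -> Mapping:
    # (location, scale) of the Gaussian score distribution per (group, truth).
    # Chosen so the zero-noise calls under the default policy land in a
    # realistic regime: high sensitivity and NPV, moderate specificity on the
    # down-classification arm, and PPVs well above the 50% floor.
    return {
        ("low", "benign"): (-0.60, 0.55),
        ("low", "malignant"): (0.50, 0.60),
        ("intermediate", "benign"): (-0.35, 0.55),
        ("intermediate", "malignant"): (0.50, 0.60),
        ("high", "benign"): (0.20, 0.60),
        ("high", "malignant"): (1.10, 0.60),
    }


@dataclass(frozen=True)
class CohortDesign:
    """Labelled validation cohort spanning the three pre-test risk groups.

    Per-group malignancy prevalence defaults sit inside each group's nominal
    risk interval (8%, 35%, 75%); scores are Gaussian per (group, truth) cell.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"low": 150, "intermediate": 300, "high": 150}
    )
    prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.08, "intermediate": 0.35, "high": 0.75}
    )
    score_params: Mapping = field(default_factory=_default_score_params)
    seed: int = 0

    def __post_init__(self):
        for g, pr in self.prevalence.items():
            if not 0.0 <= pr <= 1.0:
                raise DataError(f"prevalence for {g!r} must be in [0, 1]")
        for key, (_, scale) in self.score_params.items():
            if scale <= 0:
                raise DataError(f"score scale for {key} must be positive")


def generate_validation_cohort(design: CohortDesign) -> pd.DataFrame:
    """Draw truth by per-group prevalence, then score from the (group, truth) cell."""
    rng = substream(design.seed, "cohort")
    frames = []
    for group in ("low", "intermediate", "high"):
        n = int(design.n_per_group.get(group, 0))
        if n == 0:
            continue
        mal = rng.random(n) < design.prevalence.get(group, 0.0)
        truth = np.where(mal, "malignant", "benign")
        loc_m, sc_m = design.score_params[(group, "malignant")]
        loc_b, sc_b = design.score_params[(group, "benign")]
        scores = np.where(
            mal,
            rng.normal(loc_m, sc_m, n),
            rng.normal(loc_b, sc_b, n),
        )
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": [f"{group}_{i + 1:04d}" for i in range(n)],
                    "pre_test": group,
                    "truth": truth,
                    "score": scores,
                }
            )
        )
    if not frames:
        raise DataError("cohort design has no patients")
    return pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]
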