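"""Study orchestration: configs in, a serialisable validation report out.

``run_study`` dispatches a study config to the analysis modules and collects
a :class:`ValidationReport`.  With all-synthetic designs the whole pipeline
runs with zero external files; each study can instead point at CSV/TSV score
tables.  Reports are deterministic given (config, seed) and serialise
losslessly to JSON (no timestamps inside the payload).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import List, Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from ._rng import derive_seed
from .domain import (
    DecisionPolicy,
    PostTestCategory,
    PreTestGroup,
    classify,
    classify_scores,
    fraction_of_range,
    round_percent,
)
from .errors import ConfigError, DataError
from .interference import fit_admixture_curve, invert_threshold, test_condition_effect
from .io import read_score_table, sanitize_json
from .synthetic import (
    AdmixtureDesign,
    CohortDesign,
    ReproDesign,
    generate_admixture_series,
    generate_condition_scores,
    generate_interlab_scores,
    generate_reproducibility_scores,
    generate_validation_cohort,
)
from .tolerance import (
    NoiseGrid,
    Requirement,
    first_failure_mode,
    max_allowable_sd,
    run_noise_injection,
)
from .varcomp import concordance, decompose_variance, interlab_sd

__all__ = ["ValidationReport", "run_study", "STUDY_TYPES"]

STUDY_TYPES = (
    "reproducibility",
    "interlab",
    "rna_input",
    "gdna",
    "admixture",
    "tolerance",
    "all",
)


@dataclass
class ValidationReport:
    """Results of one or more validation studies, with provenance."""

    results: Mapping[str, dict]
    provenance: Mapping[str, object]
    summary: List[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "results": self.results,
            "provenance": self.provenance,
            "summary": self.summary,
        }
        return json.dumps(sanitize_json(payload), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        d = json.loads(text)
        return cls(results=d["results"], provenance=d["provenance"], summary=d["summary"])


def _config_hash(config: Mapping) -> str:
    canon = json.dumps(sanitize_json(dict(config)), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _policy_from(config: Mapping) -> DecisionPolicy:
    return DecisionPolicy.from_dict(config.get("policy", {}))


def _pct(x: float) -> float:
    return round_percent(x)


# ---------------------------------------------------------------------------
# individual studies
# ---------------------------------------------------------------------------

def _repro_design(cfg: Mapping, seed: int) -> ReproDesign:
    allowed = {
        "n_samples", "n_controls", "n_runs", "n_replicates_per_run",
        "sigma_run", "sigma_interaction", "sigma_residual", "score_range",
    }
    kw = {k: v for k, v in cfg.items() if k in allowed}
    return ReproDesign(seed=seed, **kw)


def _study_reproducibility(cfg: Mapping, policy: DecisionPolicy, seed: int):
    if "table" in cfg:
        frame = read_score_table(cfg["table"], "score")
    else:
        frame = generate_reproducibility_scores(_repro_design(cfg.get("design", {}), seed))
    vd = decompose_variance(
        frame,
        n_boot=int(cfg.get("n_boot", 2000)),
        seed=derive_seed(seed, "repro-boot"),
    )
    res = vd.as_dict(score_range=policy.score_range)
    lines = [
        "reproducibility: total SD {:.3f} (95% CI {:.3f} to {:.3f}), intra-run SD "
        "{:.3f}, inter-run SD {:.3f}; total SD is {:.1f}% of the score range".format(
            vd.sigma_total,
            *(vd.ci["total"] if vd.ci else (float("nan"), float("nan"))),
            vd.sigma_intra,
            vd.sigma_inter,
            _pct(fraction_of_range(vd.sigma_total, policy)),
        )
    ]
    return res, lines


def _assign_groups(sample_means: np.ndarray) -> np.ndarray:
    """Pre-test groups by score tertile of the panel (levels 1/2/3)."""
    lo, hi = np.quantile(sample_means, [1 / 3, 2 / 3])
    return np.where(sample_means <= lo, 1, np.where(sample_means <= hi, 2, 3))


def _study_interlab(cfg: Mapping, policy: DecisionPolicy, seed: int):
    reps = int(cfg.get("replicates_per_lab", 1))
    if "table" in cfg:
        frame = read_score_table(cfg["table"], "score")
    else:
        dcfg = dict(cfg.get("design", {}))
        design = ReproDesign.interlab_default(seed=seed)
        if dcfg:
            base = design.__dict__ | {k: v for k, v in dcfg.items() if k in design.__dict__}
            design = ReproDesign(**base)
        frame = generate_interlab_scores(design, replicates_per_lab=reps)
    il = interlab_sd(
        frame, n_boot=int(cfg.get("n_boot", 2000)), seed=derive_seed(seed, "interlab-boot")
    )
    # per-sample scores and calls, paired across the two labs
    labs = sorted(frame["lab_id"].unique())
    wide = frame.pivot_table(index="sample_id", columns="lab_id", values="score")
    means = frame.groupby("sample_id")["score"].mean()
    group = pd.Series(_assign_groups(means.to_numpy()), index=means.index)
    paired = frame.sort_values(["sample_id", "replicate_id", "lab_id"])
    a = paired[paired["lab_id"] == labs[0]]
    b = paired[paired["lab_id"] == labs[1]]
    pre_a = group.loc[a["sample_id"]].to_numpy()
    pre_b = group.loc[b["sample_id"]].to_numpy()
    calls_a = classify_scores(a["score"].to_numpy(), pre_a, policy)
    calls_b = classify_scores(b["score"].to_numpy(), pre_b, policy)
    conc = concordance(
        calls_a,
        calls_b,
        wide[labs[0]].to_numpy(),
        wide[labs[1]].to_numpy(),
        acceptance_bound=float(cfg.get("acceptance_bound", 0.15)),
    )
    res = il.as_dict(score_range=policy.score_range) | {"concordance": conc.as_dict()}
    lines = [
        "inter-laboratory: SD {:.3f} ({:.1f}% of score range); discordant calls "
        "{} out of {} ({:.1f}%), acceptance bound {:.0f}% -> {}".format(
            il.sigma,
            _pct(fraction_of_range(il.sigma, policy)),
            conc.n_discordant,
            conc.n_calls,
            _pct(100 * conc.discordance_rate),
            100 * conc.acceptance_bound,
            "pass" if conc.passed else "FAIL",
        ),
        f"inter-laboratory: paired-score R^2 = {conc.r_squared:.2f}",
    ]
    return res, lines


_CONDITION_DEFAULTS = {
    # levels, per-level fixed effects, samples, replicates
    "rna_input": {
        "levels": ["10", "15", "20", "36", "50"],
        "effects": [-0.05, 0.0, 0.0, 0.0, 0.0],
        "n_samples": 4,
        "replicates": 3,
    },
    "gdna": {
        "levels": ["0", "3", "5", "10"],
        "effects": [0.0, 0.0, 0.0, 0.0],
        "n_samples": 2,
        "replicates": 3,
    },
}


def _study_condition(kind: str, cfg: Mapping, policy: DecisionPolicy, seed: int):
    defaults = _CONDITION_DEFAULTS[kind]
    if "table" in cfg:
        frame = read_score_table(cfg["table"], "score")
    else:
        n = int(cfg.get("n_samples", defaults["n_samples"]))
        means = np.linspace(-0.4 * policy.score_range, 0.4 * policy.score_range, n)
        frame = generate_condition_scores(
            means,
            cfg.get("levels", defaults["levels"]),
            cfg.get("effects", defaults["effects"]),
            sigma_residual=float(cfg.get("sigma_residual", 0.117)),
            replicates=int(cfg.get("replicates", defaults["replicates"])),
            seed=derive_seed(seed, kind),
        )
    result = test_condition_effect(frame, alpha=float(cfg.get("alpha", 0.05)))
    unit = "ng RNA input" if kind == "rna_input" else "% genomic DNA"
    lines = [
        "{}: F({}, {}) = {:.2f}, p = {:.2f} -> {} effect of {}".format(
            kind,
            result.df_numerator,
            result.df_denominator,
            result.f_statistic,
            result.p_value,
            "significant" if result.significant else "no significant",
            unit,
        )
    ]
    return result.as_dict(), lines


_ADMIX_BASES = {"low": -1.0, "intermediate": -0.8, "high": 0.5}
_ADMIX_CONTAMINANTS = {"low_malignant_blood": 0.8, "high_malignant_blood": 1.7}


def _study_admixture(cfg: Mapping, policy: DecisionPolicy, seed: int):
    bases = cfg.get("base_scores", _ADMIX_BASES)
    contams = cfg.get("contaminant_scores", _ADMIX_CONTAMINANTS)
    noise = float(cfg.get("replicate_noise_sd", 0.05))
    res, lines = {}, []
    for gname, base in bases.items():
        group = PreTestGroup.from_label(gname)
        for cname, cscore in contams.items():
            design = AdmixtureDesign(
                base_score=float(base),
                contaminant_score=float(cscore),
                replicate_noise_sd=noise,
                pre_test=group,
                base_id=f"{gname}_base",
                contaminant_id=cname,
                seed=derive_seed(seed, "admix", gname, cname),
            )
            series = generate_admixture_series(design)
            curve = fit_admixture_curve(series)
            report = invert_threshold(
                curve, policy, group, base_id=design.base_id, contaminant_id=cname
            )
            key = f"{gname}|{cname}"
            res[key] = report.as_dict() | {
                "curve_family": curve.family,
                "fit_residual_sd": curve.fit_residual_sd,
            }
            for t in report.thresholds:
                lines.append(
                    "admixture: {} pre-test vs {}: {} boundary -> {}".format(
                        gname, cname, t.boundary, t.describe()
                    )
                )
    return res, lines


def _study_tolerance(cfg: Mapping, policy: DecisionPolicy, seed: int):
    if "cohort" in cfg:
        cohort = read_score_table(cfg["cohort"], "cohort")
    else:
        cohort = generate_validation_cohort(CohortDesign(seed=derive_seed(seed, "cohort")))
    gcfg = cfg.get("grid", {})
    sd_values = gcfg.get("sd_values")
    if sd_values is None:
        n_points = int(gcfg.get("n_points", 40))
        sd_values = tuple(np.logspace(np.log10(0.01), np.log10(10.0), n_points))
    grid = NoiseGrid(
        sd_values=tuple(float(s) for s in sd_values),
        n_reps=int(gcfg.get("n_reps", 1000)),
        seed=derive_seed(seed, "tolerance"),
    )
    reqs = tuple(
        Requirement(m, float(b))
        for m, b in cfg.get("requirements", {"ppv_intermediate_up": 0.50}).items()
    )
    curve = run_noise_injection(cohort, policy, grid, requirements=reqs)
    sd, pct = max_allowable_sd(curve)
    failure = first_failure_mode(curve)
    res = curve.summary() | {
        "table": curve.table.round(6).to_dict(orient="list"),
    }
    if isinstance(sd, float):
        lines = [
            "tolerance: maximum allowable noise SD {:.3f} ({:.1f}% of score range); "
            "first failing requirement: {}".format(sd, _pct(pct), failure)
        ]
    else:
        lines = [f"tolerance: {sd} - requirements already fail at the smallest noise SD"]
    return res, lines


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def run_study(config: Mapping, seed: Optional[int] = None) -> ValidationReport:
    """Run the study (or studies) named by ``config`` and assemble a report.

    ``config["study"]`` is one of :data:`STUDY_TYPES`; ``"all"`` runs every
    study on its synthetic defaults.  ``seed`` overrides ``config["seed"]``.
    """
    if "study" not in config:
        raise ConfigError("config must name a 'study'")
    study = config["study"]
    if study not in STUDY_TYPES:
        raise ConfigError(f"unknown study type {study!r}; expected one of {STUDY_TYPES}")
    seed = int(seed if seed is not None else config.get("seed", 0))
    policy = _policy_from(config)

    dispatch = {
        "reproducibility": lambda c: _study_reproducibility(c, policy, seed),
        "interlab": lambda c: _study_interlab(c, policy, seed),
        "rna_input": lambda c: _study_condition("rna_input", c, policy, seed),
        "gdna": lambda c: _study_condition("gdna", c, policy, seed),
        "admixture": lambda c: _study_admixture(c, policy, seed),
        "tolerance": lambda c: _study_tolerance(c, policy, seed),
    }
    names = list(dispatch) if study == "all" else [study]
    results, summary = {}, []
    for name in names:
        res, lines = dispatch[name](config.get(name, config if study != "all" else {}))
        results[name] = res
        summary.extend(lines)
    provenance = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "version": __version__,
        "policy": policy.to_dict(),
    }
    return ValidationReport(results=results, provenance=provenance, summary=summary)
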