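"""Orchestration of the full analysis and the parameter-recovery harness.

The analysis runs in the study's two-step pattern for each response variable
(positivity, negativity, arousal, ambivalence, emotional activation):

1. a base model testing stimulus-category (or activation-function)
   differences without moderators;
2. four moderator models, one per symptom scale, each adding the scale's
   main effect, its interactions with every level-1 term, and covariates
   (age, male, education, the respective other symptom domains), with
   conditional effects computed where the interaction reaches trend level
   (p < .10) and interaction p values Bonferroni-corrected within the
   four-moderator family.

The activation-function models additionally yield the Evaluative Space
Model quantities: the positivity offset (function main effect = difference
of intercepts at arousal 0), the negativity bias (difference of arousal
slopes), their between-subject SDs (random-slope SDs of the effect-coded
function terms), and a grid of offset/bias values at -1 SD / mean / +1 SD
of each moderator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import affect_scoring, design_builder, lmm_engine
from .affect_scoring import SCALE_MAX, add_normalized_scores
from .design_builder import (
    ModelDataset,
    attach_moderator,
    build_activation_design,
    build_ambivalence_design,
    build_category_design,
)
from .lmm_engine import (
    FitResult,
    bonferroni_adjust,
    conditional_effects,
    contrast_test,
    fit_lmm,
    wald_f_test,
)
from .synthetic_data import GeneratorParams, simulate_dataset

MODERATORS = tuple(SCALE_MAX)


@dataclass
class AnalysisConfig:
    """Switches shared by every analysis stage."""

    split_seed: int = 0
    moderators: tuple = MODERATORS
    include_covariates: bool = True
    bonferroni_family: int = 4  # interaction tests per response variable
    trend_p: float = 0.10
    compute_df: bool = True
    correlated_slopes: bool = True


@dataclass
class ESMEstimates:
    """Positivity offset / negativity bias summary of one activation model set."""

    offset: dict  # estimate, se, df, t, p, ci_low, ci_high, beta, sd_between
    bias: dict
    pos_intercept: dict
    neg_intercept: dict
    pos_slope: dict
    neg_slope: dict
    moderated: pd.DataFrame | None = None  # Table-2-style grid
    moderator_tests: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in ("offset", "bias", "pos_intercept", "neg_intercept", "pos_slope", "neg_slope")
        }
        if self.moderated is not None:
            out["moderated"] = self.moderated.to_dict("records")
        if self.moderator_tests is not None:
            out["moderator_tests"] = self.moderator_tests.to_dict("records")
        return out


def _fit_section(
    design: ModelDataset,
    participants: pd.DataFrame,
    config: AnalysisConfig,
    factor: str,
) -> dict:
    """Base model + per-moderator models + trend-gated conditional effects."""
    base = fit_lmm(design, compute_df=config.compute_df)
    section: dict = {
        "base_fit": base,
        "omnibus": wald_f_test(base, design.factors[factor]),
        "moderators": {},
    }
    inter_ps = []
    for mod in config.moderators:
        mds = attach_moderator(design, mod, participants, config.include_covariates)
        fit = fit_lmm(mds, compute_df=config.compute_df)
        inter = wald_f_test(fit, mds.factors[f"moderator_x_{factor}"])
        cond = conditional_effects(fit, factor=factor, trend_p=config.trend_p)
        section["moderators"][mod] = {
            "fit": fit,
            "interaction": inter,
            "conditional_effects": cond,
        }
        inter_ps.append(inter["p"])
    adj = bonferroni_adjust(inter_ps, config.bonferroni_family)
    for mod, p_adj in zip(config.moderators, adj):
        section["moderators"][mod]["interaction"]["p_bonferroni"] = float(p_adj)
    return section


def run_raw_response_analysis(
    trials: pd.DataFrame, participants: pd.DataFrame, config: AnalysisConfig | None = None
) -> dict:
    """Category models for positivity, negativity and arousal, then moderation."""
    config = config or AnalysisConfig()
    participants = add_normalized_scores(participants)
    out = {}
    for outcome in ("positivity", "negativity", "arousal"):
        design = build_category_design(trials, outcome)
        section = _fit_section(design, participants, config, factor="category")
        base = section["base_fit"]
        # pairwise category contrasts (neutral is the reference level)
        names = base.fixed_names
        sd_y = float(design.data[outcome].std(ddof=1))
        contrasts = {}
        for label, vec in {
            "pleasant_vs_neutral": {"cat_pleasant": 1.0},
            "unpleasant_vs_neutral": {"cat_unpleasant": 1.0},
            "unpleasant_vs_pleasant": {"cat_unpleasant": 1.0, "cat_pleasant": -1.0},
        }.items():
            c = np.zeros(base.n_fixed)
            for col, w in vec.items():
                c[names.index(col)] = w
            sd_x = float(np.std(
                sum(w * design.data[col].to_numpy(float) for col, w in vec.items()), ddof=1
            ))
            contrasts[label] = contrast_test(base, c, beta_scale=sd_x / sd_y if sd_y else None)
        section["contrasts"] = contrasts
        out[outcome] = section
    return out


def run_ambivalence_analysis(
    trials: pd.DataFrame, participants: pd.DataFrame, config: AnalysisConfig | None = None
) -> dict:
    """Ambivalence category model and its moderation, as for raw responses."""
    config = config or AnalysisConfig()
    participants = add_normalized_scores(participants)
    design = build_ambivalence_design(trials)
    section = _fit_section(design, participants, config, factor="category")
    base = section["base_fit"]
    names = base.fixed_names
    sd_y = float(design.data["ambivalence"].std(ddof=1))
    contrasts = {}
    for label, vec in {
        "neutral_vs_pleasant": {"cat_pleasant": -1.0},
        "neutral_vs_unpleasant": {"cat_unpleasant": -1.0},
        "unpleasant_vs_pleasant": {"cat_unpleasant": 1.0, "cat_pleasant": -1.0},
    }.items():
        c = np.zeros(base.n_fixed)
        for col, w in vec.items():
            c[names.index(col)] = w
        sd_x = float(np.std(
            sum(w * design.data[col].to_numpy(float) for col, w in vec.items()), ddof=1
        ))
        contrasts[label] = contrast_test(base, c, beta_scale=sd_x / sd_y if sd_y else None)
    section["contrasts"] = contrasts
    return section


def _esm_from_fit(fit: FitResult, design: ModelDataset) -> dict:
    """Extract offset/bias and per-function intercepts/slopes from a base fit."""
    names = fit.fixed_names
    sd_y = float(design.data[design.outcome].std(ddof=1))

    def ct(spec: dict, beta_cols: dict | None = None) -> dict:
        c = np.zeros(fit.n_fixed)
        for col, w in spec.items():
            c[names.index(col)] = w
        scale = None
        if beta_cols is not None and sd_y > 0:
            x = sum(w * design.data[col].to_numpy(float) for col, w in beta_cols.items())
            scale = float(np.std(x, ddof=1)) / sd_y
        return contrast_test(fit, c, beta_scale=scale)

    offset = ct({"function_pos": 1.0}, {"function_pos": 1.0})
    bias = ct({"fpos_x_arousal": -1.0}, {"fpos_x_arousal": 1.0})
    neg_int = ct({"intercept": 1.0})
    pos_int = ct({"intercept": 1.0, "function_pos": 1.0})
    neg_slope = ct({"arousal": 1.0}, {"arousal": 1.0})
    pos_slope = ct({"arousal": 1.0, "fpos_x_arousal": 1.0}, {"arousal": 1.0})
    if "subject_offset" in fit.random_effects.index:
        offset["sd_between"] = float(fit.random_effects.loc["subject_offset", "sd"])
    if "subject_bias" in fit.random_effects.index:
        bias["sd_between"] = float(fit.random_effects.loc["subject_bias", "sd"])
    return {
        "offset": offset,
        "bias": bias,
        "pos_intercept": pos_int,
        "neg_intercept": neg_int,
        "pos_slope": pos_slope,
        "neg_slope": neg_slope,
    }


def run_offset_bias_analysis(
    trials: pd.DataFrame, participants: pd.DataFrame, config: AnalysisConfig | None = None
) -> tuple[ESMEstimates, dict]:
    """Base activation model plus the four moderated models and the
    Table-2-style offset/bias grid at -1 SD / mean / +1 SD of each moderator."""
    config = config or AnalysisConfig()
    participants = add_normalized_scores(participants)
    design = build_activation_design(
        trials, seed=config.split_seed, correlated_slopes=config.correlated_slopes
    )
    base = fit_lmm(design, compute_df=config.compute_df)
    parts = _esm_from_fit(base, design)

    section: dict = {"base_fit": base, "design": design, "moderators": {}}
    grid_rows, test_rows = [], []
    inter_ps = []
    for mod in config.moderators:
        mds = attach_moderator(design, mod, participants, config.include_covariates)
        fit = fit_lmm(mds, compute_df=config.compute_df)
        names = fit.fixed_names
        sd_mod = float(mds.data["mod"].std(ddof=1))
        sd_y = float(mds.data[mds.outcome].std(ddof=1))

        fn_inter = wald_f_test(fit, ["function_pos_x_mod"])  # offset moderation
        three_way = wald_f_test(fit, ["fpos_x_arousal_x_mod"])  # bias moderation
        inter_ps.append(fn_inter["p"])

        for level, z in (("-1 SD", -sd_mod), ("mean", 0.0), ("+1 SD", sd_mod)):
            c_off = np.zeros(fit.n_fixed)
            c_off[names.index("function_pos")] = 1.0
            c_off[names.index("function_pos_x_mod")] = z
            off = contrast_test(fit, c_off)
            c_bias = np.zeros(fit.n_fixed)
            c_bias[names.index("fpos_x_arousal")] = -1.0
            c_bias[names.index("fpos_x_arousal_x_mod")] = -z
            bias = contrast_test(fit, c_bias)
            grid_rows.append(
                {
                    "moderator": mod, "level": level,
                    "offset": off["estimate"], "offset_p": off["p"],
                    "bias": bias["estimate"], "bias_p": bias["p"],
                }
            )
        # standardized moderation effects (per SD of moderator, in outcome SDs)
        b_off = fit.coef("function_pos_x_mod")
        b_bias = -fit.coef("fpos_x_arousal_x_mod")
        test_rows.append(
            {
                "moderator": mod,
                "offset_beta": b_off * sd_mod / sd_y if sd_y else np.nan,
                "offset_interaction_p": fn_inter["p"],
                "bias_beta": b_bias * sd_mod / sd_y if sd_y else np.nan,
                "bias_interaction_p": three_way["p"],
            }
        )
        section["moderators"][mod] = {
            "fit": fit,
            "function_interaction": fn_inter,
            "three_way_interaction": three_way,
        }
    adj = bonferroni_adjust(inter_ps, config.bonferroni_family) if inter_ps else []
    for mod, p_adj in zip(config.moderators, adj):
        section["moderators"][mod]["function_interaction"]["p_bonferroni"] = float(p_adj)

    estimates = ESMEstimates(
        **parts,
        moderated=pd.DataFrame(grid_rows) if grid_rows else None,
        moderator_tests=pd.DataFrame(test_rows) if test_rows else None,
    )
    return estimates, section


def run_external_benchmark(
    trials: pd.DataFrame, config: AnalysisConfig | None = None
) -> ESMEstimates:
    """Base activation model on an externally supplied trial table.

    Intended for refitting deposited study data: reads a validated long trial
    table and returns the offset/bias estimates without any moderation step.
    """
    config = config or AnalysisConfig(moderators=())
    design = build_activation_design(
        trials, seed=config.split_seed, correlated_slopes=config.correlated_slopes
    )
    base = fit_lmm(design, compute_df=config.compute_df)
    return ESMEstimates(**_esm_from_fit(base, design))


@dataclass
class AnalysisReport:
    """Everything one full run produced, serializable to JSON/TSV."""

    config: dict
    raw_responses: dict
    ambivalence: dict
    esm: ESMEstimates
    esm_section: dict
    exclusion_log: pd.DataFrame | None = None

    def summary_dict(self) -> dict:
        def fit_entry(fit: FitResult) -> dict:
            return fit.to_json_dict()

        def section_entry(sec: dict) -> dict:
            out = {"base_fit": fit_entry(sec["base_fit"]), "omnibus": sec.get("omnibus")}
            if "contrasts" in sec:
                out["contrasts"] = sec["contrasts"]
            out["moderators"] = {}
            for mod, m in sec["moderators"].items():
                entry = {k: v for k, v in m.items() if k not in ("fit", "conditional_effects")}
                entry["fit"] = fit_entry(m["fit"])
                ce = m.get("conditional_effects")
                entry["conditional_effects"] = (
                    None if ce is None else ce.reset_index().to_dict("records")
                )
                out["moderators"][mod] = entry
            return out

        return {
            "config": self.config,
            "raw_responses": {k: section_entry(v) for k, v in self.raw_responses.items()},
            "ambivalence": section_entry(self.ambivalence),
            "esm": self.esm.to_json_dict(),
            "esm_moderators": {
                mod: {
                    "function_interaction": m["function_interaction"],
                    "three_way_interaction": m["three_way_interaction"],
                    "fit": m["fit"].to_json_dict(),
                }
                for mod, m in self.esm_section["moderators"].items()
            },
            "exclusions": None
            if self.exclusion_log is None
            else self.exclusion_log.to_dict("records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_full_analysis(
    trials: pd.DataFrame,
    participants: pd.DataFrame,
    config: AnalysisConfig | None = None,
    exclusion_log: pd.DataFrame | None = None,
) -> AnalysisReport:
    """Filters are assumed applied; runs all model families in study order."""
    config = config or AnalysisConfig()
    raw = run_raw_response_analysis(trials, participants, config)
    amb = run_ambivalence_analysis(trials, participants, config)
    esm, esm_section = run_offset_bias_analysis(trials, participants, config)
    return AnalysisReport(
        config=asdict(config),
        raw_responses=raw,
        ambivalence=amb,
        esm=esm,
        esm_section=esm_section,
        exclusion_log=exclusion_log,
    )


# ---------------------------------------------------------------------------
# parameter-recovery harness
# ---------------------------------------------------------------------------


@dataclass
class RecoveryConfig:
    """Replication settings for the simulation-estimation consistency check."""

    n_reps: int = 100
    n_participants: int = 60
    per_category: int = 8  # 8/8/8 -> 24 stimuli
    seed: int = 0
    params: GeneratorParams | None = None
    compute_df: bool = True
    offset_bias_tolerance: float = 0.1  # |mean est - true| ceilings
    bias_bias_tolerance: float = 0.05
    coverage_band: tuple = (0.90, 0.98)


@dataclass
class RecoveryReport:
    """Per-parameter recovery statistics across replicates."""

    n_reps: int
    true_offset: float
    true_bias: float
    offset_estimates: list
    bias_estimates: list
    offset_coverage: float
    bias_coverage: float
    n_failed: int
    tolerances: dict
    passed: dict = field(default_factory=dict)

    @property
    def offset_mean(self) -> float:
        return float(np.mean(self.offset_estimates))

    @property
    def bias_mean(self) -> float:
        return float(np.mean(self.bias_estimates))

    @property
    def offset_rmse(self) -> float:
        return float(np.sqrt(np.mean((np.array(self.offset_estimates) - self.true_offset) ** 2)))

    @property
    def bias_rmse(self) -> float:
        return float(np.sqrt(np.mean((np.array(self.bias_estimates) - self.true_bias) ** 2)))

    def evaluate(self) -> dict:
        tol = self.tolerances
        self.passed = {
            "offset_mean": abs(self.offset_mean - self.true_offset) < tol["offset"],
            "bias_mean": abs(self.bias_mean - self.true_bias) < tol["bias"],
            "offset_coverage": tol["coverage"][0] <= self.offset_coverage <= tol["coverage"][1],
        }
        return self.passed

    def to_json(self, path) -> None:
        self.evaluate()
        payload = {
            "n_reps": self.n_reps,
            "true_offset": self.true_offset,
            "true_bias": self.true_bias,
            "offset_mean": self.offset_mean,
            "bias_mean": self.bias_mean,
            "offset_rmse": self.offset_rmse,
            "bias_rmse": self.bias_rmse,
            "offset_coverage": self.offset_coverage,
            "bias_coverage": self.bias_coverage,
            "n_failed": self.n_failed,
            "tolerances": {
                "offset": self.tolerances["offset"],
                "bias": self.tolerances["bias"],
                "coverage": list(self.tolerances["coverage"]),
            },
            "passed": self.passed,
            "offset_estimates": self.offset_estimates,
            "bias_estimates": self.bias_estimates,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)


def parameter_recovery(config: RecoveryConfig | None = None) -> RecoveryReport:
    """Simulate-and-refit replicates; summarize bias, RMSE and CI coverage.

    Each replicate draws a fresh study at the configured size, fits the base
    activation model, and records the offset/bias estimates and whether each
    95% CI covers the generating value.
    """
    config = config or RecoveryConfig()
    params = config.params or GeneratorParams(
        n_participants=config.n_participants,
        n_pleasant=config.per_category,
        n_neutral=config.per_category,
        n_unpleasant=config.per_category,
    )
    true_off, true_bias = params.positivity_offset, params.negativity_bias
    offs, biases, cov_o, cov_b = [], [], [], []
    n_failed = 0
    for child in np.random.SeedSequence(config.seed).spawn(config.n_reps):
        s = int(child.generate_state(1)[0] % 2**31)
        try:
            _, _, trials = simulate_dataset(params, seed=s)
            design = build_activation_design(trials, seed=s + 1)
            fit = fit_lmm(design, compute_df=config.compute_df)
        except Exception:
            n_failed += 1
            continue
        row = fit.fixed.loc["function_pos"]
        offs.append(float(row["estimate"]))
        cov_o.append(bool(row["ci_low"] <= true_off <= row["ci_high"]))
        rb = fit.fixed.loc["fpos_x_arousal"]
        biases.append(float(-rb["estimate"]))
        cov_b.append(bool(-rb["ci_high"] <= true_bias <= -rb["ci_low"]))
    report = RecoveryReport(
        n_reps=len(offs),
        true_offset=true_off,
        true_bias=true_bias,
        offset_estimates=offs,
        bias_estimates=biases,
        offset_coverage=float(np.mean(cov_o)) if cov_o else np.nan,
        bias_coverage=float(np.mean(cov_b)) if cov_b else np.nan,
        n_failed=n_failed,
        tolerances={
            "offset": config.offset_bias_tolerance,
            "bias": config.bias_bias_tolerance,
            "coverage": config.coverage_band,
        },
    )
    report.evaluate()
    return report
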