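"""Synthetic rating-study generator with Evaluative Space Model structure.

The generator emulates the data layout of an online picture-rating study:
261 participants × 48 stimuli (16 pleasant / 16 neutral / 16 unpleasant, half
social), three integer ratings per trial on 0-8 scales, and four strongly
inter-correlated symptom scales (three CAPE item-mean subscales, one CAS sum
score).

Ratings are generated as the inverse of the estimation model.  Arousal is
drawn per trial from the stimulus category's distribution and discretized
first; the "congruent" responses (positivity on pleasant/neutral trials,
negativity on unpleasant/neutral trials) then follow linear activation
functions of the realized arousal rating:

    positivity = p0 + d_off/2 + (p1 - d_bias/2) * arousal + s_j + noise
    negativity = n0 - d_off/2 + (n1 + d_bias/2) * arousal + s_j + noise

where d_off ~ N(moderation, sd) is the participant's positivity-offset
deviation (mean offset = p0 - n0), d_bias the negativity-bias deviation
(mean bias = n1 - p1), and s_j a by-stimulus intercept deviation.  Symptom
moderation enters d_off and d_bias linearly in the z-scored moderator(s).
Incongruent responses (e.g. positivity toward unpleasant pictures) get their
own low means.  Continuous responses are rounded to the nearest integer and
clipped to [0, 8]; the clipped fraction is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .affect_scoring import SCALE_MAX, ValidationError
from .preprocessing import CATEGORIES, RawResponseStream, assemble_trial_table


@dataclass(frozen=True)
class ModerationEffect:
    """Linear effect of one z-scored symptom scale on offset and bias."""

    offset_per_sd: float = 0.0
    bias_per_sd: float = 0.0


def _default_symptom_marginals() -> dict:
    return {
        "cape_negative": (2.00, 0.57),
        "cape_depression": (1.94, 0.57),
        "cape_positive": (1.69, 0.61),
        "cas_anhedonia": (15.0, 8.13),
    }


def _default_symptom_corr() -> np.ndarray:
    # order: cape_negative, cape_depression, cape_positive, cas_anhedonia
    return np.array(
        [
            [1.00, 0.72, 0.75, 0.50],
            [0.72, 1.00, 0.79, 0.45],
            [0.75, 0.79, 1.00, 0.35],
            [0.50, 0.45, 0.35, 1.00],
        ]
    )


def _default_moderation() -> dict:
    # per-SD slopes of offset and bias in the driving moderator, from the
    # -1 SD / mean / +1 SD grid of the moderated activation models
    return {"cape_negative": ModerationEffect(offset_per_sd=-0.66, bias_per_sd=-0.13)}


@dataclass
class GeneratorParams:
    """All dials of the synthetic study; defaults reproduce the study conditions."""

    n_participants: int = 261
    n_pleasant: int = 16
    n_neutral: int = 16
    n_unpleasant: int = 16
    social_fraction: float = 0.5

    # category arousal distributions on the 0-8 scale (mean, sd)
    arousal_pleasant: tuple[float, float] = (3.80, 2.40)
    arousal_neutral: tuple[float, float] = (2.87, 1.93)
    arousal_unpleasant: tuple[float, float] = (5.02, 2.40)

    # activation functions: intercepts at arousal = 0 and arousal slopes
    p0: float = 5.29
    p1: float = 0.01
    n0: float = 2.89
    n1: float = 0.42

    # between-subject SDs of the offset / bias deviations (total, incl. moderation)
    offset_sd: float = 0.92
    bias_sd: float = 0.17

    moderation: dict = field(default_factory=_default_moderation)

    symptom_marginals: dict = field(default_factory=_default_symptom_marginals)
    symptom_corr: np.ndarray = field(default_factory=_default_symptom_corr)

    residual_sd: float = 1.2
    stimulus_sd: float = 0.3

    # incongruent response means (flat in arousal)
    positivity_unpleasant_mean: float = 1.5
    negativity_pleasant_mean: float = 1.0
    # optional additive shifts of congruent responses on their own category
    pleasant_positivity_shift: float = 0.0
    unpleasant_negativity_shift: float = 0.0

    # demographics
    age_mean: float = 41.3
    age_sd: float = 13.7
    male_fraction: float = 0.632
    education_mean: float = 14.2
    education_sd: float = 5.0

    discretize: bool = True
    max_clip_fraction: float = 0.10

    def __post_init__(self) -> None:
        self.symptom_corr = np.asarray(self.symptom_corr, dtype=float)
        if self.symptom_corr.shape != (4, 4):
            raise ValidationError("symptom_corr must be 4x4")
        if not np.allclose(self.symptom_corr, self.symptom_corr.T):
            raise ValidationError("symptom_corr must be symmetric")
        if np.linalg.eigvalsh(self.symptom_corr).min() < -1e-10:
            raise ValidationError("symptom_corr must be positive semi-definite")
        for name, val in (("offset_sd", self.offset_sd), ("bias_sd", self.bias_sd),
                          ("residual_sd", self.residual_sd), ("stimulus_sd", self.stimulus_sd)):
            if val < 0:
                raise ValidationError(f"{name} must be >= 0")
        moderation = {}
        for k, v in self.moderation.items():
            if k not in SCALE_MAX:
                raise ValidationError(f"unknown moderator {k!r}")
            moderation[k] = v if isinstance(v, ModerationEffect) else ModerationEffect(*v)
        self.moderation = moderation
        for kind in ("offset", "bias"):
            if self._residual_var(kind) < 0:
                raise ValidationError(
                    f"moderation explains more {kind} variance than {kind}_sd allows"
                )

    # -- derived, read-only quantities ------------------------------------
    @property
    def positivity_offset(self) -> float:
        """Implied mean positivity offset p0 - n0."""
        return self.p0 - self.n0

    @property
    def negativity_bias(self) -> float:
        """Implied mean negativity bias n1 - p1."""
        return self.n1 - self.p1

    def _gamma(self, kind: str) -> np.ndarray:
        order = list(SCALE_MAX)
        return np.array(
            [getattr(self.moderation.get(m, ModerationEffect()), f"{kind}_per_sd") for m in order]
        )

    def _residual_var(self, kind: str) -> float:
        g = self._gamma(kind)
        explained = float(g @ self.symptom_corr @ g)
        total = (self.offset_sd if kind == "offset" else self.bias_sd) ** 2
        return total - explained

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorParams":
        d = dict(d)
        if "moderation" in d:
            d["moderation"] = {k: ModerationEffect(**v) if isinstance(v, Mapping) else v
                               for k, v in d["moderation"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["symptom_corr"] = self.symptom_corr.tolist()
        d["moderation"] = {k: asdict(v) for k, v in self.moderation.items()}
        return d


def _discretize(x: np.ndarray, lo: int = 0, hi: int = 8) -> tuple[np.ndarray, float]:
    rounded = np.round(x)
    clipped = np.clip(rounded, lo, hi)
    frac = float(np.mean(rounded != clipped))
    return clipped.astype(int), frac


def simulate_participants(params: GeneratorParams, seed) -> pd.DataFrame:
    """Draw demographics and correlated, discretized symptom scores.

    Symptom scores come from a latent 4-variate Gaussian with the configured
    marginals and correlation matrix, mapped onto each scale's granularity
    (CAPE item-mean grid; CAS integer sum) and clipped to the valid range.
    """
    rng = np.random.default_rng(seed)
    n = params.n_participants
    ids = [f"p{i:04d}" for i in range(1, n + 1)]
    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), 18, 75).round(0)
    male = rng.random(n) < params.male_fraction
    edu = np.clip(rng.normal(params.education_mean, params.education_sd, n), 0, 32).round(0)

    order = list(SCALE_MAX)
    z = rng.multivariate_normal(np.zeros(4), params.symptom_corr, size=n, method="cholesky")
    df = pd.DataFrame(
        {
            "participant_id": ids,
            "age": age,
            "gender": np.where(male, "male", "female"),
            "education": edu,
        }
    )
    cape_items = {"cape_negative": 14, "cape_depression": 8, "cape_positive": 20}
    for j, scale in enumerate(order):
        mean, sd = params.symptom_marginals[scale]
        raw = mean + sd * z[:, j]
        if scale == "cas_anhedonia":
            df[scale] = np.clip(np.round(raw), 0, 43).astype(int)
        else:
            step = 1.0 / cape_items[scale]  # item-mean granularity
            df[scale] = np.clip(np.round(raw / step) * step, 1.0, 4.0)
        df[f"{scale}_z"] = z[:, j]  # latent z-scores, used for moderation
    return df


def simulate_stimulus_set(params: GeneratorParams, seed) -> pd.DataFrame:
    """Stimulus table: category, sociality flag, latent by-stimulus intercept."""
    rng = np.random.default_rng(seed)
    rows = []
    counts = {"pleasant": params.n_pleasant, "neutral": params.n_neutral,
              "unpleasant": params.n_unpleasant}
    for cat in CATEGORIES:
        k = counts[cat]
        if k < 1:
            raise ValidationError(f"need at least one {cat} stimulus")
        n_social = int(round(k * params.social_fraction))
        for i in range(k):
            rows.append(
                {
                    "stimulus_id": f"s_{cat[:4]}_{i + 1:02d}",
                    "category": cat,
                    "social": i < n_social,
                    "stimulus_dev": rng.normal(0.0, params.stimulus_sd) if params.stimulus_sd > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def simulate_ratings(
    participants: pd.DataFrame,
    stimuli: pd.DataFrame,
    params: GeneratorParams,
    seed,
) -> pd.DataFrame:
    """Generate the long trial table (one row per participant × stimulus).

    Returns a frame with the standard trial columns; ``.attrs['clip_fraction']``
    reports the proportion of continuous responses altered by clipping.
    """
    rng = np.random.default_rng(seed)
    n_sub = len(participants)
    n_stim = len(stimuli)

    # subject-level offset/bias deviations around their fixed means
    order = list(SCALE_MAX)
    zmat = participants[[f"{s}_z" for s in order]].to_numpy()
    g_off, g_bias = params._gamma("offset"), params._gamma("bias")
    d_off = zmat @ g_off + rng.normal(0.0, np.sqrt(params._residual_var("offset")), n_sub)
    d_bias = zmat @ g_bias + rng.normal(0.0, np.sqrt(params._residual_var("bias")), n_sub)

    arous_par = {
        "pleasant": params.arousal_pleasant,
        "neutral": params.arousal_neutral,
        "unpleasant": params.arousal_unpleasant,
    }

    # broadcast to trial grid
    sub_idx = np.repeat(np.arange(n_sub), n_stim)
    stim_idx = np.tile(np.arange(n_stim), n_sub)
    cat = stimuli["category"].to_numpy()[stim_idx]
    s_dev = stimuli["stimulus_dev"].to_numpy()[stim_idx]

    a_mean = np.array([arous_par[c][0] for c in cat])
    a_sd = np.array([arous_par[c][1] for c in cat])
    arousal_cont = rng.normal(a_mean, a_sd)
    n_clipped = 0
    n_values = 0
    if params.discretize:
        arousal, frac_a = _discretize(arousal_cont)
        n_clipped += frac_a * arousal.size
        n_values += arousal.size
    else:
        arousal = arousal_cont

    p_int = params.p0 + d_off / 2.0
    p_slope = params.p1 - d_bias / 2.0
    n_int = params.n0 - d_off / 2.0
    n_slope = params.n1 + d_bias / 2.0

    pos = np.where(
        cat == "unpleasant",
        params.positivity_unpleasant_mean,
        p_int[sub_idx] + p_slope[sub_idx] * arousal
        + np.where(cat == "pleasant", params.pleasant_positivity_shift, 0.0),
    ) + s_dev + rng.normal(0.0, params.residual_sd, sub_idx.size)
    neg = np.where(
        cat == "pleasant",
        params.negativity_pleasant_mean,
        n_int[sub_idx] + n_slope[sub_idx] * arousal
        + np.where(cat == "unpleasant", params.unpleasant_negativity_shift, 0.0),
    ) + s_dev + rng.normal(0.0, params.residual_sd, sub_idx.size)

    if params.discretize:
        pos, frac_p = _discretize(pos)
        neg, frac_n = _discretize(neg)
        n_clipped += (frac_p + frac_n) * pos.size
        n_values += 2 * pos.size

    trials = pd.DataFrame(
        {
            "participant_id": participants["participant_id"].to_numpy()[sub_idx],
            "stimulus_id": stimuli["stimulus_id"].to_numpy()[stim_idx],
            "category": cat,
            "social": stimuli["social"].to_numpy()[stim_idx],
            "positivity": pos,
            "negativity": neg,
            "arousal": arousal,
        }
    )
    trials.attrs["clip_fraction"] = (n_clipped / n_values) if n_values else 0.0
    if params.discretize and trials.attrs["clip_fraction"] > params.max_clip_fraction:
        import warnings

        warnings.warn(
            f"clip fraction {trials.attrs['clip_fraction']:.3f} exceeds ceiling "
            f"{params.max_clip_fraction:.3f}",
            stacklevel=2,
        )
    return trials


def simulate_dataset(
    params: GeneratorParams | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: (participants, stimuli, validated trials)."""
    params = params or GeneratorParams()
    ss = np.random.SeedSequence(seed)
    s_par, s_stim, s_rat = ss.spawn(3)
    participants = simulate_participants(params, s_par)
    stimuli = simulate_stimulus_set(params, s_stim)
    trials = simulate_ratings(participants, stimuli, params, s_rat)
    if params.discretize:
        trials = assemble_trial_table(trials)
        trials.attrs["clip_fraction"] = trials.attrs.get("clip_fraction", 0.0)
    return participants, stimuli, trials


def simulate_raw_streams(
    seed: int = 0,
    n_eligible: int = 269,
    n_long_string: int = 8,
    n_incomplete: int = 12,
    n_items: int = 85,
    n_trials: int = 48,
) -> list[RawResponseStream]:
    """Raw response streams for screening demos: a census of eligible,
    careless (long-string) and incomplete participants."""
    rng = np.random.default_rng(seed)
    streams = []
    total = n_eligible + n_incomplete
    for i in range(total):
        pid = f"r{i:04d}"
        answers = list(rng.integers(1, 5, n_items))
        ratings = [tuple(rng.integers(0, 9, 3)) for _ in range(n_trials)]
        if i < n_long_string:
            # careless participant: >50 identical answers in a row inside the task
            const = tuple([4, 4, 4])
            ratings = [const] * 20 + ratings[20:]
            answers[-10:] = [4] * 10
        elif i >= n_eligible:
            k = int(rng.integers(13, 36))  # < 75% of 48 trials completed
            ratings = ratings[:k] + [None] * (n_trials - k)
        streams.append(
            RawResponseStream(
                participant_id=pid,
                questionnaire_answers=answers,
                task_ratings=ratings,
                n_trials=n_trials,
            )
        )
    return streams


def fixture_dataset(seed: int = 0, n_participants: int = 12, per_category: int = 4):
    """Small deterministic dataset for tests and examples."""
    params = GeneratorParams(
        n_participants=n_participants,
        n_pleasant=per_category,
        n_neutral=per_category,
        n_unpleasant=per_category,
    )
    return simulate_dataset(params, seed=seed)
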