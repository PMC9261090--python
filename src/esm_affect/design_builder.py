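"""Build the three analysis datasets from a validated trial table.

All designs are long-format (one observation per row) with explicit numeric
design columns, so the model engine never needs a formula language:

* category design — outcome (positivity / negativity / arousal) on a
  stimulus-category factor (neutral reference), maximal random structure
  (by-subject intercept + category slopes, by-stimulus intercept);
* ambivalence design — same structure with the per-trial ambivalence index
  as outcome;
* activation design — the Evaluative Space Model dataset: positivity ratings
  on pleasant + half the neutral stimuli and negativity ratings on unpleasant
  + the other half form a single ``emotional_activation`` outcome, predicted
  by the activation-function factor (negativity reference, so its fixed
  effect is the positivity offset), raw 0-8 arousal, and their interaction.
  The neutral stimuli are split randomly per participant so no stimulus
  contributes to both functions.

Random slopes for the activation factor use effect coding (±1/2) so a single
diagonal variance component represents between-subject offset heterogeneity
placed symmetrically on the two functions; its fitted SD is directly the
between-subject SD of the positivity offset (likewise for the bias slope).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .affect_scoring import SCALE_MAX, ValidationError, ambivalence_values, add_normalized_scores
from .preprocessing import CATEGORIES

RAW_OUTCOMES = ("positivity", "negativity", "arousal")


class DesignError(ValidationError):
    """Raised when a requested design cannot be built from the data."""


@dataclass(frozen=True)
class RandomTerm:
    """One diagonal variance component: ``column`` (None = intercept) within ``group``."""

    group: str  # grouping identifier column, e.g. "participant_id"
    column: str | None  # numeric design column; None means random intercept
    name: str


@dataclass(frozen=True)
class RandomBlock:
    """Correlated random effects within one group: unstructured k×k covariance."""

    group: str
    columns: tuple  # numeric design columns (None entries = intercept)
    names: tuple  # one label per column

    def __post_init__(self) -> None:
        if len(self.columns) != len(self.names):
            raise DesignError("RandomBlock needs one name per column")


@dataclass
class RandomStructure:
    terms: list[RandomTerm] = field(default_factory=list)
    blocks: list[RandomBlock] = field(default_factory=list)

    def validate(self, data: pd.DataFrame) -> None:
        for t in self.terms:
            if t.group not in data.columns:
                raise DesignError(f"grouping column {t.group!r} missing")
            if t.column is not None and t.column not in data.columns:
                raise DesignError(f"random-slope column {t.column!r} missing")
        for b in self.blocks:
            if b.group not in data.columns:
                raise DesignError(f"grouping column {b.group!r} missing")
            for col in b.columns:
                if col is not None and col not in data.columns:
                    raise DesignError(f"random-slope column {col!r} missing")


@dataclass
class ModelDataset:
    """Long-format analysis table with its fixed and random design declared."""

    outcome: str
    data: pd.DataFrame
    fixed_effects: list[str]  # design columns, intercept implicit
    random: RandomStructure
    factors: dict = field(default_factory=dict)  # factor name -> design columns
    meta: dict = field(default_factory=dict)
    description: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in self.data.columns:
            raise DesignError(f"outcome column {self.outcome!r} missing")
        missing = [c for c in self.fixed_effects if c not in self.data.columns]
        if missing:
            raise DesignError(f"fixed-effect columns missing: {missing}")
        self.random.validate(self.data)

    def to_csv(self, path) -> None:
        """Write the long table plus a JSON sidecar describing the design."""
        self.data.to_csv(path, index=False)
        sidecar = {
            "outcome": self.outcome,
            "fixed_effects": self.fixed_effects,
            "random_terms": [
                {"group": t.group, "column": t.column, "name": t.name}
                for t in self.random.terms
            ],
            "random_blocks": [
                {"group": b.group, "columns": list(b.columns), "names": list(b.names)}
                for b in self.random.blocks
            ],
            "factors": self.factors,
            "meta": {k: v for k, v in self.meta.items() if _json_safe(v)},
            "description": self.description,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _category_dummies(data: pd.DataFrame) -> list[str]:
    present = sorted(set(data["category"].astype(str)))
    if len(present) < 2:
        raise DesignError(f"degenerate design: only categories {present} present, no contrast estimable")
    cols = []
    for cat in ("pleasant", "unpleasant"):  # neutral is the reference level
        col = f"cat_{cat}"
        data[col] = (data["category"].astype(str) == cat).astype(float)
        cols.append(col)
    return cols


def _maximal_category_random() -> RandomStructure:
    return RandomStructure(
        [
            RandomTerm("participant_id", None, "subject_intercept"),
            RandomTerm("participant_id", "cat_pleasant", "subject_cat_pleasant"),
            RandomTerm("participant_id", "cat_unpleasant", "subject_cat_unpleasant"),
            RandomTerm("stimulus_id", None, "stimulus_intercept"),
        ]
    )


def build_category_design(trials: pd.DataFrame, outcome: str) -> ModelDataset:
    """One row per trial; outcome on the stimulus-category factor (neutral ref)."""
    if outcome not in RAW_OUTCOMES:
        raise DesignError(f"unknown outcome {outcome!r}; expected one of {RAW_OUTCOMES}")
    data = trials.copy()
    cols = _category_dummies(data)
    return ModelDataset(
        outcome=outcome,
        data=data,
        fixed_effects=cols,
        random=_maximal_category_random(),
        factors={"category": cols},
        description=f"{outcome} ~ category with maximal crossed random effects",
    )


def build_ambivalence_design(trials: pd.DataFrame) -> ModelDataset:
    """Category design with the per-trial ambivalence index as outcome."""
    data = trials.copy()
    data["ambivalence"] = ambivalence_values(data["positivity"], data["negativity"])
    cols = _category_dummies(data)
    return ModelDataset(
        outcome="ambivalence",
        data=data,
        fixed_effects=cols,
        random=_maximal_category_random(),
        factors={"category": cols},
        description="ambivalence ~ category with maximal crossed random effects",
    )


def build_activation_design(
    trials: pd.DataFrame,
    seed: int = 0,
    stratify_social: bool = False,
    correlated_slopes: bool = True,
) -> ModelDataset:
    """Activation-function dataset with a per-participant random neutral split.

    Positivity-function rows: positivity ratings on all pleasant trials plus a
    random half of the participant's neutral trials.  Negativity-function
    rows: negativity ratings on all unpleasant trials plus the other half.
    With an odd neutral count the two halves differ in size by one.  The split
    is deterministic given ``seed`` and independent of row order; with
    ``stratify_social`` it is drawn separately within social / nonsocial
    neutral stimuli.

    The by-subject random slopes for function and function×arousal form an
    unstructured (correlated) block by default — a person's offset and bias
    deviations are correlated whenever a shared factor drives both; pass
    ``correlated_slopes=False`` for independent variance components.
    """
    rng = np.random.default_rng(seed)
    base = trials.sort_values(["participant_id", "stimulus_id"], kind="mergesort").reset_index(drop=True)
    cat = base["category"].astype(str).to_numpy()
    pos_side = np.zeros(len(base), dtype=bool)  # row feeds the positivity function
    pos_side[cat == "pleasant"] = True
    neutral_counts = base.loc[cat == "neutral"].groupby("participant_id", observed=True).size()
    for pid in base["participant_id"].unique():
        if neutral_counts.get(pid, 0) < 2:
            raise DesignError(
                f"participant {pid!r} has {neutral_counts.get(pid, 0)} neutral trials; need >= 2"
            )
    for pid, grp in sorted(
        base[cat == "neutral"].groupby("participant_id", observed=True), key=lambda kv: str(kv[0])
    ):
        if stratify_social:
            chosen: list[int] = []
            for _, sub in grp.groupby("social"):
                perm = rng.permutation(len(sub))
                chosen.extend(sub.index.to_numpy()[perm[: len(sub) // 2]])
        else:
            perm = rng.permutation(len(grp))
            chosen = list(grp.index.to_numpy()[perm[: len(grp) // 2]])
        pos_side[chosen] = True
    data = pd.DataFrame(
        {
            "participant_id": base["participant_id"].to_numpy(),
            "stimulus_id": base["stimulus_id"].to_numpy(),
            "category": cat,
            "emotional_activation": np.where(
                pos_side, base["positivity"].to_numpy(float), base["negativity"].to_numpy(float)
            ),
            "function_pos": pos_side.astype(float),
            "arousal": base["arousal"].to_numpy(float),
        }
    )
    data["fpos_x_arousal"] = data["function_pos"] * data["arousal"]
    # effect-coded random-slope columns (see module docstring)
    data["f_eff"] = data["function_pos"] - 0.5
    data["f_eff_x_arousal"] = data["f_eff"] * data["arousal"]
    if correlated_slopes:
        random = RandomStructure(
            terms=[RandomTerm("stimulus_id", None, "stimulus_intercept")],
            blocks=[
                RandomBlock(
                    "participant_id",
                    ("f_eff", "f_eff_x_arousal"),
                    ("subject_offset", "subject_bias"),
                )
            ],
        )
    else:
        random = RandomStructure(
            [
                RandomTerm("participant_id", "f_eff", "subject_offset"),
                RandomTerm("participant_id", "f_eff_x_arousal", "subject_bias"),
                RandomTerm("stimulus_id", None, "stimulus_intercept"),
            ]
        )
    return ModelDataset(
        outcome="emotional_activation",
        data=data,
        fixed_effects=["function_pos", "arousal", "fpos_x_arousal"],
        random=random,
        factors={
            "function": ["function_pos"],
            "arousal": ["arousal"],
            "function_x_arousal": ["fpos_x_arousal"],
        },
        meta={"split_seed": seed},
        description="emotional_activation ~ function * arousal (activation-function dataset)",
    )


#: covariate sets: the "other" symptom domains entered alongside each moderator
OTHER_SYMPTOMS = {
    "cape_negative": ["cape_positive", "cape_depression"],
    "cape_depression": ["cape_negative", "cape_positive"],
    "cape_positive": ["cape_negative", "cape_depression"],
    # CAPE negative overlaps conceptually with anhedonia, so it is left out
    "cas_anhedonia": ["cape_positive", "cape_depression"],
}


def attach_moderator(
    design: ModelDataset,
    moderator: str,
    participants: pd.DataFrame,
    include_covariates: bool = True,
) -> ModelDataset:
    """Attach a level-2 symptom moderator and its cross-level interactions.

    Adds the normalized (unit-rescaled, sample-centered) moderator, its
    interaction with every level-1 fixed term, and — unless
    ``include_covariates=False`` — age, a male indicator, years of education
    and the respective other symptom domains as main-effect covariates.
    """
    if moderator not in SCALE_MAX:
        raise DesignError(f"unknown moderator {moderator!r}; expected one of {list(SCALE_MAX)}")
    part = participants
    if f"{moderator}_norm" not in part.columns:
        part = add_normalized_scores(part)

    keep = ["participant_id", "age", "gender", "education"] + [f"{s}_norm" for s in SCALE_MAX]
    data = design.data.merge(part[keep], on="participant_id", how="left", validate="many_to_one")
    if data[f"{moderator}_norm"].isna().any():
        raise DesignError("trials reference participants missing from the participant table")

    mod_col = "mod"
    data[mod_col] = data[f"{moderator}_norm"] - data[f"{moderator}_norm"].mean()
    fixed = list(design.fixed_effects) + [mod_col]
    inter_cols = []
    for fe in design.fixed_effects:
        col = f"{fe}_x_mod"
        data[col] = data[fe] * data[mod_col]
        inter_cols.append(col)
    fixed += inter_cols

    covariates: list[str] = []
    if include_covariates:
        data["age_c"] = data["age"] - data["age"].mean()
        data["male"] = (data["gender"] == "male").astype(float)
        data["education_c"] = data["education"] - data["education"].mean()
        covariates = ["age_c", "male", "education_c"]
        for other in OTHER_SYMPTOMS[moderator]:
            col = f"{other}_norm"
            data[col] = data[col] - data[col].mean()
            covariates.append(col)
    fixed += covariates

    factors = dict(design.factors)
    factors["moderator"] = [mod_col]
    for fac, cols in design.factors.items():
        factors[f"moderator_x_{fac}"] = [f"{c}_x_mod" for c in cols]

    meta = dict(design.meta)
    meta.update(
        moderator=moderator,
        moderator_sd=float(data[mod_col].std(ddof=1)),
        include_covariates=include_covariates,
    )
    return ModelDataset(
        outcome=design.outcome,
        data=data,
        fixed_effects=fixed,
        random=RandomStructure(list(design.random.terms), list(design.random.blocks)),
        factors=factors,
        meta=meta,
        description=design.description + f" moderated by {moderator}"
        + ("" if include_covariates else " (no covariates)"),
    )
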