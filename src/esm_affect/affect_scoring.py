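"""Questionnaire scoring, the per-stimulus ambivalence index, and effect-size helpers.

The ambivalence index follows Kaplan's decomposition of co-activated affect:
``total affect`` (the mean of the positivity and negativity ratings) captures
the strength of the joint response, ``polarity`` (the absolute difference)
captures how one-sided it is, and ambivalence is their difference

    ambivalence = (positivity + negativity) / 2 - |positivity - negativity|

On 0-8 rating scales the index ranges from -4 (a maximally polarized response,
e.g. 8 vs. 0) to 8 (maximal co-activation, 8 vs. 8).

Symptom scales: the CAPE (Community Assessment of Psychic Experiences) yields
item-mean scores in [1, 4] for its negative, depression and positive subscales;
the Chapman anhedonia scales (CAS) yield a dichotomous-item sum in [0, 43].
For cross-scale comparability every score is divided by its possible scale
maximum and centered to the sample mean before entering any model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RATING_MIN = 0
RATING_MAX = 8

#: possible maximum of each symptom scale, used for unit-rescaling
SCALE_MAX: Mapping[str, float] = {
    "cape_negative": 4.0,
    "cape_depression": 4.0,
    "cape_positive": 4.0,
    "cas_anhedonia": 43.0,
}

#: standard CAPE-42 subscale lengths (positive / negative / depression)
CAPE_SUBSCALE_ITEMS: Mapping[str, int] = {
    "cape_positive": 20,
    "cape_negative": 14,
    "cape_depression": 8,
}

SYMPTOM_SCALES = tuple(SCALE_MAX)


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class AmbivalenceValue:
    """Ambivalence index with its two components exposed."""

    value: float
    total_affect: float
    polarity: float


@dataclass
class ParticipantRecord:
    """Demographics plus raw and normalized symptom scores for one participant."""

    participant_id: str
    age: float
    gender: str  # "male" | "female" | "other" | "missing"
    education: float
    cape_negative: float
    cape_depression: float
    cape_positive: float
    cas_anhedonia: int
    cape_negative_norm: float | None = None
    cape_depression_norm: float | None = None
    cape_positive_norm: float | None = None
    cas_anhedonia_norm: float | None = None


def _check_rating(x, name: str) -> float:
    try:
        val = float(x)
    except (TypeError, ValueError):
        raise ValidationError(f"{name} rating must be numeric, got {x!r}") from None
    if not np.isfinite(val) or not (RATING_MIN <= val <= RATING_MAX):
        raise ValidationError(
            f"{name} rating must lie in [{RATING_MIN}, {RATING_MAX}], got {x!r}"
        )
    return val


def ambivalence(positivity, negativity) -> AmbivalenceValue:
    """Per-stimulus ambivalence: mean co-activation minus absolute polarity.

    Both ratings must lie on the 0-8 scale.  Examples: (8, 2) -> -1,
    (5, 5) -> 5, (6, 0) -> -3.
    """
    p = _check_rating(positivity, "positivity")
    n = _check_rating(negativity, "negativity")
    total = (p + n) / 2.0
    polarity = abs(p - n)
    return AmbivalenceValue(value=total - polarity, total_affect=total, polarity=polarity)


def ambivalence_values(positivity, negativity) -> np.ndarray:
    """Vectorized ambivalence for rating arrays (no per-element objects)."""
    p = np.asarray(positivity, dtype=float)
    n = np.asarray(negativity, dtype=float)
    if p.shape != n.shape:
        raise ValidationError("positivity and negativity arrays must have equal shape")
    bad = ~(np.isfinite(p) & np.isfinite(n)) | (p < RATING_MIN) | (p > RATING_MAX) | (
        n < RATING_MIN
    ) | (n > RATING_MAX)
    if bad.any():
        raise ValidationError(f"{int(bad.sum())} rating(s) outside [0, 8]")
    return (p + n) / 2.0 - np.abs(p - n)


def cape_scale_score(item_responses: Sequence[int]) -> float:
    """Item-mean CAPE subscale score in [1, 4].

    Missing or out-of-range items are rejected rather than imputed (the study
    instrument used forced entry, so missingness signals a data error).
    """
    items = list(item_responses)
    if len(items) == 0:
        raise ValidationError("CAPE scale needs at least one item response")
    arr = np.asarray(items, dtype=float)
    if not np.all(np.isin(arr, [1, 2, 3, 4])):
        raise ValidationError("CAPE item responses must be integers in {1, 2, 3, 4}")
    return float(arr.mean())


def cas_score(item_responses: Sequence[int], n_items: int = 43) -> int:
    """Sum score of the dichotomous anhedonia items (default 43 items)."""
    arr = np.asarray(list(item_responses), dtype=float)
    if arr.size != n_items:
        raise ValidationError(f"expected {n_items} CAS items, got {arr.size}")
    if not np.all(np.isin(arr, [0, 1])):
        raise ValidationError("CAS item responses must be 0 or 1")
    return int(arr.sum())


def normalize_symptom_scores(scores, scale_max: float) -> np.ndarray:
    """Divide scores by the scale's possible maximum, then center to the sample mean.

    The returned vector is unit-rescaled (range comparable across scales) and
    has mean zero to numerical tolerance.
    """
    if not np.isfinite(scale_max) or scale_max <= 0:
        raise ValidationError(f"scale_max must be positive, got {scale_max!r}")
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValidationError("need at least one score")
    rescaled = arr / float(scale_max)
    return rescaled - rescaled.mean()


def cohens_d(mean_a, sd_a, mean_b, sd_b, n_a: int | None = None, n_b: int | None = None) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD.

    By default the pooled SD is the unweighted root mean square of the two
    group SDs; pass both sample sizes to use the n-weighted pooled SD instead.
    """
    sd_a, sd_b = float(sd_a), float(sd_b)
    if sd_a <= 0 or sd_b <= 0:
        raise ValidationError("both SDs must be positive")
    if (n_a is None) != (n_b is None):
        raise ValidationError("provide both sample sizes or neither")
    if n_a is not None:
        if n_a < 2 or n_b < 2:
            raise ValidationError("sample sizes must be >= 2 for weighted pooling")
        pooled = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    else:
        pooled = np.sqrt((sd_a**2 + sd_b**2) / 2.0)
    return (float(mean_a) - float(mean_b)) / pooled


# ---------------------------------------------------------------------------
# participant tables
# ---------------------------------------------------------------------------

PARTICIPANT_COLUMNS = [
    "participant_id",
    "age",
    "gender",
    "education",
    "cape_negative",
    "cape_depression",
    "cape_positive",
    "cas_anhedonia",
]


def add_normalized_scores(participants: pd.DataFrame) -> pd.DataFrame:
    """Attach ``*_norm`` columns: score / scale maximum, centered to the sample mean."""
    out = participants.copy()
    for scale, scale_max in SCALE_MAX.items():
        if scale not in out.columns:
            raise ValidationError(f"participant table lacks column {scale!r}")
        out[f"{scale}_norm"] = normalize_symptom_scores(out[scale].to_numpy(), scale_max)
    return out


def read_participants_csv(path) -> pd.DataFrame:
    """Read a one-row-per-participant CSV and attach normalized scores."""
    df = pd.read_csv(path)
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"participant CSV lacks columns: {missing}")
    for scale in ("cape_negative", "cape_depression", "cape_positive"):
        vals = df[scale].to_numpy(dtype=float)
        if ((vals < 1) | (vals > 4)).any():
            raise ValidationError(f"{scale} scores must lie in [1, 4]")
    cas = df["cas_anhedonia"].to_numpy(dtype=float)
    if ((cas < 0) | (cas > 43)).any() or not np.allclose(cas, np.round(cas)):
        raise ValidationError("cas_anhedonia must be integer in [0, 43]")
    return add_normalized_scores(df)


def write_participants_csv(participants: pd.DataFrame, path) -> None:
    participants.to_csv(path, index=False)


def score_item_responses(items: pd.DataFrame) -> pd.DataFrame:
    """Score an item-level table (participant_id + item columns) to scale scores.

    Expected column conventions: ``cape_pos_01..20``, ``cape_neg_01..14``,
    ``cape_dep_01..08`` and ``cas_01..43``.
    """
    prefix = {"cape_positive": "cape_pos", "cape_negative": "cape_neg", "cape_depression": "cape_dep"}
    rows = []
    for _, row in items.iterrows():
        rec: dict = {"participant_id": row["participant_id"]}
        for scale, n in CAPE_SUBSCALE_ITEMS.items():
            cols = [f"{prefix[scale]}_{i:02d}" for i in range(1, n + 1)]
            rec[scale] = cape_scale_score([row[c] for c in cols])
        cas_cols = [f"cas_{i:02d}" for i in range(1, 44)]
        rec["cas_anhedonia"] = cas_score([row[c] for c in cas_cols])
        rows.append(rec)
    return pd.DataFrame(rows)
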