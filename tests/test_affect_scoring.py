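"""Ambivalence index, questionnaire scoring and effect-size helpers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from esm_affect import affect_scoring as sc
from esm_affect.affect_scoring import ValidationError


def brute_force_ambivalence(p, n):
    """Independent re-derivation: mean co-activation minus absolute polarity."""
    return (p + n) / 2 - abs(p - n)


class TestAmbivalence:
    @pytest.mark.parametrize(
        "p, n, expected",
        [(8, 2, -1.0), (5, 5, 5.0), (6, 0, -3.0), (0, 0, 0.0), (8, 8, 8.0), (8, 0, -4.0)],
    )
    def test_worked_examples(self, p, n, expected):
        res = sc.ambivalence(p, n)
        assert res.value == pytest.approx(expected)
        assert res.value == pytest.approx(res.total_affect - res.polarity)

    def test_components_exposed(self):
        res = sc.ambivalence(8, 2)
        assert res.total_affect == 5.0
        assert res.polarity == 6.0

    def test_full_integer_grid_matches_oracle_and_bounds(self):
        values = {
            (p, n): sc.ambivalence(p, n).value for p in range(9) for n in range(9)
        }
        for (p, n), v in values.items():
            assert v == brute_force_ambivalence(p, n)
            assert values[(n, p)] == v  # symmetry
        assert min(values.values()) == -4
        assert max(values.values()) == 8
        # extremes attained where maximal polarity / maximal co-activation occur
        assert values[(8, 0)] == values[(0, 8)] == -4
        assert values[(8, 8)] == 8

    @pytest.mark.parametrize("x", range(9))
    def test_equal_ratings_return_rating(self, x):
        assert sc.ambivalence(x, x).value == x

    @given(
        p=st.floats(min_value=0, max_value=8, allow_nan=False),
        n=st.floats(min_value=0, max_value=8, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetry_and_bounds_on_continuous_domain(self, p, n):
        v = sc.ambivalence(p, n).value
        assert v == pytest.approx(sc.ambivalence(n, p).value)
        assert -4 - 1e-9 <= v <= 8 + 1e-9

    @pytest.mark.parametrize("p, n", [(9, 0), (-1, 3), (0, 8.5), ("x", 2), (np.nan, 1)])
    def test_out_of_range_rejected(self, p, n):
        with pytest.raises(ValidationError):
            sc.ambivalence(p, n)

    def test_vectorized_matches_scalar(self):
        p = np.array([8, 5, 6, 0])
        n = np.array([2, 5, 0, 0])
        np.testing.assert_allclose(sc.ambivalence_values(p, n), [-1, 5, -3, 0])
        with pytest.raises(ValidationError):
            sc.ambivalence_values([9], [0])


class TestQuestionnaireScoring:
    @pytest.mark.parametrize(
        "items, expected",
        [([1] * 42, 1.0), ([1, 3], 2.0), ([4] * 10, 4.0)],
    )
    def test_cape_item_mean(self, items, expected):
        assert sc.cape_scale_score(items) == pytest.approx(expected)

    @pytest.mark.parametrize("items", [[], [0, 1], [1, 5], [1.5, 2]])
    def test_cape_rejects_bad_items(self, items):
        with pytest.raises(ValidationError):
            sc.cape_scale_score(items)

    @pytest.mark.parametrize(
        "items, expected",
        [([0] * 43, 0), ([1] * 43, 43), ([1] * 15 + [0] * 28, 15)],
    )
    def test_cas_sum(self, items, expected):
        assert sc.cas_score(items) == expected

    def test_cas_rejects_nonbinary_and_wrong_length(self):
        with pytest.raises(ValidationError):
            sc.cas_score([2] + [0] * 42)
        with pytest.raises(ValidationError):
            sc.cas_score([0] * 10)
        assert sc.cas_score([1, 0, 1], n_items=3) == 2  # configurable length


class TestNormalization:
    @pytest.mark.parametrize(
        "scores, smax, expected",
        [
            ([2, 4], 4, [-0.25, 0.25]),
            ([3, 3, 3], 4, [0, 0, 0]),
            ([0, 43], 43, [-0.5, 0.5]),
        ],
    )
    def test_rescale_then_center(self, scores, smax, expected):
        np.testing.assert_allclose(sc.normalize_symptom_scores(scores, smax), expected)

    @given(
        scores=st.lists(st.integers(min_value=0, max_value=43), min_size=1, max_size=30),
        smax=st.sampled_from([4.0, 43.0]),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_zero_mean_and_rank_preserved(self, scores, smax):
        out = sc.normalize_symptom_scores(scores, smax)
        assert abs(out.mean()) < 1e-12
        assert np.array_equal(np.argsort(out, kind="stable"), np.argsort(scores, kind="stable"))

    @pytest.mark.parametrize("smax", [0, -1, np.nan])
    def test_invalid_scale_max(self, smax):
        with pytest.raises(ValidationError):
            sc.normalize_symptom_scores([1, 2], smax)


class TestCohensD:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((3.80, 2.40, 5.07, 2.34), -0.54),
            ((2.87, 1.93, 3.03, 1.93), -0.08),
            ((4.0, 1.0, 4.0, 2.0), 0.0),
        ],
    )
    def test_printed_norm_comparisons(self, args, expected):
        assert round(sc.cohens_d(*args), 2) == expected

    def test_antisymmetric_and_zero_iff_equal_means(self):
        d = sc.cohens_d(3.1, 1.2, 2.4, 0.9)
        assert sc.cohens_d(2.4, 0.9, 3.1, 1.2) == pytest.approx(-d)
        assert d != 0

    def test_weighted_pooling_option(self):
        unweighted = sc.cohens_d(4, 1, 3, 2)
        weighted = sc.cohens_d(4, 1, 3, 2, n_a=100, n_b=10)
        assert weighted != pytest.approx(unweighted)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValidationError):
            sc.cohens_d(1, 0, 2, 1)


class TestParticipantTables:
    def test_normalized_columns_have_zero_mean(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c"],
                "age": [20, 30, 40],
                "gender": ["male", "female", "male"],
                "education": [12, 16, 10],
                "cape_negative": [1.0, 2.0, 3.0],
                "cape_depression": [1.5, 2.5, 1.0],
                "cape_positive": [1.0, 1.0, 4.0],
                "cas_anhedonia": [0, 20, 40],
            }
        )
        out = sc.add_normalized_scores(df)
        for scale in sc.SCALE_MAX:
            assert abs(out[f"{scale}_norm"].mean()) < 1e-12

    def test_participants_csv_roundtrip_validates(self, tmp_path):
        df = pd.DataFrame(
            {
                "participant_id": ["a", "b"],
                "age": [25, 35],
                "gender": ["male", "female"],
                "education": [12, 16],
                "cape_negative": [1.5, 2.5],
                "cape_depression": [1.0, 2.0],
                "cape_positive": [1.0, 3.0],
                "cas_anhedonia": [5, 30],
            }
        )
        path = tmp_path / "p.csv"
        sc.write_participants_csv(df, path)
        back = sc.read_participants_csv(path)
        assert "cape_negative_norm" in back.columns
        df.loc[0, "cape_negative"] = 9.0
        sc.write_participants_csv(df, path)
        with pytest.raises(ValidationError):
            sc.read_participants_csv(path)

    def test_item_level_scoring(self):
        rng = np.random.default_rng(1)
        row = {"participant_id": "a"}
        for scale, prefix, k in (
            ("cape_positive", "cape_pos", 20),
            ("cape_negative", "cape_neg", 14),
            ("cape_depression", "cape_dep", 8),
        ):
            for i in range(1, k + 1):
                row[f"{prefix}_{i:02d}"] = int(rng.integers(1, 5))
        for i in range(1, 44):
            row[f"cas_{i:02d}"] = int(rng.integers(0, 2))
        scored = sc.score_item_responses(pd.DataFrame([row]))
        assert scored.loc[0, "cape_negative"] == pytest.approx(
            np.mean([row[f"cape_neg_{i:02d}"] for i in range(1, 15)])
        )
        assert scored.loc[0, "cas_anhedonia"] == sum(row[f"cas_{i:02d}"] for i in range(1, 44))
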