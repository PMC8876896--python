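"""Ordinal encoding, windowing and the ten summary features."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moodnpi.features import (
    FEATURE_NAMES,
    EmotionSeries,
    EmptyWindowError,
    UnknownLabelError,
    encode_label,
    extract_features,
    features_dataframe,
    window_series,
)


def brute_force_features(codes: list[int]) -> dict:
    """Independent naive-loop implementation of the ten statistics."""
    n = len(codes)
    freq = {c: sum(1 for e in codes if e == c) for c in (1, 2, 3, 4)}
    mean = sum(codes) / n
    jumps = [abs(codes[i] - codes[i - 1]) for i in range(1, n)]
    if n == 1:
        sf, sr, sd = 0, 0, 0.0
    else:
        sf = sum(jumps)
        sr = max(jumps) - min(jumps)
        sd = math.sqrt(sum((e - mean) ** 2 for e in codes) / (n - 1))
    return {
        "freq_negative": freq[1] + freq[2],
        "freq_sadness": freq[2],
        "freq_anger": freq[1],
        "freq_neutrality": freq[3],
        "freq_happiness": freq[4],
        "diff_happy_sad": freq[4] - freq[2],
        "mean_amplitude": mean,
        "switch_frequency": sf,
        "switch_range": sr,
        "sd_moods": sd,
    }


def series(codes) -> EmotionSeries:
    return EmotionSeries(codes=np.asarray(codes), window=(0, 7))


class TestEncodeLabel:
    @pytest.mark.parametrize(
        "label,code",
        [("anger", 1), ("sadness", 2), ("neutrality", 3), ("happiness", 4),
         ("  Happiness ", 4), ("ANGER", 1)],
    )
    def test_ordinal_mapping_is_case_insensitive(self, label, code):
        assert encode_label(label) == code

    def test_unknown_label_names_value_and_row(self):
        with pytest.raises(UnknownLabelError, match=r"HAPPY FACE.*row 12"):
            encode_label("HAPPY FACE", row=12)


def one_per_day(days, pid="P01"):
    return pd.DataFrame(
        {"participant_id": pid, "day": list(days), "rank": 0,
         "code": [(d % 4) + 1 for d in days]}
    )


class TestWindowSeries:
    def test_seven_day_window_is_half_open(self):
        recs = one_per_day(range(10))
        s = window_series(recs, assessment_day=7, window_days=7)
        assert s.n == 7
        assert s.window == (0, 7)
        assert list(s.codes) == [(d % 4) + 1 for d in range(7)]

    def test_window_truncates_at_data_start(self):
        s = window_series(one_per_day(range(10)), assessment_day=3)
        assert s.n == 3

    def test_assessment_day_itself_is_excluded(self):
        recs = one_per_day([6, 7])
        s = window_series(recs, assessment_day=7)
        assert s.n == 1 and s.window == (0, 7)

    def test_within_day_rank_orders_ties(self):
        recs = pd.DataFrame(
            {"participant_id": "P01", "day": [5, 5, 5], "rank": [2, 0, 1],
             "code": [4, 1, 2]}
        )
        s = window_series(recs, assessment_day=7)
        assert list(s.codes) == [1, 2, 4]

    def test_empty_window_is_signalled(self):
        with pytest.raises(EmptyWindowError, match="no facial-expression data"):
            window_series(one_per_day([9]), assessment_day=7)

    def test_daily_aggregation_takes_modal_code_ties_to_lower(self):
        recs = pd.DataFrame(
            {"participant_id": "P01",
             "day": [1, 1, 1, 2, 2],
             "rank": [0, 1, 2, 0, 1],
             "code": [4, 4, 1, 2, 4]}  # day1 modal 4; day2 tie 2 vs 4 -> 2
        )
        s = window_series(recs, assessment_day=7, aggregate_daily=True)
        assert list(s.codes) == [4, 2]


class TestExtractFeatures:
    @pytest.mark.parametrize(
        "codes,expected",
        [
            (
                [4] * 7,
                dict(freq_happiness=7, freq_negative=0, diff_happy_sad=7,
                     mean_amplitude=4.0, switch_frequency=0, switch_range=0,
                     sd_moods=0.0),
            ),
            (
                [1, 2, 3, 4],
                dict(freq_anger=1, freq_sadness=1, freq_neutrality=1,
                     freq_happiness=1, freq_negative=2, diff_happy_sad=0,
                     mean_amplitude=2.5, switch_frequency=3, switch_range=0,
                     sd_moods=1.29099),
            ),
            (
                [2, 2, 4],
                dict(freq_sadness=2, freq_happiness=1, diff_happy_sad=-1,
                     mean_amplitude=2.6667, switch_frequency=2, switch_range=2,
                     sd_moods=1.15470),
            ),
        ],
    )
    def test_worked_examples(self, codes, expected):
        fv = extract_features(series(codes)).as_dict()
        for name, value in expected.items():
            assert fv[name] == pytest.approx(value, abs=1e-4), name

    def test_single_observation_window_defines_switch_and_sd_as_zero(self):
        fv = extract_features(series([3]))
        assert (fv.switch_frequency, fv.switch_range, fv.sd_moods) == (0, 0, 0.0)

    def test_rejects_codes_outside_the_scale(self):
        with pytest.raises(ValueError, match="codes"):
            series([1, 5])


@settings(max_examples=300, derandomize=True, deadline=None)
@given(st.lists(st.integers(1, 4), min_size=1, max_size=50))
def test_features_match_brute_force_oracle(codes):
    fv = extract_features(series(codes)).as_dict()
    expected = brute_force_features(codes)
    for name in FEATURE_NAMES:
        assert fv[name] == pytest.approx(expected[name], abs=1e-12), name
    # conservation: per-mood counts partition the window
    assert (fv["freq_anger"] + fv["freq_sadness"] + fv["freq_neutrality"]
            + fv["freq_happiness"]) == len(codes)
    assert 1.0 <= fv["mean_amplitude"] <= 4.0
    assert 0 <= fv["switch_range"] <= 3
    # max sample SD on {1..4}: half 1s, half 4s -> 1.5 * sqrt(n / (n - 1))
    n = len(codes)
    bound = 0.0 if n == 1 else 1.5 * math.sqrt(n / (n - 1))
    assert fv["sd_moods"] <= bound + 1e-9


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.lists(st.integers(1, 4), min_size=2, max_size=30), st.randoms())
def test_order_free_features_are_permutation_invariant(codes, rnd):
    shuffled = list(codes)
    rnd.shuffle(shuffled)
    a = extract_features(series(codes)).as_dict()
    b = extract_features(series(shuffled)).as_dict()
    for name in FEATURE_NAMES:
        if name not in ("switch_frequency", "switch_range"):
            assert a[name] == pytest.approx(b[name]), name


def test_switch_features_do_depend_on_order():
    a = extract_features(series([1, 4, 1, 4])).switch_frequency
    b = extract_features(series([1, 1, 4, 4])).switch_frequency
    assert a != b  # a witness that permutations change the switch features


class TestFeaturesDataframe:
    def test_one_row_per_covered_assessment_and_drops_empty_windows(self):
        recs = one_per_day(range(10))
        assessments = pd.DataFrame(
            {"participant_id": ["P01", "P01", "P02"], "day": [7, 9, 7],
             "npi_total": [5, 0, 3]}
        )
        feats, dropped = features_dataframe(recs, assessments)
        assert list(feats.index) == ["P01@7", "P01@9"]
        assert dropped == ["P02@7"]  # participant without any records
        assert set(FEATURE_NAMES) <= set(feats.columns)

    def test_normalize_by_n_rescales_count_features(self):
        recs = one_per_day(range(7))
        assessments = pd.DataFrame(
            {"participant_id": ["P01"], "day": [7], "npi_total": [5]}
        )
        raw, _ = features_dataframe(recs, assessments)
        norm, _ = features_dataframe(recs, assessments, normalize=True)
        n = raw.loc["P01@7", "n_obs"]
        assert norm.loc["P01@7", "freq_negative"] == pytest.approx(
            raw.loc["P01@7", "freq_negative"] / n
        )
        assert norm.loc["P01@7", "mean_amplitude"] == pytest.approx(
            raw.loc["P01@7", "mean_amplitude"]
        )
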