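"""Windowed ordinal features of facial-expression time series.

Facial-expression labels emitted by a video-based recognition system are mapped
to ordinal mood codes — anger = 1, sadness = 2, neutrality = 3, happiness = 4 —
so that "higher" means "more positive" and consecutive differences measure the
size of a mood swing.  For each neuropsychiatric (NPI) assessment, the codes
observed in the window of ``window_days`` days strictly before the assessment
day form an :class:`EmotionSeries` ``E1..EN``, which is summarised by ten
statistics:

======================  ======================================================
``freq_negative``       number of codes that are sadness or anger
``freq_sadness``        number of sadness codes
``freq_anger``          number of anger codes
``freq_neutrality``     number of neutrality codes
``freq_happiness``      number of happiness codes
``diff_happy_sad``      ``freq_happiness - freq_sadness``
``mean_amplitude``      mean of the codes (1 = most negative, 4 = most positive)
``switch_frequency``    total mood change, ``sum_{i>=2} |Ei - E(i-1)|``
``switch_range``        ``max_i |Ei - E(i-1)| - min_i |Ei - E(i-1)|``
``sd_moods``            sample standard deviation of the codes (ddof = 1)
======================  ======================================================

For a single-observation window (N = 1) the switch and dispersion statistics
are defined as 0 rather than NaN so that degenerate windows do not poison
downstream model fits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordinal encoding of the four mood phenotypes.
LABEL_CODES = {"anger": 1, "sadness": 2, "neutrality": 3, "happiness": 4}
CODE_LABELS = {code: label for label, code in LABEL_CODES.items()}

#: Canonical feature order; used for reports and for deterministic tie-breaks.
FEATURE_NAMES = [
    "freq_negative",
    "freq_sadness",
    "freq_anger",
    "freq_neutrality",
    "freq_happiness",
    "diff_happy_sad",
    "mean_amplitude",
    "switch_frequency",
    "switch_range",
    "sd_moods",
]

#: Count-type features rescaled by the optional normalise-by-N switch.
COUNT_FEATURES = [
    "freq_negative",
    "freq_sadness",
    "freq_anger",
    "freq_neutrality",
    "freq_happiness",
    "diff_happy_sad",
    "switch_frequency",
]


class UnknownLabelError(ValueError):
    """An emotion label outside the four recognised phenotypes."""


class EmptyWindowError(ValueError):
    """No facial-expression data fall inside an assessment window."""


def encode_label(label: str, row: int | None = None) -> int:
    """Map an emotion label to its ordinal code.

    Matching is case-insensitive after stripping surrounding whitespace.
    ``row`` is an optional source-row number used only in the error message.
    """
    key = str(label).strip().lower()
    try:
        return LABEL_CODES[key]
    except KeyError:
        where = f" (row {row})" if row is not None else ""
        raise UnknownLabelError(
            f"unknown emotion label {label!r}{where}; "
            f"expected one of {sorted(LABEL_CODES)}"
        ) from None


@dataclass(frozen=True)
class EmotionSeries:
    """Chronologically ordered ordinal mood codes within one window.

    ``window`` is the half-open day interval ``[start, end)`` the codes were
    drawn from.
    """

    codes: np.ndarray
    window: tuple[int, int]

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=int)
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 1 or codes.size < 1:
            raise ValueError("an EmotionSeries needs at least one code")
        if not np.isin(codes, (1, 2, 3, 4)).all():
            bad = sorted(set(codes.tolist()) - {1, 2, 3, 4})
            raise ValueError(f"mood codes must lie in {{1,2,3,4}}; got {bad}")

    @property
    def n(self) -> int:
        return int(self.codes.size)


@dataclass(frozen=True)
class FeatureVector:
    """The ten windowed summary statistics for one assessment window."""

    freq_negative: int
    freq_sadness: int
    freq_anger: int
    freq_neutrality: int
    freq_happiness: int
    diff_happy_sad: int
    mean_amplitude: float
    switch_frequency: int
    switch_range: int
    sd_moods: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def window_series(
    records: pd.DataFrame,
    assessment_day: int,
    window_days: int = 7,
    aggregate_daily: bool = False,
) -> EmotionSeries:
    """Extract one participant's codes in the window before an assessment.

    ``records`` holds one participant's observations with integer columns
    ``day`` and ``rank`` (within-day order) plus either a ``code`` or a
    ``label`` column.  The window is the half-open interval
    ``[assessment_day - window_days, assessment_day)``: the assessment day
    itself is never included.  Codes are ordered by ``(day, rank)``.

    With ``aggregate_daily=True`` the per-record codes of each day are
    collapsed to that day's modal code (ties resolved toward the lower,
    i.e. more negative, code), so N counts days rather than records.

    Raises :class:`EmptyWindowError` when no record falls in the window, so
    the caller can drop that assessment from the sample.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    start = assessment_day - window_days
    inside = records[(records["day"] >= start) & (records["day"] < assessment_day)]
    if inside.empty:
        raise EmptyWindowError(
            f"no facial-expression data in window [{start}, {assessment_day})"
        )
    inside = inside.sort_values(["day", "rank"], kind="stable")
    if "code" in inside.columns:
        codes = inside["code"].to_numpy(dtype=int)
    else:
        codes = np.array(
            [encode_label(lab, row=i) for i, lab in inside["label"].items()],
            dtype=int,
        )
    if aggregate_daily:
        days = inside["day"].to_numpy()
        daily = []
        for day in np.unique(days):  # unique() is sorted -> chronological
            counts = np.bincount(codes[days == day], minlength=5)[1:5]
            daily.append(int(np.argmax(counts)) + 1)  # argmax tie -> lower code
        codes = np.asarray(daily, dtype=int)
    return EmotionSeries(codes=codes, window=(start, assessment_day))


def extract_features(series: EmotionSeries) -> FeatureVector:
    """Compute the ten windowed statistics for one series."""
    codes = series.codes
    n = codes.size
    counts = np.bincount(codes, minlength=5)[1:5]
    freq_anger, freq_sadness, freq_neutrality, freq_happiness = (
        int(c) for c in counts
    )
    if n == 1:
        switch_frequency = switch_range = 0
        sd = 0.0
    else:
        jumps = np.abs(np.diff(codes))
        switch_frequency = int(jumps.sum())
        switch_range = int(jumps.max() - jumps.min())
        sd = float(np.std(codes, ddof=1))
    return FeatureVector(
        freq_negative=freq_sadness + freq_anger,
        freq_sadness=freq_sadness,
        freq_anger=freq_anger,
        freq_neutrality=freq_neutrality,
        freq_happiness=freq_happiness,
        diff_happy_sad=freq_happiness - freq_sadness,
        mean_amplitude=float(codes.mean()),
        switch_frequency=switch_frequency,
        switch_range=switch_range,
        sd_moods=sd,
    )


def sample_id(participant_id: str, assessment_day: int) -> str:
    """Stable identifier for one (participant, assessment) sample."""
    return f"{participant_id}@{int(assessment_day)}"


def features_dataframe(
    records: pd.DataFrame,
    assessments: pd.DataFrame,
    window_days: int = 7,
    aggregate_daily: bool = False,
    normalize: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Feature matrix for every assessment with data in its window.

    ``records`` has columns ``participant_id, day, rank`` and ``code`` or
    ``label``; ``assessments`` has ``participant_id, day, npi_total``.
    Returns ``(features, dropped)`` where ``features`` is indexed by sample id
    with columns ``participant_id, assessment_day, n_obs, npi_total`` plus the
    ten features, and ``dropped`` lists assessments whose window held no data
    (these are logged and excluded, not errors).

    ``normalize=True`` divides the count-type features by N — useful when
    windows are unequally covered; off by default so counts stay comparable
    with the raw-count convention of the feature definitions.
    """
    rows: list[dict] = []
    dropped: list[str] = []
    by_pid = dict(tuple(records.groupby("participant_id", sort=False)))
    for rec in assessments.itertuples(index=False):
        sid = sample_id(rec.participant_id, rec.day)
        part = by_pid.get(rec.participant_id)
        try:
            if part is None:
                raise EmptyWindowError(f"participant {rec.participant_id} has no records")
            series = window_series(
                part, rec.day, window_days=window_days, aggregate_daily=aggregate_daily
            )
        except EmptyWindowError as exc:
            logger.warning("dropping assessment %s: %s", sid, exc)
            dropped.append(sid)
            continue
        fv = extract_features(series).as_dict()
        if normalize:
            for name in COUNT_FEATURES:
                fv[name] = fv[name] / series.n
        rows.append(
            {
                "sample_id": sid,
                "participant_id": rec.participant_id,
                "assessment_day": int(rec.day),
                "n_obs": series.n,
                "npi_total": int(rec.npi_total),
                **fv,
            }
        )
    if not rows:
        return (
            pd.DataFrame(
                columns=["participant_id", "assessment_day", "n_obs", "npi_total"]
                + FEATURE_NAMES
            ),
            dropped,
        )
    out = pd.DataFrame(rows).set_index("sample_id")
    return out, dropped
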