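"""Synthetic day-care cohort generator.

The study's raw data — continuous facial-expression codes from a day-care
video system plus repeated NPI assessments — were never deposited, so this
module generates a cohort with the statistical structure the downstream
analysis assumes:

* each participant carries a latent symptom severity ``s ~ Beta(a, b)``;
* moods evolve as a first-order Markov chain over the ordinal codes
  {1=anger, 2=sadness, 3=neutrality, 4=happiness}: at every step the current
  mood is kept, or with probability ``0.2 + switch_slope * s`` (capped at 0.9)
  redrawn from a severity-dependent stationary distribution whose mass on the
  negative moods {1, 2} rises logistically with ``s``;
* the NPI total of an assessment is a clipped, rounded linear function of the
  realised window features — negative-mood frequency and switch frequency —
  plus Gaussian noise, so that severer and more labile participants score
  higher, echoing the positive associations of negative-mood frequency and
  mood-switch frequency with NPI and the negative ones of the
  happiness-sadness difference and mean amplitude.

Because the target is built from realised window features (not from ``s``
directly), the downstream models face a well-posed parameter-recovery
problem.  Defaults are chosen so a generated cohort matches the study's
scale: 23 participants, >11,500 records, 38 assessments, NPI totals spanning
roughly 0-50 with many exact zeros.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import ConfigError, SyntheticConfig
from .features import CODE_LABELS, FeatureVector, extract_features, window_series

#: Baseline per-step probability of redrawing the mood state.
SWITCH_BASE = 0.2
#: Cap on the per-step switch probability.
SWITCH_CAP = 0.9
#: Logit of the negative-mood mass at severity 0 (expit(-2.5) ~ 0.076).
NEG_INTERCEPT = -2.5
#: Share of the negative-mood mass given to sadness (rest to anger).
SAD_SHARE = 0.65
#: Happiness share of the non-negative mass at s=0, and its decline with s.
HAPPY_SHARE_BASE = 0.45
HAPPY_SHARE_SLOPE = 0.25


def mood_distribution(severity: float, emission_slope: float) -> np.ndarray:
    """Stationary mood probabilities (codes 1..4) at a given severity.

    The mass on the negative moods {anger, sadness} is
    ``expit(NEG_INTERCEPT + emission_slope * severity)``, monotone in
    severity; within the remaining mass the happiness share declines with
    severity so that severer participants both frown more and smile less.
    """
    p_neg = float(expit(NEG_INTERCEPT + emission_slope * severity))
    p_sad = SAD_SHARE * p_neg
    p_ang = p_neg - p_sad
    happy_share = HAPPY_SHARE_BASE - HAPPY_SHARE_SLOPE * severity
    p_hap = happy_share * (1.0 - p_neg)
    p_neu = (1.0 - p_neg) - p_hap
    probs = np.array([p_ang, p_sad, p_neu, p_hap])
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
        raise ConfigError(f"invalid mood distribution {probs} at severity {severity}")
    return probs


def switch_probability(severity: float, switch_slope: float) -> float:
    p = SWITCH_BASE + switch_slope * severity
    if p < 0:
        raise ConfigError(f"negative switch probability {p}")
    return min(p, SWITCH_CAP)


def sample_emotion_sequence(
    participant_id: str,
    severity: float,
    days: int,
    records_per_day: int,
    emission_slope: float,
    switch_slope: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Markov mood-code stream for one participant.

    Emits ``days * records_per_day`` records with columns
    ``participant_id, day, rank, label, code``.  Because a "switch" redraws
    the state from the stationary distribution itself (possibly landing on
    the same mood), the marginal mood distribution is exactly
    :func:`mood_distribution` while the realised switching rate grows with
    severity.
    """
    pi = mood_distribution(severity, emission_slope)
    p_switch = switch_probability(severity, switch_slope)
    n = days * records_per_day
    proposals = rng.choice(np.arange(1, 5), size=n, p=pi)
    redraw = rng.random(n) < p_switch
    redraw[0] = True  # the first state is always a fresh draw
    # state_i = proposal at the most recent redraw index <= i
    last = np.maximum.accumulate(np.where(redraw, np.arange(n), -1))
    codes = proposals[last]
    idx = np.arange(n)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "day": idx // records_per_day,
            "rank": idx % records_per_day,
            "label": [CODE_LABELS[c] for c in codes],
            "code": codes,
        }
    )


def assign_npi(
    window_features: FeatureVector,
    npi_coeffs: tuple[float, float, float],
    noise_sd: float,
    rng: np.random.Generator,
) -> int:
    """NPI total generated from realised window features.

    ``total = round(clip(b0 + b_neg*freq_negative + b_switch*switch_frequency
    + N(0, noise_sd), 0, 144))``.  The negative intercept produces the exact
    zeros that dominate low-severity assessments.
    """
    b0, b_neg, b_switch = (float(b) for b in npi_coeffs)
    if not np.isfinite([b0, b_neg, b_switch]).all():
        raise ConfigError("npi_coeffs must be finite")
    raw = (
        b0
        + b_neg * window_features.freq_negative
        + b_switch * window_features.switch_frequency
        + rng.normal(0.0, noise_sd)
    )
    return int(round(float(np.clip(raw, 0, 144))))


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ``(records, assessments, participants)`` for one cohort.

    Deterministic given ``config.seed``.  Every participant gets one NPI
    assessment scheduled no earlier than ``window_days`` days after data
    start (so its window is fully covered), and ``n_second_assessments``
    randomly chosen participants get a later second one.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ids = [f"P{i + 1:02d}" for i in range(cfg.n_participants)]
    sexes = rng.choice(["male", "female"], size=cfg.n_participants, p=[0.35, 0.65])
    ages = np.clip(rng.normal(83.0, 6.0, size=cfg.n_participants), 65.0, 100.0)
    severities = rng.beta(*cfg.severity_shape, size=cfg.n_participants)
    with_second = set(
        rng.choice(ids, size=cfg.n_second_assessments, replace=False).tolist()
    )

    first_hi = max(cfg.window_days, cfg.days // 2)
    second_lo = max(2 * cfg.days // 3, cfg.window_days)

    record_frames: list[pd.DataFrame] = []
    assess_rows: list[dict] = []
    for pid, severity in zip(ids, severities):
        recs = sample_emotion_sequence(
            pid,
            float(severity),
            cfg.days,
            cfg.records_per_day,
            cfg.emission_slope,
            cfg.switch_slope,
            rng,
        )
        record_frames.append(recs)
        days = [int(rng.integers(cfg.window_days, first_hi + 1))]
        if pid in with_second:
            lo = max(second_lo, days[0] + 1)
            days.append(int(rng.integers(lo, cfg.days + 1)))
        for day in days:
            series = window_series(recs, day, window_days=cfg.window_days)
            fv = extract_features(series)
            total = assign_npi(fv, cfg.npi_coeffs, cfg.noise_sd, rng)
            assess_rows.append(
                {"participant_id": pid, "day": day, "npi_total": total}
            )

    records = pd.concat(record_frames, ignore_index=True)
    assessments = pd.DataFrame(assess_rows)
    participants = pd.DataFrame(
        {
            "participant_id": ids,
            "sex": sexes,
            "age": np.round(ages, 1),
            "latent_severity": np.round(severities, 6),
        }
    )
    return records, assessments, participants
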