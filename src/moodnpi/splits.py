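"""Train/test partitioning protocols.

Three protocols mirror how the cohort's 38 assessments are partitioned for
model development and validation:

* **two-stage** — participants split by recruitment wave into Stage 1 (the
  first 7) and Stage 2 (the remaining 16); within each stage, assessments are
  split 50/50 into train and test at random;
* **patientwise k-fold** — participants (never individual assessments) are
  allocated to k folds, so no person's data leak between a training and a
  test fold; the greedy allocator also balances the folds' NPI-level
  composition;
* **minimization** — sequential Pocock–Simon covariate-adaptive allocation of
  participants to a train and a test arm, stratified by sex, age band and
  NPI level, minimising the summed marginal (range) imbalance of adjusted
  arm counts.  A total-count pseudo-factor keeps the arm ratio on target
  even when every stratification factor is constant.

"NPI level" is a coarse severity bin of the total score: 0 -> none,
1..mild_max -> mild, above -> marked (the mild cut defaults to 12, the upper
quartile of the cohort's totals).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAIN, TEST = "train", "test"
DEFAULT_FACTORS = ("sex", "age_band", "npi_level")


@dataclass
class SplitPlan:
    """One realised partition of the samples.

    ``assignments`` maps sample id to a fold label (``"fold0"``..) or arm
    (``"train"``/``"test"``); ``participants`` maps sample id to participant.
    """

    method: str
    assignments: dict[str, str]
    participants: dict[str, str]
    seed: int
    strata: dict[str, tuple] = field(default_factory=dict)

    def members(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    def groups(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.assignments),
                "participant_id": [self.participants[s] for s in self.assignments],
                "method": self.method,
                "assignment": list(self.assignments.values()),
            }
        )


def npi_level_bins(total: int, mild_max: int = 12) -> str:
    """Coarse NPI severity level: 0 none, 1..mild_max mild, above marked."""
    total = int(total)
    if not 0 <= total <= 144:
        raise ValueError(f"NPI total {total} outside the instrument range [0, 144]")
    if total == 0:
        return "none"
    if total <= mild_max:
        return "mild"
    return "marked"


def age_band(age: float, cut: float = 80.0) -> str:
    return "lt80" if float(age) < cut else "ge80"


def _check_samples(samples: pd.DataFrame) -> None:
    for col in ("participant_id", "npi_total"):
        if col not in samples.columns:
            raise ValueError(f"samples need a {col!r} column")
    if samples.index.duplicated().any():
        raise ValueError("duplicate sample ids")


def two_stage_split(
    samples: pd.DataFrame,
    stage1_participants: list[str],
    stage2_participants: list[str],
    seed: int = 0,
) -> dict[str, SplitPlan]:
    """50/50 within-stage train/test split of the two recruitment waves.

    ``samples`` is indexed by sample id with a ``participant_id`` column.
    Returns ``{"stage1": plan, "stage2": plan}``; each plan assigns every
    stage sample to ``train`` or ``test`` (train keeps the odd extra).
    """
    _check_samples(samples)
    s1, s2 = set(stage1_participants), set(stage2_participants)
    if s1 & s2:
        raise ValueError(f"stage participant sets overlap: {sorted(s1 & s2)}")
    rng = np.random.default_rng(seed)
    plans: dict[str, SplitPlan] = {}
    for name, pids in (("stage1", s1), ("stage2", s2)):
        stage = samples[samples["participant_id"].isin(pids)]
        n = len(stage)
        if n < 2:
            raise ValueError(f"{name} holds {n} samples; need at least 2 to split")
        order = rng.permutation(np.array(stage.index))
        n_train = int(np.ceil(n / 2))
        assignments = {
            sid: (TRAIN if i < n_train else TEST) for i, sid in enumerate(order)
        }
        plans[name] = SplitPlan(
            method="two_stage",
            assignments=assignments,
            participants=stage["participant_id"].to_dict(),
            seed=seed,
        )
    return plans


def patientwise_kfold(
    samples: pd.DataFrame,
    k: int = 6,
    seed: int = 0,
    mild_max: int = 12,
) -> SplitPlan:
    """Allocate participants (with all their samples) to ``k`` folds.

    Participants are processed largest-first by sample count; each goes to a
    currently-smallest fold, and among those to the fold where the
    participant's NPI level (the max level over their assessments) is least
    represented, ties resolved by a seeded draw.  Fold participant counts
    therefore never differ by more than one.
    """
    _check_samples(samples)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    per_pid = samples.groupby("participant_id")
    pids = list(per_pid.groups)
    if len(pids) < k:
        raise ValueError(f"{len(pids)} participants cannot fill {k} folds")
    pid_level = {
        pid: npi_level_bins(int(grp["npi_total"].max()), mild_max)
        for pid, grp in per_pid
    }
    pid_count = {pid: len(grp) for pid, grp in per_pid}
    order = sorted(pids, key=lambda p: (-pid_count[p], p))

    fold_pids: list[list[str]] = [[] for _ in range(k)]
    fold_levels: list[dict[str, int]] = [dict() for _ in range(k)]
    for pid in order:
        sizes = [len(f) for f in fold_pids]
        smallest = [i for i, s in enumerate(sizes) if s == min(sizes)]
        level = pid_level[pid]
        least = min(fold_levels[i].get(level, 0) for i in smallest)
        tied = [i for i in smallest if fold_levels[i].get(level, 0) == least]
        chosen = int(tied[rng.integers(len(tied))])
        fold_pids[chosen].append(pid)
        fold_levels[chosen][level] = fold_levels[chosen].get(level, 0) + 1

    pid_fold = {pid: i for i, fold in enumerate(fold_pids) for pid in fold}
    assignments = {
        sid: f"fold{pid_fold[pid]}"
        for sid, pid in samples["participant_id"].items()
    }
    return SplitPlan(
        method="patientwise_kfold",
        assignments=assignments,
        participants=samples["participant_id"].to_dict(),
        seed=seed,
        strata={sid: (pid_level[pid],) for sid, pid in samples["participant_id"].items()},
    )


def participant_strata(
    samples: pd.DataFrame,
    participants: pd.DataFrame,
    mild_max: int = 12,
    cut: float = 80.0,
) -> pd.DataFrame:
    """Per-participant stratification table (sex, age_band, npi_level)."""
    _check_samples(samples)
    level = samples.groupby("participant_id")["npi_total"].max().map(
        lambda t: npi_level_bins(int(t), mild_max)
    )
    out = participants.set_index("participant_id").loc[level.index, ["sex", "age"]]
    out["age_band"] = out["age"].map(lambda a: age_band(a, cut))
    out["npi_level"] = level
    return out.drop(columns="age")


def minimization_split(
    strata: pd.DataFrame,
    test_fraction: float = 1 / 6,
    seed: int = 0,
    factors: tuple[str, ...] = DEFAULT_FACTORS,
    biased_coin_p: float = 1.0,
) -> dict[str, str]:
    """Pocock-Simon minimization of participants into train/test arms.

    ``strata`` is indexed by participant id with one column per factor.
    Participants are processed in seeded random order; each joins the arm
    minimising the summed marginal imbalance, where per factor level the
    imbalance is the range of arm counts adjusted by the arm targets
    ``(1 - test_fraction, test_fraction)``.  An always-present total-count
    pseudo-factor keeps the overall ratio on target.  The lower-score arm is
    taken deterministically by default (``biased_coin_p=1.0``); setting
    ``biased_coin_p < 1`` plays the classical biased coin instead.  Exact
    ties are settled by a seeded fair coin.  Factors without variation are
    dropped with a warning.

    Returns ``{participant_id: "train" | "test"}``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    live = []
    for f in factors:
        if f not in strata.columns:
            raise ValueError(f"factor {f!r} missing from strata")
        if strata[f].nunique() > 1:
            live.append(f)
        else:
            warnings.warn(
                f"minimization factor {f!r} has no variation; dropped", stacklevel=2
            )
    rng = np.random.default_rng(seed)
    targets = {TRAIN: 1.0 - test_fraction, TEST: test_fraction}
    counts: dict[str, dict[tuple[str, str], int]] = {TRAIN: {}, TEST: {}}
    totals = {TRAIN: 0, TEST: 0}
    assignment: dict[str, str] = {}

    order = list(strata.index[rng.permutation(len(strata))])
    for pid in order:
        scores = {}
        for arm in (TRAIN, TEST):
            score = 0.0
            # total-count pseudo-factor: keeps the arm ratio near target
            tot = {a: totals[a] + (1 if a == arm else 0) for a in (TRAIN, TEST)}
            adj = [tot[a] / targets[a] for a in (TRAIN, TEST)]
            score += max(adj) - min(adj)
            for f in live:
                key = (f, strata.at[pid, f])
                lvl = {
                    a: counts[a].get(key, 0) + (1 if a == arm else 0)
                    for a in (TRAIN, TEST)
                }
                adj = [lvl[a] / targets[a] for a in (TRAIN, TEST)]
                score += max(adj) - min(adj)
            scores[arm] = score
        if np.isclose(scores[TRAIN], scores[TEST]):
            arm = TRAIN if rng.random() < 0.5 else TEST
        else:
            best = min(scores, key=lambda a: scores[a])
            other = TEST if best == TRAIN else TRAIN
            arm = best if rng.random() < biased_coin_p else other
        assignment[pid] = arm
        totals[arm] += 1
        for f in live:
            key = (f, strata.at[pid, f])
            counts[arm][key] = counts[arm].get(key, 0) + 1
    return assignment


def minimization_split_plan(
    samples: pd.DataFrame,
    participants: pd.DataFrame,
    test_fraction: float = 1 / 6,
    seed: int = 0,
    mild_max: int = 12,
    cut: float = 80.0,
    biased_coin_p: float = 1.0,
) -> SplitPlan:
    """Minimization allocation expanded from participants to samples."""
    strata = participant_strata(samples, participants, mild_max=mild_max, cut=cut)
    arm = minimization_split(
        strata, test_fraction=test_fraction, seed=seed, biased_coin_p=biased_coin_p
    )
    assignments = {
        sid: arm[pid] for sid, pid in samples["participant_id"].items()
    }
    return SplitPlan(
        method="minimization",
        assignments=assignments,
        participants=samples["participant_id"].to_dict(),
        seed=seed,
        strata={
            sid: tuple(strata.loc[pid]) for sid, pid in samples["participant_id"].items()
        },
    )


def random_participant_split(
    strata: pd.DataFrame, test_fraction: float = 1 / 6, seed: int = 0
) -> dict[str, str]:
    """Seeded simple-random participant split at the same arm ratio.

    The baseline minimization is compared against: the same number of
    participants goes to the test arm, chosen uniformly at random.
    """
    rng = np.random.default_rng(seed)
    pids = list(strata.index)
    n_test = max(1, int(round(test_fraction * len(pids))))
    test = set(rng.choice(pids, size=n_test, replace=False).tolist())
    return {pid: (TEST if pid in test else TRAIN) for pid in pids}


def max_marginal_imbalance(
    strata: pd.DataFrame,
    assignment: dict[str, str],
    test_fraction: float,
    factors: tuple[str, ...] = DEFAULT_FACTORS,
) -> float:
    """Worst adjusted per-factor-level arm imbalance of an allocation.

    For each factor level, arm counts are divided by the arm targets and the
    absolute difference taken; the maximum over all levels is returned.
    """
    targets = {TRAIN: 1.0 - test_fraction, TEST: test_fraction}
    worst = 0.0
    for f in factors:
        if f not in strata.columns:
            continue
        for level in strata[f].unique():
            pids = strata.index[strata[f] == level]
            n = {a: sum(1 for p in pids if assignment[p] == a) for a in (TRAIN, TEST)}
            adj = [n[a] / targets[a] for a in (TRAIN, TEST)]
            worst = max(worst, max(adj) - min(adj))
    return worst
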