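"""Two-stage, patientwise k-fold and minimization partitioning."""

import numpy as np
import pandas as pd
import pytest

from moodnpi.splits import (
    max_marginal_imbalance,
    minimization_split,
    minimization_split_plan,
    npi_level_bins,
    participant_strata,
    patientwise_kfold,
    random_participant_split,
    two_stage_split,
)


def make_samples(n_participants=23, per_participant=2, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        k = 1 + (i % per_participant)
        for j in range(k):
            rows.append(
                {
                    "sample_id": f"{pid}@{7 + j}",
                    "participant_id": pid,
                    "npi_total": int(rng.choice([0, 0, 3, 10, 25])),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


class TestNpiLevelBins:
    @pytest.mark.parametrize(
        "total,level", [(0, "none"), (1, "mild"), (12, "mild"), (13, "marked"),
                        (50, "marked")]
    )
    def test_default_boundaries(self, total, level):
        assert npi_level_bins(total) == level

    def test_out_of_range_total_rejected(self):
        with pytest.raises(ValueError, match="range"):
            npi_level_bins(145)
        with pytest.raises(ValueError, match="range"):
            npi_level_bins(-1)


class TestTwoStageSplit:
    def pids(self, samples):
        return sorted(samples["participant_id"].unique())

    def test_every_sample_lands_in_exactly_one_block(self):
        samples = make_samples()
        pids = self.pids(samples)
        plans = two_stage_split(samples, pids[:7], pids[7:], seed=3)
        seen = []
        for stage in ("stage1", "stage2"):
            for group in ("train", "test"):
                seen += plans[stage].members(group)
        assert sorted(seen) == sorted(samples.index)

    def test_halves_are_balanced_within_one_sample(self):
        samples = make_samples()
        pids = self.pids(samples)
        plans = two_stage_split(samples, pids[:7], pids[7:], seed=3)
        for stage in ("stage1", "stage2"):
            n_tr = len(plans[stage].members("train"))
            n_te = len(plans[stage].members("test"))
            assert abs(n_tr - n_te) <= 1

    def test_deterministic_under_seed(self):
        samples = make_samples()
        pids = self.pids(samples)
        a = two_stage_split(samples, pids[:7], pids[7:], seed=5)
        b = two_stage_split(samples, pids[:7], pids[7:], seed=5)
        assert a["stage1"].assignments == b["stage1"].assignments
        assert a["stage2"].assignments == b["stage2"].assignments

    def test_overlapping_stage_sets_rejected(self):
        samples = make_samples()
        pids = self.pids(samples)
        with pytest.raises(ValueError, match="overlap"):
            two_stage_split(samples, pids[:7], pids[6:], seed=0)

    def test_stage_with_too_few_samples_rejected(self):
        samples = make_samples(n_participants=3, per_participant=1)
        pids = self.pids(samples)
        with pytest.raises(ValueError, match="at least 2"):
            two_stage_split(samples, pids[:1], pids[1:], seed=0)


class TestPatientwiseKfold:
    def test_fold_participant_counts_differ_by_at_most_one(self):
        samples = make_samples(23)
        plan = patientwise_kfold(samples, k=6, seed=1)
        frame = plan.to_frame()
        sizes = frame.groupby("assignment")["participant_id"].nunique()
        assert len(sizes) == 6
        assert sizes.max() - sizes.min() <= 1

    @pytest.mark.parametrize("seed", range(5))
    def test_no_participant_straddles_folds(self, seed):
        samples = make_samples(15, seed=seed)
        plan = patientwise_kfold(samples, k=4, seed=seed)
        frame = plan.to_frame()
        assert (frame.groupby("participant_id")["assignment"].nunique() == 1).all()

    def test_k_equal_n_participants_is_leave_one_out(self):
        samples = make_samples(8, per_participant=1)
        plan = patientwise_kfold(samples, k=8, seed=0)
        sizes = plan.to_frame().groupby("assignment")["participant_id"].nunique()
        assert (sizes == 1).all()

    def test_partition_covers_every_sample_once(self):
        samples = make_samples(12)
        plan = patientwise_kfold(samples, k=4, seed=2)
        assert sorted(plan.assignments) == sorted(samples.index)

    def test_invalid_k_rejected(self):
        samples = make_samples(5)
        with pytest.raises(ValueError, match=">= 2"):
            patientwise_kfold(samples, k=1)
        with pytest.raises(ValueError, match="cannot fill"):
            patientwise_kfold(samples, k=9)


def toy_strata():
    return pd.DataFrame(
        {"sex": ["male", "female", "male", "female"]},
        index=["P1", "P2", "P3", "P4"],
    )


class TestMinimization:
    @pytest.mark.parametrize("seed", range(8))
    def test_toy_alternating_sex_balances_exactly(self, seed):
        arm = minimization_split(
            toy_strata(), test_fraction=0.5, seed=seed, factors=("sex",)
        )
        strata = toy_strata()
        for a in ("train", "test"):
            members = [p for p, g in arm.items() if g == a]
            assert len(members) == 2
            assert sorted(strata.loc[members, "sex"]) == ["female", "male"]

    def test_constant_factors_reduce_to_ratio_keeping(self):
        strata = pd.DataFrame(
            {"sex": ["male"] * 12, "age_band": ["ge80"] * 12,
             "npi_level": ["none"] * 12},
            index=[f"P{i}" for i in range(12)],
        )
        with pytest.warns(UserWarning, match="no variation"):
            arm = minimization_split(strata, test_fraction=1 / 6, seed=0)
        n_test = sum(1 for a in arm.values() if a == "test")
        assert abs(n_test - 2) <= 1

    def test_deterministic_under_seed(self):
        strata = participant_strata(make_samples(), _participants(23))
        a = minimization_split(strata, seed=4)
        b = minimization_split(strata, seed=4)
        assert a == b

    def test_plan_expands_to_all_samples(self):
        samples = make_samples(12)
        plan = minimization_split_plan(samples, _participants(12), seed=0)
        assert sorted(plan.assignments) == sorted(samples.index)
        frame = plan.to_frame()
        assert (frame.groupby("participant_id")["assignment"].nunique() == 1).all()

    def test_minimization_beats_random_on_marginal_balance(self):
        mini_scores, rand_scores = [], []
        for rep in range(50):
            samples = make_samples(18, seed=rep)
            participants = _participants(18, seed=rep)
            strata = participant_strata(samples, participants)
            mini = minimization_split(strata, test_fraction=1 / 3, seed=rep)
            rand = random_participant_split(strata, test_fraction=1 / 3, seed=rep)
            mini_scores.append(max_marginal_imbalance(strata, mini, 1 / 3))
            rand_scores.append(max_marginal_imbalance(strata, rand, 1 / 3))
        assert np.mean(mini_scores) <= np.mean(rand_scores)


def _participants(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:02d}" for i in range(n)],
            "sex": rng.choice(["male", "female"], size=n),
            "age": rng.uniform(66, 95, size=n).round(1),
        }
    )
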