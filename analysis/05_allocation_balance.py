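"""How much covariate balance does minimization buy over random splitting?

Simulates 200 participant strata tables (sex x age band x NPI level) and
compares the worst per-factor-level arm imbalance of the Pocock-Simon
minimization allocation against a seeded simple-random split at the same
1/6 test fraction.  Writes results/allocation_balance.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from moodnpi.splits import (
    max_marginal_imbalance,
    minimization_split,
    random_participant_split,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
N_COHORTS = 200
N_PARTICIPANTS = 23
TEST_FRACTION = 1 / 6


def main() -> None:
    rows = []
    for rep in range(N_COHORTS):
        rng = np.random.default_rng(rep)
        strata = pd.DataFrame(
            {
                "sex": rng.choice(["male", "female"], size=N_PARTICIPANTS),
                "age_band": rng.choice(["lt80", "ge80"], size=N_PARTICIPANTS),
                "npi_level": rng.choice(["none", "mild", "marked"], size=N_PARTICIPANTS),
            },
            index=[f"P{i:02d}" for i in range(N_PARTICIPANTS)],
        )
        mini = minimization_split(strata, test_fraction=TEST_FRACTION, seed=rep)
        rand = random_participant_split(strata, test_fraction=TEST_FRACTION, seed=rep)
        rows.append(
            {
                "cohort": rep,
                "minimization": max_marginal_imbalance(strata, mini, TEST_FRACTION),
                "random": max_marginal_imbalance(strata, rand, TEST_FRACTION),
            }
        )
    table = pd.DataFrame(rows)
    ROOT.mkdir(parents=True, exist_ok=True)
    table.to_csv(ROOT / "allocation_balance.csv", index=False)

    print(f"mean worst marginal imbalance over {N_COHORTS} cohorts "
          f"({N_PARTICIPANTS} participants, test fraction {TEST_FRACTION:.2f}):")
    print(f"  minimization : {table['minimization'].mean():.2f}")
    print(f"  random split : {table['random'].mean():.2f}")
    frac = (table["minimization"] <= table["random"]).mean()
    print(f"minimization is at least as balanced in {frac:.0%} of cohorts")


if __name__ == "__main__":
    main()
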