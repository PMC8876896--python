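"""Window each NPI assessment and compute the ten mood features.

Reads the cohort written by 01_simulate_cohort.py, extracts the 7-day
pre-assessment feature vectors, writes results/features.csv, and prints each
feature's Pearson correlation with the NPI total — the univariate screen
whose sign pattern (negative moods and switching up, happiness-sadness
difference and mean amplitude down) motivates the prediction models.
"""

from pathlib import Path

import numpy as np

from moodnpi import features_dataframe
from moodnpi.features import FEATURE_NAMES
from moodnpi.io import read_assessments, read_records

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_records(ROOT / "data" / "records.csv")
    assessments = read_assessments(ROOT / "data" / "assessments.csv")
    feats, dropped = features_dataframe(records, assessments)
    feats.to_csv(ROOT / "features.csv")

    print(f"featurised {len(feats)} assessments "
          f"({len(dropped)} dropped for empty windows)")
    print("\nfeature correlations with the NPI total:")
    for name in FEATURE_NAMES:
        r = np.corrcoef(feats[name], feats["npi_total"])[0, 1]
        print(f"  {name:<18} r = {r:+.2f}")
    print(f"\nwrote {ROOT / 'features.csv'}")


if __name__ == "__main__":
    main()
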