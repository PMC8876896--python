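"""Generate the synthetic day-care cohort the downstream analyses run on.

Writes records/assessments/participants CSVs under results/data/ and prints
the cohort's scale and NPI distribution.  The study's raw video-derived data
were never deposited; this cohort reproduces their documented scale
(23 participants, >11,500 expression records, 38 NPI assessments with many
zeros) from the generative model described in docs/methods.md.
"""

import json
from pathlib import Path

from moodnpi import SyntheticConfig, generate_cohort
from moodnpi.io import write_assessments, write_participants, write_records

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    cfg = SyntheticConfig(seed=SEED)
    records, assessments, participants = generate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    write_records(records, OUT / "records.csv")
    write_assessments(assessments, OUT / "assessments.csv")
    write_participants(participants, OUT / "participants.csv")
    (OUT / "metadata.json").write_text(
        json.dumps({"seed": SEED, "config": cfg.model_dump()}, indent=2, default=str)
    )

    totals = assessments["npi_total"]
    print(f"cohort: {participants.shape[0]} participants, "
          f"{len(records)} emotion records, {len(assessments)} NPI assessments")
    print(f"NPI totals: min {totals.min()}, median {totals.median()}, "
          f"max {totals.max()}, zeros {(totals == 0).mean():.0%}")
    print(f"wrote CSVs to {OUT}")


if __name__ == "__main__":
    main()
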