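"""Apply the index-event and temporal inclusion criteria to a dataset.

Reads a dataset directory written by 01_simulate.py, finds each patient's
first seizure-like encounter before age 21, applies the prior-contact and
two-year follow-up requirements, and writes cohort.csv with per-criterion
flags and exclusion reasons.
"""

import argparse
from pathlib import Path

from szrec.codes import default_registry
from szrec.cohort import build_cohort, write_cohort
from szrec.errors import DependencyError
from szrec.io import read_dataset


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--modality", choices=("emr", "claims"), default="emr")
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = args.data_dir / args.modality
    if not data.exists():
        raise DependencyError(f"missing dataset {data}; run 01_simulate.py")
    records = read_dataset(data)
    cohort = build_cohort(records, default_registry(), args.modality)
    out = args.out_dir / f"cohort_{args.modality}.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, out)
    print(f"[{args.modality}] {int(cohort['included'].sum())} of "
          f"{len(cohort)} patients included -> {out}")
    reasons = cohort.loc[~cohort["included"], "exclusion_reason"]
    for reason, count in reasons.value_counts().items():
        print(f"  excluded ({reason}): {count}")


if __name__ == "__main__":
    main()
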