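"""Compute the seven recurrence measures and the composite label.

Reads the dataset and cohort.csv, evaluates each expert-derived criterion in
the 2-year post-index window (7-day blanking), and writes labels.csv (one row
of eight booleans per included patient).
"""

import argparse
from pathlib import Path

from szrec.codes import default_registry
from szrec.errors import DependencyError
from szrec.io import read_dataset
from szrec.outcomes import CRITERION_FIELDS, OutcomeConfig, label_cohort, write_labels

import pandas as pd


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--modality", choices=("emr", "claims"), default="emr")
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = args.data_dir / args.modality
    cohort_path = args.out_dir / f"cohort_{args.modality}.csv"
    if not data.exists():
        raise DependencyError(f"missing dataset {data}; run 01_simulate.py")
    if not cohort_path.exists():
        raise DependencyError(f"missing {cohort_path}; run 02_cohort.py")

    records = read_dataset(data)
    cohort = pd.read_csv(cohort_path)
    labels = label_cohort(records, cohort, default_registry(),
                          OutcomeConfig())
    out = args.out_dir / f"labels_{args.modality}.csv"
    write_labels(labels, out)
    print(f"[{args.modality}] composite prevalence "
          f"{labels['composite'].mean():.3f} over {len(labels)} included "
          f"patients -> {out}")
    for field in CRITERION_FIELDS:
        print(f"  {field}: {labels[field].mean():.3f}")


if __name__ == "__main__":
    main()
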