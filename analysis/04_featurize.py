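"""Build the structured design matrix from the 1-year pre-index window.

Counts every diagnosis/medication/procedure code in [index - 365, index],
applies log(count + 1) clipped at 1, and writes the vocabulary, the dense
matrix (npz), and one selection mask per scheme (prevalence >= 1%; chi2 top
500) fitted on the full included cohort for inspection.  During model
evaluation the masks are re-fitted inside each training fold.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from szrec.codes import default_registry
from szrec.cohort import index_events
from szrec.errors import DependencyError
from szrec.features import (
    FeatureVocabulary,
    extract_code_counts,
    select_features,
    write_mask,
    write_vocabulary,
)
from szrec.io import read_dataset


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--modality", choices=("emr", "claims"), default="emr")
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = args.data_dir / args.modality
    labels_path = args.out_dir / f"labels_{args.modality}.csv"
    if not labels_path.exists():
        raise DependencyError(f"missing {labels_path}; run 03_label.py")

    records = read_dataset(data)
    labels = pd.read_csv(labels_path)
    included = list(labels["patient_id"])
    registry = default_registry()
    indexes = index_events(records, registry)
    by_id = {r.patient_id: r for r in records}
    maps = [extract_code_counts(by_id[pid], indexes[pid].index_date)
            for pid in included]

    vocab = FeatureVocabulary.fit(maps)
    x = vocab.transform(maps)
    y = labels["composite"].to_numpy(dtype=bool)

    out = args.out_dir / f"features_{args.modality}"
    out.mkdir(parents=True, exist_ok=True)
    write_vocabulary(vocab, out / "vocabulary.txt")
    sp.save_npz(out / "matrix.npz", x)
    (out / "patients.txt").write_text("\n".join(included) + "\n")
    for scheme, param in (("prevalence", 0.01), ("chi2", 500)):
        mask = select_features(x, y, scheme, param)
        write_mask(mask, out / f"mask_{scheme}.txt")
        print(f"[{args.modality}] {scheme} keeps {int(mask.sum())} of "
              f"{len(vocab.ids)} features")
    print(f"[{args.modality}] matrix {x.shape[0]} x {x.shape[1]}, "
          f"density {x.nnz / max(1, x.shape[0] * x.shape[1]):.4f} -> {out}")


if __name__ == "__main__":
    main()
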