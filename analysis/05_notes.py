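"""Run the clinical-note path on the EMR cohort.

Extracts medication mentions from note text (sectioning + negation) and
cross-validates the default term-frequency note scorer: notes are chunked
(4096-token windows, 512 overlap), chunk scores reduce to note scores and
note scores to patient classes by the largest-margin rule.  Writes
med_mentions.csv, predictions.csv (note-level) and aggregate.csv
(patient-level).
"""

import argparse
from pathlib import Path

import pandas as pd

from szrec.codes import default_registry
from szrec.cohort import index_events
from szrec.errors import DependencyError
from szrec.evaluate import make_folds
from szrec.io import read_dataset
from szrec.notes import (
    ChunkingConfig,
    HashCache,
    TermFrequencyScorer,
    aggregate_patients,
    extract_medications,
    score_notes,
    select_scoring_notes,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = args.data_dir / "emr"
    labels_path = args.out_dir / "labels_emr.csv"
    if not labels_path.exists():
        raise DependencyError(f"missing {labels_path}; run 03_label.py")

    records = read_dataset(data)
    labels = pd.read_csv(labels_path)
    y = dict(zip(labels["patient_id"], labels["composite"].astype(bool)))
    registry = default_registry()

    mention_rows = []
    for record in records:
        for note in record.notes:
            for m in extract_medications(note, registry):
                mention_rows.append({
                    "note_id": m.note_id, "patient_id": record.patient_id,
                    "surface": m.surface, "drug": m.drug,
                    "drug_class": m.drug_class, "negated": m.negated,
                    "section": m.section})
    mentions = pd.DataFrame(mention_rows)
    mentions.to_csv(args.out_dir / "med_mentions.csv", index=False,
                    lineterminator="\n")
    n_neg = int(mentions["negated"].sum()) if len(mentions) else 0
    print(f"extracted {len(mentions)} medication mentions "
          f"({n_neg} negated) from notes")

    indexes = index_events(records, registry)
    notes = select_scoring_notes(
        [r for r in records if r.patient_id in y],
        {p: e.index_date for p, e in indexes.items()})
    folds = make_folds(sorted(y), 5, seed=args.seed, labels=y)
    cache = HashCache()
    all_preds = []
    for i, test_fold in enumerate(folds):
        train = {p for j, f in enumerate(folds) if j != i for p in f}
        preds = score_notes(notes, y, TermFrequencyScorer(seed=args.seed,
                                                          cache=cache),
                            train, ChunkingConfig())
        all_preds.extend(p for p in preds if p.patient_id in set(test_fold))
    pred_df = pd.DataFrame([{"note_id": p.note_id,
                             "patient_id": p.patient_id,
                             "score": round(p.score, 6),
                             "note_type": p.note_type}
                            for p in all_preds])
    pred_df.to_csv(args.out_dir / "predictions.csv", index=False,
                   lineterminator="\n")
    agg = aggregate_patients(all_preds)
    agg.to_csv(args.out_dir / "aggregate.csv", index=False,
               lineterminator="\n")
    acc = (agg.set_index("patient_id")["predicted_class"]
           .eq(pd.Series(y)).mean())
    print(f"scored {len(pred_df)} held-out notes over 5 folds; "
          f"patient-level agreement with the composite label: {acc:.3f}")


if __name__ == "__main__":
    main()
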