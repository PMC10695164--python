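"""Full comparison report: every pipeline x modality x outcome label.

Evaluates both structured families and the note pipeline against the
composite label and each of the seven individual recurrence measures,
mirroring the sub-label stability comparison.
"""

import argparse
from pathlib import Path

from szrec.outcomes import CRITERION_FIELDS
from szrec.report import ExperimentConfig, run_experiment


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n", type=int, default=2000)
    ap.add_argument("--out-dir", type=Path, default=Path("results/report"))
    args = ap.parse_args()

    report = run_experiment(ExperimentConfig(
        n_patients=args.n, seed=args.seed,
        modalities=("emr", "claims"),
        labels=("composite",) + CRITERION_FIELDS),
        outdir=args.out_dir)
    print(f"{len(report['results'])} evaluations "
          f"-> {args.out_dir / 'report.json'}")
    composite = [r for r in report["results"]
                 if r["name"].endswith("/composite")]
    for r in composite:
        print(f"  {r['name']:45s} AUROC {r['auroc']:.3f} F1 {r['f1']:.3f}")


if __name__ == "__main__":
    main()
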