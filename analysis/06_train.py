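"""Cross-validate the structured baselines and the note pipeline.

Runs elastic-net logistic regression and gradient-boosted trees on the
pre-index features (EMR and claims) plus the note scorer on EMR notes,
against the composite label, with 95% CIs, and writes report tables.
"""

import argparse
from pathlib import Path

from szrec.report import ExperimentConfig, run_experiment


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n", type=int, default=2000)
    ap.add_argument("--out-dir", type=Path, default=Path("results/train"))
    args = ap.parse_args()

    report = run_experiment(ExperimentConfig(
        n_patients=args.n, seed=args.seed,
        modalities=("emr", "claims"), labels=("composite",)),
        outdir=args.out_dir)
    print(f"{'pipeline':45s} {'AUROC':>6s} {'F1':>6s}   95% CI (AUROC)")
    for r in report["results"]:
        lo, hi = r["auroc_ci"]
        print(f"{r['name']:45s} {r['auroc']:.3f}  {r['f1']:.3f}   "
              f"[{lo:.3f}, {hi:.3f}]")
    print(f"tables written to {args.out_dir}")


if __name__ == "__main__":
    main()
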