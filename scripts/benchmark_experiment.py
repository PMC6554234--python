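"""Optional external experiment: benchmark on the published ACP datasets.

The published ACP740 / ACP240 benchmarks are hosted at
https://github.com/haichengyi/ACP-DL.  This toolkit never downloads them
implicitly; obtain the positive/negative FASTA files yourself and point
this script at them.  Expected published reference points (5-fold CV,
LSTM): ACP740 accuracy 81.48 % / AUC 0.894; ACP240 accuracy 85.42 % /
AUC 0.906.  Because the original fold assignments, seeds and training
hyperparameters are unpublished, agreement within roughly ±5 percentage
points is the realistic expectation — this experiment is documentation,
not a gate (see docs/methods.md, "External benchmarks").

Usage:
    python scripts/benchmark_experiment.py --pos acp740_pos.fasta \
        --neg acp740_neg.fasta --seed 42 --out results/acp740/
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from acpred import compare_models, comparison_table, load_dataset


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--pos", required=True, help="positive-class FASTA")
    parser.add_argument("--neg", required=True, help="negative-class FASTA")
    parser.add_argument("--models", default="lstm,svm,rf,nb")
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args(argv)

    dataset = load_dataset(args.pos, args.neg)
    print(
        f"{dataset.name}: {dataset.n_total} peptides "
        f"({dataset.n_positive} positive / {dataset.n_negative} negative)"
    )
    reports = compare_models(
        dataset, [m.strip() for m in args.models.split(",")], seed=args.seed
    )
    args.out.mkdir(parents=True, exist_ok=True)
    for name, report in reports.items():
        report.to_tsv(args.out / f"cv_{name}.tsv")
        report.to_json(args.out / f"cv_{name}.json")
        print()
        print(report.summary())
    print()
    print(comparison_table(reports).to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
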