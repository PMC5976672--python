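"""Lasso-multinomial classification with stability selection.

Runs the three models (miRNA, proteins, miRNA + proteins, each with
unpenalised centre covariates) through the replicated 1/10-test protocol:
lambda tuned by 10-fold CV on each training set, test accuracy recorded
overall and per class, and per-feature selection frequencies aggregated.
Writes one selection-profile table per model plus an accuracy summary.
"""

import argparse
import json
from pathlib import Path

from gravesomics import classify
from gravesomics.datamodel import (Block, Scale, read_matrix,
                                   read_samplesheet)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--prep-dir", type=Path, default=Path("results/prep"))
    ap.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/classify"))
    ap.add_argument("--reps", type=int, default=150)
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cpm = read_matrix(args.prep_dir / "mirna_cpm_filtered.tsv", Block.MIRNA,
                      Scale.CPM)
    prot = read_matrix(args.prep_dir / "protein_log_filtered.tsv",
                       Block.PROTEIN, Scale.LOG_ABUNDANCE)
    sheet = read_samplesheet(args.sim_dir / "samples.tsv")

    summaries = {}
    for name, (m, p) in {"mirna": (cpm, None), "protein": (None, prot),
                         "combined": (cpm, prot)}.items():
        space = classify.build_feature_space(sheet, m, p)
        profile = classify.resample_evaluate(space, sheet.status,
                                             R=args.reps, seed=args.seed)
        profile.to_frame().to_csv(args.out_dir / f"selection_{name}.tsv",
                                  sep="\t", index=False)
        summary = profile.summary()
        summaries[name] = summary.to_dict(orient="records")
        overall = summary.iloc[0]
        print(f"{name}: accuracy {overall['accuracy']:.2f} "
              f"(sd {overall['std']:.2f}) over {args.reps} replicates")
    (args.out_dir / "accuracy_summary.json").write_text(
        json.dumps(summaries, indent=1))


if __name__ == "__main__":
    main()
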