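"""Combine differential expression and selection frequencies into the
robust-biomarker list.

Builds the five candidate sets (mirDE, protDE at q < 0.05; top-20
predictors of each classification model), evaluates the set expression
(mirDE & mirPRD) | (protDE & protPRD) | (mirprotPRD & (mirDE | protDE)),
and writes the combined table with provenance plus the Euler-diagram
counts.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from gravesomics import classify, combine
from gravesomics.classify import SelectionProfile


def _load_profile(path: Path) -> SelectionProfile:
    df = pd.read_csv(path, sep="\t")
    R = int(round(df["count"].max() / max(df["frequency"].max(), 1e-12))) \
        if df["count"].max() > 0 else 1
    return SelectionProfile(
        feature_ids=list(df["feature_id"]),
        counts=df["count"].to_numpy(float),
        frequencies=df["frequency"].to_numpy(float),
        mean_abs_coef=df["mean_abs_coef"].to_numpy(float),
        overall_accuracy=np.array([np.nan]),
        per_class_accuracy=pd.DataFrame(),
        R=R,
    )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--de-dir", type=Path, default=Path("results/de"))
    ap.add_argument("--classify-dir", type=Path,
                    default=Path("results/classify"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/biomarkers"))
    ap.add_argument("--fdr", type=float, default=0.05)
    ap.add_argument("--topk", type=int, default=20)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    de_mir = pd.read_csv(args.de_dir / "de_mirna.tsv", sep="\t")
    de_prot = pd.read_csv(args.de_dir / "de_protein.tsv", sep="\t")
    profiles = {name: _load_profile(args.classify_dir /
                                    f"selection_{name}.tsv")
                for name in ("mirna", "protein", "combined")}

    sets = combine.build_candidate_sets(
        de_mir, de_prot, profiles["mirna"], profiles["protein"],
        profiles["combined"], fdr_threshold=args.fdr, k=args.topk)
    report = combine.combine_sets(sets)
    table = combine.biomarker_table(report, de_mir, de_prot, profiles)
    table.to_csv(args.out_dir / "biomarkers.tsv", sep="\t", index=False)
    (args.out_dir / "euler_counts.json").write_text(
        json.dumps(report.term_sizes, indent=1))
    print(f"{report.term_sizes['total_with_duplicates']} set members across "
          f"the three terms, {len(report)} unique biomarkers "
          f"-> {args.out_dir / 'biomarkers.tsv'}")


if __name__ == "__main__":
    main()
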