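"""Differential expression of miRNAs (NB GLM) and proteins (multinomial logit).

Likelihood-ratio tests of the status/protein terms against reduced models,
Storey q-values, and per-contrast log2 fold-changes; also reports recovery
of the planted ground truth when available.
"""

import argparse
import json
from pathlib import Path

from gravesomics import diffexpr
from gravesomics.datamodel import (Block, Scale, read_matrix,
                                   read_samplesheet)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--prep-dir", type=Path, default=Path("results/prep"))
    ap.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/de"))
    ap.add_argument("--fdr", type=float, default=0.05)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    counts = read_matrix(args.prep_dir / "mirna_counts_filtered.tsv",
                         Block.MIRNA, Scale.RAW_COUNTS)
    prot = read_matrix(args.prep_dir / "protein_log_filtered.tsv",
                       Block.PROTEIN, Scale.LOG_ABUNDANCE)
    sheet = read_samplesheet(args.sim_dir / "samples.tsv")

    de_mir = diffexpr.run_de_mirna(counts, sheet)
    de_prot = diffexpr.run_de_protein(prot, sheet)
    de_mir.to_csv(args.out_dir / "de_mirna.tsv", sep="\t", index=False)
    de_prot.to_csv(args.out_dir / "de_protein.tsv", sep="\t", index=False)

    summary = {
        "n_mirna_tested": int(de_mir.p_value.notna().sum()),
        "n_mirna_fdr": int((de_mir.q_value < args.fdr).sum()),
        "n_protein_tested": int(de_prot.p_value.notna().sum()),
        "n_protein_fdr": int((de_prot.q_value < args.fdr).sum()),
    }
    truth_path = args.sim_dir / "ground_truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        for block, de in (("mirna", de_mir), ("protein", de_prot)):
            planted = set(truth[f"de_{block}_ids"])
            hits = set(de.loc[de.q_value < args.fdr, "feature_id"])
            detectable = planted & set(de.feature_id)
            summary[f"{block}_recovered"] = len(hits & planted)
            summary[f"{block}_detectable_planted"] = len(detectable)
            summary[f"{block}_false_hits"] = len(hits - planted)
    (args.out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    print(f"miRNA: {summary['n_mirna_fdr']} of "
          f"{summary['n_mirna_tested']} at q<{args.fdr:g}; proteins: "
          f"{summary['n_protein_fdr']} of {summary['n_protein_tested']}")
    if "mirna_recovered" in summary:
        print(f"recovery: miRNA {summary['mirna_recovered']}/"
              f"{summary['mirna_detectable_planted']} planted "
              f"({summary['mirna_false_hits']} false), protein "
              f"{summary['protein_recovered']}/"
              f"{summary['protein_detectable_planted']} "
              f"({summary['protein_false_hits']} false)")


if __name__ == "__main__":
    main()
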