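"""Normalise and filter the raw two-block tables.

miRNA: counts-per-million within each sample, then keep features with
CPM >= 2 in more than two samples. Proteins: keep features detected in
more than two samples, natural-log transform (zeros preserved), then
median-centre detected values per sample to remove mass-spec loading.
"""

import argparse
import json
from pathlib import Path

from gravesomics import preprocess
from gravesomics.datamodel import Block, Scale, read_matrix, write_matrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in-dir", type=Path, default=Path("results/sim"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/prep"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    counts = read_matrix(args.in_dir / "mirna_counts.tsv", Block.MIRNA,
                         Scale.RAW_COUNTS)
    raw_prot = read_matrix(args.in_dir / "protein_abundance.tsv",
                           Block.PROTEIN, Scale.RAW_ABUNDANCE)

    cpm = preprocess.cpm_normalize(counts)
    cpm_f, mir_rep = preprocess.filter_mirna(cpm)
    prot_f, prot_rep = preprocess.filter_proteins(raw_prot)
    prot_log = preprocess.normalize_protein_loading(
        preprocess.log_transform_proteins(prot_f))

    write_matrix(cpm_f, args.out_dir / "mirna_cpm_filtered.tsv")
    write_matrix(counts.subset_features(mir_rep.retained_ids),
                 args.out_dir / "mirna_counts_filtered.tsv")
    write_matrix(prot_log, args.out_dir / "protein_log_filtered.tsv")
    report = {
        "mirna": {"rule": mir_rep.rule, "input": mir_rep.n_input_features,
                  "retained": mir_rep.n_retained},
        "protein": {"rule": prot_rep.rule, "input": prot_rep.n_input_features,
                    "retained": prot_rep.n_retained},
    }
    (args.out_dir / "filter_report.json").write_text(
        json.dumps(report, indent=1))
    print(f"miRNA: kept {mir_rep.n_retained}/{mir_rep.n_input_features} "
          f"({mir_rep.rule}); proteins: kept "
          f"{prot_rep.n_retained}/{prot_rep.n_input_features} "
          f"({prot_rep.rule})")


if __name__ == "__main__":
    main()
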