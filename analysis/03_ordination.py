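"""Ordinate samples by principal coordinate analysis.

Euclidean distances between samples over (i) filtered log-CPM miRNA,
(ii) filtered protein log abundances, (iii) both blocks combined with
per-feature standardisation; classical PCoA of each; writes coordinates
and per-axis variance-explained fractions.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from gravesomics import ordination
from gravesomics.datamodel import (Block, OmicsMatrix, Scale, read_matrix,
                                   read_samplesheet)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--prep-dir", type=Path, default=Path("results/prep"))
    ap.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/ordination"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cpm = read_matrix(args.prep_dir / "mirna_cpm_filtered.tsv", Block.MIRNA,
                      Scale.CPM)
    log_cpm = OmicsMatrix(cpm.feature_ids, cpm.sample_ids,
                          np.log1p(cpm.values), Block.MIRNA, Scale.STANDARDIZED)
    prot = read_matrix(args.prep_dir / "protein_log_filtered.tsv",
                       Block.PROTEIN, Scale.LOG_ABUNDANCE)
    sheet = read_samplesheet(args.sim_dir / "samples.tsv")

    variance = {}
    for name, dist in {
        "mirna": ordination.euclidean_distances(log_cpm),
        "protein": ordination.euclidean_distances(prot),
        "combined": ordination.euclidean_distances(log_cpm, prot),
    }.items():
        res = ordination.pcoa(dist, k=2)
        coords = pd.DataFrame(res.coordinates, columns=["dim1", "dim2"])
        coords.insert(0, "sample_id", res.sample_ids)
        coords["status"] = sheet.status
        coords.to_csv(args.out_dir / f"pcoa_{name}.tsv", sep="\t", index=False)
        variance[name] = {
            "dim1": float(res.variance_explained[0]),
            "dim2": float(res.variance_explained[1]),
            "first_two": float(res.variance_explained[:2].sum()),
        }
        print(f"{name}: first two axes carry "
              f"{100 * variance[name]['first_two']:.1f}% of the variance")
    (args.out_dir / "variance_explained.json").write_text(
        json.dumps(variance, indent=1))


if __name__ == "__main__":
    main()
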