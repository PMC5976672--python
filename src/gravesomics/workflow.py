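"""End-to-end orchestration of the biomarker-discovery pipeline.

One call runs: CPM normalisation + expression filters, differential
expression on both blocks, the three classification models (miRNA,
protein, combined) under the resampling protocol, and the set-algebra
combiner. Thin by design — every step lives in its own module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import classify, combine, diffexpr, preprocess
from .datamodel import OmicsMatrix, SampleSheet


@dataclass
class DiscoveryResult:
    mirna_filtered: OmicsMatrix
    protein_filtered: OmicsMatrix
    de_mirna: pd.DataFrame
    de_protein: pd.DataFrame
    profiles: dict[str, classify.SelectionProfile]
    candidate_sets: combine.CandidateSets
    report: combine.BiomarkerReport
    filter_reports: dict[str, preprocess.FilterReport] = field(
        default_factory=dict)


def run_discovery(mirna_raw: OmicsMatrix, protein_raw: OmicsMatrix,
                  sheet: SampleSheet, R: int = 150, seed: int = 0,
                  fdr_threshold: float = 0.05, top_k: int = 20,
                  n_lambda: int = 100, labels=None) -> DiscoveryResult:
    """Run the full discovery pipeline on raw two-block data.

    ``labels`` overrides the sheet's status vector for the classification
    stage (permutation controls); differential expression always uses the
    sheet as given, so pass a permuted sheet for a full-null control.
    """
    cpm = preprocess.cpm_normalize(mirna_raw)
    mir_cpm_f, mir_report = preprocess.filter_mirna(cpm)
    mir_counts_f = mirna_raw.subset_features(mir_report.retained_ids)
    prot_f, prot_report = preprocess.filter_proteins(protein_raw)
    prot_log = preprocess.normalize_protein_loading(
        preprocess.log_transform_proteins(prot_f))

    de_mir = diffexpr.run_de_mirna(mir_counts_f, sheet)
    de_prot = diffexpr.run_de_protein(prot_log, sheet)

    y = list(labels) if labels is not None else list(sheet.status)
    profiles = {}
    for name, (mcpm, plog) in {
        "mirna": (mir_cpm_f, None),
        "protein": (None, prot_log),
        "combined": (mir_cpm_f, prot_log),
    }.items():
        space = classify.build_feature_space(sheet, mcpm, plog)
        profiles[name] = classify.resample_evaluate(
            space, y, R=R, seed=seed, n_lambda=n_lambda)

    sets = combine.build_candidate_sets(de_mir, de_prot, profiles["mirna"],
                                        profiles["protein"],
                                        profiles["combined"],
                                        fdr_threshold=fdr_threshold, k=top_k)
    report = combine.combine_sets(sets)
    combine.biomarker_table(report, de_mir, de_prot, profiles)
    return DiscoveryResult(mir_cpm_f, prot_log, de_mir, de_prot, profiles,
                           sets, report,
                           {"mirna": mir_report, "protein": prot_report})
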