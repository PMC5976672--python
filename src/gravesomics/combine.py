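"""Set-algebra combiner producing the robust-biomarker list.

Five candidate sets feed it: miRNAs and proteins differentially expressed
at q < threshold (mirDE, protDE) and the top-k predictors by selection
frequency from the three classification models (mirPRD, protPRD,
mirprotPRD). The combined list is

    (mirDE & mirPRD) | (protDE & protPRD) | (mirprotPRD & (mirDE | protDE))

deduplicated, with per-feature provenance recording which of the three
union terms contributed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import SelectionProfile, top_predictors


@dataclass
class CandidateSets:
    mirDE: set[str]
    protDE: set[str]
    mirPRD: set[str]
    protPRD: set[str]
    mirprotPRD: set[str]


@dataclass
class BiomarkerReport:
    combined_ids: list[str]                  # sorted, unique
    provenance: dict[str, list[str]]         # feature -> contributing terms
    table: pd.DataFrame = field(default=None, repr=False)
    term_sizes: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.combined_ids)


def build_candidate_sets(de_mirna: pd.DataFrame, de_protein: pd.DataFrame,
                         mir_profile: SelectionProfile,
                         prot_profile: SelectionProfile,
                         mirprot_profile: SelectionProfile,
                         fdr_threshold: float = 0.05,
                         k: int = 20) -> CandidateSets:
    """DE sets by q-value threshold, predictor sets by top-k frequency."""
    mir_de = _de_set(de_mirna, fdr_threshold, "miRNA")
    prot_de = _de_set(de_protein, fdr_threshold, "protein")
    return CandidateSets(
        mirDE=mir_de,
        protDE=prot_de,
        mirPRD=set(top_predictors(mir_profile, k)),
        protPRD=set(top_predictors(prot_profile, k)),
        mirprotPRD=set(top_predictors(mirprot_profile, k)),
    )


def _de_set(de: pd.DataFrame, threshold: float, what: str) -> set[str]:
    hits = set(de.loc[de["q_value"] < threshold, "feature_id"])
    if not hits:
        warnings.warn(f"no {what} features pass q < {threshold:g}",
                      stacklevel=3)
    return hits


def combine_sets(c: CandidateSets) -> BiomarkerReport:
    """Evaluate the combining expression literally and record provenance."""
    term1 = c.mirDE & c.mirPRD
    term2 = c.protDE & c.protPRD
    term3 = c.mirprotPRD & (c.mirDE | c.protDE)
    combined = sorted(term1 | term2 | term3)
    provenance = {}
    for f in combined:
        terms = []
        if f in term1:
            terms.append("mirDE&mirPRD")
        if f in term2:
            terms.append("protDE&protPRD")
        if f in term3:
            terms.append("mirprotPRD&DE")
        provenance[f] = terms
    return BiomarkerReport(
        combined_ids=combined,
        provenance=provenance,
        term_sizes={"mirDE&mirPRD": len(term1), "protDE&protPRD": len(term2),
                    "mirprotPRD&DE": len(term3),
                    "total_with_duplicates": len(term1) + len(term2)
                    + len(term3), "unique": len(combined)},
    )


def biomarker_table(report: BiomarkerReport, de_mirna: pd.DataFrame,
                    de_protein: pd.DataFrame,
                    profiles: dict[str, SelectionProfile]) -> pd.DataFrame:
    """Per-biomarker q-value, best selection frequency across models, and
    per-contrast log2 fold-changes (the published report's table layout)."""
    de = pd.concat([de_mirna, de_protein], ignore_index=True)
    de = de.set_index("feature_id")
    freq = {}
    for prof in profiles.values():
        for f, fr in zip(prof.feature_ids, prof.frequencies):
            freq[f] = max(freq.get(f, 0.0), float(fr))
    rows = []
    for f in report.combined_ids:
        row = {"feature_id": f,
               "q_value": float(de["q_value"].get(f, np.nan)),
               "selection_frequency": freq.get(f, np.nan),
               "provenance": "+".join(report.provenance[f])}
        for c in ("log2fc_GD_vs_control", "log2fc_GO_vs_control",
                  "log2fc_GO_vs_GD"):
            row[c] = float(de[c].get(f, np.nan)) if f in de.index else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    report.table = table
    return table
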