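"""Library-size normalisation and low-expression filtering.

miRNA counts are scaled within each sample to counts-per-million,
CPM_i = X_i / N * 1e6 with N the sample's total counts; only miRNAs with
CPM >= 2 in more than two samples are kept. Protein raw abundances are
natural-log transformed with the zero branch f(0) = 0 (non-detection stays
zero); only proteins detected (x > 0) in more than two samples are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import OmicsMatrix, Scale, ValidationError


@dataclass
class FilterReport:
    n_input_features: int
    n_retained: int
    retained_ids: list[str]
    rule: str

    def __post_init__(self) -> None:
        if self.n_retained != len(self.retained_ids):
            raise ValidationError("n_retained must equal |retained_ids|")
        if self.n_retained > self.n_input_features:
            raise ValidationError("cannot retain more features than input")


def cpm_normalize(counts: OmicsMatrix) -> OmicsMatrix:
    """Counts-per-million within each sample; output columns sum to 1e6."""
    if counts.scale is not Scale.RAW_COUNTS:
        raise ValidationError(f"expected raw counts, got {counts.scale.value}")
    totals = counts.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [counts.sample_ids[j] for j in zero]
        raise ValidationError(f"all-zero samples cannot be CPM-normalised: {bad}")
    cpm = counts.values / totals[None, :] * 1e6
    return OmicsMatrix(list(counts.feature_ids), list(counts.sample_ids),
                       cpm, counts.block, Scale.CPM)


def filter_mirna(cpm: OmicsMatrix, min_cpm: float = 2.0,
                 min_samples: int = 2) -> tuple[OmicsMatrix, FilterReport]:
    """Keep miRNAs with CPM >= min_cpm in strictly more than min_samples samples."""
    if cpm.scale is not Scale.CPM:
        raise ValidationError(f"expected cpm scale, got {cpm.scale.value}")
    n_qualifying = (cpm.values >= min_cpm).sum(axis=1)
    keep = n_qualifying > min_samples
    retained = [f for f, k in zip(cpm.feature_ids, keep) if k]
    report = FilterReport(
        n_input_features=len(cpm.feature_ids),
        n_retained=len(retained),
        retained_ids=retained,
        rule=f"CPM >= {min_cpm:g} in more than {min_samples} samples",
    )
    return cpm.subset_features(retained), report


def log_transform_proteins(raw: OmicsMatrix) -> OmicsMatrix:
    """Natural-log transform with explicit zero branch: f(0)=0, f(x)=ln x.

    Note the branch makes f(1) collide with f(0); mass-spec abundances are
    normally orders of magnitude above 1, so values <= 1 trigger a warning.
    """
    if raw.scale is not Scale.RAW_ABUNDANCE:
        raise ValidationError(f"expected raw abundances, got {raw.scale.value}")
    x = raw.values
    if np.any(x < 0):
        raise ValidationError("raw abundances must be non-negative")
    low = (x > 0) & (x <= 1)
    if low.any():
        warnings.warn(
            f"{int(low.sum())} abundance values in (0, 1] map into the "
            "zero/negative range of the log transform",
            stacklevel=2,
        )
    out = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), 0.0)
    return OmicsMatrix(list(raw.feature_ids), list(raw.sample_ids), out,
                       raw.block, Scale.LOG_ABUNDANCE)


def normalize_protein_loading(log_abund: OmicsMatrix) -> OmicsMatrix:
    """Median-centre detected log abundances within each sample.

    Label-free mass-spec intensities carry a per-sample loading factor
    (total protein amount, injection volume, instrument drift). On the log
    scale this is an additive per-sample shift common to all proteins; left
    in place it correlates every protein with any chance imbalance of
    loading across groups, confounding the class models. Median-centring
    the detected values per sample removes it. Zeros (non-detections) are
    left untouched; a detected value equal to the loading estimate also
    maps to exactly 0, so detection status must be derived from the raw
    matrix, never from the normalised one.
    """
    if log_abund.scale is not Scale.LOG_ABUNDANCE:
        raise ValidationError(
            f"expected log_abundance scale, got {log_abund.scale.value}")
    x = log_abund.values.copy()
    detected = x != 0
    if not detected.any():
        raise ValidationError("no detected values to normalise")
    # estimate loading on proteins detected in every sample, so the shift
    # estimate is not confounded by per-sample detection composition
    complete = detected.all(axis=1)
    for j in range(x.shape[1]):
        ref = complete if complete.sum() >= 10 else detected[:, j]
        if ref.any():
            shift = np.median(x[ref, j])
            col = detected[:, j]
            x[col, j] -= shift
    return OmicsMatrix(list(log_abund.feature_ids),
                       list(log_abund.sample_ids), x, log_abund.block,
                       Scale.LOG_ABUNDANCE)


def filter_proteins(raw: OmicsMatrix,
                    min_samples: int = 2) -> tuple[OmicsMatrix, FilterReport]:
    """Keep proteins detected (x > 0) in strictly more than min_samples samples."""
    n_detected = (raw.values > 0).sum(axis=1)
    keep = n_detected > min_samples
    retained = [f for f, k in zip(raw.feature_ids, keep) if k]
    report = FilterReport(
        n_input_features=len(raw.feature_ids),
        n_retained=len(retained),
        retained_ids=retained,
        rule=f"detected (x > 0) in more than {min_samples} samples",
    )
    return raw.subset_features(retained), report
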