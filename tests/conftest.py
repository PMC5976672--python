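import numpy as np
import pytest

from gravesomics import preprocess, simulate
from gravesomics.datamodel import SampleSheet


@pytest.fixture(scope="session")
def small_dataset():
    """Small two-block dataset with planted 2-fold effects (15/group)."""
    cfg = simulate.SimulationConfig(
        n_per_group=(15, 15, 15), n_mirna=200, n_protein=120,
        frac_de=0.1, fold_change=2.0, seed=42,
    )
    mirna, protein, sheet, truth = simulate.simulate_dataset(cfg)
    return cfg, mirna, protein, sheet, truth


@pytest.fixture(scope="session")
def filtered_blocks(small_dataset):
    """Normalised + filtered matrices from the small dataset."""
    _, mirna, protein, sheet, truth = small_dataset
    cpm = preprocess.cpm_normalize(mirna)
    cpm_f, mir_report = preprocess.filter_mirna(cpm)
    counts_f = mirna.subset_features(mir_report.retained_ids)
    prot_f, prot_report = preprocess.filter_proteins(protein)
    prot_log = preprocess.normalize_protein_loading(
        preprocess.log_transform_proteins(prot_f))
    return {
        "cpm": cpm_f, "counts": counts_f, "protein_log": prot_log,
        "sheet": sheet, "truth": truth,
        "reports": {"mirna": mir_report, "protein": prot_report},
    }


@pytest.fixture
def tiny_sheet():
    """12 samples, 4 per class, two centres."""
    n = 12
    status = ["control"] * 4 + ["GD"] * 4 + ["GO"] * 4
    centre = (["Cardiff", "Essen"] * 6)[:n]
    return SampleSheet([f"S{i}" for i in range(n)], status, centre)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
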