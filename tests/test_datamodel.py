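import numpy as np
import pytest

from gravesomics.datamodel import (
    Block,
    OmicsMatrix,
    SampleSheet,
    Scale,
    ValidationError,
    align,
    read_gmt,
    read_matrix,
    read_samplesheet,
    write_matrix,
    write_samplesheet,
)


class TestOmicsMatrix:
    def test_reads_counts_tsv_verbatim(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("feature_id\tS1\tS2\nmirA\t3\t0\nmirB\t1\t7\n")
        m = read_matrix(path, Block.MIRNA, Scale.RAW_COUNTS)
        assert m.feature_ids == ["mirA", "mirB"]
        assert m.sample_ids == ["S1", "S2"]
        np.testing.assert_array_equal(m.values, [[3, 0], [1, 7]])

    def test_duplicate_feature_id_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("feature_id\tS1\nmirA\t3\nmirA\t1\n")
        with pytest.raises(ValidationError, match="mirA"):
            read_matrix(path, Block.MIRNA, Scale.RAW_COUNTS)

    @pytest.mark.parametrize("bad_values,message", [
        ([[-1, 2]], "non-negative"),
        ([[1.5, 2.0]], "integers"),
    ])
    def test_raw_counts_must_be_nonneg_integers(self, bad_values, message):
        with pytest.raises(ValidationError, match=message):
            OmicsMatrix(["f1"], ["S1", "S2"], np.array(bad_values),
                        Block.MIRNA, Scale.RAW_COUNTS)

    def test_shape_id_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            OmicsMatrix(["f1", "f2"], ["S1"], np.zeros((1, 1)),
                        Block.MIRNA, Scale.RAW_COUNTS)

    def test_roundtrip_counts_exact(self, tmp_path, small_dataset):
        _, mirna, _, _, _ = small_dataset
        path = tmp_path / "counts.tsv"
        write_matrix(mirna, path)
        back = read_matrix(path, Block.MIRNA, Scale.RAW_COUNTS)
        assert back.feature_ids == mirna.feature_ids
        assert back.sample_ids == mirna.sample_ids
        np.testing.assert_array_equal(back.values, mirna.values)

    def test_roundtrip_abundances_close(self, tmp_path, small_dataset):
        _, _, protein, _, _ = small_dataset
        path = tmp_path / "prot.tsv"
        write_matrix(protein, path)
        back = read_matrix(path, Block.PROTEIN, Scale.RAW_ABUNDANCE)
        np.testing.assert_allclose(back.values, protein.values, rtol=1e-9)


class TestSampleSheet:
    def test_single_row_parsed(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("sample_id\tstatus\tcentre\nS1\tGD\tCardiff\n")
        sheet = read_samplesheet(path)
        assert sheet.status == ["GD"]

    def test_unknown_status_level_lists_allowed(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("sample_id\tstatus\tcentre\nS1\tgraves\tCardiff\n")
        with pytest.raises(ValidationError, match="control"):
            read_samplesheet(path)

    def test_study_design_counts(self, tmp_path):
        """46 subjects: 13 controls, 14 GD, 19 GO."""
        rows = ["sample_id\tstatus\tcentre"]
        centres = ["Cardiff", "Essen", "Milan"]
        i = 0
        for status, n in (("control", 13), ("GD", 14), ("GO", 19)):
            for _ in range(n):
                rows.append(f"S{i}\t{status}\t{centres[i % 3]}")
                i += 1
        path = tmp_path / "s.tsv"
        path.write_text("\n".join(rows) + "\n")
        sheet = read_samplesheet(path)
        assert len(sheet) == 46
        assert sheet.status_counts() == {"control": 13, "GD": 14, "GO": 19}

    def test_roundtrip(self, tmp_path, tiny_sheet):
        path = tmp_path / "s.tsv"
        write_samplesheet(tiny_sheet, path)
        back = read_samplesheet(path)
        assert back.sample_ids == tiny_sheet.sample_ids
        assert back.status == tiny_sheet.status

    def test_custom_levels(self):
        sheet = SampleSheet(["a", "b"], ["case", "ctrl"], ["X", "Y"],
                            status_levels=("ctrl", "case"),
                            centre_levels=("X", "Y"))
        assert sheet.status_counts() == {"ctrl": 1, "case": 1}

    def test_align_reorders_columns_to_sheet(self, tiny_sheet, rng):
        m = OmicsMatrix([f"f{i}" for i in range(3)],
                        list(reversed(tiny_sheet.sample_ids)),
                        rng.integers(0, 9, size=(3, 12)),
                        Block.MIRNA, Scale.RAW_COUNTS)
        aligned = align(m, tiny_sheet)
        assert aligned.sample_ids == tiny_sheet.sample_ids
        np.testing.assert_array_equal(aligned.values, m.values[:, ::-1])

    def test_align_rejects_extra_samples(self, tiny_sheet):
        m = OmicsMatrix(["f1"], tiny_sheet.sample_ids + ["S99"],
                        np.zeros((1, 13)), Block.MIRNA, Scale.RAW_COUNTS)
        with pytest.raises(ValidationError, match="S99"):
            align(m, tiny_sheet)


class TestGMT:
    def test_basic_line(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("P1\tdesc\tG1\tG2\n")
        (pw,) = read_gmt(path)
        assert pw.pathway_id == "P1"
        assert pw.gene_symbols == {"G1", "G2"}

    def test_duplicate_genes_deduplicated(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("P1\tdesc\tG1\tG1\n")
        (pw,) = read_gmt(path)
        assert len(pw.gene_symbols) == 1

    def test_short_line_is_parse_error(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("P1\tdesc\n")
        with pytest.raises(ValidationError, match="3 fields|>=1 gene"):
            read_gmt(path)
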