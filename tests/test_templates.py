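"""Fixture generator closure, field inventory, skeleton drafting."""

import hashlib
import io

import pytest
from openpyxl import Workbook

import fairsheet as fs
from fairsheet.templates import CELL_TYPE_VARIANTS


def _xlsx_bytes(bundle: fs.FixtureBundle, tmp_path, name: str) -> bytes:
    path = str(tmp_path / name)
    fs.save_workbook(bundle.workbook, path)
    with open(path, "rb") as fh:
        return fh.read()


class TestGenerateFixture:
    def test_row_layout_closure(self, row_bundle):
        """Parsing the generated workbook with the companion configuration
        reproduces the ground-truth records field by field."""
        records = list(fs.parse_workbook(row_bundle.workbook, row_bundle.parser_config))
        assert records == row_bundle.expected

    def test_block_layout_closure(self, block_bundle):
        records = list(fs.parse_workbook(block_bundle.workbook, block_bundle.parser_config))
        assert records == block_bundle.expected

    def test_sparse_layout_closure(self, sparse_row_bundle):
        records = list(
            fs.parse_workbook(sparse_row_bundle.workbook, sparse_row_bundle.parser_config)
        )
        assert records == sparse_row_bundle.expected
        # the absent-cell probability actually produced gaps
        counts = {len(r.protocol_applications[0].effects) for r in records}
        assert 0 in counts and 1 in counts

    def test_block_expected_effect_count(self, block_bundle):
        # 2 replicates x 2 timings x 9 concentrations
        assert len(block_bundle.expected[0].protocol_applications[0].effects) == 36

    def test_same_spec_byte_identical_workbooks(self, tmp_path):
        spec = fs.TemplateSpec(layout="BLOCK_LAYOUT", seed=42)
        one = _xlsx_bytes(fs.generate_fixture(spec), tmp_path, "a.xlsx")
        two = _xlsx_bytes(fs.generate_fixture(spec), tmp_path, "b.xlsx")
        assert hashlib.sha256(one).digest() == hashlib.sha256(two).digest()

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            fs.TemplateSpec(
                layout="BLOCK_LAYOUT", seed=1, block=fs.BlockGeometry(replicates=0)
            )
        with pytest.raises(ValueError):
            fs.TemplateSpec(layout="SOMETHING_ELSE", seed=1)

    def test_seed_is_mandatory(self):
        with pytest.raises(TypeError):
            fs.TemplateSpec(layout="ROW_LAYOUT")  # type: ignore[call-arg]

    def test_cell_type_variants_exercised(self, row_bundle):
        written = {
            r.protocol_applications[0].parameters["cell type"].text
            for r in row_bundle.expected
        }
        assert written == set(CELL_TYPE_VARIANTS)


class TestExtractTemplateFields:
    def test_row_inventory_contains_every_configured_field(self, row_bundle):
        inventory = fs.extract_template_fields(row_bundle.workbook)
        texts = {f.text for f in inventory}
        for header in (
            "Substance name",
            "Public name",
            "Supplier",
            "Material type",
            "CAS number",
            "Cell type",
            "Zeta potential",
            "Concentration",
        ):
            assert header in texts

    def test_empty_workbook_empty_inventory(self):
        assert fs.extract_template_fields(Workbook()) == []

    def test_block_inventory_includes_time_and_concentration_labels(self, block_bundle):
        inventory = fs.extract_template_fields(block_bundle.workbook)
        texts = {f.text for f in inventory}
        expected_labels = {f"C{i}" for i in range(1, 10)} | {"T1", "T2", "R1", "R2"}
        assert expected_labels <= texts

    def test_header_detection_marks_columns_with_numeric_data(self, row_bundle):
        inventory = fs.extract_template_fields(row_bundle.workbook)
        kinds = {f.text: f.kind for f in inventory if f.row == 0}
        assert kinds["Zeta potential"] == "label"
        assert kinds["Concentration"] == "label"


class TestSkeletonConfig:
    def test_draft_passes_validation_with_warnings(self, row_bundle):
        inventory = fs.extract_template_fields(row_bundle.workbook)
        draft = fs.skeleton_config(inventory)
        cfg = fs.load_config(draft)
        assert "SUBSTANCE_NAME" in cfg.substance_record
        assert cfg.warnings  # the TODO marker travels through the warning channel

    def test_single_column_yields_single_substance_binding(self):
        wb = Workbook()
        ws = wb.active
        ws.cell(row=1, column=1, value="Measured size")
        ws.cell(row=2, column=1, value=14.5)
        draft = fs.skeleton_config(fs.extract_template_fields(wb))
        assert list(draft["SUBSTANCE_RECORD"]) == ["SUBSTANCE_NAME"]
        assert "PROTOCOL_APPLICATIONS" not in draft

    def test_placeholders_flagged_todo(self, row_bundle):
        draft = fs.skeleton_config(fs.extract_template_fields(row_bundle.workbook))
        params = draft["PROTOCOL_APPLICATIONS"][0]["PARAMETERS"]
        assert params and all(p["NAME"].startswith("TODO: ") for p in params)

    def test_stable_under_rerun(self, row_bundle):
        inventory = fs.extract_template_fields(row_bundle.workbook)
        assert fs.skeleton_config(inventory) == fs.skeleton_config(inventory)

    def test_empty_inventory_is_an_error(self):
        with pytest.raises(ValueError):
            fs.skeleton_config([])
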