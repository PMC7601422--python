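"""Engine behaviour: cell reads, value grammar, row iteration, block expansion."""

import datetime
import random

import pytest
from openpyxl import Workbook

import fairsheet as fs
from fairsheet.config import (
    DataAccessConfig,
    EffectBlockConfig,
    ExcelDataLocation,
    IterationMode,
    ParameterRule,
    ValueGroupConfig,
)
from fairsheet.engine import (
    Cursor,
    ParseError,
    ParseReport,
    _Sheets,
    expand_effect_block,
    parse_value_expression,
    parse_workbook,
    read_cell,
)


def _cursor(row=0, sheet=0):
    return Cursor(current_row=row, primary_sheet=sheet)


class TestReadCell:
    def test_json_value_literal(self):
        wb = Workbook()
        edl = ExcelDataLocation(iteration=IterationMode.JSON_VALUE, json_value="mV")
        v = read_cell(wb, edl, _cursor())
        assert v == fs.Value(text="mV")

    def test_numeric_absolute_location(self):
        wb = Workbook()
        wb.active.cell(row=3, column=2, value=7.5)
        edl = ExcelDataLocation(
            iteration=IterationMode.ABSOLUTE_LOCATION, row_index=2, column_index=1
        )
        assert read_cell(wb, edl, _cursor()) == fs.Value(number=7.5)

    def test_blank_cell_absent(self):
        wb = Workbook()
        wb.active.cell(row=5, column=5, value="pad")  # establish bounds
        edl = ExcelDataLocation(
            iteration=IterationMode.ABSOLUTE_LOCATION, row_index=1, column_index=1
        )
        assert read_cell(wb, edl, _cursor()) is None

    @pytest.mark.parametrize("marker", ["", "n/a", "N/A", "-", "–", "  n/a  "])
    def test_na_markers_absent(self, marker):
        wb = Workbook()
        wb.active.cell(row=1, column=1, value=marker)
        edl = ExcelDataLocation(
            iteration=IterationMode.ABSOLUTE_LOCATION, row_index=0, column_index=0
        )
        assert read_cell(wb, edl, _cursor()) is None

    def test_date_becomes_iso_text(self):
        wb = Workbook()
        wb.active.cell(row=1, column=1, value=datetime.date(2020, 9, 24))
        edl = ExcelDataLocation(
            iteration=IterationMode.ABSOLUTE_LOCATION, row_index=0, column_index=0
        )
        assert read_cell(wb, edl, _cursor()) == fs.Value(text="2020-09-24")

    def test_decimal_comma_kept_as_text_with_warning(self):
        wb = Workbook()
        wb.active.cell(row=1, column=1, value="3,14")
        edl = ExcelDataLocation(
            iteration=IterationMode.ABSOLUTE_LOCATION, row_index=0, column_index=0
        )
        report = ParseReport()
        assert read_cell(wb, edl, _cursor(), report) == fs.Value(text="3,14")
        assert any("decimal-comma" in w for w in report.warnings)

    def test_out_of_bounds_absent_with_warning(self):
        wb = Workbook()
        wb.active.cell(row=1, column=1, value="x")
        edl = ExcelDataLocation(
            iteration=IterationMode.ABSOLUTE_LOCATION, row_index=50, column_index=50
        )
        report = ParseReport()
        assert read_cell(wb, edl, _cursor(), report) is None
        assert report.warnings

    def test_merged_cells_propagate_anchor_value(self):
        wb = Workbook()
        ws = wb.active
        ws.cell(row=1, column=1, value="Group A")
        ws.merge_cells("A1:C1")
        ws.cell(row=2, column=3, value=1.0)  # widen used range
        sheets = _Sheets(wb)
        assert sheets.cell(0, 0, 2) == fs.Value(text="Group A")

    def test_missing_sheet_name_is_config_time_error(self):
        wb = Workbook()
        with pytest.raises(ParseError):
            _Sheets(wb).sheet("NoSuchSheet")


class TestValueExpressionGrammar:
    # expected values frozen from enumerating the grammar's productions by hand
    @pytest.mark.parametrize(
        "raw, lo_q, lo, up_q, up",
        [
            ("<3", None, None, "<", 3.0),
            ("<=3", None, None, "<=", 3.0),
            (">3", ">", 3.0, None, None),
            (">=0.5", ">=", 0.5, None, None),
            ("~3", "~", 3.0, None, None),
            ("=3", "=", 3.0, None, None),
            ("< 3.5", None, None, "<", 3.5),
            ("3-4", ">=", 3.0, "<=", 4.0),
            ("3–4", ">=", 3.0, "<=", 4.0),
            ("1e2-2e2", ">=", 100.0, "<=", 200.0),
        ],
    )
    def test_productions(self, raw, lo_q, lo, up_q, up):
        parsed = parse_value_expression(raw)
        assert (parsed.lo_qualifier, parsed.lo_value, parsed.up_qualifier, parsed.up_value) == (
            lo_q,
            lo,
            up_q,
            up,
        )

    @pytest.mark.parametrize("raw", ["abc", "NM-100", "<abc", "3-", "--4", "1-2-3"])
    def test_non_matching_inputs_parse_to_nothing(self, raw):
        assert not parse_value_expression(raw).matched

    def test_agrees_with_independent_oracle(self):
        """Cross-check against a brute-force oracle on generated expressions."""
        rng = random.Random(0)
        qualifiers = ["<", "<=", ">", ">=", "~", "="]
        for _ in range(200):
            num = round(rng.uniform(0, 99), 2)
            if rng.random() < 0.5:
                q = rng.choice(qualifiers)
                parsed = parse_value_expression(f"{q}{num}")
                # oracle: upper-bound qualifiers populate the upper slot
                if q in ("<", "<="):
                    assert (parsed.up_qualifier, parsed.up_value) == (q, num)
                    assert parsed.lo_value is None
                else:
                    assert (parsed.lo_qualifier, parsed.lo_value) == (q, num)
                    assert parsed.up_value is None
            else:
                hi = round(num + rng.uniform(0.1, 10), 2)
                parsed = parse_value_expression(f"{num}-{hi}")
                assert (parsed.lo_value, parsed.up_value) == (num, hi)
                assert (parsed.lo_qualifier, parsed.up_qualifier) == (">=", "<=")


class TestRowIteration:
    def test_three_rows_three_records(self, row_bundle):
        records = list(parse_workbook(row_bundle.workbook, row_bundle.parser_config))
        assert len(records) == 3

    def test_header_only_sheet_yields_empty_iterator(self, row_bundle):
        wb = Workbook()
        ws = wb.active
        for col, header in enumerate(("Substance name", "CAS"), start=1):
            ws.cell(row=1, column=col, value=header)
        records = list(parse_workbook(wb, row_bundle.parser_config))
        assert records == []

    def test_blank_rows_terminate_iteration(self, row_bundle):
        wb = fs.generate_fixture(fs.TemplateSpec(layout="ROW_LAYOUT", seed=20)).workbook
        ws = wb.active
        # trailing note separated by >2 blank rows must not become a record
        ws.cell(row=10, column=1, value="note: see protocol")
        records = list(parse_workbook(wb, row_bundle.parser_config))
        assert len(records) == 3

    def test_record_independence_on_row_deletion(self):
        bundle = fs.generate_fixture(fs.TemplateSpec(layout="ROW_LAYOUT", seed=33, n_substances=4))
        full = list(parse_workbook(bundle.workbook, bundle.parser_config))
        wb2 = fs.generate_fixture(fs.TemplateSpec(layout="ROW_LAYOUT", seed=33, n_substances=4)).workbook
        wb2.active.delete_rows(3)  # drop the second data row
        partial = list(parse_workbook(wb2, bundle.parser_config))
        assert partial == [full[0], *full[2:]]

    def test_collect_and_continue_vs_strict(self, block_bundle):
        cfg = block_bundle.parser_config
        cfg.protocol_applications[0].effect_blocks[0].sub_block_grid = (40, 1)
        report = ParseReport()
        list(parse_workbook(block_bundle.workbook, cfg, report=report))
        assert any("effect block" in e for e in report.errors)
        with pytest.raises(ParseError):
            list(parse_workbook(block_bundle.workbook, cfg, strict=True))


def _brute_force_count(ws, block: EffectBlockConfig) -> int:
    """Independent cell walker: count non-absent value cells of a block."""
    na = {"", "n/a", "N/A", "-", "–"}
    count = 0
    grid_r, grid_c = block.sub_block_grid
    sub_r, sub_c = block.sub_block_size
    for gr in range(grid_r):
        for gc in range(grid_c):
            for group in block.value_groups:
                for r, c in group.value_cells:
                    row = block.block_origin[0] + gr * sub_r + r
                    col = block.block_origin[1] + gc * sub_c + c
                    v = ws.cell(row=row + 1, column=col + 1).value
                    if v is None or (isinstance(v, str) and v.strip() in na):
                        continue
                    count += 1
    return count


class TestEffectBlocks:
    def test_degenerate_block_one_record(self):
        wb = Workbook()
        wb.active.cell(row=1, column=1, value=42.0)
        block = EffectBlockConfig(
            block_origin=(0, 0),
            sub_block_grid=(1, 1),
            sub_block_size=(1, 1),
            value_groups=[ValueGroupConfig(value_cells=[(0, 0)])],
            sheet_index=0,
        )
        effects = expand_effect_block(wb, block, _cursor())
        assert len(effects) == 1
        assert effects[0].lo_value == 42.0
        assert effects[0].lo_qualifier == "="

    def test_cfe_block_expands_to_36_measurements(self, block_bundle):
        records = list(parse_workbook(block_bundle.workbook, block_bundle.parser_config))
        effects = records[0].protocol_applications[0].effects
        assert len(effects) == 36  # 2 replicates x 2 timings x 9 concentrations
        for effect in effects:
            assert set(effect.conditions) == {"replicate", "time", "concentration"}

    def test_absent_cells_reduce_the_count(self):
        bundle = fs.generate_fixture(fs.TemplateSpec(layout="BLOCK_LAYOUT", seed=20))
        ws = bundle.workbook["Test results"]
        # blank out 3 of the 36 value cells
        for row, col in ((4, 3), (5, 7), (7, 11)):
            ws.cell(row=row, column=col, value="n/a")
        records = list(parse_workbook(bundle.workbook, bundle.parser_config))
        effects = records[0].protocol_applications[0].effects
        assert len(effects) == 33
        block = bundle.parser_config.protocol_applications[0].effect_blocks[0]
        assert _brute_force_count(ws, block) == 33

    @pytest.mark.parametrize("seed", range(12))
    def test_count_law_on_random_geometries(self, seed):
        """|effects| equals the non-absent value cells of the configured grid."""
        rng = random.Random(seed)
        grid = (rng.randint(1, 3), rng.randint(1, 3))
        size = (rng.randint(1, 4), rng.randint(1, 4))
        n_groups = rng.randint(1, 3)
        groups = []
        for _ in range(n_groups):
            cells = rng.sample(
                [(r, c) for r in range(size[0]) for c in range(size[1])],
                rng.randint(1, min(10, size[0] * size[1])),
            )
            groups.append(ValueGroupConfig(value_cells=cells))
        origin = (rng.randint(0, 2), rng.randint(0, 2))
        wb = Workbook()
        ws = wb.active
        for r in range(origin[0] + grid[0] * size[0]):
            for c in range(origin[1] + grid[1] * size[1]):
                roll = rng.random()
                value = None if roll < 0.3 else ("n/a" if roll < 0.45 else rng.random())
                if value is not None:
                    ws.cell(row=r + 1, column=c + 1, value=value)
        ws.cell(
            row=origin[0] + grid[0] * size[0] + 1,
            column=origin[1] + grid[1] * size[1] + 1,
            value="pad",
        )  # ensure bounds cover the block
        block = EffectBlockConfig(
            block_origin=origin,
            sub_block_grid=grid,
            sub_block_size=size,
            value_groups=groups,
            sheet_index=0,
        )
        effects = expand_effect_block(wb, block, _cursor())
        assert len(effects) == _brute_force_count(ws, block)

    def test_block_conditions_come_from_declared_parameters(self):
        wb = Workbook()
        ws = wb.active
        ws.cell(row=1, column=2, value=10.0)  # column header (concentration)
        ws.cell(row=2, column=1, value="R1")  # row label
        ws.cell(row=2, column=2, value=5.5)  # the value
        block = EffectBlockConfig(
            block_origin=(1, 1),
            sub_block_grid=(1, 1),
            sub_block_size=(1, 1),
            value_groups=[
                ValueGroupConfig(
                    value_cells=[(0, 0)],
                    parameters=[
                        ParameterRule(name="concentration", source="COLUMN_HEADER", row_index=0,
                                      unit="ug/mL"),
                        ParameterRule(name="replicate", source="ROW_HEADER", column_index=0),
                        ParameterRule(name="medium", source="JSON_VALUE", json_value="water"),
                        ParameterRule(name="well", source="SUB_BLOCK_INDEX"),
                    ],
                )
            ],
            sheet_index=0,
        )
        effects = expand_effect_block(wb, block, _cursor())
        assert len(effects) == 1
        conditions = effects[0].conditions
        assert conditions["concentration"] == fs.Value(number=10.0, unit="ug/mL")
        assert conditions["replicate"] == fs.Value(text="R1")
        assert conditions["medium"] == fs.Value(text="water")
        assert conditions["well"] == fs.Value(number=1.0)


class TestSyntaxEquivalence:
    def test_short_and_expanded_configs_yield_identical_streams(self, row_bundle):
        expanded = _expand(row_bundle.config)
        assert expanded != row_bundle.config  # the rewrite did something
        short_records = list(parse_workbook(row_bundle.workbook, fs.load_config(row_bundle.config)))
        long_records = list(parse_workbook(row_bundle.workbook, fs.load_config(expanded)))
        assert short_records == long_records


def _expand(config: dict) -> dict:
    """Rewrite every short-syntax data location in fully expanded form."""
    import copy

    out = copy.deepcopy(config)
    da = out["DATA_ACCESS"]

    def walk(node):
        if isinstance(node, dict):
            is_edl = (
                ("COLUMN_INDEX" in node or "ROW_INDEX" in node or "JSON_VALUE" in node)
                and "SOURCE" not in node
                and "VALUE_CELLS" not in node
            )
            if is_edl:
                if "JSON_VALUE" in node:
                    node.setdefault("ITERATION", "JSON_VALUE")
                else:
                    node.setdefault("ITERATION", da["ITERATION"])
                    node.setdefault("SHEET_INDEX", da.get("SHEET_INDEX", 0))
            for v in node.values():
                walk(v)
        elif isinstance(node, list):
            for v in node:
                walk(v)

    for section in ("SUBSTANCE_RECORD", "PROTOCOL_APPLICATIONS"):
        if section in out:
            walk(out[section])
    return out
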