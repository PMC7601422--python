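"""Execution of a parser configuration against a workbook.

The engine walks the workbook as directed by the configuration: under
``ROW_SINGLE`` iteration each data row of the primary sheet becomes one
substance record; every configured data location is resolved to a cell (or a
configuration literal) and the values are assembled into substance records
with protocol applications and effect records.  Hierarchical effect blocks —
a rectangular grid of sub-blocks, each holding value groups whose cells map
one-to-one onto measurements — are expanded with the experimental conditions
("parameters of the value group") read from row/column headers or fixed
cells.

Cell handling follows lab-sheet reality: merged cells propagate the anchor
value, NA markers ("", "n/a", "-", ...) read as absent, numbers stay
numeric, dates become ISO-8601 text, and decimal commas are *not* silently
converted (a warning is emitted instead).  Errors are collected per record
by default so a curator gets a full defect report for the file; a strict
mode raises on the first error.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from typing import Any, Iterator, Optional, Union

from openpyxl import load_workbook
from openpyxl.utils import get_column_letter
from openpyxl.workbook import Workbook

from .config import (
    DataAccessConfig,
    EffectBlockConfig,
    EffectConfig,
    ExcelDataLocation,
    IterationMode,
    ParameterRule,
    ParserConfig,
    ProtocolApplicationConfig,
)
from .model import (
    Component,
    ComponentRole,
    Composition,
    EffectRecord,
    ExternalIdentifier,
    Linkage,
    ProtocolApplication,
    SubstanceRecord,
    Value,
    assign_uuids,
)

__all__ = [
    "Cursor",
    "ParseReport",
    "ParseError",
    "parse_workbook",
    "read_cell",
    "parse_value_expression",
    "expand_effect_block",
    "NA_MARKERS",
]

#: Cell contents treated as "value not reported".  Configurable per parse.
NA_MARKERS = frozenset({"", "n/a", "N/A", "-", "–"})

_ROLE_ALIASES = {
    "MAIN CONSTITUENT": ComponentRole.MAIN_CONSTITUENT,
    "MAIN_CONSTITUENT": ComponentRole.MAIN_CONSTITUENT,
    "IMPURITY": ComponentRole.IMPURITY,
    "ADDITIVE": ComponentRole.ADDITIVE,
    "CORE": ComponentRole.CORE,
    "COATING": ComponentRole.COATING,
    "FUNCTIONALISATION": ComponentRole.FUNCTIONALISATION,
    "FUNCTIONALIZATION": ComponentRole.FUNCTIONALISATION,
    "OTHER": ComponentRole.OTHER,
}

_DECIMAL_COMMA = re.compile(r"^\s*-?\d+,\d+\s*$")


class ParseError(RuntimeError):
    """Fatal parsing problem (strict mode, unreadable input, bad sheet)."""


@dataclass
class Cursor:
    """Iteration state: the current primary-sheet row (0-based)."""

    current_row: int
    primary_sheet: Union[int, str]


@dataclass
class ParseReport:
    """Collected outcome of one parse run."""

    records_parsed: int = 0
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def error(self, message: str, strict: bool = False) -> None:
        self.errors.append(message)
        if strict:
            raise ParseError(message)

    def warning(self, message: str) -> None:
        self.warnings.append(message)


def _a1(row: int, col: int) -> str:
    """0-based (row, col) rendered as A1 notation for log messages."""
    return f"{get_column_letter(col + 1)}{row + 1}"


# ---------------------------------------------------------------------------
# Sheet access

class _Sheets:
    """Workbook wrapper: sheet lookup, merged-cell anchoring, NA handling."""

    def __init__(self, wb: Workbook, na_markers: frozenset[str] = NA_MARKERS):
        self._wb = wb
        self.na_markers = na_markers
        # map every merged coordinate to its anchor so labels spanning a
        # merged header propagate to all covered cells
        self._merged: dict[str, dict[tuple[int, int], tuple[int, int]]] = {}
        for ws in wb.worksheets:
            mapping: dict[tuple[int, int], tuple[int, int]] = {}
            for rng in ws.merged_cells.ranges:
                anchor = (rng.min_row - 1, rng.min_col - 1)
                for r in range(rng.min_row - 1, rng.max_row):
                    for c in range(rng.min_col - 1, rng.max_col):
                        mapping[(r, c)] = anchor
            self._merged[ws.title] = mapping

    def sheet(self, ref: Union[int, str, None]):
        if ref is None:
            ref = 0
        if isinstance(ref, str):
            if ref not in self._wb.sheetnames:
                raise ParseError(
                    f"sheet {ref!r} not found; workbook has {self._wb.sheetnames}"
                )
            return self._wb[ref]
        if not (0 <= ref < len(self._wb.sheetnames)):
            raise ParseError(
                f"sheet index {ref} out of range; workbook has "
                f"{len(self._wb.sheetnames)} sheet(s)"
            )
        return self._wb.worksheets[ref]

    def bounds(self, ref: Union[int, str, None]) -> tuple[int, int]:
        ws = self.sheet(ref)
        return ws.max_row, ws.max_column

    def raw(self, ref: Union[int, str, None], row: int, col: int) -> Any:
        ws = self.sheet(ref)
        anchor = self._merged.get(ws.title, {}).get((row, col))
        if anchor is not None:
            row, col = anchor
        if row < 0 or col < 0:
            return None
        return ws.cell(row=row + 1, column=col + 1).value

    def cell(
        self,
        ref: Union[int, str, None],
        row: int,
        col: int,
        report: Optional[ParseReport] = None,
    ) -> Optional[Value]:
        """Typed content of one cell, or None when absent/NA."""
        value = self.raw(ref, row, col)
        return coerce_cell(value, self.na_markers, report, context=_a1(row, col))

    def row_blank(self, ref: Union[int, str, None], row: int) -> bool:
        ws = self.sheet(ref)
        if row >= ws.max_row:
            return True
        for col in range(ws.max_column):
            v = self.raw(ref, row, col)
            if v is not None and not (isinstance(v, str) and v.strip() in self.na_markers):
                return False
        return True


def coerce_cell(
    value: Any,
    na_markers: frozenset[str] = NA_MARKERS,
    report: Optional[ParseReport] = None,
    context: str = "",
) -> Optional[Value]:
    """Typed coercion of a raw cell value.

    Numbers stay numeric, date/time cells become ISO-8601 text, everything
    else is trimmed text; NA markers yield None.  Decimal commas in text are
    left untouched with a warning — silent locale guessing corrupts data.
    """
    if value is None:
        return None
    if isinstance(value, bool):
        return Value(text=str(value).upper())
    if isinstance(value, (int, float)):
        return Value(number=float(value))
    if isinstance(value, (_dt.datetime, _dt.date, _dt.time)):
        return Value(text=value.isoformat())
    text = str(value).strip()
    if text in na_markers:
        return None
    if report is not None and _DECIMAL_COMMA.match(text):
        report.warning(
            f"cell {context}: {text!r} looks like a decimal-comma number; "
            "left as text (no locale conversion)"
        )
    return Value(text=text)


# ---------------------------------------------------------------------------
# Single-location reads

def read_cell(
    sheets: Union[_Sheets, Workbook],
    edl: ExcelDataLocation,
    cursor: Cursor,
    report: Optional[ParseReport] = None,
) -> Optional[Value]:
    """Resolve one fully-expanded data location to a typed value.

    ``JSON_VALUE`` locations return the configuration literal; otherwise the
    cell addressed by the mode is read (the cursor supplies the row under
    ``ROW_SINGLE``).  Blank cells and cells outside the sheet's used range
    yield None (the latter with a warning).
    """
    if isinstance(sheets, Workbook):
        sheets = _Sheets(sheets)
    if edl.iteration is IterationMode.JSON_VALUE:
        lit = edl.json_value
        if isinstance(lit, bool):
            return Value(text=str(lit).upper())
        if isinstance(lit, (int, float)):
            return Value(number=float(lit))
        return Value(text=str(lit))
    if edl.iteration is IterationMode.ROW_SINGLE:
        row = cursor.current_row
    else:  # ABSOLUTE_LOCATION
        row = edl.row_index  # type: ignore[assignment]
    col = edl.column_index
    assert row is not None and col is not None, "EDL not resolved"
    ref = edl.sheet_ref if edl.sheet_ref is not None else cursor.primary_sheet
    max_row, max_col = sheets.bounds(ref)
    if row >= max_row or col >= max_col:
        if report is not None:
            report.warning(
                f"cell {_a1(row, col)} (row {row}, col {col}) outside used range "
                f"of sheet {ref!r}; treated as absent"
            )
        return None
    return sheets.cell(ref, row, col, report)


def _text_of(v: Optional[Value]) -> Optional[str]:
    if v is None:
        return None
    if v.text is not None:
        return v.text
    n = v.number
    return str(int(n)) if n is not None and n == int(n) else str(n)


def _number_of(v: Optional[Value]) -> Optional[float]:
    if v is None:
        return None
    if v.number is not None:
        return v.number
    try:
        return float(v.text)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return None


# ---------------------------------------------------------------------------
# Value-expression grammar

_NUM = r"[0-9]+(?:\.[0-9]+)?(?:[eE][+-]?[0-9]+)?"
_QUAL_RE = re.compile(rf"^\s*(<=|>=|<|>|~|=)\s*(-?{_NUM})\s*$")
_INTERVAL_RE = re.compile(rf"^\s*(-?{_NUM})\s*[-–]\s*(-?{_NUM})\s*$")


@dataclass(frozen=True)
class ParsedValue:
    """Outcome of parsing a textual value expression."""

    lo_qualifier: Optional[str] = None
    lo_value: Optional[float] = None
    up_qualifier: Optional[str] = None
    up_value: Optional[float] = None

    @property
    def matched(self) -> bool:
        return self.lo_value is not None or self.up_value is not None


def parse_value_expression(raw: str) -> ParsedValue:
    """Parse a qualified value or interval written as text.

    Recognizes the forms a curator meets in lab sheets: ``<3``, ``<=3``,
    ``>3``, ``>=3``, ``~3``, ``=3`` (upper-bound qualifiers fill the upper
    slot, the rest the lower), and ranges ``3-4`` / ``3–4`` which
    become the interval 3 <= x <= 4.  Anything else parses to nothing and
    the caller stores the raw text.  Total: never raises.
    """
    m = _QUAL_RE.match(raw)
    if m:
        q, num = m.group(1), float(m.group(2))
        if q in ("<", "<="):
            return ParsedValue(up_qualifier=q, up_value=num)
        return ParsedValue(lo_qualifier=q, lo_value=num)
    m = _INTERVAL_RE.match(raw)
    if m:
        lo, up = float(m.group(1)), float(m.group(2))
        return ParsedValue(lo_qualifier=">=", lo_value=lo, up_qualifier="<=", up_value=up)
    return ParsedValue()


# ---------------------------------------------------------------------------
# Effect assembly

def _build_effect(
    sheets: _Sheets,
    cfg: EffectConfig,
    cursor: Cursor,
    report: ParseReport,
) -> Optional[EffectRecord]:
    loc = cfg.locations
    get = lambda key: read_cell(sheets, loc[key], cursor, report) if key in loc else None

    effect = EffectRecord(endpoint=_text_of(get("ENDPOINT")) or "")
    effect.sample_id = _text_of(get("SAMPLE_ID"))
    effect.endpoint_type = _text_of(get("ENDPOINT_TYPE"))
    effect.unit = _text_of(get("UNIT"))
    effect.lo_qualifier = _text_of(get("LO_QUALIFIER"))
    effect.up_qualifier = _text_of(get("UP_QUALIFIER"))
    effect.err_qualifier = _text_of(get("ERR_QUALIFIER"))
    effect.lo_value = _number_of(get("LO_VALUE"))
    effect.up_value = _number_of(get("UP_VALUE"))
    effect.err_value = _number_of(get("ERR_VALUE"))
    effect.text_value = _text_of(get("TEXT_VALUE"))

    # VALUE is an alias for a plain measurement: numeric content lands in
    # lo_value with qualifier "="; qualified/interval text is parsed by the
    # expression grammar; anything else is kept verbatim as text.
    if "VALUE" in loc:
        v = get("VALUE")
        if v is not None and v.number is not None:
            effect.lo_value = v.number
            effect.lo_qualifier = effect.lo_qualifier or "="
        elif v is not None and v.text is not None:
            parsed = parse_value_expression(v.text)
            if parsed.matched:
                if parsed.lo_value is not None:
                    effect.lo_value = parsed.lo_value
                    effect.lo_qualifier = parsed.lo_qualifier
                if parsed.up_value is not None:
                    effect.up_value = parsed.up_value
                    effect.up_qualifier = parsed.up_qualifier
            else:
                effect.text_value = v.text

    for name, edl in cfg.conditions:
        v = read_cell(sheets, edl, cursor, report)
        if v is not None:
            effect.conditions[name] = v
    if effect.is_empty():
        return None
    return effect


def _eval_parameter(
    sheets: _Sheets,
    rule: ParameterRule,
    sheet_ref: Union[int, str, None],
    value_cell: tuple[int, int],
    sub_origin: tuple[int, int],
    block_origin: tuple[int, int],
    sub_block_index: int,
    report: ParseReport,
) -> Optional[Value]:
    if rule.source == "JSON_VALUE":
        lit = rule.json_value
        v = Value(number=float(lit)) if isinstance(lit, (int, float)) and not isinstance(
            lit, bool
        ) else Value(text=str(lit))
    elif rule.source == "SUB_BLOCK_INDEX":
        v = Value(number=float(sub_block_index))
    elif rule.source == "COLUMN_HEADER":
        v = sheets.cell(sheet_ref, rule.row_index, value_cell[1], report)  # type: ignore[arg-type]
    elif rule.source == "ROW_HEADER":
        v = sheets.cell(sheet_ref, value_cell[0], rule.column_index, report)  # type: ignore[arg-type]
    elif rule.source == "SUB_BLOCK_CELL":
        r, c = rule.offset  # type: ignore[misc]
        v = sheets.cell(sheet_ref, sub_origin[0] + r, sub_origin[1] + c, report)
    elif rule.source == "BLOCK_CELL":
        r, c = rule.offset  # type: ignore[misc]
        v = sheets.cell(sheet_ref, block_origin[0] + r, block_origin[1] + c, report)
    else:  # pragma: no cover - blocked by config validation
        raise ParseError(f"unknown parameter source {rule.source!r}")
    if v is not None and rule.unit is not None:
        v = Value(number=v.number, text=v.text, unit=rule.unit, qualifier=v.qualifier)
    return v


def expand_effect_block(
    sheets: Union[_Sheets, Workbook],
    block: EffectBlockConfig,
    cursor: Cursor,
    report: Optional[ParseReport] = None,
    strict: bool = False,
) -> list[EffectRecord]:
    """Expand one effect block into its individual measurements.

    One record is emitted per (sub-block x value group x value cell) whose
    cell is non-absent; each record carries every condition declared for its
    group plus the block-level endpoint/unit.  Geometry that exceeds the
    sheet's used range is reported as an error naming the block coordinates
    (the affected cells read as absent).
    """
    if isinstance(sheets, Workbook):
        sheets = _Sheets(sheets)
    report = report if report is not None else ParseReport()
    ref = block.sheet_ref if block.sheet_ref is not None else cursor.primary_sheet
    grid_rows, grid_cols = block.sub_block_grid
    sub_rows, sub_cols = block.sub_block_size
    origin = block.block_origin

    max_row, max_col = sheets.bounds(ref)
    end_row = origin[0] + grid_rows * sub_rows
    end_col = origin[1] + grid_cols * sub_cols
    if end_row > max_row or end_col > max_col:
        report.error(
            f"effect block at {_a1(*origin)} (origin row {origin[0]}, col {origin[1]}) "
            f"extends to row {end_row - 1}, col {end_col - 1}, beyond the used range "
            f"of sheet {ref!r} ({max_row} rows x {max_col} cols)",
            strict,
        )

    endpoint = _text_of(read_cell(sheets, block.endpoint, cursor, report)) if block.endpoint else ""
    endpoint_type = (
        _text_of(read_cell(sheets, block.endpoint_type, cursor, report))
        if block.endpoint_type
        else None
    )
    unit = _text_of(read_cell(sheets, block.unit, cursor, report)) if block.unit else None
    sample_id = (
        _text_of(read_cell(sheets, block.sample_id, cursor, report)) if block.sample_id else None
    )

    effects: list[EffectRecord] = []
    for gr in range(grid_rows):
        for gc in range(grid_cols):
            sub_origin = (origin[0] + gr * sub_rows, origin[1] + gc * sub_cols)
            sub_index = gr * grid_cols + gc + 1  # 1-based, row-major
            for group in block.value_groups:
                for off_r, off_c in group.value_cells:
                    cell = (sub_origin[0] + off_r, sub_origin[1] + off_c)
                    if cell[0] >= max_row or cell[1] >= max_col:
                        continue
                    v = sheets.cell(ref, cell[0], cell[1], report)
                    if v is None:
                        continue
                    effect = EffectRecord(
                        endpoint=endpoint or "",
                        endpoint_type=endpoint_type,
                        unit=unit,
                        sample_id=sample_id,
                    )
                    if v.number is not None:
                        effect.lo_value = v.number
                        effect.lo_qualifier = "="
                    else:
                        parsed = parse_value_expression(v.text or "")
                        if parsed.matched:
                            effect.lo_qualifier = parsed.lo_qualifier
                            effect.lo_value = parsed.lo_value
                            effect.up_qualifier = parsed.up_qualifier
                            effect.up_value = parsed.up_value
                        else:
                            effect.text_value = v.text
                    for rule in group.parameters:
                        pv = _eval_parameter(
                            sheets, rule, ref, cell, sub_origin, origin, sub_index, report
                        )
                        if pv is not None:
                            effect.conditions[rule.name] = pv
                    effects.append(effect)
    return effects


# ---------------------------------------------------------------------------
# Record assembly

def _build_protocol_application(
    sheets: _Sheets,
    pac: ProtocolApplicationConfig,
    cursor: Cursor,
    report: ParseReport,
    strict: bool,
) -> ProtocolApplication:
    cites = {
        key: _text_of(read_cell(sheets, edl, cursor, report))
        for key, edl in pac.citations.items()
    }
    pa = ProtocolApplication(
        citation_title=cites.get("CITATION_TITLE"),
        citation_year=cites.get("CITATION_YEAR"),
        citation_owner=cites.get("CITATION_OWNER"),
        interpretation_result=cites.get("INTERPRETATION_RESULT"),
        interpretation_criteria=cites.get("INTERPRETATION_CRITERIA"),
        investigation_uuid=cites.get("INVESTIGATION_UUID"),
        assay_uuid=cites.get("ASSAY_UUID"),
        reliability_flag=cites.get("RELIABILITY_FLAG"),
    )
    for edl in pac.protocol_guideline:
        text = _text_of(read_cell(sheets, edl, cursor, report))
        if text is not None:
            pa.protocol_guideline = [*pa.protocol_guideline, text]
    for name, edl in pac.parameters:
        v = read_cell(sheets, edl, cursor, report)
        if v is not None:
            pa.parameters[name] = v
    for eff_cfg in pac.effects:
        effect = _build_effect(sheets, eff_cfg, cursor, report)
        if effect is not None:
            pa.effects = [*pa.effects, effect]
    for block in pac.effect_blocks:
        pa.effects = [*pa.effects, *expand_effect_block(sheets, block, cursor, report, strict)]
    return pa


def _build_record(
    sheets: _Sheets,
    config: ParserConfig,
    cursor: Cursor,
    report: ParseReport,
    strict: bool,
    source_tag: str,
) -> SubstanceRecord:
    sr = config.substance_record
    get = lambda key: (
        _text_of(read_cell(sheets, sr[key], cursor, report)) if key in sr else None
    )
    record = SubstanceRecord(
        substance_name=get("SUBSTANCE_NAME") or "",
        public_name=get("PUBLIC_NAME"),
        owner_name=get("OWNER_NAME"),
        owner_uuid=get("OWNER_UUID"),
        substance_uuid=get("SUBSTANCE_UUID") or "",
        substance_type=get("SUBSTANCE_TYPE"),
    )
    seen: set[tuple[str, str]] = set()
    for system_edl, value_edl in config.external_identifiers:
        system = _text_of(read_cell(sheets, system_edl, cursor, report))
        value = _text_of(read_cell(sheets, value_edl, cursor, report))
        if system and value and (system, value) not in seen:
            seen.add((system, value))
            record.external_identifiers = [
                *record.external_identifiers,
                ExternalIdentifier(system=system, value=value),
            ]
    for comp_cfg in config.compositions:
        components: list[Component] = []
        for cc in comp_cfg.components:
            role_text = (
                _text_of(read_cell(sheets, cc.role, cursor, report)) if cc.role else None
            )
            role = _ROLE_ALIASES.get((role_text or "").strip().upper().replace("-", " "))
            if role is None:
                if role_text:
                    report.warning(
                        f"unrecognized component role {role_text!r}; recorded as OTHER"
                    )
                role = ComponentRole.OTHER
            comp = Component(
                role=role,
                name=_text_of(read_cell(sheets, cc.name, cursor, report)) if cc.name else None,
                structure=(
                    _text_of(read_cell(sheets, cc.structure, cursor, report))
                    if cc.structure
                    else None
                ),
                linkages=[Linkage(target=t, relation=rel) for t, rel in cc.linkages],
            )
            for pname, edl in cc.properties:
                v = read_cell(sheets, edl, cursor, report)
                if v is not None:
                    comp.properties[pname] = v
            components.append(comp)
        if components:
            record.compositions = [
                *record.compositions,
                Composition(composition_uuid="", components=components),
            ]
    for pac in config.protocol_applications:
        record.protocol_applications = [
            *record.protocol_applications,
            _build_protocol_application(sheets, pac, cursor, report, strict),
        ]
    return assign_uuids(record, source_tag)


def parse_workbook(
    workbook: Union[str, Workbook],
    config: ParserConfig,
    strict: bool = False,
    report: Optional[ParseReport] = None,
    na_markers: frozenset[str] = NA_MARKERS,
    source_tag: str = "XLSX",
) -> Iterator[SubstanceRecord]:
    """Iterate the substance records a workbook yields under a configuration.

    Under ``ROW_SINGLE`` each non-blank data row of the primary sheet from
    ``ROW_START`` produces one record; iteration stops at ``ROW_END`` or
    after ``STOP_ON_BLANK_ROWS`` consecutive fully blank rows.  Per-record
    problems are collected in the report (and raise immediately under
    ``strict``).
    """
    if isinstance(workbook, str):
        try:
            wb = load_workbook(workbook, data_only=True)
        except Exception as exc:
            raise ParseError(f"cannot read workbook {workbook!r}: {exc}") from exc
    else:
        wb = workbook
    sheets = _Sheets(wb, na_markers)
    report = report if report is not None else ParseReport()
    da: DataAccessConfig = config.data_access
    primary = da.sheet_ref
    sheets.sheet(primary)  # fail fast on a bad primary-sheet reference

    if da.iteration is not IterationMode.ROW_SINGLE:
        # single-record modes: the whole workbook is one substance
        cursor = Cursor(current_row=da.row_start, primary_sheet=primary)
        record = _build_record(sheets, config, cursor, report, strict, source_tag)
        report.records_parsed += 1
        yield record
        return

    max_row, _ = sheets.bounds(primary)
    row = da.row_start
    blank_run = 0
    while True:
        if da.row_end is not None and row > da.row_end:
            break
        if row >= max_row and da.row_end is None:
            break
        if sheets.row_blank(primary, row):
            blank_run += 1
            if da.row_end is None and blank_run >= da.stop_on_blank_rows:
                break
            row += 1
            continue
        blank_run = 0
        cursor = Cursor(current_row=row, primary_sheet=primary)
        try:
            record = _build_record(sheets, config, cursor, report, strict, source_tag)
        except ParseError:
            raise
        except Exception as exc:  # collect-and-continue policy
            report.error(f"row {row} (sheet {primary!r}): {exc}", strict)
            row += 1
            continue
        report.records_parsed += 1
        yield record
        row += 1
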