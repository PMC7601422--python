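"""The JSON mapping configuration dialect.

A parser configuration binds one spreadsheet template layout to the substance
data model.  It is a JSON document with three recognized top-level sections:

``DATA_ACCESS``
    how substance records are iterated (iteration mode, primary sheet, row
    range, blank-row termination) and the defaults every data location
    inherits;
``SUBSTANCE_RECORD``
    data locations for the substance-level fields (name, owner, type,
    external identifiers, composition);
``PROTOCOL_APPLICATIONS``
    an array of protocol-application mappings, each with citation/guideline
    locations, a dynamic parameter list, per-measurement ``EFFECTS`` entries
    and hierarchical ``EFFECT_BLOCKS``.

Most attributes are *Excel Data Locations* (EDLs): small objects saying
where and how one datum is read.  The reading strategy is the iteration
mode: per-row substance iteration (``ROW_SINGLE``, needs only a column),
fixed coordinates (``ABSOLUTE_LOCATION``, needs row and column), or a
literal carried in the configuration itself (``JSON_VALUE``).  A short
syntax omits any attribute whose value is defaulted in ``DATA_ACCESS``;
:func:`resolve_edl` performs that expansion.

Row and column indices are **0-based**; column letters ("A", "B", ...) are
accepted and converted.  Sheets are addressed by 0-based index or by exact
name; the name wins when both are given.

Validation collects *all* problems in one pass and reports each with the
JSON path of the offending attribute — configurations are written by hand,
so a complete defect list per file matters more than failing fast.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from typing import Any, Optional, Union

from openpyxl.utils import column_index_from_string

logger = logging.getLogger("fairsheet")

__all__ = [
    "IterationMode",
    "ExcelDataLocation",
    "DataAccessConfig",
    "ParserConfig",
    "ProtocolApplicationConfig",
    "EffectConfig",
    "EffectBlockConfig",
    "ValueGroupConfig",
    "ParameterRule",
    "ConfigIssue",
    "ConfigValidationError",
    "load_config",
    "loads_config",
    "resolve_edl",
    "emit_schema",
    "validate_instance",
]


# ---------------------------------------------------------------------------
# Iteration-mode registry

class IterationMode(str, enum.Enum):
    """Strategy for locating one datum in the workbook."""

    ROW_SINGLE = "ROW_SINGLE"
    ABSOLUTE_LOCATION = "ABSOLUTE_LOCATION"
    JSON_VALUE = "JSON_VALUE"


#: Extensible registry so further modes can be added without touching the
#: engine contract; only the three first-class modes are shipped.
ITERATION_MODES: dict[str, IterationMode] = {m.value: m for m in IterationMode}


# ---------------------------------------------------------------------------
# Error reporting

@dataclass(frozen=True)
class ConfigIssue:
    path: str
    message: str
    severity: str = "error"  # "error" | "warning"

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.path}: {self.message}"


class ConfigValidationError(ValueError):
    """Raised after a full validation pass when at least one error was found."""

    def __init__(self, issues: list[ConfigIssue]):
        self.issues = [i for i in issues if i.severity == "error"]
        self.warnings = [i for i in issues if i.severity == "warning"]
        lines = "\n".join(f"  {i.path}: {i.message}" for i in self.issues)
        super().__init__(f"{len(self.issues)} configuration problem(s):\n{lines}")


class _Issues:
    """Accumulator: the whole document is validated before failing."""

    def __init__(self) -> None:
        self.items: list[ConfigIssue] = []

    def error(self, path: str, message: str) -> None:
        self.items.append(ConfigIssue(path, message, "error"))

    def warning(self, path: str, message: str) -> None:
        self.items.append(ConfigIssue(path, message, "warning"))
        logger.warning("%s: %s", path, message)

    @property
    def errors(self) -> list[ConfigIssue]:
        return [i for i in self.items if i.severity == "error"]


# ---------------------------------------------------------------------------
# Configuration dataclasses

@dataclass
class ExcelDataLocation:
    """Coordinates for one datum, under an iteration mode."""

    iteration: Optional[IterationMode] = None
    sheet_index: Optional[int] = None
    sheet_name: Optional[str] = None
    row_index: Optional[int] = None
    column_index: Optional[int] = None
    json_value: Any = None
    source_combination: Optional[bool] = None  # reserved

    @property
    def sheet_ref(self) -> Union[int, str, None]:
        # exact name wins over index when both are present
        return self.sheet_name if self.sheet_name is not None else self.sheet_index


@dataclass
class DataAccessConfig:
    iteration: IterationMode = IterationMode.ROW_SINGLE
    sheet_index: int = 0
    sheet_name: Optional[str] = None
    row_start: int = 1
    row_end: Optional[int] = None
    #: consecutive fully-blank primary-sheet rows that end the iteration
    stop_on_blank_rows: int = 2

    @property
    def sheet_ref(self) -> Union[int, str]:
        return self.sheet_name if self.sheet_name is not None else self.sheet_index


@dataclass
class ParameterRule:
    """How one experimental condition of a value group is obtained.

    ``COLUMN_HEADER`` reads the cell in the value's column at an absolute
    header row; ``ROW_HEADER`` the cell in the value's row at an absolute
    column; ``SUB_BLOCK_CELL`` a fixed offset within the current sub-block;
    ``BLOCK_CELL`` a fixed offset from the block origin; ``SUB_BLOCK_INDEX``
    the 1-based index of the current sub-block (row-major); ``JSON_VALUE`` a
    literal.
    """

    name: str
    source: str  # COLUMN_HEADER | ROW_HEADER | SUB_BLOCK_CELL | BLOCK_CELL | SUB_BLOCK_INDEX | JSON_VALUE
    row_index: Optional[int] = None
    column_index: Optional[int] = None
    offset: Optional[tuple[int, int]] = None
    json_value: Any = None
    unit: Optional[str] = None


@dataclass
class ValueGroupConfig:
    """A set of value cells inside a sub-block sharing condition rules."""

    value_cells: list[tuple[int, int]]  # offsets within the sub-block
    parameters: list[ParameterRule] = field(default_factory=list)


@dataclass
class EffectBlockConfig:
    """A rectangular measurement region: grid of sub-blocks, each holding
    value groups whose cells map one-to-one onto effect records."""

    block_origin: tuple[int, int] = (0, 0)
    sub_block_grid: tuple[int, int] = (1, 1)  # rows_of_sub_blocks, cols_of_sub_blocks
    sub_block_size: tuple[int, int] = (1, 1)  # rows, cols
    value_groups: list[ValueGroupConfig] = field(default_factory=list)
    endpoint: Optional[ExcelDataLocation] = None
    endpoint_type: Optional[ExcelDataLocation] = None
    unit: Optional[ExcelDataLocation] = None
    sample_id: Optional[ExcelDataLocation] = None
    sheet_index: Optional[int] = None
    sheet_name: Optional[str] = None

    @property
    def sheet_ref(self) -> Union[int, str, None]:
        return self.sheet_name if self.sheet_name is not None else self.sheet_index


@dataclass
class EffectConfig:
    """Data locations for the fields of one effect (measurement) record."""

    endpoint: ExcelDataLocation
    locations: dict[str, ExcelDataLocation] = field(default_factory=dict)
    conditions: list[tuple[str, ExcelDataLocation]] = field(default_factory=list)


@dataclass
class CompositionComponentConfig:
    role: Optional[ExcelDataLocation] = None
    name: Optional[ExcelDataLocation] = None
    structure: Optional[ExcelDataLocation] = None
    properties: list[tuple[str, ExcelDataLocation]] = field(default_factory=list)
    linkages: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class CompositionConfig:
    components: list[CompositionComponentConfig] = field(default_factory=list)


@dataclass
class ProtocolApplicationConfig:
    citations: dict[str, ExcelDataLocation] = field(default_factory=dict)
    protocol_guideline: list[ExcelDataLocation] = field(default_factory=list)
    parameters: list[tuple[str, ExcelDataLocation]] = field(default_factory=list)
    effects: list[EffectConfig] = field(default_factory=list)
    effect_blocks: list[EffectBlockConfig] = field(default_factory=list)


@dataclass
class ParserConfig:
    data_access: DataAccessConfig
    substance_record: dict[str, ExcelDataLocation] = field(default_factory=dict)
    external_identifiers: list[tuple[ExcelDataLocation, ExcelDataLocation]] = field(
        default_factory=list
    )
    compositions: list[CompositionConfig] = field(default_factory=list)
    protocol_applications: list[ProtocolApplicationConfig] = field(default_factory=list)
    warnings: list[ConfigIssue] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Keyword vocabulary

_SUBSTANCE_ATTRS = (
    "SUBSTANCE_NAME",
    "PUBLIC_NAME",
    "OWNER_NAME",
    "OWNER_UUID",
    "SUBSTANCE_UUID",
    "SUBSTANCE_TYPE",
)
_PA_CITATION_ATTRS = (
    "CITATION_TITLE",
    "CITATION_YEAR",
    "CITATION_OWNER",
    "INTERPRETATION_RESULT",
    "INTERPRETATION_CRITERIA",
    "INVESTIGATION_UUID",
    "ASSAY_UUID",
    "RELIABILITY_FLAG",
)
_EFFECT_ATTRS = (
    "SAMPLE_ID",
    "ENDPOINT",
    "ENDPOINT_TYPE",
    "LO_VALUE",
    "UP_VALUE",
    "ERR_VALUE",
    "TEXT_VALUE",
    "VALUE",
    "LO_QUALIFIER",
    "UP_QUALIFIER",
    "ERR_QUALIFIER",
    "UNIT",
)
_EDL_KEYS = (
    "ITERATION",
    "SHEET_INDEX",
    "SHEET_NAME",
    "ROW_INDEX",
    "COLUMN_INDEX",
    "JSON_VALUE",
    "SOURCE_COMBINATION",
)
_PARAM_SOURCES = (
    "COLUMN_HEADER",
    "ROW_HEADER",
    "SUB_BLOCK_CELL",
    "BLOCK_CELL",
    "SUB_BLOCK_INDEX",
    "JSON_VALUE",
)


# ---------------------------------------------------------------------------
# Low-level field readers (each records issues instead of raising)

def _as_column(value: Any, path: str, issues: _Issues) -> Optional[int]:
    """Accept a 0-based integer or a column letter; return a 0-based index."""
    if isinstance(value, bool):
        issues.error(path, f"COLUMN_INDEX must be an integer or letter, found boolean {value!r}")
        return None
    if isinstance(value, int):
        if value < 0:
            issues.error(path, f"COLUMN_INDEX must be >= 0, found {value}")
            return None
        return value
    if isinstance(value, str) and value.strip().isalpha():
        return column_index_from_string(value.strip().upper()) - 1
    issues.error(
        path,
        f"COLUMN_INDEX must be an integer or letter, found {type(value).__name__} {value!r}",
    )
    return None


def _as_int(value: Any, key: str, path: str, issues: _Issues, minimum: int = 0) -> Optional[int]:
    if isinstance(value, bool) or not isinstance(value, int):
        issues.error(path, f"{key} must be an integer, found {type(value).__name__} {value!r}")
        return None
    if value < minimum:
        issues.error(path, f"{key} must be >= {minimum}, found {value}")
        return None
    return value


def _as_str(value: Any, key: str, path: str, issues: _Issues) -> Optional[str]:
    if not isinstance(value, str):
        issues.error(path, f"{key} must be a string, found {type(value).__name__} {value!r}")
        return None
    return value


def _as_pair(value: Any, key: str, path: str, issues: _Issues) -> Optional[tuple[int, int]]:
    if (
        isinstance(value, (list, tuple))
        and len(value) == 2
        and all(isinstance(v, int) and not isinstance(v, bool) for v in value)
    ):
        return (value[0], value[1])
    issues.error(path, f"{key} must be a pair of integers [row, column], found {value!r}")
    return None


def _expect_object(value: Any, path: str, issues: _Issues) -> Optional[dict]:
    if isinstance(value, dict):
        return value
    issues.error(path, f"expected a JSON object, found {type(value).__name__}")
    return None


def _expect_array(value: Any, path: str, issues: _Issues) -> Optional[list]:
    if isinstance(value, list):
        return value
    issues.error(path, f"expected a JSON array, found {type(value).__name__}")
    return None


# ---------------------------------------------------------------------------
# EDL parsing and short-syntax resolution

def _parse_edl(raw: Any, path: str, issues: _Issues) -> Optional[ExcelDataLocation]:
    """Parse one raw EDL object; no defaulting, no mode checks yet."""
    obj = _expect_object(raw, path, issues)
    if obj is None:
        return None
    edl = ExcelDataLocation()
    for key, value in obj.items():
        kpath = f"{path}.{key}"
        if key == "ITERATION":
            mode = _as_str(value, key, kpath, issues)
            if mode is not None:
                if mode in ITERATION_MODES:
                    edl.iteration = ITERATION_MODES[mode]
                else:
                    issues.error(
                        kpath,
                        f"unknown ITERATION {mode!r}; expected one of "
                        + ", ".join(sorted(ITERATION_MODES)),
                    )
        elif key == "SHEET_INDEX":
            edl.sheet_index = _as_int(value, key, kpath, issues)
        elif key == "SHEET_NAME":
            edl.sheet_name = _as_str(value, key, kpath, issues)
        elif key == "ROW_INDEX":
            edl.row_index = _as_int(value, key, kpath, issues)
        elif key == "COLUMN_INDEX":
            edl.column_index = _as_column(value, kpath, issues)
        elif key == "JSON_VALUE":
            edl.json_value = value
        elif key == "SOURCE_COMBINATION":
            edl.source_combination = bool(value)
        else:
            issues.warning(kpath, f"unknown data-location key {key!r} ignored")
    # a bare JSON_VALUE implies the JSON_VALUE mode
    if edl.iteration is None and edl.json_value is not None:
        edl.iteration = IterationMode.JSON_VALUE
    return edl


def _check_mode(edl: ExcelDataLocation, path: str, issues: _Issues) -> None:
    """Enforce per-mode requirements after defaulting."""
    if edl.iteration is None:
        issues.error(path, "ITERATION required (not defaulted by DATA_ACCESS)")
        return
    if edl.iteration is IterationMode.ROW_SINGLE:
        if edl.column_index is None:
            issues.error(path, "COLUMN_INDEX required in iteration mode ROW_SINGLE")
        if edl.row_index is not None:
            issues.error(
                path,
                "ROW_INDEX not allowed in iteration mode ROW_SINGLE "
                "(the row is obtained dynamically)",
            )
    elif edl.iteration is IterationMode.ABSOLUTE_LOCATION:
        if edl.column_index is None:
            issues.error(path, "COLUMN_INDEX required in iteration mode ABSOLUTE_LOCATION")
        if edl.row_index is None:
            issues.error(path, "ROW_INDEX required in iteration mode ABSOLUTE_LOCATION")
    elif edl.iteration is IterationMode.JSON_VALUE:
        if edl.json_value is None:
            issues.error(path, "JSON_VALUE required in iteration mode JSON_VALUE")
        for attr, key in (
            ("sheet_index", "SHEET_INDEX"),
            ("sheet_name", "SHEET_NAME"),
            ("row_index", "ROW_INDEX"),
            ("column_index", "COLUMN_INDEX"),
        ):
            if getattr(edl, attr) is not None:
                issues.error(path, f"{key} not allowed in iteration mode JSON_VALUE")


def resolve_edl(
    raw_edl: ExcelDataLocation,
    defaults: DataAccessConfig,
    path: str = "EDL",
    issues: Optional[_Issues] = None,
) -> ExcelDataLocation:
    """Expand a short-syntax data location against the DATA_ACCESS defaults.

    Every omitted defaultable attribute (iteration mode, sheet) is filled
    from ``defaults``; attributes that were given are never overridden, so
    resolution is idempotent.  A location carrying a ``JSON_VALUE`` literal
    is a self-contained mode and ignores sheet defaults.  Mode requirements
    are re-checked after filling; with no external accumulator, violations
    raise :class:`ConfigValidationError`.
    """
    local = issues if issues is not None else _Issues()
    edl = ExcelDataLocation(**vars(raw_edl))
    if edl.iteration is None:
        edl.iteration = (
            IterationMode.JSON_VALUE if edl.json_value is not None else defaults.iteration
        )
    if edl.iteration is not IterationMode.JSON_VALUE:
        if edl.sheet_index is None and edl.sheet_name is None:
            edl.sheet_index = defaults.sheet_index
            edl.sheet_name = defaults.sheet_name
    _check_mode(edl, path, local)
    if issues is None and local.errors:
        raise ConfigValidationError(local.items)
    return edl


# ---------------------------------------------------------------------------
# Section parsers

def _parse_data_access(raw: Any, issues: _Issues) -> DataAccessConfig:
    da = DataAccessConfig()
    obj = _expect_object(raw, "DATA_ACCESS", issues)
    if obj is None:
        return da
    if "ITERATION" not in obj:
        issues.error("DATA_ACCESS", "missing required key ITERATION")
    for key, value in obj.items():
        path = f"DATA_ACCESS.{key}"
        if key == "ITERATION":
            mode = _as_str(value, key, path, issues)
            if mode is not None:
                if mode in ITERATION_MODES:
                    da.iteration = ITERATION_MODES[mode]
                else:
                    issues.error(
                        path,
                        f"unknown ITERATION {mode!r}; expected one of "
                        + ", ".join(sorted(ITERATION_MODES)),
                    )
        elif key == "SHEET_INDEX":
            da.sheet_index = _as_int(value, key, path, issues) or 0
        elif key == "SHEET_NAME":
            da.sheet_name = _as_str(value, key, path, issues)
        elif key == "ROW_START":
            got = _as_int(value, key, path, issues)
            if got is not None:
                da.row_start = got
        elif key == "ROW_END":
            da.row_end = _as_int(value, key, path, issues)
        elif key == "STOP_ON_BLANK_ROWS":
            got = _as_int(value, key, path, issues, minimum=1)
            if got is not None:
                da.stop_on_blank_rows = got
        else:
            issues.warning(path, f"unknown DATA_ACCESS key {key!r} ignored")
    if da.row_end is not None and da.row_end < da.row_start:
        issues.error("DATA_ACCESS.ROW_END", f"ROW_END {da.row_end} < ROW_START {da.row_start}")
    return da


def _resolve(
    raw: Any, defaults: DataAccessConfig, path: str, issues: _Issues
) -> Optional[ExcelDataLocation]:
    edl = _parse_edl(raw, path, issues)
    if edl is None:
        return None
    return resolve_edl(edl, defaults, path, issues)


def _parse_substance_record(
    raw: Any, defaults: DataAccessConfig, cfg: ParserConfig, issues: _Issues
) -> None:
    obj = _expect_object(raw, "SUBSTANCE_RECORD", issues)
    if obj is None:
        return
    for key, value in obj.items():
        path = f"SUBSTANCE_RECORD.{key}"
        if key in _SUBSTANCE_ATTRS:
            edl = _resolve(value, defaults, path, issues)
            if edl is not None:
                cfg.substance_record[key] = edl
        elif key == "EXTERNAL_IDENTIFIERS":
            arr = _expect_array(value, path, issues)
            if arr is None:
                continue
            for i, item in enumerate(arr):
                ipath = f"{path}[{i}]"
                obj_i = _expect_object(item, ipath, issues)
                if obj_i is None:
                    continue
                missing = [k for k in ("SYSTEM", "VALUE") if k not in obj_i]
                if missing:
                    issues.error(ipath, f"missing required key(s) {', '.join(missing)}")
                    continue
                system = _resolve(obj_i["SYSTEM"], defaults, f"{ipath}.SYSTEM", issues)
                val = _resolve(obj_i["VALUE"], defaults, f"{ipath}.VALUE", issues)
                if system is not None and val is not None:
                    cfg.external_identifiers.append((system, val))
                for extra in set(obj_i) - {"SYSTEM", "VALUE"}:
                    issues.warning(f"{ipath}.{extra}", f"unknown key {extra!r} ignored")
        elif key == "COMPOSITION":
            arr = _expect_array(value, path, issues)
            if arr is None:
                continue
            for i, item in enumerate(arr):
                comp = _parse_composition(item, defaults, f"{path}[{i}]", issues)
                if comp is not None:
                    cfg.compositions.append(comp)
        else:
            issues.warning(path, f"unknown SUBSTANCE_RECORD key {key!r} ignored")


def _parse_composition(
    raw: Any, defaults: DataAccessConfig, path: str, issues: _Issues
) -> Optional[CompositionConfig]:
    obj = _expect_object(raw, path, issues)
    if obj is None:
        return None
    comp = CompositionConfig()
    arr = _expect_array(obj.get("COMPONENTS", []), f"{path}.COMPONENTS", issues)
    if arr is None:
        return comp
    if not arr:
        issues.error(f"{path}.COMPONENTS", "composition requires at least one component")
    for i, item in enumerate(arr):
        ipath = f"{path}.COMPONENTS[{i}]"
        cobj = _expect_object(item, ipath, issues)
        if cobj is None:
            continue
        cc = CompositionComponentConfig()
        for key, value in cobj.items():
            kpath = f"{ipath}.{key}"
            if key in ("ROLE", "NAME", "STRUCTURE"):
                edl = _resolve(value, defaults, kpath, issues)
                setattr(cc, key.lower(), edl)
            elif key == "PROPERTIES":
                parr = _expect_array(value, kpath, issues) or []
                for j, prop in enumerate(parr):
                    ppath = f"{kpath}[{j}]"
                    pobj = _expect_object(prop, ppath, issues)
                    if pobj is None or "NAME" not in pobj:
                        issues.error(ppath, "property requires a NAME")
                        continue
                    name = _as_str(pobj["NAME"], "NAME", f"{ppath}.NAME", issues)
                    edl = _resolve(
                        {k: v for k, v in pobj.items() if k != "NAME"},
                        defaults,
                        ppath,
                        issues,
                    )
                    if name is not None and edl is not None:
                        cc.properties.append((name, edl))
            elif key == "LINKAGES":
                larr = _expect_array(value, kpath, issues) or []
                for j, link in enumerate(larr):
                    lpath = f"{kpath}[{j}]"
                    lobj = _expect_object(link, lpath, issues)
                    if lobj is None:
                        continue
                    target = _as_int(lobj.get("TARGET"), "TARGET", f"{lpath}.TARGET", issues)
                    relation = _as_str(
                        lobj.get("RELATION"), "RELATION", f"{lpath}.RELATION", issues
                    )
                    if target is not None and relation is not None:
                        cc.linkages.append((target, relation))
            else:
                issues.warning(kpath, f"unknown component key {key!r} ignored")
        if cc.role is None:
            issues.error(ipath, "missing required key ROLE")
        comp.components.append(cc)
    # linkage targets must refer to components of this composition
    for i, cc in enumerate(comp.components):
        for target, _rel in cc.linkages:
            if not (0 <= target < len(comp.components)):
                issues.error(
                    f"{path}.COMPONENTS[{i}].LINKAGES",
                    f"linkage TARGET {target} outside composition of "
                    f"{len(comp.components)} components",
                )
    for extra in set(obj) - {"COMPONENTS"}:
        issues.warning(f"{path}.{extra}", f"unknown key {extra!r} ignored")
    return comp


def _parse_named_edl_list(
    raw: Any, defaults: DataAccessConfig, path: str, issues: _Issues
) -> list[tuple[str, ExcelDataLocation]]:
    out: list[tuple[str, ExcelDataLocation]] = []
    arr = _expect_array(raw, path, issues)
    if arr is None:
        return out
    for i, item in enumerate(arr):
        ipath = f"{path}[{i}]"
        obj = _expect_object(item, ipath, issues)
        if obj is None:
            continue
        if "NAME" not in obj:
            issues.error(ipath, "missing required key NAME")
            continue
        name = _as_str(obj["NAME"], "NAME", f"{ipath}.NAME", issues)
        edl = _resolve({k: v for k, v in obj.items() if k != "NAME"}, defaults, ipath, issues)
        if name is not None and edl is not None:
            out.append((name, edl))
    return out


def _parse_effect(
    raw: Any, defaults: DataAccessConfig, path: str, issues: _Issues
) -> Optional[EffectConfig]:
    obj = _expect_object(raw, path, issues)
    if obj is None:
        return None
    locations: dict[str, ExcelDataLocation] = {}
    conditions: list[tuple[str, ExcelDataLocation]] = []
    for key, value in obj.items():
        kpath = f"{path}.{key}"
        if key in _EFFECT_ATTRS:
            edl = _resolve(value, defaults, kpath, issues)
            if edl is not None:
                locations[key] = edl
        elif key == "CONDITIONS":
            conditions = _parse_named_edl_list(value, defaults, kpath, issues)
        else:
            issues.warning(kpath, f"unknown EFFECTS key {key!r} ignored")
    if "ENDPOINT" not in obj:
        issues.error(path, "missing required key ENDPOINT")
        return None
    endpoint = locations.get("ENDPOINT")
    if endpoint is None:
        return None
    return EffectConfig(endpoint=endpoint, locations=locations, conditions=conditions)


def _parse_parameter_rule(raw: Any, path: str, issues: _Issues) -> Optional[ParameterRule]:
    obj = _expect_object(raw, path, issues)
    if obj is None:
        return None
    missing = [k for k in ("NAME", "SOURCE") if k not in obj]
    if missing:
        issues.error(path, f"missing required key(s) {', '.join(missing)}")
        return None
    name = _as_str(obj["NAME"], "NAME", f"{path}.NAME", issues)
    source = _as_str(obj["SOURCE"], "SOURCE", f"{path}.SOURCE", issues)
    if name is None or source is None:
        return None
    if source not in _PARAM_SOURCES:
        issues.error(
            f"{path}.SOURCE",
            f"unknown SOURCE {source!r}; expected one of " + ", ".join(_PARAM_SOURCES),
        )
        return None
    rule = ParameterRule(name=name, source=source)
    if source == "COLUMN_HEADER":
        if "ROW_INDEX" not in obj:
            issues.error(path, "ROW_INDEX required for SOURCE COLUMN_HEADER")
            return None
        rule.row_index = _as_int(obj["ROW_INDEX"], "ROW_INDEX", f"{path}.ROW_INDEX", issues)
    elif source == "ROW_HEADER":
        if "COLUMN_INDEX" not in obj:
            issues.error(path, "COLUMN_INDEX required for SOURCE ROW_HEADER")
            return None
        rule.column_index = _as_column(obj["COLUMN_INDEX"], f"{path}.COLUMN_INDEX", issues)
    elif source in ("SUB_BLOCK_CELL", "BLOCK_CELL"):
        if "OFFSET" not in obj:
            issues.error(path, f"OFFSET required for SOURCE {source}")
            return None
        rule.offset = _as_pair(obj["OFFSET"], "OFFSET", f"{path}.OFFSET", issues)
    elif source == "JSON_VALUE":
        if "JSON_VALUE" not in obj:
            issues.error(path, "JSON_VALUE required for SOURCE JSON_VALUE")
            return None
        rule.json_value = obj["JSON_VALUE"]
    if "UNIT" in obj:
        rule.unit = _as_str(obj["UNIT"], "UNIT", f"{path}.UNIT", issues)
    known = {"NAME", "SOURCE", "ROW_INDEX", "COLUMN_INDEX", "OFFSET", "JSON_VALUE", "UNIT"}
    for extra in set(obj) - known:
        issues.warning(f"{path}.{extra}", f"unknown parameter key {extra!r} ignored")
    return rule


def _parse_effect_block(
    raw: Any, defaults: DataAccessConfig, path: str, issues: _Issues
) -> Optional[EffectBlockConfig]:
    obj = _expect_object(raw, path, issues)
    if obj is None:
        return None
    block = EffectBlockConfig()
    missing = [k for k in ("BLOCK_ORIGIN", "VALUE_GROUPS") if k not in obj]
    if missing:
        issues.error(path, f"missing required key(s) {', '.join(missing)}")
    for key, value in obj.items():
        kpath = f"{path}.{key}"
        if key == "BLOCK_ORIGIN":
            got = _as_pair(value, key, kpath, issues)
            if got is not None:
                block.block_origin = got
        elif key == "SUB_BLOCK_GRID":
            got = _as_pair(value, key, kpath, issues)
            if got is not None:
                if got[0] < 1 or got[1] < 1:
                    issues.error(kpath, f"SUB_BLOCK_GRID dimensions must be >= 1, found {got}")
                else:
                    block.sub_block_grid = got
        elif key == "SUB_BLOCK_SIZE":
            got = _as_pair(value, key, kpath, issues)
            if got is not None:
                if got[0] < 1 or got[1] < 1:
                    issues.error(kpath, f"SUB_BLOCK_SIZE must be at least 1x1, found {got}")
                else:
                    block.sub_block_size = got
        elif key in ("ENDPOINT", "ENDPOINT_TYPE", "UNIT", "SAMPLE_ID"):
            edl = _resolve(value, defaults, kpath, issues)
            setattr(block, key.lower(), edl)
        elif key == "SHEET_INDEX":
            block.sheet_index = _as_int(value, key, kpath, issues)
        elif key == "SHEET_NAME":
            block.sheet_name = _as_str(value, key, kpath, issues)
        elif key == "VALUE_GROUPS":
            arr = _expect_array(value, kpath, issues) or []
            for i, item in enumerate(arr):
                group = _parse_value_group(item, f"{kpath}[{i}]", issues)
                if group is not None:
                    block.value_groups.append(group)
        else:
            issues.warning(kpath, f"unknown EFFECT_BLOCKS key {key!r} ignored")
    if block.sheet_ref is None:
        block.sheet_index = defaults.sheet_index
        block.sheet_name = defaults.sheet_name
    # every value offset must lie inside the sub-block rectangle
    rows, cols = block.sub_block_size
    for i, group in enumerate(block.value_groups):
        for r, c in group.value_cells:
            if not (0 <= r < rows and 0 <= c < cols):
                issues.error(
                    f"{path}.VALUE_GROUPS[{i}]",
                    f"value cell offset ({r}, {c}) outside sub-block of size "
                    f"{rows}x{cols}",
                )
    if "BLOCK_ORIGIN" in obj and "VALUE_GROUPS" in obj and not block.value_groups:
        issues.error(f"{path}.VALUE_GROUPS", "at least one value group required")
    return block if not missing else None


def _parse_value_group(raw: Any, path: str, issues: _Issues) -> Optional[ValueGroupConfig]:
    obj = _expect_object(raw, path, issues)
    if obj is None:
        return None
    if "VALUE_CELLS" not in obj:
        issues.error(path, "missing required key VALUE_CELLS")
        return None
    cells_raw = _expect_array(obj["VALUE_CELLS"], f"{path}.VALUE_CELLS", issues)
    if cells_raw is None:
        return None
    cells: list[tuple[int, int]] = []
    for i, cell in enumerate(cells_raw):
        got = _as_pair(cell, "VALUE_CELLS entry", f"{path}.VALUE_CELLS[{i}]", issues)
        if got is not None:
            cells.append(got)
    params: list[ParameterRule] = []
    if "PARAMETERS" in obj:
        arr = _expect_array(obj["PARAMETERS"], f"{path}.PARAMETERS", issues) or []
        for i, item in enumerate(arr):
            rule = _parse_parameter_rule(item, f"{path}.PARAMETERS[{i}]", issues)
            if rule is not None:
                params.append(rule)
    for extra in set(obj) - {"VALUE_CELLS", "PARAMETERS"}:
        issues.warning(f"{path}.{extra}", f"unknown value-group key {extra!r} ignored")
    if not cells:
        issues.error(f"{path}.VALUE_CELLS", "at least one value cell required")
        return None
    return ValueGroupConfig(value_cells=cells, parameters=params)


def _parse_protocol_application(
    raw: Any, defaults: DataAccessConfig, path: str, issues: _Issues
) -> Optional[ProtocolApplicationConfig]:
    obj = _expect_object(raw, path, issues)
    if obj is None:
        return None
    pac = ProtocolApplicationConfig()
    for key, value in obj.items():
        kpath = f"{path}.{key}"
        if key in _PA_CITATION_ATTRS:
            edl = _resolve(value, defaults, kpath, issues)
            if edl is not None:
                pac.citations[key] = edl
        elif key == "PROTOCOL_GUIDELINE":
            items = value if isinstance(value, list) else [value]
            for i, item in enumerate(items):
                edl = _resolve(item, defaults, f"{kpath}[{i}]", issues)
                if edl is not None:
                    pac.protocol_guideline.append(edl)
        elif key == "PARAMETERS":
            pac.parameters = _parse_named_edl_list(value, defaults, kpath, issues)
        elif key == "EFFECTS":
            arr = _expect_array(value, kpath, issues) or []
            for i, item in enumerate(arr):
                eff = _parse_effect(item, defaults, f"{kpath}[{i}]", issues)
                if eff is not None:
                    pac.effects.append(eff)
        elif key == "EFFECT_BLOCKS":
            arr = _expect_array(value, kpath, issues) or []
            for i, item in enumerate(arr):
                block = _parse_effect_block(item, defaults, f"{kpath}[{i}]", issues)
                if block is not None:
                    pac.effect_blocks.append(block)
        else:
            issues.warning(kpath, f"unknown PROTOCOL_APPLICATIONS key {key!r} ignored")
    return pac


# ---------------------------------------------------------------------------
# Entry points

def loads_config(config_document: str) -> ParserConfig:
    """Parse and validate a JSON configuration document (text form).

    All validation problems are collected in a single pass; if any are
    errors, :class:`ConfigValidationError` is raised listing every one with
    its JSON path.  Unknown keys are warnings, never fatal.
    """
    try:
        doc = json.loads(config_document)
    except json.JSONDecodeError as exc:
        raise ConfigValidationError(
            [ConfigIssue("$", f"not valid JSON: {exc}")]
        ) from exc
    return _build_config(doc)


def load_config(source: Any) -> ParserConfig:
    """Load a configuration from a path, file object, JSON text or dict."""
    if isinstance(source, dict):
        return _build_config(source)
    if isinstance(source, str) and source.lstrip().startswith(("{", "[")):
        return loads_config(source)
    if hasattr(source, "read"):
        return loads_config(source.read())
    with open(source, encoding="utf-8") as fh:
        return loads_config(fh.read())


def _build_config(doc: Any) -> ParserConfig:
    issues = _Issues()
    obj = _expect_object(doc, "$", issues)
    if obj is None:
        raise ConfigValidationError(issues.items)
    if "DATA_ACCESS" not in obj:
        issues.error("$", "missing required section DATA_ACCESS")
    da = _parse_data_access(obj.get("DATA_ACCESS", {}), issues)
    cfg = ParserConfig(data_access=da)
    if "SUBSTANCE_RECORD" in obj:
        _parse_substance_record(obj["SUBSTANCE_RECORD"], da, cfg, issues)
    if "PROTOCOL_APPLICATIONS" in obj:
        arr = _expect_array(obj["PROTOCOL_APPLICATIONS"], "PROTOCOL_APPLICATIONS", issues) or []
        for i, item in enumerate(arr):
            pac = _parse_protocol_application(
                item, da, f"PROTOCOL_APPLICATIONS[{i}]", issues
            )
            if pac is not None:
                cfg.protocol_applications.append(pac)
    for key in set(obj) - {"DATA_ACCESS", "SUBSTANCE_RECORD", "PROTOCOL_APPLICATIONS"}:
        issues.warning(key, f"unknown top-level section {key!r} ignored")
    if issues.errors:
        raise ConfigValidationError(issues.items)
    cfg.warnings = [i for i in issues.items if i.severity == "warning"]
    return cfg


# ---------------------------------------------------------------------------
# Schema of the configuration dialect

def emit_schema() -> str:
    """Machine-readable JSON Schema of the configuration dialect.

    Intended for external validators and editor tooling; the in-package
    validator (:func:`load_config`) remains authoritative for the mode rules
    that cross-cut single attributes.
    """
    column_ref = {"oneOf": [{"type": "integer", "minimum": 0},
                            {"type": "string", "pattern": "^[A-Za-z]+$"}]}
    edl = {
        "type": "object",
        "properties": {
            "ITERATION": {"enum": sorted(ITERATION_MODES)},
            "SHEET_INDEX": {"type": "integer", "minimum": 0},
            "SHEET_NAME": {"type": "string"},
            "ROW_INDEX": {"type": "integer", "minimum": 0},
            "COLUMN_INDEX": column_ref,
            "JSON_VALUE": {},
            "SOURCE_COMBINATION": {"type": "boolean"},
        },
        "additionalProperties": False,
    }
    named_edl = {
        "type": "object",
        "properties": {"NAME": {"type": "string"}, **edl["properties"]},
        "required": ["NAME"],
        "additionalProperties": False,
    }
    pair = {
        "type": "array",
        "items": {"type": "integer"},
        "minItems": 2,
        "maxItems": 2,
    }
    parameter_rule = {
        "type": "object",
        "properties": {
            "NAME": {"type": "string"},
            "SOURCE": {"enum": list(_PARAM_SOURCES)},
            "ROW_INDEX": {"type": "integer", "minimum": 0},
            "COLUMN_INDEX": column_ref,
            "OFFSET": pair,
            "JSON_VALUE": {},
            "UNIT": {"type": "string"},
        },
        "required": ["NAME", "SOURCE"],
        "additionalProperties": False,
    }
    value_group = {
        "type": "object",
        "properties": {
            "VALUE_CELLS": {"type": "array", "items": pair, "minItems": 1},
            "PARAMETERS": {"type": "array", "items": parameter_rule},
        },
        "required": ["VALUE_CELLS"],
        "additionalProperties": False,
    }
    effect_block = {
        "type": "object",
        "properties": {
            "BLOCK_ORIGIN": pair,
            "SUB_BLOCK_GRID": pair,
            "SUB_BLOCK_SIZE": pair,
            "ENDPOINT": {"$ref": "#/$defs/edl"},
            "ENDPOINT_TYPE": {"$ref": "#/$defs/edl"},
            "UNIT": {"$ref": "#/$defs/edl"},
            "SAMPLE_ID": {"$ref": "#/$defs/edl"},
            "SHEET_INDEX": {"type": "integer", "minimum": 0},
            "SHEET_NAME": {"type": "string"},
            "VALUE_GROUPS": {"type": "array", "items": value_group, "minItems": 1},
        },
        "required": ["BLOCK_ORIGIN", "VALUE_GROUPS"],
        "additionalProperties": False,
    }
    effect = {
        "type": "object",
        "properties": {
            **{k: {"$ref": "#/$defs/edl"} for k in _EFFECT_ATTRS},
            "CONDITIONS": {"type": "array", "items": named_edl},
        },
        "required": ["ENDPOINT"],
        "additionalProperties": False,
    }
    component = {
        "type": "object",
        "properties": {
            "ROLE": {"$ref": "#/$defs/edl"},
            "NAME": {"$ref": "#/$defs/edl"},
            "STRUCTURE": {"$ref": "#/$defs/edl"},
            "PROPERTIES": {"type": "array", "items": named_edl},
            "LINKAGES": {
                "type": "array",
                "items": {
                    "type": "object",
                    "properties": {
                        "TARGET": {"type": "integer", "minimum": 0},
                        "RELATION": {"type": "string"},
                    },
                    "required": ["TARGET", "RELATION"],
                    "additionalProperties": False,
                },
            },
        },
        "required": ["ROLE"],
        "additionalProperties": False,
    }
    protocol_application = {
        "type": "object",
        "properties": {
            **{k: {"$ref": "#/$defs/edl"} for k in _PA_CITATION_ATTRS},
            "PROTOCOL_GUIDELINE": {
                "oneOf": [
                    {"$ref": "#/$defs/edl"},
                    {"type": "array", "items": {"$ref": "#/$defs/edl"}},
                ]
            },
            "PARAMETERS": {"type": "array", "items": named_edl},
            "EFFECTS": {"type": "array", "items": effect},
            "EFFECT_BLOCKS": {"type": "array", "items": effect_block},
        },
        "additionalProperties": False,
    }
    schema = {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "$id": "https://fairsheet.readthedocs.io/schemas/parser-config.json",
        "title": "fairsheet parser configuration",
        "type": "object",
        "properties": {
            "DATA_ACCESS": {
                "type": "object",
                "properties": {
                    "ITERATION": {"enum": sorted(ITERATION_MODES)},
                    "SHEET_INDEX": {"type": "integer", "minimum": 0},
                    "SHEET_NAME": {"type": "string"},
                    "ROW_START": {"type": "integer", "minimum": 0},
                    "ROW_END": {"type": "integer", "minimum": 0},
                    "STOP_ON_BLANK_ROWS": {"type": "integer", "minimum": 1},
                },
                "required": ["ITERATION"],
                "additionalProperties": False,
            },
            "SUBSTANCE_RECORD": {
                "type": "object",
                "properties": {
                    **{k: {"$ref": "#/$defs/edl"} for k in _SUBSTANCE_ATTRS},
                    "EXTERNAL_IDENTIFIERS": {
                        "type": "array",
                        "items": {
                            "type": "object",
                            "properties": {
                                "SYSTEM": {"$ref": "#/$defs/edl"},
                                "VALUE": {"$ref": "#/$defs/edl"},
                            },
                            "required": ["SYSTEM", "VALUE"],
                            "additionalProperties": False,
                        },
                    },
                    "COMPOSITION": {
                        "type": "array",
                        "items": {
                            "type": "object",
                            "properties": {
                                "COMPONENTS": {
                                    "type": "array",
                                    "items": component,
                                    "minItems": 1,
                                }
                            },
                            "required": ["COMPONENTS"],
                            "additionalProperties": False,
                        },
                    },
                },
                "additionalProperties": False,
            },
            "PROTOCOL_APPLICATIONS": {
                "type": "array",
                "items": protocol_application,
            },
        },
        "required": ["DATA_ACCESS"],
        "additionalProperties": False,
        "$defs": {"edl": edl},
    }
    return json.dumps(schema, indent=2)


# ---------------------------------------------------------------------------
# Minimal structural JSON-Schema validator
#
# Covers the subset used by the shipped schemas: type, properties,
# required, additionalProperties, items, minItems/maxItems, enum, oneOf,
# $ref into $defs, pattern, minimum.

def validate_instance(instance: Any, schema: dict, root: Optional[dict] = None,
                      path: str = "$") -> list[str]:
    """Validate ``instance`` against a schema document; return problem list."""
    import re

    root = root if root is not None else schema
    problems: list[str] = []
    if "$ref" in schema:
        target = root
        for part in schema["$ref"].lstrip("#/").split("/"):
            target = target[part]
        return validate_instance(instance, target, root, path)
    if "oneOf" in schema:
        branches = [validate_instance(instance, sub, root, path) for sub in schema["oneOf"]]
        if not any(not b for b in branches):
            problems.append(f"{path}: matches none of the alternatives")
        return problems
    if "enum" in schema and instance not in schema["enum"]:
        problems.append(f"{path}: {instance!r} not in {schema['enum']}")
    stype = schema.get("type")
    if stype is not None:
        checks = {
            "object": lambda v: isinstance(v, dict),
            "array": lambda v: isinstance(v, list),
            "string": lambda v: isinstance(v, str),
            "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
            "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
            "boolean": lambda v: isinstance(v, bool),
            "null": lambda v: v is None,
        }
        if not checks[stype](instance):
            problems.append(f"{path}: expected {stype}, found {type(instance).__name__}")
            return problems
    if isinstance(instance, dict):
        props = schema.get("properties", {})
        for key in schema.get("required", []):
            if key not in instance:
                problems.append(f"{path}: missing required key {key!r}")
        for key, value in instance.items():
            if key in props:
                problems.extend(validate_instance(value, props[key], root, f"{path}.{key}"))
            elif schema.get("additionalProperties") is False:
                problems.append(f"{path}: unknown key {key!r}")
    if isinstance(instance, list):
        if "minItems" in schema and len(instance) < schema["minItems"]:
            problems.append(f"{path}: fewer than {schema['minItems']} items")
        if "maxItems" in schema and len(instance) > schema["maxItems"]:
            problems.append(f"{path}: more than {schema['maxItems']} items")
        if "items" in schema:
            for i, item in enumerate(instance):
                problems.extend(validate_instance(item, schema["items"], root, f"{path}[{i}]"))
    if isinstance(instance, str) and "pattern" in schema:
        if not re.search(schema["pattern"], instance):
            problems.append(f"{path}: {instance!r} does not match {schema['pattern']!r}")
    if isinstance(instance, (int, float)) and not isinstance(instance, bool):
        if "minimum" in schema and instance < schema["minimum"]:
            problems.append(f"{path}: {instance} below minimum {schema['minimum']}")
    return problems
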