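"""Template and fixture tooling.

Three helpers around real-world template workflows:

* :func:`generate_fixture` builds a synthetic workbook in one of the two
  layout families seen in nanosafety data logging — a row-per-substance
  sheet (each table row one substance, fields in columns) or a block-layout
  dose-response sheet (a colony-forming-efficiency-style grid of replicate
  sub-blocks x exposure-time rows x concentration columns) — together with
  the JSON configuration that parses it and the ground-truth record list.
  All three are mutually consistent by construction and fully deterministic
  under the mandatory seed, which makes the triple the backbone of
  end-to-end testing.
* :func:`extract_template_fields` inventories a workbook's cells with a
  simple, documented header-detection heuristic.
* :func:`skeleton_config` drafts a parser configuration from such an
  inventory, with placeholder bindings flagged for the curator.

Measurement values are drawn from a seeded log-normal with a configurable
absent-cell probability; the numbers exercise NA handling and the counting
laws, and carry no biological claim.
"""

from __future__ import annotations

import io
import random
import zipfile
from dataclasses import dataclass, field as dc_field
from datetime import datetime
from typing import Optional

from openpyxl import Workbook
from openpyxl.utils import get_column_letter

from .config import ParserConfig, load_config
from .model import (
    EffectRecord,
    ExternalIdentifier,
    ProtocolApplication,
    SubstanceRecord,
    Value,
    assign_uuids,
)

__all__ = [
    "TemplateSpec",
    "BlockGeometry",
    "FixtureBundle",
    "TemplateField",
    "generate_fixture",
    "extract_template_fields",
    "skeleton_config",
    "save_workbook",
]

ROW_LAYOUT = "ROW_LAYOUT"
BLOCK_LAYOUT = "BLOCK_LAYOUT"

#: The three cell-line spellings every harmonization dictionary must unify.
CELL_TYPE_VARIANTS = ("BEAS 2B", "Beas 2B", "BEAS -2B")


@dataclass
class BlockGeometry:
    """Dose-response block: replicate sub-blocks x time rows x concentration
    columns, mirroring a colony forming efficiency (CFE) experiment."""

    replicates: int = 2
    times: int = 2
    concentrations: int = 9
    #: probability that a value cell holds an NA marker instead of a number
    absent_probability: float = 0.0
    value_log_mean: float = 4.5
    value_log_sigma: float = 0.25


@dataclass
class TemplateSpec:
    layout: str
    seed: int
    n_substances: int = 3
    block: Optional[BlockGeometry] = None
    absent_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.layout not in (ROW_LAYOUT, BLOCK_LAYOUT):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.layout == BLOCK_LAYOUT:
            if self.block is None:
                self.block = BlockGeometry()
            g = self.block
            if g.replicates < 1 or g.times < 1 or g.concentrations < 1:
                raise ValueError(f"invalid block geometry {g}")
        if self.n_substances < 0:
            raise ValueError("n_substances must be >= 0")


@dataclass
class FixtureBundle:
    workbook: Workbook
    config: dict
    expected: list[SubstanceRecord]

    @property
    def parser_config(self) -> ParserConfig:
        return load_config(self.config)


# ---------------------------------------------------------------------------
# Deterministic workbook output

_FIXED_STAMP = datetime(2000, 1, 1)


def save_workbook(wb: Workbook, path: str) -> None:
    """Write an XLSX file whose bytes depend only on the workbook content.

    The standard writer embeds wall-clock timestamps in the document
    properties and ZIP entries; identical content then yields different
    files.  Here the document dates are pinned and the archive is rewritten
    with fixed entry timestamps so repeated saves are byte-identical — a
    property the whole fixture pipeline relies on.
    """
    wb.properties.created = _FIXED_STAMP
    wb.properties.modified = _FIXED_STAMP
    buffer = io.BytesIO()
    wb.save(buffer)
    buffer.seek(0)
    with zipfile.ZipFile(buffer) as src, zipfile.ZipFile(
        path, "w", zipfile.ZIP_DEFLATED
    ) as dst:
        for name in sorted(src.namelist()):
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            dst.writestr(info, src.read(name))


# ---------------------------------------------------------------------------
# Row-layout fixture (one substance per table row)

_ROW_HEADERS = (
    "Substance name",
    "Public name",
    "Supplier",
    "Material type",
    "CAS number",
    "Cell type",
    "Zeta potential",
    "Concentration",
)

_MATERIALS = (
    ("Titanium dioxide", "nanomaterial"),
    ("Silicon dioxide", "nanomaterial"),
    ("Zinc oxide", "nanomaterial"),
    ("Silver", "nanomaterial"),
    ("Cerium dioxide", "nanomaterial"),
)


def _row_layout(spec: TemplateSpec) -> FixtureBundle:
    rng = random.Random(spec.seed)
    wb = Workbook()
    ws = wb.active
    ws.title = "Substances"
    for col, header in enumerate(_ROW_HEADERS, start=1):
        ws.cell(row=1, column=col, value=header)

    expected: list[SubstanceRecord] = []
    for i in range(spec.n_substances):
        name = f"NM-{100 + i}"
        public, mtype = _MATERIALS[i % len(_MATERIALS)]
        supplier = f"Lab {chr(ord('A') + i % 3)}"
        cas = f"{13463 + i}-67-{i % 10}"
        cell_type = CELL_TYPE_VARIANTS[i % len(CELL_TYPE_VARIANTS)]
        zeta = round(rng.lognormvariate(3.0, 0.4), 3)
        conc = round(rng.lognormvariate(1.0, 0.5), 3)
        absent = rng.random() < spec.absent_probability

        row = i + 2
        ws.cell(row=row, column=1, value=name)
        ws.cell(row=row, column=2, value=public)
        ws.cell(row=row, column=3, value=supplier)
        ws.cell(row=row, column=4, value=mtype)
        ws.cell(row=row, column=5, value=cas)
        ws.cell(row=row, column=6, value=cell_type)
        ws.cell(row=row, column=7, value="n/a" if absent else zeta)
        ws.cell(row=row, column=8, value=conc)

        effects = []
        if not absent:
            effects.append(
                EffectRecord(
                    endpoint="Zeta Potential",
                    lo_qualifier="=",
                    lo_value=zeta,
                    unit="mV",
                    conditions={"concentration": Value(number=conc)},
                )
            )
        record = SubstanceRecord(
            substance_name=name,
            public_name=public,
            owner_name=supplier,
            substance_type=mtype,
            external_identifiers=[ExternalIdentifier(system="CASRN", value=cas)],
            protocol_applications=[
                ProtocolApplication(
                    citation_title="Zeta potential measurement",
                    parameters={"cell type": Value(text=cell_type)},
                    effects=effects,
                )
            ],
        )
        expected.append(assign_uuids(record))

    config = {
        "DATA_ACCESS": {
            "ITERATION": "ROW_SINGLE",
            "SHEET_INDEX": 0,
            "ROW_START": 1,
        },
        "SUBSTANCE_RECORD": {
            "SUBSTANCE_NAME": {"COLUMN_INDEX": 0},
            "PUBLIC_NAME": {"COLUMN_INDEX": 1},
            "OWNER_NAME": {"COLUMN_INDEX": 2},
            "SUBSTANCE_TYPE": {"COLUMN_INDEX": 3},
            "EXTERNAL_IDENTIFIERS": [
                {"SYSTEM": {"JSON_VALUE": "CASRN"}, "VALUE": {"COLUMN_INDEX": 4}}
            ],
        },
        "PROTOCOL_APPLICATIONS": [
            {
                "CITATION_TITLE": {"JSON_VALUE": "Zeta potential measurement"},
                "PARAMETERS": [{"NAME": "cell type", "COLUMN_INDEX": 5}],
                "EFFECTS": [
                    {
                        "ENDPOINT": {"JSON_VALUE": "Zeta Potential"},
                        "VALUE": {"COLUMN_INDEX": 6},
                        "UNIT": {"JSON_VALUE": "mV"},
                        "CONDITIONS": [{"NAME": "concentration", "COLUMN_INDEX": 7}],
                    }
                ],
            }
        ],
    }
    return FixtureBundle(workbook=wb, config=config, expected=expected)


# ---------------------------------------------------------------------------
# Block-layout fixture (dose-response grid, one substance per file)

_CONCENTRATIONS = (0.0, 0.01, 0.1, 1.0, 5.0, 10.0, 25.0, 50.0, 100.0)


def _block_layout(spec: TemplateSpec) -> FixtureBundle:
    geometry = spec.block
    assert geometry is not None
    rng = random.Random(spec.seed)
    n_conc = geometry.concentrations
    concentrations = [
        _CONCENTRATIONS[j] if j < len(_CONCENTRATIONS) else float(100 * (j + 1))
        for j in range(n_conc)
    ]

    wb = Workbook()
    cond = wb.active
    cond.title = "Test conditions"
    for row, (label, value) in enumerate(
        (
            ("Substance", "NM-300"),
            ("CAS", "7631-86-9"),
            ("Assay", "CFE"),
            ("Endpoint", "colony forming efficiency"),
            ("Unit", "%"),
        ),
        start=1,
    ):
        cond.cell(row=row, column=1, value=label)
        cond.cell(row=row, column=2, value=value)

    results = wb.create_sheet("Test results")
    results.cell(row=1, column=1, value="CFE raw data")
    for j in range(n_conc):
        results.cell(row=2, column=3 + j, value=f"C{j + 1}")
        results.cell(row=3, column=3 + j, value=concentrations[j])
    results.cell(row=3, column=1, value="Concentration")

    origin_row = 3  # 0-based row of the first sub-block
    values: list[list[list[Optional[float]]]] = []
    for r in range(geometry.replicates):
        sub: list[list[Optional[float]]] = []
        for t in range(geometry.times):
            sheet_row = origin_row + r * geometry.times + t + 1
            if t == 0:
                results.cell(row=sheet_row, column=1, value=f"R{r + 1}")
            results.cell(row=sheet_row, column=2, value=f"T{t + 1}")
            row_vals: list[Optional[float]] = []
            for j in range(n_conc):
                v: Optional[float] = round(
                    rng.lognormvariate(geometry.value_log_mean, geometry.value_log_sigma), 3
                )
                if rng.random() < geometry.absent_probability:
                    v = None
                results.cell(
                    row=sheet_row, column=3 + j, value="n/a" if v is None else v
                )
                row_vals.append(v)
            sub.append(row_vals)
        values.append(sub)

    value_groups = [
        {
            "VALUE_CELLS": [[t, 2 + j] for j in range(n_conc)],
            "PARAMETERS": [
                {"NAME": "replicate", "SOURCE": "SUB_BLOCK_CELL", "OFFSET": [0, 0]},
                {"NAME": "time", "SOURCE": "SUB_BLOCK_CELL", "OFFSET": [t, 1]},
                {
                    "NAME": "concentration",
                    "SOURCE": "COLUMN_HEADER",
                    "ROW_INDEX": 2,
                    "UNIT": "ug/cm2",
                },
            ],
        }
        for t in range(geometry.times)
    ]
    config = {
        "DATA_ACCESS": {"ITERATION": "ABSOLUTE_LOCATION", "SHEET_INDEX": 0},
        "SUBSTANCE_RECORD": {
            "SUBSTANCE_NAME": {"ROW_INDEX": 0, "COLUMN_INDEX": 1},
            "EXTERNAL_IDENTIFIERS": [
                {
                    "SYSTEM": {"JSON_VALUE": "CASRN"},
                    "VALUE": {"ROW_INDEX": 1, "COLUMN_INDEX": 1},
                }
            ],
        },
        "PROTOCOL_APPLICATIONS": [
            {
                "CITATION_TITLE": {"ROW_INDEX": 2, "COLUMN_INDEX": 1},
                "EFFECT_BLOCKS": [
                    {
                        "SHEET_INDEX": 1,
                        "BLOCK_ORIGIN": [origin_row, 0],
                        "SUB_BLOCK_GRID": [geometry.replicates, 1],
                        "SUB_BLOCK_SIZE": [geometry.times, 2 + n_conc],
                        "ENDPOINT": {"ROW_INDEX": 3, "COLUMN_INDEX": 1},
                        "UNIT": {"ROW_INDEX": 4, "COLUMN_INDEX": 1},
                        "VALUE_GROUPS": value_groups,
                    }
                ],
            }
        ],
    }

    effects: list[EffectRecord] = []
    for r in range(geometry.replicates):
        for t in range(geometry.times):
            for j in range(n_conc):
                v = values[r][t][j]
                if v is None:
                    continue
                effects.append(
                    EffectRecord(
                        endpoint="colony forming efficiency",
                        unit="%",
                        lo_qualifier="=",
                        lo_value=v,
                        conditions={
                            "replicate": Value(text=f"R{r + 1}"),
                            "time": Value(text=f"T{t + 1}"),
                            "concentration": Value(
                                number=concentrations[j], unit="ug/cm2"
                            ),
                        },
                    )
                )
    record = SubstanceRecord(
        substance_name="NM-300",
        external_identifiers=[ExternalIdentifier(system="CASRN", value="7631-86-9")],
        protocol_applications=[
            ProtocolApplication(citation_title="CFE", effects=effects)
        ],
    )
    return FixtureBundle(workbook=wb, config=config, expected=[assign_uuids(record)])


def generate_fixture(spec: TemplateSpec) -> FixtureBundle:
    """Workbook + companion configuration + ground-truth records.

    The three artefacts are mutually consistent by construction: parsing the
    workbook under the companion configuration must reproduce the expected
    record list exactly.  Output is fully determined by the spec (including
    its mandatory seed).
    """
    if spec.layout == ROW_LAYOUT:
        return _row_layout(spec)
    return _block_layout(spec)


# ---------------------------------------------------------------------------
# Template field inventory

@dataclass
class TemplateField:
    sheet: str
    coordinate: str  # A1 notation
    row: int  # 0-based
    column: int  # 0-based
    text: str
    kind: str  # "label" | "data"


def extract_template_fields(wb: Workbook) -> list[TemplateField]:
    """Inventory the non-empty cells of a workbook.

    Heuristic (documented, overridable by editing the draft configuration):
    a cell is a ``label`` if it is text-typed and its column contains at
    least one numeric cell below it; every other non-empty cell is ``data``.
    """
    inventory: list[TemplateField] = []
    for ws in wb.worksheets:
        numeric_below: dict[int, list[int]] = {}
        for row in range(1, ws.max_row + 1):
            for col in range(1, ws.max_column + 1):
                v = ws.cell(row=row, column=col).value
                if isinstance(v, (int, float)) and not isinstance(v, bool):
                    numeric_below.setdefault(col, []).append(row)
        for row in range(1, ws.max_row + 1):
            for col in range(1, ws.max_column + 1):
                v = ws.cell(row=row, column=col).value
                if v is None or (isinstance(v, str) and not v.strip()):
                    continue
                is_label = isinstance(v, str) and any(
                    r > row for r in numeric_below.get(col, [])
                )
                inventory.append(
                    TemplateField(
                        sheet=ws.title,
                        coordinate=f"{get_column_letter(col)}{row}",
                        row=row - 1,
                        column=col - 1,
                        text=str(v),
                        kind="label" if is_label else "data",
                    )
                )
    return inventory


def skeleton_config(inventory: list[TemplateField]) -> dict:
    """Draft a parser configuration from a field inventory.

    Label cells become column bindings: the leftmost label of the topmost
    header row is proposed as the substance name, the rest as protocol
    parameters whose names are flagged ``TODO`` for the curator to bind to
    model entities.  The draft always passes :func:`~fairsheet.config.load_config`
    (warnings allowed); regeneration from the same inventory is stable.
    """
    if not inventory:
        raise ValueError("cannot draft a configuration from an empty inventory")
    labels = [f for f in inventory if f.kind == "label"]
    if not labels:
        # no header structure detected; bind the first data cell absolutely
        first = inventory[0]
        return {
            "_TODO": "no header row detected; bindings are placeholders",
            "DATA_ACCESS": {"ITERATION": "ABSOLUTE_LOCATION", "SHEET_INDEX": 0},
            "SUBSTANCE_RECORD": {
                "SUBSTANCE_NAME": {
                    "ROW_INDEX": first.row,
                    "COLUMN_INDEX": first.column,
                }
            },
        }
    header_row = min(f.row for f in labels)
    header = sorted(
        (f for f in labels if f.row == header_row), key=lambda f: f.column
    )
    name_field, rest = header[0], header[1:]
    config: dict = {
        "_TODO": "review placeholder bindings before use",
        "DATA_ACCESS": {
            "ITERATION": "ROW_SINGLE",
            "SHEET_INDEX": 0,
            "ROW_START": header_row + 1,
        },
        "SUBSTANCE_RECORD": {
            "SUBSTANCE_NAME": {"COLUMN_INDEX": name_field.column}
        },
    }
    if rest:
        config["PROTOCOL_APPLICATIONS"] = [
            {
                "PARAMETERS": [
                    {"NAME": f"TODO: {f.text}", "COLUMN_INDEX": f.column} for f in rest
                ]
            }
        ]
    return config
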