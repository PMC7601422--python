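# fairsheet

Convert heterogeneous experimental spreadsheets into a well-defined semantic
substance data model — the core step of making lab data FAIR (Findable,
Accessible, Interoperable, Reusable).

Nanosafety and chemical-substance assay results are overwhelmingly recorded
in Excel templates whose layout varies by project, lab and assay: some put
one substance per table row with fields in columns, others organise
dose–response measurements in rectangular blocks indexed by replicate,
exposure time and concentration. `fairsheet` maps any such layout onto a
single data model through a *declarative JSON mapping configuration*, so
that curators describe **where the data is**, not how to parse it.

## The data model

A **substance** (a nanomaterial is treated as a chemical substance in the
REACH sense) carries names, external identifiers (e.g. CAS numbers) and one
or more **compositions**; each composition lists **components** with roles —
main constituent, impurity, additive, or for nanomaterials core, coating,
functionalisation — and linkages between components ("covalently bonded",
"embedded", "encapsulated"). Measurements attach through **protocol
applications**: one event of applying an experimental protocol, with a
dynamic parameter list, citations/guidelines, and a set of **effect
records**. An effect record is one measurement: endpoint, a value `x = 3`,
a bounded value `x < 3`, an interval `3 < x ≤ 4`, or text, with optional
uncertainty (`± SD`), a unit, and per-measurement experimental conditions
(concentration, time, replicate, …). Substances, protocol applications and
compositions get deterministic name-based (hash) UUIDs, so re-parsing the
same source yields the same linkable identifiers.

## The mapping configuration

A configuration is JSON with three sections: `DATA_ACCESS` (iteration mode,
primary sheet, row range, and the defaults every location inherits),
`SUBSTANCE_RECORD` and `PROTOCOL_APPLICATIONS`. Most attributes are *Excel
Data Locations* — small objects saying where one datum lives under an
iteration mode:

* `ROW_SINGLE` — each table row is one substance; only a column is needed
  (the row comes from the iteration);
* `ABSOLUTE_LOCATION` — a fixed row + column;
* `JSON_VALUE` — the value is a literal in the configuration itself.

A short syntax omits anything defaulted in `DATA_ACCESS`. Dose–response
grids are described once by an `EFFECT_BLOCKS` entry — a grid of sub-blocks
holding value groups whose cells map one-to-one onto measurements, with the
experimental conditions read from row/column headers or fixed cells —
instead of enumerating every combination by hand. Validation collects
**all** problems in one pass, each with its JSON path. Rows and columns are
0-based; column letters ("A", "B", …) are accepted.

## Worked example

```python
import fairsheet as fs

bundle = fs.generate_fixture(fs.TemplateSpec(layout="ROW_LAYOUT", seed=20))
records = list(fs.parse_workbook(bundle.workbook, bundle.parser_config))
print(fs.to_native_json(records[:1]))
```

prints

```json
[
  {
    "substanceName": "NM-100",
    "publicName": "Titanium dioxide",
    "ownerName": "Lab A",
    "substanceUUID": "XLSX-dcd3fbb5-ec47-55b9-b1d8-fd9c1c0e9e30",
    "substanceType": "nanomaterial",
    "externalIdentifiers": [
      { "system": "CASRN", "value": "13463-67-0" }
    ],
    "protocolApplications": [
      {
        "uuid": "PA-554167f0-3432-5359-8780-8b5ad2e2685f",
        "citationTitle": "Zeta potential measurement",
        "parameters": { "cell type": { "text": "BEAS 2B" } },
        "effects": [
          {
            "endpoint": "Zeta Potential",
            "loQualifier": "=",
            "loValue": 12.776,
            "unit": "mV",
            "conditions": { "concentration": { "number": 2.931 } }
          }
        ]
      }
    ]
  }
]
```

One substance per spreadsheet row, its CAS number mapped as an external
identifier, the measured zeta potential stored as `x = 12.776 mV` under the
concentration it was measured at, and deterministic hash-based UUIDs. The
block-layout family works the same way: a colony-forming-efficiency-style
sheet with 2 replicates × 2 timings × 9 concentrations expands to exactly
36 effect records, each carrying `replicate`, `time` and `concentration`
conditions.

Output formats: native JSON (lossless round-trip via `from_native_json`),
ISA-JSON v1 with a nanomaterial material extension (component roles +
linkages), and an experimental minimal N-Triples dump. After parsing,
records can be harmonized against controlled dictionaries
(`fs.harmonize_record`): "BEAS 2B" / "Beas 2B" / "BEAS -2B" collapse to one
canonical cell line, originals are kept verbatim, and unmatched terms are
listed for curator review.

## Command line

```
fairsheet convert data.xlsx --config map.json --format isajson --output out.json
fairsheet validate map.json
fairsheet fields template.xlsx          # inventory a template's cells
fairsheet skeleton template.xlsx        # draft a mapping configuration
fairsheet fixture --layout BLOCK_LAYOUT --seed 5 --output-prefix fx
```

Logs go to stderr, data to files/stdout; exit status is 0 iff there were no
fatal errors, so the tool embeds in unattended import pipelines.

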