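# Methods

This note documents the model, the design choices made where the design was
genuinely open, the numerical/normalization conventions, what the synthetic
fixtures emulate, and the known limitations.

## The data model and its assumptions

The model treats a nanomaterial as a chemical substance (REACH sense): the
unit of identity is the substance, not a chemical structure. Structures are
carried as opaque text on composition components — this package never
parses line notations or computes descriptors. Measurements are modelled
generically: an effect record has no assay-specific fields; everything
specific to an experiment lives in the dynamic `parameters` (protocol
level) and `conditions` (measurement level) maps. This is what lets one
model absorb physicochemical characterisation, in-vitro dose–response and
HTS data alike; the cost is that semantic interpretation of parameter names
is deferred to harmonization dictionaries.

Values distinguish *absent* from *empty*: a blank spreadsheet cell yields
an absent field, never an empty string, so "value not reported" survives
conversion.

### Identifiers

Entity UUIDs are RFC-4122 v5 (SHA-1, name-based) over the NFC-normalized,
`|`-joined identity fields, prefixed with an entity-class tag
(`XLSX`/`PA`/`CMP`) so IDs of different classes cannot collide:

* substance — source tag + substance name + public name + owner name;
* protocol application — substance UUID + citation + guidelines +
  parameters;
* composition — substance UUID + component names.

The canonical field list per entity class is a convention of this package.
Case is preserved (two differently-cased names are different identities
until harmonization says otherwise). Investigation/assay grouping has no
universal key, so those UUIDs are set only by explicit configuration
(`INVESTIGATION_UUID` / `ASSAY_UUID` locations), never inferred.

## Configuration dialect decisions

* **Indexing is 0-based** for rows and columns, because that matches the
  programmatic workbook APIs the configurations are debugged against;
  column letters are accepted and converted since they match the user's
  mental model. Log messages show A1 notation beside the indices.
* Sheets are addressable by 0-based index or exact name; the name wins when
  both are given (templates get re-ordered more often than renamed).
* Only the three first-class iteration modes (`ROW_SINGLE`,
  `ABSOLUTE_LOCATION`, `JSON_VALUE`) are implemented; the mode enum sits
  behind a registry so further modes can be added without changing the
  engine contract. Other dialect options known from richer mapping tools
  are intentionally unimplemented dialect gaps.
* `ITERATION` is required in `DATA_ACCESS`; an EDL carrying a `JSON_VALUE`
  literal implies the `JSON_VALUE` mode and ignores sheet defaults.
* Unknown keys anywhere are warnings, never fatal — forward compatibility
  with fuller dialects; silent drops are avoided by always logging them.
* Validation is single-pass and exhaustive: configurations are handwritten
  by curators, and a complete path-qualified defect list per file is worth
  more than failing fast. `VALUE` is implemented as an alias for
  `LO_VALUE` with qualifier `=` (plain numeric measurements), with
  qualified/interval text routed through the expression grammar.

The published schema (`emit_schema()`) captures the structural dialect;
the in-package validator remains authoritative for cross-attribute mode
rules. Schema checking of instances uses a small structural validator
covering the JSON-Schema subset the shipped schemas use.

## Engine conventions

* **Blank-row termination**: under `ROW_SINGLE` without `ROW_END`,
  iteration stops after 2 consecutive fully blank primary-sheet rows
  (configurable) — real templates carry trailing notes.
* **Merged cells** propagate the anchor value to every covered coordinate,
  because templates label groups with merged headers.
* **Type coercion**: numbers stay numeric; date/time cells become ISO-8601
  text; everything else is trimmed text. Decimal commas in text are left
  untouched with a warning — silent locale guessing corrupts data. NA
  markers `{"", "n/a", "N/A", "-", "–"}` (configurable) read as absent.
* **Value expressions**: `<q><num>` with `q ∈ {<, <=, >, >=, ~, =}` and
  ranges `a-b`/`a–b` (closed interval, qualifiers `>=`/`<=`). Upper-bound
  qualifiers fill the upper slot, the rest the lower. Unparsed text is
  stored verbatim as `textValue`; nothing is guessed.
* **Uncertainty semantics** come solely from the configured
  `ERR_QUALIFIER` (e.g. "SD"); whether a column holds SD or SE is
  template knowledge this tool never infers.
* **Error policy**: collect-and-continue per record by default (curators
  want the full defect report for a file); `strict` raises on the first
  error. Block geometry exceeding the sheet's used range is an error naming
  the offending coordinates; the affected cells read as absent.
* Effect-block conditions are evaluated per value cell from the declared
  parameter rules (column header at a fixed row, row header at a fixed
  column, fixed cell within the sub-block or block, the 1-based sub-block
  index, or a literal). The effect count therefore obeys a counting law —
  emitted records = non-absent value cells over the configured geometry —
  which the tests verify against an independent brute-force cell walker.

## Harmonization

Normalization is deliberately minimal: Unicode NFKC + casefold + removal of
separator characters (space, hyphen, underscore, dot, slash). That unifies
case, spacing and punctuation variants ("BEAS 2B" ≡ "Beas 2B" ≡
"BEAS -2B") without stemming. Edit-distance "spell checking" is **not**
applied unattended — too risky — but near misses (edit distance ≤ 1) are
flagged in the miss report for curator review. Canonical terms are forced
to be fixed points of the lookup, which makes harmonization idempotent.
Originals are always retained verbatim inside the annotated term, and an
entry may carry multiple vocabulary annotations (public and private
dictionaries coexist). Dictionaries are plain JSON files, curator-editable
and version-controllable.

## Serialization

Native JSON uses lowerCamelCase forms of the configuration attribute
vocabulary; key order is fixed by construction, `None`/empty fields are
omitted, and identical records produce byte-identical text. The ISA-JSON
export emits a v1 skeleton — studies group protocol applications by
investigation UUID (one default study otherwise), assays group by protocol
identity, materials carry component roles and linkages. The bundled
nanomaterial extension schema is a **synthetic reconstruction** from the
published textual description of such an extension (role + linkages); it is
not the original schema document. The N-Triples export is experimental: a
minimal dump over a small fixed vocabulary, with sorted lines for
determinism.

## Synthetic fixtures

The generator emulates the two template families:

* **row layout** — header row + one substance per row (name, public name,
  supplier, material type, CAS, cell type, zeta potential, concentration),
  defaulting to 3 substances; cell-type cells cycle through the three
  BEAS-2B spellings so harmonization is exercised end-to-end.
* **block layout** — a colony-forming-efficiency-style workbook: a
  conditions sheet (substance, CAS, assay, endpoint, unit as labelled
  cells) and a results sheet with replicate sub-blocks stacked vertically,
  time-labelled rows and concentration-labelled columns. Defaults are the
  full CFE design of 2 replicates × 2 timings × 9 concentrations of
  silicon dioxide = 36 measurements.

Measurement values are drawn from a seeded log-normal with a configurable
absent-cell probability (default 0); the numbers exercise NA handling and
the counting law and carry no biological claim. Workbook output is
byte-deterministic: document dates are pinned and the ZIP archive is
rewritten with fixed entry timestamps, since the standard writer embeds
wall-clock time.

What the fixtures do **not** emulate: formula cells (cached values are read
as-is, and the generator writes none), styling/color semantics, multi-sheet
cross-references beyond the two-sheet block family, free-text chaos beyond
the NA markers and spelling variants listed. Passing tests show the mapping
machinery is correct on conforming layouts; they do not show robustness to
arbitrary real-world template drift, which is what the validation error
reporting and the curator-facing miss reports exist for.

Header detection in `extract_template_fields` is a single documented
heuristic — a cell is a header label if text-typed with at least one
numeric cell below it in its column — chosen for predictability over
cleverness; skeleton configurations are drafts with `TODO`-flagged bindings
by design, since field-to-entity binding is curator knowledge.

## Problem sizes

The default verification runs use fixtures of 1–6 substances, randomized
block geometries up to 3×3 sub-block grids with ≤ 3 value groups × ≤ 10
cells (100 seeds), 200 randomized records for round-trip checks and 50 for
harmonization idempotence. These sizes fully cover the combinatorics of the
block expander and serializers while keeping the whole suite fast enough to
run on every change.

## Known limitations

* No spreadsheet-formula evaluation, chart/image extraction, or
  styling-based addressing.
* XLS (pre-2007) input is not supported, only XLSX.
* RDF output is a minimal experimental dump, not a semantic mapping.
* Chemical structures are opaque text; no structure interpretation.
* Relational persistence, web services, search indexing and ontology
  reasoning are outside this package's scope.
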