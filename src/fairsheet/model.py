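"""Semantic data model for chemical substances and nanomaterials.

The model treats a nanomaterial as a chemical substance in the REACH sense:
a substance is identified by names and IDs, characterised by one or more
compositions (each a list of components with roles such as core, coating or
functionalisation), and carries the results of experimental protocols as
"protocol applications".  Each protocol application owns a dynamic parameter
list and a set of effect records — single measurements with endpoint,
value/interval, qualifiers, uncertainty, unit and per-measurement
experimental conditions (concentration, exposure time, replicate, ...).

Entity identifiers are deterministic name-based (hash) UUIDs so that
re-parsing the same source yields the same linkable IDs.
"""

from __future__ import annotations

import enum
import unicodedata
import uuid as _uuid
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "ComponentRole",
    "Value",
    "AnnotationTerm",
    "AnnotatedTerm",
    "ExternalIdentifier",
    "Linkage",
    "Component",
    "Composition",
    "EffectRecord",
    "ProtocolApplication",
    "SubstanceRecord",
    "QUALIFIERS",
    "generate_uuid",
    "merge_records",
    "MergeConflictError",
]

#: Relational qualifiers attachable to a value or an interval bound.
QUALIFIERS = ("=", "<", "<=", ">", ">=", "~")


class ComponentRole(str, enum.Enum):
    """Role of a component within a composition.

    Classical substance roles (main constituent / impurity / additive) plus
    the nanomaterial-specific roles (core / coating / functionalisation).
    """

    MAIN_CONSTITUENT = "MAIN_CONSTITUENT"
    IMPURITY = "IMPURITY"
    ADDITIVE = "ADDITIVE"
    CORE = "CORE"
    COATING = "COATING"
    FUNCTIONALISATION = "FUNCTIONALISATION"
    OTHER = "OTHER"


class _Frozen(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class Value(_Frozen):
    """Carrier for a dynamic parameter or condition value.

    Exactly one of ``number`` / ``text`` is set; an optional unit and
    relational qualifier may accompany either.
    """

    number: Optional[float] = None
    text: Optional[str] = None
    unit: Optional[str] = None
    qualifier: Optional[str] = None

    @model_validator(mode="after")
    def _xor(self) -> "Value":
        if (self.number is None) == (self.text is None):
            raise ValueError("Value requires exactly one of 'number' or 'text'")
        return self


class AnnotationTerm(_Frozen):
    """A controlled-vocabulary or ontology term attached to an entry."""

    vocabulary: str
    term_id: str
    label: Optional[str] = None


class AnnotatedTerm(_Frozen):
    """A harmonized text entry.

    ``original`` is the verbatim source text; ``canonical`` the dictionary
    form.  More than one vocabulary term may annotate a single entry (private
    and public dictionaries coexist), and the list may be empty.
    """

    original: str
    canonical: str
    annotations: list[AnnotationTerm] = []


#: Fields that may hold either raw text or a harmonized term.
TextOrTerm = Union[str, AnnotatedTerm]


class ExternalIdentifier(_Frozen):
    """An identifier in an external system, e.g. ``("CASRN", "13463-67-7")``."""

    system: str
    value: str

    @model_validator(mode="after")
    def _nonempty(self) -> "ExternalIdentifier":
        if not self.system.strip() or not self.value.strip():
            raise ValueError("ExternalIdentifier requires non-empty system and value")
        return self


class Linkage(_Frozen):
    """Relation between two components of one composition.

    ``target`` is the index of the other component within the composition;
    ``relation`` is free text such as "covalently bonded", "embedded" or
    "encapsulated".
    """

    target: int
    relation: str


class Component(_Frozen):
    role: ComponentRole
    name: Optional[str] = None
    #: Line notation or formula; carried opaquely, never interpreted.
    structure: Optional[str] = None
    properties: dict[str, Value] = {}
    linkages: list[Linkage] = []


class Composition(_Frozen):
    composition_uuid: str
    components: list[Component]

    @model_validator(mode="after")
    def _check(self) -> "Composition":
        if not self.components:
            raise ValueError("Composition requires at least one component")
        n = len(self.components)
        for i, comp in enumerate(self.components):
            for link in comp.linkages:
                if not (0 <= link.target < n):
                    raise ValueError(
                        f"component {i} linkage target {link.target} outside "
                        f"composition of {n} components"
                    )
        return self


class EffectRecord(_Frozen):
    """One measurement.

    The value may be a plain number (``lo_value`` with qualifier "="), an
    interval (``lo_value``/``up_value`` with their qualifiers, e.g.
    3 < x <= 4), or text.  Uncertainty is a separate value with its own
    qualifier (e.g. "SD").  ``conditions`` holds the experimental factors of
    this single measurement (concentration, time, replicate, ...), ordered as
    configured.
    """

    sample_id: Optional[str] = None
    endpoint: TextOrTerm = ""
    endpoint_type: Optional[str] = None
    lo_qualifier: Optional[str] = None
    lo_value: Optional[float] = None
    up_qualifier: Optional[str] = None
    up_value: Optional[float] = None
    err_qualifier: Optional[str] = None
    err_value: Optional[float] = None
    text_value: Optional[str] = None
    unit: Optional[TextOrTerm] = None
    conditions: dict[str, Value] = {}

    @model_validator(mode="after")
    def _check_qualifiers(self) -> "EffectRecord":
        for q in (self.lo_qualifier, self.up_qualifier):
            if q is not None and q not in QUALIFIERS:
                raise ValueError(f"qualifier {q!r} not in {QUALIFIERS}")
        return self

    def is_empty(self) -> bool:
        return self.lo_value is None and self.up_value is None and self.text_value is None


class ProtocolApplication(_Frozen):
    """One event of applying an experimental protocol to a substance."""

    uuid: str = ""
    citation_title: Optional[str] = None
    citation_year: Optional[str] = None
    citation_owner: Optional[str] = None
    protocol_guideline: list[str] = []
    interpretation_result: Optional[str] = None
    interpretation_criteria: Optional[str] = None
    parameters: dict[str, Value] = {}
    effects: list[EffectRecord] = []
    #: Optional grouping keys; set only by explicit configuration.
    investigation_uuid: Optional[str] = None
    assay_uuid: Optional[str] = None
    reliability_flag: Optional[str] = None


class SubstanceRecord(_Frozen):
    substance_name: TextOrTerm = ""
    public_name: Optional[str] = None
    owner_name: Optional[str] = None
    owner_uuid: Optional[str] = None
    substance_uuid: str = ""
    substance_type: Optional[str] = None
    external_identifiers: list[ExternalIdentifier] = []
    compositions: list[Composition] = []
    protocol_applications: list[ProtocolApplication] = []

    @model_validator(mode="after")
    def _no_duplicate_ids(self) -> "SubstanceRecord":
        seen = set()
        for xid in self.external_identifiers:
            key = (xid.system, xid.value)
            if key in seen:
                raise ValueError(f"duplicate external identifier {key}")
            seen.add(key)
        return self


# ---------------------------------------------------------------------------
# Deterministic identifiers


def _term_text(value: TextOrTerm) -> str:
    return value.original if isinstance(value, AnnotatedTerm) else value


def generate_uuid(namespace_tag: str, canonical_fields: list[str]) -> str:
    """Name-based (v5) UUID over a canonical serialization of identity fields.

    The canonical form is the NFC-normalized, "|"-joined sequence
    ``tag|field1|field2|...`` hashed under the RFC-4122 URL namespace; the
    returned string is prefixed with the namespace tag so identifiers of
    different entity classes can never collide.  Stable across runs and
    platforms.
    """
    if not canonical_fields:
        raise ValueError("generate_uuid requires at least one canonical field")
    canonical = "|".join(
        unicodedata.normalize("NFC", f) for f in [namespace_tag, *canonical_fields]
    )
    return f"{namespace_tag}-{_uuid.uuid5(_uuid.NAMESPACE_URL, canonical)}"


def assign_uuids(record: SubstanceRecord, source_tag: str = "XLSX") -> SubstanceRecord:
    """Fill in missing deterministic UUIDs on a record, in place.

    The substance UUID hashes the identity fields (name, public name, owner);
    each protocol application hashes the substance UUID plus its protocol
    identity (citation/guideline) and parameters, so identical experiments on
    identical substances regenerate identical IDs.
    """
    if not record.substance_uuid:
        record.substance_uuid = generate_uuid(
            source_tag,
            [
                _term_text(record.substance_name),
                record.public_name or "",
                record.owner_name or "",
            ],
        )
    for pa in record.protocol_applications:
        if not pa.uuid:
            fields = [
                record.substance_uuid,
                pa.citation_title or "",
                pa.citation_year or "",
                *pa.protocol_guideline,
                *(f"{k}={_param_repr(v)}" for k, v in pa.parameters.items()),
            ]
            pa.uuid = generate_uuid("PA", fields)
    for comp in record.compositions:
        if not comp.composition_uuid:
            comp.composition_uuid = generate_uuid(
                "CMP",
                [record.substance_uuid, *(c.name or str(c.role) for c in comp.components)],
            )
    return record


def _param_repr(v: Value) -> str:
    core = repr(v.number) if v.number is not None else (v.text or "")
    return f"{core} {v.unit}" if v.unit else core


# ---------------------------------------------------------------------------
# Merging record fragments


class MergeConflictError(ValueError):
    """Two fragments with the same substance UUID disagree on identity."""


def merge_records(records: list[SubstanceRecord]) -> list[SubstanceRecord]:
    """Merge fragments that share a substance UUID.

    Multiple sheets or configurations may each yield part of the same
    substance; fragments are unioned: external identifiers deduplicated,
    compositions and protocol applications concatenated.  Order of first
    appearance is preserved.  Conflicting substance names for one UUID raise
    :class:`MergeConflictError`.
    """
    merged: dict[str, SubstanceRecord] = {}
    order: list[str] = []
    for rec in records:
        if not rec.substance_uuid:
            raise ValueError("merge_records requires substance_uuid on every record")
        uid = rec.substance_uuid
        if uid not in merged:
            merged[uid] = rec.model_copy(deep=True)
            order.append(uid)
            continue
        base = merged[uid]
        a, b = _term_text(base.substance_name), _term_text(rec.substance_name)
        if a and b and a != b:
            raise MergeConflictError(
                f"substance {uid}: conflicting names {a!r} and {b!r}"
            )
        for xid in rec.external_identifiers:
            if (xid.system, xid.value) not in {
                (e.system, e.value) for e in base.external_identifiers
            }:
                base.external_identifiers = [*base.external_identifiers, xid]
        base.compositions = [*base.compositions, *(c.model_copy(deep=True) for c in rec.compositions)]
        base.protocol_applications = [
            *base.protocol_applications,
            *(p.model_copy(deep=True) for p in rec.protocol_applications),
        ]
        for attr in ("public_name", "owner_name", "owner_uuid", "substance_type"):
            if getattr(base, attr) is None and getattr(rec, attr) is not None:
                setattr(base, attr, getattr(rec, attr))
        if not a and b:
            base.substance_name = rec.substance_name
    return [merged[u] for u in order]
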