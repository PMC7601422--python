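"""Serialization of substance records.

Three output forms:

* **native JSON** — a lossless, deterministic serialization of the data
  model under lowerCamelCase versions of the configuration attribute
  vocabulary (``substanceName``, ``loQualifier``, ...).  Reading it back
  with :func:`from_native_json` reproduces the records exactly.
* **ISA-JSON** — an Investigation/Study/Assay skeleton where studies group
  protocol applications by investigation, assays group them by protocol
  identity, substances appear as source materials carrying the nanomaterial
  extension (component roles and linkages: a coating may be covalently
  bonded to the core, a constituent embedded or encapsulated), and every
  measurement is a data node with its conditions as factor values.
* **N-Triples** — an experimental minimal triple dump over a small fixed
  vocabulary; full semantic mapping is out of scope.

Identical records serialize to byte-identical output.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Any, Optional, Union

from .model import (
    AnnotatedTerm,
    AnnotationTerm,
    Component,
    ComponentRole,
    Composition,
    EffectRecord,
    ExternalIdentifier,
    Linkage,
    ProtocolApplication,
    SubstanceRecord,
    Value,
)

__all__ = [
    "to_native_json",
    "from_native_json",
    "to_isa_json",
    "to_ntriples",
    "isa_extension_schema",
    "SerializationError",
]


class SerializationError(ValueError):
    """A document does not conform to the native JSON layout."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


# ---------------------------------------------------------------------------
# native JSON: writing

def _clean(obj: dict) -> dict:
    return {k: v for k, v in obj.items() if v is not None and v != [] and v != {}}


def _value_out(v: Value) -> dict:
    return _clean(
        {"number": v.number, "text": v.text, "unit": v.unit, "qualifier": v.qualifier}
    )


def _term_out(t: Union[str, AnnotatedTerm, None]) -> Any:
    if isinstance(t, AnnotatedTerm):
        return _clean(
            {
                "original": t.original,
                "canonical": t.canonical,
                "annotations": [
                    _clean({"vocabulary": a.vocabulary, "termId": a.term_id, "label": a.label})
                    for a in t.annotations
                ],
            }
        )
    return t


def _effect_out(e: EffectRecord) -> dict:
    return _clean(
        {
            "sampleID": e.sample_id,
            "endpoint": _term_out(e.endpoint),
            "endpointType": e.endpoint_type,
            "loQualifier": e.lo_qualifier,
            "loValue": e.lo_value,
            "upQualifier": e.up_qualifier,
            "upValue": e.up_value,
            "errQualifier": e.err_qualifier,
            "errValue": e.err_value,
            "textValue": e.text_value,
            "unit": _term_out(e.unit),
            "conditions": {k: _value_out(v) for k, v in e.conditions.items()},
        }
    )


def _pa_out(pa: ProtocolApplication) -> dict:
    return _clean(
        {
            "uuid": pa.uuid or None,
            "citationTitle": pa.citation_title,
            "citationYear": pa.citation_year,
            "citationOwner": pa.citation_owner,
            "protocolGuideline": list(pa.protocol_guideline),
            "interpretationResult": pa.interpretation_result,
            "interpretationCriteria": pa.interpretation_criteria,
            "parameters": {k: _value_out(v) for k, v in pa.parameters.items()},
            "effects": [_effect_out(e) for e in pa.effects],
            "investigationUUID": pa.investigation_uuid,
            "assayUUID": pa.assay_uuid,
            "reliabilityFlag": pa.reliability_flag,
        }
    )


def _component_out(c: Component) -> dict:
    return _clean(
        {
            "role": c.role.value,
            "name": c.name,
            "structure": c.structure,
            "properties": {k: _value_out(v) for k, v in c.properties.items()},
            "linkages": [{"target": l.target, "relation": l.relation} for l in c.linkages],
        }
    )


def _record_out(r: SubstanceRecord) -> dict:
    return _clean(
        {
            "substanceName": _term_out(r.substance_name),
            "publicName": r.public_name,
            "ownerName": r.owner_name,
            "ownerUUID": r.owner_uuid,
            "substanceUUID": r.substance_uuid or None,
            "substanceType": r.substance_type,
            "externalIdentifiers": [
                {"system": x.system, "value": x.value} for x in r.external_identifiers
            ],
            "composition": [
                _clean(
                    {
                        "compositionUUID": comp.composition_uuid or None,
                        "components": [_component_out(c) for c in comp.components],
                    }
                )
                for comp in r.compositions
            ],
            "protocolApplications": [_pa_out(pa) for pa in r.protocol_applications],
        }
    )


def to_native_json(records: list[SubstanceRecord], indent: Optional[int] = 2) -> str:
    """Lossless, deterministic JSON text for a list of substance records."""
    return json.dumps(
        [_record_out(r) for r in records], indent=indent, ensure_ascii=False
    )


# ---------------------------------------------------------------------------
# native JSON: reading

def _req(obj: dict, key: str, path: str) -> Any:
    if key not in obj:
        raise SerializationError(f"{path}.{key}", "missing required key")
    return obj[key]


def _expect(obj: Any, kind: type, path: str) -> Any:
    if not isinstance(obj, kind):
        raise SerializationError(path, f"expected {kind.__name__}, found {type(obj).__name__}")
    return obj


def _value_in(obj: Any, path: str) -> Value:
    _expect(obj, dict, path)
    try:
        return Value(
            number=obj.get("number"),
            text=obj.get("text"),
            unit=obj.get("unit"),
            qualifier=obj.get("qualifier"),
        )
    except ValueError as exc:
        raise SerializationError(path, str(exc)) from exc


def _term_in(obj: Any, path: str) -> Union[str, AnnotatedTerm, None]:
    if obj is None or isinstance(obj, str):
        return obj
    _expect(obj, dict, path)
    return AnnotatedTerm(
        original=_req(obj, "original", path),
        canonical=_req(obj, "canonical", path),
        annotations=[
            AnnotationTerm(
                vocabulary=_req(a, "vocabulary", f"{path}.annotations[{i}]"),
                term_id=_req(a, "termId", f"{path}.annotations[{i}]"),
                label=a.get("label"),
            )
            for i, a in enumerate(obj.get("annotations", []))
        ],
    )


def _effect_in(obj: Any, path: str) -> EffectRecord:
    _expect(obj, dict, path)
    try:
        return EffectRecord(
            sample_id=obj.get("sampleID"),
            endpoint=_term_in(obj.get("endpoint", ""), f"{path}.endpoint"),
            endpoint_type=obj.get("endpointType"),
            lo_qualifier=obj.get("loQualifier"),
            lo_value=obj.get("loValue"),
            up_qualifier=obj.get("upQualifier"),
            up_value=obj.get("upValue"),
            err_qualifier=obj.get("errQualifier"),
            err_value=obj.get("errValue"),
            text_value=obj.get("textValue"),
            unit=_term_in(obj.get("unit"), f"{path}.unit"),
            conditions={
                k: _value_in(v, f"{path}.conditions.{k}")
                for k, v in _expect(obj.get("conditions", {}), dict, f"{path}.conditions").items()
            },
        )
    except ValueError as exc:
        raise SerializationError(path, str(exc)) from exc


def _pa_in(obj: Any, path: str) -> ProtocolApplication:
    _expect(obj, dict, path)
    return ProtocolApplication(
        uuid=obj.get("uuid", ""),
        citation_title=obj.get("citationTitle"),
        citation_year=obj.get("citationYear"),
        citation_owner=obj.get("citationOwner"),
        protocol_guideline=list(obj.get("protocolGuideline", [])),
        interpretation_result=obj.get("interpretationResult"),
        interpretation_criteria=obj.get("interpretationCriteria"),
        parameters={
            k: _value_in(v, f"{path}.parameters.{k}")
            for k, v in _expect(obj.get("parameters", {}), dict, f"{path}.parameters").items()
        },
        effects=[
            _effect_in(e, f"{path}.effects[{i}]") for i, e in enumerate(obj.get("effects", []))
        ],
        investigation_uuid=obj.get("investigationUUID"),
        assay_uuid=obj.get("assayUUID"),
        reliability_flag=obj.get("reliabilityFlag"),
    )


def _component_in(obj: Any, path: str) -> Component:
    _expect(obj, dict, path)
    try:
        role = ComponentRole(_req(obj, "role", path))
    except ValueError as exc:
        raise SerializationError(f"{path}.role", str(exc)) from exc
    return Component(
        role=role,
        name=obj.get("name"),
        structure=obj.get("structure"),
        properties={
            k: _value_in(v, f"{path}.properties.{k}")
            for k, v in obj.get("properties", {}).items()
        },
        linkages=[
            Linkage(
                target=_req(l, "target", f"{path}.linkages[{i}]"),
                relation=_req(l, "relation", f"{path}.linkages[{i}]"),
            )
            for i, l in enumerate(obj.get("linkages", []))
        ],
    )


def _record_in(obj: Any, path: str) -> SubstanceRecord:
    _expect(obj, dict, path)
    try:
        return SubstanceRecord(
            substance_name=_term_in(obj.get("substanceName", ""), f"{path}.substanceName"),
            public_name=obj.get("publicName"),
            owner_name=obj.get("ownerName"),
            owner_uuid=obj.get("ownerUUID"),
            substance_uuid=obj.get("substanceUUID", ""),
            substance_type=obj.get("substanceType"),
            external_identifiers=[
                ExternalIdentifier(
                    system=_req(x, "system", f"{path}.externalIdentifiers[{i}]"),
                    value=_req(x, "value", f"{path}.externalIdentifiers[{i}]"),
                )
                for i, x in enumerate(obj.get("externalIdentifiers", []))
            ],
            compositions=[
                Composition(
                    composition_uuid=c.get("compositionUUID", ""),
                    components=[
                        _component_in(cm, f"{path}.composition[{i}].components[{j}]")
                        for j, cm in enumerate(_req(c, "components", f"{path}.composition[{i}]"))
                    ],
                )
                for i, c in enumerate(obj.get("composition", []))
            ],
            protocol_applications=[
                _pa_in(p, f"{path}.protocolApplications[{i}]")
                for i, p in enumerate(obj.get("protocolApplications", []))
            ],
        )
    except SerializationError:
        raise
    except ValueError as exc:
        raise SerializationError(path, str(exc)) from exc


def from_native_json(document: str) -> list[SubstanceRecord]:
    """Parse native JSON text back into records; inverse of
    :func:`to_native_json`.  Layout violations raise
    :class:`SerializationError` naming the JSON path."""
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise SerializationError("$", f"not valid JSON: {exc}") from exc
    _expect(doc, list, "$")
    return [_record_in(item, f"$[{i}]") for i, item in enumerate(doc)]


# ---------------------------------------------------------------------------
# ISA-JSON

_ROLE_LABELS = {
    ComponentRole.MAIN_CONSTITUENT: "main constituent",
    ComponentRole.IMPURITY: "impurity",
    ComponentRole.ADDITIVE: "additive",
    ComponentRole.CORE: "core",
    ComponentRole.COATING: "coating",
    ComponentRole.FUNCTIONALISATION: "functionalisation",
    ComponentRole.OTHER: "other",
}


def _plain(t: Union[str, AnnotatedTerm, None]) -> str:
    if isinstance(t, AnnotatedTerm):
        return t.canonical
    return t or ""


def isa_extension_schema() -> dict:
    """The bundled nanomaterial material-extension schema (JSON)."""
    text = resources.files("fairsheet.schemas").joinpath(
        "isa_nanomaterial_extension_schema.json"
    ).read_text(encoding="utf-8")
    return json.loads(text)


def _isa_material(record: SubstanceRecord) -> dict:
    components = []
    for comp in record.compositions:
        for i, c in enumerate(comp.components):
            entry: dict[str, Any] = {
                "@id": f"#component/{record.substance_uuid}/{len(components)}",
                "role": _ROLE_LABELS[c.role],
            }
            if c.name:
                entry["name"] = c.name
            if c.structure:
                entry["structure"] = c.structure
            if c.linkages:
                entry["linkages"] = [
                    {
                        "source": f"#component/{record.substance_uuid}/{len(components)}",
                        "target": f"#component/{record.substance_uuid}/"
                        f"{len(components) - i + l.target}",
                        "relation": l.relation,
                    }
                    for l in c.linkages
                ]
            components.append(entry)
    material: dict[str, Any] = {
        "@id": f"#material/{record.substance_uuid}",
        "name": _plain(record.substance_name),
        "type": "Source Name",
        "characteristics": [
            {
                "category": {"annotationValue": x.system},
                "value": {"annotationValue": x.value},
            }
            for x in record.external_identifiers
        ],
    }
    if record.substance_type:
        material["characteristics"].append(
            {
                "category": {"annotationValue": "substance type"},
                "value": {"annotationValue": record.substance_type},
            }
        )
    if components:
        material["components"] = components
    return material


def _isa_data_node(record: SubstanceRecord, pa: ProtocolApplication,
                   effect: EffectRecord, index: int) -> dict:
    result = _clean(
        {
            "loQualifier": effect.lo_qualifier,
            "loValue": effect.lo_value,
            "upQualifier": effect.up_qualifier,
            "upValue": effect.up_value,
            "errQualifier": effect.err_qualifier,
            "errValue": effect.err_value,
            "textValue": effect.text_value,
            "unit": _plain(effect.unit) or None,
        }
    )
    return {
        "@id": f"#data/{pa.uuid}/{index}",
        "name": _plain(effect.endpoint),
        "type": "Derived Data File",
        "result": result,
        "factorValues": [
            _clean(
                {
                    "category": {"annotationValue": name},
                    "value": (
                        {"annotationValue": v.text} if v.text is not None else v.number
                    ),
                    "unit": {"annotationValue": v.unit} if v.unit else None,
                }
            )
            for name, v in effect.conditions.items()
        ],
    }


def _assay_key(pa: ProtocolApplication) -> str:
    if pa.assay_uuid:
        return pa.assay_uuid
    endpoints = sorted({_plain(e.endpoint) for e in pa.effects})
    return "|".join(
        [pa.citation_title or "", *pa.protocol_guideline, *endpoints]
    ) or "default"


def to_isa_json(records: list[SubstanceRecord], indent: Optional[int] = 2) -> str:
    """ISA-JSON v1 skeleton for a list of substance records.

    One investigation; studies group protocol applications by investigation
    UUID (one default study otherwise); assays group by protocol identity;
    source materials carry nanomaterial components with roles and linkages;
    every measurement is reachable as a data node whose factor values are
    the measurement conditions.
    """
    studies_map: dict[str, dict] = {}
    for record in records:
        material = _isa_material(record)
        pas = record.protocol_applications or []
        for pa in pas:
            study_key = pa.investigation_uuid or "default"
            study = studies_map.setdefault(
                study_key,
                {
                    "identifier": study_key if study_key != "default" else "study-1",
                    "title": "",
                    "materials": {"sources": [], "samples": [], "otherMaterials": []},
                    "assays": {},
                    "protocols": [],
                },
            )
            if material["@id"] not in {m["@id"] for m in study["materials"]["sources"]}:
                study["materials"]["sources"].append(material)
            akey = _assay_key(pa)
            assay = study["assays"].setdefault(
                akey,
                {
                    "@id": f"#assay/{len(study['assays'])}",
                    "measurementType": {
                        "annotationValue": _plain(pa.effects[0].endpoint) if pa.effects else ""
                    },
                    "technologyType": {"annotationValue": pa.citation_title or ""},
                    "dataFiles": [],
                    "materials": {"samples": []},
                },
            )
            if material["@id"] not in {
                m["@id"] for m in assay["materials"]["samples"]
            }:
                assay["materials"]["samples"].append({"@id": material["@id"]})
            for i, effect in enumerate(pa.effects):
                assay["dataFiles"].append(
                    _isa_data_node(record, pa, effect, len(assay["dataFiles"]))
                )
            if pa.protocol_guideline:
                known = {p["name"] for p in study["protocols"]}
                for g in pa.protocol_guideline:
                    if g not in known:
                        study["protocols"].append(
                            {"@id": f"#protocol/{len(study['protocols'])}", "name": g}
                        )
                        known.add(g)
        if not pas:
            study = studies_map.setdefault(
                "default",
                {
                    "identifier": "study-1",
                    "title": "",
                    "materials": {"sources": [], "samples": [], "otherMaterials": []},
                    "assays": {},
                    "protocols": [],
                },
            )
            if material["@id"] not in {m["@id"] for m in study["materials"]["sources"]}:
                study["materials"]["sources"].append(material)

    studies = []
    for study in studies_map.values():
        study_out = dict(study)
        study_out["assays"] = list(study["assays"].values())
        studies.append(study_out)
    doc = {
        "investigation": {
            "@id": "#investigation/1",
            "identifier": "investigation-1",
            "studies": studies,
        }
    }
    return json.dumps(doc, indent=indent, ensure_ascii=False)


# ---------------------------------------------------------------------------
# N-Triples (experimental)

_VOCAB = "https://fairsheet.readthedocs.io/vocab#"


def to_ntriples(records: list[SubstanceRecord]) -> str:
    """Experimental minimal triple dump (N-Triples).

    Subjects are substance UUID URNs; predicates come from a small fixed
    vocabulary (name, external identifier, protocol application, endpoint,
    value).  No claim to a published semantic mapping is made.
    """
    from rdflib import Graph, Literal, Namespace, URIRef

    vocab = Namespace(_VOCAB)
    g = Graph()
    for record in records:
        subject = URIRef(f"urn:substance:{record.substance_uuid}")
        g.add((subject, vocab.substanceName, Literal(_plain(record.substance_name))))
        for x in record.external_identifiers:
            g.add((subject, vocab.externalIdentifier, Literal(f"{x.system}:{x.value}")))
        for pa in record.protocol_applications:
            pa_ref = URIRef(f"urn:protocolApplication:{pa.uuid}")
            g.add((subject, vocab.protocolApplication, pa_ref))
            for i, effect in enumerate(pa.effects):
                node = URIRef(f"urn:effect:{pa.uuid}:{i}")
                g.add((pa_ref, vocab.effect, node))
                g.add((node, vocab.endpoint, Literal(_plain(effect.endpoint))))
                if effect.lo_value is not None:
                    g.add((node, vocab.loValue, Literal(effect.lo_value)))
                if effect.unit:
                    g.add((node, vocab.unit, Literal(_plain(effect.unit))))
    lines = sorted(g.serialize(format="nt").splitlines())
    return "\n".join(line for line in lines if line.strip()) + "\n"
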