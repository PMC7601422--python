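"""Serialization: native JSON round-trip, ISA-JSON structure, determinism."""

import json
import random

import pytest

import fairsheet as fs
from fairsheet.config import validate_instance
from fairsheet.model import (
    Component,
    ComponentRole,
    Composition,
    EffectRecord,
    Linkage,
    ProtocolApplication,
    SubstanceRecord,
)
from fairsheet.serialize import (
    SerializationError,
    from_native_json,
    isa_extension_schema,
    to_isa_json,
    to_native_json,
    to_ntriples,
)


class TestNativeJson:
    def test_empty_list(self):
        assert to_native_json([], indent=None) == "[]"
        assert from_native_json("[]") == []

    def test_fixture_round_trip(self, row_bundle, block_bundle):
        for bundle in (row_bundle, block_bundle):
            records = bundle.expected
            assert from_native_json(to_native_json(records)) == records

    def test_randomized_round_trip(self):
        from conftest import random_record

        rng = random.Random(99)
        records = [random_record(rng) for _ in range(40)]
        assert from_native_json(to_native_json(records)) == records

    def test_interval_value_key_layout(self):
        # the open-closed interval 3 < x <= 4
        record = SubstanceRecord(
            substance_name="NM-1",
            protocol_applications=[
                ProtocolApplication(
                    effects=[
                        EffectRecord(
                            endpoint="size",
                            lo_qualifier=">",
                            lo_value=3.0,
                            up_qualifier="<=",
                            up_value=4.0,
                        )
                    ]
                )
            ],
        )
        doc = json.loads(to_native_json([record]))
        effect = doc[0]["protocolApplications"][0]["effects"][0]
        assert effect["loQualifier"] == ">"
        assert effect["loValue"] == 3.0
        assert effect["upQualifier"] == "<="
        assert effect["upValue"] == 4.0

    def test_truncated_document_is_a_parse_error(self):
        with pytest.raises(SerializationError):
            from_native_json('[{"substanceName": "NM-1"')

    def test_layout_violation_names_the_path(self):
        bad = '[{"protocolApplications": [{"effects": [{"conditions": 3}]}]}]'
        with pytest.raises(SerializationError) as err:
            from_native_json(bad)
        assert "conditions" in str(err.value)

    def test_deterministic_bytes(self):
        from conftest import random_record

        records = [random_record(random.Random(5)) for _ in range(3)]
        again = [random_record(random.Random(5)) for _ in range(3)]
        assert to_native_json(records).encode() == to_native_json(again).encode()


def _nano_record() -> SubstanceRecord:
    return fs.model.assign_uuids(
        SubstanceRecord(
            substance_name="NM-coated",
            compositions=[
                Composition(
                    composition_uuid="",
                    components=[
                        Component(role=ComponentRole.CORE, name="SiO2"),
                        Component(
                            role=ComponentRole.COATING,
                            name="PEG",
                            linkages=[Linkage(target=0, relation="covalently bonded")],
                        ),
                    ],
                )
            ],
            protocol_applications=[
                ProtocolApplication(
                    effects=[EffectRecord(endpoint="viability", lo_value=87.0, unit="%")]
                )
            ],
        )
    )


class TestIsaJson:
    def test_minimal_cardinality(self):
        doc = json.loads(to_isa_json([_nano_record()]))
        studies = doc["investigation"]["studies"]
        assert len(studies) == 1
        assert len(studies[0]["assays"]) == 1
        assert len(studies[0]["materials"]["sources"]) == 1

    def test_linkage_object_present_with_both_endpoints(self):
        doc = json.loads(to_isa_json([_nano_record()]))
        material = doc["investigation"]["studies"][0]["materials"]["sources"][0]
        coating = material["components"][1]
        link = coating["linkages"][0]
        assert link["relation"] == "covalently bonded"
        assert link["source"] == coating["@id"]
        assert link["target"] == material["components"][0]["@id"]

    def test_empty_input_yields_valid_empty_investigation(self):
        doc = json.loads(to_isa_json([]))
        assert doc["investigation"]["studies"] == []

    def test_materials_validate_against_bundled_extension_schema(self, block_bundle):
        schema = isa_extension_schema()
        records = [_nano_record(), *block_bundle.expected]
        doc = json.loads(to_isa_json(records))
        materials = [
            m
            for study in doc["investigation"]["studies"]
            for m in study["materials"]["sources"]
        ]
        assert materials
        for material in materials:
            assert validate_instance(material, schema) == []

    def test_effects_reachable_as_data_nodes_with_factor_values(self, block_bundle):
        doc = json.loads(to_isa_json(block_bundle.expected))
        assay = doc["investigation"]["studies"][0]["assays"][0]
        assert len(assay["dataFiles"]) == 36
        categories = {
            fv["category"]["annotationValue"]
            for node in assay["dataFiles"]
            for fv in node["factorValues"]
        }
        assert categories == {"replicate", "time", "concentration"}

    def test_studies_group_by_investigation_uuid(self):
        a = _nano_record()
        b = _nano_record()
        b.substance_name = "NM-other"
        b.substance_uuid = ""
        fs.model.assign_uuids(b)
        a.protocol_applications[0].investigation_uuid = "INV-1"
        b.protocol_applications[0].investigation_uuid = "INV-2"
        doc = json.loads(to_isa_json([a, b]))
        identifiers = {s["identifier"] for s in doc["investigation"]["studies"]}
        assert identifiers == {"INV-1", "INV-2"}


class TestNTriples:
    def test_minimal_dump_is_deterministic_and_typed(self):
        record = _nano_record()
        nt = to_ntriples([record])
        assert nt == to_ntriples([record])
        assert f"urn:substance:{record.substance_uuid}" in nt
        assert "substanceName" in nt and "NM-coated" in nt
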