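"""Data-model invariants: deterministic identifiers and fragment merging."""

import random
import uuid

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fairsheet.model import (
    Component,
    ComponentRole,
    Composition,
    EffectRecord,
    ExternalIdentifier,
    Linkage,
    MergeConflictError,
    SubstanceRecord,
    Value,
    assign_uuids,
    generate_uuid,
    merge_records,
)


class TestGenerateUuid:
    def test_deterministic(self):
        assert generate_uuid("XLSX", ["NM-100", "ProjectA"]) == generate_uuid(
            "XLSX", ["NM-100", "ProjectA"]
        )

    def test_distinct_inputs_distinct_outputs(self):
        assert generate_uuid("XLSX", ["NM-100"]) != generate_uuid("XLSX", ["NM-101"])

    def test_namespace_tags_prevent_cross_entity_collisions(self):
        a = generate_uuid("SUBSTANCE", ["NM-100"])
        b = generate_uuid("PA", ["NM-100"])
        assert a.split("-", 1)[1] != b.split("-", 1)[1]

    def test_reference_digest(self):
        # frozen from an independent one-line computation:
        # uuid.uuid5(uuid.NAMESPACE_URL, "XLSX|NM-100")
        assert generate_uuid("XLSX", ["NM-100"]) == (
            "XLSX-ef92a33a-c78d-5920-9adf-596b75e399f7"
        )
        assert generate_uuid("XLSX", ["NM-100"]) == "XLSX-" + str(
            uuid.uuid5(uuid.NAMESPACE_URL, "XLSX|NM-100")
        )

    def test_empty_fields_rejected(self):
        with pytest.raises(ValueError):
            generate_uuid("XLSX", [])

    @given(st.lists(st.text(min_size=1), min_size=1, max_size=4))
    def test_stable_and_tag_prefixed(self, fields):
        out = generate_uuid("TAG", fields)
        assert out.startswith("TAG-")
        assert out == generate_uuid("TAG", fields)

    def test_regenerating_uuids_reproduces_them(self):
        rng = random.Random(5)
        from conftest import random_record

        record = random_record(rng)
        stripped = record.model_copy(deep=True)
        stripped.substance_uuid = ""
        for pa in stripped.protocol_applications:
            pa.uuid = ""
        assert assign_uuids(stripped) == record


def _fragment(name="NM-100", **kw) -> SubstanceRecord:
    return assign_uuids(SubstanceRecord(substance_name=name, **kw))


class TestMergeRecords:
    def test_union_semantics(self):
        with_id = _fragment(
            external_identifiers=[ExternalIdentifier(system="CASRN", value="1")]
        )
        from fairsheet.model import ProtocolApplication

        with_effects = _fragment(
            protocol_applications=[
                ProtocolApplication(
                    effects=[EffectRecord(endpoint="e", lo_value=float(i)) for i in range(3)]
                )
            ]
        )
        with_effects = assign_uuids(with_effects)
        merged = merge_records([with_id, with_effects])
        assert len(merged) == 1
        assert merged[0].external_identifiers == with_id.external_identifiers
        assert len(merged[0].protocol_applications[0].effects) == 3

    def test_disjoint_uuids_identity(self):
        records = [_fragment("NM-100"), _fragment("NM-101"), _fragment("NM-102")]
        assert merge_records(records) == records

    def test_conflicting_names_raise_listing_both(self):
        a = _fragment("NM100")
        b = _fragment("NM-200")
        b.substance_uuid = a.substance_uuid
        with pytest.raises(MergeConflictError) as err:
            merge_records([a, b])
        assert "NM100" in str(err.value) and "NM-200" in str(err.value)

    def test_idempotent(self):
        records = [
            _fragment("NM-100"),
            _fragment("NM-100"),
            _fragment("NM-101"),
        ]
        once = merge_records(records)
        assert merge_records(once) == once


class TestInvariants:
    def test_value_number_xor_text(self):
        with pytest.raises(ValueError):
            Value()
        with pytest.raises(ValueError):
            Value(number=1.0, text="x")

    def test_duplicate_external_identifiers_rejected(self):
        dup = ExternalIdentifier(system="CASRN", value="1")
        with pytest.raises(ValueError):
            SubstanceRecord(substance_name="x", external_identifiers=[dup, dup])

    def test_blank_external_identifier_rejected(self):
        with pytest.raises(ValueError):
            ExternalIdentifier(system=" ", value="1")

    def test_linkage_targets_must_exist(self):
        core = Component(role=ComponentRole.CORE)
        bad = Component(
            role=ComponentRole.COATING,
            linkages=[Linkage(target=5, relation="covalently bonded")],
        )
        with pytest.raises(ValueError):
            Composition(composition_uuid="c", components=[core, bad])

    def test_composition_needs_components(self):
        with pytest.raises(ValueError):
            Composition(composition_uuid="c", components=[])

    def test_effect_qualifier_vocabulary(self):
        with pytest.raises(ValueError):
            EffectRecord(endpoint="e", lo_qualifier="<<", lo_value=1.0)
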