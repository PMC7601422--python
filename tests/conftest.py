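"""Shared fixtures: synthetic workbooks and randomized records.

All test inputs are generated programmatically; nothing binary is stored.
"""

from __future__ import annotations

import random

import pytest
from hypothesis import settings

import fairsheet as fs
from fairsheet.model import (
    EffectRecord,
    ExternalIdentifier,
    ProtocolApplication,
    SubstanceRecord,
    Value,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def row_bundle() -> fs.FixtureBundle:
    return fs.generate_fixture(fs.TemplateSpec(layout="ROW_LAYOUT", seed=20))


@pytest.fixture(scope="session")
def block_bundle() -> fs.FixtureBundle:
    """CFE-style dose-response block: 2 replicates x 2 timings x 9 concentrations."""
    return fs.generate_fixture(fs.TemplateSpec(layout="BLOCK_LAYOUT", seed=20))


@pytest.fixture(scope="session")
def sparse_row_bundle() -> fs.FixtureBundle:
    return fs.generate_fixture(
        fs.TemplateSpec(layout="ROW_LAYOUT", seed=21, n_substances=6, absent_probability=0.4)
    )


def all_bundles() -> list[fs.FixtureBundle]:
    """Every bundled fixture family, for pipeline-wide checks."""
    return [
        fs.generate_fixture(fs.TemplateSpec(layout="ROW_LAYOUT", seed=20)),
        fs.generate_fixture(fs.TemplateSpec(layout="BLOCK_LAYOUT", seed=20)),
        fs.generate_fixture(
            fs.TemplateSpec(
                layout="BLOCK_LAYOUT",
                seed=22,
                block=fs.BlockGeometry(replicates=3, times=2, concentrations=4,
                                       absent_probability=0.2),
            )
        ),
    ]


# ---------------------------------------------------------------------------
# Randomized records (independent of the parsing pipeline)

_WORDS = ("alpha", "beta", "gamma", "delta", "zeta", "kappa", "sigma", "omega")
_UNITS = ("mV", "nm", "%", "ug/mL", None)
_QUALIFIERS = ("=", "<", "<=", ">", ">=", "~", None)


def _rand_value(rng: random.Random) -> Value:
    if rng.random() < 0.5:
        return Value(number=round(rng.uniform(-100, 100), 4), unit=rng.choice(_UNITS))
    return Value(text=rng.choice(_WORDS), unit=rng.choice(_UNITS))


def _rand_effect(rng: random.Random) -> EffectRecord:
    effect = EffectRecord(
        endpoint=rng.choice(_WORDS),
        endpoint_type=rng.choice((None, "P-CHEM", "TOX")),
        unit=rng.choice(_UNITS),
    )
    form = rng.randrange(3)
    if form == 0:
        effect.lo_qualifier = "="
        effect.lo_value = round(rng.uniform(0, 50), 3)
    elif form == 1:
        effect.lo_qualifier = ">"
        effect.lo_value = round(rng.uniform(0, 5), 3)
        effect.up_qualifier = "<="
        effect.up_value = effect.lo_value + round(rng.uniform(0.1, 5), 3)
    else:
        effect.text_value = rng.choice(_WORDS)
    if rng.random() < 0.3:
        effect.err_qualifier = "SD"
        effect.err_value = round(rng.uniform(0, 2), 3)
    for _ in range(rng.randrange(3)):
        effect.conditions[rng.choice(("concentration", "time", "replicate", "pH"))] = (
            _rand_value(rng)
        )
    return effect


def random_record(rng: random.Random) -> SubstanceRecord:
    """A structurally varied, always-valid substance record."""
    name = f"NM-{rng.randrange(100, 999)}"
    record = SubstanceRecord(
        substance_name=name,
        public_name=rng.choice((None, rng.choice(_WORDS))),
        owner_name=rng.choice((None, "Lab A", "Lab B")),
        substance_type=rng.choice((None, "nanomaterial")),
    )
    used: set[tuple[str, str]] = set()
    for _ in range(rng.randrange(3)):
        pair = (rng.choice(("CASRN", "EC", "JRC")), f"{rng.randrange(10**6)}")
        if pair not in used:
            used.add(pair)
            record.external_identifiers = [
                *record.external_identifiers,
                ExternalIdentifier(system=pair[0], value=pair[1]),
            ]
    for _ in range(rng.randrange(1, 3)):
        pa = ProtocolApplication(
            citation_title=rng.choice((None, "assay run")),
            citation_year=rng.choice((None, "2019")),
            protocol_guideline=rng.sample(("OECD 318", "ISO 13099"), rng.randrange(2)),
            effects=[_rand_effect(rng) for _ in range(rng.randrange(4))],
        )
        for _ in range(rng.randrange(2)):
            pa.parameters[rng.choice(("cell type", "medium", "instrument"))] = _rand_value(rng)
        record.protocol_applications = [*record.protocol_applications, pa]
    return fs.model.assign_uuids(record)
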