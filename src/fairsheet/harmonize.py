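"""Post-parse metadata harmonization.

Lab spreadsheets written by hundreds of organisations use wildly varying
spellings for the same entity — "BEAS 2B", "Beas 2B" and "BEAS -2B" are one
cell line.  Harmonization is applied *after* import and is deliberately
minimal: a dictionary lookup normalizes spelling/case/abbreviation variants
and attaches zero or more controlled-vocabulary annotation terms, while the
original text is always retained verbatim so curators can inspect and
re-annotate later.  Terms missing from the dictionary pass through
unchanged and are listed in a miss report for curator review; no
edit-distance "spell checking" is applied unattended, but near misses
(edit distance 1) are flagged in the report.

Dictionary files are curator-editable UTF-8 JSON::

    {"entries": {"zeta potential": "zeta potential", "zetapotential": ...},
     "annotations": {"zeta potential": [
         {"vocabulary": "NPO", "term_id": "NPO_1302", "label": "zeta potential"}]}}

Keys of ``entries`` are matched after :func:`normalize_key`; canonical terms
must be fixed points of the lookup so harmonization is idempotent.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Optional, Union

from .model import (
    AnnotatedTerm,
    AnnotationTerm,
    EffectRecord,
    SubstanceRecord,
    Value,
)

__all__ = [
    "Dictionary",
    "HarmonizationReport",
    "normalize_key",
    "harmonize_record",
    "load_dictionary",
]

_STRIP = re.compile(r"[ \t\n\r_./-]+")


def normalize_key(raw: str) -> str:
    """Deterministic lookup key: NFKC + casefold, separators collapsed away.

    Spaces, hyphens, underscores, dots and slashes are removed entirely so
    "BEAS 2B", "Beas 2B" and "BEAS -2B" all collapse to ``beas2b``.
    Aggressive stemming or edit-distance matching is intentionally not done.
    """
    text = unicodedata.normalize("NFKC", raw).casefold()
    return _STRIP.sub("", text).strip()


@dataclass
class Dictionary:
    """A lookup table for one field class (endpoints, cell types, ...)."""

    entries: dict[str, str] = field(default_factory=dict)  # normalized key -> canonical
    annotations: dict[str, list[AnnotationTerm]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fixed = {}
        for key, canonical in self.entries.items():
            fixed[normalize_key(key)] = canonical
        self.entries = fixed
        # canonical terms must be fixed points of the lookup
        for canonical in list(self.entries.values()):
            self.entries.setdefault(normalize_key(canonical), canonical)

    def lookup(self, raw: str) -> Optional[str]:
        return self.entries.get(normalize_key(raw))

    def annotate(self, canonical: str) -> list[AnnotationTerm]:
        return list(self.annotations.get(canonical, []))


def load_dictionary(source) -> Dictionary:
    """Load a dictionary from a JSON file path, file object or dict."""
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source, encoding="utf-8") as fh:
            doc = json.load(fh)
    annotations = {
        canonical: [AnnotationTerm(**term) for term in terms]
        for canonical, terms in doc.get("annotations", {}).items()
    }
    return Dictionary(entries=dict(doc.get("entries", {})), annotations=annotations)


@dataclass
class HarmonizationReport:
    """Terms the dictionaries did not cover, for curator review."""

    misses: list[tuple[str, str]] = field(default_factory=list)  # (field class, original)
    near_misses: list[tuple[str, str, str]] = field(default_factory=list)

    def as_tsv(self) -> str:
        lines = ["field_class\toriginal\tnearest"]
        near = {(fc, orig): cand for fc, orig, cand in self.near_misses}
        for fc, orig in self.misses:
            lines.append(f"{fc}\t{orig}\t{near.get((fc, orig), '')}")
        return "\n".join(lines) + "\n"


def _edit1(a: str, b: str) -> bool:
    """True when the normalized keys differ by at most one edit."""
    if abs(len(a) - len(b)) > 1:
        return False
    if len(a) > len(b):
        a, b = b, a
    i = j = edits = 0
    while i < len(a) and j < len(b):
        if a[i] == b[j]:
            i += 1
            j += 1
            continue
        edits += 1
        if edits > 1:
            return False
        if len(a) == len(b):
            i += 1
        j += 1
    return edits + (len(b) - j) <= 1


def _harmonize_text(
    value: Union[str, AnnotatedTerm, None],
    field_class: str,
    dictionaries: dict[str, Dictionary],
    report: HarmonizationReport,
) -> Union[str, AnnotatedTerm, None]:
    if value is None:
        return None
    dictionary = dictionaries.get(field_class)
    if dictionary is None:
        return value
    original = value.original if isinstance(value, AnnotatedTerm) else value
    canonical = dictionary.lookup(original)
    if canonical is None:
        report.misses.append((field_class, original))
        key = normalize_key(original)
        for cand_key, cand in dictionary.entries.items():
            if _edit1(key, cand_key):
                report.near_misses.append((field_class, original, cand))
                break
        return value
    return AnnotatedTerm(
        original=original, canonical=canonical, annotations=dictionary.annotate(canonical)
    )


def _harmonize_condition(
    name: str,
    value: Value,
    dictionaries: dict[str, Dictionary],
    report: HarmonizationReport,
) -> Value:
    # text-valued conditions may carry a per-name dictionary ("condition:cell type")
    field_class = f"condition:{normalize_key(name)}"
    if value.text is None or field_class not in dictionaries:
        return value
    out = _harmonize_text(value.text, field_class, dictionaries, report)
    if isinstance(out, AnnotatedTerm):
        return Value(text=out.canonical, unit=value.unit, qualifier=value.qualifier)
    return value


def harmonize_record(
    record: SubstanceRecord,
    dictionaries: dict[str, Dictionary],
    report: Optional[HarmonizationReport] = None,
) -> SubstanceRecord:
    """Dictionary lookup over a record's targeted text fields.

    ``dictionaries`` maps a field class to its lookup table; recognized
    classes are ``"substance_name"``, ``"endpoint"``, ``"unit"`` and
    ``"condition:<normalized name>"`` for text-valued experimental
    conditions.  Matched fields become :class:`AnnotatedTerm` (original kept
    verbatim); unmatched terms pass through and are listed in the report.
    The input record is not mutated.  Idempotent: canonical terms are fixed
    points, so a second pass is a no-op.
    """
    report = report if report is not None else HarmonizationReport()
    out = record.model_copy(deep=True)
    out.substance_name = _harmonize_text(
        out.substance_name, "substance_name", dictionaries, report
    )
    for pa in out.protocol_applications:
        new_effects: list[EffectRecord] = []
        for effect in pa.effects:
            eff = effect.model_copy(deep=True)
            eff.endpoint = _harmonize_text(eff.endpoint, "endpoint", dictionaries, report)
            eff.unit = _harmonize_text(eff.unit, "unit", dictionaries, report)
            eff.conditions = {
                name: _harmonize_condition(name, value, dictionaries, report)
                for name, value in eff.conditions.items()
            }
            new_effects.append(eff)
        pa.effects = new_effects
    return out
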