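"""Guideline knowledge base: the gold standard for clinical-pathway triage.

A :class:`KnowledgeBase` holds symptom and finding definitions plus pathway
templates, each template carrying an urgency disposition — ``REFERRAL`` or
``TREATABLE``.  Templates act as the *exit criterion*: a candidate pathway is
valid only if it matches a template, otherwise it is ``NOT_CLASSIFIED``.

The on-disk format is a small JSON dialect (see :data:`FORMAT_VERSION`):

.. code-block:: json

    {"format_version": "1", "version": "demo-guidelines-1.0",
     "symptoms": [{"id": "fever", "name": "Fever", "dominant": true,
                   "value_kind": "binary"}],
     "findings": [{"id": "anaemia", "name": "Anaemia"}],
     "templates": [{"id": "cp1", "symptoms": ["fever"], "findings": [],
                    "urgency": "R"}]}

Numeric symptoms (blood-pressure style inputs) carry a ``threshold`` and a
comparison ``direction`` and are binarized at measurement time.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

from .errors import FormatError, ReferentialIntegrityError, UnknownIdError

FORMAT_VERSION = "1"

_ID_RE = re.compile(r"^[a-z0-9_]+$")


class Urgency(str, Enum):
    """Triage disposition of a pathway.

    ``NOT_CLASSIFIED`` is never attached to a guideline template; it marks a
    queried pathway that matches no template.
    """

    REFERRAL = "R"
    TREATABLE = "T"
    NOT_CLASSIFIED = "NC"

    @property
    def color(self) -> str:
        return {"R": "red", "T": "green", "NC": "grey"}[self.value]


@dataclass(frozen=True)
class SymptomDef:
    id: str
    name: str
    dominant: bool = False
    value_kind: str = "binary"  # "binary" | "numeric"
    threshold: Optional[float] = None
    direction: str = ">="  # numeric kind: positive when value <direction> threshold

    def __post_init__(self) -> None:
        _check_id(self.id, "symptom")
        if self.value_kind not in ("binary", "numeric"):
            raise FormatError(
                f"value_kind must be 'binary' or 'numeric', got {self.value_kind!r}",
                path=f"symptoms[{self.id}].value_kind",
            )
        if self.value_kind == "numeric":
            if self.threshold is None or not _finite(self.threshold):
                raise FormatError(
                    "numeric symptom requires a finite threshold",
                    path=f"symptoms[{self.id}].threshold",
                )
            if self.direction not in (">=", "<=", ">", "<"):
                raise FormatError(
                    f"direction must be one of >=, <=, >, <; got {self.direction!r}",
                    path=f"symptoms[{self.id}].direction",
                )

    def binarize(self, value) -> bool:
        """Map a measured value to presence/absence."""
        if self.value_kind == "binary":
            return bool(value)
        v = float(value)
        t = float(self.threshold)
        return {
            ">=": v >= t,
            "<=": v <= t,
            ">": v > t,
            "<": v < t,
        }[self.direction]


@dataclass(frozen=True)
class FindingDef:
    id: str
    name: str

    def __post_init__(self) -> None:
        _check_id(self.id, "finding")


@dataclass(frozen=True)
class PathwayTemplate:
    """A guideline clinical pathway: symptoms (+ findings) -> urgency."""

    id: str
    symptom_ids: tuple[str, ...]
    finding_ids: tuple[str, ...] = ()
    urgency: Urgency = Urgency.TREATABLE
    source_tag: str = ""

    def __post_init__(self) -> None:
        _check_id(self.id, "template")
        object.__setattr__(self, "symptom_ids", tuple(self.symptom_ids))
        object.__setattr__(self, "finding_ids", tuple(self.finding_ids))
        if not self.symptom_ids:
            raise FormatError(
                "template symptom list must be non-empty",
                path=f"templates[{self.id}].symptoms",
            )
        if self.urgency not in (Urgency.REFERRAL, Urgency.TREATABLE):
            raise FormatError(
                "template urgency must be REFERRAL or TREATABLE",
                path=f"templates[{self.id}].urgency",
            )

    @property
    def symptom_set(self) -> frozenset[str]:
        return frozenset(self.symptom_ids)

    @property
    def finding_set(self) -> frozenset[str]:
        return frozenset(self.finding_ids)


@dataclass
class KnowledgeBase:
    """Validated set of symptoms, findings and pathway templates."""

    version: str
    symptoms: dict[str, SymptomDef] = field(default_factory=dict)
    findings: dict[str, FindingDef] = field(default_factory=dict)
    templates: dict[str, PathwayTemplate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        unresolved = []
        seen_pairs: dict[tuple[frozenset, frozenset], str] = {}
        for t in self.templates.values():
            for s in t.symptom_ids:
                if s not in self.symptoms:
                    unresolved.append(s)
            for f in t.finding_ids:
                if f not in self.findings:
                    unresolved.append(f)
            key = (t.symptom_set, t.finding_set)
            if key in seen_pairs:
                raise FormatError(
                    f"duplicate (symptoms, findings) pair with template "
                    f"{seen_pairs[key]!r}",
                    path=f"templates[{t.id}]",
                )
            seen_pairs[key] = t.id
        if unresolved:
            raise ReferentialIntegrityError(
                f"unresolved ids: {sorted(set(unresolved))}",
                unresolved=sorted(set(unresolved)),
                path="templates",
            )

    def coverage_warnings(self) -> list[str]:
        """Soft checks for a production triage KB (not load failures)."""
        warnings = []
        present = {t.urgency for t in self.templates.values()}
        for u in (Urgency.REFERRAL, Urgency.TREATABLE):
            if u not in present:
                warnings.append(f"no template with urgency {u.name}")
        if not any(s.dominant for s in self.symptoms.values()):
            warnings.append("no dominant symptom flagged")
        return warnings

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "version": self.version,
            "symptoms": [
                {
                    "id": s.id,
                    "name": s.name,
                    "dominant": s.dominant,
                    "value_kind": s.value_kind,
                    **(
                        {"threshold": s.threshold, "direction": s.direction}
                        if s.value_kind == "numeric"
                        else {}
                    ),
                }
                for s in self.symptoms.values()
            ],
            "findings": [{"id": f.id, "name": f.name} for f in self.findings.values()],
            "templates": [
                {
                    "id": t.id,
                    "symptoms": list(t.symptom_ids),
                    "findings": list(t.finding_ids),
                    "urgency": t.urgency.value,
                    **({"source_tag": t.source_tag} if t.source_tag else {}),
                }
                for t in self.templates.values()
            ],
        }

    def __eq__(self, other) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return (
            self.version == other.version
            and self.symptoms == other.symptoms
            and self.findings == other.findings
            and self.templates == other.templates
        )


def _finite(x) -> bool:
    try:
        return abs(float(x)) < float("inf")
    except (TypeError, ValueError):
        return False


def _check_id(ident: str, kind: str) -> None:
    if not isinstance(ident, str) or not _ID_RE.match(ident):
        raise FormatError(
            f"{kind} id must match [a-z0-9_]+, got {ident!r}", path=f"{kind}.id"
        )


def _require(doc: Mapping, key: str, path: str):
    if key not in doc:
        raise FormatError(f"missing required key {key!r}", path=path)
    return doc[key]


Source = Union[str, Path, IO[str], Mapping]


def load_knowledge_base(source: Source) -> KnowledgeBase:
    """Load and validate a knowledge base from the JSON dialect.

    ``source`` may be a path, an open text stream, a JSON string, or an
    already-parsed mapping.  Loading is lossless: ``load(dump(kb)) == kb``.
    """
    doc = _read_document(source)
    if not isinstance(doc, Mapping):
        raise FormatError("top level must be a JSON object", path="$")
    fv = _require(doc, "format_version", "$")
    if str(fv) != FORMAT_VERSION:
        raise FormatError(
            f"unsupported format_version {fv!r} (expected {FORMAT_VERSION!r})",
            path="format_version",
        )
    version = str(_require(doc, "version", "$"))

    symptoms: dict[str, SymptomDef] = {}
    for i, raw in enumerate(_require(doc, "symptoms", "$")):
        path = f"symptoms[{i}]"
        s = SymptomDef(
            id=_require(raw, "id", path),
            name=str(_require(raw, "name", path)),
            dominant=bool(raw.get("dominant", False)),
            value_kind=raw.get("value_kind", "binary"),
            threshold=raw.get("threshold"),
            direction=raw.get("direction", ">="),
        )
        if s.id in symptoms:
            raise FormatError(f"duplicate symptom id {s.id!r}", path=path)
        symptoms[s.id] = s

    findings: dict[str, FindingDef] = {}
    for i, raw in enumerate(doc.get("findings", [])):
        path = f"findings[{i}]"
        f = FindingDef(id=_require(raw, "id", path), name=str(_require(raw, "name", path)))
        if f.id in findings:
            raise FormatError(f"duplicate finding id {f.id!r}", path=path)
        findings[f.id] = f

    templates: dict[str, PathwayTemplate] = {}
    for i, raw in enumerate(_require(doc, "templates", "$")):
        path = f"templates[{i}]"
        urgency_code = _require(raw, "urgency", path)
        try:
            urgency = Urgency(urgency_code)
        except ValueError:
            raise FormatError(
                f"urgency must be 'R' or 'T', got {urgency_code!r}", path=f"{path}.urgency"
            ) from None
        t = PathwayTemplate(
            id=_require(raw, "id", path),
            symptom_ids=tuple(_require(raw, "symptoms", path)),
            finding_ids=tuple(raw.get("findings", [])),
            urgency=urgency,
            source_tag=str(raw.get("source_tag", "")),
        )
        if t.id in templates:
            raise FormatError(f"duplicate template id {t.id!r}", path=path)
        templates[t.id] = t

    return KnowledgeBase(version=version, symptoms=symptoms, findings=findings, templates=templates)


def _read_document(source: Source):
    if isinstance(source, Mapping):
        return source
    if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("{")):
        with open(source, "r", encoding="utf-8") as fh:
            return json.load(fh)
    if isinstance(source, str):
        try:
            return json.loads(source)
        except json.JSONDecodeError as exc:
            raise FormatError(f"malformed JSON: {exc}", path="$") from exc
    try:
        return json.load(source)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed JSON: {exc}", path="$") from exc


def write_knowledge_base(kb: KnowledgeBase, target: Union[str, Path, IO[str]]) -> None:
    """Serialize ``kb`` to the JSON dialect (round-trip safe)."""
    doc = kb.to_dict()
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=False)
            fh.write("\n")
    else:
        json.dump(doc, target, indent=2, sort_keys=False)


def validate_pathway(
    kb: KnowledgeBase,
    symptom_ids: Sequence[str],
    finding_ids: Iterable[str] = (),
) -> tuple[Optional[str], Urgency]:
    """Apply the exit criterion: match a pathway against the guideline.

    A pathway matches a template when its symptom *set* equals the template's
    symptom set and its finding set is a superset of the template's findings
    (order is recorded elsewhere but not used for matching).  Returns the
    matching template id and its urgency, or ``(None, NOT_CLASSIFIED)``.
    """
    for s in symptom_ids:
        if s not in kb.symptoms:
            raise UnknownIdError("symptom", s)
    finding_ids = tuple(finding_ids)
    for f in finding_ids:
        if f not in kb.findings:
            raise UnknownIdError("finding", f)
    sset = frozenset(symptom_ids)
    fset = frozenset(finding_ids)
    if not sset:
        return None, Urgency.NOT_CLASSIFIED
    matches = [
        t
        for t in kb.templates.values()
        if t.symptom_set == sset and fset >= t.finding_set
    ]
    if not matches:
        return None, Urgency.NOT_CLASSIFIED
    # Superset finding semantics can match several templates even though
    # (symptoms, findings) pairs are unique; prefer the most specific one.
    best = min(matches, key=lambda t: (-len(t.finding_set), t.id))
    return best.id, best.urgency


def dominant_symptoms(kb: KnowledgeBase) -> list[SymptomDef]:
    """Symptoms flagged as dominant entry points, ordered by id."""
    return sorted((s for s in kb.symptoms.values() if s.dominant), key=lambda s: s.id)
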