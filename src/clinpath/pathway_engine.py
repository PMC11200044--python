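"""Interactive clinical-pathway processing: generate, rank, prune.

The engine consumes measured symptoms (MSs) one at a time.  After each MS the
candidate list contains exactly the guideline templates *consistent* with the
accumulated evidence:

* every positively measured symptom is contained in the template, and
* no negatively measured symptom is required by the template.

Each candidate keeps a frequency counter: the number of measured symptoms that
support it (it enters at 1 and is incremented whenever a newly measured
positive symptom is one of its own).  Ranking puts referral candidates first
(safety), then higher frequency, then template id for determinism.  Pruning
filters the ranked list and, when a filter empties it, walks an explicit
relaxation schedule instead of failing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import (
    DuplicateMeasurementError,
    ModeUnavailableError,
    ParameterError,
    UnknownIdError,
)
from .knowledge_base import KnowledgeBase, SymptomDef, Urgency, validate_pathway


@dataclass(frozen=True)
class MeasuredSymptom:
    """A symptom observation for the presented case.

    ``value`` is a bool for binary symptoms or a number for numeric ones
    (binarized through the symptom's threshold).
    """

    symptom_id: str
    value: object
    order_index: int = 0

    def positive(self, kb: KnowledgeBase) -> bool:
        if self.symptom_id not in kb.symptoms:
            raise UnknownIdError("symptom", self.symptom_id)
        return kb.symptoms[self.symptom_id].binarize(self.value)


@dataclass
class CandidatePathway:
    template_id: str
    symptom_ids: frozenset[str]
    finding_ids: frozenset[str]
    urgency: Urgency
    frequency: int = 1
    provenance: str = "GUIDELINE"


@dataclass
class PathwayWorkspace:
    """Mutable state of one triage session."""

    kb: KnowledgeBase
    measured: list[MeasuredSymptom] = field(default_factory=list)
    candidates: list[CandidatePathway] = field(default_factory=list)

    def positive_ids(self) -> set[str]:
        return {m.symptom_id for m in self.measured if m.positive(self.kb)}

    def negative_ids(self) -> set[str]:
        return {m.symptom_id for m in self.measured if not m.positive(self.kb)}

    def to_dict(self) -> dict:
        return {
            "kb_version": self.kb.version,
            "measured": [
                {"symptom_id": m.symptom_id, "value": m.value, "order_index": m.order_index}
                for m in self.measured
            ],
            "candidates": [
                {
                    "template_id": c.template_id,
                    "symptoms": sorted(c.symptom_ids),
                    "findings": sorted(c.finding_ids),
                    "urgency": c.urgency.value,
                    "frequency": c.frequency,
                    "provenance": c.provenance,
                }
                for c in self.candidates
            ],
        }


@dataclass(frozen=True)
class PruneConfig:
    """Pruning parameters; ``relaxation_steps`` are successively weaker."""

    min_frequency: int = 0
    urgency_filter: Optional[frozenset[Urgency]] = None
    required_findings: Optional[frozenset[str]] = None
    max_kept: Optional[int] = None
    relaxation_steps: tuple["PruneConfig", ...] = ()

    def __post_init__(self) -> None:
        if self.min_frequency < 0:
            raise ParameterError("min_frequency must be non-negative")
        if self.max_kept is not None and self.max_kept < 1:
            raise ParameterError("max_kept must be >= 1 when present")
        if self.urgency_filter is not None:
            object.__setattr__(self, "urgency_filter", frozenset(self.urgency_filter))
        if self.required_findings is not None:
            object.__setattr__(self, "required_findings", frozenset(self.required_findings))
        prev = self
        for step in self.relaxation_steps:
            if not _weaker_or_equal(prev, step):
                raise ParameterError(
                    "relaxation_steps must be successively weaker configs"
                )
            prev = step

    def weakest(self) -> "PruneConfig":
        return self.relaxation_steps[-1] if self.relaxation_steps else self


ALL_PERMISSIVE = PruneConfig()


def default_relaxation(cfg: PruneConfig) -> PruneConfig:
    """Attach a one-step fall-back to the all-permissive config."""
    if cfg.relaxation_steps:
        return cfg
    return replace(cfg, relaxation_steps=(ALL_PERMISSIVE,))


def _weaker_or_equal(strong: PruneConfig, weak: PruneConfig) -> bool:
    if weak.min_frequency > strong.min_frequency:
        return False
    if weak.urgency_filter is not None:
        if strong.urgency_filter is None or not weak.urgency_filter >= strong.urgency_filter:
            return False
    if weak.required_findings is not None:
        if strong.required_findings is None or not weak.required_findings <= strong.required_findings:
            return False
    if weak.max_kept is not None:
        if strong.max_kept is None or weak.max_kept < strong.max_kept:
            return False
    return True


@dataclass
class RankedPathwayList:
    entries: list[CandidatePathway]
    rank_labels: list[str]
    applied_config: Optional[PruneConfig] = None
    relaxation_exhausted: bool = False

    def __len__(self) -> int:
        return len(self.entries)


# ----------------------------------------------------------------- entry point


def select_entry_point(
    kb: KnowledgeBase,
    history=None,
    mode: str = "RANDOM",
    seed: Optional[int] = None,
) -> SymptomDef:
    """Choose the first symptom to probe.

    ``HISTORICAL`` uses the most frequent first-recorded symptom in the
    history store (ties by id); ``DOMINANT`` takes the first dominant symptom
    by id; ``RANDOM`` draws uniformly over KB symptoms under ``seed``.
    """
    mode = mode.upper()
    if mode == "HISTORICAL":
        firsts = [] if history is None else [
            r.first_symptom for r in history.records if r.first_symptom
        ]
        if not firsts:
            raise ModeUnavailableError(
                "no historical first-symptom evidence; fall back to RANDOM"
            )
        counts: dict[str, int] = {}
        for s in firsts:
            counts[s] = counts.get(s, 0) + 1
        best = min(counts, key=lambda s: (-counts[s], s))
        return kb.symptoms[best]
    if mode == "DOMINANT":
        dom = sorted((s for s in kb.symptoms.values() if s.dominant), key=lambda s: s.id)
        if not dom:
            raise ModeUnavailableError("no dominant symptom flagged; fall back to RANDOM")
        return dom[0]
    if mode == "RANDOM":
        if seed is None:
            raise ParameterError("RANDOM mode requires a seed for reproducibility")
        ids = sorted(kb.symptoms)
        rng = np.random.default_rng(seed)
        return kb.symptoms[ids[int(rng.integers(len(ids)))]]
    raise ParameterError(f"unknown entry-point mode {mode!r}")


# ----------------------------------------------------------------- generation


def new_workspace(kb: KnowledgeBase) -> PathwayWorkspace:
    return PathwayWorkspace(kb=kb)


def _consistent_templates(ws: PathwayWorkspace):
    """Templates compatible with all measured evidence (brute-force safe)."""
    pos = ws.positive_ids()
    neg = ws.negative_ids()
    if not pos:
        return []
    return [
        t
        for t in ws.kb.templates.values()
        if t.symptom_set >= pos and not (t.symptom_set & neg)
    ]


def step(ws: PathwayWorkspace, ms: MeasuredSymptom) -> PathwayWorkspace:
    """Record one measured symptom and refresh the candidate list in place.

    Retained candidates whose template contains the new positive symptom get
    their frequency incremented; newly consistent templates enter at 1.
    """
    if ms.symptom_id not in ws.kb.symptoms:
        raise UnknownIdError("symptom", ms.symptom_id)
    if any(m.symptom_id == ms.symptom_id for m in ws.measured):
        raise DuplicateMeasurementError(f"symptom {ms.symptom_id!r} already measured")
    ws.measured.append(ms)

    consistent = {t.id: t for t in _consistent_templates(ws)}
    positive = ms.positive(ws.kb)

    kept: list[CandidatePathway] = []
    seen: set[str] = set()
    for cand in ws.candidates:
        if cand.template_id in consistent:
            if positive and ms.symptom_id in cand.symptom_ids:
                cand.frequency += 1
            kept.append(cand)
            seen.add(cand.template_id)
    for tid in sorted(consistent):
        if tid in seen:
            continue
        t = consistent[tid]
        # exit criterion: every listed candidate is validated against the CGs
        matched_id, urgency = validate_pathway(ws.kb, t.symptom_ids, t.finding_ids)
        if matched_id is None:
            continue
        kept.append(
            CandidatePathway(
                template_id=matched_id,
                symptom_ids=t.symptom_set,
                finding_ids=t.finding_set,
                urgency=urgency,
                frequency=1,
            )
        )
    ws.candidates = kept
    return ws


def generate_candidates(ws: PathwayWorkspace, ms: MeasuredSymptom) -> PathwayWorkspace:
    """Process the *first* measured symptom (thin alias of :func:`step`)."""
    if ws.measured:
        raise DuplicateMeasurementError(
            "generate_candidates is for the first measured symptom; use step()"
        )
    return step(ws, ms)


# -------------------------------------------------------------------- ranking


_URGENCY_ORDER = {Urgency.REFERRAL: 0, Urgency.TREATABLE: 1, Urgency.NOT_CLASSIFIED: 2}


def rank_candidates(ws: PathwayWorkspace) -> RankedPathwayList:
    """Total-order ranking: urgency (referral first), frequency desc, id asc."""
    entries = sorted(
        ws.candidates,
        key=lambda c: (_URGENCY_ORDER[c.urgency], -c.frequency, c.template_id),
    )
    return RankedPathwayList(
        entries=entries, rank_labels=[c.urgency.color for c in entries]
    )


# -------------------------------------------------------------------- pruning


def _apply_filters(entries: Sequence[CandidatePathway], cfg: PruneConfig):
    out = [c for c in entries if c.frequency >= cfg.min_frequency]
    if cfg.urgency_filter is not None:
        out = [c for c in out if c.urgency in cfg.urgency_filter]
    if cfg.required_findings is not None:
        out = [c for c in out if c.finding_ids >= cfg.required_findings]
    if cfg.max_kept is not None:
        out = out[: cfg.max_kept]
    return out


def prune_candidates(ranked: RankedPathwayList, cfg: PruneConfig) -> RankedPathwayList:
    """Filter the ranked list; on empty result walk the relaxation schedule."""
    schedule = (cfg,) + tuple(cfg.relaxation_steps)
    result: list[CandidatePathway] = []
    applied = schedule[-1]
    exhausted = True
    for candidate_cfg in schedule:
        result = _apply_filters(ranked.entries, candidate_cfg)
        if result:
            applied = candidate_cfg
            exhausted = False
            break
    return RankedPathwayList(
        entries=result,
        rank_labels=[c.urgency.color for c in result],
        applied_config=applied,
        relaxation_exhausted=exhausted,
    )
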