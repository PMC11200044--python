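"""Shared fixtures: all test data are generated programmatically."""

import pandas as pd
import pytest

from clinpath.evidence_engine import HistoricalRecord, HistoryStore
from clinpath.knowledge_base import (
    FindingDef,
    KnowledgeBase,
    PathwayTemplate,
    SymptomDef,
    Urgency,
)


@pytest.fixture
def toy_kb() -> KnowledgeBase:
    """Small hand-built KB: 4 symptoms (one numeric), 2 findings, 5 templates."""
    symptoms = {
        "fever": SymptomDef(id="fever", name="Fever", dominant=True),
        "headache": SymptomDef(id="headache", name="Headache"),
        "bleeding": SymptomDef(id="bleeding", name="Vaginal bleeding", dominant=True),
        "bp": SymptomDef(
            id="bp",
            name="Systolic blood pressure",
            value_kind="numeric",
            threshold=140.0,
            direction=">=",
        ),
    }
    findings = {
        "anaemia": FindingDef(id="anaemia", name="Anaemia"),
        "proteinuria": FindingDef(id="proteinuria", name="Proteinuria"),
    }
    templates = {
        "cp1": PathwayTemplate(
            id="cp1", symptom_ids=("fever",), urgency=Urgency.TREATABLE
        ),
        "cp2": PathwayTemplate(
            id="cp2", symptom_ids=("fever", "headache"), urgency=Urgency.TREATABLE
        ),
        "cp3": PathwayTemplate(
            id="cp3", symptom_ids=("bleeding",), urgency=Urgency.REFERRAL
        ),
        "cp4": PathwayTemplate(
            id="cp4",
            symptom_ids=("bp", "headache"),
            finding_ids=("proteinuria",),
            urgency=Urgency.REFERRAL,
        ),
        "cp5": PathwayTemplate(
            id="cp5", symptom_ids=("fever", "bleeding"), urgency=Urgency.REFERRAL
        ),
    }
    return KnowledgeBase(
        version="demo-guidelines-1.0",
        symptoms=symptoms,
        findings=findings,
        templates=templates,
    )


@pytest.fixture
def toy_history(toy_kb) -> HistoryStore:
    """Six-record separable history: bleeding -> referral, fever -> treatable."""
    recs = []
    for i in range(3):
        recs.append(
            HistoricalRecord(
                record_id=f"r{i}",
                positive_symptoms=frozenset({"bleeding"}),
                findings=frozenset(),
                disposition=Urgency.REFERRAL,
                first_symptom="bleeding",
            )
        )
    for i in range(3, 6):
        recs.append(
            HistoricalRecord(
                record_id=f"r{i}",
                positive_symptoms=frozenset({"fever"}),
                findings=frozenset(),
                disposition=Urgency.TREATABLE,
                first_symptom="fever",
            )
        )
    return HistoryStore(records=recs, kb=toy_kb)


@pytest.fixture
def tiny_likert():
    """Hand-sized Likert dataset: 2 constructs x 2 items, 6 respondents."""
    from clinpath.likert_stats import LikertDataset

    scores = pd.DataFrame(
        {
            "q1": [4, 5, 3, 4, 5, 2],
            "q2": [4, 4, 3, 5, 5, 2],
            "q3": [2, 3, 4, 5, 3, 1],
            "q4": [1, 3, 5, 4, 3, 2],
        },
        index=pd.Index([f"r{i}" for i in range(6)], name="respondent_id"),
    )
    return LikertDataset(
        scores=scores,
        construct_map={"q1": "quality", "q2": "quality", "q3": "use", "q4": "use"},
        site=pd.Series(
            ["a", "a", "a", "b", "b", "b"], index=scores.index
        ),
        session=pd.Series(["1", "1", "2", "2", "2", "2"], index=scores.index),
    )
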