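"""Data-driven evidence: Bernoulli naive Bayes over historical records and
assembly of the concordance table.

Historical card-sheet records carry presence/absence of symptoms and a final
disposition (referral vs locally treatable).  A Laplace-smoothed Bernoulli
naive-Bayes model supplies class priors and per-symptom conditionals:

    prior(c)      = (n_c + a) / (n + 2a)
    P(s | c)      = (n_{s,c} + a) / (n_c + 2a)

with pseudo-count ``a > 0``.  Posteriors multiply presence *and* absence
factors over every KB symptom.  The "accuracy" attached to the concordance
table is leave-one-out accuracy on the history store, with prediction ties
resolved to REFERRAL (safety-first).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Union

from .errors import (
    FormatError,
    InsufficientDataError,
    ParameterError,
    UnknownIdError,
)
from .knowledge_base import KnowledgeBase, Urgency
from .pathway_engine import RankedPathwayList

CLASSES = (Urgency.REFERRAL, Urgency.TREATABLE)

#: Column order of the concordance table (fixed report contract).
CONCORDANCE_COLUMNS = (
    "symptoms",
    "findings",
    "urgency",
    "cp",
    "cp_frequency",
    "accuracy",
    "prior",
    "posterior",
)


@dataclass(frozen=True)
class HistoricalRecord:
    record_id: str
    positive_symptoms: frozenset[str]
    findings: frozenset[str]
    disposition: Urgency
    first_symptom: Optional[str] = None

    def __post_init__(self) -> None:
        if self.disposition not in CLASSES:
            raise FormatError(
                f"disposition must be R or T, got {self.disposition}",
                path=f"records[{self.record_id}].disposition",
            )


@dataclass
class HistoryStore:
    records: list[HistoricalRecord]
    kb: KnowledgeBase

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.record_id in seen:
                raise FormatError(f"duplicate record id {r.record_id!r}", path="records")
            seen.add(r.record_id)
            for s in r.positive_symptoms:
                if s not in self.kb.symptoms:
                    raise UnknownIdError("symptom", s)
            for f in r.findings:
                if f not in self.kb.findings:
                    raise UnknownIdError("finding", f)

    def __len__(self) -> int:
        return len(self.records)


def load_history_csv(source: Union[str, Path, IO[str]], kb: KnowledgeBase) -> HistoryStore:
    """Read the history dialect: ``record_id, symptoms, findings, disposition,
    first_symptom`` with semicolon-joined id lists."""
    close = False
    if isinstance(source, (str, Path)):
        fh = open(source, "r", encoding="utf-8", newline="")
        close = True
    else:
        fh = source
    try:
        reader = csv.DictReader(fh)
        required = {"record_id", "symptoms", "findings", "disposition", "first_symptom"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise FormatError(f"missing columns: {missing}", path="header")
        records = []
        for i, row in enumerate(reader):
            try:
                disposition = Urgency(row["disposition"].strip())
            except ValueError:
                raise FormatError(
                    f"disposition must be R or T, got {row['disposition']!r}",
                    path=f"row[{i}].disposition",
                ) from None
            records.append(
                HistoricalRecord(
                    record_id=row["record_id"].strip(),
                    positive_symptoms=frozenset(_split(row["symptoms"])),
                    findings=frozenset(_split(row["findings"])),
                    disposition=disposition,
                    first_symptom=row["first_symptom"].strip() or None,
                )
            )
    finally:
        if close:
            fh.close()
    return HistoryStore(records=records, kb=kb)


def write_history_csv(history: HistoryStore, target: Union[str, Path, IO[str]]) -> None:
    close = False
    if isinstance(target, (str, Path)):
        fh = open(target, "w", encoding="utf-8", newline="")
        close = True
    else:
        fh = target
    try:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "symptoms", "findings", "disposition", "first_symptom"])
        for r in history.records:
            writer.writerow(
                [
                    r.record_id,
                    ";".join(sorted(r.positive_symptoms)),
                    ";".join(sorted(r.findings)),
                    r.disposition.value,
                    r.first_symptom or "",
                ]
            )
    finally:
        if close:
            fh.close()


def _split(cell: str) -> list[str]:
    cell = cell.strip()
    return [tok for tok in cell.split(";") if tok] if cell else []


# ------------------------------------------------------------------ the model


@dataclass
class NaiveBayesModel:
    class_priors: dict[Urgency, float]
    cond_probs: dict[tuple[str, Urgency], float]
    smoothing: float
    n_train: int
    symptom_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        total = sum(self.class_priors.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"class priors must sum to 1, got {total}")


def fit_naive_bayes(history: HistoryStore, smoothing: float = 1.0) -> NaiveBayesModel:
    """Fit the smoothed Bernoulli model; deterministic in the store."""
    if smoothing <= 0:
        raise ParameterError("smoothing pseudo-count must be positive")
    n = len(history)
    if n == 0:
        raise InsufficientDataError("history store is empty")
    class_counts = {c: 0 for c in CLASSES}
    for r in history.records:
        class_counts[r.disposition] += 1
    priors = {c: (class_counts[c] + smoothing) / (n + 2 * smoothing) for c in CLASSES}
    symptom_ids = tuple(sorted(history.kb.symptoms))
    cond: dict[tuple[str, Urgency], float] = {}
    for c in CLASSES:
        present = {s: 0 for s in symptom_ids}
        for r in history.records:
            if r.disposition != c:
                continue
            for s in r.positive_symptoms:
                present[s] += 1
        denom = class_counts[c] + 2 * smoothing
        for s in symptom_ids:
            cond[(s, c)] = (present[s] + smoothing) / denom
    return NaiveBayesModel(
        class_priors=priors,
        cond_probs=cond,
        smoothing=smoothing,
        n_train=n,
        symptom_ids=symptom_ids,
    )


def posterior(model: NaiveBayesModel, positive_symptoms: Iterable[str]) -> dict[Urgency, float]:
    """P(class | symptom pattern), normalized over {REFERRAL, TREATABLE}.

    The likelihood includes absence factors for every KB symptom not listed
    as positive; computed in log space for numerical safety.
    """
    pos = set(positive_symptoms)
    unknown = pos - set(model.symptom_ids)
    if unknown:
        raise UnknownIdError("symptom", sorted(unknown)[0])
    logpost = {}
    for c in CLASSES:
        lp = math.log(model.class_priors[c])
        for s in model.symptom_ids:
            p = model.cond_probs[(s, c)]
            lp += math.log(p) if s in pos else math.log(1.0 - p)
        logpost[c] = lp
    m = max(logpost.values())
    unnorm = {c: math.exp(lp - m) for c, lp in logpost.items()}
    z = sum(unnorm.values())
    return {c: v / z for c, v in unnorm.items()}


def predict(model: NaiveBayesModel, positive_symptoms: Iterable[str]) -> Urgency:
    """Argmax posterior; ties resolved to REFERRAL (safety-first)."""
    post = posterior(model, positive_symptoms)
    if post[Urgency.REFERRAL] >= post[Urgency.TREATABLE]:
        return Urgency.REFERRAL
    return Urgency.TREATABLE


def estimate_accuracy(history: HistoryStore, smoothing: float = 1.0) -> float:
    """Leave-one-out accuracy of the naive-Bayes disposition prediction."""
    n = len(history)
    if n < 2:
        raise InsufficientDataError("leave-one-out accuracy needs >= 2 records")
    correct = 0
    for i in range(n):
        rest = HistoryStore(
            records=history.records[:i] + history.records[i + 1 :], kb=history.kb
        )
        model = fit_naive_bayes(rest, smoothing=smoothing)
        if predict(model, history.records[i].positive_symptoms) == history.records[i].disposition:
            correct += 1
    return correct / n


# ----------------------------------------------------------- concordance table


@dataclass
class EvidenceRow:
    symptoms: frozenset[str]
    findings: frozenset[str]
    urgency: Urgency
    cp: str
    cp_frequency: int
    accuracy: float
    prior: float
    posterior: float

    def as_record(self) -> dict:
        return {
            "symptoms": ";".join(sorted(self.symptoms)),
            "findings": ";".join(sorted(self.findings)),
            "urgency": self.urgency.value,
            "cp": self.cp,
            "cp_frequency": self.cp_frequency,
            "accuracy": self.accuracy,
            "prior": self.prior,
            "posterior": self.posterior,
        }


@dataclass
class ConcordanceTable:
    rows: list[EvidenceRow]
    model_meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def to_records(self) -> list[dict]:
        return [r.as_record() for r in self.rows]

    def to_csv(self, target: Union[str, Path, IO[str]]) -> None:
        close = False
        if isinstance(target, (str, Path)):
            fh = open(target, "w", encoding="utf-8", newline="")
            close = True
        else:
            fh = target
        try:
            writer = csv.DictWriter(fh, fieldnames=list(CONCORDANCE_COLUMNS))
            writer.writeheader()
            for rec in self.to_records():
                writer.writerow(rec)
        finally:
            if close:
                fh.close()

    def to_json(self, target: Union[str, Path, IO[str], None] = None) -> Optional[str]:
        doc = {"model_meta": self.model_meta, "rows": self.to_records()}
        text = json.dumps(doc, indent=2)
        if target is None:
            return text
        if isinstance(target, (str, Path)):
            Path(target).write_text(text + "\n", encoding="utf-8")
        else:
            target.write(text)
        return None


def build_concordance_table(
    pruned: RankedPathwayList,
    model: NaiveBayesModel,
    accuracy: float,
) -> ConcordanceTable:
    """One evidence row per pruned candidate, in ranked order.

    ``prior`` is the class prior of the row's urgency; ``posterior`` is the
    row-urgency posterior given the candidate's own symptom set.
    """
    rows = []
    for cand in pruned.entries:
        post = posterior(model, cand.symptom_ids)
        rows.append(
            EvidenceRow(
                symptoms=cand.symptom_ids,
                findings=cand.finding_ids,
                urgency=cand.urgency,
                cp=cand.template_id,
                cp_frequency=cand.frequency,
                accuracy=accuracy,
                prior=model.class_priors[cand.urgency],
                posterior=post[cand.urgency],
            )
        )
    return ConcordanceTable(
        rows=rows,
        model_meta={
            "smoothing": model.smoothing,
            "n_train": model.n_train,
            "accuracy_method": "leave-one-out",
        },
    )


@dataclass(frozen=True)
class Suggestion:
    """Top-ranked evidence row; the frontline worker decides."""

    row: EvidenceRow
    advisory_only: bool = True


def recommend(table: ConcordanceTable) -> Optional[Suggestion]:
    """Return the top row as an advisory suggestion.

    ``None`` is the no-evidence signal (empty table): the caller should relax
    pruning or gather more measurements — it is not an error.
    """
    if not table.rows:
        return None
    return Suggestion(row=table.rows[0], advisory_only=True)
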