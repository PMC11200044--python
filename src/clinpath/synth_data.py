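"""Synthetic test inputs: toy guideline KBs, naive-Bayes-structured patient
histories, and Likert evaluation datasets with a known latent path structure.

Every generator is a pure function of (spec, seed), so all downstream modules
are testable without any external data.

The Likert generator draws construct scores from a linear structural model and
emits 5-point items through fixed thresholds.  By default it uses a
*composite* measurement design: within each block, residuals are constrained
so that the construct score is an exact linear combination of its indicators.
Under that design the PLS path algorithm's population estimand equals the
configured path coefficients, which makes parameter-recovery experiments
well-posed.  An iid-residual ``"factor"`` noise mode is available for studying
attenuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, SemSpecError
from .evidence_engine import HistoricalRecord, HistoryStore
from .knowledge_base import (
    FindingDef,
    KnowledgeBase,
    PathwayTemplate,
    SymptomDef,
    Urgency,
)
from .likert_stats import LikertDataset
from .pls_sem import Construct, SecondOrder, SemSpec, StructPath

# ------------------------------------------------------------------- toy KBs


def gen_toy_kb(n_symptoms: int = 6, n_templates: int = 8, seed: int = 0) -> KnowledgeBase:
    """Random but valid toy guideline KB.

    Both urgency classes are represented, at least one symptom is flagged
    dominant, and (symptoms, findings) pairs are unique.  Deterministic under
    ``seed``.
    """
    if n_symptoms < 2 or n_templates < 2:
        raise ParameterError("need n_symptoms >= 2 and n_templates >= 2")
    max_subsets = 2**n_symptoms - 1
    if n_templates > max_subsets:
        raise ParameterError(
            f"cannot build {n_templates} distinct templates from {n_symptoms} symptoms"
        )
    rng = np.random.default_rng(seed)
    n_dom = max(1, n_symptoms // 3)
    symptoms = {
        f"s{i + 1}": SymptomDef(id=f"s{i + 1}", name=f"Symptom {i + 1}", dominant=i < n_dom)
        for i in range(n_symptoms)
    }
    n_findings = max(2, n_symptoms // 2)
    findings = {
        f"f{i + 1}": FindingDef(id=f"f{i + 1}", name=f"Finding {i + 1}")
        for i in range(n_findings)
    }
    sids = sorted(symptoms)
    fids = sorted(findings)
    templates: dict[str, PathwayTemplate] = {}
    used: set[tuple[frozenset, frozenset]] = set()
    i = 0
    while len(templates) < n_templates:
        size = int(rng.integers(1, min(3, n_symptoms) + 1))
        chosen = tuple(sorted(rng.choice(sids, size=size, replace=False)))
        n_find = int(rng.integers(0, min(2, n_findings) + 1))
        chosen_f = tuple(sorted(rng.choice(fids, size=n_find, replace=False)))
        key = (frozenset(chosen), frozenset(chosen_f))
        if key in used:
            continue
        used.add(key)
        urgency = Urgency.REFERRAL if len(templates) % 2 == 0 else Urgency.TREATABLE
        i += 1
        templates[f"cp{i}"] = PathwayTemplate(
            id=f"cp{i}",
            symptom_ids=chosen,
            finding_ids=chosen_f,
            urgency=urgency,
            source_tag="toy",
        )
    return KnowledgeBase(
        version=f"toy-kb-seed{seed}", symptoms=symptoms, findings=findings, templates=templates
    )


# ------------------------------------------------------------------ histories


@dataclass(frozen=True)
class HistoryGenSpec:
    """Bernoulli naive-Bayes generative model for patient histories."""

    class_priors: tuple[float, float] = (0.3, 0.7)  # (REFERRAL, TREATABLE)
    cond_probs: Optional[Mapping[str, tuple[float, float]]] = None  # sid -> (p|R, p|T)
    finding_prob: float = 0.2
    n_records: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_priors) - 1.0) > 1e-9:
            raise ParameterError("class priors must sum to 1")
        if not all(0 < p < 1 for p in self.class_priors):
            raise ParameterError("class priors must lie in (0, 1)")
        if self.cond_probs is not None:
            for sid, (pr, pt) in self.cond_probs.items():
                if not (0 < pr < 1 and 0 < pt < 1):
                    raise ParameterError(f"conditional for {sid!r} outside (0, 1)")

    def to_dict(self) -> dict:
        return {
            "class_priors": list(self.class_priors),
            "cond_probs": (
                None
                if self.cond_probs is None
                else {s: list(v) for s, v in self.cond_probs.items()}
            ),
            "finding_prob": self.finding_prob,
            "n_records": self.n_records,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "HistoryGenSpec":
        kwargs = dict(doc)
        kwargs["class_priors"] = tuple(doc.get("class_priors", (0.3, 0.7)))
        cond = doc.get("cond_probs")
        if cond is not None:
            kwargs["cond_probs"] = {s: tuple(v) for s, v in cond.items()}
        return cls(**kwargs)


def random_history_spec(kb: KnowledgeBase, n_records: int = 200, seed: int = 0) -> HistoryGenSpec:
    """Draw per-symptom conditionals in [0.1, 0.9] for a given KB."""
    rng = np.random.default_rng(seed)
    cond = {
        sid: (float(rng.uniform(0.1, 0.9)), float(rng.uniform(0.1, 0.9)))
        for sid in sorted(kb.symptoms)
    }
    return HistoryGenSpec(cond_probs=cond, n_records=n_records, seed=seed)


def gen_history(kb: KnowledgeBase, spec: HistoryGenSpec) -> HistoryStore:
    """Sample records from the Bernoulli NB model; first_symptom is the first
    positive symptom in id order."""
    cond = spec.cond_probs or {
        sid: (0.6, 0.3) for sid in sorted(kb.symptoms)
    }
    unknown = set(cond) - set(kb.symptoms)
    if unknown:
        raise ParameterError(f"cond_probs reference unknown symptoms: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    sids = sorted(cond)
    fids = sorted(kb.findings)
    records = []
    for i in range(spec.n_records):
        is_referral = rng.random() < spec.class_priors[0]
        cls = Urgency.REFERRAL if is_referral else Urgency.TREATABLE
        col = 0 if is_referral else 1
        positives = frozenset(s for s in sids if rng.random() < cond[s][col])
        recorded_findings = frozenset(f for f in fids if rng.random() < spec.finding_prob)
        first = min(positives) if positives else None
        records.append(
            HistoricalRecord(
                record_id=f"h{i + 1:05d}",
                positive_symptoms=positives,
                findings=recorded_findings,
                disposition=cls,
                first_symptom=first,
            )
        )
    return HistoryStore(records=records, kb=kb)


# ------------------------------------------------------------- Likert surveys


@dataclass(frozen=True)
class LikertGenSpec:
    """Latent path model + measurement design for Likert response data.

    ``items`` maps each construct to its indicator loadings (empty mapping =
    latent-only construct, e.g. a higher-order composite).  ``paths`` carry
    the true standardized coefficients; ``exo_corr`` the correlations among
    exogenous constructs.  Continuous indicators are cut at ``thresholds``
    (+ ``threshold_shift``) into scores 1..5 unless ``discretize`` is off.

    Construct and item *order* is part of the spec: it fixes the order in
    which random draws are consumed, so two specs that differ only in
    ordering produce different (equally valid) samples.  Serialize with
    order preserved (e.g. ``yaml.safe_dump(..., sort_keys=False)``).
    """

    items: Mapping[str, Mapping[str, float]]
    paths: tuple[tuple[str, str, float], ...]
    exo_corr: Mapping[frozenset, float] = field(default_factory=dict)
    n_per_site: tuple[int, ...] = (42, 31)
    site_shifts: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    round1_counts: tuple[int, ...] = (0, 0)
    thresholds: tuple[float, float, float, float] = (-1.5, -0.5, 0.5, 1.5)
    threshold_shift: float = 0.0
    discretize: bool = True
    noise_mode: str = "composite"  # "composite" | "factor"
    seed: int = 0

    def __post_init__(self) -> None:
        cuts = np.asarray(self.thresholds, dtype=float)
        if len(cuts) != 4 or not np.all(np.diff(cuts) > 0):
            raise ParameterError("thresholds must be 4 strictly increasing cut points")
        for construct, lam in self.items.items():
            for item, a in lam.items():
                if not (0 < a <= 1):
                    raise ParameterError(
                        f"loading for {item!r} in {construct!r} must lie in (0, 1]"
                    )
        if self.noise_mode not in ("composite", "factor"):
            raise ParameterError("noise_mode must be 'composite' or 'factor'")
        if any(n < 1 for n in self.n_per_site):
            raise ParameterError("each site needs at least one respondent")
        if len(self.round1_counts) != len(self.n_per_site):
            raise ParameterError("round1_counts must align with n_per_site")

    @property
    def construct_names(self) -> list[str]:
        return list(self.items)

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return {
            "items": {c: dict(lam) for c, lam in self.items.items()},
            "paths": [[s, t, b] for s, t, b in self.paths],
            "exo_corr": [
                {"a": sorted(pair)[0], "b": sorted(pair)[1], "r": r}
                for pair, r in self.exo_corr.items()
            ],
            "n_per_site": list(self.n_per_site),
            "site_shifts": {c: list(v) for c, v in self.site_shifts.items()},
            "round1_counts": list(self.round1_counts),
            "thresholds": list(self.thresholds),
            "threshold_shift": self.threshold_shift,
            "discretize": self.discretize,
            "noise_mode": self.noise_mode,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "LikertGenSpec":
        kwargs = dict(doc)
        kwargs["paths"] = tuple((s, t, float(b)) for s, t, b in doc.get("paths", []))
        kwargs["exo_corr"] = {
            frozenset((e["a"], e["b"])): float(e["r"]) for e in doc.get("exo_corr", [])
        }
        for key in ("n_per_site", "round1_counts", "thresholds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "site_shifts" in kwargs:
            kwargs["site_shifts"] = {
                c: tuple(v) for c, v in kwargs["site_shifts"].items()
            }
        return cls(**kwargs)


def _implied_phi(spec: LikertGenSpec) -> tuple[list[str], np.ndarray]:
    """Population construct correlation matrix implied by the path model."""
    names = spec.construct_names
    idx = {n: i for i, n in enumerate(names)}
    parents: dict[str, list[tuple[str, float]]] = {n: [] for n in names}
    for s, t, b in spec.paths:
        if s not in idx or t not in idx:
            raise SemSpecError(f"path {s}->{t} references unknown construct")
        parents[t].append((s, b))
    # topological order
    order: list[str] = []
    placed: set[str] = set()
    pending = list(names)
    while pending:
        progressed = False
        for n in list(pending):
            if all(p in placed for p, _ in parents[n]):
                order.append(n)
                placed.add(n)
                pending.remove(n)
                progressed = True
        if not progressed:
            raise SemSpecError("path structure is cyclic")
    phi = np.eye(len(names))
    for pair, r in spec.exo_corr.items():
        a, b = tuple(pair)
        phi[idx[a], idx[b]] = phi[idx[b], idx[a]] = r
    for n in order:
        if not parents[n]:
            continue
        j = idx[n]
        ps = [idx[p] for p, _ in parents[n]]
        bs = np.array([b for _, b in parents[n]])
        var_sys = float(bs @ phi[np.ix_(ps, ps)] @ bs)
        if var_sys >= 1.0:
            raise SemSpecError(
                f"construct {n!r}: systematic variance {var_sys:.3f} >= 1; "
                "reduce path coefficients or parent correlations"
            )
        for m in range(len(names)):
            if m == j:
                continue
            phi[j, m] = phi[m, j] = float(bs @ phi[ps, m])
        phi[j, j] = 1.0
    try:
        np.linalg.cholesky(phi + 1e-12 * np.eye(len(names)))
    except np.linalg.LinAlgError as exc:
        raise SemSpecError("implied construct covariance is not positive definite") from exc
    return names, phi


def _composite_direction(a: np.ndarray, iters: int = 200) -> Optional[np.ndarray]:
    """Unit vector v of the residual projection, solved by fixed point so the
    PLS proxy of the block coincides with the generating construct score."""
    d = 1.0 - a**2
    if np.all(d < 1e-12):
        return None  # noise-free block
    v = np.sqrt(d) * a
    v = v / np.linalg.norm(v)
    for _ in range(iters):
        s2 = a**2 + d * (1.0 - v**2)
        v_new = np.sqrt(d) * a / s2
        v_new = v_new / np.linalg.norm(v_new)
        if np.max(np.abs(v_new - v)) < 1e-13:
            v = v_new
            break
        v = v_new
    return v


def gen_likert(spec: LikertGenSpec):
    """Generate a Likert dataset (or continuous indicator frame).

    Returns a :class:`~clinpath.likert_stats.LikertDataset` whose ``scale``
    is ``"likert5"`` when discretizing, ``"continuous"`` otherwise.
    """
    names, phi = _implied_phi(spec)
    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(phi)
    frames = []
    sites = []
    sessions = []
    item_cols = [item for lam in spec.items.values() for item in lam]
    for s_idx, n in enumerate(spec.n_per_site):
        z = rng.standard_normal((n, len(names)))
        zeta = z @ chol.T
        for c, shifts in spec.site_shifts.items():
            if len(shifts) != len(spec.n_per_site):
                raise ParameterError(f"site_shifts[{c!r}] must align with n_per_site")
            zeta[:, names.index(c)] += shifts[s_idx]
        block_cols = []
        for c in names:
            lam = spec.items[c]
            if not lam:
                continue
            a = np.array([lam[i] for i in lam], dtype=float)
            k = len(a)
            noise = rng.standard_normal((n, k))
            if spec.noise_mode == "composite":
                v = _composite_direction(a)
                if v is None:
                    e = np.zeros((n, k))
                else:
                    e = (noise - np.outer(noise @ v, v)) * np.sqrt(1.0 - a**2)
            else:
                e = noise * np.sqrt(1.0 - a**2)
            x = zeta[:, names.index(c)][:, None] * a + e
            block_cols.append(pd.DataFrame(x, columns=list(lam)))
        frames.append(pd.concat(block_cols, axis=1)[item_cols])
        sites.extend([f"site_{s_idx + 1}"] * n)
        r1 = spec.round1_counts[s_idx]
        sessions.extend(["round_1"] * r1 + ["round_2"] * (n - r1))
    raw = pd.concat(frames, axis=0, ignore_index=True)
    index = pd.Index([f"r{i + 1:03d}" for i in range(len(raw))], name="respondent_id")
    raw.index = index
    construct_map = {item: c for c, lam in spec.items.items() for item in lam}
    if spec.discretize:
        cuts = np.asarray(spec.thresholds, dtype=float) + spec.threshold_shift
        scored = pd.DataFrame(
            np.digitize(raw.to_numpy(), cuts) + 1, index=index, columns=raw.columns
        )
        scale = "likert5"
    else:
        scored = raw
        scale = "continuous"
    return LikertDataset(
        scores=scored,
        construct_map=construct_map,
        site=pd.Series(sites, index=index),
        session=pd.Series(sessions, index=index),
        item_names=dict(DEFAULT_ITEM_NAMES) if item_cols == list(DEFAULT_ITEM_NAMES) else {},
        scale=scale,
    )


# ------------------------------------------- the CDSS acceptance-study design


#: 22-item instrument: item column -> human-readable name.
DEFAULT_ITEM_NAMES = {
    "item_01": "Learnability",
    "item_02": "Operability",
    "item_03": "User interface",
    "item_04": "Data entry",
    "item_05": "Advice display",
    "item_06": "Legibility",
    "item_07": "Response time",
    "item_08": "Stability",
    "item_09": "Security",
    "item_10": "CP performance",
    "item_11": "Change in order behavior",
    "item_12": "Change in CP",
    "item_13": "Effectiveness",
    "item_14": "Overall usefulness",
    "item_15": "Adherence to standards",
    "item_16": "Medical quality",
    "item_17": "User knowledge and skills",
    "item_18": "Usage",
    "item_19": "Confirmation of expectations",
    "item_20": "Satisfaction with overall quality",
    "item_21": "Overall satisfaction",
    "item_22": "Intention to use",
}

#: True item loadings of the default design.  Two deliberately weak items
#: (legibility, medical quality) sit below the 0.70 retention rule.
DEFAULT_LOADINGS = {
    "perceived_ease_of_use": {
        "item_01": 0.721,
        "item_02": 0.738,
        "item_03": 0.746,
        "item_04": 0.856,
        "item_05": 0.836,
        "item_06": 0.650,
    },
    "system_quality": {"item_07": 0.934, "item_08": 0.944},
    "information_quality": {"item_09": 0.825, "item_10": 0.930},
    "decision_changes": {"item_11": 0.856, "item_12": 0.856},
    "process_changes": {
        "item_13": 0.773,
        "item_14": 0.813,
        "item_15": 0.896,
        "item_16": 0.650,
        "item_17": 0.762,
    },
    "acceptance": {
        "item_18": 0.738,
        "item_19": 0.819,
        "item_20": 0.806,
        "item_21": 0.846,
        "item_22": 0.815,
    },
}

#: True standardized path coefficients of the default acceptance model.
DEFAULT_TRUE_PATHS = (
    ("perceived_ease_of_use", "acceptance", 0.015),
    ("system_quality", "acceptance", 0.321),
    ("information_quality", "acceptance", 0.149),
    ("information_quality", "perceived_ease_of_use", 0.678),
    ("system_quality", "perceived_ease_of_use", 0.021),
    ("perceived_benefits", "acceptance", 0.486),
    ("decision_changes", "perceived_benefits", 0.374),
    ("process_changes", "perceived_benefits", 0.749),
)


def acceptance_genspec(
    n_per_site: tuple[int, ...] = (42, 31),
    discretize: bool = True,
    seed: int = 0,
    with_site_effects: bool = True,
    threshold_shift: float = -1.2,
) -> LikertGenSpec:
    """Generator spec emulating the two-site acceptance evaluation.

    Six measured constructs over 22 five-point items plus a latent
    perceived-benefits composite of the two change constructs; true path
    coefficients and loadings default to the acceptance model's configuration.
    The two change constructs are generated orthogonal to the quality
    constructs so every configured path is also the population value that a
    composite-based PLS fit estimates.  The threshold shift of -1.2 produces
    the ceiling-heavy score profile typical of post-use questionnaires
    (item means near 4.3, ~75% agreement).
    """
    items = dict(DEFAULT_LOADINGS)
    items["perceived_benefits"] = {}
    site_shifts = {}
    if with_site_effects and len(n_per_site) >= 2:
        # second site scored system quality / acceptance higher
        shift = tuple(0.0 if i == 0 else 0.45 for i in range(len(n_per_site)))
        site_shifts = {"system_quality": shift, "acceptance": shift}
    round1 = tuple(4 if i == 0 else 0 for i in range(len(n_per_site)))
    return LikertGenSpec(
        items=items,
        paths=DEFAULT_TRUE_PATHS,
        exo_corr={
            frozenset(("system_quality", "information_quality")): 0.60,
            frozenset(("decision_changes", "process_changes")): 0.503,
        },
        n_per_site=tuple(n_per_site),
        site_shifts=site_shifts,
        round1_counts=round1,
        threshold_shift=threshold_shift,
        discretize=discretize,
        seed=seed,
    )


def acceptance_model_spec(items: Optional[Mapping[str, Sequence[str]]] = None) -> SemSpec:
    """SEM spec of the acceptance model: six hypothesized directional paths
    (H1..H6) with perceived benefits as a formative second-order composite of
    decision changes and process changes."""
    blocks = {c: list(lam) for c, lam in DEFAULT_LOADINGS.items()} if items is None else {
        c: list(v) for c, v in items.items()
    }
    constructs = tuple(
        Construct(name=c, indicators=tuple(inds), mode="A") for c, inds in blocks.items()
    )
    return SemSpec(
        constructs=constructs,
        paths=(
            StructPath("perceived_ease_of_use", "acceptance", "H1"),
            StructPath("system_quality", "acceptance", "H2"),
            StructPath("information_quality", "acceptance", "H3"),
            StructPath("information_quality", "perceived_ease_of_use", "H4"),
            StructPath("system_quality", "perceived_ease_of_use", "H5"),
            StructPath("perceived_benefits", "acceptance", "H6"),
        ),
        second_order=(
            SecondOrder(
                name="perceived_benefits",
                components=("decision_changes", "process_changes"),
                mode="B",
            ),
        ),
    )
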