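"""Variance-based structural equation modeling (PLS path modeling).

Implements the classical partial-least-squares path algorithm: indicators are
standardized, outer weights start equal, and inner proxies (path, factor or
centroid weighting scheme) alternate with outer weight updates (mode A:
indicator-proxy correlations; mode B: multiple-regression weights) until the
largest outer-weight change falls below tolerance.  Path coefficients are then
ordinary least squares on the standardized latent scores, with one R^2 per
endogenous construct.

Higher-order constructs use the two-stage approach: the lower-order model is
fitted first, its latent scores become (typically formative, mode B)
indicators of the higher-order construct in a second fit.

Inference is by percentile bootstrap over respondents, with per-replicate
construct sign correction against the original solution, bootstrap-SD t
statistics referred to a t distribution with B-1 degrees of freedom
(switchable to the normal reference), and percentile confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, SemSpecError

# ------------------------------------------------------------------ the spec


@dataclass(frozen=True)
class Construct:
    name: str
    indicators: tuple[str, ...]
    mode: str = "A"  # "A" reflective, "B" formative

    def __post_init__(self) -> None:
        object.__setattr__(self, "indicators", tuple(self.indicators))
        if self.mode not in ("A", "B"):
            raise SemSpecError(f"construct {self.name!r}: mode must be 'A' or 'B'")
        if not self.indicators:
            raise SemSpecError(f"construct {self.name!r} has no indicators")


@dataclass(frozen=True)
class StructPath:
    source: str
    target: str
    hypothesis: Optional[str] = None


@dataclass(frozen=True)
class SecondOrder:
    name: str
    components: tuple[str, ...]
    mode: str = "B"
    approach: str = "two_stage"

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if self.approach != "two_stage":
            raise SemSpecError(f"unsupported higher-order approach {self.approach!r}")


@dataclass(frozen=True)
class SemSpec:
    constructs: tuple[Construct, ...]
    paths: tuple[StructPath, ...]
    second_order: tuple[SecondOrder, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "constructs", tuple(self.constructs))
        object.__setattr__(self, "paths", tuple(self.paths))
        object.__setattr__(self, "second_order", tuple(self.second_order))
        names = [c.name for c in self.constructs] + [h.name for h in self.second_order]
        if len(names) != len(set(names)):
            raise SemSpecError("construct names must be unique")
        seen_items: dict[str, str] = {}
        for c in self.constructs:
            for ind in c.indicators:
                if ind in seen_items:
                    raise SemSpecError(
                        f"indicator {ind!r} appears in both {seen_items[ind]!r} "
                        f"and {c.name!r}"
                    )
                seen_items[ind] = c.name
        known = set(names)
        for p in self.paths:
            for end in (p.source, p.target):
                if end not in known:
                    raise SemSpecError(f"path references unknown construct {end!r}")
        for h in self.second_order:
            for comp in h.components:
                if comp not in {c.name for c in self.constructs}:
                    raise SemSpecError(
                        f"second-order {h.name!r} component {comp!r} is not a construct"
                    )
        self._toposort(names)  # raises on cycles

    def _toposort(self, names: Sequence[str]) -> list[str]:
        preds: dict[str, set[str]] = {n: set() for n in names}
        for p in self.paths:
            preds[p.target].add(p.source)
        order, ready = [], [n for n in names if not preds[n]]
        remaining = {n: set(ps) for n, ps in preds.items() if ps}
        while ready:
            n = ready.pop(0)
            order.append(n)
            for m in list(remaining):
                remaining[m].discard(n)
                if not remaining[m]:
                    ready.append(m)
                    del remaining[m]
        if remaining:
            raise SemSpecError(f"structural graph has a cycle involving {sorted(remaining)}")
        return order

    # ---------------------------------------------------------------- io
    def to_dict(self) -> dict:
        return {
            "constructs": [
                {"name": c.name, "mode": c.mode, "indicators": list(c.indicators)}
                for c in self.constructs
            ],
            "paths": [
                {
                    "from": p.source,
                    "to": p.target,
                    **({"hypothesis": p.hypothesis} if p.hypothesis else {}),
                }
                for p in self.paths
            ],
            "second_order": [
                {
                    "name": h.name,
                    "components": list(h.components),
                    "mode": h.mode,
                    "approach": h.approach,
                }
                for h in self.second_order
            ],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "SemSpec":
        try:
            constructs = tuple(
                Construct(
                    name=c["name"],
                    indicators=tuple(c["indicators"]),
                    mode=c.get("mode", "A"),
                )
                for c in doc["constructs"]
            )
            paths = tuple(
                StructPath(source=p["from"], target=p["to"], hypothesis=p.get("hypothesis"))
                for p in doc.get("paths", [])
            )
            second = tuple(
                SecondOrder(
                    name=h["name"],
                    components=tuple(h["components"]),
                    mode=h.get("mode", "B"),
                    approach=h.get("approach", "two_stage"),
                )
                for h in doc.get("second_order", [])
            )
        except KeyError as exc:
            raise SemSpecError(f"missing key {exc} in SEM spec document") from exc
        return cls(constructs=constructs, paths=paths, second_order=second)

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "SemSpec":
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        return cls.from_dict(json.loads(text))

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")


# --------------------------------------------------------------- compilation


class _Compiled:
    """Spec resolved against a concrete column layout, for fast refits."""

    __slots__ = (
        "names",
        "blocks",
        "modes",
        "neighbors",
        "preds",
        "succs",
        "indicator_cols",
        "endo",
    )

    def __init__(self, spec: SemSpec, columns: Sequence[str]):
        col_idx = {c: i for i, c in enumerate(columns)}
        self.names = [c.name for c in spec.constructs]
        name_idx = {n: j for j, n in enumerate(self.names)}
        self.blocks = []
        self.modes = []
        self.indicator_cols = []
        for c in spec.constructs:
            missing = [i for i in c.indicators if i not in col_idx]
            if missing:
                raise SemSpecError(
                    f"construct {c.name!r}: indicator columns missing from data: {missing}"
                )
            self.blocks.append(np.array([col_idx[i] for i in c.indicators], dtype=int))
            self.modes.append(c.mode)
            self.indicator_cols.append(list(c.indicators))
        k = len(self.names)
        self.preds = [[] for _ in range(k)]
        self.succs = [[] for _ in range(k)]
        for p in spec.paths:
            s, t = name_idx[p.source], name_idx[p.target]
            self.preds[t].append(s)
            self.succs[s].append(t)
        self.neighbors = [sorted(set(self.preds[j]) | set(self.succs[j])) for j in range(k)]
        self.endo = [j for j in range(k) if self.preds[j]]


# -------------------------------------------------------------------- fitting


@dataclass
class SemFit:
    """Result of one PLS fit (possibly the second stage of a two-stage run)."""

    outer_loadings: pd.Series
    outer_weights: pd.Series
    latent_scores: pd.DataFrame
    path_coefficients: dict[tuple[str, str], float]
    r_squared: dict[str, float]
    iterations: int
    converged: bool
    scheme: str
    spec: SemSpec
    stage1: Optional["SemFit"] = None

    def beta(self, source: str, target: str) -> float:
        return self.path_coefficients[(source, target)]

    def paths_frame(self) -> pd.DataFrame:
        rows = [
            {"source": s, "target": t, "beta": b}
            for (s, t), b in self.path_coefficients.items()
        ]
        return pd.DataFrame(rows)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise ParameterError(f"indicator column {bad} has zero variance")
    return (x - mu) / sd


def _fit_arrays(
    x: np.ndarray,
    comp: _Compiled,
    scheme: str,
    tol: float,
    max_iter: int,
):
    """Core iteration on a standardized matrix; returns raw numpy results."""
    n, _ = x.shape
    k = len(comp.names)
    denom = n - 1
    weights = [np.ones(len(b)) for b in comp.blocks]
    scores = np.empty((n, k))
    for j in range(k):
        y = x[:, comp.blocks[j]] @ weights[j]
        ysd = y.std(ddof=1)
        if ysd == 0:
            raise ParameterError(f"degenerate proxy for construct {comp.names[j]!r}")
        weights[j] = weights[j] / ysd
        scores[:, j] = y / ysd

    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        corr = scores.T @ scores / denom
        inner = np.zeros((k, k))
        for j in range(k):
            nb = comp.neighbors[j]
            if not nb:
                continue
            if scheme == "centroid":
                for m in nb:
                    inner[j, m] = np.sign(corr[j, m]) or 1.0
            elif scheme == "factor":
                for m in nb:
                    inner[j, m] = corr[j, m]
            else:  # path scheme
                ps = comp.preds[j]
                if ps:
                    sub = corr[np.ix_(ps, ps)]
                    rhs = corr[ps, j]
                    try:
                        b = np.linalg.solve(sub, rhs)
                    except np.linalg.LinAlgError as exc:
                        raise ParameterError(
                            f"singular inner regression for construct "
                            f"{comp.names[j]!r}"
                        ) from exc
                    for m, bm in zip(ps, b):
                        inner[j, m] = bm
                for m in comp.succs[j]:
                    inner[j, m] = corr[j, m]

        max_delta = 0.0
        for j in range(k):
            if comp.neighbors[j]:
                z = scores @ inner[j]
                zsd = z.std(ddof=1)
                if zsd == 0:
                    z = scores[:, j]
                else:
                    z = z / zsd
            else:
                z = scores[:, j]
            xb = x[:, comp.blocks[j]]
            if comp.modes[j] == "A":
                w = xb.T @ z / denom
            else:
                s_bb = xb.T @ xb / denom
                try:
                    w = np.linalg.solve(s_bb, xb.T @ z / denom)
                except np.linalg.LinAlgError as exc:
                    raise ParameterError(
                        f"singular mode-B regression for construct {comp.names[j]!r}"
                    ) from exc
            y = xb @ w
            ysd = y.std(ddof=1)
            if ysd == 0:
                raise ParameterError(
                    f"degenerate proxy for construct {comp.names[j]!r}"
                )
            w = w / ysd
            max_delta = max(max_delta, float(np.max(np.abs(w - weights[j]))))
            weights[j] = w
            scores[:, j] = xb @ w
        if max_delta < tol:
            converged = True
            break

    # final standardization + sign anchoring on the dominant loading
    loadings = []
    for j in range(k):
        scores[:, j] = (scores[:, j] - scores[:, j].mean()) / scores[:, j].std(ddof=1)
        lam = x[:, comp.blocks[j]].T @ scores[:, j] / denom
        if lam[int(np.argmax(np.abs(lam)))] < 0:
            weights[j] = -weights[j]
            scores[:, j] = -scores[:, j]
            lam = -lam
        loadings.append(lam)

    corr = scores.T @ scores / denom
    betas: dict[tuple[int, int], float] = {}
    r2: dict[int, float] = {}
    for j in comp.endo:
        ps = comp.preds[j]
        sub = corr[np.ix_(ps, ps)]
        rhs = corr[ps, j]
        try:
            b = np.linalg.solve(sub, rhs)
        except np.linalg.LinAlgError as exc:
            raise ParameterError(
                f"singular structural regression for construct {comp.names[j]!r}"
            ) from exc
        for m, bm in zip(ps, b):
            betas[(m, j)] = float(bm)
        r2[j] = float(b @ rhs)
    return weights, loadings, scores, betas, r2, iterations, converged


def fit_pls(
    data: pd.DataFrame,
    spec: SemSpec,
    scheme: str = "path",
    tol: float = 1e-7,
    max_iter: int = 300,
) -> SemFit:
    """Fit a (flat, no second-order) PLS path model.

    Non-convergence at ``max_iter`` is flagged (``converged=False``) and the
    last iterate is still returned.
    """
    scheme = scheme.lower()
    if scheme not in ("path", "factor", "centroid"):
        raise ParameterError(f"unknown inner weighting scheme {scheme!r}")
    if spec.second_order:
        raise SemSpecError("use fit_sem() for specs with second-order constructs")
    comp = _Compiled(spec, list(data.columns))
    cols = [i for b in comp.indicator_cols for i in b]
    x = _standardize(data[cols].to_numpy(dtype=float))
    comp2 = _Compiled(spec, cols)
    n_pred = max((len(p) for p in comp2.preds), default=0)
    if len(data) <= n_pred + 1:
        raise ParameterError("need n > number of predictors + 1 respondents")
    weights, loadings, scores, betas, r2, iters, conv = _fit_arrays(
        x, comp2, scheme, tol, max_iter
    )
    return _package_fit(
        data.index, comp2, spec, scheme, weights, loadings, scores, betas, r2, iters, conv
    )


def _package_fit(index, comp, spec, scheme, weights, loadings, scores, betas, r2, iters, conv):
    w_series = {}
    l_series = {}
    for j, cols in enumerate(comp.indicator_cols):
        for i, cname in enumerate(cols):
            w_series[cname] = float(weights[j][i])
            l_series[cname] = float(loadings[j][i])
    return SemFit(
        outer_loadings=pd.Series(l_series),
        outer_weights=pd.Series(w_series),
        latent_scores=pd.DataFrame(scores, index=index, columns=comp.names),
        path_coefficients={
            (comp.names[s], comp.names[t]): b for (s, t), b in betas.items()
        },
        r_squared={comp.names[j]: v for j, v in r2.items()},
        iterations=iters,
        converged=conv,
        scheme=scheme,
        spec=spec,
    )


# ----------------------------------------------------------- two-stage models


def _stage1_spec(spec: SemSpec) -> SemSpec:
    """Replace each higher-order construct by its components in the paths."""
    expand = {h.name: h.components for h in spec.second_order}
    paths = []
    for p in spec.paths:
        sources = expand.get(p.source, (p.source,))
        targets = expand.get(p.target, (p.target,))
        for s in sources:
            for t in targets:
                paths.append(StructPath(source=s, target=t, hypothesis=None))
    # drop duplicates while preserving order
    seen, uniq = set(), []
    for p in paths:
        key = (p.source, p.target)
        if key not in seen:
            seen.add(key)
            uniq.append(p)
    return SemSpec(constructs=spec.constructs, paths=tuple(uniq), second_order=())


def resolve_second_order(
    data: pd.DataFrame,
    spec: SemSpec,
    scheme: str = "path",
    tol: float = 1e-7,
    max_iter: int = 300,
) -> tuple[pd.DataFrame, SemSpec, SemFit]:
    """Two-stage resolution of higher-order constructs.

    Stage 1 fits the flattened lower-order model and extracts component latent
    scores; the returned data/spec use those scores as indicators of each
    higher-order construct (mode B by default).  Returns
    ``(stage2_data, stage2_spec, stage1_fit)``.
    """
    if not spec.second_order:
        raise SemSpecError("spec has no second-order constructs to resolve")
    stage1 = fit_pls(data, _stage1_spec(spec), scheme=scheme, tol=tol, max_iter=max_iter)
    component_of = {}
    for h in spec.second_order:
        for c in h.components:
            component_of[c] = h.name

    keep_constructs = [c for c in spec.constructs if c.name not in component_of]
    aug = data.copy()
    new_constructs = list(keep_constructs)
    for h in spec.second_order:
        ind_names = []
        for c in h.components:
            col = f"{c}__score"
            aug[col] = stage1.latent_scores[c].to_numpy()
            ind_names.append(col)
        new_constructs.append(Construct(name=h.name, indicators=tuple(ind_names), mode=h.mode))
    stage2_spec = SemSpec(
        constructs=tuple(new_constructs), paths=spec.paths, second_order=()
    )
    return aug, stage2_spec, stage1


def fit_sem(
    data: pd.DataFrame,
    spec: SemSpec,
    scheme: str = "path",
    tol: float = 1e-7,
    max_iter: int = 300,
) -> SemFit:
    """Fit a full model, resolving second-order constructs when present."""
    if not spec.second_order:
        return fit_pls(data, spec, scheme=scheme, tol=tol, max_iter=max_iter)
    aug, spec2, stage1 = resolve_second_order(
        data, spec, scheme=scheme, tol=tol, max_iter=max_iter
    )
    fit = fit_pls(aug, spec2, scheme=scheme, tol=tol, max_iter=max_iter)
    fit.stage1 = stage1
    fit.converged = fit.converged and stage1.converged
    # Report component -> higher-order coefficients: the higher-order score is
    # an exact combination of its (standardized) component scores, so the
    # standardized outer weights are the regression coefficients.
    for h in spec.second_order:
        y = fit.latent_scores[h.name].to_numpy()
        cols = [f"{c}__score" for c in h.components]
        xc = aug[cols].to_numpy(dtype=float)
        xc = (xc - xc.mean(axis=0)) / xc.std(axis=0, ddof=1)
        b, *_ = np.linalg.lstsq(xc, y, rcond=None)
        for comp_name, coef in zip(h.components, b):
            fit.path_coefficients[(comp_name, h.name)] = float(coef)
        ss_res = float(np.sum((y - xc @ b) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        fit.r_squared[h.name] = 1.0 - ss_res / ss_tot
    return fit


def retain_items(
    data: pd.DataFrame,
    spec: SemSpec,
    threshold: float = 0.70,
    scheme: str = "path",
) -> tuple[SemSpec, dict[str, list[str]]]:
    """Measurement validation: drop reflective indicators loading below the
    threshold (each block keeps at least its strongest indicator)."""
    fit = fit_sem(data, spec, scheme=scheme)
    loadings = fit.outer_loadings if fit.stage1 is None else fit.stage1.outer_loadings
    dropped: dict[str, list[str]] = {}
    new_constructs = []
    for c in spec.constructs:
        if c.mode != "A":
            new_constructs.append(c)
            continue
        lam = loadings[list(c.indicators)]
        keep = [i for i in c.indicators if lam[i] >= threshold]
        if not keep:
            keep = [lam.abs().idxmax()]
        drop = [i for i in c.indicators if i not in keep]
        if drop:
            dropped[c.name] = drop
        new_constructs.append(replace(c, indicators=tuple(keep)))
    return (
        SemSpec(
            constructs=tuple(new_constructs),
            paths=spec.paths,
            second_order=spec.second_order,
        ),
        dropped,
    )


# ------------------------------------------------------------------ bootstrap


@dataclass
class BootstrapResult:
    paths: list[tuple[str, str]]
    original: np.ndarray
    sd: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    n_dropped: int
    seed: int
    alpha: float
    p_reference: str
    high_drop_warning: bool

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": [s for s, _ in self.paths],
                "target": [t for _, t in self.paths],
                "beta": self.original,
                "sd": self.sd,
                "t": self.t_stat,
                "p": self.p_value,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def stat(self, source: str, target: str) -> dict:
        i = self.paths.index((source, target))
        return {
            "beta": float(self.original[i]),
            "sd": float(self.sd[i]),
            "t": float(self.t_stat[i]),
            "p": float(self.p_value[i]),
            "ci": (float(self.ci_low[i]), float(self.ci_high[i])),
        }


def _construct_signs(fit: SemFit, reference: SemFit) -> dict[str, float]:
    """Per-construct sign of the replicate relative to the original fit,
    judged on the inner product of (stage-2) outer loadings."""
    signs = {}
    for c in fit.spec.constructs:
        lam_f = fit.outer_loadings[list(c.indicators)].to_numpy()
        lam_r = reference.outer_loadings[list(c.indicators)].to_numpy()
        dot = float(lam_f @ lam_r)
        signs[c.name] = -1.0 if dot < 0 else 1.0
    return signs


def bootstrap(
    data: pd.DataFrame,
    spec: SemSpec,
    n_boot: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    scheme: str = "path",
    tol: float = 1e-7,
    max_iter: int = 300,
    p_reference: str = "t",
) -> BootstrapResult:
    """Percentile bootstrap over respondents with sign correction.

    Each replicate resamples rows with replacement and refits the full model
    (including second-order resolution).  Replicates that fail to converge are
    dropped and counted; more than 5% drops raises the warning flag.
    """
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    if p_reference not in ("t", "normal"):
        raise ParameterError("p_reference must be 't' or 'normal'")
    original = fit_sem(data, spec, scheme=scheme, tol=tol, max_iter=max_iter)
    path_keys = list(original.path_coefficients)
    orig = np.array([original.path_coefficients[k] for k in path_keys])
    rng = np.random.default_rng(seed)
    n = len(data)
    reps = np.empty((n_boot, len(path_keys)))
    kept = 0
    dropped = 0
    if not spec.second_order:
        # fast array path: resample and refit on raw numpy buffers
        comp = _Compiled(spec, list(data.columns))
        cols = [i for b in comp.indicator_cols for i in b]
        comp = _Compiled(spec, cols)
        x = data[cols].to_numpy(dtype=float)
        name_idx = {nm: j for j, nm in enumerate(comp.names)}
        key_idx = [(name_idx[s], name_idx[t]) for s, t in path_keys]
        orig_loadings = [
            original.outer_loadings[list(c)].to_numpy() for c in comp.indicator_cols
        ]
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                xs = _standardize(x[idx])
                _, loadings, _, betas, _, _, conv = _fit_arrays(
                    xs, comp, scheme, tol, max_iter
                )
            except ParameterError:
                dropped += 1
                continue
            if not conv:
                dropped += 1
                continue
            signs = np.array(
                [
                    -1.0 if float(lam @ ref) < 0 else 1.0
                    for lam, ref in zip(loadings, orig_loadings)
                ]
            )
            reps[kept] = [
                betas[(s, t)] * signs[s] * signs[t] for s, t in key_idx
            ]
            kept += 1
    else:
        # second-order models rebuild their stage-2 data per replicate, so
        # the resample goes through fit_sem on the raw indicator frame
        raw = data.reset_index(drop=True)
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            sample = raw.iloc[idx]
            sample = sample.reset_index(drop=True)
            try:
                fit = fit_sem(sample, spec, scheme=scheme, tol=tol, max_iter=max_iter)
            except ParameterError:
                dropped += 1
                continue
            if not fit.converged:
                dropped += 1
                continue
            signs = _construct_signs(fit, original)
            if fit.stage1 is not None and original.stage1 is not None:
                stage1_signs = _construct_signs(fit.stage1, original.stage1)
                signs = {**stage1_signs, **signs}
            row = np.array(
                [
                    fit.path_coefficients[k] * signs.get(k[0], 1.0) * signs.get(k[1], 1.0)
                    for k in path_keys
                ]
            )
            reps[kept] = row
            kept += 1
    if kept == 0:
        raise ParameterError("all bootstrap replicates failed to converge")
    reps = reps[:kept]
    sd = reps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore"):
        t_stat = np.abs(orig) / sd
    df = kept - 1
    if p_reference == "t":
        p = 2.0 * sps.t.sf(t_stat, df)
    else:
        p = 2.0 * sps.norm.sf(t_stat)
    lo = np.percentile(reps, 100 * alpha / 2.0, axis=0)
    hi = np.percentile(reps, 100 * (1 - alpha / 2.0), axis=0)
    return BootstrapResult(
        paths=[(s, t) for (s, t) in path_keys],
        original=orig,
        sd=sd,
        t_stat=t_stat,
        p_value=np.minimum(p, 1.0),
        ci_low=lo,
        ci_high=hi,
        n_boot=kept,
        n_dropped=dropped,
        seed=seed,
        alpha=alpha,
        p_reference=p_reference,
        high_drop_warning=dropped > 0.05 * n_boot,
    )


# ------------------------------------------------------- hypothesis decisions


@dataclass(frozen=True)
class HypothesisDecision:
    hypothesis: str
    source: str
    target: str
    beta: float
    sd: float
    t_stat: float
    p_value: float
    verdict: str  # "Accepted" | "Rejected"


def hypothesis_verdict(beta: float, p_value: float, alpha: float = 0.05) -> str:
    """Directional decision rule: accept iff p < alpha and the estimate is
    positive (hypotheses state a *positive* effect); p == alpha rejects."""
    return "Accepted" if (p_value < alpha and beta > 0) else "Rejected"


def decide_hypotheses(
    fit: SemFit,
    boot: BootstrapResult,
    hypotheses: Optional[Sequence[tuple[str, str, str]]] = None,
    alpha: float = 0.05,
) -> list[HypothesisDecision]:
    """Decision table for the model's directional hypotheses.

    ``hypotheses`` is a list of (label, source, target); when omitted, the
    tagged paths of the fitted spec are used.
    """
    if hypotheses is None:
        hypotheses = [
            (p.hypothesis, p.source, p.target)
            for p in fit.spec.paths
            if p.hypothesis
        ]
        if not hypotheses and fit.stage1 is not None:
            hypotheses = [
                (p.hypothesis, p.source, p.target)
                for p in fit.stage1.spec.paths
                if p.hypothesis
            ]
    decisions = []
    for label, src, tgt in hypotheses:
        if (src, tgt) not in boot.paths:
            raise SemSpecError(f"hypothesis {label!r} names unknown path {src}->{tgt}")
        s = boot.stat(src, tgt)
        decisions.append(
            HypothesisDecision(
                hypothesis=label,
                source=src,
                target=tgt,
                beta=s["beta"],
                sd=s["sd"],
                t_stat=s["t"],
                p_value=s["p"],
                verdict=hypothesis_verdict(s["beta"], s["p"], alpha=alpha),
            )
        )
    return decisions


def decisions_frame(decisions: Sequence[HypothesisDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "hypothesis": [d.hypothesis for d in decisions],
            "path": [f"{d.source} -> {d.target}" for d in decisions],
            "beta": [d.beta for d in decisions],
            "sd": [d.sd for d in decisions],
            "t": [d.t_stat for d in decisions],
            "p": [d.p_value for d in decisions],
            "conclusion": [d.verdict for d in decisions],
        }
    )
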