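"""Distribution choice, AICc beam search, candidate filtering and averaging.

The published per-observation Vuong statistic appears in print as
V = sqrt(N) * mean(m) / (s_m * m); the trailing "* m" cannot be right for a
scalar statistic (m is a vector) and is treated as a typesetting error.  The
standard form V = sqrt(N) * mean(m) / s_m is implemented here, which is what
the cited software (pscl's ``vuong``) computes.

The model search is a branching beam: each iteration extends every base
model with each absent pool predictor, and every fitted model within
ΔAICc <= 2 of the iteration's best becomes a base for the next iteration, as
long as the incumbent best AICc keeps decreasing.  Duplicate predictor sets
reached along different paths are fitted once.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from snowcross.count_models import (
    INTERCEPT,
    CountModelSpec,
    FittedCountModel,
    fit,
)
from snowcross.synthetic import CountDataset, ZERO_INFLATED_FAMILIES

FAMILY_COMPLEXITY = {"poisson": 0, "zip": 1, "negbin": 1, "zinb": 2}

REMOTE_APPROACHES = ("200m", "500m", "1km", "3-scales")
APPROACHES = REMOTE_APPROACHES + ("digitized", "combined")


# ---------------------------------------------------------------------------
# tests on pairs of fitted models
# ---------------------------------------------------------------------------

def lr_test(
    ll_restricted: float, ll_general: float, df_diff: int
) -> dict[str, float]:
    """Likelihood-ratio test of a nested pair: 2 (l1 - l0) against chi^2(df).

    The statistic is clamped at zero; a general model fitting worse than its
    restriction (beyond tolerance) indicates an optimizer failure upstream and
    triggers a warning entry in the result.
    """
    if df_diff < 1:
        raise ValueError("df_diff must be >= 1")
    raw = 2.0 * (ll_general - ll_restricted)
    warning = raw < -1e-6
    statistic = max(raw, 0.0)
    return {
        "statistic": statistic,
        "p": float(stats.chi2.sf(statistic, df_diff)),
        "df": df_diff,
        "warning": warning,
    }


@dataclass(frozen=True)
class VuongResult:
    """Non-nested comparison of two models via per-observation log-ratios."""

    V: float
    N: int
    m_bar: float
    s_m: float
    preference: str  # "model1" | "model2" | "neither" | "undefined"
    p_one_sided: float
    undefined: bool = False


def vuong_test(
    model1: FittedCountModel, model2: FittedCountModel, data: CountDataset
) -> VuongResult:
    """Vuong statistic V = sqrt(N) * mean(m) / s_m, m_i = ln(mu1_i / mu2_i).

    mu_k_i is model k's predicted probability of the observed count y_i; both
    models must be fitted on the same observations.  V > 1.96 prefers model 1,
    V < -1.96 prefers model 2, otherwise neither.  Identical predicted
    probabilities (s_m = 0) leave the statistic undefined, flagged.
    """
    if model1.n != data.n or model2.n != data.n:
        raise ValueError("both models must use the same observations as `data`")
    y = np.asarray(data.counts)
    p1 = model1.pmf(y, data.predictors)
    p2 = model2.pmf(y, data.predictors)
    m = np.log(np.clip(p1, 1e-300, None)) - np.log(np.clip(p2, 1e-300, None))
    n = len(m)
    m_bar = float(np.mean(m))
    s_m = float(np.std(m, ddof=1)) if n > 1 else 0.0
    if s_m == 0.0:
        return VuongResult(
            V=math.nan,
            N=n,
            m_bar=m_bar,
            s_m=0.0,
            preference="undefined",
            p_one_sided=math.nan,
            undefined=True,
        )
    V = math.sqrt(n) * m_bar / s_m
    if V > 1.96:
        preference = "model1"
    elif V < -1.96:
        preference = "model2"
    else:
        preference = "neither"
    return VuongResult(
        V=V,
        N=n,
        m_bar=m_bar,
        s_m=s_m,
        preference=preference,
        p_one_sided=float(stats.norm.sf(V)),
    )


def pick_distribution(
    fits: Mapping[str, FittedCountModel], data: CountDataset | None = None
) -> dict:
    """Choose a count family from the four intercept-only fits.

    Reports the likelihood-ratio tests (Poisson vs NB, ZIP vs ZINB), the
    Vuong tests (Poisson vs ZIP, NB vs ZINB) and the AIC ranking, then picks
    the family with the lowest AIC; exact ties go to the simplest family and
    are flagged.  Missing fits — or a missing ``data`` table, which makes the
    per-observation Vuong statistic uncomputable — yield a partial decision,
    flagged.
    """
    present = {f: m for f, m in fits.items() if m is not None}
    partial = set(present) != {"poisson", "negbin", "zip", "zinb"} or data is None

    report: dict = {"partial": partial, "lr": {}, "vuong": {}, "aic": {}}
    for name, restricted, general in (
        ("poisson_vs_negbin", "poisson", "negbin"),
        ("zip_vs_zinb", "zip", "zinb"),
    ):
        if restricted in present and general in present:
            report["lr"][name] = lr_test(
                present[restricted].log_likelihood,
                present[general].log_likelihood,
                present[general].df - present[restricted].df,
            )
    if data is not None:
        for name, base, inflated in (
            ("poisson_vs_zip", "poisson", "zip"),
            ("negbin_vs_zinb", "negbin", "zinb"),
        ):
            if base in present and inflated in present:
                res = vuong_test(present[inflated], present[base], data)
                report["vuong"][name] = res

    report["aic"] = {f: m.aic for f, m in present.items()}
    best_aic = min(report["aic"].values())
    tied = sorted(
        (f for f, a in report["aic"].items() if abs(a - best_aic) < 1e-9),
        key=lambda f: FAMILY_COMPLEXITY[f],
    )
    report["family"] = tied[0]
    report["tie"] = len(tied) > 1
    report["justification"] = _justify(report)
    return report


def _justify(report: dict) -> list[str]:
    chain = []
    lr = report["lr"].get("poisson_vs_negbin")
    if lr is not None:
        verdict = "overdispersion" if lr["p"] < 0.05 else "no overdispersion"
        chain.append(
            f"LRT Poisson vs NB: stat={lr['statistic']:.3f}, p={lr['p']:.3g} ({verdict})"
        )
    lr = report["lr"].get("zip_vs_zinb")
    if lr is not None:
        chain.append(f"LRT ZIP vs ZINB: stat={lr['statistic']:.3f}, p={lr['p']:.3g}")
    for name, res in report["vuong"].items():
        chain.append(f"Vuong {name}: V={res.V:.3f} -> {res.preference}")
    chain.append(f"AIC ranking picks {report['family']}")
    return chain


# ---------------------------------------------------------------------------
# model search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchConfig:
    beam_delta: float = 2.0
    max_iterations: int | None = None
    use_aicc: bool = True

    def criterion(self, model: FittedCountModel) -> float:
        value = model.aicc() if self.use_aicc else model.aic
        return value if math.isfinite(value) else math.inf


@dataclass
class CandidateModelSet:
    """All models fitted for one approach/family, plus search provenance."""

    approach: str
    family: str
    models: list[FittedCountModel]
    trace: list[dict] = field(default_factory=list)
    filter_log: list[dict] = field(default_factory=list)
    config: SearchConfig = field(default_factory=SearchConfig)

    def ranked(self) -> list[FittedCountModel]:
        return sorted(self.models, key=self.config.criterion)

    @property
    def best(self) -> FittedCountModel:
        return self.ranked()[0]

    @property
    def best_criterion(self) -> float:
        return self.config.criterion(self.best)

    def write_trace(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for entry in self.trace:
                fh.write(json.dumps(entry) + "\n")


def _spec_key(spec: CountModelSpec) -> tuple:
    zero = (
        tuple(sorted(spec.zero_predictors))
        if spec.zero_predictors is not None
        else None
    )
    return (spec.family, tuple(sorted(spec.count_predictors)), zero)


def _make_spec(
    family: str, predictors: Sequence[str], zi_variant: str | None
) -> CountModelSpec:
    predictors = tuple(predictors)
    if family in ZERO_INFLATED_FAMILIES:
        if zi_variant == "intercept":
            return CountModelSpec(family, predictors, ())
        if zi_variant == "mirror":
            return CountModelSpec(family, predictors, predictors)
        raise ValueError(f"zi_variant must be 'intercept' or 'mirror', got {zi_variant!r}")
    return CountModelSpec(family, predictors, None)


class _FitCache:
    def __init__(self, data: CountDataset):
        self.data = data
        self.cache: dict[tuple, FittedCountModel | None] = {}
        self.trace: list[dict] = []

    def get(self, spec: CountModelSpec) -> FittedCountModel | None:
        key = _spec_key(spec)
        if key in self.cache:
            return self.cache[key]
        try:
            model = fit(spec, self.data)
            status = "ok" if model.converged else "not-converged"
        except Exception as exc:  # fit failures are logged, never fatal
            model = None
            status = f"error: {exc}"
        self.cache[key] = model
        self.trace.append(
            {
                "family": spec.family,
                "count_predictors": list(spec.count_predictors),
                "zero_predictors": (
                    list(spec.zero_predictors)
                    if spec.zero_predictors is not None
                    else None
                ),
                "log_likelihood": model.log_likelihood if model else None,
                "df": model.df if model else None,
                "aicc": model.aicc() if model else None,
                "status": status,
            }
        )
        return model if (model is not None and model.converged) else None


def iterative_search(
    data: CountDataset,
    family: str,
    predictor_pool: Sequence[str],
    zi_variant: str | None = None,
    config: SearchConfig = SearchConfig(),
    approach: str = "combined",
    _cache: "_FitCache | None" = None,
) -> CandidateModelSet:
    """Branching AICc beam search over a predictor pool.

    Starts from the intercept-only model; each iteration extends every base
    model with every absent pool predictor; all models within
    ``config.beam_delta`` of the iteration's best criterion become the next
    bases.  The search stops when no extension lowers the incumbent best
    criterion (a tie counts as "no reduction").  Every fitted model is
    recorded in the returned set; failures are logged and skipped.
    """
    cache = _cache or _FitCache(data)
    crit = config.criterion

    base_spec = _make_spec(family, (), zi_variant)
    base_model = cache.get(base_spec)
    if base_model is None:
        raise RuntimeError("intercept-only model failed to fit")
    recorded: dict[tuple, FittedCountModel] = {_spec_key(base_spec): base_model}
    bases = [base_model]
    incumbent = crit(base_model)

    iteration = 0
    while predictor_pool:
        iteration += 1
        if config.max_iterations is not None and iteration > config.max_iterations:
            break
        iteration_models: dict[tuple, FittedCountModel] = {}
        for base in bases:
            have = set(base.spec.count_predictors)
            for pred in predictor_pool:
                if pred in have:
                    continue
                spec = _make_spec(family, (*base.spec.count_predictors, pred), zi_variant)
                key = _spec_key(spec)
                model = cache.get(spec)
                if model is None:
                    continue
                recorded[key] = model
                iteration_models[key] = model
        if not iteration_models:
            break
        it_best = min(crit(m) for m in iteration_models.values())
        if it_best >= incumbent:
            break
        incumbent = it_best
        bases = [
            m
            for m in iteration_models.values()
            if crit(m) <= it_best + config.beam_delta
        ]

    return CandidateModelSet(
        approach=approach,
        family=family,
        models=list(recorded.values()),
        trace=list(cache.trace),
        config=config,
    )


def search_with_variants(
    data: CountDataset,
    family: str,
    predictor_pool: Sequence[str],
    config: SearchConfig = SearchConfig(),
    approach: str = "combined",
) -> CandidateModelSet:
    """Run the search; for zero-inflated families run both zero-part variants
    (intercept-only and mirrored) as separate lists and pool them before
    ranking."""
    if family not in ZERO_INFLATED_FAMILIES:
        return iterative_search(data, family, predictor_pool, None, config, approach)
    cache = _FitCache(data)
    merged: dict[tuple, FittedCountModel] = {}
    for variant in ("intercept", "mirror"):
        result = iterative_search(
            data, family, predictor_pool, variant, config, approach, _cache=cache
        )
        for model in result.models:
            merged[_spec_key(model.spec)] = model
    return CandidateModelSet(
        approach=approach,
        family=family,
        models=list(merged.values()),
        trace=list(cache.trace),
        config=config,
    )


def exhaustive_search(
    data: CountDataset,
    family: str,
    predictor_pool: Sequence[str],
    zi_variant: str | None = None,
    config: SearchConfig = SearchConfig(),
    approach: str = "exhaustive",
) -> CandidateModelSet:
    """Fit every subset of the pool (2^k models); for small pools only."""
    if len(predictor_pool) > 16:
        raise ValueError("exhaustive search is limited to pools of <= 16 predictors")
    cache = _FitCache(data)
    recorded = []
    pool = list(predictor_pool)
    for mask in range(2 ** len(pool)):
        subset = tuple(p for i, p in enumerate(pool) if mask >> i & 1)
        model = cache.get(_make_spec(family, subset, zi_variant))
        if model is not None:
            recorded.append(model)
    return CandidateModelSet(
        approach=approach,
        family=family,
        models=recorded,
        trace=list(cache.trace),
        config=config,
    )


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def filter_candidates(
    candidate_set: CandidateModelSet,
    p_cutoff: float = 0.15,
    magnitude_cap: float = 50.0,
) -> CandidateModelSet:
    """Drop non-informative candidate models, logging every removal.

    A model is removed when any non-intercept coefficient (count or zero
    part) has p > ``p_cutoff``, or when any coefficient magnitude or standard
    error exceeds ``magnitude_cap`` (symptom of a degenerate fit).  Intercepts
    are exempt from the p filter so intercept-only models always survive it.
    """
    kept: list[FittedCountModel] = []
    log: list[dict] = []
    for model in candidate_set.models:
        reason = _removal_reason(model, p_cutoff, magnitude_cap)
        if reason is None:
            kept.append(model)
        else:
            log.append(
                {
                    "family": model.spec.family,
                    "count_predictors": list(model.spec.count_predictors),
                    "zero_predictors": (
                        list(model.spec.zero_predictors)
                        if model.spec.zero_predictors is not None
                        else None
                    ),
                    "reason": reason,
                }
            )
    return CandidateModelSet(
        approach=candidate_set.approach,
        family=candidate_set.family,
        models=kept,
        trace=candidate_set.trace,
        filter_log=candidate_set.filter_log + log,
        config=candidate_set.config,
    )


def _removal_reason(
    model: FittedCountModel, p_cutoff: float, magnitude_cap: float
) -> str | None:
    table = model.coefficients()
    coef_rows = table[table["part"].isin(["count", "zero"])]
    for row in coef_rows.itertuples(index=False):
        if abs(row.estimate) > magnitude_cap:
            return f"|estimate|>{magnitude_cap:g} ({row.part}:{row.name})"
        if np.isfinite(row.se) and row.se > magnitude_cap:
            return f"SE>{magnitude_cap:g} ({row.part}:{row.name})"
        if not np.isfinite(row.se):
            return f"SE undefined ({row.part}:{row.name})"
    predictors = coef_rows[coef_rows["name"] != INTERCEPT]
    for row in predictors.itertuples(index=False):
        if not np.isfinite(row.p) or row.p > p_cutoff:
            return f"p>{p_cutoff:g} ({row.part}:{row.name})"
    return None


def akaike_weights(criteria: Sequence[float]) -> np.ndarray:
    """exp(-delta/2) weights, normalized; invariant to a common offset."""
    values = np.asarray(criteria, dtype=float)
    delta = values - values.min()
    raw = np.exp(-delta / 2.0)
    return raw / raw.sum()


@dataclass
class AveragedModel:
    """ΔAICc <= 2 members of a candidate set with their Akaike weights."""

    members: list[FittedCountModel]
    deltas: np.ndarray
    weights: np.ndarray
    n_for_aicc: int

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Akaike-weight average of the member models' predicted means."""
        out = np.zeros(len(table))
        for w, model in zip(self.weights, self.members):
            out += w * model.predict_mean(table)
        return out

    def coefficient_table(self) -> pd.DataFrame:
        """Full model average: a predictor absent from a member contributes 0."""
        names: list[tuple[str, str]] = []
        for model in self.members:
            for row in model.coefficients().itertuples(index=False):
                if row.part in {"count", "zero"} and (row.part, row.name) not in names:
                    names.append((row.part, row.name))
        rows = []
        for part, name in names:
            est = 0.0
            for w, model in zip(self.weights, self.members):
                coef = model.count_coef if part == "count" else model.zero_coef
                est += w * coef.get(name, 0.0)
            rows.append({"part": part, "name": name, "estimate": est})
        return pd.DataFrame(rows)


def average_models(
    candidate_set: CandidateModelSet, delta_max: float = 2.0
) -> AveragedModel:
    """Average the ΔAICc <= ``delta_max`` subset of a ranked candidate set."""
    if not candidate_set.models:
        raise ValueError("cannot average an empty candidate set")
    crit = candidate_set.config.criterion
    ranked = candidate_set.ranked()
    best = crit(ranked[0])
    members = [m for m in ranked if crit(m) - best <= delta_max]
    deltas = np.array([crit(m) - best for m in members])
    weights = akaike_weights([crit(m) for m in members])
    return AveragedModel(
        members=members,
        deltas=deltas,
        weights=weights,
        n_for_aicc=members[0].n,
    )


# ---------------------------------------------------------------------------
# cross-approach comparison
# ---------------------------------------------------------------------------

@dataclass
class ApproachComparison:
    """Best criterion per approach x family, with winner flags."""

    table: pd.DataFrame  # index: family, columns: approach
    overall_best: tuple[str, str]  # (approach, family)
    per_family_best: dict[str, str]  # family -> approach
    best_remote: tuple[str, str]  # best among remote-sensed approaches
    ties: bool


def compare_approaches(
    results: Mapping[tuple[str, str], CandidateModelSet | float],
) -> ApproachComparison:
    """Rank approaches x families by their best criterion value.

    ``results`` maps (approach, family) to a candidate set (or directly to a
    best-criterion value).  Empty cells may be omitted; they are reported as
    NaN.  The best remote-sensed approach (200 m / 500 m / 1 km / 3-scales)
    is flagged separately because only those feed the predictive maps.
    """
    approaches = sorted({a for a, _ in results}, key=_approach_order)
    families = sorted({f for _, f in results}, key=lambda f: FAMILY_COMPLEXITY[f])
    table = pd.DataFrame(index=families, columns=approaches, dtype=float)
    for (approach, family), value in results.items():
        if isinstance(value, CandidateModelSet):
            value = value.best_criterion if value.models else math.nan
        table.loc[family, approach] = value

    flat = table.stack()
    if flat.dropna().empty:
        raise ValueError("no non-empty cells to compare")
    best_value = flat.min()
    winners = flat[np.isclose(flat, best_value, rtol=0, atol=1e-9)]
    overall = (winners.index[0][1], winners.index[0][0])  # (approach, family)

    per_family = {}
    for family in families:
        row = table.loc[family].dropna()
        if not row.empty:
            per_family[family] = row.idxmin()

    remote_cols = [a for a in approaches if a in REMOTE_APPROACHES]
    remote = table[remote_cols].stack().dropna() if remote_cols else pd.Series(dtype=float)
    if remote.empty:
        best_remote = ("", "")
    else:
        fam, app = remote.idxmin()
        best_remote = (app, fam)

    return ApproachComparison(
        table=table,
        overall_best=overall,
        per_family_best=per_family,
        best_remote=best_remote,
        ties=len(winners) > 1,
    )


def _approach_order(name: str) -> tuple[int, str]:
    try:
        return (APPROACHES.index(name), name)
    except ValueError:
        return (len(APPROACHES), name)


def summed_importance(
    averaged: Mapping[tuple[str, str], AveragedModel],
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Signed inclusion counts of count-part predictors across frameworks.

    ``averaged`` maps (dataset, group) — e.g. ("highway", "deer") — to that
    group's averaged model.  A variable counts once per framework, as positive
    or negative according to its averaged coefficient sign.  Scale-suffixed
    variants (``water_500m``) roll up to their base variable name.
    """
    rows: dict[str, dict[str, int]] = {}
    datasets = sorted({d for d, _ in averaged})
    for (dataset, _group), model in averaged.items():
        table = model.coefficient_table()
        counted: set[str] = set()
        for row in table.itertuples(index=False):
            if row.part != "count" or row.name == INTERCEPT:
                continue
            base = _strip_scale_suffix(row.name)
            if base in counted:
                continue
            counted.add(base)
            sign = "positive" if row.estimate > 0 else "negative"
            rows.setdefault(base, {})
            key = f"{dataset}_{sign}"
            rows[base][key] = rows[base].get(key, 0) + 1
    index = list(variables) if variables is not None else sorted(rows)
    columns = [f"{d}_{s}" for d in datasets for s in ("positive", "negative")]
    out = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    for var, counts in rows.items():
        if var in out.index:
            for key, value in counts.items():
                out.loc[var, key] = value
    return out


def _strip_scale_suffix(name: str) -> str:
    for suffix in ("_200m", "_500m", "_1000m"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name
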