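"""Cohort statistics: feature–grade tests, survival models, cutoffs, tables.

The analysis chain mirrors a standard imaging-biomarker workup:
Kruskal–Wallis across ordinal IHC grades with Dunn's rank-based post-hoc
pairwise comparisons, Mann–Whitney U between binary groups, univariate Cox
screening feeding a multivariate Cox proportional-hazards model (Efron tie
handling), ROC-based cutoff selection by Youden's J, Kaplan–Meier curves
with the log-rank test, and a stage × imaging-group recurrence table.

Hazard ratios are reported per clinically conventional units (e.g. CoV per
0.10, SLR per 1.0, MTV per 10 cm³); covariates are divided by their unit
before fitting so that the printed HR is per that unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

from .cohort import Cohort

__all__ = [
    "KWResult",
    "DunnResult",
    "CoxResult",
    "CutoffResult",
    "KMCurve",
    "StratTable",
    "kruskal_wallis_by_grade",
    "dunn_posthoc",
    "mann_whitney",
    "cox_fit",
    "univariate_screen",
    "roc_cutoff",
    "km_logrank",
    "recurrence_strat_table",
    "DEFAULT_COX_SCALINGS",
]

logger = logging.getLogger(__name__)

#: per-unit covariate scalings used when reporting hazard ratios
DEFAULT_COX_SCALINGS: dict[str, float] = {
    "cov_suv": 0.10,
    "uniformity": 0.10,
    "mtv_cm3": 10.0,
    "tlg_g": 10.0,
    "slr": 1.0,
    "blr": 1.0,
}


def _records(cohort) -> pd.DataFrame:
    if isinstance(cohort, Cohort):
        return cohort.records
    return cohort


def _grade_groups(df: pd.DataFrame, feature_name: str, marker: str):
    col = marker if marker in df.columns else f"{marker}_grade"
    sub = df[[feature_name, col]].dropna()
    if len(sub) < len(df):
        logger.info("excluded %d records with missing values", len(df) - len(sub))
    return [
        sub.loc[sub[col] == g, feature_name].to_numpy(dtype=float)
        for g in sorted(sub[col].unique())
    ]


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


@dataclass
class KWResult:
    h_statistic: float
    df: int
    p_value: float
    group_sizes: tuple[int, ...]


@dataclass
class DunnResult:
    pairs: tuple[tuple[int, int], ...]
    z_values: tuple[float, ...]
    p_values: tuple[float, ...]
    adjustment: str = "none"


def kruskal_wallis_by_grade(cohort, feature_name: str, marker: str) -> KWResult:
    """Tie-corrected Kruskal–Wallis H across the marker's grade groups."""
    groups = [g for g in _grade_groups(_records(cohort), feature_name, marker) if g.size > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty grade groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return KWResult(0.0, len(groups) - 1, 1.0, tuple(len(g) for g in groups))
    h, p = sps.kruskal(*groups)
    return KWResult(float(h), len(groups) - 1, float(p), tuple(len(g) for g in groups))


def dunn_posthoc(
    cohort, feature_name: str, marker: str, pairs=None, adjustment: str = "none"
) -> DunnResult:
    """Dunn's rank-based post-hoc pairwise z tests with tie-corrected variance.

    ``z(i, j) = (r̄_i − r̄_j) / sqrt((N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j))``
    with tie term ``T = Σ (t³ − t)`` over tied value groups.  Two-sided p per
    pair; ``adjustment`` ∈ {none, bonferroni, holm}.
    """
    groups = _grade_groups(_records(cohort), feature_name, marker)
    k = len(groups)
    if pairs is None:
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    for i, j in pairs:
        if groups[i].size == 0 or groups[j].size == 0:
            raise ValueError(f"pair ({i}, {j}) references an empty group")

    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(k)]

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_core = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    zs, ps = [], []
    for i, j in pairs:
        se = np.sqrt(var_core * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        zs.append(float(z))
        ps.append(float(2.0 * sps.norm.sf(abs(z))))

    ps = _adjust_pvalues(ps, adjustment)
    return DunnResult(tuple(pairs), tuple(zs), tuple(ps), adjustment=adjustment)


def _adjust_pvalues(ps, method: str):
    ps = np.asarray(ps, dtype=float)
    if method == "none":
        pass
    elif method == "bonferroni":
        ps = np.minimum(ps * len(ps), 1.0)
    elif method == "holm":
        order = np.argsort(ps)
        adj = np.empty_like(ps)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, ps[idx] * (len(ps) - rank))
            adj[idx] = min(running, 1.0)
        ps = adj
    else:
        raise ValueError(f"unknown adjustment {method!r}")
    return [float(p) for p in ps]


def mann_whitney(cohort, feature_name: str, binary_factor: str, level=None):
    """Mann–Whitney U between the two levels of a binary factor.

    U is reported for the first (sorted) level's group.  Exact p by
    enumeration when both groups have n ≤ 8 and there are no ties, else the
    tie-corrected normal approximation.
    """
    df = _records(cohort)
    sub = df[[feature_name, binary_factor]].dropna()
    levels = sorted(sub[binary_factor].unique()) if level is None else level
    if len(levels) != 2:
        raise ValueError(f"{binary_factor!r} must have exactly two levels, got {levels}")
    x = sub.loc[sub[binary_factor] == levels[0], feature_name].to_numpy(dtype=float)
    y = sub.loc[sub[binary_factor] == levels[1], feature_name].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (x.size <= 8 and y.size <= 8) else "asymptotic"
    try:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:  # exact method refuses ties
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# survival models
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    covariates: tuple[str, ...]
    coefficients: dict[str, float]
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]
    scalings: dict[str, float]
    log_likelihood: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "CI95_low": self.ci_lower,
                "CI95_high": self.ci_upper,
                "p": self.p_values,
                "per_unit": {c: self.scalings.get(c, 1.0) for c in self.covariates},
            }
        )


def cox_fit(
    cohort,
    covariates,
    scalings: dict[str, float] | None = None,
    duration_col: str = "rfs_months",
    event_col: str = "event",
) -> CoxResult:
    """Cox proportional-hazards fit with Efron tie handling and Wald CIs.

    Covariates are divided by their per-unit scaling before fitting so the
    reported hazard ratio is per that unit (CoV per 0.10, SLR per 1.0, ...).
    """
    df = _records(cohort)
    scalings = {**DEFAULT_COX_SCALINGS, **(scalings or {})}
    covariates = list(covariates)
    sub = df[covariates + [duration_col, event_col]].dropna()
    dropped = len(df) - len(sub)
    if dropped:
        logger.info("cox_fit: excluded %d records with missing values", dropped)
    if sub[event_col].sum() < 1:
        raise ValueError("no events in the cohort; Cox model is not identifiable")
    work = sub.copy()
    for cov in covariates:
        work[cov] = work[cov] / scalings.get(cov, 1.0)
    cph = CoxPHFitter()
    cph.fit(work, duration_col=duration_col, event_col=event_col, show_progress=False)
    s = cph.summary
    return CoxResult(
        covariates=tuple(covariates),
        coefficients={c: float(s.loc[c, "coef"]) for c in covariates},
        hazard_ratios={c: float(s.loc[c, "exp(coef)"]) for c in covariates},
        ci_lower={c: float(np.exp(s.loc[c, "coef lower 95%"])) for c in covariates},
        ci_upper={c: float(np.exp(s.loc[c, "coef upper 95%"])) for c in covariates},
        p_values={c: float(s.loc[c, "p"]) for c in covariates},
        scalings={c: scalings.get(c, 1.0) for c in covariates},
        log_likelihood=float(cph.log_likelihood_),
    )


def univariate_screen(
    cohort,
    candidate_covariates,
    alpha: float = 0.05,
    scalings: dict[str, float] | None = None,
    duration_col: str = "rfs_months",
    event_col: str = "event",
):
    """Covariates with univariate Cox p < alpha, in input order.

    Returns ``(selected, results)`` where ``results`` maps each candidate to
    its univariate :class:`CoxResult`.
    """
    if not candidate_covariates:
        raise ValueError("candidate covariate list is empty")
    selected, results = [], {}
    for cov in candidate_covariates:
        res = cox_fit(cohort, [cov], scalings, duration_col, event_col)
        results[cov] = res
        if res.p_values[cov] < alpha:
            selected.append(cov)
    if not selected:
        logger.info("univariate screen: no covariate significant at alpha=%g", alpha)
    return selected, results


# ---------------------------------------------------------------------------
# cutoffs, survival curves, stratified table
# ---------------------------------------------------------------------------


@dataclass
class CutoffResult:
    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    direction: str = "high_positive"  # which side of the cutoff predicts an event
    criterion: str = "youden"


def roc_cutoff(cohort, feature_name: str, outcome: str = "event") -> CutoffResult:
    """ROC-derived dichotomization cutoff maximizing Youden's J.

    Scans midpoints of consecutive sorted unique feature values.  Both
    dichotomization directions are considered (event-positive above or below
    the cutoff, e.g. low CoV adverse vs high SLR adverse) and the recorded
    ``direction`` names the winning one.  Ties in J break toward the lower
    cutoff; the maximal J over cutoffs equals the two-sample
    Kolmogorov–Smirnov distance between the event and non-event feature
    distributions.
    """
    df = _records(cohort)
    sub = df[[feature_name, outcome]].dropna()
    y = sub[outcome].to_numpy(dtype=int)
    x = sub[feature_name].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    uniq = np.unique(x)
    if uniq.size < 2:
        raise ValueError("feature is constant; no cutoff exists")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    best: CutoffResult | None = None
    for m in mids:
        pred = x > m
        sens = float((pred & (y == 1)).sum() / n_pos)
        spec = float((~pred & (y == 0)).sum() / n_neg)
        j = sens + spec - 1.0
        for direction, jj, se, sp in (
            ("high_positive", j, sens, spec),
            ("low_positive", -j, 1.0 - sens, 1.0 - spec),
        ):
            if best is None or jj > best.youden_j + 1e-15:
                best = CutoffResult(float(m), jj, se, sp, direction=direction)
    return best


@dataclass
class KMCurve:
    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    events: int

    def survival_at(self, t: float) -> float:
        """Product-limit estimate at time t (step function, right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_logrank(cohort, grouping: str, duration_col: str = "rfs_months", event_col: str = "event"):
    """Kaplan–Meier curve per group plus the log-rank test across groups.

    Returns ``(curves, chi2, p)`` where ``curves`` maps group label to
    :class:`KMCurve` (Greenwood variance available through lifelines).
    """
    df = _records(cohort)
    sub = df[[grouping, duration_col, event_col]].dropna()
    groups = sorted(sub[grouping].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    curves = {}
    for g in groups:
        gd = sub[sub[grouping] == g]
        if len(gd) == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(gd[duration_col], gd[event_col], label=str(g))
        ev = kmf.event_table
        curves[g] = KMCurve(
            group=str(g),
            times=ev.index.to_numpy(dtype=float),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(),
            at_risk=ev["at_risk"].to_numpy(dtype=int),
            n=len(gd),
            events=int(gd[event_col].sum()),
        )
    lr = multivariate_logrank_test(sub[duration_col], sub[grouping], sub[event_col])
    return curves, float(lr.test_statistic), float(lr.p_value)


@dataclass
class StratTable:
    """Events/total/rate per (stage group, imaging group) cell."""

    cells: dict[tuple[str, str], dict]
    excluded: int = 0
    cov_cutoff: float = 0.25
    slr_cutoff: float = 0.83

    STAGE_GROUPS = ("I-II", "III-IV")
    IMAGING_GROUPS = ("both_favorable", "mixed", "both_unfavorable")

    def rate(self, stage_group: str, imaging_group: str):
        cell = self.cells[(stage_group, imaging_group)]
        return None if cell["total"] == 0 else 100.0 * cell["events"] / cell["total"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sg, ig), cell in self.cells.items():
            r = self.rate(sg, ig)
            rows.append(
                {
                    "stage_group": sg,
                    "imaging_group": ig,
                    "events": cell["events"],
                    "total": cell["total"],
                    "rate_pct": np.nan if r is None else round(r, 1),
                }
            )
        return pd.DataFrame(rows)


def recurrence_strat_table(
    cohort, cov_cutoff: float = 0.25, slr_cutoff: float = 0.83
) -> StratTable:
    """Recurrence rates stratified by TNM stage group × imaging risk group.

    Imaging groups: both favorable (CoV > cutoff AND SLR < cutoff), mixed
    (exactly one unfavorable), both unfavorable (CoV ≤ cutoff AND SLR ≥
    cutoff).  Records missing CoV, SLR or stage are excluded with a logged
    count.
    """
    df = _records(cohort)
    sub = df[["tnm_stage", "cov_suv", "slr", "event"]].dropna()
    excluded = len(df) - len(sub)
    if excluded:
        logger.info("strat table: excluded %d records with missing values", excluded)

    stage_group = np.where(sub["tnm_stage"].isin(["I", "II"]), "I-II", "III-IV")
    cov_fav = sub["cov_suv"].to_numpy() > cov_cutoff
    slr_fav = sub["slr"].to_numpy() < slr_cutoff
    imaging = np.where(
        cov_fav & slr_fav,
        "both_favorable",
        np.where(~cov_fav & ~slr_fav, "both_unfavorable", "mixed"),
    )
    events = sub["event"].to_numpy(dtype=int)

    cells = {}
    for sg in StratTable.STAGE_GROUPS:
        for ig in StratTable.IMAGING_GROUPS:
            sel = (stage_group == sg) & (imaging == ig)
            cells[(sg, ig)] = {"events": int(events[sel].sum()), "total": int(sel.sum())}
    return StratTable(cells=cells, excluded=excluded, cov_cutoff=cov_cutoff, slr_cutoff=slr_cutoff)
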