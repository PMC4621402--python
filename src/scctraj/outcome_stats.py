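"""Outcome definitions and the inferential battery.

The outcome is the pre-minus-post KS-II change score (positive =
symptom relief); *improvement* is a change strictly greater than the
KS-II reliable-change threshold (56.6 by default), everything else —
no reliable change or deterioration — counts as "no improvement".

The battery relates trajectory shape and fluctuation to outcome:

* likelihood-ratio (G) tests on improvement x shape 2x2 tables, for the
  whole sample and within each personality disposition
  (:func:`shape_frequency_tests`);
* Pearson correlations between fluctuation (RMSE) and change within
  disposition strata (:func:`subgroup_correlation`);
* the moderation regression ``change ~ rmse * pd_fi`` where ``pd_fi``
  indicates the integrated-functional disposition against the pooled
  other three (:func:`fit_interaction_model`);
* a two-factor ANOVA of change on shape x pd_fi with partial eta²
  (:func:`two_way_anova`);
* the intercept-only three-level variance-components model (subjects in
  therapy groups in therapeutic units) fitted by ML/REML
  (:func:`variance_components_null`).

Functions operate on a *cohort table*: a pandas DataFrame with one row
per subject carrying at least the columns each function documents
(``change``, ``improved``, ``shape``, ``disposition``, ``rmse``,
``group_id``, ``unit_id``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .cohort import Disposition
from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidArgumentError,
    InvalidCohortError,
    InvalidTableError,
    UndefinedCorrelationError,
)
from .psychometrics import KS2, InstrumentSpec
from .trajectory import ShapeLabel

__all__ = [
    "change_score",
    "improvement_flag",
    "FourfoldTable",
    "GTestResult",
    "g_test_2x2",
    "ShapeFrequencyTest",
    "shape_frequency_tests",
    "subgroup_correlation",
    "InteractionFit",
    "fit_interaction_model",
    "AnovaResult",
    "two_way_anova",
    "WaldStat",
    "VarianceComponents",
    "variance_components_null",
]

log = logging.getLogger(__name__)

IF = Disposition.INTEGRATED_FUNCTIONAL.value


def change_score(
    ks2_pre: float, ks2_post: float, instrument: InstrumentSpec = KS2
) -> float:
    """Pre-minus-post symptom change; positive values mean improvement."""
    for label, score in (("pre", ks2_pre), ("post", ks2_post)):
        if not instrument.in_range(score):
            raise InvalidArgumentError(
                f"{instrument.name} {label} score {score} outside "
                f"[{instrument.score_min}, {instrument.score_max}]"
            )
    return float(ks2_pre - ks2_post)


def improvement_flag(change: float, threshold: float = 56.6) -> bool:
    """True iff the change exceeds the reliable-change threshold (strict)."""
    if threshold <= 0:
        raise InvalidArgumentError("threshold must be > 0")
    return change > threshold


# ---------------------------------------------------------------------------
# Likelihood-ratio tests on fourfold tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FourfoldTable:
    """2x2 counts: rows improvement/no-improvement, columns in/out of shape."""

    a: int  # improved, in shape
    b: int  # improved, not in shape
    c: int  # not improved, in shape
    d: int  # not improved, not in shape

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise InvalidTableError("cells must be non-negative integers")
        if self.a + self.b + self.c + self.d < 1:
            raise InvalidTableError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> Tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class GTestResult:
    statistic: float
    df: int
    p: float


def g_test_2x2(table: FourfoldTable) -> GTestResult:
    """Likelihood-ratio test of independence on a fourfold table.

    ``G = 2 sum O ln(O/E)`` with expecteds from the independence
    margins and the ``0 ln 0 = 0`` convention; referred to chi²(1).
    Zero margins are rejected (the test is undefined there).
    """
    if any(m == 0 for m in table.margins()):
        raise InvalidTableError(f"zero margin in {table}")
    g, p, dof, _ = stats.chi2_contingency(
        table.to_array(), correction=False, lambda_="log-likelihood"
    )
    return GTestResult(statistic=float(g), df=int(dof), p=float(p))


@dataclass(frozen=True)
class ShapeFrequencyTest:
    stratum: str
    shape: str
    table: FourfoldTable
    result: Optional[GTestResult]
    skipped: bool = False
    note: str = ""


def shape_frequency_tests(cohort: pd.DataFrame) -> List[ShapeFrequencyTest]:
    """Improvement x shape G-tests for the whole sample and each disposition.

    For each stratum (whole sample plus the four dispositions) and each
    of the five shapes, builds the 2x2 table of improvement against
    membership in that shape (vs all other shapes) and runs the
    likelihood-ratio test.  Strata/shapes with a zero margin are
    returned with ``skipped=True`` and a note instead of a result.
    """
    required = {"shape", "disposition", "improved"}
    missing = required - set(cohort.columns)
    if missing:
        raise InvalidArgumentError(f"cohort table lacks columns {sorted(missing)}")
    strata = [("whole_sample", cohort)]
    for disp in Disposition:
        strata.append((disp.value, cohort[cohort["disposition"] == disp.value]))
    out: List[ShapeFrequencyTest] = []
    for name, sub in strata:
        improved = sub["improved"].astype(bool)
        for shape in ShapeLabel:
            in_shape = sub["shape"] == shape.value
            tab = FourfoldTable(
                a=int((improved & in_shape).sum()),
                b=int((improved & ~in_shape).sum()),
                c=int((~improved & in_shape).sum()),
                d=int((~improved & ~in_shape).sum()),
            ) if len(sub) else None
            if tab is None or any(m == 0 for m in tab.margins()):
                note = "empty stratum" if tab is None else "zero margin"
                log.info("G-test skipped for %s / %s: %s", name, shape.value, note)
                out.append(ShapeFrequencyTest(name, shape.value,
                                              tab or FourfoldTable(0, 0, 0, 1),
                                              None, skipped=True, note=note))
                continue
            out.append(ShapeFrequencyTest(name, shape.value, tab, g_test_2x2(tab)))
    return out


# ---------------------------------------------------------------------------
# Correlation and moderation
# ---------------------------------------------------------------------------

def _stratum_mask(cohort: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum in ("whole", "whole_sample"):
        return pd.Series(True, index=cohort.index)
    if stratum in (d.value for d in Disposition):
        return cohort["disposition"] == stratum
    if stratum in ("other_three", "not_integrated_functional"):
        return cohort["disposition"] != IF
    raise InvalidArgumentError(f"unknown stratum {stratum!r}")


def subgroup_correlation(
    cohort: pd.DataFrame, stratum: str = "whole"
) -> Tuple[float, int, float]:
    """Pearson r between fluctuation RMSE and change within a stratum.

    ``stratum`` is ``"whole"``, one of the four disposition values, or
    ``"other_three"`` (everyone but integrated-functional).  Returns
    ``(r, n, p)`` with a two-sided p.
    """
    sub = cohort[_stratum_mask(cohort, stratum)]
    n = len(sub)
    if n < 3:
        raise InsufficientDataError(f"stratum {stratum!r} has n={n} < 3")
    x = sub["rmse"].to_numpy(float)
    y = sub["change"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError(f"zero variance in stratum {stratum!r}")
    r, p = stats.pearsonr(x, y)
    return float(r), n, float(p)


@dataclass(frozen=True)
class InteractionFit:
    """OLS moderation fit ``change ~ rmse * pd_fi`` with sequential R²."""

    params: Dict[str, float]
    tvalues: Dict[str, float]
    pvalues: Dict[str, float]
    incremental_r2: Dict[str, float]  # sequential, in the order rmse, pd_fi, rmse:pd_fi
    total_r2: float
    n: int


def fit_interaction_model(cohort: pd.DataFrame) -> InteractionFit:
    """Moderation of the fluctuation-outcome slope by disposition.

    ``pd_fi`` is 1 for integrated-functional subjects, 0 for the pooled
    other three dispositions, so the ``rmse`` coefficient is the slope
    of the pooled-others group and the interaction coefficient is the
    integrated-functional minus pooled-others slope difference.
    Explained variance per term is the sequential (incremental) R² when
    terms enter in the order rmse, pd_fi, rmse x pd_fi.
    """
    df = cohort.copy()
    df["pd_fi"] = (df["disposition"] == IF).astype(float)
    if df["pd_fi"].nunique() < 2:
        raise InvalidCohortError("both disposition strata must be non-empty")
    if df["rmse"].std() == 0:
        raise DegenerateDesignError("rmse has zero variance")
    y = df["change"].to_numpy(float)
    terms = ["rmse", "pd_fi", "rmse:pd_fi"]
    X = pd.DataFrame({
        "Intercept": 1.0,
        "rmse": df["rmse"].to_numpy(float),
        "pd_fi": df["pd_fi"].to_numpy(float),
    })
    X["rmse:pd_fi"] = X["rmse"] * X["pd_fi"]
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DegenerateDesignError("collinear moderation design")
    full = sm.OLS(y, X).fit()
    incremental: Dict[str, float] = {}
    prev_r2 = 0.0
    cols = ["Intercept"]
    for term in terms:
        cols.append(term)
        r2 = sm.OLS(y, X[cols]).fit().rsquared
        incremental[term] = float(r2 - prev_r2)
        prev_r2 = float(r2)
    return InteractionFit(
        params={k: float(v) for k, v in full.params.items()},
        tvalues={k: float(v) for k, v in full.tvalues.items()},
        pvalues={k: float(v) for k, v in full.pvalues.items()},
        incremental_r2=incremental,
        total_r2=float(full.rsquared),
        n=len(df),
    )


# ---------------------------------------------------------------------------
# Two-factor ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    """Shape x disposition-contrast ANOVA with partial eta² and cell stats."""

    table: pd.DataFrame          # index: term; columns: sum_sq, df, F, p, partial_eta2
    cell_stats: pd.DataFrame     # index: (shape, pd_fi); columns: mean, sd, n
    dropped_levels: Tuple[str, ...] = ()


def two_way_anova(cohort: pd.DataFrame) -> AnovaResult:
    """Two-factor ANOVA of change on shape (5 levels) x pd_fi (2 levels).

    Uses Type-III sums of squares with sum-to-zero contrasts (the
    common factorial default for unbalanced designs) and reports
    partial eta² = SS_effect / (SS_effect + SS_error) per term together
    with the cell means and SDs.  Factor levels with no observations
    are dropped with a notice.
    """
    df = cohort.copy()
    df["pd_fi"] = np.where(df["disposition"] == IF, "if", "other")
    present = [s.value for s in ShapeLabel if (df["shape"] == s.value).any()]
    dropped = tuple(s.value for s in ShapeLabel if s.value not in present)
    if dropped:
        log.info("ANOVA: dropping empty shape levels %s", dropped)
    df = df[df["shape"].isin(present)]
    if df["pd_fi"].nunique() < 2 or len(present) < 2:
        raise InvalidCohortError("ANOVA needs >= 2 levels on both factors")
    model = smf.ols(
        "change ~ C(shape, Sum) * C(pd_fi, Sum)", data=df
    ).fit()
    at = anova_lm(model, typ=3)
    at = at.rename(index=lambda s: (
        s.replace("C(shape, Sum):C(pd_fi, Sum)", "shape:pd_fi")
         .replace("C(shape, Sum)", "shape")
         .replace("C(pd_fi, Sum)", "pd_fi")
    ))
    ss_err = float(at.loc["Residual", "sum_sq"])
    rows = {}
    for term in ("shape", "pd_fi", "shape:pd_fi"):
        ss = float(at.loc[term, "sum_sq"])
        rows[term] = {
            "sum_sq": ss,
            "df": float(at.loc[term, "df"]),
            "F": float(at.loc[term, "F"]),
            "p": float(at.loc[term, "PR(>F)"]),
            "partial_eta2": ss / (ss + ss_err) if ss + ss_err > 0 else 0.0,
        }
    rows["Residual"] = {
        "sum_sq": ss_err, "df": float(at.loc["Residual", "df"]),
        "F": np.nan, "p": np.nan, "partial_eta2": np.nan,
    }
    cells = (
        df.groupby(["shape", "pd_fi"])["change"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
    )
    return AnovaResult(table=pd.DataFrame(rows).T, cell_stats=cells,
                       dropped_levels=dropped)


# ---------------------------------------------------------------------------
# Three-level variance-components null model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaldStat:
    estimate: float
    se: float
    z: float
    p: float


@dataclass(frozen=True)
class VarianceComponents:
    """Null-model variance decomposition with Wald (estimate/SE) tests."""

    residual: float
    var_group: float
    var_unit: float
    intercept: float
    wald: Dict[str, WaldStat]
    loglik: float
    method: str
    notes: Tuple[str, ...] = ()


def _vc_neg_criterion(theta, y, Zs, reml):
    """Negative (RE)ML criterion for the intercept-only nested model.

    ``theta`` holds (residual, *component variances*) in the order of
    ``Zs``; the grand mean is profiled out by GLS.
    """
    n = len(y)
    V = theta[0] * np.eye(n)
    for s2, Z in zip(theta[1:], Zs):
        V += s2 * (Z @ Z.T)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ones = np.ones(n)
    Vi_y = np.linalg.solve(L.T, np.linalg.solve(L, y))
    Vi_1 = np.linalg.solve(L.T, np.linalg.solve(L, ones))
    denom = float(ones @ Vi_1)
    mu = float(ones @ Vi_y) / denom
    r = y - mu
    Vi_r = Vi_y - mu * Vi_1
    quad = float(r @ Vi_r)
    crit = 0.5 * (logdet + quad + n * math.log(2 * math.pi))
    if reml:
        crit += 0.5 * math.log(denom)
    return crit


def variance_components_null(
    cohort: pd.DataFrame, reml: bool = True
) -> VarianceComponents:
    """Intercept-only three-level random-intercept model for change scores.

    Level 1 is the subject, level 2 the therapy group, level 3 the
    therapeutic unit (groups nested in units).  The Gaussian (restricted)
    likelihood is maximised directly over the non-negative variance
    components with the grand mean profiled out; Wald statistics are
    estimate/SE with SEs from the numerically differentiated observed
    information, referred to a standard normal.  With a single group
    and/or unit the corresponding component is fixed at zero with a
    note (it is not identifiable).
    """
    y = cohort["change"].to_numpy(float)
    n = len(y)
    if n < 2:
        raise InsufficientDataError("need at least 2 subjects")
    notes: List[str] = []
    comp_names: List[str] = []
    Zs: List[np.ndarray] = []
    for name, col in (("var_group", "group_id"), ("var_unit", "unit_id")):
        codes, levels = pd.factorize(cohort[col].astype(str))
        if len(levels) < 2:
            notes.append(f"{name}: single level, component fixed at 0")
            continue
        Z = np.zeros((n, len(levels)))
        Z[np.arange(n), codes] = 1.0
        comp_names.append(name)
        Zs.append(Z)
    s2 = float(np.var(y))
    method = "REML" if reml else "ML"
    if s2 == 0.0:
        wald = {k: WaldStat(0.0, math.nan, math.nan, math.nan)
                for k in ["residual", *comp_names]}
        return VarianceComponents(0.0, 0.0, 0.0, float(np.mean(y)), wald,
                                  loglik=math.inf, method=method,
                                  notes=tuple(notes + ["zero outcome variance"]))

    m = 1 + len(Zs)
    # optimise on the scale of var(y) for conditioning
    def f(u):
        return _vc_neg_criterion(u * s2, y, Zs, reml)

    best = None
    starts = [np.r_[1.0, [0.25] * len(Zs)],
              np.r_[1.0, [0.01] * len(Zs)],
              np.r_[0.5, [0.5] * len(Zs)]]
    bounds = [(1e-10, None)] + [(0.0, None)] * len(Zs)
    for u0 in starts:
        res = optimize.minimize(f, u0[:m], method="L-BFGS-B", bounds=bounds,
                                options={"ftol": 1e-14, "gtol": 1e-10,
                                         "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x * s2
    crit = float(best.fun)

    # observed information by central finite differences on the variance scale
    wald: Dict[str, WaldStat] = {}
    names = ["residual", *comp_names]
    h = np.maximum(1e-4 * np.abs(theta), 1e-7 * s2)

    def g(t):
        return _vc_neg_criterion(np.maximum(t, 0.0), y, Zs, reml)

    H = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            if i == j:
                H[i, i] = (g(theta + ei) - 2 * crit + g(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    g(theta + ei + ej) - g(theta + ei - ej)
                    - g(theta - ei + ej) + g(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        ses = np.sqrt(np.where(np.diag(cov) > 0, np.diag(cov), np.nan))
    except np.linalg.LinAlgError:
        ses = np.full(m, np.nan)
    for k, name in enumerate(names):
        est = float(theta[k])
        se = float(ses[k])
        z = est / se if se and not math.isnan(se) and se > 0 else math.nan
        p = 2 * stats.norm.sf(abs(z)) if not math.isnan(z) else math.nan
        wald[name] = WaldStat(est, se, z, float(p) if not math.isnan(z) else math.nan)

    comp = dict(zip(comp_names, theta[1:]))
    # recover the GLS grand mean at the optimum
    V = theta[0] * np.eye(n)
    for s2k, Z in zip(theta[1:], Zs):
        V += s2k * (Z @ Z.T)
    Vi1 = np.linalg.solve(V, np.ones(n))
    mu = float(Vi1 @ y) / float(Vi1 @ np.ones(n))
    return VarianceComponents(
        residual=float(theta[0]),
        var_group=float(comp.get("var_group", 0.0)),
        var_unit=float(comp.get("var_unit", 0.0)),
        intercept=mu,
        wald=wald,
        loglik=-crit,
        method=method,
        notes=tuple(notes),
    )
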