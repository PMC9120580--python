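"""Cohort statistics: demographics, covariate-adjusted group comparison,
and severity/symptom rank correlations.

The group comparison is an ANCOVA: a linear model
``value ~ intercept + group + age + sex`` with the group effect tested by
the t statistic on the group coefficient (equivalently the partial F, its
square).  Adjusted group means are model predictions at the grand-mean
covariates.  Multiple comparisons within a table family are handled by
Bonferroni correction, p_adj = min(1, m * p).  Rank correlations are
Spearman's, implemented as Pearson correlation of mid-ranks (the standard
tie correction); missing values are deleted pairwise throughout.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import SubjectRecord, ValidationError

#: continuous demographics variables reported per group
DEMOGRAPHIC_VARIABLES = (
    "age",
    "bmi",
    "heart_rate",
    "systolic_bp",
    "diastolic_bp",
    "psqi",
    "ess",
    "ahi",
    "sao2_nadir",
    "sao2_baseline",
    "delta_sao2",
)

#: the reported severity/symptom correlation panel:
#: (clinical variable, ROI, component) pairs within OSA subjects
DEFAULT_CORRELATION_PANEL = (
    ("ess", "projection", "dxy"),
    ("sao2_nadir", "projection", "dxx"),
    ("delta_sao2", "projection", "dxx"),
    ("ahi", "association", "dzz"),
)


@dataclass
class GroupComparison:
    variable: str
    adjusted_means: Dict[str, float]
    raw_p: float
    adjusted_p: float
    family_size: int
    covariates: Tuple[str, ...]
    group_effect: float = math.nan  # OSA minus control, covariate-adjusted
    f_statistic: float = math.nan
    n: int = 0


@dataclass
class CorrelationResult:
    clinical_variable: str
    roi: str
    component: str
    r: Optional[float]
    p: Optional[float]
    n: int
    estimable: bool = True


def bonferroni(p: float, family_size: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if family_size < 1:
        raise ValidationError("family size must be >= 1")
    return min(1.0, family_size * p)


def delta_sao2(baseline: float, nadir: float) -> float:
    """Oxygen-desaturation depth: baseline SaO2 minus SaO2 nadir (%)."""
    for name, v in (("baseline", baseline), ("nadir", nadir)):
        if not (0 < v <= 100):
            raise ValidationError(f"SaO2 {name} must lie in (0, 100], got {v}")
    if nadir > baseline:
        warnings.warn(
            f"SaO2 nadir ({nadir}) exceeds baseline ({baseline}); "
            "keeping the negative desaturation",
            stacklevel=2,
        )
    return baseline - nadir


def bp_average(systolic: float, diastolic: float) -> float:
    """Average blood pressure: mean of systolic and diastolic (mmHg)."""
    return (systolic + diastolic) / 2.0


def classify_ahi(ahi: float) -> str:
    """OSA severity category from the apnea-hypopnea index (events/hour):
    <5 none, 5-14 mild, 15-30 moderate, >30 severe."""
    if ahi < 0 or not np.isfinite(ahi):
        raise ValidationError(f"AHI must be finite and non-negative, got {ahi}")
    if ahi < 5:
        return "none"
    if ahi < 15:
        return "mild"
    if ahi <= 30:
        return "moderate"
    return "severe"


def flag_sleep_scores(psqi: float, ess: float) -> Tuple[bool, bool]:
    """Abnormality flags: PSQI > 5 and ESS > 10, both strict."""
    if psqi < 0 or ess < 0:
        raise ValidationError("sleep scores must be non-negative")
    return psqi > 5, ess > 10


def _group_values(records: Sequence[SubjectRecord], variable: str):
    out = {"OSA": [], "control": []}
    for rec in records:
        v = rec.delta_sao2 if variable == "delta_sao2" else getattr(rec, variable)
        if v is not None and np.isfinite(v):
            out[rec.group].append(float(v))
    return {g: np.asarray(v) for g, v in out.items()}


def ttest_from_stats(mean1, sd1, n1, mean2, sd2, n2, welch: bool = False):
    """Two-sided independent t-test from printed summary statistics."""
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch
    )
    return float(res.statistic), float(res.pvalue)


def demographics_table(
    records: Sequence[SubjectRecord], welch: bool = False, yates: bool = False
) -> pd.DataFrame:
    """Per-variable group means +/- SD with group-difference p-values.

    Continuous variables use the independent-samples t-test
    (pooled-variance by default, Welch by flag); sex uses the 2x2 Pearson
    chi-square (no continuity correction by default).  Missing values are
    excluded per variable, with the per-group n reported.
    """
    rows = []
    for variable in DEMOGRAPHIC_VARIABLES:
        groups = _group_values(records, variable)
        osa, ctl = groups["OSA"], groups["control"]
        row = {
            "variable": variable,
            "osa_mean": osa.mean() if len(osa) else math.nan,
            "osa_sd": osa.std(ddof=1) if len(osa) > 1 else math.nan,
            "osa_n": len(osa),
            "control_mean": ctl.mean() if len(ctl) else math.nan,
            "control_sd": ctl.std(ddof=1) if len(ctl) > 1 else math.nan,
            "control_n": len(ctl),
            "test": "t",
            "p": math.nan,
        }
        if len(osa) > 1 and len(ctl) > 1:
            if osa.std() == 0 and ctl.std() == 0:
                row["p"] = math.nan if osa.mean() != ctl.mean() else 1.0
            else:
                res = stats.ttest_ind(osa, ctl, equal_var=not welch)
                row["p"] = float(res.pvalue)
        rows.append(row)

    counts = np.zeros((2, 2))
    for rec in records:
        counts[0 if rec.group == "OSA" else 1, 0 if rec.sex == "male" else 1] += 1
    sex_row = {
        "variable": "sex_male_female",
        "osa_mean": counts[0, 0],
        "osa_sd": counts[0, 1],
        "osa_n": int(counts[0].sum()),
        "control_mean": counts[1, 0],
        "control_sd": counts[1, 1],
        "control_n": int(counts[1].sum()),
        "test": "chi2",
        "p": math.nan,
    }
    try:
        _, p, _, _ = stats.chi2_contingency(counts, correction=yates)
        sex_row["p"] = float(p)
    except ValueError:
        pass  # a zero marginal leaves the chi-square undefined
    rows.append(sex_row)
    return pd.DataFrame(rows)


def ancova_group_compare(
    values: np.ndarray,
    group: Sequence[str],
    age: np.ndarray,
    sex: Sequence[str],
    family_size: int = 1,
    variable: str = "",
) -> GroupComparison:
    """Covariate-adjusted (age, sex) group comparison of one outcome.

    Sex is coded male = 0, female = 1; group OSA = 1, control = 0.
    Constant covariate columns are dropped (the model then reduces exactly
    to the pooled-variance two-sample t-test).  Subjects with a missing
    outcome or covariate are excluded listwise for this outcome.
    """
    values = np.asarray(
        [math.nan if v is None else float(v) for v in values], dtype=float
    )
    g = np.asarray([1.0 if str(x) == "OSA" else 0.0 for x in group])
    age = np.asarray([math.nan if v is None else float(v) for v in age], dtype=float)
    sx = np.asarray([1.0 if str(x) == "female" else 0.0 for x in sex])
    keep = np.isfinite(values) & np.isfinite(age)
    values, g, age, sx = values[keep], g[keep], age[keep], sx[keep]
    n = len(values)
    if len(np.unique(g)) < 2:
        raise ValidationError("both groups must be present")
    if n < 4:
        raise ValidationError(f"too few complete subjects for ANCOVA (n = {n})")

    columns = [("intercept", np.ones(n)), ("group", g)]
    for name, col in (("age", age), ("sex", sx)):
        if np.ptp(col) > 0:
            columns.append((name, col))
    names = [c[0] for c in columns]
    X = np.column_stack([c[1] for c in columns])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for j in range(2, X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X):
                raise ValidationError(f"covariate {names[j]!r} is collinear")
        raise ValidationError("design matrix is rank deficient")

    if n - X.shape[1] <= 0:
        raise ValidationError("no residual degrees of freedom")
    fit = sm.OLS(values, X).fit()
    beta = np.asarray(fit.params)
    tstat = float(fit.tvalues[1])
    raw_p = float(fit.pvalues[1])

    x_ref = {"intercept": 1.0, "group": 0.0, "age": age.mean(), "sex": sx.mean()}
    base = np.array([x_ref[name] for name in names])
    adj_control = float(base @ beta)
    base[names.index("group")] = 1.0
    adj_osa = float(base @ beta)

    return GroupComparison(
        variable=variable,
        adjusted_means={"OSA": adj_osa, "control": adj_control},
        raw_p=float(raw_p),
        adjusted_p=bonferroni(float(raw_p), family_size) if np.isfinite(raw_p) else math.nan,
        family_size=family_size,
        covariates=tuple(names[2:]),
        group_effect=float(beta[1]),
        f_statistic=float(tstat**2) if np.isfinite(tstat) else math.nan,
        n=n,
    )


def _midranks(x: np.ndarray) -> np.ndarray:
    """Mid-ranks (average rank for ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman(
    x: Sequence,
    y: Sequence,
    clinical_variable: str = "x",
    roi: str = "",
    component: str = "y",
    exact: bool = False,
) -> CorrelationResult:
    """Spearman rank correlation with pairwise deletion of missing pairs.

    r is the Pearson correlation of mid-ranks (tie-corrected); the
    two-sided p comes from t = r * sqrt((n-2) / (1-r^2)).  With
    ``exact=True`` and n <= 9 the p-value is computed by exhaustive
    permutation instead.
    """
    x = np.asarray([math.nan if v is None else float(v) for v in x], dtype=float)
    y = np.asarray([math.nan if v is None else float(v) for v in y], dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            clinical_variable, roi, component, r=None, p=None, n=n, estimable=False
        )
    rx, ry = _midranks(x), _midranks(y)
    rx_c, ry_c = rx - rx.mean(), ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    r = float(rx_c @ ry_c) / denom

    if exact:
        if n > 9:
            raise ValidationError("exact permutation p only supported for n <= 9")
        perms = np.array(list(itertools.permutations(ry)))
        perms_c = perms - perms.mean(axis=1, keepdims=True)
        norms = np.sqrt((perms_c**2).sum(axis=1) * float(rx_c @ rx_c))
        r_all = (perms_c @ rx_c) / norms
        p = float(np.mean(np.abs(r_all) >= abs(r) - 1e-12))
    else:
        r_cl = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
        tstat = r_cl * math.sqrt((n - 2) / (1 - r_cl**2))
        p = float(2 * stats.t.sf(abs(tstat), n - 2))
    return CorrelationResult(clinical_variable, roi, component, r=r, p=p, n=n)


def severity_correlation_panel(
    records: Sequence[SubjectRecord],
    panel: Sequence[Tuple[str, str, str]] = DEFAULT_CORRELATION_PANEL,
    full_grid: bool = False,
) -> List[CorrelationResult]:
    """Severity/symptom vs diffusivity-component correlations in OSA subjects.

    The default panel is the reported set (projection: ESS-Dxy,
    SaO2-nadir-Dxx, dSaO2-Dxx; association: AHI-Dzz); ``full_grid=True``
    crosses every severity variable with every component in both ROIs.
    Cells with fewer than 3 complete pairs are reported as not estimable.
    """
    osa = [r for r in records if r.group == "OSA" and r.alps is not None]
    if full_grid:
        clin_vars = ("ahi", "sao2_nadir", "delta_sao2", "psqi", "ess")
        from .types import COMPONENT_NAMES

        panel = [
            (cv, roi, comp)
            for cv in clin_vars
            for roi in ("projection", "association")
            for comp in COMPONENT_NAMES
        ]
    results = []
    for clin_var, roi, comp in panel:
        clin = [
            r.delta_sao2 if clin_var == "delta_sao2" else getattr(r, clin_var)
            for r in osa
        ]
        diff = [getattr(r.alps, roi)[comp] for r in osa]
        try:
            results.append(spearman(clin, diff, clin_var, roi, comp))
        except ValidationError:
            n = sum(
                1
                for c, d in zip(clin, diff)
                if c is not None and d is not None
            )
            results.append(
                CorrelationResult(clin_var, roi, comp, None, None, n, estimable=False)
            )
    return results


def correlation_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "clinical_variable": c.clinical_variable,
                "roi": c.roi,
                "component": c.component,
                "r": c.r,
                "p": c.p,
                "n": c.n,
                "estimable": c.estimable,
            }
            for c in results
        ]
    )


def format_p(p: float) -> str:
    """Report p at three decimals with a '<0.001' floor."""
    if not np.isfinite(p):
        return "undefined"
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def group_outcome_table(
    records: Sequence[SubjectRecord],
    outcomes: Sequence[str] = ("alps", "d_xmean", "d_yzmean"),
    family_size: Optional[int] = None,
) -> pd.DataFrame:
    """ANCOVA table over per-subject ALPS outcomes (Bonferroni family =
    the number of outcomes unless overridden)."""
    m = family_size if family_size is not None else len(outcomes)
    subs = [r for r in records if r.alps is not None]
    rows = []
    for outcome in outcomes:
        vals = []
        for r in subs:
            row = r.alps.to_row()
            vals.append(row["alps"] if outcome == "alps" else row[outcome])
        osa_vals = np.asarray([v for v, r in zip(vals, subs) if r.group == "OSA"])
        ctl_vals = np.asarray([v for v, r in zip(vals, subs) if r.group == "control"])
        cmp = ancova_group_compare(
            vals,
            [r.group for r in subs],
            [r.age for r in subs],
            [r.sex for r in subs],
            family_size=m,
            variable=outcome,
        )
        rows.append(
            {
                "variable": outcome,
                "osa_mean": osa_vals.mean(),
                "osa_sd": osa_vals.std(ddof=1),
                "osa_median": float(np.median(osa_vals)),
                "control_mean": ctl_vals.mean(),
                "control_sd": ctl_vals.std(ddof=1),
                "control_median": float(np.median(ctl_vals)),
                "adjusted_osa_mean": cmp.adjusted_means["OSA"],
                "adjusted_control_mean": cmp.adjusted_means["control"],
                "group_effect": cmp.group_effect,
                "raw_p": cmp.raw_p,
                "bonferroni_p": cmp.adjusted_p,
                "family_size": m,
                "n": cmp.n,
            }
        )
    return pd.DataFrame(rows)
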