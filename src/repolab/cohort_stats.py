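"""Case-control statistics: summaries, group tests and the confounder model.

Continuous variables are summarised as mean +/- SEM and compared across
groups with the (tie-corrected) Kruskal-Wallis test; binary variables are
summarised as percentages and compared with Fisher's exact test (two-sided,
probability-mass rule by default).  A value is flagged abnormal when it lies
more than 2 reference SDs from the reference mean.  The confounder analysis
is an ordinary least-squares fit of a morphology outcome on the group label
plus demographic and treatment covariates, with BMI dropped by default to
avoid its structural collinearity with height and weight.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (CollinearCovariatesError, EmptyGroupError,
                     InvalidReferenceError)

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class GroupComparison:
    """One summary-table row: a variable compared between two groups."""
    variable: str
    control_summary: str
    case_summary: str
    test: str                   # "kruskal_wallis" | "fisher_exact"
    statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


@dataclass
class LinearModelResult:
    """OLS confounder-model output for one morphology outcome."""
    outcome: str
    coefficients: pd.DataFrame   # index: covariate; columns: coef, se, p_value
    n: int
    r_squared: float


def summarize(values) -> tuple[float, float, int]:
    """Mean and SEM (SD/sqrt(n), n-1 denominator) of one group's values.

    A single observation yields SEM 0 with a warning; an empty group raises
    :class:`EmptyGroupError`.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n == 0:
        raise EmptyGroupError("empty group")
    if n == 1:
        warnings.warn("SEM undefined for a single observation; reported as 0",
                      stacklevel=2)
        return float(x[0]), 0.0, 1
    return float(x.mean()), float(x.std(ddof=1) / math.sqrt(n)), n


def flag_abnormal(value: float, reference_mean: float, reference_sd: float) -> bool:
    """True iff the value lies strictly more than 2 SDs from the reference."""
    if reference_sd <= 0:
        raise InvalidReferenceError("invalid reference")
    return abs(value - reference_mean) > 2.0 * reference_sd


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All-identical data yield (0, 1) rather than an error.
    """
    clean = [np.asarray(g, dtype=float) for g in groups]
    if len(clean) < 2 or any(g.size == 0 for g in clean):
        raise EmptyGroupError("empty group")
    pooled = np.concatenate(clean)
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*clean)
    return float(h), float(p)


def fisher_exact(table, method: str = "prob") -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Computed with exact integer arithmetic on the hypergeometric
    distribution.  ``method="prob"`` (default) sums the probabilities of all
    tables with the observed margins that are no more likely than the
    observed one; ``method="doubling"`` doubles the smaller tail probability
    (capped at 1).  A zero margin yields p = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a non-negative 2x2 table")
    a = int(t[0, 0])
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # integer weights proportional to the hypergeometric pmf
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    total = sum(weights)
    w_obs = weights[a - lo]
    if method == "prob":
        p_num = sum(w for w in weights if w <= w_obs)
    elif method == "doubling":
        lower = sum(weights[:a - lo + 1])
        upper = sum(weights[a - lo:])
        p_num = min(2 * min(lower, upper), total)
    else:
        raise ValueError(f"unknown method {method!r}")
    return p_num / total


_DEFAULT_COVARIATES = (
    "group", "age", "sex", "height", "weight", "dyslipidemia", "hypertension",
    "fhx_ihd", "aspirin", "acei_arb", "ccb", "beta_blocker", "statin",
    "thiazide",
)


def _encode_design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """0/1-encode the group label, sex and boolean columns."""
    design = pd.DataFrame(index=df.index)
    for col in covariates:
        s = df[col]
        if col == "group":
            design[col] = (s != "control").astype(float)
        elif s.dtype == object:
            levels = sorted(s.dropna().unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {col!r} has >2 categorical levels")
            design[col] = (s == levels[-1]).astype(float)
        else:
            design[col] = s.astype(float)
    return design


def fit_linear_model(data: pd.DataFrame, outcome: str,
                     covariates=None, drop_bmi: bool = True) -> LinearModelResult:
    """OLS of a morphology outcome on group plus clinical covariates.

    BMI is excluded by default because it is (near-)collinear with height
    and weight; pass ``drop_bmi=False`` to keep it.  A rank-deficient design
    raises :class:`CollinearCovariatesError` naming the dependent columns.
    """
    if covariates is None:
        covariates = [c for c in _DEFAULT_COVARIATES if c in data.columns]
        if not drop_bmi and "bmi" in data.columns:
            covariates.append("bmi")
        elif drop_bmi and "bmi" in data.columns:
            logger.info("dropping BMI from the linear model (collinear with "
                        "height and weight)")
    frame = data.dropna(subset=[outcome])
    design = _encode_design(frame, covariates)
    x = sm.add_constant(design.to_numpy(), has_constant="add")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify columns inside the span of their predecessors
        offending = []
        cols = ["const"] + list(design.columns)
        for j in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, :j + 1]) == np.linalg.matrix_rank(x[:, :j]):
                offending.append(cols[j])
        raise CollinearCovariatesError(offending or cols[1:])
    model = sm.OLS(frame[outcome].to_numpy(dtype=float), x).fit()
    coef = pd.DataFrame(
        {"coef": model.params[1:], "se": model.bse[1:], "p_value": model.pvalues[1:]},
        index=list(design.columns))
    return LinearModelResult(outcome=outcome, coefficients=coef,
                             n=int(model.nobs), r_squared=float(model.rsquared))


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

def render_p(p: float) -> str:
    """Render a p-value the way clinical tables do."""
    if p >= SIGNIFICANCE_LEVEL:
        return "NS"
    if p < 0.01:
        return "<0.01"
    return f"{p:.2f}"


def format_percent(count: int, n: int) -> str:
    """Percentage to one decimal, e.g. 27 of 74 -> '36.5'."""
    return f"{100.0 * count / n:.1f}" if n else "0.0"


def _is_binary(s: pd.Series) -> bool:
    vals = set(s.dropna().unique())
    return vals <= {0, 1, True, False} or (s.dtype == object and len(vals) <= 2)


def build_summary_table(data: pd.DataFrame, variables=None,
                        group_col: str = "group") -> pd.DataFrame:
    """Per-variable two-group comparison table.

    Continuous variables get mean +/- SEM per group and a Kruskal-Wallis p;
    binary variables get percentages and a Fisher's exact p.  p-values are
    rendered "NS" at p >= 0.05 and "<0.01" below 0.01.
    """
    groups = data[group_col]
    is_control = groups == "control"
    control, case = data[is_control], data[~is_control]
    if variables is None:
        variables = [c for c in data.columns
                     if c not in (group_col, "subject_id", "theta_true",
                                  "usable", "error")
                     and not c.startswith("qc_")]
    rows = []
    for var in variables:
        s = data[var]
        if s.dropna().empty:
            continue
        if _is_binary(s):
            if s.dtype == object:
                levels = sorted(s.dropna().unique())
                pos = s == levels[-1]
            else:
                pos = s.astype(float) > 0
            a, b = int(pos[is_control].sum()), int((~pos)[is_control].sum())
            c, d = int(pos[~is_control].sum()), int((~pos)[~is_control].sum())
            p = fisher_exact([[a, b], [c, d]])
            comp = GroupComparison(
                variable=var,
                control_summary=format_percent(a, a + b),
                case_summary=format_percent(c, c + d),
                test="fisher_exact", statistic=float("nan"), p_value=p)
        else:
            ctrl_vals = control[var].dropna()
            case_vals = case[var].dropna()
            if len(ctrl_vals) == 0 or len(case_vals) == 0:
                continue
            m0, sem0, _ = summarize(ctrl_vals)
            m1, sem1, _ = summarize(case_vals)
            h, p = kruskal_wallis(ctrl_vals, case_vals)
            comp = GroupComparison(
                variable=var,
                control_summary=f"{m0:.2f} ± {sem0:.2f}",
                case_summary=f"{m1:.2f} ± {sem1:.2f}",
                test="kruskal_wallis", statistic=h, p_value=p)
        rows.append({"variable": comp.variable,
                     "control": comp.control_summary,
                     "case": comp.case_summary,
                     "test": comp.test,
                     "statistic": comp.statistic,
                     "p_value": comp.p_value,
                     "p_rendered": render_p(comp.p_value),
                     "significant": comp.significant})
    return pd.DataFrame(rows)
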