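"""Cohort statistics: group comparisons, adjusted regressions, correlations.

The analysis stage joins the per-eye morphometric table to a clinical table
(group, age, sex, comorbidity flags, visual acuity in logMAR at baseline /
examination day / one year, central macular thickness, injection count) and
reproduces the study's tests:

* Student's t of each metric vs the control group, paired t between occluded
  and fellow eyes and between hemifields of the same eye;
* ANOVA across the five groups for continuous demographics, chi-square for
  categorical ones, Mann–Whitney for injection counts;
* per-metric "univariate" linear regressions of visual acuity adjusted for
  age and sex: an ordinary least-squares fit of the outcome on
  (rescaled metric, age, sex), reporting the metric's coefficient and its
  two-sided p.

Unit rescalings applied to predictors before regression (and only there):
length sums mm → cm, branch number → hundreds, mean lengths µm → tens of
µm; tortuosity and density stay as-is. Outcomes follow the logMAR
convention (lower = better); the acuity change is 1-year minus baseline,
so negative values mean improvement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

GROUPS = ("control", "BRVO_eye", "BRVO_fellow", "CRVO_eye", "CRVO_fellow")

#: predictor rescaling divisors (metric units → regression units)
RESCALE = {
    "branch_number": 100.0,  # per 100 branches
    "sum_bl_mm": 10.0,       # mm → cm
    "sum_el_mm": 10.0,       # mm → cm
    "mean_bl_um": 10.0,      # per 10 µm
    "mean_el_um": 10.0,      # per 10 µm
    "vt": 1.0,
    "vd": 1.0,
}

ALPHA = 0.05


def logmar_from_snellen(numerator: float, denominator: float) -> float:
    """logMAR = −log10(Snellen fraction); 20/20 → 0, 20/200 → 1."""
    if numerator <= 0 or denominator <= 0:
        raise ValueError("Snellen numerator and denominator must be positive")
    return float(-np.log10(numerator / denominator))


def va_change(va_1yr: np.ndarray, va_baseline: np.ndarray,
              convention: str = "final_minus_baseline") -> np.ndarray:
    """Acuity change in logMAR; negative = improvement under the default."""
    va_1yr = np.asarray(va_1yr, dtype=float)
    va_baseline = np.asarray(va_baseline, dtype=float)
    if convention == "final_minus_baseline":
        return va_1yr - va_baseline
    if convention == "baseline_minus_final":
        return va_baseline - va_1yr
    raise ValueError(f"unknown change convention {convention!r}")


@dataclass(frozen=True)
class RegressionResult:
    parameter: str
    beta: float
    p_value: float
    n: int
    covariates: tuple[str, ...]
    rescale_divisor: float
    degenerate: bool = False


def adjusted_univariate_regression(table: pd.DataFrame, metric: str,
                                   outcome: str,
                                   covariates=("age", "sex"),
                                   rescale: float | None = None,
                                   min_n: int = 5) -> RegressionResult:
    """OLS of ``outcome`` on (rescaled metric, age, sex); reports the
    metric's coefficient and two-sided p from its t statistic."""
    cols = [metric, outcome, *covariates]
    data = table[cols].dropna()
    n = len(data)
    if n < min_n:
        raise ValueError(f"need at least {min_n} complete records, got {n}")
    divisor = RESCALE.get(metric, 1.0) if rescale is None else rescale
    x_metric = data[metric].to_numpy(dtype=float) / divisor
    if np.ptp(x_metric) == 0:
        raise ValueError(f"no variance in predictor {metric!r}")
    X = np.column_stack([x_metric] +
                        [data[c].to_numpy(dtype=float) for c in covariates])
    X = sm.add_constant(X, prepend=False)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates)")
    y = data[outcome].to_numpy(dtype=float)
    degenerate = np.ptp(y) == 0
    fit = sm.OLS(y, X).fit()
    return RegressionResult(parameter=metric, beta=float(fit.params[0]),
                            p_value=float(fit.pvalues[0]) if not degenerate else 1.0,
                            n=n, covariates=tuple(covariates),
                            rescale_divisor=divisor, degenerate=degenerate)


def regression_table(table: pd.DataFrame, metrics, outcome: str,
                     **kwargs) -> pd.DataFrame:
    """Beta/p grid over several metrics — one regression per metric."""
    rows = []
    for m in metrics:
        r = adjusted_univariate_regression(table, m, outcome, **kwargs)
        rows.append({"parameter": m, "beta": r.beta, "p": r.p_value, "n": r.n})
    return pd.DataFrame(rows)


def students_t_vs_control(values: np.ndarray, control: np.ndarray):
    """Two-sided Student's t (equal-variance) against the control group."""
    res = sps.ttest_ind(np.asarray(values, float), np.asarray(control, float),
                        equal_var=True)
    return float(res.statistic), float(res.pvalue)


def paired_t(a: np.ndarray, b: np.ndarray):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired test requires equal-length, aligned samples")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def pearson_correlation(x: np.ndarray, y: np.ndarray):
    """Sample Pearson r with two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def group_comparisons(metrics_table: pd.DataFrame, clinical: pd.DataFrame,
                      value_cols=None, adjust: str | None = None) -> pd.DataFrame:
    """Per metric/layer/region tests of each group against control plus the
    occluded-vs-fellow paired contrast.

    ``metrics_table`` is the long-format per-eye table; ``clinical`` carries
    eye_id, group and patient_id. Returns one row per
    (layer, region, metric, contrast). ``adjust='bh'`` optionally applies a
    Benjamini–Hochberg correction (off by default).
    """
    from .metrics import METRIC_COLUMNS

    value_cols = list(value_cols) if value_cols is not None else list(METRIC_COLUMNS)
    merged = metrics_table.merge(clinical[["eye_id", "group", "patient_id"]],
                                 on="eye_id", how="left")
    rows = []
    for (layer, region), sub in merged.groupby(["layer", "region"], sort=True):
        ctrl_all = merged[(merged["group"] == "control") & (merged["layer"] == layer)]
        for col in value_cols:
            ctrl = ctrl_all[col].dropna().to_numpy()
            for grp in GROUPS[1:]:
                vals = sub.loc[sub["group"] == grp, col].dropna().to_numpy()
                if len(vals) >= 2 and len(ctrl) >= 2:
                    t, p = students_t_vs_control(vals, ctrl)
                    rows.append({"layer": layer, "region": region, "metric": col,
                                 "contrast": f"{grp}_vs_control", "stat": t,
                                 "p": p, "n": len(vals)})
        # paired occluded-vs-fellow on patients present in both groups
        for eye_grp, fellow_grp in (("BRVO_eye", "BRVO_fellow"),
                                    ("CRVO_eye", "CRVO_fellow")):
            eyes = sub[sub["group"] == eye_grp].set_index("patient_id")
            fellows = sub[sub["group"] == fellow_grp].set_index("patient_id")
            common = eyes.index.intersection(fellows.index)
            if len(common) >= 2:
                for col in value_cols:
                    a = eyes.loc[common, col].to_numpy(dtype=float)
                    b = fellows.loc[common, col].to_numpy(dtype=float)
                    ok = ~(np.isnan(a) | np.isnan(b))
                    if ok.sum() >= 2:
                        t, p = paired_t(a[ok], b[ok])
                        rows.append({"layer": layer, "region": region,
                                     "metric": col,
                                     "contrast": f"{eye_grp}_vs_fellow_paired",
                                     "stat": t, "p": p, "n": int(ok.sum())})
    out = pd.DataFrame(rows)
    if adjust == "bh" and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    if len(out):
        out["significant"] = out[("p_adj" if adjust == "bh" else "p")] < ALPHA
    return out


def demographics_tests(clinical: pd.DataFrame) -> pd.DataFrame:
    """ANOVA for continuous demographics across the five groups, chi-square
    for categorical flags, Mann–Whitney for injection counts."""
    rows = []
    for col in ("age", "va_baseline", "cmt_um"):
        if col in clinical:
            samples = [g[col].dropna().to_numpy()
                       for _, g in clinical.groupby("group") if g[col].notna().sum() >= 2]
            if len(samples) >= 2:
                f, p = sps.f_oneway(*samples)
                rows.append({"variable": col, "test": "anova",
                             "stat": float(f), "p": float(p)})
    for col in ("sex", "dm", "htn"):
        if col in clinical:
            ct = pd.crosstab(clinical["group"], clinical[col])
            if ct.shape[0] >= 2 and ct.shape[1] >= 2:
                chi2, p, _, _ = sps.chi2_contingency(ct)
                rows.append({"variable": col, "test": "chi2",
                             "stat": float(chi2), "p": float(p)})
    if "n_injections" in clinical:
        a = clinical.loc[clinical["group"] == "BRVO_eye", "n_injections"].dropna()
        b = clinical.loc[clinical["group"] == "CRVO_eye", "n_injections"].dropna()
        if len(a) >= 2 and len(b) >= 2:
            u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            rows.append({"variable": "n_injections", "test": "mannwhitney",
                         "stat": float(u), "p": float(p)})
    return pd.DataFrame(rows)
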