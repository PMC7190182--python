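"""Group-by-side statistics for bilateral canal measurements.

Per parameter, a linear mixed model ``value ~ group + side + group:side``
with a common unstructured 2x2 within-subject covariance over the right and
left measurements (REML) tests whether the right-minus-left difference
differs between groups (the interaction contrast). For complete bilateral
data this is exactly the pooled two-sample t-test on per-subject R-L
differences, which serves as the closed form; with missing sides the
covariance is estimated by numerical REML. Confidence intervals use
t quantiles with n1 + n2 - 2 degrees of freedom.

The nine interaction p-values are corrected with the Benjamini-Liu
step-down FDR procedure (distinct from Benjamini-Hochberg step-up).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .parameters import PARAMETERS

log = logging.getLogger(__name__)

__all__ = [
    "MixedModelResult",
    "FdrResult",
    "validate_table",
    "side_difference_model",
    "benjamini_liu_adjust",
    "run_all_parameters",
    "summarize_groups",
    "summarize_by_curve_type",
    "summarize_cobb",
]


@dataclass
class MixedModelResult:
    """Group-by-side model fit for one parameter."""

    parameter: str
    groups: tuple[str, str]
    n_per_group: tuple[int, int]
    cell_means: dict[tuple[str, str], float]
    group_diffs: dict[str, tuple[float, float, float]]  # group -> (est, lo, hi)
    interaction: float
    interaction_ci: tuple[float, float]
    p_value: float
    df: float
    covariance: np.ndarray
    method: str = "reml"

    def __post_init__(self) -> None:
        lo, hi = self.interaction_ci
        if not (lo - 1e-9 <= self.interaction <= hi + 1e-9):
            raise ValueError("CI must contain the point estimate")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class FdrResult:
    """Nominal and Benjamini-Liu adjusted p-values."""

    parameters: list[str]
    pvalues: np.ndarray
    adjusted: np.ndarray
    q: float = 0.05
    flags: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        self.adjusted = np.asarray(self.adjusted, dtype=float)
        self.flags = self.adjusted < self.q

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.parameters,
            "p_value": self.pvalues,
            "fdr_adjusted_p": self.adjusted,
            "significant": self.flags,
        })


def validate_table(table: pd.DataFrame, require_group: bool = True) -> pd.DataFrame:
    """Validate a long-format measurement table.

    Required columns: subject_id, side (R/L), parameter, value (and group).
    At most one value per subject x side x parameter.
    """
    required = {"subject_id", "side", "parameter", "value"}
    if require_group:
        required = required | {"group"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    bad_side = set(table["side"].unique()) - {"R", "L"}
    if bad_side:
        raise ValueError(f"unknown side values: {sorted(bad_side)}")
    unknown = set(table["parameter"].unique()) - set(PARAMETERS)
    if unknown:
        raise ValueError(f"unknown parameter names: {sorted(unknown)}")
    dup = table.duplicated(subset=["subject_id", "side", "parameter"])
    if dup.any():
        row = table[dup].iloc[0]
        raise ValueError(
            f"duplicate measurement for subject {row['subject_id']!r}, "
            f"parameter {row['parameter']!r}, side {row['side']!r}"
        )
    if not np.issubdtype(np.asarray(table["value"]).dtype, np.number):
        raise ValueError("values must be numeric")
    return table


def _group_order(table: pd.DataFrame) -> tuple[str, str]:
    groups = list(pd.unique(table["group"]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    if set(groups) == {"AIS", "control"}:
        return ("AIS", "control")
    return tuple(groups)  # type: ignore[return-value]


def _pivot_param(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    sub = table[table["parameter"] == parameter]
    wide = sub.pivot(index="subject_id", columns="side", values="value")
    for s in ("R", "L"):
        if s not in wide.columns:
            wide[s] = np.nan
    groups = sub.drop_duplicates("subject_id").set_index("subject_id")["group"]
    wide = wide.reset_index()
    wide["group"] = wide["subject_id"].map(groups)
    return wide


def _complete_case_fit(wide, groups):
    """Closed-form REML for complete bilateral data: cell means + pooled
    within-group covariance; interaction test == pooled t on R-L
    differences."""
    g1 = wide[wide["group"] == groups[0]]
    g2 = wide[wide["group"] == groups[1]]
    n1, n2 = len(g1), len(g2)
    d1 = (g1["R"] - g1["L"]).to_numpy(dtype=float)
    d2 = (g2["R"] - g2["L"]).to_numpy(dtype=float)
    S = np.zeros((2, 2))
    for g in (g1, g2):
        y = g[["R", "L"]].to_numpy(dtype=float)
        S += (len(g) - 1) * np.cov(y, rowvar=False)
    S /= n1 + n2 - 2
    est = float(d1.mean() - d2.mean())
    var_d = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    se = np.sqrt(var_d * (1 / n1 + 1 / n2))
    se_g = {groups[0]: np.sqrt(var_d / n1), groups[1]: np.sqrt(var_d / n2)}
    cell_means = {}
    for g, sub in zip(groups, (g1, g2)):
        for s in ("R", "L"):
            cell_means[(g, s)] = float(sub[s].mean())
    gdiffs = {groups[0]: float(d1.mean()), groups[1]: float(d2.mean())}
    return est, se, gdiffs, se_g, cell_means, S, (n1, n2)


def _reml_objective(theta, ys, masks, cells):
    a, b, c = theta
    L = np.array([[np.exp(a), 0.0], [b, np.exp(c)]])
    Sigma = L @ L.T
    XtVX = np.zeros((4, 4))
    XtVy = np.zeros(4)
    logdet = 0.0
    for y, m, cell in zip(ys, masks, cells):
        V = Sigma[np.ix_(m, m)]
        Vi = np.linalg.inv(V)
        X = np.zeros((m.sum(), 4))
        for r, cidx in enumerate(cell):
            X[r, cidx] = 1.0
        XtVX += X.T @ Vi @ X
        XtVy += X.T @ Vi @ y
        logdet += np.linalg.slogdet(V)[1]
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return 1e12, None, None
    quad = 0.0
    for y, m, cell in zip(ys, masks, cells):
        V = Sigma[np.ix_(m, m)]
        Vi = np.linalg.inv(V)
        X = np.zeros((m.sum(), 4))
        for r, cidx in enumerate(cell):
            X[r, cidx] = 1.0
        r_ = y - X @ beta
        quad += r_ @ Vi @ r_
    sign, logdet_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return 1e12, None, None
    nll = 0.5 * (logdet + quad + logdet_x)
    return nll, beta, XtVX


def _numeric_reml_fit(wide, groups):
    """Numerical REML for data with missing sides (cells: g1R g1L g2R g2L)."""
    ys, masks, cells = [], [], []
    for _, row in wide.iterrows():
        obs = ~np.isnan([row["R"], row["L"]])
        if not obs.any():
            continue
        gidx = 0 if row["group"] == groups[0] else 1
        y = np.array([row["R"], row["L"]])[obs]
        cell = [2 * gidx + s for s, o in zip((0, 1), obs) if o]
        ys.append(y)
        masks.append(obs)
        cells.append(cell)
    # initialize from complete cases
    comp = wide.dropna(subset=["R", "L"])
    if len(comp) >= 3:
        S0 = np.cov(comp[["R", "L"]].to_numpy(dtype=float), rowvar=False)
    else:
        v = np.nanvar(wide[["R", "L"]].to_numpy(dtype=float)) or 1.0
        S0 = np.eye(2) * v
    S0 = S0 + 1e-6 * np.eye(2)
    L0 = np.linalg.cholesky(S0)
    x0 = np.array([np.log(L0[0, 0]), L0[1, 0], np.log(L0[1, 1])])
    res = optimize.minimize(
        lambda th: _reml_objective(th, ys, masks, cells)[0],
        x0, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    nll, beta, XtVX = _reml_objective(res.x, ys, masks, cells)
    if beta is None or not np.all(np.isfinite(beta)):
        raise np.linalg.LinAlgError("singular REML fit")
    a, b, c = res.x
    Lc = np.array([[np.exp(a), 0.0], [b, np.exp(c)]])
    Sigma = Lc @ Lc.T
    C = np.linalg.inv(XtVX)
    contrast = np.array([1.0, -1.0, -1.0, 1.0])
    est = float(contrast @ beta)
    se = float(np.sqrt(contrast @ C @ contrast))
    d1 = np.array([1.0, -1.0, 0.0, 0.0])
    d2 = np.array([0.0, 0.0, 1.0, -1.0])
    gdiffs = {groups[0]: float(d1 @ beta), groups[1]: float(d2 @ beta)}
    se_g = {groups[0]: float(np.sqrt(d1 @ C @ d1)),
            groups[1]: float(np.sqrt(d2 @ C @ d2))}
    cell_means = {
        (groups[0], "R"): float(beta[0]), (groups[0], "L"): float(beta[1]),
        (groups[1], "R"): float(beta[2]), (groups[1], "L"): float(beta[3]),
    }
    n1 = int((wide["group"] == groups[0]).sum())
    n2 = int((wide["group"] == groups[1]).sum())
    return est, se, gdiffs, se_g, cell_means, Sigma, (n1, n2)


def side_difference_model(table: pd.DataFrame, parameter: str) -> MixedModelResult:
    """Fit ``value ~ group + side + group:side`` with a common unstructured
    2x2 R/L covariance (REML) and test the group-by-side interaction.

    For complete bilateral data the interaction estimate equals the
    difference in group mean R-L differences and the test is the pooled
    two-sample t-test on per-subject differences. Falls back to that t-test
    (complete cases only, with a warning) if the REML fit is singular.
    """
    validate_table(table)
    groups = _group_order(table)
    wide = _pivot_param(table, parameter)
    for g in groups:
        if (wide["group"] == g).sum() < 2:
            raise ValueError(f"parameter {parameter!r}: fewer than 2 subjects in {g!r}")

    complete = not wide[["R", "L"]].isna().to_numpy().any()
    method = "reml-closed-form" if complete else "reml-numeric"
    if complete:
        fit = _complete_case_fit(wide, groups)
    else:
        try:
            fit = _numeric_reml_fit(wide, groups)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"{parameter}: singular REML fit; falling back to the "
                "complete-case difference t-test", RuntimeWarning, stacklevel=2,
            )
            fit = _complete_case_fit(wide.dropna(subset=["R", "L"]), groups)
            method = "t-fallback"
    est, se, gdiffs, se_g, cell_means, Sigma, (n1, n2) = fit

    df = n1 + n2 - 2
    tcrit = sps.t.ppf(0.975, df)
    if se > 0:
        tstat = est / se
        p = float(2 * sps.t.sf(abs(tstat), df))
        ci = (est - tcrit * se, est + tcrit * se)
    else:  # degenerate: zero residual variance in the differences
        p = 1.0 if abs(est) < 1e-12 else 0.0
        ci = (est, est)
    group_diffs = {
        g: (gdiffs[g], gdiffs[g] - tcrit * se_g[g], gdiffs[g] + tcrit * se_g[g])
        for g in groups
    }
    return MixedModelResult(
        parameter=parameter, groups=groups, n_per_group=(n1, n2),
        cell_means=cell_means, group_diffs=group_diffs,
        interaction=est, interaction_ci=ci, p_value=p, df=float(df),
        covariance=np.asarray(Sigma), method=method,
    )


def benjamini_liu_adjust(pvals, parameters: list[str] | None = None,
                         q: float = 0.05) -> FdrResult:
    """Benjamini-Liu step-down FDR-adjusted p-values.

    With ordered p_(1) <= ... <= p_(m), the step-j raw value is
    ``min(1, (m-j+1) * (1 - (1 - p_(j))^(m-j+1)) / m)`` and the adjusted
    value is the running maximum over steps <= j, mapped back to the input
    order (ties keep input position). Adjusted values dominate the nominal
    ones and are permutation-equivariant in the input order.
    """
    p = np.asarray(pvals, dtype=float).reshape(-1)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    j = np.arange(1, m + 1)
    raw = np.minimum(1.0, (m - j + 1) * (1.0 - (1.0 - ps) ** (m - j + 1)) / m)
    adj_sorted = np.maximum.accumulate(raw)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    names = parameters if parameters is not None else [f"p{i+1}" for i in range(m)]
    return FdrResult(list(names), p, adjusted, q=q)


def run_all_parameters(
    table: pd.DataFrame, q: float = 0.05
) -> tuple[dict[str, MixedModelResult], FdrResult]:
    """One interaction model per canonical parameter, then Benjamini-Liu
    FDR across the nominal interaction p-values. Parameters absent from the
    table are excluded with a warning (reducing m)."""
    validate_table(table)
    results: dict[str, MixedModelResult] = {}
    present = set(table["parameter"].unique())
    for param in PARAMETERS:
        if param not in present:
            warnings.warn(f"parameter {param!r} missing from table; excluded "
                          "from the FDR family", RuntimeWarning, stacklevel=2)
            continue
        results[param] = side_difference_model(table, param)
    if not results:
        raise ValueError("no parameters could be modelled")
    names = list(results)
    fdr = benjamini_liu_adjust([results[n].p_value for n in names], names, q=q)
    return results, fdr


def summarize_groups(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Mean and sample SD (n-1) per parameter and group x side cell."""
    validate_table(table)
    rows = []
    for (param, group, side), sub in table.groupby(["parameter", "group", "side"]):
        v = sub["value"].dropna().to_numpy(dtype=float)
        rows.append({
            "parameter": param, "group": group, "side": side, "n": len(v),
            "mean": round(float(np.mean(v)), decimals) if len(v) else np.nan,
            "sd": round(float(np.std(v, ddof=1)), decimals) if len(v) > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def _per_subject_differences(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    wide = _pivot_param(validate_table(table), parameter)
    wide["diff"] = wide["R"] - wide["L"]
    return wide


def summarize_by_curve_type(
    table: pd.DataFrame,
    curves: pd.DataFrame,
    parameter: str = "lateral_inclination",
) -> pd.DataFrame:
    """Mean R-L difference of a parameter stratified by scoliosis curve type.

    AIS subjects are matched to ``curves`` (columns patient_id, curve_type);
    control subjects form a single stratum. SD is missing for n = 1 strata.
    """
    wide = _per_subject_differences(table, parameter)
    ais = wide[wide["group"] == "AIS"].copy()
    unmatched = set(ais["subject_id"]) - set(curves["patient_id"])
    if unmatched:
        raise ValueError(f"AIS subjects without curve records: {sorted(unmatched)}")
    ais = ais.merge(curves[["patient_id", "curve_type"]],
                    left_on="subject_id", right_on="patient_id")
    ctrl = wide[wide["group"] != "AIS"].copy()
    ctrl["curve_type"] = "Control"
    rows = []
    for ctype, sub in pd.concat([ctrl, ais]).groupby("curve_type", sort=False):
        d = sub["diff"].dropna().to_numpy(dtype=float)
        rows.append({
            "curve_type": ctype, "n": len(d),
            "mean_diff": float(np.mean(d)) if len(d) else np.nan,
            "sd": float(np.std(d, ddof=1)) if len(d) > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def summarize_cobb(curves: pd.DataFrame) -> pd.DataFrame:
    """Cobb-angle summaries per curve pattern.

    Single-curve patterns report the mean/SD of their angles. Biphasic
    (double major) curves list two angles per patient; since either
    aggregation is defensible, both the all-angles and the per-patient
    maximum summaries are reported. Includes pattern counts and percents.
    """
    if len(curves) == 0:
        raise ValueError("no curve records")
    total = len(curves)
    rows = []
    for ctype, sub in curves.groupby("curve_type", sort=False):
        single = sub["cobb1"].dropna().to_numpy(dtype=float)
        if ctype == "Biphasic":
            allang = sub[["cobb1", "cobb2"]].to_numpy(dtype=float).ravel()
            allang = allang[~np.isnan(allang)]
            mx = sub[["cobb1", "cobb2"]].max(axis=1).to_numpy(dtype=float)
            for label, v in (("Biphasic (all angles)", allang),
                             ("Biphasic (per-patient max)", mx)):
                rows.append({
                    "pattern": label, "n_patients": len(sub),
                    "percent": round(100 * len(sub) / total, 1),
                    "mean": round(float(np.mean(v)), 1),
                    "sd": round(float(np.std(v, ddof=1)), 1) if len(v) > 1 else np.nan,
                })
        else:
            rows.append({
                "pattern": ctype, "n_patients": len(sub),
                "percent": round(100 * len(sub) / total, 1),
                "mean": round(float(np.mean(single)), 1),
                "sd": round(float(np.std(single, ddof=1)), 1) if len(single) > 1 else np.nan,
            })
    return pd.DataFrame(rows)
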