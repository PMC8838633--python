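"""Statistical battery for JVA-versus-CSA trial tables.

Implements the study-level analyses: repeated-measures correlation (common
slope across participants via ANCOVA), linear mixed models with sex x level
fixed effects and a participant random intercept, Tukey-adjusted estimated
marginal mean contrasts, per-participant regressions with median/IQR
summaries, Wilcoxon rank-sum comparison of individual slopes, reliability
stratification by the observed change in CSA, and pooled anthropometric
correlations.

Trial tables are pandas DataFrames with columns: ``participant``, ``sex``
("M"/"F"), ``condition`` ("HDT"/"LBNP"), ``level`` (signed degrees or mmHg),
``jva`` (a.u.), ``csa`` (cm**2), and optionally ``baseline_csa`` (cm**2,
the level-0 HDT measurement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range
import statsmodels.formula.api as smf

__all__ = [
    "RmcorrResult",
    "IndividualFit",
    "LmmResult",
    "rmcorr",
    "individual_fits",
    "summarize_fits",
    "compare_slopes",
    "fit_lmm",
    "stratify_reliability",
    "anthropometric_correlations",
    "percent_difference",
    "demographics_ttest",
]


@dataclass(frozen=True)
class RmcorrResult:
    """Common-slope (repeated-measures) correlation from the ANCOVA model."""

    r_rm: float
    ci_low: float
    ci_high: float
    p: float
    common_slope: float
    df: int
    n_participants: int


@dataclass(frozen=True)
class IndividualFit:
    """Per-participant ordinary least squares of JVA on CSA."""

    participant: str
    sex: str
    condition: str
    slope: float
    intercept: float
    r: float
    n: int
    delta_csa: float  # max - min observed CSA, cm**2


@dataclass
class LmmResult:
    """Mixed-model fixed effects, marginal means, and Tukey sex contrasts."""

    fixed_effects: pd.Series
    p_values: dict
    emm: pd.DataFrame          # columns: sex, level, emm, se
    contrasts: pd.DataFrame    # per-level sex contrasts with Tukey-adjusted p
    df_method: str = "between-within"
    converged: bool = True
    extras: dict = field(default_factory=dict)


def percent_difference(a: float, b: float) -> float:
    """Percent by which ``a`` exceeds ``b``: 100 * (a - b) / b."""
    return 100.0 * (a - b) / b


def rmcorr(records: pd.DataFrame, x: str = "csa", y: str = "jva") -> RmcorrResult:
    """Repeated-measures correlation: common slope across participants.

    Fits the ANCOVA y ~ participant-intercepts + x by least squares.  The
    effect size is sign(slope) * sqrt(SS_x / (SS_x + SS_error)) where SS_x is
    the reduction in residual sum of squares attributable to the covariate
    after the participant factor; df = N_obs - N_participants - 1; the p
    value comes from the F test of the covariate; the CI from a Fisher-z
    interval using the repeated-measures df.
    """
    df = records[["participant", x, y]].dropna().copy()
    ok_parts = df.groupby("participant")[x].nunique()
    bad = ok_parts[ok_parts < 2].index
    if len(bad):
        warnings.warn(
            f"excluding participants with constant {x}: {sorted(map(str, bad))}",
            stacklevel=2,
        )
        df = df[~df["participant"].isin(bad)]
    parts = df["participant"].unique()
    if len(parts) < 2 or (df.groupby("participant").size() < 2).any():
        raise ValueError("rmcorr needs >= 2 participants with >= 2 points each")

    dummies = pd.get_dummies(df["participant"], dtype=float).to_numpy()
    xv = df[x].to_numpy(float)
    yv = df[y].to_numpy(float)
    X_full = np.column_stack([dummies, xv])
    beta, *_ = np.linalg.lstsq(X_full, yv, rcond=None)
    rss_full = float(((yv - X_full @ beta) ** 2).sum())
    beta0, *_ = np.linalg.lstsq(dummies, yv, rcond=None)
    rss_reduced = float(((yv - dummies @ beta0) ** 2).sum())
    ss_x = max(rss_reduced - rss_full, 0.0)
    slope = float(beta[-1])

    dof = len(df) - len(parts) - 1
    if dof < 1:
        raise ValueError("not enough residual degrees of freedom for rmcorr")
    denom = ss_x + rss_full
    r_rm = float(np.sign(slope) * np.sqrt(ss_x / denom)) if denom > 0 else 0.0
    if rss_full > 0:
        f_stat = ss_x / (rss_full / dof)
        p = float(sps.f.sf(f_stat, 1, dof))
    else:
        p = 0.0 if ss_x > 0 else 1.0
    if abs(r_rm) < 1.0 and dof > 1:
        z = np.arctanh(r_rm)
        se = 1.0 / np.sqrt(dof - 1)
        lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    else:
        lo = hi = r_rm
    return RmcorrResult(
        r_rm=r_rm, ci_low=float(lo), ci_high=float(hi), p=p,
        common_slope=slope, df=int(dof), n_participants=int(len(parts)),
    )


def individual_fits(records: pd.DataFrame, x: str = "csa", y: str = "jva", min_points: int = 3) -> list[IndividualFit]:
    """Per-(participant, condition) ordinary least squares of y on x.

    Groups with fewer than ``min_points`` observations or a constant
    covariate are omitted.  Negative-slope fits are retained.
    """
    fits: list[IndividualFit] = []
    for (pid, cond), g in records.groupby(["participant", "condition"], sort=True):
        g = g.dropna(subset=[x, y])
        if len(g) < min_points or g[x].nunique() < 2:
            continue
        res = sps.linregress(g[x].to_numpy(float), g[y].to_numpy(float))
        fits.append(
            IndividualFit(
                participant=str(pid),
                sex=str(g["sex"].iloc[0]),
                condition=str(cond),
                slope=float(res.slope),
                intercept=float(res.intercept),
                r=float(res.rvalue),
                n=int(len(g)),
                delta_csa=float(g[x].max() - g[x].min()),
            )
        )
    return fits


def summarize_fits(fits: list[IndividualFit]) -> pd.DataFrame:
    """Median and IQR of slope and r per sex x condition (type-7 quantiles)."""
    if not fits:
        return pd.DataFrame()
    df = pd.DataFrame([vars(f) for f in fits])
    rows = []
    for (cond, sex), g in df.groupby(["condition", "sex"]):
        rows.append(
            {
                "condition": cond,
                "sex": sex,
                "n": len(g),
                "slope_median": g["slope"].median(),
                "slope_q25": g["slope"].quantile(0.25),
                "slope_q75": g["slope"].quantile(0.75),
                "r_median": g["r"].median(),
                "r_q25": g["r"].quantile(0.25),
                "r_q75": g["r"].quantile(0.75),
            }
        )
    return pd.DataFrame(rows)


def compare_slopes(slopes_a, slopes_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on two groups of individual slopes.

    Exact enumeration when the combined sample is small and tie-free,
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _level_order(levels) -> list[str]:
    return [str(lv) for lv in sorted(set(levels), key=abs)]


def fit_lmm(
    records: pd.DataFrame,
    response: str = "jva",
    include_baseline_csa: bool = False,
) -> LmmResult:
    """Random-intercept mixed model: response ~ level x sex + (1 | participant).

    Condition level enters as a categorical factor (sum coding) and sex as a
    centered +/-0.5 contrast, so main effects are averages over the other
    factor.  Fit by REML.  Fixed-effect tests are Wald F tests with
    between-within denominator degrees of freedom (sex: N - 2; level and
    interaction: (N - 2)(k - 1)).  Estimated marginal means are reported per
    sex x level with per-level sex contrasts adjusted over the family of all
    sex x level cell means via the studentized range.
    """
    df = records.dropna(subset=[response, "level", "sex", "participant"]).copy()
    if df["sex"].nunique() < 2:
        raise ValueError("both sexes must be present")
    levels = _level_order(df["level"])
    if len(levels) < 2:
        raise ValueError("need at least two condition levels")
    df["level_f"] = pd.Categorical(df["level"].astype(str), categories=levels, ordered=True)
    df["sex_e"] = np.where(df["sex"] == "M", 0.5, -0.5)
    formula = f"{response} ~ C(level_f, Sum) * sex_e"
    if include_baseline_csa:
        if "baseline_csa" not in df:
            raise ValueError("baseline_csa column required for the covariate model")
        formula += " + baseline_csa"

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["participant"])
        fit = None
        for method in ("lbfgs", "powell", "cg"):
            try:
                fit = model.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if fit is None:
            raise ValueError("mixed model could not be fit (singular design?)")

    names = list(fit.fe_params.index)
    theta = fit.fe_params.to_numpy()
    vcov = fit.cov_params().loc[names, names].to_numpy()

    n_sub = df["participant"].nunique()
    k = len(levels)
    df_sex = max(n_sub - 2, 1)
    df_within = max((n_sub - 2) * (k - 1), 1)

    def joint_f(idx: list[int], ddf: int) -> float:
        c = np.zeros((len(idx), len(theta)))
        for i, j in enumerate(idx):
            c[i, j] = 1.0
        est = c @ theta
        cov = c @ vcov @ c.T
        f_stat = float(est @ np.linalg.solve(cov, est)) / len(idx)
        return float(sps.f.sf(f_stat, len(idx), ddf))

    idx_level = [i for i, n in enumerate(names) if n.startswith("C(level_f") and ":" not in n]
    idx_sex = [i for i, n in enumerate(names) if n == "sex_e"]
    idx_int = [i for i, n in enumerate(names) if ":" in n]
    p_values = {
        "level": joint_f(idx_level, df_within),
        "sex": joint_f(idx_sex, df_sex),
        "sex_x_level": joint_f(idx_int, df_within),
    }
    if include_baseline_csa:
        p_values["baseline_csa"] = joint_f(
            [i for i, n in enumerate(names) if n == "baseline_csa"], df_sex
        )

    # Cell means via the fitted design; covariate held at its mean.
    design_info = model.data.design_info
    from patsy import build_design_matrices

    cells = []
    for sex, sex_e in (("F", -0.5), ("M", 0.5)):
        for lv in levels:
            new = {"level_f": [lv], "sex_e": [sex_e]}
            if include_baseline_csa:
                new["baseline_csa"] = [float(df["baseline_csa"].mean())]
            row = np.asarray(build_design_matrices([design_info], new)[0])[0]
            est = float(row @ theta)
            se = float(np.sqrt(row @ vcov @ row))
            cells.append({"sex": sex, "level": float(lv), "emm": est, "se": se, "_row": row})
    emm = pd.DataFrame(cells)

    n_means = 2 * k
    contrasts = []
    for lv in levels:
        sub = emm[emm["level"] == float(lv)]
        row_m = sub[sub["sex"] == "M"]["_row"].iloc[0]
        row_f = sub[sub["sex"] == "F"]["_row"].iloc[0]
        d = row_m - row_f
        est = float(d @ theta)
        se = float(np.sqrt(d @ vcov @ d))
        tval = est / se if se > 0 else np.inf
        p_adj = float(studentized_range.sf(np.sqrt(2.0) * abs(tval), n_means, df_within))
        contrasts.append(
            {"level": float(lv), "estimate_m_minus_f": est, "se": se, "t": tval,
             "p_tukey": min(p_adj, 1.0)}
        )
    emm = emm.drop(columns=["_row"])

    return LmmResult(
        fixed_effects=fit.fe_params,
        p_values=p_values,
        emm=emm,
        contrasts=pd.DataFrame(contrasts),
        df_method="between-within",
        converged=bool(fit.converged),
        extras={"group_var": float(fit.cov_re.iloc[0, 0]), "resid_var": float(fit.scale)},
    )


def stratify_reliability(fits: list[IndividualFit], threshold: float = 0.15) -> dict:
    """IQR of individual r below/above the observed-change-in-CSA threshold.

    Pools both conditions and sexes.  Empty or singleton strata are flagged
    rather than fatal.
    """
    r_low = np.array([f.r for f in fits if f.delta_csa < threshold])
    r_high = np.array([f.r for f in fits if f.delta_csa >= threshold])

    def iqr(vals: np.ndarray):
        if len(vals) < 2:
            return None
        q25, q75 = np.percentile(vals, [25, 75])  # linear interpolation (type 7)
        return float(q25), float(q75)

    out = {
        "threshold": threshold,
        "n_low": int(len(r_low)),
        "n_high": int(len(r_high)),
        "iqr_low": iqr(r_low),
        "iqr_high": iqr(r_high),
        "flags": [],
    }
    for name, vals in (("low", r_low), ("high", r_high)):
        if len(vals) < 2:
            out["flags"].append(f"{name}-delta stratum has < 2 fits")
    for key, src in (("iqr_width_low", out["iqr_low"]), ("iqr_width_high", out["iqr_high"])):
        out[key] = None if src is None else src[1] - src[0]
    return out


def anthropometric_correlations(table: pd.DataFrame, jva_col: str = "jva_baseline") -> dict:
    """Pooled Pearson correlations of baseline JVA with muscle thickness and depth."""
    if len(table) < 3:
        raise ValueError("need at least 3 participants")
    out = {}
    for key, col in (("scm_thickness", "scm_thickness"), ("ijv_depth", "ijv_depth")):
        x = table[col].to_numpy(float)
        y = table[jva_col].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"zero variance in {col} or {jva_col}")
        r, p = sps.pearsonr(x, y)
        out[key] = {"r": float(r), "p": float(p)}
    return out


def demographics_ttest(cohort: pd.DataFrame, column: str) -> tuple[float, float]:
    """Two-sample Student's t-test (equal variances) of a demographic column by sex."""
    m = cohort.loc[cohort["sex"] == "M", column].to_numpy(float)
    f = cohort.loc[cohort["sex"] == "F", column].to_numpy(float)
    res = sps.ttest_ind(m, f, equal_var=True)
    return float(res.statistic), float(res.pvalue)
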