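"""Mixed-model length/practice effects and group comparisons.

Per-group analyses are linear mixed-effects models on per-speaker cell
means with a fixed intercept and slope and a per-speaker random intercept
(REML, via statsmodels MixedLM).  Predictor coding anchors the intercept
where the design anchors it: (length − 2) for ISI models (length 2 is the
shortest sequence yielding an interval), (length − 1) for error models,
(run − 1) for practice models.  Two-group interaction models add a group
main effect and a group x predictor interaction whose coefficient is the
slope difference.  Group comparisons are one-way ANOVAs with Bonferroni
post-hocs, falling back to Kruskal–Wallis when Levene's test rejects
homogeneity of variance.

Error-rate effects are fitted both on the arcsine scale asin(sqrt(p))
(variance-stabilised) and on the raw percentage scale; reported percentage
slopes come from the latter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm


def bonferroni_alpha(k: int) -> float:
    """Bonferroni-adjusted significance threshold 0.05/k."""
    if k < 1:
        raise ValueError("number of tests must be >= 1")
    return 0.05 / k


@dataclass
class ModelFit:
    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    t_slope: float
    df_resid: int
    p_slope: float
    random_intercept_var: float
    predictor_coding: str
    scale: str
    method: str = "mixedlm"          # "mixedlm" or "ols-fallback"
    note: str = ""
    interaction: float | None = None
    interaction_se: float | None = None
    t_interaction: float | None = None
    p_interaction: float | None = None


_CODING = {"isi": ("length", 2), "arcsineErr": ("length", 1), "pctErr": ("length", 1)}


def _fit_random_intercept(df: pd.DataFrame, xcols: list[str], y: str) -> tuple:
    """Random-intercept fit with OLS fallback on singular/failed fits.

    Returns (params, ses, re_var, method, note).  For the balanced designs
    used here the fixed-effect point estimates of the two routes coincide.
    """
    exog = sm.add_constant(df[xcols].to_numpy(dtype=float))
    endog = df[y].to_numpy(dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(endog, exog, groups=df["speaker"].to_numpy())
            res = model.fit(reml=True)
            params = np.asarray(res.fe_params, dtype=float)
            ses = np.asarray(res.bse_fe, dtype=float)
            re_var = float(np.asarray(res.cov_re).ravel()[0])
        if not np.all(np.isfinite(params)) or not np.all(np.isfinite(ses)):
            raise np.linalg.LinAlgError("non-finite mixed-model estimates")
        return params, ses, re_var, "mixedlm", ""
    except Exception as exc:  # singular fit, zero variance, convergence failure
        res = sm.OLS(endog, exog).fit()
        note = f"mixed-model fit failed ({type(exc).__name__}); OLS on cell means"
        return (np.asarray(res.params), np.asarray(res.bse),
                0.0, "ols-fallback", note)


def _slope_fit(df: pd.DataFrame, xcol: str, anchor: int, y: str,
               scale: str) -> ModelFit:
    x = df[xcol].to_numpy(dtype=float) - anchor
    work = df.assign(_x=x)
    params, ses, re_var, method, note = _fit_random_intercept(work, ["_x"], y)
    nobs = len(work)
    dfres = nobs - 2
    t = params[1] / ses[1] if ses[1] > 0 else np.inf * np.sign(params[1] or 1)
    p = float(2 * sps.t.sf(abs(t), dfres)) if np.isfinite(t) else 0.0
    return ModelFit(
        intercept=float(params[0]), intercept_se=float(ses[0]),
        slope=float(params[1]), slope_se=float(ses[1]), t_slope=float(t),
        df_resid=dfres, p_slope=min(max(p, np.nextafter(0, 1)), 1.0),
        random_intercept_var=re_var,
        predictor_coding=f"({xcol} - {anchor})", scale=scale,
        method=method, note=note,
    )


def fit_length_model(table: pd.DataFrame, outcome: str) -> ModelFit:
    """Sequence-length effect on per-speaker mean outcomes.

    ``table`` columns: speaker, length, value.  ISI models use lengths 2–5
    with (length − 2) coding; error models use lengths 1–5 with
    (length − 1) coding.  ``outcome`` is "isi" (ms), "arcsineErr"
    (radians) or "pctErr" (percentage points).
    """
    if outcome not in _CODING:
        raise ValueError(f"unknown outcome {outcome!r}")
    _, anchor = _CODING[outcome]
    df = table[table["length"] >= anchor].copy()
    if df["length"].nunique() < 2 or df["speaker"].nunique() < 2:
        raise ValueError("need >=2 lengths and >=2 speakers")
    scale = {"isi": "ms", "arcsineErr": "arcsine", "pctErr": "percent"}[outcome]
    return _slope_fit(df, "length", anchor, "value", scale)


def fit_practice_model(table: pd.DataFrame, outcome: str) -> ModelFit:
    """Practice (run) effect on per-speaker mean outcomes; (run − 1) coding."""
    if table["run"].nunique() < 2 or table["speaker"].nunique() < 2:
        raise ValueError("need >=2 runs and >=2 speakers")
    scale = {"isi": "ms", "arcsineErr": "arcsine", "pctErr": "percent"}[outcome]
    return _slope_fit(table, "run", 1, "value", scale)


def fit_interaction_model(table: pd.DataFrame, predictor: str) -> ModelFit:
    """Combined two-group model with a group x predictor interaction.

    ``table`` columns: speaker, group (exactly two levels), predictor
    column ("length" or "run"), value.  Group is coded 0/1 in sorted level
    order; the interaction coefficient is the slope difference
    (group 1 − group 0).
    """
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError("interaction model needs exactly two groups")
    anchor = 2 if predictor == "length" else 1
    df = table.copy()
    if predictor == "length":
        df = df[df["length"] >= 2]
    df["_x"] = df[predictor].astype(float) - anchor
    df["_g"] = (df["group"] == groups[1]).astype(float)
    df["_gx"] = df["_g"] * df["_x"]
    params, ses, re_var, method, note = _fit_random_intercept(df, ["_g", "_x", "_gx"], "value")
    nobs = len(df)
    dfres = nobs - 4
    t_sl = params[2] / ses[2] if ses[2] > 0 else np.inf
    t_ix = params[3] / ses[3] if ses[3] > 0 else np.inf
    return ModelFit(
        intercept=float(params[0]), intercept_se=float(ses[0]),
        slope=float(params[2]), slope_se=float(ses[2]), t_slope=float(t_sl),
        df_resid=dfres,
        p_slope=float(2 * sps.t.sf(abs(t_sl), dfres)) if np.isfinite(t_sl) else 0.0,
        random_intercept_var=re_var,
        predictor_coding=f"({predictor} - {anchor}); group {groups[1]} = 1",
        scale="ms", method=method, note=note,
        interaction=float(params[3]), interaction_se=float(ses[3]),
        t_interaction=float(t_ix),
        p_interaction=float(2 * sps.t.sf(abs(t_ix), dfres)) if np.isfinite(t_ix) else 0.0,
    )


@dataclass
class GroupComparison:
    measure: str
    anova_f: float
    anova_df: tuple[int, int]
    anova_p: float
    levene_f: float
    levene_p: float
    kruskal_chi2: float
    kruskal_p: float
    used_test: str                   # "anova" or "kruskal" (Levene fallback)
    bonferroni_alpha: float
    post_hoc: list[tuple[str, float, float]]   # (pair, mean diff, adj p)


def compare_groups(speaker_means: pd.DataFrame, measure: str = "isi") -> GroupComparison:
    """One-way group comparison of per-speaker overall means.

    ANOVA with Bonferroni-corrected pairwise post-hocs; when Levene's test
    rejects equality of variance (p < 0.05) the omnibus test switches to
    Kruskal–Wallis.  ``speaker_means`` columns: speaker, group, value.
    """
    groups = sorted(speaker_means["group"].unique())
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    samples = [speaker_means.loc[speaker_means["group"] == g, "value"].to_numpy()
               for g in groups]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs >=2 speakers")
    f, p_anova = sps.f_oneway(*samples)
    lf, lp = sps.levene(*samples)
    kh, kp = sps.kruskal(*samples)
    n = sum(len(s) for s in samples)
    pairs = list(combinations(range(len(groups)), 2))
    alpha = bonferroni_alpha(len(pairs))
    post = []
    for i, j in pairs:
        diff = float(np.mean(samples[i]) - np.mean(samples[j]))
        _, pt = sps.ttest_ind(samples[i], samples[j])
        post.append((f"{groups[i]}-{groups[j]}", diff, float(min(1.0, pt * len(pairs)))))
    return GroupComparison(
        measure=measure, anova_f=float(f), anova_df=(len(groups) - 1, n - len(groups)),
        anova_p=float(p_anova), levene_f=float(lf), levene_p=float(lp),
        kruskal_chi2=float(kh), kruskal_p=float(kp),
        used_test="kruskal" if lp < 0.05 else "anova",
        bonferroni_alpha=alpha, post_hoc=post,
    )


def fit_summary(fit: ModelFit) -> str:
    lines = [
        f"coding {fit.predictor_coding}, scale {fit.scale}, method {fit.method}",
        f"intercept {fit.intercept:.3f} (SE {fit.intercept_se:.3f})",
        f"slope {fit.slope:.3f} (SE {fit.slope_se:.3f}), "
        f"t({fit.df_resid}) = {fit.t_slope:.2f}, p = {fit.p_slope:.4g}",
        f"random intercept variance {fit.random_intercept_var:.3f}",
    ]
    if fit.interaction is not None:
        lines.append(
            f"interaction {fit.interaction:.3f} (SE {fit.interaction_se:.3f}), "
            f"t({fit.df_resid}) = {fit.t_interaction:.2f}, p = {fit.p_interaction:.4g}"
        )
    if fit.note:
        lines.append(f"note: {fit.note}")
    return "\n".join(lines)
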