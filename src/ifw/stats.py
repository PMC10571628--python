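"""Longitudinal group statistics on ROI tables.

Implements the study design used for cortical ROI measures: a linear
mixed-effects (LME) model per ROI,

    value ~ Group + Time + Group:Time + age + sex + ICV,  random intercept
    per subject,

with the healthy-control (HC) group as the reference level.  The Group
effect is interpreted at Time = 0 (baseline differences); the Group x Time
interaction encodes group differences in yearly rate of change.  Omnibus
Wald F tests are followed by Tukey-adjusted pairwise contrasts of the
three groups (on baseline offsets or on marginal slopes), and p-values are
FDR-adjusted (Benjamini-Hochberg) across the eight cortical ROIs.  Helper
routines compute per-subject rates of change (OLS slopes), Spearman
associations with clinical scores, and Fisher's z comparison of two
independent correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import dmatrices
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .roi import LOBES

logger = logging.getLogger(__name__)

GROUPS = ("HC", "CHR-NP", "CHR-P")
CONTRAST_ORDER = ("CHR-P vs HC", "CHR-NP vs HC", "CHR-P vs CHR-NP")

_FORMULA = "value ~ C(group, Treatment('HC')) * time + age_z + sex + icv_z"
_DUMMY = {
    "CHR-NP": "C(group, Treatment('HC'))[T.CHR-NP]",
    "CHR-P": "C(group, Treatment('HC'))[T.CHR-P]",
}


@dataclass
class EffectTest:
    statistic: float
    df_num: int
    df_den: float
    pvalue: float


@dataclass
class LmeRoiResult:
    """Per-ROI LME fit: fixed effects, omnibus tests and bookkeeping."""

    roi: str
    measure: str
    n_obs: int
    n_subjects: int
    fe_params: pd.Series
    fe_cov: pd.DataFrame
    df_den: float
    group_test: EffectTest
    interaction_test: EffectTest
    converged: bool
    singular: bool


@dataclass
class LongitudinalResult:
    """Omnibus effects (FDR-adjusted across ROIs) plus pairwise contrasts."""

    effects: pd.DataFrame
    contrasts: pd.DataFrame
    alpha: float
    fits: dict = field(default_factory=dict, repr=False)


def _prepare(table: pd.DataFrame, measure: str, roi: str) -> pd.DataFrame:
    df = table[(table["measure_name"] == measure) & (table["roi"] == roi)].copy()
    required = ["subject_id", "group", "timepoint_years", "value", "age", "sex", "icv"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"table lacks required column(s): {missing_cols}")
    n0 = len(df)
    df = df.dropna(subset=required)
    if len(df) < n0:
        logger.info("dropped %d row(s) with missing data (listwise)", n0 - len(df))
    if df.empty:
        raise ValueError(f"no rows for measure={measure!r}, roi={roi!r}")

    counts = df.groupby("group")["subject_id"].nunique()
    for g in GROUPS:
        if counts.get(g, 0) < 3:
            raise ValueError(
                f"group {g} has {counts.get(g, 0)} subject(s); need >= 3 per group"
            )
    if df["sex"].dtype == object:
        df["sex"] = df["sex"].map({"M": 1, "F": 0, "m": 1, "f": 0}).astype(float)
    df["sex"] = df["sex"].astype(float)
    df["time"] = df["timepoint_years"].astype(float)
    for col, zcol in (("age", "age_z"), ("icv", "icv_z")):
        x = df[col].astype(float)
        sd = x.std(ddof=0)
        df[zcol] = (x - x.mean()) / sd if sd > 0 else 0.0
    return df


def _wald_f(
    beta: np.ndarray, cov: np.ndarray, idx: list[int], df_den: float
) -> EffectTest:
    est = beta[idx]
    V = cov[np.ix_(idx, idx)]
    q = len(idx)
    try:
        stat = float(est @ np.linalg.solve(V, est)) / q
    except np.linalg.LinAlgError:
        stat = float(est @ np.linalg.pinv(V) @ est) / q
    p = float(sps.f.sf(stat, q, df_den))
    return EffectTest(statistic=stat, df_num=q, df_den=df_den, pvalue=p)


def fit_lme(
    table: pd.DataFrame, measure: str, roi: str, reml: bool = True
) -> LmeRoiResult:
    """Fit the per-ROI mixed model and compute omnibus Group / Group x Time tests.

    Age and ICV are z-scored internally for numerical conditioning (the
    group, time and interaction tests are invariant to this).  A fit whose
    residual variance collapses (e.g. deterministic data) or that fails to
    converge falls back to the exact ordinary-least-squares solution and
    is flagged ``singular`` rather than silently returned.
    """
    df = _prepare(table, measure, roi)

    y, X = dmatrices(_FORMULA, df, return_type="dataframe")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(
            "model matrix is rank deficient (e.g. a single timepoint per "
            "subject makes time and interaction terms inestimable)"
        )

    k_fe = X.shape[1]
    n_obs = len(df)
    df_den = float(n_obs - k_fe)
    singular = False
    converged = True
    fe_params = fe_cov = None
    var_y = float(np.var(df["value"]))
    use_ols = False

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = smf.mixedlm(_FORMULA, df, groups=df["subject_id"])
            result = model.fit(reml=reml, method="lbfgs")
        converged = bool(result.converged)
        fe_params = result.fe_params
        fe_cov = result.cov_params().loc[fe_params.index, fe_params.index]
        bad = (
            not converged
            or not np.all(np.isfinite(fe_params.to_numpy()))
            or not np.all(np.isfinite(fe_cov.to_numpy()))
            or result.scale < 1e-14 * max(var_y, 1e-300)
        )
        if bad:
            # collapsed residual variance / failed optimization: the GLS
            # estimate equals OLS on such data, which stays finite
            singular = True
            use_ols = True
        elif any("onvergence" in str(w.message) for w in caught):
            singular = True  # boundary warning: keep estimates, flag the fit
    except Exception as exc:  # noqa: BLE001 - degenerate likelihoods vary
        logger.warning(
            "mixed model failed for %s/%s (%s); exact OLS fallback", measure, roi, exc
        )
        singular = True
        use_ols = True

    if use_ols:
        converged = False
        ols = sm.OLS(y.to_numpy().ravel(), X.to_numpy()).fit()
        fe_params = pd.Series(ols.params, index=X.columns)
        fe_cov = pd.DataFrame(ols.cov_params(), index=X.columns, columns=X.columns)

    names = list(fe_params.index)
    group_idx = [names.index(_DUMMY[g]) for g in ("CHR-NP", "CHR-P")]
    inter_idx = [names.index(_DUMMY[g] + ":time") for g in ("CHR-NP", "CHR-P")]
    beta = fe_params.to_numpy()
    cov = fe_cov.to_numpy()

    return LmeRoiResult(
        roi=roi,
        measure=measure,
        n_obs=n_obs,
        n_subjects=int(df["subject_id"].nunique()),
        fe_params=fe_params,
        fe_cov=fe_cov,
        df_den=df_den,
        group_test=_wald_f(beta, cov, group_idx, df_den),
        interaction_test=_wald_f(beta, cov, inter_idx, df_den),
        converged=converged,
        singular=singular,
    )


def posthoc_pairwise(fit: LmeRoiResult, effect: str = "group") -> pd.DataFrame:
    """Tukey-adjusted pairwise contrasts of the three groups.

    ``effect="group"`` contrasts baseline offsets (estimated marginal
    means at time 0, identical covariates); ``effect="interaction"``
    contrasts marginal yearly slopes.  The 3-comparison family is adjusted
    with the studentized-range distribution at the fit's residual df.
    """
    if effect not in ("group", "interaction"):
        raise ValueError("effect must be 'group' or 'interaction'")
    suffix = "" if effect == "group" else ":time"
    names = list(fit.fe_params.index)
    k = len(names)
    vec = {}
    for g in ("CHR-NP", "CHR-P"):
        c = np.zeros(k)
        c[names.index(_DUMMY[g] + suffix)] = 1.0
        vec[g] = c
    contrasts = {
        "CHR-P vs HC": vec["CHR-P"],
        "CHR-NP vs HC": vec["CHR-NP"],
        "CHR-P vs CHR-NP": vec["CHR-P"] - vec["CHR-NP"],
    }
    beta = fit.fe_params.to_numpy()
    cov = fit.fe_cov.to_numpy()
    rows = []
    for label in CONTRAST_ORDER:
        c = contrasts[label]
        est = float(c @ beta)
        se = float(np.sqrt(max(c @ cov @ c, 0.0)))
        if se > 0:
            t = est / se
            p = float(sps.studentized_range.sf(np.sqrt(2) * abs(t), 3, fit.df_den))
        else:
            t = np.inf if est != 0 else 0.0
            p = 0.0 if est != 0 else 1.0
        rows.append(
            {
                "roi": fit.roi,
                "effect": effect,
                "contrast": label,
                "estimate": est,
                "se": se,
                "tstat": t,
                "p_tukey": min(p, 1.0),
                "df": fit.df_den,
            }
        )
    return pd.DataFrame(rows)


def fdr_adjust(
    pvals, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment; returns (adjusted, reject)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be within [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def run_longitudinal(
    table: pd.DataFrame,
    measure: str = "ifw",
    rois: tuple[str, ...] = LOBES,
    alpha: float = 0.05,
) -> LongitudinalResult:
    """Per-ROI LME fits, FDR across ROIs, and pairwise contrasts.

    Contrasts are computed for every ROI; the ``significant`` flag on the
    omnibus row indicates which survive the FDR threshold.
    """
    fits = {roi: fit_lme(table, measure, roi) for roi in rois}
    effect_rows = []
    contrast_frames = []
    for effect in ("group", "interaction"):
        tests = {
            roi: (f.group_test if effect == "group" else f.interaction_test)
            for roi, f in fits.items()
        }
        p_adj, reject = fdr_adjust([tests[r].pvalue for r in rois], alpha=alpha)
        for i, roi in enumerate(rois):
            t = tests[roi]
            effect_rows.append(
                {
                    "roi": roi,
                    "effect": effect,
                    "F": t.statistic,
                    "df_num": t.df_num,
                    "df_den": t.df_den,
                    "p": t.pvalue,
                    "p_fdr": p_adj[i],
                    "significant": bool(reject[i]),
                    "singular": fits[roi].singular,
                }
            )
            contrast_frames.append(posthoc_pairwise(fits[roi], effect))
    return LongitudinalResult(
        effects=pd.DataFrame(effect_rows),
        contrasts=pd.concat(contrast_frames, ignore_index=True),
        alpha=alpha,
        fits=fits,
    )


def subject_slopes(
    table: pd.DataFrame, measure: str, roi: str
) -> pd.DataFrame:
    """Per-subject OLS slope (units/year) of the longitudinal measure.

    Subjects with fewer than two distinct timepoints are excluded (and
    logged), matching the rate-of-change definition used for correlation
    analyses.
    """
    df = table[(table["measure_name"] == measure) & (table["roi"] == roi)]
    df = df.dropna(subset=["value", "timepoint_years"])
    rows = []
    excluded = 0
    for subject, grp in df.groupby("subject_id"):
        t = grp["timepoint_years"].to_numpy(dtype=float)
        y = grp["value"].to_numpy(dtype=float)
        if np.unique(t).size < 2:
            excluded += 1
            continue
        slope = float(np.polyfit(t, y, 1)[0])
        rows.append(
            {
                "subject_id": subject,
                "roi": roi,
                "measure": measure,
                "slope": slope,
                "n_timepoints": int(np.unique(t).size),
            }
        )
    if excluded:
        logger.info(
            "excluded %d subject(s) without two distinct timepoints", excluded
        )
    return pd.DataFrame(rows, columns=["subject_id", "roi", "measure", "slope", "n_timepoints"])


def spearman_assoc(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a two-sided p-value.

    Pairwise-complete: rows with a missing member are dropped.  Constant
    input yields (nan, nan) with a warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def compare_correlations(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Fisher's z test of two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)),
    two-sided normal p.  Antisymmetric under swapping the groups.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 (Fisher transform undefined at 1)")
    for n in (n1, n2):
        if n < 4:
            raise ValueError("each group needs at least 4 observations")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)
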