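"""Linear mixed-effects inference on per-maneuver workload features.

Each feature (CPF peak, EDA amplitude, HR AUC, HQR) is modelled with a
random intercept per pilot.  A fixed factor (the classical partition, the
four-zone partition, or the experience group) is retained only if adding it
both lowers the AIC of the maximum-likelihood fit and is significant in a
likelihood-ratio test at alpha.  Residual normality is checked
(Shapiro-Wilk); on rejection the response is log-transformed (requires a
strictly positive response) and the fit repeated once.  Reported estimates
come from a restricted-maximum-likelihood refit, and all pairwise level
contrasts are corrected for multiplicity with the Benjamini-Hochberg false
discovery rate procedure.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "LMEReport",
    "Contrast",
    "build_feature_table",
    "fit_lme",
    "check_residuals_and_transform",
    "pairwise_contrasts",
    "run_full_inference",
]

FACTORS = ("classical", "zone", "group")
_EXCLUDED_LEVELS = {"Excluded", "Unlabeled", "Unzoned"}


@dataclass
class Contrast:
    level_a: str
    level_b: str
    estimate: float      # mean(level_a) - mean(level_b)
    se: float
    p_raw: float
    p_adjusted: float | None = None

    def __str__(self) -> str:  # sign convention "A > B: EST"
        hi, lo, est = (self.level_a, self.level_b, self.estimate)
        if est < 0:
            hi, lo, est = lo, hi, -est
        p = self.p_adjusted if self.p_adjusted is not None else self.p_raw
        return f"{hi} > {lo}: EST = {est:.4g} (p = {p:.4g})"


@dataclass
class LMEReport:
    response: str
    factor: str
    transform: str                 # none | log
    null_aic: float
    factor_aic: float
    anova_p: float
    retained: bool
    alpha: float
    levels: list[str] = field(default_factory=list)
    fixed_effects: dict[str, float] = field(default_factory=dict)  # level -> estimated mean
    fixed_se: dict[str, float] = field(default_factory=dict)
    contrasts: list[Contrast] = field(default_factory=list)
    shapiro_p: float | None = None
    degenerate: bool = False
    n_obs: int = 0
    _reml_result: object = None    # statsmodels result, for contrast covariances

    def summary_row(self) -> dict:
        return {
            "response": self.response,
            "factor": self.factor,
            "transform": self.transform,
            "null_aic": self.null_aic,
            "factor_aic": self.factor_aic,
            "anova_p": self.anova_p,
            "retained": self.retained,
            "n_obs": self.n_obs,
        }


def build_feature_table(
    metadata: pd.DataFrame,
    values: pd.Series | np.ndarray,
    response: str = "value",
) -> pd.DataFrame:
    """Assemble the modelling table: one row per maneuver.

    ``metadata`` must carry ``pilot_id``, ``classical``, ``zone`` and
    ``group`` columns; partition levels marked excluded/unlabeled are
    dropped from the corresponding factor by downstream fitting, not here.
    """
    df = metadata[["pilot_id", "classical", "zone", "group"]].copy()
    df[response] = np.asarray(values, dtype=float)
    df["group"] = df["group"].map(lambda g: f"Group{g}")
    return df


def _prepare(table: pd.DataFrame, factor: str, response: str) -> pd.DataFrame:
    if factor not in FACTORS:
        raise ValueError(f"factor must be one of {FACTORS}, got {factor!r}")
    df = table.dropna(subset=[response, factor, "pilot_id"]).copy()
    df = df[~df[factor].astype(str).isin(_EXCLUDED_LEVELS)]
    levels = sorted(df[factor].astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than two levels after filtering")
    if df["pilot_id"].nunique() < 3:
        raise ValueError("need at least 3 pilots for the random-intercept model")
    df[factor] = pd.Categorical(df[factor].astype(str), categories=levels)
    return df


def _robust_fit(model, reml: bool):
    """Fit a MixedLM across several optimizers; keep the best-likelihood fit.

    The profiled (restricted) likelihood surface is flat near a singular
    random-effect variance, where individual optimizers stall or raise;
    taking the highest-likelihood successful fit is just (RE)ML estimation
    done carefully.
    """
    best = None
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in ("lbfgs", "bfgs", "powell", "cg"):
            try:
                res = model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if np.isfinite(res.llf) and (best is None or res.llf > best.llf + 1e-9):
                best = res
            if best is not None and getattr(res, "converged", False):
                break
    if best is None:
        raise RuntimeError(f"mixed-model fit failed: {last_exc}") from last_exc
    return best


def _fit_ml_pair(df: pd.DataFrame, factor: str, response: str):
    null = _robust_fit(smf.mixedlm(f"{response} ~ 1", df, groups=df["pilot_id"]),
                       reml=False)
    full = _robust_fit(smf.mixedlm(f"{response} ~ C({factor})", df, groups=df["pilot_id"]),
                       reml=False)
    return null, full


def fit_lme(
    table: pd.DataFrame,
    factor: str,
    response: str = "value",
    alpha: float = 0.05,
    transform: str = "none",
) -> LMEReport:
    """Fit the null and factor mixed models and decide factor retention.

    The null model is an intercept plus a random intercept per pilot; the
    factor model adds the fixed factor.  Both are fitted by maximum
    likelihood for the AIC / likelihood-ratio comparison; the reported
    level means come from a REML refit.  ``retained`` requires both an AIC
    decrease and LRT significance at ``alpha``.
    """
    df = _prepare(table, factor, response)
    y = df[response].to_numpy()
    if transform == "log":
        if (y <= 0).any():
            raise ValueError("log transform requires a strictly positive response")
        df = df.assign(**{response: np.log(y)})
        y = df[response].to_numpy()

    levels = list(df[factor].cat.categories)
    report = LMEReport(
        response=response, factor=factor, transform=transform,
        null_aic=np.nan, factor_aic=np.nan, anova_p=np.nan,
        retained=False, alpha=alpha, levels=levels, n_obs=len(df),
    )
    if np.ptp(y) == 0:
        report.degenerate = True
        report.anova_p = 1.0
        return report

    null_ml, full_ml = _fit_ml_pair(df, factor, response)
    lrt = 2.0 * (full_ml.llf - null_ml.llf)
    df_diff = len(levels) - 1
    anova_p = float(spstats.chi2.sf(max(lrt, 0.0), df_diff))
    report.null_aic = float(null_ml.aic)
    report.factor_aic = float(full_ml.aic)
    report.anova_p = anova_p
    report.retained = bool(full_ml.aic < null_ml.aic and anova_p < alpha)

    reml = _robust_fit(
        smf.mixedlm(f"{response} ~ 0 + C({factor})", df, groups=df["pilot_id"]),
        reml=True,
    )
    names = [f"C({factor})[{lev}]" for lev in levels]
    report.fixed_effects = {lev: float(reml.params[nm]) for lev, nm in zip(levels, names)}
    report.fixed_se = {lev: float(reml.bse[nm]) for lev, nm in zip(levels, names)}
    report._reml_result = reml
    if getattr(reml, "cov_re", None) is not None:
        re_var = float(np.asarray(reml.cov_re)[0, 0])
        if not np.isfinite(re_var) or re_var < 1e-12:
            report.degenerate = True  # singular random-effect variance
    report.shapiro_p = _residual_shapiro(reml)
    return report


def _residual_shapiro(result) -> float:
    try:
        resid = np.asarray(result.resid)
    except ValueError:
        # singular random-effect fit: fall back to marginal residuals
        resid = np.asarray(result.model.endog) - \
            np.asarray(result.model.exog) @ np.asarray(result.fe_params)
    if len(resid) < 3:
        return np.nan
    if len(resid) > 4500:  # Shapiro-Wilk implementation limit
        rng = np.random.default_rng(0)
        resid = rng.choice(resid, 4500, replace=False)
    return float(spstats.shapiro(resid).pvalue)


def check_residuals_and_transform(
    report: LMEReport,
    table: pd.DataFrame,
    alpha: float = 0.05,
) -> LMEReport:
    """Refit on the log scale when residual Gaussianity is rejected.

    The transform is applied at most once; a non-positive response with
    rejected normality raises, since the log model is infeasible.
    """
    if report.transform != "none" or report.shapiro_p is None or np.isnan(report.shapiro_p):
        return report
    if report.shapiro_p >= alpha:
        return report
    y = table.dropna(subset=[report.response])[report.response].to_numpy(dtype=float)
    if (y <= 0).any():
        raise ValueError(
            "residual normality rejected but the response is not strictly "
            "positive: log transform infeasible"
        )
    return fit_lme(table, report.factor, response=report.response,
                   alpha=report.alpha, transform="log")


def pairwise_contrasts(report: LMEReport, fdr_method: str = "fdr_bh") -> list[Contrast]:
    """All pairwise level differences of a retained factor, FDR-corrected.

    Wald z-tests on the REML fixed-effect estimates; adjusted p-values by
    Benjamini-Hochberg (monotone, never below the raw p).
    """
    if not report.retained:
        raise ValueError("pairwise contrasts are defined only for a retained factor")
    reml = report._reml_result
    if reml is None:
        raise ValueError("report carries no fitted model")
    levels = report.levels
    names = [f"C({report.factor})[{lev}]" for lev in levels]
    cov = np.asarray(reml.cov_params().loc[names, names])
    est = np.array([report.fixed_effects[lev] for lev in levels])
    out: list[Contrast] = []
    for i, j in itertools.combinations(range(len(levels)), 2):
        diff = est[i] - est[j]
        se = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
        z = diff / se if se > 0 else np.inf * np.sign(diff)
        p = float(2 * spstats.norm.sf(abs(z)))
        out.append(Contrast(levels[i], levels[j], float(diff), se, p))
    padj = multipletests([c.p_raw for c in out], method=fdr_method)[1]
    for c, p in zip(out, padj):
        c.p_adjusted = float(p)
    report.contrasts = out
    return out


def run_full_inference(
    tables: dict[str, pd.DataFrame],
    factors: tuple[str, ...] = FACTORS,
    alpha: float = 0.05,
    fdr_method: str = "fdr_bh",
    auto_transform: bool = True,
) -> dict[tuple[str, str], LMEReport]:
    """One mixed-model comparison per (feature, factor) pair.

    ``tables`` maps feature names to modelling tables (see
    :func:`build_feature_table`).  Returns reports keyed by
    ``(feature, factor)``; each retained factor carries its FDR-corrected
    pairwise contrasts.
    """
    if not tables:
        raise ValueError("no feature tables supplied")
    reports: dict[tuple[str, str], LMEReport] = {}
    for feature, table in tables.items():
        if table.empty:
            raise ValueError(f"feature table {feature!r} is empty")
        for factor in factors:
            rep = fit_lme(table, factor, response="value", alpha=alpha)
            if auto_transform:
                try:
                    rep = check_residuals_and_transform(rep, table, alpha=alpha)
                except ValueError:
                    pass  # non-positive response: keep the untransformed fit
            rep.response = feature
            if rep.retained:
                pairwise_contrasts(rep, fdr_method=fdr_method)
            reports[(feature, factor)] = rep
    return reports


def retention_matrix(reports: dict[tuple[str, str], LMEReport]) -> pd.DataFrame:
    """Summary matrix of retained flags, features x factors."""
    feats = sorted({k[0] for k in reports})
    facs = [f for f in FACTORS if any(k[1] == f for k in reports)]
    return pd.DataFrame(
        [[reports[(ft, fa)].retained for fa in facs] for ft in feats],
        index=feats, columns=facs,
    )
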