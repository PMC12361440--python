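"""Sex-stratified GLM covariate adjustment of analyte levels.

For each analyte and each fetal sex a generalized linear model

    analyte ~ gestational age at delivery (weeks) + pregravid BMI^2
              + labor initiation + smoking + illicit drug use

is fitted. The family is chosen per analyte by a fixed rule: Gaussian with
identity link unless the analyte's distribution is non-normal by an
Anderson-Darling test (p < 0.05) or more than 2.5% of its values lie beyond
|z| = 3, in which case a gamma family with log link is used. Gestational-age
p-values are Benjamini-Hochberg corrected across all analytes within a sex;
significant analytes (q < 0.05) have their nuisance-covariate contribution
removed, preserving location through the intercept.

Gaussian identity-link fits are ordinary least squares and are computed in
closed form (batched across analytes); gamma fits use statsmodels' IRLS.
Maternal age is deliberately excluded: it is strongly anticorrelated with
gestational age at delivery and would inflate multicollinearity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad
from statsmodels.stats.multitest import multipletests

from .datatypes import SEXES, OmicsLayer, align_layers, qualify, validate_cohort

logger = logging.getLogger(__name__)

#: Model terms in design-matrix order.
TERMS = ("intercept", "ga", "bmi_sq", "labor", "smoking", "drug")

#: Nuisance terms removed during adjustment (everything except the intercept).
NUISANCE_TERMS = ("ga", "bmi_sq", "labor", "smoking", "drug")


def design_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Design matrix with intercept, GA (weeks), BMI squared and binaries.

    ``bmi_sq`` is the squared pregravid BMI entering as a single term (no
    accompanying linear term).
    """
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "ga": cohort["ga_weeks"].astype(float),
            "bmi_sq": cohort["bmi"].astype(float) ** 2,
            "labor": cohort["labor_init"].astype(float),
            "smoking": cohort["smoking"].astype(float),
            "drug": cohort["drug_use"].astype(float),
        },
        index=cohort.index,
    )
    return X


# ---------------------------------------------------------------------------
# family selection
# ---------------------------------------------------------------------------

@dataclass
class FamilyDecision:
    analyte_id: str
    ad_p: float
    outlier_frac: float
    decision: str  # "gaussian" | "gamma"
    reason: str


def select_family(
    values: np.ndarray | pd.Series,
    analyte_id: str = "",
    ad_alpha: float = 0.05,
    z_threshold: float = 3.0,
    max_outlier_frac: float = 0.025,
) -> FamilyDecision:
    """Choose Gaussian vs gamma for one analyte (pure function of the vector).

    Gamma is selected iff the Anderson-Darling normality p is below
    ``ad_alpha`` or the fraction of values with |z| > ``z_threshold``
    (z-scores from the analyte's own mean and sample sd) exceeds
    ``max_outlier_frac``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise ValueError("family selection needs at least 8 observations")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError(f"analyte {analyte_id!r} has zero variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, ad_p = normal_ad(v)
    z = (v - v.mean()) / sd
    outlier_frac = float(np.mean(np.abs(z) > z_threshold))
    non_normal = ad_p < ad_alpha
    has_outliers = outlier_frac > max_outlier_frac
    if non_normal or has_outliers:
        reason = " and ".join(
            r
            for r, hit in [
                (f"AD p={ad_p:.3g} < {ad_alpha}", non_normal),
                (f"outlier fraction {outlier_frac:.3g} > {max_outlier_frac}", has_outliers),
            ]
            if hit
        )
        return FamilyDecision(analyte_id, float(ad_p), outlier_frac, "gamma", reason)
    return FamilyDecision(analyte_id, float(ad_p), outlier_frac, "gaussian", "normal, no outliers")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class GlmFit:
    analyte_id: str
    layer: str
    sex: str
    family: str  # "gaussian" | "gamma"
    link: str  # "identity" | "log"
    coef: dict[str, float]
    ga_p: float
    converged: bool = True
    shift: float = 0.0  # positive shift applied before a gamma fit
    ga_q: float = float("nan")
    significant_ga: bool = False


def _ols_batch(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form least squares for many analytes at once.

    Returns (coefficients p x m, two-sided GA-term p-values length m). The
    GA p-value uses the usual t statistic on n - p degrees of freedom.
    """
    n, p = X.shape
    if Y.ndim == 1:
        Y = Y[:, None]
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    ga_idx = TERMS.index("ga")
    se_ga = np.sqrt(np.maximum(sigma2 * xtx_inv[ga_idx, ga_idx], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_ga > 0, beta[ga_idx] / se_ga, np.inf * np.sign(beta[ga_idx]))
    ga_p = 2.0 * stats.t.sf(np.abs(t), dof)
    # exact fits (zero residual) have se 0; their GA p is 0 unless beta is 0 too
    ga_p = np.where(se_ga == 0, np.where(beta[ga_idx] == 0, 1.0, 0.0), ga_p)
    return beta, ga_p


def fit_glm(
    values: np.ndarray | pd.Series,
    X: pd.DataFrame,
    decision: FamilyDecision,
    layer: str = "",
    sex: str = "",
) -> GlmFit:
    """Fit one analyte's GLM under the selected family.

    Gaussian/identity uses closed-form least squares; gamma/log uses
    statsmodels IRLS, with a recorded positive shift of |min| + 1e-6 when the
    response is not strictly positive. Non-convergence is flagged, not raised.
    """
    y = np.asarray(values, dtype=float)
    Xv = X[list(TERMS)].to_numpy(dtype=float)
    if decision.decision == "gaussian":
        beta, ga_p = _ols_batch(y, Xv)
        coef = dict(zip(TERMS, beta[:, 0]))
        return GlmFit(decision.analyte_id, layer, sex, "gaussian", "identity", coef, float(ga_p[0]))
    shift = 0.0
    y_min = y.min()
    if y_min <= 0:
        shift = abs(y_min) + 1e-6
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y + shift, Xv, family=sm.families.Gamma(link=sm.families.links.Log()))
            res = model.fit(maxiter=200)
        # a perfect (zero-deviance) fit can stop IRLS without the flag set
        converged = np.isfinite(res.params).all() and (
            bool(getattr(res, "converged", True)) or res.deviance <= 1e-8
        )
        coef = dict(zip(TERMS, res.params))
        ga_p = float(res.pvalues[TERMS.index("ga")])
    except Exception as exc:  # perfect separation, singular IRLS steps, ...
        logger.warning("gamma GLM failed for %s (%s): %s", decision.analyte_id, sex, exc)
        converged = False
        coef = {t: float("nan") for t in TERMS}
        ga_p = float("nan")
    return GlmFit(
        decision.analyte_id, layer, sex, "gamma", "log", coef, ga_p,
        converged=converged, shift=shift,
    )


def fit_layer(
    layer: OmicsLayer,
    X: pd.DataFrame,
    sex: str = "",
) -> list[GlmFit]:
    """Family-select and fit every analyte of one layer for one sample set.

    Gaussian analytes are fitted in one batched least-squares call; gamma
    analytes fall back to per-analyte IRLS. Zero-variance analytes are
    recorded as non-converged fits and excluded from the BH family later.
    """
    values = layer.values.loc[X.index]
    fits: list[GlmFit] = []
    gaussian_cols: list[str] = []
    decisions: dict[str, FamilyDecision] = {}
    for col in values.columns:
        try:
            decision = select_family(values[col].to_numpy(), analyte_id=col)
        except ValueError as exc:
            logger.warning("family selection failed for %s (%s): %s", col, sex, exc)
            fits.append(
                GlmFit(col, layer.name, sex, "gaussian", "identity",
                       {t: float("nan") for t in TERMS}, float("nan"), converged=False)
            )
            continue
        decisions[col] = decision
        if decision.decision == "gaussian":
            gaussian_cols.append(col)

    if gaussian_cols:
        Y = values[gaussian_cols].to_numpy(dtype=float)
        beta, ga_p = _ols_batch(Y, X[list(TERMS)].to_numpy(dtype=float))
        for j, col in enumerate(gaussian_cols):
            coef = dict(zip(TERMS, beta[:, j]))
            fits.append(
                GlmFit(col, layer.name, sex, "gaussian", "identity", coef, float(ga_p[j]))
            )
    for col, decision in decisions.items():
        if decision.decision == "gamma":
            fits.append(fit_glm(values[col].to_numpy(), X, decision, layer=layer.name, sex=sex))
    return fits


# ---------------------------------------------------------------------------
# BH calling and adjustment
# ---------------------------------------------------------------------------

def call_ga_regulated(fits: list[GlmFit], q_threshold: float = 0.05) -> set[str]:
    """BH-correct GA p-values across analytes; mark and return significant ids.

    The family is all converged fits passed in (one sex, all layers pooled).
    Mutates ``ga_q`` and ``significant_ga`` on the fits.
    """
    usable = [f for f in fits if f.converged and np.isfinite(f.ga_p)]
    if not usable:
        raise ValueError("no converged fits to correct")
    excluded = len(fits) - len(usable)
    if excluded:
        logger.warning("%d non-converged fits excluded from the BH family", excluded)
    pvals = np.array([f.ga_p for f in usable])
    reject, q, _, _ = multipletests(pvals, alpha=q_threshold, method="fdr_bh")
    called = set()
    for fit, qi, rej in zip(usable, q, reject):
        fit.ga_q = float(qi)
        fit.significant_ga = bool(rej)
        if rej:
            called.add(fit.analyte_id)
    return called


def adjust_values(
    values: np.ndarray | pd.Series,
    fit: GlmFit,
    X: pd.DataFrame,
    remove: tuple[str, ...] = NUISANCE_TERMS,
    preserve: str = "mean",
) -> np.ndarray:
    """Remove fitted nuisance-covariate effects from an analyte vector.

    Gaussian/identity subtracts the nuisance part of the linear predictor;
    gamma/log does the same on the log scale of the (shift-corrected) values
    and maps back multiplicatively. ``preserve`` controls the location left
    behind:

    * ``"mean"`` (default) — subtract the mean-centered nuisance predictor,
      so the group's observed mean level is preserved. Because fits are
      sex-stratified, this keeps adjusted levels comparable across sexes
      when the two sexes' samples are later pooled.
    * ``"intercept"`` — subtract the raw nuisance predictor, leaving values
      located at the fitted intercept (the level extrapolated to
      all-covariates-zero).

    ``remove`` can be restricted (e.g. to ``("ga",)``) to take out only the
    gestational-age term.
    """
    if preserve not in ("mean", "intercept"):
        raise ValueError("preserve must be 'mean' or 'intercept'")
    y = np.asarray(values, dtype=float)
    eta_nuis = np.zeros(len(y))
    for term in remove:
        eta_nuis += fit.coef[term] * X[term].to_numpy(dtype=float)
    if preserve == "mean":
        eta_nuis = eta_nuis - eta_nuis.mean()
    if fit.family == "gaussian":
        return y - eta_nuis
    y_shifted = y + fit.shift
    if (y_shifted <= 0).any():
        raise ValueError(
            f"gamma adjustment undefined for nonpositive values of {fit.analyte_id!r}"
        )
    return np.exp(np.log(y_shifted) - eta_nuis) - fit.shift


def adjust_layers(
    layers: list[OmicsLayer],
    cohort: pd.DataFrame,
    q_threshold: float = 0.05,
    remove: tuple[str, ...] = NUISANCE_TERMS,
    preserve: str = "mean",
) -> tuple[list[OmicsLayer], pd.DataFrame, dict[str, set[str]]]:
    """Full sex-stratified adjustment of all layers.

    For each fetal sex independently: select families, fit GLMs, BH-correct
    GA p-values across all analytes of that sex, and replace the values of
    significant analytes (for that sex's samples only) with their
    covariate-adjusted versions. Non-significant analytes pass through
    unchanged.

    Returns the adjusted layers, a tidy fits table, and the per-sex sets of
    GA-regulated (layer-qualified) analyte ids.
    """
    validate_cohort(cohort)
    align_layers(layers)
    # adjusted values are continuous (a gamma/log adjustment rescales counts
    # multiplicatively), so the output layers are abundance-kind
    adjusted = [OmicsLayer(layer.name, layer.values.copy(), "abundance") for layer in layers]
    records = []
    ga_regulated: dict[str, set[str]] = {}
    for sex in SEXES:
        idx = cohort.index[cohort["fetal_sex"] == sex]
        if len(idx) == 0:
            ga_regulated[sex] = set()
            continue
        X = design_matrix(cohort.loc[idx])
        sex_fits: list[tuple[OmicsLayer, GlmFit]] = []
        for layer in adjusted:
            for fit in fit_layer(layer, X, sex=sex):
                sex_fits.append((layer, fit))
        call_ga_regulated([f for _, f in sex_fits], q_threshold)
        called = set()
        for layer, fit in sex_fits:
            if fit.significant_ga:
                called.add(qualify(layer.name, fit.analyte_id))
                col = layer.values.loc[idx, fit.analyte_id]
                layer.values.loc[idx, fit.analyte_id] = adjust_values(
                    col, fit, X, remove, preserve
                )
            records.append(
                dict(
                    analyte_id=fit.analyte_id,
                    layer=fit.layer,
                    sex=fit.sex,
                    family=fit.family,
                    link=fit.link,
                    **{f"coef_{t}": fit.coef[t] for t in TERMS},
                    ga_p=fit.ga_p,
                    ga_q=fit.ga_q,
                    significant_ga=fit.significant_ga,
                    converged=fit.converged,
                    shift=fit.shift,
                )
            )
        ga_regulated[sex] = called
        logger.info("%s: %d / %d analytes GA-regulated at q < %g",
                    sex, len(called), len(sex_fits), q_threshold)
    return adjusted, pd.DataFrame(records), ga_regulated


# ---------------------------------------------------------------------------
# covariate screening
# ---------------------------------------------------------------------------

def screen_covariates(
    cohort: pd.DataFrame, vif_threshold: float = 5.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise covariate correlations and variance inflation factors.

    VIF for covariate j is 1 / (1 - R^2) from regressing it (with intercept)
    on the other covariates. A constant covariate has undefined VIF (NaN,
    flagged); perfect collinearity yields +inf, which always exceeds the
    warning threshold.
    """
    X = design_matrix(cohort).drop(columns="intercept")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 covariates to screen")
    corr = X.corr()
    rows = []
    for col in X.columns:
        y = X[col].to_numpy(dtype=float)
        if y.std() == 0:
            rows.append(dict(covariate=col, vif=float("nan"), flag=True,
                             note="constant covariate, VIF undefined"))
            continue
        others = X.drop(columns=col).to_numpy(dtype=float)
        A = np.column_stack([np.ones(len(y)), others])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        ss_res = float((resid**2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        vif = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append(dict(covariate=col, vif=vif, flag=vif > vif_threshold, note=""))
    vif_table = pd.DataFrame(rows).set_index("covariate")
    flagged = vif_table.index[vif_table["flag"]].tolist()
    if flagged:
        logger.warning("covariates above VIF threshold %g: %s", vif_threshold, flagged)
    return corr, vif_table
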