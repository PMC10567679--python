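"""Treatment-effect and dimensionality inference on stability facets.

Two linear mixed-model designs are used, matching the randomized-block
layout of the experiment:

* facet responses — treatment (Control vs NPK) as the fixed effect with
  random intercepts for site and for block nested within site;
* correlation responses — pairwise Pearson correlations computed across
  blocks within each (site, treatment), with treatment fixed and site as
  the only random effect.

Models are fit by REML (statsmodels ``MixedLM``); t-tests use
containment-style denominator degrees of freedom (observations minus
innermost grouping units minus one), the convention of conventional
nested-LMM software.  Singular nested fits fall back to a site-only
random intercept and are flagged.
"""

from __future__ import annotations

import itertools
import math
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .stability import FACETS

logger = logging.getLogger(__name__)

__all__ = [
    "EffectEstimate",
    "pearson",
    "correlation_tables",
    "lmm_facet_effect",
    "lmm_correlation_effect",
    "facet_effects_table",
    "correlation_effects_table",
]

CORE_ASPECTS = ("biomass", "richness", "composition")


@dataclass
class EffectEstimate:
    """NPK - Control fixed-effect contrast with per-treatment means."""

    response: str
    estimate: float
    se: float
    df: float
    tstat: float
    pvalue: float
    mean_control: float
    mean_npk: float
    ci_control: tuple[float, float]
    ci_npk: tuple[float, float]
    n_obs: int
    fallback_site_only: bool = False
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = dict(
            response=self.response, estimate=self.estimate, se=self.se, df=self.df,
            tstat=self.tstat, pvalue=self.pvalue, mean_control=self.mean_control,
            mean_npk=self.mean_npk,
            ci_control_lo=self.ci_control[0], ci_control_hi=self.ci_control[1],
            ci_npk_lo=self.ci_npk[0], ci_npk_hi=self.ci_npk[1],
            n_obs=self.n_obs, fallback_site_only=self.fallback_site_only,
        )
        row.update(self.extra)
        return row


def pearson(x, y) -> float:
    """Pearson product-moment correlation; requires n >= 3 and nonzero variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson requires at least 3 complete pairs")
    if (x == x[0]).all() or (y == y[0]).all():
        raise ValueError("pearson undefined with a zero-variance argument")
    with warnings.catch_warnings():
        # nearly-constant inputs are legitimate here (3 blocks, tiny noise)
        warnings.simplefilter("ignore", sps.NearConstantInputWarning)
        return float(sps.pearsonr(x, y).statistic)


def correlation_tables(
    facets: pd.DataFrame,
    aspects: tuple[str, ...] = CORE_ASPECTS,
    min_n: int = 3,
) -> pd.DataFrame:
    """Pairwise Pearson correlations among stability measures, per site x treatment.

    Within each (site, treatment), facet values vary across blocks; the
    table holds, for every site and treatment, all 10 facet pairs within
    each aspect (``comparison_type == "within_aspect"``) and all 3 aspect
    pairs for each facet (``"among_aspect"``).  Pairs with fewer than
    ``min_n`` complete finite block values, or with a zero-variance member,
    are skipped with a log message.
    """
    sub = facets[facets["aspect"].isin(aspects)].copy()
    sub["measure"] = sub["aspect"] + "|" + sub["facet"]
    wide = sub.pivot_table(index=["site", "block", "treatment"], columns="measure",
                           values="value", aggfunc="first")

    pairs: list[tuple[str, str, str]] = []
    for aspect in aspects:
        for f_a, f_b in itertools.combinations(FACETS, 2):
            pairs.append(("within_aspect", f"{aspect}|{f_a}", f"{aspect}|{f_b}"))
    for facet in FACETS:
        for a_a, a_b in itertools.combinations(aspects, 2):
            pairs.append(("among_aspect", f"{a_a}|{facet}", f"{a_b}|{facet}"))

    rows = []
    for (site, trt), grp in wide.groupby(level=["site", "treatment"]):
        for ctype, m_a, m_b in pairs:
            if m_a not in grp.columns or m_b not in grp.columns:
                continue
            pair = grp[[m_a, m_b]].dropna()
            pair = pair[np.isfinite(pair).all(axis=1)]
            if len(pair) < min_n:
                continue
            x, y = pair[m_a].to_numpy(), pair[m_b].to_numpy()
            if (x == x[0]).all() or (y == y[0]).all():
                logger.info("zero-variance pair %s ~ %s at %s/%s dropped", m_a, m_b, site, trt)
                continue
            rows.append(dict(site=site, treatment=trt, comparison_type=ctype,
                             measure_a=m_a, measure_b=m_b,
                             r=pearson(x, y), n=len(pair)))
    return pd.DataFrame(rows, columns=["site", "treatment", "comparison_type",
                                       "measure_a", "measure_b", "r", "n"])


def _fit_mixedlm(data: pd.DataFrame, nested_block: bool):
    """REML fit of value ~ npk with site (and optionally block-in-site) intercepts.

    A response with (near-)zero residual variance makes the mixed model
    unfittable; ordinary least squares then gives the same point estimates
    and a degenerate covariance, which the caller reports as such.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if nested_block:
                model = smf.mixedlm("value ~ npk", data, groups=data["site"],
                                    re_formula="1", vc_formula={"block": "0 + C(block)"})
            else:
                model = smf.mixedlm("value ~ npk", data, groups=data["site"], re_formula="1")
            return model.fit(reml=True)
        except (np.linalg.LinAlgError, ValueError):
            logger.warning("mixed model unfittable (degenerate response); using OLS")
            return smf.ols("value ~ npk", data).fit()


def _effect_from_fit(result, data: pd.DataFrame, response: str, df_denom: float,
                     fallback: bool) -> EffectEstimate:
    params = result.params
    cov = np.nan_to_num(result.cov_params().loc[["Intercept", "npk"], ["Intercept", "npk"]]
                        .to_numpy())
    est = float(params["npk"])
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    if se > 0:
        tstat = est / se
        pvalue = 2.0 * sps.t.sf(abs(tstat), df_denom)
    else:  # degenerate (zero-residual) fit
        tstat = 0.0 if est == 0 else math.copysign(math.inf, est)
        pvalue = 1.0 if est == 0 else 0.0
    tcrit = sps.t.ppf(0.975, df_denom)
    mean_c = float(params["Intercept"])
    var_c = max(cov[0, 0], 0.0)
    mean_n = mean_c + est
    var_n = max(cov[0, 0] + cov[1, 1] + 2.0 * cov[0, 1], 0.0)
    se_c, se_n = np.sqrt(var_c), np.sqrt(var_n)
    return EffectEstimate(
        response=response, estimate=est, se=se, df=df_denom, tstat=tstat,
        pvalue=float(pvalue), mean_control=mean_c, mean_npk=mean_n,
        ci_control=(mean_c - tcrit * se_c, mean_c + tcrit * se_c),
        ci_npk=(mean_n - tcrit * se_n, mean_n + tcrit * se_n),
        n_obs=len(data), fallback_site_only=fallback,
    )


def lmm_facet_effect(facets: pd.DataFrame, aspect: str, facet: str) -> EffectEstimate:
    """Treatment effect on one stability facet.

    Fits ``value ~ treatment`` with random intercepts for site and block
    nested within site (REML) and returns the NPK - Control contrast with
    a two-tailed t-test.  The denominator df is ``n_obs - n_blocks - 1``
    since treatment varies within blocks.
    """
    data = facets[(facets["aspect"] == aspect) & (facets["facet"] == facet)].copy()
    data = data[np.isfinite(data["value"])]
    if data["site"].nunique() < 2:
        raise ValueError(f"{aspect}/{facet}: need >= 2 sites for the mixed model")
    if set(data["treatment"].unique()) != {"Control", "NPK"}:
        raise ValueError(f"{aspect}/{facet}: both treatments must be present")
    data["npk"] = (data["treatment"] == "NPK").astype(float)

    fallback = False
    try:
        result = _fit_mixedlm(data, nested_block=True)
        if not np.all(np.isfinite(result.bse[["Intercept", "npk"]])):
            raise ValueError("non-finite standard errors")
    except Exception as exc:  # singular / non-converged nested fit
        logger.warning("%s/%s: nested fit failed (%s); refitting with site-only intercept",
                       aspect, facet, exc)
        fallback = True
        result = _fit_mixedlm(data, nested_block=False)

    if fallback:
        df_denom = len(data) - data["site"].nunique() - 1
    else:
        n_blocks = data.groupby(["site", "block"]).ngroups
        df_denom = len(data) - n_blocks - 1
    df_denom = max(df_denom, 1)
    return _effect_from_fit(result, data, f"{aspect}|{facet}", df_denom, fallback)


def lmm_correlation_effect(
    records: pd.DataFrame,
    measure_a: str,
    measure_b: str,
    fisher_z: bool = False,
) -> EffectEstimate:
    """Treatment effect on the correlation between two stability measures.

    The response is the per-(site, treatment) Pearson r (optionally
    Fisher-z transformed); treatment is fixed and site a random intercept.
    Per-treatment mean correlations with model-based 95% CIs are returned
    for the "CI does not overlap 0" significance display; with
    ``fisher_z`` the means and CIs are reported back on the r scale.
    """
    data = records[(records["measure_a"] == measure_a)
                   & (records["measure_b"] == measure_b)].copy()
    both = data.groupby("site")["treatment"].nunique()
    if (both == 2).sum() < 2:
        raise ValueError(f"{measure_a} ~ {measure_b}: need >= 2 sites with both treatments")
    data["value"] = np.arctanh(np.clip(data["r"], -1 + 1e-12, 1 - 1e-12)) if fisher_z else data["r"]
    data["npk"] = (data["treatment"] == "NPK").astype(float)

    result = _fit_mixedlm(data, nested_block=False)
    df_denom = max(len(data) - data["site"].nunique() - 1, 1)
    eff = _effect_from_fit(result, data, f"{measure_a}~{measure_b}", df_denom, False)
    if fisher_z:
        eff.mean_control = float(np.tanh(eff.mean_control))
        eff.mean_npk = float(np.tanh(eff.mean_npk))
        eff.ci_control = tuple(np.tanh(eff.ci_control))
        eff.ci_npk = tuple(np.tanh(eff.ci_npk))
        eff.extra["scale"] = "fisher_z"
    return eff


def facet_effects_table(facets: pd.DataFrame,
                        aspects: tuple[str, ...] | None = None) -> pd.DataFrame:
    """One treatment-effect row per aspect x facet (skips unfittable cells)."""
    if aspects is None:
        aspects = tuple(facets["aspect"].unique())
    rows = []
    for aspect in aspects:
        for facet in FACETS:
            try:
                eff = lmm_facet_effect(facets, aspect, facet)
            except ValueError as exc:
                logger.info("skipping %s/%s: %s", aspect, facet, exc)
                continue
            row = eff.to_row()
            row.update(aspect=aspect, facet=facet)
            rows.append(row)
    return pd.DataFrame(rows)


def correlation_effects_table(records: pd.DataFrame, fisher_z: bool = False) -> pd.DataFrame:
    """Treatment effect on every correlation pair present in ``records``."""
    rows = []
    key = ["comparison_type", "measure_a", "measure_b"]
    for (ctype, m_a, m_b), _grp in records.groupby(key):
        try:
            eff = lmm_correlation_effect(records, m_a, m_b, fisher_z=fisher_z)
        except ValueError as exc:
            logger.info("skipping %s ~ %s: %s", m_a, m_b, exc)
            continue
        row = eff.to_row()
        row.update(comparison_type=ctype, measure_a=m_a, measure_b=m_b)
        rows.append(row)
    return pd.DataFrame(rows)
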