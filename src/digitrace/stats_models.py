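"""Declarative mixed-model analyses of reading change and finger kinematics.

Model specifications mirror the study design: reading-change gains are
modelled as Modality x Phase plus a priori cognitive covariates with a
random intercept per participant; finger-kinematic responses are modelled
as Decoding skill x Session x Phase with random intercepts for participant
(and word, for word-level analyses).  Effects are reported unstandardised
(b in native units: score points, mm/s, ms) with SE, t, CI, semi-partial
R-squared per the Nakagawa-Schielzeth approach as modified by Johnson, and
AIC/BIC/RMSE for model comparison.  Two-group descriptive comparisons use
a Shapiro-Wilk normality gate: a two-sample t test when both groups pass,
a Wilcoxon rank-sum test otherwise.

The solver backend is statsmodels MixedLM.  Degrees of freedom for fixed
effects use a between-within approximation (between-subject terms get
group-level df, within-subject terms residual df); this is an
approximation to the likelihood-based df methods used by lme4-family
tools and is labelled as such in every fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats as sps

DEFAULT_COVARIATES = ("age", "similarities", "matrix", "vocabulary",
                      "oral_comprehension", "memory_span", "cancellation",
                      "selective_attention", "motor_skills")


@dataclass
class ModelSpec:
    """A declarative mixed-model specification."""

    response: str
    fixed: str                       # patsy right-hand side
    group: str = "subject_id"        # random-intercept grouping factor
    extra_re: tuple = ()             # additional crossed random intercepts
    df_method: str = "between-within"
    reml: bool = True

    @property
    def formula(self) -> str:
        return f"{self.response} ~ {self.fixed}"


@dataclass
class ModelFit:
    """Fixed-effect estimates and fit statistics for one mixed model."""

    spec: ModelSpec
    terms: pd.DataFrame              # index term, columns b/se/t/df/p/ci_low/ci_high
    llf: float
    k_params: int
    aic: float
    bic: float
    rmse: float
    n_obs: int
    n_groups: int
    r2_model: float
    var_fixed: float
    var_random: float
    var_resid: float
    singular: bool
    reml: bool
    endog: np.ndarray = field(repr=False, default=None)
    exog: np.ndarray = field(repr=False, default=None)
    fe_params: pd.Series = field(repr=False, default=None)
    cov_params: pd.DataFrame = field(repr=False, default=None)
    design_info: object = field(repr=False, default=None)

    def term(self, name: str) -> pd.Series:
        if name not in self.terms.index:
            raise KeyError(f"term {name!r} not in model "
                           f"({list(self.terms.index)})")
        return self.terms.loc[name]


def _between_within_df(exog: np.ndarray, groups: np.ndarray,
                       names: Sequence[str]) -> dict[str, float]:
    """Between-within df: columns constant within every group are
    between-subject (df = n_groups - n_between), others within-subject
    (df = n_obs - n_groups - n_within)."""
    frame = pd.DataFrame(exog, columns=list(names))
    frame["_g"] = groups
    nun = frame.groupby("_g").nunique()
    between = {c for c in names if (nun[c] <= 1).all()}
    n_obs, n_groups = exog.shape[0], len(nun)
    df_b = max(n_groups - len(between), 1)
    df_w = max(n_obs - n_groups - (len(names) - len(between)), 1)
    return {c: (df_b if c in between else df_w) for c in names}


def fit_mixed(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit a mixed model per ``spec`` on ``data`` and assemble the report."""
    data = data.reset_index(drop=True)
    needed = {spec.group, *spec.extra_re}
    missing = sorted(c for c in needed if c not in data.columns)
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if spec.extra_re:
        # crossed random intercepts via variance components on one supergroup
        vcf = {spec.group: f"0 + C({spec.group})"}
        for re in spec.extra_re:
            if data[re].nunique() < 2:
                raise ValueError(
                    f"random effect {re!r} has a single level; inestimable")
            vcf[re] = f"0 + C({re})"
        data = data.assign(_all=1)
        model = smf.mixedlm(spec.formula, data, groups="_all", vc_formula=vcf)
    else:
        model = smf.mixedlm(spec.formula, data, groups=data[spec.group])
    result = None
    last_err: Exception | None = None
    for method in ("lbfgs", "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = model.fit(reml=spec.reml, method=[method])
            break
        except np.linalg.LinAlgError as err:  # ill-conditioned score step
            last_err = err
    if result is None:
        raise RuntimeError(f"mixed-model fit failed: {last_err}")

    fe = result.fe_params
    cov = result.cov_params().loc[fe.index, fe.index]
    exog = model.exog
    names = list(model.exog_names)
    design_info = getattr(model.data, "design_info", None)
    groups = data[spec.group].to_numpy()
    dfs = _between_within_df(exog, groups, names)

    rows = []
    for name in names:
        b = float(fe[name])
        se = float(np.sqrt(cov.loc[name, name]))
        df_t = dfs[name]
        tval = b / se if se > 0 else np.nan
        p = 2 * sps.t.sf(abs(tval), df_t) if np.isfinite(tval) else np.nan
        crit = sps.t.ppf(0.975, df_t)
        rows.append({"term": name, "b": b, "se": se, "t": tval, "df": df_t,
                     "p": p, "ci_low": b - crit * se, "ci_high": b + crit * se})
    terms = pd.DataFrame(rows).set_index("term")

    endog = np.asarray(model.endog, dtype=float)
    fitted_fixed = exog @ fe.to_numpy()
    var_fixed = float(np.var(fitted_fixed))
    var_resid = float(result.scale)
    # total random-intercept variance: classic cov_re plus variance components
    var_random = float(np.trace(result.cov_re)) if result.cov_re.size else 0.0
    vcomp = getattr(result, "vcomp", np.empty(0))
    var_random += float(np.sum(vcomp))
    total = var_fixed + var_random + var_resid
    r2_model = var_fixed / total if total > 0 else np.nan
    singular = bool(var_random <= 1e-8 * max(total, 1e-12))

    k = len(fe) + int(result.cov_re.size and result.cov_re.shape[0]) \
        + len(vcomp) + 1  # + residual scale
    llf = float(result.llf)
    aic = 2 * k - 2 * llf
    bic = k * np.log(len(endog)) - 2 * llf
    try:
        resid = np.asarray(result.resid, dtype=float)
    except (ValueError, np.linalg.LinAlgError):
        # singular RE covariance: statsmodels cannot predict random effects,
        # fall back to marginal residuals
        resid = endog - fitted_fixed
    rmse = float(np.sqrt(np.mean(resid ** 2)))

    return ModelFit(spec=spec, terms=terms, llf=llf, k_params=k, aic=aic,
                    bic=bic, rmse=rmse, n_obs=len(endog),
                    n_groups=int(pd.unique(groups).size),
                    r2_model=float(r2_model), var_fixed=var_fixed,
                    var_random=var_random, var_resid=var_resid,
                    singular=singular, reml=spec.reml, endog=endog,
                    exog=exog, fe_params=fe, cov_params=cov,
                    design_info=design_info)


# --- the study's two model families ------------------------------------------

def fit_reading_change_model(data: pd.DataFrame,
                             covariates: Sequence[str] = DEFAULT_COVARIATES,
                             response: str = "gain",
                             reml: bool = True) -> ModelFit:
    """Reading change ~ Modality x Phase + cognitive covariates +
    (1 | subject).  One row per subject x phase; reference levels are the
    paper modality and phase 1, so the modality coefficient reads as
    digit-tracking minus paper."""
    required = [response, "modality", "phase", "subject_id", *covariates]
    missing = sorted(c for c in required if c not in data.columns)
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    fixed = "C(modality, Treatment('paper')) * C(phase)"
    if covariates:
        fixed += " + " + " + ".join(covariates)
    spec = ModelSpec(response=response, fixed=fixed, reml=reml)
    fit = fit_mixed(spec, data)
    if fit.singular:
        warnings.warn("random-intercept variance estimated at zero "
                      "(singular fit)")
    return fit


def fit_kinematics_model(data: pd.DataFrame, response: str,
                         include_word_re: bool = False,
                         reml: bool = True) -> ModelFit:
    """Kinematic response ~ Decoding x Session x Phase + (1 | subject)
    [+ (1 | word)].  Decoding reference level 'poor' so the main decoding
    coefficient is the good - poor contrast; session and phase are
    categorical."""
    required = [response, "decoding", "session", "phase", "subject_id"]
    if include_word_re:
        required.append("word")
    missing = sorted(c for c in required if c not in data.columns)
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if data["session"].nunique() < 2:
        raise ValueError("only one session present: session interactions "
                         "are inestimable")
    fixed = "C(decoding, Treatment('poor')) * C(session) * C(phase)"
    spec = ModelSpec(response=response, fixed=fixed,
                     extra_re=("word",) if include_word_re else (),
                     reml=reml)
    return fit_mixed(spec, data)


def marginal_contrast(fit: ModelFit, data: pd.DataFrame,
                      factor: str = "decoding",
                      levels: tuple[str, str] = ("good", "poor"),
                      ) -> dict[str, float]:
    """Estimated marginal contrast ``levels[0] - levels[1]`` for a factor,
    averaging fixed-effect predictions over the observed levels of every
    other factor in the design (balanced grid, emmeans-style)."""
    if fit.design_info is None:
        raise ValueError("fit carries no design information")
    other = [c for c in ("session", "phase") if c in data.columns]
    grid_vals = {c: sorted(data[c].unique()) for c in other}
    rows = []
    for level in levels:
        combos = [{}]
        for c in other:
            combos = [{**combo, c: v} for combo in combos for v in grid_vals[c]]
        for combo in combos:
            rows.append({factor: level, **combo})
    grid = pd.DataFrame(rows)
    (X,) = patsy.build_design_matrices([fit.design_info], grid)
    X = np.asarray(X)
    per = X.shape[0] // 2
    cvec = X[:per].mean(axis=0) - X[per:].mean(axis=0)
    b = float(cvec @ fit.fe_params.to_numpy())
    se = float(np.sqrt(cvec @ fit.cov_params.to_numpy() @ cvec))
    df_t = max(fit.n_groups - 2, 1)
    crit = sps.t.ppf(0.975, df_t)
    tval = b / se if se > 0 else np.nan
    return {"estimate": b, "se": se, "t": tval, "df": df_t,
            "p": 2 * sps.t.sf(abs(tval), df_t),
            "ci_low": b - crit * se, "ci_high": b + crit * se}


# --- effect sizes and model comparison ---------------------------------------

def semi_partial_r2(fit: ModelFit, term: str) -> float:
    """Semi-partial R-squared of one fixed-effect term: the drop in
    fixed-prediction variance when the term's coefficients are zeroed,
    over the model's total variance (fixed + random + residual);
    Nakagawa-Schielzeth as modified by Johnson."""
    if fit.design_info is None:
        raise ValueError("fit carries no design information")
    slices = fit.design_info.term_name_slices
    if term not in slices:
        raise KeyError(f"term {term!r} not in model "
                       f"({list(slices)})")
    beta = fit.fe_params.to_numpy().copy()
    full = fit.exog @ beta
    beta[slices[term]] = 0.0
    reduced = fit.exog @ beta
    total = fit.var_fixed + fit.var_random + fit.var_resid
    num = float(np.var(full) - np.var(reduced))
    return max(num, 0.0) / total


def compare_models(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """AIC/BIC/RMSE table (sorted by AIC) for fits on identical
    observations; use ML (reml=False) fits when fixed structures differ."""
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0].endog
    for f in fits[1:]:
        if f.n_obs != fits[0].n_obs or not np.allclose(f.endog, ref):
            raise ValueError("fits are not on identical observation sets")
    if any(f.reml for f in fits) and len({f.spec.fixed for f in fits}) > 1:
        warnings.warn("comparing REML fits with different fixed structures; "
                      "refit with reml=False for valid AIC comparison")
    rows = [{"model": f.spec.formula, "k": f.k_params, "logLik": f.llf,
             "AIC": f.aic, "BIC": f.bic, "RMSE": f.rmse} for f in fits]
    return pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)


# --- normality-gated two-group tests -----------------------------------------

@dataclass
class GroupComparison:
    measure: str
    means: dict[str, float]
    sems: dict[str, float]
    test: str            # 't' or 'wilcoxon'
    statistic: float
    p: float
    shapiro_p: dict[str, float]


def group_comparison(values_by_group: Mapping[str, Sequence[float]],
                     measure: str = "", alpha: float = 0.05) -> GroupComparison:
    """Two-sided two-group comparison with a Shapiro-Wilk gate: both groups
    normal at ``alpha`` -> two-sample t test; otherwise Wilcoxon rank-sum."""
    if len(values_by_group) != 2:
        raise ValueError("exactly two groups required")
    (ga, xa), (gb, xb) = [(k, np.asarray(v, dtype=float))
                          for k, v in values_by_group.items()]
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("need at least 3 observations per group")
    sh = {ga: float(sps.shapiro(xa).pvalue), gb: float(sps.shapiro(xb).pvalue)}
    normal = all(p > alpha for p in sh.values())
    if normal:
        res = sps.ttest_ind(xa, xb)
        test = "t"
    else:
        res = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        test = "wilcoxon"
    return GroupComparison(
        measure=measure,
        means={ga: float(np.mean(xa)), gb: float(np.mean(xb))},
        sems={ga: float(sps.sem(xa)), gb: float(sps.sem(xb))},
        test=test, statistic=float(res.statistic), p=float(res.pvalue),
        shapiro_p=sh)
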