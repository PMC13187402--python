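"""Mixed-effects characterisation of substate speed and entropy.

Substate metrics are modelled with the fixed structure
``value ~ emotion * condition * substate`` and a random intercept plus
condition slope per subject, fitted by REML.  Entropy is log-transformed
before fitting (its distribution is right-skewed and bounded at zero);
speed is modelled on its original scale.  If the random-slope fit is
singular or fails to converge, the random structure falls back to an
intercept-only model, and finally to OLS, each step logged.  Pairwise
contrasts are estimated-marginal-mean differences with Bonferroni
correction within each family; R-squared follows the Nakagawa
variance-partition definitions (marginal = fixed effects only,
conditional = fixed + random).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

__all__ = [
    "MixedModelResult",
    "fit_substate_lmm",
    "pairwise_contrasts",
    "r_squared",
]

_FIXED = "value ~ C(emotion) * C(condition) * C(substate)"
_LOG_EPS = 1e-3


@dataclass
class MixedModelResult:
    fixed_effects: pd.DataFrame        # term, estimate, se, z, p
    anova: pd.DataFrame                # effect, F, df_num, df_den, p
    variance_components: dict
    r2_marginal: float
    r2_conditional: float
    random_structure: str              # "intercept+slope" | "intercept" | "none"
    data: pd.DataFrame = field(repr=False, default=None)
    result: object = field(repr=False, default=None)
    response: str = "speed"


def _is_singular(res) -> bool:
    try:
        cov_re = np.asarray(res.cov_re)
        if cov_re.size and np.min(np.linalg.eigvalsh(cov_re)) < 1e-8:
            return True
    except Exception:
        return True
    return not res.converged


def fit_substate_lmm(data: pd.DataFrame, response: str = "speed"
                     ) -> MixedModelResult:
    """Fit value ~ emotion x condition x substate + (1 + condition | subject).

    ``data`` is a long table with columns trial, subject, emotion,
    condition, substate, value.  ``response='log_entropy'`` log-transforms
    the value column (log(v + 1e-3)) before fitting.
    """
    if response not in {"speed", "log_entropy"}:
        raise ValueError("response must be 'speed' or 'log_entropy'")
    df = data.copy()
    required = {"subject", "emotion", "condition", "substate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects for a mixed model")
    df = df.dropna(subset=["value"])
    if response == "log_entropy":
        df["value"] = np.log(df["value"] + _LOG_EPS)

    structures = [("intercept+slope", "~C(condition)"), ("intercept", None)]
    res, structure = None, "none"
    for name, re_formula in structures:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(_FIXED, df, groups=df["subject"],
                                    re_formula=re_formula)
                cand = model.fit(reml=True, method="lbfgs", maxiter=200)
            if _is_singular(cand):
                log.warning("random structure %s singular; simplifying", name)
                continue
            res, structure = cand, name
            break
        except Exception as e:  # pragma: no cover - solver-dependent
            log.warning("random structure %s failed (%s); simplifying", name, e)
    if res is None:
        log.warning("falling back to fixed-effects-only OLS")
        res = smf.ols(_FIXED, df).fit()
        structure = "none"

    fe = pd.DataFrame({
        "term": res.params.index if structure == "none" else res.fe_params.index,
        "estimate": (res.params if structure == "none" else res.fe_params).values,
    })
    bse = res.bse[: len(fe)]
    fe["se"] = np.asarray(bse)
    fe["z"] = fe["estimate"] / fe["se"]
    fe["p"] = 2 * stats.norm.sf(np.abs(fe["z"]))

    anova = _type3_wald(res, df, structure)
    vc = _variance_components(res, structure)
    r2m, r2c = _nakagawa_r2(res, df, structure)
    return MixedModelResult(fixed_effects=fe, anova=anova,
                            variance_components=vc, r2_marginal=r2m,
                            r2_conditional=r2c, random_structure=structure,
                            data=df, result=res, response=response)


def _design_info(df: pd.DataFrame):
    return patsy.dmatrix(_FIXED.split("~")[1], df, return_type="dataframe")


def _fixed_params(res, structure: str) -> tuple[np.ndarray, np.ndarray]:
    if structure == "none":
        return np.asarray(res.params), np.asarray(res.cov_params())
    beta = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[: len(beta), : len(beta)]
    return beta, cov


def _type3_wald(res, df: pd.DataFrame, structure: str) -> pd.DataFrame:
    """Type III Wald F tests per fixed effect term.

    Denominator df is the residual df (n - p); an approximation to the
    Satterthwaite df that is asymptotically equivalent at these balanced
    designs.
    """
    X = _design_info(df)
    terms = X.design_info.term_names
    beta, cov = _fixed_params(res, structure)
    n, p = X.shape
    rows = []
    for term in terms:
        if term == "Intercept":
            continue
        sl = X.design_info.term_name_slices[term]
        idx = np.arange(p)[sl]
        L = np.zeros((len(idx), p))
        L[np.arange(len(idx)), idx] = 1.0
        est = L @ beta
        V = L @ cov @ L.T
        try:
            F = float(est @ np.linalg.solve(V, est)) / len(idx)
        except np.linalg.LinAlgError:
            F = np.nan
        df_den = n - p
        pval = float(stats.f.sf(F, len(idx), df_den)) if np.isfinite(F) else np.nan
        rows.append({"effect": term, "F": F, "df_num": len(idx),
                     "df_den": df_den, "p": pval})
    return pd.DataFrame(rows)


def _variance_components(res, structure: str) -> dict:
    if structure == "none":
        return {"subject_intercept": 0.0, "condition_slope": 0.0,
                "residual": float(res.mse_resid)}
    cov_re = np.asarray(res.cov_re)
    out = {"subject_intercept": float(cov_re[0, 0]),
           "residual": float(res.scale)}
    out["condition_slope"] = float(cov_re[1, 1]) if cov_re.shape[0] > 1 else 0.0
    out["cov_re"] = cov_re
    return out


def _nakagawa_r2(res, df: pd.DataFrame, structure: str) -> tuple[float, float]:
    X = _design_info(df).to_numpy()
    beta, _ = _fixed_params(res, structure)
    var_f = float(np.var(X @ beta))
    if structure == "none":
        var_r, var_e = 0.0, float(res.mse_resid)
    else:
        var_e = float(res.scale)
        cov_re = np.asarray(res.cov_re)
        if cov_re.shape[0] > 1:
            Z = patsy.dmatrix("~C(condition)", df, return_type="dataframe").to_numpy()
            var_r = float(np.mean(np.einsum("ij,jk,ik->i", Z, cov_re, Z)))
        else:
            var_r = float(cov_re[0, 0])
    total = var_f + var_r + var_e
    return var_f / total, (var_f + var_r) / total


def r_squared(model: MixedModelResult) -> tuple[float, float]:
    """(marginal, conditional) Nakagawa R-squared of a fitted model."""
    return model.r2_marginal, model.r2_conditional


def pairwise_contrasts(model: MixedModelResult, family: str,
                       correction: str = "bonferroni") -> pd.DataFrame:
    """Bonferroni-corrected pairwise level differences for one factor family.

    ``family`` may be a single factor (``emotion``, ``condition``,
    ``substate``) or an interaction slice ``factor@slicer=level`` (e.g.
    ``emotion@substate=transition``): pairwise differences of the factor's
    estimated marginal means within that slice.  Marginal means average the
    model's fixed-effect predictions over a balanced grid of the remaining
    factors.
    """
    df = model.data
    factors = {"emotion", "condition", "substate"}
    slicer = None
    if "@" in family:
        family, cond = family.split("@", 1)
        sk, sv = cond.split("=", 1)
        slicer = (sk.strip(), sv.strip())
    family = family.strip()
    if family not in factors:
        raise KeyError(f"unknown factor family {family!r}")

    levels = {f: sorted(df[f].unique()) for f in factors}
    if slicer:
        if slicer[0] not in factors or slicer[1] not in levels[slicer[0]]:
            raise KeyError(f"unknown slice {slicer!r}")
        levels[slicer[0]] = [slicer[1]]

    beta, cov = _fixed_params(model.result, model.random_structure)

    def emm_vector(level) -> np.ndarray:
        others = [f for f in factors if f != family]
        grid = pd.DataFrame([
            {family: level, others[0]: a, others[1]: b}
            for a in levels[others[0]] for b in levels[others[1]]])
        X = patsy.build_design_matrices(
            [_design_info(df).design_info], grid)[0]
        return np.asarray(X).mean(axis=0)

    n, p = _design_info(df).shape
    df_den = n - p
    rows = []
    pairs = list(itertools.combinations(levels[family], 2))
    for a, b in pairs:
        L = emm_vector(a) - emm_vector(b)
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        t = est / se if se > 0 else np.nan
        raw = 2 * float(stats.t.sf(abs(t), df_den)) if np.isfinite(t) else np.nan
        corr = min(1.0, raw * len(pairs)) if correction == "bonferroni" else raw
        rows.append({"pair": f"{a} - {b}", "estimate": est, "se": se,
                     "t": t, "df": df_den, "p_raw": raw, "p_corrected": corr})
    return pd.DataFrame(rows)
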