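"""The statistical battery: age and block effects on vocal and social metrics.

Vocal responses are modelled per individual per block with age class, block
(continuous) and optionally their interaction as fixed effects, accounting for
repeated measures per individual and nesting within flocks.  Families follow
the data type: negative binomial (log link) for call counts, Gaussian for
area change, beta (logit link) for the overlap proportions.  Network density
is binomial over the 6 possible edges per flock; strength is negative
binomial for interaction counts and gamma (inverse link) for proximity.

Estimation uses maximum likelihood with the repeated-measures structure
handled either by explicit random intercepts (Gaussian, via a linear mixed
model) or by cluster-robust covariance at the individual/flock level (the
non-Gaussian families).  Wald statistics are reported as t for Gaussian
responses and z otherwise.

Age is coded as a young-adult indicator (``age_young`` = 1 for young, 0 for
old), so a positive age coefficient means a higher response in young adults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.othermod.betareg import BetaModel

ALPHA_INTERACTION = 0.05
FAMILIES = ("negative_binomial", "gaussian", "beta", "binomial", "gamma")

#: response -> family, following the data-type mapping of the battery
DEFAULT_FAMILY = {
    "vocal_output": "negative_binomial",
    "diversity_change": "gaussian",
    "plasticity": "beta",
    "convergence": "beta",
    "density": "binomial",
    "strength_affiliation": "negative_binomial",
    "strength_agonism": "negative_binomial",
    "strength_proximity": "gamma",
}

#: overlap/area responses are defined relative to baseline, so only
#: post-flock blocks enter the model
BASELINE_RELATIVE = {"diversity_change", "plasticity", "convergence"}


@dataclass
class ModelSpec:
    """What to fit: response, family, fixed and random structure."""

    response: str
    family: str
    fixed: tuple[str, ...] = ("age", "block")
    interaction: bool = True
    random: tuple[str, ...] = ("individual", "flock")

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def stat_type(self) -> str:
        return "t" if self.family == "gaussian" else "z"


def vocal_model_spec(response: str, interaction: bool = True) -> ModelSpec:
    return ModelSpec(
        response=response,
        family=DEFAULT_FAMILY[response],
        fixed=("age", "block"),
        interaction=interaction,
        random=("individual", "flock"),
    )


def network_model_spec(metric: str, dimension: str) -> ModelSpec:
    """Density: GLM with age only, no random effects (one value per flock).
    Strength: age fixed effect with flock as the grouping factor."""
    if metric == "density":
        return ModelSpec(
            response="density",
            family="binomial",
            fixed=("age",),
            interaction=False,
            random=(),
        )
    if metric == "strength":
        key = f"strength_{dimension}"
        return ModelSpec(
            response=key,
            family=DEFAULT_FAMILY[key],
            fixed=("age",),
            interaction=False,
            random=("flock",),
        )
    raise ValueError(f"unknown network metric {metric!r}")


@dataclass
class ModelFit:
    """Fixed-effect estimates with Wald statistics, plus fit diagnostics."""

    spec: ModelSpec
    table: pd.DataFrame  # term, estimate, se, statistic, stat_type, p_value
    converged: bool = True
    degenerate: bool = False
    interaction_dropped: bool | None = None
    random_variances: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def coef(self, term: str) -> pd.Series:
        row = self.table[self.table["term"] == term]
        if row.empty:
            raise KeyError(f"term {term!r} not in fit")
        return row.iloc[0]

    def pvalue(self, term: str) -> float:
        return float(self.coef(term)["p_value"])


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def _prepare(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = data.copy()
    if "age_young" not in df.columns:
        if "age_class" not in df.columns:
            raise ValueError("data needs an age_class or age_young column")
        df["age_young"] = (df["age_class"] == "young").astype(int)
    if spec.response in BASELINE_RELATIVE and "block" in df.columns:
        df = df[df["block"] >= 2]
    ycol = spec.response
    df = df.dropna(subset=[ycol])
    if spec.family == "beta":
        y = df[ycol].to_numpy(dtype=float)
        n = len(y)
        # boundary squeeze: beta support is the open interval (0, 1)
        y = np.where(y <= 0.0, 0.5 / n, y)
        y = np.where(y >= 1.0, (n - 0.5) / n, y)
        df = df.assign(**{ycol: y})
    return df.reset_index(drop=True)


def _formula(spec: ModelSpec) -> str:
    terms = []
    if "age" in spec.fixed:
        terms.append("age_young")
    if "block" in spec.fixed:
        terms.append("block")
    if spec.interaction and {"age", "block"} <= set(spec.fixed):
        terms.append("age_young:block")
    return f"{spec.response} ~ " + " + ".join(terms)


def _term_names(spec: ModelSpec) -> dict[str, str]:
    names = {"Intercept": "intercept", "age_young": "age", "block": "block",
             "age_young:block": "age:block"}
    return names


def _result_table(params, bse, pvalues, spec: ModelSpec) -> pd.DataFrame:
    names = _term_names(spec)
    rows = []
    for term in params.index:
        if term in ("precision", "alpha", "Group Var") or term.endswith("Var"):
            continue
        est, se = float(params[term]), float(bse[term])
        rows.append(
            {
                "term": names.get(term, term),
                "estimate": est,
                "se": se,
                "statistic": est / se if se > 0 else np.nan,
                "stat_type": spec.stat_type,
                "p_value": float(pvalues[term]),
            }
        )
    return pd.DataFrame(rows)


def _cluster_groups(df: pd.DataFrame, spec: ModelSpec) -> np.ndarray | None:
    """Cluster-robust grouping: the coarsest random-effect level present.

    Age varies between flocks, so the sandwich must cluster at the flock
    level to absorb both flock- and individual-level correlation.
    """
    for level in ("flock", "individual"):
        if level in spec.random and level in df.columns:
            if df[level].nunique() > 1:
                return pd.Categorical(df[level]).codes
    return None


def _t_pvalues(table: pd.DataFrame, df_denom: float) -> pd.DataFrame:
    """Replace normal-based Wald p-values with t(df) ones; with few clusters
    the normal reference is anti-conservative."""
    from scipy.stats import t as t_dist

    table = table.copy()
    stat = table["statistic"].to_numpy(dtype=float)
    table["p_value"] = 2 * t_dist.sf(np.abs(stat), df_denom)
    return table


def _is_degenerate(table: pd.DataFrame) -> bool:
    est = table["estimate"].to_numpy()
    se = table["se"].to_numpy()
    return bool(
        np.any(~np.isfinite(est))
        or np.any(~np.isfinite(se))
        or np.any(np.abs(est) > 15)
        or np.any(se > 100)
    )


# ---------------------------------------------------------------------------
# family-specific fitters
# ---------------------------------------------------------------------------

def _fit_gaussian(df: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    formula = _formula(spec)
    random = [r for r in spec.random if r in df.columns
              and df[r].nunique() > 1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if {"individual", "flock"} <= set(random):
            model = smf.mixedlm(
                formula, df, groups="flock", re_formula="1",
                vc_formula={"individual": "0 + C(individual)"},
            )
            res = model.fit()
        elif random:
            model = smf.mixedlm(formula, df, groups=random[0])
            res = model.fit()
        else:
            res = smf.ols(formula, df).fit()
    fixed = [t for t in res.params.index
             if t in ("Intercept", "age_young", "block", "age_young:block")]
    table = _result_table(res.params[fixed], res.bse[fixed],
                          res.pvalues[fixed], spec)
    if random:
        # age varies between groups; reference the Wald statistics against
        # t with group-count-based denominator df
        n_groups = df[random[0] if "flock" not in random else "flock"].nunique()
        table = _t_pvalues(table, max(n_groups - 2, 2))
    rvar = {}
    if hasattr(res, "cov_re") and random:
        rvar["flock" if "flock" in random else random[0]] = float(
            np.asarray(res.cov_re)[0, 0]
        )
        if hasattr(res, "vcomp") and len(getattr(res, "vcomp", [])) > 0:
            rvar["individual"] = float(res.vcomp[0])
        rvar["residual"] = float(res.scale)
    converged = bool(getattr(res, "converged", True))
    return ModelFit(spec=spec, table=table, converged=converged,
                    degenerate=_is_degenerate(table),
                    random_variances=rvar)


def _fit_negative_binomial(df: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """NB2 with log link.  With grouping present, the mean model is estimated
    by GEE (exchangeable working correlation, clusters at the coarsest random
    level) with the Mancl-DeRouen bias-reduced covariance, which keeps Wald
    tests calibrated at a dozen clusters; the NB shape is profiled from a
    pooled maximum-likelihood fit."""
    formula = _formula(spec)
    groups = _cluster_groups(df, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled = smf.negativebinomial(formula, df).fit(disp=0, maxiter=200)
        alpha = float(pooled.params.get("alpha", 1.0))
        if groups is not None:
            gee = smf.gee(
                formula, groups=groups, data=df,
                family=sm.families.NegativeBinomial(alpha=max(alpha, 1e-6)),
                cov_struct=sm.cov_struct.Exchangeable(),
            )
            res = gee.fit(cov_type="bias_reduced")
            converged = bool(getattr(res, "converged", True))
        else:
            res = pooled
            converged = bool(pooled.mle_retvals.get("converged", True))
    table = _result_table(res.params, res.bse, res.pvalues, spec)
    if groups is not None:
        table = _t_pvalues(table, max(len(np.unique(groups)) - 1, 2))
    return ModelFit(
        spec=spec, table=table, converged=converged,
        degenerate=_is_degenerate(table),
        diagnostics={"nb_alpha": alpha},
    )


def _fit_beta(df: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    formula = _formula(spec)
    groups = _cluster_groups(df, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BetaModel.from_formula(formula, df)
        if groups is not None:
            res = model.fit(disp=0, cov_type="cluster",
                            cov_kwds={"groups": groups})
        else:
            res = model.fit(disp=0)
    table = _result_table(res.params, res.bse, res.pvalues, spec)
    if groups is not None:
        table = _t_pvalues(table, max(len(np.unique(groups)) - 1, 2))
    converged = bool(res.mle_retvals.get("converged", True))
    return ModelFit(
        spec=spec, table=table, converged=converged,
        degenerate=_is_degenerate(table),
        diagnostics={"precision": float(res.params.get("precision", np.nan))},
    )


def _fit_binomial(df: pd.DataFrame, spec: ModelSpec,
                  trials: int = 6) -> ModelFit:
    """Density as successes out of the possible edges per flock."""
    successes = np.round(df[spec.response].to_numpy(dtype=float) * trials)
    endog = np.column_stack([successes, trials - successes])
    exog_cols = ["age_young"] if "age" in spec.fixed else []
    exog = sm.add_constant(df[exog_cols]) if exog_cols else np.ones((len(df), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    params = res.params.rename({"const": "Intercept"})
    bse = res.bse.rename({"const": "Intercept"})
    pvals = res.pvalues.rename({"const": "Intercept"})
    table = _result_table(params, bse, pvals, spec)
    return ModelFit(spec=spec, table=table, converged=True,
                    degenerate=_is_degenerate(table))


def _fit_gamma(df: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    formula = _formula(spec)
    groups = _cluster_groups(df, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.glm(formula, df, family=sm.families.Gamma())
        if groups is not None:
            res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
        else:
            res = model.fit()
    table = _result_table(res.params, res.bse, res.pvalues, spec)
    if groups is not None:
        table = _t_pvalues(table, max(len(np.unique(groups)) - 1, 2))
    return ModelFit(spec=spec, table=table, converged=True,
                    degenerate=_is_degenerate(table))


_FITTERS = {
    "gaussian": _fit_gaussian,
    "negative_binomial": _fit_negative_binomial,
    "beta": _fit_beta,
    "binomial": _fit_binomial,
    "gamma": _fit_gamma,
}


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def fit_vocal_model(metrics: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit one vocal response.  Non-convergence is flagged on the returned
    fit rather than raised."""
    df = _prepare(metrics, spec)
    try:
        return _FITTERS[spec.family](df, spec)
    except Exception as exc:  # noqa: BLE001 - flagged, not raised
        return ModelFit(
            spec=spec,
            table=pd.DataFrame(
                columns=["term", "estimate", "se", "statistic", "stat_type",
                         "p_value"]
            ),
            converged=False,
            degenerate=True,
            diagnostics={"error": str(exc)},
        )


def drop_interaction_if_ns(
    metrics: pd.DataFrame,
    spec: ModelSpec,
    alpha: float = ALPHA_INTERACTION,
) -> ModelFit:
    """Fit the full model with the age x block interaction; when the
    interaction is nonsignificant at ``alpha`` (or inestimable), refit
    without it and return the reduced fit.  The decision is recorded on the
    returned fit."""
    full_spec = replace(spec, interaction=True)
    full = fit_vocal_model(metrics, full_spec)
    try:
        p = full.pvalue("age:block")
    except KeyError:
        p = np.nan
    # alpha >= 1 disables the interaction term outright
    if np.isnan(p) or p >= alpha or alpha >= 1.0:
        reduced = fit_vocal_model(metrics, replace(spec, interaction=False))
        reduced.interaction_dropped = True
        reduced.diagnostics["interaction_p"] = float(p)
        return reduced
    full.interaction_dropped = False
    return full


def fit_network_model(metrics: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit one network metric (density per flock, strength per bird)."""
    return fit_vocal_model(metrics, spec)


def fit_battery(
    vocal_metrics: pd.DataFrame | None = None,
    network_metrics: pd.DataFrame | None = None,
    alpha: float = ALPHA_INTERACTION,
) -> pd.DataFrame:
    """Fit the full model battery and return one tidy table mirroring the
    (response, fixed effect, estimate, s.e., critical value, p-value) layout."""
    rows = []
    if vocal_metrics is not None:
        for response in ("vocal_output", "diversity_change", "plasticity",
                         "convergence"):
            if response not in vocal_metrics.columns:
                continue
            fit = drop_interaction_if_ns(
                vocal_metrics, vocal_model_spec(response), alpha=alpha
            )
            t = fit.table.assign(
                response=response,
                interaction_dropped=fit.interaction_dropped,
                converged=fit.converged,
                degenerate=fit.degenerate,
            )
            rows.append(t)
    if network_metrics is not None:
        for dimension in sorted(network_metrics["dimension"].unique()):
            sub = network_metrics[network_metrics["dimension"] == dimension]
            dens = sub.drop_duplicates("flock")[
                ["flock", "age_class", "density"]
            ]
            fit = fit_network_model(dens, network_model_spec("density", dimension))
            rows.append(fit.table.assign(
                response=f"density_{dimension}", converged=fit.converged,
                interaction_dropped=None, degenerate=fit.degenerate,
            ))
            spec = network_model_spec("strength", dimension)
            sdf = sub.rename(columns={"strength": spec.response})
            fit = fit_network_model(sdf, spec)
            rows.append(fit.table.assign(
                response=spec.response, converged=fit.converged,
                interaction_dropped=None, degenerate=fit.degenerate,
            ))
    if not rows:
        return pd.DataFrame()
    out = pd.concat(rows, ignore_index=True)
    cols = ["response", "term", "estimate", "se", "statistic", "stat_type",
            "p_value", "interaction_dropped", "converged", "degenerate"]
    return out[cols]
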