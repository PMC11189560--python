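"""Phenotypic tests of local adaptation and fitness-proxy associations.

The local-adaptation criterion is phenotypic: for the fitness-proxy trait, a
linear mixed model with soil line (the soil a population evolved in), soil
(the soil a plant is grown in) and their interaction as fixed factors and
replicate as a random intercept is fitted to the reciprocal-transplant data.
A significant soil line x soil (G x E) interaction combined with a
significant, positive "local vs foreign" contrast (local lines outperform
foreign lines grown in the same soil) is the verdict of local adaptation;
the "home vs away" contrast is supplementary. Fixed terms are tested with
1-df Wald chi-squares on the REML fit (sum-to-zero factor coding, so main
effects are marginal), contrasts with t-tests from the fixed-effect
covariance at residual degrees of freedom.

Also provided: trait-evolution contrasts between generations 1 and 10 for
plants grown in their local soil only (foreign-grown plants are excluded so
evolved change is not confounded with soil-induced plasticity), and the
fitness-proxy association models — a binary response model for seeds/no
seeds, a linear model on the seed-producing subset (the zero-inflated seed
set is split in two), a Poisson model for pollinator first choices, and the
visits-seeds correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .exceptions import ConfigurationError, DegenerateFitError
from .synthetic_experiment import SOILS

logger = logging.getLogger(__name__)

_CELLS = [(line, soil) for line in SOILS for soil in SOILS]


@dataclass
class GxEModelResult:
    """Fixed-term Wald tests, cell means and covariance of the G x E model."""

    terms: dict
    cell_means: dict
    cell_cov: np.ndarray
    replicate_var: float
    resid_df: int
    n_obs: int


@dataclass
class ContrastResult:
    contrast: str
    estimate: float
    se: float
    t_stat: float
    p_value: float
    df: int


@dataclass
class LocalAdaptationVerdict:
    adapted: bool
    interaction_p: float
    contrast_p: float
    contrast_estimate: float
    alpha: float


def _cell_design(line: str, soil: str) -> np.ndarray:
    """Row of the sum-coded 2x2 design for one soil_line x soil_grown cell."""
    cl = 1.0 if line == SOILS[0] else -1.0
    cs = 1.0 if soil == SOILS[0] else -1.0
    return np.array([1.0, cl, cs, cl * cs])


def fit_gxe(data: pd.DataFrame, trait: str = "open_flowers") -> GxEModelResult:
    """Fit trait ~ soil_line * soil_grown with a replicate random intercept.

    Falls back to the boundary fit (ordinary least squares, replicate
    variance 0) when the replicate variance converges to zero or the mixed
    fit fails.
    """
    for col in ("soil_line", "soil_grown", "replicate", trait):
        if col not in data.columns:
            raise ConfigurationError(f"column {col!r} missing")
    counts = data.groupby(["soil_line", "soil_grown"]).size()
    for cell in _CELLS:
        if counts.get(cell, 0) < 2:
            raise ConfigurationError(
                f"fewer than 2 observations in cell soil_line={cell[0]}, "
                f"soil_grown={cell[1]}"
            )
    formula = (
        f"{trait} ~ C(soil_line, Sum(omit='{SOILS[1]}')) * "
        f"C(soil_grown, Sum(omit='{SOILS[1]}'))"
    )
    fe_names = None
    replicate_var = 0.0
    fit = None
    if data["replicate"].nunique() > 1:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data, groups=data["replicate"])
                fit = model.fit(reml=True)
            replicate_var = float(fit.cov_re.iloc[0, 0])
            if not np.isfinite(replicate_var) or replicate_var < 0:
                fit = None
        except Exception:  # singular / non-converged boundary fits
            fit = None
    if fit is not None:
        beta = fit.fe_params.to_numpy()
        fe_names = list(fit.fe_params.index)
        cov = np.asarray(fit.cov_params().loc[fe_names, fe_names])
    else:
        ols = smf.ols(formula, data).fit()
        beta = ols.params.to_numpy()
        fe_names = list(ols.params.index)
        cov = np.asarray(ols.cov_params())
        replicate_var = 0.0

    order = [0, 1, 2, 3]  # Intercept, SL, S, SL:S — patsy emits in this order
    terms = {}
    for name, idx in (("soil_lines", 1), ("soil", 2), ("soil_lines_x_soil", 3)):
        chi2 = float(beta[idx] ** 2 / cov[idx, idx])
        terms[name] = {"chi2": chi2, "p_value": float(stats.chi2.sf(chi2, 1))}

    L = np.vstack([_cell_design(*cell) for cell in _CELLS])
    means = L @ beta[order]
    cell_cov = L @ cov[np.ix_(order, order)] @ L.T
    return GxEModelResult(
        terms=terms,
        cell_means={cell: float(m) for cell, m in zip(_CELLS, means)},
        cell_cov=cell_cov,
        replicate_var=replicate_var,
        resid_df=len(data) - 4,
        n_obs=len(data),
    )


def contrasts(model: GxEModelResult) -> dict:
    """Local-vs-foreign and home-vs-away contrasts from the fitted cell means.

    Positive estimates mean the local (resp. home) cells exceed the foreign
    (resp. away) cells. In a 2x2 transplant the two contrasts involve the
    same four cell means: local/foreign compares lines within a growing
    soil, home/away compares soils within a line.
    """
    for cell in _CELLS:
        if cell not in model.cell_means:
            raise ConfigurationError(f"missing cell {cell}")
    means = np.array([model.cell_means[c] for c in _CELLS])
    local = np.array([1.0 if line == soil else -1.0 for line, soil in _CELLS]) / 2.0
    out = {}
    for label in ("local_vs_foreign", "home_vs_away"):
        est = float(local @ means)
        se = float(np.sqrt(local @ model.cell_cov @ local))
        t = est / se if se > 0 else np.inf * np.sign(est)
        p = float(2 * stats.t.sf(abs(t), model.resid_df))
        out[label] = ContrastResult(label, est, se, float(t), p, model.resid_df)
    return out


def assess_local_adaptation(
    model: GxEModelResult, contrast_results: dict, alpha: float = 0.05
) -> LocalAdaptationVerdict:
    """Adapted iff the G x E interaction and the local-vs-foreign contrast are
    both significant and the contrast is positive (no multiplicity correction
    across traits)."""
    inter_p = model.terms["soil_lines_x_soil"]["p_value"]
    lvf = contrast_results["local_vs_foreign"]
    adapted = inter_p < alpha and lvf.p_value < alpha and lvf.estimate > 0
    return LocalAdaptationVerdict(adapted, inter_p, lvf.p_value, lvf.estimate, alpha)


@dataclass
class FitnessProxyReport:
    binary: pd.DataFrame | None
    binary_degenerate: bool
    truncated: pd.DataFrame | None
    poisson: pd.DataFrame | None
    visits_seeds_r: float | None
    visits_seeds_p: float | None


def _coef_frame(fit, covariates) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": fit.params.index,
            "coef": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "p_value": fit.pvalues.to_numpy(),
        }
    ).query("term in @covariates")


def fitness_proxy_models(
    data: pd.DataFrame,
    covariates=("open_flowers",),
    seed_col: str = "seed_set",
    choice_col: str = "first_choices",
    visits_col: str = "visits",
) -> FitnessProxyReport:
    """Associate candidate traits with the fitness components.

    Seed set is zero-inflated, so it is modelled in two parts: a binary GLM
    on seeds/no-seeds and a linear model restricted to seed-producing plants.
    First choices (counts) get a log-link Poisson GLM. Perfect separation in
    the binary model is flagged rather than reported as an estimate.
    """
    covariates = list(covariates)
    rhs = " + ".join(covariates)
    binary = truncated = poisson = None
    degenerate = False
    if seed_col in data.columns:
        d = data.dropna(subset=[seed_col] + covariates).copy()
        d["_produced"] = (d[seed_col] > 0).astype(float)
        if d["_produced"].nunique() < 2:
            degenerate = True
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = smf.glm(
                        f"_produced ~ {rhs}", d, family=sm.families.Binomial()
                    ).fit()
                if np.any(np.abs(fit.params.to_numpy()) > 50):
                    degenerate = True
                else:
                    binary = _coef_frame(fit, covariates)
            except Exception:
                degenerate = True
        pos = d[d[seed_col] > 0]
        if len(pos) > len(covariates) + 1:
            truncated = _coef_frame(smf.ols(f"{seed_col} ~ {rhs}", pos).fit(),
                                    covariates)
    if choice_col in data.columns:
        d = data.dropna(subset=[choice_col] + covariates)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.glm(
                f"{choice_col} ~ {rhs}", d, family=sm.families.Poisson()
            ).fit()
        poisson = _coef_frame(fit, covariates)
    r = p = None
    if visits_col in data.columns and seed_col in data.columns:
        d = data.dropna(subset=[visits_col, seed_col])
        if len(d) > 2:
            r, p = stats.pearsonr(d[visits_col], d[seed_col])
            r, p = float(r), float(p)
    return FitnessProxyReport(binary, degenerate, truncated, poisson, r, p)


def trait_evolution(
    data: pd.DataFrame,
    trait: str = "open_flowers",
    generations=(1, 10),
) -> pd.DataFrame:
    """Generation-10 minus generation-1 contrast per treatment, local soil only.

    Fits a cell-means mixed model (one mean per treatment x generation,
    replicate random intercept) — the generation x treatment interaction
    model — and extracts the within-treatment generation contrast. Plants
    grown in foreign soil are excluded (their trait values mix evolved
    change with plastic soil response).
    """
    g1, g10 = generations
    local = data[data["soil_grown"] == data["soil_line"]].copy()
    n_excluded = len(data) - len(local)
    if n_excluded:
        logger.info("trait_evolution: excluded %d foreign-soil plants", n_excluded)
    present = set(local["generation"].unique())
    if not {g1, g10} <= present:
        raise ConfigurationError(
            f"need generations {g1} and {g10}, found {sorted(present)}"
        )
    local = local[local["generation"].isin([g1, g10])]
    local["_cell"] = (
        local["treatment"].astype(str) + ":g" + local["generation"].astype(str)
    )
    formula = f"{trait} ~ 0 + C(_cell)"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, local, groups=local["replicate"]).fit(
                reml=True
            )
        params, cov = fit.fe_params, fit.cov_params()
        names = list(params.index)
        cov = np.asarray(cov.loc[names, names])
    except Exception:
        ols = smf.ols(formula, local).fit()
        params, cov = ols.params, np.asarray(ols.cov_params())
        names = list(params.index)
    beta = params.to_numpy()
    resid_df = len(local) - len(names)

    rows = []
    for trt in local["treatment"].unique():
        c = np.zeros(len(names))
        for gen, sign in ((g10, 1.0), (g1, -1.0)):
            label = f"C(_cell)[{trt}:g{gen}]"
            if label not in names:
                raise ConfigurationError(f"missing cell {trt}:g{gen}")
            c[names.index(label)] = sign
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        t = est / se if se > 0 else np.nan
        rows.append(
            {
                "treatment": trt,
                "estimate": est,
                "se": se,
                "t_stat": t,
                "p_value": float(2 * stats.t.sf(abs(t), resid_df)),
                "df": resid_df,
            }
        )
    return pd.DataFrame(rows)
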