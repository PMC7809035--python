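"""Module/gene - trait association models.

Implements the longitudinal random-slope extraction for cognitive decline,
the covariate-adjusted linear association of a module meta-feature (or a
single gene) with pathology/cognition traits, multiplicity handling
(Bonferroni and Benjamini-Hochberg), and the regression-attenuation
quantification of how much of an exposure's effect a mediator accounts for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_COVARIATES",
    "AssociationResult",
    "validate_phenotypes",
    "fit_decline_slopes",
    "associate",
    "association_grid",
    "adjust_multiplicity",
    "MediatedFraction",
    "mediated_variance_fraction",
]

#: covariate set used by every trait model unless overridden
DEFAULT_COVARIATES = ("age_death", "sex", "study", "rin", "pmi")

REQUIRED_PHENOTYPES = (
    "amyloid_sqrt",
    "tau_sqrt",
    "decline_slope",
    "age_death",
    "sex",
    "study",
    "rin",
    "pmi",
)


def validate_phenotypes(phen: pd.DataFrame) -> pd.DataFrame:
    """Check the documented phenotype schema (see module docstring)."""
    missing = [c for c in REQUIRED_PHENOTYPES if c not in phen.columns]
    if missing:
        raise ValueError(f"phenotype table missing required columns: {missing}")
    if phen.index.has_duplicates:
        raise ValueError("duplicated subject ids in phenotype table")
    return phen


@dataclass(frozen=True)
class AssociationResult:
    predictor: str
    trait: str
    beta: float
    se: float
    t: float
    p: float
    n: int
    covariates: tuple = DEFAULT_COVARIATES
    model: str = "ols"

    def as_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "trait": self.trait,
            "beta": self.beta,
            "se": self.se,
            "t": self.t,
            "p": self.p,
            "n": self.n,
            "model": self.model,
            "covariates": ";".join(self.covariates),
        }


# ---------------------------------------------------------------------------
# cognitive decline slopes
# ---------------------------------------------------------------------------

def fit_decline_slopes(observations: pd.DataFrame, min_subjects: int = 30) -> pd.Series:
    """Person-specific slopes of global cognition from a mixed-effects model.

    Fits cognition ~ year + age + sex + education with a correlated random
    intercept and slope per subject, and returns each subject's conditional
    (shrunken, BLUP-style) slope: the fixed year effect plus the subject's
    random slope. Subjects with fewer than 2 visits get a missing slope.

    When the within-subject residual variance is numerically zero the mixed
    likelihood is singular; per-subject OLS slopes (the exact noiseless
    limit of the conditional modes) are returned instead.
    """
    req = {"subject_id", "year", "cognition", "age", "sex", "education"}
    missing = req - set(observations.columns)
    if missing:
        raise ValueError(f"longitudinal table missing columns: {sorted(missing)}")
    obs = observations.copy()
    visit_counts = obs.groupby("subject_id")["year"].count()
    usable = visit_counts.index[visit_counts >= 2]
    if (visit_counts >= 3).sum() < min_subjects:
        raise ValueError(f"need >= {min_subjects} subjects with >= 3 visits")
    fit_obs = obs[obs["subject_id"].isin(usable)]

    # per-subject OLS slopes double as the degenerate-path answer
    def _ols_slope(g: pd.DataFrame) -> tuple[float, float]:
        t = g["year"].to_numpy(dtype=float)
        y = g["cognition"].to_numpy(dtype=float)
        beta = np.polyfit(t, y, 1)
        resid = y - np.polyval(beta, t)
        return beta[0], float(resid @ resid)

    per_subject = {sid: _ols_slope(g) for sid, g in fit_obs.groupby("subject_id")}
    rss = sum(v[1] for v in per_subject.values())
    dof = len(fit_obs) - 2 * len(per_subject)
    if dof <= 0 or rss / dof < 1e-12:
        slopes = pd.Series({sid: v[0] for sid, v in per_subject.items()})
    else:
        # center time: slope estimates are invariant to the year origin and
        # the optimization is much better conditioned
        fit_obs = fit_obs.assign(year=fit_obs["year"] - fit_obs["year"].mean())
        exog = sm.add_constant(fit_obs[["year", "age", "sex", "education"]].astype(float))
        model = sm.MixedLM(
            fit_obs["cognition"].astype(float),
            exog,
            groups=fit_obs["subject_id"],
            exog_re=sm.add_constant(fit_obs[["year"]].astype(float)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(reml=True, method=["lbfgs", "powell"])
        if not np.isfinite(result.params).all():
            raise RuntimeError(f"mixed model failed to converge: {result.params}")
        fixed_slope = result.fe_params["year"]
        # conditional modes b_i = G Z_i' (Z_i G Z_i' + s2 I)^-1 r_i computed
        # directly: stays defined when the slope variance shrinks to zero
        G = np.asarray(result.cov_re)
        s2 = float(result.scale)
        fe = result.fe_params
        slopes = {}
        for sid, g in fit_obs.groupby("subject_id"):
            Z = np.column_stack([np.ones(len(g)), g["year"].to_numpy(dtype=float)])
            X = np.column_stack(
                [np.ones(len(g)), g[["year", "age", "sex", "education"]].to_numpy(dtype=float)]
            )
            r = g["cognition"].to_numpy(dtype=float) - X @ fe.to_numpy()
            V = Z @ G @ Z.T + s2 * np.eye(len(g))
            b = G @ Z.T @ np.linalg.solve(V, r)
            slopes[sid] = fixed_slope + b[1]
        slopes = pd.Series(slopes)
    all_subjects = pd.Index(observations["subject_id"].unique())
    return slopes.reindex(all_subjects).rename("decline_slope")


# ---------------------------------------------------------------------------
# trait association
# ---------------------------------------------------------------------------

def associate(
    predictor: pd.Series,
    trait: str,
    phen: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    extra_covariates: pd.DataFrame | None = None,
) -> AssociationResult:
    """OLS association of a predictor with a trait, covariate-adjusted.

    ``predictor`` is subject-aligned (typically a module meta-feature);
    ``extra_covariates`` supports the cell-type-adjusted variant by passing
    other module meta-features as additional columns.
    """
    name = predictor.name or "predictor"
    if name == trait or name in covariates:
        raise ValueError(f"predictor {name!r} overlaps the trait or covariates")
    data = phen.loc[:, [trait, *covariates]].copy()
    data[name] = predictor.reindex(phen.index)
    if extra_covariates is not None:
        for col in extra_covariates.columns:
            if col in data.columns:
                raise ValueError(f"extra covariate {col!r} duplicates an existing column")
            data[col] = extra_covariates[col].reindex(phen.index)
    data = data.dropna()
    n = len(data)
    n_params = data.shape[1]  # trait swapped for intercept
    if n < n_params + 2:
        raise ValueError(f"too few complete cases (n={n}) for {n_params - 1} regressors")
    exog = sm.add_constant(data.drop(columns=trait).astype(float))
    fit = sm.OLS(data[trait].astype(float), exog).fit()
    return AssociationResult(
        predictor=name,
        trait=trait,
        beta=float(fit.params[name]),
        se=float(fit.bse[name]),
        t=float(fit.tvalues[name]),
        p=float(fit.pvalues[name]),
        n=n,
        covariates=tuple(covariates),
    )


def association_grid(
    scores: pd.DataFrame,
    traits,
    phen: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    extra_covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tidy table of associate() over every module x trait pair."""
    rows = []
    for module_id in scores.columns:
        for trait in traits:
            res = associate(
                scores[module_id], trait, phen, covariates, extra_covariates
            )
            rows.append(res.as_dict())
    return pd.DataFrame(rows)


def adjust_multiplicity(p, method: str = "bh", alpha: float = 0.05):
    """Multiple-testing flags plus the operative threshold.

    Bonferroni rejects p < alpha/m and reports alpha/m. Benjamini-Hochberg
    runs the standard step-up and reports the largest rejected raw p as the
    data-dependent threshold (0 when nothing is rejected).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bonferroni":
        threshold = alpha / p.size
        reject = p < threshold
    elif method == "bh":
        reject = multipletests(p, alpha=alpha, method="fdr_bh")[0]
        threshold = float(p[reject].max()) if reject.any() else 0.0
    else:
        raise ValueError("method must be 'bonferroni' or 'bh'")
    return reject, float(threshold)


# ---------------------------------------------------------------------------
# mediated variance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediatedFraction:
    """Two labeled answers to "how much of the exposure effect is mediated".

    ``attenuation`` is 1 - beta_adjusted/beta_unadjusted (coefficient
    attenuation when the mediator enters the model). ``variance_ratio`` is
    1 - dR2_with/dR2_without, where dR2 is the exposure's incremental R^2 in
    models with and without the mediator. Both are NaN (``defined`` False)
    when the unadjusted exposure effect is indistinguishable from zero.
    """

    trait: str
    exposure: str
    mediator: str
    attenuation: float
    variance_ratio: float
    beta_unadjusted: float
    beta_adjusted: float
    defined: bool


def _r2(y: pd.Series, X: pd.DataFrame) -> float:
    return float(sm.OLS(y, sm.add_constant(X)).fit().rsquared)


def mediated_variance_fraction(
    trait: str,
    exposure: str,
    mediator: pd.Series,
    phen: pd.DataFrame,
    covariates=None,
) -> MediatedFraction:
    """Fraction of an exposure's trait effect accounted for by a mediator."""
    if covariates is None:
        covariates = tuple(c for c in DEFAULT_COVARIATES if c != exposure)
    med_name = mediator.name or "mediator"
    data = phen.loc[:, [trait, exposure, *covariates]].copy()
    data[med_name] = mediator.reindex(phen.index)
    data = data.dropna().astype(float)
    if abs(np.corrcoef(data[exposure], data[med_name])[0, 1]) > 0.999:
        raise ValueError("mediator is collinear with the exposure")
    y = data[trait]
    base = data[list(covariates)]
    with_exp = data[[exposure, *covariates]]
    with_med = data[[med_name, *covariates]]
    full = data[[exposure, med_name, *covariates]]

    fit_unadj = sm.OLS(y, sm.add_constant(with_exp)).fit()
    fit_adj = sm.OLS(y, sm.add_constant(full)).fit()
    b0, b1 = float(fit_unadj.params[exposure]), float(fit_adj.params[exposure])
    defined = abs(float(fit_unadj.tvalues[exposure])) >= 1.0
    dr2_without = _r2(y, with_exp) - _r2(y, base)
    dr2_with = _r2(y, full) - _r2(y, with_med)
    if defined and b0 != 0 and dr2_without > 0:
        attenuation = 1.0 - b1 / b0
        variance_ratio = 1.0 - dr2_with / dr2_without
    else:
        attenuation = variance_ratio = float("nan")
        defined = False
    return MediatedFraction(
        trait=trait,
        exposure=exposure,
        mediator=med_name,
        attenuation=attenuation,
        variance_ratio=variance_ratio,
        beta_unadjusted=b0,
        beta_adjusted=b1,
        defined=defined,
    )
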