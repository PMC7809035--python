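"""Attenuation-based mediation tests and ordering of variable triples.

The decision rule: if the coefficient of A on B is significant (p < alpha)
in a covariate-adjusted regression, but loses significance once a third
variable C enters the model, the A-B relationship is called *mediated*
through C. Running the rule over all orderings of a triple ranks which
sequence of events is most consistent with the cross-sectional data; the
output is deliberately labeled an ordering consistent with the data, not a
causal claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MediationResult",
    "OrderingResult",
    "verdict_rule",
    "mediation_test",
    "order_triple",
    "orderings_table",
]


def verdict_rule(p_direct: float, p_conditional: float, alpha: float = 0.05) -> str:
    """The two-threshold mediation verdict.

    ``no_association`` iff p_direct >= alpha; ``mediated`` iff p_direct <
    alpha and p_conditional >= alpha; ``not_mediated`` otherwise.
    """
    if p_direct >= alpha:
        return "no_association"
    if p_conditional >= alpha:
        return "mediated"
    return "not_mediated"


@dataclass(frozen=True)
class MediationResult:
    triple: tuple  # (A, B, C) = (exposure, outcome, candidate mediator)
    p_direct: float
    beta_direct: float
    p_conditional: float
    beta_conditional: float
    verdict: str  # mediated | not_mediated | no_association
    attenuation: float


@dataclass(frozen=True)
class OrderingResult:
    ordering: tuple  # (upstream, mediator, downstream)
    mediation: MediationResult
    upstream_mediator_p: float
    mediator_downstream_p: float
    supported: bool


def _aligned(columns: dict, covariates: pd.DataFrame | None) -> pd.DataFrame:
    data = pd.DataFrame(columns)
    if covariates is not None:
        for col in covariates.columns:
            data[col] = covariates[col]
    return data.dropna().astype(float)


def _ols_term(y: pd.Series, X: pd.DataFrame, term: str) -> tuple[float, float]:
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return float(fit.params[term]), float(fit.pvalues[term])


def mediation_test(
    a: pd.Series,
    b: pd.Series,
    c: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    names: tuple = ("A", "B", "C"),
) -> MediationResult:
    """Two-regression mediation verdict for exposure A, outcome B, mediator C.

    Fits B ~ A + covariates and B ~ A + C + covariates. Verdicts:
    ``no_association`` if A is not significant alone; ``mediated`` if A is
    significant alone but not with C in the model; ``not_mediated``
    otherwise. Attenuation = 1 - beta_conditional/beta_direct.
    """
    an, bn, cn = names
    data = _aligned({an: a, bn: b, cn: c}, covariates)
    if len(data) < (data.shape[1] + 2):
        raise ValueError("too few complete cases for the mediation models")
    if abs(np.corrcoef(data[an], data[cn])[0, 1]) > 0.999:
        raise ValueError(f"exposure {an!r} and mediator {cn!r} are collinear")
    cov_cols = [col for col in data.columns if col not in (an, bn, cn)]
    beta_d, p_d = _ols_term(data[bn], data[[an, *cov_cols]], an)
    beta_c, p_c = _ols_term(data[bn], data[[an, cn, *cov_cols]], an)
    verdict = verdict_rule(p_d, p_c, alpha)
    attenuation = 1.0 - beta_c / beta_d if beta_d != 0 else float("nan")
    return MediationResult(
        triple=(an, bn, cn),
        p_direct=p_d,
        beta_direct=beta_d,
        p_conditional=p_c,
        beta_conditional=beta_c,
        verdict=verdict,
        attenuation=attenuation,
    )


def order_triple(
    x: pd.Series,
    y: pd.Series,
    z: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    names: tuple = ("X", "Y", "Z"),
) -> list[OrderingResult]:
    """Evaluate all six orderings of a triple under the mediation rule.

    An ordering U -> M -> D is *supported* when the U-D relationship is
    mediated by M while U-M and M-D each stay significant given the third
    variable. All verdicts are returned; the supported set may be empty or
    contain several orderings (ties are reported, not resolved).
    """
    series = dict(zip(names, (x, y, z)))
    results = []
    import itertools

    for up, down in itertools.permutations(names, 2):
        mid = next(n for n in names if n not in (up, down))
        med = mediation_test(
            series[up],
            series[down],
            series[mid],
            covariates,
            alpha=alpha,
            names=(up, down, mid),
        )
        data = _aligned({n: series[n] for n in names}, covariates)
        cov_cols = [col for col in data.columns if col not in names]
        # U-M association given D; M-D association given U
        _, p_um = _ols_term(data[mid], data[[up, down, *cov_cols]], up)
        _, p_md = _ols_term(data[down], data[[mid, up, *cov_cols]], mid)
        supported = med.verdict == "mediated" and p_um < alpha and p_md < alpha
        results.append(
            OrderingResult(
                ordering=(up, mid, down),
                mediation=med,
                upstream_mediator_p=p_um,
                mediator_downstream_p=p_md,
                supported=supported,
            )
        )
    return results


def orderings_table(results: list[OrderingResult]) -> pd.DataFrame:
    """Tidy one-row-per-ordering summary of ``order_triple`` output."""
    rows = []
    for r in results:
        rows.append(
            {
                "upstream": r.ordering[0],
                "mediator": r.ordering[1],
                "downstream": r.ordering[2],
                "p_direct": r.mediation.p_direct,
                "beta_direct": r.mediation.beta_direct,
                "p_conditional": r.mediation.p_conditional,
                "beta_conditional": r.mediation.beta_conditional,
                "verdict": r.mediation.verdict,
                "attenuation": r.mediation.attenuation,
                "supported": r.supported,
            }
        )
    return pd.DataFrame(rows)
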