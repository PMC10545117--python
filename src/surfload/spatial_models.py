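"""Population-level regressions against expansion covariates.

Each population is one observation; metrics produced by the other stages
(Ho, betaST, Tajima's D, piN/piS, load counts, alpha/omega, tree root
distance) are regressed on expansion covariates such as the distance to the
southernmost site.  Under a serial-founder expansion these regressions carry
the signature of expansion load: diversity declines and deleterious burden
rises away from the source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


def assemble_metric_table(
    stage_outputs: dict[str, pd.Series | pd.DataFrame],
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Join per-population metric series (column name -> Series indexed by
    population) onto the covariate table; provenance records the producing
    stage for each column."""
    table = covariates.copy()
    provenance = {c: "popmap" for c in table.columns}
    for name, values in stage_outputs.items():
        if isinstance(values, pd.DataFrame):
            raise TypeError(f"stage output {name!r} must be a Series per population")
        missing = set(table.index) - set(values.index)
        if missing:
            import warnings

            warnings.warn(f"populations {sorted(missing)} missing from stage {name!r}")
        table[name] = values.reindex(table.index)
        provenance[name] = getattr(values, "name", None) or name
    return table, provenance


@dataclass
class RegressionResult:
    response: str
    predictor: str
    slope: float
    intercept: float
    r_squared: float       # plain R^2
    r_squared_adj: float
    p_value: float         # two-sided slope p
    n: int


def fit_linear(
    table: pd.DataFrame,
    response: str,
    predictor: str,
    exclude: list[str] | None = None,
) -> RegressionResult:
    """OLS of one metric on one covariate, optionally excluding populations
    (sensitivity analysis for outlier rivers)."""
    df = table[[response, predictor]].astype(float).dropna()
    if exclude:
        df = df.drop(index=[e for e in exclude if e in df.index])
    if len(df) < 3:
        raise ValueError(f"need >= 3 populations, have {len(df)}")
    x = df[predictor].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    y = df[response].to_numpy()
    if np.ptp(y) == 0:  # constant response: flat line, no explained variance
        return RegressionResult(response, predictor, 0.0, float(y[0]), 0.0, 0.0, 1.0, len(df))
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        response=response,
        predictor=predictor,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        r_squared_adj=float(max(fit.rsquared_adj, 0.0)),
        p_value=float(fit.pvalues[1]),
        n=len(df),
    )


def regression_table(
    table: pd.DataFrame,
    responses: list[str],
    predictor: str,
    exclude: list[str] | None = None,
) -> pd.DataFrame:
    rows = []
    for resp in responses:
        try:
            r = fit_linear(table, resp, predictor, exclude)
        except ValueError:
            continue
        rows.append(
            {
                "response": r.response,
                "predictor": r.predictor,
                "slope": r.slope,
                "intercept": r.intercept,
                "r2": r.r_squared,
                "r2_adj": r.r_squared_adj,
                "p": r.p_value,
                "n": r.n,
            }
        )
    return pd.DataFrame(rows)
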