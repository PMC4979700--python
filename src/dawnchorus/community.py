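"""Vocalization diversity indices and ACI–covariate association.

Diversity of a species (or pseudo-species) count table follows the standard
formulas: richness S, Shannon entropy H = -sum p_i ln p_i in nats, and
Gini–Simpson probability 1 - sum p_i^2.  The association between daily ACI
and a predictor (call counts, temperature, ...) is an ordinary least-squares
fit reporting slope, standard error and R^2 — the claim tested is the sign
and strength of the relationship, not any particular link function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass(frozen=True)
class DiversityResult:
    """Richness, Shannon (nats) and Gini–Simpson of one sample."""

    richness: int
    shannon: float
    simpson: float


@dataclass(frozen=True)
class AssociationResult:
    """OLS summary of ACI against a daily predictor."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    n: int
    grouping: str = "none"


def diversity(counts) -> DiversityResult:
    """Diversity indices from per-species vocalization counts.

    ``counts`` is a sequence/Series of non-negative counts (zero entries are
    ignored); total must be positive.
    """
    c = np.asarray(
        counts.values if isinstance(counts, pd.Series) else counts, dtype=float
    )
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise ValueError("counts must be non-negative and finite")
    c = c[c > 0]
    total = c.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    p = c / total
    return DiversityResult(
        richness=int(c.size),
        shannon=float(-np.sum(p * np.log(p))),
        simpson=float(1.0 - np.sum(p**2)),
    )


def diversity_by_sample(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample diversity from a long table (sample_id, species, count)."""
    rows = []
    for sample, grp in table.groupby("sample_id", sort=True):
        d = diversity(grp.groupby("species")["count"].sum())
        rows.append(
            {
                "sample_id": sample,
                "richness": d.richness,
                "shannon": d.shannon,
                "simpson": d.simpson,
            }
        )
    return pd.DataFrame(rows)


def associate(
    response, predictor, grouping: str = "none", groups=None
) -> AssociationResult:
    """OLS association of a daily response (ACI) with a predictor.

    ``grouping="within_date_centered"`` centres both variables within the
    groups given by ``groups`` (e.g. dates with multiple windows) before the
    fit, absorbing between-group level differences.  Pairs with missing
    values are dropped; at least 3 complete pairs are required and the
    predictor must vary.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.size != x.size:
        raise ValueError("response and predictor lengths differ")
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if y.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {y.size}")
    if grouping == "within_date_centered":
        if groups is None:
            raise ValueError("grouping requires groups")
        g = pd.Series(np.asarray(groups)[ok])
        y = y - pd.Series(y).groupby(g).transform("mean").to_numpy()
        x = x - pd.Series(x).groupby(g).transform("mean").to_numpy()
    elif grouping != "none":
        raise ValueError(f"unknown grouping {grouping!r}")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return AssociationResult(
        slope=float(model.params[1]),
        slope_se=float(model.bse[1]),
        intercept=float(model.params[0]),
        intercept_se=float(model.bse[0]),
        r_squared=float(model.rsquared),
        n=int(y.size),
        grouping=grouping,
    )
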