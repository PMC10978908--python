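"""Seasonal climate summaries, climate/elevation PCA, and cline regressions.

The input is a flat per-accession table whose monthly climate columns
follow the ``{var}_{01..12}`` convention of the WorldClim 2.1 monthly
variables (``temp``, ``prec``, ``srad``, ``vapr``, ``wind``), plus
``lat``, ``lon`` and ``elev``.  Raster extraction is out of scope; real
extracts drop straight in as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phenostats import PCAResult, pca, scale_uv

CLIMATE_VARS = ("temp", "prec", "srad", "vapr", "wind")
WINTER_MONTHS = (11, 12, 1, 2)
SUMMER_MONTHS = (3, 4, 5, 6)


def month_col(var: str, month: int) -> str:
    return f"{var}_{month:02d}"


def seasonal_means(
    table: pd.DataFrame, variables: tuple[str, ...] = CLIMATE_VARS
) -> pd.DataFrame:
    """Per-accession winter (Nov–Feb) and summer (Mar–Jun) means per variable.

    Output columns are suffixed ``_1`` (winter) and ``_2`` (summer);
    latitude/longitude/elevation columns are carried through when present.
    A missing month is an error naming the accession and month.
    """
    out = pd.DataFrame(index=table.index)
    for carry in ("accession", "lat", "lon", "elev"):
        if carry in table.columns:
            out[carry] = table[carry]
    for var in variables:
        for month in range(1, 13):
            col = month_col(var, month)
            if col not in table.columns:
                raise ValueError(f"missing month column {col!r}")
            bad = table[table[col].isna()]
            if len(bad):
                acc = (
                    bad["accession"].iloc[0]
                    if "accession" in bad.columns
                    else bad.index[0]
                )
                raise ValueError(
                    f"accession {acc!r}: missing value for month column {col!r}"
                )
        winter = table[[month_col(var, m) for m in WINTER_MONTHS]].mean(axis=1)
        summer = table[[month_col(var, m) for m in SUMMER_MONTHS]].mean(axis=1)
        out[f"{var}_1"] = winter
        out[f"{var}_2"] = summer
    return out


def climate_pca(
    seasonal: pd.DataFrame,
    variables: tuple[str, ...] = CLIMATE_VARS,
    include_elevation: bool = True,
) -> PCAResult:
    """Unit-variance normalization then PCA of seasonal climate (+ elevation)."""
    if len(seasonal) < 3:
        raise ValueError("need at least 3 accessions")
    cols = [f"{v}_{s}" for v in variables for s in (1, 2)]
    if include_elevation:
        if "elev" not in seasonal.columns:
            raise ValueError("elevation column 'elev' not found")
        cols.append("elev")
    data = seasonal[cols]
    try:
        scaled = scale_uv(data)
    except ValueError as exc:
        raise ValueError(f"climate variable failed scaling: {exc}") from exc
    return pca(scaled)


@dataclass(frozen=True)
class ClineFit:
    slope: float
    intercept: float
    r: float
    p: float
    n: int


def cline_test(x, y) -> ClineFit | None:
    """OLS regression of y on x with Pearson r and its two-sided p-value.

    Pairs with a missing member are excluded.  Returns ``None`` (absent)
    when x has zero variance; raises if fewer than 3 complete pairs remain.
    The p-value comes from the t distribution with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        return None
    res = stats.linregress(x, y)
    return ClineFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=len(x),
    )


def cline_table(
    data: pd.DataFrame, predictors: list[str], responses: list[str]
) -> pd.DataFrame:
    """Run :func:`cline_test` for every predictor/response pair."""
    rows = []
    for xcol in predictors:
        for ycol in responses:
            fit = cline_test(data[xcol], data[ycol])
            if fit is None:
                continue
            rows.append(
                {
                    "x": xcol,
                    "y": ycol,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r": fit.r,
                    "p": fit.p,
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)
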