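"""Small-area aggregation, deprivation linkage and the income gradient.

Proxies are pooled to MSOA level by concatenating the baskets of every
store in the MSOA (pooling counts, not averaging per-store probabilities,
which keeps the law-of-total-probability identity exact). Deprivation
features measured at LSOA level are carried up by unweighted means over
the member LSOAs. Area features are then related to the proxies by
Pearson correlation, and the headline income contrast is the relative
difference in mean P(P|M) between the top and bottom deciles of area
income.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._util import income_deciles
from .proxies import ProxyMeasures, compute_proxies, restrict_to_customers
from .synth import REGION_FEATURES

logger = logging.getLogger(__name__)

#: proxy / volume measures correlated against area features
MEASURES = ["total_transactions", "p_m", "p_p", "p_p_given_m"]


def lsoa_to_msoa(lsoa: pd.DataFrame) -> pd.DataFrame:
    """Average LSOA features up to their parent MSOAs (unweighted means)."""
    feature_cols = [c for c in lsoa.columns if c not in ("lsoa_id", "msoa_id")]
    if lsoa["msoa_id"].isna().any():
        raise ValueError("every LSOA must have an MSOA parent")
    return lsoa.groupby("msoa_id", sort=True)[feature_cols].mean().reset_index()


def _proxies_row(p: ProxyMeasures) -> dict:
    return {
        "total_transactions": p.n_baskets,
        "p_m": p.p_m,
        "p_p": p.p_p,
        "p_p_given_m": np.nan if p.p_p_given_m is None else p.p_p_given_m,
        "p_p_given_notm": np.nan if p.p_p_given_notm is None else p.p_p_given_notm,
        "mpr": np.nan if p.mpr is None else p.mpr,
    }


def msoa_proxies(baskets: pd.DataFrame, stores: pd.DataFrame) -> pd.DataFrame:
    """Pool baskets across each MSOA's stores and compute proxies per MSOA.

    Baskets at stores with no MSOA mapping are excluded with a logged
    count. Undefined conditionals (e.g. an MSOA with no menstrual baskets)
    appear as NaN — an explicit missing flag in the tabular output.
    """
    lookup = stores.set_index("store_id")["msoa_id"]
    msoa = baskets["store_id"].map(lookup)
    unmapped = int(msoa.isna().sum())
    if unmapped:
        logger.warning(
            "excluded %d basket(s) at stores with no MSOA mapping", unmapped
        )
    pooled = baskets.loc[msoa.notna()].copy()
    pooled["msoa_id"] = msoa[msoa.notna()].to_numpy()
    rows = {
        mid: _proxies_row(compute_proxies(group))
        for mid, group in pooled.groupby("msoa_id", sort=True)
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "msoa_id"
    return out.reset_index()


def region_table(msoa_features: pd.DataFrame, proxies: pd.DataFrame) -> pd.DataFrame:
    """Join MSOA deprivation features with MSOA proxy measures."""
    return msoa_features.merge(proxies, on="msoa_id", how="inner")


def study_region_table(
    baskets: pd.DataFrame,
    stores: pd.DataFrame,
    msoa_features: pd.DataFrame,
    menstrual_pain_customers,
) -> pd.DataFrame:
    """Region table with each measure computed on its own customer set.

    Transaction volume, P(M) and P(P) are basket frequencies over all
    customers' baskets pooled per MSOA, while the menstrual-pain
    conditionals P(P|M), P(P|¬M) and the MPR are computed within the
    menstrual-pain customer set — the set whose co-purchasing behaviour
    the menstrual-pain proxy describes. Restricting the conditional to
    that set also avoids diluting the area signal with the (binomially
    noisy) share of customers who never co-purchase.
    """
    all_prox = msoa_proxies(baskets, stores)
    mp_prox = msoa_proxies(
        restrict_to_customers(baskets, menstrual_pain_customers), stores
    )
    combined = all_prox[["msoa_id", "total_transactions", "p_m", "p_p"]].merge(
        mp_prox[["msoa_id", "p_p_given_m", "p_p_given_notm", "mpr"]],
        on="msoa_id",
        how="left",
    )
    return region_table(msoa_features, combined)


def correlation_table(
    region: pd.DataFrame,
    features: list[str] | None = None,
    measures: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson r and two-sided p-value for each feature × measure pair.

    MSOAs with an undefined value in either member of a pair are excluded
    pairwise. Cells with fewer than 3 complete pairs or zero variance are
    NaN (undefined, flagged).
    """
    features = features or [c for c in REGION_FEATURES if c in region.columns]
    measures = measures or [c for c in MEASURES if c in region.columns]
    r = pd.DataFrame(index=features, columns=measures, dtype=float)
    p = pd.DataFrame(index=features, columns=measures, dtype=float)
    for f in features:
        for m in measures:
            pair = region[[f, m]].dropna()
            x = pair[f].to_numpy(dtype=float)
            y = pair[m].to_numpy(dtype=float)
            if len(pair) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning("correlation %s vs %s undefined", f, m)
                continue
            res = stats.pearsonr(x, y)
            r.loc[f, m] = res.statistic
            p.loc[f, m] = res.pvalue
    out = pd.concat({"r": r, "p": p}, axis=1)
    out.index.name = "feature"
    return out


def income_gradient(
    region: pd.DataFrame,
    value_col: str = "p_p_given_m",
    income_col: str = "household_income",
    n_groups: int = 10,
) -> float:
    """Relative reduction (%) in mean ``value_col`` from top to bottom
    income decile.

    Areas are ranked by ``income_col`` and split into ``n_groups``
    quantile groups (deciles by default); the gradient is
    ``(top mean − bottom mean) / top mean × 100``. Requires at least
    ``n_groups`` areas with a defined value.
    """
    data = region[[income_col, value_col]].dropna()
    if len(data) < n_groups:
        raise ValueError(
            f"need >= {n_groups} areas with defined {value_col}, got {len(data)}"
        )
    groups = income_deciles(data[income_col], n_groups=n_groups)
    vals = data[value_col].to_numpy(dtype=float)
    bottom = vals[groups == 1]
    top = vals[groups == n_groups]
    if bottom.size == 0 or top.size == 0:
        raise ValueError("empty income decile")
    top_mean = top.mean()
    if top_mean == 0:
        raise ValueError("top-decile mean is zero; gradient undefined")
    return float((top_mean - bottom.mean()) / top_mean * 100.0)
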