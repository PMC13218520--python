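"""Probabilistic proxy measures and descriptive statistics.

All probabilities are basket-frequency estimates over the basket universe
supplied by the caller (typically all baskets of a chosen customer set,
store or area):

* ``P(M)`` — probability a basket contains a menstrual item (menstruation
  prevalence proxy);
* ``P(P)`` — probability a basket contains a pain item (pain proxy);
* ``P(P|M)``, ``P(P|¬M)`` — conditional pain frequencies within the
  menstrual / non-menstrual basket partitions;
* ``MPR = P(P|M) / P(P|¬M)`` — the Menstrual Pain Purchasing Ratio;
  values above 1 mean pain items are preferentially co-purchased with
  menstrual items.

Undefined quantities (no menstrual baskets, or a zero denominator) are
``None``, never sentinel numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProxyMeasures:
    """Proxy probabilities for one basket universe.

    The law of total probability holds exactly on the same universe:
    ``P_P == P_P_given_M * P_M + P_P_given_notM * (1 - P_M)``.
    """

    n_baskets: int
    p_m: float
    p_p: float
    p_p_given_m: float | None
    p_p_given_notm: float | None
    mpr: float | None

    @property
    def conditionals_defined(self) -> bool:
        return self.p_p_given_m is not None and self.p_p_given_notm is not None

    @property
    def mpr_defined(self) -> bool:
        return self.mpr is not None


@dataclass(frozen=True)
class CustomerSets:
    """Customers with at least one menstrual / pain / menstrual-pain basket.

    The menstrual-pain set (customers with >=1 basket carrying both flags)
    is a subset of both other sets.
    """

    menstrual: frozenset
    pain: frozenset
    menstrual_pain: frozenset


def compute_proxies(baskets: pd.DataFrame) -> ProxyMeasures:
    """Compute proxy measures over a table of flagged baskets."""
    n = len(baskets)
    if n == 0:
        raise ValueError("cannot compute proxies over zero baskets")
    m = baskets["has_menstrual"].to_numpy()
    p = baskets["has_pain"].to_numpy()
    n_m = int(m.sum())
    p_m = n_m / n
    p_p = int(p.sum()) / n

    p_p_given_m = float(p[m].sum() / n_m) if n_m > 0 else None
    n_notm = n - n_m
    p_p_given_notm = float(p[~m].sum() / n_notm) if n_notm > 0 else None
    if p_p_given_m is None:
        logger.warning("no menstrual baskets: conditional proxies undefined")
    mpr = None
    if p_p_given_m is not None and p_p_given_notm is not None and p_p_given_notm > 0:
        mpr = p_p_given_m / p_p_given_notm
    return ProxyMeasures(
        n_baskets=n,
        p_m=float(p_m),
        p_p=float(p_p),
        p_p_given_m=p_p_given_m,
        p_p_given_notm=p_p_given_notm,
        mpr=mpr,
    )


def customer_sets(baskets: pd.DataFrame) -> CustomerSets:
    """Build the menstrual, pain and menstrual-pain customer sets."""
    cust = baskets["customer_id"]
    m = baskets["has_menstrual"]
    p = baskets["has_pain"]
    return CustomerSets(
        menstrual=frozenset(cust[m]),
        pain=frozenset(cust[p]),
        menstrual_pain=frozenset(cust[m & p]),
    )


def restrict_to_customers(baskets: pd.DataFrame, customers) -> pd.DataFrame:
    """All baskets (of any content) belonging to the given customers."""
    mask = baskets["customer_id"].isin(list(customers))
    return baskets.loc[mask]


def customer_summary(baskets: pd.DataFrame, sets: CustomerSets) -> pd.DataFrame:
    """Per-customer means of basket counts, items and spend for each set.

    Returns one row per non-empty set (``menstrual``, ``pain``,
    ``menstrual_pain``) with columns ``n_customers, mean_transactions,
    mean_items, mean_spend``. Empty sets are omitted with a warning.
    """
    per_cust = baskets.groupby("customer_id").agg(
        transactions=("basket_id", "size"),
        items=("n_units", "sum"),
        spend=("spend", "sum"),
    )
    rows = {}
    for name, ids in (
        ("menstrual", sets.menstrual),
        ("pain", sets.pain),
        ("menstrual_pain", sets.menstrual_pain),
    ):
        if not ids:
            logger.warning("customer set %r is empty; summary omitted", name)
            continue
        sub = per_cust.loc[per_cust.index.isin(list(ids))]
        rows[name] = {
            "n_customers": len(sub),
            "mean_transactions": float(sub["transactions"].mean()),
            "mean_items": float(sub["items"].mean()),
            "mean_spend": float(sub["spend"].mean()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def cross_set_ratios(summary: pd.DataFrame) -> pd.DataFrame:
    """Ratios of menstrual-pain customer means to the other sets' means."""
    out = {}
    for other in ("pain", "menstrual"):
        if "menstrual_pain" in summary.index and other in summary.index:
            out[f"menstrual_pain_vs_{other}"] = (
                summary.loc["menstrual_pain", ["mean_transactions", "mean_items", "mean_spend"]]
                / summary.loc[other, ["mean_transactions", "mean_items", "mean_spend"]]
            )
    return pd.DataFrame(out).T


def _units_sold(
    transactions: pd.DataFrame, product_classes: pd.Series, product_class: str
) -> pd.Series:
    cls = transactions["product_id"].map(product_classes).fillna("other")
    sub = transactions.loc[np.asarray(cls == product_class)]
    return sub.groupby("product_id", observed=True)["quantity"].sum()


def top_products(
    transactions: pd.DataFrame,
    product_classes: pd.Series,
    catalogue: pd.DataFrame,
    product_class: str,
    k: int = 20,
) -> pd.DataFrame:
    """Top-k products of a class ranked by units sold.

    ``share_pct`` is the product's units as a percentage of all units sold
    in the class; the attribute ``coverage_pct`` on the returned frame is
    the sum of the top-k shares. If fewer than ``k`` products have sales,
    all are returned and ``truncated`` is set in the attrs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    units = _units_sold(transactions, product_classes, product_class)
    total = units.sum()
    ranked = units.sort_values(ascending=False)
    truncated = len(ranked) < k
    if truncated:
        logger.warning(
            "only %d %s products with sales (k=%d); returning all",
            len(ranked), product_class, k,
        )
    top = ranked.head(k)
    meta = catalogue.set_index("product_id")
    out = pd.DataFrame(
        {
            "product_id": top.index,
            "description": meta.loc[top.index, "description"].to_numpy(),
            "category": meta.loc[top.index, "category"].to_numpy(),
            "unit_price": meta.loc[top.index, "unit_price"].to_numpy(),
            "units_sold": top.to_numpy(),
            "share_pct": (top / total * 100.0).to_numpy(),
        }
    ).reset_index(drop=True)
    out.attrs["coverage_pct"] = float(out["share_pct"].sum())
    out.attrs["truncated"] = truncated
    out.attrs["category_counts"] = out["category"].value_counts().to_dict()
    return out


def coverage_from_shares(shares) -> float:
    """Coverage of a ranked product list: the sum of its percentage shares."""
    return float(np.asarray(shares, dtype=float).sum())


def price_frequency_correlation(
    transactions: pd.DataFrame,
    product_classes: pd.Series,
    catalogue: pd.DataFrame,
    product_class: str,
) -> float | None:
    """Pearson correlation of unit price vs units sold within a class.

    Computed over products of the class that recorded sales. Requires at
    least 3 such products; zero price variance yields ``None`` with a
    warning (undefined, flagged).
    """
    units = _units_sold(transactions, product_classes, product_class)
    if len(units) < 3:
        raise ValueError(
            f"need >=3 {product_class} products with sales, got {len(units)}"
        )
    prices = catalogue.set_index("product_id").loc[units.index, "unit_price"]
    if np.ptp(prices.to_numpy()) == 0 or np.ptp(units.to_numpy()) == 0:
        logger.warning("zero variance: price-frequency correlation undefined")
        return None
    r, _ = stats.pearsonr(prices.to_numpy(dtype=float), units.to_numpy(dtype=float))
    return float(r)
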