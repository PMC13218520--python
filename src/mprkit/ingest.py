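"""Reading, validation and basket construction for transaction logs.

A *basket* (one till receipt) is the unit over which all proxy
probabilities are defined. Product classification follows the retailer
category strings: "tampon" / "sanitary pad" → menstrual, "Pain Relief
Oral" / "Topical Pain Relief" → pain, everything else → other
(case-insensitive exact matching).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "customer_id",
    "date",
    "store_id",
    "product_id",
    "quantity",
    "unit_price",
]

MENSTRUAL_CATEGORIES = frozenset({"tampon", "sanitary pad"})
PAIN_CATEGORIES = frozenset({"pain relief oral", "topical pain relief"})
_KNOWN_CATEGORIES = MENSTRUAL_CATEGORIES | PAIN_CATEGORIES | {"other"}


class SchemaError(ValueError):
    """The input file does not match the documented schema."""


class CorruptLogError(ValueError):
    """The transaction log violates a structural invariant."""


def read_transactions(path: str | Path) -> pd.DataFrame:
    """Read and validate a transaction-log CSV.

    Rows with malformed dates, non-positive quantities, negative prices or
    empty identifiers are dropped; the rejection count is logged and
    stored in ``df.attrs["n_rejected"]``. A missing required column or an
    empty file raises :class:`SchemaError`.
    """
    try:
        df = pd.read_csv(path, dtype={"customer_id": str, "store_id": str,
                                      "product_id": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if "basket_id" in df.columns:
        df["basket_id"] = df["basket_id"].astype(str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no transaction rows")

    date = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    quantity = pd.to_numeric(df["quantity"], errors="coerce")
    price = pd.to_numeric(df["unit_price"], errors="coerce")
    id_cols = ["customer_id", "store_id", "product_id"]
    ids_ok = np.ones(len(df), dtype=bool)
    for col in id_cols:
        ids_ok &= df[col].notna().to_numpy() & (df[col].astype(str).str.len() > 0)

    valid = (
        date.notna().to_numpy()
        & quantity.notna().to_numpy()
        & (quantity >= 1).to_numpy()
        & price.notna().to_numpy()
        & (price >= 0).to_numpy()
        & ids_ok
    )
    n_rejected = int((~valid).sum())
    if n_rejected:
        logger.warning("rejected %d malformed transaction row(s)", n_rejected)
    out = df.loc[valid].copy()
    out["date"] = date[valid]
    out["quantity"] = quantity[valid].astype(np.int64)
    out["unit_price"] = price[valid].astype(float)
    out = out.reset_index(drop=True)
    out.attrs["n_rejected"] = n_rejected
    return out


def classify_products(catalogue: pd.DataFrame) -> pd.Series:
    """Map each product to a class in {'menstrual', 'pain', 'other'}.

    Matching is exact on the category string, case-insensitively. Category
    strings outside the known retailer vocabulary are classified 'other'
    with a logged warning.
    """
    if "category" not in catalogue.columns:
        raise SchemaError("catalogue lacks a 'category' column")
    cat = catalogue["category"].astype(str).str.strip().str.lower()
    unknown = sorted(set(cat) - _KNOWN_CATEGORIES)
    if unknown:
        logger.warning(
            "unknown product categories classified as 'other': %s", unknown
        )
    cls = np.where(
        cat.isin(MENSTRUAL_CATEGORIES),
        "menstrual",
        np.where(cat.isin(PAIN_CATEGORIES), "pain", "other"),
    )
    return pd.Series(cls, index=catalogue["product_id"].to_numpy(), name="product_class")


def build_baskets(
    transactions: pd.DataFrame, product_classes: pd.Series
) -> pd.DataFrame:
    """Group item lines into baskets with menstrual/pain content flags.

    If the input lacks a ``basket_id`` column, one is synthesised from
    (customer_id, store_id, date) — one basket per shopping trip. A
    basket spanning two customers raises :class:`CorruptLogError`.

    Returns one row per basket: ``basket_id, customer_id, store_id, date,
    n_lines, n_units, spend, has_menstrual, has_pain``.
    """
    t = transactions
    if "basket_id" not in t.columns:
        basket_key = (
            t["customer_id"].astype(str)
            + "|"
            + t["store_id"].astype(str)
            + "|"
            + t["date"].astype(str)
        )
    else:
        basket_key = t["basket_id"]

    cls = t["product_id"].map(product_classes)
    if cls.isna().any():
        cls = cls.fillna("other")
    work = pd.DataFrame(
        {
            "basket_id": np.asarray(basket_key),
            "customer_id": t["customer_id"].to_numpy(),
            "store_id": t["store_id"].to_numpy(),
            "date": t["date"].to_numpy(),
            "quantity": t["quantity"].to_numpy(),
            "value": (t["quantity"] * t["unit_price"]).to_numpy(),
            "is_menstrual": (cls == "menstrual").to_numpy(),
            "is_pain": (cls == "pain").to_numpy(),
        }
    )
    g = work.groupby("basket_id", sort=False)
    baskets = g.agg(
        customer_id=("customer_id", "first"),
        _customer_last=("customer_id", "last"),
        store_id=("store_id", "first"),
        date=("date", "first"),
        n_lines=("quantity", "size"),
        n_units=("quantity", "sum"),
        spend=("value", "sum"),
        has_menstrual=("is_menstrual", "any"),
        has_pain=("is_pain", "any"),
    ).reset_index()
    # lines are contiguous per basket only in sorted logs, so check both ends
    mismatch = baskets["customer_id"] != baskets["_customer_last"]
    if mismatch.any():
        bad = baskets.loc[mismatch, "basket_id"].iloc[0]
        raise CorruptLogError(
            f"basket {bad!r} spans multiple customers; log is corrupt"
        )
    # 'first'/'last' agreeing does not rule out A,B,A orderings; verify fully
    nun = g["customer_id"].nunique()
    if (nun > 1).any():
        bad = nun[nun > 1].index[0]
        raise CorruptLogError(
            f"basket {bad!r} spans multiple customers; log is corrupt"
        )
    return baskets.drop(columns=["_customer_last"])
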