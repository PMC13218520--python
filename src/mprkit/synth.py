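"""Synthetic loyalty-card data generator.

Produces itemised transaction logs, a product catalogue, an LSOA-level
deprivation table with a store lookup, and a ground-truth record, with the
statistical structure the downstream analysis assumes:

* per-customer menstrual cycles: inter-onset gaps drawn from a normal
  distribution (mean 28 d, sd 3.8 d) truncated to the physiological
  21-35 day window, with missed purchases and stock-up noise;
* conditional pain co-purchase: menstrual baskets of pain-prone customers
  include a pain item with probability ``p_pain_given_menstrual`` scaled
  by the customer's area income decile; all other baskets carry the
  background rate ``p_pain_given_nonmenstrual``;
* an area income gradient: decile scales are linear in decile rank and
  mean-centred, so the top-vs-bottom relative contrast equals
  ``income_gradient`` while the population mean stays at the configured
  conditional probability;
* a product catalogue whose price-popularity correlation is stronger
  (more negative) for pain items than for menstrual items.

All randomness derives from ``SimulationConfig.seed`` through fixed named
streams, so outputs are bit-identical across runs with the same config.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._util import income_deciles, weighted_choice
from .config import ConfigError, SimulationConfig

logger = logging.getLogger(__name__)

_STREAM_CATALOGUE = 1
_STREAM_REGIONS = 2
_STREAM_TRANSACTIONS = 3

#: catalogue category labels used by the retailer-style classification
CATEGORY_TAMPON = "tampon"
CATEGORY_PAD = "sanitary pad"
CATEGORY_ORAL_PAIN = "Pain Relief Oral"
CATEGORY_TOPICAL_PAIN = "Topical Pain Relief"
CATEGORY_OTHER = "other"


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def decile_scales(income_gradient: float, n_groups: int = 10) -> np.ndarray:
    """Multiplicative pain-propensity scale per income decile (1 = poorest).

    Linear in decile rank and normalised to mean 1, so that
    ``(scale[-1] - scale[0]) / scale[-1] == income_gradient`` while the
    population-average conditional probability is left unchanged.
    """
    d = np.arange(n_groups, dtype=float)
    raw = (1.0 - income_gradient) + income_gradient * d / (n_groups - 1)
    return raw / raw.mean()


@dataclass(frozen=True)
class GroundTruth:
    """Parameters the analysis should recover, derived from config alone."""

    mpr: float
    p_pain_given_menstrual: float
    p_pain_given_nonmenstrual: float
    cycle_mean_days: float
    cycle_sd_days: float
    cycle_mode_days: int
    menstrual_pain_customer_fraction: float
    income_gradient_pct: float
    decile_scales: tuple

    def to_dict(self) -> dict:
        d = asdict(self)
        d["decile_scales"] = [float(x) for x in self.decile_scales]
        return d


def true_parameters(config: SimulationConfig) -> GroundTruth:
    """Deterministic ground truth for recovery tests; involves no sampling.

    The true MPR is defined within the menstrual-pain customer set (the
    pain-prone subpopulation), where the basket-level conditional pain
    probability averages exactly ``p_pain_given_menstrual`` because the
    decile scales are mean-centred.
    """
    if config.cycle_sd_days == 0:
        trunc_sd = 0.0
    else:
        a = (config.cycle_lower_days - config.cycle_mean_days) / config.cycle_sd_days
        b = (config.cycle_upper_days - config.cycle_mean_days) / config.cycle_sd_days
        trunc_sd = float(
            stats.truncnorm.std(a, b, loc=config.cycle_mean_days, scale=config.cycle_sd_days)
        )
    return GroundTruth(
        mpr=config.p_pain_given_menstrual / config.p_pain_given_nonmenstrual,
        p_pain_given_menstrual=config.p_pain_given_menstrual,
        p_pain_given_nonmenstrual=config.p_pain_given_nonmenstrual,
        cycle_mean_days=config.cycle_mean_days,
        cycle_sd_days=trunc_sd,
        cycle_mode_days=int(round(config.cycle_mean_days)),
        menstrual_pain_customer_fraction=config.pain_prone_fraction,
        income_gradient_pct=100.0 * config.income_gradient,
        decile_scales=tuple(float(x) for x in decile_scales(config.income_gradient)),
    )


# ---------------------------------------------------------------------------
# catalogue


def _catalogue_group(
    rng: np.random.Generator,
    n: int,
    rho: float,
    price_mu: float,
    price_sigma: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (unit_price, popularity) with Gaussian-copula correlation rho."""
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
    price = np.round(np.exp(price_mu + price_sigma * z1), 2)
    price = np.maximum(price, 0.05)
    popularity = np.exp(0.7 * z2)
    return price, popularity


def generate_catalogue(config: SimulationConfig) -> pd.DataFrame:
    """Generate the product catalogue.

    Returns a frame with columns ``product_id, description, category,
    unit_price, pack_size, popularity``. Popularity weights drive product
    choice within a class during transaction generation, so the realised
    price-frequency correlation follows the planted copula correlation:
    stronger (more negative) for pain items than for menstrual items.
    """
    rng = _rng(config, _STREAM_CATALOGUE)
    groups = [
        # (n, category, rho, log-price mean, log-price sd)
        (config.n_tampon_products, CATEGORY_TAMPON, config.price_frequency_corr_menstrual, np.log(2.0), 0.45),
        (config.n_pad_products, CATEGORY_PAD, config.price_frequency_corr_menstrual, np.log(1.5), 0.45),
        (config.n_oral_pain_products, CATEGORY_ORAL_PAIN, config.price_frequency_corr_pain, np.log(1.4), 0.7),
        (config.n_topical_pain_products, CATEGORY_TOPICAL_PAIN, config.price_frequency_corr_pain, np.log(3.0), 0.5),
        (config.n_other_products, CATEGORY_OTHER, -0.2, np.log(3.0), 0.8),
    ]
    frames = []
    offset = 0
    for n, category, rho, mu, sigma in groups:
        price, popularity = _catalogue_group(rng, n, rho, mu, sigma)
        pack = rng.choice([10, 12, 14, 16, 20, 24, 32], size=n)
        frames.append(
            pd.DataFrame(
                {
                    "product_id": [f"P{offset + i:04d}" for i in range(n)],
                    "description": [f"{category} item {i + 1}" for i in range(n)],
                    "category": category,
                    "unit_price": price,
                    "pack_size": pack,
                    "popularity": popularity,
                }
            )
        )
        offset += n
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# regions

#: deprivation / demographic feature columns carried at LSOA (and MSOA) level
REGION_FEATURES = [
    "imd_score",
    "household_income",
    "electricity_spend",
    "jobseekers_claimants",
    "room_occupancy",
    "population_all",
    "population_children",
    "population_working",
    "population_older",
]


def generate_regions(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the LSOA deprivation table and the store→MSOA lookup.

    LSOAs nest in MSOAs (4-5 per MSOA by default). Weekly household income
    varies across MSOAs so deciles are well defined; LSOA incomes are a
    mean-preserving spread of their MSOA's latent income, so the MSOA mean
    recovered by averaging LSOAs equals the latent value used to plant the
    income effect. Deprivation features co-vary with income with realistic
    signs (IMD and jobseeker claims fall with income, electricity spend
    rises) plus independent noise.
    """
    if config.n_msoas < 10 and config.income_gradient > 0:
        warnings.warn(
            "fewer than 10 MSOAs with a non-zero income gradient: income "
            "deciles are degenerate",
            stacklevel=2,
        )
    rng = _rng(config, _STREAM_REGIONS)
    m = config.n_msoas
    msoa_ids = np.array([f"M{i:05d}" for i in range(m)])
    latent_income = rng.normal(550.0, 110.0, m).clip(250.0, None)

    n_lsoas = rng.integers(config.lsoas_per_msoa_min, config.lsoas_per_msoa_max + 1, m)
    msoa_idx = np.repeat(np.arange(m), n_lsoas)
    k = msoa_idx.size

    # mean-preserving spread of income within each MSOA
    eps = rng.normal(0.0, 0.03, k) * latent_income[msoa_idx]
    eps -= pd.Series(eps).groupby(msoa_idx).transform("mean").to_numpy()
    lsoa_income = latent_income[msoa_idx] + eps

    zi = (lsoa_income - 550.0) / 110.0
    imd = np.clip(22.0 - 8.0 * zi + rng.normal(0.0, 4.0, k), 1.0, 75.0)
    electricity = np.clip(1200.0 + 250.0 * zi + rng.normal(0.0, 120.0, k), 300.0, None)
    jobseekers = np.clip(0.030 - 0.012 * zi + rng.normal(0.0, 0.006, k), 0.001, 0.15)
    occupancy = np.clip(2.4 - 0.15 * zi + rng.normal(0.0, 0.20, k), 1.2, 4.0)
    pop_all = rng.integers(1200, 2200, k).astype(float)
    share_children = np.clip(rng.normal(0.19, 0.03, k), 0.05, 0.35)
    share_older = np.clip(rng.normal(0.19, 0.04, k), 0.05, 0.40)
    share_working = np.clip(1.0 - share_children - share_older, 0.3, None)

    lsoa = pd.DataFrame(
        {
            "lsoa_id": [f"L{i:05d}" for i in range(k)],
            "msoa_id": msoa_ids[msoa_idx],
            "imd_score": np.round(imd, 2),
            "household_income": np.round(lsoa_income, 2),
            "electricity_spend": np.round(electricity, 2),
            "jobseekers_claimants": np.round(jobseekers, 4),
            "room_occupancy": np.round(occupancy, 3),
            "population_all": pop_all,
            "population_children": np.round(pop_all * share_children),
            "population_working": np.round(pop_all * share_working),
            "population_older": np.round(pop_all * share_older),
        }
    )

    n_stores = m * config.stores_per_msoa
    stores = pd.DataFrame(
        {
            "store_id": [f"S{i:04d}" for i in range(n_stores)],
            "msoa_id": np.repeat(msoa_ids, config.stores_per_msoa),
        }
    )
    return lsoa, stores


# ---------------------------------------------------------------------------
# transactions


def draw_cycle_gaps(
    config: SimulationConfig, rng: np.random.Generator, size: int | tuple
) -> np.ndarray:
    """Draw integer inter-onset gaps from the truncated cycle distribution.

    Continuous draws from a normal truncated to
    ``[cycle_lower_days, cycle_upper_days]`` are rounded to whole days, so
    every gap lies inside the physiological window by construction. A zero
    standard deviation degenerates to the rounded mean.
    """
    if config.cycle_sd_days == 0:
        return np.full(size, int(round(config.cycle_mean_days)), dtype=np.int64)
    a = (config.cycle_lower_days - config.cycle_mean_days) / config.cycle_sd_days
    b = (config.cycle_upper_days - config.cycle_mean_days) / config.cycle_sd_days
    draws = stats.truncnorm.rvs(
        a, b, loc=config.cycle_mean_days, scale=config.cycle_sd_days,
        size=size, random_state=rng,
    )
    return np.rint(draws).astype(np.int64)


def generate_transactions(
    config: SimulationConfig,
    catalogue: pd.DataFrame,
    regions_lsoa: pd.DataFrame,
    stores: pd.DataFrame,
) -> pd.DataFrame:
    """Generate the itemised transaction log.

    Customers are assigned uniformly to MSOAs and shop at one home store.
    Shopping trips arrive at ``trip_rate_per_week``; menstruating
    customers additionally generate cycle-onset menstrual purchases (each
    onset recorded with probability ``1 - purchase_miss_prob``) and
    stock-up menstrual purchases at a fraction ``stockup_prob`` of
    ordinary trips. One basket per (customer, date); same-day events
    merge. Output is sorted by customer then date.

    Returns a line-level frame: ``customer_id, basket_id, date, store_id,
    product_id, quantity, unit_price``.
    """
    rng = _rng(config, _STREAM_TRANSACTIONS)
    span = config.span_days
    n = config.n_customers
    m = config.n_msoas

    msoa_income = (
        regions_lsoa.groupby("msoa_id", sort=True)["household_income"].mean()
    )
    msoa_ids = msoa_income.index.to_numpy()
    deciles = income_deciles(msoa_income.to_numpy())  # 1..10 per MSOA
    scales = decile_scales(config.income_gradient)[deciles - 1]

    stores_by_msoa = stores.groupby("msoa_id")["store_id"].apply(list)
    msoas_with_store = [i for i, mid in enumerate(msoa_ids) if mid in stores_by_msoa.index]
    if not msoas_with_store:
        raise ConfigError("no MSOA hosts a store; customers cannot shop")

    # customer attributes
    cust_msoa = rng.choice(np.array(msoas_with_store), size=n)
    cust_store = np.array(
        [
            stores_by_msoa[msoa_ids[i]][rng.integers(len(stores_by_msoa[msoa_ids[i]]))]
            for i in cust_msoa
        ]
    )
    menstruating = rng.random(n) < config.menstruating_fraction
    prone = menstruating & (rng.random(n) < config.pain_prone_fraction)
    cust_scale = scales[cust_msoa]

    # ordinary shopping trips
    n_trips = rng.poisson(config.trip_rate_per_week * span / 7.0, n)
    trip_cust = np.repeat(np.arange(n), n_trips)
    trip_day = rng.integers(0, span, n_trips.sum())

    # cycle onsets for menstruating customers, plus per-cycle stock-ups
    # (one extra menstrual purchase at a uniformly chosen non-onset day
    # of the cycle, with probability stockup_prob per cycle)
    mens_idx = np.flatnonzero(menstruating)
    onset_cust = np.empty(0, dtype=np.int64)
    onset_day = np.empty(0, dtype=np.int64)
    stock_cust = np.empty(0, dtype=np.int64)
    stock_day = np.empty(0, dtype=np.int64)
    if mens_idx.size:
        max_cycles = int(span // config.cycle_lower_days) + 2
        gaps = draw_cycle_gaps(config, rng, (mens_idx.size, max_cycles))
        # first onset uniform within the first cycle, then cumulative gaps
        first = (rng.random(mens_idx.size) * gaps[:, 0]).astype(np.int64)
        onsets = first[:, None] + np.concatenate(
            [np.zeros((mens_idx.size, 1), dtype=np.int64), np.cumsum(gaps[:, 1:], axis=1)],
            axis=1,
        )
        in_span = onsets < span
        keep = in_span & (rng.random(onsets.shape) >= config.purchase_miss_prob)
        rows, cols = np.nonzero(keep)
        onset_cust = mens_idx[rows]
        onset_day = onsets[rows, cols]

        stock = in_span & (rng.random(onsets.shape) < config.stockup_prob)
        s_rows, s_cols = np.nonzero(stock)
        s_gap = gaps[s_rows, s_cols]
        offset = 1 + (rng.random(s_rows.size) * (s_gap - 1)).astype(np.int64)
        s_day = onsets[s_rows, s_cols] + offset
        ok = s_day < span
        stock_cust = mens_idx[s_rows[ok]]
        stock_day = s_day[ok]

    # one basket per (customer, day); same-day events merge
    events = pd.DataFrame(
        {
            "customer": np.concatenate([trip_cust, onset_cust, stock_cust]),
            "day": np.concatenate([trip_day, onset_day, stock_day]),
            "menstrual": np.concatenate(
                [
                    np.zeros(trip_cust.size, dtype=bool),
                    np.ones(onset_cust.size + stock_cust.size, dtype=bool),
                ]
            ),
        }
    )
    baskets = (
        events.groupby(["customer", "day"], sort=False)["menstrual"]
        .any()
        .reset_index()
    )
    b_cust = baskets["customer"].to_numpy()
    b_day = baskets["day"].to_numpy()
    b_menstrual = baskets["menstrual"].to_numpy()

    # pain inclusion: prone customers' menstrual baskets carry the scaled
    # conditional probability; non-prone menstrual baskets never include
    # pain; everything else carries the background rate
    p_pain = np.where(
        b_menstrual,
        np.where(
            prone[b_cust],
            config.p_pain_given_menstrual * cust_scale[b_cust],
            0.0,
        ),
        config.p_pain_given_nonmenstrual,
    )
    b_pain = rng.random(b_cust.size) < p_pain

    # item lines: every basket gets one everyday item, plus class items
    cat = catalogue
    cls_other = cat.index[cat["category"] == CATEGORY_OTHER].to_numpy()
    cls_mens = cat.index[cat["category"].isin([CATEGORY_TAMPON, CATEGORY_PAD])].to_numpy()
    cls_pain = cat.index[
        cat["category"].isin([CATEGORY_ORAL_PAIN, CATEGORY_TOPICAL_PAIN])
    ].to_numpy()
    pop = cat["popularity"].to_numpy()

    def _lines(basket_rows: np.ndarray, class_rows: np.ndarray, qty: np.ndarray):
        prods = class_rows[weighted_choice(rng, pop[class_rows], basket_rows.size)]
        return basket_rows, prods, qty

    nb = b_cust.size
    all_rows = np.arange(nb)
    parts = [
        _lines(all_rows, cls_other, 1 + (rng.random(nb) < 0.3).astype(np.int64)),
        _lines(np.flatnonzero(b_menstrual), cls_mens, np.ones(int(b_menstrual.sum()), dtype=np.int64)),
        _lines(np.flatnonzero(b_pain), cls_pain, np.ones(int(b_pain.sum()), dtype=np.int64)),
    ]
    line_basket = np.concatenate([p[0] for p in parts])
    line_prod = np.concatenate([p[1] for p in parts])
    line_qty = np.concatenate([p[2] for p in parts])

    prod_ids = cat["product_id"].to_numpy()
    prod_price = cat["unit_price"].to_numpy()
    store_codes, store_labels = pd.factorize(cust_store)

    out = pd.DataFrame(
        {
            "customer_id": b_cust[line_basket],
            # day < 10**4 always (span <= ~7300), so this key is unique
            "basket_id": b_cust[line_basket] * 10_000 + b_day[line_basket],
            "date": pd.Timestamp(config.period_start)
            + pd.to_timedelta(b_day[line_basket], unit="D"),
            "store_id": pd.Categorical.from_codes(
                store_codes[b_cust[line_basket]], categories=store_labels
            ),
            "product_id": pd.Categorical.from_codes(line_prod, categories=prod_ids),
            "quantity": line_qty,
            "unit_price": prod_price[line_prod],
        }
    )
    out = out.sort_values(["customer_id", "date", "basket_id"], kind="stable")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# dataset writer


def write_dataset(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate the full synthetic dataset and write it as CSV/JSON files.

    Writes ``catalogue.csv``, ``regions_lsoa.csv``, ``stores.csv``,
    ``transactions.csv`` and ``ground_truth.json`` into ``out_dir`` and
    returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalogue = generate_catalogue(config)
    regions, stores = generate_regions(config)
    transactions = generate_transactions(config, catalogue, regions, stores)
    paths = {
        "catalogue": out / "catalogue.csv",
        "regions_lsoa": out / "regions_lsoa.csv",
        "stores": out / "stores.csv",
        "transactions": out / "transactions.csv",
        "ground_truth": out / "ground_truth.json",
    }
    catalogue.to_csv(paths["catalogue"], index=False)
    regions.to_csv(paths["regions_lsoa"], index=False)
    stores.to_csv(paths["stores"], index=False)
    transactions.to_csv(paths["transactions"], index=False, date_format="%Y-%m-%d")
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {"config": config.to_dict(), "truth": true_parameters(config).to_dict()},
            fh,
            indent=2,
        )
    logger.info(
        "wrote synthetic dataset to %s (%d transaction lines)", out, len(transactions)
    )
    return paths
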