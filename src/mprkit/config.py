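"""Configuration objects shared across the simulation and analysis stages.

Defaults encode the study conditions the pipeline is calibrated to: a
28-day menstrual cycle (sd 3.8 days) bounded by the conventional 21-35 day
physiological window, a 50% pain co-purchase propensity within menstrual
baskets against a 12.82% background pain rate (ratio 3.9), a 26.7%
pain-prone fraction of menstruating customers, and a 32% top-to-bottom
income-decile contrast in menstrual-pain purchasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date
from typing import Any


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic loyalty-card panel.

    The generator emulates a two-year itemised transaction log for a panel
    of customers spread over small areas (MSOAs, each containing a few LSOA
    neighbourhoods), with per-customer menstrual cycles driving menstrual
    product purchases and a planted area-income gradient in menstrual-pain
    co-purchasing.

    Notes
    -----
    ``pain_prone_fraction`` controls customer heterogeneity: only this
    fraction of menstruating customers ever co-purchase pain relief in a
    menstrual basket (at ``p_pain_given_menstrual``, scaled by their area's
    income decile). The remainder manage pain outside menstrual baskets, so
    their menstrual baskets never contain a pain item while their other
    baskets carry the background rate. This is what makes the
    menstrual-pain customer set a strict, calibrated subset of menstrual
    customers rather than (asymptotically) all of them.
    """

    n_customers: int = 5000
    n_msoas: int = 60
    lsoas_per_msoa_min: int = 4
    lsoas_per_msoa_max: int = 5
    stores_per_msoa: int = 1
    period_start: date = date(2013, 1, 1)
    period_end: date = date(2014, 12, 31)
    menstruating_fraction: float = 0.5
    cycle_mean_days: float = 28.0
    cycle_sd_days: float = 3.8
    cycle_lower_days: int = 21
    cycle_upper_days: int = 35
    purchase_miss_prob: float = 0.3
    stockup_prob: float = 0.05
    trip_rate_per_week: float = 1.0
    p_pain_given_menstrual: float = 0.50
    p_pain_given_nonmenstrual: float = 0.1282
    pain_prone_fraction: float = 0.267
    income_gradient: float = 0.32
    n_tampon_products: int = 15
    n_pad_products: int = 15
    n_oral_pain_products: int = 25
    n_topical_pain_products: int = 10
    n_other_products: int = 150
    price_frequency_corr_pain: float = -0.80
    price_frequency_corr_menstrual: float = -0.50
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "menstruating_fraction": self.menstruating_fraction,
            "purchase_miss_prob": self.purchase_miss_prob,
            "stockup_prob": self.stockup_prob,
            "p_pain_given_menstrual": self.p_pain_given_menstrual,
            "p_pain_given_nonmenstrual": self.p_pain_given_nonmenstrual,
            "pain_prone_fraction": self.pain_prone_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        if self.p_pain_given_nonmenstrual <= 0:
            raise ConfigError("p_pain_given_nonmenstrual must be > 0")
        if not 21 <= self.cycle_mean_days <= 35:
            raise ConfigError(
                f"cycle_mean_days must lie in [21, 35], got {self.cycle_mean_days}"
            )
        if self.cycle_sd_days < 0:
            raise ConfigError("cycle_sd_days must be non-negative")
        if not 0 < self.cycle_lower_days <= self.cycle_upper_days:
            raise ConfigError("cycle bounds must satisfy 0 < lower <= upper")
        if self.income_gradient < 0:
            raise ConfigError("income_gradient must be non-negative")
        if self.income_gradient >= 2:
            raise ConfigError("income_gradient >= 2 makes decile scales negative")
        if self.n_customers < 1:
            raise ConfigError("n_customers must be >= 1")
        if self.n_msoas < 2:
            raise ConfigError("n_msoas must be >= 2")
        if not 1 <= self.lsoas_per_msoa_min <= self.lsoas_per_msoa_max:
            raise ConfigError("lsoas_per_msoa bounds invalid")
        if self.stores_per_msoa < 0:
            raise ConfigError("stores_per_msoa must be >= 0")
        if self.trip_rate_per_week <= 0:
            raise ConfigError("trip_rate_per_week must be positive")
        for name in (
            "n_tampon_products",
            "n_pad_products",
            "n_oral_pain_products",
            "n_topical_pain_products",
            "n_other_products",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1 (empty category)")
        if self.span_days < self.cycle_mean_days:
            raise ConfigError(
                "simulation period is shorter than one menstrual cycle; "
                "no purchase intervals are derivable"
            )
        # the top income decile must not push pain probability past 1
        top_scale = (1.0 + self.income_gradient / 2.0) / max(
            1.0 - self.income_gradient / 2.0, 1e-12
        )
        if self.p_pain_given_menstrual * top_scale > 1.0 + 1e-12:
            raise ConfigError(
                "p_pain_given_menstrual exceeds 1 in the top income decile "
                "under the configured income_gradient"
            )

    @property
    def span_days(self) -> int:
        """Number of days in the simulated period (inclusive of both ends)."""
        return (self.period_end - self.period_start).days + 1

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["period_start"] = self.period_start.isoformat()
        d["period_end"] = self.period_end.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        for key in ("period_start", "period_end"):
            if key in d and isinstance(d[key], str):
                d[key] = date.fromisoformat(d[key])
        return cls(**d)


@dataclass(frozen=True)
class PeriodicityConfig:
    """Physiological filter bounds for inter-purchase intervals (inclusive).

    The 21-35 day window is the conventionally reported range of a normal
    menstrual cycle; intervals outside it are attributed to missed trips,
    stock-ups or shopping elsewhere rather than to cycle length.
    """

    lower_bound_days: int = 21
    upper_bound_days: int = 35

    def __post_init__(self) -> None:
        if not 0 < self.lower_bound_days <= self.upper_bound_days:
            raise ConfigError("bounds must satisfy 0 < lower <= upper")
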