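"""MSOA aggregation, deprivation linkage and the income gradient."""

import numpy as np
import pandas as pd
import pytest

import mprkit as mk
from conftest import make_baskets


class TestLsoaToMsoa:
    def test_unweighted_mean(self):
        lsoa = pd.DataFrame(
            {
                "lsoa_id": ["l1", "l2", "l3", "l4"],
                "msoa_id": ["m1"] * 4,
                "household_income": [10.0, 20.0, 30.0, 40.0],
            }
        )
        out = mk.lsoa_to_msoa(lsoa)
        assert out.loc[0, "household_income"] == 25.0

    def test_single_lsoa_passthrough(self):
        lsoa = pd.DataFrame(
            {"lsoa_id": ["l1"], "msoa_id": ["m1"], "imd_score": [17.3]}
        )
        assert mk.lsoa_to_msoa(lsoa).loc[0, "imd_score"] == 17.3

    def test_matches_group_mean_oracle(self, rng):
        lsoa = pd.DataFrame(
            {
                "lsoa_id": [f"l{i}" for i in range(40)],
                "msoa_id": rng.choice(["m1", "m2", "m3"], 40),
                "a": rng.normal(size=40),
                "b": rng.normal(size=40),
            }
        )
        out = mk.lsoa_to_msoa(lsoa).set_index("msoa_id")
        for mid in ("m1", "m2", "m3"):
            sub = lsoa[lsoa["msoa_id"] == mid]
            assert out.loc[mid, "a"] == pytest.approx(sub["a"].mean())
            assert out.loc[mid, "b"] == pytest.approx(sub["b"].mean())


def stores_lookup(mapping):
    return pd.DataFrame(
        {"store_id": list(mapping), "msoa_id": list(mapping.values())}
    )


class TestMsoaProxies:
    def test_single_store_equals_store_proxies(self):
        b = make_baskets(
            [(True, True), (True, False), (False, False), (False, True)],
            store_ids=["s1"] * 4,
        )
        out = mk.msoa_proxies(b, stores_lookup({"s1": "m1"}))
        direct = mk.compute_proxies(b)
        row = out.set_index("msoa_id").loc["m1"]
        assert row["p_m"] == direct.p_m
        assert row["p_p_given_m"] == direct.p_p_given_m
        assert row["total_transactions"] == direct.n_baskets

    def test_pooling_is_not_averaging(self):
        # store A: 1 menstrual basket of 1 with pain -> P(P|M)=1
        # store B: 4 menstrual baskets, 0 with pain   -> P(P|M)=0
        # pooled: 1/5 = 0.2, while the store mean would be 0.5
        flags = [(True, True)] + [(True, False)] * 4
        b = make_baskets(flags, store_ids=["sA"] + ["sB"] * 4)
        out = mk.msoa_proxies(b, stores_lookup({"sA": "m1", "sB": "m1"}))
        assert out.loc[0, "p_p_given_m"] == pytest.approx(0.2)

    def test_pooling_invariant_exact(self, small_sim):
        """MSOA proxies equal compute_proxies on the concatenation of the
        member stores' baskets."""
        baskets = small_sim["baskets"]
        stores = small_sim["stores"]
        out = mk.msoa_proxies(baskets, stores).set_index("msoa_id")
        lookup = stores.set_index("store_id")["msoa_id"]
        msoa = baskets["store_id"].map(lookup)
        for mid in out.index[:5]:
            direct = mk.compute_proxies(baskets[np.asarray(msoa == mid)])
            assert out.loc[mid, "p_p_given_m"] == pytest.approx(
                direct.p_p_given_m, abs=1e-12
            )
            assert out.loc[mid, "total_transactions"] == direct.n_baskets

    def test_no_menstrual_baskets_flagged_nan(self):
        b = make_baskets([(False, True), (False, False)], store_ids=["s1", "s1"])
        out = mk.msoa_proxies(b, stores_lookup({"s1": "m1"}))
        assert np.isnan(out.loc[0, "p_p_given_m"])
        assert np.isnan(out.loc[0, "mpr"])

    def test_unmapped_store_excluded(self):
        b = make_baskets([(True, True), (True, True)], store_ids=["s1", "sX"])
        out = mk.msoa_proxies(b, stores_lookup({"s1": "m1"}))
        assert out.loc[0, "total_transactions"] == 1


class TestCorrelationTable:
    def region(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "msoa_id": [f"m{i}" for i in range(30)],
                "household_income": rng.normal(500, 100, 30),
                "imd_score": rng.normal(20, 5, 30),
                "total_transactions": rng.integers(100, 1000, 30),
                "p_m": rng.uniform(0.05, 0.2, 30),
                "p_p": rng.uniform(0.1, 0.3, 30),
                "p_p_given_m": rng.uniform(0.1, 0.5, 30),
            }
        )
        return df

    def test_perfect_correlation(self):
        region = self.region()
        region["feature_eq"] = region["p_m"]
        out = mk.correlation_table(region, features=["feature_eq"], measures=["p_m"])
        assert out.loc["feature_eq", ("r", "p_m")] == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        region = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0], "p_m": [1.0, 3.0, 2.0]}
        )
        out = mk.correlation_table(region, features=["x"], measures=["p_m"])
        assert out.loc["x", ("r", "p_m")] == pytest.approx(0.5)

    def test_symmetry_and_bounds(self):
        region = self.region()
        a = mk.correlation_table(region, features=["imd_score"], measures=["p_m"])
        b = mk.correlation_table(region, features=["p_m"], measures=["imd_score"])
        assert a.loc["imd_score", ("r", "p_m")] == pytest.approx(
            b.loc["p_m", ("r", "imd_score")]
        )
        full = mk.correlation_table(region)
        r = full["r"].to_numpy(dtype=float)
        assert np.all(np.abs(r[np.isfinite(r)]) <= 1.0 + 1e-12)

    def test_zero_variance_flagged(self):
        region = self.region()
        region["flat"] = 1.0
        out = mk.correlation_table(region, features=["flat"], measures=["p_m"])
        assert np.isnan(out.loc["flat", ("r", "p_m")])

    def test_planted_income_signal_positive(self, small_sim):
        region = mk.region_table(
            mk.lsoa_to_msoa(small_sim["lsoa"]),
            mk.msoa_proxies(small_sim["baskets"], small_sim["stores"]),
        )
        out = mk.correlation_table(region)
        assert out.loc["household_income", ("r", "p_p_given_m")] > 0


class TestIncomeGradient:
    def region_with_deciles(self, top_mean, bottom_mean):
        incomes = np.arange(20, dtype=float)  # two areas per decile
        vals = np.full(20, (top_mean + bottom_mean) / 2)
        vals[:2] = bottom_mean
        vals[-2:] = top_mean
        return pd.DataFrame(
            {"household_income": incomes, "p_p_given_m": vals}
        )

    def test_arithmetic(self):
        region = self.region_with_deciles(top_mean=0.50, bottom_mean=0.34)
        assert mk.income_gradient(region) == pytest.approx(32.0)

    def test_flat_effect_is_zero(self):
        region = self.region_with_deciles(top_mean=0.4, bottom_mean=0.4)
        assert mk.income_gradient(region) == pytest.approx(0.0)

    def test_too_few_areas_rejected(self):
        region = pd.DataFrame(
            {"household_income": np.arange(5.0), "p_p_given_m": np.ones(5)}
        )
        with pytest.raises(ValueError):
            mk.income_gradient(region)

    def test_recovers_planted_gradient(self, small_sim):
        region = mk.region_table(
            mk.lsoa_to_msoa(small_sim["lsoa"]),
            mk.msoa_proxies(small_sim["baskets"], small_sim["stores"]),
        )
        g = mk.income_gradient(region)
        # 20 MSOAs / 2000 customers: wide Monte-Carlo band around 32%
        assert 10 < g < 55

    def test_null_gradient_centred_on_zero_across_seeds(self):
        """With no planted income effect, the recovered gradient scatters
        around zero and income is not systematically correlated with
        P(P|M)."""
        gradients, rs = [], []
        for seed in range(20):
            cfg = mk.SimulationConfig(
                n_customers=6000, n_msoas=40, income_gradient=0.0, seed=seed
            )
            cat = mk.generate_catalogue(cfg)
            lsoa, stores = mk.generate_regions(cfg)
            baskets = mk.build_baskets(
                mk.generate_transactions(cfg, cat, lsoa, stores),
                mk.classify_products(cat),
            )
            region = mk.region_table(
                mk.lsoa_to_msoa(lsoa), mk.msoa_proxies(baskets, stores)
            )
            gradients.append(mk.income_gradient(region))
            corr = mk.correlation_table(
                region, features=["household_income"], measures=["p_p_given_m"]
            )
            rs.append(corr.loc["household_income", ("r", "p_p_given_m")])
        assert abs(np.median(gradients)) < 10
        assert 0.1 < np.mean(np.array(rs) > 0) < 0.9
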