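"""Proxy probabilities, customer sets and descriptive statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mprkit as mk
from conftest import make_baskets

flag_lists = st.lists(
    st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60
)


class TestComputeProxies:
    def test_hand_enumerated_four_baskets(self):
        b = make_baskets([(True, False), (True, True), (False, True), (False, False)])
        p = mk.compute_proxies(b)
        assert p.p_m == 0.5
        assert p.p_p == 0.5
        assert p.p_p_given_m == 0.5
        assert p.p_p_given_notm == 0.5
        assert p.mpr == 1.0

    @settings(deadline=None, derandomize=True)
    @given(flags=flag_lists)
    def test_law_of_total_probability_exact(self, flags):
        p = mk.compute_proxies(make_baskets(flags))
        if p.conditionals_defined:
            recon = p.p_p_given_m * p.p_m + p.p_p_given_notm * (1 - p.p_m)
            assert recon == pytest.approx(p.p_p, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(flags=flag_lists)
    def test_mpr_invariant_to_duplicating_every_basket(self, flags):
        b = make_baskets(flags)
        doubled = make_baskets(flags + flags)
        p1, p2 = mk.compute_proxies(b), mk.compute_proxies(doubled)
        if p1.mpr_defined:
            assert p2.mpr == pytest.approx(p1.mpr)

    def test_no_menstrual_baskets_flags_undefined(self):
        p = mk.compute_proxies(make_baskets([(False, True), (False, False)]))
        assert p.p_p_given_m is None
        assert not p.mpr_defined

    def test_no_nonmenstrual_baskets_flags_undefined_mpr(self):
        p = mk.compute_proxies(make_baskets([(True, True), (True, False)]))
        assert p.p_p_given_notm is None
        assert p.mpr is None

    def test_zero_baskets_rejected(self):
        with pytest.raises(ValueError):
            mk.compute_proxies(make_baskets([]).iloc[:0])

    def test_half_subsample_agrees_within_sampling_error(self, small_sim):
        baskets = small_sim["baskets"]
        full = mk.compute_proxies(baskets)
        half = mk.compute_proxies(baskets.sample(frac=0.5, random_state=1))
        for attr in ("p_m", "p_p"):
            v_full, v_half = getattr(full, attr), getattr(half, attr)
            se = np.sqrt(v_full * (1 - v_full) / (len(baskets) // 2))
            assert abs(v_half - v_full) < 4 * se


class TestCustomerSets:
    def test_separate_baskets_not_menstrual_pain(self):
        b = make_baskets(
            [(True, False), (False, True)], customer_ids=["c1", "c1"]
        )
        s = mk.customer_sets(b)
        assert "c1" in s.menstrual and "c1" in s.pain
        assert "c1" not in s.menstrual_pain

    def test_joint_basket_in_all_three_sets(self):
        s = mk.customer_sets(make_baskets([(True, True)], customer_ids=["c1"]))
        assert "c1" in s.menstrual and "c1" in s.pain and "c1" in s.menstrual_pain

    def test_menstrual_pain_is_subset_of_both(self, small_sim):
        s = mk.customer_sets(small_sim["baskets"])
        assert s.menstrual_pain <= s.menstrual
        assert s.menstrual_pain <= s.pain

    def test_fraction_recovers_ground_truth(self, small_sim):
        truth = mk.true_parameters(small_sim["config"])
        s = mk.customer_sets(small_sim["baskets"])
        frac = len(s.menstrual_pain) / len(s.menstrual)
        se = np.sqrt(frac * (1 - frac) / len(s.menstrual))
        assert abs(frac - truth.menstrual_pain_customer_fraction) < 3 * se


class TestCustomerSummary:
    def test_single_customer_means(self):
        b = make_baskets([(True, True), (True, False)], customer_ids=["c1", "c1"])
        b["n_units"] = [2, 1]
        b["spend"] = [6.0, 4.0]
        summary = mk.customer_summary(b, mk.customer_sets(b))
        row = summary.loc["menstrual_pain"]
        assert row["n_customers"] == 1
        assert row["mean_transactions"] == 2
        assert row["mean_items"] == 3
        assert row["mean_spend"] == 10.0

    def test_summary_matches_brute_force_oracle(self, small_sim):
        baskets = small_sim["baskets"].head(20000)
        sets = mk.customer_sets(baskets)
        summary = mk.customer_summary(baskets, sets)
        # brute force: loop customers in the menstrual set
        ids = list(sets.menstrual)
        txs, items, spends = [], [], []
        for cid in ids:
            cb = baskets[baskets["customer_id"] == cid]
            txs.append(len(cb))
            items.append(cb["n_units"].sum())
            spends.append(cb["spend"].sum())
        assert summary.loc["menstrual", "mean_transactions"] == pytest.approx(
            np.mean(txs)
        )
        assert summary.loc["menstrual", "mean_items"] == pytest.approx(np.mean(items))
        assert summary.loc["menstrual", "mean_spend"] == pytest.approx(np.mean(spends))

    def test_identical_customers_give_unit_ratios(self):
        b = make_baskets(
            [(True, True), (True, True)], customer_ids=["c1", "c2"]
        )
        summary = mk.customer_summary(b, mk.customer_sets(b))
        ratios = mk.proxies.cross_set_ratios(summary)
        assert np.allclose(ratios.to_numpy(dtype=float), 1.0)


def simple_catalogue():
    return pd.DataFrame(
        {
            "product_id": ["a", "b", "c"],
            "description": ["a", "b", "c"],
            "category": ["tampon", "tampon", "sanitary pad"],
            "unit_price": [1.0, 2.0, 3.0],
        }
    )


def sales_lines(units):
    rows = []
    for pid, n in units.items():
        rows += [["c1", "b%s%d" % (pid, i), "2013-01-01", "s1", pid, 1, 1.0]
                 for i in range(n)]
    df = pd.DataFrame(
        rows,
        columns=["customer_id", "basket_id", "date", "store_id",
                 "product_id", "quantity", "unit_price"],
    )
    df["date"] = pd.to_datetime(df["date"])
    return df


class TestTopProducts:
    def test_coverage_arithmetic(self):
        cat = simple_catalogue()
        classes = mk.classify_products(cat)
        t = sales_lines({"a": 50, "b": 30, "c": 20})
        top = mk.top_products(t, classes, cat, "menstrual", k=2)
        assert top.attrs["coverage_pct"] == pytest.approx(80.0)
        assert list(top["product_id"]) == ["a", "b"]

    def test_k_beyond_catalogue_returns_all(self):
        cat = simple_catalogue()
        classes = mk.classify_products(cat)
        t = sales_lines({"a": 5, "b": 3, "c": 2})
        top = mk.top_products(t, classes, cat, "menstrual", k=10)
        assert len(top) == 3
        assert top.attrs["truncated"]
        assert top.attrs["coverage_pct"] == pytest.approx(100.0)

    def test_category_split_reported(self):
        cat = simple_catalogue()
        classes = mk.classify_products(cat)
        t = sales_lines({"a": 5, "b": 3, "c": 2})
        top = mk.top_products(t, classes, cat, "menstrual", k=3)
        assert top.attrs["category_counts"] == {"tampon": 2, "sanitary pad": 1}


class TestPriceFrequencyCorrelation:
    def test_perfect_anticorrelation(self):
        cat = simple_catalogue()
        classes = mk.classify_products(cat)
        t = sales_lines({"a": 3, "b": 2, "c": 1})
        r = mk.price_frequency_correlation(t, classes, cat, "menstrual")
        assert r == pytest.approx(-1.0)

    def test_perfect_correlation(self):
        cat = simple_catalogue()
        classes = mk.classify_products(cat)
        t = sales_lines({"a": 1, "b": 2, "c": 3})
        r = mk.price_frequency_correlation(t, classes, cat, "menstrual")
        assert r == pytest.approx(1.0)

    def test_zero_price_variance_undefined(self):
        cat = simple_catalogue()
        cat["unit_price"] = 2.0
        classes = mk.classify_products(cat)
        t = sales_lines({"a": 1, "b": 2, "c": 3})
        assert mk.price_frequency_correlation(t, classes, cat, "menstrual") is None

    def test_realised_correlation_stronger_for_pain(self, small_sim):
        r_pain = mk.price_frequency_correlation(
            small_sim["transactions"], small_sim["classes"],
            small_sim["catalogue"], "pain",
        )
        r_mens = mk.price_frequency_correlation(
            small_sim["transactions"], small_sim["classes"],
            small_sim["catalogue"], "menstrual",
        )
        assert abs(r_pain) > abs(r_mens)


class TestSeedStability:
    def test_median_mpr_across_seeds_recovers_truth(self):
        """Median of the MPR estimate across 20 seeded replicates stays
        within ±0.15 of the generator's true ratio."""
        truth = mk.true_parameters(mk.SimulationConfig())
        estimates = []
        for seed in range(20):
            cfg = mk.SimulationConfig(n_customers=800, n_msoas=12, seed=seed)
            cat = mk.generate_catalogue(cfg)
            lsoa, stores = mk.generate_regions(cfg)
            baskets = mk.build_baskets(
                mk.generate_transactions(cfg, cat, lsoa, stores),
                mk.classify_products(cat),
            )
            sets = mk.customer_sets(baskets)
            p = mk.compute_proxies(
                mk.restrict_to_customers(baskets, sets.menstrual_pain)
            )
            estimates.append(p.mpr)
        assert np.median(estimates) == pytest.approx(truth.mpr, abs=0.15)
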