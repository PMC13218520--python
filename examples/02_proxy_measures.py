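"""Estimate the Menstrual Pain Purchasing Ratio from simulated baskets.

Builds baskets from a simulated transaction log, forms the menstrual,
pain and menstrual-pain customer sets, and computes the proxy
probabilities within the menstrual-pain set — the set whose
co-purchasing the MPR describes. An MPR well above 1 means pain relief
is bought together with menstrual products far more often than it is
bought alone.
"""

import mprkit as mk

config = mk.SimulationConfig(n_customers=5000, n_msoas=40, seed=42)
catalogue = mk.generate_catalogue(config)
lsoa, stores = mk.generate_regions(config)
transactions = mk.generate_transactions(config, catalogue, lsoa, stores)
baskets = mk.build_baskets(transactions, mk.classify_products(catalogue))

sets = mk.customer_sets(baskets)
pct = 100 * len(sets.menstrual_pain) / len(sets.menstrual)
print(f"customers: {len(sets.menstrual)} menstrual, {len(sets.pain)} pain, "
      f"{len(sets.menstrual_pain)} menstrual-pain")
print(f"menstrual customers who ever co-purchase pain: {pct:.1f}%")

mp_baskets = mk.restrict_to_customers(baskets, sets.menstrual_pain)
p = mk.compute_proxies(mp_baskets)
print(f"within the menstrual-pain set ({p.n_baskets} baskets):")
print(f"  P(M)     = {p.p_m:.4f}   (menstruation proxy)")
print(f"  P(P)     = {p.p_p:.4f}   (pain proxy)")
print(f"  P(P|M)   = {p.p_p_given_m:.4f}")
print(f"  P(P|nonM)= {p.p_p_given_notm:.4f}")
print(f"  MPR      = {p.mpr:.3f}  (true value {mk.true_parameters(config).mpr:.3f})")
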