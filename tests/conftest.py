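import numpy as np
import pandas as pd
import pytest

import mprkit as mk


def make_baskets(flags, customer_ids=None, dates=None, store_ids=None):
    """Build a basket table from (has_menstrual, has_pain) flag pairs."""
    n = len(flags)
    customer_ids = customer_ids if customer_ids is not None else list(range(n))
    dates = dates if dates is not None else ["2013-01-01"] * n
    store_ids = store_ids if store_ids is not None else ["S0"] * n
    return pd.DataFrame(
        {
            "basket_id": list(range(n)),
            "customer_id": customer_ids,
            "store_id": store_ids,
            "date": pd.to_datetime(dates),
            "n_lines": 1,
            "n_units": 1,
            "spend": 1.0,
            "has_menstrual": [f[0] for f in flags],
            "has_pain": [f[1] for f in flags],
        }
    )


@pytest.fixture(scope="session")
def small_config():
    return mk.SimulationConfig(n_customers=2000, n_msoas=20, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_config):
    """A modest simulated panel shared across module tests."""
    catalogue = mk.generate_catalogue(small_config)
    lsoa, stores = mk.generate_regions(small_config)
    transactions = mk.generate_transactions(small_config, catalogue, lsoa, stores)
    classes = mk.classify_products(catalogue)
    baskets = mk.build_baskets(transactions, classes)
    return {
        "config": small_config,
        "catalogue": catalogue,
        "lsoa": lsoa,
        "stores": stores,
        "transactions": transactions,
        "classes": classes,
        "baskets": baskets,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
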