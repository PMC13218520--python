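"""Small shared helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd


def income_deciles(values: pd.Series | np.ndarray, n_groups: int = 10) -> np.ndarray:
    """Assign 1-based quantile-group ranks (1 = lowest) to ``values``.

    Ties are broken by position ('first'), so groups are as equal-sized as
    possible regardless of duplicates. The same convention is used by the
    data generator when planting the income effect and by the regional
    gradient estimator, so the planted contrast is recoverable exactly up
    to Monte-Carlo noise.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    ranks = s.rank(method="first")
    groups = np.ceil(ranks / len(s) * n_groups).astype(int)
    return np.clip(groups, 1, n_groups)


def weighted_choice(
    rng: np.random.Generator, weights: np.ndarray, size: int
) -> np.ndarray:
    """Vectorised sampling of ``size`` indices with probability ∝ weights."""
    cdf = np.cumsum(weights, dtype=float)
    cdf /= cdf[-1]
    return np.searchsorted(cdf, rng.random(size), side="right")
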