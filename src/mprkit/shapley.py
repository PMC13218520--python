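"""Model-agnostic Shapley value estimation by permutation sampling.

Estimates per-feature Shapley values of a prediction function at given
evaluation points, relative to a background dataset that represents the
"feature absent" distribution. For each Monte-Carlo sample a random
feature permutation and one background row per evaluation point are
drawn; walking the permutation and switching features one at a time from
the background value to the evaluation value yields every feature's
marginal contribution from a single chain of model calls. Averaging over
samples gives unbiased Shapley estimates with the efficiency property
``sum_j phi_j ≈ f(x) − E_background[f]``.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd


def sampling_shapley(
    predict: Callable[[np.ndarray], np.ndarray],
    x_eval: np.ndarray,
    background: np.ndarray,
    n_samples: int = 64,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Estimate Shapley values for each row of ``x_eval``.

    Parameters
    ----------
    predict : callable mapping an (n, d) array to n scalar outputs.
    x_eval : (n, d) evaluation points.
    background : (m, d) background data representing absent features.
    n_samples : Monte-Carlo permutation samples per evaluation point.

    Returns
    -------
    (n, d) array of estimated Shapley values.
    """
    rng = rng or np.random.default_rng()
    x_eval = np.asarray(x_eval, dtype=float)
    background = np.asarray(background, dtype=float)
    n, d = x_eval.shape
    phi = np.zeros((n, d))
    for _ in range(n_samples):
        perm = rng.permutation(d)
        base = background[rng.integers(len(background), size=n)]
        # chain of d+1 coalitions: background -> ... -> full evaluation point
        chain = np.empty((d + 1, n, d))
        current = base.copy()
        chain[0] = current
        for k, j in enumerate(perm):
            current = current.copy()
            current[:, j] = x_eval[:, j]
            chain[k + 1] = current
        preds = np.asarray(predict(chain.reshape(-1, d))).reshape(d + 1, n)
        for k, j in enumerate(perm):
            phi[:, j] += preds[k + 1] - preds[k]
    return phi / n_samples


def shapley_table(
    predict: Callable[[np.ndarray], np.ndarray],
    x_eval: pd.DataFrame,
    background: pd.DataFrame,
    n_samples: int = 64,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-feature attribution summary, ranked by mean |Shapley value|.

    ``value_effect`` is the Pearson correlation between a feature's value
    and its Shapley value across evaluation points: positive means high
    feature values push predictions toward the positive class.
    """
    cols = list(x_eval.columns)
    phi = sampling_shapley(
        predict, x_eval.to_numpy(), background[cols].to_numpy(), n_samples, rng
    )
    mean_abs = np.abs(phi).mean(axis=0)
    effects = []
    xv = x_eval.to_numpy(dtype=float)
    for j in range(len(cols)):
        if np.ptp(xv[:, j]) == 0 or np.ptp(phi[:, j]) == 0:
            effects.append(0.0)
        else:
            effects.append(float(np.corrcoef(xv[:, j], phi[:, j])[0, 1]))
    out = pd.DataFrame(
        {"feature": cols, "mean_abs_shap": mean_abs, "value_effect": effects}
    )
    out = out.sort_values("mean_abs_shap", ascending=False).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
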