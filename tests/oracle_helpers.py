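"""Independent brute-force oracles used by the test suite.

These deliberately reimplement each statistic in the most literal way
possible (explicit loops, flood-fill labelling via scikit-image, textbook
normal equations) so they share no code path with the package.
"""

from __future__ import annotations

import numpy as np
from skimage.measure import label as sk_label

_CONN = {6: 1, 18: 2, 26: 3}


def brute_tfce(vol: np.ndarray, height_power=2.0, extent_power=0.5,
               n_steps=100, connectivity=26, dh=None) -> np.ndarray:
    """Literal TFCE: explicit threshold loop + flood-fill component labels."""
    vol = np.asarray(vol, dtype=float)
    vmax = vol.max()
    out = np.zeros_like(vol)
    if vmax <= 0:
        return out
    if dh is None:
        # max-anchored ladder: h_k = vmax * (k / n), weight vmax / n
        dh = vmax / n_steps
        n_levels = n_steps
        heights = vmax * (np.arange(1, n_levels + 1) / n_levels)
    else:
        n_levels = int(np.floor(vmax / dh + 1e-12))
        heights = dh * np.arange(1, n_levels + 1)
    for k in range(1, n_levels + 1):
        h = heights[k - 1]
        supra = vol >= h
        labels = sk_label(supra, connectivity=_CONN[connectivity])
        sizes = np.bincount(labels.ravel())
        contrib = np.zeros_like(out)
        contrib[supra] = sizes[labels[supra]] ** extent_power * h**height_power * dh
        out += contrib
    return out


def ols_oracle(y: np.ndarray, X: np.ndarray) -> dict:
    """Textbook OLS via pseudoinverse; semi-partial R² by residualisation.

    Column 1 of X is the regressor of interest; column 0 the intercept.
    """
    n, p = X.shape
    beta = np.linalg.pinv(X) @ y
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    t = beta[1] / np.sqrt(cov[1, 1])
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss
    # semi-partial R^2: extra sum of squares of the regressor of interest
    X_red = np.delete(X, 1, axis=1)
    beta_red = np.linalg.pinv(X_red) @ y
    rss_red = float(np.sum((y - X_red @ beta_red) ** 2))
    sp_r2 = (rss_red - rss) / tss
    return {"beta": beta[1], "t": float(t), "r2": r2, "sp_r2": sp_r2, "df": df}


def one_sample_t_map(data: np.ndarray) -> np.ndarray:
    """Literal per-voxel one-sample t (mean / SE), zero at zero variance."""
    out = np.zeros(data.shape[1])
    n = data.shape[0]
    for v in range(data.shape[1]):
        sd = data[:, v].std(ddof=1)
        if sd > 0:
            out[v] = data[:, v].mean() / (sd / np.sqrt(n))
    return out


def exhaustive_sign_flip_p(data: np.ndarray, mask: np.ndarray,
                           tfce_kwargs: dict | None = None) -> dict:
    """Exact corrected p-values over all 2^n sign patterns (identity = obs).

    Returns per-direction corrected p vectors over the masked voxels using
    p = (1 + #{non-identity pattern max >= obs}) / 2^n.
    """
    tfce_kwargs = tfce_kwargs or {}
    n, V = data.shape
    shape = mask.shape

    def tfce_map_of(t_vec, sign):
        vol = np.zeros(shape)
        vol[mask] = sign * t_vec
        return brute_tfce(vol, **tfce_kwargs)

    t_obs = one_sample_t_map(data)
    obs = {d: tfce_map_of(t_obs, s)[mask] for d, s in [("positive", 1), ("negative", -1)]}

    maxima = {"positive": [], "negative": []}
    for code in range(1, 2**n):
        signs = np.array([1.0 - 2.0 * ((code >> b) & 1) for b in range(n)])
        t_perm = one_sample_t_map(signs[:, None] * data)
        for d, s in [("positive", 1), ("negative", -1)]:
            maxima[d].append(tfce_map_of(t_perm, s).max())

    out = {}
    for d in ("positive", "negative"):
        null = np.asarray(maxima[d])
        out[d] = np.array([(1 + np.sum(null >= o)) / 2**n for o in obs[d]])
    return out


def exhaustive_y_permutation_p(data: np.ndarray, y: np.ndarray, mask: np.ndarray,
                               tfce_kwargs: dict | None = None) -> dict:
    """Exact corrected p over all n! outcome orders (identity excluded from
    the null), intercept-plus-field design, per-voxel pseudoinverse fits."""
    from itertools import permutations

    tfce_kwargs = tfce_kwargs or {}
    n, V = data.shape
    shape = mask.shape

    def t_map_of(y_vec):
        t = np.zeros(V)
        for v in range(V):
            X = np.column_stack([np.ones(n), data[:, v]])
            if np.ptp(X[:, 1]) == 0:
                continue
            t[v] = ols_oracle(y_vec, X)["t"]
        return t

    def tfce_masked(t_vec, sign):
        vol = np.zeros(shape)
        vol[mask] = sign * t_vec
        return brute_tfce(vol, **tfce_kwargs)

    orders = list(permutations(range(n)))
    t_obs = t_map_of(y)
    obs = {d: tfce_masked(t_obs, s)[mask] for d, s in [("positive", 1), ("negative", -1)]}
    maxima = {"positive": [], "negative": []}
    for order in orders[1:]:
        t_perm = t_map_of(y[list(order)])
        for d, s in [("positive", 1), ("negative", -1)]:
            maxima[d].append(tfce_masked(t_perm, s).max())
    out = {}
    n_group = len(orders)
    for d in ("positive", "negative"):
        null = np.asarray(maxima[d])
        out[d] = np.array([(1 + np.sum(null >= o)) / n_group for o in obs[d]])
    return out
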