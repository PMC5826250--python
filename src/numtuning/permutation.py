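"""Group-level randomization inference: sign-flip permutation and BH adjustment."""

from __future__ import annotations

import numpy as np

from .exceptions import InsufficientDataError

__all__ = ["sign_flip_test", "bh_adjust"]


def sign_flip_test(diffs, n_permutations: int = 10000, seed: int = 0):
    """Two-sided sign-flip permutation test of mean(diffs) == 0.

    Under the null of a symmetric distribution of per-subject differences
    around zero, the sign of each difference is exchangeable.  The statistic
    is the mean difference; the p-value uses the add-one correction
    ``p = (1 + #{|perm| >= |obs|}) / (1 + B)`` so it can never be exactly 0.

    Parameters
    ----------
    diffs : array_like
        One paired difference per subject (>= 3 subjects required).
    n_permutations : int
        Number of random signings (B).
    seed : int
        Seed of the permutation stream; results are deterministic given it.

    Returns
    -------
    (observed_mean, p_value) tuple.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 1 or len(diffs) < 3:
        raise InsufficientDataError(
            f"sign-flip test needs >= 3 paired differences, got {diffs.size}"
        )
    obs = float(diffs.mean())
    rng = np.random.default_rng(int(seed))
    signs = rng.choice((-1.0, 1.0), size=(int(n_permutations), len(diffs)))
    perm = (signs * diffs).mean(axis=1)
    n_extreme = int(np.sum(np.abs(perm) >= abs(obs)))
    p = (1.0 + n_extreme) / (1.0 + n_permutations)
    return obs, float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for one family of tests.

    Step-up procedure: adjusted p_(i) = min over j >= i of (m/j) p_(j),
    capped at 1.  Input order is preserved.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out
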