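"""Shared permutation-test plumbing (add-one p-values, tie handling)."""

from __future__ import annotations

import numpy as np

__all__ = ["add_one_pvalue"]


def add_one_pvalue(
    observed: float,
    null_samples: np.ndarray,
    *,
    alternative: str = "greater",
    tie_break: str = "conservative",
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value with the add-one rule.

    p = (1 + #{null at least as extreme as observed}) / (n + 1), so p is never
    zero and lies on the grid {1/(n+1), ..., 1}.

    ``alternative`` is "greater", "less" or "two-sided" (two-sided uses
    |null - mean| vs |obs - mean|).  ``tie_break="random"`` resolves ties with
    the observed value uniformly, which makes the p-value exactly uniform
    under an exchangeable null even for discrete statistics; the default
    counts ties as extreme (conservative).
    """
    null = np.asarray(null_samples, dtype=float)
    n = null.size
    if alternative == "greater":
        more, ties = np.sum(null > observed), np.sum(null == observed)
    elif alternative == "less":
        more, ties = np.sum(null < observed), np.sum(null == observed)
    elif alternative == "two-sided":
        center = null.mean()
        d_obs = abs(observed - center)
        d_null = np.abs(null - center)
        more, ties = np.sum(d_null > d_obs), np.sum(d_null == d_obs)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    if tie_break == "conservative":
        extreme = more + ties
    elif tie_break == "random":
        if rng is None:
            raise ValueError("tie_break='random' requires an rng")
        extreme = more + rng.integers(0, int(ties) + 1)
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    return (1 + int(extreme)) / (n + 1)
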