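"""Two-isolate motif statistics, degree-preserving nulls, and grain reciprocity.

A pair of isolates (i, j) with both directed entries observed falls into one
of six unordered motifs built from positive/negative/absent interactions:

    (0,0)  no interaction either way
    (+,0)  one-way promotion
    (-,0)  one-way inhibition
    (+,+)  mutual promotion
    (-,-)  mutual inhibition
    (+,-)  promotion answered by inhibition

Enrichment is assessed against random networks that preserve, for every
isolate, the number of incoming and outgoing positive and negative arrows and
the missing-entry mask.  Randomization swaps the endpoints of random same-sign
arrow pairs (j1->i1, j2->i2 become j1->i2, j2->i1), rejecting swaps that would
create an existing arrow, touch the diagonal, or land on a missing entry; one
cycle swaps one positive and one negative arrow pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._permutation import add_one_pvalue
from .interaction_data import NEG, NONE, POS, SignedMatrix

__all__ = [
    "MOTIFS",
    "MotifCounts",
    "count_pair_motifs",
    "randomize_preserving_degrees",
    "motif_enrichment",
    "intragrain_motifs",
    "reciprocity_continuous",
    "find_clonal_isolates",
]

#: canonical motif order (labels use the unordered pair of arrow signs)
MOTIFS = ("0,0", "+,0", "-,0", "+,+", "-,-", "+,-")

_MOTIF_OF_PAIR = {
    (NONE, NONE): "0,0",
    (POS, NONE): "+,0", (NONE, POS): "+,0",
    (NEG, NONE): "-,0", (NONE, NEG): "-,0",
    (POS, POS): "+,+",
    (NEG, NEG): "-,-",
    (POS, NEG): "+,-", (NEG, POS): "+,-",
}


@dataclass
class MotifCounts:
    counts: dict[str, int]
    n_pairs_evaluated: int

    def frequencies(self) -> np.ndarray:
        if self.n_pairs_evaluated == 0:
            return np.full(len(MOTIFS), np.nan)
        return np.array([self.counts[m] for m in MOTIFS]) / self.n_pairs_evaluated


def count_pair_motifs(m: SignedMatrix, pair_mask: np.ndarray | None = None) -> MotifCounts:
    """Count the six motifs over unordered pairs with both entries observed.

    ``pair_mask``, if given, is a symmetric boolean K x K matrix restricting
    which pairs are evaluated (used for intra-grain counts).
    """
    counts = {name: 0 for name in MOTIFS}
    n = 0
    k = m.k
    for i in range(k):
        for j in range(i + 1, k):
            if m.missing[i, j] or m.missing[j, i]:
                continue
            if pair_mask is not None and not pair_mask[i, j]:
                continue
            counts[_MOTIF_OF_PAIR[(int(m.values[i, j]), int(m.values[j, i]))]] += 1
            n += 1
    return MotifCounts(counts, n)


def _motif_frequencies_fast(values: np.ndarray, observed: np.ndarray,
                            pair_mask: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Vectorized motif frequency vector in MOTIFS order."""
    iu, ju = np.triu_indices(values.shape[0], k=1)
    a = values[iu, ju]
    b = values[ju, iu]
    ok = observed[iu, ju] & observed[ju, iu]
    if pair_mask is not None:
        ok &= pair_mask[iu, ju]
    a, b = a[ok], b[ok]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    counts = np.array([
        np.sum((lo == 0) & (hi == 0)),
        np.sum((lo == 0) & (hi == 1)),
        np.sum((lo == -1) & (hi == 0)),
        np.sum((lo == 1) & (hi == 1)),
        np.sum((lo == -1) & (hi == -1)),
        np.sum((lo == -1) & (hi == 1)),
    ], dtype=float)
    n = int(a.size)
    return (counts / n if n else np.full(6, np.nan)), n


@dataclass
class RandomizationDiagnostics:
    n_cycles: int
    failed_cycles: int = 0
    identity_returned: bool = False


def randomize_preserving_degrees(
    m: SignedMatrix,
    n_cycles: int = 2000,
    seed: int | np.random.Generator = 0,
    max_proposals: int = 100,
    _inplace: bool = False,
) -> tuple[SignedMatrix, RandomizationDiagnostics]:
    """Randomize a signed network preserving every isolate's signed in/out degrees.

    Each cycle attempts to swap the endpoints of one random pair of positive
    arrows and one random pair of negative arrows; a swap is valid when both
    created arrows land on currently-empty, non-missing, off-diagonal entries.
    Up to ``max_proposals`` proposals are tried per swap; a cycle that cannot
    find a legal swap for either sign is counted as failed.  If no cycle
    succeeds at all the input is returned unchanged with
    ``identity_returned=True``.

    The chain is lazy: each swap is skipped with probability 1/2, which makes
    it aperiodic (a strict swap-per-cycle chain is periodic on small matrices
    whose swap graph is bipartite, so some degree-compatible matrices would
    never be sampled at a fixed cycle count).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = m.values if _inplace else m.values.copy()
    # blocked cells: missing entries and the diagonal can never receive an arrow
    blocked = m.missing | np.eye(m.k, dtype=bool)
    arrows = {}
    for sign in (POS, NEG):
        r, c = np.nonzero((values == sign) & ~blocked)
        arrows[sign] = [r.tolist(), c.tolist()]

    diag = RandomizationDiagnostics(n_cycles=n_cycles)
    any_success = False
    # arrow counts are invariant under swaps, so proposal indices can be
    # drawn in batches up front (python-level rng calls dominate otherwise)
    batches = {}
    for sign in (POS, NEG):
        n_arrows = len(arrows[sign][0])
        if n_arrows >= 2:
            batches[sign] = iter([])
    vals = values  # locals for speed
    for _ in range(n_cycles):
        cycle_ok = False
        for sign in (POS, NEG):
            rows, cols = arrows[sign]
            n_arrows = len(rows)
            if n_arrows < 2:
                continue
            it = batches[sign]
            lazy_skip = False
            for _try in range(max_proposals):
                try:
                    a, b = next(it)
                except StopIteration:
                    it = iter(rng.integers(0, 2 * n_arrows,
                                           size=(4096, 2)).tolist())
                    batches[sign] = it
                    a, b = next(it)
                if _try == 0 and a >= n_arrows:
                    lazy_skip = True  # lazy chain: skip this swap half the time
                    break
                a %= n_arrows
                b %= n_arrows
                if a == b:
                    continue
                i1, j1 = rows[a], cols[a]
                i2, j2 = rows[b], cols[b]
                # swap heads: j1->i1, j2->i2  =>  j1->i2, j2->i1
                if i1 == i2 or j1 == j2 or i2 == j1 or i1 == j2:
                    continue
                if vals[i2, j1] != 0 or vals[i1, j2] != 0:
                    continue
                if blocked[i2, j1] or blocked[i1, j2]:
                    continue
                vals[i1, j1] = 0
                vals[i2, j2] = 0
                vals[i2, j1] = sign
                vals[i1, j2] = sign
                rows[a], rows[b] = i2, i1
                cols[a], cols[b] = j1, j2
                cycle_ok = True
                break
            if lazy_skip:
                cycle_ok = True  # holding in place is a valid chain step
        if cycle_ok:
            any_success = True
        else:
            diag.failed_cycles += 1
    if not any_success:
        diag.identity_returned = True
    out = m if _inplace else SignedMatrix(values, m.missing.copy(), list(m.isolates))
    return out, diag


def motif_enrichment(
    m: SignedMatrix,
    n_networks: int = 1000,
    n_cycles: int = 2000,
    seed: int | np.random.Generator = 0,
    tie_break: str = "conservative",
) -> dict:
    """Per-motif enrichment of the observed network against the degree-preserving null.

    For each motif: relative deviation = (observed - null mean) / null mean,
    and a one-sided add-one p-value in the direction of the observed
    deviation (both tails are reported alongside).  A motif whose null mean
    is zero gets deviation nan.

    Returns a dict with per-motif records and the null frequency samples.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    observed_mask = ~m.missing
    obs_freq, n_pairs = _motif_frequencies_fast(m.values, observed_mask)
    null = np.empty((n_networks, len(MOTIFS)))
    work = SignedMatrix(m.values.copy(), m.missing.copy(), list(m.isolates))
    for b in range(n_networks):
        work.values[:] = m.values  # fresh start each draw
        randomize_preserving_degrees(work, n_cycles=n_cycles, seed=rng, _inplace=True)
        null[b] = _motif_frequencies_fast(work.values, observed_mask)[0]

    motifs = {}
    for idx, name in enumerate(MOTIFS):
        mean = null[:, idx].mean()
        dev = (obs_freq[idx] - mean) / mean if mean > 0 else np.nan
        p_hi = add_one_pvalue(obs_freq[idx], null[:, idx], alternative="greater",
                              tie_break=tie_break, rng=rng)
        p_lo = add_one_pvalue(obs_freq[idx], null[:, idx], alternative="less",
                              tie_break=tie_break, rng=rng)
        tail = "greater" if obs_freq[idx] >= mean else "less"
        motifs[name] = {
            "observed_freq": float(obs_freq[idx]),
            "null_mean": float(mean),
            "null_sd": float(null[:, idx].std()),
            "rel_deviation": float(dev) if np.isfinite(dev) else None,
            "p": p_hi if tail == "greater" else p_lo,
            "tail": tail,
            "p_greater": p_hi,
            "p_less": p_lo,
        }
    return {"motifs": motifs, "n_pairs": n_pairs, "n_networks": n_networks,
            "n_cycles": n_cycles, "null_frequencies": null}


def _same_grain_mask(grains: list[str]) -> np.ndarray:
    g = np.asarray(grains, dtype=object)
    return (g[:, None] == g[None, :]) & ~np.eye(len(grains), dtype=bool)


def intragrain_motifs(
    m: SignedMatrix,
    grains: list[str],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    tie_break: str = "conservative",
    strata: np.ndarray | None = None,
) -> dict:
    """Motif frequencies over same-grain pairs, tested by grain-label permutation.

    The null permutes the assignment of isolates to grains (grain sizes
    preserved) and recomputes the intra-grain motif frequencies; the p-value
    per motif is one-sided in the direction of the observed deviation from the
    permutation mean.  ``strata`` (per-isolate labels, e.g. 16S similarity
    clusters) restricts permutations to within-stratum shuffles, controlling
    for a tendency of related isolates to share grains.  Returns
    ``applicable=False`` when there are fewer than two grains or no
    same-grain pair.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if len(set(grains)) < 2:
        return {"applicable": False}
    mask = _same_grain_mask(list(grains))
    observed_mask = ~m.missing
    obs, n_pairs = _motif_frequencies_fast(m.values, observed_mask, mask)
    if n_pairs == 0:
        return {"applicable": False}
    labels = np.asarray(grains, dtype=object)
    strata_groups = None
    if strata is not None:
        strata = np.asarray(strata)
        strata_groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    null = np.empty((n_perm, len(MOTIFS)))
    for b in range(n_perm):
        if strata_groups is None:
            perm = rng.permutation(labels)
        else:
            perm = labels.copy()
            for idx in strata_groups:
                perm[idx] = perm[rng.permutation(idx)]
        pm = (perm[:, None] == perm[None, :]) & ~np.eye(len(labels), dtype=bool)
        null[b] = _motif_frequencies_fast(m.values, observed_mask, pm)[0]
    motifs = {}
    for idx, name in enumerate(MOTIFS):
        ok = np.isfinite(null[:, idx])
        mean = null[ok, idx].mean()
        tail = "greater" if obs[idx] >= mean else "less"
        motifs[name] = {
            "intragrain_freq": float(obs[idx]),
            "null_mean": float(mean),
            "p": add_one_pvalue(obs[idx], null[ok, idx], alternative=tail,
                                tie_break=tie_break, rng=rng),
            "tail": tail,
        }
    return {"applicable": True, "motifs": motifs, "n_same_grain_pairs": n_pairs,
            "n_perm": n_perm}


def reciprocity_continuous(
    cont: np.ndarray,
    grains: list[str],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    rederive_threshold: bool = False,
) -> dict:
    """Threshold-free reciprocity analysis of the continuous appearance-time matrix.

    For every unordered pair the asymmetry is d = |t(i<-j) - t(j<-i)| (days),
    with complete/aerial inhibitions already mapped to the 10-day code by
    :func:`strepnet.interaction_data.to_continuous`.  The reciprocity
    threshold is the d value maximizing the Kolmogorov-style gap
    |CDF_all(d) - CDF_same_grain(d)|; pairs with d <= threshold are called
    reciprocal.  The intra-grain reciprocal fraction is tested by grain-label
    permutation (upper tail, add-one).  ``rederive_threshold`` recomputes the
    threshold inside every permutation, removing the circularity of choosing
    it on the observed labels.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if len(set(grains)) < 2:
        return {"applicable": False}
    cont = np.asarray(cont, dtype=float)
    k = cont.shape[0]
    iu, ju = np.triu_indices(k, k=1)
    delta = np.abs(cont[iu, ju] - cont[ju, iu])
    ok = np.isfinite(delta)
    same = np.asarray(grains, dtype=object)[iu] == np.asarray(grains, dtype=object)[ju]

    d_all = np.sort(delta[ok])
    grid = np.unique(d_all)
    cdf_all = np.searchsorted(d_all, grid, side="right") / d_all.size

    def _gap_curve(same_mask: np.ndarray) -> np.ndarray | None:
        """CDF_same - CDF_all on the grid of observed asymmetries."""
        d_same = np.sort(delta[ok & same_mask])
        if d_same.size == 0:
            return None
        cdf_same = np.searchsorted(d_same, grid, side="right") / d_same.size
        return cdf_same - cdf_all

    def _intra_frac(same_mask: np.ndarray, thr: float) -> float:
        sel = ok & same_mask
        if not sel.any():
            return np.nan
        return float(np.mean(delta[sel] <= thr))

    gaps = _gap_curve(same)
    thr = float(grid[np.argmax(np.abs(gaps))])
    obs_frac = _intra_frac(same, thr)
    obs_gap = float(gaps.max())  # reciprocity excess: same-grain CDF above all-pair CDF
    labels = np.asarray(grains, dtype=object)
    null = np.full(n_perm, np.nan)
    for b in range(n_perm):
        perm = rng.permutation(labels)
        s = perm[iu] == perm[ju]
        if rederive_threshold:
            g = _gap_curve(s)
            null[b] = np.nan if g is None else float(g.max())
        else:
            null[b] = _intra_frac(s, thr)
    okn = np.isfinite(null)
    obs_stat = obs_gap if rederive_threshold else obs_frac
    p = add_one_pvalue(obs_stat, null[okn], alternative="greater",
                       tie_break="random", rng=rng)
    return {"applicable": True, "threshold": thr,
            "intragrain_reciprocal_fraction": obs_frac,
            "max_cdf_gap": obs_gap, "p": p, "n_perm": int(okn.sum()),
            "statistic": obs_stat}


def find_clonal_isolates(m: SignedMatrix, phylo_dists: np.ndarray) -> np.ndarray:
    """Flag redundant members of clonal groups.

    Isolates are grouped (transitively) when their 16S distance is zero and
    all mutually non-missing sender and receiver entries agree; within each
    group every isolate but one representative is flagged clonal.
    """
    k = m.k
    d = np.asarray(phylo_dists, dtype=float)
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(k):
        for j in range(i + 1, k):
            if d[i, j] != 0:
                continue
            keep = np.ones(k, dtype=bool)
            keep[[i, j]] = False
            col_ok = ~(m.missing[:, i] | m.missing[:, j]) & keep
            row_ok = ~(m.missing[i, :] | m.missing[j, :]) & keep
            if (m.values[col_ok, i] == m.values[col_ok, j]).all() and \
               (m.values[i, row_ok] == m.values[j, row_ok]).all():
                parent[find(i)] = find(j)
    flags = np.zeros(k, dtype=bool)
    seen: set[int] = set()
    for i in range(k):
        root = find(i)
        if root in seen:
            flags[i] = True
        else:
            seen.add(root)
    return flags
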