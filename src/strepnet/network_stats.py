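"""Density, degrees, sender-receiver asymmetry, and phylogeny-phenotype statistics.

All statistics operate on receiver x sender matrices (entry ``(i, j)`` = effect
of sender ``j`` on receiver ``i``), exclude the diagonal, and use per-isolate
denominators of available (non-missing) entries so that defective wells reduce
information rather than bias the result.

The sender-receiver asymmetry is

    Q = (Var_r - Var_s) / (Var_r + Var_s),

the normalized contrast between the population variances of the per-isolate
receiver-degree and sender-degree fractions.  Q is in [-1, 1]; negative Q
means the sender-degree distribution is the broader one, i.e. interactions are
statistically determined by the sender ("sender-determined"); positive Q means
receiver-determined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from ._permutation import add_one_pvalue
from .interaction_data import InteractionExperiment, SignedMatrix

__all__ = [
    "DegreeSummary",
    "interaction_density",
    "degree_fractions",
    "sender_receiver_asymmetry",
    "degree_summary",
    "degree_distributions",
    "degree_correlation",
    "count_distinct_profiles",
    "profile_distance",
    "phylo_distance",
    "pairwise_phylo_distances",
    "inhibition_vs_phylo_curve",
    "sender_receiver_divergence_test",
]


class UndefinedResultError(ValueError):
    """Raised when a statistic has an empty denominator."""


@dataclass(frozen=True)
class DegreeSummary:
    sender_frac: np.ndarray
    receiver_frac: np.ndarray
    density: float
    Q: float


def _binary_values(m: SignedMatrix) -> np.ndarray:
    v = np.abs(m.values) if (m.values < 0).any() else m.values
    if not np.isin(v, (0, 1)).all():
        raise ValueError("matrix must be binary (0/1) or sign-coded")
    return v.astype(float)


def interaction_density(m: SignedMatrix) -> float:
    """Fraction of interacting ordered pairs among non-missing off-diagonal entries."""
    use = m.off_diagonal()
    if not use.any():
        raise UndefinedResultError("all off-diagonal entries missing")
    return float(_binary_values(m)[use].mean())


def degree_fractions(m: SignedMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-isolate (sender_frac, receiver_frac) over available entries.

    ``sender_frac[j]`` = fraction of receivers that sender ``j`` inhibits,
    among the non-missing off-diagonal entries of column ``j``; receiver_frac
    analogously over rows.
    """
    v = _binary_values(m)
    use = m.off_diagonal()
    with np.errstate(invalid="ignore"):
        sender = np.where(use, v, 0).sum(axis=0) / use.sum(axis=0)
        receiver = np.where(use, v, 0).sum(axis=1) / use.sum(axis=1)
    return sender, receiver


def sender_receiver_asymmetry(m: SignedMatrix) -> float:
    """Q = (Var_r - Var_s)/(Var_r + Var_s) over degree fractions (population variance)."""
    if m.k < 2:
        raise ValueError("need at least 2 isolates")
    sender, receiver = degree_fractions(m)
    var_s = float(np.var(sender[np.isfinite(sender)]))
    var_r = float(np.var(receiver[np.isfinite(receiver)]))
    if var_s + var_r == 0:
        return 0.0
    return (var_r - var_s) / (var_r + var_s)


def degree_summary(m: SignedMatrix) -> DegreeSummary:
    sender, receiver = degree_fractions(m)
    return DegreeSummary(sender, receiver, interaction_density(m),
                         sender_receiver_asymmetry(m))


def degree_distributions(
    m: SignedMatrix,
    clonal_flags: np.ndarray | None = None,
    n_bins: int = 10,
) -> dict[str, np.ndarray]:
    """Histograms of sender and receiver degree fractions on [0, 1].

    Returns bin edges plus, for each axis, total counts and the counts
    contributed by isolates flagged clonal (the light-colored bar portions).
    Histogram totals equal the isolate count.
    """
    sender, receiver = degree_fractions(m)
    clonal = (np.zeros(m.k, dtype=bool) if clonal_flags is None
              else np.asarray(clonal_flags, dtype=bool))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out: dict[str, np.ndarray] = {"bin_edges": edges}
    for name, frac in (("sender", sender), ("receiver", receiver)):
        frac = np.where(np.isfinite(frac), frac, 0.0)
        out[name] = np.histogram(frac, bins=edges)[0]
        out[f"{name}_clonal"] = np.histogram(frac[clonal], bins=edges)[0]
    return out


def degree_correlation(
    m: SignedMatrix,
    other: np.ndarray | str = "receiver",
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Spearman correlation of sender degree vs another per-isolate quantity.

    ``other`` is either the string "receiver" (receiver degree fraction) or a
    per-isolate real vector (e.g. growth rate on non-conditioned media).  The
    p-value is a label-permutation test with the add-one rule.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sender, receiver = degree_fractions(m)
    y = receiver if isinstance(other, str) and other == "receiver" else np.asarray(other, float)
    ok = np.isfinite(sender) & np.isfinite(y)
    x, y = sender[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedResultError("correlation undefined for a constant vector")
    rho = float(sstats.spearmanr(x, y).statistic)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = sstats.spearmanr(x, rng.permutation(y)).statistic
    if alternative == "two-sided":
        p = add_one_pvalue(abs(rho), np.abs(null), alternative="greater")
    else:
        p = add_one_pvalue(rho, null, alternative=alternative)
    return rho, p


def _profile_diff_counts(
    t: np.ndarray, i: int, j: int, delta_days: float
) -> tuple[int, int]:
    """Count sender and receiver positions where isolates i, j differ by more
    than ``delta_days`` in appearance time in *every* replicate.

    ``t`` is the (K, K, R) appearance-time array.  A position is comparable
    when neither value is nan in any replicate; two complete inhibitions
    (inf) count as equal.
    """
    def _count(a: np.ndarray, b: np.ndarray) -> int:
        # a, b: (positions, R)
        comparable = ~(np.isnan(a) | np.isnan(b)).any(axis=1)
        with np.errstate(invalid="ignore"):
            diff = np.abs(a - b)
        diff[np.isinf(a) & np.isinf(b)] = 0.0  # both complete -> equal
        big = (diff > delta_days).all(axis=1) & comparable
        return int(big.sum())

    keep = np.ones(t.shape[0], dtype=bool)
    keep[[i, j]] = False
    n_sender = _count(t[keep, i, :], t[keep, j, :])      # columns: i, j as senders
    n_receiver = _count(t[i, keep, :], t[j, keep, :])    # rows: i, j as receivers
    return n_sender, n_receiver


def count_distinct_profiles(
    exp: InteractionExperiment,
    delta_days: float = 2.0,
    min_positions: int = 3,
) -> int:
    """Number of distinct phenotypic profiles among the isolates.

    Two isolates are *distinct* when they differ by more than ``delta_days``
    in appearance time, in both replicates, at >= ``min_positions`` sender or
    >= ``min_positions`` receiver positions.  Since "distinct" is not
    transitive, profiles are counted as connected components of the
    complementary not-distinct graph (single linkage), a lower bound on the
    number of distinct phenotypes.
    """
    if exp.n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    k = exp.k
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(k):
        for j in range(i + 1, k):
            ns, nr = _profile_diff_counts(exp.appearance_time, i, j, delta_days)
            if not (ns >= min_positions or nr >= min_positions):
                parent[find(i)] = find(j)
    return len({find(i) for i in range(k)})


def profile_distance(m: SignedMatrix, i: int, j: int, axis: str = "sender") -> float:
    """Fraction of positions at which two interaction profiles differ.

    ``axis="sender"`` compares columns i and j (whom each inhibits);
    ``axis="receiver"`` compares rows (who inhibits each).  Positions i and j
    themselves and positions missing in either profile are excluded.
    """
    if axis == "sender":
        a, b = m.values[:, i], m.values[:, j]
        ma, mb = m.missing[:, i], m.missing[:, j]
    elif axis == "receiver":
        a, b = m.values[i, :], m.values[j, :]
        ma, mb = m.missing[i, :], m.missing[j, :]
    else:
        raise ValueError("axis must be 'sender' or 'receiver'")
    keep = ~(ma | mb)
    keep[[i, j]] = False
    if not keep.any():
        raise UndefinedResultError("no comparable positions")
    return float(np.mean(a[keep] != b[keep]))


def phylo_distance(
    seq_i: str, seq_j: str,
    mask_i: np.ndarray | None = None,
    mask_j: np.ndarray | None = None,
) -> tuple[float, int]:
    """Fraction of differing 16S positions (and their count).

    Only positions that are high-quality in both sequences are compared.
    A gap aligned to a base counts as a difference; two gaps count as equal.
    """
    if len(seq_i) != len(seq_j):
        raise ValueError("sequences must be aligned to equal length")
    a = np.frombuffer(seq_i.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_j.encode(), dtype=np.uint8)
    keep = np.ones(a.size, dtype=bool)
    if mask_i is not None:
        keep &= np.asarray(mask_i, dtype=bool)
    if mask_j is not None:
        keep &= np.asarray(mask_j, dtype=bool)
    if not keep.any():
        raise UndefinedResultError("no shared high-quality positions")
    diff = (a != b) & keep
    n_diff = int(diff.sum())
    return n_diff / int(keep.sum()), n_diff


def pairwise_phylo_distances(exp: InteractionExperiment) -> np.ndarray:
    """K x K matrix of pairwise 16S distances (nan where undefined)."""
    k = exp.k
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                d[i, j] = d[j, i] = phylo_distance(
                    exp.seq16s[i], exp.seq16s[j], exp.qual_mask[i], exp.qual_mask[j])[0]
            except UndefinedResultError:
                d[i, j] = d[j, i] = np.nan
    return d


def inhibition_vs_phylo_curve(
    m: SignedMatrix, dists: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Probability of inhibition among ordered pairs closer than each distance cutoff.

    ``dists`` is a symmetric K x K matrix of pairwise distances (16S fraction,
    or divergence generations for simulated communities).  Returns
    (cutoffs, probability, n_pairs); the cutoffs are the sorted unique
    observed distances plus one point beyond the maximum, whose value is the
    overall interaction density.
    """
    v = _binary_values(m)
    use = m.off_diagonal()
    d = np.asarray(dists, dtype=float)
    ok = use & np.isfinite(d)
    pair_d = d[ok]
    pair_v = v[ok]
    uniq = np.unique(pair_d)
    cutoffs = np.append(uniq, uniq[-1] + (np.ptp(uniq) or 1.0) * 1e-9)
    prob = np.full(cutoffs.size, np.nan)
    n_pairs = np.zeros(cutoffs.size, dtype=int)
    for idx, c in enumerate(cutoffs):
        sel = pair_d < c if idx < cutoffs.size - 1 else np.ones(pair_d.size, bool)
        n_pairs[idx] = sel.sum()
        if n_pairs[idx]:
            prob[idx] = pair_v[sel].mean()
    return cutoffs, prob, n_pairs


def _pairwise_profile_ratio(m: SignedMatrix) -> np.ndarray:
    """K x K matrix of sender/receiver profile-distance ratios.

    Entry (i, j) is sender_dist(i, j) / receiver_dist(i, j); nan marks pairs
    excluded from the divergence statistic (both distances zero, or no
    comparable positions).  A zero receiver distance with nonzero sender
    distance uses half a position (0.5 / #compared) as the denominator so
    the ratio stays finite.
    """
    k = m.k
    ratio = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                ds = profile_distance(m, i, j, "sender")
                dr = profile_distance(m, i, j, "receiver")
            except UndefinedResultError:
                continue
            if ds == 0 and dr == 0:
                continue
            if dr == 0:
                keep = ~(m.missing[i, :] | m.missing[j, :])
                keep[[i, j]] = False
                dr = 0.5 / int(keep.sum())
            ratio[i, j] = ratio[j, i] = ds / dr
    return ratio


def _divergence_statistic(ratio: np.ndarray, ident: np.ndarray) -> tuple[float, int]:
    """Mean profile-distance ratio over identical-16S pairs (upper triangle)."""
    iu, ju = np.triu_indices(ratio.shape[0], k=1)
    vals = ratio[iu, ju][ident[iu, ju]]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return np.nan, 0
    return float(vals.mean()), int(vals.size)


def sender_receiver_divergence_test(
    m: SignedMatrix,
    seqs: list[str],
    masks: list[np.ndarray],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Do sender profiles diverge faster than receiver profiles at zero 16S distance?

    The statistic is the mean ratio of sender-profile to receiver-profile
    distance over pairs with identical 16S sequences.  The null distribution
    permutes the assignment of 16S sequences to isolates, so under the null
    the profile of which pairs are "identical" is random with the same
    multiplicity.  Returns a dict with the statistic, the add-one permutation
    p (upper tail), pair count, and an ``applicable`` flag (False when no
    identical-16S pairs exist).
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = m.k
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            dist[i, j] = dist[j, i] = phylo_distance(seqs[i], seqs[j],
                                                     masks[i], masks[j])[0]
    ident = (dist == 0) & ~np.eye(k, dtype=bool)
    if not ident.any():
        return {"applicable": False, "statistic": np.nan, "p": np.nan, "n_pairs": 0}
    ratio = _pairwise_profile_ratio(m)
    stat, n_pairs = _divergence_statistic(ratio, ident)
    null = np.full(n_perm, np.nan)
    for b in range(n_perm):
        perm = rng.permutation(k)
        null[b] = _divergence_statistic(ratio, ident[np.ix_(perm, perm)])[0]
    ok = np.isfinite(null)
    p = add_one_pvalue(stat, null[ok], alternative="greater")
    return {"applicable": True, "statistic": stat, "p": p, "n_pairs": n_pairs,
            "n_perm": int(ok.sum())}
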