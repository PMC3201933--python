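"""Synthetic-data generators.

Two kinds of synthetic data drive validation:

* :func:`random_srp_community` draws strains with i.i.d.
  producer/resistant/sensitive states, for which the interaction density has
  the closed form 1 - (1 - p_P p_S)^L;

* :func:`synthetic_experiment` emulates the soil-isolate interaction
  experiment: a pure-birth genealogy of K isolates whose latent production
  and sensitivity profiles turn over along branches (production faster than
  sensitivity, so sender profiles diverge faster than receiver profiles),
  16S sequences mutating more slowly than the profiles, grains assigned with
  tunable coupling to the genealogy, planted within-grain reciprocity,
  growth promotions, replicated appearance times with noise, complete and
  aerial-only inhibitions, defective wells, and clonal duplicate isolates.
  A ground-truth record accompanies the data so every pipeline stage can be
  checked exactly in the noise-free limit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ecoevo import P, R, S
from .interaction_data import (
    NEG,
    NONE,
    POS,
    InteractionExperiment,
    SignedMatrix,
    write_experiment,
)

__all__ = [
    "TriangleParams",
    "ExperimentSimParams",
    "random_srp_community",
    "srp_density_closed_form",
    "synthetic_experiment",
    "make_fixture_suite",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TriangleParams:
    """A point in the production/resistance/sensitivity probability triangle."""

    p_P: float
    p_R: float
    p_S: float
    L: int = 40
    K: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_P, self.p_R, self.p_S)
        if any(p < 0 for p in probs):
            raise ValueError("probabilities must be nonnegative")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")


def random_srp_community(tp: TriangleParams) -> np.ndarray:
    """K x L SRP matrix with i.i.d. states drawn from (p_P, p_R, p_S)."""
    rng = np.random.default_rng(tp.seed)
    return rng.choice(
        np.array([P, R, S], dtype=np.int8),
        size=(tp.K, tp.L),
        p=[tp.p_P, tp.p_R, tp.p_S],
    )


def srp_density_closed_form(tp: TriangleParams) -> float:
    """Expected interaction density of a random SRP community:
    P(j inhibits i) = 1 - (1 - p_P p_S)^L."""
    return 1.0 - (1.0 - tp.p_P * tp.p_S) ** tp.L


@dataclass(frozen=True)
class ExperimentSimParams:
    """Configuration of the experiment emulator.

    The defaults describe a collection the size of the measured one: 64
    isolates from 4 grains, latent profiles over 40 compounds, pure-birth
    genealogy of unit depth.  ``sender_turnover`` is the per-lineage rate of
    production-profile flips per unit branch length and is three times
    ``receiver_turnover`` (sensitivity flips), planting the
    sender-diverges-faster signal; ``mut_16s`` is the expected number of 16S
    substitutions per unit branch length, slow enough that close pairs have
    identical sequences while their profiles already differ.
    ``reciprocity_boost`` is the probability that a same-grain pair gets its
    interactions symmetrized.  Appearance times are in days.
    """

    K: int = 64
    G: int = 4
    L: int = 40
    seq_len: int = 300
    mut_16s: float = 4.0          # expected substitutions per unit branch length
    sender_turnover: float = 9.0  # production-profile forget rate per unit branch
    receiver_turnover: float = 3.0
    decouple_16s: bool = False    # assign 16S to isolates at random (null mode)
    gap_rate: float = 0.0         # per-site alignment-gap probability per lineage
    p_produce: float = 0.02       # initial per-compound production probability
    p_sensitive: float = 0.5      # initial per-compound sensitivity probability
    L_promo: int = 20             # promoter-compound count (heritable promotions)
    p_promo_produce: float = 0.05
    p_promo_susceptible: float = 0.3
    reciprocity_boost: float = 0.7
    iid_interactions: bool = False  # replace heritable rule-based signs by iid signs
    grain_phylo_coupling: float = 0.7
    baseline_days: float = 2.5
    baseline_sd: float = 0.4
    delay_days: tuple[float, float] = (2.0, 6.0)     # planted inhibition delay range
    speedup_days: tuple[float, float] = (0.6, 1.5)   # planted promotion speedup range
    p_complete: float = 0.4       # inhibitions that are complete (no colony)
    p_aerial_given_inhibition: float = 0.4
    p_aerial_only: float = 0.15   # inhibitions expressed only as aerial inhibition
    n_replicates: int = 2
    noise_sd: float = 0.15
    missing_rate: float = 0.02
    clonal_duplicates: int = 4
    hq_fraction: float = 0.95     # per-position high-quality probability
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.K >= self.G >= 1):
            raise ValueError("need K >= G >= 1")
        if self.clonal_duplicates >= self.K:
            raise ValueError("clonal_duplicates must be < K")
        for name in ("mut_16s", "sender_turnover", "receiver_turnover",
                     "noise_sd", "missing_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _pure_birth_tree(n_leaves: int, rng: np.random.Generator):
    """Yule genealogy; returns (parents, branch_lengths, leaf ids, depth).

    Nodes are numbered in creation order; node 0 is the root.  Each split
    replaces a random active lineage with two children; split times are the
    sorted uniform order statistics on (0, 1), so total depth is 1.
    """
    times = np.sort(rng.uniform(0.0, 1.0, size=n_leaves - 1)) if n_leaves > 1 else []
    parents = {0: None}
    node_start = {0: 0.0}
    active = [0]
    nxt = 1
    for t in times:
        lin = active.pop(rng.integers(len(active)))
        for _ in range(2):
            parents[nxt] = lin
            node_start[nxt] = t
            active.append(nxt)
            nxt += 1
    # branch of a node spans from its start to its end (its split or 1.0)
    branch_len = {}
    node_end = {n: 1.0 for n in parents}
    for node, par in parents.items():
        if par is not None:
            node_end[par] = min(node_end[par], node_start[node])
    for node in parents:
        branch_len[node] = max(0.0, node_end[node] - node_start[node])
    leaves = [n for n in parents if node_end[n] == 1.0]
    return parents, branch_len, leaves


def _evolve_down_tree(parents, branch_len, leaves, root_state: np.ndarray,
                      rate: float, rng: np.random.Generator,
                      alphabet: np.ndarray | None = None,
                      p_on: float | None = None) -> dict[int, np.ndarray]:
    """Propagate a vector down the tree.

    Sequences (``alphabet`` given): Poisson(rate * branch) substitutions at
    uniform positions, each to a different base.  Binary profiles (``p_on``
    given): a per-position telegraph process — over a branch of length t each
    position forgets its state with probability 1 - exp(-rate * t) and
    redraws it as Bernoulli(p_on), so the on-frequency p_on is stationary
    along the whole tree.
    """
    order = sorted(parents, key=lambda n: (parents[n] is not None, n))
    states: dict[int, np.ndarray] = {}
    for node in order:
        par = parents[node]
        base = root_state if par is None else states[par]
        vec = base.copy()
        t = branch_len[node]
        if alphabet is not None:
            n_subs = rng.poisson(rate * t)
            for _ in range(n_subs):
                pos = rng.integers(vec.size)
                choices = alphabet[alphabet != vec[pos]]
                vec[pos] = choices[rng.integers(choices.size)]
        else:
            forget = rng.random(vec.size) < -np.expm1(-rate * t)
            vec[forget] = (rng.random(int(forget.sum())) < p_on).astype(vec.dtype)
        states[node] = vec
    return {leaf: states[leaf] for leaf in leaves}


def _tree_leaf_order(parents, leaves) -> list[int]:
    """Leaves ordered by a depth-first traversal (clade-contiguous)."""
    children: dict[int, list[int]] = {}
    for node, par in parents.items():
        if par is not None:
            children.setdefault(par, []).append(node)
    order = []
    stack = [0]
    while stack:
        node = stack.pop()
        if node in children:
            stack.extend(reversed(children[node]))
        else:
            order.append(node)
    return [leaf for leaf in order if leaf in set(leaves)]


def synthetic_experiment(sp: ExperimentSimParams) -> tuple[InteractionExperiment, dict]:
    """Generate an experiment-like dataset plus its ground-truth record.

    The truth record contains the planted sign matrix (receiver x sender,
    values -1/0/1 with -9 for entries whose wells were all defective), the
    grain labels, the clonal duplicate map, and the latent profiles.
    """
    rng = np.random.default_rng(sp.seed)
    n_base = sp.K - sp.clonal_duplicates
    parents, branch_len, leaves = _pure_birth_tree(n_base, rng)

    root_seq = _BASES[rng.integers(0, 4, size=sp.seq_len)]
    root_prod = (rng.random(sp.L) < sp.p_produce).astype(np.int8)
    root_sens = (rng.random(sp.L) < sp.p_sensitive).astype(np.int8)
    root_promo_p = (rng.random(sp.L_promo) < sp.p_promo_produce).astype(np.int8)
    root_promo_s = (rng.random(sp.L_promo) < sp.p_promo_susceptible).astype(np.int8)

    seqs = _evolve_down_tree(parents, branch_len, leaves, root_seq,
                             sp.mut_16s, rng, alphabet=_BASES)
    prods = _evolve_down_tree(parents, branch_len, leaves, root_prod,
                              sp.sender_turnover, rng, p_on=sp.p_produce)
    senss = _evolve_down_tree(parents, branch_len, leaves, root_sens,
                              sp.receiver_turnover, rng, p_on=sp.p_sensitive)
    # promoter compounds evolve like antibiotics: production (sender side)
    # turns over faster than susceptibility (receiver side)
    promos_p = _evolve_down_tree(parents, branch_len, leaves, root_promo_p,
                                 sp.sender_turnover, rng, p_on=sp.p_promo_produce)
    promos_s = _evolve_down_tree(parents, branch_len, leaves, root_promo_s,
                                 sp.receiver_turnover, rng, p_on=sp.p_promo_susceptible)

    # clade-contiguous order, then grain assignment with genealogy coupling
    ordered = _tree_leaf_order(parents, leaves)
    blocks = np.array_split(np.arange(n_base), sp.G)
    grain_idx = np.empty(n_base, dtype=int)
    for g, block in enumerate(blocks):
        grain_idx[block] = g
    decouple = rng.random(n_base) > sp.grain_phylo_coupling
    grain_idx[decouple] = rng.integers(0, sp.G, size=int(decouple.sum()))

    # everything planted is decided at the level of the n_base distinct
    # lineages and then expanded to K isolates, so clonal duplicates share
    # their source's interactions exactly (only replicate noise differs)
    nb = n_base
    leaf_of_base = list(ordered)
    prod_base = np.stack([prods[l] for l in leaf_of_base])
    sens_base = np.stack([senss[l] for l in leaf_of_base])
    seq_base = np.stack([seqs[l] for l in leaf_of_base])

    promo_p_base = np.stack([promos_p[l] for l in leaf_of_base])
    promo_s_base = np.stack([promos_s[l] for l in leaf_of_base])

    if sp.iid_interactions:
        # null mode: signs are iid with roughly the rule-based marginal rates,
        # with no phylogenetic correlation or reciprocity structure
        p_neg = 1.0 - (1.0 - sp.p_produce * sp.p_sensitive) ** sp.L
        p_pos = (1.0 - (1.0 - sp.p_promo_produce * sp.p_promo_susceptible) ** sp.L_promo)
        u = rng.random((nb, nb))
        signs_b = np.where(u < p_neg, NEG,
                           np.where(u < p_neg + p_pos * (1 - p_neg), POS, NONE)).astype(np.int8)
        np.fill_diagonal(signs_b, NONE)
    else:
        inhibits = (prod_base[None, :, :] & sens_base[:, None, :]).any(axis=2)
        promotes = (promo_p_base[None, :, :] & promo_s_base[:, None, :]).any(axis=2)
        signs_b = np.where(inhibits, NEG, np.where(promotes, POS, NONE)).astype(np.int8)
        np.fill_diagonal(signs_b, NONE)

    # within-grain reciprocity: with prob reciprocity_boost a same-grain pair
    # with any interaction is made fully symmetric (sign and, later, timing)
    boosted = np.zeros((nb, nb), dtype=bool)
    for i in range(nb):
        for j in range(i + 1, nb):
            if grain_idx[i] != grain_idx[j]:
                continue
            a, b = signs_b[i, j], signs_b[j, i]
            if (a != NONE or b != NONE) and rng.random() < sp.reciprocity_boost:
                keep = a if a != NONE else b
                signs_b[i, j] = signs_b[j, i] = keep
                boosted[i, j] = boosted[j, i] = True

    # effect magnitudes and special inhibition modes
    complete_b = (signs_b == NEG) & (rng.random((nb, nb)) < sp.p_complete)
    aerial_only_b = (signs_b == NEG) & ~complete_b & (rng.random((nb, nb)) < sp.p_aerial_only)
    aerial_b = complete_b & (rng.random((nb, nb)) < sp.p_aerial_given_inhibition)
    aerial_b |= aerial_only_b
    delay = rng.uniform(*sp.delay_days, size=(nb, nb))
    speedup = rng.uniform(*sp.speedup_days, size=(nb, nb))

    # boosted pairs share their effect magnitudes and inhibition mode, so
    # their reciprocal appearance times match (the continuous reciprocity
    # signal), not just their signs
    iu, ju = np.triu_indices(nb, k=1)
    bpairs = boosted[iu, ju]
    for arr in (complete_b, aerial_only_b, aerial_b):
        arr[ju[bpairs], iu[bpairs]] = arr[iu[bpairs], ju[bpairs]]
    for arr in (delay, speedup):
        arr[ju[bpairs], iu[bpairs]] = arr[iu[bpairs], ju[bpairs]]

    base_days = rng.normal(sp.baseline_days, sp.baseline_sd, size=nb).clip(min=1.0)
    t_true_b = np.tile(base_days[:, None], (1, nb))
    t_true_b = np.where((signs_b == NEG) & ~aerial_only_b, t_true_b + delay, t_true_b)
    t_true_b = np.where(signs_b == POS, np.maximum(t_true_b - speedup, 0.25), t_true_b)
    t_true_b = np.where(complete_b, np.inf, t_true_b)

    # expand to K isolates (clonal duplicates replicate their source lineage)
    dup_sources = rng.choice(nb, size=sp.clonal_duplicates, replace=False)
    members = list(range(nb)) + [int(d) for d in dup_sources]
    K = sp.K
    grain_of = [f"G{grain_idx[m] + 1}" for m in members]
    prod_mat = prod_base[members]
    sens_mat = sens_base[members]
    seq_mat = seq_base[members]
    if sp.gap_rate > 0:
        # alignment gaps (counted as ordinary differences downstream)
        gaps = rng.random(seq_mat.shape) < sp.gap_rate
        seq_mat = np.where(gaps, np.uint8(ord("-")), seq_mat)
    if sp.decouple_16s:
        # null mode: sequences carry no information about the genealogy or
        # the clonal structure (shuffled across the final isolate set)
        seq_mat = seq_mat[rng.permutation(K)]
    ix = np.ix_(members, members)
    signs = signs_b[ix].copy()
    complete = complete_b[ix].copy()
    aerial_only = aerial_only_b[ix].copy()
    aerial = aerial_b[ix].copy()
    t_true = t_true_b[ix].copy()
    baseline = base_days[np.asarray(members)]
    # a duplicate and its source behave like the source with itself: no interaction
    np.fill_diagonal(signs, NONE)

    appearance = np.empty((K, K, sp.n_replicates))
    for r in range(sp.n_replicates):
        noise = rng.normal(0.0, sp.noise_sd, size=(K, K)) if sp.noise_sd > 0 else 0.0
        appearance[:, :, r] = np.where(np.isinf(t_true), np.inf, t_true + noise)
    defective = rng.random((K, K, sp.n_replicates)) < sp.missing_rate
    appearance[defective] = np.nan
    all_defective = defective.all(axis=2)

    n_ctrl = max(2, sp.n_replicates)
    control = baseline[:, None] + (
        rng.normal(0.0, sp.noise_sd, size=(K, n_ctrl)) if sp.noise_sd > 0 else 0.0)

    qual = rng.random((K, sp.seq_len)) < sp.hq_fraction

    isolates = [f"I{m + 1:02d}{'d' if k >= n_base else ''}" for k, m in enumerate(members)]
    exp = InteractionExperiment(
        isolates=isolates,
        appearance_time=appearance,
        control_time=control,
        aerial_inhibited=aerial.astype(float),
        grain_of=grain_of,
        seq16s=["".join(chr(c) for c in row) for row in seq_mat],
        qual_mask=[row.copy() for row in qual],
    )
    truth_signs = signs.astype(int).copy()
    truth_signs[all_defective] = -9
    np.fill_diagonal(truth_signs, 0)
    truth = {
        "signs": truth_signs,
        "n_defective_entries": int(all_defective.sum()),
        "grain_of": grain_of,
        "clonal_source": {isolates[n_base + k]: isolates[members.index(int(d))]
                          for k, d in enumerate(dup_sources)},
        "production": prod_mat,
        "sensitivity": sens_mat,
        "complete": complete,
        "aerial_only": aerial_only,
        "baseline_days": baseline,
    }
    return exp, truth


# ---------------------------------------------------------------------------
# canonical small fixtures
# ---------------------------------------------------------------------------

def q_asymmetry_fixture() -> SignedMatrix:
    """4x4 binary matrix whose sender-receiver asymmetry is exactly -0.8:
    senders 1 and 2 inhibit everyone, senders 3 and 4 no one."""
    v = np.zeros((4, 4), dtype=np.int8)
    v[:, 0] = 1
    v[:, 1] = 1
    np.fill_diagonal(v, 0)
    return SignedMatrix(v, np.zeros((4, 4), bool), ["a", "b", "c", "d"])


def density_fixture() -> SignedMatrix:
    """3x3 matrix with exactly the (1<-2) and (2<-1) arrows set: density 2/6."""
    v = np.zeros((3, 3), dtype=np.int8)
    v[0, 1] = 1
    v[1, 0] = 1
    return SignedMatrix(v, np.zeros((3, 3), bool), ["a", "b", "c"])


def motif_fixture() -> SignedMatrix:
    """3-node signed matrix exercising several motifs: a<->b mutual NEG,
    a->c POS one-way, b-c no interaction."""
    v = np.zeros((3, 3), dtype=np.int8)
    v[0, 1] = NEG
    v[1, 0] = NEG
    v[2, 0] = POS
    return SignedMatrix(v, np.zeros((3, 3), bool), ["a", "b", "c"])


def make_fixture_suite(seed: int, directory: str | Path) -> dict:
    """Write the canonical small datasets used across the test surface.

    Deterministic in ``seed``; fixtures are small (3-8 isolates) with
    hand-verifiable statistics.  Returns a manifest of what was written.
    """
    from .interaction_data import write_signed

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_signed(q_asymmetry_fixture(), d / "q_asymmetry.tsv")
    write_signed(density_fixture(), d / "density.tsv")
    write_signed(motif_fixture(), d / "motifs.tsv")
    sp = ExperimentSimParams(K=8, G=2, L=10, seq_len=60, clonal_duplicates=1,
                             noise_sd=0.0, missing_rate=0.0, seed=seed)
    exp, truth = synthetic_experiment(sp)
    write_experiment(exp, d / "small_experiment")
    manifest = {
        "seed": seed,
        "files": sorted(str(p.relative_to(d)) for p in d.rglob("*") if p.is_file()),
        "truth_signs": truth["signs"].tolist(),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
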