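"""Eco-evolutionary simulator of antibiotic-producing microbial communities.

Each strain carries a state vector Z over L antibiotics with entries in
{S, R, P}: sensitive, resistant, producer.  Strain j inhibits strain i
(A_{i<-j} = 1) when j produces at least one antibiotic to which i is
sensitive.  With fractional abundances n_j, the fitness of strain i is

    f_i = f0_i * (1 + eps * ((1 - lam) * G_i - H_i))

    H_i = sum_j n_j A_{i<-j} eta^{A_{j<-i}}        harm received
    G_i = sum_j n_j A_{j<-i} eta^{A_{i<-j}}        benefit of inhibiting
    f0_i = prod_a (1-cP_a)^[Z_ia=P] (1-cR_a)^[Z_ia=R]

where eps in (0, 1] is the selection intensity per ecological cycle, lam the
spite parameter (lam = 0 makes inhibition a zero-sum game, lam = 1 pure
spite with no benefit to the inhibitor), and 1 - eta the protection by
inhibition (an inhibitor that is itself inhibited by its target has its
effect multiplied by eta).  Production and resistance carry multiplicative
costs cP, cR per antibiotic.

Dynamics are Wright-Fisher: each generation N individuals are drawn
multinomially with probabilities proportional to n_i f_i, then mutation
events flip single antibiotic positions within the SRP state space at rates
mu times directed multipliers (loss of function faster than gain; gaining
resistance easier than gaining production).  Genotype classes, not
individuals, are tracked, which makes population sizes of 10^6 tractable.
A lineage table (genotype id -> parent id, birth generation) supports
divergence-time analyses of sampled isolates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .interaction_data import SignedMatrix

__all__ = [
    "S", "R", "P",
    "ModelParams",
    "CommunityState",
    "Snapshot",
    "build_inhibition_matrix",
    "compute_fitness",
    "step_generation",
    "apply_hgt",
    "run",
    "sample_isolates",
    "functional_diversity",
    "turnover_fraction",
    "producer_invasion_threshold",
    "invasion_succeeds",
    "sample_distributed_costs",
    "grid_scan",
]

# SRP state codes
S, R, P = 0, 1, 2
_STATE_NAMES = "SRP"

#: default directed mutation-rate multipliers (times the base rate mu):
#: loss of function is faster than gain, and gaining resistance is easier
#: than gaining production.
DEFAULT_REL_RATES = {
    ("S", "R"): 1.0, ("S", "P"): 0.1,
    ("R", "P"): 0.1, ("R", "S"): 10.0,
    ("P", "S"): 10.0, ("P", "R"): 10.0,
}


def _rate_matrix(rel_rates: dict) -> np.ndarray:
    q = np.zeros((3, 3))
    for (a, b), v in rel_rates.items():
        q[_STATE_NAMES.index(a), _STATE_NAMES.index(b)] = v
    return q


@dataclass(frozen=True)
class ModelParams:
    """Simulation parameters.

    Defaults correspond to the headline regime: N = 10^6 individuals,
    eps = 0.05, lam = 0.15, eta = 0.7, L = 40 antibiotics, mu = 5e-7 per
    position per generation.  Production cost defaults to half the producer
    invasion threshold eps(1-lam)/(1+eps(1-lam)); resistance cost is below
    it (production costlier than resistance).
    """

    L: int = 40
    N: int = 1_000_000
    eps: float = 0.05
    lam: float = 0.15
    eta: float = 0.7
    cost_P: float | np.ndarray = 0.0204
    cost_R: float | np.ndarray = 0.005
    mu: float = 5e-7
    rel_rates: tuple = tuple(sorted(DEFAULT_REL_RATES.items()))
    hgt_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1 or self.N < 2:
            raise ValueError("need L >= 1 and N >= 2")
        if not (0 < self.eps <= 1):
            raise ValueError("eps must be in (0, 1]")
        if not (0 <= self.lam <= 1):
            raise ValueError("lam must be in [0, 1]")
        if not (0 < self.eta <= 1):
            raise ValueError("eta must be in (0, 1]")
        for c in (np.atleast_1d(self.cost_P), np.atleast_1d(self.cost_R)):
            if (c < 0).any() or (c >= 1).any():
                raise ValueError("costs must lie in [0, 1)")
        if self.mu < 0 or self.hgt_prob < 0:
            raise ValueError("rates must be >= 0")

    @property
    def cost_P_vec(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.cost_P, float), (self.L,))

    @property
    def cost_R_vec(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.cost_R, float), (self.L,))

    @property
    def rate_multipliers(self) -> np.ndarray:
        return _rate_matrix(dict(self.rel_rates))


@dataclass
class CommunityState:
    """Extant genotype classes plus the lineage forest.

    Z : (G, L) int8 array of SRP states; counts : (G,) ints summing to N;
    ids : unique genotype ids; lineage maps every ever-created id to
    (parent_id or -1, birth_generation).
    """

    Z: np.ndarray
    counts: np.ndarray
    ids: np.ndarray
    generation: int = 0
    lineage: dict[int, tuple[int, int]] = field(default_factory=dict)
    next_id: int = 0
    run_id: int = 0

    @classmethod
    def founder(cls, params: ModelParams, run_id: int = 0) -> "CommunityState":
        """Single all-sensitive strain at count N."""
        state = cls(
            Z=np.zeros((1, params.L), dtype=np.int8),
            counts=np.array([params.N], dtype=np.int64),
            ids=np.array([0], dtype=np.int64),
            lineage={0: (-1, 0)},
            next_id=1,
            run_id=run_id,
        )
        return state

    @property
    def n_genotypes(self) -> int:
        return len(self.ids)

    @property
    def abundances(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def prune(self) -> None:
        """Drop extinct genotype classes (lineage table is kept)."""
        keep = self.counts > 0
        if not keep.all():
            self.Z = self.Z[keep]
            self.counts = self.counts[keep]
            self.ids = self.ids[keep]

    def prune_lineage(self) -> None:
        """Shrink the lineage table to ancestors of extant genotypes."""
        keep: set[int] = set()
        for gid in self.ids.tolist():
            g = int(gid)
            while g != -1 and g not in keep:
                keep.add(g)
                g = self.lineage[g][0]
        self.lineage = {g: self.lineage[g] for g in keep}

    def ancestors(self, gid: int) -> list[tuple[int, int]]:
        """(id, birth_gen) chain from ``gid`` up to its root, inclusive."""
        chain = []
        g = int(gid)
        while g != -1:
            parent, birth = self.lineage[g]
            chain.append((g, birth))
            g = parent
        return chain


@dataclass
class Snapshot:
    """Lightweight record of the genotype composition at one time point."""

    run_id: int
    generation: int
    profiles: dict[bytes, int]  # Z row bytes -> count

    @classmethod
    def of(cls, state: CommunityState) -> "Snapshot":
        profiles: dict[bytes, int] = {}
        for row, c in zip(state.Z, state.counts):
            key = row.tobytes()
            profiles[key] = profiles.get(key, 0) + int(c)
        return cls(state.run_id, state.generation, profiles)


def build_inhibition_matrix(Z: np.ndarray) -> np.ndarray:
    """A[i, j] = 1 iff strain j produces an antibiotic to which i is sensitive.

    The diagonal is always zero because a position cannot be both P and S.
    """
    Z = np.asarray(Z)
    sens = Z == S
    prod = Z == P
    # pack into 64-bit words so the pairwise test is O(G^2 * L/64)
    n_words = (Z.shape[1] + 63) // 64
    smask = np.zeros((Z.shape[0], n_words), dtype=np.uint64)
    pmask = np.zeros_like(smask)
    for w in range(n_words):
        sl = slice(64 * w, 64 * (w + 1))
        weights = (np.uint64(1) << np.arange(sens[:, sl].shape[1], dtype=np.uint64))
        smask[:, w] = sens[:, sl] @ weights
        pmask[:, w] = prod[:, sl] @ weights
    A = np.zeros((Z.shape[0], Z.shape[0]), dtype=bool)
    for w in range(n_words):
        A |= (smask[:, w, None] & pmask[None, :, w]) != 0
    return A


def compute_fitness(state: CommunityState, params: ModelParams,
                    A: np.ndarray | None = None) -> np.ndarray:
    """Per-genotype fitness vector under the interaction model."""
    if A is None:
        A = build_inhibition_matrix(state.Z)
    n = state.abundances
    eta_T = np.where(A.T, params.eta, 1.0)
    eta_A = np.where(A, params.eta, 1.0)
    H = (A * eta_T) @ n          # harm: inhibitors of i, protected if counter-inhibited
    G = (A.T * eta_A) @ n        # benefit: strains i inhibits
    f0 = np.exp(
        (state.Z == P) @ np.log1p(-params.cost_P_vec)
        + (state.Z == R) @ np.log1p(-params.cost_R_vec)
    )
    f = f0 * (1.0 + params.eps * ((1.0 - params.lam) * G - H))
    if (f < 0).any():
        raise ValueError("negative fitness; eps must not exceed 1")
    return f


def _mutation_weights(state: CommunityState, params: ModelParams):
    """Per-genotype state counts and per-state total outgoing rates."""
    rate_out = params.mu * params.rate_multipliers.sum(axis=1)  # per position, by state
    n_per_state = np.stack([(state.Z == s).sum(axis=1) for s in (S, R, P)], axis=1)
    per_genotype = n_per_state @ rate_out  # expected events per individual per gen
    return n_per_state, rate_out, per_genotype


def step_generation(state: CommunityState, params: ModelParams,
                    rng: np.random.Generator) -> CommunityState:
    """Advance one Wright-Fisher generation (selection, mutation, optional HGT).

    Mutates ``state`` in place and returns it.  Population size is exactly
    conserved; mutation events are Poisson-thinned over genotypes and
    positions proportionally to their per-position outgoing rates.
    """
    if rng is None:
        raise ValueError("an explicit seeded Generator is required")
    f = compute_fitness(state, params)
    w = state.counts * f
    state.counts = rng.multinomial(params.N, w / w.sum())
    state.prune()

    if params.mu > 0:
        _apply_mutations(state, params, rng)
    if params.hgt_prob > 0:
        apply_hgt(state, params, rng)

    state.generation += 1
    state.prune()
    return state


def _apply_mutations(state: CommunityState, params: ModelParams,
                     rng: np.random.Generator) -> None:
    n_per_state, rate_out, per_genotype = _mutation_weights(state, params)
    lam_total = float(state.counts @ per_genotype)
    if lam_total <= 0:
        return
    n_events = rng.poisson(lam_total)
    if n_events == 0:
        return
    q = params.rate_multipliers
    gen = state.generation + 1  # children are born into the new generation
    weights = state.counts * per_genotype
    picks = rng.choice(state.n_genotypes, size=n_events, p=weights / weights.sum())
    new_rows, new_counts, new_ids = [], [], []
    for g in picks:
        if state.counts[g] <= 0:
            continue  # class emptied by earlier events this generation
        # pick the source state proportional to (count of positions) * rate_out
        sw = n_per_state[g] * rate_out
        src = rng.choice(3, p=sw / sw.sum())
        positions = np.flatnonzero(state.Z[g] == src)
        pos = positions[rng.integers(positions.size)]
        dst = rng.choice(3, p=q[src] / q[src].sum())
        child = state.Z[g].copy()
        child[pos] = dst
        state.counts[g] -= 1
        new_rows.append(child)
        new_counts.append(1)
        cid = state.next_id
        state.next_id += 1
        state.lineage[cid] = (int(state.ids[g]), gen)
        new_ids.append(cid)
    if new_rows:
        state.Z = np.vstack([state.Z, np.asarray(new_rows, dtype=np.int8)])
        state.counts = np.concatenate([state.counts, np.asarray(new_counts, dtype=np.int64)])
        state.ids = np.concatenate([state.ids, np.asarray(new_ids, dtype=np.int64)])


def apply_hgt(state: CommunityState, params: ModelParams,
              rng: np.random.Generator) -> CommunityState:
    """Within-population horizontal gene transfer.

    Each of Binomial(N, hgt_prob) recipients pairs with an abundance-weighted
    donor; a uniformly chosen P/R position of the donor is copied into the
    recipient when that is a gain of function (S->R, S->P or R->P).
    """
    if params.hgt_prob <= 0:
        raise ValueError("hgt_prob must be > 0")
    n_events = rng.binomial(params.N, params.hgt_prob)
    gen = state.generation + 1
    for _ in range(n_events):
        p_abund = state.counts / state.counts.sum()
        rec = rng.choice(state.n_genotypes, p=p_abund)
        don = rng.choice(state.n_genotypes, p=p_abund)
        if state.counts[rec] <= 0:
            continue
        donor_pr = np.flatnonzero(state.Z[don] != S)
        if donor_pr.size == 0:
            continue
        pos = donor_pr[rng.integers(donor_pr.size)]
        if state.Z[don][pos] <= state.Z[rec][pos]:
            continue  # not a gain (S < R < P ordering)
        child = state.Z[rec].copy()
        child[pos] = state.Z[don][pos]
        state.counts[rec] -= 1
        cid = state.next_id
        state.next_id += 1
        state.lineage[cid] = (int(state.ids[rec]), gen)
        state.Z = np.vstack([state.Z, child[None, :]])
        state.counts = np.concatenate([state.counts, [1]])
        state.ids = np.concatenate([state.ids, [cid]])
    return state


# ---------------------------------------------------------------------------
# sampling, diversity, turnover
# ---------------------------------------------------------------------------

def sample_isolates(
    state: CommunityState,
    K: int,
    n_draws: int = 1,
    rng: np.random.Generator | None = None,
) -> list[tuple[SignedMatrix, np.ndarray]]:
    """Sample K individuals (duplicates allowed) and return their interaction
    matrix plus pairwise divergence times.

    Each draw samples K individuals proportionally to abundance, mirroring
    the way clonal isolates appear in the experimental collection.  The
    divergence time of a pair is the number of generations since their
    lineages split: the current generation minus the birth generation of the
    earliest branch below their most recent common lineage ancestor (0 for
    two copies of the same genotype).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = rng or np.random.default_rng(0)
    out = []
    A_full = build_inhibition_matrix(state.Z)
    anc_cache: dict[int, dict[int, int]] = {}

    def ancestors_of(gid: int) -> dict[int, int]:
        if gid not in anc_cache:
            anc_cache[gid] = dict(state.ancestors(gid))
        return anc_cache[gid]

    for _ in range(n_draws):
        idx = rng.choice(state.n_genotypes, size=K, p=state.abundances)
        A = A_full[np.ix_(idx, idx)].astype(np.int8)
        div = np.zeros((K, K))
        for a in range(K):
            for b in range(a + 1, K):
                gi, gj = int(state.ids[idx[a]]), int(state.ids[idx[b]])
                if gi == gj:
                    continue
                anc_i, anc_j = ancestors_of(gi), ancestors_of(gj)
                split = None
                # walk i's chain from the leaf: first node also ancestral to j
                prev_birth = None
                for node, birth in state.ancestors(gi):
                    if node in anc_j:
                        # branch below the MRCA on i's side (or gi itself)
                        below_i = prev_birth
                        # branch below the MRCA on j's side
                        below_j = None
                        pb = None
                        for nj, bj in state.ancestors(gj):
                            if nj == node:
                                below_j = pb
                                break
                            pb = bj
                        cands = [x for x in (below_i, below_j) if x is not None]
                        split = min(cands) if cands else birth
                        break
                    prev_birth = birth
                div[a, b] = div[b, a] = state.generation - (split or 0)
        names = [f"iso{a}" for a in range(K)]
        matrix = SignedMatrix(-A, np.zeros((K, K), dtype=bool), names)
        out.append((matrix, div))
    return out


def community_density(state: CommunityState) -> float:
    """Abundance-weighted probability that one random strain inhibits another,
    among pairs of *distinct* genotypes.

    At small population sizes a sizeable fraction of sampled isolate pairs
    are clones (identical genotypes never inhibit each other, since a
    position cannot be both P and S), which dilutes matrix density; this
    community-level density conditions on the pair being distinct and is the
    right observable for "every species inhibits almost every other".
    """
    # aggregate lineage classes with identical Z first
    groups: dict[bytes, float] = {}
    rows: dict[bytes, np.ndarray] = {}
    for row, a in zip(state.Z, state.abundances):
        key = row.tobytes()
        groups[key] = groups.get(key, 0.0) + float(a)
        rows[key] = row
    Z = np.stack([rows[k] for k in groups])
    n = np.array([groups[k] for k in groups])
    A = build_inhibition_matrix(Z)
    w = np.outer(n, n)
    p_same = float(np.trace(w))
    if p_same >= 1.0:
        return 0.0
    return float((A * w).sum() / (1.0 - p_same))


def functional_diversity(state: CommunityState) -> float:
    """Exponential Shannon-Wiener diversity of functional classes.

    Two genotypes are functionally equivalent when they have identical rows
    and columns of the inhibition matrix restricted to the extant community
    (they interact identically, as senders and receivers, with everything
    alive).  Returns a number >= 1 (effective number of classes).
    """
    A = build_inhibition_matrix(state.Z)
    keys: dict[bytes, float] = {}
    n = state.abundances
    for g in range(state.n_genotypes):
        key = A[g].tobytes() + A[:, g].tobytes()
        keys[key] = keys.get(key, 0.0) + n[g]
    p = np.array(list(keys.values()))
    p = p[p > 0]
    return float(np.exp(-(p * np.log(p)).sum()))


def turnover_fraction(s1: Snapshot, s2: Snapshot, presence_threshold: int = 1) -> float:
    """Fraction of t1 genotype profiles (count >= threshold) still present at t2."""
    if s1.run_id != s2.run_id:
        raise ValueError("snapshots come from different runs")
    at_t1 = {z for z, c in s1.profiles.items() if c >= presence_threshold}
    if not at_t1:
        return float("nan")
    present_t2 = {z for z, c in s2.profiles.items() if c >= presence_threshold}
    return len(at_t1 & present_t2) / len(at_t1)


def producer_invasion_threshold(params: ModelParams) -> float:
    """Maximal production cost at which a producer can invade an all-sensitive
    population: c_max = eps(1-lam) / (1 + eps(1-lam))."""
    s = params.eps * (1.0 - params.lam)
    return s / (1.0 + s)


def invasion_succeeds(
    params: ModelParams,
    cost_p: float,
    rng: np.random.Generator,
    init_freq: float = 0.1,
    max_generations: int = 1500,
) -> bool:
    """Simulate a single producer invading an all-S resident; True when the
    producer reaches majority.  Mutation is off so the outcome isolates the
    selective effect of production."""
    p = replace(params, cost_P=cost_p, mu=0.0, hgt_prob=0.0)
    state = CommunityState.founder(p)
    n_inv = max(1, int(round(init_freq * p.N)))
    invader = np.zeros((1, p.L), dtype=np.int8)
    invader[0, 0] = P
    state.Z = np.vstack([state.Z, invader])
    state.counts = np.array([p.N - n_inv, n_inv], dtype=np.int64)
    state.ids = np.array([0, 1], dtype=np.int64)
    state.lineage[1] = (0, 0)
    state.next_id = 2
    for _ in range(max_generations):
        step_generation(state, p, rng)
        producer_alive = (state.Z[:, 0] == P)
        freq = state.counts[producer_alive].sum() / p.N
        if freq == 0.0:
            return False
        if freq > 0.5:
            return True
    return bool(freq > 0.5)


def sample_distributed_costs(params: ModelParams, rng: np.random.Generator) -> np.ndarray:
    """Per-antibiotic production costs ~ Uniform[c_R, c_max] (distributed-cost
    model extension).  Requires a scalar resistance cost below c_max."""
    c_r = float(np.atleast_1d(params.cost_R)[0])
    c_max = producer_invasion_threshold(params)
    if c_r >= c_max:
        raise ValueError(f"cost_R ({c_r}) must be below c_max ({c_max:.4f})")
    return rng.uniform(c_r, c_max, size=params.L)


# ---------------------------------------------------------------------------
# trajectories and scans
# ---------------------------------------------------------------------------

def run(
    params: ModelParams,
    n_generations: int,
    burn_in: int = 20_000,
    record_every: int = 1000,
    sample_K: int = 64,
    n_sample_draws: int = 8,
    keep_divergences: bool = False,
) -> dict:
    """Run the simulator from the all-sensitive founder and record statistics.

    After ``burn_in`` generations, every ``record_every`` generations the
    interaction matrix statistics (density and sender-receiver asymmetry Q,
    averaged over ``n_sample_draws`` samples of ``sample_K`` isolates drawn
    with replacement), the functional diversity of the full community, and a
    composition snapshot are recorded.  Fully reproducible from
    (params, params.seed).
    """
    from .network_stats import interaction_density, sender_receiver_asymmetry

    rng = np.random.default_rng(params.seed)
    state = CommunityState.founder(params, run_id=params.seed)
    records: list[dict] = []
    snapshots: list[Snapshot] = []
    for gen in range(1, n_generations + 1):
        step_generation(state, params, rng)
        if gen % 2000 == 0:
            state.prune_lineage()
        if gen >= burn_in and (gen - burn_in) % record_every == 0:
            draws = sample_isolates(state, sample_K, n_sample_draws, rng)
            dens, qs = [], []
            for matrix, _ in draws:
                dens.append(interaction_density(matrix))
                qs.append(sender_receiver_asymmetry(matrix))
            rec = {
                "generation": state.generation,
                "density": float(np.mean(dens)),
                "Q": float(np.mean(qs)),
                "diversity": functional_diversity(state),
                "n_genotypes": state.n_genotypes,
            }
            if keep_divergences:
                rec["draws"] = draws
            records.append(rec)
            snapshots.append(Snapshot.of(state))
    return {"params": params, "records": records, "snapshots": snapshots,
            "final_state": state}


def grid_scan(
    params: ModelParams,
    cP_grid: np.ndarray,
    cR_grid: np.ndarray,
    n_generations: int = 30_000,
    burn_in: int = 20_000,
    record_every: int = 1000,
    sample_K: int = 64,
    n_sample_draws: int = 8,
) -> "pd.DataFrame":
    """Mean steady-state density and Q over a grid of production/resistance costs.

    Per grid point the trajectory protocol of :func:`run` is applied and the
    recorded densities and asymmetries are averaged.  The returned frame also
    marks whether each point lies above the cP = cR diagonal and the seed used.
    """
    import pandas as pd

    cP_grid = np.atleast_1d(cP_grid)
    cR_grid = np.atleast_1d(cR_grid)
    if cP_grid.size == 0 or cR_grid.size == 0:
        raise ValueError("grids must be non-empty")
    rows = []
    for a, c_p in enumerate(cP_grid):
        for b, c_r in enumerate(cR_grid):
            seed = params.seed + 1000 * a + b
            p = replace(params, cost_P=float(c_p), cost_R=float(c_r), seed=seed)
            res = run(p, n_generations, burn_in, record_every, sample_K, n_sample_draws)
            recs = res["records"]
            rows.append({
                "cost_P": float(c_p),
                "cost_R": float(c_r),
                "density": float(np.mean([r["density"] for r in recs])),
                "Q": float(np.mean([r["Q"] for r in recs])),
                "above_diagonal": bool(c_p > c_r),
                "seed": seed,
                "n_records": len(recs),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# snapshot / lineage export
# ---------------------------------------------------------------------------

def write_snapshot_tsv(state: CommunityState, path) -> None:
    with open(path, "w") as fh:
        fh.write("genotype\tcount\tid\tparent_id\tbirth_gen\n")
        for row, c, gid in zip(state.Z, state.counts, state.ids):
            geno = "".join(_STATE_NAMES[s] for s in row)
            parent, birth = state.lineage[int(gid)]
            fh.write(f"{geno}\t{int(c)}\t{int(gid)}\t{parent}\t{birth}\n")


def write_lineage_tsv(state: CommunityState, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tparent_id\tbirth_gen\n")
        for gid, (parent, birth) in sorted(state.lineage.items()):
            fh.write(f"{gid}\t{parent}\t{birth}\n")
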