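# Methods

This note documents the models, statistics, defaults and design choices in
`strepnet`, and what its synthetic-data validation does and does not show.

## Interaction classification

Inputs are replicated colony appearance times (days) of every receiver on
media conditioned by every sender, appearance times on non-conditioned
control media, and boolean aerial-mycelium-inhibition flags.  Matrices are
receiver × sender throughout: entry (i, j) is the effect of sender j on
receiver i.  `inf` encodes a complete inhibition (no colony within the
observation window), `nan` a defective well.  Diagonal entries are stored —
self-inhibition occurs — but every statistic excludes them.

Each entry's replicates are aggregated by the **median** over valid
replicates and compared to the receiver's median control time.  The median
was chosen for robustness to single defective or outlier wells; the
replicate count is small (2 by default), so mean and median rarely differ.
An entry is:

* **negative** if the median delay exceeds `neg_delay_days` (default 1 d;
  3 d selects strong inhibitions only), or the entry is complete, or
  (optionally) the aerial-mycelium flag is set;
* **positive** if the median speedup is at least `pos_speedup_days`
  (default 0.5 d, i.e. 12 h earlier appearance);
* **missing** if all replicates are defective, or if replicates disagree in
  sign with both magnitudes beyond `neg_delay_days` ("inconsistent
  replicas").  The inconsistency rule is a design choice — the magnitude
  guard avoids discarding entries whose replicates merely straddle zero by
  noise — and is configurable through the threshold it reuses.

The continuous transform keeps the median appearance time per entry and maps
complete and aerial inhibitions to `complete_code_days` (10 d), so
threshold-free analyses can treat aerial inhibition as complete inhibition.

## Network statistics

Degrees are **fractions with per-isolate denominators** of available
(non-missing, off-diagonal) entries, so missing wells reduce information
without biasing rates.  The sender–receiver asymmetry is

    Q = (Var_r − Var_s) / (Var_r + Var_s)  ∈ [−1, 1],

the normalized contrast of the population variances of receiver- and
sender-degree fractions.  The normalization is a design choice: the raw
variance difference of fractions is bounded by 0.25 and cannot express the
strongly sender-determined matrices this system produces; the normalized
form keeps the sign convention (negative = sender-determined) and is
antisymmetric under transposition.  When both variances vanish Q is defined
as 0.

**Distinct profiles** follow a lower-bound convention: two isolates are
distinct when they differ by more than 2 d, in every replicate, at ≥ 3
sender or ≥ 3 receiver positions (positions involving the pair itself are
excluded).  "Distinct" is not transitive, so profiles are counted as
connected components of the complementary not-distinct graph (single
linkage), which can only undercount — appropriate for "at least this many
profiles" statements.

**Phylogenetic distance** is the fraction of differing positions among
positions that are high-quality in both sequences of an aligned pair; a gap
aligned to a base is an ordinary difference, two gaps agree.  Pairs with no
shared high-quality positions are errors rather than zeros.

**Sender/receiver divergence.**  For pairs with identical 16S the statistic
is the mean ratio of sender-profile to receiver-profile distance on the
classified matrix.  Pairs with both distances zero carry no information and
are excluded; a zero receiver distance with nonzero sender distance
substitutes half a position (0.5/#compared) for the denominator so the ratio
stays finite — the statistic should be read together with the pair count,
and sensitivity to this substitution can be probed by re-running at a
different floor.  The null permutes the assignment of (sequence, quality
mask) bundles to isolates; because the permuted objects are the sequences,
the number of identical pairs is invariant and only their placement
randomizes.

## Permutation tests and p-values

All permutation p-values use the add-one rule, p = (1 + #extreme)/(n + 1),
so p ∈ {1/(n+1), …, 1} and never 0.  For discrete statistics (motif
frequencies) ties with the observed value are counted as extreme by default
(conservative); a randomized tie-break option resolves ties uniformly, which
makes the null distribution of p exactly uniform under exchangeability and
is what the calibration tests assert.  Enrichment p-values are one-sided in
the direction of the observed deviation; both tails are always reported in
the result records.

## Motif analysis

Pairs with both arrows observed fall into six unordered motifs
((0,0), (+,0), (−,0), (+,+), (−,−), (+,−)).  The null model preserves, for
every isolate, the number of incoming and outgoing positive and negative
arrows and the missing-entry mask: random same-sign arrow pairs
(j1→i1, j2→i2) have their heads swapped to (j1→i2, j2→i1) when both created
arrows land on empty, non-missing, off-diagonal cells; one cycle attempts
one positive and one negative swap, with a budget of 100 proposals per swap.
The chain is **lazy** (each swap skipped with probability 1/2): a strict
swap-per-cycle chain is periodic on small matrices whose swap graph is
bipartite, and laziness makes the ensemble cover the whole degree class.
Default 2000 cycles per ensemble member (roughly 1–2 attempted moves per
arrow on a 64-isolate matrix); an exhaustive-enumeration check on a 5-node
fixture confirms the chain reaches every degree-compatible matrix.  A known
irreducibility caveat of endpoint-swap chains remains: a directed 3-cycle
and its reversal are degree-compatible but not mutually reachable without
diagonal intermediates; this is a property of the move set, not of the
implementation, and is negligible for matrices of realistic size and
density.

Grain reciprocity is tested by permuting the assignment of isolates to
grains (sizes preserved) and recomputing motif frequencies over same-grain
pairs; an optional within-strata permutation (strata supplied by the caller,
e.g. 16S similarity clusters) controls for relatedness within grains.

**Continuous reciprocity.**  For every pair, Δ = |t(i←j) − t(j←i)| with the
10-day complete/aerial code.  The default protocol picks the threshold at
the maximal |CDF_all − CDF_same-grain| gap and permutation-tests the
intra-grain fraction of pairs with Δ ≤ threshold.  Because the threshold is
chosen on the observed labels, this default is anti-conservative; the
`rederive_threshold` variant instead uses the signed maximal CDF gap itself
as the permutation statistic (rederived inside every permutation), which is
exactly calibrated and is the variant used wherever error rates are
asserted.  (With per-permutation thresholds the raw intra-grain fraction
would not be comparable across permutations, which is why the gap replaces
it.)

## Eco-evolutionary model

Strain i carries `Z_iα ∈ {S, R, P}` over L antibiotics; j inhibits i
(`A_{i←j} = 1`) iff some α has `Z_jα = P` and `Z_iα = S`.  Fitness:

    f_i  = f0_i · (1 + ε[(1−λ)·G_i − H_i])
    H_i  = Σ_j n_j A_{i←j} η^{A_{j←i}}          (harm, attenuated by η when
                                                 the inhibitor is counter-inhibited)
    G_i  = Σ_j n_j A_{j←i} η^{A_{i←j}}          (benefit of inhibiting)
    f0_i = Π_α (1−c_P,α)^[Z=P] (1−c_R,α)^[Z=R]  (multiplicative costs)

This linear multiplicative form is fixed by the constraints the model must
satisfy: Σ_i n_i (G_i − H_i) = 0 identically (an index-relabeling identity),
so at λ = 0 inhibition is exactly zero-sum; at λ = 1 the inhibitor gains
nothing (pure spite); ε ≤ 1 guarantees non-negative fitness because
H_i ≤ 1; and a rare producer invading an all-sensitive population gains
(1−c)(1+ε(1−λ)) per generation, giving the closed-form invasion threshold
c_max = ε(1−λ)/(1+ε(1−λ)), which the invasion simulations bracket from both
sides.

**Dynamics** are Wright–Fisher over genotype classes: each generation the N
individuals are redrawn multinomially with weights n_i f_i; then mutation
events are drawn Poisson with the exact total rate Σ_g count_g · r_g, where
r_g sums the per-position outgoing rates of genotype g's states.  Each event
picks a genotype proportionally to count × rate, a position proportionally
to its state's outgoing rate, and a target state proportionally to the
directed rates — the exact thinning of per-individual-per-position rates
(uniform choices would distort the stationary SRP composition when the six
directed rates differ).  Each event creates a new genotype class with a
lineage link; classes emptied by drift are pruned.  This class-level scheme
makes N = 10⁶ tractable on one core.

Directed mutation multipliers (× base rate μ): S→R = 1, S→P = 0.1,
R→P = 0.1, R→S = 10, P→S = 10, P→R = 10 — loss of function faster than
gain, gaining resistance easier than gaining production; fully configurable,
and the qualitative behavior is robust to alternatives.  Optional
within-population HGT: with probability 10⁻⁴ per individual, a recipient
copies a random P/R position from an abundance-weighted donor when that is a
gain of function.

**Defaults** (headline regime): N = 10⁶, ε = 0.05, λ = 0.15, η = 0.7,
L = 40, μ = 5·10⁻⁷ per position per generation.  Costs default to
c_P = 0.5·c_max ≈ 0.0204 (half the invasion threshold, a natural midpoint of
the viable range) and c_R = 0.005 < c_P, inside the balanced
sender-determined region.  Scaled-down runs used throughout the tests and
the acceptance script keep the population evolutionary rate μN ≈ 0.5 per
position while reducing cost: L = 20, N = 3·10⁴, μ = 1.7·10⁻⁵, 8000
generations with 3000 burn-in — sizes chosen so the full suite and script
run on one core in minutes while preserving the regime structure.

**Lineages and sampling.**  Isolates are sampled with replacement
proportional to abundance, mirroring the clonal isolates of a real
collection.  The divergence time of a sampled pair is the number of
generations since their lineages split: the birth generation of the earliest
branch below their most recent common lineage ancestor (0 for two copies of
the same genotype).  **Functional diversity** is the exponential
Shannon–Wiener index over classes of genotypes with identical inhibition
rows and columns against the extant community.  **Turnover** is the fraction
of genotype profiles present at t₁ (count ≥ 1 by default; a frequency
threshold is available) that survive to t₂.

At reduced N a sizeable fraction of sampled pairs are clones, and identical
genotypes cannot inhibit each other (P and S are exclusive per position), so
sampled-matrix density underestimates "every species inhibits almost every
other" in the dense regime.  `community_density` therefore reports the
abundance-weighted inhibition probability among *distinct* genotypes, the
appropriate observable for that regime; sampled-matrix density remains the
observable for the balanced regime, where clone pairs are rare.

## Synthetic experiment generator

The generator emulates the structure of the measured dataset: 64 isolates
from 4 grains, two replicates, ~2% defective wells, 4 clonal duplicates,
aligned 16S (300 sites by default, ~95% high-quality positions, optional
alignment gaps).  A pure-birth genealogy of unit depth carries three latent
per-lineage profiles: production and sensitivity over 40 antibiotic-like
compounds and production/susceptibility over 20 promoter compounds.  Each
profile position evolves as a **telegraph process** — over a branch of
length t it forgets its state with probability 1 − e^(−rate·t) and redraws
from its stationary frequency — so planted interaction density stays at the
balanced ~0.3 level along the whole tree (a naive toggle process drifts
production frequency toward 1/2 and saturates density).  Sender-side rates
(production, default 9 per unit branch) exceed receiver-side rates
(sensitivity, default 3), planting the sender-diverges-faster signal; 16S
substitutes at 4 per unit branch, slow enough that many close pairs are
16S-identical while their profiles already differ.  Planted inhibitions get
delays of 2–6 d (40% complete, 15% aerial-only), promotions speedups of
0.6–1.5 d; replicate noise is Gaussian (σ = 0.15 d).  Same-grain pairs with
any interaction are symmetrized — sign, magnitude and inhibition mode — with
probability 0.7, planting the reciprocity signal; grains couple to the
genealogy (70% clade assignment) so the relatedness-within-grains control
path is exercised.

Null modes are per signal, because several apparent signals are genuine
properties of the generative process rather than test artifacts:

* `decouple_16s` shuffles sequences across isolates — the null for the
  divergence test.  Merely equalizing the latent turnover rates does *not*
  remove the signal: one production change moves a whole matrix column while
  one sensitivity change barely moves a row, so matrix-level sender
  divergence is structurally faster; the test correctly detects this.
* `reciprocity_boost = 0`, `grain_phylo_coupling = 0`,
  `clonal_duplicates = 0` — the null for grain tests.  Clones are perfectly
  reciprocal and always co-resident, a real planted signal.
* `iid_interactions` draws signs i.i.d. at the rule-based marginal rates —
  the null for motif enrichment.  The production/sensitivity rule itself
  enriches mutual inhibition relative to degree-matched nulls (as the
  simulated communities do), so a rule-based generator is never null for
  this test.

What passing these tests shows — and does not.  The generator reproduces the
*structure* of the measured data (replication, missingness, clones, grains,
signed effects, 16S) and known relationships between its parts, so a green
suite shows the pipeline recovers planted effects at realistic sizes and
calibrates its tests under exchangeable nulls.  It does not emulate
morphological phenotypes, media or condition dependence of interactions,
16S indel processes (gaps are injected i.i.d., not evolved), intransitive or
higher-order chemical interactions, or measurement artifacts beyond missing
wells — conclusions about real data still require the real data.

## Numerical conventions and degenerate inputs

Statistics with empty denominators (all entries missing, no comparable
positions, no shared high-quality sites) raise explicit errors rather than
returning 0 or nan; not-applicable analyses (no identical-16S pairs, a
single grain) return a flagged result.  Q with both degree variances zero is
0 by convention.  Ratio floors, tie handling and one-sided tail selection
are described above.  All randomness flows through seeded numpy Generators;
the same (parameters, seed) reproduces every trajectory and test statistic
bit-exactly.

## Known limitations

The model is non-spatial, ignores antibiotics as common goods,
cross-protection, positive interactions and resource competition — these
exclusions are part of the model's definition, not omissions of the
implementation.  The endpoint-swap null has the 3-cycle irreducibility
caveat noted above.  The default continuous-reciprocity protocol inherits
the threshold-choice circularity of its definition; use the rederived
variant when calibration matters.  Scaled-down simulations preserve regime
structure but not quantitative values tied to N = 10⁶ (fixation times,
absolute diversity); quantities reported by the acceptance script at reduced
N should be compared at the level of regime membership and sign, not digit
precision.
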