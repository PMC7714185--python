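# Methods

## Generative model

The latent social structure is a two-level mixture of circular bivariate
Gaussians. `n_I` independenters are placed i.i.d. `N(0, σ_I² I)`; the j-th
depender of subgroup i is placed `N(x_i, σ_D² I)`. Covariances are diagonal
isotropic exactly; no correlation parameter is exposed. `σ_D` defaults to 1
and functions as the distance unit — only the ratio `σ_I/σ_D` matters for
cluster separability. Agent IDs are 1-based: independenters take IDs
`1..n_I`; the j-th depender of subgroup i takes `n_I + (i−1)·n_D + j`, so
dependers follow all independenters and are grouped by subgroup (this
indexing is a bijection onto `n_I+1..N`). Draw order is fixed — all
independenter coordinates in ID order, then all depender offsets in ID
order — so a given seeded generator yields bit-identical populations across
platforms.

## Serialization

The greedy rule chains on the *last* mover only: after a uniformly random
initiator, step i selects `argmin_{x ∈ remaining} ‖y_{i−1} − x‖`. Squared
distances are used (the argmin is invariant) and ties break toward the
lowest agent ID. Under the continuous model ties have probability zero, but
a deterministic tie-break is required for file replay and cross-platform
reproducibility. The forced-initiator argument exists purely as a
test/replay hook; the simulation path always samples uniformly.

Each observed movement re-draws the agent coordinates (same latent subgroup
memberships), modelling repeated field observations of a group that has
re-arranged itself between events. One simulation run therefore consumes
`n_exp` (population, movement) pairs, aggregates the `n_exp` path
adjacencies into a weighted graph, and clusters once.

## Community detection

Modularity is the standard Newman weighted form at resolution 1. The
Louvain optimization is delegated to networkx's
`louvain_communities` (weighted, resolution 1, seeded), which implements
the two-phase local-move/aggregation scheme; the package pins down the
contract — seeded determinism, canonical community labels renumbered
`1..n_eval` by first appearance in agent-ID order — and carries its own
modularity implementation plus an exhaustive set-partition oracle
(`best_partition_bruteforce`, capped at 10 nodes; Bell numbers grow too
fast beyond that) against which the heuristic is validated. The Louvain
seed for each simulation is drawn from that run's replicate stream, making
the entire run a function of one master seed.

Edgeless graphs (possible only at N = 1) have undefined modularity and
raise rather than score; the experiment runner refuses N < 2 for the same
reason. Isolated nodes, which can occur only in re-ingested external edge
lists, become singleton communities.

## Scoring and replication

The score is the cluster-count ratio `r = n_eval/n_I`; it measures only how
many communities were found, not their composition (in the separated regime
the two coincide in practice — the recovery tests check full label
agreement). Replicates are averaged arithmetically; the SD reported
alongside is the population SD (ddof = 0) of replicate scores, so a
single-replicate cell reports SD 0 rather than NaN.

Seeding uses numpy `SeedSequence(master, spawn_key=(…, replicate))`:
child streams depend only on the master seed and their key, never on
execution order, so sweeps are reproducible bit-for-bit and could be
parallelized without changing results. Sweep cells are keyed by their
row-major cell index.

## Analytic merge checks

Merging true clusters p and q changes modularity by
`ΔQ = m/M − K_p K_q / 2M²`, with `K_p` the sum of node strengths over p
(the convention under which the identity is exact; verified against direct
modularity differencing to 1e−12). For the expected between-cluster weight
under uniformly random orderings of separated blocks, two values are
reported side by side: the ordered-pair normalization `n_exp/n_I`
("as-printed"), and the exhaustive enumeration over all `n_I!` block
orderings for a fixed unordered pair, which gives `2·n_exp/n_I` — at
`n_I = 2` the unique pair is adjacent in every movement, so the expectation
is exactly `n_exp`. The discrepancy is surfaced deliberately rather than
reconciled; it does not affect the qualitative conclusion that the merge
condition `m < K_p K_q/2M` holds comfortably for large `n_exp`. Enumeration
is exhaustive up to `n_I = 8`; beyond that the symmetry-exact closed form
(adjacency probability `2/n_I`) is used, which the enumeration reproduces
exactly on every case it can reach.

The sufficient bound `(n_D n_exp)²/2M` uses the separated-regime strength
bound `K_p, K_q ≤ n_D·n_exp`, which counts the `n_D` within-block edges a
terminal block receives per movement; interior blocks receive `n_D + 1`
edge endpoints, so the bound is exact for terminal blocks and slightly
optimistic for interior ones. This is surfaced here rather than corrected,
as the empirical merge check evaluates the true `K_p` anyway.

## Synthetic data and what the tests show

The generator *is* the study system: isotropic Gaussian subgroups of equal
size and spread, independently re-drawn per observation, serialized without
misidentification or missed agents. Real single-file data adds observation
noise (masked identities, partial files), unequal subgroup sizes, and
spatial persistence between observations — none of which are modelled, so
passing tests validate the method's behaviour under the idealized
generative assumptions, not on field data.

Problem sizes in the test suite follow the study conditions where they are
cheap (1000 replicates for the headline mean score; 500 per cell for the
monotonicity contrasts) and a reduced 4×4×2×2 grid at 100 replicates per
cell for the score-surface shape, whose full-resolution contour values are
stochastic and figure-read and therefore checked as qualitative
monotonicity of the recovery error `|r̄ − 1|` rather than as numbers.

## Known behaviours and limitations

- With many tiny subgroups (e.g. `n_I = 20`, `n_D = 1`) Louvain merges
  2-agent clusters and under-counts (`r̄ ≈ 0.67` at `σ_I = 100`,
  `n_exp = 30`): the classic modularity resolution limit. This matches the
  qualitative surface (scores improve with larger `n_D`, smaller `n_I`) and
  is asserted as such, not as perfect recovery.
- At `σ_I = 1` subgroups overlap heavily and movements interleave them;
  scores degrade and, with many dependers and few observations, can
  overshoot 1. Only the monotone trends are asserted there.
- `n_I = 1` is scoreable (`r = n_eval`) but excluded from "smaller n_I is
  better" comparisons, which start at `n_I = 2`.
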