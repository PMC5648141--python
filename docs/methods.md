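# Methods

## Evidence model

The unit of evidence is a publication record (identifier, title, abstract).
A *functional gene group* is a named, ordered list of member terms (gene
symbols and aliases) treated as one network node; a group is "present" in a
record if any member term matches the record's title or abstract. The
prior-knowledge matrix keeps only records in which at least two distinct
groups are present — a single-group mention carries no co-occurrence
information — and stores presence as 0/1. Co-mention is a deliberately
coarse proxy for interaction: it cannot distinguish positive from negative
regulation, direct from indirect contact, or assertion from refutation, and
no linguistic analysis is attempted.

### Term matching

A member term matches where it is delimited at its **start** by
text-begin, space, `(`, `)`, `[`, `]`, or `-`, and at its **end** by
text-end, any of those, or `.`, `,`, `:`, `;`. Terms are matched literally
(regex metacharacters escaped), so aliases containing punctuation are legal
search terms; the delimiter test applies to the characters *around* the
term, whatever the term contains. Only the ASCII hyphen-minus is treated as
a dash; texts containing Unicode dashes should be normalized upstream.

Two points the matching rules leave open are exposed as options with
documented defaults:

* **Case.** Gene symbols appear in inconsistent case in abstracts
  (`STAT3`, `Stat3`, `stat3`), so matching is case-insensitive by default;
  a `case_insensitive=False` flag restores exact case.
* **"Most commonly observed" members.** When a group's member list is
  reduced to its top-k most frequent members, frequency is *document*
  frequency by default (number of records containing the member at least
  once); `by="occurrences"` switches to total occurrence counts. Ties keep
  the original member order so the reduction is deterministic.

Title and abstract are concatenated with a single space before matching;
because a space is a valid delimiter on both sides, this is equivalent to
matching the fields separately.

## K2 structure learning

Each variable is binary (group present/absent in a record). For node i with
parent set Π, r = 2 states, parent configurations j and counts N_jk
(records with configuration j and state k), N_j = Σ_k N_jk, the local
score is the uniform-Dirichlet marginal likelihood

    g(i, Π) = ∏_j [ (r−1)! / (N_j + r − 1)! ] ∏_k N_jk!

computed in log space with `scipy.special.gammaln`. Configurations never
observed contribute a factor of 1 and are skipped (the implementation packs
parent states into integer codes and uses `bincount`, so an unobserved
configuration simply has N_j = 0 and contributes exactly zero in log
space). Missing values are not supported; inputs are validated as strictly
{0, 1}.

Given a topological ordering, K2 visits nodes in order and greedily adds,
among the node's not-yet-used predecessors, the parent that most increases
g, stopping when no candidate gives a **strict** increase or the parent cap
is hit. Defaults: `max_parents = 5`. Score ties between candidates are
broken toward the lowest node index, making the learned DAG a deterministic
function of (data, ordering). Acyclicity is guaranteed by construction and
re-checked by the `DirectedNetwork` invariants.

Orderings are sampled with the start node pinned and the remaining n−1
nodes uniformly permuted, `topologies_per_start` times for each of the n
possible start nodes (n × t DAGs per ensemble). Duplicate orderings are
permitted — with n ≥ 10 they are rare, and deduplication would bias the
edge counts that the consensus weights estimate. Ensemble learning is a
pure map over the order list; each start node draws its orderings from its
own `SeedSequence([seed, start])` substream, so results do not depend on
scheduling.

## Consensus and resolution

Directed adjacency matrices are summed (`accumulate`), then direction is
discarded by `W + Wᵀ` with the canonical serialization keeping the upper
triangle (`symmetrize`). Since a DAG contains at most one of a→b / b→a,
each undirected weight lies in [0, n_networks].

Edge resolution = weight / max weight. `filter_by_resolution` keeps edges
with resolution **≥** the threshold by default: the inclusive convention is
what makes a resolution-1.0 network non-empty (it contains exactly the
maximal-weight edges), which the stability protocols rely on; a
`strict=True` flag provides the strict-inequality variant. Zero-weight
pairs are never returned at any threshold, and the resolution of an
all-zero network is undefined (an error for direct queries; the stability
protocols treat such a network as an empty edge set, which can only arise
on degenerate inputs such as independent columns).

`classify_edges` labels a filtered edge set against user-supplied reference
pathway edges: *conserved* if the endpoints share a pathway whose reference
contains the edge, *novel* if they share a pathway but the edge is absent
from its reference, *cross-pathway* if the endpoints' pathways differ.
Negative-control nodes get their own pathway label so control–control
edges are judged against an (empty) control reference.

## Stability protocols

Agreement between two consensus networks at a resolution threshold is
Cohen's kappa over the binary labelling of all n(n−1)/2 unordered node
pairs: with a/b/c/d the both-present / only-first / only-second /
both-absent counts, p_o = (a+d)/N, p_e = ((a+b)(a+c)+(c+d)(b+d))/N², and
κ = (p_o − p_e)/(1 − p_e). If p_e = 1 (for a 2×2 table this forces two
identical constant labellings) κ is set to 1.0 under perfect agreement and
0.0 otherwise, and flagged `degenerate`. The default resolution grid is
0.1–1.0 in steps of 0.1.

* **Sample splits** — rows are randomly partitioned into `n_folds`
  near-equal sections (remainder spread over the first folds). Per fold, a
  consensus from the fold's rows (test) is compared with one from all other
  rows (predicted). Both networks of a fold are built from the *same*
  topology set: sharing the orderings isolates the sample-size effect from
  topology-sampling noise and makes identical evidence yield identical
  networks. Defaults to 4 topologies per start node — enough for a stable
  consensus (see below) at a tenth of the cost of large ensembles.
* **Topology counts** — one consensus per requested ensemble size, each
  size drawing fresh orderings from its own substream; every successive
  size pair is compared, plus smallest-vs-largest. Reports carry the full
  (a, b, c, d, κ) grid and min/max/mean summaries per comparison.

All randomness descends from one master seed through documented
`SeedSequence` keys, so every report is exactly reproducible.

## Synthetic evidence

`sample_records` draws records ancestrally from a planted DAG with explicit
CPTs; exact marginals for validation come from joint enumeration (≤ 20
nodes). Two planted families are provided:

* `chain_fork_collider_model` — the 10-node default benchmark (chain, fork,
  collider, tail chain) with strong conditionals (0.9 when any parent is
  on, 0.1 otherwise), n = 5,000 records: small enough for desk-scale
  ensembles, structured enough to exercise orientation-ambiguous motifs.
* `random_pathway_model` — a seeded random DAG at pathway scale (≈1.3
  parents per node on average, capped at 3; "any parent on" → 0.85, else
  0.10; root marginal 0.3) standing in for literature evidence over a
  pathway's gene groups when the real matrices are not available.

These stand-ins reproduce the *dependency* character of co-mention data
(strong, sparse, acyclic-generatable) but not its extreme row sparsity,
long-tailed group popularity, or inter-record correlation from citation
chains, so passing stability floors on them demonstrates the method's
internal stability, not its behavior on any particular literature corpus.

`make_corpus` embeds designated member terms in designated delimiter
contexts amid filler words checked to share no substrings with any member,
so mining the corpus reproduces the designed presence matrix exactly (the
round-trip property test).

## Problem sizes and numerical choices

The acceptance experiments run at pathway scale but reduced row count, the
package's chosen desk-scale conditions: 27 groups × 5,000 records for the
stability protocols (10 folds × 4 topologies per start; topology sizes
4/8/12), and 45 groups × 3,000 records × 8 topologies per start (360 DAGs)
for the two-pathway-scale experiment. Scores are compared with ordinary
float comparison; ties (bitwise-equal log scores) occur for exactly
equivalent parent candidates and are resolved by node index as above.
Factorials are never formed explicitly — everything is `gammaln` sums — so
scores are finite for any record count. Seeds derived from the master seed
are masked to 31 bits.

The local-score oracle test enumerates all 2-column datasets with ≤ 6 rows
and all 3-column datasets with ≤ 4 rows exhaustively and samples the
6-row × 3-column boundary randomly; full enumeration at the boundary
(2^18 datasets) adds no distinct count patterns worth the runtime.

## Known limitations

* Co-mention evidence conflates interaction with co-review; the matcher
  has no disambiguation for aliases that are common English words (e.g.
  "CIS"), which inflates document frequencies for such members.
* K2's greedy search is optimal only per ordering; the consensus weights
  mitigate but do not eliminate ordering bias, and edge weights are counts,
  not calibrated posterior probabilities.
* Collider motifs produce spurious parent–parent edges at high resolution
  (Markov equivalence); the classification step will report them as novel.
* Binary variables only; no support for occurrence counts or multi-state
  evidence.
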