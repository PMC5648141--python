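"""Stability protocols: edge-set agreement between consensus networks.

Two protocols probe whether the inferred edge sets are robust:

* **Sample-split stability** — the publication rows are split into folds;
  for each fold a *test* consensus (fold rows only) is compared with a
  *predicted* consensus (all remaining rows).
* **Topology-size stability** — consensus networks built from differing
  numbers of random orderings per start node are compared pairwise
  (each size against the next, plus smallest against largest).

Agreement is Cohen's kappa over the binary presence/absence of every
possible undirected edge at each resolution threshold, i.e. the
chance-corrected proportion of node pairs on which the two networks agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from consensusbn.consensus import (
    ConsensusNetwork,
    consensus_from_ensemble,
    filter_by_resolution,
)
from consensusbn.corpus import PriorKnowledgeMatrix
from consensusbn.k2 import K2Config, learn_ensemble

__all__ = [
    "AgreementTable",
    "KappaResult",
    "StabilityReport",
    "DEFAULT_RESOLUTIONS",
    "agreement_table",
    "cohen_kappa",
    "sample_split_stability",
    "topology_size_stability",
]

Edge = tuple[int, int]

#: The reference resolution grid: 0.1 to 1.0 in steps of 0.1.
DEFAULT_RESOLUTIONS: tuple[float, ...] = tuple(
    round(0.1 * i, 1) for i in range(1, 11)
)


@dataclass(frozen=True)
class AgreementTable:
    """2x2 contingency over all unordered node pairs for two edge sets."""

    both_present: int
    only_first: int
    only_second: int
    both_absent: int

    def __post_init__(self) -> None:
        if min(self.both_present, self.only_first,
               self.only_second, self.both_absent) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return (self.both_present + self.only_first
                + self.only_second + self.both_absent)


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa for one network pair at one resolution threshold."""

    table: AgreementTable
    p_observed: float
    p_expected: float
    kappa: float
    resolution: float | None = None
    degenerate: bool = False  # p_expected == 1; kappa set by convention


def agreement_table(
    edges_a: Iterable[Edge],
    edges_b: Iterable[Edge],
    n_nodes: int,
) -> AgreementTable:
    """Cross-tabulate edge presence over all n(n-1)/2 unordered pairs."""

    def canon(edges: Iterable[Edge]) -> set[Edge]:
        out = set()
        for a, b in edges:
            if a == b:
                raise ValueError("self-edges are not valid")
            if not (0 <= a < n_nodes and 0 <= b < n_nodes):
                raise ValueError(f"edge ({a},{b}) outside 0..{n_nodes - 1}")
            out.add((min(a, b), max(a, b)))
        return out

    A, B = canon(edges_a), canon(edges_b)
    n_pairs = n_nodes * (n_nodes - 1) // 2
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    return AgreementTable(
        both_present=a,
        only_first=b,
        only_second=c,
        both_absent=n_pairs - a - b - c,
    )


def cohen_kappa(
    table: AgreementTable,
    resolution: float | None = None,
) -> KappaResult:
    """Chance-corrected agreement for a 2x2 table.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement rate and
    p_e the rate expected from the marginals.  When p_e == 1 the formula is
    undefined (both raters constant); by convention the result is 1.0 under
    perfect agreement and 0.0 otherwise, flagged ``degenerate``.
    """
    n = table.total
    if n <= 0:
        raise ValueError("agreement table is empty")
    a, b = table.both_present, table.only_first
    c, d = table.only_second, table.both_absent
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if p_e >= 1.0:
        kappa = 1.0 if (b == 0 and c == 0) else 0.0
        return KappaResult(table, p_o, p_e, kappa, resolution, degenerate=True)
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(table, p_o, p_e, kappa, resolution)


@dataclass
class StabilityReport:
    """Kappa grid for a stability experiment: one row per (test, resolution)."""

    protocol: str
    results: list[tuple[str, KappaResult]]  # (test id, result)
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for test_id, r in self.results:
            rows.append(
                {
                    "test_id": test_id,
                    "resolution": r.resolution,
                    "a": r.table.both_present,
                    "b": r.table.only_first,
                    "c": r.table.only_second,
                    "d": r.table.both_absent,
                    "kappa": r.kappa,
                    "degenerate": r.degenerate,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Min/max/mean kappa per comparison, across the resolution grid."""
        df = self.to_frame()
        return (
            df.groupby("test_id", sort=False)["kappa"]
            .agg(["min", "max", "mean"])
            .reset_index()
        )

    def min_kappa(self, resolutions: Sequence[float] | None = None) -> float:
        df = self.to_frame()
        if resolutions is not None:
            df = df[df["resolution"].isin(resolutions)]
        return float(df["kappa"].min())


def _compare_grid(
    net_a: ConsensusNetwork,
    net_b: ConsensusNetwork,
    resolutions: Sequence[float],
    test_id: str,
) -> list[tuple[str, KappaResult]]:
    n = net_a.n_nodes

    def edges(net: ConsensusNetwork, res: float) -> set[Edge]:
        # an edgeless consensus network has no defined resolutions; for the
        # agreement protocol it simply contributes an empty edge set
        return filter_by_resolution(net, res) if net.max_weight > 0 else set()

    out = []
    for res in resolutions:
        ea = edges(net_a, res)
        eb = edges(net_b, res)
        out.append((test_id, cohen_kappa(agreement_table(ea, eb, n), res)))
    return out


def _derive_seed(master: int, *key: int) -> int:
    return int(
        np.random.SeedSequence([master, *key]).generate_state(1)[0]
    ) & 0x7FFFFFFF


def sample_split_stability(
    data: PriorKnowledgeMatrix,
    n_folds: int = 10,
    resolutions: Sequence[float] = DEFAULT_RESOLUTIONS,
    topologies_per_start: int = 4,
    config: K2Config = K2Config(),
) -> StabilityReport:
    """Fold-wise agreement between small-sample and large-sample networks.

    The rows are randomly partitioned into ``n_folds`` near-equal sections
    (remainder spread over the first folds).  For each fold, a consensus
    network from the fold's rows alone (test) is compared against one from
    all remaining rows (predicted), with kappa computed at every resolution.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    m = data.n_rows
    if m < n_folds:
        raise ValueError("fewer rows than folds")
    rng = np.random.default_rng(_derive_seed(config.seed, 101))
    perm = rng.permutation(m)
    base, extra = divmod(m, n_folds)
    folds: list[np.ndarray] = []
    start = 0
    for f in range(n_folds):
        size = base + (1 if f < extra else 0)
        folds.append(perm[start : start + size])
        start += size
    if any(len(f) == 0 for f in folds):
        raise ValueError("empty fold; reduce n_folds")

    results: list[tuple[str, KappaResult]] = []
    for f, fold_idx in enumerate(folds):
        rest_idx = np.concatenate([folds[g] for g in range(n_folds) if g != f])
        # test and predicted networks share one topology set per fold, so
        # the comparison isolates the sample-size effect from topology
        # sampling noise (and identical evidence yields identical networks)
        fold_cfg = K2Config(config.max_parents, _derive_seed(config.seed, 2, f))
        test_net = consensus_from_ensemble(
            learn_ensemble(data.subset_rows(fold_idx), topologies_per_start, fold_cfg),
            group_names=data.group_names,
        )
        pred_net = consensus_from_ensemble(
            learn_ensemble(data.subset_rows(rest_idx), topologies_per_start, fold_cfg),
            group_names=data.group_names,
        )
        results.extend(
            _compare_grid(test_net, pred_net, resolutions, f"fold_{f + 1}")
        )
    return StabilityReport("sample_split", results, config.seed)


def topology_size_stability(
    data: PriorKnowledgeMatrix,
    sizes: Sequence[int],
    resolutions: Sequence[float] = DEFAULT_RESOLUTIONS,
    config: K2Config = K2Config(),
) -> StabilityReport:
    """Agreement between consensus networks of differing ensemble sizes.

    One consensus network is built per entry of ``sizes`` (topologies per
    start node); each successive pair is compared, plus the pair formed by
    the smallest and largest sizes, at every resolution.
    """
    sizes = [int(s) for s in sizes]
    if len(sizes) < 2:
        raise ValueError("need at least two sizes to compare")
    if any(s < 1 for s in sizes) or any(
        b <= a for a, b in zip(sizes, sizes[1:])
    ):
        raise ValueError("sizes must be strictly increasing and >= 1")

    nets: dict[int, ConsensusNetwork] = {}
    for s in sizes:
        cfg = K2Config(config.max_parents, _derive_seed(config.seed, 3, s))
        nets[s] = consensus_from_ensemble(
            learn_ensemble(data, s, cfg), group_names=data.group_names
        )
    comparisons = list(zip(sizes, sizes[1:]))
    extreme = (sizes[0], sizes[-1])
    if extreme not in comparisons:
        comparisons.append(extreme)
    results: list[tuple[str, KappaResult]] = []
    for a, b in comparisons:
        results.extend(
            _compare_grid(nets[a], nets[b], resolutions, f"{a}_vs_{b}")
        )
    return StabilityReport("topology_size", results, config.seed)
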