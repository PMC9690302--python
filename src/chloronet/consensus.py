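"""Stability-selection consensus over subsampled network inferences.

The network is re-inferred on ``k`` random subsamples of the sample columns
(each holding a fraction ``f`` of the samples, drawn without replacement)
and an edge enters the consensus network when it recurs in at least ``m``
of the ``k`` runs; its confidence is the recurrence fraction ``m / k``. The
reference configuration is k = 6 half-sample subsets with a 5-of-6
retention rule (confidence 83.3%).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grn import Edge, EngineConfig, ExpressionMatrix, Network, infer_network

__all__ = ["ConsensusConfig", "subsample_columns", "consensus_network", "edge_confidence"]


@dataclass
class ConsensusConfig:
    n_subsets: int = 6
    subsample_fraction: float = 0.5
    min_occurrence: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if not 1 <= self.min_occurrence <= self.n_subsets:
            raise ValueError("min_occurrence must lie in [1, n_subsets]")


def subsample_columns(
    matrix: ExpressionMatrix, fraction: float, seed: int, index: int
) -> ExpressionMatrix:
    """Select ``floor(fraction * n_samples)`` distinct sample columns
    uniformly without replacement, keeping their original order.

    The draw is seeded by ``(seed, index)`` so subset ``index`` of a run is
    reproducible yet distinct from its siblings. Gene rows are unchanged.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = len(matrix.samples)
    n_keep = int(np.floor(fraction * n))
    if n_keep < 3:
        raise ValueError(f"subsample of {n_keep} samples is too small to fit on")
    rng = np.random.default_rng([seed, index])
    cols = np.sort(rng.choice(n, size=n_keep, replace=False))
    sub = matrix.values.iloc[:, cols]
    return ExpressionMatrix(values=sub, regulators=list(matrix.regulators))


def edge_confidence(occurrence: int, k: int) -> float:
    """Recurrence percentage of an edge over ``k`` runs, to one decimal
    (5 of 6 -> 83.3)."""
    if not 0 <= occurrence <= k:
        raise ValueError(f"occurrence {occurrence} outside [0, {k}]")
    return round(100.0 * occurrence / k, 1)


def consensus_network(
    matrix: ExpressionMatrix,
    engine_config: EngineConfig | None = None,
    consensus_config: ConsensusConfig | None = None,
) -> Network:
    """Infer one network per subsample and keep edges recurring at least
    ``min_occurrence`` times; edge weight is the mean over the runs that
    contain it, confidence the recurrence fraction."""
    engine_config = engine_config or EngineConfig()
    cc = consensus_config or ConsensusConfig()
    occurrences: dict[tuple[str, str], int] = {}
    weight_sums: dict[tuple[str, str], float] = {}
    for i in range(cc.n_subsets):
        sub = subsample_columns(matrix, cc.subsample_fraction, cc.rng_seed, i)
        ec = replace(engine_config, rng_seed=engine_config.rng_seed + i)
        net = infer_network(sub, ec)
        for key, edge in net.edges.items():
            occurrences[key] = occurrences.get(key, 0) + 1
            weight_sums[key] = weight_sums.get(key, 0.0) + edge.weight
    edges = {
        key: Edge(
            regulator=key[0],
            target=key[1],
            weight=weight_sums[key] / occ,
            occurrence=occ,
            confidence=occ / cc.n_subsets,
        )
        for key, occ in occurrences.items()
        if occ >= cc.min_occurrence
    }
    return Network(edges=edges, n_subsets=cc.n_subsets)
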