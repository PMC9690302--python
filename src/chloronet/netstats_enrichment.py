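"""Network summary statistics and Fisher/FDR term enrichment.

Summaries cover regulator/target/edge counts, out-degree hubs, the share of
edges driven by regulators linked to each polymorphism group, and Venn-style
region counts over gene sets. Enrichment tests a target gene set against a
background with the two-tailed Fisher exact test per term and
Benjamini-Hochberg FDR control across terms.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .grn import Network

__all__ = [
    "network_summary",
    "hub_genes",
    "group_edge_fractions",
    "venn_counts",
    "EnrichmentResult",
    "fisher_enrichment",
    "bh_fdr",
    "read_gmt",
    "write_gmt",
    "read_group_map",
]

logger = logging.getLogger(__name__)


def network_summary(network: Network) -> dict:
    """Regulator/target/edge counts plus out- and in-degree tables."""
    if not network.edges:
        raise ValueError("network has no edges")
    out_deg: dict[str, int] = {}
    in_deg: dict[str, int] = {}
    for r, t in network.edges:
        out_deg[r] = out_deg.get(r, 0) + 1
        in_deg[t] = in_deg.get(t, 0) + 1
    return {
        "n_regulators": len(out_deg),
        "n_targets": len(in_deg),
        "n_edges": network.n_edges,
        "out_degree": pd.Series(out_deg).sort_values(ascending=False),
        "in_degree": pd.Series(in_deg).sort_values(ascending=False),
    }


def hub_genes(network: Network, top_n: int = 10) -> list[str]:
    """Top regulators by out-degree (descending), ties broken by ID."""
    if not network.edges:
        raise ValueError("network has no edges")
    out_deg: dict[str, int] = {}
    for r, _ in network.edges:
        out_deg[r] = out_deg.get(r, 0) + 1
    ranked = sorted(out_deg, key=lambda r: (-out_deg[r], r))
    return ranked[:top_n]


def group_edge_fractions(
    network: Network, group_map: Mapping[str, Iterable[str]]
) -> dict[str, float]:
    """Percentage of edges whose regulator carries each group label.

    ``group_map`` links a regulator to the polymorphism groups of its
    associated chloroplast gene(s); regulators absent from the map are
    unassociated. A multi-label regulator's edges count once per label but
    only once in the ``any`` total, so ``any`` can be below the label sum.
    """
    n = network.n_edges
    if n == 0:
        raise ValueError("network has no edges")
    labels = {r: {str(g) for g in gs} for r, gs in group_map.items()}
    per_group: dict[str, int] = {}
    any_count = 0
    for r, _ in network.edges:
        groups = labels.get(r, set())
        if groups:
            any_count += 1
        for g in groups:
            per_group[g] = per_group.get(g, 0) + 1
    out = {g: 100.0 * c / n for g, c in sorted(per_group.items())}
    out["any"] = 100.0 * any_count / n
    return out


def venn_counts(sets: Mapping[str, Iterable]) -> dict[frozenset, int]:
    """Exclusive region counts for the Venn diagram of the named sets.

    The key ``frozenset({'A', 'B'})`` maps to the number of elements in A
    and B but in no other set; every non-empty combination of set names is
    reported (zero counts included).
    """
    named = {k: set(v) for k, v in sets.items()}
    if not named:
        raise ValueError("no sets given")
    names = sorted(named)
    out: dict[frozenset, int] = {}
    universe = set().union(*named.values())
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(universe)
            for nm in combo:
                inside &= named[nm]
            for nm in names:
                if nm not in combo:
                    inside -= named[nm]
            out[frozenset(combo)] = len(inside)
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's 2x2 table, Fisher p, and BH-adjusted q.

    ``a``/``b`` split the target set by term membership; ``c``/``d`` split
    the rest of the background, so ``a + b`` is the target-set size and the
    table total is the background size.
    """

    term: str
    description: str
    a: int
    b: int
    c: int
    d: int
    p: float
    q: float

    @property
    def significant(self) -> bool:
        return self.q < 0.05


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def fisher_enrichment(
    target_set: Iterable[str],
    background: Iterable[str],
    term_sets: Mapping[str, Iterable[str]],
    descriptions: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Two-tailed Fisher enrichment of each term in the target set vs the
    background, BH-corrected across all tested terms.

    Terms with no background overlap are skipped (logged); the p-value sums
    hypergeometric probabilities of all tables as or less probable than the
    observed one (the convention of mainstream statistics tools).
    """
    targets = set(target_set)
    bg = set(background)
    if not targets:
        raise ValueError("target set is empty")
    if not targets <= bg:
        raise ValueError("target set is not contained in the background")
    descriptions = descriptions or {}
    rows = []
    for term, members in term_sets.items():
        in_term = set(members) & bg
        if not in_term:
            logger.info("term %s has no background overlap; skipped", term)
            continue
        a = len(targets & in_term)
        b = len(targets - in_term)
        c = len(in_term - targets)
        d = len(bg) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((term, a, b, c, d, float(p)))
    if not rows:
        return []
    q = bh_fdr([r[5] for r in rows])
    return [
        EnrichmentResult(
            term=term,
            description=descriptions.get(term, ""),
            a=a,
            b=b,
            c=c,
            d=d,
            p=p,
            q=float(qi),
        )
        for (term, a, b, c, d, p), qi in zip(rows, q)
    ]


# ---------------------------------------------------------------------------
# File formats


def read_gmt(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read GMT term sets; returns (term -> members, term -> description)."""
    term_sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            term_sets[parts[0]] = {g for g in parts[2:] if g}
            descriptions[parts[0]] = parts[1]
    return term_sets, descriptions


def write_gmt(term_sets: Mapping[str, Iterable[str]], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term, members in term_sets.items():
            desc = descriptions.get(term, "na")
            fh.write("\t".join([term, desc, *sorted(set(members))]) + "\n")


def read_group_map(path) -> dict[str, set[str]]:
    """Read a ``regulator<TAB>group`` TSV into a regulator -> labels map."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) != 2 or parts[0] == "regulator":
                continue
            out.setdefault(parts[0], set()).add(parts[1])
    return out
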