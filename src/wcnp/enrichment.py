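"""Over-representation analysis and weight-coefficient re-ranking.

Each pathway is tested with the upper-tail hypergeometric test (the
one-sided Fisher's exact test used by standard ORA tools): with a universe
of N genes, a pathway of K genes, and a query of n genes, the p-value for
an observed overlap k is P(X >= k), X ~ Hypergeometric(N, K, n). P-values
are corrected per collection with Benjamini-Hochberg. Pathways are then
re-ranked by their weight coefficient C (descending), and the rank delta
(unweighted rank minus weighted rank; positive = promoted) reports how the
weighting changed each pathway's standing.

Tie-breaking is deterministic: unweighted rank orders by ascending p, then
descending overlap k, then pathway id; weighted rank orders by descending
C, then ascending p, then pathway id. With all-equal weights the two
orderings therefore coincide exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .gene_sets import GeneSet, normalize_gene
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "pathway_id", "description", "k", "K", "n", "N",
    "p_value", "fdr_bh", "unweighted_rank", "weight_c", "weighted_rank",
    "rank_delta",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Pathway gene sets plus the gene universe used for testing.

    Default universe is the union of all pathway genes (the annotation
    universe); a caller-supplied universe restricts pathway genes to it.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self):
        restricted = {}
        for pid, (desc, genes) in self.sets.items():
            genes = frozenset(normalize_gene(g) for g in genes) & self.universe
            if not genes:
                continue
            restricted[pid] = (desc, genes)
        object.__setattr__(self, "sets", restricted)

    @classmethod
    def from_sets(
        cls,
        sets: Mapping[str, tuple[str, frozenset[str]]],
        universe: frozenset[str] | None = None,
    ) -> "GeneSetCollection":
        norm_sets = {
            pid: (desc, frozenset(normalize_gene(g) for g in genes))
            for pid, (desc, genes) in sets.items()
        }
        if universe is None:
            universe = frozenset().union(*(g for _, g in norm_sets.values())) if norm_sets else frozenset()
        else:
            universe = frozenset(normalize_gene(g) for g in universe)
        return cls(norm_sets, universe)

    def __len__(self) -> int:
        return len(self.sets)

    def genes_of(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id][1]

    def as_gene_map(self) -> dict[str, frozenset[str]]:
        return {pid: genes for pid, (_, genes) in self.sets.items()}


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-pathway ORA statistics with unweighted and weighted ranks."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = set(RESULT_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValidationError(f"enrichment table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.table)

    def write(self, path) -> None:
        self.table[RESULT_COLUMNS].to_csv(Path(path), sep="\t", index=False)


def _unweighted_order(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(
        ["p_value", "k", "pathway_id"], ascending=[True, False, True]
    ).reset_index(drop=True)


def hypergeom_enrich(
    query: GeneSet, collection: GeneSetCollection, k_min: int = 0
) -> EnrichmentResult:
    """Upper-tail hypergeometric ORA with BH correction and unweighted ranks.

    Genes are restricted to the collection's universe. Pathways with overlap
    below ``k_min`` are dropped before BH (default 0: all tested pathways
    form the BH family). Weighted columns are initialized to the unweighted
    ordering (C = 0) until :func:`rerank_by_weight` is applied.
    """
    if not collection.universe:
        raise ValidationError("empty universe")
    q = query.genes & collection.universe
    if not q:
        raise ValidationError("query shares no genes with the universe")
    N = len(collection.universe)
    n = len(q)
    rows = []
    for pid, (desc, genes) in collection.sets.items():
        K = len(genes)
        k = len(q & genes)
        if k < k_min:
            continue
        # P(X >= k) with X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((pid, desc, k, K, n, N, min(p, 1.0)))
    if not rows:
        raise ValidationError("no pathway passed the overlap filter")
    df = pd.DataFrame(
        rows, columns=["pathway_id", "description", "k", "K", "n", "N", "p_value"]
    )
    df["fdr_bh"] = stats.false_discovery_control(df["p_value"], method="bh")
    df = _unweighted_order(df)
    df["unweighted_rank"] = np.arange(1, len(df) + 1)
    df["weight_c"] = 0.0
    df["weighted_rank"] = df["unweighted_rank"]
    df["rank_delta"] = 0
    return EnrichmentResult(df[RESULT_COLUMNS])


def rerank_by_weight(
    result: EnrichmentResult, c_scores: Mapping[str, float]
) -> EnrichmentResult:
    """Re-rank pathways by descending weight coefficient C.

    A pure permutation: p-values, counts and BH values are untouched.
    Pathways missing from ``c_scores`` get C = 0 with a logged warning.
    rank_delta = unweighted_rank - weighted_rank (positive = promoted).
    """
    df = result.table.copy()
    missing = [pid for pid in df["pathway_id"] if pid not in c_scores]
    if missing:
        logger.warning(
            "%d pathway(s) missing from weight table, treated as C = 0: %s",
            len(missing), missing[:5],
        )
    df["weight_c"] = [float(c_scores.get(pid, 0.0)) for pid in df["pathway_id"]]
    df = df.sort_values(
        ["weight_c", "p_value", "pathway_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    df["weighted_rank"] = np.arange(1, len(df) + 1)
    df["rank_delta"] = df["unweighted_rank"] - df["weighted_rank"]
    return EnrichmentResult(df[RESULT_COLUMNS])


def enrich_and_rerank(
    query: GeneSet,
    collection: GeneSetCollection,
    component_table,
    edges,
    k_min: int = 0,
) -> EnrichmentResult:
    """Compose ORA -> weight cascade -> re-ranking (the end-to-end workflow)."""
    from .weighting import compute_weights

    result = hypergeom_enrich(query, collection, k_min=k_min)
    weights = compute_weights(component_table, edges, collection.as_gene_map())
    return rerank_by_weight(result, weights.c_scores)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_gmt(path, universe: frozenset[str] | None = None) -> GeneSetCollection:
    """GMT: tab-separated ``id  description  gene1  gene2 ...`` per line."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for ln, line in enumerate(path.read_text().splitlines()):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{ln + 1}: GMT line needs id, description, >=1 gene")
        pid, desc, genes = parts[0], parts[1], parts[2:]
        if pid in sets:
            raise ParseError(f"{path}:{ln + 1}: duplicate pathway id {pid!r}")
        sets[pid] = (desc, frozenset(g for g in genes if g.strip()))
    return GeneSetCollection.from_sets(sets, universe)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([pid, desc] + sorted(genes))
        for pid, (desc, genes) in sorted(collection.sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_enrichment_table(path) -> EnrichmentResult:
    return EnrichmentResult(pd.read_csv(Path(path), sep="\t"))
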