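"""Component-target-pathway networks and STRING-style PPI filtering.

The tripartite network links components to the key targets they are
predicted to hit (edge weight = the component's A score) and key targets to
the pathways containing them (edge weight = the target's B score). PPI edge
lists are STRING-style TSVs whose combined score comes in two common
dialects (0-1000 integers or normalized 0-1); scores are normalized to the
0-1 scale, edges canonicalized as undirected pairs, and the confidence
filter is strictly greater-than, so a score of exactly 0.900 fails a 0.9
("highest confidence") threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .chem_profile import ComponentTable, normalize_name
from .enrichment import GeneSetCollection
from .errors import ParseError, ValidationError
from .gene_sets import GeneSet, normalize_gene
from .weighting import TargetMap, component_scores, target_scores

logger = logging.getLogger(__name__)

NODE_KINDS = {"component", "target", "pathway"}
EDGE_KINDS = {"component-target", "target-pathway", "ppi"}
_EDGE_ENDPOINTS = {
    "component-target": {"component", "target"},
    "target-pathway": {"target", "pathway"},
    "ppi": {"target"},
}


@dataclass(frozen=True)
class PpiEdgeList:
    """Undirected PPI edges with combined scores normalized to [0, 1].

    Pairs are canonicalized (a < b lexicographically) and deduplicated;
    when both A-B and B-A rows occur the higher score is kept.
    """

    rows: tuple[tuple[str, str, float], ...]

    def __post_init__(self):
        seen = set()
        for a, b, s in self.rows:
            if a >= b:
                raise ValidationError(f"PPI pair not canonical: ({a!r}, {b!r})")
            if not (0.0 <= s <= 1.0):
                raise ValidationError(f"normalized PPI score {s} not in [0, 1]")
            if (a, b) in seen:
                raise ValidationError(f"duplicate PPI pair ({a!r}, {b!r})")
            seen.add((a, b))

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[str, str, float]], scale: str = "auto"
    ) -> "PpiEdgeList":
        """Build from raw rows, normalizing scores and canonicalizing pairs.

        ``scale``: 'auto' (any score > 1 implies the 0-1000 dialect),
        'milli' (0-1000) or 'unit' (0-1).
        """
        raw = [(normalize_gene(a), normalize_gene(b), float(s)) for a, b, s in rows]
        if scale not in {"auto", "milli", "unit"}:
            raise ValidationError(f"unknown PPI score scale {scale!r}")
        scores = [s for _, _, s in raw]
        if any(s < 0 or s > 1000 for s in scores):
            raise ValidationError("PPI scores must lie in [0, 1] or [0, 1000]")
        if scale == "auto":
            scale = "milli" if any(s > 1.0 for s in scores) else "unit"
        div = 1000.0 if scale == "milli" else 1.0
        best: dict[tuple[str, str], float] = {}
        for a, b, s in raw:
            if a == b:
                raise ValidationError(f"PPI self-loop on {a!r}")
            pair = (a, b) if a < b else (b, a)
            s /= div
            if pair in best and best[pair] != s:
                logger.warning("duplicate PPI pair %s; keeping max score", pair)
            best[pair] = max(best.get(pair, 0.0), s)
        return cls(tuple(sorted((a, b, s) for (a, b), s in best.items())))

    def __len__(self) -> int:
        return len(self.rows)


def filter_ppi_edges(edges: PpiEdgeList, min_confidence: float = 0.9) -> PpiEdgeList:
    """Retain edges with normalized score strictly above ``min_confidence``."""
    if not (0.0 <= min_confidence <= 1.0):
        raise ValidationError(f"min_confidence must be in [0, 1], got {min_confidence}")
    return PpiEdgeList(tuple(r for r in edges.rows if r[2] > min_confidence))


@dataclass
class TripartiteNetwork:
    """Typed component/target/pathway graph backed by networkx."""

    graph: nx.Graph

    def __post_init__(self):
        for node, data in self.graph.nodes(data=True):
            if data.get("kind") not in NODE_KINDS:
                raise ValidationError(f"node {node!r} has invalid kind {data.get('kind')!r}")
        for u, v, data in self.graph.edges(data=True):
            kind = data.get("kind")
            if kind not in EDGE_KINDS:
                raise ValidationError(f"edge ({u!r}, {v!r}) has invalid kind {kind!r}")
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
            kinds = {self.graph.nodes[u]["kind"], self.graph.nodes[v]["kind"]}
            if kinds != _EDGE_ENDPOINTS[kind]:
                raise ValidationError(
                    f"edge ({u!r}, {v!r}) kind {kind!r} inconsistent with endpoints {kinds}"
                )
            w = data.get("weight", 0.0)
            if w < 0:
                raise ValidationError(f"edge ({u!r}, {v!r}) has negative weight")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_kind(self, kind: str) -> frozenset[str]:
        return frozenset(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == kind
        )

    def node_multiset(self) -> frozenset[tuple[str, str]]:
        return frozenset((n, d["kind"]) for n, d in self.graph.nodes(data=True))

    def edge_multiset(self) -> frozenset[tuple[str, str, str]]:
        out = set()
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.add((a, b, d["kind"]))
        return frozenset(out)


def drop_isolated_nodes(net: TripartiteNetwork) -> TripartiteNetwork:
    """Remove degree-0 nodes ("hide free proteins"); edges unchanged."""
    g = net.graph.copy()
    g.remove_nodes_from(list(nx.isolates(g)))
    return TripartiteNetwork(g)


def build_tripartite(
    table: ComponentTable,
    edges: TargetMap,
    pathways: GeneSetCollection,
    key_targets: GeneSet,
    ppi: PpiEdgeList | None = None,
) -> TripartiteNetwork:
    """Component-target(-pathway) network restricted to the key-target set.

    Component-target edges carry the component's A score (summed over table
    rows sharing the name); target-pathway edges carry the target's B.
    Only targets in ``key_targets`` become nodes; optional PPI edges are
    added between key targets present in the filtered edge list.
    """
    g = nx.Graph()
    a_by_name: dict[str, float] = {}
    for (name, _cas), score in component_scores(table).items():
        a_by_name[name] = a_by_name.get(name, 0.0) + score
    b = target_scores(table, edges) if len(edges) else {}
    keys = key_targets.genes
    for comp, target in sorted(edges.edges):
        if target not in keys:
            continue
        g.add_node(comp, kind="component")
        g.add_node(target, kind="target")
        g.add_edge(comp, target, kind="component-target", weight=a_by_name[comp])
    for pid, genes in pathways.as_gene_map().items():
        for t in sorted(genes & keys):
            if t not in g:
                g.add_node(t, kind="target")
            g.add_node(pid, kind="pathway")
            g.add_edge(t, pid, kind="target-pathway", weight=b.get(t, 0.0))
    if ppi is not None:
        for a, bb, s in ppi.rows:
            if a in keys and bb in keys:
                g.add_node(a, kind="target")
                g.add_node(bb, kind="target")
                g.add_edge(a, bb, kind="ppi", weight=s)
    return TripartiteNetwork(g)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_ppi(path, scale: str = "auto") -> PpiEdgeList:
    """STRING-style TSV ``protein_a  protein_b  combined_score``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot read PPI table {path}: {exc}") from exc
    missing = {"protein_a", "protein_b", "combined_score"} - set(df.columns)
    if missing:
        raise ParseError(f"PPI table {path} missing columns: {sorted(missing)}")
    return PpiEdgeList.from_rows(
        zip(df["protein_a"], df["protein_b"], df["combined_score"]), scale=scale
    )


def write_ppi(edges: PpiEdgeList, path, scale: str = "unit") -> None:
    rows = edges.rows
    if scale == "milli":
        rows = tuple((a, b, round(s * 1000)) for a, b, s in rows)
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"]).to_csv(
        Path(path), sep="\t", index=False
    )


def write_sif(net: TripartiteNetwork, path) -> None:
    """SIF export: ``source  interaction-kind  target`` (weights not carried).

    Edges are oriented by kind (component->target, target->pathway) so node
    kinds can be recovered on re-parse.
    """
    g = net.graph
    rows = []
    for u, v, d in g.edges(data=True):
        kind = d["kind"]
        if kind == "component-target" and g.nodes[u]["kind"] != "component":
            u, v = v, u
        elif kind == "target-pathway" and g.nodes[u]["kind"] != "target":
            u, v = v, u
        elif kind == "ppi":
            u, v = sorted((u, v))
        rows.append(f"{u}\t{kind}\t{v}")
    lines = sorted(rows)
    # isolated nodes exported as bare node lines, per SIF convention
    connected = {n for e in net.edge_multiset() for n in e[:2]}
    lines += sorted(n for n, _ in net.node_multiset() if n not in connected)
    Path(path).write_text("\n".join(lines) + "\n")


def read_sif(path, node_kinds: dict[str, str] | None = None) -> TripartiteNetwork:
    """Parse a SIF file; node kinds are inferred from edge kinds.

    Bare (isolated) node lines need ``node_kinds`` to recover their kind.
    """
    g = nx.Graph()
    for ln, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            node = parts[0]
            kind = (node_kinds or {}).get(node)
            if kind is None:
                raise ParseError(f"{path}:{ln + 1}: isolated node {node!r} needs node_kinds")
            g.add_node(node, kind=kind)
            continue
        if len(parts) != 3:
            raise ParseError(f"{path}:{ln + 1}: expected 'source kind target'")
        a, kind, b = parts
        if kind not in EDGE_KINDS:
            raise ParseError(f"{path}:{ln + 1}: unknown edge kind {kind!r}")
        if kind == "ppi":
            ka = kb = "target"
        elif kind == "component-target":
            ka, kb = "component", "target"
        else:
            ka, kb = "target", "pathway"
        g.add_node(a, kind=ka)
        g.add_node(b, kind=kb)
        g.add_edge(a, b, kind=kind, weight=0.0)
    return TripartiteNetwork(g)


def write_graphml(net: TripartiteNetwork, path) -> None:
    nx.write_graphml(net.graph, Path(path))


def read_graphml(path) -> TripartiteNetwork:
    return TripartiteNetwork(nx.read_graphml(Path(path)))
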