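"""Weight-coefficient cascade: component A, target B, pathway C.

Each component's score is A = OB * I, the product of its oral
bioavailability (fraction in [0, 1]) and its relative content I (GC peak
area percent). A target's score B is the sum of A over the components
predicted to hit it; a pathway's score C is the sum of B over its member
targets. The cascade is purely additive: a component hitting several
targets contributes its full A to each, and a compound listed under two
table rows (e.g. two isomers sharing a name but not a CAS number) hit by
the same target contributes both rows' A values.

C is a raw sum with no pathway-size normalization; downstream use is
rank-only, so the content scale (percent vs fraction) does not change
conclusions, but the percent scale is fixed here for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .chem_profile import Component, ComponentTable, normalize_name
from .errors import ParseError, ValidationError
from .gene_sets import normalize_gene


@dataclass(frozen=True)
class TargetMap:
    """Deduplicated component->target bipartite edges.

    Component names and target symbols are stored normalized; duplicate
    (component, target) pairs from merged prediction sources count once.
    """

    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs) -> "TargetMap":
        return cls(
            frozenset(
                (normalize_name(c), normalize_gene(t)) for c, t in pairs
            )
        )

    @property
    def components(self) -> frozenset[str]:
        return frozenset(c for c, _ in self.edges)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(t for _, t in self.edges)

    def targets_of(self, component_name: str) -> frozenset[str]:
        norm = normalize_name(component_name)
        return frozenset(t for c, t in self.edges if c == norm)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class WeightTable:
    """A per component row (keyed by normalized (name, CAS)), B per target, C per pathway."""

    a_scores: Mapping[tuple[str, str], float]
    b_scores: Mapping[str, float]
    c_scores: Mapping[str, float]


def component_score(ob: float, content_i: float) -> float:
    """A = OB * I."""
    if not (0.0 <= ob <= 1.0):
        raise ValidationError(f"OB must be in [0, 1], got {ob}")
    if content_i < 0:
        raise ValidationError(f"content must be >= 0, got {content_i}")
    return ob * content_i


def component_scores(table: ComponentTable) -> dict[tuple[str, str], float]:
    """A for every table row; OB must be present on every component."""
    scores: dict[tuple[str, str], float] = {}
    for c in table:
        if c.oral_bioavailability is None:
            raise ValidationError(
                f"component {c.name!r} has no OB; OB is caller-supplied, never imputed"
            )
        scores[c.key] = component_score(c.oral_bioavailability, c.area_pct)
    return scores


def target_scores(table: ComponentTable, edges: TargetMap) -> dict[str, float]:
    """B(t) = sum of A over components linked to t.

    An edge names a component by (normalized) name; every table row sharing
    that name contributes its A. Targets with no edges are absent from the
    result (not zero-filled). Edges naming a component missing from the
    table raise a ValidationError naming it.
    """
    a = component_scores(table)
    names = table.names
    dangling = sorted(edges.components - names)
    if dangling:
        raise ValidationError(f"target map references unknown components: {dangling}")
    a_by_name: dict[str, float] = {}
    for (name, _cas), score in a.items():
        a_by_name[name] = a_by_name.get(name, 0.0) + score
    b: dict[str, float] = {}
    for comp, target in edges.edges:
        b[target] = b.get(target, 0.0) + a_by_name[comp]
    return b


def pathway_scores(
    b: Mapping[str, float], pathways: Mapping[str, frozenset[str]]
) -> dict[str, float]:
    """C(p) = sum of B over the pathway's targets present in ``b``.

    ``pathways`` maps pathway id -> gene symbols; genes without a B score
    contribute 0. Every pathway id appears in the result (possibly 0).
    """
    return {
        pid: float(sum(b.get(normalize_gene(g), 0.0) for g in genes))
        for pid, genes in pathways.items()
    }


def compute_weights(
    table: ComponentTable,
    edges: TargetMap,
    pathways: Mapping[str, frozenset[str]],
) -> WeightTable:
    a = component_scores(table)
    b = target_scores(table, edges)
    c = pathway_scores(b, pathways)
    return WeightTable(a_scores=a, b_scores=b, c_scores=c)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_target_map(path) -> TargetMap:
    """TSV ``component  target``; ``#`` comments and a header row tolerated."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    for ln, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{ln + 1}: expected 2 tab-separated fields")
        if ln == 0 and parts[0].lower() == "component" and parts[1].lower() == "target":
            continue
        pairs.append((parts[0], parts[1]))
    return TargetMap.from_pairs(pairs)


def write_target_map(edges: TargetMap, path) -> None:
    lines = ["component\ttarget"]
    lines += [f"{c}\t{t}" for c, t in sorted(edges.edges)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_weight_tables(weights: WeightTable, out_dir) -> dict[str, Path]:
    """TSV reports (component A / target B / pathway C), sorted descending."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    a_df = pd.DataFrame(
        [(name, cas, v) for (name, cas), v in weights.a_scores.items()],
        columns=["component", "cas", "A"],
    ).sort_values(["A", "component"], ascending=[False, True])
    paths["a"] = out_dir / "component_A.tsv"
    a_df.to_csv(paths["a"], sep="\t", index=False)
    b_df = pd.DataFrame(
        sorted(weights.b_scores.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["target", "B"],
    )
    paths["b"] = out_dir / "target_B.tsv"
    b_df.to_csv(paths["b"], sep="\t", index=False)
    c_df = pd.DataFrame(
        sorted(weights.c_scores.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["pathway", "C"],
    )
    paths["c"] = out_dir / "pathway_C.tsv"
    c_df.to_csv(paths["c"], sep="\t", index=False)
    return paths
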