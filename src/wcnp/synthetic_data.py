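"""Seeded generator for a complete, internally consistent input bundle.

The generator emulates the statistical shape of a small network-pharmacology
study: a ~20-component essential-oil profile with one dominant constituent
(contents drawn from a symmetric Dirichlet and scaled to 100%), uniform oral
bioavailabilities, a component->target bipartite map, a disease gene list, a
differential-expression table in which a stated fraction of the universe
passes the default thresholds, a pathway collection (GMT) and a STRING-style
PPI edge list.

One pathway is *planted*: its member key targets are wired to the
highest-scoring components so that its weight coefficient C exceeds every
other pathway's by construction, while several decoy pathways carry larger
raw overlaps with the key-target query and therefore outrank it in the
unweighted over-representation analysis. Re-ranking by C should promote the
planted pathway to the top — that promotion, not the enrichment itself, is
what downstream tests exercise.

A manifest records every planted ground-truth quantity, with A/B/C computed
by an independent brute-force triple loop kept separate from the pipeline's
weighting code path.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem_profile as cp
from . import enrichment as en
from . import gene_sets as gs
from . import network as nw
from . import weighting as wt
from .errors import ValidationError


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the stated study-like world."""

    seed: int = 0
    n_components: int = 20
    n_targets: int = 60
    n_pathways: int = 25
    pathway_size_range: tuple[int, int] = (10, 40)
    universe_size: int = 500
    frac_de: float = 0.1
    n_key_targets: int = 26
    n_planted_targets: int = 6
    n_decoy_pathways: int = 4
    planted_pathway_id: str = "PW_PLANTED"
    planted_weight_boost: float = 4.0
    planted_de_shift: float = 2.0
    content_concentration: float = 0.5
    ob_range: tuple[float, float] = (0.2, 0.9)

    def validate(self) -> None:
        if self.n_components <= 0 or self.n_targets <= 0 or self.n_pathways <= 0:
            raise ValidationError("counts must be positive")
        if self.universe_size < self.n_targets + int(self.frac_de * self.universe_size):
            raise ValidationError("universe too small for targets plus DE genes")
        if not (0.0 <= self.frac_de <= 1.0):
            raise ValidationError("frac_de must be in [0, 1]")
        lo, hi = self.ob_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("ob_range must satisfy 0 <= lo <= hi <= 1")
        lo_p, hi_p = self.pathway_size_range
        if not (1 <= lo_p <= hi_p <= self.universe_size):
            raise ValidationError("pathway_size_range inconsistent with universe")
        if self.planted_weight_boost < 1.0:
            raise ValidationError("planted_weight_boost must be >= 1")
        if self.n_key_targets > self.n_targets:
            raise ValidationError("n_key_targets cannot exceed n_targets")
        if self.n_planted_targets > self.n_key_targets:
            raise ValidationError("n_planted_targets cannot exceed n_key_targets")
        if self.n_decoy_pathways + 1 > self.n_pathways:
            raise ValidationError("need n_pathways > n_decoy_pathways")
        if round(self.frac_de * self.universe_size) < self.n_key_targets:
            raise ValidationError("frac_de too small to cover the key targets")
        if self.content_concentration <= 0:
            raise ValidationError("content_concentration must be > 0")


@dataclass
class Bundle:
    """In-memory input bundle plus the ground-truth manifest."""

    component_table: cp.ComponentTable
    ladder: cp.AlkaneLadder
    target_map: wt.TargetMap
    disease_genes: gs.GeneSet
    de_table: gs.DiffExprTable
    pathways: en.GeneSetCollection
    ppi: nw.PpiEdgeList
    manifest: dict


FILE_NAMES = {
    "components": "components.csv",
    "ladder": "alkane_ladder.csv",
    "target_map": "target_map.tsv",
    "disease": "disease_genes.txt",
    "de_table": "de_table.tsv",
    "gmt": "pathways.gmt",
    "ppi": "ppi_edges.tsv",
    "manifest": "manifest.json",
}


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def generate(config: SimConfig) -> Bundle:
    """Generate the full bundle in memory; deterministic given config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- alkane ladder (C8..C24, strictly increasing retention times) -------
    carbons = list(range(8, 25))
    increments = rng.uniform(1.5, 3.0, size=len(carbons))
    times = 5.0 + np.cumsum(increments)
    ladder = cp.AlkaneLadder(tuple(zip(carbons, np.round(times, 4))))

    # --- component table -----------------------------------------------------
    contents = rng.dirichlet(
        np.full(config.n_components, config.content_concentration)
    ) * 100.0
    obs = rng.uniform(*config.ob_range, size=config.n_components)
    rts = np.sort(rng.uniform(ladder.t_min, ladder.t_max, size=config.n_components))
    components = tuple(
        cp.Component(
            name=f"compound-{i + 1:02d}",
            cas=f"{100000 + i}-00-{i % 10}",
            retention_time=float(round(rts[i], 4)),
            area_pct=float(round(contents[i], 6)),
            oral_bioavailability=float(round(obs[i], 4)),
        )
        for i in range(config.n_components)
    )
    table = cp.ComponentTable(components)
    a_by_name = {
        cp.normalize_name(c.name): c.oral_bioavailability * c.area_pct
        for c in components
    }
    top_components = sorted(a_by_name, key=lambda k: (-a_by_name[k], k))

    # --- gene universe, targets, key targets ---------------------------------
    universe = _gene_names(config.universe_size)
    targets = sorted(rng.choice(universe, size=config.n_targets, replace=False))
    key_targets = sorted(
        rng.choice(targets, size=config.n_key_targets, replace=False)
    )
    planted_targets = sorted(
        rng.choice(key_targets, size=config.n_planted_targets, replace=False)
    )
    other_key = [t for t in key_targets if t not in planted_targets]

    # --- bipartite target map -------------------------------------------------
    # baseline: every target hit by 1-3 random components
    names = sorted(a_by_name)
    edges: set[tuple[str, str]] = set()
    for t in targets:
        k = int(rng.integers(1, 4))
        for c in rng.choice(names, size=k, replace=False):
            edges.add((str(c), t))
    # planted boost: wire planted targets to the top-A components
    n_boost = int(round(config.planted_weight_boost)) - 1
    if n_boost > 0:
        for t in planted_targets:
            for c in top_components[:n_boost]:
                edges.add((c, t))

    # --- DE table --------------------------------------------------------------
    n_de = int(round(config.frac_de * config.universe_size))
    non_target_pool = [g for g in universe if g not in set(targets)]
    extra_de = sorted(
        rng.choice(non_target_pool, size=n_de - config.n_key_targets, replace=False)
    )
    signal = set(key_targets) | set(extra_de)
    rows = []
    for g in universe:
        if g in signal:
            lfc = (config.planted_de_shift + abs(rng.normal(0.0, 0.5))) * rng.choice([-1.0, 1.0])
            fdr = rng.uniform(0.0, 0.04)
        else:
            lfc = rng.normal(0.0, 0.3)
            fdr = rng.uniform(0.05, 1.0)
        rows.append((g, round(float(lfc), 6), round(float(fdr), 8)))
    de_table = gs.DiffExprTable(pd.DataFrame(rows, columns=["gene", "log2fc", "fdr"]))

    # --- disease gene list -------------------------------------------------------
    n_disease_extra = config.universe_size // 3
    disease_pool = [g for g in universe if g not in set(key_targets)]
    disease_extra = rng.choice(disease_pool, size=n_disease_extra, replace=False)
    disease = gs.GeneSet.from_symbols(
        "disease", sorted(set(key_targets) | set(map(str, disease_extra)))
    )

    # --- pathway collection -------------------------------------------------------
    lo_p, hi_p = config.pathway_size_range
    # filler genes exclude planted targets so only the planted pathway carries them
    filler_pool = [g for g in universe if g not in set(planted_targets)]
    sets: dict[str, tuple[str, frozenset[str]]] = {}

    size = int(rng.integers(lo_p, hi_p + 1))
    n_fill = max(0, size - len(planted_targets))
    fill = rng.choice(
        [g for g in filler_pool if g not in set(key_targets)], size=n_fill, replace=False
    )
    sets[config.planted_pathway_id] = (
        "planted pathway (high weight coefficient)",
        frozenset(planted_targets) | frozenset(map(str, fill)),
    )

    for d in range(config.n_decoy_pathways):
        size = int(rng.integers(lo_p, hi_p + 1))
        n_keys = min(len(other_key), max(config.n_planted_targets + 4, size // 2))
        keys = rng.choice(other_key, size=n_keys, replace=False)
        n_fill = max(0, size - n_keys)
        fill = rng.choice(
            [g for g in filler_pool if g not in set(other_key)],
            size=n_fill, replace=False,
        )
        sets[f"PW_DECOY_{d + 1:02d}"] = (
            f"decoy pathway {d + 1} (large overlap, low weight)",
            frozenset(map(str, keys)) | frozenset(map(str, fill)),
        )

    n_random = config.n_pathways - 1 - config.n_decoy_pathways
    for r in range(n_random):
        size = int(rng.integers(lo_p, hi_p + 1))
        genes = rng.choice(filler_pool, size=size, replace=False)
        sets[f"PW_RAND_{r + 1:02d}"] = (
            f"background pathway {r + 1}",
            frozenset(map(str, genes)),
        )
    pathways = en.GeneSetCollection.from_sets(sets, universe=frozenset(universe))

    # Guarantee (boost > 1 only): planted C strictly exceeds every other
    # pathway's C. Planted targets appear in no other pathway, so wiring
    # them to further top components raises only the planted C; the loop
    # is deterministic and terminates once the margin is achieved or the
    # component list is exhausted.
    if config.planted_weight_boost > 1.0:
        gene_map = pathways.as_gene_map()

        def _c_scores() -> dict[str, float]:
            b: dict[str, float] = {}
            for comp, t in edges:
                b[t] = b.get(t, 0.0) + a_by_name[cp.normalize_name(comp)]
            return {
                pid: sum(b.get(g, 0.0) for g in genes)
                for pid, genes in gene_map.items()
            }

        next_idx = n_boost
        while next_idx < len(top_components):
            c_now = _c_scores()
            planted_c = c_now[config.planted_pathway_id]
            rival = max(v for p, v in c_now.items() if p != config.planted_pathway_id)
            if planted_c > rival:
                break
            for t in planted_targets:
                edges.add((top_components[next_idx], t))
            next_idx += 1
    target_map = wt.TargetMap.from_pairs(sorted(edges))

    # --- PPI edges ----------------------------------------------------------------
    ppi_rows: dict[tuple[str, str], int] = {}
    n_background = 150
    for _ in range(n_background):
        a, b = rng.choice(targets, size=2, replace=False)
        pair = (str(min(a, b)), str(max(a, b)))
        ppi_rows.setdefault(pair, int(rng.integers(0, 1001)))
    for i, a in enumerate(planted_targets):
        for b in planted_targets[i + 1:]:
            pair = (min(a, b), max(a, b))
            ppi_rows[pair] = int(rng.integers(901, 1001))
    ppi = nw.PpiEdgeList.from_rows(
        [(a, b, s) for (a, b), s in sorted(ppi_rows.items())], scale="milli"
    )

    # --- ground-truth manifest (independent brute-force oracle) --------------------
    manifest = _build_manifest(
        config, table, target_map, pathways, key_targets, planted_targets, signal
    )
    return Bundle(
        component_table=table,
        ladder=ladder,
        target_map=target_map,
        disease_genes=disease,
        de_table=de_table,
        pathways=pathways,
        ppi=ppi,
        manifest=manifest,
    )


def _brute_force_weights(
    table: cp.ComponentTable,
    target_map: wt.TargetMap,
    pathways: en.GeneSetCollection,
) -> tuple[dict, dict, dict]:
    """Straightforward triple loop over (component, target, pathway) incidences.

    Kept deliberately independent of wcnp.weighting: plain loops, no shared
    helpers beyond name normalization.
    """
    a: dict[str, float] = {}
    for comp in table:
        key = f"{comp.name}|{comp.cas}"
        a[key] = comp.oral_bioavailability * comp.area_pct
    b: dict[str, float] = {}
    for comp_name, target in target_map.edges:
        total = 0.0
        for comp in table:
            if cp.normalize_name(comp.name) == comp_name:
                total += comp.oral_bioavailability * comp.area_pct
        b[target] = b.get(target, 0.0) + total
    c: dict[str, float] = {}
    for pid, genes in pathways.as_gene_map().items():
        total = 0.0
        for t, score in b.items():
            if t in genes:
                total += score
        c[pid] = total
    return a, b, c


def _build_manifest(config, table, target_map, pathways, key_targets,
                    planted_targets, signal) -> dict:
    a, b, c = _brute_force_weights(table, target_map, pathways)
    c_rank = sorted(c, key=lambda p: (-c[p], p))
    n_de = int(round(config.frac_de * config.universe_size))
    return {
        "config": dataclasses.asdict(config),
        "planted_pathway_id": config.planted_pathway_id,
        "planted_targets": list(planted_targets),
        "key_targets": list(key_targets),
        "de_signal_genes": sorted(signal),
        "expected_deg_count": {"min": n_de, "max": n_de},
        "deg_thresholds": {"fdr_max": 0.05, "lfc_min": 1.0},
        "true_a": a,
        "true_b": b,
        "true_c": c,
        "c_ranking": c_rank,
        "planted_c_is_max": c_rank[0] == config.planted_pathway_id,
        "pathway_ids": sorted(pathways.as_gene_map()),
    }


def generate_bundle(config: SimConfig, out_dir) -> dict[str, Path]:
    """Generate and write the bundle files; returns the path map.

    Byte-identical output for identical configs (fixed float formatting,
    sorted orderings, no global random state).
    """
    bundle = generate(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: out_dir / v for k, v in FILE_NAMES.items()}
    cp.write_component_table(bundle.component_table, paths["components"])
    cp.write_alkane_ladder(bundle.ladder, paths["ladder"])
    wt.write_target_map(bundle.target_map, paths["target_map"])
    gs.write_gene_list(bundle.disease_genes, paths["disease"])
    gs.write_de_table(bundle.de_table, paths["de_table"])
    en.write_gmt(bundle.pathways, paths["gmt"])
    nw.write_ppi(bundle.ppi, paths["ppi"], scale="milli")
    paths["manifest"].write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n"
    )
    return paths


def ground_truth(config: SimConfig) -> dict:
    """Regenerate the bundle and return the ground-truth manifest only."""
    return generate(config).manifest
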