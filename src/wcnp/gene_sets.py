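"""Gene identifiers, DEG threshold filtering and set intersections.

Differentially expressed genes (DEGs) are selected from a precomputed
differential-expression table by an FDR cut (strict ``<`` by default) and a
|log2 fold-change| cut (inclusive ``>=`` by default); both boundary
semantics are explicit configuration because published criteria are often
ambiguous. The key-target set of a multi-component preparation is the
three-way intersection of predicted component targets, disease genes and
DEGs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)


def normalize_gene(symbol: str) -> str:
    """Trim and upper-case; no alias or ortholog mapping."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    label: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.label:
            raise ValidationError("gene-set label must be non-empty")

    @classmethod
    def from_symbols(cls, label: str, symbols: Iterable[str]) -> "GeneSet":
        return cls(label, frozenset(normalize_gene(s) for s in symbols if s.strip()))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return normalize_gene(symbol) in self.genes


@dataclass(frozen=True)
class DiffExprTable:
    """Rows of (gene, log2fc, fdr); one row per normalized gene."""

    frame: pd.DataFrame  # columns: gene, log2fc, fdr

    def __post_init__(self):
        df = self.frame
        missing = {"gene", "log2fc", "fdr"} - set(df.columns)
        if missing:
            raise ParseError(f"DE table missing columns: {sorted(missing)}")
        genes = df["gene"].map(normalize_gene)
        dup = genes[genes.duplicated()]
        if not dup.empty:
            raise ValidationError(
                f"duplicate gene rows after normalization: {sorted(set(dup))[:5]}"
            )
        if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
            raise ValidationError("fdr values must lie in [0, 1]")
        object.__setattr__(
            self,
            "frame",
            pd.DataFrame(
                {"gene": genes, "log2fc": df["log2fc"].astype(float),
                 "fdr": df["fdr"].astype(float)}
            ).reset_index(drop=True),
        )

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class DegResult:
    selected: GeneSet
    n_up: int
    n_down: int
    thresholds: tuple[float, float]  # (fdr_max, lfc_min)

    def __post_init__(self):
        if self.n_up + self.n_down != len(self.selected):
            raise ValidationError("n_up + n_down must equal |selected|")


def select_degs(
    table: DiffExprTable,
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
    *,
    fdr_strict: bool = True,
    lfc_inclusive: bool = True,
) -> DegResult:
    """Threshold filter: fdr < fdr_max (strict by default) and |log2fc| >= lfc_min.

    Genes with log2fc == 0 are neither up nor down and are excluded from the
    selection (with a warning if they otherwise pass the thresholds).
    """
    if not (0.0 < fdr_max <= 1.0):
        raise ValidationError(f"fdr_max must be in (0, 1], got {fdr_max}")
    if lfc_min < 0:
        raise ValidationError(f"lfc_min must be >= 0, got {lfc_min}")
    df = table.frame
    fdr_ok = df["fdr"] < fdr_max if fdr_strict else df["fdr"] <= fdr_max
    lfc = df["log2fc"].abs()
    lfc_ok = lfc >= lfc_min if lfc_inclusive else lfc > lfc_min
    passed = df[fdr_ok & lfc_ok]
    zero = passed[passed["log2fc"] == 0]
    if not zero.empty:
        logger.warning(
            "%d gene(s) pass thresholds with log2fc == 0; excluded from DEG set",
            len(zero),
        )
        passed = passed[passed["log2fc"] != 0]
    n_up = int((passed["log2fc"] > 0).sum())
    n_down = int((passed["log2fc"] < 0).sum())
    return DegResult(
        selected=GeneSet.from_symbols("degs", passed["gene"]),
        n_up=n_up,
        n_down=n_down,
        thresholds=(fdr_max, lfc_min),
    )


def three_way_intersection(
    component_targets: GeneSet, disease_genes: GeneSet, degs: GeneSet
) -> GeneSet:
    """Set-theoretic intersection yielding the key-target set."""
    genes = component_targets.genes & disease_genes.genes & degs.genes
    return GeneSet("key_targets", frozenset(genes))


VENN_REGIONS = ("100", "010", "001", "110", "101", "011", "111")


def venn_counts(a: GeneSet, b: GeneSet, c: GeneSet) -> dict[str, int]:
    """Exclusive three-set Venn region counts, keyed by membership pattern.

    Key "abc" has '1' where the gene belongs to (a, b, c) respectively;
    the seven counts sum to |a ∪ b ∪ c|.
    """
    counts = dict.fromkeys(VENN_REGIONS, 0)
    for g in a.genes | b.genes | c.genes:
        key = f"{int(g in a.genes)}{int(g in b.genes)}{int(g in c.genes)}"
        counts[key] += 1
    return counts


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_de_table(path) -> DiffExprTable:
    """TSV with header ``gene  log2fc  fdr``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot read DE table {path}: {exc}") from exc
    return DiffExprTable(df)


def write_de_table(table: DiffExprTable, path) -> None:
    table.frame.to_csv(Path(path), sep="\t", index=False)


def read_gene_list(path, label: str | None = None) -> GeneSet:
    """One symbol per line or TSV first column; ``#`` comments ignored."""
    path = Path(path)
    symbols: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbols.append(line.split("\t")[0])
    return GeneSet.from_symbols(label or path.stem, symbols)


def write_gene_list(genes: GeneSet, path) -> None:
    Path(path).write_text("\n".join(sorted(genes.genes)) + "\n")
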