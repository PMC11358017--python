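"""Plain-text input/output: GMT gene sets, expression matrices, label tables.

All tabular files are TSV. Expression matrices are genes x samples with the
gene identifier in the first column; label tables have columns ``sample`` and
``response`` with values ``responder`` / ``nonresponder``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (one GMT line)."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set needs a name")
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str], description: str = "") -> "GeneSet":
        genes = list(genes)
        unique = frozenset(genes)
        if len(unique) != len(genes):
            raise ValueError(f"gene set {name!r} contains duplicate ids")
        return cls(name=name, genes=unique, description=description)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
        sets.append(GeneSet.from_iterable(fields[0], fields[2:], description=fields[1]))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = []
    for s in sets:
        lines.append("\t".join([s.name, s.description, *sorted(s.genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Genes x samples log-expression matrix from TSV (first column = gene id)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    return mat.astype(float)


def read_labels(path: str | Path) -> pd.Series:
    """Sample -> response label series from a two-column TSV."""
    tab = pd.read_csv(path, sep="\t")
    required = {"sample", "response"}
    if not required.issubset(tab.columns):
        raise ValueError(f"label table must have columns {sorted(required)}")
    return tab.set_index("sample")["response"].astype(str)


def read_celltype_means(path: str | Path) -> pd.DataFrame:
    """Long table with columns dataset, gene, cell_type, mean_expr."""
    tab = pd.read_csv(path, sep="\t")
    required = {"dataset", "gene", "cell_type", "mean_expr"}
    if not required.issubset(tab.columns):
        raise ValueError(f"cell-type mean table must have columns {sorted(required)}")
    return tab


def read_dose_response(path: str | Path) -> pd.DataFrame:
    """Dose-response TSV with columns concentration_M, replicate, response."""
    tab = pd.read_csv(path, sep="\t")
    required = {"concentration_M", "replicate", "response"}
    if not required.issubset(tab.columns):
        raise ValueError(f"dose-response table must have columns {sorted(required)}")
    return tab
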