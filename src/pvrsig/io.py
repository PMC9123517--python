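"""Readers and writers for the pipeline's plain-text interchange formats.

Counts matrices and ranked signatures travel as TSV, gene sets as GMT,
interaction networks as three-column edge lists, drug catalogs and cell
matrices as CSV. All writers emit deterministic output (stable row order,
fixed float formatting) so that repeated runs under the same seed are
byte-identical.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from pathlib import Path

import pandas as pd

from .signature import GeneSet, RankedSignature

FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: ``name TAB description TAB gene1 TAB gene2 ...``."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
        sets.append(GeneSet(name, frozenset(genes)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path, description: str = "na") -> None:
    lines = []
    for gs in sets:
        lines.append("\t".join([gs.name, description, *sorted(gs.members)]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- counts / labels

def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene×sample integer count matrix; first column = gene ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FORMAT)


def read_groups(path: str | Path) -> pd.Series:
    """Sample→group labels from a two-column CSV (sample, group)."""
    frame = pd.read_csv(path)
    return pd.Series(frame.iloc[:, 1].values, index=frame.iloc[:, 0].astype(str))


def write_groups(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample": groups.index, "group": groups.values}).to_csv(path, index=False)


# ---------------------------------------------------------------- DE / signature

def read_de_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"gene", "log2fc", "p", "padj"} - set(frame.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return frame


def write_de_table(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_signature(path: str | Path) -> RankedSignature:
    frame = pd.read_csv(path, sep="\t")
    return RankedSignature(frame["gene"].tolist(), frame["score"].to_numpy())


def write_signature(signature: RankedSignature, path: str | Path) -> None:
    signature.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------- cell matrix

def read_cell_matrix(path: str | Path):
    """Cell×marker CSV with mandatory ``sample`` and ``entity`` columns."""
    from .imc import CellMatrix

    frame = pd.read_csv(path)
    for col in ("sample", "entity"):
        if col not in frame.columns:
            raise ValueError(f"cell matrix needs a {col!r} column")
    markers = [c for c in frame.columns if c not in ("sample", "entity")]
    return CellMatrix(
        intensities=frame[markers].astype(float),
        sample=frame["sample"].astype(str),
        entity=frame["entity"].astype(str),
    )


def write_cell_matrix(matrix, path: str | Path) -> None:
    frame = matrix.intensities.copy()
    frame.insert(0, "entity", matrix.entity.values)
    frame.insert(0, "sample", matrix.sample.values)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------- misc tables

def write_table(frame: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    frame.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")
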