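"""Interaction-network filtering of the disease signature.

Signature genes are retained only if they have at least one known
interaction with another signature gene in a STRING-style scored edge
list — the rationale being that well-connected, pathway-embedded genes
are the more credible therapeutic targets. Degree is counted within the
induced subgraph on the signature, not against the whole proteome.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable
from pathlib import Path

import networkx as nx
import pandas as pd

from .signature import GeneSet

__all__ = ["InteractionNetwork", "load_string_edges", "filter_by_interaction"]


class InteractionNetwork:
    """Undirected scored gene-gene interaction network.

    Wraps a :class:`networkx.Graph`; edges carry a ``combined_score`` in
    [0, 1000] (the STRING convention). Self-loops are rejected and
    symmetric duplicates collapse onto a single edge.
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]] = ()):
        self.graph = nx.Graph()
        for a, b, score in edges:
            self.add_edge(a, b, score)

    def add_edge(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        if not 0 <= score <= 1000:
            raise ValueError(f"combined_score {score} outside [0, 1000]")
        self.graph.add_edge(a, b, combined_score=float(score))

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree_within(self, genes: Iterable[str]) -> dict[str, int]:
        """Degree of each gene in the induced subgraph on ``genes``."""
        genes = set(genes)
        sub = self.graph.subgraph(genes & set(self.graph.nodes))
        return {g: (sub.degree(g) if g in sub else 0) for g in genes}

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_a": min(a, b), "gene_b": max(a, b), "combined_score": d["combined_score"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        frame = pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"])
        return frame.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def load_string_edges(path: str | Path, score_threshold: float = 400.0) -> InteractionNetwork:
    """Read a STRING-style edge list TSV (gene_a, gene_b, combined_score).

    A header row is auto-detected (non-numeric third field). Edges below
    ``score_threshold`` are discarded; self-loops are dropped with a
    warning; symmetric duplicates collapse (the last score read wins).
    """
    network = InteractionNetwork()
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        a, b, raw_score = fields[0], fields[1], fields[2]
        try:
            score = float(raw_score)
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise ValueError(f"{path}:{lineno}: non-numeric combined_score {raw_score!r}")
        if a == b:
            warnings.warn(f"{path}:{lineno}: self-loop on {a!r} dropped", UserWarning, stacklevel=2)
            continue
        if score >= score_threshold:
            network.add_edge(a, b, score)
    return network


def filter_by_interaction(
    genes: GeneSet, network: InteractionNetwork, min_degree: int = 1
) -> GeneSet:
    """Retain genes with >= ``min_degree`` interactions among themselves.

    The degree is computed on the subgraph induced by ``genes``: an edge
    to a gene outside the signature does not count. Orphan genes (no
    qualifying interaction) are removed.
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    degrees = network.degree_within(genes.members)
    kept = frozenset(g for g, d in degrees.items() if d >= min_degree)
    return GeneSet(genes.name, kept)
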