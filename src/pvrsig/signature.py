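"""Disease-signature construction from bulk expression data.

Builds the ranked disease signature that drives the drug-repurposing
screen: an internal two-group differential-expression stand-in on raw
counts, DEG filtering at effect-size and FDR thresholds, log2-fold-change
ranking, TPM normalization for cell-type scoring, hypergeometric
over-representation, and Benjamini-Hochberg adjustment.

The internal DE routine is a deliberately simple approximation (median-of-
ratios size factors, pseudocounted fold changes, Welch test on
log-normalized counts); reproducing a full negative-binomial GLM fit is a
non-goal. Externally computed DE tables with columns ``gene``, ``log2fc``,
``p``, ``padj`` are accepted everywhere a DE table is.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "RankedSignature",
    "compute_tpm",
    "internal_de",
    "filter_degs",
    "rank_signature",
    "ora_hypergeometric",
    "bh_adjust",
]

DE_COLUMNS = ("gene", "log2fc", "p", "padj")


@dataclasses.dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers.

    Members are stored as a frozenset; iteration is in sorted order so
    that every downstream consumer sees a deterministic gene order.
    Empty member sets are permitted for operation outputs (e.g. a DEG
    filter that matches nothing); gene sets read from GMT are always
    non-empty.
    """

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.name:
            raise ValueError("gene set name must be non-empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: object) -> bool:
        return gene in self.members

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))

    def intersection(self, genes: Iterable[str]) -> frozenset[str]:
        return self.members.intersection(genes)


class RankedSignature:
    """Genes ordered by descending score (log2 fold change, disease vs control).

    Ties in the score are broken lexicographically by gene id so the
    ranking is reproducible regardless of input order. Direction labels
    are ``up`` for positive scores and ``down`` otherwise.
    """

    def __init__(self, genes: Iterable[str], scores: Iterable[float]):
        genes = list(genes)
        scores = np.asarray(list(scores), dtype=float)
        if len(genes) != len(scores):
            raise ValueError("genes and scores must have equal length")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene ids in signature")
        order = np.lexsort((genes, -scores))
        self.genes: list[str] = [genes[i] for i in order]
        self.scores: np.ndarray = scores[order]
        self._rank = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in self._rank

    def rank_of(self, gene: str) -> int:
        """0-based position of ``gene`` in the ranking."""
        return self._rank[gene]

    @property
    def directions(self) -> list[str]:
        return ["up" if s > 0 else "down" for s in self.scores]

    def top(self, n: int) -> list[str]:
        return self.genes[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "score": self.scores})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RankedSignature":
        return cls(frame["gene"].tolist(), frame["score"].to_numpy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"RankedSignature(n={len(self)})"


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series | np.ndarray) -> pd.DataFrame:
    """Transcripts-per-million normalization of a gene×sample count matrix.

    Per sample: ``rate_g = count_g / (length_g / 1000)`` and
    ``TPM_g = rate_g / sum(rate) * 1e6``, so every column sums to one
    million unless the sample has no reads at all (all-zero column is
    passed through with a warning).
    """
    lengths = pd.Series(np.asarray(lengths, dtype=float), index=counts.index)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be strictly positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rate = counts.div(lengths / 1_000.0, axis=0)
    totals = rate.sum(axis=0)
    zero_cols = totals[totals == 0].index
    if len(zero_cols):
        warnings.warn(
            f"samples with all-zero counts left as all-zero TPM: {list(zero_cols)}",
            UserWarning,
            stacklevel=2,
        )
    totals = totals.replace(0, np.nan)
    tpm = rate.div(totals, axis=1) * 1e6
    return tpm.fillna(0.0)


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (reference = per-gene geometric mean)."""
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    usable = np.all(np.isfinite(log_counts), axis=1)
    if not usable.any():
        # degenerate matrix: fall back to library-size scaling
        totals = counts.sum(axis=0)
        return totals / np.exp(np.mean(np.log(totals)))
    log_gm = log_counts[usable].mean(axis=1)
    log_sf = np.median(log_counts[usable] - log_gm[:, None], axis=0)
    return np.exp(log_sf)


def internal_de(
    counts: pd.DataFrame,
    groups: pd.Series | Iterable[str],
    *,
    disease: str | None = None,
    control: str | None = None,
) -> pd.DataFrame:
    """Two-group differential expression stand-in on raw counts.

    Normalizes by median-of-ratios size factors, reports
    ``log2fc = log2((mean_norm_disease + 0.5) / (mean_norm_control + 0.5))``
    and a Welch (unequal-variance) test on ``log2(normalized + 1)``;
    ``padj`` is Benjamini-Hochberg over the genes actually tested. Genes
    with zero counts in every sample are excluded from testing and carry
    ``log2fc = 0``, ``p = padj = 1``.

    When ``disease``/``control`` are omitted the two group labels are
    taken in sorted order as (control, disease).

    Returns a DataFrame with columns ``gene``, ``base_mean``, ``log2fc``,
    ``p``, ``padj``.
    """
    groups = pd.Series(list(groups), index=counts.columns)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    if control is None and disease is None:
        control, disease = labels
    elif control is None or disease is None:
        raise ValueError("give both disease and control labels, or neither")
    if {disease, control} != set(labels):
        raise ValueError("disease/control labels do not match the group column")
    n_d = int((groups == disease).sum())
    n_c = int((groups == control).sum())
    if min(n_d, n_c) < 2:
        raise ValueError("each group needs at least two samples")

    mat = counts.to_numpy(dtype=float)
    if not np.allclose(mat, np.round(mat)):
        warnings.warn("non-integer counts supplied to internal_de", UserWarning, stacklevel=2)

    sf = _size_factors(mat)
    norm = mat / sf
    d_cols = (groups == disease).to_numpy()
    c_cols = (groups == control).to_numpy()
    mean_d = norm[:, d_cols].mean(axis=1)
    mean_c = norm[:, c_cols].mean(axis=1)
    base_mean = norm.mean(axis=1)
    log2fc = np.log2((mean_d + 0.5) / (mean_c + 0.5))

    expressed = mat.sum(axis=1) > 0
    log2fc[~expressed] = 0.0

    log_norm = np.log2(norm + 1.0)
    p = np.ones(len(counts))
    if expressed.any():
        res = stats.ttest_ind(
            log_norm[np.ix_(expressed, d_cols)],
            log_norm[np.ix_(expressed, c_cols)],
            axis=1,
            equal_var=False,
        )
        p_tested = np.nan_to_num(res.pvalue, nan=1.0)
        p[expressed] = p_tested
    padj = np.ones(len(counts))
    if expressed.any():
        padj[expressed] = bh_adjust(p[expressed])
    return pd.DataFrame(
        {
            "gene": counts.index.astype(str),
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
        }
    ).reset_index(drop=True)


def filter_degs(
    records: pd.DataFrame, lfc_thresh: float = 2.0, alpha: float = 0.05
) -> tuple[GeneSet, GeneSet]:
    """Split a DE table into up-/down-regulated DEG sets.

    Strict inequalities: up means ``log2fc > lfc_thresh`` and
    ``padj < alpha``; down means ``log2fc < -lfc_thresh`` and
    ``padj < alpha``. Boundary values are excluded.
    """
    if lfc_thresh <= 0 or alpha <= 0:
        raise ValueError("thresholds must be positive")
    up = records.loc[(records["log2fc"] > lfc_thresh) & (records["padj"] < alpha), "gene"]
    down = records.loc[(records["log2fc"] < -lfc_thresh) & (records["padj"] < alpha), "gene"]
    return GeneSet("up", frozenset(up)), GeneSet("down", frozenset(down))


def rank_signature(records: pd.DataFrame, expressed_only: bool = True) -> RankedSignature:
    """Order a DE table by descending log2 fold change into a signature.

    With ``expressed_only`` and a ``base_mean`` column present, genes with
    zero normalized mean (zero reads in all samples) are dropped first.
    Ties are broken lexicographically by gene id.
    """
    if records["gene"].duplicated().any():
        dupes = records.loc[records["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    frame = records
    if expressed_only and "base_mean" in frame.columns:
        frame = frame[frame["base_mean"] > 0]
    return RankedSignature(frame["gene"].tolist(), frame["log2fc"].to_numpy())


def ora_hypergeometric(
    query: GeneSet, annotation: GeneSet, universe: Iterable[str]
) -> tuple[int, float]:
    """Over-representation of ``annotation`` inside ``query``.

    Upper-tail hypergeometric p-value ``P(X >= overlap)`` with population
    ``|universe|``, success states ``|annotation ∩ universe|`` and draws
    ``|query|``.
    """
    universe = frozenset(universe)
    if not query.members <= universe:
        raise ValueError("query genes must be contained in the universe")
    ann = annotation.members & universe
    if not ann:
        raise ValueError("annotation does not intersect the universe")
    overlap = len(query.members & ann)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(ann), len(query)))
    return overlap, min(p, 1.0)


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
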