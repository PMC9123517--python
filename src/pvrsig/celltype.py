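"""Cell-type enrichment scoring of bulk transcriptomes.

Scores user-supplied cell-type marker gene sets against each sample's
TPM profile with a single-sample rank-based enrichment statistic (the
ssGSEA integral): genes are ranked by expression within the sample and
the score is the summed gap between the weighted cumulative distribution
of marker genes and the uniform cumulative distribution of non-markers.
Group differences per cell type are assessed with the Mann-Whitney U
test (exact enumeration at small sample sizes).

This is the raw per-sample enrichment statistic only: no cross-sample
rescaling, no proprietary signature compendium, no spillover correction.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .signature import GeneSet, bh_adjust

__all__ = [
    "CellTypeScoreTable",
    "ssgsea_score",
    "score_all",
    "compare_groups",
    "compare_all",
]

EXACT_MAX_N = 8  # exact Mann-Whitney enumeration up to this many samples per group


@dataclasses.dataclass
class CellTypeScoreTable:
    """Cell-type × sample enrichment scores plus per-sample group labels."""

    scores: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.groups is not None:
            missing = set(self.scores.columns) - set(self.groups.index)
            if missing:
                raise ValueError(f"samples without group label: {sorted(missing)}")


def ssgsea_score(expression: pd.Series, members: GeneSet, alpha: float = 0.25) -> float:
    """Single-sample enrichment of ``members`` in one expression profile.

    Genes are ranked by expression descending (ties lexicographic by gene
    id). With N genes and position i counted from the top, hits carry
    weight ``(N - i + 1)^alpha`` normalized over hits, misses advance a
    uniform ECDF; the score sums ``P_hit(i) - P_miss(i)`` over all
    positions. Depends only on the expression ranks.
    """
    genes = expression.index.astype(str).tolist()
    values = expression.to_numpy(dtype=float)
    n = len(genes)
    order = np.lexsort((genes, -values))
    hit = np.fromiter((genes[i] in members for i in order), dtype=bool, count=n)
    k = int(hit.sum())
    if k == 0:
        raise ValueError("no gene-set member in the expression profile")
    if k == n:
        raise ValueError("gene set covers every gene; miss ECDF undefined")
    pos_weight = (n - np.arange(1, n + 1) + 1).astype(float) ** alpha
    hit_w = np.where(hit, pos_weight, 0.0)
    p_hit = np.cumsum(hit_w) / hit_w.sum()
    p_miss = np.cumsum(~hit) / (n - k)
    return float(np.sum(p_hit - p_miss))


def score_all(
    tpm: pd.DataFrame,
    signatures: Iterable[GeneSet],
    alpha: float = 0.25,
    groups: pd.Series | None = None,
) -> CellTypeScoreTable:
    """Score every signature against every sample of a TPM matrix.

    Signatures that do not intersect the gene universe are dropped with a
    warning; at least one must remain.
    """
    import warnings

    universe = set(tpm.index.astype(str))
    usable = []
    for gs in signatures:
        if gs.members & universe:
            usable.append(gs)
        else:
            warnings.warn(f"signature {gs.name!r} disjoint from genes; dropped",
                          UserWarning, stacklevel=2)
    if not usable:
        raise ValueError("no signature intersects the gene universe")
    rows = {
        gs.name: [ssgsea_score(tpm[c], gs, alpha) for c in tpm.columns] for gs in usable
    }
    scores = pd.DataFrame(rows, index=tpm.columns).T
    return CellTypeScoreTable(scores=scores, groups=groups)


def _exact_mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration (handles ties).

    U uses midrank tie handling; the two-sided p-value is the null
    probability of a U at least as far from n1*n2/2 as observed, over all
    C(n1+n2, n1) group assignments.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    n1, n2 = len(x), len(y)
    n = n1 + n2
    offset = n1 * (n1 + 1) / 2
    u_obs = ranks[:n1].sum() - offset
    center = n1 * n2 / 2
    dev_obs = abs(u_obs - center)
    hits = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - center) >= dev_obs - 1e-12:
            hits += 1
    return float(u_obs), hits / comb(n, n1)


def compare_groups(
    table: CellTypeScoreTable, cell_type: str, group_a: str, group_b: str
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of one cell type's scores.

    Exact enumeration when both groups have at most eight samples,
    tie-corrected normal approximation otherwise. Returns (U, p) with U
    counted for ``group_a``.
    """
    if table.groups is None:
        raise ValueError("score table carries no group labels")
    for g in (group_a, group_b):
        if (table.groups == g).sum() < 2:
            raise ValueError(f"group {g!r} needs >=2 samples")
    row = table.scores.loc[cell_type]
    x = row[table.groups.reindex(row.index) == group_a].to_numpy(dtype=float)
    y = row[table.groups.reindex(row.index) == group_b].to_numpy(dtype=float)
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return _exact_mannwhitney(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_all(
    table: CellTypeScoreTable, group_a: str, group_b: str
) -> pd.DataFrame:
    """Mann-Whitney comparison for every cell type, BH-adjusted."""
    rows = []
    for ct in table.scores.index:
        u, p = compare_groups(table, ct, group_a, group_b)
        rows.append({"cell_type": ct, "U": u, "p": p})
    frame = pd.DataFrame(rows)
    frame["padj"] = bh_adjust(frame["p"])
    return frame
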