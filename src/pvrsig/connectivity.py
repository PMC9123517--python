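"""Inverse-signature connectivity scoring of candidate drugs.

Each drug's downregulated gene set is tested for enrichment at the top of
the disease-ranked gene list with the weighted Kolmogorov-Smirnov-like
running-sum statistic of GSEA: walking the ranking from most to least
upregulated, a hit adds its normalized |score|^p weight and a miss
subtracts 1/(N - n_hits); the enrichment score (ES) is the signed maximal
deviation of this running sum. A drug whose downregulated genes
concentrate among the most disease-upregulated genes scores a large
positive ES and plausibly reverses the disease profile.

Significance is calibrated by gene-set permutation: null ES values for
random sets of the same size drawn from the ranking. The normalized
enrichment score (NES) divides the observed ES by the mean |null ES| of
matching sign, and the one-sided permutation p-value carries the standard
+1 correction, so p >= 1/(n_perm + 1).
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .drugs import DrugProfile
from .signature import GeneSet, RankedSignature, bh_adjust

__all__ = [
    "EnrichmentResult",
    "enrichment_score",
    "permutation_null",
    "score_drug",
    "rank_drugs",
    "plot_running_sum",
]


@dataclasses.dataclass
class EnrichmentResult:
    """Enrichment of one gene set against one ranking."""

    set_name: str
    es: float
    nes: float
    p: float
    padj: float | None
    set_size: int
    leading_edge: list[str]
    running_sum: np.ndarray | None = None
    scorable: bool = True


# magnitude ties between the positive and negative extremum go to the
# positive side; judged at a small tolerance so float summation order
# cannot flip the sign (exact ties occur, e.g. when the miss step divides
# the hit weights evenly)
TIE_EPS = 1e-9


def _prefer_positive(hi: float, lo: float) -> bool:
    return abs(hi) >= abs(lo) - TIE_EPS


def enrichment_score(
    ranked: RankedSignature, members: GeneSet, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted running-sum enrichment of ``members`` in ``ranked``.

    Returns ``(es, running_sum, leading_edge)`` where ``running_sum`` is
    the value after each rank position and the leading edge contains the
    member genes at or before the extremum (positive ES) or after it
    (negative ES). When the signed maximal deviations tie in magnitude
    the positive one is reported.
    """
    n = len(ranked)
    hit_mask = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=n)
    k = int(hit_mask.sum())
    if k == 0:
        raise ValueError("no gene-set member present in the ranking")
    if k == n:
        raise ValueError("gene set covers the entire ranking; complement is empty")
    w = np.abs(ranked.scores) ** weight_exponent
    w = np.where(hit_mask, w, 0.0)
    total = w.sum()
    if total == 0:
        w = hit_mask.astype(float)
        total = float(k)
    steps = np.where(hit_mask, w / total, -1.0 / (n - k))
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    hi, lo = running[i_max], min(running[i_min], 0.0)
    if _prefer_positive(hi, lo):
        es = float(hi)
        leading = [g for i, g in enumerate(ranked.genes) if hit_mask[i] and i <= i_max]
    else:
        es = float(lo)
        leading = [g for i, g in enumerate(ranked.genes) if hit_mask[i] and i > i_min]
    return es, running, leading


def permutation_null(
    ranked: RankedSignature,
    set_size: int,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Null ES distribution for random gene sets of ``set_size``.

    Sets are drawn uniformly without replacement from the ranked genes;
    the computation is vectorized across permutations.
    """
    n = len(ranked)
    if not 1 <= set_size < n:
        raise ValueError(f"set_size must be in [1, {n - 1}]")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    # k smallest of n uniforms per row = a uniform k-subset of positions
    pos = np.argpartition(rng.random((n_perm, n)), set_size - 1, axis=1)[:, :set_size]
    pos.sort(axis=1)
    scores = ranked.scores
    k = set_size
    w = np.abs(scores[pos]) ** weight_exponent
    total = w.sum(axis=1, keepdims=True)
    degenerate = total[:, 0] == 0
    if degenerate.any():
        w[degenerate] = 1.0
        total[degenerate] = k
    cum = np.cumsum(w, axis=1) / total
    miss_step = 1.0 / (n - k)
    misses_before = pos - np.arange(k)
    at_hit = cum - misses_before * miss_step
    before_hit = np.concatenate([np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) - misses_before * miss_step
    hi = at_hit.max(axis=1)
    lo = np.minimum(before_hit.min(axis=1), 0.0)
    return np.where(np.abs(hi) >= np.abs(lo) - TIE_EPS, hi, lo)


def score_drug(
    ranked: RankedSignature,
    drug: DrugProfile,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    seed: int | None = None,
    keep_running_sum: bool = False,
    null_es: np.ndarray | None = None,
) -> EnrichmentResult:
    """Score one drug's down-set against the disease ranking.

    Down-set genes absent from the ranking are silently dropped;
    ``set_size`` records the intersection size. ``null_es`` lets callers
    share a precomputed permutation null across drugs with equal
    intersection sizes. One-sided p among same-sign nulls with the +1
    correction; NES = es / mean(|null es| of the same sign). A drug whose
    down-set misses the ranking entirely comes back flagged unscorable.
    """
    if drug.down_genes is None:
        raise ValueError(f"drug {drug.name!r} has no attached down-set")
    members = drug.down_genes.intersection(ranked.genes)
    if not members:
        warnings.warn(f"drug {drug.name!r}: down-set disjoint from ranking; unscorable",
                      UserWarning, stacklevel=2)
        return EnrichmentResult(drug.name, np.nan, np.nan, np.nan, None, 0, [], None, False)
    member_set = GeneSet(drug.down_genes.name, members)
    es, running, leading = enrichment_score(ranked, member_set, weight_exponent)
    if null_es is None:
        null_es = permutation_null(ranked, len(members), n_perm, weight_exponent, seed)
    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    p = (1 + int((np.abs(null_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
    mean_mag = float(np.abs(null_es[same_sign]).mean()) if n_same else np.nan
    nes = es / mean_mag if n_same else np.nan
    return EnrichmentResult(
        set_name=drug.name,
        es=es,
        nes=nes,
        p=p,
        padj=None,
        set_size=len(members),
        leading_edge=leading,
        running_sum=running if keep_running_sum else None,
    )


def rank_drugs(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """BH-adjust across scorable drugs and order the candidate table.

    Sorted by NES descending, ties by adjusted p ascending then name.
    Unscorable results (empty intersection) are excluded.
    """
    scorable = [r for r in results if r.scorable]
    if not scorable:
        raise ValueError("no scorable enrichment results")
    padj = bh_adjust([r.p for r in scorable])
    for r, q in zip(scorable, padj):
        r.padj = float(q)
    frame = pd.DataFrame(
        {
            "drug": [r.set_name for r in scorable],
            "es": [r.es for r in scorable],
            "nes": [r.nes for r in scorable],
            "p": [r.p for r in scorable],
            "padj": [r.padj for r in scorable],
            "set_size": [r.set_size for r in scorable],
            "leading_edge": [";".join(r.leading_edge) for r in scorable],
        }
    )
    frame = frame.sort_values(
        ["nes", "padj", "drug"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return frame


def plot_running_sum(
    result: EnrichmentResult, ranked: RankedSignature, path: str
) -> None:
    """Enrichment-curve plot (running sum over rank positions) for one drug."""
    if result.running_sum is None:
        raise ValueError("score with keep_running_sum=True to plot")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(np.arange(1, len(ranked) + 1), result.running_sum, color="green", lw=1)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("rank in disease signature")
    ax.set_ylabel("running enrichment")
    ax.set_title(f"{result.set_name}: ES={result.es:.3f}, NES={result.nes:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
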