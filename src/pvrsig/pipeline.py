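"""End-to-end synthetic drug-repurposing screen.

Wires the full pipeline together on generated data: simulate two-group
counts, run the internal DE stand-in, build the ranked disease signature,
retain interaction-supported DEGs, filter and target-map a simulated drug
catalog, attach perturbation down-sets, and rank all scorable drugs by
permutation-calibrated NES. Used by the demo CLI and for benchmarking
planted-drug recovery.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import connectivity, drugs as drugs_mod, network as network_mod, signature as sig_mod
from .signature import GeneSet, RankedSignature
from .synthetic import (
    SimTruth,
    simulate_bulk_counts,
    simulate_drug_catalog,
    simulate_network,
)

__all__ = ["ScreenResult", "run_drug_screen"]


@dataclasses.dataclass
class ScreenResult:
    """Everything the synthetic screen produced, plus the planted truth."""

    de_table: pd.DataFrame
    up_genes: GeneSet
    down_genes: GeneSet
    ranked: RankedSignature
    filtered_genes: GeneSet
    orphans: frozenset[str]
    scored: list[connectivity.EnrichmentResult]
    table: pd.DataFrame
    truth: SimTruth

    @property
    def planted_rank(self) -> int:
        """1-based rank of the planted drug in the final table."""
        pos = self.table.index[self.table["drug"] == self.truth.planted_drug]
        if len(pos) == 0:
            raise ValueError("planted drug absent from the result table")
        return int(pos[0]) + 1


def run_drug_screen(
    seed: int,
    n_genes: int = 2000,
    n_per_group: int = 8,
    de_fraction: float = 0.10,
    effect_log2fc: float = 3.0,
    dispersion: float = 0.1,
    n_decoys: int = 20,
    planted_overlap: int = 30,
    set_size: int = 30,
    top_n: int = 50,
    n_orphans: int = 5,
    edge_prob: float = 0.10,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    lfc_thresh: float = 2.0,
    alpha: float = 0.05,
) -> ScreenResult:
    """Run the synthetic screen end to end under one master seed.

    Sub-seeds for each stochastic stage are spawned deterministically
    from ``seed``. Permutation nulls are shared between drugs whose
    down-sets have identical intersection size with the ranking.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)

    counts, groups, truth = simulate_bulk_counts(
        n_genes, n_per_group, de_fraction, effect_log2fc, dispersion, int(sub[0])
    )
    de_table = sig_mod.internal_de(counts, groups, disease="disease", control="control")
    up, down = sig_mod.filter_degs(de_table, lfc_thresh=lfc_thresh, alpha=alpha)
    ranked = sig_mod.rank_signature(de_table)

    catalog, drug_truth = simulate_drug_catalog(
        ranked, n_decoys, planted_overlap, set_size, int(sub[1]), top_n=top_n
    )
    truth = dataclasses.replace(truth, planted_drug=drug_truth.planted_drug)

    planted_targets = catalog[0].targets
    orphan_pool = sorted(up.members - planted_targets)
    orphan_rng = np.random.default_rng(int(sub[2]))
    orphans = frozenset(
        orphan_rng.choice(orphan_pool, size=min(n_orphans, len(orphan_pool)), replace=False)
    )
    net = simulate_network(sorted(up.members), edge_prob, orphans, int(sub[2]))
    filtered = network_mod.filter_by_interaction(up, net)

    surviving = drugs_mod.filter_catalog(catalog)
    surviving = drugs_mod.map_targets(surviving, filtered)
    profiles = [d.down_genes for d in catalog if d.down_genes is not None]
    surviving = drugs_mod.attach_profiles(surviving, profiles)

    null_cache: dict[int, np.ndarray] = {}
    scored = []
    for i, drug in enumerate(surviving):
        k = len(drug.down_genes.intersection(ranked.genes))
        if k and k not in null_cache:
            null_cache[k] = connectivity.permutation_null(
                ranked, k, n_perm, weight_exponent, int(sub[3]) + k
            )
        scored.append(
            connectivity.score_drug(
                ranked,
                drug,
                n_perm=n_perm,
                weight_exponent=weight_exponent,
                seed=int(sub[3]) + i,
                null_es=null_cache.get(k),
            )
        )
    table = connectivity.rank_drugs(scored)
    return ScreenResult(
        de_table=de_table,
        up_genes=up,
        down_genes=down,
        ranked=ranked,
        filtered_genes=filtered,
        orphans=orphans,
        scored=scored,
        table=table,
        truth=truth,
    )
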