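"""Synthetic inputs with known ground truth for every pipeline stage.

Generates the full complement of study-shaped inputs — two-group
negative-binomial bulk counts with planted fold-change effects, a
drug catalog whose planted drug's down-set overlaps the top of the
disease signature, an Erdős–Rényi-style interaction network with
designated orphan genes, and multivariate cell populations with distinct
marker means — so the pipeline can be exercised and benchmarked end to
end with no external downloads. Every generator is a pure function of
its arguments and seed.

The count model is the standard RNA-seq simulation convention: gene
baseline means log-uniform on [1, 1e4], negative binomial with
var = mu + dispersion * mu^2, and planted genes have their group-2 mean
multiplied by 2^effect_log2fc.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .drugs import DrugProfile
from .network import InteractionNetwork
from .signature import GeneSet, RankedSignature

__all__ = [
    "SimTruth",
    "simulate_bulk_counts",
    "simulate_drug_catalog",
    "simulate_network",
    "simulate_cell_matrix",
]

BASELINE_MEAN_RANGE = (1.0, 1e4)


@dataclasses.dataclass
class SimTruth:
    """Ground truth planted by the generators, for scoring downstream stages."""

    de_genes: frozenset[str] = frozenset()
    effect_log2fc: dict[str, float] = dataclasses.field(default_factory=dict)
    planted_drug: str | None = None
    cell_labels: np.ndarray | None = None


def simulate_bulk_counts(
    n_genes: int,
    n_per_group: int,
    de_fraction: float,
    effect_log2fc: float,
    dispersion: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.Series, SimTruth]:
    """Two-group negative-binomial count matrix with planted effects.

    A random ``de_fraction`` of genes has its disease-group mean
    multiplied by ``2**effect_log2fc``; all planted genes share that
    effect. Groups are labelled ``control`` and ``disease``; samples are
    ``C1..Cn`` and ``D1..Dn``. Identical (args, seed) give bit-identical
    output.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must lie in [0, 1]")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    lo, hi = BASELINE_MEAN_RANGE
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    effects = np.zeros(n_genes)
    effects[de_idx] = effect_log2fc
    mu_control = mu
    mu_disease = mu * 2.0**effects

    r = 1.0 / dispersion  # NB size; var = mu + dispersion * mu^2

    def draw(mean: np.ndarray, n_samples: int) -> np.ndarray:
        p = r / (r + mean)
        return rng.negative_binomial(r, p[:, None], size=(len(mean), n_samples))

    counts = np.concatenate(
        [draw(mu_control, n_per_group), draw(mu_disease, n_per_group)], axis=1
    )
    samples = [f"C{i + 1}" for i in range(n_per_group)] + [
        f"D{i + 1}" for i in range(n_per_group)
    ]
    frame = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    groups = pd.Series(
        ["control"] * n_per_group + ["disease"] * n_per_group, index=samples, name="group"
    )
    truth = SimTruth(
        de_genes=frozenset(genes[i] for i in de_idx),
        effect_log2fc={genes[i]: effect_log2fc for i in de_idx},
    )
    return frame, groups, truth


_FAIL_MODES = (
    {"organism": "Rat", "known_action": "yes", "groups": frozenset({"approved"})},
    {"organism": "Humans", "known_action": "no", "groups": frozenset({"approved"})},
    {"organism": "Humans", "known_action": "yes", "groups": frozenset({"investigational"})},
)


def simulate_drug_catalog(
    disease_signature: RankedSignature,
    n_decoys: int,
    planted_overlap: int,
    set_size: int,
    seed: int,
    top_n: int = 50,
    decoy_fail_fraction: float = 0.25,
) -> tuple[list[DrugProfile], SimTruth]:
    """Drug catalog with one planted inverse-matched drug plus decoys.

    The planted drug's down-set contains ``planted_overlap`` genes drawn
    from the top ``top_n`` of the signature (the most disease-upregulated
    genes), the remainder random from the rest of the ranking; its
    catalog attributes always pass the organism/known-action/approved
    filters and it targets signature genes. Decoys carry uniformly random
    down-sets; a ``decoy_fail_fraction`` of them get attributes that fail
    the catalog filter, the rest pass.
    """
    n = len(disease_signature)
    if not planted_overlap <= set_size <= n:
        raise ValueError("need planted_overlap <= set_size <= signature length")
    if top_n < planted_overlap:
        raise ValueError("top_n must be >= planted_overlap")
    rng = np.random.default_rng(seed)
    genes = disease_signature.genes
    top = genes[:top_n]
    rest = genes[top_n:]

    planted_down = list(rng.choice(top, size=planted_overlap, replace=False))
    if set_size > planted_overlap:
        planted_down += list(rng.choice(rest, size=set_size - planted_overlap, replace=False))
    planted = DrugProfile(
        drug_id="DRUG0000",
        name="planted-drug",
        targets=frozenset(rng.choice(top, size=min(3, len(top)), replace=False)),
        organism="Humans",
        known_action="yes",
        groups=frozenset({"approved"}),
        down_genes=GeneSet("planted-drug", frozenset(planted_down)),
    )

    drugs = [planted]
    n_fail = int(round(decoy_fail_fraction * n_decoys))
    # decoy targets come from the top tenth of the ranking so that decoys
    # plausibly target disease genes and survive target mapping
    target_pool = genes[: max(top_n, n // 10)]
    for i in range(n_decoys):
        down = frozenset(rng.choice(genes, size=set_size, replace=False))
        targets = frozenset(rng.choice(target_pool, size=min(3, len(target_pool)), replace=False))
        name = f"decoy-{i + 1:03d}"
        attrs = (
            dict(_FAIL_MODES[i % len(_FAIL_MODES)])
            if i < n_fail
            else {"organism": "Humans", "known_action": "yes", "groups": frozenset({"approved"})}
        )
        drugs.append(
            DrugProfile(
                drug_id=f"DRUG{i + 1:04d}",
                name=name,
                targets=targets,
                down_genes=GeneSet(name, down),
                **attrs,
            )
        )
    truth = SimTruth(planted_drug=planted.name)
    return drugs, truth


def simulate_network(
    genes: list[str],
    edge_prob: float,
    orphans: set[str] | frozenset[str] = frozenset(),
    seed: int = 0,
) -> InteractionNetwork:
    """Erdős–Rényi interaction network; designated orphans get degree 0.

    Each unordered pair of non-orphan genes is connected independently
    with probability ``edge_prob``; combined scores are uniform on
    [400, 1000), above the default STRING medium-confidence threshold.
    """
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must lie in [0, 1]")
    orphans = set(orphans)
    if not orphans <= set(genes):
        raise ValueError("orphans must be a subset of genes")
    rng = np.random.default_rng(seed)
    connectable = [g for g in genes if g not in orphans]
    network = InteractionNetwork()
    m = len(connectable)
    if m >= 2 and edge_prob > 0:
        iu = np.triu_indices(m, k=1)
        mask = rng.random(len(iu[0])) < edge_prob
        scores = rng.uniform(400.0, 1000.0, size=len(iu[0]))
        for a, b, s in zip(iu[0][mask], iu[1][mask], scores[mask]):
            network.add_edge(connectable[a], connectable[b], float(s))
    return network


def simulate_cell_matrix(
    populations: list[tuple[int, np.ndarray]],
    noise_sd: float,
    seed: int,
    marker_names: list[str] | None = None,
    entities: list[str] | None = None,
):
    """Gaussian cell populations around distinct marker mean vectors.

    Each population contributes ``n_cells`` cells at its mean vector plus
    N(0, noise_sd) noise, truncated at zero (intensities are
    non-negative). Per-population entity labels default to ``pop1``,
    ``pop2``, ...; the sample id equals the entity label.
    """
    from .imc import CellMatrix

    if not populations:
        raise ValueError("at least one population required")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    means = [np.asarray(m, dtype=float) for _, m in populations]
    dims = {m.shape for m in means}
    if len(dims) != 1:
        raise ValueError("all population mean vectors must have the same length")
    n_markers = means[0].size
    if marker_names is None:
        marker_names = [f"M{j + 1}" for j in range(n_markers)]
    if entities is None:
        entities = [f"pop{i + 1}" for i in range(len(populations))]
    if len(entities) != len(populations):
        raise ValueError("one entity label per population required")
    rng = np.random.default_rng(seed)
    blocks, labels, ent = [], [], []
    for i, ((n_cells, _), mean) in enumerate(zip(populations, means)):
        block = mean[None, :] + rng.normal(0.0, noise_sd or 0.0, size=(n_cells, n_markers))
        blocks.append(np.clip(block, 0.0, None))
        labels += [i] * n_cells
        ent += [entities[i]] * n_cells
    matrix = CellMatrix(
        intensities=pd.DataFrame(np.concatenate(blocks), columns=marker_names),
        sample=pd.Series(ent),
        entity=pd.Series(ent),
    )
    truth = SimTruth(cell_labels=np.asarray(labels))
    return matrix, truth
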