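"""Drug-catalog filtering and target mapping.

Candidate therapeutics come from a DrugBank-like catalog snapshot (flat
CSV, one row per drug-target pair). The screen keeps approved drugs with
a pharmacologically known action on a human target, maps each to its
targets inside the disease signature, and attaches the drug's
downregulated gene set from a perturbation reference (CMap-like GMT) for
connectivity scoring.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable
from pathlib import Path

import pandas as pd

from .signature import GeneSet

__all__ = [
    "DrugProfile",
    "read_catalog",
    "filter_catalog",
    "map_targets",
    "attach_profiles",
]


@dataclasses.dataclass
class DrugProfile:
    """One drug's catalog attributes, targets and perturbation down-set."""

    drug_id: str
    name: str
    targets: frozenset[str]
    organism: str
    known_action: str
    groups: frozenset[str]
    down_genes: GeneSet | None = None
    signature_targets: frozenset[str] = frozenset()

    def _key(self) -> str:
        return self.name.strip().casefold()


def read_catalog(path: str | Path) -> list[DrugProfile]:
    """Read a catalog CSV: drug_id, name, target_gene, organism, known_action, groups.

    One row per drug-target pair; ``groups`` is semicolon-separated.
    Rows for the same ``drug_id`` are merged into one profile.
    """
    frame = pd.read_csv(path, dtype=str).fillna("")
    required = {"drug_id", "name", "target_gene", "organism", "known_action", "groups"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    profiles: dict[str, DrugProfile] = {}
    for _, row in frame.iterrows():
        did = row["drug_id"]
        if did not in profiles:
            profiles[did] = DrugProfile(
                drug_id=did,
                name=row["name"],
                targets=frozenset(),
                organism=row["organism"],
                known_action=row["known_action"],
                groups=frozenset(g.strip() for g in row["groups"].split(";") if g.strip()),
            )
        prof = profiles[did]
        if row["target_gene"]:
            prof.targets = prof.targets | {row["target_gene"]}
    return list(profiles.values())


def write_catalog(drugs: Iterable[DrugProfile], path: str | Path) -> None:
    rows = []
    for d in drugs:
        targets = sorted(d.targets) or [""]
        for t in targets:
            rows.append(
                {
                    "drug_id": d.drug_id,
                    "name": d.name,
                    "target_gene": t,
                    "organism": d.organism,
                    "known_action": d.known_action,
                    "groups": ";".join(sorted(d.groups)),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def filter_catalog(drugs: Iterable[DrugProfile]) -> list[DrugProfile]:
    """Keep approved drugs with known action on a human target.

    Criteria (all required, case-insensitive): organism == "humans",
    known_action == "yes", "approved" in groups. Drugs with a missing
    attribute are excluded with a warning.
    """
    kept = []
    for drug in drugs:
        if not drug.organism or not drug.known_action or not drug.groups:
            warnings.warn(
                f"drug {drug.drug_id!r} missing filter attribute; excluded",
                UserWarning,
                stacklevel=2,
            )
            continue
        if (
            drug.organism.strip().casefold() == "humans"
            and drug.known_action.strip().casefold() == "yes"
            and any(g.strip().casefold() == "approved" for g in drug.groups)
        ):
            kept.append(drug)
    return kept


def map_targets(drugs: Iterable[DrugProfile], signature_genes: GeneSet) -> list[DrugProfile]:
    """Retain drugs with >=1 target inside the signature; annotate those targets."""
    kept = []
    for drug in drugs:
        in_sig = drug.targets & signature_genes.members
        if in_sig:
            kept.append(dataclasses.replace(drug, signature_targets=frozenset(in_sig)))
    return kept


def attach_profiles(
    drugs: Iterable[DrugProfile], profiles: Iterable[GeneSet]
) -> list[DrugProfile]:
    """Attach each drug's downregulated gene set from a perturbation GMT.

    GMT set names are matched to the drug id or name after case-folding
    and whitespace trimming; drugs without a matching profile are dropped
    with a warning, unmatched GMT entries are ignored.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("empty perturbation profile collection")
    by_name = {gs.name.strip().casefold(): gs for gs in profiles}
    kept = []
    for drug in drugs:
        gs = by_name.get(drug._key()) or by_name.get(drug.drug_id.strip().casefold())
        if gs is None:
            warnings.warn(
                f"no perturbation profile for drug {drug.name!r}; dropped",
                UserWarning,
                stacklevel=2,
            )
            continue
        kept.append(dataclasses.replace(drug, down_genes=gs))
    return kept
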