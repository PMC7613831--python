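"""Tubule cell-type localization of transcripts and drug/PPAR stratification.

A reference atlas gives the abundance of each feature across the 14 rat
tubular epithelial cell types, ordered along the nephron from the proximal
tubule segments S1-S3 through the collecting duct. Each transcript is
localized to its site of maximal abundance and assigned to the proximal
tubule (argmax in S1-S3) or the rest of the renal tubule. Concordant
treatment-responsive DEGs are then stratified by medication / PPAR-isotype
responsiveness, atlas presence, and tubular compartment, yielding the nested
count/percentage summaries behind the study's doughnut and Venn figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .de import DEGSet, _round_half_away

#: Fixed cell-type ontology order along the nephron.
CELL_TYPES = (
    "S1", "S2", "S3", "DTL1", "DTL2", "DTL3", "ATL",
    "mTAL", "cTAL", "DCT", "CNT", "CCD", "OMCD", "IMCD",
)
PT_TYPES = frozenset({"S1", "S2", "S3"})

DRUGS = ("fenofibrate", "liraglutide", "metformin", "ramipril", "rosuvastatin")
PPAR_ISOTYPES = ("PPARA", "PPARD", "PPARG")


@dataclass
class AtlasMatrix:
    """Features x 14 cell types nonnegative abundance reference."""

    abundance: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.abundance.columns) != list(CELL_TYPES):
            raise ValueError("atlas columns must be the 14 cell types in ontology order")
        if self.abundance.index.duplicated().any():
            raise ValueError("duplicate atlas features")
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("atlas abundances must be nonnegative")

    @property
    def features(self) -> set[str]:
        return set(self.abundance.index)


@dataclass
class DrugTargetNetwork:
    """Entity (drug or PPAR isotype) -> target gene set, optional edge signs."""

    targets: dict[str, set[str]]
    signs: dict[str, dict[str, int]] | None = None

    def __post_init__(self) -> None:
        for e, t in self.targets.items():
            if not t:
                raise ValueError(f"empty target set for {e!r}")

    def entities(self) -> list[str]:
        return list(self.targets)


def average_expression_by_type(
    cell_matrix: pd.DataFrame, cell_labels: pd.Series
) -> pd.DataFrame:
    """Per-cell-type arithmetic mean expression (cells x features input).

    Returns features x cell types, columns restricted to labels present,
    in ontology order where applicable.
    """
    if cell_labels.isna().any() or not set(cell_matrix.index) <= set(cell_labels.index):
        raise ValueError("every cell must be labelled")
    labels = cell_labels.loc[cell_matrix.index]
    means = cell_matrix.groupby(labels.to_numpy()).mean().T
    ordered = [c for c in CELL_TYPES if c in means.columns]
    extra = [c for c in means.columns if c not in CELL_TYPES]
    return means[ordered + extra]


def localize_features(features: set[str], atlas: AtlasMatrix) -> pd.DataFrame:
    """Assign each feature to its cell type of maximal abundance.

    Returns a frame indexed by feature with columns: in_atlas, cell_type,
    compartment ('proximal_tubule' | 'rest_of_tubule'), tie. Ties on the
    maximum are broken by ontology order and flagged.
    """
    rows = []
    ab = atlas.abundance
    for f in sorted(features):
        if f not in ab.index:
            rows.append({"feature": f, "in_atlas": False, "cell_type": None,
                         "compartment": None, "tie": False})
            continue
        vals = ab.loc[f]
        top = vals.max()
        winners = [c for c in CELL_TYPES if vals[c] == top]
        ct = winners[0]
        rows.append(
            {
                "feature": f,
                "in_atlas": True,
                "cell_type": ct,
                "compartment": "proximal_tubule" if ct in PT_TYPES else "rest_of_tubule",
                "tie": len(winners) > 1,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def _node(count: int, denom: int) -> dict:
    pct = _round_half_away(100.0 * count / denom, 1) if denom else 0.0
    return {"count": count, "pct": pct}


def stratify_by_responsiveness(
    concordant: DEGSet,
    network: DrugTargetNetwork,
    atlas: AtlasMatrix,
    focal_entity: str,
) -> dict:
    """Nested stratification of concordant DEGs by entity responsiveness.

    Level 1: genes responsive to >= 1 network entity, split into
    focal-entity-responsive vs responsive only to other entities (percentages
    on the responsive-to-any denominator). Level 2: presence in the atlas.
    Level 3: tubular compartment among atlas-present genes (percentages on
    the atlas-present denominator).
    """
    if focal_entity not in network.targets:
        raise ValueError(f"unknown focal entity {focal_entity!r}")
    genes = concordant.genes
    responsive = {g for g in genes if any(g in t for t in network.targets.values())}
    focal = responsive & network.targets[focal_entity]
    other = responsive - focal
    loc = localize_features(responsive, atlas) if responsive else None

    def branch(members: set[str]) -> dict:
        if not members:
            return {
                "count": 0, "pct": _node(0, len(responsive))["pct"],
                "in_atlas": {"count": 0, "pct": 0.0,
                             "proximal_tubule": _node(0, 0), "rest_of_tubule": _node(0, 0)},
                "not_in_atlas": _node(0, 0),
            }
        sub = loc.loc[sorted(members)]
        present = sub[sub["in_atlas"]]
        pt = int((present["compartment"] == "proximal_tubule").sum())
        rest = int((present["compartment"] == "rest_of_tubule").sum())
        out = _node(len(members), len(responsive))
        out["in_atlas"] = {
            **_node(len(present), len(members)),
            "proximal_tubule": _node(pt, len(present)),
            "rest_of_tubule": _node(rest, len(present)),
        }
        out["not_in_atlas"] = _node(len(members) - len(present), len(members))
        return out

    return {
        "focal_entity": focal_entity,
        "n_input": len(genes),
        "responsive_any": _node(len(responsive), len(genes)),
        "focal": branch(focal),
        "other": branch(other),
    }


def multiway_overlap(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Membership-pattern (Venn region) counts for 2-8 named sets."""
    if not 2 <= len(sets) <= 8:
        raise ValueError("multiway_overlap supports 2-8 sets")
    names = list(sets)
    universe = set().union(*sets.values())
    counts: dict[tuple[bool, ...], int] = {}
    for g in universe:
        pattern = tuple(g in sets[n] for n in names)
        counts[pattern] = counts.get(pattern, 0) + 1
    rows = []
    for pattern in product([False, True], repeat=len(names)):
        if not any(pattern):
            continue
        rows.append({**{n: p for n, p in zip(names, pattern)},
                     "count": counts.get(pattern, 0)})
    return pd.DataFrame(rows)


def fraction_of_known_targets(degs: set[str], targets: set[str]) -> float:
    """Percentage (1 decimal) of an entity's known targets hit by the DEGs."""
    if not targets:
        raise ValueError("target set is empty")
    return _round_half_away(100.0 * len(degs & targets) / len(targets), 1)
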