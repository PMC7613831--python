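"""Over-representation analysis (ORA) and a simplified upstream-regulator score.

ORA uses the hypergeometric upper tail: for a query of n genes drawn from a
universe of N, the probability of observing at least k hits in an annotated
set of size K. The regulator activation score is a sign-consistency z over a
regulator's known targets: z = (n_consistent - n_inconsistent) / sqrt(n),
called activated at z >= 2 and inhibited at z <= -2. This is a documented
simplification of proprietary knowledge-base scores: it preserves the
qualitative contract (direction-consistent target regulation drives the
activation call) without their curated edge weighting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .de import DEGSet, adjust_bh


@dataclass
class GeneSetCollection:
    """Named gene sets over a fixed universe (e.g. Reactome pathways, GO terms)."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set: {name!r}")
            if not members <= self.universe:
                raise ValueError(f"gene set {name!r} not contained in universe")


@dataclass(frozen=True)
class RegulatorCall:
    regulator: str
    n_overlap: int
    z: float | None
    state: str  # 'activated' | 'inhibited' | 'undetermined'


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: one set per line, name TAB description TAB genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def ora(query: set[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each collection set.

    p = P(X >= k) for X ~ Hypergeom(N, K, n); BH adjustment across sets.
    Query genes outside the universe are dropped with a warning.
    """
    if not query:
        raise ValueError("empty query gene set")
    outside = query - collection.universe
    if outside:
        warnings.warn(f"{len(outside)} query genes outside universe dropped")
    q = query & collection.universe
    N = len(collection.universe)
    n = len(q)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        overlap = q & members
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append(
            {
                "set": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": min(p, 1.0),
                "genes": ",".join(sorted(overlap)),
            }
        )
    res = pd.DataFrame(rows).set_index("set")
    res["padj"] = adjust_bh(res["p"].to_numpy())
    return res


def compare_clusters(
    queries: dict[str, set[str]], collection: GeneSetCollection
) -> pd.DataFrame:
    """Per-query ORA concatenated long-format, BH within each query."""
    if not queries:
        raise ValueError("at least one query required")
    blocks = []
    for label, q in queries.items():
        block = ora(q, collection).reset_index()
        block.insert(0, "query", label)
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)


def regulator_activation_score(
    targets: dict[str, int], degs: DEGSet, regulator: str = ""
) -> RegulatorCall:
    """Sign-consistency activation z over a regulator's target edges.

    ``targets`` maps target gene -> expected sign (+1 regulator-activated,
    -1 regulator-repressed). Over the n targets that are DEGs,
    z = (consistent - inconsistent)/sqrt(n); |z| >= 2 calls the state.
    """
    for g, s in targets.items():
        if s not in (+1, -1):
            raise ValueError(f"expected sign for {g!r} must be +1 or -1, got {s}")
    n_cons = n_incons = 0
    for gene, sign in targets.items():
        d = degs.directions.get(gene)
        if d is None:
            continue
        observed = +1 if d == "up" else -1
        if observed == sign:
            n_cons += 1
        else:
            n_incons += 1
    n = n_cons + n_incons
    if n == 0:
        return RegulatorCall(regulator, 0, None, "undetermined")
    z = (n_cons - n_incons) / math.sqrt(n)
    state = "activated" if z >= 2 else "inhibited" if z <= -2 else "undetermined"
    return RegulatorCall(regulator, n, z, state)
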