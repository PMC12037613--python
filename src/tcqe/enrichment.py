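"""Pathway over-representation analysis and cross-omics pathway intersection.

Over-representation uses the one-sided hypergeometric upper tail: for a
query of n ids drawn from a universe of N, a pathway with K members in
the universe and k of them in the query has

    p = P(X >= k) = sum_{i=k}^{min(K,n)} C(K,i) C(N-K,n-i) / C(N,n).

p-values are Benjamini-Hochberg adjusted across all tested pathways.
The cross-omics step is an exact set intersection of the pathway names
called enriched in each arm (network-pharmacology targets vs differential
metabolites), followed by mapping the ranked key targets onto the common
pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import GeneSetCollection

log = logging.getLogger("tcqe")


def hypergeometric_enrichment(
    query: set[str],
    sets: GeneSetCollection,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Query members outside the universe are dropped (count logged); sets
    with no member in the universe are skipped.  Returns a frame with
    columns pathway, k, K, n, N, p_value, p_adjusted sorted by p_value.
    """
    uni = set(universe) if universe is not None else sets.default_universe()
    if not uni:
        raise ValidationError("enrichment: empty universe")
    dropped = len(query - uni)
    if dropped:
        log.warning("enrichment: %d query id(s) outside the universe dropped", dropped)
    q = set(query) & uni
    N, n = len(uni), len(q)

    rows = []
    for name, members in sets.sets.items():
        pathway = set(members) & uni
        K = len(pathway)
        if K == 0:
            continue
        k = len(q & pathway)
        # upper tail P(X >= k); survival function is P(X > k-1)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway": name, "k": k, "K": K, "n": n, "N": N, "p_value": p})
    if not rows:
        return pd.DataFrame(
            columns=["pathway", "k", "K", "n", "N", "p_value", "p_adjusted"]
        )
    df = pd.DataFrame(rows)
    df["p_value"] = df["p_value"].clip(upper=1.0)
    df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["p_value", "pathway"], kind="stable").reset_index(drop=True)


def enriched_pathways(results: pd.DataFrame, p_max: float = 0.05) -> set[str]:
    """Pathways called enriched: BH-adjusted p <= p_max."""
    return set(results.loc[results["p_adjusted"] <= p_max, "pathway"])


@dataclass
class PathwayIntersection:
    pathways_arm_a: set[str]
    pathways_arm_b: set[str]
    common: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.common = sorted(self.pathways_arm_a & self.pathways_arm_b)


def intersect_pathways(arm_a: set[str], arm_b: set[str]) -> PathwayIntersection:
    """Exact, order-independent intersection of two enriched-pathway sets."""
    return PathwayIntersection(set(arm_a), set(arm_b))


def select_integrated_targets(
    key_targets: list[str],
    common_pathways: set[str] | list[str],
    sets: GeneSetCollection,
) -> list[tuple[str, list[str]]]:
    """Map ranked key targets onto the common pathways.

    Returns each key target that belongs to at least one common pathway,
    paired with the sorted list of those pathways, preserving the input
    (network) ranking of the targets.  Targets on no common pathway are
    dropped.
    """
    common = set(common_pathways)
    out: list[tuple[str, list[str]]] = []
    for target in key_targets:
        hits = sorted(
            name for name in common if name in sets.sets and target in sets.members(name)
        )
        if hits:
            out.append((target, hits))
    return out
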