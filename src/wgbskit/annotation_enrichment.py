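"""DMR composition summaries and self-contained gene-set enrichment.

Enrichment of DMR-related genes (DMGs) is a central hypergeometric
upper-tail test against user-supplied gene sets (GMT text), with BH
q-values across sets. This deliberately omits length-bias weighting
(Wallenius-style corrections need per-gene length data that is not part
of this pipeline's inputs); output metadata says so.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dmr_detection import DISTAL, Dmr

logger = logging.getLogger(__name__)

#: emitted with every enrichment table
ENRICHMENT_METHOD = "central-hypergeometric (no length-bias weighting)"


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets over a universe of annotatable gene ids."""

    sets: dict[str, tuple[str, frozenset[str]]]  # set_id -> (name, members)
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ConfigurationError("gene universe is empty")
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise ConfigurationError(f"gene set {set_id!r} is empty")
            extra = members - self.universe
            if extra:
                raise ConfigurationError(
                    f"gene set {set_id!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    @classmethod
    def from_gmt(
        cls, path: str | os.PathLike, universe: Iterable[str] | None = None
    ) -> "GeneSetCollection":
        """Read GMT: one set per line, tab-separated id, description,
        members. Universe defaults to the union of all members."""
        sets: dict[str, tuple[str, frozenset[str]]] = {}
        union: set[str] = set()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ConfigurationError(
                        f"{path}: GMT line needs id, description and at "
                        f"least one member"
                    )
                set_id, name = fields[0], fields[1]
                members = frozenset(f for f in fields[2:] if f)
                sets[set_id] = (name, members)
                union |= members
        uni = frozenset(universe) if universe is not None else frozenset(union)
        return cls(sets=sets, universe=uni)


def composition_table(dmrs: Sequence[Dmr]) -> pd.DataFrame:
    """Counts and fractions of DMRs per annotation category, by context."""
    rows = []
    for d in dmrs:
        rows.append({"context": d.context, "annotation": d.annotation})
    if not rows:
        return pd.DataFrame(
            columns=["context", "annotation", "count", "fraction"]
        )
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["context", "annotation"]).size().rename("count").reset_index()
    )
    totals = counts.groupby("context")["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts


def dmg_ids(dmrs: Sequence[Dmr], include_distal: bool = False) -> list[str]:
    """Genes with at least one mapped DMR (DMGs).

    By default distal-intergenic DMRs do not qualify their nearest gene;
    *include_distal* switches that on.
    """
    out = set()
    for d in dmrs:
        if d.gene_id is None:
            continue
        if d.annotation == DISTAL and not include_distal:
            continue
        out.add(d.gene_id)
    return sorted(out)


def enrich(
    dmg_list: Iterable[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric over-representation of DMGs in each gene set.

    For a set of size K in a universe of size N, with n DMGs of which k
    fall in the set, p = P(X >= k) for X ~ Hypergeometric(N, K, n).
    Returns a frame sorted by p with BH q-values across sets.
    """
    dmgs = set(dmg_list)
    outside = dmgs - collection.universe
    if outside:
        logger.info(
            "%d DMG(s) outside the annotation universe dropped", len(outside)
        )
        dmgs &= collection.universe
    N = len(collection.universe)
    n = len(dmgs)
    rows = []
    for set_id, (name, members) in collection.sets.items():
        K = len(members)
        k = len(dmgs & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"set_id": set_id, "name": name, "k": k, "K": K, "n": n, "N": N,
             "p_value": p}
        )
    df = pd.DataFrame(rows)
    if len(df):
        _, q, _, _ = multipletests(df["p_value"].to_numpy(), method="fdr_bh")
        df["q_value"] = q
        df = df.sort_values(["p_value", "set_id"], kind="mergesort")
        df = df.reset_index(drop=True)
    df.attrs["method"] = ENRICHMENT_METHOD
    return df
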