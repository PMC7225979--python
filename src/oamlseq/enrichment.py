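"""Pathway over-representation of mutated genes by Fisher's exact test."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["PathwayTable", "pathway_enrichment"]


@dataclass(frozen=True)
class PathwayTable:
    """Pathway -> gene-set map over a fixed gene universe."""

    pathways: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty gene universe")
        for name, genes in self.pathways.items():
            stray = set(genes) - self.universe
            if stray:
                raise ValueError(
                    f"pathway {name!r} contains genes outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    @classmethod
    def from_dict(cls, pathways: Mapping[str, Iterable[str]],
                  universe: Iterable[str] | None = None) -> "PathwayTable":
        frozen = {k: frozenset(v) for k, v in pathways.items()}
        if universe is None:
            uni = frozenset().union(*frozen.values()) if frozen else frozenset()
        else:
            uni = frozenset(universe)
        return cls(frozen, uni)


def pathway_enrichment(
    affected: Iterable[str],
    table: PathwayTable,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-pathway over-representation of mutation-affected genes.

    For each pathway a one-sided (greater) Fisher exact test of the 2x2
    table [affected in pathway, affected outside; unaffected in pathway,
    unaffected outside] over the gene universe, with BH adjustment across
    pathways (``adjust=False`` copies raw p into q). Affected genes outside
    the universe are dropped with a warning.
    """
    affected = set(affected)
    stray = affected - set(table.universe)
    if stray:
        logger.warning("dropping %d affected genes outside the universe: %s",
                       len(stray), sorted(stray)[:5])
        affected &= set(table.universe)
    n_universe = len(table.universe)
    n_affected = len(affected)

    rows = []
    for name in sorted(table.pathways):
        genes = table.pathways[name]
        k = len(affected & genes)
        m = len(genes)
        a, b = k, n_affected - k
        c, d = m - k, n_universe - m - (n_affected - k)
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({
            "pathway": name,
            "n_pathway": m,
            "n_affected_in_pathway": k,
            "n_affected": n_affected,
            "n_universe": n_universe,
            "odds_ratio": float(odds),
            "p": float(p),
        })
    frame = pd.DataFrame(rows, columns=["pathway", "n_pathway",
                                        "n_affected_in_pathway", "n_affected",
                                        "n_universe", "odds_ratio", "p"])
    if frame.empty:
        frame["q"] = pd.Series(dtype=float)
        return frame
    frame["q"] = multipletests(frame["p"], method="fdr_bh")[1] if adjust \
        else frame["p"]
    return frame
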