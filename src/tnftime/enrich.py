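"""Hypergeometric over-representation analysis over user-supplied gene sets.

Gene sets come from a GMT file (term, description, members...). For a
query list drawn from an analysis universe of N genes, a set with K
members in the universe and an overlap of k with the n query genes gets
the upper-tail hypergeometric p-value P(X >= k); p-values are BH-adjusted
across the tested terms. The universe should be the analyzed background
(e.g. all expressed genes), not the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import scipy.stats

from .diffexpr import bh_adjust


@dataclass
class GeneSetCollection:
    """term_id -> (term name, member gene ids)."""

    names: dict[str, str]
    members: dict[str, frozenset[str]]

    def __len__(self) -> int:
        return len(self.members)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a tab-separated GMT file (term, description, genes...)."""
    names: dict[str, str] = {}
    members: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT lines need term, description and >= 1 gene"
            )
        term, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if not genes:
            raise ValueError(f"{path}:{lineno}: gene set {term!r} is empty")
        if term in members:
            raise ValueError(f"{path}:{lineno}: duplicated term id {term!r}")
        names[term] = desc
        members[term] = frozenset(genes)
    return GeneSetCollection(names=names, members=members)


def hypergeom_enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    min_set_size: int = 5,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` against ``sets``.

    Set members are intersected with the universe before testing; terms
    with fewer than ``min_set_size`` universe members are skipped. Returns
    a DataFrame (term, name, k, K, n, N, p, fdr) sorted by FDR then p.
    """
    universe = frozenset(universe)
    query = frozenset(query)
    outside = query - universe
    if outside:
        raise ValueError(
            f"query gene(s) outside the universe: {sorted(outside)[:10]}"
        )
    n_query = len(query)
    n_universe = len(universe)
    rows = []
    for term in sorted(sets.members):
        in_universe = sets.members[term] & universe
        big_k = len(in_universe)
        if big_k == 0 or big_k < min_set_size:
            continue
        k = len(in_universe & query)
        p = scipy.stats.hypergeom.sf(k - 1, n_universe, big_k, n_query)
        rows.append(
            {
                "term": term,
                "name": sets.names[term],
                "k": k,
                "K": big_k,
                "n": n_query,
                "N": n_universe,
                "p": float(p),
            }
        )
    result = pd.DataFrame(
        rows, columns=["term", "name", "k", "K", "n", "N", "p"]
    )
    if len(result):
        result["fdr"] = bh_adjust(result["p"].to_numpy())
        result = result.sort_values(["fdr", "p", "term"], ignore_index=True)
    else:
        result["fdr"] = pd.Series(dtype=float)
    return result
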