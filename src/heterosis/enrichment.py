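"""Hypergeometric over-representation of a gene list against GMT collections.

Given a query (for instance the non-additively expressed genes), a background
universe and a gene-set collection, each term is scored by the upper tail of
the hypergeometric distribution, P(X >= k) for X ~ Hypergeom(N, K, n), with
Benjamini-Hochberg correction across the terms that survive the size filters.
Collections (e.g. GO vs KEGG) are corrected separately by calling
:func:`enrich` once per collection. Results are fully deterministic; ties in
p are broken by term identifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeometric_tail",
    "enrich",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene set members must be non-empty")


@dataclass(frozen=True)
class GeneSetCollection:
    """Mapping term_id -> GeneSet with unique term identifiers."""

    sets: Mapping[str, GeneSet]

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.sets[term_id]

    def term_ids(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (term_id <tab> description <tab> genes...).

    Duplicate genes within a line are deduplicated with a warning; a line
    with fewer than three fields or a repeated term id is an error.
    """
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields (need >= 3)"
                )
            term_id, name, *genes = fields
            if term_id in sets:
                raise ValueError(f"{path}: duplicate term id {term_id!r} at line {lineno}")
            unique = frozenset(genes)
            if len(unique) < len(genes):
                logger.warning(
                    "%s: line %d (%s): %d duplicate gene(s) removed",
                    path, lineno, term_id, len(genes) - len(unique),
                )
            sets[term_id] = GeneSet(name=name, genes=unique)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for term_id, gs in collection.sets.items():
            fh.write("\t".join([term_id, gs.name, *sorted(gs.genes)]) + "\n")


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` = query/term overlap, ``K`` = term size in the universe, ``n`` =
    query size, ``N`` = universe size.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K <= N and 0 <= n <= N (k={k}, K={K}, n={n}, N={N})")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n) (k={k}, K={K}, n={n}, N={N})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 2000,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``query`` within ``universe`` for each term.

    Terms are intersected with the universe before size filtering; BH runs
    across surviving terms only. Returns a DataFrame with columns
    ``term_id, name, k, K, n, N, p, q, significant`` sorted by (p, term_id).
    """
    query = set(query)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    offenders = sorted(query - universe)
    if offenders:
        raise ValueError(
            f"query genes outside the universe (up to 20 shown): {offenders[:20]}"
        )
    N = len(universe)
    n = len(query)
    rows = []
    for term_id, gs in collection.sets.items():
        members = gs.genes & universe
        K = len(members)
        if K < min_size or K > max_size:
            continue
        k = len(members & query)
        rows.append(
            {
                "term_id": term_id,
                "name": gs.name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeometric_tail(k, K, n, N),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "name", "k", "K", "n", "N", "p"]
    )
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < q_threshold
        out = out.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
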