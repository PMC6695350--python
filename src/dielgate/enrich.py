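"""Over-representation statistics for gene-set overlaps.

Two equivalent views of the same exact test are provided:

* :func:`hypergeometric_overlap` — tail probabilities of the overlap k
  between a query and a reference set drawn from a finite universe,
  with an upper tail for enrichment (P(X >= k)) and a lower tail for
  depletion (P(X <= k));
* :func:`fisher_overrepresentation` — the one-sided Fisher exact test of
  the corresponding 2x2 table per set in a collection, with
  Benjamini-Hochberg adjustment across the collection.

Genes outside the declared universe are dropped (with a warning) before
counting, so cross-study comparisons are always restricted to the genes
detectable in both experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneSetCollection, ValidationError
from .de import bh_adjust


@dataclass
class EnrichmentResult:
    """Overlap counts and exact p-values, one row per tested set.

    ``table`` columns: ``universe_N``, ``set_K``, ``query_n``,
    ``overlap_k``, ``expected`` (= nK/N), ``p``, ``q`` (BH across the
    collection) and ``tail``.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


def _restrict(name: str, genes, universe: set) -> set:
    genes = set(genes)
    outside = genes - universe
    if outside:
        warnings.warn(
            f"{len(outside)} gene(s) in {name} are outside the universe "
            "and were dropped",
            stacklevel=3,
        )
    return genes & universe


def _tail_p(N: int, K: int, n: int, k: int, tail: str) -> float:
    """Exact hypergeometric tail; the point mass at k is included in both."""
    if tail == "enrichment":
        return float(stats.hypergeom.sf(k - 1, N, K, n))
    if tail == "depletion":
        return float(stats.hypergeom.cdf(k, N, K, n))
    raise ValidationError(f"tail must be 'enrichment' or 'depletion', got {tail!r}")


def hypergeometric_overlap(
    query, reference, universe, tail: str = "enrichment"
) -> EnrichmentResult:
    """Exact overlap test between a query and a single reference set."""
    universe = set(universe)
    if not universe:
        raise ValidationError("universe is empty")
    q = _restrict("query", query, universe)
    r = _restrict("reference", reference, universe)
    N, K, n = len(universe), len(r), len(q)
    k = len(q & r)
    table = pd.DataFrame(
        {
            "universe_N": [N],
            "set_K": [K],
            "query_n": [n],
            "overlap_k": [k],
            "expected": [n * K / N],
            "p": [_tail_p(N, K, n, k, tail)],
            "tail": [tail],
        },
        index=pd.Index(["reference"], name="set"),
    )
    table["q"] = table["p"]
    return EnrichmentResult(table)


def fisher_overrepresentation(
    query, sets: GeneSetCollection, universe, tail: str = "enrichment"
) -> EnrichmentResult:
    """One-sided Fisher exact over-representation per set, BH across sets.

    The one-sided Fisher p of the 2x2 table (in/out query x in/out set)
    equals the hypergeometric tail probability of the overlap, so results
    are directly comparable with :func:`hypergeometric_overlap`.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("universe is empty")
    q = _restrict("query", query, universe)
    N, n = len(universe), len(q)
    rows = []
    for name in sets.names():
        members = _restrict(f"set {name!r}", sets[name], universe)
        K = len(members)
        k = len(q & members)
        rows.append(
            {
                "set": name,
                "universe_N": N,
                "set_K": K,
                "query_n": n,
                "overlap_k": k,
                "expected": n * K / N,
                "p": _tail_p(N, K, n, k, tail),
                "tail": tail,
            }
        )
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = bh_adjust(table["p"].to_numpy())
    return EnrichmentResult(table)
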