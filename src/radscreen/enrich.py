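"""Gene-set over-representation analysis (hypergeometric ORA).

Tests whether a query list (e.g. DEGs) overlaps a named gene set more
than expected by chance, against the background of all expressed genes
(the universe).  The p-value is the hypergeometric upper tail
P(X >= k) for overlap k, set size K, query size n, universe size N —
the >= convention, since off-by-one here is a classic source of
discrepancies between tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .screen import bh_adjust

__all__ = ["GeneSetCollection", "read_gmt", "ora", "hypergeom_upper_tail"]


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) — the ORA p-value."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member...

    Duplicate members within a set are counted once (with a warning);
    a duplicate set name or a line with fewer than three fields is an
    error naming the line.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            uniq = frozenset(members)
            if len(uniq) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} has duplicate members; deduplicated",
                    stacklevel=2,
                )
            sets[name] = uniq
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def ora(
    query,
    sets: GeneSetCollection | dict,
    universe,
    min_k: int = 1,
    set_size_bounds: tuple[int, int] = (5, 500),
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each set.

    Parameters
    ----------
    query
        Gene ids of interest; members outside the universe are dropped
        with a warning.
    sets
        A :class:`GeneSetCollection` or plain mapping name -> genes.
    universe
        Background gene ids (all expressed genes).
    min_k
        Minimum overlap for a set to be tested (0 tests everything,
        including sets the query misses entirely, which get p = 1).
    set_size_bounds
        (lo, hi) bounds on set size *after* intersection with the
        universe; sets outside are excluded and listed in
        ``result.attrs["excluded"]``.

    Returns
    -------
    pandas.DataFrame
        One row per tested set: K, n, k, N, p, q (BH across tested
        sets), and the overlapping gene ids, sorted by p.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    qset = set(query)
    if not qset:
        raise ValueError("empty query")
    outside = qset - uni
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped", stacklevel=2
        )
        qset &= uni
        if not qset:
            raise ValueError("no query gene lies in the universe")
    mapping = sets.sets if isinstance(sets, GeneSetCollection) else sets

    N, n = len(uni), len(qset)
    lo, hi = set_size_bounds
    rows, excluded = [], []
    for name in sorted(mapping):
        members = set(mapping[name]) & uni
        K = len(members)
        if not lo <= K <= hi:
            excluded.append(name)
            continue
        overlap = sorted(members & qset)
        k = len(overlap)
        if k < min_k:
            excluded.append(name)
            continue
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append(
            {
                "set": name,
                "K": K,
                "n": n,
                "k": k,
                "N": N,
                "p": min(p, 1.0),
                "genes": ",".join(overlap),
            }
        )
    result = pd.DataFrame(rows, columns=["set", "K", "n", "k", "N", "p", "genes"])
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result = result[["set", "K", "n", "k", "N", "p", "q", "genes"]]
        result = result.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    else:
        result["q"] = []
    result.attrs["excluded"] = excluded
    return result
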