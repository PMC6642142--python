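"""Over-representation analysis of gene lists against gene-set
collections.

For a universe of N genes, a set with K members in the universe, and a
query list of n genes with k hits in the set, the right-tail
hypergeometric p = P[X >= k], X ~ Hypergeom(N, K, n) — the one-sided
Fisher exact enrichment test.  Benjamini-Hochberg adjustment is applied
across all tested sets.  The default universe is the assay platform
(every feature that was tested for differential expression), not the
genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

__all__ = ["EnrichmentRecord", "hypergeom_ora", "bh_adjust"]


@dataclass(frozen=True)
class EnrichmentRecord:
    set_id: str
    description: str
    overlap_count: int  # k
    list_size: int      # n
    set_size: int       # K (after intersecting with the universe)
    universe_size: int  # N
    p: float
    q: float


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values:
    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_ora(
    gene_list: Iterable[str],
    universe: Iterable[str],
    gene_sets: GeneSetCollection,
) -> list[EnrichmentRecord]:
    """Right-tail hypergeometric ORA of ``gene_list`` against every set,
    each intersected with ``universe`` first.  Records are sorted by p
    then set_id; BH q across all tested sets."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    query = set(gene_list)
    stray = sorted(query - uni)
    if stray:
        raise ValueError(f"genes in list but not universe: {stray}")
    n_univ, n_list = len(uni), len(query)
    rows = []
    for sid, (desc, members) in gene_sets.sets.items():
        in_uni = set(members) & uni
        if not in_uni:
            continue
        k = len(query & in_uni)
        big_k = len(in_uni)
        p = float(hypergeom.sf(k - 1, n_univ, big_k, n_list))
        rows.append((sid, desc, k, big_k, min(p, 1.0)))
    q = bh_adjust([r[4] for r in rows])
    records = [
        EnrichmentRecord(
            set_id=sid, description=desc, overlap_count=k, list_size=n_list,
            set_size=big_k, universe_size=n_univ, p=p, q=float(qi),
        )
        for (sid, desc, k, big_k, p), qi in zip(rows, q)
    ]
    records.sort(key=lambda r: (r.p, r.set_id))
    return records
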