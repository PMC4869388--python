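"""Exhaustive scoring of every SNP combination of orders 1..n.

Each order is processed in two passes over the lexicographic stream of
combinations: the first accumulates the mean |CI| that anchors the NCI
normalization, the second ranks by NCI while keeping only a bounded heap of
the current top K.  This keeps memory at O(top_k) per order even in the
C(10^4, 3) regime.
"""

from __future__ import annotations

import heapq
import logging
from itertools import combinations
from typing import Iterator

from .co_information import CoInformationEngine, NormalizationContext, nci
from .data_io import EffectRecord, GenotypeDataset
from .errors import DegeneratePhenotypeError

__all__ = ["enumerate_combinations", "exhaustive_search"]

logger = logging.getLogger(__name__)

_PROGRESS_EVERY = 1_000_000


def enumerate_combinations(n_snps: int, order: int) -> Iterator[tuple[int, ...]]:
    """Yield all C(N, order) sorted 1-based index tuples in lexicographic order."""
    if not 1 <= order <= n_snps:
        raise ValueError(f"order must be in [1, {n_snps}], got {order}")
    return combinations(range(1, n_snps + 1), order)


def exhaustive_search(
    dataset: GenotypeDataset,
    max_order: int,
    top_k: int,
) -> dict[int, list[EffectRecord]]:
    """Score every combination of each order 1..max_order; return ranked top-k lists.

    Per order, all C(N, k) combinations are scored by CI, the normalization
    context is built from the complete per-order CI sets, and records are
    ranked by descending NCI with ties broken by ascending lexicographic
    tuple.  Deterministic.
    """
    n = dataset.n_snps
    if not 1 <= max_order <= n:
        raise ValueError(f"max_order must be in [1, {n}], got {max_order}")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    engine = CoInformationEngine(dataset, memoize_ci=False)
    if engine.h_pheno <= 0:
        raise DegeneratePhenotypeError("phenotype entropy is zero")

    # pass 1: mean |CI| per order
    means: dict[int, float] = {}
    for order in range(1, max_order + 1):
        total = 0.0
        count = 0
        for combo in enumerate_combinations(n, order):
            total += abs(engine.ci(combo))
            count += 1
            if count % _PROGRESS_EVERY == 0:
                logger.info("order %d: scored %d combinations (pass 1)", order, count)
        means[order] = total / count
    ctx = NormalizationContext(h_pheno=engine.h_pheno, mean_ci_by_order=means)

    # pass 2: top-k heap per order, ranked by NCI (ties: lexicographically
    # smaller tuple wins, hence the negated tuple in the heap key)
    results: dict[int, list[EffectRecord]] = {}
    for order in range(1, max_order + 1):
        heap: list[tuple[float, tuple[int, ...], float]] = []
        count = 0
        for combo in enumerate_combinations(n, order):
            ci_val = engine.ci(combo)
            nci_val = nci(ci_val, order, ctx)
            key = (nci_val, tuple(-s for s in combo))
            if len(heap) < top_k:
                heapq.heappush(heap, (*key, ci_val))
            elif key > heap[0][:2]:
                heapq.heapreplace(heap, (*key, ci_val))
            count += 1
            if count % _PROGRESS_EVERY == 0:
                logger.info("order %d: scored %d combinations (pass 2)", order, count)
        ranked = sorted(heap, key=lambda item: (-item[0], tuple(-s for s in item[1])))
        results[order] = [
            EffectRecord(
                snps=tuple(-s for s in neg_combo),
                order=order,
                ci=ci_val,
                nci=nci_val,
            )
            for nci_val, neg_combo, ci_val in ranked
        ]
    return results
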