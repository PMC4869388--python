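"""Co-information based association measures between SNP sets and the phenotype.

The central quantity is the co-information (interaction information) of *n*
SNP columns S1..Sn and the binary phenotype C,

    CI(S1;...;Sn;C) = - sum_{T subseteq V} (-1)^(n+1-|T|) H(T),

an alternating sum of joint entropies over every subset T of
V = {S1, ..., Sn, C}.  For n = 1 this reduces to the mutual information
I(S;C) >= 0; for n >= 2 the sign carries meaning (positive: synergy,
negative: redundancy).  All entropies use log base 2 (bits); probabilities
are maximum-likelihood cell frequencies with 0 log 0 := 0.

Because CI magnitudes shrink systematically with the order, combinations of
different orders are ranked on a normalized scale,

    NCI = (CI / H(C)) * (mean|CI_1| / mean|CI_n|),

where the order means are taken over all *considered* combinations of each
order (all of them in an exhaustive search; the distinct evaluated ones in a
stochastic search).  The cumulative measure CCI sums NCI over a combination
and those of its subsets that pass per-order thresholds.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_io import EffectRecord, GenotypeDataset
from .errors import (
    DegeneratePhenotypeError,
    MissingOrderError,
    UndefinedNormalizationError,
)

__all__ = [
    "joint_entropy",
    "co_information",
    "CoInformationEngine",
    "NormalizationContext",
    "ThresholdSet",
    "build_normalization_context",
    "nci",
    "cci",
]


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def joint_entropy(*columns: Sequence[int]) -> float:
    """Joint entropy, in bits, of one or more categorical vectors.

    Cells are the observed joint categories; unobserved cells contribute
    nothing.  Raises ``ValueError`` on length mismatch.
    """
    if not columns:
        raise ValueError("at least one column is required")
    arrays = [np.asarray(c) for c in columns]
    m = arrays[0].shape[0]
    if m < 1:
        raise ValueError("columns must be non-empty")
    if any(a.ndim != 1 or a.shape[0] != m for a in arrays):
        raise ValueError("all columns must be one-dimensional and of equal length")
    if len(arrays) == 1:
        _, counts = np.unique(arrays[0], return_counts=True)
    else:
        _, counts = np.unique(np.stack(arrays, axis=1), axis=0, return_counts=True)
    return _entropy_from_counts(counts)


class CoInformationEngine:
    """Entropy/co-information evaluator bound to one dataset.

    Genotype columns have radix 3 and the phenotype radix 2, so a joint cell
    is a mixed-radix code amenable to ``bincount``; small subsets (singles
    and pairs) are memoized because inclusion-exclusion revisits them across
    overlapping combinations.
    """

    _MEMO_MAX_SNPS = 2  # memoize subset entropies up to this many SNP columns
    _BINCOUNT_LIMIT = 1 << 22

    def __init__(self, dataset: GenotypeDataset, memoize_ci: bool = True):
        self.dataset = dataset
        self._geno = dataset.genotypes.astype(np.int64)
        self._pheno = dataset.phenotype.astype(np.int64)
        self._m = dataset.n_individuals
        self._memoize_ci = memoize_ci
        self._entropy_memo: dict[tuple[tuple[int, ...], bool], float] = {}
        self._ci_memo: dict[tuple[int, ...], float] = {}
        self.h_pheno = self.entropy((), with_pheno=True)

    def entropy(self, snps: tuple[int, ...], with_pheno: bool) -> float:
        """Joint entropy in bits of the given 1-based SNP columns (+ phenotype)."""
        if not snps and not with_pheno:
            return 0.0
        key = (snps, with_pheno)
        memo = len(snps) <= self._MEMO_MAX_SNPS
        if memo and key in self._entropy_memo:
            return self._entropy_memo[key]
        code = np.zeros(self._m, dtype=np.int64)
        radix = 1
        for s in snps:
            code = code * 3 + self._geno[:, s - 1]
            radix *= 3
        if with_pheno:
            code = code * 2 + self._pheno
            radix *= 2
        if radix <= max(self._BINCOUNT_LIMIT, 4 * self._m):
            counts = np.bincount(code, minlength=0)
            counts = counts[counts > 0]
        else:
            _, counts = np.unique(code, return_counts=True)
        h = _entropy_from_counts(counts)
        if memo:
            self._entropy_memo[key] = h
        return h

    def ci(self, snps: Iterable[int]) -> float:
        """Co-information CI(S1;...;Sn;C) for a tuple of distinct SNP indices."""
        key = tuple(sorted(int(s) for s in snps))
        n = len(key)
        if n == 0:
            raise ValueError("at least one SNP index is required")
        if len(set(key)) != n:
            raise ValueError(f"duplicate SNP indices in {key}")
        if key[0] < 1 or key[-1] > self.dataset.n_snps:
            raise IndexError(f"SNP indices {key} outside [1, {self.dataset.n_snps}]")
        if key in self._ci_memo:
            return self._ci_memo[key]
        total = 0.0
        # subsets T of V = {S1..Sn, C}; sign (-1)^(n+1-|T|), H(empty) = 0
        for r in range(n + 1):
            for sub in combinations(key, r):
                for with_pheno in (False, True):
                    size = r + with_pheno
                    if size == 0:
                        continue
                    sign = -1.0 if (n + 1 - size) % 2 == 0 else 1.0
                    total += sign * self.entropy(sub, with_pheno)
        if self._memoize_ci:
            self._ci_memo[key] = total
        return total


def co_information(dataset: GenotypeDataset, snps: Sequence[int]) -> float:
    """Co-information, in bits, between the given SNPs and the phenotype."""
    return CoInformationEngine(dataset).ci(snps)


@dataclasses.dataclass(frozen=True)
class NormalizationContext:
    """Phenotype entropy plus per-order mean |CI| magnitudes.

    Turns a raw CI value into the order-normalized NCI.  ``mean_ci_by_order``
    holds the mean magnitude over the combinations considered at each order.
    """

    h_pheno: float
    mean_ci_by_order: Mapping[int, float]

    def __post_init__(self):
        if self.h_pheno <= 0:
            raise DegeneratePhenotypeError("H(C) must be > 0 to normalize")
        if 1 not in self.mean_ci_by_order:
            raise MissingOrderError("order-1 mean is required (the NCI reference scale)")
        if any(v < 0 for v in self.mean_ci_by_order.values()):
            raise ValueError("mean |CI| magnitudes must be non-negative")
        object.__setattr__(self, "mean_ci_by_order", dict(self.mean_ci_by_order))

    @property
    def mean_ci_order1(self) -> float:
        return self.mean_ci_by_order[1]


@dataclasses.dataclass(frozen=True)
class ThresholdSet:
    """Per-order NCI thresholds defining the set CS of contributing combinations.

    A combination belongs to CS when a threshold is stated for its order and
    its NCI reaches it; orders without a stated threshold never contribute.
    """

    by_order: Mapping[int, float]

    def __post_init__(self):
        object.__setattr__(self, "by_order", dict(self.by_order))

    def passes(self, order: int, nci_value: float) -> bool:
        thr = self.by_order.get(order)
        return thr is not None and nci_value >= thr


def build_normalization_context(
    dataset: GenotypeDataset,
    considered: Mapping[int, Sequence[tuple[int, ...]]],
    engine: CoInformationEngine | None = None,
) -> NormalizationContext:
    """Build the NCI context from explicit per-order lists of combinations.

    ``considered[k]`` are the order-k tuples whose |CI| values are averaged;
    the order-1 list must be present and non-empty.
    """
    eng = engine if engine is not None else CoInformationEngine(dataset)
    if eng.h_pheno <= 0:
        raise DegeneratePhenotypeError("phenotype entropy is zero")
    if 1 not in considered or len(considered[1]) == 0:
        raise MissingOrderError("considered[1] must be a non-empty list of single SNPs")
    means: dict[int, float] = {}
    for order, tuples in considered.items():
        if len(tuples) == 0:
            raise MissingOrderError(f"no combinations listed for order {order}")
        vals = [abs(eng.ci(t)) for t in tuples]
        means[order] = float(np.mean(vals))
    return NormalizationContext(h_pheno=eng.h_pheno, mean_ci_by_order=means)


def nci(ci_value: float, order: int, ctx: NormalizationContext) -> float:
    """Order-normalized interaction effect NCI = (CI/H(C)) * (mean|CI_1|/mean|CI_n|).

    For order 1 the balance coefficient is exactly 1, so NCI = I(S;C)/H(C).
    """
    if order == 1:
        return ci_value / ctx.h_pheno
    if order not in ctx.mean_ci_by_order:
        raise MissingOrderError(f"no mean |CI| recorded for order {order}")
    denom = ctx.mean_ci_by_order[order]
    if denom <= 0:
        raise UndefinedNormalizationError(f"mean |CI| for order {order} is zero")
    return (ci_value / ctx.h_pheno) * (ctx.mean_ci_order1 / denom)


def cci(
    target: Sequence[int],
    scored: Sequence[EffectRecord],
    thresholds: ThresholdSet,
) -> float:
    """Cumulative interaction effect of ``target``.

    Sums NCI over every non-empty subset of the target (the target itself
    included) that has a record in ``scored`` and whose NCI passes the
    threshold for its order.  Subsets without a record contribute nothing.
    """
    key = tuple(sorted(int(s) for s in target))
    lookup = {rec.snps: rec for rec in scored}
    total = 0.0
    for r in range(1, len(key) + 1):
        for sub in combinations(key, r):
            rec = lookup.get(sub)
            if rec is not None and thresholds.passes(len(sub), rec.nci):
                total += rec.nci
    return total
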