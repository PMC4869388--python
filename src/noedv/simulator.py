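"""Case-control genotype simulator driven by penetrance models.

Ground-truth SNPs are sampled under Hardy-Weinberg equilibrium at their
minor-allele frequencies and disease status is assigned with probability
f(g), the penetrance of the joint ground-truth genotype g.  Rejection
sampling continues until exact case/control quotas are met; background SNPs
(independent, no LD) are then drawn at MAFs uniform over a configured
range.  The module also provides the analytic prevalence and per-SNP
marginal penetrance of a model — a model is *pure* (no main effects) when
every SNP's marginal penetrance is constant across its three genotypes —
and the Power1/2/3 evaluation of detector output over replicates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data_io import EffectRecord, GenotypeDataset, default_snp_names
from .errors import FormatError, InfeasibleModelError

__all__ = [
    "PenetranceModel",
    "SimulationConfig",
    "SimulationResult",
    "genotype_frequencies",
    "prevalence",
    "marginal_penetrance",
    "simulate_dataset",
    "evaluate_power",
    "read_model_file",
    "write_model_file",
]

_MAX_ATTEMPTS = 10_000_000


@dataclasses.dataclass(frozen=True)
class PenetranceModel:
    """MAFs of the k ground-truth SNPs plus the 3^k penetrance table.

    ``table`` is indexed with the genotype of SNP 1 varying slowest (C-order
    over the (3, ..., 3) genotype grid); entries are disease probabilities.
    """

    mafs: tuple[float, ...]
    table: np.ndarray

    def __post_init__(self):
        mafs = tuple(float(m) for m in self.mafs)
        if any(not 0 < m <= 0.5 for m in mafs):
            raise ValueError(f"MAFs must lie in (0, 0.5], got {mafs}")
        k = len(mafs)
        table = np.asarray(self.table, dtype=float).reshape(-1)
        if table.size != 3**k:
            raise ValueError(f"penetrance table must have 3^{k} = {3**k} entries, got {table.size}")
        if np.any((table < 0) | (table > 1)):
            raise ValueError("penetrance values must lie in [0, 1]")
        object.__setattr__(self, "mafs", mafs)
        object.__setattr__(self, "table", table.reshape((3,) * k))

    @property
    def n_truth_snps(self) -> int:
        return len(self.mafs)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Panel size, exact case/control quotas, background MAF range, and seed."""

    n_snps: int
    cases: int
    controls: int
    background_maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int | None = None

    def __post_init__(self):
        if self.cases < 1 or self.controls < 1:
            raise ValueError("cases and controls must both be >= 1")
        lo, hi = self.background_maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("background MAF range must lie within (0, 0.5]")


@dataclasses.dataclass(frozen=True)
class SimulationResult:
    """A simulated dataset plus its ground truth.

    ``truth``: sorted 1-based column indices of the ground-truth SNPs;
    ``truth_positions``: same columns in model-SNP order (position i hosts
    model SNP i); ``background_mafs``: the drawn MAF of every column (NaN at
    truth columns).
    """

    dataset: GenotypeDataset
    truth: tuple[int, ...]
    truth_positions: tuple[int, ...]
    background_mafs: np.ndarray


def genotype_frequencies(maf: float) -> tuple[float, float, float]:
    """HWE genotype probabilities (p^2, 2pq, q^2) for codes (0, 1, 2), q = MAF."""
    if not 0 < maf <= 0.5:
        raise ValueError(f"MAF must lie in (0, 0.5], got {maf}")
    q = maf
    p = 1.0 - q
    return (p * p, 2 * p * q, q * q)


def _genotype_grid_probs(model: PenetranceModel) -> np.ndarray:
    """Joint HWE probability of every genotype combination, shaped (3,)*k."""
    probs = np.ones((), dtype=float)
    for maf in model.mafs:
        probs = np.multiply.outer(probs, np.asarray(genotype_frequencies(maf)))
    return probs


def prevalence(model: PenetranceModel) -> float:
    """Population disease probability: sum_g P(g) f(g) under HWE genotypes."""
    return float((_genotype_grid_probs(model) * model.table).sum())


def marginal_penetrance(model: PenetranceModel, snp: int) -> tuple[float, float, float]:
    """E[f | SNP = v] for v in (0, 1, 2), averaging over the other SNPs' HWE.

    ``snp`` is the 1-based index within the model.  A model is pure when
    this triple is constant (equal to the prevalence) for every SNP.
    """
    k = model.n_truth_snps
    if not 1 <= snp <= k:
        raise ValueError(f"model SNP index must be in [1, {k}]")
    axis = snp - 1
    probs = _genotype_grid_probs(model)
    other_axes = tuple(a for a in range(k) if a != axis)
    joint = (probs * model.table).sum(axis=other_axes)
    weight = probs.sum(axis=other_axes)
    return tuple(float(j / w) for j, w in zip(joint, weight))


def simulate_dataset(
    model: PenetranceModel,
    config: SimulationConfig,
) -> SimulationResult:
    """Draw a case-control dataset with exact quotas; reproducible from the seed.

    Ground-truth SNPs are placed at recorded random columns.  Disease status
    depends only on the ground-truth genotypes, so rejection sampling runs
    on those k columns alone and background genotypes are generated for the
    accepted individuals afterwards.
    """
    k = model.n_truth_snps
    if config.n_snps < k:
        raise ValueError(f"n_snps must be >= {k} ground-truth SNPs")
    prev = prevalence(model)
    if prev == 0.0 and config.cases > 0:
        raise InfeasibleModelError("model prevalence is 0; no cases can be generated")
    if prev == 1.0 and config.controls > 0:
        raise InfeasibleModelError("model prevalence is 1; no controls can be generated")

    rng = np.random.default_rng(config.seed)
    positions = rng.choice(config.n_snps, size=k, replace=False) + 1  # model order

    flat_table = model.table.reshape(-1)
    need_cases, need_controls = config.cases, config.controls
    kept_geno: list[np.ndarray] = []
    kept_pheno: list[np.ndarray] = []
    attempts = 0
    batch = max(2 * (config.cases + config.controls), 1000)
    while need_cases > 0 or need_controls > 0:
        if attempts >= _MAX_ATTEMPTS:
            raise InfeasibleModelError(
                f"exceeded {_MAX_ATTEMPTS} sampled individuals without filling quotas"
            )
        b = min(batch, _MAX_ATTEMPTS - attempts)
        attempts += b
        geno = np.empty((b, k), dtype=np.int8)
        for j, maf in enumerate(model.mafs):
            geno[:, j] = rng.choice(3, size=b, p=genotype_frequencies(maf))
        flat_idx = np.zeros(b, dtype=np.int64)
        for j in range(k):
            flat_idx = flat_idx * 3 + geno[:, j]
        disease = rng.random(b) < flat_table[flat_idx]
        # accept in draw order, skipping individuals of an already-filled class
        case_idx = np.flatnonzero(disease)[:need_cases]
        control_idx = np.flatnonzero(~disease)[:need_controls]
        take = np.sort(np.concatenate([case_idx, control_idx]))
        kept_geno.append(geno[take])
        kept_pheno.append(disease[take].astype(np.int8))
        need_cases -= case_idx.size
        need_controls -= control_idx.size

    truth_geno = np.concatenate(kept_geno, axis=0)
    phenotype = np.concatenate(kept_pheno)
    m = truth_geno.shape[0]

    genotypes = np.empty((m, config.n_snps), dtype=np.int8)
    background_mafs = np.full(config.n_snps, np.nan)
    truth_cols = set(int(p) for p in positions)
    lo, hi = config.background_maf_range
    for col in range(1, config.n_snps + 1):
        if col in truth_cols:
            continue
        maf = rng.uniform(lo, hi)
        background_mafs[col - 1] = maf
        genotypes[:, col - 1] = rng.choice(3, size=m, p=genotype_frequencies(maf))
    for j, col in enumerate(positions):
        genotypes[:, col - 1] = truth_geno[:, j]

    dataset = GenotypeDataset(genotypes, phenotype, tuple(default_snp_names(config.n_snps)))
    return SimulationResult(
        dataset=dataset,
        truth=tuple(sorted(int(p) for p in positions)),
        truth_positions=tuple(int(p) for p in positions),
        background_mafs=background_mafs,
    )


def evaluate_power(
    results: Sequence,
    truth: Sequence[int],
    top_k: int,
) -> tuple[float, float, float]:
    """Replicate-level detection power of ranked effect lists.

    Over replicates (each a ranked list of records, or an order->list map
    merged by descending NCI): Power1 = fraction where at least one
    ground-truth SNP appears among the top-k records; Power2 = fraction
    where every ground-truth SNP appears (possibly across records);
    Power3 = fraction where the exact ground-truth combination is itself a
    reported record.  Power3 <= Power2 <= Power1 by construction.
    """
    if len(results) == 0:
        raise ValueError("at least one replicate is required")
    truth_set = set(int(s) for s in truth)
    truth_tuple = tuple(sorted(truth_set))
    hits1 = hits2 = hits3 = 0
    for rep in results:
        if isinstance(rep, Mapping):
            records = sorted(
                (r for recs in rep.values() for r in recs),
                key=lambda r: (-r.nci, r.snps),
            )
        else:
            records = list(rep)
        records = records[:top_k]
        reported = {s for rec in records for s in rec.snps}
        if truth_set & reported:
            hits1 += 1
        if truth_set <= reported:
            hits2 += 1
        if any(rec.snps == truth_tuple for rec in records):
            hits3 += 1
    n = len(results)
    return (hits1 / n, hits2 / n, hits3 / n)


def interaction_threshold_model(
    maf: float = 0.5,
    baseline: float = 0.05,
    risk: float = 0.8,
) -> PenetranceModel:
    """Two-SNP threshold model with both marginal and interaction effects.

    Penetrance jumps from ``baseline`` to ``risk`` only when *both* SNPs
    carry at least one minor allele; a strong, high-heritability pairwise
    interaction that also leaves visible main effects.
    """
    table = np.full((3, 3), baseline)
    table[1:, 1:] = risk
    return PenetranceModel(mafs=(maf, maf), table=table)


def xor_model(maf: float = 0.5) -> PenetranceModel:
    """Deterministic two-SNP parity model: disease iff g1 + g2 is odd.

    Penetrance is 0/1, so the phenotype is an exact function of the two
    ground-truth genotypes — the classic pure-synergy fixture.
    """
    g = np.arange(3)
    table = ((g[:, None] + g[None, :]) % 2).astype(float)
    return PenetranceModel(mafs=(maf, maf), table=table)


def read_model_file(path: str | Path) -> PenetranceModel:
    """Parse a model file: a MAF line then the 3^k penetrance values.

    Values are comma- or whitespace-separated; penetrance entries may span
    several lines and follow C-order (genotype of SNP 1 slowest).  Lines
    starting with '#' are comments.
    """
    numbers: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            try:
                numbers.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"non-numeric value in model file {path}: {line!r}") from exc
    if not numbers:
        raise FormatError(f"model file {path} is empty")
    mafs = numbers[0]
    table = [v for row in numbers[1:] for v in row]
    if len(table) != 3 ** len(mafs):
        raise FormatError(
            f"expected 3^{len(mafs)} = {3 ** len(mafs)} penetrance values, got {len(table)}"
        )
    return PenetranceModel(mafs=tuple(mafs), table=np.asarray(table))


def write_model_file(model: PenetranceModel, path: str | Path) -> None:
    """Inverse of :func:`read_model_file` (one penetrance row per slowest index)."""
    with open(path, "w") as fh:
        fh.write(",".join(repr(m) for m in model.mafs) + "\n")
        flat = model.table.reshape(-1)
        per_row = 3 ** (model.n_truth_snps - 1)
        for i in range(0, flat.size, per_row):
            fh.write(",".join(repr(float(v)) for v in flat[i : i + per_row]) + "\n")
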