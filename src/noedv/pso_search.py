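"""Particle-swarm search for epistatic interactions of mixed orders 1..n.

Each particle carries its own interaction order K (fixed at initialization,
drawn uniformly from [1, n]), a position of K distinct 1-based SNP indices,
and a real-valued velocity per component.  The fitness is NCI; because NCI
is a positive rescaling of CI within an order, particles compare candidate
solutions on the raw CI scale and the NCI is attached when results are
reported under the final normalization context.

Three modifications distinguish this swarm from the textbook PSO:

* per-order global bests: Gbest is kept separately for every order present
  in the swarm, so particles of different orders do not compete;
* a dynamic inertia weight driven by how often a SNP has appeared in the
  personal bests so far — rare SNPs keep exploring (W -> 1), ubiquitous
  ones exploit (W -> 0);
* opposition-based learning: alongside each updated position its mirror
  1 + N - position is evaluated, widening coverage of the index range.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .co_information import CoInformationEngine, NormalizationContext, nci
from .data_io import EffectRecord, GenotypeDataset
from .errors import DegeneratePhenotypeError

__all__ = [
    "PsoParams",
    "Particle",
    "Swarm",
    "initialize_swarm",
    "inertia_weight",
    "update_velocity",
    "update_position",
    "opposite_position",
    "step",
    "pso_search",
    "run_pso",
]


@dataclasses.dataclass(frozen=True)
class PsoParams:
    """Swarm configuration: Q particles, G iterations, acceleration c1/c2.

    ``max_order`` is the largest interaction order n considered; particle
    orders are drawn uniformly from [1, n].  Defaults Q=500, G=10 follow the
    reference benchmark setting; c1 = c2 = 2.0 are the classical PSO
    acceleration constants.
    """

    max_order: int
    particles: int = 500
    iterations: int = 10
    c1: float = 2.0
    c2: float = 2.0
    seed: int | None = None

    def __post_init__(self):
        if self.particles < 1:
            raise ValueError("particle count must be >= 1")
        if self.iterations < 1:
            raise ValueError("iteration count must be >= 1")
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("acceleration factors must be > 0")


@dataclasses.dataclass
class Particle:
    """One candidate solution: K distinct SNP indices plus its velocity and memory.

    ``pbest`` stays aligned with the position's component slots (it is a
    previously visited position, not a sorted set), so the attraction terms
    PS_k - S_k act on corresponding components; ``pbest_combo`` is the
    sorted-tuple view used for scoring and reporting.
    """

    order: int
    position: np.ndarray  # K distinct ints in [1, N], unsorted
    velocity: np.ndarray  # K floats in [1-N, N-1]
    pbest: np.ndarray  # best visited position, slot-aligned
    pbest_ci: float

    @property
    def pbest_combo(self) -> tuple[int, ...]:
        return tuple(sorted(int(s) for s in self.pbest))


class Swarm:
    """Full PSO state: particles, per-order global bests, SNP occurrence counts.

    ``evaluated`` maps order -> {sorted tuple -> CI} over every distinct
    combination scored so far; it feeds the per-order mean |CI| of the NCI
    normalization.  ``history`` records the per-order Gbest CI after each
    iteration (index 0 = state at initialization).
    """

    def __init__(
        self,
        dataset: GenotypeDataset,
        params: PsoParams,
        rng: np.random.Generator,
    ):
        self.dataset = dataset
        self.params = params
        self.rng = rng
        self.engine = CoInformationEngine(dataset)
        if self.engine.h_pheno <= 0:
            raise DegeneratePhenotypeError("phenotype entropy is zero")
        self.particles: list[Particle] = []
        self.gbest: dict[int, tuple[tuple[int, ...], float]] = {}
        self.gbest_position: dict[int, np.ndarray] = {}  # slot-aligned view
        self.counts = np.zeros(dataset.n_snps, dtype=np.int64)
        self.evaluated: dict[int, dict[tuple[int, ...], float]] = {}
        self.history: list[dict[int, float]] = []
        self.iteration = 0

    @property
    def n_snps(self) -> int:
        return self.dataset.n_snps

    def score(self, combo: tuple[int, ...]) -> float:
        """CI of a sorted combination, recorded into the evaluated set."""
        ci_val = self.engine.ci(combo)
        self.evaluated.setdefault(len(combo), {})[combo] = ci_val
        return ci_val

    def normalization_context(self) -> NormalizationContext:
        means = {
            order: float(np.mean([abs(v) for v in vals.values()]))
            for order, vals in self.evaluated.items()
        }
        return NormalizationContext(h_pheno=self.engine.h_pheno, mean_ci_by_order=means)

    def _record_history(self) -> None:
        self.history.append({o: ci for o, (_t, ci) in sorted(self.gbest.items())})


def initialize_swarm(dataset: GenotypeDataset, params: PsoParams) -> Swarm:
    """Random initialization of positions, velocities, Pbests and per-order Gbests.

    All N order-1 CI values are computed exhaustively up front — they anchor
    the NCI normalization and already cover the whole order-1 space, so no
    swarm budget is spent there: particle orders are uniform on [2, n] (on
    [1, 1] when n = 1).  Positions are uniform draws of distinct indices;
    velocities uniform in [1-N, N-1].  Fully reproducible from ``params.seed``.
    """
    n = dataset.n_snps
    if params.max_order > n:
        raise ValueError(f"max_order {params.max_order} exceeds SNP count {n}")
    rng = np.random.default_rng(params.seed)
    swarm = Swarm(dataset, params, rng)

    # exact order-1 reference scale for NCI (cheap: N evaluations)
    for s in range(1, n + 1):
        swarm.score((s,))

    min_order = min(2, params.max_order)
    for _ in range(params.particles):
        order = int(rng.integers(min_order, params.max_order + 1))
        position = rng.choice(n, size=order, replace=False) + 1
        velocity = rng.uniform(1 - n, n - 1, size=order)
        combo = tuple(sorted(int(x) for x in position))
        ci_val = swarm.score(combo)
        position = position.astype(np.int64)
        swarm.particles.append(
            Particle(order=order, position=position,
                     velocity=velocity, pbest=position.copy(), pbest_ci=ci_val)
        )

    for p in swarm.particles:
        current = swarm.gbest.get(p.order)
        if current is None or p.pbest_ci > current[1]:
            swarm.gbest[p.order] = (p.pbest_combo, p.pbest_ci)
            swarm.gbest_position[p.order] = p.pbest.copy()
        for s in p.pbest:
            swarm.counts[s - 1] += 1
    swarm._record_history()
    return swarm


def inertia_weight(counts: np.ndarray, snp: int) -> float:
    """W = (max(count) - count[snp]) / (max(count) - min(count)), in [0, 1].

    The rarest SNP gets W = 1 (explore), the most frequent W = 0 (exploit).
    When all counts are equal the ratio degenerates to 0/0; W := 1 then, so
    an undifferentiated swarm keeps exploring.
    """
    counts = np.asarray(counts)
    hi = int(counts.max())
    lo = int(counts.min())
    if hi == lo:
        return 1.0
    return float((hi - counts[snp - 1]) / (hi - lo))


def update_velocity(
    particle: Particle,
    gbest_tuple: Sequence[int],
    counts: np.ndarray,
    params: PsoParams,
    rng: np.random.Generator,
    n_snps: int,
) -> np.ndarray:
    """Component-wise velocity update with dynamic inertia and resample clamp.

    v~_k = W_k * v_k + c1*r1*(PS_k - S_k) + c2*r2*(GS_k - S_k) with fresh
    r1, r2 per component; the inertia weight W_k is taken at the Pbest
    component PS_k.  ``gbest_tuple`` must be slot-aligned with the particle's
    order.  Out-of-range results are replaced by a uniform draw from
    [1-N, N-1].
    """
    if len(gbest_tuple) != particle.order:
        raise RuntimeError("gbest order does not match particle order")
    lo, hi = 1 - n_snps, n_snps - 1
    new_v = np.empty(particle.order, dtype=float)
    for k in range(particle.order):
        w = inertia_weight(counts, particle.pbest[k])
        r1 = rng.uniform(0.0, 1.0)
        r2 = rng.uniform(0.0, 1.0)
        v = (
            w * particle.velocity[k]
            + params.c1 * r1 * (particle.pbest[k] - particle.position[k])
            + params.c2 * r2 * (gbest_tuple[k] - particle.position[k])
        )
        new_v[k] = v if lo <= v <= hi else rng.uniform(lo, hi)
    return new_v


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def update_position(
    particle: Particle,
    new_velocity: np.ndarray,
    n_snps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """S~ = S + v, rounded to the nearest index; out-of-range components are
    redrawn uniformly from [1, N].  Duplicate indices within the particle are
    re-drawn until all components are distinct (a combination of repeated
    SNPs carries no co-information meaning)."""
    new_pos = np.empty(particle.order, dtype=np.int64)
    for k in range(particle.order):
        s_tilde = particle.position[k] + new_velocity[k]
        if 1 <= s_tilde <= n_snps:
            new_pos[k] = _round_half_away(float(s_tilde))
        else:
            new_pos[k] = int(rng.integers(1, n_snps + 1))
    seen = set()
    for k in range(particle.order):
        while new_pos[k] in seen:
            new_pos[k] = int(rng.integers(1, n_snps + 1))
        seen.add(int(new_pos[k]))
    return new_pos


def opposite_position(position: Sequence[int], n_snps: int) -> tuple[int, ...]:
    """Opposition-based mirror: component-wise 1 + N - S (an involution)."""
    return tuple(1 + n_snps - int(s) for s in position)


def step(swarm: Swarm, dataset: GenotypeDataset | None = None) -> Swarm:
    """Advance the swarm by one iteration (in place; returns the swarm).

    For each particle the velocity and position are updated, the new
    position and its opposite are scored, and Pbest becomes the best of
    {position, opposite, old Pbest} (incumbent retained on ties).  Counts
    are then tallied over all current Pbests and each per-order Gbest is
    updated when strictly improved — hence Gbest scores never decrease.
    """
    if dataset is not None and dataset is not swarm.dataset:
        raise ValueError("step must use the dataset the swarm was initialized with")
    n = swarm.n_snps
    for p in swarm.particles:
        gb_position = swarm.gbest_position[p.order]
        p.velocity = update_velocity(p, gb_position, swarm.counts, swarm.params, swarm.rng, n)
        p.position = update_position(p, p.velocity, n, swarm.rng)
        mirror = np.asarray(opposite_position(p.position, n), dtype=np.int64)
        ci_pos = swarm.score(tuple(sorted(int(x) for x in p.position)))
        ci_opp = swarm.score(tuple(sorted(int(x) for x in mirror)))
        if ci_pos > p.pbest_ci:
            p.pbest, p.pbest_ci = p.position.copy(), ci_pos
        if ci_opp > p.pbest_ci:
            p.pbest, p.pbest_ci = mirror, ci_opp

    for p in swarm.particles:
        for s in p.pbest:
            swarm.counts[s - 1] += 1

    for order in swarm.gbest:
        peers = [p for p in swarm.particles if p.order == order]
        best = max(peers, key=lambda p: p.pbest_ci)
        if best.pbest_ci > swarm.gbest[order][1]:
            swarm.gbest[order] = (best.pbest_combo, best.pbest_ci)
            swarm.gbest_position[order] = best.pbest.copy()

    swarm.iteration += 1
    swarm._record_history()
    return swarm


def run_pso(dataset: GenotypeDataset, params: PsoParams) -> Swarm:
    """Initialize and iterate the swarm for the configured number of iterations."""
    swarm = initialize_swarm(dataset, params)
    for _ in range(params.iterations):
        step(swarm)
    return swarm


def pso_search(
    dataset: GenotypeDataset,
    params: PsoParams,
    top_k: int,
) -> dict[int, list[EffectRecord]]:
    """Run the swarm and report ranked epistatic interactions per order.

    The result is the de-duplicated set of final Pbests, grouped by order,
    sorted by descending NCI under the normalization context accumulated
    over all distinct evaluated combinations (ties: ascending lexicographic
    tuple), truncated to ``top_k`` per order.  Reproducible from the seed.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    swarm = run_pso(dataset, params)
    return report(swarm, top_k)


def report(swarm: Swarm, top_k: int) -> dict[int, list[EffectRecord]]:
    """Rank the swarm's final Pbests per order under the current context.

    The order-1 ranking always comes from the exhaustive single-SNP scores
    taken at initialization; orders >= 2 come from the particles' Pbests.
    """
    ctx = swarm.normalization_context()
    by_order: dict[int, dict[tuple[int, ...], float]] = {1: dict(swarm.evaluated[1])}
    for p in swarm.particles:
        by_order.setdefault(p.order, {})[p.pbest_combo] = p.pbest_ci
    results: dict[int, list[EffectRecord]] = {}
    for order in sorted(by_order):
        scored = [
            EffectRecord(snps=combo, order=order, ci=ci_val, nci=nci(ci_val, order, ctx))
            for combo, ci_val in by_order[order].items()
        ]
        scored.sort(key=lambda r: (-r.nci, r.snps))
        results[order] = scored[:top_k]
    return results
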