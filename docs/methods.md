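# Methods

## Problem setting

Given M case/control individuals genotyped at N SNPs (genotypes coded 0 =
homozygous common, 1 = heterozygous, 2 = homozygous minor; phenotype C with
0 = control, 1 = case), the package scores SNP combinations of orders 1..n
for association with the phenotype, searches the combinatorial space either
exhaustively or with a particle swarm, and organizes the detected effects
into a hypergraph for downstream analysis. Only binary phenotypes are
supported; missing genotypes are rejected rather than imputed.

## Association measures

**Co-information.** For SNPs S1..Sn and phenotype C, with V = {S1,...,Sn, C},

    CI(S1;...;Sn;C) = - Σ_{T ⊆ V} (-1)^(n+1-|T|) H(T),

where H(T) is the joint plug-in entropy of the variables in T. All
entropies are in bits (base-2 logarithms); probabilities are
maximum-likelihood cell frequencies over the observed joint categories with
0·log 0 := 0 and no pseudocounts. For n = 1 the sum collapses to the mutual
information I(S;C) ≥ 0; for n ≥ 2 the sign is informative — positive values
indicate synergy among the SNPs with respect to the phenotype, negative
values redundancy. The base is immaterial for rankings (it cancels in the
normalization below); bits make the canonical two-SNP XOR fixture score
exactly +1.

A consequence of the alternating sum worth noting: a tuple containing a
constant (zero-entropy) column has CI exactly 0 — subsets with and without
the constant carry equal entropies and opposite signs and cancel pairwise.

**NCI (order-normalized effect).** Raw CI magnitudes shrink systematically
with the order, so combinations of different orders are ranked on

    NCI = (CI / H(C)) · (mean|CI_1| / mean|CI_n|),

where the order means are taken over the *considered* combinations of each
order: every combination of that order in exhaustive mode, the distinct
evaluated combinations in PSO mode (the order-1 mean is always exact — all
N singles are scored). The means use absolute values: CI can be negative at
n ≥ 2, and a signed mean near zero would explode or flip the sign of the
balance coefficient, which is meant to act as a positive scale factor. For
order 1 the coefficient is exactly 1, so NCI = I(S;C)/H(C) ∈ [0, 1]. Within
one order NCI is a positive rescaling of CI, so within-order rankings are
identical under either measure.

**CCI (cumulative effect).** The total contribution of a combination is the
sum of NCI over itself and all non-empty subsets that (a) have a scored
record and (b) pass a user-specified per-order NCI threshold. Orders without
a stated threshold never contribute; subsets without a record contribute
nothing.

## Search strategies

**Exhaustive.** Each order 1..n streams its C(N, k) combinations twice in
lexicographic order: pass one accumulates the mean |CI|, pass two computes
NCI and maintains a bounded heap of the top K. Memory is O(top_k) per
order, which is what makes the order-3 regime at large N feasible. Ties in
NCI are broken by ascending lexicographic tuple, making output fully
deterministic. Entropies of singles and pairs are memoized (inclusion-
exclusion revisits them constantly across overlapping combinations); joint
cells are mixed-radix integer codes counted with `bincount`.

**Particle swarm.** Particles carry a fixed interaction order K, a position
of K distinct SNP indices, and a per-component real velocity in [1-N, N-1].
Fitness is NCI (compared on the CI scale, which is equivalent within an
order). Per iteration and component k:

    v~ = W·v + c1·r1·(PS_k - S_k) + c2·r2·(GS_k - S_k)

with fresh r1, r2 ~ U(0,1) per component; out-of-range velocities are
replaced by a uniform draw from [1-N, N-1]. Positions move by S~ = S + v,
rounded to the nearest index; out-of-range components are redrawn uniformly
from [1, N], and duplicate indices within a particle are redrawn until
distinct. The inertia weight is dynamic:
W = (max(count) - count[PS_k]) / (max(count) - min(count)), where count
tallies how often each SNP has appeared in personal bests since
initialization — rare SNPs keep exploring (W = 1), ubiquitous ones exploit
(W = 0). When all counts are equal the ratio is 0/0 and W := 1, since an
undifferentiated swarm should explore. Opposition-based learning evaluates
the mirror 1 + N - position alongside each updated position; the personal
best becomes the best of {position, mirror, old best} (incumbent kept on
ties), and a global best is maintained per order, updated only on strict
improvement — so per-order Gbest scores are non-decreasing by construction.

Design choices made where the procedure was genuinely open:

* *Slot alignment.* Personal and global bests are stored as visited
  positions aligned with the particle's component slots, not as sorted
  sets; the attraction terms PS_k - S_k and GS_k - S_k only make sense
  between corresponding components. Sorted tuples are used for scoring,
  de-duplication and reporting.
* *Order allocation.* All N order-1 CI values are computed exhaustively at
  initialization (they anchor the NCI scale and cost only O(N)), so the
  order-1 space is already fully enumerated; particle orders are therefore
  drawn uniformly from [2, n] (from {1} when n = 1), and the order-1
  ranking in PSO output comes from that enumeration. Spending half the
  swarm on an already-enumerated order measurably halves the effective
  budget at the orders that need searching.
* *Rounding.* int(·) is round-half-away-from-zero, keeping position updates
  symmetric for negative velocities.
* Defaults: Q = 500 particles, G = 10 iterations (the benchmark
  configuration used throughout), c1 = c2 = 2.0 (the classical PSO
  acceleration constants). A single seeded generator drives all randomness;
  the seed is recorded in run metadata.

## Epistasis hypergraph

Real vertices are SNPs weighted by their order-1 NCI (main effect); virtual
vertices are order-≥2 combinations weighted by their NCI, with one
unweighted edge per member SNP. Duplicate records for a tuple keep the
maximum weight. A SNP referenced only inside interactions still receives a
real vertex — its weight is computed from the dataset when one is supplied,
else it defaults to 0 with a warning. Degree of a real vertex counts the
interactions containing the SNP (Σ degrees = Σ virtual-vertex orders, a
handshake identity used as a self-check). Connected components are computed
on the bipartite incidence graph and ordered by smallest member SNP so
exports are diff-stable. Empirical penetrance of a combination is
cases(g)/individuals(g) per observed joint genotype; unobserved cells are
reported as missing, never as zero. Exports are GraphML (via networkx) and
DOT; vertex attributes carry kind, label, weight and order so renderers can
size vertices in proportion to their weights.

## Simulator

Ground-truth SNPs follow Hardy-Weinberg genotype frequencies (p², 2pq, q²)
at their MAFs; disease status is Bernoulli with probability f(g), the
penetrance of the joint ground-truth genotype. Because the phenotype
depends only on the truth SNPs, rejection sampling runs on those k columns
until the exact case and control quotas are met (capped at 10^7 draws, with
an analytic prevalence pre-check catching infeasible models first), and
background SNPs — independent, no linkage disequilibrium — are drawn
afterwards for the accepted individuals at MAFs uniform on (0.05, 0.5).
Truth columns are placed at recorded random positions so detectors cannot
exploit placement.

Analytic helpers: prevalence = Σ_g P(g) f(g); marginal penetrance of a
model SNP = E[f | genotype of that SNP] under HWE of the others. A model is
*pure* (no main effects) when every marginal triple is constant — the
parity (XOR) model at MAF 0.5 is pure, and is the package's deterministic
fixture. The second built-in model raises penetrance from 0.05 to 0.8 when
both SNPs carry at least one minor allele (MAF 0.5): a strong,
high-heritability interaction with visible marginal effects, used for the
recovery benchmarks. Both are fixed study conditions, not tuning knobs.

What the generator does *not* emulate: LD structure, covariates,
genotyping error, population stratification, quantitative traits. Passing
recovery tests therefore demonstrates correctness of the measures and
searches under idealized sampling, not field performance on real GWAS data.

**Detection power.** Over replicates of a detector's top-K list: Power1 =
fraction where at least one ground-truth SNP appears; Power2 = fraction
where all of them appear (possibly across records); Power3 = fraction where
the exact ground-truth combination is itself a reported record. By
construction Power3 ≤ Power2 ≤ Power1.

## Problem sizes used in tests and the acceptance script

Measure identities are verified on hundreds of random 200-individual
tables against independently coded oracles (plug-in entropy via Counter;
brute-force subset enumeration). Exhaustive recovery uses the deterministic
parity model at N = 50, 1000 + 1000 individuals, 20 replicates. The PSO
benchmark uses the threshold model at N = 100, 2000 + 2000 individuals,
Q = 500, G = 10, 20 seeded runs — the search evaluates roughly 10^4 of the
4950 candidate pairs per run, and whenever the planted pair is sampled at
all it ranks first, so residual misses are coverage-limited. Simulator
calibration checks exact quotas, per-SNP empirical MAF within ±0.02 at
M = 4000, and Monte-Carlo prevalence at 10^5 draws within three standard
errors of the analytic value.

## Known limitations

* Plug-in entropies are biased at small cell counts; no bias correction or
  permutation p-values are provided — rankings, not calibrated tests, are
  the output.
* The per-order means in PSO mode depend on the evaluated set, so NCI
  values from different runs are comparable only within a run.
* CCI depends on which subsets happen to be scored; with a truncated
  effect list it is a lower bound on the full cumulative effect.
* The PSO searches an unstructured index space; nothing about adjacency of
  SNP indices is meaningful, so convergence relies on fitness feedback and
  coverage, and power decays on much larger panels at fixed Q·G.
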