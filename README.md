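# noedv

Co-information based detection and hypergraph analysis of *n*-order
epistatic interactions in case-control SNP data.

Many disease associations missed by single-marker GWAS scans live in the
joint, nonlinear effects of several SNPs. `noedv` scores SNP combinations
of orders 1..n against a binary phenotype with information-theoretic
measures, searches the combinatorial space either exhaustively or with a
modified particle swarm, organizes the detected effects into an epistasis
hypergraph, and ships a penetrance-model simulator so the entire pipeline
can be exercised and benchmarked without external data. It is aimed at
statistical geneticists and methods developers working on epistasis
detection.

## The measures

For SNPs S₁..Sₙ and phenotype C, with V = {S₁,...,Sₙ, C}, the
**co-information**

CI(S₁;...;Sₙ;C) = − Σ_{T⊆V} (−1)^(n+1−|T|) H(T)

is an alternating sum of joint entropies (bits) over all subsets of V. For
n = 1 it is the mutual information I(S;C); for n ≥ 2, positive CI means
synergy, negative means redundancy. Because CI magnitudes shrink with the
order, combinations are ranked by the **normalized effect**

NCI = (CI / H(C)) · (mean|CI₁| / mean|CIₙ|),

where the per-order means run over the considered combinations of each
order. The **cumulative effect** CCI sums NCI over a combination and its
subsets that pass per-order thresholds. The detected effects form a
hypergraph whose real vertices are SNPs (weight = order-1 NCI) and whose
virtual vertices are interactions (weight = order-n NCI), linked by one
edge per member SNP. See `docs/methods.md` for the full model description.

## Worked example

Simulate a 30-SNP panel where penetrance jumps from 0.05 to 0.8 whenever
both planted SNPs carry at least one minor allele, then search all pairs:

```python
from noedv import (
    SimulationConfig, interaction_threshold_model, simulate_dataset,
    exhaustive_search, prevalence,
)

model = interaction_threshold_model()   # penetrance 0.05 -> 0.8 when both SNPs carry a minor allele
print(f"model prevalence: {prevalence(model):.4f}")

sim = simulate_dataset(model, SimulationConfig(n_snps=30, cases=500, controls=500, seed=42))
print(f"planted pair: {sim.truth}")

results = exhaustive_search(sim.dataset, max_order=2, top_k=3)
for rec in results[2]:
    print(f"order-2  {rec.snps}  CI={rec.ci:.4f} bits  NCI={rec.nci:.4f}")
for rec in results[1][:2]:
    print(f"order-1  {rec.snps}  CI={rec.ci:.4f} bits  NCI={rec.nci:.4f}")
```

Output:

```
model prevalence: 0.4719
planted pair: (3, 24)
order-2  (3, 24)  CI=0.0707 bits  NCI=0.3875
order-2  (4, 18)  CI=0.0137 bits  NCI=0.0752
order-2  (19, 20)  CI=0.0134 bits  NCI=0.0734
order-1  (24,)  CI=0.2394 bits  NCI=0.2394
order-1  (3,)  CI=0.2287 bits  NCI=0.2287
```

The planted pair (3, 24) tops the order-2 ranking with five times the CI of
the best noise pair: its 0.0707 bits of pairwise synergy come on top of the
strong main effects (0.23-0.24 bits of mutual information each) that the
threshold model also induces. The same pipeline is available from the
shell:

```bash
noedv simulate --model model.txt --n-snps 100 --cases 2000 --controls 2000 --seed 7 --out sim/
noedv detect --input sim/genotypes.csv --max-order 2 --search pso \
      --particles 500 --iterations 10 --seed 7 --top-k 10 --out run/
noedv hypergraph --effects run/effects_all.csv --input sim/genotypes.csv \
      --format graphml --out run/epistasis.graphml
```

`detect --search pso` runs the modified particle swarm (per-order global
bests, occurrence-count inertia weight, opposition-based learning) and
writes ranked effect lists per order plus an iteration log of the
non-decreasing per-order best scores; `hypergraph` builds and exports the
epistasis hypergraph (GraphML or DOT) for any effect list, including lists
produced by other detectors in the same delimited format.

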