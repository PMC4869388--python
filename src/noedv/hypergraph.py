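"""Epistasis hypergraph: construction, degree/connectivity analysis, exports.

The hypergraph has two vertex kinds.  A *real* vertex is a SNP whose weight
is its order-1 NCI (the main effect); a *virtual* vertex is an interaction
of order >= 2 whose weight is that combination's NCI.  Each virtual vertex
of order k is linked by k unweighted edges, one to each member SNP.  The
bipartite incidence structure makes standard graph tooling (networkx,
GraphML/DOT consumers) directly applicable.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import networkx as nx

from .co_information import (
    CoInformationEngine,
    NormalizationContext,
    ThresholdSet,
    cci,
    nci,
)
from .data_io import EffectRecord, GenotypeDataset

__all__ = [
    "Hypergraph",
    "build_hypergraph",
    "vertex_degrees",
    "connected_components",
    "estimate_penetrance",
    "rank_effects",
    "export_graph",
]


@dataclasses.dataclass
class Hypergraph:
    """Weighted real/virtual vertices plus unweighted SNP-interaction edges.

    ``real_vertices`` maps a 1-based SNP index to its main-effect weight;
    ``virtual_vertices`` maps a sorted index tuple (order >= 2) to its
    interaction weight; ``edges`` holds (snp, tuple) incidence pairs.
    """

    real_vertices: dict[int, float] = dataclasses.field(default_factory=dict)
    virtual_vertices: dict[tuple[int, ...], float] = dataclasses.field(default_factory=dict)
    edges: set[tuple[int, tuple[int, ...]]] = dataclasses.field(default_factory=set)

    def to_networkx(self) -> nx.Graph:
        """Incidence graph with string node ids stable across exports."""
        g = nx.Graph()
        for snp in sorted(self.real_vertices):
            g.add_node(
                f"SNP{snp}", kind="real", label=f"SNP{snp}",
                weight=float(self.real_vertices[snp]), order=1,
            )
        for combo in sorted(self.virtual_vertices):
            vid = ":".join(f"SNP{s}" for s in combo)
            g.add_node(
                vid, kind="virtual", label=vid,
                weight=float(self.virtual_vertices[combo]), order=len(combo),
            )
        for snp, combo in sorted(self.edges):
            g.add_edge(f"SNP{snp}", ":".join(f"SNP{s}" for s in combo))
        return g


def _flatten(effects) -> list[EffectRecord]:
    if isinstance(effects, Mapping):
        out: list[EffectRecord] = []
        for order in sorted(effects):
            out.extend(effects[order])
        return out
    return list(effects)


def build_hypergraph(
    effects,
    dataset: GenotypeDataset | None = None,
) -> Hypergraph:
    """Build the hypergraph from effect lists (a flat list or an order->list map).

    Every order-1 record becomes a real vertex; every order>=2 record a
    virtual vertex with one edge per member SNP.  A SNP referenced only
    inside interactions still gets a real vertex: its weight is the order-1
    NCI computed from ``dataset`` when one is supplied, else 0 with a
    warning.  Duplicate records for the same tuple keep the largest NCI.
    """
    records = _flatten(effects)
    hg = Hypergraph()
    for rec in records:
        if rec.order == 1:
            snp = rec.snps[0]
            if snp not in hg.real_vertices or rec.nci > hg.real_vertices[snp]:
                hg.real_vertices[snp] = rec.nci
        else:
            prev = hg.virtual_vertices.get(rec.snps)
            if prev is None or rec.nci > prev:
                hg.virtual_vertices[rec.snps] = rec.nci
            for snp in rec.snps:
                hg.edges.add((snp, rec.snps))

    missing = sorted(
        {s for combo in hg.virtual_vertices for s in combo} - set(hg.real_vertices)
    )
    if missing:
        if dataset is not None:
            engine = CoInformationEngine(dataset)
            for snp in missing:
                hg.real_vertices[snp] = engine.ci((snp,)) / engine.h_pheno
        else:
            warnings.warn(
                f"no order-1 effects and no dataset for SNPs {missing}; "
                "their main-effect weights default to 0",
                stacklevel=2,
            )
            for snp in missing:
                hg.real_vertices[snp] = 0.0
    return hg


def vertex_degrees(hg: Hypergraph) -> dict[int, int]:
    """Number of interactions each SNP participates in (incident edge count)."""
    degrees = {snp: 0 for snp in hg.real_vertices}
    for snp, _combo in hg.edges:
        degrees[snp] += 1
    return degrees


def connected_components(hg: Hypergraph) -> list[set]:
    """Maximal connected vertex sets (real SNP indices and virtual tuples mixed).

    Ordered deterministically by each component's smallest member SNP.
    """
    g = nx.Graph()
    for snp in hg.real_vertices:
        g.add_node(("snp", snp))
    for combo in hg.virtual_vertices:
        g.add_node(("int", combo))
    for snp, combo in hg.edges:
        g.add_edge(("snp", snp), ("int", combo))
    components = [{payload for _kind, payload in comp} for comp in nx.connected_components(g)]

    def smallest_snp(members: set) -> int:
        snps = [m for m in members if isinstance(m, int)]
        return min(snps) if snps else min(min(m) for m in members)

    components.sort(key=smallest_snp)
    return components


def estimate_penetrance(
    dataset: GenotypeDataset,
    snps: Sequence[int],
) -> dict[tuple[int, ...], float]:
    """Empirical penetrance table of a SNP combination.

    For each *observed* joint genotype g of the tuple the estimate is
    cases(g) / individuals(g); unobserved cells are absent from the result
    (missing, not zero).
    """
    key = tuple(int(s) for s in snps)
    cols = [dataset.column(s) for s in key]
    totals: dict[tuple[int, ...], int] = {}
    cases: dict[tuple[int, ...], int] = {}
    pheno = dataset.phenotype
    for i in range(dataset.n_individuals):
        cell = tuple(int(c[i]) for c in cols)
        totals[cell] = totals.get(cell, 0) + 1
        cases[cell] = cases.get(cell, 0) + int(pheno[i])
    return {cell: cases[cell] / totals[cell] for cell in sorted(totals)}


def rank_effects(
    effects,
    by: str = "nci",
    thresholds: ThresholdSet | None = None,
) -> list[EffectRecord]:
    """Order records by descending NCI or CCI (ties: ascending tuple).

    CCI ranking computes each record's cumulative effect over the supplied
    pool of records and requires per-order thresholds; the returned records
    carry the computed ``cci``.
    """
    records = _flatten(effects)
    if by == "nci":
        return sorted(records, key=lambda r: (-r.nci, r.snps))
    if by == "cci":
        if thresholds is None:
            raise ValueError("CCI ranking requires a ThresholdSet")
        rescored = [
            dataclasses.replace(rec, cci=cci(rec.snps, records, thresholds))
            for rec in records
        ]
        return sorted(rescored, key=lambda r: (-r.cci, r.snps))
    raise ValueError(f"unknown ranking measure {by!r}")


def export_graph(hg: Hypergraph, path, fmt: str = "graphml") -> None:
    """Write the incidence graph as GraphML or DOT.

    Vertices carry ``kind`` (real/virtual), ``label``, ``weight`` and
    ``order`` attributes so renderers can size nodes in proportion to their
    weights.
    """
    g = hg.to_networkx()
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("graph epistasis {\n")
            for node, attrs in sorted(g.nodes(data=True)):
                shape = "circle" if attrs["kind"] == "real" else "doublecircle"
                fh.write(
                    f'  "{node}" [label="{attrs["label"]}", kind="{attrs["kind"]}", '
                    f'weight="{attrs["weight"]}", order="{attrs["order"]}", shape={shape}];\n'
                )
            for u, v in sorted(g.edges()):
                fh.write(f'  "{u}" -- "{v}";\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")
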