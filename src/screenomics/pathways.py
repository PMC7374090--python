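"""Pathway essentialness scoring over KGML-derived gene graphs.

Screen hits are mapped onto a pathway's gene graph and the pathway is
scored by how enriched and how interconnected its hits are: each hit gene
contributes a weight alpha + lambda * (fraction of its neighbours that are
also hits), the weights are summed and scaled by the proportion of the
pathway's measured genes that are hits.  Hits directly linked to other
hits therefore receive more weight.  Only genes inside the screen universe
(the genes actually measured) enter any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .screen import HitCall


@dataclass
class PathwayGraph:
    """Undirected simple graph over gene symbols for one KEGG pathway."""

    pathway_id: str
    title: str
    graph: nx.Graph = field(default_factory=nx.Graph)
    empty_warning: bool = False

    @property
    def genes(self) -> set[str]:
        return set(self.graph.nodes)

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class PathwayScore:
    pathway_id: str
    title: str
    score: float
    n_hits: int
    proportion: float
    rank: int | None = None


@dataclass(frozen=True)
class PathwayHitAnnotation:
    gene: str
    rank: int
    intensity: float
    expression_lfc: float | None = None
    drugs: tuple[str, ...] = ()


def build_pathway_graph(
    pathway_id: str,
    title: str,
    nodes: Iterable[str],
    edges: Iterable[tuple[str, str]],
) -> PathwayGraph:
    """Assemble a simple undirected gene graph; self-loops and duplicate
    edges collapse away, edges touching unknown genes are dropped."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in edges:
        if u != v and g.has_node(u) and g.has_node(v):
            g.add_edge(u, v)
    return PathwayGraph(
        pathway_id=pathway_id,
        title=title,
        graph=g,
        empty_warning=g.number_of_nodes() == 0,
    )


def map_hits_to_pathway(
    pathway: PathwayGraph,
    hits: Sequence[HitCall],
    n_genes_in_screen: int | None = None,
    store=None,
    cell_line: str | None = None,
) -> list[PathwayHitAnnotation]:
    """Annotate the pathway's hit genes for map export.

    Colour intensity encodes hit strength: 1 - (rank - 1)/(n - 1), clipped
    to [0, 1], so the rank-1 hit is darkest.  When a store and cell line
    are given, expression and drug annotations are attached.
    """
    if n_genes_in_screen is None:
        n_genes_in_screen = len(hits)
    denom = max(1, n_genes_in_screen - 1)
    out = []
    for h in sorted(hits, key=lambda h: h.rank):
        if not h.is_hit or h.gene not in pathway.genes:
            continue
        intensity = min(1.0, max(0.0, 1.0 - (h.rank - 1) / denom))
        lfc = None
        drugs: tuple[str, ...] = ()
        if store is not None:
            if store.expression is not None and cell_line is not None:
                lfc = store.expression_lfc(cell_line, h.gene)
            if store.drugs is not None:
                drugs = store.drugs_for(h.gene)
        out.append(
            PathwayHitAnnotation(
                gene=h.gene, rank=h.rank, intensity=intensity,
                expression_lfc=lfc, drugs=drugs,
            )
        )
    return out


def pathway_score(
    pathway: PathwayGraph,
    hit_genes: Iterable[str],
    universe: Iterable[str],
    alpha: float = 1.0,
    lam: float = 1.0,
) -> PathwayScore:
    """Score one pathway for one cell line.

    The pathway's genes are first intersected with the screen universe.
    Each hit node g contributes w(g) = alpha + lam * h(g)/max(1, d(g)),
    where d(g) is g's degree within the restricted pathway and h(g) the
    number of its neighbours that are hits.  The score is the weight sum
    times the proportion of restricted pathway genes that are hits, so it
    is zero exactly when there are no hits.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("screen universe is empty")
    members = pathway.genes & universe
    sub = pathway.graph.subgraph(members)
    hits_in = set(hit_genes) & members
    raw = 0.0
    for g in hits_in:
        deg = sub.degree(g)
        hit_nbrs = sum(1 for n in sub.neighbors(g) if n in hits_in)
        raw += alpha + lam * hit_nbrs / max(1, deg)
    proportion = len(hits_in) / len(members) if members else 0.0
    return PathwayScore(
        pathway_id=pathway.pathway_id,
        title=pathway.title,
        score=raw * proportion,
        n_hits=len(hits_in),
        proportion=proportion,
    )


def rank_pathways(
    hit_genes: Iterable[str],
    pathways: Sequence[PathwayGraph],
    universe: Iterable[str],
    alpha: float = 1.0,
    lam: float = 1.0,
) -> list[PathwayScore]:
    """Rank all pathways for one cell line: descending score, ties broken by
    proportion then pathway id; rank is the 1-based position."""
    hit_genes = set(hit_genes)
    universe = set(universe)
    scored = [
        pathway_score(p, hit_genes, universe, alpha=alpha, lam=lam)
        for p in pathways
    ]
    scored.sort(key=lambda s: (-s.score, -s.proportion, s.pathway_id))
    return [
        PathwayScore(
            pathway_id=s.pathway_id, title=s.title, score=s.score,
            n_hits=s.n_hits, proportion=s.proportion, rank=i,
        )
        for i, s in enumerate(scored, start=1)
    ]


def rank_cell_lines(
    pathway: PathwayGraph,
    per_line_hits: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    all_pathways: Sequence[PathwayGraph] | None = None,
    alpha: float = 1.0,
    lam: float = 1.0,
) -> list[tuple[str, int, float]]:
    """Rank cell lines by their reliance on one pathway.

    Returns (cell line, rank-in-line, score) rows sorted by score
    descending, ties alphabetical.  Rank-in-line is this pathway's rank
    within the line's own full pathway ranking over ``all_pathways``
    (defaulting to just the queried pathway).
    """
    if all_pathways is None:
        all_pathways = [pathway]
    universe = set(universe)
    rows = []
    for line in sorted(per_line_hits):
        hits = set(per_line_hits[line])
        full = rank_pathways(hits, all_pathways, universe, alpha=alpha, lam=lam)
        mine = next(s for s in full if s.pathway_id == pathway.pathway_id)
        rows.append((line, mine.rank, mine.score))
    rows.sort(key=lambda r: (-r[2], r[0]))
    return rows
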