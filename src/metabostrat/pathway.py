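"""Pathway over-representation and topology impact analysis.

A selected metabolite panel is tested against compound-level pathways
two ways:

* enrichment: the upper-tail hypergeometric probability of observing at
  least the matched number of panel compounds in a pathway, given the
  background compound universe, with BH-FDR across pathways;
* impact: the share of the pathway's relative betweenness centrality
  carried by the matched compounds. Betweenness is normalized by
  (|V|-1)(|V|-2)/2, so a compound sitting on every shortest path scores
  1; impact is the hit-node centrality sum over the all-node sum.

A small synthetic pathway library (toy compound graphs for the
glycerophospholipid, linoleic acid, arachidonic acid, tryptophan and
arginine/creatinine neighborhoods) is bundled for tests and worked
examples; it is NOT a curated database.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import networkx as nx
import pandas as pd
from scipy import stats as sps

from .validate import bh_fdr


@dataclass
class PathwayGraph:
    """A compound-level pathway: membership set plus undirected edges."""

    pathway_id: str
    name: str
    members: frozenset[str]
    edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        cleaned = []
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u!r} in pathway {self.pathway_id}")
            if u not in self.members or v not in self.members:
                raise ValueError(
                    f"edge ({u}, {v}) leaves pathway {self.pathway_id} membership"
                )
            cleaned.append((u, v))
        self.edges = tuple(cleaned)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.members))
        g.add_edges_from(self.edges)
        return g


@dataclass
class EnrichmentRow:
    """One pathway's enrichment evidence for a selected panel."""

    pathway_id: str
    name: str
    k_hits: int
    K_members: int
    n_selected: int
    N_background: int
    p_hyper: float
    impact: float
    p_fdr: float = float("nan")


def ora_hypergeometric(selected, pathway: PathwayGraph, background) -> float:
    """Upper-tail hypergeometric P(X >= k) for the pathway overlap.

    ``N`` = background size, ``K`` = pathway members inside the
    background, ``n`` = selected compounds, ``k`` = selected compounds
    in the pathway. Exact summation via the hypergeometric survival
    function.
    """
    selected = set(selected)
    background = set(background)
    offenders = selected - background
    if offenders:
        raise ValueError(f"selected compounds outside background: {sorted(offenders)}")
    members = pathway.members & background
    n_cap = len(background)
    k_path = len(members)
    n_sel = len(selected)
    k_hit = len(selected & members)
    if k_hit == 0:
        return 1.0
    # P(X >= k) = sf(k - 1)
    return float(sps.hypergeom.sf(k_hit - 1, n_cap, k_path, n_sel))


def relative_betweenness(pathway: PathwayGraph) -> dict[str, float]:
    """Relative betweenness centrality per compound node.

    Normalized by (|V|-1)(|V|-2)/2 for undirected graphs; graphs with
    fewer than 3 nodes have no in-between positions and return zeros.
    """
    g = pathway.graph()
    if g.number_of_nodes() < 3:
        return {node: 0.0 for node in g.nodes}
    return dict(nx.betweenness_centrality(g, normalized=True))


def pathway_impact(pathway: PathwayGraph, hits) -> float:
    """Share of total pathway centrality carried by the hit compounds."""
    hits = set(hits)
    offenders = hits - set(pathway.members)
    if offenders:
        raise ValueError(f"hits outside pathway membership: {sorted(offenders)}")
    centrality = relative_betweenness(pathway)
    total = sum(centrality.values())
    if total == 0:
        return 0.0
    return float(sum(centrality[h] for h in hits) / total)


def enrich_panel(
    panel_kegg_ids,
    pathways: list[PathwayGraph],
    background=None,
) -> list[EnrichmentRow]:
    """Enrichment plus impact for a panel of KEGG-mapped compounds.

    Panel entries with no KEGG id (empty strings) are dropped; the
    default background is the union of all pathway members. Rows are
    sorted by hypergeometric p, with BH-FDR across pathways.
    """
    panel = {str(c) for c in panel_kegg_ids if str(c).strip() not in ("", "nan", "/")}
    if background is None:
        background = set().union(*(p.members for p in pathways)) | panel
    background = set(background)
    if not background:
        raise ValueError("background compound set is empty")
    panel &= background  # ORA is defined on background-mappable compounds
    rows = []
    for pw in pathways:
        members = pw.members & background
        hits = panel & members
        rows.append(
            EnrichmentRow(
                pathway_id=pw.pathway_id,
                name=pw.name,
                k_hits=len(hits),
                K_members=len(members),
                n_selected=len(panel),
                N_background=len(background),
                p_hyper=ora_hypergeometric(panel, pw, background),
                impact=pathway_impact(pw, hits),
            )
        )
    p_fdr = bh_fdr([r.p_hyper for r in rows])
    for row, q in zip(rows, p_fdr):
        row.p_fdr = float(q)
    rows.sort(key=lambda r: (r.p_hyper, r.pathway_id))
    return rows


def enrichment_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# pathway library IO
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file: pathway_id <tab> description <tab> members..."""
    out: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = (parts[1], [m for m in parts[2:] if m])
    return out


def read_pathways(gmt_path, edges_path=None) -> list[PathwayGraph]:
    """Assemble PathwayGraph objects from a GMT file plus an edge TSV."""
    gmt = read_gmt(gmt_path)
    edge_map: dict[str, list[tuple[str, str]]] = {}
    if edges_path is not None:
        edges = pd.read_csv(edges_path, sep="\t", dtype=str)
        for _, row in edges.iterrows():
            edge_map.setdefault(row["pathway_id"], []).append(
                (row["source"], row["target"])
            )
    return [
        PathwayGraph(
            pathway_id=pid,
            name=name,
            members=frozenset(members),
            edges=tuple(edge_map.get(pid, ())),
        )
        for pid, (name, members) in gmt.items()
    ]


def bundled_pathways() -> list[PathwayGraph]:
    """The bundled synthetic (toy) pathway library."""
    data = resources.files("metabostrat.data")
    with resources.as_file(data.joinpath("pathways.gmt")) as gmt_path, resources.as_file(
        data.joinpath("pathway_edges.tsv")
    ) as edges_path:
        return read_pathways(gmt_path, edges_path)
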