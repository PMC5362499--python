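"""KEGG-style pathway topologies as undirected gene graphs.

KGML documents are flattened: every gene of one entry is connected to every
gene of a related entry (direction and relation subtype dropped), and two
enzyme entries are connected whenever one reaction's product compound is the
other's substrate (enzymes sharing a common metabolite). Group entries are
expanded to their component gene entries. Documents from which no gene-gene
structure can be extracted raise :class:`StructureNotExtractableError` so the
caller can exclude them.

Two fixture topologies back the simulation studies: a 20-gene linear chain
and a synthetic ERBB-signalling-style graph bundled as packaged data
(modelled on the published KEGG ERBB topology; see the data file).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import pandas as pd
from lxml import etree

__all__ = [
    "PathwayGraph",
    "StructureNotExtractableError",
    "kgml_to_graph",
    "fixture_pathways",
    "planted_regions",
    "read_edge_list",
    "write_edge_list",
]


class StructureNotExtractableError(ValueError):
    """Raised when a KGML document yields no gene-gene graph structure."""


@dataclass
class PathwayGraph:
    """Undirected, simple gene graph for one pathway."""

    id: str
    name: str
    graph: nx.Graph = field(repr=False)
    origin: str = "fixture"  # {"kgml", "fixture"}

    def __post_init__(self) -> None:
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from((u, v) for u, v in self.graph.edges if u != v)
        self.graph = g

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}


def _entry_genes(entry) -> list[str]:
    return [tok for tok in (entry.get("name") or "").split() if tok and tok != "undefined"]


def kgml_to_graph(source) -> PathwayGraph:
    """Parse a KGML document (path, bytes or string) into a PathwayGraph."""
    if isinstance(source, (str, bytes)) and (isinstance(source, bytes) or source.lstrip().startswith("<")):
        data = source.encode() if isinstance(source, str) else source
        root = etree.fromstring(data)
    else:
        root = etree.parse(str(source)).getroot()

    entries = {e.get("id"): e for e in root.findall("entry")}

    def genes_of(entry_id: str) -> list[str]:
        entry = entries.get(entry_id)
        if entry is None:
            return []
        etype = entry.get("type")
        if etype == "gene":
            return _entry_genes(entry)
        if etype == "group":
            out: list[str] = []
            for comp in entry.findall("component"):
                out.extend(genes_of(comp.get("id")))
            return out
        return []

    g = nx.Graph()
    for eid in entries:
        g.add_nodes_from(genes_of(eid))

    # protein-protein / gene-expression relations -> all-vs-all gene edges
    for rel in root.findall("relation"):
        if rel.get("type") == "maplink":
            continue
        a, b = genes_of(rel.get("entry1")), genes_of(rel.get("entry2"))
        for u in a:
            for v in b:
                if u != v:
                    g.add_edge(u, v)

    # reactions: connect enzymes when one's product is another's substrate
    reactions = []
    for rx in root.findall(".//reaction"):
        subs = {s.get("name") for s in rx.findall("substrate")}
        prods = {p.get("name") for p in rx.findall("product")}
        enzymes: list[str] = []
        rname = rx.get("name")
        for eid, entry in entries.items():
            if rname and rname in (entry.get("reaction") or "").split():
                enzymes.extend(genes_of(eid))
        reactions.append((subs, prods, enzymes))
    for subs1, prods1, enz1 in reactions:
        for subs2, _prods2, enz2 in reactions:
            if enz1 is enz2:
                continue
            if prods1 & subs2:
                for u in enz1:
                    for v in enz2:
                        if u != v:
                            g.add_edge(u, v)

    if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
        raise StructureNotExtractableError("pathway structure not extractable from KGML")
    pid = root.get("name", "unknown")
    return PathwayGraph(id=pid, name=root.get("title", pid), graph=g, origin="kgml")


def _linear_fixture() -> PathwayGraph:
    nodes = [f"g{i:02d}" for i in range(1, 21)]
    g = nx.Graph()
    nx.add_path(g, nodes)
    return PathwayGraph(id="linear", name="linear 20-gene pathway", graph=g, origin="fixture")


def _erbb_fixture() -> PathwayGraph:
    with resources.files("lncsubpath.data").joinpath("erbb_edges.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    g = nx.Graph()
    g.add_edges_from(zip(df["gene_a"], df["gene_b"]))
    return PathwayGraph(id="erbb", name="ERBB-style signalling fixture", graph=g, origin="fixture")


def fixture_pathways() -> dict[str, PathwayGraph]:
    """The two simulation topologies: 'linear' and 'erbb'."""
    return {"linear": _linear_fixture(), "erbb": _erbb_fixture()}


def planted_regions() -> dict[str, dict]:
    """Bundled planted dysregulation regions, keyed by region id; each value
    has 'pathway' and 'nodes'."""
    with resources.files("lncsubpath.data").joinpath("planted_regions.json").open() as fh:
        data = json.load(fh)
    return {k: v for k, v in data.items() if not k.startswith("_")}


def read_edge_list(path) -> list[PathwayGraph]:
    """Read a pathway edge-list TSV (pathway_id, gene_a, gene_b) into one
    PathwayGraph per pathway id."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for pid, sub in df.groupby("pathway_id", sort=True):
        g = nx.Graph()
        g.add_edges_from(zip(sub["gene_a"], sub["gene_b"]))
        out.append(PathwayGraph(id=str(pid), name=str(pid), graph=g, origin="fixture"))
    return out


def write_edge_list(pathways, path) -> None:
    rows = []
    for pw in pathways:
        for u, v in sorted(tuple(sorted(e)) for e in pw.graph.edges):
            rows.append((pw.id, u, v))
    pd.DataFrame(rows, columns=["pathway_id", "gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)
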