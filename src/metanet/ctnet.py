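"""Compound--target bipartite network over a disease gene set.

Predicted targets of each metabolite are intersected with a disease gene
list (e.g. cancer-associated genes); metabolites with a nonempty overlap
become compound nodes linked to the overlapped targets. A compound's
degree -- the number of distinct disease targets it reaches -- is read as
a bioactivity prior: compounds hitting many disease proteins are
prioritized for follow-up. An externally computed protein--protein
interaction table can be imported (score-thresholded) for overlay in graph
viewers; no PPI retrieval or clustering happens here.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from metanet.targets import TargetPredictionResult

logger = logging.getLogger(__name__)

PPI_SCORE_MIN = 0.7  # strict ">": combined scores at exactly 0.7 are dropped


@dataclass
class DiseaseGeneSet:
    """A named set of disease-associated gene/protein identifiers."""

    name: str
    ids: set[str]
    source: str = ""


@dataclass
class BipartiteNetwork:
    """Compound--target bipartite graph; edges only run between the two sides."""

    compound_nodes: set[str]
    target_nodes: set[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        for c, t in self.edges:
            if c not in self.compound_nodes or t not in self.target_nodes:
                raise ValueError(f"edge ({c}, {t}) references a missing node")
        if self.compound_nodes & self.target_nodes:
            raise ValueError("compound and target node sets overlap")

    def degree(self, compound_id: str) -> int:
        return sum(1 for c, _ in self.edges if c == compound_id)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for c in sorted(self.compound_nodes):
            g.add_node(c, kind="compound")
        for t in sorted(self.target_nodes):
            g.add_node(t, kind="target")
        for c, t in sorted(self.edges):
            g.add_edge(c, t)
        return g


@dataclass
class CompoundRanking:
    """Compounds ordered by bipartite degree desc, ties by id ascending."""

    entries: list[tuple[str, int]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def read_disease_list(path: str | Path, name: str = "disease") -> DiseaseGeneSet:
    """Read a disease gene list: one identifier per line, '#' comments."""
    path = Path(path)
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                ids.add(token)
    return DiseaseGeneSet(name=name, ids=ids, source=str(path))


def write_disease_list(gene_set: DiseaseGeneSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {gene_set.name}\n")
        for gid in sorted(gene_set.ids):
            fh.write(gid + "\n")
    return path


def overlap_targets(pred: TargetPredictionResult, disease: DiseaseGeneSet) -> frozenset[str]:
    """Intersection of the metabolite's predicted targets with the disease set.

    The prediction side is the union of the Dice and Tanimoto channel
    target sets.
    """
    return frozenset(pred.all_targets & disease.ids)


def build_network(
    results: Sequence[TargetPredictionResult], disease: DiseaseGeneSet
) -> BipartiteNetwork:
    """Build the compound--target network over the disease gene set.

    Each metabolite with a nonempty overlap contributes one compound node
    and one edge per overlapped target; metabolites with empty overlap are
    omitted. An entirely empty network is valid but logged.
    """
    compounds: set[str] = set()
    targets: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for r in results:
        hit = overlap_targets(r, disease)
        if not hit:
            continue
        compounds.add(r.metabolite_id)
        for t in hit:
            targets.add(t)
            edges.add((r.metabolite_id, t))
    if not edges:
        logger.warning("compound-target network is empty: no predicted target overlaps %s", disease.name)
    return BipartiteNetwork(compounds, targets, edges)


def rank_compounds(net: BipartiteNetwork) -> CompoundRanking:
    """Rank compounds by number of disease targets reached (degree)."""
    degrees = {c: 0 for c in net.compound_nodes}
    for c, _ in net.edges:
        degrees[c] += 1
    ordered = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    return CompoundRanking(ordered)


def import_ppi_table(
    path: str | Path, score_min: float = PPI_SCORE_MIN
) -> list[tuple[str, str, float]]:
    """Import a protein--protein interaction TSV (protein A, protein B, score).

    Edges with combined score strictly greater than ``score_min`` are
    retained; malformed rows are skipped and counted in a log message. The
    table is used only for export/overlay.
    """
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    skipped = 0
    n_rows = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if i == 0 and row and not _is_float(row[-1]):
                continue  # header
            n_rows += 1
            if len(row) < 3 or not _is_float(row[2]):
                skipped += 1
                continue
            score = float(row[2])
            if score > score_min:
                edges.append((row[0].strip(), row[1].strip(), score))
    if skipped:
        logger.info("skipped %d malformed PPI rows", skipped)
    if n_rows == 0:
        logger.warning("PPI table %s is empty", path)
    return edges


def _is_float(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def export_bipartite(
    net: BipartiteNetwork,
    ranking: CompoundRanking,
    prefix: str | Path,
    ppi_edges: Iterable[tuple[str, str, float]] | None = None,
) -> dict[str, Path]:
    """Write the compound--target network for external graph viewers.

    Produces ``<prefix>.edges.tsv`` (compound, target), ``<prefix>.nodes.tsv``
    (id, kind, degree) with compound degrees from ``ranking``, and
    ``<prefix>.graphml``. PPI edges, when given, are appended to the GraphML
    as ``kind="ppi"`` overlay edges between target nodes.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    degree_of = dict(ranking.entries)
    edge_path = prefix.with_suffix(".edges.tsv")
    with open(edge_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["compound", "target"])
        for c, t in sorted(net.edges):
            w.writerow([c, t])
    target_degree: dict[str, int] = {t: 0 for t in net.target_nodes}
    for _, t in net.edges:
        target_degree[t] += 1
    node_path = prefix.with_suffix(".nodes.tsv")
    with open(node_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "kind", "degree"])
        for c in sorted(net.compound_nodes):
            w.writerow([c, "compound", degree_of.get(c, 0)])
        for t in sorted(net.target_nodes):
            w.writerow([t, "target", target_degree[t]])
    g = net.to_networkx()
    for c, d in ranking.entries:
        g.nodes[c]["degree"] = d
    for t, d in target_degree.items():
        g.nodes[t]["degree"] = d
    if ppi_edges:
        for a, b, score in ppi_edges:
            if a in net.target_nodes and b in net.target_nodes:
                g.add_edge(a, b, kind="ppi", score=score)
    graphml_path = prefix.with_suffix(".graphml")
    nx.write_graphml(g, graphml_path)
    return {"edges": edge_path, "nodes": node_path, "graphml": graphml_path}
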