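"""Modified-cosine similarity and molecular-network topology.

A molecular network connects MS/MS spectra whose fragmentation patterns are
similar. The modified cosine allows a fragment of one spectrum to match a
fragment of the other either at (nearly) the same m/z or offset by the
difference of the two precursor masses, so structural analogues that differ
by a single substituent still pair up. Connected components of the filtered
graph are "molecular families" of putatively related compounds.

The score here is computed as an exact maximum-weight one-to-one assignment
of candidate peak pairs (Hungarian algorithm), with square-root intensity
weighting and unit-norm spectra, so the score is a true cosine in [0, 1].
A greedy best-first variant (the heuristic used by common networking
servers) is available via ``method="greedy"``; it never exceeds the exact
score.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from metanet.spectra import Spectrum, SpectrumCollection

logger = logging.getLogger(__name__)

#: Defaults for network construction and library matching.
FRAGMENT_TOL = 0.05  # Da
PRECURSOR_TOL = 0.05  # Da
SCORE_MIN = 0.6  # network edges: strictly greater than
MIN_MATCHED = 4  # network edges: at least
TOP_K = 10
FAMILY_MAX = 100
LIBRARY_SCORE_MIN = 0.7
LIBRARY_MIN_MATCHED = 6


@dataclass(frozen=True, slots=True)
class SimilarityEdge:
    """An undirected similarity edge; source_id < target_id lexicographically."""

    source_id: str
    target_id: str
    score: float
    matched_peaks: int

    def __post_init__(self) -> None:
        if self.source_id >= self.target_id:
            raise ValueError("source_id must sort before target_id")
        if not 0.0 <= self.score <= 1.0 + 1e-12:
            raise ValueError(f"score out of [0,1]: {self.score}")

    def other(self, node: str) -> str:
        return self.target_id if node == self.source_id else self.source_id


@dataclass(slots=True)
class MolecularNetwork:
    """The filtered similarity graph with molecular-family labels."""

    node_ids: set[str]
    edges: list[SimilarityEdge]
    family_of: dict[str, str]
    params: dict = field(default_factory=dict)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in sorted(self.node_ids):
            g.add_node(n, family=self.family_of.get(n, ""))
        for e in self.edges:
            g.add_edge(e.source_id, e.target_id, score=e.score, matched_peaks=e.matched_peaks)
        return g


@dataclass(frozen=True, slots=True)
class LibraryHit:
    """A query spectrum matched to a library spectrum above threshold."""

    query_id: str
    library_id: str
    compound_name: str
    score: float
    matched_peaks: int
    precursor_delta: float
    is_best: bool = False


def _normalized_sqrt_vector(spectrum: Spectrum) -> np.ndarray:
    v = np.sqrt(np.asarray(spectrum.intensities, dtype=float))
    norm = np.linalg.norm(v)
    if norm == 0:
        return v
    return v / norm


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    fragment_tol: float = FRAGMENT_TOL,
    method: Literal["exact", "greedy"] = "exact",
) -> tuple[float, int]:
    """Modified-cosine similarity between two spectra.

    Candidate peak pairs (i, j) are those with ``|mz_a[i] - mz_b[j]| <=
    fragment_tol`` (direct) or ``|mz_a[i] - mz_b[j] - delta| <= fragment_tol``
    where ``delta = precursor_a - precursor_b`` (precursor-shifted). Each
    peak participates in at most one pair. Pair weight is the product of the
    two unit-norm square-root intensities; the score is the weight of the
    optimal one-to-one assignment, and ``matched_peaks`` counts assigned
    pairs with positive weight.

    Returns ``(score, matched_peaks)`` with ``0 <= score <= 1``.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("modified_cosine requires non-empty spectra")
    if fragment_tol <= 0:
        raise ValueError("fragment_tol must be > 0")
    va = _normalized_sqrt_vector(a)
    vb = _normalized_sqrt_vector(b)
    mza = np.asarray(a.mzs)
    mzb = np.asarray(b.mzs)
    delta = a.precursor_mz - b.precursor_mz
    diff = mza[:, None] - mzb[None, :]
    eligible = (np.abs(diff) <= fragment_tol) | (np.abs(diff - delta) <= fragment_tol)
    weights = np.where(eligible, va[:, None] * vb[None, :], 0.0)
    if not eligible.any():
        return 0.0, 0
    if method == "exact":
        rows, cols = linear_sum_assignment(weights, maximize=True)
        chosen = weights[rows, cols]
        score = float(chosen.sum())
        matched = int(np.count_nonzero(chosen > 0))
    elif method == "greedy":
        order = np.argsort(weights, axis=None)[::-1]
        used_a: set[int] = set()
        used_b: set[int] = set()
        score = 0.0
        matched = 0
        for flat in order:
            i, j = divmod(int(flat), weights.shape[1])
            w = weights[i, j]
            if w <= 0:
                break
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            score += float(w)
            matched += 1
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(score, 1.0), matched


def pairwise_edges(
    coll: SpectrumCollection,
    fragment_tol: float = FRAGMENT_TOL,
    score_min: float = SCORE_MIN,
    min_matched: int = MIN_MATCHED,
    method: Literal["exact", "greedy"] = "exact",
) -> list[SimilarityEdge]:
    """Score all unordered spectrum pairs and keep edges passing thresholds.

    An edge is retained only if ``score > score_min`` (strict) and
    ``matched_peaks >= min_matched`` (inclusive).
    """
    if len(coll) == 0:
        raise ValueError("empty spectrum collection")
    spectra = sorted(coll.spectra, key=lambda s: s.spectrum_id)
    edges: list[SimilarityEdge] = []
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            score, matched = modified_cosine(spectra[i], spectra[j], fragment_tol, method)
            if score > score_min and matched >= min_matched:
                edges.append(
                    SimilarityEdge(
                        spectra[i].spectrum_id, spectra[j].spectrum_id, score, matched
                    )
                )
    return edges


def _rank_key(edge: SimilarityEdge, node: str):
    # neighbors ranked by score descending, ties by partner id ascending
    return (-edge.score, edge.other(node))


def mutual_top_k_filter(edges: Sequence[SimilarityEdge], k: int = TOP_K) -> list[SimilarityEdge]:
    """Keep an edge (u, v) only if each endpoint ranks the other in its top k.

    Neighbor rank lists are ordered by score descending with ties broken by
    partner id ascending, so the result is deterministic. With ``k`` at least
    the maximum degree this filter is the identity.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    incident: dict[str, list[SimilarityEdge]] = {}
    for e in edges:
        incident.setdefault(e.source_id, []).append(e)
        incident.setdefault(e.target_id, []).append(e)
    top: dict[str, set[str]] = {}
    for node, es in incident.items():
        ranked = sorted(es, key=lambda e: _rank_key(e, node))
        top[node] = {e.other(node) for e in ranked[:k]}
    return [
        e
        for e in edges
        if e.target_id in top[e.source_id] and e.source_id in top[e.target_id]
    ]


def _family_labels(graph: nx.Graph) -> dict[str, str]:
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    labels: dict[str, str] = {}
    for i, comp in enumerate(comps, start=1):
        for node in comp:
            labels[node] = f"F{i:04d}"
    return labels


def cap_family_size(
    edges: Sequence[SimilarityEdge],
    family_max: int = FAMILY_MAX,
    node_ids: Iterable[str] | None = None,
    params: dict | None = None,
) -> MolecularNetwork:
    """Cap molecular-family sizes by pruning lowest-scoring edges.

    While any connected component exceeds ``family_max`` nodes, the
    lowest-scoring edge inside an oversized component is removed (ties broken
    lexicographically by (source, target)) and components are recomputed.
    Components already within the cap are never modified. ``node_ids`` may
    supply singleton nodes that carry no edge; they keep a family label.
    """
    if family_max < 1:
        raise ValueError("family_max must be >= 1")
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.source_id, e.target_id, edge=e)
    if node_ids is not None:
        g.add_nodes_from(node_ids)
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > family_max]
        if not oversized:
            break
        candidates = [
            g.edges[u, v]["edge"]
            for comp in oversized
            for u, v in g.subgraph(comp).edges
        ]
        victim = min(candidates, key=lambda e: (e.score, e.source_id, e.target_id))
        g.remove_edge(victim.source_id, victim.target_id)
    kept = sorted(
        (d["edge"] for _, _, d in g.edges(data=True)),
        key=lambda e: (e.source_id, e.target_id),
    )
    return MolecularNetwork(
        node_ids=set(g.nodes),
        edges=kept,
        family_of=_family_labels(g),
        params=dict(params or {}),
    )


def build_molecular_network(
    coll: SpectrumCollection,
    fragment_tol: float = FRAGMENT_TOL,
    score_min: float = SCORE_MIN,
    min_matched: int = MIN_MATCHED,
    top_k: int = TOP_K,
    family_max: int = FAMILY_MAX,
    method: Literal["exact", "greedy"] = "exact",
) -> MolecularNetwork:
    """Full network construction chain: score, threshold, mutual top-k, cap.

    Filters are applied in that order: the score/matched-peak thresholds
    first, the mutual top-k rank filter on the surviving edges, then the
    family-size cap. All spectra remain as nodes (singletons keep a family).
    """
    edges = pairwise_edges(coll, fragment_tol, score_min, min_matched, method)
    edges = mutual_top_k_filter(edges, top_k)
    net = cap_family_size(
        edges,
        family_max,
        node_ids=[s.spectrum_id for s in coll],
        params={
            "fragment_tol": fragment_tol,
            "score_min": score_min,
            "min_matched": min_matched,
            "top_k": top_k,
            "family_max": family_max,
        },
    )
    return net


def library_search(
    coll: SpectrumCollection,
    library: SpectrumCollection,
    precursor_tol: float = PRECURSOR_TOL,
    fragment_tol: float = FRAGMENT_TOL,
    score_min: float = LIBRARY_SCORE_MIN,
    min_matched: int = LIBRARY_MIN_MATCHED,
) -> list[LibraryHit]:
    """Match query spectra against a spectral library.

    Candidates are library spectra whose precursor lies within
    ``precursor_tol`` of the query's; candidates are scored with the
    modified cosine and retained when ``score > score_min`` and
    ``matched_peaks >= min_matched``. Hits are reported per query sorted by
    score descending, with the best hit flagged.
    """
    if precursor_tol <= 0 or fragment_tol <= 0:
        raise ValueError("tolerances must be > 0")
    if len(library) == 0:
        logger.warning("library search against an empty library: no hits")
        return []
    hits: list[LibraryHit] = []
    for q in coll:
        q_hits: list[LibraryHit] = []
        for ref in library:
            delta = q.precursor_mz - ref.precursor_mz
            if abs(delta) > precursor_tol:
                continue
            score, matched = modified_cosine(q, ref, fragment_tol)
            if score > score_min and matched >= min_matched:
                name = ref.metadata.get("compound_name", ref.spectrum_id)
                q_hits.append(
                    LibraryHit(q.spectrum_id, ref.spectrum_id, name, score, matched, delta)
                )
        q_hits.sort(key=lambda h: (-h.score, h.library_id))
        for rank, h in enumerate(q_hits):
            hits.append(
                LibraryHit(
                    h.query_id,
                    h.library_id,
                    h.compound_name,
                    h.score,
                    h.matched_peaks,
                    h.precursor_delta,
                    is_best=(rank == 0),
                )
            )
    return hits


def export_network(
    net: MolecularNetwork,
    hits: Sequence[LibraryHit] | None,
    prefix: str | Path,
) -> dict[str, Path]:
    """Write the network for external graph viewers.

    Produces ``<prefix>.edges.tsv`` (source, target, score, matched_peaks),
    ``<prefix>.nodes.tsv`` (id, family, best library hit name and score;
    empty strings when there is no hit), and ``<prefix>.graphml``.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    best: dict[str, LibraryHit] = {}
    for h in hits or []:
        if h.is_best:
            best[h.query_id] = h
    edge_path = prefix.with_suffix(".edges.tsv")
    with open(edge_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["source", "target", "score", "matched_peaks"])
        for e in net.edges:
            w.writerow([e.source_id, e.target_id, f"{e.score:.6f}", e.matched_peaks])
    node_path = prefix.with_suffix(".nodes.tsv")
    with open(node_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "family", "library_hit", "library_score"])
        for n in sorted(net.node_ids):
            h = best.get(n)
            w.writerow(
                [n, net.family_of.get(n, ""), h.compound_name if h else "", f"{h.score:.6f}" if h else ""]
            )
    g = net.to_networkx()
    for n in g.nodes:
        h = best.get(n)
        if h is not None:
            g.nodes[n]["library_hit"] = h.compound_name
            g.nodes[n]["library_score"] = h.score
    graphml_path = prefix.with_suffix(".graphml")
    nx.write_graphml(g, graphml_path)
    return {"edges": edge_path, "nodes": node_path, "graphml": graphml_path}
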