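"""Modified cosine (vs brute-force oracle), topology filters, library search."""

import itertools

import numpy as np
import pytest

from metanet.networking import (
    SimilarityEdge,
    cap_family_size,
    library_search,
    modified_cosine,
    mutual_top_k_filter,
    pairwise_edges,
)

from conftest import collection, make_spectrum, random_spectrum


def brute_force_modified_cosine(a, b, fragment_tol):
    """Independent oracle: exhaustive search over all one-to-one pairings.

    Enumerates every injective mapping from a subset of a's peaks to b's
    peaks in which each pair is a candidate (direct or precursor-shifted),
    and returns the maximum total weight with its pair count. Exponential;
    only usable for tiny spectra.
    """
    va = np.sqrt(np.asarray(a.intensities, dtype=float))
    va /= np.linalg.norm(va)
    vb = np.sqrt(np.asarray(b.intensities, dtype=float))
    vb /= np.linalg.norm(vb)
    delta = a.precursor_mz - b.precursor_mz
    candidates = [
        (i, j)
        for i in range(len(a))
        for j in range(len(b))
        if abs(a.mzs[i] - b.mzs[j]) <= fragment_tol
        or abs(a.mzs[i] - b.mzs[j] - delta) <= fragment_tol
    ]
    best_score, best_matched = 0.0, 0
    for r in range(1, min(len(a), len(b)) + 1):
        for combo in itertools.combinations(candidates, r):
            rows = [i for i, _ in combo]
            cols = [j for _, j in combo]
            if len(set(rows)) < r or len(set(cols)) < r:
                continue
            score = sum(va[i] * vb[j] for i, j in combo)
            if score > best_score + 1e-15:
                best_score = score
                best_matched = sum(1 for i, j in combo if va[i] * vb[j] > 0)
    return min(best_score, 1.0), best_matched


class TestModifiedCosine:
    def test_self_similarity_is_one(self, five_peak_spectrum):
        score, matched = modified_cosine(five_peak_spectrum, five_peak_spectrum, 0.05)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert matched == len(five_peak_spectrum)

    def test_disjoint_peaks_score_zero(self):
        a = make_spectrum("a", 300.0, [(100.0, 1.0), (150.0, 1.0)])
        b = make_spectrum("b", 300.0, [(120.0, 1.0), (170.0, 1.0)])
        score, matched = modified_cosine(a, b, 0.05)
        assert score == 0.0 and matched == 0

    def test_shifted_peaks_match_via_precursor_delta(self):
        # b is a 10-Da-heavier analogue: every fragment shifted by +10
        a = make_spectrum("a", 300.0, [(100.0, 1.0), (150.0, 4.0), (250.0, 9.0)])
        b = make_spectrum("b", 310.0, [(110.0, 1.0), (160.0, 4.0), (260.0, 9.0)])
        score, matched = modified_cosine(a, b, 0.05)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert matched == 3

    def test_hand_example_matches_brute_force(self):
        a = make_spectrum("a", 300.0, [(100.0, 1.0), (150.0, 4.0), (250.0, 9.0)])
        b = make_spectrum("b", 310.0, [(100.0, 1.0), (160.0, 4.0), (260.0, 9.0)])
        score, matched = modified_cosine(a, b, 0.05)
        expected_score, expected_matched = brute_force_modified_cosine(a, b, 0.05)
        assert score == pytest.approx(expected_score, abs=1e-12)
        assert matched == expected_matched

    def test_oracle_equivalence_on_random_small_spectra(self):
        rng = np.random.default_rng(42)
        for trial in range(30):
            n_a, n_b = rng.integers(1, 6, 2)
            a = random_spectrum(rng, "a", int(n_a))
            b = random_spectrum(rng, "b", int(n_b))
            score, matched = modified_cosine(a, b, 5.0)  # wide tol -> many candidates
            escore, ematched = brute_force_modified_cosine(a, b, 5.0)
            assert score == pytest.approx(escore, abs=1e-10), f"trial {trial}"
            assert matched == ematched, f"trial {trial}"

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a = random_spectrum(rng, "a", int(rng.integers(2, 8)))
            b = random_spectrum(rng, "b", int(rng.integers(2, 8)))
            sab = modified_cosine(a, b, 1.0)
            sba = modified_cosine(b, a, 1.0)
            assert sab[0] == pytest.approx(sba[0], abs=1e-10)
            assert sab[1] == sba[1]

    def test_score_bounds(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = random_spectrum(rng, "a", int(rng.integers(2, 12)))
            b = random_spectrum(rng, "b", int(rng.integers(2, 12)))
            score, matched = modified_cosine(a, b, 2.0)
            assert 0.0 <= score <= 1.0
            assert 0 <= matched <= min(len(a), len(b))

    def test_greedy_never_exceeds_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = random_spectrum(rng, "a", int(rng.integers(2, 10)))
            b = random_spectrum(rng, "b", int(rng.integers(2, 10)))
            exact, _ = modified_cosine(a, b, 2.0)
            greedy, _ = modified_cosine(a, b, 2.0, method="greedy")
            assert greedy <= exact + 1e-12

    def test_matchms_cross_check(self):
        """Independent implementation check: our exact-assignment score is
        never below the greedy score of the reference matchms
        ModifiedCosine (same sqrt-intensity weighting), and agrees exactly
        for identical spectra."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine as MatchmsModifiedCosine

        rng = np.random.default_rng(19)
        sim = MatchmsModifiedCosine(tolerance=0.05, intensity_power=0.5)
        for _ in range(20):
            a = random_spectrum(rng, "a", int(rng.integers(3, 10)))
            b = random_spectrum(rng, "b", int(rng.integers(3, 10)))
            ma = matchms.Spectrum(
                mz=np.asarray(a.mzs), intensities=np.asarray(a.intensities),
                metadata={"precursor_mz": a.precursor_mz}, metadata_harmonization=False)
            mb = matchms.Spectrum(
                mz=np.asarray(b.mzs), intensities=np.asarray(b.intensities),
                metadata={"precursor_mz": b.precursor_mz}, metadata_harmonization=False)
            ref = sim.pair(ma, mb)
            ours, _ = modified_cosine(a, b, 0.05)
            assert ours >= float(ref["score"]) - 1e-8
        s = random_spectrum(rng, "s", 6)
        ms = matchms.Spectrum(
            mz=np.asarray(s.mzs), intensities=np.asarray(s.intensities),
            metadata={"precursor_mz": s.precursor_mz}, metadata_harmonization=False)
        ours, _ = modified_cosine(s, s, 0.05)
        assert ours == pytest.approx(float(sim.pair(ms, ms)["score"]), abs=1e-9)

    def test_empty_spectrum_rejected(self, five_peak_spectrum):
        empty = make_spectrum("e", 300.0, [])
        with pytest.raises(ValueError):
            modified_cosine(five_peak_spectrum, empty, 0.05)


def _equal_intensity_pair(shared: int, total: int):
    """Two same-precursor spectra with `total` unit peaks sharing `shared`:
    modified cosine is exactly shared/total."""
    base = [(100.0 + 10 * i, 1.0) for i in range(shared)]
    a = make_spectrum("a", 500.0, base + [(300.0 + 10 * i, 1.0) for i in range(total - shared)])
    b = make_spectrum("b", 500.0, base + [(400.0 + 10 * i, 1.0) for i in range(total - shared)])
    return a, b


class TestPairwiseEdges:
    def test_identical_spectra_edge(self, five_peak_spectrum):
        other = make_spectrum(
            "s2", five_peak_spectrum.precursor_mz,
            list(zip(five_peak_spectrum.mzs, five_peak_spectrum.intensities)))
        edges = pairwise_edges(collection(five_peak_spectrum, other), 0.05, 0.6, 4)
        assert len(edges) == 1
        assert edges[0].score == pytest.approx(1.0, abs=1e-12)
        assert edges[0].matched_peaks == 5

    def test_score_threshold_is_strict(self):
        a, b = _equal_intensity_pair(shared=3, total=5)  # score exactly 0.6
        score, matched = modified_cosine(a, b, 0.05)
        assert score == pytest.approx(0.6, abs=1e-12)
        assert pairwise_edges(collection(a, b), 0.05, 0.6, 3) == []
        kept = pairwise_edges(collection(a, b), 0.05, 0.6 - 1e-9, 3)
        assert len(kept) == 1

    def test_matched_peak_threshold_is_inclusive(self):
        a, b = _equal_intensity_pair(shared=3, total=4)  # score 0.75, 3 matches
        assert pairwise_edges(collection(a, b), 0.05, 0.6, 4) == []
        kept = pairwise_edges(collection(a, b), 0.05, 0.6, 3)
        assert len(kept) == 1 and kept[0].matched_peaks == 3


def _star_edges(n_leaves: int):
    return [
        SimilarityEdge(*sorted(["hub", f"leaf{i:02d}"]), score=0.99 - 0.01 * i, matched_peaks=5)
        for i in range(n_leaves)
    ]


class TestMutualTopK:
    def test_identity_when_k_at_least_degree(self):
        edges = _star_edges(8)
        assert mutual_top_k_filter(edges, 8) == edges
        assert mutual_top_k_filter(edges, 100) == edges

    def test_star_keeps_top_k_leaves(self):
        edges = _star_edges(12)
        kept = mutual_top_k_filter(edges, 10)
        # every leaf has degree 1 (hub in its top anything); hub keeps its 10 best
        expected = sorted(edges, key=lambda e: -e.score)[:10]
        assert sorted(kept, key=lambda e: -e.score) == expected

    def test_triangle_k1_keeps_best_edge_only(self):
        ab = SimilarityEdge("a", "b", 0.9, 5)
        bc = SimilarityEdge("b", "c", 0.8, 5)
        ac = SimilarityEdge("a", "c", 0.7, 5)
        # rank lists: a -> [b, c]; b -> [a, c]; c -> [b, a]; only (a,b) mutual at k=1
        assert mutual_top_k_filter([ab, bc, ac], 1) == [ab]


class TestFamilyCapping:
    def test_no_change_when_under_cap(self):
        edges = [SimilarityEdge("a", "b", 0.9, 5), SimilarityEdge("b", "c", 0.8, 5)]
        net = cap_family_size(edges, family_max=3)
        assert net.edges == sorted(edges, key=lambda e: (e.source_id, e.target_id))
        assert len(set(net.family_of.values())) == 1

    def test_path_pruned_in_ascending_score_order(self):
        # path n1-n2-n3-n4-n5 with scores 0.9, 0.8, 0.7, 0.65; cap 3:
        # remove 0.65 -> components {n1..n4}, {n5}; still oversized ->
        # remove 0.7 -> {n1,n2,n3}, {n4}, {n5}: all within cap
        edges = [
            SimilarityEdge("n1", "n2", 0.9, 5),
            SimilarityEdge("n2", "n3", 0.8, 5),
            SimilarityEdge("n3", "n4", 0.7, 5),
            SimilarityEdge("n4", "n5", 0.65, 5),
        ]
        net = cap_family_size(edges, family_max=3)
        assert {(e.source_id, e.target_id) for e in net.edges} == {("n1", "n2"), ("n2", "n3")}
        fams = {}
        for node, fam in net.family_of.items():
            fams.setdefault(fam, set()).add(node)
        assert sorted(len(v) for v in fams.values()) == [1, 1, 3]

    def test_cap_one_removes_all_edges(self):
        edges = [SimilarityEdge("a", "b", 0.9, 5), SimilarityEdge("b", "c", 0.8, 5)]
        net = cap_family_size(edges, family_max=1)
        assert net.edges == []
        assert len(set(net.family_of.values())) == 3

    def test_random_graphs_respect_cap(self):
        import networkx as nx

        rng = np.random.default_rng(5)
        for trial in range(100):
            n = int(rng.integers(5, 25))
            p = float(rng.uniform(0.1, 0.5))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
            edges = [
                SimilarityEdge(f"v{min(u, v):03d}", f"v{max(u, v):03d}",
                               float(rng.uniform(0.6, 1.0)), 4)
                for u, v in g.edges
            ]
            cap = int(rng.integers(1, 8))
            net = cap_family_size(edges, family_max=cap)
            comp_sizes = {}
            for node, fam in net.family_of.items():
                comp_sizes[fam] = comp_sizes.get(fam, 0) + 1
            assert max(comp_sizes.values(), default=0) <= cap, f"trial {trial}"


class TestLibrarySearch:
    def test_identity_hit(self, tmp_path):
        rng = np.random.default_rng(23)
        q = random_spectrum(rng, "q", 8)
        lib = make_spectrum("L0", q.precursor_mz, list(zip(q.mzs, q.intensities)),
                            metadata={"compound_name": "compound zero"})
        hits = library_search(collection(q), collection(lib), 0.05, 0.05, 0.7, 6)
        assert len(hits) == 1
        assert hits[0].score == pytest.approx(1.0, abs=1e-12)
        assert hits[0].compound_name == "compound zero"
        assert hits[0].is_best

    def test_precursor_tolerance_excludes_candidates(self):
        rng = np.random.default_rng(29)
        q = random_spectrum(rng, "q", 8)
        lib = make_spectrum("L0", q.precursor_mz + 0.06, list(zip(q.mzs, q.intensities)))
        assert library_search(collection(q), collection(lib), 0.05, 0.05, 0.7, 6) == []

    def test_min_matched_peaks_rejects(self):
        # identical 5-peak spectra: perfect score but only 5 matched < 6
        base = [(100.0 + 30 * i, float(10 + i)) for i in range(5)]
        q = make_spectrum("q", 400.0, base)
        lib = make_spectrum("L0", 400.0, base)
        assert library_search(collection(q), collection(lib), 0.05, 0.05, 0.7, 6) == []

    def test_empty_library_warns(self, caplog):
        q = make_spectrum("q", 400.0, [(100, 1), (110, 1)])
        with caplog.at_level("WARNING"):
            assert library_search(collection(q), collection(), 0.05, 0.05) == []
        assert any("empty library" in r.message for r in caplog.records)


class TestExport:
    def test_export_and_graphml_round_trip(self, tmp_path):
        import csv

        import networkx as nx

        edges = [SimilarityEdge("a", "b", 0.9, 5), SimilarityEdge("b", "c", 0.8, 5)]
        net = cap_family_size(edges, family_max=10, node_ids=["a", "b", "c", "lonely"])
        from metanet.networking import LibraryHit, export_network

        hits = [LibraryHit("a", "L0", "quercetin-like", 0.95, 7, 0.001, is_best=True)]
        paths = export_network(net, hits, tmp_path / "net")
        with open(paths["edges"]) as fh:
            rows = list(csv.reader(fh, delimiter="\t"))
        assert len(rows) == 3  # header + 2 edges
        with open(paths["nodes"]) as fh:
            node_rows = {r[0]: r for r in csv.reader(fh, delimiter="\t")}
        assert node_rows["a"][2] == "quercetin-like"
        assert node_rows["lonely"][2] == ""  # empty field, not "NA"
        g = nx.read_graphml(paths["graphml"])
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 2
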