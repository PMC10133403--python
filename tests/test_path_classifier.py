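import itertools
from functools import lru_cache

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from latentomics.path_classifier import (
    Path,
    PathwayGraph,
    cluster_paths_method_b,
    edit_distance,
    extract_paths,
    fit_method_a,
    predict_label,
    sample_reference_paths_method_b,
    similarity,
    similarity_matrix,
    train_label_ensemble,
    vote_verdicts,
)

from conftest import paths_and_labels


def oracle_edit_distance(a: tuple, b: tuple) -> int:
    """Plain recursive Levenshtein with memoization (independent oracle)."""

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        x = 0 if a[i - 1] == b[j - 1] else 1
        return min(rec(i - 1, j) + 1, rec(i, j - 1) + 1, rec(i - 1, j - 1) + x)

    return rec(len(a), len(b))


ALPHABET = ("w", "x", "y", "z")
seqs = st.lists(st.sampled_from(ALPHABET), min_size=0, max_size=6).map(tuple)


class TestEditDistance:
    def test_base_cases(self):
        assert edit_distance(("a", "b", "c"), ("a", "b", "c")) == 0
        assert edit_distance(("a", "b", "c"), ("a", "x", "c")) == 1
        assert edit_distance(("a", "b"), ()) == 2
        assert edit_distance((), ("q",)) == 1

    def test_exhaustive_oracle_agreement(self):
        """~1e4 sampled pairs of length <= 6 over a 4-identifier alphabet
        agree exactly with the recursive oracle."""
        rng = np.random.default_rng(0)
        pool = [
            tuple(rng.choice(ALPHABET, size=rng.integers(0, 7)))
            for _ in range(200)
        ]
        pairs = rng.integers(0, len(pool), size=(10_000, 2))
        for i, j in pairs:
            assert edit_distance(pool[i], pool[j]) == oracle_edit_distance(
                pool[i], pool[j]
            )

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(1)
        pool = [
            tuple(rng.choice(ALPHABET, size=rng.integers(0, 7)))
            for _ in range(60)
        ]
        triples = rng.integers(0, len(pool), size=(1000, 3))
        for i, j, k in triples:
            a, b, c = pool[i], pool[j], pool[k]
            assert edit_distance(a, a) == 0
            assert edit_distance(a, b) == edit_distance(b, a)
            assert edit_distance(a, c) <= edit_distance(a, b) + edit_distance(b, c)

    @settings(max_examples=200, derandomize=True)
    @given(seqs, seqs)
    def test_property_oracle_agreement(self, a, b):
        assert edit_distance(a, b) == oracle_edit_distance(a, b)


class TestSimilarity:
    def test_known_values(self):
        p = Path(tuple("abcde"))
        assert similarity(p, p) == 1.0
        assert similarity(("a", "b", "c"), ("a", "x", "c")) == pytest.approx(2 / 3)
        assert similarity(("a", "b"), ("x", "y")) == 0.0

    def test_both_empty_errors(self):
        with pytest.raises(ValueError):
            similarity((), ())

    def test_identity_iff_equal(self):
        rng = np.random.default_rng(2)
        pool = [tuple(rng.choice(ALPHABET, size=rng.integers(1, 6)))
                for _ in range(50)]
        for a, b in itertools.product(pool[:20], pool[:20]):
            assert (similarity(a, b) == 1.0) == (a == b)

    @settings(max_examples=100, derandomize=True)
    @given(seqs.filter(len), seqs.filter(len))
    def test_invariant_under_renaming(self, a, b):
        rename = {"w": "n1", "x": "n2", "y": "n3", "z": "n4"}
        ra = tuple(rename[c] for c in a)
        rb = tuple(rename[c] for c in b)
        assert similarity(a, b) == similarity(ra, rb)


class TestExtractPaths:
    def test_branching_graph(self):
        g = nx.DiGraph([("a", "b"), ("b", "c"), ("a", "d")])
        got = {p.components for p in extract_paths(g, "a")}
        assert got == {("a", "b", "c"), ("a", "d")}

    def test_cycle_is_cut(self):
        g = nx.DiGraph([("a", "b"), ("b", "a"), ("b", "c")])
        got = {p.components for p in extract_paths(g, "a")}
        assert got == {("a", "b", "c")}

    def test_isolated_target(self):
        g = nx.DiGraph()
        g.add_node("a")
        assert [p.components for p in extract_paths(g, "a")] == [("a",)]

    def test_unknown_start_errors(self):
        with pytest.raises(KeyError):
            extract_paths(nx.DiGraph([("a", "b")]), "zzz")

    def test_max_paths_truncation_warns(self):
        g = nx.DiGraph()
        for i in range(6):
            g.add_edge("s", f"m{i}")
            g.add_edge(f"m{i}", f"t{i}")
        with pytest.warns(UserWarning, match="truncated"):
            got = extract_paths(g, "s", max_paths=3)
        assert len(got) == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_dfs_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(10)]
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for a, b in itertools.permutations(nodes, 2):
            if rng.random() < 0.15:
                g.add_edge(a, b)
        sinks = [n for n in g if g.out_degree(n) == 0]
        start = nodes[0]
        expected = set()
        if g.out_degree(start) == 0:
            expected = {(start,)}
        else:
            for s in sinks:
                for p in nx.all_simple_paths(g, start, s):
                    expected.add(tuple(p))
        got = {p.components for p in extract_paths(g, start, max_paths=10_000)}
        assert got == expected


class TestMethodA:
    def make_paths(self, n, rng, with_motif=None):
        out = []
        for i in range(n):
            fill = [f"f{i}_{t}" for t in range(int(rng.integers(2, 5)))]
            out.append(Path(tuple(fill + (list(with_motif) if with_motif else []))))
        return out

    def test_rank_one_matrix_keeps_single_component(self):
        rng = np.random.default_rng(0)
        refs = self.make_paths(4, rng, with_motif=("m1", "m2"))
        # identical training paths: similarity matrix rows identical -> rank <= 1
        train = [Path(("q1", "q2", "m1", "m2"))] * 6
        recipe = fit_method_a(train, refs)
        assert recipe.n_components == 1

    def test_retained_components_match_eigen_scan(self):
        rng = np.random.default_rng(1)
        a = rng.random((20, 8))
        from sklearn.decomposition import PCA

        pca = PCA(svd_solver="full").fit(a)
        ratios = pca.explained_variance_ratio_
        expected = int(np.searchsorted(np.cumsum(ratios), 0.99) + 1)

        # brute-force cumulative-eigenvalue scan on the covariance
        cov = np.cov(a, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        frac = np.cumsum(eig) / eig.sum()
        brute = int(np.argmax(frac >= 0.99) + 1)
        assert expected == brute

    def test_variance_retention_contract(self, pathway_signal):
        paths, y = paths_and_labels(pathway_signal)
        refs = [p for p, pos in zip(paths, y) if pos][:40]
        recipe = fit_method_a(paths[:80], refs)
        kept = recipe.pca.explained_variance_ratio_[: recipe.n_components].sum()
        assert kept >= 0.99 - 1e-9
        x = recipe.transform(paths[:80])
        assert x.shape == (80, recipe.n_components)
        assert recipe.n_components <= min(80, len(refs))

    def test_no_reference_paths_errors(self):
        with pytest.raises(ValueError):
            fit_method_a([Path(("a",))], [])


class TestMethodB:
    def test_identical_paths_share_cluster(self):
        p = Path(("x", "a", "b"))
        others = [Path(("x", "a", "b")), Path(("y", "c", "d")), Path(("z", "e"))]
        labels = cluster_paths_method_b([p, Path(("x", "a", "b"))], others)
        assert labels[0] == labels[1]

    def test_planted_motif_groups_recovered(self):
        rng = np.random.default_rng(3)
        g1 = [Path(("x", f"u{i}", "m1", "m2", "m3")) for i in range(3)]
        g2 = [Path(("x", f"v{i}", "k1", "k2", "k3")) for i in range(3)]
        all_paths = g1 + g2 + [
            Path(tuple(rng.choice(["a", "b", "c", "d", "e"], 5))) for _ in range(10)
        ]
        labels = cluster_paths_method_b(g1 + g2, all_paths)
        assert len({labels[i] for i in range(3)}) == 1
        assert len({labels[i] for i in range(3, 6)}) == 1
        assert labels[0] != labels[3]

    def test_constant_row_becomes_singleton_with_warning(self):
        # a length-1 path equally dissimilar to everything: constant profile
        xs = [Path(("q",)), Path(("x", "a", "b")), Path(("x", "a", "c"))]
        refs = [Path(("r1", "r2", "r3")), Path(("s1", "s2", "s3"))]
        with pytest.warns(UserWarning, match="constant"):
            labels = cluster_paths_method_b(xs, refs)
        assert labels[0] not in labels[1:]

    @pytest.mark.parametrize(
        "n_pairs, group_sizes, expected_cap",
        [(5, [3, 200, 7, 1, 150], 100), (1, [700], 500)],
    )
    def test_reference_sampling_cap(self, n_pairs, group_sizes, expected_cap):
        rng = np.random.default_rng(0)
        labeled = []
        for pair_id, size in enumerate(group_sizes):
            for i in range(size):
                labeled.append(
                    (Path((f"s{pair_id}", f"p{i}")), f"s{pair_id}", 0)
                )
        out = sample_reference_paths_method_b(labeled, rng)
        from collections import Counter

        got = Counter(p.start for p in out)
        for pair_id, size in enumerate(group_sizes):
            assert got[f"s{pair_id}"] == min(size, expected_cap)


class TestVoting:
    def test_quoted_rule_examples(self):
        verdict, votes = vote_verdicts(np.array([[0.6]] * 6 + [[0.4]] * 4))
        assert verdict[0] and votes[0] == 6
        verdict, _ = vote_verdicts(np.array([[0.9]] * 5 + [[0.1]] * 5))
        assert not verdict[0]
        verdict, votes = vote_verdicts(np.full((10, 1), 0.5))
        assert verdict[0] and votes[0] == 10

    def test_monotone_in_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.random((10, 30))
        base, _ = vote_verdicts(scores)
        bumped, _ = vote_verdicts(np.clip(scores + 0.2, 0, 1))
        assert not (base & ~bumped).any()


class TestEnsemble:
    def test_single_class_label_errors(self, pathway_signal):
        paths, _ = paths_and_labels(pathway_signal)
        with pytest.raises(ValueError):
            train_label_ensemble(paths[:40], [True] * 40, "L00", seed=0)

    def test_deterministic_given_seed(self, pathway_signal):
        paths, y = paths_and_labels(pathway_signal)
        e1 = train_label_ensemble(paths, y, "L00", method="A", seed=4)
        e2 = train_label_ensemble(paths, y, "L00", method="A", seed=4)
        p1 = predict_label(e1, paths[:25])
        p2 = predict_label(e2, paths[:25])
        assert p1["votes"].tolist() == p2["votes"].tolist()
        assert e1.metrics == e2.metrics

    def test_predict_output_schema(self, pathway_signal):
        paths, y = paths_and_labels(pathway_signal)
        ens = train_label_ensemble(paths, y, "L00", method="B", seed=5)
        out = predict_label(ens, paths[:12])
        assert list(out.columns) == [
            "path_id", "start", "path", "votes", "fraction", "verdict",
        ]
        assert out.attrs["scores"].shape == (10, 12)
        assert ((out["fraction"] * 10).round() == out["votes"]).all()

    def test_ensemble_has_ten_models(self, pathway_signal):
        paths, y = paths_and_labels(pathway_signal)
        ens = train_label_ensemble(paths, y, "L00", method="A", seed=6)
        assert len(ens.models) == 10


class TestPathwayGraphType:
    def test_targets_must_be_nodes(self):
        g = nx.DiGraph([("a", "b")])
        with pytest.raises(ValueError):
            PathwayGraph(g, {"drug1": {"zz"}})

    def test_label_inheritance(self):
        g = nx.DiGraph([("a", "b")])
        pg = PathwayGraph(
            g, {"d1": {"a"}, "d2": {"a"}},
            drug_ti={"d1": {"TI1"}, "d2": {"TI2"}},
            drug_se={"d1": {"SE1"}},
        )
        assert pg.node_labels("TI")["a"] == {"TI1", "TI2"}
        assert pg.node_labels("SE")["a"] == {"SE1"}
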