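"""Interaction networks, homophily fractions, neighbor scores, and AUC."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import build_corpus
from edtribes.labels import ClassLabel
from edtribes.networks import (
    build_network,
    favorite_preference,
    inclass_fractions,
    neighbor_scores,
    network_auc,
)

PA, PR = ClassLabel.PRO_ANA, ClassLabel.PRO_RECOVERY


def _two_user_corpus():
    return build_corpus(
        users=["a", "b"],
        photos=[{"photo_id": "p1", "owner_id": "b", "day": 0}],
        comments=[
            {"photo_id": "p1", "commenter_id": "a", "day": 1},
            {"photo_id": "p1", "commenter_id": "a", "day": 2},
            {"photo_id": "p1", "commenter_id": "a", "day": 3},
        ],
        favorites=[("p1", "a")],
        contacts=[("a", "b")],
    )


class TestBuild:
    def test_single_comment_edge_weight(self):
        corpus = build_corpus(
            users=["a", "b"],
            photos=[{"photo_id": "p1", "owner_id": "b", "day": 0}],
            comments=[{"photo_id": "p1", "commenter_id": "a", "day": 1}],
        )
        g = build_network(corpus, {"a": PA, "b": PR}, "comments")
        assert g["a"]["b"]["weight"] == 1

    def test_repeat_comments_accumulate_weight(self):
        g = build_network(_two_user_corpus(), {"a": PA, "b": PR}, "comments")
        assert g["a"]["b"]["weight"] == 3

    def test_unlabeled_users_excluded_and_isolates_kept(self):
        corpus = _two_user_corpus()
        labels = {"a": PA}  # b unlabeled
        g = build_network(corpus, labels, "comments")
        assert set(g.nodes) == {"a"}
        assert g.number_of_edges() == 0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_network(_two_user_corpus(), {"a": PA, "b": PR}, "likes")

    def test_edges_match_relational_join_oracle(self, small_synthetic, small_labels):
        corpus, _ = small_synthetic
        g = build_network(corpus, small_labels, "comments")
        owner = corpus.photos.set_index("photo_id")["owner_id"]
        comm = {u for u, l in small_labels.items() if l in (PA, PR)}
        expected: dict[tuple, int] = {}
        for row in corpus.comments.itertuples():
            s, d = row.commenter_id, owner[row.photo_id]
            if s in comm and d in comm and s != d:
                expected[(s, d)] = expected.get((s, d), 0) + 1
        got = {(u, v): d["weight"] for u, v, d in g.edges(data=True)}
        assert got == expected


class TestFractions:
    def _graph(self, edges):
        g = nx.DiGraph()
        for s, d, w in edges:
            g.add_edge(s, d, weight=w)
        return g

    def test_all_inclass_gives_ones(self):
        labels = {"a": PA, "b": PA, "x": PR, "y": PR}
        g = self._graph([("a", "b", 5), ("x", "y", 2)])
        s = inclass_fractions(g, labels)
        assert s.frac_pa == pytest.approx(1.0)
        assert s.frac_pr == pytest.approx(1.0)

    def test_uniform_table_gives_zero_chi2(self):
        labels = {"a": PA, "b": PA, "x": PR, "y": PR}
        g = self._graph(
            [("a", "b", 10), ("a", "x", 10), ("x", "y", 10), ("x", "a", 10)]
        )
        s = inclass_fractions(g, labels)
        assert s.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_no_outedges_is_signalled(self):
        labels = {"a": PA, "x": PR, "y": PR}
        s = inclass_fractions(self._graph([("x", "y", 1)]), labels)
        assert s.frac_pa is None
        assert s.warnings

    def test_contingency_conserves_total_edge_weight(self, small_synthetic, small_labels):
        corpus, _ = small_synthetic
        g = build_network(corpus, small_labels, "comments")
        s = inclass_fractions(g, small_labels)
        assert s.contingency.sum() == sum(d["weight"] for _, _, d in g.edges(data=True))

    def test_planted_comment_homophily_recovered(self, small_synthetic, small_labels):
        corpus, truth = small_synthetic
        g = build_network(corpus, small_labels, "comments")
        s = inclass_fractions(g, small_labels)
        planted = truth.homophily["comment"]
        assert s.frac_pa == pytest.approx(planted["pa"], abs=0.05)
        assert s.frac_pr == pytest.approx(planted["pr"], abs=0.05)


class TestFavorites:
    def _pref_graph(self, pa_to_pa, pa_to_pr):
        g = nx.DiGraph()
        g.add_edge("a", "p", weight=pa_to_pa)
        g.add_edge("a", "r", weight=pa_to_pr)
        return g, {"a": PA, "p": PA, "r": PR}

    def test_even_split_ratio_one(self):
        g, labels = self._pref_graph(10, 10)
        assert favorite_preference(g, labels).pa_ratio == pytest.approx(1.0)

    def test_ninety_ten_ratio_nine(self):
        g, labels = self._pref_graph(90, 10)
        assert favorite_preference(g, labels).pa_ratio == pytest.approx(9.0)

    def test_no_pa_favorites_is_signalled(self):
        g = nx.DiGraph()
        g.add_edge("r", "p", weight=1)
        pref = favorite_preference(g, {"r": PR, "p": PA})
        assert pref.pa_shares is None
        assert pref.warnings

    def test_shares_match_counting_oracle(self, small_synthetic, small_labels):
        corpus, _ = small_synthetic
        g = build_network(corpus, small_labels, "favorites")
        pref = favorite_preference(g, small_labels)
        owner = corpus.photos.set_index("photo_id")["owner_id"]
        counts = {PA: 0, PR: 0}
        total = 0
        for row in corpus.favorites.itertuples():
            s, d = row.user_id, owner[row.photo_id]
            if small_labels.get(s) is PA and small_labels.get(d) in counts and s != d:
                counts[small_labels[d]] += 1
                total += 1
        assert pref.pa_shares["pro_ana"] == pytest.approx(counts[PA] / total)
        assert pref.pa_shares["pro_recovery"] == pytest.approx(counts[PR] / total)


class TestNeighborScores:
    def test_counts_and_isolates(self):
        g = nx.DiGraph()
        labels = {"x": PA, "a": PA, "b": PA, "c": PA, "d": PR, "iso": PR}
        for n in labels:
            g.add_node(n)
        g.add_edge("x", "a")
        g.add_edge("b", "x")
        g.add_edge("x", "c")
        g.add_edge("d", "x")
        scores = neighbor_scores(g, labels).set_index("user_id")
        assert scores.loc["x", "score"] == 2  # 3 PA minus 1 PR
        assert scores.loc["iso", "score"] == 0

    def test_matches_adjacency_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            g = nx.gnp_random_graph(50, 0.1, seed=int(rng.integers(1e6)), directed=True)
            g = nx.relabel_nodes(g, {i: f"u{i}" for i in range(50)})
            labels = {f"u{i}": (PA if rng.random() < 0.5 else PR) for i in range(50)}
            scores = neighbor_scores(g, labels).set_index("user_id")
            A = nx.to_numpy_array(g, nodelist=[f"u{i}" for i in range(50)])
            und = ((A + A.T) > 0).astype(int)
            np.fill_diagonal(und, 0)
            is_pa = np.array([labels[f"u{i}"] is PA for i in range(50)])
            expected = und @ is_pa - und @ (~is_pa)
            got = scores.loc[[f"u{i}" for i in range(50)], "score"].to_numpy()
            assert np.array_equal(got, expected)

    def test_weighted_variant_counts_interactions(self):
        g = nx.DiGraph()
        g.add_edge("x", "a", weight=3)
        g.add_edge("a", "x", weight=2)
        labels = {"x": PR, "a": PA}
        unweighted = neighbor_scores(g, labels).set_index("user_id")
        weighted = neighbor_scores(g, labels, weighted=True).set_index("user_id")
        assert unweighted.loc["x", "score"] == 1
        assert weighted.loc["x", "score"] == 5


class TestAuc:
    def _frame(self, scores):
        return pd.DataFrame(
            {"user_id": [f"u{i}" for i in range(len(scores))],
             "n_pa_neighbors": 0, "n_pr_neighbors": 0, "score": scores}
        )

    def test_perfect_separation_is_one(self):
        labels = {f"u{i}": (PA if i < 3 else PR) for i in range(6)}
        assert network_auc(self._frame([5, 4, 3, 2, 1, 0]), labels) == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        labels = {f"u{i}": (PA if i < 3 else PR) for i in range(6)}
        assert network_auc(self._frame([1] * 6), labels) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        labels = {f"u{i}": PA for i in range(4)}
        with pytest.raises(ValueError):
            network_auc(self._frame([1, 2, 3, 4]), labels)

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = 30
            scores = rng.integers(-5, 6, size=n).astype(float)
            labels = {f"u{i}": (PA if rng.random() < 0.5 else PR) for i in range(n)}
            if len({l for l in labels.values()}) < 2:
                continue
            auc = network_auc(self._frame(scores), labels)
            pos = [scores[i] for i in range(n) if labels[f"u{i}"] is PA]
            neg = [scores[i] for i in range(n) if labels[f"u{i}"] is PR]
            conc = sum(
                1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
            )
            assert auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)
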