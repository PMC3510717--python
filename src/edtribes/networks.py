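"""Interaction networks, homophily measures, and neighbor-based prediction.

The four typed graphs over labeled community users are contacts (directed,
as stored), comments (commenter → photo owner, weighted by comment count),
favorites (favoriter → photo owner, weighted by favorite count) and tags
(undirected, from thresholded TF-IDF cosine similarity).  On each network
the module quantifies in-/cross-community interaction (weighted in-class
fractions with a chi-square test), the favoriting preference ratio, and how
well a user's class is predicted by the difference between their pro-ana and
pro-recovery neighbor counts, scored by the area under the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from edtribes.corpus import Corpus
from edtribes.labels import ClassLabel
from edtribes.similarity import build_tfidf, tag_similarity_graph, user_documents

__all__ = [
    "build_network",
    "inclass_fractions",
    "favorite_preference",
    "neighbor_scores",
    "network_auc",
    "InclassSummary",
    "FavoritePreference",
    "export_graphml",
]

NETWORK_KINDS = ("contacts", "comments", "favorites", "tags")
_COMMUNITY = (ClassLabel.PRO_ANA, ClassLabel.PRO_RECOVERY)


def _community_nodes(labels: dict[str, ClassLabel]) -> list[str]:
    return sorted(u for u, l in labels.items() if l in _COMMUNITY)


def build_network(
    corpus: Corpus,
    labels: dict[str, ClassLabel],
    kind: str,
    restrict_to_labeled: bool = True,
    tag_mode: str = "fixed",
    tag_threshold: float = 0.99,
    tag_target_edges: int | None = None,
) -> nx.DiGraph | nx.Graph:
    """Build one of the four interaction networks over community users.

    Contacts, comments and favorites are directed with integer weights
    (interaction counts); tags is undirected, built from user-level TF-IDF
    cosine similarity (see :func:`edtribes.similarity.tag_similarity_graph`).
    Self-edges are dropped; nodes are restricted to pro-ana / pro-recovery
    labeled users (every such user appears, including isolates).
    """
    if kind not in NETWORK_KINDS:
        raise ValueError(f"unknown network kind: {kind}")
    if kind == "tags":
        docs, users = user_documents(corpus, labels)
        if not users:
            g = nx.Graph(kind="tags")
            return g
        vectors = build_tfidf(docs, doc_ids=users)
        return tag_similarity_graph(
            vectors, labels, mode=tag_mode, threshold=tag_threshold,
            target_edges=tag_target_edges,
        )

    nodes = _community_nodes(labels)
    node_set = set(nodes)
    g = nx.DiGraph(kind=kind)
    for u in nodes:
        g.add_node(u, community=labels[u].value)

    if kind == "contacts":
        pairs = [
            (r.from_user, r.to_user)
            for r in corpus.contacts.itertuples()
            if not restrict_to_labeled or (r.from_user in node_set and r.to_user in node_set)
        ]
    else:
        owner = corpus.photos.set_index("photo_id")["owner_id"]
        src_col = "commenter_id" if kind == "comments" else "user_id"
        table = corpus.comments if kind == "comments" else corpus.favorites
        pairs = []
        if len(table):
            src = table[src_col]
            dst = table["photo_id"].map(owner)
            for s, d in zip(src, dst):
                if not restrict_to_labeled or (s in node_set and d in node_set):
                    pairs.append((s, d))

    for s, d in pairs:
        if s == d:
            continue  # self-edges dropped
        if g.has_edge(s, d):
            g[s][d]["weight"] += 1
        else:
            g.add_edge(s, d, weight=1)
    return g


@dataclass
class InclassSummary:
    """Weighted in-class interaction fractions with a chi-square test."""

    frac_pa: float | None  # in-class fraction of PA users' out-interactions
    frac_pr: float | None
    contingency: np.ndarray  # rows: source class (pa, pr); cols: target (pa, pr)
    chi2: float | None
    pvalue: float | None
    warnings: list = field(default_factory=list)


def _weighted_2x2(g, labels) -> np.ndarray:
    table = np.zeros((2, 2))
    row = {ClassLabel.PRO_ANA: 0, ClassLabel.PRO_RECOVERY: 1}
    edges = g.edges(data=True)
    directed = g.is_directed()
    for u, v, data in edges:
        lu, lv = labels.get(u), labels.get(v)
        if lu not in row or lv not in row:
            continue
        w = data.get("weight", 1)
        table[row[lu], row[lv]] += w
        if not directed:
            table[row[lv], row[lu]] += w
    return table


def inclass_fractions(g, labels: dict[str, ClassLabel]) -> InclassSummary:
    """Per-class in-class fraction of (weighted) out-interactions.

    The fraction for a source class is the weight of its edges landing on
    the same class over all its out-edge weight; the chi-square statistic is
    computed on the weighted 2×2 source × target table with 1 df (no
    continuity correction).  For undirected networks each edge counts once
    from each endpoint.
    """
    table = _weighted_2x2(g, labels)
    warnings = []
    fracs = []
    for i, name in enumerate(("pro_ana", "pro_recovery")):
        total = table[i].sum()
        if total == 0:
            fracs.append(None)
            warnings.append(f"{name}: no out-interactions, fraction undefined")
        else:
            fracs.append(float(table[i, i] / total))
    if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        chi2, p = float(chi2), float(p)
    else:
        chi2 = p = None
        warnings.append("degenerate contingency table: chi-square undefined")
    return InclassSummary(fracs[0], fracs[1], table, chi2, p, warnings)


@dataclass
class FavoritePreference:
    """Favoriting target-class shares per source class and the PA ratio."""

    pa_shares: dict | None  # {"pro_ana": share, "pro_recovery": share}
    pr_shares: dict | None
    pa_ratio: float | None  # PA users' share_to_pa / share_to_pr
    warnings: list = field(default_factory=list)


def favorite_preference(g, labels: dict[str, ClassLabel]) -> FavoritePreference:
    """How each community distributes its favorites over target classes.

    The headline number is the pro-ana preference ratio: the share of PA
    users' favorites going to PA-posted photos divided by the share going to
    PR-posted photos.  Undefined cells are None with a warning.
    """
    table = _weighted_2x2(g, labels)
    warnings = []
    shares = []
    for i, name in enumerate(("pro_ana", "pro_recovery")):
        total = table[i].sum()
        if total == 0:
            shares.append(None)
            warnings.append(f"{name} users have no favorites: shares undefined")
        else:
            shares.append(
                {"pro_ana": float(table[i, 0] / total), "pro_recovery": float(table[i, 1] / total)}
            )
    ratio = None
    if shares[0] is not None:
        if shares[0]["pro_recovery"] > 0:
            ratio = shares[0]["pro_ana"] / shares[0]["pro_recovery"]
        else:
            warnings.append("pro_ana favorites never target pro_recovery: ratio undefined")
    return FavoritePreference(shares[0], shares[1], ratio, warnings)


def neighbor_scores(
    g, labels: dict[str, ClassLabel], weighted: bool = False
) -> pd.DataFrame:
    """Per-node neighbor-difference scores.

    Neighbors are the union of in- and out-neighbors.  By default each
    distinct neighbor counts once; with ``weighted`` the total interaction
    weight to/from the neighbor counts instead.  The score is
    ``n_pa_neighbors - n_pr_neighbors``; isolated nodes score 0.
    """
    rows = []
    for node in sorted(g.nodes):
        if g.is_directed():
            neigh = set(g.successors(node)) | set(g.predecessors(node))
        else:
            neigh = set(g.neighbors(node))
        neigh.discard(node)
        n_pa = n_pr = 0.0
        for v in neigh:
            lab = labels.get(v)
            if lab not in _COMMUNITY:
                continue
            if weighted:
                w = 0.0
                if g.has_edge(node, v):
                    w += g[node][v].get("weight", 1)
                if g.is_directed() and g.has_edge(v, node):
                    w += g[v][node].get("weight", 1)
            else:
                w = 1.0
            if lab is ClassLabel.PRO_ANA:
                n_pa += w
            else:
                n_pr += w
        rows.append(
            {"user_id": node, "n_pa_neighbors": n_pa, "n_pr_neighbors": n_pr,
             "score": n_pa - n_pr}
        )
    return pd.DataFrame(rows, columns=["user_id", "n_pa_neighbors", "n_pr_neighbors", "score"])


def network_auc(scores: pd.DataFrame, labels: dict[str, ClassLabel]) -> float:
    """Area under the ROC curve of the neighbor score as a pro-ana predictor.

    Uses the rank (Mann-Whitney) formulation with midranks, i.e. tied pairs
    receive half credit.  Raises when only one class is present.
    """
    lab = scores["user_id"].map(lambda u: labels.get(u))
    mask = lab.isin(_COMMUNITY)
    y = (lab[mask] == ClassLabel.PRO_ANA).to_numpy()
    s = scores.loc[mask.to_numpy(), "score"].to_numpy(dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: a single class among scored users")
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def export_graphml(g, path) -> None:
    """GraphML export with the community label as a node attribute."""
    nx.write_graphml(g, path)
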