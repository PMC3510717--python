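"""TF-IDF tag vectors, cosine similarity, and the tag-similarity graph.

Documents are bags of tags — either single photos or users (the
concatenation of a user's photo tags).  Weights follow the classic vector
space model, ``tf(t, d) * ln(N / df(t))`` with natural log and no smoothing;
document frequency is computed on the same collection being vectorised.
Mean pairwise cosine similarities within and between the two communities
summarise how alike the communities' tag usage is; thresholding user-level
cosine similarity yields the fourth ("tags") interaction network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy import stats

from edtribes.labels import ClassLabel

__all__ = [
    "TfidfVectors",
    "SimilaritySummary",
    "build_tfidf",
    "cosine",
    "class_pair_similarity",
    "tag_similarity_graph",
    "CalibrationError",
]


class CalibrationError(RuntimeError):
    """Raised when the tags-graph threshold cannot reach the target edge count."""


@dataclass
class TfidfVectors:
    """A TF-IDF-weighted document collection in sparse form.

    ``matrix`` rows are documents over ``vocabulary``; ``norms`` holds the
    Euclidean norms (zero for empty documents).
    """

    matrix: sp.csr_matrix
    vocabulary: list[str]
    doc_ids: list[str]
    norms: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.norms = np.asarray(sp.linalg.norm(self.matrix, axis=1)).ravel()

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def vector(self, i: int) -> dict[str, float]:
        """Document ``i`` as a tag → weight mapping (zero weights omitted)."""
        row = self.matrix.getrow(i).tocoo()
        return {self.vocabulary[j]: float(v) for j, v in zip(row.col, row.data) if v != 0.0}

    def unit_matrix(self) -> sp.csr_matrix:
        """Rows scaled to unit norm; zero-norm rows stay zero."""
        inv = np.where(self.norms > 0, 1.0 / np.where(self.norms > 0, self.norms, 1.0), 0.0)
        return sp.diags(inv) @ self.matrix

    def cosine(self, i: int, j: int) -> float:
        ni, nj = self.norms[i], self.norms[j]
        if ni == 0.0 or nj == 0.0:
            return 0.0
        dot = float(self.matrix.getrow(i).multiply(self.matrix.getrow(j)).sum())
        return dot / (ni * nj)


def build_tfidf(
    documents: Sequence[Sequence[str]],
    tf_mode: str = "raw",
    idf_mode: str = "log",
    doc_ids: Sequence[str] | None = None,
) -> TfidfVectors:
    """TF-IDF vectors for a collection of tag lists.

    ``tf_mode``: ``raw`` (count within document, the default) or ``binary``.
    ``idf_mode``: ``log`` (``ln(N / df)``, no smoothing) or ``none``.
    A term occurring in every document gets zero weight under ``log``; an
    empty document yields a zero vector with norm 0.
    """
    if len(documents) == 0:
        raise ValueError("need at least one document")
    if tf_mode not in ("raw", "binary"):
        raise ValueError(f"unknown tf_mode: {tf_mode}")
    if idf_mode not in ("log", "none"):
        raise ValueError(f"unknown idf_mode: {idf_mode}")
    vocab: dict[str, int] = {}
    rows, cols, vals = [], [], []
    df_sets: list[set[int]] = []
    for i, doc in enumerate(documents):
        counts: dict[int, int] = {}
        for t in doc:
            j = vocab.setdefault(t, len(vocab))
            counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(1.0 if tf_mode == "binary" else float(c))
        df_sets.append(set(counts))
    n_docs, n_terms = len(documents), len(vocab)
    mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(n_docs, max(n_terms, 1)), dtype=float
    )
    if idf_mode == "log" and n_terms:
        df = np.zeros(n_terms)
        for s in df_sets:
            for j in s:
                df[j] += 1
        idf = np.log(n_docs / df)
        mat = mat @ sp.diags(idf)
    vocab_list = [t for t, _ in sorted(vocab.items(), key=lambda kv: kv[1])]
    ids = list(doc_ids) if doc_ids is not None else [str(i) for i in range(n_docs)]
    if len(ids) != n_docs:
        raise ValueError("doc_ids length mismatch")
    return TfidfVectors(matrix=mat.tocsr(), vocabulary=vocab_list, doc_ids=ids)


def cosine(v1: Mapping[str, float], v2: Mapping[str, float]) -> float:
    """Cosine similarity of two sparse tag → weight mappings.

    Defined as 0 when either vector has zero norm.
    """
    n1 = np.sqrt(sum(w * w for w in v1.values()))
    n2 = np.sqrt(sum(w * w for w in v2.values()))
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    dot = sum(w * v2[t] for t, w in v1.items() if t in v2)
    return dot / (n1 * n2)


@dataclass
class SimilaritySummary:
    """Mean cosine similarities within and between the two communities."""

    mean_within_pa: float | None
    mean_within_pr: float | None
    mean_between: float | None
    n_pairs: dict
    mode: dict  # per cell: "exhaustive" | "sampled"
    ranksum_p: dict  # descriptive p-values between cells; pairs not independent
    warnings: list = field(default_factory=list)


def _pair_sample_sims(U, idx_a, idx_b, n, rng, within: bool) -> np.ndarray:
    if within:
        i = idx_a[rng.integers(0, len(idx_a), size=2 * n)]
        a, b = i[:n], i[n:]
        keep = a != b
        a, b = a[keep], b[keep]
    else:
        a = idx_a[rng.integers(0, len(idx_a), size=n)]
        b = idx_b[rng.integers(0, len(idx_b), size=n)]
    return np.asarray(U[a].multiply(U[b]).sum(axis=1)).ravel()


def class_pair_similarity(
    vectors: TfidfVectors,
    doc_class: Sequence[ClassLabel],
    max_pairs: int = 2_000_000,
    seed: int = 0,
    ranksum_sample: int = 50_000,
) -> SimilaritySummary:
    """Average pairwise cosine similarity within and between communities.

    Exhaustive means are computed in closed form from sums of unit vectors
    (mathematically identical to averaging all pairs); when a cell has more
    than ``max_pairs`` pairs the mean is instead taken over a seeded uniform
    pair sample and the cell is marked ``sampled``.  Rank-sum p-values
    between cells are computed on seeded pair samples and are descriptive
    only, since pairs sharing a document are not independent.
    """
    doc_class = list(doc_class)
    if len(doc_class) != len(vectors):
        raise ValueError("doc_class length mismatch")
    rng = np.random.default_rng(seed)
    U = vectors.unit_matrix().tocsr()
    idx = {
        "pa": np.flatnonzero([c is ClassLabel.PRO_ANA for c in doc_class]),
        "pr": np.flatnonzero([c is ClassLabel.PRO_RECOVERY for c in doc_class]),
    }
    warnings = []
    means: dict[str, float | None] = {}
    n_pairs: dict[str, int] = {}
    mode: dict[str, str] = {}
    samples: dict[str, np.ndarray] = {}

    for cell, (a, b) in (
        ("within_pa", ("pa", "pa")),
        ("within_pr", ("pr", "pr")),
        ("between", ("pa", "pr")),
    ):
        ia, ib = idx[a], idx[b]
        within = a == b
        npair = len(ia) * (len(ia) - 1) // 2 if within else len(ia) * len(ib)
        n_pairs[cell] = npair
        if (within and len(ia) < 2) or (not within and (len(ia) == 0 or len(ib) == 0)):
            means[cell] = None
            mode[cell] = "undefined"
            warnings.append(f"{cell}: fewer than 2 documents, mean undefined")
            continue
        if npair <= max_pairs:
            if within:
                S = np.asarray(U[ia].sum(axis=0)).ravel()
                sum_norm2 = float(np.asarray(U[ia].multiply(U[ia]).sum()))
                total = (float(S @ S) - sum_norm2) / 2.0
            else:
                Sa = np.asarray(U[ia].sum(axis=0)).ravel()
                Sb = np.asarray(U[ib].sum(axis=0)).ravel()
                total = float(Sa @ Sb)
            means[cell] = total / npair
            mode[cell] = "exhaustive"
        else:
            sims = _pair_sample_sims(U, ia, ib, max_pairs, rng, within)
            means[cell] = float(sims.mean())
            mode[cell] = "sampled"
        samples[cell] = _pair_sample_sims(
            U, ia, ib, min(ranksum_sample, max(npair, 1)), rng, within
        )

    ranksum_p: dict[str, float] = {}
    for c1, c2 in (("within_pa", "within_pr"), ("within_pa", "between"), ("within_pr", "between")):
        if c1 in samples and c2 in samples and len(samples[c1]) and len(samples[c2]):
            ranksum_p[f"{c1}_vs_{c2}"] = float(
                stats.mannwhitneyu(samples[c1], samples[c2], alternative="two-sided").pvalue
            )
    return SimilaritySummary(
        means["within_pa"], means["within_pr"], means["between"],
        n_pairs, mode, ranksum_p, warnings,
    )


def photo_documents(corpus, labels, flags=None, relevant_only: bool = False):
    """Photos of community users as (documents, classes, photo_ids).

    With ``relevant_only`` the collection is restricted to flagged photos.
    """
    docs, classes, ids = [], [], []
    for row in corpus.photos.itertuples():
        cls = labels.get(row.owner_id)
        if cls not in (ClassLabel.PRO_ANA, ClassLabel.PRO_RECOVERY):
            continue
        if relevant_only and flags is not None and not bool(flags.get(row.photo_id, False)):
            continue
        docs.append(list(row.tags))
        classes.append(cls)
        ids.append(row.photo_id)
    return docs, classes, ids


def user_documents(corpus, labels):
    """Community users as tag documents (concatenated photo tags)."""
    users = sorted(
        u for u, l in labels.items() if l in (ClassLabel.PRO_ANA, ClassLabel.PRO_RECOVERY)
    )
    by_owner: dict[str, list[str]] = {u: [] for u in users}
    for row in corpus.photos.itertuples():
        if row.owner_id in by_owner:
            by_owner[row.owner_id].extend(row.tags)
    return [by_owner[u] for u in users], users


def tag_similarity_graph(
    vectors: TfidfVectors,
    labels: dict[str, ClassLabel],
    mode: str = "fixed",
    threshold: float = 0.99,
    target_edges: int | None = None,
    target_tolerance: float = 0.05,
) -> nx.Graph:
    """Undirected user graph linking users with near-identical tag profiles.

    An edge joins users whose user-level TF-IDF cosine similarity reaches
    the threshold.  ``mode="fixed"`` uses ``threshold`` directly;
    ``mode="calibrated"`` picks the threshold whose edge count comes within
    ``target_tolerance`` of ``target_edges`` (to match the sparsity of the
    other interaction networks), raising :class:`CalibrationError` when the
    similarity distribution cannot reach it.
    """
    if mode not in ("fixed", "calibrated"):
        raise ValueError(f"unknown mode: {mode}")
    U = vectors.unit_matrix().tocsr()
    sims = (U @ U.T).toarray()
    n = sims.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = sims[iu]

    if mode == "calibrated":
        if target_edges is None:
            raise ValueError("calibrated mode needs target_edges")
        if target_edges <= 0:
            thr = 1.0 + 1e-9
        else:
            order = np.sort(vals)[::-1]
            if target_edges > len(order):
                raise CalibrationError("fewer possible edges than the target")
            thr = order[target_edges - 1]
            achieved = int((vals >= thr).sum())
            if abs(achieved - target_edges) > target_tolerance * target_edges:
                raise CalibrationError(
                    f"ties prevent calibration: {achieved} edges at best vs target {target_edges}"
                )
    else:
        thr = threshold

    g = nx.Graph(kind="tags", threshold=float(thr), mode=mode)
    for uid in vectors.doc_ids:
        lab = labels.get(uid)
        g.add_node(uid, community=lab.value if lab is not None else "unlabeled")
    src, dst = np.nonzero(np.triu(sims >= thr, k=1))
    for i, j in zip(src, dst):
        g.add_edge(vectors.doc_ids[i], vectors.doc_ids[j], weight=1.0)
    return g
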