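"""Cohort construction: seed-user rules and rater-label aggregation.

Candidate community members are found by four seed rules (term search in
tags/title/description, uploads to eating-disorder groups, commenting on
qualifying photos, and favoriting photos with a specific tag combination).
Likert-scale ratings by independent raters are averaged into class labels,
with a chance-corrected multi-rater agreement coefficient (mean pairwise
Cohen's kappa by default, Fleiss' kappa optionally) and a permutation
p-value.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from edtribes.corpus import Corpus
from edtribes.labels import ClassLabel

__all__ = [
    "SeedRuleConfig",
    "find_seed_users",
    "aggregate_rater_labels",
    "rater_agreement",
    "cohen_kappa",
    "AgreementUndefinedError",
    "labels_from_truth",
    "community_users",
]

_TOKEN_RE = re.compile(r"[\w-]+", re.UNICODE)


class AgreementUndefinedError(ValueError):
    """Raised when every rater assigned a single identical category."""


@dataclass
class SeedRuleConfig:
    """Thresholds and term lists for the four seed rules."""

    search_terms: list[str] = field(
        default_factory=lambda: ["thinspo", "thinspiration", "pro-ana"]
    )
    group_ids: list[str] = field(
        default_factory=lambda: [
            "eating-disorders-art",
            "anorexia-nervosa",
            "anorexia-help",
            "ed-healing",
        ]
    )
    min_photos: int = 2
    min_comments: int = 2
    favorite_required_tags: frozenset = frozenset({"thinspo", "skinny"})
    favorite_any_of: frozenset = frozenset({"pretty", "cute", "beautiful"})
    min_favorites: int = 2

    def __post_init__(self) -> None:
        if min(self.min_photos, self.min_comments, self.min_favorites) < 1:
            raise ValueError("seed-rule thresholds must be >= 1")


def _tokens(text: str) -> set[str]:
    """Punctuation-aware whole tokens; hyphenated terms stay one token."""
    return set(_TOKEN_RE.findall(text.lower()))


def _photo_matches_terms(row, terms: set[str]) -> bool:
    if terms & set(row.tags):
        return True
    return bool(terms & _tokens(f"{row.title} {row.description}"))


def find_seed_users(corpus: Corpus, config: SeedRuleConfig | None = None) -> dict[str, set[str]]:
    """Map each candidate user to the set of seed rules they matched.

    Rules (all honour the per-user ``active`` attribute):

    * ``search`` — uploaded at least ``min_photos`` photos where a search
      term occurs in the tags, title or description (whole-token match, so
      ``pro-ana`` matches the hyphenated token but not substrings).
    * ``group`` — uploaded at least ``min_photos`` photos to a listed group.
    * ``commenter`` — commented on at least ``min_comments`` distinct
      qualifying photos (term-matched or group-posted).
    * ``favoriter`` — favorited at least ``min_favorites`` photos tagged
      with every required tag plus at least one of the any-of set.
    """
    config = config or SeedRuleConfig()
    result: dict[str, set[str]] = {}
    if not len(corpus.photos):
        return result
    active = set(corpus.users.loc[corpus.users["active"].astype(bool), "user_id"])
    terms = {t.lower() for t in config.search_terms}
    groups = set(config.group_ids)

    term_matched: set[str] = set()
    group_matched: set[str] = set()
    search_counts: dict[str, int] = {}
    group_counts: dict[str, int] = {}
    fav_qualifying: set[str] = set()
    req, any_of = set(config.favorite_required_tags), set(config.favorite_any_of)

    for row in corpus.photos.itertuples():
        tags = set(row.tags)
        if _photo_matches_terms(row, terms):
            term_matched.add(row.photo_id)
            search_counts[row.owner_id] = search_counts.get(row.owner_id, 0) + 1
        if groups & set(row.group_ids):
            group_matched.add(row.photo_id)
            group_counts[row.owner_id] = group_counts.get(row.owner_id, 0) + 1
        if req <= tags and (any_of & tags):
            fav_qualifying.add(row.photo_id)

    def add(user: str, rule: str) -> None:
        if user in active:
            result.setdefault(user, set()).add(rule)

    for user, n in search_counts.items():
        if n >= config.min_photos:
            add(user, "search")
    for user, n in group_counts.items():
        if n >= config.min_photos:
            add(user, "group")

    qualifying = term_matched | group_matched
    if len(corpus.comments):
        on_qual = corpus.comments[corpus.comments["photo_id"].isin(qualifying)]
        per_user = on_qual.groupby("commenter_id")["photo_id"].nunique()
        for user, n in per_user.items():
            if n >= config.min_comments:
                add(user, "commenter")

    if len(corpus.favorites):
        favs = corpus.favorites[corpus.favorites["photo_id"].isin(fav_qualifying)]
        per_user = favs.groupby("user_id")["photo_id"].nunique()
        for user, n in per_user.items():
            if n >= config.min_favorites:
                add(user, "favoriter")

    return result


def aggregate_rater_labels(
    scores: pd.DataFrame, pa_threshold: float = 3.5, pr_threshold: float = 2.5
) -> dict[str, ClassLabel]:
    """Average each user's Likert scores (1..5) into a class label.

    Mean score ``>= pa_threshold`` → pro-ana, ``<= pr_threshold`` →
    pro-recovery, otherwise neutral.  Missing scores are ignored in the
    mean; a user with no scores at all is unlabeled.
    """
    if pr_threshold >= pa_threshold:
        raise ValueError("pr_threshold must be below pa_threshold")
    labels: dict[str, ClassLabel] = {}
    means = scores.mean(axis=1, skipna=True)
    for user, mean in means.items():
        if pd.isna(mean):
            labels[user] = ClassLabel.UNLABELED
        elif mean >= pa_threshold:
            labels[user] = ClassLabel.PRO_ANA
        elif mean <= pr_threshold:
            labels[user] = ClassLabel.PRO_RECOVERY
        else:
            labels[user] = ClassLabel.NEUTRAL
    return labels


def _discretize(scores: pd.DataFrame, pa_t: float, pr_t: float) -> pd.DataFrame:
    cat = pd.DataFrame(index=scores.index, columns=scores.columns, dtype=object)
    cat[scores >= pa_t] = "pa"
    cat[scores <= pr_t] = "pr"
    cat[(scores < pa_t) & (scores > pr_t)] = "neutral"
    return cat


def cohen_kappa(a: np.ndarray, b: np.ndarray) -> float | None:
    """Cohen's kappa from the contingency table; None when chance agreement is 1."""
    mask = pd.notna(a) & pd.notna(b)
    a, b = a[mask], b[mask]
    if len(a) == 0:
        return None
    cats = sorted(set(a) | set(b))
    n = len(a)
    po = float(np.mean(a == b))
    pe = sum(np.mean(a == c) * np.mean(b == c) for c in cats)
    if pe >= 1.0 - 1e-15:
        return None
    return (po - pe) / (1.0 - pe)


def _mean_pairwise_cohen(cat: pd.DataFrame) -> float:
    vals = []
    for c1, c2 in itertools.combinations(cat.columns, 2):
        k = cohen_kappa(cat[c1].to_numpy(), cat[c2].to_numpy())
        if k is not None:
            vals.append(k)
    if not vals:
        raise AgreementUndefinedError(
            "agreement undefined: a single identical category across all raters"
        )
    return float(np.mean(vals))


def _fleiss_kappa(cat: pd.DataFrame) -> float:
    cats = sorted({v for v in cat.to_numpy().ravel() if pd.notna(v)})
    counts = np.stack([(cat == c).sum(axis=1).to_numpy() for c in cats], axis=1)
    n_ij = counts.sum(axis=1)
    keep = n_ij >= 2
    counts, n_ij = counts[keep], n_ij[keep]
    if not len(counts):
        raise AgreementUndefinedError("agreement undefined: fewer than 2 ratings per item")
    p_i = (counts * (counts - 1)).sum(axis=1) / (n_ij * (n_ij - 1))
    p_bar = p_i.mean()
    pj = counts.sum(axis=0) / counts.sum()
    pe = float((pj**2).sum())
    if pe >= 1.0 - 1e-15:
        raise AgreementUndefinedError(
            "agreement undefined: a single identical category across all raters"
        )
    return float((p_bar - pe) / (1 - pe))


def rater_agreement(
    scores: pd.DataFrame,
    method: str = "cohen",
    pa_threshold: float = 3.5,
    pr_threshold: float = 2.5,
    n_permutations: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Chance-corrected multi-rater agreement with a permutation p-value.

    Scores are discretised per rater by the class thresholds, then agreement
    is the mean pairwise Cohen's kappa over rater pairs (``method="cohen"``,
    the default reading for multiple independent raters) or Fleiss' kappa
    (``method="fleiss"``).  The p-value is the fraction of column-wise
    permutations achieving at least the observed coefficient.
    """
    if scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need at least 2 raters and 2 items")
    if method not in ("cohen", "fleiss"):
        raise ValueError(f"unknown agreement method: {method}")
    stat = _mean_pairwise_cohen if method == "cohen" else _fleiss_kappa
    cat = _discretize(scores, pa_threshold, pr_threshold)
    observed = stat(cat)

    rng = np.random.default_rng(seed)
    hits = 0
    used = 0
    for _ in range(n_permutations):
        perm = cat.apply(lambda col: col.sample(frac=1.0, random_state=rng.integers(2**31)).to_numpy())
        try:
            k = stat(perm)
        except AgreementUndefinedError:  # pragma: no cover - degenerate shuffle
            continue
        used += 1
        if k >= observed - 1e-12:
            hits += 1
    pvalue = (hits + 1) / (used + 1) if used else float("nan")
    return observed, float(pvalue)


# ---------------------------------------------------------------------------
# conveniences


def labels_from_truth(truth) -> dict[str, ClassLabel]:
    """Ground-truth labels of a synthetic corpus as a label mapping."""
    return {u: ClassLabel(c) for u, c in truth.latent_class.items()}


def community_users(labels: dict[str, ClassLabel]) -> dict[ClassLabel, list[str]]:
    """Users per community class, sorted for determinism."""
    out: dict[ClassLabel, list[str]] = {
        ClassLabel.PRO_ANA: [],
        ClassLabel.PRO_RECOVERY: [],
    }
    for user, lab in labels.items():
        if lab in out:
            out[lab].append(user)
    for lab in out:
        out[lab].sort()
    return out
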