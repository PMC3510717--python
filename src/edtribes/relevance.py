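"""Relevant-tag selection and tag/volume statistics.

A tag is "highly relevant" when it appears solely in content owned by the
two eating-disorder communities, or is at least ``ratio_threshold`` (default
10) times more likely there than in neutral users' content.  Photos carrying
at least one such tag are flagged relevant; those flags drive the cessation
and hazard analyses downstream.  The module also ranks class-indicative tags
by user-prevalence probability ratios, computes tag-family usage fractions,
monthly posting-volume series with their rank correlation, and shares of
self-portrait-tagged photos.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from edtribes.corpus import Corpus, normalize_tag
from edtribes.labels import ClassLabel

__all__ = [
    "RelevantTagSet",
    "VolumeSummary",
    "SelfPortraitShares",
    "select_relevant_tags",
    "flag_relevant_photos",
    "indicative_tags",
    "tag_usage_stats",
    "tag_rank_correlation",
    "monthly_volume",
    "self_portrait_stats",
    "SELF_TAG_DEFAULT",
]

SELF_TAG_DEFAULT = frozenset({"self", "self-portrait", "me"})

_COMMUNITY = (ClassLabel.PRO_ANA, ClassLabel.PRO_RECOVERY)


@dataclass
class RelevantTagSet:
    """Tags selected by the solely-in or likelihood-ratio rule."""

    tags: set
    ratio_threshold: float
    min_support: int
    no_neutral_baseline: bool = False  # only the solely-in rule could apply

    def __contains__(self, tag: str) -> bool:
        return tag in self.tags


def _owner_class(corpus: Corpus, labels: dict[str, ClassLabel]) -> pd.Series:
    return corpus.photos["owner_id"].map(lambda u: labels.get(u, ClassLabel.UNLABELED))


def select_relevant_tags(
    corpus: Corpus,
    labels: dict[str, ClassLabel],
    ratio_threshold: float = 10.0,
    min_support: int = 3,
) -> RelevantTagSet:
    """Select tags that mark eating-disorder content.

    ED content is every photo owned by a pro-ana or pro-recovery user; the
    neutral baseline is photos owned by neutral-labeled users.  A tag ``t``
    is selected iff its total occurrences reach ``min_support`` and either
    it never occurs in neutral content (the solely-in rule, which also
    handles the divide-by-zero case) or its photo-level occurrence rate in
    ED content is at least ``ratio_threshold`` times its rate in neutral
    content (inclusive boundary).
    """
    owner_class = _owner_class(corpus, labels)
    is_ed = owner_class.isin(_COMMUNITY).to_numpy()
    is_neutral = (owner_class == ClassLabel.NEUTRAL).to_numpy()
    n_ed = int(is_ed.sum())
    n_neutral = int(is_neutral.sum())

    ed_counts: dict[str, int] = {}
    neutral_counts: dict[str, int] = {}
    total_counts: dict[str, int] = {}
    for tags, ed, neu in zip(corpus.photos["tags"], is_ed, is_neutral):
        for t in set(tags):
            total_counts[t] = total_counts.get(t, 0) + 1
            if ed:
                ed_counts[t] = ed_counts.get(t, 0) + 1
            elif neu:
                neutral_counts[t] = neutral_counts.get(t, 0) + 1

    selected: set[str] = set()
    for tag, c_ed in ed_counts.items():
        if total_counts[tag] < min_support:
            continue
        c_neu = neutral_counts.get(tag, 0)
        if c_neu == 0:
            selected.add(tag)
        elif n_neutral and n_ed:
            ratio = (c_ed / n_ed) / (c_neu / n_neutral)
            if ratio >= ratio_threshold:
                selected.add(tag)
    return RelevantTagSet(
        tags=selected,
        ratio_threshold=ratio_threshold,
        min_support=min_support,
        no_neutral_baseline=(n_neutral == 0),
    )


def flag_relevant_photos(corpus: Corpus, tag_set: RelevantTagSet) -> pd.Series:
    """Flag each photo relevant iff it carries at least one selected tag.

    Returns a boolean Series indexed by ``photo_id`` and also stores the
    flag on the photos table (``is_relevant``).
    """
    sel = tag_set.tags
    flags = corpus.photos["tags"].map(lambda ts: not sel.isdisjoint(ts))
    flags.index = corpus.photos["photo_id"]
    corpus.photos["is_relevant"] = flags.to_numpy()
    return flags


def _user_tag_prevalence(corpus: Corpus, users: list[str]) -> dict[str, int]:
    """Number of the given users using each tag at least once."""
    users_set = set(users)
    seen: dict[str, set] = {}
    sub = corpus.photos[corpus.photos["owner_id"].isin(users_set)]
    for owner, tags in zip(sub["owner_id"], sub["tags"]):
        for t in set(tags):
            seen.setdefault(t, set()).add(owner)
    return {t: len(s) for t, s in seen.items()}


def indicative_tags(
    corpus: Corpus,
    labels: dict[str, ClassLabel],
    top_k: int = 20,
    smoothing: float = 1.0,
) -> tuple[list[str], list[str]]:
    """Rank tags by the ratio of class-usage probabilities.

    ``P(tag | class)`` is user-level prevalence — the fraction of the
    class's users using the tag at least once — with additive smoothing on
    the user counts.  Returns the ``top_k`` tags most indicative of pro-ana
    (highest PA/PR ratio) and of pro-recovery (highest PR/PA ratio).  Ties
    break by higher raw probability, then lexicographically.
    """
    pa_users = [u for u, l in labels.items() if l is ClassLabel.PRO_ANA]
    pr_users = [u for u, l in labels.items() if l is ClassLabel.PRO_RECOVERY]
    if not pa_users or not pr_users:
        raise ValueError("both communities need at least one labeled user")
    pa_prev = _user_tag_prevalence(corpus, pa_users)
    pr_prev = _user_tag_prevalence(corpus, pr_users)
    vocab = set(pa_prev) | set(pr_prev)

    def ranked(num_prev, num_n, den_prev, den_n):
        rows = []
        for t in vocab:
            p_num = (num_prev.get(t, 0) + smoothing) / (num_n + 2 * smoothing)
            p_den = (den_prev.get(t, 0) + smoothing) / (den_n + 2 * smoothing)
            raw = num_prev.get(t, 0) / num_n
            rows.append((p_num / p_den, raw, t))
        rows.sort(key=lambda r: (-r[0], -r[1], r[2]))
        return [t for _, _, t in rows[:top_k]]

    return (
        ranked(pa_prev, len(pa_users), pr_prev, len(pr_users)),
        ranked(pr_prev, len(pr_users), pa_prev, len(pa_users)),
    )


def tag_usage_stats(
    corpus: Corpus, labels: dict[str, ClassLabel], family
) -> dict[ClassLabel, float]:
    """Fraction of each class's users using any tag in the family.

    ``family`` is an explicit list of tag variants (e.g. thinspiration /
    thinspo); no stemming is attempted.
    """
    family = {normalize_tag(t) for t in family}
    out: dict[ClassLabel, float] = {}
    for cls in (ClassLabel.PRO_ANA, ClassLabel.PRO_RECOVERY, ClassLabel.NEUTRAL):
        members = [u for u, l in labels.items() if l is cls]
        if not members:
            out[cls] = float("nan")
            continue
        users_using: set[str] = set()
        sub = corpus.photos[corpus.photos["owner_id"].isin(set(members))]
        for owner, tags in zip(sub["owner_id"], sub["tags"]):
            if family & set(tags):
                users_using.add(owner)
        out[cls] = len(users_using) / len(members)
    return out


def tag_rank_correlation(
    corpus: Corpus, labels: dict[str, ClassLabel]
) -> tuple[float, float, int]:
    """Spearman correlation of tag frequencies across the two communities.

    Frequencies are photo-level occurrence counts; the correlation is over
    the shared vocabulary (tags used at least once by each community).
    Returns ``(rho, pvalue, n_shared_tags)``.
    """
    owner_class = _owner_class(corpus, labels)
    counts = {c: {} for c in _COMMUNITY}
    for tags, cls in zip(corpus.photos["tags"], owner_class):
        if cls in counts:
            for t in set(tags):
                counts[cls][t] = counts[cls].get(t, 0) + 1
    shared = sorted(set(counts[ClassLabel.PRO_ANA]) & set(counts[ClassLabel.PRO_RECOVERY]))
    if len(shared) < 2:
        return float("nan"), float("nan"), len(shared)
    pa = [counts[ClassLabel.PRO_ANA][t] for t in shared]
    pr = [counts[ClassLabel.PRO_RECOVERY][t] for t in shared]
    rho, p = stats.spearmanr(pa, pr)
    return float(rho), float(p), len(shared)


@dataclass
class VolumeSummary:
    """Monthly relevant-photo counts per class plus summary statistics."""

    series: pd.DataFrame  # index: contiguous monthly PeriodIndex; cols pa_count, pr_count
    spearman_rho: float | None
    spearman_p: float | None
    median_photos_pa: float | None
    median_photos_pr: float | None
    ranksum_p: float | None
    warnings: list = field(default_factory=list)


def monthly_volume(
    corpus: Corpus, labels: dict[str, ClassLabel], flags: pd.Series
) -> VolumeSummary:
    """Monthly relevant-photo series per class, their rank correlation, and
    per-class medians of total photos per user with a rank-sum p-value.

    Binning is by UTC calendar month; the Spearman correlation uses months
    where either class posted at least one relevant photo.  Medians are over
    all labeled users of each class (all their photos, relevant or not).
    """
    warnings: list[str] = []
    photos = corpus.photos
    owner_class = _owner_class(corpus, labels)
    is_rel = photos["photo_id"].map(flags).fillna(False).astype(bool)

    months = photos["posted_at"].dt.tz_convert("UTC").dt.tz_localize(None).dt.to_period("M")
    if len(photos):
        span = pd.period_range(months.min(), months.max(), freq="M")
    else:
        span = pd.PeriodIndex([], freq="M")
    series = pd.DataFrame(0, index=span, columns=["pa_count", "pr_count"])
    for cls, col in ((ClassLabel.PRO_ANA, "pa_count"), (ClassLabel.PRO_RECOVERY, "pr_count")):
        sel = months[is_rel.to_numpy() & (owner_class == cls).to_numpy()]
        vc = sel.value_counts()
        series.loc[vc.index, col] = vc.to_numpy()

    active = series[(series["pa_count"] > 0) | (series["pr_count"] > 0)]
    if len(active) >= 2 and len(span) >= 2:
        rho, p = stats.spearmanr(active["pa_count"], active["pr_count"])
        rho, p = float(rho), float(p)
    else:
        rho = p = None
        warnings.append("volume span below 2 months: correlation undefined")

    def _counts(cls):
        members = [u for u, l in labels.items() if l is cls]
        if not members:
            return None
        per_user = photos.groupby("owner_id").size()
        return np.array([per_user.get(u, 0) for u in sorted(members)])

    pa_counts, pr_counts = _counts(ClassLabel.PRO_ANA), _counts(ClassLabel.PRO_RECOVERY)
    med_pa = float(np.median(pa_counts)) if pa_counts is not None else None
    med_pr = float(np.median(pr_counts)) if pr_counts is not None else None
    if pa_counts is not None and pr_counts is not None and len(pa_counts) and len(pr_counts):
        ranksum_p = float(stats.mannwhitneyu(pa_counts, pr_counts, alternative="two-sided").pvalue)
    else:
        ranksum_p = None
        warnings.append("a class has no labeled users: rank-sum undefined")

    return VolumeSummary(series, rho, p, med_pa, med_pr, ranksum_p, warnings)


@dataclass
class SelfPortraitShares:
    """Class shares of self-tagged photos, overall and among relevant photos."""

    pa_share_self: float | None
    pa_share_all: float | None
    pa_share_self_relevant: float | None
    pa_share_relevant: float | None
    pr_share_self: float | None
    pr_share_all: float | None
    pr_share_self_relevant: float | None
    pr_share_relevant: float | None
    warnings: list = field(default_factory=list)


def self_portrait_stats(
    corpus: Corpus,
    labels: dict[str, ClassLabel],
    flags: pd.Series,
    self_tags=SELF_TAG_DEFAULT,
) -> SelfPortraitShares:
    """Share of self-portrait-tagged photos attributable to each community.

    Shares are computed among labeled-community photos: e.g.
    ``pa_share_self`` is the pro-ana fraction of community photos carrying a
    self tag, to be read against ``pa_share_all``, the pro-ana fraction of
    all community photos.  Zero denominators yield None with a warning.
    """
    self_tags = {normalize_tag(t) for t in self_tags}
    owner_class = _owner_class(corpus, labels)
    comm = owner_class.isin(_COMMUNITY).to_numpy()
    is_pa = (owner_class == ClassLabel.PRO_ANA).to_numpy() & comm
    has_self = corpus.photos["tags"].map(lambda ts: bool(self_tags & set(ts))).to_numpy()
    is_rel = corpus.photos["photo_id"].map(flags).fillna(False).astype(bool).to_numpy()
    warnings: list[str] = []

    def share(mask):
        denom = int((mask & comm).sum())
        if denom == 0:
            return None
        return float((mask & is_pa).sum() / denom)

    all_photos = np.ones(len(corpus.photos), dtype=bool)
    pa_self = share(has_self)
    pa_all = share(all_photos)
    pa_self_rel = share(has_self & is_rel)
    pa_rel = share(is_rel)
    for name, v in (
        ("self-tagged", pa_self),
        ("all", pa_all),
        ("self-tagged relevant", pa_self_rel),
        ("relevant", pa_rel),
    ):
        if v is None:
            warnings.append(f"no {name} community photos: share undefined")

    def inv(v):
        return None if v is None else 1.0 - v

    return SelfPortraitShares(
        pa_self, pa_all, pa_self_rel, pa_rel,
        inv(pa_self), inv(pa_all), inv(pa_self_rel), inv(pa_rel),
        warnings,
    )
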