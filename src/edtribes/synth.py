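"""Synthetic two-community corpus generator with known ground truth.

The generator emulates the structure of a photo-sharing site hosting two
antagonistic communities (pro-ana and pro-recovery) plus a neutral background
population:

* class-specific tag distributions over a vocabulary partitioned into
  pro-ana signature, pro-recovery signature, shared eating-disorder and
  background tags, with deliberate cross-class tag leakage (pro-recovery
  users adopting pro-ana signature tags for visibility);
* homophilous contact, comment and favorite generation where the planted
  per-class parameter *is* the source-side in-class interaction fraction the
  analysis later measures;
* posting timestamps on a 10-day grid with a monthly multiplicative growth
  trend and heavy-tailed (lognormal) per-user volumes;
* a relevant-posting process whose per-interval event probability is
  ``1 - exp(-h0 * exp(beta . (x - ref)))`` with ``x`` the log1p-transformed
  hazard covariates of the user's own history, so proportional-hazards
  parameter recovery is well-posed;
* posting cessation arising from that process, recorded in the ground truth.

Every downstream stage can therefore be checked against planted parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from edtribes.corpus import Corpus, validate_corpus, _empty_frame  # noqa: F401
from edtribes.corpus import COMMENT_COLUMNS, CONTACT_COLUMNS, FAVORITE_COLUMNS, PHOTO_COLUMNS, USER_COLUMNS

__all__ = [
    "TagModel",
    "GeneratorParams",
    "GroundTruth",
    "generate_corpus",
    "generate_rater_matrix",
    "simulate_hazard_panel",
    "sign_pattern_preset",
    "PA_SIGNATURE",
    "PR_SIGNATURE",
    "SHARED_ED",
    "BACKGROUND_TAGS",
    "SELF_TAGS",
    "HAZARD_COVARIATES",
]

PA_SIGNATURE = [
    "thinspo", "thinspiration", "pro-ana", "ana", "skinny",
    "thin", "bones", "hipbones", "collarbones", "fasting",
]
PR_SIGNATURE = [
    "recovery", "ed-recovery", "prorecovery", "healing", "hope",
    "strength", "anti-ana", "ed-awareness", "nourish", "health",
]
SHARED_ED = ["anorexia", "eating-disorder", "ed", "bulimia", "body-image"]
SELF_TAGS = ["self", "self-portrait", "me"]
BACKGROUND_TAGS = [
    "cat", "dog", "sunset", "beach", "sky", "flower", "tree", "city", "music",
    "art", "friends", "food", "coffee", "rain", "snow", "summer", "winter",
    "autumn", "spring", "night", "light", "portrait", "nature", "travel",
    "street", "architecture", "bird", "garden", "home", "car", "vintage",
    "film", "nikon", "canon", "bw", "macro", "landscape", "water", "sea",
    "mountain", "clouds", "moon", "stars", "family", "party", "school",
    "book", "drawing", "paint", "dance", "smile", "hair", "dress", "shoes",
    "mirror", "window", "door", "wall", "graffiti", "pretty",
]
ED_GROUPS = ["eating-disorders-art", "anorexia-nervosa", "anorexia-help", "ed-healing"]

#: Covariate order used by every hazard-related routine in the package.
HAZARD_COVARIATES = [
    "relevant_photos",
    "views",
    "views_relevant",
    "comments_same",
    "comments_other",
    "frac_comments_same",
]

_COMMUNITIES = ("pa", "pr")
_CLASS_NAMES = {"pa": "pro_ana", "pr": "pro_recovery", "neutral": "neutral"}


@dataclass
class TagModel:
    """Per-class tag distributions with cross-class leakage.

    Relevant photos draw signature tags from the owner's class pool
    (signature + shared ED vocabulary); with probability ``leak_pr_uses_pa``
    a pro-recovery relevant photo additionally carries pro-ana signature tags
    (and vice versa with ``leak_pa_uses_pr``).  Background tags follow a
    Zipf-weighted categorical so tag frequencies are realistically skewed.
    """

    pa_signature: list[str] = field(default_factory=lambda: list(PA_SIGNATURE))
    pr_signature: list[str] = field(default_factory=lambda: list(PR_SIGNATURE))
    shared_ed: list[str] = field(default_factory=lambda: list(SHARED_ED))
    background: list[str] = field(default_factory=lambda: list(BACKGROUND_TAGS))
    leak_pa_uses_pr: float = 0.05
    leak_pr_uses_pa: float = 0.30
    signature_tags_per_photo: float = 1.5
    background_tags_per_photo: float = 2.0
    zipf_exponent: float = 0.8
    self_tag_rate_relevant: dict = field(default_factory=lambda: {"pa": 0.30, "pr": 0.30})
    self_tag_rate_other: dict = field(
        default_factory=lambda: {"pa": 0.10, "pr": 0.20, "neutral": 0.12}
    )
    group_post_rate: float = 0.15


@dataclass
class GeneratorParams:
    """All knobs of the synthetic corpus, reproducible given a seed.

    Homophily parameters are the *source-side* in-class fractions: e.g.
    ``contact_homophily["pr"] = 0.72`` means 72% of contacts made by
    pro-recovery users point at pro-recovery users.  Defaults echo the
    qualitative pattern of the communities this package studies (pro-ana
    favorite homophily far above pro-recovery's; pro-recovery users roughly
    twice as prolific) at roughly one fifth of the original volumes; they are
    illustrative study conditions, not measured ground truth.
    """

    n_pa: int = 150
    n_pr: int = 150
    n_neutral: int = 200
    time_span: tuple[str, str] = ("2009-01-01", "2012-02-01")
    growth_rate: float = 1.03
    photos_per_user_median: dict = field(
        default_factory=lambda: {"pa": 21.0, "pr": 39.0, "neutral": 15.0}
    )
    photos_per_user_sigma: float = 0.8
    relevant_fraction: dict = field(
        default_factory=lambda: {"pa": 0.20, "pr": 0.20, "neutral": 0.0}
    )
    contact_homophily: dict = field(default_factory=lambda: {"pa": 0.59, "pr": 0.72})
    comment_homophily: dict = field(default_factory=lambda: {"pa": 0.74, "pr": 0.83})
    favorite_homophily: dict = field(default_factory=lambda: {"pa": 0.89, "pr": 0.56})
    comments_per_photo: float = 1.5
    views_per_photo_mean: float = 30.0
    views_dispersion: float = 1.2
    user_view_sigma: float = 0.7
    contacts_per_user: float = 8.0
    favorites_per_user: float = 4.0
    hazard_betas: dict = field(
        default_factory=lambda: {"pa": [0.0] * 6, "pr": [0.0] * 6}
    )
    relevant_stop_prob: float = 0.5
    hazard_feature_set: str = "recent"
    hazard_ref: list | None = None
    max_interval_hazard: float = 0.7
    resolution_days: int = 10
    window_days: int = 30
    cessation_gap_days: int = 90
    tag_model: TagModel = field(default_factory=TagModel)

    def __post_init__(self) -> None:
        for name in ("contact_homophily", "comment_homophily", "favorite_homophily"):
            for v in getattr(self, name).values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} must be in [0,1], got {v}")
        for v in self.relevant_fraction.values():
            if not 0.0 <= v < 1.0:
                raise ValueError(f"relevant_fraction must be in [0,1), got {v}")
        if min(self.n_pa, self.n_pr, self.n_neutral) < 0:
            raise ValueError("user counts must be >= 0")
        if self.n_pa + self.n_pr + self.n_neutral == 0 and self.comments_per_photo > 0:
            raise ValueError("cannot generate comments with zero users")
        if self.hazard_feature_set not in ("cumulative", "recent"):
            raise ValueError("hazard_feature_set must be 'cumulative' or 'recent'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["time_span"] = list(self.time_span)
        return d


@dataclass
class GroundTruth:
    """What the generator planted, for downstream acceptance checks."""

    latent_class: dict  # user_id -> "pro_ana" | "pro_recovery" | "neutral"
    relevant_photos: set  # photo_ids whose tags came from the ED vocabularies
    cessation: pd.DataFrame  # user_id, ceased, censored, last_relevant_date, gap_days
    hazard_betas: dict
    homophily: dict
    params: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "latent_class": self.latent_class,
            "relevant_photos": sorted(self.relevant_photos),
            "cessation": self.cessation.assign(
                last_relevant_date=self.cessation["last_relevant_date"].astype(str)
            ).to_dict(orient="records"),
            "hazard_betas": self.hazard_betas,
            "homophily": self.homophily,
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def sign_pattern_preset(n_per_class: int = 120, seed_span_intervals: int = 80) -> GeneratorParams:
    """Illustrative preset planting opposite short-term cross-class comment effects.

    Pro-ana users' relevant-posting hazard *rises* with recent other-class
    comments while pro-recovery users' hazard *falls*, mimicking the
    qualitative entrenchment pattern this package is designed to detect.
    The coefficient magnitudes are illustrative, not measured values.
    """
    start = pd.Timestamp("2009-01-01")
    end = start + pd.Timedelta(days=10 * seed_span_intervals)
    return GeneratorParams(
        n_pa=n_per_class,
        n_pr=n_per_class,
        n_neutral=60,
        time_span=(str(start.date()), str(end.date())),
        hazard_betas={
            "pa": [0.0, 0.0, 0.0, 0.0, 0.8, 0.0],
            "pr": [0.0, 0.0, 0.0, 0.0, -0.8, 0.0],
        },
        hazard_feature_set="recent",
        hazard_ref=[0.5, 3.5, 1.5, 0.8, 0.5, 0.4],
        relevant_fraction={"pa": 0.18, "pr": 0.18, "neutral": 0.0},
        comments_per_photo=2.0,
    )


# ---------------------------------------------------------------------------
# corpus generation


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def _interval_times(rng: np.random.Generator, starts: np.ndarray, res_days: int) -> np.ndarray:
    """Random second-resolution offsets within a 10-day interval."""
    return starts + rng.integers(0, res_days * 86400, size=len(starts))


def generate_corpus(params: GeneratorParams, seed: int) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus with planted two-community structure.

    The same ``(params, seed)`` pair always yields an identical corpus.
    Returns the validated :class:`~edtribes.corpus.Corpus` and the
    :class:`GroundTruth` describing what was planted.
    """
    rng = np.random.default_rng(seed)
    tm = params.tag_model
    res = params.resolution_days
    start = pd.Timestamp(params.time_span[0], tz="UTC")
    end = pd.Timestamp(params.time_span[1], tz="UTC")
    n_intervals = max(1, int((end - start).days // res))
    win = max(1, params.window_days // res)

    classes = np.array(
        ["pa"] * params.n_pa + ["pr"] * params.n_pr + ["neutral"] * params.n_neutral
    )
    n_users = len(classes)
    if n_users == 0:
        empty = Corpus(
            users=_empty_frame(USER_COLUMNS),
            photos=_empty_frame(PHOTO_COLUMNS),
            comments=_empty_frame(COMMENT_COLUMNS),
            contacts=_empty_frame(CONTACT_COLUMNS),
            favorites=_empty_frame(FAVORITE_COLUMNS),
            observation_end=end,
        )
        truth = GroundTruth({}, set(), _empty_cessation(), params.hazard_betas, {}, params.to_dict())
        return empty, truth
    user_ids = np.array([f"u{i:05d}" for i in range(n_users)])
    is_comm = np.isin(classes, _COMMUNITIES)

    # activity windows and volumes
    start_iv = rng.integers(0, max(1, int(0.6 * n_intervals)), size=n_users)
    medians = np.array([params.photos_per_user_median[c] for c in classes])
    n_target = rng.lognormal(np.log(np.maximum(medians, 0.1)), params.photos_per_user_sigma)
    growth = params.growth_rate ** (np.arange(n_intervals) * res / 30.44)
    # per-user per-interval non-relevant posting rate, normalised to hit n_target
    tail = growth[::-1].cumsum()[::-1]  # sum of growth from t to end
    lam0 = n_target / tail[np.minimum(start_iv, n_intervals - 1)]

    view_mult = rng.lognormal(-params.user_view_sigma**2 / 2, params.user_view_sigma, n_users)
    h0 = np.array([-np.log1p(-params.relevant_fraction.get(c, 0.0)) for c in classes])
    # a planted fraction of community users lose interest in posting relevant
    # content at a random interval, while their other posting continues; this
    # seeds genuine (uncensored) cessation events
    stops = np.full(n_users, np.iinfo(np.int64).max)
    stopper = (rng.random(n_users) < params.relevant_stop_prob) & is_comm
    if stopper.any():
        lo = start_iv[stopper] + 1
        stops[stopper] = lo + rng.integers(
            0, np.maximum(int(0.9 * n_intervals) - lo, 1)
        )
    betas = {c: np.asarray(params.hazard_betas[c], dtype=float) for c in _COMMUNITIES}
    ref = np.zeros(6) if params.hazard_ref is None else np.asarray(params.hazard_ref, float)

    # running covariate state
    cum = np.zeros((5, n_users))  # rel, views, views_rel, com_same, com_other
    ring = np.zeros((win, 5, n_users))  # per-interval increments of the last `win` intervals

    # per-photo records (column arrays)
    ph_owner: list[np.ndarray] = []
    ph_time: list[np.ndarray] = []
    ph_views: list[np.ndarray] = []
    ph_rel: list[np.ndarray] = []
    cm_photo: list[np.ndarray] = []
    cm_user: list[np.ndarray] = []
    cm_time: list[np.ndarray] = []
    photo_count = 0

    comment_shares = _comment_shares(classes, medians)
    nb_n = params.views_dispersion
    class_idx = {c: np.flatnonzero(classes == c) for c in ("pa", "pr", "neutral")}

    for t in range(n_intervals):
        active = start_iv <= t
        iv_start_s = int((start + pd.Timedelta(days=t * res)).timestamp())
        iv_end_s = iv_start_s + res * 86400
        inc = np.zeros((5, n_users))

        # hazard of a relevant-posting event from history covariates
        if params.hazard_feature_set == "cumulative":
            cov = cum
        else:
            cov = ring.sum(axis=0)
        x = np.log1p(cov)
        denom = cov[3] + cov[4]
        frac_same = np.where(denom > 0, cov[3] / np.maximum(denom, 1e-12), 0.0)
        x_full = np.vstack([x[0], x[1], x[2], x[3], x[4], np.log1p(frac_same)])
        hz = np.zeros(n_users)
        for c in _COMMUNITIES:
            idx = class_idx[c]
            if len(idx) == 0:
                continue
            lin = betas[c] @ (x_full[:, idx] - ref[:, None])
            hz[idx] = h0[idx] * np.exp(lin)
        hz = np.minimum(hz, params.max_interval_hazard)
        p_event = 1.0 - np.exp(-hz)
        rel_event = (rng.random(n_users) < p_event) & active & is_comm & (t < stops)

        # photos this interval
        lam = np.where(active, lam0 * growth[t], 0.0)
        n_nonrel = rng.poisson(lam)
        owners = np.concatenate(
            [np.repeat(np.arange(n_users), n_nonrel), np.flatnonzero(rel_event)]
        )
        relflag = np.concatenate(
            [np.zeros(int(n_nonrel.sum()), bool), np.ones(int(rel_event.sum()), bool)]
        )
        if len(owners):
            times = rng.integers(iv_start_s, iv_end_s, size=len(owners))
            views = rng.negative_binomial(
                nb_n, nb_n / (nb_n + params.views_per_photo_mean * view_mult[owners])
            )
            ph_owner.append(owners)
            ph_time.append(times)
            ph_views.append(views)
            ph_rel.append(relflag)
            np.add.at(inc[1], owners, views.astype(float))
            np.add.at(inc[2], owners[relflag], views[relflag].astype(float))
            np.add.at(inc[0], owners[relflag], 1.0)

            # comments, source-first so the planted homophily is the
            # source-side in-class fraction
            pool = {c: np.flatnonzero(np.isin(classes[owners], [c])) for c in ("pa", "pr")}
            for s in ("pa", "pr", "neutral"):
                s_users = class_idx[s]
                s_users = s_users[active[s_users]] if len(s_users) else s_users
                if len(s_users) == 0 or comment_shares[s] == 0:
                    continue
                m = rng.poisson(params.comments_per_photo * len(owners) * comment_shares[s])
                if m == 0:
                    continue
                if s == "neutral":
                    tgt = rng.integers(0, len(owners), size=m)
                else:
                    hsame = params.comment_homophily[s]
                    same = rng.random(m) < hsame
                    tgt = np.full(m, -1)
                    for cls, mask in ((s, same), ("pa" if s == "pr" else "pr", ~same)):
                        k = int(mask.sum())
                        if k and len(pool[cls]):
                            tgt[mask] = rng.choice(pool[cls], size=k)
                    keep = tgt >= 0
                    tgt = tgt[keep]
                    m = len(tgt)
                    if m == 0:
                        continue
                commenters = rng.choice(s_users, size=m)
                keep = commenters != owners[tgt]  # no self-comments
                tgt, commenters = tgt[keep], commenters[keep]
                if len(tgt) == 0:
                    continue
                pt = times[tgt]
                ct = pt + rng.integers(1, np.maximum(iv_end_s - pt, 2))
                cm_photo.append(photo_count + tgt)
                cm_user.append(commenters)
                cm_time.append(ct)
                own = owners[tgt]
                comm_is_comm = is_comm[commenters] & is_comm[own]
                same_cls = (classes[commenters] == classes[own]) & comm_is_comm
                other_cls = (classes[commenters] != classes[own]) & comm_is_comm
                np.add.at(inc[3], own[same_cls], 1.0)
                np.add.at(inc[4], own[other_cls], 1.0)
            photo_count += len(owners)

        cum += inc
        ring[t % win] = inc

    photos_df, truth_rel, pid_by_creation = _assemble_photos(
        rng, params, classes, user_ids, ph_owner, ph_time, ph_views, ph_rel
    )
    comments_df = _assemble_comments(cm_photo, cm_user, cm_time, pid_by_creation, user_ids)
    contacts_df = _make_contacts(rng, params, classes, user_ids, class_idx)
    favorites_df = _make_favorites(rng, params, classes, user_ids, photos_df, class_idx)

    join_dates = [(start + pd.Timedelta(days=int(s) * res)).date().isoformat() for s in start_iv]
    users_df = pd.DataFrame(
        {
            "user_id": user_ids,
            "join_date": join_dates,
            "seed_methods": [[] for _ in range(n_users)],
            "latent_class": [_CLASS_NAMES[c] for c in classes],
            "active": [True] * n_users,
        },
        columns=USER_COLUMNS,
    ).sort_values("user_id").reset_index(drop=True)

    corpus = Corpus(
        users=users_df,
        photos=photos_df,
        comments=comments_df,
        contacts=contacts_df,
        favorites=favorites_df,
        observation_end=end,
    )
    validate_corpus(corpus)

    cess = _ground_truth_cessation(photos_df, truth_rel, users_df, end, params.cessation_gap_days)
    truth = GroundTruth(
        latent_class={u: _CLASS_NAMES[c] for u, c in zip(user_ids, classes)},
        relevant_photos=truth_rel,
        cessation=cess,
        hazard_betas={k: list(map(float, v)) for k, v in params.hazard_betas.items()},
        homophily={
            "contact": dict(params.contact_homophily),
            "comment": dict(params.comment_homophily),
            "favorite": dict(params.favorite_homophily),
        },
        params=params.to_dict(),
    )
    return corpus, truth


def _comment_shares(classes: np.ndarray, medians: np.ndarray) -> dict:
    activity = {}
    total = 0.0
    for c in ("pa", "pr", "neutral"):
        mask = classes == c
        activity[c] = float(medians[mask].sum()) if mask.any() else 0.0
        total += activity[c]
    if total == 0:
        return {c: 0.0 for c in activity}
    return {c: v / total for c, v in activity.items()}


def _tags_for_photo(
    rng: np.random.Generator, tm: TagModel, cls: str, relevant: bool, bg_weights: np.ndarray
) -> list[str]:
    tags: list[str] = []
    if relevant:
        if cls == "pa":
            pool = tm.pa_signature + tm.shared_ed
            leak_pool, leak_p = tm.pr_signature, tm.leak_pa_uses_pr
        else:
            pool = tm.pr_signature + tm.shared_ed
            leak_pool, leak_p = tm.pa_signature, tm.leak_pr_uses_pa
        k = 1 + rng.poisson(tm.signature_tags_per_photo)
        tags.extend(rng.choice(pool, size=min(k, len(pool)), replace=False))
        if rng.random() < leak_p:
            tags.extend(rng.choice(leak_pool, size=min(2, len(leak_pool)), replace=False))
        n_bg = rng.poisson(1.0)
    else:
        n_bg = 1 + rng.poisson(tm.background_tags_per_photo)
    if n_bg:
        tags.extend(rng.choice(tm.background, size=min(n_bg, len(tm.background)), p=bg_weights, replace=False, shuffle=False))
    rate = (
        tm.self_tag_rate_relevant.get(cls, 0.0)
        if relevant
        else tm.self_tag_rate_other.get(cls, 0.0)
    )
    if rng.random() < rate:
        tags.append(SELF_TAGS[rng.integers(len(SELF_TAGS))])
    seen: dict[str, None] = {}
    for t in tags:
        seen.setdefault(str(t))
    return list(seen)


def _assemble_photos(rng, params, classes, user_ids, ph_owner, ph_time, ph_views, ph_rel):
    tm = params.tag_model
    if not ph_owner:
        return _empty_frame(PHOTO_COLUMNS), set(), np.empty(0, object)
    owners = np.concatenate(ph_owner)
    times = np.concatenate(ph_time)
    views = np.concatenate(ph_views)
    rel = np.concatenate(ph_rel)
    order = np.argsort(times, kind="stable")
    owners, times, views, rel = owners[order], times[order], views[order], rel[order]
    photo_ids = [f"p{i:06d}" for i in range(len(owners))]
    # map creation index (the order photos were appended during the interval
    # loop, which comment records reference) -> time-ordered photo_id
    pid_by_creation = np.empty(len(order), dtype=object)
    pid_by_creation[order] = np.array(photo_ids, dtype=object)
    bg_w = _zipf_weights(len(tm.background), tm.zipf_exponent)
    tags = [
        _tags_for_photo(rng, tm, classes[o], bool(r), bg_w) for o, r in zip(owners, rel)
    ]
    group_ids = [
        [ED_GROUPS[rng.integers(len(ED_GROUPS))]]
        if r and rng.random() < tm.group_post_rate
        else []
        for r in rel
    ]
    df = pd.DataFrame(
        {
            "photo_id": photo_ids,
            "owner_id": user_ids[owners],
            "posted_at": pd.to_datetime(times, unit="s", utc=True),
            "title": [f"photo {pid}" for pid in photo_ids],
            "description": ["" for _ in photo_ids],
            "tags": tags,
            "view_count": views.astype(int),
            "group_ids": group_ids,
            "is_relevant": [None] * len(photo_ids),
        },
        columns=PHOTO_COLUMNS,
    )
    truth_rel = {pid for pid, r in zip(photo_ids, rel) if r}
    return df, truth_rel, pid_by_creation


def _assemble_comments(cm_photo, cm_user, cm_time, pid_by_creation, user_ids):
    if not cm_photo:
        return _empty_frame(COMMENT_COLUMNS)
    photo_idx = np.concatenate(cm_photo)
    users = np.concatenate(cm_user)
    times = np.concatenate(cm_time)
    order = np.argsort(times, kind="stable")
    photo_idx, users, times = photo_idx[order], users[order], times[order]
    return pd.DataFrame(
        {
            "comment_id": [f"c{i:07d}" for i in range(len(users))],
            "photo_id": pid_by_creation[photo_idx],
            "commenter_id": user_ids[users],
            "commented_at": pd.to_datetime(times, unit="s", utc=True),
        },
        columns=COMMENT_COLUMNS,
    )


def _make_contacts(rng, params, classes, user_ids, class_idx):
    rows_from, rows_to = [], []
    n_users = len(classes)
    all_idx = np.arange(n_users)
    for u in range(n_users):
        k = rng.poisson(params.contacts_per_user)
        if k == 0:
            continue
        c = classes[u]
        if c in _COMMUNITIES:
            h = params.contact_homophily[c]
            other = "pa" if c == "pr" else "pr"
            in_pool = class_idx[c][class_idx[c] != u]
            out_pool = class_idx[other]
            k_in = rng.binomial(k, h)
            k_out = k - k_in
            # sample without replacement so deduplication cannot bias the
            # planted in-class fraction
            tgt = []
            if k_in and len(in_pool):
                tgt.append(rng.choice(in_pool, size=min(k_in, len(in_pool)), replace=False))
            if k_out and len(out_pool):
                tgt.append(rng.choice(out_pool, size=min(k_out, len(out_pool)), replace=False))
            tgt = np.concatenate(tgt) if tgt else np.empty(0, int)
        else:
            pool = all_idx[all_idx != u]
            if len(pool) == 0:
                continue
            tgt = rng.choice(pool, size=min(k, len(pool)), replace=False)
        rows_from.extend([u] * len(tgt))
        rows_to.extend(tgt.tolist())
    if not rows_from:
        return _empty_frame(CONTACT_COLUMNS)
    df = pd.DataFrame({"from_user": user_ids[rows_from], "to_user": user_ids[rows_to]})
    return df.drop_duplicates().reset_index(drop=True)


def _make_favorites(rng, params, classes, user_ids, photos_df, class_idx):
    if not len(photos_df):
        return _empty_frame(FAVORITE_COLUMNS)
    owner_class = photos_df["owner_id"].map(
        dict(zip(user_ids, classes))
    ).to_numpy()
    photo_ids = photos_df["photo_id"].to_numpy()
    owner_ids = photos_df["owner_id"].to_numpy()
    pools = {c: np.flatnonzero(owner_class == c) for c in ("pa", "pr", "neutral")}
    rows_p, rows_u = [], []
    for s in ("pa", "pr", "neutral"):
        users = class_idx[s]
        if len(users) == 0:
            continue
        total = rng.poisson(params.favorites_per_user * len(users))
        if total == 0:
            continue
        if s in _COMMUNITIES:
            h = params.favorite_homophily[s]
            other = "pa" if s == "pr" else "pr"
            same = rng.random(total) < h
            tgt = np.full(total, -1)
            for cls, mask in ((s, same), (other, ~same)):
                k = int(mask.sum())
                if k and len(pools[cls]):
                    tgt[mask] = rng.choice(pools[cls], size=k)
            tgt = tgt[tgt >= 0]
        else:
            tgt = rng.integers(0, len(photo_ids), size=total)
        if len(tgt) == 0:
            continue
        favers = user_ids[rng.choice(users, size=len(tgt))]
        keep = favers != owner_ids[tgt]  # no self-favorites
        rows_p.extend(photo_ids[tgt[keep]].tolist())
        rows_u.extend(favers[keep].tolist())
    if not rows_p:
        return _empty_frame(FAVORITE_COLUMNS)
    df = pd.DataFrame({"photo_id": rows_p, "user_id": rows_u})
    return df.drop_duplicates().reset_index(drop=True)


def _empty_cessation() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["user_id", "ceased", "censored", "last_relevant_date", "gap_days"]
    )


def _ground_truth_cessation(photos_df, truth_rel, users_df, obs_end, gap_days):
    """Apply the cessation rule to the emitted timeline with true relevance."""
    if not len(photos_df):
        return _empty_cessation()
    rel_mask = photos_df["photo_id"].isin(truth_rel)
    rows = []
    comm_users = users_df.loc[
        users_df["latent_class"].isin(["pro_ana", "pro_recovery"]), "user_id"
    ]
    by_owner = dict(tuple(photos_df.groupby("owner_id")))
    for uid in comm_users:
        ph = by_owner.get(uid)
        if ph is None:
            continue
        rel_times = ph.loc[ph["photo_id"].isin(truth_rel), "posted_at"]
        if rel_times.empty:
            continue
        last_rel = rel_times.max()
        after = ph.loc[~ph["photo_id"].isin(truth_rel), "posted_at"]
        has_other_after = bool((after > last_rel).any())
        tail_days = (obs_end - last_rel).days
        censored = tail_days < gap_days
        ceased = (not censored) and has_other_after
        rows.append(
            {
                "user_id": uid,
                "ceased": ceased,
                "censored": censored,
                "last_relevant_date": last_rel,
                "gap_days": int(tail_days),
            }
        )
    return pd.DataFrame(rows) if rows else _empty_cessation()


# ---------------------------------------------------------------------------
# rater matrix


def generate_rater_matrix(
    truth: GroundTruth, n_raters: int = 5, noise_rate: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Simulate independent Likert ratings (1..5) of each labeled user.

    Score 5 means strongly pro-ana, 1 strongly pro-recovery, 3 neutral.  With
    ``noise_rate=0`` every rater reports the class-consistent extreme; with
    ``noise_rate=1`` every score is uniform on 1..5.
    """
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError("noise_rate must be in [0,1]")
    if n_raters < 1:
        raise ValueError("need at least one rater")
    rng = np.random.default_rng(seed)
    true_score = {"pro_ana": 5, "pro_recovery": 1, "neutral": 3}
    users = sorted(u for u, c in truth.latent_class.items() if c in true_score)
    base = np.array([true_score[truth.latent_class[u]] for u in users])
    scores = np.tile(base[:, None], (1, n_raters))
    noisy = rng.random(scores.shape) < noise_rate
    scores[noisy] = rng.integers(1, 6, size=int(noisy.sum()))
    return pd.DataFrame(
        scores, index=pd.Index(users, name="user_id"),
        columns=[f"rater_{i + 1}" for i in range(n_raters)],
    )


# ---------------------------------------------------------------------------
# direct hazard-panel simulation


def simulate_hazard_panel(
    n_users: int,
    n_intervals: int,
    betas,
    seed: int,
    feature_set: str = "recent",
    baseline_hazard: float = 0.10,
    ref: list | None = None,
    window_intervals: int = 3,
    photo_rate: float = 1.2,
    views_per_photo: float = 30.0,
    comment_rate_same: float = 1.0,
    comment_rate_other: float = 0.6,
    user_sigma: float = 0.6,
) -> pd.DataFrame:
    """Simulate a counting-process panel directly, without a full corpus.

    Per user and 10-day interval: ordinary photos arrive Poisson with
    user-specific lognormal heterogeneity; views accrue per photo
    (lognormal-dispersed); same-/other-class comments arrive Poisson with
    independent user-level rates.  A relevant-posting event occurs with
    probability ``1 - exp(-h0 * exp(beta . (x - ref)))`` where ``x`` holds the
    log1p-transformed covariates of the user's history (strictly before the
    interval).  This makes proportional-hazards recovery of ``betas``
    well-posed on the log1p covariate scale.

    Returns a long DataFrame with one row per user-interval holding the six
    covariates of the requested feature set (raw counts, pre-transform), the
    event indicator, and ``interval`` / ``user_id`` keys.
    """
    if feature_set not in ("cumulative", "recent"):
        raise ValueError("feature_set must be 'cumulative' or 'recent'")
    rng = np.random.default_rng(seed)
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (6,):
        raise ValueError("betas must have six entries")
    if ref is None:
        ref = (
            np.array([0.5, 4.2, 1.8, 1.0, 0.7, 0.4])
            if feature_set == "recent"
            else np.array([1.5, 6.0, 3.5, 2.5, 2.0, 0.4])
        )
    ref = np.asarray(ref, dtype=float)

    act = rng.lognormal(-user_sigma**2 / 2, user_sigma, n_users)
    view_mult = rng.lognormal(-0.245, 0.7, n_users)
    com_mult = rng.lognormal(-user_sigma**2 / 2, user_sigma, n_users)

    cum = np.zeros((5, n_users))
    ring = np.zeros((window_intervals, 5, n_users))
    out = np.empty((n_users * n_intervals, 8))
    events_total = 0

    for t in range(n_intervals):
        cov = cum if feature_set == "cumulative" else ring.sum(axis=0)
        denom = cov[3] + cov[4]
        frac = np.where(denom > 0, cov[3] / np.maximum(denom, 1e-12), 0.0)
        x = np.vstack([np.log1p(cov), np.log1p(frac)[None, :]])
        lin = betas @ (x - ref[:, None])
        h = np.minimum(baseline_hazard * np.exp(lin), 0.8)
        event = rng.random(n_users) < (1.0 - np.exp(-h))
        events_total += int(event.sum())

        rows = slice(t * n_users, (t + 1) * n_users)
        out[rows, 0] = t
        out[rows, 1:7] = np.vstack([cov, frac[None, :]]).T
        out[rows, 7] = event

        inc = np.zeros((5, n_users))
        n_photos = rng.poisson(act * photo_rate) + event
        # per-photo lognormal view dispersion keeps view covariates
        # identifiable next to the photo-count covariates
        photo_noise = rng.lognormal(-0.5, 1.0, n_users)
        views = rng.poisson(n_photos * views_per_photo * view_mult * photo_noise)
        inc[0] = event
        inc[1] = views
        inc[2] = rng.poisson(
            event * views_per_photo * view_mult * rng.lognormal(-0.5, 1.0, n_users)
        )
        inc[3] = rng.poisson(com_mult * comment_rate_same * np.maximum(n_photos, 0))
        inc[4] = rng.poisson(com_mult * comment_rate_other * np.maximum(n_photos, 0))
        cum += inc
        ring[t % window_intervals] = inc

    prefix = "cum_" if feature_set == "cumulative" else "recent_"
    cols = [
        prefix + "relevant_photos",
        prefix + "views",
        prefix + "views_relevant",
        prefix + "comments_same",
        prefix + "comments_other",
        prefix + "frac_comments_same",
    ]
    df = pd.DataFrame(out, columns=["interval"] + cols + ["event"])
    df["interval"] = df["interval"].astype(int)
    df["event"] = df["event"].astype(bool)
    df["user_id"] = np.tile([f"u{i:05d}" for i in range(n_users)], n_intervals)
    df["class"] = "pro_ana"
    return df
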