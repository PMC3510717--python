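"""Posting-cessation detection and per-image follow-up statistics.

A community user "ceases" when they stop posting highly relevant photos for
at least ``gap_days`` (default 90, the deterministic reading of "3 months")
while continuing to post other photos — the continued other posting rules
out users who simply abandoned the site.  A user whose observation window
after their final relevant photo is shorter than the gap cannot be
classified and is censored.

The follow-up table asks, for each relevant photo that received comments
from labeled users, whether the poster subsequently ceased, broken down by
poster class × commenter class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from edtribes.corpus import Corpus
from edtribes.labels import ClassLabel

__all__ = [
    "CessationEvent",
    "CessationNotApplicable",
    "detect_cessation",
    "detect_all_cessation",
    "image_followup_table",
    "FollowupTable",
]

_COMMUNITY = (ClassLabel.PRO_ANA, ClassLabel.PRO_RECOVERY)


class CessationNotApplicable(ValueError):
    """The user has no relevant photos, so cessation is undefined."""


@dataclass
class CessationEvent:
    """Outcome of the relevant-posting-stop rule for one user."""

    user_id: str
    ceased: bool
    censored: bool
    abandoned: bool  # no posting of any kind after the last relevant photo
    last_relevant_date: pd.Timestamp
    gap_days: int  # observed days from last relevant photo to observation end


def _classify(
    rel_times: pd.Series,
    other_times: pd.Series,
    gap_days: int,
    observation_end: pd.Timestamp,
) -> tuple[bool, bool, bool, pd.Timestamp, int]:
    last_rel = rel_times.max()
    tail_days = int((observation_end - last_rel) / pd.Timedelta(days=1))
    censored = tail_days < gap_days
    has_other_after = bool((other_times > last_rel).any()) if len(other_times) else False
    abandoned = not censored and not has_other_after
    ceased = not censored and has_other_after
    return ceased, censored, abandoned, last_rel, tail_days


def detect_cessation(
    corpus: Corpus,
    flags: pd.Series,
    user_id: str,
    gap_days: int = 90,
    observation_end: pd.Timestamp | None = None,
) -> CessationEvent:
    """Apply the cessation rule to one user.

    ``ceased`` requires an observation window of at least ``gap_days`` after
    the user's final relevant photo with at least one non-relevant photo
    posted in it.  With a shorter window the user is censored; with no
    posting at all after the final relevant photo the user counts as having
    abandoned the site (excluded from cessation rates).

    Raises :class:`CessationNotApplicable` when the user has no relevant
    photos.
    """
    obs_end = observation_end or corpus.observation_end
    photos = corpus.photos[corpus.photos["owner_id"] == user_id]
    is_rel = photos["photo_id"].map(flags).fillna(False).astype(bool).to_numpy()
    if not is_rel.any():
        raise CessationNotApplicable(f"user {user_id} has no relevant photos")
    times = photos["posted_at"]
    ceased, censored, abandoned, last_rel, tail = _classify(
        times[is_rel], times[~is_rel], gap_days, obs_end
    )
    return CessationEvent(user_id, ceased, censored, abandoned, last_rel, tail)


def detect_all_cessation(
    corpus: Corpus,
    flags: pd.Series,
    labels: dict[str, ClassLabel],
    gap_days: int = 90,
    observation_end: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """Cessation events for every community user with at least one relevant photo."""
    obs_end = observation_end or corpus.observation_end
    rows = []
    rel_flag = corpus.photos["photo_id"].map(flags).fillna(False).astype(bool).to_numpy()
    for user_id, grp in corpus.photos.assign(_rel=rel_flag).groupby("owner_id"):
        if labels.get(user_id) not in _COMMUNITY:
            continue
        is_rel = grp["_rel"].to_numpy()
        if not is_rel.any():
            continue
        times = grp["posted_at"]
        ceased, censored, abandoned, last_rel, tail = _classify(
            times[is_rel], times[~is_rel], gap_days, obs_end
        )
        rows.append(
            {
                "user_id": user_id,
                "class": labels[user_id].value,
                "ceased": ceased,
                "censored": censored,
                "abandoned": abandoned,
                "last_relevant_date": last_rel,
                "gap_days": tail,
            }
        )
    cols = ["user_id", "class", "ceased", "censored", "abandoned", "last_relevant_date", "gap_days"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class FollowupTable:
    """Cessation rates and mean days-to-cessation by poster × commenter class.

    Cells are keyed ``(poster, commented_by)`` with classes ``pro_ana`` /
    ``pro_recovery``.  ``rates`` holds the fraction of cell photos followed
    by the poster's cessation (None when the cell is empty); ``mean_days``
    averages, over ceased-only photos, the days from the photo to the
    poster's final relevant photo; ``counts`` is the number of unit photos.
    """

    rates: dict
    mean_days: dict
    counts: dict
    attribution: str  # "nonexclusive" | "exclusive"
    warnings: list = field(default_factory=list)


def image_followup_table(
    corpus: Corpus,
    labels: dict[str, ClassLabel],
    flags: pd.Series,
    events: pd.DataFrame,
    attribution: str = "nonexclusive",
) -> FollowupTable:
    """Per-image cessation follow-up by poster class × commenter class.

    The unit is a relevant photo with at least one comment from a labeled
    community user.  Under the default non-exclusive attribution a photo
    with both PA and PR comments contributes to both commenter columns;
    ``exclusive`` restricts each column to photos commented by only that
    class.  A photo is followed by cessation iff its poster ceased and the
    photo was posted no later than the poster's final relevant photo; photos
    of posters still posting relevant content near the observation end
    (censored) count as not followed.  Photos of posters who abandoned the
    site entirely are excluded, mirroring the rule's rationale.
    """
    if attribution not in ("nonexclusive", "exclusive"):
        raise ValueError(f"unknown attribution mode: {attribution}")
    ev = events.set_index("user_id")
    owner = corpus.photos.set_index("photo_id")["owner_id"]
    posted = corpus.photos.set_index("photo_id")["posted_at"]

    # commenter classes per photo
    commenter_class = corpus.comments["commenter_id"].map(
        lambda u: labels.get(u, ClassLabel.UNLABELED)
    )
    has_pa: dict[str, bool] = {}
    has_pr: dict[str, bool] = {}
    for pid, cls in zip(corpus.comments["photo_id"], commenter_class):
        if cls is ClassLabel.PRO_ANA:
            has_pa[pid] = True
        elif cls is ClassLabel.PRO_RECOVERY:
            has_pr[pid] = True

    cells: dict[tuple, list] = {
        (p, c): []
        for p in ("pro_ana", "pro_recovery")
        for c in ("pro_ana", "pro_recovery")
    }
    for pid in corpus.photos["photo_id"]:
        if not bool(flags.get(pid, False)):
            continue
        uid = owner[pid]
        poster = labels.get(uid)
        if poster not in _COMMUNITY or uid not in ev.index:
            continue
        row = ev.loc[uid]
        if bool(row["abandoned"]):
            continue
        pa_c, pr_c = has_pa.get(pid, False), has_pr.get(pid, False)
        if not (pa_c or pr_c):
            continue
        if attribution == "exclusive":
            pa_c, pr_c = pa_c and not pr_c, pr_c and not pa_c
        followed = bool(row["ceased"]) and posted[pid] <= row["last_relevant_date"]
        days = (
            int((row["last_relevant_date"] - posted[pid]) / pd.Timedelta(days=1))
            if followed
            else None
        )
        for flag, col in ((pa_c, "pro_ana"), (pr_c, "pro_recovery")):
            if flag:
                cells[(poster.value, col)].append((followed, days))

    rates, mean_days, counts = {}, {}, {}
    warnings = []
    for key, items in cells.items():
        counts[key] = len(items)
        if not items:
            rates[key] = None
            mean_days[key] = None
            warnings.append(f"cell {key}: empty, rate undefined")
            continue
        followed = [f for f, _ in items]
        rates[key] = float(np.mean(followed))
        ceased_days = [d for f, d in items if f]
        mean_days[key] = float(np.mean(ceased_days)) if ceased_days else None
    return FollowupTable(rates, mean_days, counts, attribution, warnings)
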