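"""Shared fixtures: hand-built tiny corpora and session-scoped synthetic ones."""

from __future__ import annotations

import pandas as pd
import pytest

from edtribes.corpus import (
    COMMENT_COLUMNS,
    CONTACT_COLUMNS,
    FAVORITE_COLUMNS,
    PHOTO_COLUMNS,
    USER_COLUMNS,
    Corpus,
    validate_corpus,
)
from edtribes.labels import ClassLabel
from edtribes.synth import GeneratorParams, generate_corpus

EPOCH = pd.Timestamp("2010-01-01", tz="UTC")


def ts(days: float) -> pd.Timestamp:
    """Timestamp ``days`` after the test epoch."""
    return EPOCH + pd.Timedelta(days=days)


def build_corpus(
    users=(),
    photos=(),
    comments=(),
    contacts=(),
    favorites=(),
    observation_end=None,
    validate: bool = True,
) -> Corpus:
    """Construct a corpus from terse row specs.

    ``users`` entries are ids or dicts; ``photos`` dicts accept ``day``
    instead of ``posted_at`` and default everything else; ``comments``
    likewise accept ``day``.
    """
    user_rows = []
    for u in users:
        row = {"user_id": u} if isinstance(u, str) else dict(u)
        row.setdefault("join_date", None)
        row.setdefault("seed_methods", [])
        row.setdefault("latent_class", None)
        row.setdefault("active", True)
        user_rows.append(row)
    photo_rows = []
    for p in photos:
        row = dict(p)
        if "day" in row:
            row["posted_at"] = ts(row.pop("day"))
        row.setdefault("title", "")
        row.setdefault("description", "")
        row.setdefault("tags", [])
        row.setdefault("view_count", 0)
        row.setdefault("group_ids", [])
        row.setdefault("is_relevant", None)
        photo_rows.append(row)
    comment_rows = []
    for i, c in enumerate(comments):
        row = dict(c)
        if "day" in row:
            row["commented_at"] = ts(row.pop("day"))
        row.setdefault("comment_id", f"c{i:04d}")
        comment_rows.append(row)
    contact_rows = [
        {"from_user": a, "to_user": b} if not isinstance(e, dict) else dict(e)
        for e in contacts
        for a, b in [e if not isinstance(e, dict) else (e["from_user"], e["to_user"])]
    ]
    favorite_rows = [
        dict(f) if isinstance(f, dict) else {"photo_id": f[0], "user_id": f[1]}
        for f in favorites
    ]

    def frame(rows, columns):
        if rows:
            return pd.DataFrame(rows, columns=columns)
        return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})

    corpus = Corpus(
        users=frame(user_rows, USER_COLUMNS),
        photos=frame(photo_rows, PHOTO_COLUMNS),
        comments=frame(comment_rows, COMMENT_COLUMNS),
        contacts=frame(contact_rows, CONTACT_COLUMNS),
        favorites=frame(favorite_rows, FAVORITE_COLUMNS),
        observation_end=observation_end,
    )
    if validate:
        validate_corpus(corpus)
    return corpus


SMALL_PARAMS = GeneratorParams(
    n_pa=30,
    n_pr=30,
    n_neutral=40,
    time_span=("2010-01-01", "2011-07-01"),
)


@pytest.fixture(scope="session")
def small_synthetic():
    """A compact generated corpus with ground truth, shared across tests."""
    return generate_corpus(SMALL_PARAMS, seed=11)


@pytest.fixture(scope="session")
def small_labels(small_synthetic):
    _, truth = small_synthetic
    return {u: ClassLabel(c) for u, c in truth.latent_class.items()}
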