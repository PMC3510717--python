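"""Corpus schema, readers/writers and validation.

A corpus is five linked record tables describing activity on a photo-sharing
site: users, photos (with tag lists, timestamps and view counts), comments,
directed contacts and favorites.  On disk a corpus directory holds

* ``users.csv`` — ``user_id, join_date, seed_methods, latent_class, active``
* ``photos.jsonl`` — one JSON object per photo (tags and group ids as arrays)
* ``comments.csv`` — ``comment_id, photo_id, commenter_id, commented_at``
* ``contacts.csv`` — ``from_user, to_user``
* ``favorites.csv`` — ``photo_id, user_id``

Timestamps are ISO-8601 UTC at second resolution; ``join_date`` may be a bare
date.  Tags are normalised to lowercase with surrounding whitespace stripped;
internal punctuation is kept, so ``self-portrait`` and ``selfportrait`` remain
distinct tags.  Writing is canonical (stable sort by id, fixed field order) so
that load→write→load round-trips are byte-identical.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "Corpus",
    "CorpusLoadError",
    "CorpusIntegrityError",
    "load_corpus",
    "write_corpus",
    "validate_corpus",
    "normalize_tag",
]

USER_COLUMNS = ["user_id", "join_date", "seed_methods", "latent_class", "active"]
PHOTO_COLUMNS = [
    "photo_id",
    "owner_id",
    "posted_at",
    "title",
    "description",
    "tags",
    "view_count",
    "group_ids",
    "is_relevant",
]
COMMENT_COLUMNS = ["comment_id", "photo_id", "commenter_id", "commented_at"]
CONTACT_COLUMNS = ["from_user", "to_user"]
FAVORITE_COLUMNS = ["photo_id", "user_id"]

SEED_METHODS = frozenset({"search", "group", "commenter", "favoriter"})

_TS_FORMAT = "%Y-%m-%dT%H:%M:%SZ"


class CorpusLoadError(RuntimeError):
    """A corpus file is missing or malformed."""


class CorpusIntegrityError(ValueError):
    """A referential-integrity or invariant violation, listing offending ids."""


def normalize_tag(tag: str) -> str:
    """Lowercase and strip surrounding whitespace; keep internal punctuation."""
    return tag.strip().lower()


@dataclass
class Corpus:
    """The five linked record tables plus the observation horizon.

    ``observation_end`` defaults to the latest timestamp in the corpus and
    marks the right edge of the observation window used for censoring in the
    cessation analysis.
    """

    users: pd.DataFrame
    photos: pd.DataFrame
    comments: pd.DataFrame
    contacts: pd.DataFrame
    favorites: pd.DataFrame
    observation_end: pd.Timestamp | None = field(default=None)

    def __post_init__(self) -> None:
        if self.observation_end is None:
            self.observation_end = self._max_timestamp()
        elif self.observation_end.tzinfo is None:
            self.observation_end = self.observation_end.tz_localize("UTC")

    def _max_timestamp(self) -> pd.Timestamp | None:
        stamps = []
        if len(self.photos):
            stamps.append(self.photos["posted_at"].max())
        if len(self.comments):
            stamps.append(self.comments["commented_at"].max())
        return max(stamps) if stamps else None

    @property
    def n_users(self) -> int:
        return len(self.users)

    def photos_of(self, user_id: str) -> pd.DataFrame:
        return self.photos[self.photos["owner_id"] == user_id]

    def equals(self, other: "Corpus") -> bool:
        """Record-level equality of all five tables (ignores row order)."""
        for name in ("users", "photos", "comments", "contacts", "favorites"):
            a = getattr(self, name).reset_index(drop=True)
            b = getattr(other, name).reset_index(drop=True)
            if len(a) != len(b) or list(a.columns) != list(b.columns):
                return False
            key = a.columns[0]
            a = a.sort_values(list(a.columns[:2])).reset_index(drop=True)
            b = b.sort_values(list(b.columns[:2])).reset_index(drop=True)
            for col in a.columns:
                av, bv = a[col].tolist(), b[col].tolist()
                if av != bv:
                    return False
        return True


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_ts(value: str, *, where: str) -> pd.Timestamp:
    try:
        ts = pd.Timestamp(value)
    except ValueError as exc:  # pragma: no cover - defensive
        raise CorpusLoadError(f"unparseable timestamp {value!r} in {where}") from exc
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.tz_convert("UTC")


def _format_ts(ts: pd.Timestamp) -> str:
    return ts.tz_convert("UTC").strftime(_TS_FORMAT)


def _empty_frame(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


def _read_csv(path: Path, columns: list[str]) -> list[dict]:
    if not path.exists():
        raise CorpusLoadError(f"missing corpus file: {path.name}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != columns:
            raise CorpusLoadError(
                f"{path.name}: expected header {columns}, got {reader.fieldnames}"
            )
        return list(reader)


# ---------------------------------------------------------------------------
# load / write


def load_corpus(directory: str | Path, observation_end: str | None = None) -> Corpus:
    """Read and validate a corpus directory.

    Parameters
    ----------
    directory
        Path holding the five corpus files.
    observation_end
        Optional ISO date overriding the default observation horizon (the
        latest timestamp in the corpus).

    Raises
    ------
    CorpusLoadError
        If a file is missing or malformed (names the file).
    CorpusIntegrityError
        If referential integrity or a schema invariant is violated (lists the
        offending ids).
    """
    directory = Path(directory)

    user_rows = _read_csv(directory / "users.csv", USER_COLUMNS)
    users = []
    for row in user_rows:
        methods = sorted(m for m in row["seed_methods"].split(";") if m)
        users.append(
            {
                "user_id": row["user_id"],
                "join_date": row["join_date"] or None,
                "seed_methods": methods,
                "latent_class": row["latent_class"] or None,
                "active": row["active"] != "false",
            }
        )
    users_df = pd.DataFrame(users, columns=USER_COLUMNS) if users else _empty_frame(USER_COLUMNS)

    photos_path = directory / "photos.jsonl"
    if not photos_path.exists():
        raise CorpusLoadError("missing corpus file: photos.jsonl")
    photos = []
    with open(photos_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusLoadError(f"photos.jsonl line {lineno}: invalid JSON") from exc
            photos.append(
                {
                    "photo_id": rec["photo_id"],
                    "owner_id": rec["owner_id"],
                    "posted_at": _parse_ts(rec["posted_at"], where="photos.jsonl"),
                    "title": rec.get("title", ""),
                    "description": rec.get("description", ""),
                    "tags": [normalize_tag(t) for t in rec.get("tags", [])],
                    "view_count": int(rec.get("view_count", 0)),
                    "group_ids": list(rec.get("group_ids", [])),
                    "is_relevant": rec.get("is_relevant", None),
                }
            )
    photos_df = pd.DataFrame(photos, columns=PHOTO_COLUMNS) if photos else _empty_frame(PHOTO_COLUMNS)

    comment_rows = _read_csv(directory / "comments.csv", COMMENT_COLUMNS)
    comments_df = (
        pd.DataFrame(
            [
                {
                    "comment_id": r["comment_id"],
                    "photo_id": r["photo_id"],
                    "commenter_id": r["commenter_id"],
                    "commented_at": _parse_ts(r["commented_at"], where="comments.csv"),
                }
                for r in comment_rows
            ],
            columns=COMMENT_COLUMNS,
        )
        if comment_rows
        else _empty_frame(COMMENT_COLUMNS)
    )

    contact_rows = _read_csv(directory / "contacts.csv", CONTACT_COLUMNS)
    contacts_df = (
        pd.DataFrame(contact_rows, columns=CONTACT_COLUMNS)
        if contact_rows
        else _empty_frame(CONTACT_COLUMNS)
    )

    favorite_rows = _read_csv(directory / "favorites.csv", FAVORITE_COLUMNS)
    favorites_df = (
        pd.DataFrame(favorite_rows, columns=FAVORITE_COLUMNS)
        if favorite_rows
        else _empty_frame(FAVORITE_COLUMNS)
    )

    corpus = Corpus(
        users=users_df,
        photos=photos_df,
        comments=comments_df,
        contacts=contacts_df,
        favorites=favorites_df,
        observation_end=pd.Timestamp(observation_end) if observation_end else None,
    )
    validate_corpus(corpus)
    return corpus


def write_corpus(corpus: Corpus, directory: str | Path) -> None:
    """Write a corpus canonically: stable ordering by id, fixed field order.

    Canonical output makes round-trips deterministic: loading the written
    files and writing them again produces byte-identical output.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def dump_csv(name: str, columns: list[str], rows: list[list[str]]) -> None:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(columns)
        writer.writerows(rows)
        (directory / name).write_text(buf.getvalue(), encoding="utf-8")

    users = corpus.users.sort_values("user_id")
    dump_csv(
        "users.csv",
        USER_COLUMNS,
        [
            [
                r.user_id,
                r.join_date or "",
                ";".join(sorted(r.seed_methods)),
                r.latent_class or "",
                "true" if r.active else "false",
            ]
            for r in users.itertuples()
        ],
    )

    photos = corpus.photos.sort_values("photo_id")
    with open(directory / "photos.jsonl", "w", encoding="utf-8") as fh:
        for r in photos.itertuples():
            rec = {
                "photo_id": r.photo_id,
                "owner_id": r.owner_id,
                "posted_at": _format_ts(r.posted_at),
                "title": r.title,
                "description": r.description,
                "tags": list(r.tags),
                "view_count": int(r.view_count),
                "group_ids": list(r.group_ids),
            }
            if r.is_relevant is not None:
                rec["is_relevant"] = bool(r.is_relevant)
            fh.write(json.dumps(rec, sort_keys=True, ensure_ascii=False) + "\n")

    comments = corpus.comments.sort_values("comment_id")
    dump_csv(
        "comments.csv",
        COMMENT_COLUMNS,
        [
            [r.comment_id, r.photo_id, r.commenter_id, _format_ts(r.commented_at)]
            for r in comments.itertuples()
        ],
    )

    contacts = corpus.contacts.sort_values(["from_user", "to_user"])
    dump_csv(
        "contacts.csv",
        CONTACT_COLUMNS,
        [[r.from_user, r.to_user] for r in contacts.itertuples()],
    )

    favorites = corpus.favorites.sort_values(["photo_id", "user_id"])
    dump_csv(
        "favorites.csv",
        FAVORITE_COLUMNS,
        [[r.photo_id, r.user_id] for r in favorites.itertuples()],
    )


# ---------------------------------------------------------------------------
# validation


def _offenders(ids) -> str:
    ids = sorted(map(str, set(ids)))
    shown = ", ".join(ids[:10])
    more = f" (+{len(ids) - 10} more)" if len(ids) > 10 else ""
    return shown + more


def validate_corpus(corpus: Corpus) -> None:
    """Check every schema invariant; raise :class:`CorpusIntegrityError` on failure.

    Checks: unique user/photo/comment ids, referential integrity of all
    cross-table references, tag normalisation, non-negative view counts,
    comments not predating their photo, no duplicate or self contacts, and
    unique (photo, user) favorites.
    """
    users, photos = corpus.users, corpus.photos
    comments, contacts, favorites = corpus.comments, corpus.contacts, corpus.favorites

    if users["user_id"].duplicated().any():
        dup = users.loc[users["user_id"].duplicated(), "user_id"]
        raise CorpusIntegrityError(f"duplicate user_id: {_offenders(dup)}")
    known_users = set(users["user_id"])

    bad_methods = [
        r.user_id for r in users.itertuples() if not set(r.seed_methods) <= SEED_METHODS
    ]
    if bad_methods:
        raise CorpusIntegrityError(f"unknown seed_methods for users: {_offenders(bad_methods)}")

    if photos["photo_id"].duplicated().any():
        dup = photos.loc[photos["photo_id"].duplicated(), "photo_id"]
        raise CorpusIntegrityError(f"duplicate photo_id: {_offenders(dup)}")
    dangling = photos.loc[~photos["owner_id"].isin(known_users), "photo_id"]
    if len(dangling):
        raise CorpusIntegrityError(f"photos with unknown owner_id: {_offenders(dangling)}")
    if len(photos):
        if (photos["view_count"].astype(int) < 0).any():
            bad = photos.loc[photos["view_count"].astype(int) < 0, "photo_id"]
            raise CorpusIntegrityError(f"negative view_count: {_offenders(bad)}")
        for r in photos.itertuples():
            if any(t != normalize_tag(t) for t in r.tags):
                raise CorpusIntegrityError(f"unnormalised tags on photo {r.photo_id}")

    if comments["comment_id"].duplicated().any():
        dup = comments.loc[comments["comment_id"].duplicated(), "comment_id"]
        raise CorpusIntegrityError(f"duplicate comment_id: {_offenders(dup)}")
    known_photos = set(photos["photo_id"])
    bad = comments.loc[~comments["photo_id"].isin(known_photos), "comment_id"]
    if len(bad):
        raise CorpusIntegrityError(f"comments on unknown photos: {_offenders(bad)}")
    bad = comments.loc[~comments["commenter_id"].isin(known_users), "comment_id"]
    if len(bad):
        raise CorpusIntegrityError(f"comments by unknown users: {_offenders(bad)}")
    if len(comments):
        posted = photos.set_index("photo_id")["posted_at"]
        early = comments.loc[
            comments["commented_at"].values < posted.loc[comments["photo_id"]].values,
            "comment_id",
        ]
        if len(early):
            raise CorpusIntegrityError(f"comments predating their photo: {_offenders(early)}")

    for col in CONTACT_COLUMNS:
        bad = contacts.loc[~contacts[col].isin(known_users), col]
        if len(bad):
            raise CorpusIntegrityError(f"contacts with unknown {col}: {_offenders(bad)}")
    if len(contacts):
        if contacts.duplicated().any():
            dup = contacts.loc[contacts.duplicated()].apply(tuple, axis=1)
            raise CorpusIntegrityError(f"duplicate contact edges: {_offenders(dup)}")
        loops = contacts.loc[contacts["from_user"] == contacts["to_user"], "from_user"]
        if len(loops):
            raise CorpusIntegrityError(f"self-loop contacts: {_offenders(loops)}")

    bad = favorites.loc[~favorites["photo_id"].isin(known_photos), "photo_id"]
    if len(bad):
        raise CorpusIntegrityError(f"favorites of unknown photos: {_offenders(bad)}")
    bad = favorites.loc[~favorites["user_id"].isin(known_users), "user_id"]
    if len(bad):
        raise CorpusIntegrityError(f"favorites by unknown users: {_offenders(bad)}")
    if len(favorites) and favorites.duplicated().any():
        dup = favorites.loc[favorites.duplicated()].apply(tuple, axis=1)
        raise CorpusIntegrityError(f"duplicate favorites: {_offenders(dup)}")
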