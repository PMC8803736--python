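"""Data model and readers/writers for user post streams, lexicons and feature tables.

The on-disk contract is deliberately plain text:

* posts: JSON Lines, one post object per line with keys ``user_id``, ``text``,
  ``timestamp`` (ISO-8601, hour resolution or finer), ``is_original``,
  ``has_picture``, ``has_location`` and optional ``polarity`` (0 negative,
  1 neutral, 2 positive);
* labels: a sidecar CSV ``user_id,label`` so unlabeled corpora can be scored;
* lexicons: a directory of UTF-8 term lists, one term per line, file stem =
  category name;
* feature tables: CSV with header ``user_id,label,<feature names...>`` plus a
  ``*.schema.json`` manifest mapping feature name -> feature group.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POLARITY_NEGATIVE, POLARITY_NEUTRAL, POLARITY_POSITIVE = 0, 1, 2
VALID_POLARITIES = (POLARITY_NEGATIVE, POLARITY_NEUTRAL, POLARITY_POSITIVE)

#: feature groups a feature name may belong to
GROUP_TEXTUAL = "textual"
GROUP_BEHAVIOR = "behavior"


@dataclass(frozen=True)
class PostRecord:
    """A single microblog post by one user."""

    user_id: str
    text: str
    timestamp: datetime
    is_original: bool = True
    has_picture: bool = False
    has_location: bool = False
    polarity: int | None = None

    def __post_init__(self) -> None:
        if self.polarity is not None and self.polarity not in VALID_POLARITIES:
            raise ValueError(
                f"polarity must be one of {VALID_POLARITIES} or None, "
                f"got {self.polarity!r}"
            )


@dataclass
class UserRecord:
    """A user and their time-ordered post stream, optionally labeled.

    ``label`` is 1 for a depressed user, 0 for a control user, None when
    unknown (scoring-time corpora).
    """

    user_id: str
    posts: list[PostRecord]
    label: int | None = None

    def __post_init__(self) -> None:
        for p in self.posts:
            if p.user_id != self.user_id:
                raise ValueError(
                    f"post user_id {p.user_id!r} != record user_id {self.user_id!r}"
                )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")


@dataclass
class LexiconSet:
    """Named term lists: emotion categories, pronoun classes, specific words.

    ``categories`` maps a category name (e.g. ``"sad"``, ``"first_singular"``,
    ``"negation"``) to its set of terms.  Categories are non-empty and terms
    unique within a category.
    """

    categories: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, terms in self.categories.items():
            if not terms:
                raise ValueError(f"lexicon category {name!r} is empty")

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.categories[name]

    def __contains__(self, name: str) -> bool:
        return name in self.categories

    @property
    def names(self) -> list[str]:
        return list(self.categories)


@dataclass
class FeatureTable:
    """Per-user feature vectors with labels — the interchange object between stages.

    Rows follow ``user_ids`` order; ``labels`` is None for unlabeled tables.
    ``provenance`` maps each feature name to its group ("textual"/"behavior").
    NaN values are replaced by 0 with a logged warning: every feature is a
    rate or proportion for which an empty denominator means "no signal".
    """

    feature_names: list[str]
    X: np.ndarray
    user_ids: list[str]
    labels: np.ndarray | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"X shape {self.X.shape} inconsistent with "
                f"{len(self.feature_names)} feature names"
            )
        if len(self.user_ids) != self.X.shape[0]:
            raise ValueError("user_ids length != number of rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.X.shape[0],):
                raise ValueError("labels length != number of rows")
            bad = set(np.unique(self.labels)) - {0, 1}
            if bad:
                raise ValueError(f"labels must be binary 0/1, found {sorted(bad)}")
        if np.isnan(self.X).any():
            n_bad = int(np.isnan(self.X).sum())
            logger.warning("feature table contains %d NaN values; set to 0", n_bad)
            self.X = np.nan_to_num(self.X, nan=0.0)

    @property
    def n_users(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def group_of(self, name: str) -> str:
        """Feature group, inferred from the name prefix when no provenance entry."""
        if name in self.provenance:
            return self.provenance[name]
        return GROUP_BEHAVIOR if name.startswith("beh_") else GROUP_TEXTUAL

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        """Restrict to the given features, preserving this table's column order."""
        wanted = set(names)
        missing = wanted - set(self.feature_names)
        if missing:
            raise KeyError(f"unknown features: {sorted(missing)}")
        keep = [i for i, n in enumerate(self.feature_names) if n in wanted]
        kept_names = [self.feature_names[i] for i in keep]
        return FeatureTable(
            feature_names=kept_names,
            X=self.X[:, keep].copy(),
            user_ids=list(self.user_ids),
            labels=None if self.labels is None else self.labels.copy(),
            provenance={n: self.group_of(n) for n in kept_names},
        )

    def subset_groups(self, groups: Iterable[str]) -> "FeatureTable":
        gset = set(groups)
        return self.subset_features(
            [n for n in self.feature_names if self.group_of(n) in gset]
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "user_id", self.user_ids)
        labels = (
            [math.nan] * self.n_users if self.labels is None else self.labels
        )
        df.insert(1, "label", labels)
        return df


def _parse_timestamp(value: str, lineno: int) -> datetime:
    try:
        return datetime.fromisoformat(str(value))
    except ValueError as exc:
        raise ValueError(f"line {lineno}: unparseable timestamp {value!r}") from exc


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a sidecar ``user_id,label`` CSV into a mapping."""
    df = pd.read_csv(path, dtype={"user_id": str})
    if not {"user_id", "label"} <= set(df.columns):
        raise ValueError(f"labels file {path} must have columns user_id,label")
    return dict(zip(df["user_id"], df["label"].astype(int)))


def read_posts(
    path: str | Path, labels: str | Path | Mapping[str, int] | None = None
) -> list[UserRecord]:
    """Read a JSON Lines post file into UserRecords grouped by user.

    Posts are grouped by ``user_id`` (first-seen order) and sorted by
    timestamp within each user.  ``labels`` may be a sidecar CSV path or a
    mapping; users absent from it stay unlabeled.
    """
    label_map: Mapping[str, int] = {}
    if labels is not None:
        label_map = labels if isinstance(labels, Mapping) else read_labels(labels)

    by_user: dict[str, list[PostRecord]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"line {lineno}: malformed JSON: {exc}") from exc
            try:
                polarity = obj.get("polarity")
                post = PostRecord(
                    user_id=str(obj["user_id"]),
                    text=str(obj.get("text", "")),
                    timestamp=_parse_timestamp(obj["timestamp"], lineno),
                    is_original=bool(obj.get("is_original", True)),
                    has_picture=bool(obj.get("has_picture", False)),
                    has_location=bool(obj.get("has_location", False)),
                    polarity=None if polarity is None else int(polarity),
                )
            except KeyError as exc:
                raise ValueError(f"line {lineno}: missing field {exc}") from exc
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            by_user.setdefault(post.user_id, []).append(post)

    users = []
    for uid, posts in by_user.items():
        posts.sort(key=lambda p: p.timestamp)  # stable: duplicates preserved
        users.append(
            UserRecord(user_id=uid, posts=posts, label=label_map.get(uid))
        )
    return users


def write_posts(users: Iterable[UserRecord], path: str | Path) -> None:
    """Write UserRecords back to JSON Lines (inverse of :func:`read_posts`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for user in users:
            for p in user.posts:
                obj = {
                    "user_id": p.user_id,
                    "text": p.text,
                    "timestamp": p.timestamp.isoformat(),
                    "is_original": p.is_original,
                    "has_picture": p.has_picture,
                    "has_location": p.has_location,
                }
                if p.polarity is not None:
                    obj["polarity"] = p.polarity
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def write_user_labels(users: Iterable[UserRecord], path: str | Path) -> None:
    rows = [
        {"user_id": u.user_id, "label": u.label}
        for u in users
        if u.label is not None
    ]
    pd.DataFrame(rows, columns=["user_id", "label"]).to_csv(path, index=False)


def read_lexicons(directory: str | Path) -> LexiconSet:
    """Load a directory of term-list files into a LexiconSet.

    One UTF-8 file per category, one term per line, file stem = category name.
    Terms are trimmed; duplicates within a file are kept once with a warning.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"no lexicon files in {directory}")
    categories: dict[str, frozenset[str]] = {}
    for f in files:
        terms: list[str] = []
        seen: set[str] = set()
        for raw in f.read_text(encoding="utf-8").splitlines():
            term = raw.strip()
            if not term:
                continue
            if term in seen:
                logger.warning(
                    "duplicate term %r in lexicon %s; kept once", term, f.name
                )
                continue
            seen.add(term)
            terms.append(term)
        if not terms:
            raise ValueError(f"lexicon category file {f} is empty")
        categories[f.stem] = frozenset(terms)
    return LexiconSet(categories=categories)


def write_lexicons(lexicons: LexiconSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, terms in lexicons.categories.items():
        (directory / f"{name}.txt").write_text(
            "\n".join(sorted(terms)) + "\n", encoding="utf-8"
        )


def _schema_path(path: Path) -> Path:
    return path.with_name(path.stem + ".schema.json")


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV plus a schema manifest.

    Values are written with 17 significant digits so a write→read round trip
    is value-exact.
    """
    path = Path(path)
    df = table.to_dataframe()
    df.to_csv(path, index=False, float_format="%.17g")
    manifest = {
        "feature_names": table.feature_names,
        "groups": {n: table.group_of(n) for n in table.feature_names},
    }
    _schema_path(path).write_text(json.dumps(manifest, indent=1), encoding="utf-8")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature-table CSV written by :func:`write_feature_table`.

    The header must contain ``user_id`` and ``label`` (any position); all
    remaining columns are features, in written order.
    """
    path = Path(path)
    # round_trip parsing: the default C float parser is lossy in the last ulp
    df = pd.read_csv(path, dtype={"user_id": str}, float_precision="round_trip")
    if not {"user_id", "label"} <= set(df.columns):
        raise ValueError(
            f"feature table {path} header must contain user_id and label"
        )
    feature_names = [c for c in df.columns if c not in ("user_id", "label")]
    labels = None
    if len(df) and df["label"].notna().all():
        labels = df["label"].astype(int).to_numpy()
    provenance: dict[str, str] = {}
    schema = _schema_path(path)
    if schema.exists():
        manifest = json.loads(schema.read_text(encoding="utf-8"))
        if manifest.get("feature_names") != feature_names:
            raise ValueError(
                f"schema manifest {schema} does not match CSV feature columns"
            )
        provenance = dict(manifest.get("groups", {}))
    if len(df) == 0:
        X = np.empty((0, len(feature_names)))
    else:
        X = df[feature_names].to_numpy(dtype=float)
    return FeatureTable(
        feature_names=feature_names,
        X=X,
        user_ids=list(df["user_id"].astype(str)),
        labels=labels,
        provenance=provenance,
    )
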