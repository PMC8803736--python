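"""Per-user feature extraction: text statistics and posting behavior.

All features are rates or proportions, never raw counts, so that users with
very different posting volumes are comparable: duplicating every post of a
user exactly k times leaves every feature unchanged.

The default schema has 52 features:

====================  ==  ==========================================
part-of-speech        20  proportion of each POS tag among all tokens
emotion words          7  per-1000-token rate per emotion category
personal pronouns      6  per-1000-token rate per pronoun class
specific words         2  negation / interrogative per-1000-token rate
post polarity          3  proportion of annotated posts per polarity
posting habits         3  proportion original / with picture / with location
posting time          11  4 six-hour bins + 7 weekdays (proportions)
====================  ==  ==========================================

POS tagging is an injection point (``Tagger``): any callable mapping post
text to a sequence of TaggedToken works, e.g. an adapter around a real
Chinese segmenter.  The shipped :class:`LookupTagger` (whitespace split +
token→tag map) is sufficient for synthetic corpora.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .io import (
    GROUP_BEHAVIOR,
    GROUP_TEXTUAL,
    FeatureTable,
    LexiconSet,
    PostRecord,
    UserRecord,
)

logger = logging.getLogger(__name__)

#: default 20-tag part-of-speech inventory (a convention: the categories a
#: Chinese tagger distinguishes, including onomatopoeia and idioms)
DEFAULT_POS_INVENTORY: tuple[str, ...] = (
    "noun",
    "verb",
    "adjective",
    "adverb",
    "pronoun",
    "numeral",
    "measure",
    "conjunction",
    "preposition",
    "particle",
    "interjection",
    "onomatopoeia",
    "idiom",
    "time_word",
    "place_word",
    "locative",
    "auxiliary",
    "modal",
    "status_word",
    "other",
)

EMOTION_CATEGORIES: tuple[str, ...] = (
    "happy",
    "like",
    "anger",
    "sad",
    "fear",
    "surprise",
    "disgust",
)

PRONOUN_CATEGORIES: tuple[str, ...] = (
    "first_singular",
    "first_plural",
    "second_singular",
    "second_plural",
    "third_person",
    "others_word",
)

SPECIFIC_CATEGORIES: tuple[str, ...] = ("negation", "interrogative")

WEEKDAY_NAMES: tuple[str, ...] = ("mon", "tue", "wed", "thu", "fri", "sat", "sun")
HOUR_BIN_NAMES: tuple[str, ...] = ("h00_06", "h06_12", "h12_18", "h18_24")


@dataclass(frozen=True)
class TaggedToken:
    token: str
    pos: str


#: a tagger maps post text to a (possibly empty) token sequence; it must be
#: deterministic for a fixed input
Tagger = Callable[[str], Sequence[TaggedToken]]


@dataclass
class LookupTagger:
    """Fallback tagger: whitespace split + token→tag lookup.

    Unknown tokens get ``default_tag``.  Adequate for pre-segmented or
    synthetic text; real Chinese text needs a segmenter adapter instead.
    """

    tag_map: Mapping[str, str] = field(default_factory=dict)
    default_tag: str = "other"

    def __call__(self, text: str) -> list[TaggedToken]:
        return [
            TaggedToken(tok, self.tag_map.get(tok, self.default_tag))
            for tok in text.split()
        ]


@dataclass
class FeatureSchema:
    """Ordered feature names with group provenance for a chosen subset of groups."""

    names: list[str]
    groups: dict[str, str]

    @property
    def n_features(self) -> int:
        return len(self.names)


def default_schema(
    inventory: Sequence[str] = DEFAULT_POS_INVENTORY,
    groups: Sequence[str] = (GROUP_TEXTUAL, GROUP_BEHAVIOR),
) -> FeatureSchema:
    """Build the feature schema for the requested groups (default: all 52)."""
    names: list[str] = []
    prov: dict[str, str] = {}

    def add(name: str, group: str) -> None:
        names.append(name)
        prov[name] = group

    gset = set(groups)
    unknown = gset - {GROUP_TEXTUAL, GROUP_BEHAVIOR}
    if unknown:
        raise ValueError(f"unknown feature groups: {sorted(unknown)}")
    if GROUP_TEXTUAL in gset:
        for tag in inventory:
            add(f"pos_{tag}", GROUP_TEXTUAL)
        for emo in EMOTION_CATEGORIES:
            add(f"emo_{emo}", GROUP_TEXTUAL)
        for pron in PRONOUN_CATEGORIES:
            add(f"pron_{pron}", GROUP_TEXTUAL)
        for cat in SPECIFIC_CATEGORIES:
            add(f"spec_{cat}", GROUP_TEXTUAL)
        for pol in ("negative", "neutral", "positive"):
            add(f"pol_{pol}", GROUP_TEXTUAL)
    if GROUP_BEHAVIOR in gset:
        for flag in ("original", "picture", "location"):
            add(f"beh_{flag}", GROUP_BEHAVIOR)
        for hb in HOUR_BIN_NAMES:
            add(f"beh_{hb}", GROUP_BEHAVIOR)
        for wd in WEEKDAY_NAMES:
            add(f"beh_wd_{wd}", GROUP_BEHAVIOR)
    return FeatureSchema(names=names, groups=prov)


def pos_proportions(
    tagged: Sequence[TaggedToken], inventory: Sequence[str] = DEFAULT_POS_INVENTORY
) -> np.ndarray:
    """Proportion of each POS tag among a user's tokens, in inventory order.

    Zero tokens yields an all-zero vector with a warning (low-content user).
    """
    counts = np.zeros(len(inventory))
    if not tagged:
        logger.warning("pos_proportions: user has no tokens")
        return counts
    index = {tag: i for i, tag in enumerate(inventory)}
    for tok in tagged:
        if tok.pos not in index:
            raise ValueError(f"POS tag {tok.pos!r} not in inventory")
        counts[index[tok.pos]] += 1
    return counts / counts.sum()


def lexicon_rates(
    tagged: Sequence[TaggedToken],
    lexicons: LexiconSet,
    categories: Sequence[str],
) -> np.ndarray:
    """Per-1000-token occurrence rate of each lexicon category.

    rate(c) = (#tokens whose surface form is in category c) / T * 1000,
    where T is the user's total token count.  Exact membership tests only.
    """
    rates = np.zeros(len(categories))
    if not tagged:
        logger.warning("lexicon_rates: user has no tokens")
        return rates
    total = len(tagged)
    for i, cat in enumerate(categories):
        terms = lexicons[cat]
        rates[i] = sum(1 for t in tagged if t.token in terms) / total * 1000.0
    return rates


def polarity_proportions(posts: Sequence[PostRecord]) -> np.ndarray:
    """Proportion of (negative, neutral, positive) posts among annotated posts.

    Posts without a polarity annotation are excluded from the denominator;
    no annotated posts yields zeros with a warning.
    """
    annotated = [p.polarity for p in posts if p.polarity is not None]
    out = np.zeros(3)
    if not annotated:
        logger.warning("polarity_proportions: no polarity-annotated posts")
        return out
    for pol in annotated:
        out[pol] += 1
    return out / out.sum()


def behavior_features(posts: Sequence[PostRecord]) -> np.ndarray:
    """Posting-behavior vector: 3 habit proportions, 4 hour bins, 7 weekdays.

    Hour bins are half-open [0,6), [6,12), [12,18), [18,24); the week runs
    Monday-first.  Habit proportions are over all posts; time proportions over
    posts with a parseable timestamp (always the case for PostRecord).
    """
    n = len(posts)
    if n == 0:
        logger.warning("behavior_features: user has no posts")
        return np.zeros(3 + 4 + 7)
    flags = np.array(
        [
            sum(p.is_original for p in posts),
            sum(p.has_picture for p in posts),
            sum(p.has_location for p in posts),
        ],
        dtype=float,
    ) / n
    hours = np.zeros(4)
    weekdays = np.zeros(7)
    for p in posts:
        hours[p.timestamp.hour // 6] += 1
        weekdays[p.timestamp.weekday()] += 1
    return np.concatenate([flags, hours / n, weekdays / n])


def _user_row(
    user: UserRecord,
    lexicons: LexiconSet,
    tagger: Tagger,
    inventory: Sequence[str],
    schema: FeatureSchema,
) -> np.ndarray:
    tagged: list[TaggedToken] = []
    for post in user.posts:
        tagged.extend(tagger(post.text))
    if not tagged:
        logger.warning(
            "user %s has no tokens; emitting zero row (exclusion candidate)",
            user.user_id,
        )
    parts: dict[str, np.ndarray] = {}
    gset = set(schema.groups.values())
    if GROUP_TEXTUAL in gset:
        parts["pos"] = pos_proportions(tagged, inventory)
        parts["emo"] = lexicon_rates(tagged, lexicons, EMOTION_CATEGORIES)
        parts["pron"] = lexicon_rates(tagged, lexicons, PRONOUN_CATEGORIES)
        parts["spec"] = lexicon_rates(tagged, lexicons, SPECIFIC_CATEGORIES)
        parts["pol"] = polarity_proportions(user.posts)
    if GROUP_BEHAVIOR in gset:
        parts["beh"] = behavior_features(user.posts)
    row = np.concatenate([parts[k] for k in ("pos", "emo", "pron", "spec", "pol", "beh") if k in parts])
    assert row.shape == (schema.n_features,)
    return row


def build_feature_table(
    users: Sequence[UserRecord],
    lexicons: LexiconSet,
    tagger: Tagger,
    inventory: Sequence[str] = DEFAULT_POS_INVENTORY,
    groups: Sequence[str] = (GROUP_TEXTUAL, GROUP_BEHAVIOR),
) -> FeatureTable:
    """Featurize a corpus into a FeatureTable, one row per user in input order.

    Labels are attached when every user carries one; a mixed/absent labeling
    yields an unlabeled table.
    """
    schema = default_schema(inventory, groups)
    X = np.vstack(
        [_user_row(u, lexicons, tagger, inventory, schema) for u in users]
    ) if users else np.empty((0, schema.n_features))
    labels = None
    if users and all(u.label is not None for u in users):
        labels = np.array([u.label for u in users], dtype=int)
    return FeatureTable(
        feature_names=list(schema.names),
        X=X,
        user_ids=[u.user_id for u in users],
        labels=labels,
        provenance=dict(schema.groups),
    )
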