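"""Timeline ingestion and word extraction.

Turns raw per-user tweet timelines into cleaned, lemmatized word-occurrence
streams.  The steps mirror the standard word-extraction pipeline for social
media text: restrict every timeline to a common observation window ``T``
(so that usage frequencies are comparable across users), strip the syntactic
marks peculiar to the medium (@-mentions, #-hashtags, links, emoji), drop
functional words (stop-words), normalise inflected forms through a pluggable
lemmatizer, and finally remove hapax legomena (words occurring exactly once,
mostly misspellings).

Only lexical words survive, each occurrence still tied to the tweet it came
from — the tweet link is what later connects word occurrences to topics.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from egowords.errors import ConfigError, MalformedInputError, TimelineRejectedError

#: days per year used to convert the observation window to a timedelta
DAYS_PER_YEAR = 365.25

Lemmatizer = Callable[[str], str]


@dataclass(frozen=True)
class Tweet:
    """A single dated message of one user (the ego)."""

    tweet_id: str
    ego_id: str
    timestamp: datetime
    text: str | None = None
    tokens: tuple[str, ...] | None = None
    include: bool = True


@dataclass
class Timeline:
    """One user's tweets, sorted ascending by timestamp.

    ``window_T`` is set (in years) once the timeline has been restricted to
    the common observation window.
    """

    ego_id: str
    tweets: list[Tweet] = field(default_factory=list)
    window_T: float | None = None

    def span_years(self) -> float:
        if not self.tweets:
            return 0.0
        dt = self.tweets[-1].timestamp - self.tweets[0].timestamp
        return dt.total_seconds() / (DAYS_PER_YEAR * 86400.0)


@dataclass
class OccurrenceStream:
    """Surviving word occurrences of one ego: ``(lemma, tweet_id)`` pairs."""

    ego_id: str
    occurrences: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.occurrences)

    def lemma_counts(self) -> Counter:
        return Counter(lemma for lemma, _ in self.occurrences)


# --------------------------------------------------------------------------
# timeline windowing

def window_timeline(timeline: Timeline, T: float) -> Timeline:
    """Restrict a timeline to its most recent ``T`` years.

    Timelines spanning less than ``T`` years cannot support frequency
    estimates over the window and are rejected (``TimelineRejectedError``).
    The boundary is inclusive: a span of exactly ``T`` years is accepted and
    keeps every tweet.
    """
    if T <= 0:
        raise ConfigError(f"observation window T must be positive, got {T}")
    if not timeline.tweets:
        raise TimelineRejectedError(f"ego {timeline.ego_id}: empty timeline")
    tweets = sorted(timeline.tweets, key=lambda t: t.timestamp)
    window = timedelta(days=T * DAYS_PER_YEAR)
    span = tweets[-1].timestamp - tweets[0].timestamp
    if span < window:
        raise TimelineRejectedError(
            f"ego {timeline.ego_id}: span {span} shorter than window {window}"
        )
    cutoff = tweets[-1].timestamp - window
    kept = [t for t in tweets if t.timestamp >= cutoff]
    return Timeline(ego_id=timeline.ego_id, tweets=kept, window_T=float(T))


def window_timelines(
    timelines: Iterable[Timeline], T: float
) -> tuple[list[Timeline], list[str]]:
    """Window every timeline; returns (accepted, rejected ego ids)."""
    accepted: list[Timeline] = []
    rejected: list[str] = []
    for tl in timelines:
        try:
            accepted.append(window_timeline(tl, T))
        except TimelineRejectedError:
            rejected.append(tl.ego_id)
    return accepted, rejected


# --------------------------------------------------------------------------
# text cleaning

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
_HASHTAG_RE = re.compile(r"#\w+")
# unicode letters, optionally with internal apostrophes ("don't");
# digits, punctuation, emoji and other symbols never enter a token
_TOKEN_RE = re.compile(r"[^\W\d_]+(?:'[^\W\d_]+)*")


def clean_text(text: str) -> list[str]:
    """Tokenize a tweet, dropping mentions, hashtags, links and emoji.

    Hashtag tokens are removed entirely (prefix and body): they are treated
    as syntactic marks of the medium, not as words.  The output is a
    lowercase token sequence; duplicates are preserved.  Idempotent on its
    own output.
    """
    stripped = _URL_RE.sub(" ", text)
    stripped = _MENTION_RE.sub(" ", stripped)
    stripped = _HASHTAG_RE.sub(" ", stripped)
    return _TOKEN_RE.findall(stripped.lower())


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load a one-word-per-line stop-word list (packaged English default)."""
    if path is None:
        ref = resources.files("egowords").joinpath("data/stopwords_en.txt")
        content = ref.read_text(encoding="utf-8")
    else:
        p = Path(path)
        if not p.is_file():
            raise ConfigError(f"stop-word list not found: {p}")
        content = p.read_text(encoding="utf-8")
    return frozenset(w.strip().lower() for w in content.splitlines() if w.strip())


def remove_functional_words(
    tokens: Sequence[str], stopwords: Iterable[str]
) -> list[str]:
    """Drop functional (stop) words; order and duplicates preserved."""
    table = stopwords if isinstance(stopwords, (set, frozenset)) else set(stopwords)
    return [t for t in tokens if t not in table]


# --------------------------------------------------------------------------
# lemmatization

def identity_lemmatizer(token: str) -> str:
    """The trivial total mapping: every token is its own lemma."""
    return token


class DictionaryLemmatizer:
    """Lemmatizer backed by an explicit form→lemma dictionary.

    Unknown tokens pass through unchanged, so the mapping is total.  The
    dictionary can be loaded from a two-column TSV (form, lemma).
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self.mapping = dict(mapping or {})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DictionaryLemmatizer":
        p = Path(path)
        if not p.is_file():
            raise ConfigError(f"lemma dictionary not found: {p}")
        df = pd.read_csv(p, sep="\t", header=None, names=["form", "lemma"], dtype=str)
        return cls(dict(zip(df["form"], df["lemma"])))

    def __call__(self, token: str) -> str:
        return self.mapping.get(token, token)


def lemmatize(tokens: Sequence[str], lemmatizer: Lemmatizer) -> list[str]:
    """Map every token to its lemma; length is preserved."""
    return [lemmatizer(t) for t in tokens]


# --------------------------------------------------------------------------
# occurrence stream

def build_occurrence_stream(
    timeline: Timeline, processed: Mapping[str, Sequence[str]]
) -> OccurrenceStream:
    """Assemble the hapax-filtered occurrence stream of one ego.

    ``processed`` maps tweet_id to that tweet's cleaned, stop-word-free,
    lemmatized token sequence.  Lemmas whose total count over the whole
    timeline is 1 are removed (hapax filter); every surviving occurrence
    keeps its tweet_id.
    """
    totals: Counter = Counter()
    for tweet in timeline.tweets:
        totals.update(processed.get(tweet.tweet_id, ()))
    occ: list[tuple[str, str]] = []
    for tweet in timeline.tweets:
        for lemma in processed.get(tweet.tweet_id, ()):
            if totals[lemma] >= 2:
                occ.append((lemma, tweet.tweet_id))
    return OccurrenceStream(ego_id=timeline.ego_id, occurrences=occ)


def process_timeline(
    timeline: Timeline,
    stopwords: Iterable[str],
    lemmatizer: Lemmatizer = identity_lemmatizer,
) -> OccurrenceStream:
    """Run cleaning, stop-word removal, lemmatization and the hapax filter."""
    table = stopwords if isinstance(stopwords, (set, frozenset)) else set(stopwords)
    processed: dict[str, list[str]] = {}
    for tweet in timeline.tweets:
        if tweet.tokens is not None:
            tokens = [t.lower() for t in tweet.tokens]
        else:
            tokens = clean_text(tweet.text or "")
        tokens = remove_functional_words(tokens, table)
        processed[tweet.tweet_id] = lemmatize(tokens, lemmatizer)
    return build_occurrence_stream(timeline, processed)


# --------------------------------------------------------------------------
# I/O

def read_timelines(path: str | Path) -> list[Timeline]:
    """Read JSON Lines tweets and group them into per-ego timelines.

    Each record needs ``ego_id``, ``tweet_id``, ``timestamp`` (ISO-8601) and
    either ``text`` or ``tokens``.  Records with ``include`` set to false
    (exclusions marked upstream, e.g. retweets or non-English tweets) are
    skipped.  Unparseable timestamps raise ``MalformedInputError`` naming the
    tweet.
    """
    by_ego: dict[str, list[Tweet]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise MalformedInputError(f"{path}:{line_no}: invalid JSON") from exc
            tweet_id = str(rec.get("tweet_id", f"line{line_no}"))
            if not rec.get("include", True):
                continue
            try:
                ts = datetime.fromisoformat(rec["timestamp"])
            except (KeyError, TypeError, ValueError) as exc:
                raise MalformedInputError(
                    f"tweet {tweet_id}: unparseable timestamp {rec.get('timestamp')!r}"
                ) from exc
            tokens = rec.get("tokens")
            tweet = Tweet(
                tweet_id=tweet_id,
                ego_id=str(rec["ego_id"]),
                timestamp=ts,
                text=rec.get("text"),
                tokens=tuple(tokens) if tokens is not None else None,
            )
            by_ego.setdefault(tweet.ego_id, []).append(tweet)
    return [
        Timeline(ego_id=ego, tweets=sorted(tweets, key=lambda t: t.timestamp))
        for ego, tweets in sorted(by_ego.items())
    ]


def streams_to_frame(streams: Iterable[OccurrenceStream]) -> pd.DataFrame:
    """Long-format occurrence table: ego_id, lemma, tweet_id."""
    rows = [
        (s.ego_id, lemma, tweet_id)
        for s in streams
        for lemma, tweet_id in s.occurrences
    ]
    return pd.DataFrame(rows, columns=["ego_id", "lemma", "tweet_id"])


def write_occurrences(streams: Iterable[OccurrenceStream], path: str | Path) -> None:
    streams_to_frame(streams).to_csv(path, sep="\t", index=False)


def read_occurrences(path: str | Path) -> list[OccurrenceStream]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for ego, grp in df.groupby("ego_id", sort=True):
        out.append(
            OccurrenceStream(
                ego_id=str(ego),
                occurrences=list(zip(grp["lemma"], grp["tweet_id"])),
            )
        )
    return out
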