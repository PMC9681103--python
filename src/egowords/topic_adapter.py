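"""Per-tweet topic assignments and topic-count reduction.

The semantic stages consume per-tweet topic assignments produced by an
external embedding + clustering stage (e.g. a BERTopic-style pipeline).
Hard assignments put a tweet in exactly one topic (or mark it an outlier
with an empty distribution); soft assignments give each tweet a
sub-stochastic distribution over topics.

Because such pipelines may emit many hundreds of fine-grained topics, the
adapter also implements an iterative reduction: repeatedly merge the
smallest topic (by hard-assigned tweet count) into the topic whose TF-IDF
document vector is most cosine-similar, summing per-tweet probabilities, and
stop at a target number of topics (100 by default).  Probability mass per
tweet is conserved exactly at every step, and the merge map derived from the
hard configuration can be replayed onto soft assignments.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from egowords.errors import ValidationError

logger = logging.getLogger(__name__)

_TOL = 1e-9


@dataclass
class TopicAssignment:
    """A tweet's distribution over topics; empty means outlier."""

    tweet_id: str
    dist: dict[str, float] = field(default_factory=dict)

    @property
    def is_outlier(self) -> bool:
        return not self.dist

    def total(self) -> float:
        return sum(self.dist.values())

    def hard_topic(self) -> str | None:
        """The single positive topic of a hard assignment, if any."""
        return next(iter(self.dist), None)


def validate_assignment(a: TopicAssignment, mode: str) -> None:
    if any(p < 0 for p in a.dist.values()):
        raise ValidationError(f"tweet {a.tweet_id}: negative probability")
    total = a.total()
    if mode == "hard":
        positive = [c for c, p in a.dist.items() if p > 0]
        if len(positive) > 1:
            raise ValidationError(
                f"tweet {a.tweet_id}: hard assignment with {len(positive)} topics"
            )
        if positive and abs(total - 1.0) > _TOL:
            raise ValidationError(
                f"tweet {a.tweet_id}: hard assignment with mass {total}"
            )
    elif mode == "soft":
        if total > 1.0 + _TOL:
            raise ValidationError(
                f"tweet {a.tweet_id}: soft assignment mass {total} exceeds 1"
            )
    else:
        raise ValueError(f"mode must be 'hard' or 'soft', got {mode!r}")


def load_assignments(
    path: str | Path, mode: str = "hard"
) -> dict[str, TopicAssignment]:
    """Read a TSV of (tweet_id, topic_id, prob); prob omitted means 1.0.

    Hard mode accepts one-hot or empty (outlier) distributions; soft mode
    accepts sub-stochastic ones.  Violations raise ``ValidationError`` naming
    the tweet.
    """
    df = pd.read_csv(path, sep="\t", dtype={"tweet_id": str, "topic_id": str})
    if "prob" not in df.columns:
        df["prob"] = 1.0
    out: dict[str, TopicAssignment] = {}
    for tweet_id, grp in df.groupby("tweet_id", sort=True):
        dist = {
            str(row.topic_id): float(row.prob)
            for row in grp.itertuples()
            if float(row.prob) > 0
        }
        a = TopicAssignment(tweet_id=str(tweet_id), dist=dist)
        validate_assignment(a, mode)
        out[a.tweet_id] = a
    return out


# --------------------------------------------------------------------------
# topic documents and TF-IDF similarity

def build_topic_documents(
    tweet_terms: Mapping[str, Sequence[str]],
    assignments: Mapping[str, TopicAssignment],
) -> dict[str, Counter]:
    """Aggregate term counts of all hard-assigned tweets per topic.

    Outlier tweets contribute nothing.  Topics that end up with zero tweets
    are dropped with a warning.
    """
    docs: dict[str, Counter] = {}
    for tweet_id, a in assignments.items():
        topic = a.hard_topic()
        if topic is None:
            continue
        terms = tweet_terms.get(tweet_id)
        docs.setdefault(topic, Counter())
        if terms:
            docs[topic].update(terms)
    empty = [t for t, c in docs.items() if not c]
    for t in empty:
        logger.warning("topic %s has no terms; dropped from documents", t)
        del docs[t]
    return docs


def _tfidf_vectors(docs: Mapping[str, Counter]) -> dict[str, dict[str, float]]:
    """Raw-count TF times idf = log(N_docs / df) over the live documents."""
    n_docs = len(docs)
    df_counts: Counter = Counter()
    for counts in docs.values():
        df_counts.update(set(counts))
    idf = {term: math.log(n_docs / df) for term, df in df_counts.items()}
    return {
        topic: {term: tf * idf[term] for term, tf in counts.items()}
        for topic, counts in docs.items()
    }


def _cosine(u: Mapping[str, float], v: Mapping[str, float]) -> float:
    dot = sum(w * v[t] for t, w in u.items() if t in v)
    nu = math.sqrt(sum(w * w for w in u.values()))
    nv = math.sqrt(sum(w * w for w in v.values()))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return dot / (nu * nv)


def tfidf_cosine(
    doc_a: Counter, doc_b: Counter, corpus: Iterable[Counter] | None = None
) -> float:
    """Cosine similarity of the two documents' TF-IDF vectors.

    IDF is computed over ``corpus`` (defaults to just the two documents).
    Symmetric; a zero vector has similarity 0 by convention.
    """
    docs = list(corpus) if corpus is not None else [doc_a, doc_b]
    keyed = {i: d for i, d in enumerate(docs)}
    vecs = _tfidf_vectors(keyed)
    ia = next(i for i, d in keyed.items() if d is doc_a)
    ib = next(i for i, d in keyed.items() if d is doc_b)
    return _cosine(vecs[ia], vecs[ib])


# --------------------------------------------------------------------------
# topic reduction

@dataclass
class MergeStep:
    absorbed: str
    absorbing: str
    similarity: float
    n_topics_after: int
    mean_pairwise_similarity: float


@dataclass
class MergeTrace:
    """Record of an iterative topic reduction (one entry per merge)."""

    steps: list[MergeStep] = field(default_factory=list)

    def merge_map(self) -> dict[str, str]:
        """Final old-topic -> surviving-topic mapping (paths compressed)."""
        parent: dict[str, str] = {}
        for s in self.steps:
            parent[s.absorbed] = s.absorbing
        def root(t: str) -> str:
            while t in parent:
                t = parent[t]
            return t
        return {t: root(t) for t in parent}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.n_topics_after, s.mean_pairwise_similarity, s.absorbed,
                 s.absorbing, s.similarity)
                for s in self.steps
            ],
            columns=[
                "n_topics", "mean_pairwise_similarity", "absorbed",
                "absorbing", "merge_similarity",
            ],
        )


def _mean_pairwise_similarity(vecs: Mapping[str, Mapping[str, float]]) -> float:
    topics = sorted(vecs)
    if len(topics) < 2:
        return float("nan")
    sims = [
        _cosine(vecs[a], vecs[b])
        for i, a in enumerate(topics)
        for b in topics[i + 1 :]
    ]
    return float(np.mean(sims))


def apply_merge_map(
    assignments: Mapping[str, TopicAssignment], merge_map: Mapping[str, str]
) -> dict[str, TopicAssignment]:
    """Replay a merge map onto (hard or soft) assignments, summing masses."""
    out: dict[str, TopicAssignment] = {}
    for tweet_id, a in assignments.items():
        dist: dict[str, float] = {}
        for topic, p in a.dist.items():
            target = merge_map.get(topic, topic)
            dist[target] = dist.get(target, 0.0) + p
        out[tweet_id] = TopicAssignment(tweet_id=tweet_id, dist=dist)
    return out


def reduce_topics(
    assignments: Mapping[str, TopicAssignment],
    documents: Mapping[str, Counter],
    target_k: int = 100,
) -> tuple[dict[str, TopicAssignment], MergeTrace]:
    """Merge topics until ``target_k`` remain.

    At each step the smallest topic by hard-assigned tweet count is absorbed
    by its most TF-IDF-cosine-similar peer; per-tweet probabilities of the
    merged pair are summed, so each tweet's total mass is conserved exactly.
    TF-IDF vectors are recomputed after every merge so that similarities
    reflect the combined documents.  Ties (smallest size, best similarity)
    go to the lexicographically smallest topic id.
    """
    docs = {t: Counter(c) for t, c in documents.items()}
    if target_k < 1:
        raise ValueError("target_k must be >= 1")
    if target_k > len(docs):
        raise ValueError(
            f"target_k={target_k} exceeds the {len(docs)} live topics"
        )
    sizes: Counter = Counter()
    for a in assignments.values():
        topic = a.hard_topic()
        if topic is not None and topic in docs:
            sizes[topic] += 1
    trace = MergeTrace()
    while len(docs) > target_k:
        smallest = min(docs, key=lambda t: (sizes.get(t, 0), t))
        vecs = _tfidf_vectors(docs)
        others = [t for t in docs if t != smallest]
        sims = {t: _cosine(vecs[smallest], vecs[t]) for t in others}
        best_sim = max(sims.values())
        # deterministic tie-break: among max-similarity topics pick lowest id
        best = min(t for t, s in sims.items() if s == best_sim)
        docs[best] = docs[best] + docs[smallest]
        del docs[smallest]
        sizes[best] = sizes.get(best, 0) + sizes.pop(smallest, 0)
        after_vecs = _tfidf_vectors(docs)
        trace.steps.append(
            MergeStep(
                absorbed=smallest,
                absorbing=best,
                similarity=best_sim,
                n_topics_after=len(docs),
                mean_pairwise_similarity=_mean_pairwise_similarity(after_vecs),
            )
        )
    reduced = apply_merge_map(assignments, trace.merge_map())
    return reduced, trace
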