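"""Structure-preserving null model: shuffle words, keep the skeleton.

To test whether a semantic observation is a property of *which* words sit in
which ring (rather than of the layered structure itself), the null model
keeps every ring's unique-word count and total occurrence count fixed while
randomly permuting which words occupy which (ring, occurrence-count) slot.
A word carries its own topic distribution — the per-topic fraction of its
hard-assigned occurrences — into whatever slot it lands in, and adopts the
slot's occurrence count.  Null ring profiles are then the slot-count-weighted
averages of the resident words' distributions.

The two invariants |W_u'(e,r)| = |W_u(e,r)| and O'(e,r) = O(e,r) hold
exactly (integer equality) for every replicate by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from egowords.ego_structure import EgoNetwork
from egowords.errors import UndefinedProfileError
from egowords.preprocess import OccurrenceStream
from egowords.semantic_profile import entropy, split_into_rings, topic_counts
from egowords.topic_adapter import TopicAssignment


def word_topic_distribution(
    stream: OccurrenceStream,
    assignments: Mapping[str, TopicAssignment],
    topics: Sequence[str],
) -> dict[str, np.ndarray | None]:
    """Per-lemma topic distribution from hard-assigned occurrences.

    For each lemma, the share of its occurrences whose tweet is
    hard-assigned to each topic.  Lemmas whose occurrences all come from
    outlier tweets carry no information and map to None.
    """
    index = {c: k for k, c in enumerate(topics)}
    acc: dict[str, np.ndarray] = {}
    for lemma, tweet_id in stream.occurrences:
        a = assignments.get(tweet_id)
        vec = acc.setdefault(lemma, np.zeros(len(topics)))
        if a is None or a.is_outlier:
            continue
        topic = a.hard_topic()
        vec[index[topic]] += 1
    out: dict[str, np.ndarray | None] = {}
    for lemma, vec in acc.items():
        total = vec.sum()
        out[lemma] = vec / total if total > 0 else None
    return out


@dataclass
class NullEgoNetwork:
    """One shuffled replicate of an ego network.

    ``placement[r]`` lists ``(lemma, slot_count)`` pairs for ring ``r``: the
    words assigned to that ring's occurrence-count slots by the permutation.
    """

    ego_id: str
    placement: dict[int, list[tuple[str, int]]]

    def ring_word_count(self, r: int) -> int:
        return len(self.placement[r])

    def ring_occurrences(self, r: int) -> int:
        return sum(count for _, count in self.placement[r])


def shuffle_ego(
    ego: EgoNetwork,
    stream: OccurrenceStream,
    word_dists: Mapping[str, np.ndarray | None],
    rng: np.random.Generator,
) -> NullEgoNetwork:
    """Assign the ego's words to the fixed (ring, count) slots at random.

    The multiset of occurrence-count slots per ring is taken from the real
    ego network; a uniform random permutation places words into slots (this
    single-pass formulation is equivalent to the pairwise-swap view of the
    shuffle).  A word placed in a slot adopts the slot's count.  Words with
    no usable topic distribution (all occurrences in outlier tweets) are
    excluded from shuffling along with their slots, keeping the null ring
    profiles well defined.
    """
    counts = stream.lemma_counts()
    rings = split_into_rings(ego, stream)
    slots: list[tuple[int, int]] = []  # (ring, occurrence count)
    words: list[str] = []
    for r in sorted(rings):
        for lemma, n in sorted(rings[r].word_counts().items()):
            if word_dists.get(lemma) is None:
                continue
            slots.append((r, n))
            words.append(lemma)
    if len(words) < 2:
        raise ValueError(f"ego {ego.ego_id}: need >= 2 distributed words to shuffle")
    perm = rng.permutation(len(words))
    placement: dict[int, list[tuple[str, int]]] = {r: [] for r in sorted(rings)}
    for slot_idx, word_idx in enumerate(perm):
        r, n = slots[slot_idx]
        placement[r].append((words[word_idx], n))
    return NullEgoNetwork(ego_id=ego.ego_id, placement=placement)


def null_ring_profile(
    null_ego: NullEgoNetwork,
    ring: int,
    word_dists: Mapping[str, np.ndarray | None],
) -> np.ndarray:
    """Slot-count-weighted average of resident words' topic distributions."""
    entries = null_ego.placement.get(ring, [])
    num = None
    denom = 0
    for lemma, count in entries:
        dist = word_dists.get(lemma)
        if dist is None:
            continue
        num = dist * count if num is None else num + dist * count
        denom += count
    if num is None or denom == 0:
        raise UndefinedProfileError(
            f"ego {null_ego.ego_id} ring {ring}: no distributed words in null ring"
        )
    return num / denom


def null_descriptors(
    null_ego: NullEgoNetwork,
    word_dists: Mapping[str, np.ndarray | None],
) -> pd.DataFrame:
    """Per-ring N, N_norm, H, O for one shuffled replicate."""
    rows = []
    for r in sorted(null_ego.placement):
        try:
            profile = null_ring_profile(null_ego, r, word_dists)
        except UndefinedProfileError:
            continue
        o = null_ego.ring_occurrences(r)
        n, n_norm = topic_counts(profile, o)
        rows.append((null_ego.ego_id, r, n, n_norm, entropy(profile), o))
    return pd.DataFrame(rows, columns=["ego_id", "ring", "N", "N_norm", "H", "O"])


def null_ensemble(
    egos: Sequence[EgoNetwork],
    streams: Mapping[str, OccurrenceStream],
    assignments: Mapping[str, TopicAssignment],
    topics: Sequence[str],
    reps: int = 10,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Descriptors of ``reps`` shuffled replicates of every ego.

    Returns a long frame (ego_id, rep, ring, N, N_norm, H, O); summarise
    with :func:`egowords.cli_report.aggregate_with_ci` as needed.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    frames = []
    for ego in egos:
        stream = streams[ego.ego_id]
        dists = word_topic_distribution(stream, assignments, topics)
        for rep in range(reps):
            null_ego = shuffle_ego(ego, stream, dists, rng)
            df = null_descriptors(null_ego, dists)
            df.insert(1, "rep", rep)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
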