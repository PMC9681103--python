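"""Ring-wise semantic profiles and their descriptors.

The semantic profile of a ring is the probability distribution over topics
obtained by summing, over every word occurrence in the ring, the topic
distribution of the tweet the occurrence came from, and normalising:

    P_r(c) = sum_{w in W(e,r)} P_{m(w)}(c) / sum_{c'} sum_w P_{m(w)}(c')

Profiles are compared and characterised with:

* ``N``: the number of topics with positive share, and ``N_norm = N / O``,
  topics per word occurrence in the ring;
* Shannon entropy in nats (natural log), so a uniform profile over 100
  topics has H = ln 100 ≈ 4.60 and a point mass has H = 0;
* the Jensen–Shannon *distance* (square root of the JS divergence, natural
  log), bounded by sqrt(ln 2) ≈ 0.833.

Analyses are carried out on rings, not cumulative layers, to avoid counting
the inner topics twice.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from egowords.ego_structure import EgoNetwork
from egowords.errors import UndefinedProfileError
from egowords.preprocess import OccurrenceStream
from egowords.topic_adapter import TopicAssignment

#: JS distance upper bound: sqrt(ln 2)
JS_MAX = float(np.sqrt(np.log(2.0)))


@dataclass
class RingOccurrences:
    """The word occurrences of one ring of one ego network."""

    ego_id: str
    ring: int
    occurrences: list[tuple[str, str]]  # (lemma, tweet_id)

    @property
    def O(self) -> int:
        """Total occurrence count in the ring."""
        return len(self.occurrences)

    def word_counts(self) -> Counter:
        return Counter(lemma for lemma, _ in self.occurrences)


def split_into_rings(
    ego: EgoNetwork, stream: OccurrenceStream
) -> dict[int, RingOccurrences]:
    """Partition an ego's occurrence stream by the ring of each lemma."""
    ring_of = ego.ring_index()
    per_ring: dict[int, list[tuple[str, str]]] = {i: [] for i in range(1, ego.tau + 1)}
    for lemma, tweet_id in stream.occurrences:
        per_ring[ring_of[lemma]].append((lemma, tweet_id))
    return {
        i: RingOccurrences(ego_id=ego.ego_id, ring=i, occurrences=occ)
        for i, occ in per_ring.items()
    }


# --------------------------------------------------------------------------
# profiles

def ring_profile(
    ring: RingOccurrences,
    assignments: Mapping[str, TopicAssignment],
    topics: Sequence[str],
) -> np.ndarray:
    """Topic distribution of a ring from its occurrences' tweet assignments.

    Occurrences from outlier tweets (empty distributions) carry no topic
    information and drop out of both numerator and denominator.  Raises
    ``UndefinedProfileError`` when no occurrence carries any mass.
    """
    index = {c: k for k, c in enumerate(topics)}
    acc = np.zeros(len(topics))
    for _, tweet_id in ring.occurrences:
        a = assignments.get(tweet_id)
        if a is None or a.is_outlier:
            continue
        for c, p in a.dist.items():
            acc[index[c]] += p
    total = acc.sum()
    if total <= 0:
        raise UndefinedProfileError(
            f"ego {ring.ego_id} ring {ring.ring}: no topic mass "
            "(all occurrences from outlier tweets)"
        )
    return acc / total


def counted_occurrences(
    ring: RingOccurrences,
    assignments: Mapping[str, TopicAssignment],
    include_outliers: bool = False,
) -> int:
    """Occurrences entering the denominator of N_norm.

    By default occurrences from outlier tweets are excluded, consistent with
    their exclusion from the profile itself; set ``include_outliers`` to
    count every occurrence instead.
    """
    if include_outliers:
        return ring.O
    return sum(
        1
        for _, tweet_id in ring.occurrences
        if (a := assignments.get(tweet_id)) is not None and not a.is_outlier
    )


def topic_counts(profile: np.ndarray, n_occurrences: int) -> tuple[int, float]:
    """``N`` (topics with positive share) and ``N_norm = N / O``."""
    if n_occurrences <= 0:
        raise UndefinedProfileError("N_norm undefined for a ring with O = 0")
    n = int(np.count_nonzero(np.asarray(profile) > 0))
    return n, n / n_occurrences


def entropy(profile: np.ndarray) -> float:
    """Shannon entropy in nats; 0·log 0 contributes 0."""
    p = np.asarray(profile, dtype=float)
    pos = p[p > 0]
    return float(-(pos * np.log(pos)).sum()) + 0.0  # avoid -0.0


# --------------------------------------------------------------------------
# distances

def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL divergence with natural log; terms with p(c)=0 contribute 0."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    mask = p > 0
    return float((p[mask] * np.log(p[mask] / q[mask])).sum())


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    m = (np.asarray(p, dtype=float) + np.asarray(q, dtype=float)) / 2.0
    return (kl_divergence(p, m) + kl_divergence(q, m)) / 2.0


def js_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen–Shannon distance: sqrt of the JS divergence (natural log).

    Symmetric, zero iff the profiles coincide, bounded by sqrt(ln 2) ≈ 0.833.
    """
    return float(np.sqrt(max(js_divergence(p, q), 0.0)))


def distance_matrix(profiles: Mapping[int, np.ndarray]) -> pd.DataFrame:
    """Symmetric ring-by-ring JS distance matrix for one ego.

    ``profiles`` maps ring index to profile; rings with a missing profile
    get NaN rows/columns (excluded from cross-ego averages).
    """
    rings = sorted(profiles)
    if len(rings) < 2:
        raise ValueError("distance matrix needs at least 2 ring profiles")
    mat = pd.DataFrame(0.0, index=rings, columns=rings)
    for i, ri in enumerate(rings):
        for rj in rings[i + 1 :]:
            d = js_distance(profiles[ri], profiles[rj])
            mat.loc[ri, rj] = d
            mat.loc[rj, ri] = d
    return mat


def average_distance_matrices(matrices: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Cell-wise mean over egos; missing (NaN) cells are excluded per cell."""
    mats = list(matrices)
    if not mats:
        raise ValueError("no distance matrices to average")
    stacked = np.stack([m.to_numpy(dtype=float) for m in mats])
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(stacked, axis=0)
    return pd.DataFrame(avg, index=mats[0].index, columns=mats[0].columns)


# --------------------------------------------------------------------------
# convenience: all descriptors per ego

def ring_descriptors(
    ego: EgoNetwork,
    stream: OccurrenceStream,
    assignments: Mapping[str, TopicAssignment],
    topics: Sequence[str],
    include_outliers_in_norm: bool = False,
) -> pd.DataFrame:
    """Per-ring profile descriptors for one ego: N, N_norm, H, O.

    Rings whose profile is undefined (all-outlier occurrences) are skipped.
    """
    rows = []
    for i, ring in split_into_rings(ego, stream).items():
        try:
            profile = ring_profile(ring, assignments, topics)
        except UndefinedProfileError:
            continue
        o = counted_occurrences(ring, assignments, include_outliers_in_norm)
        n, n_norm = topic_counts(profile, o)
        rows.append((ego.ego_id, i, n, n_norm, entropy(profile), o))
    return pd.DataFrame(
        rows, columns=["ego_id", "ring", "N", "N_norm", "H", "O"]
    )


def ego_profiles(
    ego: EgoNetwork,
    stream: OccurrenceStream,
    assignments: Mapping[str, TopicAssignment],
    topics: Sequence[str],
) -> dict[int, np.ndarray]:
    """All defined ring profiles of one ego."""
    out: dict[int, np.ndarray] = {}
    for i, ring in split_into_rings(ego, stream).items():
        try:
            out[i] = ring_profile(ring, assignments, topics)
        except UndefinedProfileError:
            continue
    return out


def whole_network_profile(
    ego: EgoNetwork,
    stream: OccurrenceStream,
    assignments: Mapping[str, TopicAssignment],
    topics: Sequence[str],
) -> np.ndarray:
    """Occurrence-weighted profile of the full ego network (union of rings)."""
    whole = RingOccurrences(
        ego_id=ego.ego_id, ring=0, occurrences=list(stream.occurrences)
    )
    return ring_profile(whole, assignments, topics)
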