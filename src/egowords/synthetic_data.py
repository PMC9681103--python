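"""Synthetic corpora with known structural and semantic ground truth.

The generator emulates the features of per-user Twitter timelines that the
pipeline depends on, with every generating parameter recorded:

* **Structure** — each ego's vocabulary is drawn ring by ring: ring sizes
  follow a geometric profile (the innermost ring is ``innermost_shrink``
  times smaller than ring 2; sizes roughly double outwards), and log
  frequencies come from Gaussian components with strictly decreasing means.
  The innermost component sits further from ring 2 than the regular spacing
  (``inner_gap_factor``), mirroring the sparsity of the very top of a
  Zipf-like frequency table.
* **Semantics** — topic generation is word-anchored: every word owns a topic
  distribution.  Ring-1 words share a steeply concentrated distribution over
  a small set of *fingerprint* topics (plus a small uniform diversity floor:
  the most-used words touch many topics).  Outer-ring words are point masses
  on a "home" topic drawn from the ego's interest mix: the fingerprint
  topics with a flatter emphasis, plus a per-ego *active background* set of
  mid-weight topics.  Each occurrence samples a topic from its word's
  distribution; occurrences with the same sampled topic are packed into
  topic-pure tweets, so per-tweet hard assignments are exact ground truth.
* **Noise hooks** — hapax words (single occurrence, removed by the
  preprocessing filter) and functional words are injected so the cleaning
  stages have something to do.

Identical config + seed yields byte-identical corpora.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from egowords.errors import ConfigError
from egowords.preprocess import DAYS_PER_YEAR, Timeline, Tweet
from egowords.topic_adapter import TopicAssignment


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters of a synthetic study corpus."""

    n_egos: int = 20
    tau_star: int = 6                  # true number of frequency layers
    ring2_size: int = 15               # unique words in ring 2
    growth_ratio: float = 2.0          # ring size ratio outwards from ring 2
    innermost_shrink: float = 5.0      # ring2 size / ring1 size
    log_freq_outer_mean: float = 2.5   # ln(uses/yr) of the outermost component
    log_freq_sep: float = 1.0          # spacing of component means (ln units)
    inner_gap_factor: float = 1.0      # ring1-ring2 spacing, in units of sep
    log_freq_sd: float = 0.2           # component sd (ln units)
    inner_sd_factor: float = 0.5       # ring-1 component sd, relative
    n_topics: int = 50
    n_fingerprint: int = 5
    ring1_decay: float = 0.4           # fingerprint weight decay in ring-1 words
    fingerprint_decay: float = 0.9     # fingerprint decay in the home-topic mix
    ring1_diversity: float = 0.12      # uniform mass spread by ring-1 words
    fingerprint_mass: float = 0.45     # P(home topic is a fingerprint topic)
    n_active_background: int = 15      # per-ego active background topics
    active_decay: float = 0.85         # geometric decay of active weights
    tweet_len_mean: float = 8.0        # Poisson mean tokens per tweet
    hapax_rate: float = 0.05           # hapax words per core vocabulary word
    stopword_frac: float = 0.15        # injected functional tokens per token
    T: float = 1.0                     # observation window in years
    end_date: str = "2026-01-01T00:00:00"

    def ring_sizes(self) -> list[int]:
        sizes = [max(1, round(self.ring2_size / self.innermost_shrink))]
        for i in range(self.tau_star - 1):
            sizes.append(round(self.ring2_size * self.growth_ratio**i))
        return sizes

    def component_means(self) -> list[float]:
        means = [0.0] * self.tau_star
        for i in range(1, self.tau_star):
            means[i] = self.log_freq_outer_mean + self.log_freq_sep * (
                self.tau_star - 1 - i
            )
        means[0] = means[1] + self.log_freq_sep * self.inner_gap_factor
        return means

    def validate(self) -> None:
        if self.n_egos < 1 or self.tau_star < 2 or self.n_topics < 2:
            raise ConfigError("n_egos, tau_star and n_topics must be positive")
        if self.n_fingerprint + self.n_active_background > self.n_topics:
            raise ConfigError(
                f"{self.n_topics} topics cannot host {self.n_fingerprint} "
                f"fingerprint plus {self.n_active_background} active topics"
            )
        if not 0 < self.fingerprint_mass < 1:
            raise ConfigError("fingerprint_mass must be in (0, 1)")
        means = self.component_means()
        if means != sorted(means, reverse=True):
            raise ConfigError("component means must be strictly decreasing")

    @property
    def separation_over_sd(self) -> float:
        """Component separation in units of the component sd."""
        return self.log_freq_sep / self.log_freq_sd

    def topic_ids(self) -> list[str]:
        return [f"t{k:03d}" for k in range(self.n_topics)]

    def fingerprint_topics(self) -> list[str]:
        return self.topic_ids()[: self.n_fingerprint]


@dataclass
class GroundTruth:
    """What the generator actually did for one ego."""

    ego_id: str
    ring_of_lemma: dict[str, int]
    topic_of_tweet: dict[str, str]
    fingerprint_topics: list[str]
    word_distributions: dict[str, np.ndarray] = field(default_factory=dict)


_STOPTOKENS = ("the", "and", "of", "to", "a", "in", "is", "it", "for", "with")


def _geometric(n: int, decay: float) -> np.ndarray:
    w = decay ** np.arange(n)
    return w / w.sum()


def _ego_topic_model(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One ego's (ring-1 word distribution, home-topic weights).

    Ring-1 words share a steep distribution over the fingerprint topics plus
    a uniform diversity floor.  Outer-ring words draw a single home topic
    from the ego's interest mix: fingerprint topics with flatter weights,
    and a per-ego random set of active background topics with mildly
    decaying weights.
    """
    k = config.n_topics
    nf = config.n_fingerprint
    ring1 = np.zeros(k)
    ring1[:nf] = (1.0 - config.ring1_diversity) * _geometric(
        nf, config.ring1_decay
    )
    ring1 += config.ring1_diversity / k
    home_weights = np.zeros(k)
    home_weights[:nf] = config.fingerprint_mass * _geometric(
        nf, config.fingerprint_decay
    )
    actives = nf + rng.permutation(k - nf)[: config.n_active_background]
    home_weights[actives] = (1.0 - config.fingerprint_mass) * _geometric(
        config.n_active_background, config.active_decay
    )
    return ring1, home_weights


def generate_vocabulary(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[dict[str, int], dict[str, int], dict[str, np.ndarray]]:
    """One ego's core vocabulary: (ring per lemma, occurrence counts,
    per-word topic distributions).

    Occurrence counts are log-normal draws from the per-ring components,
    floored at 2 (hapax are added separately).  This is the structural part
    of the generator; :func:`generate_ego` wraps it with tweets and topics.
    """
    config.validate()
    sizes = config.ring_sizes()
    means = config.component_means()
    ring1_dist, home_weights = _ego_topic_model(config, rng)
    ring_of: dict[str, int] = {}
    counts: dict[str, int] = {}
    dists: dict[str, np.ndarray] = {}
    w = 0
    for ring_idx, (size, mu) in enumerate(zip(sizes, means), start=1):
        sd = config.log_freq_sd * (
            config.inner_sd_factor if ring_idx == 1 else 1.0
        )
        for _ in range(size):
            lemma = f"w{w:04d}"
            w += 1
            logf = rng.normal(mu, sd)
            counts[lemma] = max(2, int(round(np.exp(logf))))
            ring_of[lemma] = ring_idx
            if ring_idx == 1:
                dists[lemma] = ring1_dist
            else:
                home = int(rng.choice(config.n_topics, p=home_weights))
                dist = np.zeros(config.n_topics)
                dist[home] = 1.0
                dists[lemma] = dist
    return ring_of, counts, dists


def generate_ego(
    config: SyntheticConfig, seed: int | np.random.Generator, ego_id: str = "ego0"
) -> tuple[Timeline, dict[str, TopicAssignment], GroundTruth]:
    """Generate one ego's timeline, hard topic assignments and ground truth."""
    config.validate()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    topics = config.topic_ids()
    ring_of, counts, dists = generate_vocabulary(config, rng)
    n_hapax = round(len(counts) * config.hapax_rate)
    hapax = []
    for j in range(n_hapax):
        lemma = f"h{j:04d}"
        counts[lemma] = 1
        dists[lemma] = np.full(config.n_topics, 1.0 / config.n_topics)
        hapax.append(lemma)

    # every occurrence samples a topic from its word's distribution
    occ_lemmas: list[str] = []
    occ_topics: list[int] = []
    for lemma in counts:
        n = counts[lemma]
        draws = rng.choice(config.n_topics, size=n, p=dists[lemma])
        occ_lemmas.extend([lemma] * n)
        occ_topics.extend(draws.tolist())
    occ_lemmas_arr = np.array(occ_lemmas)
    occ_topics_arr = np.array(occ_topics)

    # pack same-topic occurrences into topic-pure tweets
    tweets: list[Tweet] = []
    assignments: dict[str, TopicAssignment] = {}
    topic_of_tweet: dict[str, str] = {}
    end = datetime.fromisoformat(config.end_date)
    window = timedelta(days=config.T * DAYS_PER_YEAR)
    tweet_no = 0
    tweet_tokens: list[tuple[str, list[str]]] = []
    for topic_idx in range(config.n_topics):
        members = occ_lemmas_arr[occ_topics_arr == topic_idx]
        if members.size == 0:
            continue
        members = members[rng.permutation(members.size)]
        pos = 0
        while pos < members.size:
            length = max(1, int(rng.poisson(config.tweet_len_mean)))
            chunk = members[pos : pos + length].tolist()
            pos += length
            tweet_id = f"{ego_id}-m{tweet_no:05d}"
            tweet_no += 1
            n_stop = int(rng.binomial(len(chunk), config.stopword_frac))
            stops = rng.choice(len(_STOPTOKENS), size=n_stop)
            tokens = chunk + [_STOPTOKENS[s] for s in stops]
            tokens = [tokens[i] for i in rng.permutation(len(tokens))]
            tweet_tokens.append((tweet_id, tokens))
            topic_of_tweet[tweet_id] = topics[topic_idx]
            assignments[tweet_id] = TopicAssignment(
                tweet_id=tweet_id, dist={topics[topic_idx]: 1.0}
            )
    # timestamps: uniform over the window, first and last pinned to its ends
    n_tweets = len(tweet_tokens)
    offsets = rng.uniform(0.0, 1.0, size=n_tweets)
    if n_tweets >= 2:
        offsets[0], offsets[-1] = 0.0, 1.0
    order = rng.permutation(n_tweets)
    for (tweet_id, tokens), frac in zip(tweet_tokens, offsets[order]):
        tweets.append(
            Tweet(
                tweet_id=tweet_id,
                ego_id=ego_id,
                timestamp=end - window + frac * window,
                tokens=tuple(tokens),
            )
        )
    # ensure full span regardless of permutation
    if n_tweets >= 2:
        span = max(t.timestamp for t in tweets) - min(t.timestamp for t in tweets)
        if span < window:
            first = tweets[0]
            tweets[0] = Tweet(
                tweet_id=first.tweet_id, ego_id=ego_id,
                timestamp=end - window, tokens=first.tokens,
            )
            last = tweets[-1]
            tweets[-1] = Tweet(
                tweet_id=last.tweet_id, ego_id=ego_id,
                timestamp=end, tokens=last.tokens,
            )
    tweets.sort(key=lambda t: t.timestamp)
    timeline = Timeline(ego_id=ego_id, tweets=tweets, window_T=config.T)
    truth = GroundTruth(
        ego_id=ego_id,
        ring_of_lemma=ring_of,
        topic_of_tweet=topic_of_tweet,
        fingerprint_topics=config.fingerprint_topics(),
        word_distributions={w_: d for w_, d in dists.items() if w_ not in hapax},
    )
    return timeline, assignments, truth


def generate_study(
    config: SyntheticConfig, seed: int
) -> Iterator[tuple[Timeline, dict[str, TopicAssignment], GroundTruth]]:
    """Yield ``n_egos`` independent egos, reproducibly from one seed."""
    rng = np.random.default_rng(seed)
    for i in range(config.n_egos):
        yield generate_ego(config, rng, ego_id=f"ego{i:03d}")


def generate_corpus(config: SyntheticConfig, out_dir: str | Path, seed: int) -> dict:
    """Write a corpus to disk in the pipeline's own input formats.

    Emits ``timelines.jsonl`` (pre-tokenized tweets), ``assignments.tsv``
    (hard per-tweet topics), ``truth_rings.tsv`` (lemma -> true ring) and
    ``truth_meta.json``.  Returns a manifest of record counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_tweets = 0
    assign_rows = []
    ring_rows = []
    with open(out / "timelines.jsonl", "w", encoding="utf-8") as fh:
        for timeline, assignments, truth in generate_study(config, seed):
            for t in timeline.tweets:
                rec = {
                    "ego_id": t.ego_id,
                    "tweet_id": t.tweet_id,
                    "timestamp": t.timestamp.isoformat(),
                    "tokens": list(t.tokens or ()),
                }
                fh.write(json.dumps(rec) + "\n")
                n_tweets += 1
            for tweet_id, a in sorted(assignments.items()):
                topic = a.hard_topic()
                assign_rows.append((tweet_id, topic, 1.0))
            for lemma, ring in sorted(truth.ring_of_lemma.items()):
                ring_rows.append((truth.ego_id, lemma, ring))
    pd.DataFrame(assign_rows, columns=["tweet_id", "topic_id", "prob"]).to_csv(
        out / "assignments.tsv", sep="\t", index=False
    )
    pd.DataFrame(ring_rows, columns=["ego_id", "lemma", "ring"]).to_csv(
        out / "truth_rings.tsv", sep="\t", index=False
    )
    meta = {
        "config": asdict(config),
        "seed": seed,
        "fingerprint_topics": config.fingerprint_topics(),
        "n_tweets": n_tweets,
    }
    with open(out / "truth_meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return {
        "n_egos": config.n_egos,
        "n_tweets": n_tweets,
        "n_assignment_rows": len(assign_rows),
        "n_ring_rows": len(ring_rows),
    }
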