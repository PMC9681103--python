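"""The ego network of words: frequency layers and structural statistics.

Each user's lemma frequencies (uses per year over the observation window) are
grouped by mode-seeking clustering of their natural-log values — mean shift
with a Gaussian kernel, run directly in one dimension.  The resulting
clusters, ranked by decreasing mean frequency, are the *rings* of the ego
network; *layer* ``i`` is the cumulative union of rings 1..i, and the scaling
ratio ``rho_i = |L_i| / |L_{i-1}|`` measures the relative growth of
consecutive layers.  ``tau`` is the number of clusters the mode-seeking finds
for an ego — typically 5–7 on long-tailed vocabularies.

Structural summaries aggregate over egos sharing the same ``tau``: mean layer
sizes and scaling ratios with 95% confidence intervals, the ``tau``
histogram, and OLS regressions of each layer's size on the size of the
outermost layer (whose self-slope is identically 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from egowords.errors import ConfigError, UndefinedRegressionError
from egowords.preprocess import OccurrenceStream

#: Gaussian kernel bandwidth on natural-log frequencies.  0.2 resolves
#: frequency modes whose means differ by a factor of ~e^0.8 ≈ 2.2 or more,
#: matching the 2–3x scaling observed between consecutive layers; being a
#: fixed width in log units it is invariant under rescaling all frequencies.
DEFAULT_BANDWIDTH = 0.2


@dataclass
class FrequencyTable:
    """Per-ego lemma occurrence counts and yearly usage frequencies."""

    ego_id: str
    counts: dict[str, int]
    T: float

    def frequency(self, lemma: str) -> float:
        return self.counts[lemma] / self.T

    def lemmas(self) -> list[str]:
        return list(self.counts)

    def frequencies(self) -> np.ndarray:
        return np.array([n / self.T for n in self.counts.values()], dtype=float)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class EgoNetwork:
    """Frequency-ranked clusters of one ego's vocabulary.

    ``clusters[0]`` (ring 1) holds the most frequently used lemmas.  Rings
    partition the vocabulary; layers are their cumulative unions.
    """

    ego_id: str
    clusters: list[frozenset[str]]
    table: FrequencyTable

    @property
    def tau(self) -> int:
        return len(self.clusters)

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(self.table.counts)

    def ring(self, i: int) -> frozenset[str]:
        """Ring ``i`` (1-based): cluster ``i`` alone."""
        return self.clusters[i - 1]

    def layer(self, i: int) -> frozenset[str]:
        """Layer ``i`` (1-based): union of clusters 1..i."""
        out: set[str] = set()
        for c in self.clusters[:i]:
            out |= c
        return frozenset(out)

    def layer_sizes(self) -> np.ndarray:
        sizes = np.cumsum([len(c) for c in self.clusters])
        return sizes.astype(int)

    def rho(self, i: int) -> float:
        """Scaling ratio |layer i| / |layer i-1|, defined for i >= 2."""
        if i < 2 or i > self.tau:
            raise ValueError(f"rho is defined for 2 <= i <= tau, got {i}")
        sizes = self.layer_sizes()
        return sizes[i - 1] / sizes[i - 2]

    def scaling_ratios(self) -> np.ndarray:
        sizes = self.layer_sizes().astype(float)
        return sizes[1:] / sizes[:-1]

    def ring_index(self) -> dict[str, int]:
        """Lemma -> 1-based ring index."""
        return {w: i + 1 for i, c in enumerate(self.clusters) for w in c}


# --------------------------------------------------------------------------
# frequency table

def compute_frequency_table(stream: OccurrenceStream, T: float) -> FrequencyTable:
    """Count occurrences per lemma and convert to uses per year (f = n / T)."""
    if T <= 0:
        raise ConfigError(f"observation window T must be positive, got {T}")
    counts = dict(stream.lemma_counts())
    return FrequencyTable(ego_id=stream.ego_id, counts=counts, T=float(T))


# --------------------------------------------------------------------------
# 1-D Gaussian mean shift

def _mean_shift_modes(
    x: np.ndarray, bandwidth: float, max_iter: int = 500, tol: float = 1e-8
) -> np.ndarray:
    """Shift every point uphill to a mode of the Gaussian KDE of ``x``.

    Returns the converged position of each point.  Vectorised over points;
    1-D only.
    """
    pts = x.astype(float).copy()
    for _ in range(max_iter):
        w = np.exp(-0.5 * ((pts[:, None] - x[None, :]) / bandwidth) ** 2)
        shifted = (w @ x) / w.sum(axis=1)
        if np.max(np.abs(shifted - pts)) < tol:
            return shifted
        pts = shifted
    return pts


def cluster_log_frequencies(
    freqs: Sequence[float] | np.ndarray,
    bandwidth: float | None = None,
    max_iter: int = 500,
) -> tuple[np.ndarray, int]:
    """Cluster frequencies by Gaussian mean shift on their natural logs.

    Returns ``(labels, tau)`` where labels are 0-based cluster indices
    relabelled so that cluster 0 holds the highest frequencies (cluster
    rank order equals frequency order; clusters never interleave, a property
    of 1-D mode seeking).  All-identical inputs yield a single cluster.

    Parameters
    ----------
    freqs : positive frequencies (uses per year).
    bandwidth : Gaussian kernel width on the log scale; default
        ``DEFAULT_BANDWIDTH``.
    """
    f = np.asarray(freqs, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise ValueError("freqs must be a non-empty 1-D array")
    if np.any(f <= 0):
        raise ValueError("frequencies must be strictly positive")
    h = DEFAULT_BANDWIDTH if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ConfigError(f"bandwidth must be positive, got {h}")
    x = np.log(f)
    if np.unique(x).size == 1:
        return np.zeros(f.size, dtype=int), 1
    modes = _mean_shift_modes(x, h, max_iter=max_iter)
    # group converged positions: gaps above h/2 separate distinct modes
    order = np.argsort(modes, kind="stable")
    sorted_modes = modes[order]
    breaks = np.where(np.diff(sorted_modes) > h / 2)[0]
    group_of_sorted = np.zeros(f.size, dtype=int)
    for b in breaks:
        group_of_sorted[b + 1 :] += 1
    groups = np.empty(f.size, dtype=int)
    groups[order] = group_of_sorted
    n_groups = group_of_sorted[-1] + 1 if f.size else 0
    # rank clusters by descending mean log frequency -> cluster 0 = most used
    means = np.array([x[groups == g].mean() for g in range(n_groups)])
    rank_of_group = np.empty(n_groups, dtype=int)
    rank_of_group[np.argsort(-means, kind="stable")] = np.arange(n_groups)
    labels = rank_of_group[groups]
    return labels, int(n_groups)


# --------------------------------------------------------------------------
# building the network

def build_ego_network(
    table: FrequencyTable, labels: Sequence[int] | np.ndarray
) -> EgoNetwork:
    """Assemble an ego network from a frequency table and cluster labels.

    ``labels[i]`` is the cluster of ``table.lemmas()[i]``.  Clusters are
    ranked by descending mean frequency; exact ties are broken by giving the
    lower rank to the cluster containing the lexicographically smallest
    lemma, so the construction is deterministic.
    """
    lemmas = table.lemmas()
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (len(lemmas),):
        raise ValueError("labels must cover every lemma exactly once")
    members: dict[int, list[str]] = {}
    for lemma, lab in zip(lemmas, labels):
        members.setdefault(int(lab), []).append(lemma)
    def sort_key(lab: int) -> tuple[float, str]:
        ws = members[lab]
        mean_f = float(np.mean([table.counts[w] for w in ws])) / table.T
        return (-mean_f, min(ws))
    ordered = sorted(members, key=sort_key)
    clusters = [frozenset(members[lab]) for lab in ordered]
    return EgoNetwork(ego_id=table.ego_id, clusters=clusters, table=table)


def ego_network_from_stream(
    stream: OccurrenceStream,
    T: float,
    bandwidth: float | None = None,
) -> EgoNetwork:
    """Convenience: frequency table -> clustering -> ego network."""
    table = compute_frequency_table(stream, T)
    labels, _ = cluster_log_frequencies(table.frequencies(), bandwidth=bandwidth)
    return build_ego_network(table, labels)


# --------------------------------------------------------------------------
# structural statistics

def mean_ci95(values: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Mean and 95% normal-approximation CI half-width (1.96 * SE).

    With a single value the half-width is NaN (undefined), the mean is still
    reported.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mean_ci95 requires at least one value")
    mean = float(v.mean())
    if v.size == 1:
        return mean, float("nan")
    half = 1.96 * v.std(ddof=1) / math.sqrt(v.size)
    return mean, float(half)


def regress_layer_sizes(egos: Sequence[EgoNetwork]) -> np.ndarray:
    """OLS slope of each layer's size on the outermost layer's size.

    All egos must share the same ``tau``; at least 3 are required.  The
    regression includes an intercept; only slopes are returned.  The slope
    for the outermost layer on itself is exactly 1.
    """
    if len(egos) < 3:
        raise ValueError("need at least 3 egos for a layer-size regression")
    taus = {e.tau for e in egos}
    if len(taus) != 1:
        raise ValueError(f"egos must share the same tau, got {sorted(taus)}")
    tau = taus.pop()
    sizes = np.array([e.layer_sizes() for e in egos], dtype=float)
    outer = sizes[:, -1]
    if np.allclose(outer.std(), 0.0):
        raise UndefinedRegressionError(
            "outermost layer size has zero variance across egos"
        )
    slopes = np.empty(tau)
    for i in range(tau - 1):
        slopes[i] = stats.linregress(outer, sizes[:, i]).slope
    slopes[tau - 1] = 1.0
    return slopes


@dataclass
class StructuralSummary:
    """Aggregated structure over a set of ego networks."""

    tau_histogram: pd.Series
    #: per tau group: DataFrame with layer index, mean size, ci95, n
    layer_sizes: dict[int, pd.DataFrame] = field(default_factory=dict)
    #: per tau group: DataFrame with layer index (>= 2), mean rho, ci95, n
    scaling_ratios: dict[int, pd.DataFrame] = field(default_factory=dict)
    #: per tau group: regression slope of |L_i| on |L_tau| (NaN if < 3 egos)
    regression_slopes: dict[int, np.ndarray] = field(default_factory=dict)


def summarize_structure(
    egos: Sequence[EgoNetwork], taus: Iterable[int] | None = None
) -> StructuralSummary:
    """Structural statistics per tau group.

    ``taus`` selects which groups to summarise; by default, the modal
    (most frequent) tau values — every tau attaining the maximum count in
    the histogram.
    """
    if not egos:
        raise ValueError("summarize_structure requires a non-empty set of egos")
    tau_counts = pd.Series([e.tau for e in egos]).value_counts().sort_index()
    tau_counts.index.name = "tau"
    tau_counts.name = "n_egos"
    if taus is None:
        peak = tau_counts.max()
        taus = [int(t) for t, n in tau_counts.items() if n == peak]
    summary = StructuralSummary(tau_histogram=tau_counts)
    for tau in taus:
        group = [e for e in egos if e.tau == tau]
        if not group:
            continue
        sizes = np.array([e.layer_sizes() for e in group], dtype=float)
        rows = []
        for i in range(tau):
            mean, half = mean_ci95(sizes[:, i])
            rows.append((i + 1, mean, half, len(group)))
        summary.layer_sizes[tau] = pd.DataFrame(
            rows, columns=["layer", "mean_size", "ci95", "n_egos"]
        )
        if tau >= 2:
            ratios = np.array([e.scaling_ratios() for e in group], dtype=float)
            rows = []
            for i in range(tau - 1):
                mean, half = mean_ci95(ratios[:, i])
                rows.append((i + 2, mean, half, len(group)))
            summary.scaling_ratios[tau] = pd.DataFrame(
                rows, columns=["layer", "mean_rho", "ci95", "n_egos"]
            )
        if len(group) >= 3:
            try:
                summary.regression_slopes[tau] = regress_layer_sizes(group)
            except UndefinedRegressionError:
                summary.regression_slopes[tau] = np.full(tau, np.nan)
    return summary


# --------------------------------------------------------------------------
# I/O

def ego_networks_to_frame(egos: Iterable[EgoNetwork]) -> pd.DataFrame:
    """Long-format table: ego_id, lemma, ring, n, f."""
    rows = []
    for e in egos:
        for ring_idx, cluster in enumerate(e.clusters, start=1):
            for lemma in sorted(cluster):
                n = e.table.counts[lemma]
                rows.append((e.ego_id, lemma, ring_idx, n, n / e.table.T))
    return pd.DataFrame(rows, columns=["ego_id", "lemma", "ring", "n", "f"])
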