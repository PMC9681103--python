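"""Primary topics and their cross-ring pulling power.

Each ring profile is split into *primary* (high-share, ``U_r``) and
non-primary (``L_r``) topics with a two-class Jenks natural-breaks
optimisation of the positive shares: the break minimising the summed
within-class squared deviations.  A silhouette score of the 2-class split is
attached as a quality diagnostic (reported, not gated).

The pulling power of ring ``r_x`` on ring ``r_y`` is then measured by:

* coverage ``K_TOP``: total share of ``U_rx`` topics in ``r_y``'s profile;
* strength ``S_TOP`` / ``S_BOTTOM``: mean share per topic of ``U_rx`` (resp.
  ``L_rx``) in ``r_y``'s profile;
* joint strengths over ``U_rx ∩ U_ry`` and ``U_rx ∩ L_ry``;
* the sigma contrasts: joint strength minus the corresponding within-ring
  baseline (``S_TOP(ry)`` or ``S_BOTTOM(ry)``), with a paired two-sided
  t-test across egos.

Egos for which an intersection set is empty are excluded from that cell's
cross-ego average (the per-topic mean is undefined there); each cell reports
the ego count it was computed on so the exclusion bookkeeping is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score

from egowords.errors import DegenerateSplitError


@dataclass
class PrimarySplit:
    """Primary/non-primary partition of one ring's positive-share topics."""

    ego_id: str
    ring: int
    primary: frozenset[str]
    secondary: frozenset[str]
    silhouette: float


def _best_break(values: np.ndarray) -> int:
    """Index ``b`` splitting sorted ``values`` into [0:b) and [b:) with
    minimal total within-class sum of squared deviations.

    Computed with prefix sums in O(n); equivalent to exhaustive search over
    the possible breaks of a 2-class Jenks optimisation.  Only breaks at a
    strict increase are candidates, so equal shares always land in the same
    class and min(upper) > max(lower) holds.
    """
    n = values.size
    c1 = np.cumsum(values)
    c2 = np.cumsum(values**2)
    b = np.arange(1, n)  # lower class size
    ssd_low = c2[b - 1] - c1[b - 1] ** 2 / b
    sum_hi = c1[-1] - c1[b - 1]
    ssd_hi = (c2[-1] - c2[b - 1]) - sum_hi**2 / (n - b)
    total = ssd_low + ssd_hi
    strict = values[b] > values[b - 1]
    total = np.where(strict, total, np.inf)
    return int(b[np.argmin(total)])


def _silhouette_1d(values: np.ndarray, split: int) -> float:
    """Mean silhouette of the 2-class split of sorted 1-D values."""
    if values.size <= 2:
        # one sample per class: separation is trivially perfect
        return 1.0
    labels = np.zeros(values.size, dtype=int)
    labels[split:] = 1
    return float(silhouette_score(values.reshape(-1, 1), labels))


def jenks_two_split(
    profile: Mapping[str, float] | Sequence[tuple[str, float]],
    ego_id: str = "",
    ring: int = 0,
) -> PrimarySplit:
    """Optimal 2-class natural-breaks split of a profile's positive shares.

    The upper class is the primary-topic set ``U_r``.  By construction the
    smallest primary share strictly exceeds the largest non-primary one.
    All-equal shares admit no natural break and raise
    ``DegenerateSplitError``.
    """
    items = list(profile.items()) if isinstance(profile, Mapping) else list(profile)
    positive = [(c, p) for c, p in items if p > 0]
    if len(positive) < 2:
        raise DegenerateSplitError(
            f"ego {ego_id} ring {ring}: need >= 2 positive shares to split"
        )
    positive.sort(key=lambda cp: (cp[1], cp[0]))
    values = np.array([p for _, p in positive], dtype=float)
    if np.allclose(values, values[0]):
        raise DegenerateSplitError(
            f"ego {ego_id} ring {ring}: all shares equal, no natural break"
        )
    b = _best_break(values)
    lower = frozenset(c for c, _ in positive[:b])
    upper = frozenset(c for c, _ in positive[b:])
    sil = _silhouette_1d(values, b)
    return PrimarySplit(
        ego_id=ego_id, ring=ring, primary=upper, secondary=lower, silhouette=sil
    )


# --------------------------------------------------------------------------
# per-ego set statistics

def coverage(topic_set: frozenset[str] | set[str], profile: Mapping[str, float]) -> float:
    """Cumulative share of the set's topics in a profile (K)."""
    return float(sum(profile.get(c, 0.0) for c in topic_set))


def strength(topic_set: frozenset[str] | set[str], profile: Mapping[str, float]) -> float | None:
    """Mean share per topic of the set in a profile (S); None if empty set."""
    if not topic_set:
        return None
    return coverage(topic_set, profile) / len(topic_set)


# --------------------------------------------------------------------------
# cross-ego pulling power table

def profile_to_mapping(profile: np.ndarray, topics: Sequence[str]) -> dict[str, float]:
    return {c: float(p) for c, p in zip(topics, profile)}


@dataclass
class PullingPowerCell:
    rx: int
    ry: int
    metric: str
    value: float
    n_egos: int
    p_value: float | None = None


def pulling_power_table(
    splits: Mapping[str, Mapping[int, PrimarySplit]],
    profiles: Mapping[str, Mapping[int, Mapping[str, float]]],
) -> pd.DataFrame:
    """All pairwise pulling-power statistics across egos.

    ``splits[ego][ring]`` and ``profiles[ego][ring]`` give each ego's
    per-ring primary split and semantic profile.  For every ordered ring
    pair (rx, ry), rx != ry, the cross-ego means of K_TOP, S_TOP, S_BOTTOM,
    S_TOP(rx,ry), S_TOP(rx),BOTTOM(ry) are computed, along with the sigma
    contrasts and their paired two-sided t-tests (p-value None when fewer
    than 2 egos contribute).

    Returns a long-format frame: rx, ry, metric, value, n_egos, p_value.
    """
    rings = sorted({r for per_ego in splits.values() for r in per_ego})
    cells: list[PullingPowerCell] = []
    for rx in rings:
        for ry in rings:
            if rx == ry:
                continue
            per_metric: dict[str, list[float]] = {
                "K_TOP": [], "S_TOP": [], "S_BOTTOM": [],
                "S_TOP_TOP": [], "S_TOP_BOTTOM": [],
            }
            sigma_tt: list[float] = []   # paired diffs for sigma_TOP(rx,ry)
            sigma_tb: list[float] = []   # paired diffs for sigma_TOP,BOTTOM
            for ego, per_ring in splits.items():
                if rx not in per_ring or ry not in per_ring:
                    continue
                prof_y = profiles[ego].get(ry)
                if prof_y is None:
                    continue
                sx, sy = per_ring[rx], per_ring[ry]
                per_metric["K_TOP"].append(coverage(sx.primary, prof_y))
                s_top = strength(sx.primary, prof_y)
                if s_top is not None:
                    per_metric["S_TOP"].append(s_top)
                s_bottom = strength(sx.secondary, prof_y)
                if s_bottom is not None:
                    per_metric["S_BOTTOM"].append(s_bottom)
                s_tt = strength(sx.primary & sy.primary, prof_y)
                if s_tt is not None:
                    per_metric["S_TOP_TOP"].append(s_tt)
                    base = strength(sy.primary, prof_y)
                    if base is not None:
                        sigma_tt.append(s_tt - base)
                s_tb = strength(sx.primary & sy.secondary, prof_y)
                if s_tb is not None:
                    per_metric["S_TOP_BOTTOM"].append(s_tb)
                    base = strength(sy.secondary, prof_y)
                    if base is not None:
                        sigma_tb.append(s_tb - base)
            for metric, vals in per_metric.items():
                if vals:
                    cells.append(
                        PullingPowerCell(rx, ry, metric, float(np.mean(vals)), len(vals))
                    )
            for metric, diffs in (("SIGMA_TOP_TOP", sigma_tt),
                                  ("SIGMA_TOP_BOTTOM", sigma_tb)):
                if diffs:
                    arr = np.array(diffs)
                    if arr.size >= 2 and arr.std() > 0:
                        p = float(stats.ttest_1samp(arr, 0.0).pvalue)
                    else:
                        p = None
                    cells.append(
                        PullingPowerCell(rx, ry, metric, float(arr.mean()),
                                         arr.size, p)
                    )
    return pd.DataFrame(
        [(c.rx, c.ry, c.metric, c.value, c.n_egos, c.p_value) for c in cells],
        columns=["rx", "ry", "metric", "value", "n_egos", "p_value"],
    )


def splits_to_frame(splits: Mapping[str, Mapping[int, PrimarySplit]]) -> pd.DataFrame:
    """Long-format table of primary splits: ego_id, ring, topic, class, silhouette."""
    rows = []
    for ego, per_ring in splits.items():
        for ring, s in sorted(per_ring.items()):
            for c in sorted(s.primary):
                rows.append((ego, ring, c, "U", s.silhouette))
            for c in sorted(s.secondary):
                rows.append((ego, ring, c, "L", s.silhouette))
    return pd.DataFrame(
        rows, columns=["ego_id", "ring", "topic_id", "class", "silhouette"]
    )
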