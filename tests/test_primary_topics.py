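"""Jenks 2-class splits and cross-ring pulling-power statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egowords.errors import DegenerateSplitError
from egowords.primary_topics import (
    PrimarySplit,
    coverage,
    jenks_two_split,
    pulling_power_table,
    strength,
)


def brute_force_split(shares):
    """Exhaustive 2-class natural-breaks optimum over sorted positive shares."""
    items = sorted(((c, p) for c, p in shares.items() if p > 0),
                   key=lambda cp: (cp[1], cp[0]))
    values = [p for _, p in items]
    best, best_ssd = None, np.inf
    for b in range(1, len(values)):
        if values[b] <= values[b - 1]:
            continue
        lo, hi = np.array(values[:b]), np.array(values[b:])
        ssd = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if ssd < best_ssd:
            best_ssd, best = ssd, b
    return frozenset(c for c, _ in items[best:])


class TestJenksTwoSplit:
    def test_clear_break(self):
        shares = {"a": 0.30, "b": 0.28, "c": 0.02, "d": 0.01, "e": 0.01}
        split = jenks_two_split(shares)
        assert split.primary == {"a", "b"}
        assert split.secondary == {"c", "d", "e"}

    def test_two_topics(self):
        split = jenks_two_split({"a": 0.9, "b": 0.1})
        assert split.primary == {"a"}

    def test_all_equal_is_degenerate(self):
        with pytest.raises(DegenerateSplitError):
            jenks_two_split({"a": 0.25, "b": 0.25, "c": 0.25, "d": 0.25})

    def test_single_positive_share_is_degenerate(self):
        with pytest.raises(DegenerateSplitError):
            jenks_two_split({"a": 1.0, "b": 0.0})

    def test_min_primary_exceeds_max_secondary(self, rng):
        for _ in range(100):
            p = rng.dirichlet(np.ones(12) * 0.4)
            shares = {f"c{k}": float(v) for k, v in enumerate(p)}
            try:
                split = jenks_two_split(shares)
            except DegenerateSplitError:
                continue
            assert min(shares[c] for c in split.primary) > max(
                shares[c] for c in split.secondary
            )

    @given(st.integers(min_value=0, max_value=100_000))
    @settings(max_examples=200, deadline=None)
    def test_equals_exhaustive_search(self, seed):
        gen = np.random.default_rng(seed)
        n = int(gen.integers(2, 21))
        p = gen.dirichlet(np.ones(n) * gen.uniform(0.2, 2.0))
        shares = {f"c{k:02d}": float(v) for k, v in enumerate(p)}
        if np.allclose(p, p[0]):
            return
        split = jenks_two_split(shares)
        assert split.primary == brute_force_split(shares)

    def test_silhouette_high_for_well_separated_classes(self):
        split = jenks_two_split({"a": 0.45, "b": 0.44, "c": 0.06, "d": 0.05})
        assert split.silhouette > 0.8


class TestSetStatistics:
    PROFILE = {"c1": 0.4, "c2": 0.3, "c3": 0.2, "c4": 0.1}

    def test_coverage_of_everything_is_one(self):
        assert coverage(set(self.PROFILE), self.PROFILE) == pytest.approx(1.0)

    def test_coverage_of_disjoint_set_is_zero(self):
        assert coverage({"zz"}, self.PROFILE) == 0.0

    def test_coverage_sums_members(self):
        assert coverage({"c1", "c4"}, self.PROFILE) == pytest.approx(0.5)

    def test_strength_is_mean_share(self):
        assert strength({"c1", "c4"}, self.PROFILE) == pytest.approx(0.25)

    def test_strength_of_singleton_is_its_share(self):
        assert strength({"c2"}, self.PROFILE) == pytest.approx(0.3)

    def test_strength_of_empty_set_is_none(self):
        assert strength(frozenset(), self.PROFILE) is None

    def test_strength_times_size_equals_coverage(self, rng):
        topics = list(self.PROFILE)
        for _ in range(50):
            k = int(rng.integers(1, 5))
            subset = frozenset(rng.choice(topics, size=k, replace=False))
            assert strength(subset, self.PROFILE) * len(subset) == pytest.approx(
                coverage(subset, self.PROFILE), abs=1e-12
            )


def make_split(ego, ring, primary, secondary):
    return PrimarySplit(ego, ring, frozenset(primary), frozenset(secondary), 1.0)


class TestPullingPowerTable:
    def test_hand_built_four_topic_ego(self):
        profiles = {
            "e1": {
                1: {"c1": 0.6, "c2": 0.3, "c3": 0.08, "c4": 0.02},
                2: {"c1": 0.35, "c2": 0.15, "c3": 0.4, "c4": 0.1},
            }
        }
        splits = {
            "e1": {
                1: make_split("e1", 1, {"c1", "c2"}, {"c3", "c4"}),
                2: make_split("e1", 2, {"c1", "c3"}, {"c2", "c4"}),
            }
        }
        table = pulling_power_table(splits, profiles)
        def cell(rx, ry, metric):
            row = table[(table.rx == rx) & (table.ry == ry) & (table.metric == metric)]
            return float(row.value.iloc[0])

        # Coverage/strength of ring 1's primaries in ring 2
        assert cell(1, 2, "K_TOP") == pytest.approx(0.5)
        assert cell(1, 2, "S_TOP") == pytest.approx(0.25)
        assert cell(1, 2, "S_BOTTOM") == pytest.approx(0.25)
        # joint: U1 ∩ U2 = {c1}; U1 ∩ L2 = {c2}
        assert cell(1, 2, "S_TOP_TOP") == pytest.approx(0.35)
        assert cell(1, 2, "S_TOP_BOTTOM") == pytest.approx(0.15)
        # sigma = joint strength minus own-ring baseline
        assert cell(1, 2, "SIGMA_TOP_TOP") == pytest.approx(0.35 - 0.375)
        assert cell(1, 2, "SIGMA_TOP_BOTTOM") == pytest.approx(0.15 - 0.125)

    def test_identical_primaries_reduce_to_own_strength(self):
        profiles = {
            "e1": {
                1: {"c1": 0.7, "c2": 0.2, "c3": 0.1},
                2: {"c1": 0.5, "c2": 0.4, "c3": 0.1},
            }
        }
        same = {"c1", "c2"}
        splits = {
            "e1": {
                1: make_split("e1", 1, same, {"c3"}),
                2: make_split("e1", 2, same, {"c3"}),
            }
        }
        table = pulling_power_table(splits, profiles)
        s_tt = table[(table.rx == 1) & (table.ry == 2) & (table.metric == "S_TOP_TOP")]
        s_top_own = table[(table.rx == 1) & (table.ry == 2) & (table.metric == "S_TOP")]
        assert float(s_tt.value.iloc[0]) == pytest.approx(float(s_top_own.value.iloc[0]))
        # U1 ∩ L2 empty: that cell reports no egos
        s_tb = table[(table.rx == 1) & (table.ry == 2) & (table.metric == "S_TOP_BOTTOM")]
        assert s_tb.empty

    def test_sigma_equals_independent_recomputation(self, rng):
        """sigma cells equal recomputing their constituent strengths per ego."""
        topics = [f"c{k}" for k in range(8)]
        profiles, splits = {}, {}
        for e in range(12):
            ego = f"e{e}"
            profiles[ego], splits[ego] = {}, {}
            for r in (1, 2):
                p = rng.dirichlet(np.ones(8) * 0.4)
                prof = {c: float(v) for c, v in zip(topics, p)}
                profiles[ego][r] = prof
                try:
                    splits[ego][r] = jenks_two_split(prof, ego_id=ego, ring=r)
                except DegenerateSplitError:
                    pass
        table = pulling_power_table(splits, profiles)
        for rx, ry in [(1, 2), (2, 1)]:
            diffs = []
            for ego in profiles:
                if rx not in splits.get(ego, {}) or ry not in splits.get(ego, {}):
                    continue
                ux = splits[ego][rx].primary
                uy = splits[ego][ry].primary
                inter = ux & uy
                if not inter:
                    continue
                s_tt = strength(inter, profiles[ego][ry])
                base = strength(uy, profiles[ego][ry])
                diffs.append(s_tt - base)
            row = table[
                (table.rx == rx) & (table.ry == ry) & (table.metric == "SIGMA_TOP_TOP")
            ]
            if diffs:
                assert float(row.value.iloc[0]) == pytest.approx(np.mean(diffs))
                assert int(row.n_egos.iloc[0]) == len(diffs)
            else:
                assert row.empty

    def test_primary_elsewhere_boost_detected(self, rng):
        """A +0.02 share boost for primary-elsewhere topics yields a positive
        sigma with p < .001 across 200 egos.

        Ring 2 has three primary topics; the two that are also primary in
        ring 1 receive a small boost, so the joint strength exceeds the
        within-ring primary baseline.
        """
        topics = [f"c{k}" for k in range(10)]
        profiles, splits = {}, {}
        for e in range(200):
            ego = f"e{e:03d}"
            tail1 = rng.dirichlet(np.ones(8)) * 0.45
            p1 = np.r_[0.30, 0.25, tail1]               # U_1 = {c0, c1}
            tail2 = rng.dirichlet(np.ones(7)) * 0.25
            p2 = np.r_[0.28, 0.24, 0.19, tail2]          # U_2 = {c0, c1, c2}
            p2[[0, 1]] += 0.02                           # boost U_1 members
            p2 /= p2.sum()
            profiles[ego] = {
                1: {c: float(v) for c, v in zip(topics, p1)},
                2: {c: float(v) for c, v in zip(topics, p2)},
            }
            splits[ego] = {
                r: jenks_two_split(profiles[ego][r], ego_id=ego, ring=r)
                for r in (1, 2)
            }
        table = pulling_power_table(splits, profiles)
        row = table[
            (table.rx == 1) & (table.ry == 2) & (table.metric == "SIGMA_TOP_TOP")
        ]
        assert float(row.value.iloc[0]) > 0
        assert float(row.p_value.iloc[0]) < 1e-3

    def test_all_cells_within_bounds(self, rng):
        topics = [f"c{k}" for k in range(10)]
        profiles, splits = {}, {}
        for e in range(10):
            ego = f"e{e}"
            profiles[ego], splits[ego] = {}, {}
            for r in (1, 2, 3):
                p = rng.dirichlet(np.ones(10) * 0.3)
                prof = {c: float(v) for c, v in zip(topics, p)}
                profiles[ego][r] = prof
                splits[ego][r] = jenks_two_split(prof, ego_id=ego, ring=r)
        table = pulling_power_table(splits, profiles)
        plain = table[~table.metric.str.startswith("SIGMA")]
        assert ((plain.value >= 0) & (plain.value <= 1)).all()
        sigma = table[table.metric.str.startswith("SIGMA")]
        assert ((sigma.value >= -1) & (sigma.value <= 1)).all()
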