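import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import evatcrop as ec
from evatcrop import fuzzy


PARTITION = fuzzy.FuzzyPartition(variable="tmax", l=10.0, m=20.0, h=30.0)


@st.composite
def partitions(draw):
    l = draw(st.floats(-50, 50, allow_nan=False))
    width = draw(st.floats(0.1, 100, allow_nan=False))
    return fuzzy.FuzzyPartition(variable="tmax", l=l, m=l + width / 2, h=l + width)


class TestPartitions:
    def test_fit_anchors_at_min_max_with_midpoint_peak(self, site):
        frame = pd.DataFrame({"tmin": [0.0, 1.0, 4.0], "tmax": [10.0, 25.0, 30.0]},
                             index=pd.date_range("2001-01-01", periods=3))
        s = ec.WeatherSeries(frame=frame, site=site)
        p = fuzzy.fit_partition(s, "tmax")
        assert (p.l, p.m, p.h) == (10.0, 20.0, 30.0)
        q = fuzzy.fit_partition(s, "tmin")
        assert (q.l, q.m, q.h) == (0.0, 2.0, 4.0)

    def test_fit_matches_brute_force_scan(self, synthetic_decade):
        train, _ = ec.chronological_split(synthetic_decade, 0.7)
        parts = fuzzy.fit_partitions(train)
        for v in train.variables:
            lo = min(r.value(v) for r in train.records())
            hi = max(r.value(v) for r in train.records())
            assert parts[v].l == lo and parts[v].h == hi
            assert parts[v].m == (lo + hi) / 2

    def test_constant_variable_rejected(self, site):
        frame = pd.DataFrame({"tmin": [5.0, 5.0], "tmax": [9.0, 9.5]},
                             index=pd.date_range("2001-01-01", periods=2))
        with pytest.raises(ValueError, match="constant"):
            fuzzy.fit_partition(ec.WeatherSeries(frame=frame, site=site), "tmin")


class TestMembership:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (10.0, (1, 0, 0)),   # left vertex
            (20.0, (0, 1, 0)),   # peak
            (30.0, (0, 0, 1)),   # right vertex
            (15.0, (0.5, 0.5, 0)),
            (25.0, (0, 0.5, 0.5)),
            (5.0, (1, 0, 0)),    # clamped below range
            (35.0, (0, 0, 1)),   # clamped above range
        ],
    )
    def test_vertex_and_clamping_identities(self, x, expected):
        np.testing.assert_allclose(fuzzy.membership_degrees(x, PARTITION),
                                   expected, atol=1e-12)

    @settings(max_examples=300, derandomize=True)
    @given(p=partitions(), x=st.floats(-200, 200, allow_nan=False))
    def test_partition_of_unity_and_bounds(self, p, x):
        mu = fuzzy.membership_degrees(x, p)
        assert np.all(mu >= 0) and np.all(mu <= 1)
        assert abs(mu.sum() - 1.0) < 1e-9


class TestCombinations:
    def test_catalogue_is_base_pair_times_subsets(self):
        combos = fuzzy.standard_combinations()
        assert len(combos) == 8
        got = {c.variables for c in combos}
        expected = set()
        for r in range(4):
            for extra in itertools.combinations(fuzzy.OPTIONAL_VARS, r):
                expected.add(tuple(v for v in ec.weather.VARIABLES
                                   if v in fuzzy.BASE_PAIR + extra))
        assert got == expected
        assert all(set(fuzzy.BASE_PAIR) <= set(c.variables) for c in combos)

    def test_documented_id_to_variable_mapping(self):
        by_id = {c.id: c.variables for c in fuzzy.standard_combinations()}
        assert by_id["C1"] == ("tmin", "tmax")
        assert by_id["C2"] == ("tmin", "tmax", "ws")
        assert by_id["C5"] == ("tmin", "tmax", "ws", "rh")
        assert by_id["C8"] == ("tmin", "tmax", "ws", "rh", "sr")

    def test_rule_group_sizes_and_total(self):
        sizes = [c.n_rules for c in fuzzy.standard_combinations()]
        assert sizes == [9, 27, 27, 27, 81, 81, 81, 243]
        assert fuzzy.total_rule_count() == 576

    def test_rule_group_ordering_is_lexicographic(self):
        g = fuzzy.enumerate_rule_group(fuzzy.combination_by_id("C2"))
        assert g.id == "RG2"
        assert len(g.rules) == 27
        assert len(set(g.rules)) == 27
        assert g.rules[0].labels == ("low", "low", "low")
        assert g.rules[-1].labels == ("high", "high", "high")
        # last variable varies fastest
        assert g.rules[1].labels == ("low", "low", "medium")
        # re-enumeration is permutation-stable
        assert fuzzy.enumerate_rule_group(fuzzy.combination_by_id("C2")).rules == g.rules


class TestFiringAndNormalization:
    PARTS = {
        "tmin": fuzzy.FuzzyPartition("tmin", 0.0, 10.0, 20.0),
        "tmax": fuzzy.FuzzyPartition("tmax", 10.0, 20.0, 30.0),
    }

    def _record(self, tmin, tmax):
        return ec.WeatherRecord(date=pd.Timestamp("2001-01-01"), tmin=tmin, tmax=tmax)

    def test_all_medium_record_is_one_hot(self):
        g = fuzzy.enumerate_rule_group(fuzzy.combination_by_id("C1"))
        p = fuzzy.fire_rule_group(self._record(10.0, 20.0), g, self.PARTS)
        expected = np.zeros(9)
        expected[g.rules.index(fuzzy.Rule(("medium", "medium")))] = 1.0
        np.testing.assert_allclose(p, expected, atol=1e-12)

    def test_products_match_hand_multiplication(self):
        # degrees: tmin=5 -> (0.5, 0.5, 0); tmax=27.5 -> (0, 0.25, 0.75)
        g = fuzzy.enumerate_rule_group(fuzzy.combination_by_id("C1"))
        p = fuzzy.fire_rule_group(self._record(5.0, 27.5), g, self.PARTS)
        d1, d2 = (0.5, 0.5, 0.0), (0.0, 0.25, 0.75)
        expected = [d1[i] * d2[j] for i in range(3) for j in range(3)]
        np.testing.assert_allclose(p, expected, atol=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_degree_label_annihilates_rule(self):
        g = fuzzy.enumerate_rule_group(fuzzy.combination_by_id("C1"))
        p = fuzzy.fire_rule_group(self._record(0.0, 15.0), g, self.PARTS)
        for i, rule in enumerate(g.rules):
            if rule.labels[0] != "low":  # tmin at l: only the low label is live
                assert p[i] == 0.0

    def test_normalize_hand_example_and_guard(self):
        np.testing.assert_allclose(fuzzy.normalize_firings([1.0, 1.0, 2.0]),
                                   [0.25, 0.25, 0.5], atol=1e-12)
        np.testing.assert_allclose(fuzzy.normalize_firings([0.3] * 5), [0.2] * 5,
                                   atol=1e-12)
        with pytest.raises(ValueError, match="zero"):
            fuzzy.normalize_firings([0.0, 0.0, 0.0])

    def test_transform_composes_fire_and_normalize(self, synthetic_decade):
        parts = fuzzy.fit_partitions(synthetic_decade)
        combo = fuzzy.combination_by_id("C5")
        g = fuzzy.enumerate_rule_group(combo)
        X = fuzzy.transform_series(synthetic_decade, combo, parts)
        assert X.shape == (len(synthetic_decade), combo.n_rules)
        for i, rec in enumerate(synthetic_decade.records()[:10]):
            by_hand = fuzzy.normalize_firings(fuzzy.fire_rule_group(rec, g, parts))
            np.testing.assert_allclose(X[i], by_hand, atol=1e-12)

    def test_out_of_range_record_still_fires(self):
        combo = fuzzy.combination_by_id("C1")
        vec = fuzzy.transform(self._record(-40.0, 90.0), combo, self.PARTS)
        assert vec.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(vec >= 0)

    def test_missing_variable_named(self, synthetic_decade):
        parts = fuzzy.fit_partitions(synthetic_decade)
        combo = fuzzy.combination_by_id("C2")
        rec = self._record(5.0, 15.0)  # record lacks ws
        g = fuzzy.enumerate_rule_group(combo)
        with pytest.raises(KeyError, match="ws"):
            fuzzy.fire_rule_group(rec, g, parts)


class TestAlgebraicInvariants:
    """Randomized checks of the pre-normalization sum and interim-vector laws."""

    def test_firings_sum_to_one_before_normalization(self):
        rng = np.random.default_rng(11)
        parts = {
            "tmin": fuzzy.FuzzyPartition("tmin", 2.0, 11.0, 20.0),
            "tmax": fuzzy.FuzzyPartition("tmax", 12.0, 23.0, 34.0),
            "ws": fuzzy.FuzzyPartition("ws", 0.0, 2.0, 4.0),
            "rh": fuzzy.FuzzyPartition("rh", 20.0, 60.0, 100.0),
            "sr": fuzzy.FuzzyPartition("sr", 2.0, 15.0, 28.0),
        }
        for combo in fuzzy.standard_combinations():
            g = fuzzy.enumerate_rule_group(combo)
            k = len(combo.variables)
            values = rng.uniform(-10, 110, size=(200, k))
            p = fuzzy._fire_matrix(values, g, parts)
            assert np.all(p >= 0) and np.all(p <= 1)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
            vecs = fuzzy.normalize_firings(p)
            np.testing.assert_allclose(vecs.sum(axis=1), 1.0, atol=1e-9)
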