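"""Synthetic-cohort indicator tests: rates, survivor functions, SPPR1, SMAC1."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import fertisim as fs
from fertisim.exceptions import DataError

AGES = np.arange(15, 50)


def surface_from_rates(rates, year=2000):
    """A one-year rate surface from a length-35 rate vector."""
    return pd.DataFrame({year: rates}, index=pd.Index(AGES, name="a"))


rate_vectors = arrays(
    float, 35, elements=st.floats(0.0, 0.99, allow_nan=False)
)


class TestRateSurface:
    def test_simple_ratio(self):
        cells = pd.DataFrame({"a": [20], "t": [2000], "events": [5], "exposure": [50]})
        surf = fs.rate_surface(cells)
        assert surf.loc[20, 2000] == pytest.approx(0.1)

    def test_zero_exposure_is_empty_marker(self):
        cells = pd.DataFrame({"a": [20], "t": [2000], "events": [0], "exposure": [0]})
        surf = fs.rate_surface(cells)
        assert np.isnan(surf.loc[20, 2000])

    def test_events_exceeding_exposure_rejected(self):
        cells = pd.DataFrame({"a": [20], "t": [2000], "events": [7], "exposure": [5]})
        with pytest.raises(DataError):
            fs.rate_surface(cells)

    def test_hand_tabulated_three_women(self, flat_macro, three_women):
        py = fs.build_person_years(three_women, flat_macro, (1960, 2010))
        surf = fs.rate_surface(fs.tabulate_event_log(py))
        # woman 1 (born 1960) has her birth at age 25 in 1985; woman 2
        # (born 1950) is also at risk in 1985, aged 35
        assert surf.loc[25, 1985] == pytest.approx(1.0)
        assert surf.loc[35, 1985] == pytest.approx(0.0)
        # 1980: woman 1 aged 20 and woman 2 aged 30 at risk, no events
        assert surf.loc[20, 1980] == 0.0 and surf.loc[30, 1980] == 0.0


class TestSppr1:
    def test_null_schedule(self):
        assert fs.sppr1(surface_from_rates(np.zeros(35)), 2000) == 0.0

    def test_constant_rate_closed_form(self):
        surf = surface_from_rates(np.full(35, 0.1))
        assert fs.sppr1(surf, 2000) == pytest.approx(1 - 0.9**35)

    def test_single_rate(self):
        rates = np.zeros(35)
        rates[20 - 15] = 0.5
        assert fs.sppr1(surface_from_rates(rates), 2000) == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None)
    @given(rate_vectors, st.integers(0, 34), st.floats(0.001, 0.5))
    def test_raising_any_rate_never_decreases_sppr1(self, rates, i, bump):
        base = fs.sppr1(surface_from_rates(rates), 2000)
        rates2 = rates.copy()
        rates2[i] = min(rates2[i] + bump, 1.0)
        assert fs.sppr1(surface_from_rates(rates2), 2000) >= base - 1e-12


class TestSurvivorFunction:
    def test_null_schedule_survives(self):
        S = fs.survivor_function(surface_from_rates(np.zeros(35)), 2000)
        assert (S == 1.0).all()

    def test_single_decrement(self):
        rates = np.zeros(35)
        rates[0] = 0.5
        S = fs.survivor_function(surface_from_rates(rates), 2000)
        assert S.loc[15] == 1.0
        assert (S.loc[16:] == 0.5).all()

    @settings(max_examples=50, deadline=None)
    @given(rate_vectors)
    def test_terminal_survivor_equals_product(self, rates):
        S = fs.survivor_function(surface_from_rates(rates), 2000)
        assert S.loc[50] == pytest.approx(np.prod(1 - rates))
        assert (np.diff(S.to_numpy()) <= 1e-12).all()  # nonincreasing

    @settings(max_examples=50, deadline=None)
    @given(rate_vectors)
    def test_sppr1_is_one_minus_terminal_survivor(self, rates):
        surf = surface_from_rates(rates)
        S = fs.survivor_function(surf, 2000)
        assert fs.sppr1(surf, 2000) == pytest.approx(1 - S.loc[50])


class TestSmac1:
    def test_point_mass(self):
        rates = np.zeros(35)
        rates[20 - 15] = 0.5
        assert fs.smac1(surface_from_rates(rates), 2000) == pytest.approx(20.0)

    def test_two_term_hand_computation(self):
        rates = np.zeros(35)
        rates[20 - 15] = 0.5
        rates[30 - 15] = 1.0
        assert fs.smac1(surface_from_rates(rates), 2000) == pytest.approx(25.0)

    def test_empty_cohort_undefined(self):
        assert np.isnan(fs.smac1(surface_from_rates(np.zeros(35)), 2000))

    @settings(max_examples=50, deadline=None)
    @given(rate_vectors)
    def test_matches_brute_force_weighted_mean(self, rates):
        got = fs.smac1(surface_from_rates(rates), 2000)
        S = np.concatenate(([1.0], np.cumprod(1 - rates)))
        w = S[:-1] - S[1:]
        if w.sum() <= 0:
            assert np.isnan(got)
        else:
            assert got == pytest.approx(np.sum(AGES * w) / w.sum())
            assert 15 <= got <= 49


class TestReplicateMean:
    def _series(self, sppr, smac=20.0, year=2000):
        return pd.DataFrame(
            {"sppr1": [sppr], "smac1": [smac]}, index=pd.Index([year], name="year")
        )

    def test_identical_replicates(self):
        out = fs.replicate_mean([self._series(0.8)] * 3)
        assert out.loc[2000, "sppr1"] == pytest.approx(0.8)
        assert out.loc[2000, "sppr1_n"] == 3

    def test_two_replicate_average(self):
        out = fs.replicate_mean([self._series(0.7), self._series(0.9)])
        assert out.loc[2000, "sppr1"] == pytest.approx(0.8)

    def test_undefined_replicates_excluded(self):
        out = fs.replicate_mean(
            [self._series(0.8, smac=np.nan), self._series(0.6, smac=25.0)]
        )
        assert out.loc[2000, "smac1"] == pytest.approx(25.0)
        assert out.loc[2000, "smac1_n"] == 1

    def test_all_undefined_stays_undefined(self):
        out = fs.replicate_mean([self._series(0.8, smac=np.nan)] * 2)
        assert np.isnan(out.loc[2000, "smac1"])


class TestObservedIndicators:
    def test_all_childless(self):
        lc = pd.DataFrame(
            {
                "woman_id": range(10),
                "birth_year": 1960,
                "level": "ISCED2",
                "leaving_age": 16,
                "first_birth_year": np.nan,
            }
        )
        obs = fs.observed_indicators(lc, (1975, 2009))
        assert (obs["sppr1"] == 0.0).all()

    def test_universal_birth_at_25(self):
        lc = pd.DataFrame(
            {
                "woman_id": range(10),
                "birth_year": 1960,
                "level": "ISCED2",
                "leaving_age": 16,
                "first_birth_year": 1985.0,
            }
        )
        obs = fs.observed_indicators(lc, (1975, 2009))
        assert obs.loc[1985, "sppr1"] == pytest.approx(1.0)
        assert obs.loc[1985, "smac1"] == pytest.approx(25.0)

    def test_matches_brute_force_tabulation(self, macro, population):
        lc, _ = population
        lc = lc.iloc[::300].reset_index(drop=True)  # ~17 women across cohorts
        window = (1960, 2010)
        obs = fs.observed_indicators(lc, window)
        # brute force: per-year decremental rates from a python loop
        exposure, events = {}, {}
        for _, w in lc.iterrows():
            fby = w.first_birth_year
            for a in range(15, 50):
                t = int(w.birth_year) + a
                if t < 1960 or t > 2010:
                    continue
                if np.isfinite(fby) and t > fby:
                    break
                exposure[(a, t)] = exposure.get((a, t), 0) + 1
                if np.isfinite(fby) and t == fby:
                    events[(a, t)] = events.get((a, t), 0) + 1
        for year in obs.index:
            prod = 1.0
            for a in range(15, 50):
                ex = exposure.get((a, year), 0)
                if ex:
                    prod *= 1 - events.get((a, year), 0) / ex
            assert obs.loc[year, "sppr1"] == pytest.approx(1 - prod)
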