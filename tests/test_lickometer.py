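"""Lickometer parsing, drink merging, cleaning and feature oracles."""
import math

import numpy as np
import pytest

from photolick.lickometer import (
    BIN_S,
    Drink,
    LickRecord,
    bin_to_drinks,
    clean_events,
    compute_intake,
    intersession_intake,
    microstructure,
    read_lick_log,
    write_lick_log,
)
from tests.conftest import make_session, random_lick_session


def brute_force_drinks(records):
    """Independent merge oracle: scan integer window indices."""
    windows = {int(round(r.bin_start / BIN_S)): r for r in records}
    drinks = []
    for w in sorted(windows):
        if drinks and w - 1 in windows and drinks[-1]["windows"][-1] == w - 1:
            drinks[-1]["windows"].append(w)
        else:
            drinks.append({"windows": [w]})
    out = []
    for d in drinks:
        recs = [windows[w] for w in d["windows"]]
        out.append(
            (
                d["windows"][0] * BIN_S,
                (d["windows"][-1] + 1) * BIN_S,
                sum(r.n_events for r in recs),
                sum(r.event_duration for r in recs),
            )
        )
    return out


class TestReadWrite:
    def test_roundtrip(self, tmp_path):
        session = make_session([(0.0, 2, 0.8), (3.0, 1, 0.2)], bottle_pre=150.0,
                               bottle_post=149.0, body_weight=25.0)
        path = tmp_path / "log.csv"
        write_lick_log(session, path)
        back = read_lick_log(path)
        assert len(back.records) == 2
        assert back.records[0] == LickRecord(0.0, 2, 0.8)
        assert back.animal_id == session.animal_id
        assert back.bottle_pre == 150.0

    def test_empty_records_section_is_valid(self, tmp_path):
        session = make_session([])
        path = tmp_path / "log.csv"
        write_lick_log(session, path)
        assert read_lick_log(path).records == []

    def test_overlong_event_duration_names_the_row(self, tmp_path):
        session = make_session([(0.0, 2, 0.8)])
        path = tmp_path / "log.csv"
        write_lick_log(session, path)
        with open(path, "a") as fh:
            fh.write("3.0,1,3.5\n")
        with pytest.raises(ValueError, match="record 2"):
            read_lick_log(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# animal_id=X\n# sex=male\n# fluid=water\n"
                        "# session_index=1\n# week=1\n# duration=7200\n"
                        "bin_start_s,n_events\n0.0,2\n")
        with pytest.raises(ValueError, match="expected columns"):
            read_lick_log(path)

    def test_non_monotone_bins_rejected(self):
        session = make_session([(3.0, 2, 0.8), (0.0, 1, 0.2)])
        with pytest.raises(ValueError, match="strictly increasing"):
            session.validate()


class TestBinToDrinks:
    def test_adjacent_windows_merge(self):
        session = make_session([(0.0, 2, 0.8), (3.0, 1, 0.2)])
        (drink,) = bin_to_drinks(session)
        assert (drink.start, drink.end, drink.length) == (0.0, 6.0, 6.0)
        assert drink.n_events == 3
        assert drink.event_duration == pytest.approx(1.0)

    def test_separated_windows_stay_apart(self):
        session = make_session([(0.0, 2, 0.8), (9.0, 1, 0.2)])
        drinks = bin_to_drinks(session)
        assert [d.start for d in drinks] == [0.0, 9.0]

    def test_empty_session(self):
        assert bin_to_drinks(make_session([])) == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            session = random_lick_session(rng)
            got = [
                (d.start, d.end, d.n_events, d.event_duration)
                for d in bin_to_drinks(session)
            ]
            assert got == brute_force_drinks(session.records)

    def test_idempotent_on_merged_output(self):
        rng = np.random.default_rng(11)
        session = random_lick_session(rng)
        drinks = bin_to_drinks(session)
        # a session rebuilt from the merged windows merges identically
        rebuilt = make_session(
            [(r.bin_start, r.n_events, r.event_duration)
             for d in drinks for r in d.records],
            duration=session.duration,
        )
        again = bin_to_drinks(rebuilt)
        assert [(d.start, d.end, d.n_events) for d in again] == [
            (d.start, d.end, d.n_events) for d in drinks
        ]


def _colinear_drinks(slope=2.0, n=20):
    drinks = []
    t = 0.0
    for i in range(1, n + 1):
        dur = 0.5 * i
        drinks.append(Drink(t, t + 3.0, int(round(slope * dur)), dur,
                            [LickRecord(t, int(round(slope * dur)), min(dur, 3.0))]))
        t += 9.0
    return drinks


class TestCleanEvents:
    def test_exact_line_removes_nothing(self):
        drinks = _colinear_drinks()
        kept, removed, model = clean_events(drinks)
        assert removed == []
        assert kept == drinks
        assert model.slope == pytest.approx(2.0)
        assert np.allclose(model.residuals, 0.0, atol=1e-9)

    def test_single_outlier_removed_and_matches_independent_fit(self):
        drinks = _colinear_drinks()
        bad = Drink(500.0, 503.0, int(2 * 5.0 + 10), 5.0)  # +10 events off the line
        drinks = drinks + [bad]
        kept, removed, model = clean_events(drinks)
        assert removed == [bad]
        assert len(kept) == 20
        # independent brute-force Theil-Sen: median of pairwise slopes
        x = np.array([d.event_duration for d in drinks])
        y = np.array([d.n_events for d in drinks])
        slopes = [
            (y[j] - y[i]) / (x[j] - x[i])
            for i in range(len(x))
            for j in range(i + 1, len(x))
            if x[j] != x[i]
        ]
        assert model.slope == pytest.approx(np.median(slopes))
        assert model.slope == pytest.approx(2.0)
        assert model.residuals[-1] == pytest.approx(10.0, abs=1e-9)
        assert np.all(np.abs(model.residuals[:-1]) < 1e-9)

    def test_high_leverage_leak_removed(self):
        """A slow leak (very long duration, ordinary event count) must not
        capture the fitted line through sheer leverage."""
        drinks = _colinear_drinks()
        leak = Drink(600.0, 633.0, 20, 50.0)  # 10x duration at ordinary events
        kept, removed, model = clean_events(drinks + [leak])
        assert removed == [leak]
        assert len(kept) == 20

    def test_too_few_drinks_pass_through(self):
        drinks = _colinear_drinks(n=2)
        with pytest.warns(UserWarning, match="fewer than 3"):
            kept, removed, model = clean_events(drinks)
        assert kept == drinks and removed == [] and model is None

    def test_degenerate_equal_durations_pass_through(self):
        drinks = [Drink(9.0 * i, 9.0 * i + 3.0, i + 1, 1.0) for i in range(5)]
        with pytest.warns(UserWarning, match="degenerate"):
            kept, removed, model = clean_events(drinks)
        assert kept == drinks and model is None

    def test_event_conservation(self):
        rng = np.random.default_rng(3)
        session = random_lick_session(rng)
        drinks = bin_to_drinks(session)
        kept, removed, _ = clean_events(drinks)
        assert sum(d.n_events for d in kept) + sum(d.n_events for d in removed) == \
            session.total_events


class TestMicrostructure:
    def test_latency_and_idi_definitions(self):
        session = make_session([(99.0, 3, 0.5), (399.0, 2, 0.3)])
        drinks = bin_to_drinks(session)
        summ = microstructure(session, drinks)
        assert summ.latency_to_drink == 99.0
        assert summ.mean_inter_drink_interval == pytest.approx(300.0)
        assert summ.n_drinks == 2

    def test_single_drink_has_no_idi(self):
        session = make_session([(99.0, 3, 0.5)])
        summ = microstructure(session, bin_to_drinks(session))
        assert math.isnan(summ.mean_inter_drink_interval)

    def test_empty_session_latency_undefined(self):
        session = make_session([])
        summ = microstructure(session, [])
        assert math.isnan(summ.latency_to_drink)
        assert summ.n_drinks == 0

    def test_latency_uses_raw_records_before_cleaning(self):
        # first window belongs to a drink that cleaning would remove
        session = make_session([(12.0, 50, 0.01), (300.0, 4, 0.5)])
        drinks = bin_to_drinks(session)
        summ = microstructure(session, drinks[1:])  # pretend cleaning dropped it
        assert summ.latency_to_drink == 12.0
        assert summ.n_drinks == 1

    def test_frontload_matches_brute_force(self):
        rng = np.random.default_rng(19)
        for _ in range(200):
            session = random_lick_session(rng)
            drinks = bin_to_drinks(session)
            summ = microstructure(session, drinks)
            oracle = sum(r.n_events for r in session.records if r.bin_start < 1800.0)
            assert summ.frontload_events == oracle


class TestIntake:
    def test_water_arithmetic(self):
        assert compute_intake(100.0, 99.0, 25.0, "water") == pytest.approx(40.0)

    def test_alcohol_uses_solution_and_ethanol_densities(self):
        # 0.9687 g of 20 % v/v solution = 1 mL -> 0.2 mL EtOH -> 0.157890 g
        got = compute_intake(100.0, 100.0 - 0.9687, 25.0, "alcohol")
        assert got == pytest.approx(6.3156, abs=1e-4)

    def test_zero_consumption(self):
        assert compute_intake(100.0, 100.0, 25.0, "water") == 0.0

    def test_negative_consumption_rejected(self):
        with pytest.raises(ValueError, match="negative consumption"):
            compute_intake(100.0, 101.0, 25.0, "water")

    def test_intersession_equals_water_intake(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            pre = float(rng.uniform(100, 300))
            post = pre - float(rng.uniform(0, 10))
            bw = float(rng.uniform(18, 35))
            assert intersession_intake(pre, post, bw) == compute_intake(pre, post, bw, "water")
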