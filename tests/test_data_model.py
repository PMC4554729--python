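import math
from datetime import date, datetime, timedelta

import numpy as np
import pytest

from secrbayes.data_model import (
    CaptureHistory,
    CaptureRecord,
    OccasionCalendar,
    TrapArray,
    build_capture_history,
    capture_frequency,
    capture_success,
    filter_capture_records,
    mmdm,
    read_capture_records,
    read_trap_deployment,
    write_capture_records,
    write_trap_deployment,
)
from secrbayes.errors import ConsistencyError, DomainError, FormatError

from conftest import make_history


class TestReadCaptureRecords:
    def test_well_formed(self, tmp_path):
        p = tmp_path / "caps.csv"
        p.write_text(
            "LOC_ID,ANIMAL_ID,TIMESTAMP\n"
            "T1,A1,2013-01-05T10:00:00\n"
            "T2,A1,2013-01-06T11:30:00\n"
            "T1,A2,2013-01-07T02:15:00\n"
        )
        records = read_capture_records(p)
        assert len(records) == 3
        assert records[0].trap_id == "T1"
        assert records[0].individual_id == "A1"
        assert records[0].timestamp == datetime(2013, 1, 5, 10)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "caps.csv"
        p.write_text("LOC_ID,TIMESTAMP\nT1,2013-01-05T10:00:00\n")
        with pytest.raises(FormatError, match="ANIMAL_ID"):
            read_capture_records(p)

    def test_bad_timestamp_reports_line(self, tmp_path):
        p = tmp_path / "caps.csv"
        p.write_text("LOC_ID,ANIMAL_ID,TIMESTAMP\nT1,A1,notadate\n")
        with pytest.raises(FormatError, match="line 2"):
            read_capture_records(p)

    def test_occasion_dialect(self, tmp_path):
        p = tmp_path / "caps.csv"
        p.write_text("LOC_ID,ANIMAL_ID,SO\nT1,A1,5\n")
        (rec,) = read_capture_records(p)
        assert rec.occasion == 4  # 1-based on disk

    def test_write_read_roundtrip(self, tmp_path):
        records = [
            CaptureRecord("A1", "T1", timestamp=datetime(2013, 2, 1, 8, 30)),
            CaptureRecord("A2", "T3", timestamp=datetime(2013, 2, 2, 23, 59)),
        ]
        p = tmp_path / "rt.csv"
        write_capture_records(p, records)
        assert read_capture_records(p) == records


class TestTrapDeployment:
    def test_roundtrip(self, tmp_path, square_traps):
        p = tmp_path / "traps.csv"
        write_trap_deployment(p, square_traps)
        back = read_trap_deployment(p)
        assert back.trap_ids == square_traps.trap_ids
        np.testing.assert_array_equal(back.x, square_traps.x)
        np.testing.assert_array_equal(back.activity, square_traps.activity)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ConsistencyError, match="unique"):
            TrapArray(("T1", "T1"), np.zeros(2), np.zeros(2), np.ones((2, 3), dtype=int))

    def test_trap_days(self, square_traps):
        assert square_traps.trap_days == 20


class TestFilter:
    def _rec(self, iid, trap, when):
        return CaptureRecord(iid, trap, timestamp=when)

    def test_dedup_same_trap(self):
        t0 = datetime(2013, 1, 10, 12)
        recs = [self._rec("A1", "T1", t0), self._rec("A1", "T1", t0 + timedelta(hours=1))]
        kept, log = filter_capture_records(recs, dedup_window_hours=6)
        assert len(kept) == 1
        assert log.reasons() == ["dedup"]

    def test_different_traps_kept(self):
        t0 = datetime(2013, 1, 10, 12)
        recs = [self._rec("A1", "T1", t0), self._rec("A1", "T2", t0 + timedelta(hours=1))]
        kept, log = filter_capture_records(recs, dedup_window_hours=6)
        assert len(kept) == 2 and len(log) == 0

    def test_headline_81_to_76(self):
        """81 raw records, 3 same-trap dupes + 2 incomplete-day captures -> 76."""
        base = datetime(2013, 1, 10, 12)
        recs = [
            self._rec(f"A{i}", f"T{i % 20}", base + timedelta(days=i)) for i in range(76)
        ]
        # three within-window duplicates of record 0 (same animal, same trap)
        recs += [self._rec("A0", "T0", base + timedelta(hours=h)) for h in (1, 2, 3)]
        # two captures on the partial pickup day of trap T50
        pickup = datetime(2013, 3, 20, 9, 30)
        recs += [
            self._rec("A70", "T50", datetime(2013, 3, 20, 7, 0)),
            self._rec("A71", "T50", datetime(2013, 3, 20, 8, 0)),
        ]
        deployment = {"T50": (datetime(2013, 1, 1), pickup)}
        assert len(recs) == 81
        kept, log = filter_capture_records(recs, 6, deployment)
        assert len(kept) == 76
        assert sorted(log.reasons()) == ["dedup"] * 3 + ["incomplete_day"] * 2

    def test_idempotent(self):
        rng_base = datetime(2013, 1, 10)
        recs = [
            self._rec("A1", "T1", rng_base + timedelta(hours=h)) for h in (0, 2, 5, 13, 30)
        ]
        kept, _ = filter_capture_records(recs, 6)
        kept2, log2 = filter_capture_records(kept, 6)
        assert kept2 == kept and len(log2) == 0

    def test_empty_input(self):
        kept, log = filter_capture_records([], 6)
        assert kept == [] and len(log) == 0

    def test_bad_window(self):
        with pytest.raises(DomainError):
            filter_capture_records([], 0)


class TestBuildCaptureHistory:
    def test_shapes_and_collapse(self, square_traps):
        cal = OccasionCalendar(date(2013, 1, 1), 5)
        recs = [
            CaptureRecord("A1", "T1", timestamp=datetime(2013, 1, 1, 10)),
            CaptureRecord("A1", "T1", timestamp=datetime(2013, 1, 1, 22)),  # same day
            CaptureRecord("A1", "T2", timestamp=datetime(2013, 1, 1, 12)),
            CaptureRecord("A2", "T4", timestamp=datetime(2013, 1, 3, 4)),
        ]
        hist = build_capture_history(recs, square_traps, cal)
        assert hist.y.shape == (2, 4, 5)
        assert hist.n_captures == 3  # same-day same-trap collapsed
        assert hist.y[0, :, 0].sum() == 2  # two traps on one occasion

    def test_empty_records_error(self, square_traps):
        with pytest.raises(ConsistencyError):
            build_capture_history([], square_traps, None)

    def test_inactive_trap_occasion_error(self, square_traps):
        traps = TrapArray(
            square_traps.trap_ids,
            square_traps.x,
            square_traps.y,
            np.array(square_traps.activity, copy=True),
        )
        traps.activity[0, 0] = 0
        recs = [CaptureRecord("A1", "T1", occasion=0)]
        with pytest.raises(ConsistencyError, match="inactive"):
            build_capture_history(recs, traps, None)

    def test_roundtrip_with_simulator(self, coarse_scenario):
        """Rebuilding the history from records reproduces per-individual counts."""
        sc = coarse_scenario
        hist = build_capture_history(sc.capture_records(), sc.traps, None)
        assert capture_frequency(hist) == capture_frequency(sc.history)
        np.testing.assert_array_equal(hist.y, sc.history.y)


class TestCaptureSuccess:
    def test_paper_headline(self):
        assert round(capture_success(76, 2906), 2) == 2.62

    def test_zero_captures(self):
        assert capture_success(0, 1000) == 0.0

    def test_simple(self):
        assert capture_success(5, 200) == 2.5

    def test_domain_error(self):
        with pytest.raises(DomainError):
            capture_success(10, 0)

    def test_trap_days_conservation(self, square_traps):
        assert square_traps.trap_days == square_traps.activity.sum()


class TestCaptureFrequency:
    def test_reported_distribution_totals_38(self):
        """{1: 12, 2: 4, 3: 1, 4: 2, 7: 1} -> 38 captures total."""
        rows = []
        spec = {1: 12, 2: 4, 3: 1, 4: 2, 7: 1}
        for count, n_ind in spec.items():
            for _ in range(n_ind):
                row = np.zeros((8, 7), dtype=np.int8)
                row.flat[:count] = 1
                rows.append(row)
        hist = make_history(np.stack(rows))
        freq = capture_frequency(hist)
        assert freq == spec
        assert sum(c * n for c, n in freq.items()) == 38 == hist.n_captures

    def test_single(self):
        y = np.zeros((1, 2, 3), dtype=np.int8)
        y[0, 0, 0] = 1
        assert capture_frequency(make_history(y)) == {1: 1}

    def test_all_zero_row_unreachable(self):
        y = np.zeros((2, 2, 2), dtype=np.int8)
        y[0, 0, 0] = 1
        with pytest.raises(ConsistencyError):
            make_history(y)


class TestMMDM:
    def test_simple_means(self):
        traps = TrapArray(
            ("T1", "T2", "T3", "T4"),
            np.array([0.0, 2000.0, 4000.0, 6000.0]),
            np.zeros(4),
            np.ones((4, 3), dtype=int),
        )
        y = np.zeros((3, 4, 3), dtype=np.int8)
        y[0, 0, 0] = y[0, 1, 1] = 1  # max 2 km
        y[1, 0, 0] = y[1, 2, 1] = 1  # max 4 km
        y[2, 0, 0] = y[2, 3, 1] = 1  # max 6 km
        res = mmdm(make_history(y), traps)
        assert res.mmdm == pytest.approx(4000.0)
        assert res.half_mmdm == pytest.approx(2000.0)
        assert res.n == 3

    def test_single_pair(self):
        traps = TrapArray(
            ("T1", "T2"), np.array([0.0, 3100.0]), np.zeros(2), np.ones((2, 2), dtype=int)
        )
        y = np.zeros((1, 2, 2), dtype=np.int8)
        y[0, 0, 0] = y[0, 1, 1] = 1
        res = mmdm(make_history(y), traps)
        assert res.mmdm == pytest.approx(3100.0)

    def test_undefined_when_no_recaptures(self, square_traps):
        y = np.zeros((2, 4, 5), dtype=np.int8)
        y[0, 0, 0] = 1
        y[1, 1, 2] = 1
        res = mmdm(make_history(y), square_traps)
        assert not res.defined
        assert math.isnan(res.mmdm)

    def test_half_is_exactly_half(self, coarse_scenario):
        res = mmdm(coarse_scenario.history, coarse_scenario.traps)
        assert res.half_mmdm == res.mmdm / 2.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        n_traps, n_ind, n_occ = 15, 10, 6
        traps = TrapArray(
            tuple(f"T{j}" for j in range(n_traps)),
            rng.uniform(0, 10_000, n_traps),
            rng.uniform(0, 10_000, n_traps),
            np.ones((n_traps, n_occ), dtype=int),
        )
        y = (rng.random((n_ind, n_traps, n_occ)) < 0.08).astype(np.int8)
        y[:, 0, 0] = 1  # ensure every individual captured
        hist = make_history(y)
        res = mmdm(hist, traps)

        # exhaustive O(n^2) pairwise scan, independent of the implementation
        expected = {}
        for i, iid in enumerate(hist.individual_ids):
            traps_used = [j for j in range(n_traps) if y[i, j].any()]
            if len(traps_used) < 2:
                continue
            best = 0.0
            for a in traps_used:
                for b in traps_used:
                    d = math.hypot(traps.x[a] - traps.x[b], traps.y[a] - traps.y[b])
                    best = max(best, d)
            expected[iid] = best
        assert set(res.per_individual) == set(expected)
        for iid in expected:
            assert res.per_individual[iid] == pytest.approx(expected[iid])
        assert res.mmdm == pytest.approx(np.mean(list(expected.values())))
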