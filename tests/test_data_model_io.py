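"""Domain-type invariants and on-disk round trips."""

import json

import numpy as np
import pandas as pd
import pytest

import surgskill.io as sio
from surgskill.datatypes import (
    METRIC_SCOPES,
    SEGMENT_IDS,
    ForceTrace,
    FormatError,
    Group,
    KinematicTrace,
    MetricValue,
    SegmentAnnotation,
    ValidationError,
)

ALL_SCOPES = ("tweezers", "needle_holder", "both", "left_hand", "right_hand")


def _kin_csv(path, rows, header="# units: time=s, position=cm\n", cols="time,x,y,z"):
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(cols + "\n")
        for r in rows:
            fh.write(",".join("" if v is None else f"{v:.12g}" for v in r) + "\n")


class TestKinematicCsv:
    def test_straight_line_fixture(self, tmp_path):
        rows = [(k / 120, k / 120, 0.0, 0.0) for k in range(4)]
        _kin_csv(tmp_path / "k.csv", rows)
        tr = sio.read_kinematic_csv(tmp_path / "k.csv", "left_tweezers")
        assert tr.n_samples == 4
        assert tr.sample_rate == pytest.approx(120.0)
        assert not tr.has_gaps

    def test_duplicate_timestamp_rejected(self, tmp_path):
        rows = [(0.0, 0, 0, 0), (1 / 120, 1, 0, 0), (1 / 120, 2, 0, 0)]
        _kin_csv(tmp_path / "k.csv", rows)
        with pytest.raises(ValidationError, match="index 2"):
            sio.read_kinematic_csv(tmp_path / "k.csv", "left_tweezers")

    def test_nan_row_flagged_as_gap(self, tmp_path):
        rows = [(k / 120, None if k == 2 else float(k), 0.0, 0.0) for k in range(5)]
        _kin_csv(tmp_path / "k.csv", rows)
        tr = sio.read_kinematic_csv(tmp_path / "k.csv", "left_tweezers")
        assert tr.gap_indices.tolist() == [2]

    def test_missing_column_is_format_error(self, tmp_path):
        _kin_csv(tmp_path / "k.csv", [(0, 0, 0), (1 / 120, 1, 0)], cols="time,x,y")
        with pytest.raises(FormatError, match="z"):
            sio.read_kinematic_csv(tmp_path / "k.csv", "left_tweezers")

    def test_undeclared_units_rejected(self, tmp_path):
        _kin_csv(tmp_path / "k.csv", [(0, 0, 0, 0), (1 / 120, 1, 0, 0)], header="")
        with pytest.raises(FormatError, match="units"):
            sio.read_kinematic_csv(tmp_path / "k.csv", "left_tweezers")


class TestForceCsv:
    def _write(self, path, rows):
        with open(path, "w") as fh:
            fh.write("# units: time=s, force=N\n")
            fh.write("time,thumb,index,middle\n")
            for r in rows:
                fh.write(",".join(f"{v:.12g}" for v in r) + "\n")

    def test_zero_forces_no_clipping(self, tmp_path):
        self._write(tmp_path / "f.csv", [(k / 40, 0, 0, 0) for k in range(3)])
        tr = sio.read_force_csv(tmp_path / "f.csv", "left")
        assert tr.n_clipped == 0

    def test_negative_sample_clipped_with_count(self, tmp_path):
        self._write(tmp_path / "f.csv", [(0, 0.5, 0.5, 0.5), (1 / 40, -0.1, 0.5, 0.5),
                                         (2 / 40, 0.5, 0.5, 0.5)])
        tr = sio.read_force_csv(tmp_path / "f.csv", "left")
        assert tr.n_clipped == 1
        assert tr.channels["thumb"][1] == 0.0

    def test_duration_from_rate(self, tmp_path):
        self._write(tmp_path / "f.csv", [(k / 40, 1, 1, 1) for k in range(80)])
        tr = sio.read_force_csv(tmp_path / "f.csv", "right")
        assert tr.duration == pytest.approx(79 / 40)

    def test_missing_finger_column(self, tmp_path):
        with open(tmp_path / "f.csv", "w") as fh:
            fh.write("# units: time=s, force=N\ntime,thumb,index\n0,1,1\n0.025,1,1\n")
        with pytest.raises(FormatError, match="middle"):
            sio.read_force_csv(tmp_path / "f.csv", "left")


class TestSegments:
    @pytest.fixture
    def trace(self):
        n = 400
        return KinematicTrace(
            "left_tweezers", 120.0, np.arange(n) / 120.0, np.zeros((n, 3))
        )

    def _write(self, path, payload):
        with open(path, "w") as fh:
            json.dump(payload, fh)

    def test_valid_contiguous_windows(self, tmp_path, trace):
        self._write(tmp_path / "s.json",
                    {"S1": [0, 100], "S2": [100, 200], "S3": [200, 300], "S4": [300, 400]})
        segs = sio.read_segments(tmp_path / "s.json", trace)
        assert [s.segment_id for s in segs] == list(SEGMENT_IDS)
        assert segs[0].t0 == 0.0
        assert segs[0].tf == pytest.approx(100 / 120)

    def test_overlap_rejected(self, tmp_path, trace):
        self._write(tmp_path / "s.json",
                    {"S1": [0, 100], "S2": [90, 200], "S3": [200, 300], "S4": [300, 400]})
        with pytest.raises(ValidationError, match="overlap"):
            sio.read_segments(tmp_path / "s.json", trace)

    def test_missing_segment_rejected(self, tmp_path, trace):
        self._write(tmp_path / "s.json", {"S1": [0, 100], "S2": [100, 200], "S3": [200, 300]})
        with pytest.raises(FormatError):
            sio.read_segments(tmp_path / "s.json", trace)

    def test_out_of_bounds_rejected(self, tmp_path, trace):
        self._write(tmp_path / "s.json",
                    {"S1": [0, 100], "S2": [100, 200], "S3": [200, 300], "S4": [300, 500]})
        with pytest.raises(ValidationError, match="exceeds"):
            sio.read_segments(tmp_path / "s.json", trace)


class TestScopeLegality:
    @pytest.mark.parametrize("metric", list(METRIC_SCOPES))
    @pytest.mark.parametrize("scope", ALL_SCOPES)
    def test_all_metric_scope_pairs(self, metric, scope):
        kwargs = dict(metric=metric, scope=scope, segment_id="S1",
                      subject_id="X", group=Group.NOVICE, trial_index=1, value=1.0)
        if scope in METRIC_SCOPES[metric]:
            assert MetricValue(**kwargs).scope == scope
        else:
            with pytest.raises(ValidationError, match="not legal"):
                MetricValue(**kwargs)


class TestTables:
    def test_empty_metric_table_has_header_only(self, tmp_path):
        sio.write_metric_table([], tmp_path / "m.csv")
        df = sio.read_metric_table(tmp_path / "m.csv")
        assert len(df) == 0 and "value" in df.columns

    def test_single_value_round_trip(self, tmp_path):
        mv = MetricValue("path_length", "tweezers", "S2", "N01", Group.NOVICE, 2, 12.345678901)
        sio.write_metric_table([mv], tmp_path / "m.csv")
        df = sio.read_metric_table(tmp_path / "m.csv")
        assert len(df) == 1
        assert df.loc[0, "value"] == pytest.approx(12.345678901, abs=1e-9)


class TestTrialRoundTrip:
    def test_full_trial_round_trip(self, tmp_path, novice_trial):
        trial, _ = novice_trial
        manifest = sio.write_trial(trial, tmp_path / "t")
        back = sio.read_trial(manifest)
        for a, b in ((trial.left_kin, back.left_kin), (trial.right_kin, back.right_kin)):
            np.testing.assert_allclose(b.positions, a.positions, atol=1e-9)
            np.testing.assert_allclose(b.timestamps, a.timestamps, atol=1e-9)
        for a, b in ((trial.left_force, back.left_force), (trial.right_force, back.right_force)):
            for f in ("thumb", "index", "middle"):
                np.testing.assert_allclose(b.channels[f], a.channels[f], atol=1e-9)
        assert [(s.k0, s.kf) for s in back.segments] == [(s.k0, s.kf) for s in trial.segments]
        assert back.group == trial.group and back.ali_score == trial.ali_score

    def test_missing_force_file_tolerated(self, tmp_path, novice_trial):
        trial, _ = novice_trial
        manifest = sio.write_trial(trial, tmp_path / "t")
        (tmp_path / "t" / "left_force.csv").unlink()
        back = sio.read_trial(manifest)
        assert back.left_force is None and back.right_force is not None

    def test_comparison_table_round_trip(self, tmp_path, novice_trial, intermediate_trial):
        from surgskill.pipeline import compare_cohort, cohort_metric_table

        table = cohort_metric_table([novice_trial[0], intermediate_trial[0]])
        res = compare_cohort(table)
        sio.write_comparison_table(res.results, tmp_path / "c.csv")
        back = sio.read_comparison_table(tmp_path / "c.csv")
        orig = res.frame
        assert len(back) == len(orig) == 52
        pd.testing.assert_series_equal(
            back["median_novice"], orig["median_novice"], atol=1e-9, check_exact=False
        )
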