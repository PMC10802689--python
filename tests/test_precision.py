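"""Localization-precision formula and the residence-time/precision filters."""

import numpy as np
import pandas as pd
import pytest

from poremap import (
    PrecisionParams,
    classify_and_filter,
    classify_trajectory,
    combine_precision,
    localization_precision,
)
from poremap.precision import ANCHORED, FREE_DYE, UNBOUND

from conftest import make_table, single_trajectory


class TestPrecisionFormula:
    def test_immobile_limit_matches_hand_evaluation(self):
        # frozen independent hand evaluation of the closed form at
        # s0=150, a=120, b=2, N=1000, D=0, F=2
        p = PrecisionParams(N=1000, a=120.0, b=2.0, s0=150.0, D=0.0, dt=50.0, F=2.0)
        assert localization_precision(p) == pytest.approx(9.597361020983229, rel=1e-12)

    def test_motion_blur_vanishes_at_zero_diffusion(self):
        static = PrecisionParams(N=500, D=0.0, dt=2.0)
        longer = PrecisionParams(N=500, D=0.0, dt=500.0)
        # with D = 0 the acquisition time has no effect: s = s0 exactly
        assert localization_precision(static) == localization_precision(longer)

    def test_background_free_scaling_with_photons(self):
        p1 = PrecisionParams(N=1000, b=0.0)
        p2 = PrecisionParams(N=2000, b=0.0)
        assert localization_precision(p2) == pytest.approx(
            localization_precision(p1) / np.sqrt(2), rel=1e-12
        )

    def test_strictly_decreasing_in_photon_count(self):
        sigmas = [
            localization_precision(PrecisionParams(N=n, D=5.0))
            for n in [100, 300, 1000, 3000, 10_000, 1e6]
        ]
        assert all(a > b for a, b in zip(sigmas, sigmas[1:]))
        assert sigmas[-1] < 0.5  # sigma -> 0 as N -> inf

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PrecisionParams(N=0)
        with pytest.raises(ValueError):
            PrecisionParams(N=100, dt=0.0)
        with pytest.raises(ValueError):
            PrecisionParams(N=100, F=0.5)


class TestCombinePrecision:
    @pytest.mark.parametrize(
        "d1,d2,expected",
        [(3.0, 4.0, 5.0), (7.0, 0.0, 7.0), (7.0, 7.0, 7.0 * np.sqrt(2))],
    )
    def test_quadrature_sum(self, d1, d2, expected):
        assert combine_precision(d1, d2) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            combine_precision(-1.0, 2.0)


class TestDwellClassification:
    @pytest.mark.parametrize(
        "n_frames,frame_time,expected",
        [
            (1, 2.0, FREE_DYE),  # ~3 ms passage at the 2 ms rate
            (5, 2.0, UNBOUND),  # 10 ms dwell: unbound labeled protein
            (10, 50.0, ANCHORED),  # 0.5 s dwell: anchored
            (2, 50.0, ANCHORED),  # at the 50 ms rate 2 frames = 100 ms
        ],
    )
    def test_classes(self, n_frames, frame_time, expected):
        assert classify_trajectory(n_frames, frame_time) == expected


def _mapping_table():
    """A 50 ms-rate recording: blips plus anchored trajectories and rejects."""
    rng = np.random.default_rng(0)
    parts = [
        # sub-frame visitor: one 50 ms frame (dwell 50 ms, not anchored)
        single_trajectory([[0, 0]], frame_time=50.0, traj_id="blip", precision=8.0),
        # anchored, good: 10 frames, precision 8
        single_trajectory(rng.normal(size=(10, 2)), frame_time=50.0, traj_id="good",
                          precision=8.0),
        # anchored but poor precision
        single_trajectory(rng.normal(size=(10, 2)), frame_time=50.0, traj_id="blurry",
                          precision=12.0),
        # anchored but too long (> 40 frames)
        single_trajectory(rng.normal(size=(50, 2)), frame_time=50.0, traj_id="toolong",
                          precision=8.0),
        # anchored but too short (< 4 frames)
        single_trajectory(rng.normal(size=(3, 2)), frame_time=50.0, traj_id="tooshort",
                          precision=8.0),
    ]
    return pd.concat(parts, ignore_index=True)


class TestClassifyAndFilter:
    def test_only_good_anchored_trajectory_retained(self):
        table = _mapping_table()
        filtered, report = classify_and_filter(table, frame_time=50.0)
        assert set(filtered["traj_id"]) == {"good"}
        by_id = report.set_index("traj_id")
        assert by_id.loc["blip", "reason"] == "class"
        assert by_id.loc["blurry", "reason"] == "precision"
        assert by_id.loc["toolong", "reason"] == "length"
        assert by_id.loc["tooshort", "reason"] == "length"

    def test_dwell_classes_at_fast_frame_rate(self):
        # a 2 ms-rate recording sees all three dwell populations
        rng = np.random.default_rng(1)
        table = pd.concat(
            [
                single_trajectory([[0, 0]], frame_time=2.0, traj_id="dye"),
                single_trajectory(rng.normal(size=(5, 2)), frame_time=2.0,
                                  traj_id="unbound"),
                single_trajectory(rng.normal(size=(100, 2)), frame_time=2.0,
                                  traj_id="stuck"),
            ],
            ignore_index=True,
        )
        _, report = classify_and_filter(table, frame_time=2.0)
        by_id = report.set_index("traj_id")
        assert by_id.loc["dye", "class"] == FREE_DYE
        assert by_id.loc["unbound", "class"] == UNBOUND
        assert by_id.loc["stuck", "class"] == ANCHORED

    def test_every_row_has_exactly_one_disposition(self):
        table = _mapping_table()
        filtered, report = classify_and_filter(table)
        assert len(report) == table["traj_id"].nunique()
        retained = set(report.loc[report["retained"], "traj_id"])
        rejected = set(report.loc[~report["retained"], "traj_id"])
        assert retained | rejected == set(table["traj_id"])
        assert not (retained & rejected)
        assert (report.loc[~report["retained"], "reason"] != "").all()

    def test_idempotent(self):
        table = _mapping_table()
        once, _ = classify_and_filter(table)
        twice, _ = classify_and_filter(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_gap_in_frames_fails_continuity(self):
        pos = np.zeros((10, 2))
        tab = single_trajectory(pos, frame_time=50.0, traj_id="gappy", precision=5.0)
        tab.loc[5:, "frame"] += 3  # missing frame indices
        tab.loc[5:, "t_ms"] += 150.0
        _, report = classify_and_filter(tab)
        assert report.iloc[0]["reason"] == "length"

    def test_empty_table_warns_not_raises(self):
        table = _mapping_table().iloc[0:0]
        with pytest.warns(UserWarning):
            filtered, report = classify_and_filter(table)
        assert len(filtered) == 0 and len(report) == 0
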