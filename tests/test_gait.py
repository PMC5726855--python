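"""Phase-event detection, phase differences, circular statistics and the
operational gait classifier on constructed fixtures."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import quadgait as qg
from quadgait.dynamics import CellConstants, SystemState
from quadgait.gait import (GaitLabel, PhaseEvents, TrotBin, _is_bound,
                           _is_gallop, _is_trot, _is_walk, bin_percentages,
                           circular_distance)
from quadgait.simulate import Trajectory

C = CellConstants()
LIMB_IDS = {"LF": "fore-left-RG-F", "RF": "fore-right-RG-F",
            "LH": "hind-left-RG-F", "RH": "hind-right-RG-F"}

V_ON, V_OFF = -40.0, -60.0   # f = 0.2 (flexion) / 0 (extension)


def square_wave_trajectory(period_ms: float, duty: float,
                           phase: dict[str, float],
                           duration_ms: int = 4000) -> Trajectory:
    """Synthetic flexor-center traces: square waves with known onsets.

    Limb ``L`` is in flexion on [k*T + phase[L]*T, k*T + (phase[L]+duty)*T).
    """
    t = np.arange(duration_ms + 1, dtype=float)
    ids = tuple(LIMB_IDS.values())
    V = np.empty((len(t), 4))
    for j, (limb, pid) in enumerate(LIMB_IDS.items()):
        local = ((t - phase[limb] * period_ms) / period_ms) % 1.0
        V[:, j] = np.where(local < duty, V_ON, V_OFF)
    state = SystemState(np.full(4, V_OFF), np.zeros(0), np.zeros(4))
    return Trajectory(t=t, V=V, h=np.zeros((len(t), 0)),
                      alpha=np.zeros(len(t)), ids=ids, final_state=state)


class TestDetectPhases:
    def test_square_wave_onsets_recovered(self):
        T = 250.0
        traj = square_wave_trajectory(T, 0.4, dict(LF=0, RF=0, LH=0, RH=0))
        ev = qg.detect_phases(traj, C)
        onsets = ev.onsets["LH"]
        expected = np.arange(1, 16) * T       # first period starts at t=0
        # onsets land within one sample of the construction
        assert np.all(np.abs(onsets[:15] - expected[:len(onsets[:15])]) <= 1.0)
        assert ev.frequency == pytest.approx(1000.0 / T, rel=1e-6)

    def test_tonic_activity_reports_no_rhythm(self):
        t = np.arange(2001, dtype=float)
        V = np.full((len(t), 4), V_ON)
        traj = Trajectory(t=t, V=V, h=np.zeros((len(t), 0)),
                          alpha=np.zeros(len(t)),
                          ids=tuple(LIMB_IDS.values()),
                          final_state=SystemState(np.full(4, V_ON),
                                                  np.zeros(0), np.zeros(4)))
        ev = qg.detect_phases(traj, C)
        assert not ev.has_rhythm
        assert np.isnan(ev.frequency)

    def test_flexion_extension_durations(self):
        T, duty = 200.0, 0.3
        traj = square_wave_trajectory(T, duty, dict(LF=0, RF=0, LH=0, RH=0))
        ev = qg.detect_phases(traj, C)
        assert np.allclose(ev.flexion_durations("LH"), duty * T, atol=1.1)
        assert np.allclose(ev.extension_durations("LH"), (1 - duty) * T,
                           atol=1.1)


class TestPhaseDifferences:
    def test_synchronized_fixture_all_zero(self):
        traj = square_wave_trajectory(250.0, 0.4,
                                      dict(LF=0, RF=0, LH=0, RH=0))
        pd = qg.phase_differences(qg.detect_phases(traj, C))
        for vals in pd.as_dict().values():
            vals = vals[np.isfinite(vals)]
            assert np.all(np.minimum(vals, 1 - vals) < 0.01)

    def test_ideal_trot_fixture(self):
        """Diagonal pairs synchronous, left-right in antiphase."""
        traj = square_wave_trajectory(
            250.0, 0.3, dict(LH=0.0, RF=0.0, RH=0.5, LF=0.5))
        pd = qg.phase_differences(qg.detect_phases(traj, C))
        assert circular_distance(np.nanmean(pd.hind_lr), 0.5) < 0.01
        assert circular_distance(np.nanmean(pd.homolateral), 0.5) < 0.01
        assert circular_distance(np.nanmean(pd.diagonal), 0.0) < 0.01
        assert circular_distance(np.nanmean(pd.fore_lr), 0.5) < 0.01

    def test_walk_fixture_quarter_lags(self):
        """Lateral-sequence walk: quarter-period lags RH->RF->LH->LF."""
        traj = square_wave_trajectory(
            400.0, 0.25, dict(RH=0.0, RF=0.25, LH=0.5, LF=0.75))
        pd = qg.phase_differences(qg.detect_phases(traj, C))
        assert circular_distance(np.nanmean(pd.hind_lr), 0.5) < 0.01
        assert circular_distance(np.nanmean(pd.homolateral), 0.25) < 0.01
        assert circular_distance(np.nanmean(pd.diagonal), 0.75) < 0.01

    def test_global_time_shift_invariance(self):
        base = square_wave_trajectory(
            250.0, 0.3, dict(LH=0.0, RF=0.1, RH=0.45, LF=0.6))
        ev = qg.detect_phases(base, C)
        shifted = PhaseEvents(
            onsets={k: v + 133.7 for k, v in ev.onsets.items()},
            offsets={k: v + 133.7 for k, v in ev.offsets.items()})
        a = qg.phase_differences(ev)
        b = qg.phase_differences(shifted)
        for key in a.as_dict():
            va, vb = a.as_dict()[key], b.as_dict()[key]
            n = min(len(va), len(vb))
            mask = np.isfinite(va[:n]) & np.isfinite(vb[:n])
            assert np.allclose(va[:n][mask], vb[:n][mask], atol=1e-9)


class TestCircularStats:
    def test_constant_values(self):
        mean, sd = qg.circular_stats(np.array([0.1, 0.1, 0.1]))
        assert mean == pytest.approx(0.1)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_wraparound_mean(self):
        mean, _ = qg.circular_stats(np.array([0.95, 0.05]))
        assert circular_distance(mean, 0.0) < 1e-9

    def test_sd_against_resultant_formula(self):
        """Brute-force circular sd from the mean resultant length."""
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, 500)
        angles = 2 * np.pi * vals
        R = np.hypot(np.cos(angles).mean(), np.sin(angles).mean())
        expected = np.sqrt(-2 * np.log(R)) / (2 * np.pi)
        _, sd = qg.circular_stats(vals)
        assert sd == pytest.approx(expected, rel=1e-9)
        assert sd > 0.2      # uniform phases: large spread

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            qg.circular_stats(np.array([]))


class TestClassifier:
    @pytest.mark.parametrize("hind,homo,diag,ext_longer,label", [
        (0.5, 0.5, 0.0, True, GaitLabel.TROT),
        (0.5, 0.5, 0.95, False, GaitLabel.TROT),
        (0.0, 0.5, 0.5, False, GaitLabel.BOUND),
        (0.99, 0.5, 0.5, False, GaitLabel.BOUND),
        (0.5, 0.25, 0.75, True, GaitLabel.WALK),
        (0.5, 0.3, 0.7, False, GaitLabel.UNCLASSIFIED),  # walk needs ext>flex
        (0.1, 0.5, 0.5, False, GaitLabel.GALLOP),
        (0.9, 0.4, 0.6, True, GaitLabel.GALLOP),
        (0.5, 0.05, 0.5, True, GaitLabel.UNCLASSIFIED),
        (float("nan"), 0.5, 0.5, True, GaitLabel.UNCLASSIFIED),
    ])
    def test_examples(self, hind, homo, diag, ext_longer, label):
        assert qg.classify_gait(hind, homo, diag, ext_longer) is label

    @given(st.tuples(st.floats(0, 1, exclude_max=True),
                     st.floats(0, 1, exclude_max=True),
                     st.floats(0, 1, exclude_max=True)))
    def test_regions_disjoint_off_boundaries(self, point):
        """Away from the interval boundaries, at most one gait region
        contains any phase-difference triple (grid oracle)."""
        hind, homo, diag = point
        edges = (0.0, 0.025, 0.1, 0.25, 0.4, 0.6, 0.75, 0.9, 0.975)
        if any(abs(x - e) < 1e-6 for x in point for e in edges):
            return
        hits = sum([_is_walk(hind, homo, diag), _is_trot(hind, homo, diag),
                    _is_gallop(hind, homo, diag),
                    _is_bound(hind, homo, diag)])
        assert hits <= 1

    @given(st.tuples(st.floats(0, 1, exclude_max=True),
                     st.floats(0, 1, exclude_max=True),
                     st.floats(0, 1, exclude_max=True)))
    def test_left_right_relabel_invariance(self, point):
        """Mirroring left/right maps the left-right phase d to 1-d and
        must not change the gait label (regions symmetric about 0.5)."""
        hind, homo, diag = point
        edges = (0.0, 0.025, 0.1, 0.25, 0.4, 0.6, 0.75, 0.9, 0.975)
        if any(abs(x - e) < 1e-6 for x in point for e in edges):
            return
        mirrored = ((1 - hind) % 1.0, homo, diag)
        assert qg.classify_gait(hind, homo, diag, True) is \
            qg.classify_gait(*mirrored, True)


class TestTrotBins:
    @pytest.mark.parametrize("x,bin_", [
        (0.5, TrotBin.TROT),
        (1 / 3, TrotBin.TROT),
        (0.0, TrotBin.SYNC),
        (0.9, TrotBin.SYNC),
        (0.25, TrotBin.QUARTER),
        (0.75, TrotBin.QUARTER),
        (1 / 6, TrotBin.QUARTER),
        (5 / 6, TrotBin.SYNC),
    ])
    def test_edges_and_centers(self, x, bin_):
        assert qg.bin_for_trot(x) is bin_

    @given(st.floats(0, 1, exclude_max=True))
    def test_bins_partition_the_circle(self, x):
        assert sum(qg.bin_for_trot(x) is b for b in TrotBin) == 1

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        pct = bin_percentages(rng.uniform(0, 1, 1000))
        assert sum(pct.values()) == pytest.approx(100.0)
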