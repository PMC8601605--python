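"""F/F0 normalization, spike detection, kymographs, pattern classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capouch import (
    ClassifierConfig,
    ModelParameters,
    SimulationConfig,
    classify_pattern,
    detect_spikes,
    integrated_activity,
    make_kymograph,
    normalize_trace,
    oscillation_metrics,
    spikes_per_area,
)
from capouch.geometry import VplcField
from capouch.quantify import ActivityReport
from capouch.simulate import TissueTrajectory


def synthetic_trajectory(tissue, c_matrix, dt=10.0):
    T = c_matrix.shape[0]
    n = tissue.n_cells
    return TissueTrajectory(
        t=np.arange(T) * dt,
        p=np.zeros((T, n)),
        c=np.asarray(c_matrix, dtype=float),
        r=np.ones((T, n)),
        tissue=tissue,
        vplc=VplcField(np.zeros(n), np.zeros(n, dtype=bool)),
        params=ModelParameters(),
        config=SimulationConfig(duration=(T - 1) * dt, sample_interval=dt),
    )


class TestNormalizeTrace:
    def test_constant_trace_maps_to_ones(self):
        assert np.allclose(normalize_trace(np.full(50, 0.3)), 1.0)

    def test_isolated_excursion_scales_to_ratio(self):
        trace = np.full(100, 0.2)
        trace[40] = 0.6
        f = normalize_trace(trace)
        assert f[40] == pytest.approx(3.0)

    @given(k=st.floats(0.01, 100))
    @settings(deadline=None)
    def test_scale_invariance(self, k):
        rng = np.random.default_rng(0)
        trace = 0.1 + rng.uniform(0, 1, 80)
        assert np.allclose(normalize_trace(trace * k), normalize_trace(trace))

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            normalize_trace(np.zeros(30))


class TestDetectSpikes:
    def test_constant_trace_has_no_events(self):
        t = np.arange(100) * 10.0
        assert detect_spikes(np.full(100, 0.5), t) == []

    def test_two_gaussian_bumps(self):
        t = np.arange(0, 900, 1.0)
        trace = 1.0 + 2.0 * (
            np.exp(-((t - 200) ** 2) / (2 * 15**2))
            + np.exp(-((t - 500) ** 2) / (2 * 15**2))
        )
        events = detect_spikes(trace, t, threshold=1.5, normalized=True)
        assert len(events) == 2
        assert events[0].t_peak == pytest.approx(200, abs=2)
        assert events[1].t_peak == pytest.approx(500, abs=2)

    def test_triangular_pulse_half_width(self):
        # isosceles triangle, base 20 s, apex 2.0 on unit baseline:
        # half-max level 1.5 is crossed at the midpoints, so WHM = 10 s
        t = np.arange(0, 200, 1.0)
        trace = np.ones_like(t)
        ramp = np.abs(t - 100) <= 10
        trace[ramp] = 2.0 - np.abs(t - 100)[ramp] / 10.0
        events = detect_spikes(trace, t, threshold=1.2, normalized=True)
        assert len(events) == 1
        assert events[0].whm == pytest.approx(10.0, abs=1e-9)
        assert events[0].amplitude == pytest.approx(2.0)

    def test_nearby_excursions_merge(self):
        t = np.arange(0, 300, 1.0)
        trace = np.ones_like(t)
        trace[(t > 100) & (t < 110)] = 2.0
        trace[(t > 115) & (t < 125)] = 2.0
        assert len(detect_spikes(trace, t, min_separation=20.0,
                                 normalized=True)) == 1
        assert len(detect_spikes(trace, t, min_separation=2.0,
                                 normalized=True)) == 2

    def test_invariant_to_raw_scaling(self):
        t = np.arange(0, 600, 10.0)
        rng = np.random.default_rng(5)
        raw = 0.2 + 0.01 * rng.uniform(size=len(t))
        raw[20:23] = 0.8
        a = detect_spikes(raw, t)
        b = detect_spikes(raw * 7.3, t)
        assert [(e.t_peak, e.whm) for e in a] == [(e.t_peak, e.whm) for e in b]

    def test_threshold_must_exceed_baseline(self):
        with pytest.raises(ValueError):
            detect_spikes(np.ones(10), np.arange(10.0), threshold=0.9)


class TestOscillationMetrics:
    def test_periodic_trace_frequency(self):
        t = np.arange(0, 1200, 1.0)
        trace = 1.0 + np.maximum(np.sin(2 * np.pi * t / 120), 0.0) ** 4
        freq, amp, whm = oscillation_metrics(trace, t, normalized=True)
        assert freq == pytest.approx(1 / 120, rel=0.02)
        assert amp == pytest.approx(2.0, rel=0.01)
        assert whm > 0

    def test_single_peak_frequency_absent(self):
        t = np.arange(0, 600, 1.0)
        trace = 1.0 + 1.5 * np.exp(-((t - 300) ** 2) / (2 * 20**2))
        freq, amp, whm = oscillation_metrics(trace, t, normalized=True)
        assert freq is None
        assert amp > 1.5


class TestKymograph:
    def test_quiescent_trajectory_constant_rows(self, small_tissue):
        c = np.full((60, small_tissue.n_cells), 0.06)
        traj = synthetic_trajectory(small_tissue, c)
        line = np.array([[-10, 0.0], [10, 0.0]])
        kymo = make_kymograph(traj, line)
        assert np.allclose(kymo.intensity, 1.0)
        assert np.all(np.diff(kymo.positions) >= 0)

    def test_single_active_cell_single_banded_row(self, small_tissue):
        c = np.full((60, small_tissue.n_cells), 0.06)
        line = np.array([[-10, 0.0], [10, 0.0]])
        # activate one cell near the line
        target = int(np.argmin(np.abs(small_tissue.centroids[:, 1])))
        c[::6, target] = 0.5
        kymo = make_kymograph(synthetic_trajectory(small_tissue, c), line)
        varying = np.ptp(kymo.intensity, axis=1) > 0.1
        assert varying.sum() == 1
        assert kymo.cell_ids[np.flatnonzero(varying)[0]] == target

    def test_missing_line_rejected(self, small_tissue):
        traj = synthetic_trajectory(
            small_tissue, np.full((60, small_tissue.n_cells), 0.06)
        )
        with pytest.raises(ValueError, match="line"):
            make_kymograph(traj, np.array([[100, 100], [120, 120]]))


class TestClassifier:
    def test_quiescent_is_none(self, small_tissue):
        c = np.full((80, small_tissue.n_cells), 0.06)
        label, diag = classify_pattern(synthetic_trajectory(small_tissue, c))
        assert label == "none"
        assert diag["n_events"] == 0

    def test_persistent_global_activation_is_fluttering(self, small_tissue):
        c = np.full((80, small_tissue.n_cells), 0.06)
        c[40:] = 0.5  # every cell elevated for half the recording
        label, _ = classify_pattern(synthetic_trajectory(small_tissue, c))
        assert label == "fluttering"

    def test_single_cell_blips_are_spikes(self, small_tissue):
        c = np.full((80, small_tissue.n_cells), 0.06)
        c[20, 5] = 0.5
        c[50, 30] = 0.5
        label, diag = classify_pattern(synthetic_trajectory(small_tissue, c))
        assert label == "spikes"
        assert diag["max_event_span"] == 1

    def test_compact_cluster_is_transient(self, small_tissue):
        c = np.full((80, small_tissue.n_cells), 0.06)
        # a standing multicellular flash: a cell and its neighbours, no travel
        nbrs = [j for i, j in small_tissue.edges if i == 0]
        nbrs += [i for i, j in small_tissue.edges if j == 0]
        group = [0] + nbrs[:4]
        c[np.ix_(range(30, 34), group)] = 0.5
        label, diag = classify_pattern(synthetic_trajectory(small_tissue, c))
        assert label == "ICT"
        assert diag["max_event_span"] == len(group)

    def test_deterministic_and_permutation_equivariant(self, small_tissue):
        rng = np.random.default_rng(9)
        c = 0.06 + 0.5 * (rng.uniform(size=(80, small_tissue.n_cells)) > 0.97)
        traj = synthetic_trajectory(small_tissue, c)
        label1, _ = classify_pattern(traj)
        label2, _ = classify_pattern(traj)
        assert label1 == label2
        perm = rng.permutation(small_tissue.n_cells)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        traj_p = synthetic_trajectory(small_tissue.relabel(perm), c[:, inv])
        label3, _ = classify_pattern(traj_p)
        assert label3 == label1

    def test_short_trajectory_rejected(self, small_tissue):
        c = np.full((10, small_tissue.n_cells), 0.06)
        with pytest.raises(ValueError, match="10 min"):
            classify_pattern(synthetic_trajectory(small_tissue, c))

    def test_rubric_thresholds_configurable(self, small_tissue):
        c = np.full((80, small_tissue.n_cells), 0.06)
        c[20, 5] = 0.5
        traj = synthetic_trajectory(small_tissue, c)
        strict = ClassifierConfig(activity_threshold=10.0)
        label, _ = classify_pattern(traj, config=strict)
        assert label == "none"


class TestActivityIntegrals:
    def test_quiescent_integrated_activity_zero(self, small_tissue):
        traj = synthetic_trajectory(
            small_tissue, np.full((80, small_tissue.n_cells), 0.06)
        )
        assert integrated_activity(traj) == 0.0

    def test_doubling_periodic_activity_doubles_integral(self, small_tissue):
        n = small_tissue.n_cells
        block = np.full((60, n), 0.06)
        block[::10] = 0.3
        once = synthetic_trajectory(small_tissue, block)
        twice = synthetic_trajectory(small_tissue, np.vstack([block, block]))
        assert integrated_activity(twice) == pytest.approx(
            2 * integrated_activity(once), rel=0.05
        )

    def test_spikes_per_area_arithmetic(self, small_tissue):
        report = ActivityReport(tissue_spike_count=12)
        assert spikes_per_area(report, small_tissue) == pytest.approx(
            12 / small_tissue.total_area()
        )
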