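"""Phase-sorted cycle reconstruction and quantitative maps.

The binning oracle is an explicit per-voxel / per-frame loop, kept
deliberately naive and independent of the vectorized implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from preful.io import ImageSeries
from preful.motion import RegisteredSeries
from preful.core import (
    PhaseResolvedCycle,
    cardiac_filtered_series,
    compute_fvl_correlation_map,
    compute_perfusion_map,
    compute_ventilation_map,
    extract_cardiac_phase,
    healthy_reference_region,
    reconstruct_cycle,
    select_mid_bin,
)


def _registered(frames, dt=0.3):
    frames = np.asarray(frames, dtype=float)
    return RegisteredSeries(
        frames=frames,
        reference_frame_index=0,
        displacement_magnitude_px=np.zeros(frames.shape[0]),
        frame_interval_s=dt,
    )


def brute_force_cycle(frames, phases, mask, n_bins):
    """Oracle: explicit loops over voxels, frames and bins."""
    T, ny, nx = frames.shape
    values = np.full((n_bins, ny, nx), np.nan)
    occupancy = np.zeros(n_bins, dtype=int)
    assignments = {b: [] for b in range(n_bins)}
    for i in range(T):
        if not np.isfinite(phases[i]):
            continue
        b = int(np.floor((phases[i] % 1.0) * n_bins))
        b = min(b, n_bins - 1)
        assignments[b].append(i)
        occupancy[b] += 1
    for y in range(ny):
        for x in range(nx):
            if not mask[y, x]:
                continue
            for b in range(n_bins):
                if assignments[b]:
                    acc = 0.0
                    for i in assignments[b]:  # running sum in time order
                        acc += frames[i, y, x]
                    values[b, y, x] = acc / len(assignments[b])
    return values, occupancy


class TestReconstructCycle:
    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(42)
        frames = rng.uniform(0, 100, size=(30, 4, 4))
        phases = rng.uniform(0, 1, size=30)
        mask = np.ones((4, 4), dtype=bool)
        cycle = reconstruct_cycle(_registered(frames), phases, mask, n_bins=5)
        expect, occ = brute_force_cycle(frames, phases, mask, 5)
        np.testing.assert_array_equal(cycle.occupancy, occ)
        assert not cycle.interpolated.any()
        np.testing.assert_array_equal(cycle.values, expect)

    def test_worked_pairwise_means(self):
        # phases land pairwise in each of 5 bins -> bin values are the
        # pairwise means of consecutive frames
        frames = np.arange(10, dtype=float).reshape(10, 1, 1) * 10
        phases = np.array([0.0, 0.05, 0.25, 0.30, 0.45, 0.50,
                           0.65, 0.70, 0.85, 0.90])
        mask = np.ones((1, 1), dtype=bool)
        cycle = reconstruct_cycle(_registered(frames), phases, mask, n_bins=5)
        np.testing.assert_array_equal(cycle.occupancy, [2] * 5)
        np.testing.assert_allclose(
            cycle.values[:, 0, 0], [5.0, 25.0, 45.0, 65.0, 85.0]
        )

    def test_constant_series_all_bins_equal(self):
        frames = np.full((20, 2, 2), 7.0)
        phases = np.linspace(0, 0.99, 20)
        cycle = reconstruct_cycle(
            _registered(frames), phases, np.ones((2, 2), bool), 5
        )
        np.testing.assert_allclose(cycle.values, 7.0)

    def test_bin_edge_floor_convention(self):
        frames = np.arange(5, dtype=float).reshape(5, 1, 1)
        phases = np.array([0.0, 0.2, 0.4, 0.6, 0.8])  # phase*5 integral
        cycle = reconstruct_cycle(
            _registered(frames), phases, np.ones((1, 1), bool), 5
        )
        np.testing.assert_array_equal(cycle.values[:, 0, 0],
                                      [0.0, 1.0, 2.0, 3.0, 4.0])

    def test_empty_bins_interpolated_and_flagged(self):
        frames = np.arange(8, dtype=float).reshape(8, 1, 1)
        # bins 0, 1, 3, 4 occupied; bin 2 empty
        phases = np.array([0.05, 0.1, 0.25, 0.3, 0.65, 0.7, 0.85, 0.9])
        cycle = reconstruct_cycle(
            _registered(frames), phases, np.ones((1, 1), bool), 5
        )
        np.testing.assert_array_equal(
            cycle.interpolated, [False, False, True, False, False]
        )
        v1, v3 = cycle.values[1, 0, 0], cycle.values[3, 0, 0]
        assert cycle.values[2, 0, 0] == pytest.approx((v1 + v3) / 2)

    def test_insufficient_coverage_rejected(self):
        frames = np.zeros((20, 1, 1))
        phases = np.full(20, 0.01)  # single occupied bin out of 5
        with pytest.raises(ValueError, match="phase coverage"):
            reconstruct_cycle(
                _registered(frames), phases, np.ones((1, 1), bool), 5
            )

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=15, deadline=None)
    def test_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(10, 40))
        frames = rng.normal(size=(T, 3, 3)) * 10
        phases = rng.uniform(0, 1, size=T)
        phases[rng.uniform(size=T) < 0.1] = np.nan
        mask = rng.uniform(size=(3, 3)) > 0.3
        if not mask.any():
            mask[0, 0] = True
        try:
            cycle = reconstruct_cycle(_registered(frames), phases, mask, 5)
        except ValueError:
            return  # coverage errors are legitimate for adverse draws
        expect, occ = brute_force_cycle(frames, phases, mask, 5)
        np.testing.assert_array_equal(cycle.occupancy, occ)
        occupied = ~cycle.interpolated
        np.testing.assert_array_equal(
            cycle.values[occupied], expect[occupied]
        )


class TestCardiacPhase:
    def test_phantom_frequency_within_one_fft_bin(self, default_run):
        result, truth = default_run
        df = 1.0 / (250 * 0.3)
        assert abs(result.cardiac_freq_hz - 1.2) <= df

    def test_pure_sinusoid_phase_advance(self):
        dt, f = 0.3, 1.0
        t = np.arange(300) * dt
        seed_signal = 10 + 3 * np.cos(2 * np.pi * f * t)
        frames = np.tile(seed_signal[:, None, None], (1, 4, 4))
        reg = _registered(frames, dt)
        phase, fdet = extract_cardiac_phase(reg, np.ones((4, 4), bool))
        assert fdet == pytest.approx(f, abs=1.0 / (300 * dt))
        d = np.diff(phase[50:250]) % 1.0
        np.testing.assert_allclose(d, (f * dt) % 1.0, atol=0.02)

    def test_respiratory_only_rejected(self):
        t = np.arange(200) * 0.3
        r = 0.5 * (1 - np.cos(2 * np.pi * 0.25 * t))
        frames = np.tile((100 - 10 * r)[:, None, None], (1, 4, 4))
        with pytest.raises(ValueError, match="no cardiac signal"):
            extract_cardiac_phase(_registered(frames), np.ones((4, 4), bool))

    def test_phase_matches_peak_interpolation_oracle(self, default_phantom):
        """Analytic-signal phase vs brute-force peak-to-peak interpolation.

        Both conventions put phase 0 at blood-signal maxima (peak inflow),
        so they must agree to within 0.05 cycles RMS between the first and
        last detected peak.
        """
        from scipy.signal import find_peaks

        series, truth = default_phantom
        reg = _registered(series.frames, series.frame_interval_s)
        phase, fdet = extract_cardiac_phase(reg, truth.blood_region_mask)

        seed_sig = series.frames[:, truth.blood_region_mask].mean(axis=1)
        min_sep = max(int(round(0.5 / fdet / series.frame_interval_s)), 1)
        peaks, _ = find_peaks(seed_sig, distance=min_sep)
        # 3-point parabolic refinement: the cardiac cycle spans < 3 frames,
        # so integer peak indices alone carry up to 0.2 cycles of
        # quantization
        refined = []
        for p in peaks:
            if 0 < p < len(seed_sig) - 1:
                a, b, c = seed_sig[p - 1], seed_sig[p], seed_sig[p + 1]
                denom = a - 2 * b + c
                shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
                refined.append(p + np.clip(shift, -0.5, 0.5))
        oracle = np.full(series.n_frames, np.nan)
        for p0, p1 in zip(refined[:-1], refined[1:]):
            idx = np.arange(int(np.ceil(p0)), int(np.ceil(p1)))
            oracle[idx] = (idx - p0) / (p1 - p0)
        valid = np.isfinite(oracle)
        delta = (phase[valid] - oracle[valid]) % 1.0
        delta = np.minimum(delta, 1.0 - delta)
        rms = np.sqrt(np.mean(delta**2))
        assert rms < 0.05


class TestVentilationMap:
    def _cycle_from_values(self, per_bin_values):
        arr = np.asarray(per_bin_values, dtype=float)[:, None, None]
        n = arr.shape[0]
        return PhaseResolvedCycle(
            values=arr,
            occupancy=np.ones(n, dtype=int),
            interpolated=np.zeros(n, dtype=bool),
            mask=np.ones((1, 1), dtype=bool),
        )

    def test_worked_example(self):
        # S_insp=90, S_exp=110, S_mid=100 -> 100*(100/90 - 100/110) = 20.20
        cycle = self._cycle_from_values([110, 104, 90, 95, 100])
        vmap = compute_ventilation_map(cycle, mid_bin=4)
        assert vmap.values[0, 0] == pytest.approx(20.2020202)

    def test_no_modulation_gives_zero(self):
        cycle = self._cycle_from_values([100.0] * 5)
        vmap = compute_ventilation_map(cycle, mid_bin=2)
        assert vmap.values[0, 0] == 0.0

    def test_mid_bin_out_of_range(self):
        cycle = self._cycle_from_values([1, 2, 3, 4, 5])
        with pytest.raises(IndexError):
            compute_ventilation_map(cycle, mid_bin=5)

    def test_nonpositive_sinsp_is_no_data(self):
        cycle = self._cycle_from_values([-1.0, 2, 3, 4, 5])
        vmap = compute_ventilation_map(cycle, mid_bin=2)
        assert np.isnan(vmap.values[0, 0])

    @given(st.floats(0.1, 10.0))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_global_scaling_invariance(self, k):
        vals = np.array([110, 104, 90, 95, 100], dtype=float)
        base = compute_ventilation_map(
            self._cycle_from_values(vals), mid_bin=4
        ).values[0, 0]
        scaled = compute_ventilation_map(
            self._cycle_from_values(vals * k), mid_bin=4
        ).values[0, 0]
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_phantom_recovery(self, default_run):
        from conftest import VENT_TRUTH_PCT

        result, truth = default_run
        common = result.lungs.mask & truth.lung_mask
        recovered = np.nanmean(result.vent_map.values[common])
        assert recovered == pytest.approx(VENT_TRUTH_PCT, rel=0.05)


class TestPerfusionMap:
    def _cycle(self, voxel_amplitudes, blood_amp):
        """2-bin-extremes cycle: amplitudes realized as min 0 / max amp."""
        amps = np.asarray(voxel_amplitudes, dtype=float)
        ny = amps.shape[0]
        values = np.zeros((5, ny, 1))
        values[0, :, 0] = amps  # max at bin 0, min 0 elsewhere
        blood = np.zeros((ny, 1), dtype=bool)
        blood[-1, 0] = True
        values[0, -1, 0] = blood_amp
        mask = np.ones((ny, 1), dtype=bool)
        return PhaseResolvedCycle(
            values=values, occupancy=np.ones(5, int),
            interpolated=np.zeros(5, bool), mask=mask,
        ), blood

    def test_ratio_arithmetic(self):
        # last voxel is the blood reference (amp 50); 5 -> 10 %, 0 -> 0 %
        cycle, blood = self._cycle([5.0, 0.0, 0.0], blood_amp=50.0)
        q = compute_perfusion_map(cycle, blood)
        assert q.values[0, 0] == pytest.approx(10.0)
        assert q.values[1, 0] == 0.0
        assert q.values[2, 0] == pytest.approx(100.0)

    def test_blood_region_mean_is_100(self, default_run):
        result, truth = default_run
        # recompute on the full map including the blood region
        from preful.core import (
            cardiac_band_amplitude, reconstruct_cycle, compute_perfusion_map,
            extract_cardiac_phase,
        )
        reg = result.registered
        blood = result.blood_region
        phase, _ = extract_cardiac_phase(reg, blood)
        card = reconstruct_cycle(
            cardiac_filtered_series(reg), phase,
            result.lungs.mask | blood, 15,
        )
        q = compute_perfusion_map(card, blood)
        assert np.nanmean(q.values[blood]) == pytest.approx(100.0)

    def test_zero_blood_amplitude_rejected(self):
        cycle, blood = self._cycle([5.0, 0.0, 0.0], blood_amp=0.0)
        with pytest.raises(ValueError, match="zero cardiac amplitude"):
            compute_perfusion_map(cycle, blood)


class TestHealthyReference:
    def test_percentile_selection_1_to_100(self):
        values = np.arange(1.0, 101.0).reshape(10, 10)
        from preful.core import QuantitativeMap

        vmap = QuantitativeMap(values=values, kind="ventilation_pct",
                               mask=np.ones((10, 10), bool))
        region = healthy_reference_region(vmap)
        # P80 = 80.2, P90 = 90.1 -> values 81..90; row-major layout puts
        # them in one 4-connected run
        selected = sorted(values[region].astype(int))
        assert selected == list(range(81, 91))

    def test_all_equal_returns_whole_mask(self):
        from preful.core import QuantitativeMap

        mask = np.ones((5, 5), bool)
        vmap = QuantitativeMap(values=np.full((5, 5), 3.0),
                               kind="ventilation_pct", mask=mask)
        region = healthy_reference_region(vmap)
        np.testing.assert_array_equal(region, mask)

    def test_too_few_voxels_rejected(self):
        from preful.core import QuantitativeMap

        mask = np.zeros((5, 5), bool)
        mask[0, :] = True
        vmap = QuantitativeMap(values=np.ones((5, 5)),
                               kind="ventilation_pct", mask=mask)
        with pytest.raises(ValueError, match="too few"):
            healthy_reference_region(vmap)


class TestFvlCorrelation:
    def _cycle(self, voxel_curves, mask=None):
        arr = np.asarray(voxel_curves, dtype=float)  # (n_vox, n_bins)
        n_vox, n_bins = arr.shape
        values = arr.T[:, :, None]  # (n_bins, n_vox, 1)
        mask = np.ones((n_vox, 1), bool) if mask is None else mask
        return PhaseResolvedCycle(
            values=values, occupancy=np.ones(n_bins, int),
            interpolated=np.zeros(n_bins, bool), mask=mask,
        )

    def test_identical_cycle_r1_negated_rm1(self):
        b = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        curve = 100 + 10 * np.sin(b)
        cycle = self._cycle([curve, curve, 200 - 10 * np.sin(b)])
        ref = np.zeros((3, 1), bool)
        ref[0, 0] = True
        fvl = compute_fvl_correlation_map(cycle, ref)
        assert fvl.values[1, 0] == pytest.approx(1.0)
        assert fvl.values[2, 0] == pytest.approx(-1.0)

    def test_quadrature_pair_uncorrelated(self):
        n = 12
        b = np.arange(n) * 2 * np.pi / n
        cycle = self._cycle([np.sin(b), np.cos(b)])
        ref = np.zeros((2, 1), bool)
        ref[0, 0] = True
        fvl = compute_fvl_correlation_map(cycle, ref)
        assert abs(fvl.values[1, 0]) < 1e-12

    def test_zero_variance_voxel_is_no_data(self):
        b = np.arange(10) * 2 * np.pi / 10
        cycle = self._cycle([np.sin(b), np.zeros(10)])
        ref = np.zeros((2, 1), bool)
        ref[0, 0] = True
        fvl = compute_fvl_correlation_map(cycle, ref)
        assert np.isnan(fvl.values[1, 0])

    @given(st.floats(0.5, 5.0), st.floats(-50.0, 50.0))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_affine_invariance(self, scale, offset):
        b = np.arange(10) * 2 * np.pi / 10
        curve = 100 + 10 * np.sin(b) + 3 * np.cos(2 * b)
        ref_curve = 100 + 10 * np.sin(b)
        base = self._cycle([ref_curve, curve])
        tf = self._cycle([ref_curve, scale * curve + offset])
        ref = np.zeros((2, 1), bool)
        ref[0, 0] = True
        r0 = compute_fvl_correlation_map(base, ref).values[1, 0]
        r1 = compute_fvl_correlation_map(tf, ref).values[1, 0]
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestSelectMidBin:
    def test_mid_bin_on_phantom_cycle(self, default_run):
        result, _ = default_run
        assert 0 <= result.mid_bin < result.config.n_bins

    def test_flat_cycle_rejected(self):
        vals = np.full((5, 2, 2), 1.0)
        cycle = PhaseResolvedCycle(
            values=vals, occupancy=np.ones(5, int),
            interpolated=np.zeros(5, bool), mask=np.ones((2, 2), bool),
        )
        with pytest.raises(ValueError, match="flat"):
            select_mid_bin(cycle)
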