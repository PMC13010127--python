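"""Phase-resolved cycle reconstruction and the quantitative maps.

Each voxel's free-breathing signal is a superposition of a slow
proton-density (ventilation) component and a fast blood-inflow (perfusion)
component.  Sorting frames by respiratory or cardiac phase into bins and
averaging within each bin reconstructs one representative cycle per voxel;
the three quantitative maps derive from those cycles:

* regional ventilation  RV = 100 * (S_mid/S_insp - S_mid/S_exp), with
  S_insp the cycle minimum (inspiration dilutes proton density), S_exp the
  cycle maximum, and S_mid the value at the mid-expiration bin;
* normalized perfusion  Q = 100 * cardiac peak-to-trough amplitude,
  referenced to the mean amplitude of the full-blood region;
* flow-volume-loop correlation: Pearson correlation between a voxel's
  ventilation-cycle flow curve and that of a healthy reference region (the
  largest connected component between the 80th and 90th ventilation
  percentiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .motion import RegisteredSeries, _zero_lag_lowpass
from .segmentation import STRUCTURE_4

__all__ = [
    "PhaseResolvedCycle",
    "QuantitativeMap",
    "cardiac_band_amplitude",
    "extract_cardiac_phase",
    "reconstruct_cycle",
    "select_mid_bin",
    "compute_ventilation_map",
    "compute_perfusion_map",
    "healthy_reference_region",
    "compute_fvl_correlation_map",
]


@dataclass
class PhaseResolvedCycle:
    """Per-voxel signal over phase bins, defined inside ``mask`` only.

    ``values`` has shape (n_bins, ny, nx); outside the mask it is NaN.
    Bins that received no frame are filled by circular linear interpolation
    and flagged in ``interpolated``.
    """

    values: np.ndarray
    occupancy: np.ndarray  # frames per bin
    interpolated: np.ndarray  # bool per bin
    mask: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


@dataclass
class QuantitativeMap:
    """Per-voxel scalar map restricted to a mask; NaN marks no-data."""

    values: np.ndarray
    kind: Literal["ventilation_pct", "perfusion_pct", "fvl_correlation"]
    mask: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return self.mask & np.isfinite(self.values)

    def finite_values(self) -> np.ndarray:
        return self.values[self.valid]


def _bandpass(
    x: np.ndarray, band: tuple[float, float], fs: float, axis: int = 0
) -> np.ndarray:
    lo, hi = band
    nyq = fs / 2.0
    if not (0 < lo < hi):
        raise ValueError(f"invalid band {band}")
    hi = min(hi, 0.99 * nyq)
    b, a = sps.butter(3, [lo / nyq, hi / nyq], btype="band")
    padlen = min(3 * max(len(a), len(b)), x.shape[axis] - 1)
    return sps.filtfilt(b, a, x, axis=axis, padlen=padlen)


def cardiac_band_amplitude(
    registered: RegisteredSeries,
    band_hz: tuple[float, float] = (0.6, 2.0),
) -> np.ndarray:
    """Per-voxel cardiac-band amplitude map (2*sqrt(2)*RMS of the
    band-passed time course, i.e. the peak-to-trough of an equivalent
    sinusoid).  Used to locate the full-blood region before any cardiac
    phase exists."""
    fs = 1.0 / registered.frame_interval_s
    T, ny, nx = registered.frames.shape
    flat = registered.frames.reshape(T, -1)
    bp = _bandpass(flat - flat.mean(axis=0), band_hz, fs)
    rms = np.sqrt(np.mean(bp**2, axis=0))
    return (2.0 * np.sqrt(2.0) * rms).reshape(ny, nx)


def cardiac_filtered_series(
    registered: RegisteredSeries,
    band_hz: tuple[float, float] = (0.6, 2.0),
) -> RegisteredSeries:
    """Copy of the registered series with only the cardiac band retained.

    Phase-sorting the raw signal into cardiac bins leaves respiratory
    leakage in the per-bin means (the slow component does not average to
    the same value in every cardiac bin over a finite series), which biases
    cardiac amplitudes upward; band-passing each voxel's time course first
    isolates the blood-inflow component.
    """
    fs = 1.0 / registered.frame_interval_s
    T = registered.frames.shape[0]
    flat = registered.frames.reshape(T, -1)
    bp = _bandpass(flat - flat.mean(axis=0), band_hz, fs)
    return RegisteredSeries(
        frames=bp.reshape(registered.frames.shape),
        reference_frame_index=registered.reference_frame_index,
        displacement_magnitude_px=registered.displacement_magnitude_px,
        frame_interval_s=registered.frame_interval_s,
        flagged_frames=registered.flagged_frames,
    )


def extract_cardiac_phase(
    registered: RegisteredSeries,
    blood_seed: np.ndarray,
    band_hz: tuple[float, float] = (0.6, 2.0),
    min_band_fraction: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Per-frame cardiac phase in [0, 1) from the blood-seed mean signal.

    The seed-region mean is band-passed; the dominant frequency is the
    spectral-magnitude peak in the band.  The band-passed RMS must carry
    at least ``min_band_fraction`` of the total AC RMS, otherwise the seed
    carries no cardiac signal to phase-sort (a purely respiratory series
    leaks only ~0.5 % of its power into the cardiac band).  Phase is the
    analytic-signal angle, shifted so that phase 0 sits at signal maxima
    (peak inflow).

    Returns (phase, detected frequency in Hz).
    """
    blood_seed = np.asarray(blood_seed, dtype=bool)
    if not blood_seed.any():
        raise ValueError("blood seed region is empty")
    fs = 1.0 / registered.frame_interval_s
    x = registered.frames[:, blood_seed].mean(axis=1)
    x = x - x.mean()

    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        raise ValueError(f"cardiac band {band_hz} contains no spectral bins")
    f_card = float(freqs[in_band][np.argmax(spec[in_band])])

    bp = _bandpass(x, band_hz, fs)
    total_rms = np.sqrt(np.mean(x**2))
    band_rms = np.sqrt(np.mean(bp**2))
    if total_rms == 0 or band_rms / total_rms < min_band_fraction:
        frac = 0.0 if total_rms == 0 else band_rms / total_rms
        raise ValueError(
            "no cardiac signal: cardiac band carries only "
            f"{100 * frac:.2f} % of the seed signal's AC power"
        )
    analytic = sps.hilbert(bp)
    phase = np.mod(np.angle(analytic) / (2.0 * np.pi), 1.0)
    return phase, f_card


def reconstruct_cycle(
    registered: RegisteredSeries,
    phases: np.ndarray,
    mask: np.ndarray,
    n_bins: int = 15,
    max_empty_fraction: float = 0.3,
) -> PhaseResolvedCycle:
    """Sort frames into phase bins and average per voxel.

    Frame i goes to bin floor(phase_i * n_bins) (phases exactly 1.0 wrap to
    bin 0); frames with undefined (NaN) phase are skipped.  Empty bins are
    filled by circular linear interpolation between the nearest occupied
    bins and flagged; more than ``max_empty_fraction`` empty bins is an
    error (insufficient phase coverage).
    """
    if n_bins < 5:
        raise ValueError("need at least 5 phase bins")
    phases = np.asarray(phases, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    usable = np.isfinite(phases)
    if usable.sum() < n_bins:
        raise ValueError("fewer usable frames than phase bins")
    bins = np.floor(np.mod(phases[usable], 1.0) * n_bins).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    frames = registered.frames[usable]

    ny, nx = mask.shape
    values = np.zeros((n_bins, ny, nx))
    occupancy = np.bincount(bins, minlength=n_bins)
    # accumulate frame-by-frame in time order: bit-reproducible against a
    # per-voxel loop that sums assigned frames in the same order
    for i in range(frames.shape[0]):
        values[bins[i]] += frames[i]
    for b in range(n_bins):
        if occupancy[b]:
            values[b] /= occupancy[b]

    empty = occupancy == 0
    if empty.mean() > max_empty_fraction:
        raise ValueError(
            f"insufficient phase coverage: {empty.sum()}/{n_bins} bins empty"
        )
    if empty.any():
        occ_idx = np.flatnonzero(~empty)
        for b in np.flatnonzero(empty):
            # nearest occupied neighbours on the circle
            dist_fwd = (occ_idx - b) % n_bins
            dist_bwd = (b - occ_idx) % n_bins
            nxt = occ_idx[np.argmin(np.where(dist_fwd == 0, n_bins, dist_fwd))]
            prv = occ_idx[np.argmin(np.where(dist_bwd == 0, n_bins, dist_bwd))]
            d_p = (b - prv) % n_bins
            d_n = (nxt - b) % n_bins
            w = d_p / (d_p + d_n)
            values[b] = (1 - w) * values[prv] + w * values[nxt]
    values[:, ~mask] = np.nan
    return PhaseResolvedCycle(
        values=values, occupancy=occupancy, interpolated=empty, mask=mask
    )


def select_mid_bin(cycle: PhaseResolvedCycle) -> int:
    """Mid-expiration bin of a respiratory cycle.

    The mask-mean per-bin signal has its maximum at end-expiration (bin
    near 0 by phase construction) and its minimum at end-inspiration; the
    mid-expiration bin is the one on the expiratory return (from the
    minimum bin forward, wrapping, up to the maximum bin) whose mean signal
    is closest to the midpoint of the two extremes.  Earliest bin wins ties.
    """
    mean_cycle = np.nanmean(cycle.values[:, cycle.mask], axis=1)
    b_max = int(np.argmax(mean_cycle))
    b_min = int(np.argmin(mean_cycle))
    if b_max == b_min:
        raise ValueError("flat cycle: no respiratory modulation")
    target = 0.5 * (mean_cycle[b_max] + mean_cycle[b_min])
    n = cycle.n_bins
    seg = [(b_min + k) % n for k in range(1, (b_max - b_min) % n)]
    if not seg:
        seg = [b_min]
    dists = [abs(mean_cycle[b] - target) for b in seg]
    return int(seg[int(np.argmin(dists))])


def compute_ventilation_map(
    resp_cycle: PhaseResolvedCycle, mid_bin: int
) -> QuantitativeMap:
    """Regional ventilation (%) per voxel.

    RV = 100 * (S_mid/S_insp - S_mid/S_exp) with S_insp/S_exp the
    per-voxel minimum/maximum over the reconstructed respiratory cycle and
    S_mid the value at ``mid_bin``.  Voxels with non-positive S_insp or no
    temporal variance are no-data.
    """
    if not (0 <= mid_bin < resp_cycle.n_bins):
        raise IndexError(f"mid bin {mid_bin} out of range")
    vals = resp_cycle.values
    with np.errstate(invalid="ignore", divide="ignore"):
        s_insp = np.min(vals, axis=0)
        s_exp = np.max(vals, axis=0)
        s_mid = vals[mid_bin]
        rv = 100.0 * (s_mid / s_insp - s_mid / s_exp)
    rv[~resp_cycle.mask] = np.nan
    rv[resp_cycle.mask & (s_insp <= 0)] = np.nan
    rv[resp_cycle.mask & (s_exp == s_insp)] = 0.0
    return QuantitativeMap(values=rv, kind="ventilation_pct", mask=resp_cycle.mask)


def compute_perfusion_map(
    card_cycle: PhaseResolvedCycle, blood_region: np.ndarray
) -> QuantitativeMap:
    """Normalized perfusion (%) per voxel.

    Per-voxel amplitude is the peak-to-trough of the reconstructed cardiac
    cycle; values are scaled so the full-blood region's mean amplitude is
    100 % by construction.
    """
    blood_region = np.asarray(blood_region, dtype=bool)
    vals = card_cycle.values
    amp = np.max(vals, axis=0) - np.min(vals, axis=0)
    ref = float(np.nanmean(amp[blood_region]))
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError("blood region has zero cardiac amplitude")
    q = 100.0 * amp / ref
    q[~card_cycle.mask] = np.nan
    return QuantitativeMap(values=q, kind="perfusion_pct", mask=card_cycle.mask)


def healthy_reference_region(
    vent_map: QuantitativeMap, min_voxels: int = 10
) -> np.ndarray:
    """Largest 4-connected region between the 80th and 90th ventilation
    percentiles (linear-interpolation percentiles over valid lung voxels)."""
    valid = vent_map.valid
    if valid.sum() < min_voxels:
        raise ValueError(f"too few valid lung voxels ({int(valid.sum())})")
    vals = vent_map.values[valid]
    p80, p90 = np.percentile(vals, [80, 90], method="linear")
    sel = valid & (vent_map.values >= p80) & (vent_map.values <= p90)
    if not sel.any():
        raise ValueError("empty healthy-reference selection")
    lab, count = ndimage.label(sel, structure=STRUCTURE_4)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, count + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _flow_curves(resp_cycle: PhaseResolvedCycle) -> np.ndarray:
    """Circular central-difference flow of the per-voxel volume proxy."""
    v = resp_cycle.values
    return 0.5 * (np.roll(v, -1, axis=0) - np.roll(v, 1, axis=0))


def compute_fvl_correlation_map(
    resp_cycle: PhaseResolvedCycle, reference_region: np.ndarray
) -> QuantitativeMap:
    """Flow-volume-loop correlation map.

    Per voxel, the volume proxy is the reconstructed respiratory-cycle
    signal; flow is its circular central difference across phase bins.  The
    map value is the Pearson correlation between the voxel's flow curve and
    the reference region's mean flow curve, in [-1, 1]; zero-variance
    voxels are no-data.
    """
    reference_region = np.asarray(reference_region, dtype=bool)
    if not reference_region.any():
        raise ValueError("reference region is empty")
    flow = _flow_curves(resp_cycle)
    ref_flow = flow[:, reference_region].mean(axis=1)
    ref_c = ref_flow - ref_flow.mean()
    ref_norm = np.sqrt((ref_c**2).sum())
    if ref_norm == 0:
        raise ValueError("reference flow curve has zero variance")

    n, ny, nx = flow.shape
    f = flow.reshape(n, -1)
    fc = f - f.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        norms = np.sqrt((fc**2).sum(axis=0))
        r = (fc * ref_c[:, None]).sum(axis=0) / (norms * ref_norm)
    r = r.reshape(ny, nx)
    r[~resp_cycle.mask] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return QuantitativeMap(values=r, kind="fvl_correlation", mask=resp_cycle.mask)
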