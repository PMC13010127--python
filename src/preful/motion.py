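"""Respiratory signal extraction, mid-expiration selection, and registration.

The global lung signal tracks breathing because parenchymal proton density
is diluted on inspiration: end-expiration is the signal *maximum*.  A
zero-lag low-pass isolates the respiratory component, end-expiration peaks
and end-inspiration troughs are detected, and a respiratory phase in
[0, 1) is assigned by linear time interpolation between consecutive
end-expiration peaks (phase 0 at each peak).  All frames are then warped
nonrigidly onto the mid-expiration reference frame with a symmetric-forces
demons registration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import signal as sps

from .io import ImageSeries, RunConfig

__all__ = [
    "RespiratorySignal",
    "RegisteredSeries",
    "coarse_body_mask",
    "global_lung_signal",
    "extract_respiratory_signal",
    "select_mid_expiration_frame",
    "register_series",
]


@dataclass
class RespiratorySignal:
    """Per-frame respiratory surrogate and its phase decomposition."""

    raw: np.ndarray
    smoothed: np.ndarray
    end_expiration_peaks: np.ndarray  # frame indices, signal maxima
    end_inspiration_troughs: np.ndarray  # frame indices, signal minima
    phase: np.ndarray  # [0,1) between first/last peak, NaN outside
    frame_interval_s: float
    est_freq_hz: float

    @property
    def usable(self) -> np.ndarray:
        """Frames with a defined respiratory phase."""
        return np.isfinite(self.phase)


@dataclass
class RegisteredSeries:
    """All frames warped onto the reference-frame geometry."""

    frames: np.ndarray
    reference_frame_index: int
    displacement_magnitude_px: np.ndarray  # per-frame mean |u|
    displacement_fields: np.ndarray | None = None  # (T, ny, nx, 2) as (dy, dx)
    frame_interval_s: float = 1.0
    flagged_frames: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def coarse_body_mask(series: ImageSeries) -> np.ndarray:
    """Coarse body-minus-bright-core mask from the temporal mean image.

    Used for the global respiratory surrogate before any proper
    segmentation exists (which itself needs the registered series): body by
    the lower threshold of a 3-class multi-Otsu on the temporal mean (air /
    lung / soft tissue), minus the brightest decile inside it (large
    vessels / mediastinal core whose cardiac pulsation would contaminate
    the respiratory surrogate).
    """
    from skimage.filters import threshold_multiotsu
    from scipy import ndimage

    mean_img = series.frames.mean(axis=0)
    try:
        t_low = threshold_multiotsu(mean_img, classes=3)[0]
    except ValueError:
        t_low = float(mean_img.mean())
    body = mean_img > t_low
    body = ndimage.binary_fill_holes(body)
    lab, n = ndimage.label(body)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        body = lab == (1 + int(np.argmax(sizes)))
    core = mean_img > np.percentile(mean_img[body], 90)
    mask = body & ~core
    if not mask.any():
        mask = body
    return mask


def global_lung_signal(series: ImageSeries, coarse_mask: np.ndarray) -> np.ndarray:
    """Mean signal inside ``coarse_mask`` per frame."""
    coarse_mask = np.asarray(coarse_mask, dtype=bool)
    if not coarse_mask.any():
        raise ValueError("coarse mask is empty")
    return series.frames[:, coarse_mask].mean(axis=1)


def _zero_lag_lowpass(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        return x.copy()
    b, a = sps.butter(3, cutoff_hz / nyq, btype="low")
    padlen = min(3 * max(len(a), len(b)), x.size - 1)
    return sps.filtfilt(b, a, x, padlen=padlen)


def lowpass_frames(series: ImageSeries, cutoff_hz: float) -> np.ndarray:
    """Per-voxel zero-lag low-pass of the whole series (registration
    guidance: keeps respiratory motion, drops cardiac intensity change)."""
    fs = 1.0 / series.frame_interval_s
    T = series.n_frames
    flat = series.frames.reshape(T, -1)
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        return series.frames.copy()
    b, a = sps.butter(3, cutoff_hz / nyq, btype="low")
    padlen = min(3 * max(len(a), len(b)), T - 1)
    out = sps.filtfilt(b, a, flat, axis=0, padlen=padlen)
    return out.reshape(series.frames.shape)


def _dominant_freq(x: np.ndarray, fs: float, fmax: float) -> float:
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    in_band = (freqs > 0) & (freqs <= fmax)
    if not in_band.any() or spec[in_band].max() == 0:
        return 0.0
    return float(freqs[in_band][np.argmax(spec[in_band])])


def extract_respiratory_signal(
    series: ImageSeries,
    coarse_mask: np.ndarray,
    cutoff_hz: float = 0.5,
) -> RespiratorySignal:
    """Low-pass the global signal and decompose it into breaths.

    Raises if fewer than two end-expiration peaks are found (series too
    short, or no respiratory modulation present).
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    fs = 1.0 / series.frame_interval_s
    raw = global_lung_signal(series, coarse_mask)
    smoothed = _zero_lag_lowpass(raw, cutoff_hz, fs)

    f_est = _dominant_freq(smoothed, fs, cutoff_hz)
    if f_est <= 0:
        raise ValueError(
            "no respiratory frequency detectable below the cutoff; "
            "series too short or motionless"
        )
    min_sep = max(int(round(0.5 / f_est * fs)), 1)
    amp = smoothed.max() - smoothed.min()
    prom = 0.1 * amp if amp > 0 else None
    peaks, _ = sps.find_peaks(smoothed, distance=min_sep, prominence=prom)
    troughs, _ = sps.find_peaks(-smoothed, distance=min_sep, prominence=prom)
    if peaks.size < 2:
        raise ValueError(
            f"fewer than 2 breaths detected ({peaks.size} end-expiration peaks); "
            "series too short or motionless"
        )

    phase = np.full(series.n_frames, np.nan)
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        idx = np.arange(p0, p1)
        phase[idx] = (idx - p0) / (p1 - p0)
    phase[peaks[-1]] = 0.0
    return RespiratorySignal(
        raw=raw,
        smoothed=smoothed,
        end_expiration_peaks=peaks,
        end_inspiration_troughs=troughs,
        phase=phase,
        frame_interval_s=series.frame_interval_s,
        est_freq_hz=f_est,
    )


def select_mid_expiration_frame(resp: RespiratorySignal) -> int:
    """Frame whose smoothed signal is closest to mid-position on an
    expiratory limb.

    The target level is the midpoint between the median end-expiration peak
    level and the median end-inspiration trough level.  Candidate frames are
    taken from the descending segments that leave each end-expiration peak
    (down to the following trough, or the end of the series); ties break to
    the earliest frame.
    """
    s = resp.smoothed
    peaks = resp.end_expiration_peaks
    if peaks.size < 1:
        raise ValueError("no full breath present")
    trough_levels = (
        s[resp.end_inspiration_troughs]
        if resp.end_inspiration_troughs.size
        else np.array([s.min()])
    )
    target = 0.5 * (np.median(s[peaks]) + np.median(trough_levels))

    candidates: list[int] = []
    for p in peaks:
        later_troughs = resp.end_inspiration_troughs[resp.end_inspiration_troughs > p]
        end = int(later_troughs[0]) if later_troughs.size else s.size - 1
        candidates.extend(range(int(p), end + 1))
    candidates = sorted(set(candidates))
    dist = np.array([abs(s[i] - target) for i in candidates])
    return int(candidates[int(np.argmin(dist))])


def _demons_register(
    moving: np.ndarray,
    reference: np.ndarray,
    iterations: int,
    smoothing_sigma: float,
    intensity_threshold: float = 0.0,
) -> np.ndarray:
    """Register one frame to the reference; return the (dy, dx) field.

    ``intensity_threshold`` (absolute signal units): intensity differences
    below it exert no demons force, so slow signal-intensity changes
    (parenchymal compression, blood inflow) are not mistaken for motion.
    """
    ref = sitk.GetImageFromArray(reference.astype(np.float64))
    mov = sitk.GetImageFromArray(moving.astype(np.float64))
    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetNumberOfIterations(iterations)
    demons.SetStandardDeviations(smoothing_sigma)
    if intensity_threshold > 0:
        demons.SetIntensityDifferenceThreshold(intensity_threshold)
    field = demons.Execute(ref, mov)
    arr_field = sitk.GetArrayFromImage(field)  # (ny, nx, 2) as (dx, dy)
    return arr_field[..., ::-1]


def _apply_field(moving: np.ndarray, field_dydx: np.ndarray) -> np.ndarray:
    """Resample ``moving`` through a (dy, dx) displacement field (pull)."""
    ny, nx = moving.shape
    rows, cols = np.mgrid[0:ny, 0:nx].astype(float)
    from scipy import ndimage
    return ndimage.map_coordinates(
        moving, [rows + field_dydx[..., 0], cols + field_dydx[..., 1]],
        order=1, mode="nearest",
    )


def register_series(
    series: ImageSeries,
    reference_frame_index: int,
    config: RunConfig | None = None,
    keep_fields: bool = True,
    guidance_frames: np.ndarray | None = None,
) -> RegisteredSeries:
    """Warp every frame nonrigidly onto the reference frame.

    A symmetric-forces demons registration with Gaussian field smoothing;
    the reference frame is passed through untouched.  The displacement
    fields are in pixels, ordered (dy, dx), and map reference coordinates
    to moving-frame coordinates (pull convention).

    ``guidance_frames``, when given, are used to *estimate* the fields
    while the warp is applied to ``series.frames``: passing a temporally
    low-passed copy of the series lets the solver see respiratory motion
    but not cardiac blood-inflow intensity changes, which are signal, not
    displacement.
    """
    cfg = config or RunConfig()
    if not (0 <= reference_frame_index < series.n_frames):
        raise IndexError(f"reference frame {reference_frame_index} out of range")
    guide = series.frames if guidance_frames is None else np.asarray(guidance_frames)
    if guide.shape != series.frames.shape:
        raise ValueError("guidance frames must match the series shape")
    ref_guide = guide[reference_frame_index]
    lo, hi = np.percentile(ref_guide, [1, 99])
    intensity_thresh = cfg.registration_intensity_threshold_frac * (hi - lo)
    ref = series.frames[reference_frame_index]
    ny, nx = ref.shape
    out = np.empty_like(series.frames)
    mags = np.zeros(series.n_frames)
    fields = np.zeros((series.n_frames, ny, nx, 2)) if keep_fields else None
    flagged = []
    for i in range(series.n_frames):
        if i == reference_frame_index:
            out[i] = ref
            continue
        try:
            field = _demons_register(
                guide[i], ref_guide,
                cfg.registration_iterations, cfg.registration_smoothing_sigma,
                intensity_thresh,
            )
            warped = _apply_field(series.frames[i], field)
        except RuntimeError as exc:  # pragma: no cover - solver failure path
            warnings.warn(f"registration failed for frame {i}: {exc}", stacklevel=2)
            flagged.append(i)
            out[i] = series.frames[i]
            continue
        if not np.all(np.isfinite(warped)):
            warnings.warn(f"registration produced non-finite values at frame {i}",
                          stacklevel=2)
            flagged.append(i)
            out[i] = series.frames[i]
            continue
        out[i] = warped
        mags[i] = float(np.hypot(field[..., 0], field[..., 1]).mean())
        if fields is not None:
            fields[i] = field
    return RegisteredSeries(
        frames=out,
        reference_frame_index=reference_frame_index,
        displacement_magnitude_px=mags,
        displacement_fields=fields,
        frame_interval_s=series.frame_interval_s,
        flagged_frames=np.array(flagged, dtype=int),
    )
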