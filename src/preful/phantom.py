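"""Seeded dynamic lung MRI phantom with analytic ground truth.

The phantom emulates a single coronal free-breathing 2D+t proton-MRI slice:
parenchymal signal is compressed over the respiratory cycle (proton-density
dilution, so end-expiration is the signal maximum), blood-supplied voxels
pulse over the cardiac cycle, the diaphragm displaces the caudal lung, and
optional Gaussian (or Rician) noise is added.  Every generated series ships
with the analytic truth needed to verify the downstream pipeline: masks,
the per-voxel ventilation and perfusion-amplitude truth maps, the phase
waveforms, and the per-frame displacement truth.

Signal model, per voxel x and frame time t::

    lung:   S(x,t) = S0(x) * (1 - a(x) * r(t)) + A_q(x) * c(t)
    blood:  S(x,t) = S0(x) + A_q(x) * c(t)
    other:  S(x,t) = S0(x)

with r(t), c(t) periodic waveforms in [0, 1] (r = 0 at end-expiration,
r = 1 at end-inspiration), a(x) the local compression amplitude and A_q(x)
the cardiac pulsation amplitude in signal units.  The regional-ventilation
value this model implies analytically is

    RV(x) = 100 * (1 - a(x)/2) * a(x) / (1 - a(x))   [percent]

(the mid-position signal divided by the cycle minimum, minus the same
divided by the cycle maximum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .io import ImageSeries

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "DefectRegion",
    "generate_phantom",
    "resp_waveform",
    "cardiac_waveform",
    "insert_defect_regions",
    "analytic_ventilation_pct",
]

#: fraction of the cycle spent inspiring in the asymmetric waveform
_ASYM_INSP_FRACTION = 0.35


def analytic_ventilation_pct(a: np.ndarray | float) -> np.ndarray | float:
    """Regional ventilation (%) implied by a compression amplitude ``a``.

    RV = 100 * (1 - a/2) * a / (1 - a); e.g. a=0.10 -> 10.556 %.
    """
    a = np.asarray(a, dtype=float)
    out = 100.0 * (1.0 - 0.5 * a) * a / (1.0 - a)
    return out if out.ndim else float(out)


def resp_waveform(
    t: np.ndarray | float,
    freq: float,
    shape: Literal["sinusoid", "asymmetric"] = "sinusoid",
) -> np.ndarray | float:
    """Respiratory waveform r(t) in [0, 1]; 0 = end-expiration, 1 = end-inspiration.

    Parameters
    ----------
    t : seconds
    freq : breathing frequency in Hz, must be positive
    shape : "sinusoid" (raised cosine) or "asymmetric" (inspiration occupies
        35 % of the period, expiration the remaining 65 %)
    """
    if freq <= 0:
        raise ValueError(f"respiratory frequency must be positive, got {freq}")
    t = np.asarray(t, dtype=float)
    if shape == "sinusoid":
        out = 0.5 * (1.0 - np.cos(2.0 * np.pi * freq * t))
    elif shape == "asymmetric":
        phase = np.mod(freq * t, 1.0)
        p = _ASYM_INSP_FRACTION
        insp = 0.5 * (1.0 - np.cos(np.pi * phase / p))
        exp = 0.5 * (1.0 + np.cos(np.pi * (phase - p) / (1.0 - p)))
        out = np.where(phase < p, insp, exp)
    else:  # pragma: no cover - guarded by type hints
        raise ValueError(f"unknown waveform shape {shape!r}")
    return out if out.ndim else float(out)


def cardiac_waveform(t: np.ndarray | float, freq: float) -> np.ndarray | float:
    """Cardiac blood-inflow waveform c(t) in [0, 1] (raised cosine, c(0)=0)."""
    if freq <= 0:
        raise ValueError(f"cardiac frequency must be positive, got {freq}")
    t = np.asarray(t, dtype=float)
    out = 0.5 * (1.0 - np.cos(2.0 * np.pi * freq * t))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DefectRegion:
    """Elliptical defect inserted into a truth mask.

    ``center`` and ``radii`` are in pixels (row, col).  ``multiplier``
    scales the local amplitude: 0 kills the modulation entirely, 1 leaves
    it untouched.
    """

    center: tuple[float, float]
    radii: tuple[float, float]
    multiplier: float = 0.1

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        dr = (rows - self.center[0]) / self.radii[0]
        dc = (cols - self.center[1]) / self.radii[1]
        return dr * dr + dc * dc <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of the synthetic dynamic series.

    Defaults follow the emulated acquisition: 128x128 matrix, 250 frames at
    300 ms (74.7 s first-to-last), breathing at 0.25 Hz and cardiac
    pulsation at 1.2 Hz, well below the 1.667 Hz Nyquist limit of the
    3.33 Hz frame rate.
    """

    grid_shape: tuple[int, int] = (128, 128)
    n_frames: int = 250
    frame_interval_s: float = 0.3
    resp_freq_hz: float = 0.25
    cardiac_freq_hz: float = 1.2
    resp_shape: Literal["sinusoid", "asymmetric"] = "sinusoid"
    vent_amplitude: float = 0.10
    perf_amplitude_lung: float = 4.0
    perf_amplitude_blood: float = 40.0
    baseline_background: float = 10.0
    baseline_body: float = 120.0
    baseline_lung: float = 55.0
    baseline_blood: float = 200.0
    vent_defect_regions: tuple[DefectRegion, ...] = ()
    perf_defect_regions: tuple[DefectRegion, ...] = ()
    diaphragm_motion_px: float = 0.0
    noise_sigma: float = 0.0
    noise_model: Literal["gaussian", "rician"] = "gaussian"
    pixel_spacing_mm: tuple[float, float] = (1.7, 1.7)
    seed: int = 0

    def validate(self) -> None:
        ny, nx = self.grid_shape
        if ny < 16 or nx < 16:
            raise ValueError(
                f"grid {self.grid_shape} is degenerate; need at least 16 px per side"
            )
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")
        nyquist = 1.0 / (2.0 * self.frame_interval_s)
        if self.cardiac_freq_hz >= nyquist:
            raise ValueError(
                f"cardiac frequency {self.cardiac_freq_hz} Hz is at or above the "
                f"Nyquist limit {nyquist:.3f} Hz of the frame rate; the pulsation "
                "would alias and cannot be recovered"
            )
        if not (0.0 <= self.vent_amplitude < 1.0):
            raise ValueError("vent_amplitude must lie in [0, 1)")
        for reg in (*self.vent_defect_regions, *self.perf_defect_regions):
            if not (0.0 <= reg.multiplier <= 1.0):
                raise ValueError("defect amplitude multipliers must lie in [0, 1]")
        if self.resp_freq_hz <= 0:
            raise ValueError("respiratory frequency must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vent_defect_regions"] = [asdict(r) for r in self.vent_defect_regions]
        d["perf_defect_regions"] = [asdict(r) for r in self.perf_defect_regions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("vent_defect_regions", "perf_defect_regions"):
            d[key] = tuple(
                DefectRegion(
                    center=tuple(r["center"]),
                    radii=tuple(r["radii"]),
                    multiplier=r.get("multiplier", 0.1),
                )
                for r in d.get(key, ())
            )
        for key in ("grid_shape", "pixel_spacing_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Analytic truth accompanying a generated phantom series."""

    lung_mask: np.ndarray
    blood_region_mask: np.ndarray
    body_mask: np.ndarray
    true_ventilation_map: np.ndarray
    true_perfusion_amplitude_map: np.ndarray
    vent_defect_mask: np.ndarray
    perf_defect_mask: np.ndarray
    resp_phase: np.ndarray
    cardiac_phase: np.ndarray
    resp_value: np.ndarray
    displacement_field_truth: np.ndarray  # (n_frames, ny, nx) vertical px offsets
    vent_defect_area_fraction: float
    perf_defect_area_fraction: float

    def __post_init__(self) -> None:
        assert not np.any(self.vent_defect_mask & ~self.lung_mask)
        assert not np.any(self.perf_defect_mask & ~self.lung_mask)
        assert not np.any(self.blood_region_mask & self.lung_mask)


def defect_covering_fraction(
    spec: PhantomSpec,
    fraction: float,
    lung: Literal["left", "right"] = "left",
    multiplier: float = 0.1,
) -> DefectRegion:
    """Elliptical defect sized to cover ``fraction`` of the *total* lung area.

    The defect is a scaled copy of one lung ellipse, concentric with it, so
    it lies fully inside that lung; with two equal lungs a scale factor of
    sqrt(2*fraction) yields the requested total-area fraction (fraction
    must be below 0.5).
    """
    if not (0.0 < fraction < 0.5):
        raise ValueError("fraction must lie in (0, 0.5) for a single-lung defect")
    ny, nx = spec.grid_shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    sign = -1.0 if lung == "left" else 1.0
    scale = float(np.sqrt(2.0 * fraction))
    return DefectRegion(
        center=(cy, cx + sign * 0.21 * nx),
        radii=(scale * 0.32 * ny, scale * 0.14 * nx),
        multiplier=multiplier,
    )


def _anatomy(spec: PhantomSpec):
    """Static anatomy masks: body ellipse, two lung ellipses, aorta disc."""
    ny, nx = spec.grid_shape
    rows, cols = np.mgrid[0:ny, 0:nx].astype(float)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0

    def ellipse(c_row, c_col, r_row, r_col):
        return ((rows - c_row) / r_row) ** 2 + ((cols - c_col) / r_col) ** 2 <= 1.0

    body = ellipse(cy, cx, 0.46 * ny, 0.42 * nx)
    lung_l = ellipse(cy, cx - 0.21 * nx, 0.32 * ny, 0.14 * nx)
    lung_r = ellipse(cy, cx + 0.21 * nx, 0.32 * ny, 0.14 * nx)
    lungs = lung_l | lung_r
    # aorta: small bright disc in the inter-lung corridor, slightly cranial
    blood = ellipse(cy - 0.08 * ny, cx, 0.05 * ny, 0.035 * nx)
    blood &= ~lungs
    return body, lungs, blood, rows, cols


def insert_defect_regions(
    lung_mask: np.ndarray,
    regions: Sequence[DefectRegion],
    seed: int = 0,
) -> np.ndarray:
    """Rasterize elliptical defect regions, clipped to the lung mask.

    Regions entirely outside the lung contribute nothing (with a warning).
    The ``seed`` argument is accepted for interface stability; the current
    region shapes are deterministic ellipses and do not consume randomness.
    """
    out = np.zeros_like(lung_mask, dtype=bool)
    ny, nx = lung_mask.shape
    rows, cols = np.mgrid[0:ny, 0:nx].astype(float)
    for reg in regions:
        inside = reg.contains(rows, cols)
        clipped = inside & lung_mask
        if inside.any() and not clipped.any():
            warnings.warn(
                f"defect region centered at {reg.center} lies fully outside the "
                "lung; it contributes no defect voxels",
                stacklevel=2,
            )
            continue
        out |= clipped
    return out


def _defect_multiplier_map(
    lung_mask: np.ndarray, regions: Sequence[DefectRegion]
) -> np.ndarray:
    """Per-voxel amplitude multiplier (1 outside defects)."""
    mult = np.ones(lung_mask.shape, dtype=float)
    ny, nx = lung_mask.shape
    rows, cols = np.mgrid[0:ny, 0:nx].astype(float)
    for reg in regions:
        inside = reg.contains(rows, cols) & lung_mask
        mult[inside] = np.minimum(mult[inside], reg.multiplier)
    return mult


def _vertical_warp(frame: np.ndarray, ramp: np.ndarray, shift: float) -> np.ndarray:
    """Pull-warp ``frame`` down by ``shift * ramp`` pixels (linear interp)."""
    ny, nx = frame.shape
    rows, cols = np.mgrid[0:ny, 0:nx].astype(float)
    src_rows = rows - shift * ramp
    return ndimage.map_coordinates(frame, [src_rows, cols], order=1, mode="nearest")


def generate_phantom(spec: PhantomSpec) -> tuple[ImageSeries, GroundTruth]:
    """Generate the dynamic series and its analytic ground truth.

    Identical ``spec`` (including ``seed``) yields bit-identical output.
    """
    spec.validate()
    ny, nx = spec.grid_shape
    body, lungs, blood, rows, cols = _anatomy(spec)

    vent_defects = insert_defect_regions(lungs, spec.vent_defect_regions, spec.seed)
    perf_defects = insert_defect_regions(lungs, spec.perf_defect_regions, spec.seed)
    vent_mult = _defect_multiplier_map(lungs, spec.vent_defect_regions)
    perf_mult = _defect_multiplier_map(lungs, spec.perf_defect_regions)

    a_map = np.where(lungs, spec.vent_amplitude * vent_mult, 0.0)
    q_map = np.where(lungs, spec.perf_amplitude_lung * perf_mult, 0.0)
    q_map = np.where(blood, spec.perf_amplitude_blood, q_map)

    s0 = np.full((ny, nx), spec.baseline_background)
    s0[body] = spec.baseline_body
    s0[lungs] = spec.baseline_lung
    s0[blood] = spec.baseline_blood

    t = np.arange(spec.n_frames) * spec.frame_interval_s
    r = np.asarray(resp_waveform(t, spec.resp_freq_hz, spec.resp_shape))
    c = np.asarray(cardiac_waveform(t, spec.cardiac_freq_hz))

    # diaphragm ramp: 0 above the lung apex, 1 at/below the caudal lung edge
    if spec.diaphragm_motion_px != 0.0:
        lung_rows = np.where(lungs.any(axis=1))[0]
        top, bottom = lung_rows[0], lung_rows[-1]
        ramp = np.clip((rows - top) / max(bottom - top, 1), 0.0, 1.0)
    else:
        ramp = None

    rng = np.random.default_rng(spec.seed)
    frames = np.empty((spec.n_frames, ny, nx), dtype=float)
    displacement = np.zeros((spec.n_frames, ny, nx), dtype=float)
    for i in range(spec.n_frames):
        frame = s0 * (1.0 - a_map * r[i]) + q_map * c[i]
        if ramp is not None:
            shift = spec.diaphragm_motion_px * r[i]
            frame = _vertical_warp(frame, ramp, shift)
            displacement[i] = shift * ramp
        frames[i] = frame
    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, frames.shape)
        if spec.noise_model == "rician":
            noise2 = rng.normal(0.0, spec.noise_sigma, frames.shape)
            frames = np.hypot(frames + noise, noise2)
        else:
            frames = frames + noise

    series = ImageSeries(
        frames=frames,
        pixel_spacing_mm=spec.pixel_spacing_mm,
        frame_interval_s=spec.frame_interval_s,
        identifier=f"phantom-seed{spec.seed}",
    )
    n_lung = int(lungs.sum())
    truth = GroundTruth(
        lung_mask=lungs,
        blood_region_mask=blood,
        body_mask=body,
        true_ventilation_map=np.where(lungs, analytic_ventilation_pct(a_map), np.nan),
        true_perfusion_amplitude_map=q_map,
        vent_defect_mask=vent_defects,
        perf_defect_mask=perf_defects,
        resp_phase=np.mod(spec.resp_freq_hz * t, 1.0),
        cardiac_phase=np.mod(spec.cardiac_freq_hz * t, 1.0),
        resp_value=r,
        displacement_field_truth=displacement,
        vent_defect_area_fraction=float(vent_defects.sum()) / n_lung,
        perf_defect_area_fraction=float(perf_defects.sum()) / n_lung,
    )
    return series, truth
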