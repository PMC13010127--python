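"""Readers/writers for the formats the pipeline touches, and run configuration.

Dynamic series are stored as 4D NIfTI (X x Y x 1 x T) with the frame
interval in the header; masks are 0/1 integer NIfTI aligned voxel-for-voxel
with the series; subject tables are plain CSV; configuration is YAML; metric
reports go out as JSON and CSV.  DICOM series directories are read-only
inputs, sorted into acquisition order by instance/acquisition metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
import yaml

__all__ = [
    "ImageSeries",
    "SubjectRecord",
    "RunConfig",
    "read_series",
    "write_series",
    "read_mask",
    "write_mask",
    "write_map",
    "read_map",
    "write_report",
    "read_subject_table",
    "REPORT_COLUMNS",
]

#: report columns, named per the standard measure abbreviations
REPORT_COLUMNS = [
    "id",
    "V",
    "Q",
    "VDP",
    "QDP",
    "VQM defect",
    "VQM non-defect",
]


@dataclass
class ImageSeries:
    """A 2D+t signal series S(x, t).

    ``frames`` has shape (n_frames, ny, nx), ordered in acquisition time.
    """

    frames: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    frame_interval_s: float = 1.0
    identifier: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n_frames, ny, nx); got shape {self.frames.shape}"
            )
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("series contains non-finite signal values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def duration_s(self) -> float:
        """Time from first to last frame."""
        return (self.n_frames - 1) * self.frame_interval_s


@dataclass
class SubjectRecord:
    """One row of the cohort table."""

    id: str
    group: Literal["HV", "LOPD"]
    vc_percent: float = np.nan
    fvc_percent: float = np.nan
    fev1_percent: float = np.nan
    pef_percent: float = np.nan
    niv: bool = False
    metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id or not self.group:
            raise ValueError("id and group must be non-empty")
        for name in ("vc_percent", "fvc_percent", "fev1_percent", "pef_percent"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass
class RunConfig:
    """Everything a pipeline run needs beyond the input series.

    Serializes losslessly to/from YAML so a report can always be traced to
    the exact configuration that produced it.
    """

    # defect thresholds (calibrated at 1.5 T in the source literature)
    perfusion_defect_threshold: float = 2.0
    vent_defect_fraction: float = 0.40
    fvl_defect_threshold: float = 0.9
    vdp_mode: Literal["regional_ventilation", "fvl"] = "regional_ventilation"
    # temporal filtering
    resp_lowpass_hz: float = 0.5
    cardiac_band_hz: tuple[float, float] = (0.6, 2.0)
    # phase-resolved reconstruction
    n_bins: int = 15
    # registration
    registration_iterations: int = 40
    registration_smoothing_sigma: float = 2.0
    # demons intensity-difference threshold, as a fraction of the reference
    # frame's robust intensity range: differences below it (ventilation /
    # inflow signal changes, which are signal rather than displacement)
    # produce no force
    registration_intensity_threshold_frac: float = 0.05
    # conventions
    percentile_method: str = "linear"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["cardiac_band_hz"] = list(self.cardiac_band_hz)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "cardiac_band_hz" in d:
            d["cardiac_band_hz"] = tuple(d["cardiac_band_hz"])
        return cls(**d)


def _nifti_from_frames(frames: np.ndarray, spacing, frame_interval_s) -> nib.Nifti1Image:
    # stored X x Y x 1 x T: move time last, transpose row/col to X/Y
    data = np.transpose(frames, (2, 1, 0))[:, :, np.newaxis, :]
    affine = np.diag([spacing[1], spacing[0], 1.0, 1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_zooms((spacing[1], spacing[0], 1.0, frame_interval_s))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    return img


def write_series(series: ImageSeries, path: str | Path) -> Path:
    """Write a 2D+t series as X x Y x 1 x T NIfTI."""
    path = Path(path)
    img = _nifti_from_frames(
        series.frames, series.pixel_spacing_mm, series.frame_interval_s
    )
    img.header["descrip"] = series.identifier.encode()[:79]
    nib.save(img, path)
    return path


def _read_series_nifti(path: Path, frame_interval_s: float | None) -> ImageSeries:
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[2] != 1:
        raise ValueError(
            f"{path}: expected a single-slice 2D+t volume (X x Y x 1 x T), "
            f"got shape {data.shape}; multi-slice 3D input is not supported"
        )
    zooms = img.header.get_zooms()
    dt = frame_interval_s if frame_interval_s is not None else float(zooms[3])
    if dt <= 0:
        raise ValueError(
            f"{path}: no temporal resolution in the NIfTI header; pass "
            "frame_interval_s explicitly"
        )
    frames = np.transpose(data[:, :, 0, :], (2, 1, 0)).astype(float)
    ident = ""
    try:
        ident = img.header["descrip"].tobytes().decode().rstrip("\x00")
    except Exception:
        pass
    return ImageSeries(
        frames=frames,
        pixel_spacing_mm=(float(zooms[1]), float(zooms[0])),
        frame_interval_s=dt,
        identifier=ident or path.stem,
    )


def _read_series_dicom(path: Path, frame_interval_s: float | None) -> ImageSeries:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ".ima", ""})
    datasets = []
    for f in files:
        if f.is_dir():
            continue
        try:
            datasets.append(pydicom.dcmread(f))
        except Exception:
            continue
    if not datasets:
        raise ValueError(f"{path}: no readable DICOM files found")
    # acquisition order: AcquisitionTime if present, else InstanceNumber
    def sort_key(ds):
        at = getattr(ds, "AcquisitionTime", None)
        if at not in (None, ""):
            return (0, float(at))
        return (1, int(getattr(ds, "InstanceNumber", 0)))

    datasets.sort(key=sort_key)
    frames = np.stack([ds.pixel_array.astype(float) for ds in datasets])
    spacing = getattr(datasets[0], "PixelSpacing", [1.0, 1.0])
    dt = frame_interval_s
    if dt is None:
        rep = getattr(datasets[0], "RepetitionTime", None)
        if rep not in (None, ""):
            dt = float(rep) / 1000.0
    if dt is None or dt <= 0:
        raise ValueError(
            f"{path}: DICOM headers carry no usable frame interval; pass "
            "frame_interval_s explicitly"
        )
    return ImageSeries(
        frames=frames,
        pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
        frame_interval_s=dt,
        identifier=str(getattr(datasets[0], "SeriesDescription", path.name)),
    )


def read_series(
    path: str | Path,
    format: Literal["nifti", "dicom_dir"] | None = None,
    frame_interval_s: float | None = None,
) -> ImageSeries:
    """Read a dynamic 2D+t series from NIfTI or a DICOM directory.

    ``format`` is inferred from the path when omitted.  ``frame_interval_s``
    overrides (or supplies, when the header lacks it) the temporal spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "dicom_dir" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_series_nifti(path, frame_interval_s)
    if format == "dicom_dir":
        return _read_series_dicom(path, frame_interval_s)
    raise ValueError(f"unknown series format {format!r}")


def write_mask(mask: np.ndarray, path: str | Path, spacing=(1.0, 1.0)) -> Path:
    """Write a boolean mask as 0/1 uint8 NIfTI (X x Y)."""
    path = Path(path)
    data = np.transpose(np.asarray(mask, dtype=np.uint8), (1, 0))
    affine = np.diag([spacing[1], spacing[0], 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), path)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(Path(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim > 2:
        data = np.squeeze(data)
    if data.ndim != 2:
        raise ValueError(f"{path}: mask must be 2D, got shape {data.shape}")
    return np.transpose(data, (1, 0)).astype(bool)


def write_map(values: np.ndarray, path: str | Path, spacing=(1.0, 1.0)) -> Path:
    """Write a per-voxel scalar map as float32 NIfTI; NaN marks no-data."""
    path = Path(path)
    data = np.transpose(np.asarray(values, dtype=np.float32), (1, 0))
    affine = np.diag([spacing[1], spacing[0], 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), path)
    return path


def read_map(path: str | Path) -> np.ndarray:
    img = nib.load(Path(path))
    data = np.squeeze(np.asanyarray(img.dataobj))
    return np.transpose(data, (1, 0)).astype(float)


def write_report(rows: list[dict], path: str | Path) -> Path:
    """Write metric rows as CSV (one column per standard measure) and JSON.

    ``path`` is the CSV path; a sibling ``.json`` carries the full rows
    including provenance fields.
    """
    path = Path(path)
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS if not rows else None)
    if rows:
        cols = [c for c in REPORT_COLUMNS if c in df.columns]
        extra = [c for c in df.columns if c not in REPORT_COLUMNS]
        df = df[cols + extra]
    df.to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps(rows, indent=2, default=float))
    return path


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Read the cohort CSV into SubjectRecords.

    Required columns: id, group.  Recognized clinical columns: vc_percent,
    fvc_percent, fev1_percent, pef_percent, niv.  All remaining numeric
    columns become per-subject metrics.
    """
    df = pd.read_csv(path)
    missing = {"id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"subject table is missing required columns: {sorted(missing)}")
    known = {"id", "group", "vc_percent", "fvc_percent", "fev1_percent", "pef_percent", "niv"}
    records = []
    for _, row in df.iterrows():
        metrics = {
            c: float(row[c])
            for c in df.columns
            if c not in known and pd.api.types.is_number(row[c])
        }
        records.append(
            SubjectRecord(
                id=str(row["id"]),
                group=str(row["group"]),
                vc_percent=float(row.get("vc_percent", np.nan)),
                fvc_percent=float(row.get("fvc_percent", np.nan)),
                fev1_percent=float(row.get("fev1_percent", np.nan)),
                pef_percent=float(row.get("pef_percent", np.nan)),
                niv=bool(row.get("niv", False)),
                metrics=metrics,
            )
        )
    return records
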