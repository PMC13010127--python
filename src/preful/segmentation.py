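"""Lung parenchyma segmentation and full-blood reference localization.

The lung mask is a classical intensity/morphology baseline on the
temporal-mean image of the registered series (lungs are the large
low-intensity regions inside the body on proton MRI); a user-supplied mask
can bypass it.  The full-blood reference — the region whose cardiac-cycle
signal amplitude is highest *between* the lungs, typically aorta or another
great vessel — defines 100 % on the normalized perfusion scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_isodata, threshold_multiotsu

__all__ = ["LungMask", "segment_lungs", "find_full_blood_region", "validate_user_mask"]

#: 4-connectivity structuring element used for every labeling operation
STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class LungMask:
    """Binary lung mask with per-lung component labels."""

    mask: np.ndarray
    labels: np.ndarray  # 0 background, 1 left (smaller column centroid), 2 right
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)

    @property
    def area_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_mm2(self) -> float:
        return self.area_voxels * self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1]

    @property
    def n_components(self) -> int:
        return int(self.labels.max())


def _largest_components(mask: np.ndarray, n: int) -> np.ndarray:
    lab, count = ndimage.label(mask, structure=STRUCTURE_4)
    if count == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, count + 1))
    keep = 1 + np.argsort(sizes)[::-1][:n]
    return np.isin(lab, keep)


def _label_left_right(mask: np.ndarray) -> np.ndarray:
    lab, count = ndimage.label(mask, structure=STRUCTURE_4)
    if count == 0:
        return lab
    cents = ndimage.center_of_mass(mask, lab, index=np.arange(1, count + 1))
    order = np.argsort([c[1] for c in cents])  # by column centroid
    out = np.zeros_like(lab)
    for new, old in enumerate(order, start=1):
        out[lab == old + 1] = new
    return out


def segment_lungs(
    mean_image: np.ndarray,
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
    min_area_fraction: float = 0.005,
) -> LungMask:
    """Intensity + morphology lung segmentation on a temporal-mean image.

    The image has three broad intensity classes — air background, lung
    parenchyma, and soft tissue — so the body outline comes from the lower
    threshold of a 3-class multi-Otsu (largest component, holes filled)
    and the lung/soft-tissue split from an ISODATA (intermeans) threshold
    restricted to the body, which lands midway between the class means
    even when the intensity gap is wide.  Lung candidates are
    morphologically opened and closed and the two largest components
    kept.  Deterministic.
    """
    mean_image = np.asarray(mean_image, dtype=float)
    if mean_image.max() == mean_image.min():
        raise ValueError("no lung candidate: image is uniform")
    try:
        t_low = threshold_multiotsu(mean_image, classes=3)[0]
    except ValueError as exc:  # fewer than 3 grey levels present
        raise ValueError(f"no lung candidate: {exc}") from exc
    body = mean_image > t_low
    body = ndimage.binary_fill_holes(body)
    body = _largest_components(body, 1)

    t_lung = threshold_isodata(mean_image[body])
    cand = body & (mean_image < t_lung)
    cand = ndimage.binary_opening(cand, structure=STRUCTURE_4, iterations=2)
    cand = ndimage.binary_closing(cand, structure=STRUCTURE_4, iterations=2)
    cand &= body
    # drop specks
    lab, count = ndimage.label(cand, structure=STRUCTURE_4)
    if count == 0:
        raise ValueError("no lung candidate found inside the body outline")
    min_area = min_area_fraction * mean_image.size
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, count + 1))
    cand = np.isin(lab, 1 + np.flatnonzero(sizes >= min_area))
    if not cand.any():
        raise ValueError("no lung candidate of plausible size found")
    mask = _largest_components(cand, 2)
    return LungMask(
        mask=mask, labels=_label_left_right(mask), pixel_spacing_mm=pixel_spacing_mm
    )


def validate_user_mask(mask: np.ndarray, shape: tuple[int, int],
                       pixel_spacing_mm=(1.0, 1.0)) -> LungMask:
    """Wrap a user-supplied lung mask, validating geometry."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(shape):
        raise ValueError(f"user mask shape {mask.shape} does not match series {shape}")
    if not mask.any():
        raise ValueError("user mask is empty")
    return LungMask(mask=mask, labels=_label_left_right(mask),
                    pixel_spacing_mm=pixel_spacing_mm)


def _interlung_corridor(lungs: LungMask) -> np.ndarray:
    """Bounding corridor between the two lung components, excluding lungs."""
    if lungs.n_components < 2:
        raise ValueError("corridor undefined: need two lung components")
    left = lungs.labels == 1
    right = lungs.labels == 2
    rows = np.where(lungs.mask.any(axis=1))[0]
    col_lo = int(np.where(left.any(axis=0))[0].max())
    col_hi = int(np.where(right.any(axis=0))[0].min())
    if col_hi <= col_lo:
        raise ValueError("corridor undefined: lung components overlap in columns")
    corridor = np.zeros_like(lungs.mask)
    corridor[rows.min(): rows.max() + 1, col_lo: col_hi + 1] = True
    corridor &= ~lungs.mask
    return corridor


def find_full_blood_region(
    perf_amplitude_map: np.ndarray,
    lungs: LungMask,
    floor_percentile: float = 75.0,
) -> np.ndarray:
    """Locate the full-blood reference in the inter-lung corridor.

    Candidates are corridor voxels whose cardiac amplitude exceeds an
    adaptive floor — the ``floor_percentile`` of corridor amplitudes or
    half the corridor maximum, whichever is higher (the percentile alone
    degenerates when most of the corridor is static, and the half-maximum
    alone would fail if the corridor were mostly vessel); among the
    candidates' 4-connected components the one with the highest mean
    amplitude wins, ties broken by larger area, then by smaller centroid
    column.
    """
    amp = np.asarray(perf_amplitude_map, dtype=float)
    corridor = _interlung_corridor(lungs)
    if not corridor.any():
        raise ValueError("no blood reference found: empty inter-lung corridor")
    floor = max(
        float(np.percentile(amp[corridor], floor_percentile)),
        0.5 * float(amp[corridor].max()),
    )
    cand = corridor & (amp > floor)
    if not cand.any():
        raise ValueError("no blood reference found: no voxel above the amplitude floor")
    lab, count = ndimage.label(cand, structure=STRUCTURE_4)
    best = None
    best_key = None
    for k in range(1, count + 1):
        comp = lab == k
        mean_amp = float(amp[comp].mean())
        area = int(comp.sum())
        cent_col = float(np.where(comp)[1].mean())
        key = (mean_amp, area, -cent_col)
        if best_key is None or key > best_key:
            best, best_key = comp, key
    assert best is not None and not np.any(best & lungs.mask)
    return best
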