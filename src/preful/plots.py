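"""QC figures: mask overlays and the four-panel functional map layout."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["save_mask_overlay", "save_map_panel"]


def save_mask_overlay(mean_image, lung_mask, blood_region, path) -> Path:
    """Lung (blue) and full-blood (red) contours on the temporal mean."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(mean_image, cmap="gray")
    ax.contour(lung_mask, levels=[0.5], colors="tab:blue", linewidths=1.2)
    ax.contour(blood_region, levels=[0.5], colors="tab:red", linewidths=1.2)
    ax.set_axis_off()
    ax.set_title("lung + full-blood reference")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def save_map_panel(result, path) -> Path:
    """Perfusion, ventilation, ventilation-defect and V/Q-match panels."""
    fig, axes = plt.subplots(1, 4, figsize=(16, 4.2))
    q = np.ma.masked_invalid(result.perf_map.values)
    v = np.ma.masked_invalid(result.vent_map.values)
    im0 = axes[0].imshow(q, cmap="inferno")
    axes[0].set_title("perfusion (%)")
    fig.colorbar(im0, ax=axes[0], fraction=0.046)
    im1 = axes[1].imshow(v, cmap="viridis")
    axes[1].set_title("ventilation (%)")
    fig.colorbar(im1, ax=axes[1], fraction=0.046)

    vent_def = np.where(result.classification.vent_defect, 1.0, np.nan)
    axes[2].imshow(np.ma.masked_invalid(result.vent_map.values), cmap="gray")
    axes[2].imshow(np.ma.masked_invalid(vent_def), cmap="cool", vmin=0, vmax=1)
    axes[2].set_title("ventilation defects")

    match = np.where(result.classification.category_mask("vqm_nondefect"),
                     1.0, np.nan)
    axes[3].imshow(np.ma.masked_invalid(result.vent_map.values), cmap="gray")
    axes[3].imshow(np.ma.masked_invalid(match), cmap="summer", vmin=0, vmax=1)
    axes[3].set_title("V/Q match")
    for ax in axes:
        ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
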