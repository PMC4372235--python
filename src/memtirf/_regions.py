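"""Shared mask-geometry helpers: principal axes of labelled cells."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RegionAxes:
    """Principal-axis frame of one labelled cell, in pixel units.

    ``centroid`` is (row, col); ``major``/``minor`` are unit vectors in
    (row, col) space; ``half_length``/``half_width`` are the half extents of
    the footprint along those axes.
    """

    centroid: np.ndarray
    major: np.ndarray
    minor: np.ndarray
    half_length: float
    half_width: float

    @property
    def cylinder_half_length(self) -> float:
        """Half extent of the cylindrical section (pole caps trimmed)."""
        return max(self.half_length - self.half_width, 0.0)


def region_axes(labels: np.ndarray, cell_id: int) -> RegionAxes:
    """Centroid and principal axes of cell ``cell_id`` in a label image."""
    rr, cc = np.nonzero(labels == cell_id)
    if rr.size == 0:
        raise ValueError(f"cell {cell_id} not present in mask")
    coords = np.column_stack([rr, cc]).astype(float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / max(len(coords) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    major = evecs[:, 1]
    minor = evecs[:, 0]
    # deterministic sign convention
    if major[0] < 0 or (major[0] == 0 and major[1] < 0):
        major = -major
    if minor[0] < 0 or (minor[0] == 0 and minor[1] < 0):
        minor = -minor
    t = centered @ major
    q = centered @ minor
    # +0.5: pixel centers to pixel edges
    return RegionAxes(
        centroid=centroid,
        major=major,
        minor=minor,
        half_length=float((t.max() - t.min()) / 2.0 + 0.5),
        half_width=float((q.max() - q.min()) / 2.0 + 0.5),
    )


def touches_border(labels: np.ndarray, cell_id: int, margin: int = 1) -> bool:
    rr, cc = np.nonzero(labels == cell_id)
    h, w = labels.shape
    return bool(
        (rr < margin).any()
        or (cc < margin).any()
        or (rr >= h - margin).any()
        or (cc >= w - margin).any()
    )
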