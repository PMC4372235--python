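"""Synthetic image formation: TIRF / epifluorescence rendering of trajectories.

The renderer turns one or more simulated trajectories into a time-lapse
intensity stack.  In TIRF mode the excitation follows the evanescent field,
``w = exp(-z/d)`` with ``z`` the membrane height above the coverslip, so
molecules at the bottom of the cell are excited (and bleached) strongly
while molecules on top are nearly dark.  Emission weight equals excitation
weight.  Photobleaching is applied per rendered frame, before emission;
bleach state is written back into the trajectory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .sim import CellGeometry, ConfigError, Trajectory

__all__ = [
    "OpticsConfig",
    "ImageStack",
    "LabelMask",
    "RenderError",
    "excitation_weight",
    "render_stack",
]

_POISSON_GAUSS_CROSSOVER = 1000.0


class RenderError(RuntimeError):
    """Raised for trajectory/optics metadata mismatches."""


@dataclass(frozen=True)
class OpticsConfig:
    """Image-formation parameters.

    ``bleach_coefficient`` is the bleaching rate (1/s during exposure) at
    excitation weight 1; the per-frame bleaching probability of a molecule
    at weight ``w`` is ``1 - exp(-beta * w * exposure)``.
    ``expected_photons=True`` disables all stochastic noise (bleaching
    becomes a deterministic survival weight) for oracle tests.
    """

    mode: str  # "epifluorescence" | "tirf"
    evanescent_depth: float = 0.1  # µm
    photons_per_fluorophore: float = 100.0  # per exposure at weight 1
    bleach_coefficient: float = 0.0  # 1/s at weight 1
    psf_sigma: float = 0.1  # µm
    pixel_size: float = 0.08  # µm
    exposure: float = 0.1  # s
    frame_interval: float = 0.1  # s
    image_shape: tuple[int, int] = (96, 96)
    camera_offset: float = 100.0  # counts
    read_noise_sd: float = 2.0  # counts
    seed: int = 0
    expected_photons: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("epifluorescence", "tirf"):
            raise ConfigError(f"mode must be 'epifluorescence' or 'tirf', got {self.mode!r}")
        if self.mode == "tirf" and not (np.isfinite(self.evanescent_depth) and self.evanescent_depth > 0):
            raise ConfigError("evanescent_depth must be positive in tirf mode")
        if self.psf_sigma <= 0 or self.pixel_size <= 0:
            raise ConfigError("psf_sigma and pixel_size must be positive")
        if self.exposure <= 0 or self.frame_interval <= 0:
            raise ConfigError("exposure and frame_interval must be positive")
        if self.exposure > self.frame_interval + 1e-12:
            raise ConfigError("exposure must not exceed frame_interval")
        for name in ("photons_per_fluorophore", "bleach_coefficient", "read_noise_sd", "camera_offset"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and non-negative, got {v}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(d["image_shape"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OpticsConfig":
        d = dict(d)
        d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)


@dataclass
class ImageStack:
    """Time-ordered 2-D frames with physical metadata."""

    frames: np.ndarray  # (T, H, W) counts, float
    pixel_size: float  # µm
    frame_interval: float  # s

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def save_tiff(self, path, metadata_path=None) -> None:
        data = np.clip(np.round(self.frames), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data, photometric="minisblack")
        if metadata_path is None:
            metadata_path = str(path) + ".meta.json"
        with open(metadata_path, "w") as fh:
            json.dump(
                {"pixel_size_um": self.pixel_size, "frame_interval_s": self.frame_interval},
                fh,
            )

    @classmethod
    def from_tiff(cls, path, metadata_path=None) -> "ImageStack":
        data = tifffile.imread(path).astype(float)
        if data.ndim == 2:
            data = data[None]
        if metadata_path is None:
            metadata_path = str(path) + ".meta.json"
        with open(metadata_path) as fh:
            meta = json.load(fh)
        return cls(data, meta["pixel_size_um"], meta["frame_interval_s"])


@dataclass
class LabelMask:
    """Integer label image: 0 = background, k = cell k."""

    labels: np.ndarray  # (H, W) int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def save_tiff(self, path) -> None:
        tifffile.imwrite(path, self.labels.astype(np.uint16), photometric="minisblack")

    @classmethod
    def from_tiff(cls, path) -> "LabelMask":
        return cls(tifffile.imread(path).astype(np.int32))


def excitation_weight(
    theta: np.ndarray | float, geometry: CellGeometry, optics: OpticsConfig
) -> np.ndarray | float:
    """Relative excitation of a membrane molecule at azimuth ``theta``.

    Epifluorescence excites uniformly (weight 1).  TIRF weight is
    ``exp(-z/d)`` with ``z = radius * (1 - cos theta)``.
    """
    if optics.mode == "epifluorescence":
        return np.ones_like(np.asarray(theta, dtype=float)) if np.ndim(theta) else 1.0
    z = geometry.height_above_coverslip(theta)
    return np.exp(-np.asarray(z, dtype=float) / optics.evanescent_depth)


def _sample_photon_counts(rng: np.random.Generator, mean: np.ndarray) -> np.ndarray:
    """Poisson sample, Gaussian-approximated above the crossover mean."""
    out = np.empty_like(mean)
    small = mean < _POISSON_GAUSS_CROSSOVER
    if small.any():
        out[small] = rng.poisson(mean[small])
    big = ~small
    if big.any():
        out[big] = np.maximum(np.round(rng.normal(mean[big], np.sqrt(mean[big]))), 0.0)
    return out


def _project_to_pixels(
    s: np.ndarray, theta: np.ndarray, geometry: CellGeometry, optics: OpticsConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Map surface coordinates to (row, col) pixel coordinates.

    The µm origin maps to the image center; axial position runs along the
    cell orientation, lateral offset is ``radius * sin(theta)``.
    """
    h, w = optics.image_shape
    phi = geometry.orientation
    ux, uy = np.cos(phi), np.sin(phi)
    axial = s - geometry.length / 2.0
    lateral = geometry.radius * np.sin(theta)
    x = geometry.center_xy[0] + axial * ux - lateral * uy
    y = geometry.center_xy[1] + axial * uy + lateral * ux
    col = x / optics.pixel_size + (w - 1) / 2.0
    row = y / optics.pixel_size + (h - 1) / 2.0
    return row, col


def _deposit_bilinear(img: np.ndarray, row: np.ndarray, col: np.ndarray, val: np.ndarray) -> None:
    h, w = img.shape
    r0 = np.floor(row).astype(int)
    c0 = np.floor(col).astype(int)
    fr = row - r0
    fc = col - c0
    for dr, dc, wt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr
        cc = c0 + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        np.add.at(img, (rr[ok], cc[ok]), val[ok] * wt[ok])


def _footprint_mask(geometry: CellGeometry, optics: OpticsConfig) -> np.ndarray:
    """Projected spherocylinder footprint of a cell (boolean image)."""
    h, w = optics.image_shape
    rows, cols = np.mgrid[0:h, 0:w]
    x = (cols - (w - 1) / 2.0) * optics.pixel_size - geometry.center_xy[0]
    y = (rows - (h - 1) / 2.0) * optics.pixel_size - geometry.center_xy[1]
    phi = geometry.orientation
    ux, uy = np.cos(phi), np.sin(phi)
    axial = x * ux + y * uy
    lateral = -x * uy + y * ux
    half = geometry.length / 2.0
    axial_clamped = np.clip(axial, -half, half)
    d2 = (axial - axial_clamped) ** 2 + lateral**2
    return d2 <= geometry.radius**2


def render_stack(
    traj: Trajectory | list[Trajectory],
    optics: OpticsConfig,
    n_frames: int | None = None,
) -> tuple[ImageStack, LabelMask]:
    """Render trajectories into a synthetic image stack plus label mask.

    Accepts a single trajectory or a list (a field of cells composited into
    one image; cells are labelled 1..k in list order).  The trajectory is
    sampled every ``frame_interval / dt`` steps, which must be an integer
    multiple.  Bleach states are written back into each trajectory.
    """
    trajs = [traj] if isinstance(traj, Trajectory) else list(traj)
    if not trajs:
        raise RenderError("no trajectories to render")

    strides = []
    for tr in trajs:
        ratio = optics.frame_interval / tr.config.dt
        stride = int(round(ratio))
        if stride < 1 or abs(ratio - stride) > 1e-6 * max(1, stride):
            raise RenderError(
                f"frame_interval {optics.frame_interval} s is not an integer "
                f"multiple of trajectory dt {tr.config.dt} s"
            )
        strides.append(stride)
    max_frames = min((tr.n_frames - 1) // st for tr, st in zip(trajs, strides)) + 1
    if n_frames is None:
        n_frames = max_frames
    elif n_frames > max_frames:
        raise RenderError(f"requested {n_frames} frames but trajectories support {max_frames}")

    h, w = optics.image_shape
    rng = np.random.default_rng(np.random.SeedSequence(optics.seed, spawn_key=(0,)))
    sigma_px = optics.psf_sigma / optics.pixel_size

    alive = [np.ones(tr.n_particles, dtype=bool) for tr in trajs]
    survival = [np.ones(tr.n_particles) for tr in trajs]
    bleach_frame = [np.full(tr.n_particles, -1, dtype=int) for tr in trajs]
    beta = optics.bleach_coefficient

    frames = np.empty((n_frames, h, w))
    for f in range(n_frames):
        photon_img = np.zeros((h, w))
        for ti, tr in enumerate(trajs):
            snap = f * strides[ti]
            g = tr.config.geometry
            theta = np.mod(tr.arc_raw[snap] / g.radius, 2.0 * np.pi)
            s_wrapped = tr.s[snap]
            wgt = np.asarray(excitation_weight(theta, g, optics))
            if beta > 0:
                p_bleach = -np.expm1(-beta * wgt * optics.exposure)
                if optics.expected_photons:
                    survival[ti] = survival[ti] * (1.0 - p_bleach)
                else:
                    u = rng.random(tr.n_particles)
                    newly = alive[ti] & (u < p_bleach)
                    if newly.any():
                        alive[ti][newly] = False
                        bleach_frame[ti][newly] = snap
            mean_photons = optics.photons_per_fluorophore * wgt
            if optics.expected_photons:
                emitted = mean_photons * survival[ti]
                sel = emitted > 0
            else:
                sel = alive[ti]
                emitted = np.zeros(tr.n_particles)
                if sel.any():
                    emitted[sel] = _sample_photon_counts(rng, mean_photons[sel])
            if sel.any():
                row, col = _project_to_pixels(s_wrapped[sel], theta[sel], g, optics)
                _deposit_bilinear(photon_img, row, col, emitted[sel])
        img = gaussian_filter(photon_img, sigma_px, mode="constant") + optics.camera_offset
        if not optics.expected_photons and optics.read_noise_sd > 0:
            img = img + rng.normal(0.0, optics.read_noise_sd, size=(h, w))
        frames[f] = np.maximum(img, 0.0)

    # write bleach state back into trajectories
    for ti, tr in enumerate(trajs):
        for p in np.flatnonzero(bleach_frame[ti] >= 0):
            tr.bleached[bleach_frame[ti][p] :, p] = True

    labels = np.zeros((h, w), dtype=np.int32)
    for ti, tr in enumerate(trajs):
        fp = _footprint_mask(tr.config.geometry, optics)
        labels[(labels == 0) & fp] = ti + 1

    stack = ImageStack(frames, optics.pixel_size, optics.frame_interval)
    return stack, LabelMask(labels)
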