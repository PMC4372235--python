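"""Continuous-photobleaching traces and global two-phase exponential fits.

Per-cell traces are background-subtracted mean intensities normalized to
100 at the first frame.  The model per condition c is

    I_c(t) = A_c * exp(-k_fast * t) + (100 - A_c) * exp(-K_c * t)

with no offset (decay to 0) and a single fast rate shared by all
conditions.  The slow rate ``K_c`` is the diffusion-limited readout: under
partial (TIRF) illumination, faster lateral diffusion lets molecules leave
the excited zone before bleaching, so the observed pool depletes more
slowly and K is smaller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.optimize import least_squares

from .optics import ImageStack, LabelMask

__all__ = [
    "BleachTrace",
    "BleachFit",
    "FitError",
    "cell_trace",
    "default_background_region",
    "fit_photobleach_global",
    "compare_conditions",
    "read_traces_csv",
    "write_traces_csv",
    "fits_to_frame",
]


class FitError(RuntimeError):
    """Raised when the global fit fails to converge from every start."""


@dataclass
class BleachTrace:
    """Normalized per-cell decay curve; first point is exactly 100."""

    cell_id: int
    condition: str
    times: np.ndarray  # s, strictly increasing from 0
    normalized_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.normalized_intensity = np.asarray(self.normalized_intensity, dtype=float)
        if self.times.size != self.normalized_intensity.size:
            raise ValueError("times and intensities must have equal length")
        if self.times[0] != 0 or not np.all(np.diff(self.times) > 0):
            raise ValueError("times must increase strictly from 0")
        if self.normalized_intensity[0] != 100.0:
            raise ValueError("first normalized value must be exactly 100")


@dataclass
class BleachFit:
    """Fitted two-phase decay parameters for one condition."""

    condition: str
    K: float  # slow (diffusion-limited) rate, 1/s
    k_fast: float  # shared fast rate, 1/s
    A_fast: float  # fast amplitude in [0, 100]
    SEM_K: float
    R2: float
    n: int  # cells
    at_bound: bool = False
    times: np.ndarray = field(default=None, repr=False)
    mean_curve: np.ndarray = field(default=None, repr=False)
    fitted_curve: np.ndarray = field(default=None, repr=False)


def default_background_region(mask: LabelMask | np.ndarray, margin_px: int = 5) -> np.ndarray:
    """Background = pixels at least ``margin_px`` away from every cell."""
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    dist = distance_transform_edt(labels == 0)
    region = dist >= margin_px
    if not region.any():
        raise ValueError("no background pixels far enough from cells")
    return region


def cell_trace(
    stack: ImageStack,
    mask: LabelMask | np.ndarray,
    cell_id: int,
    background_region: np.ndarray | None = None,
    condition: str = "",
) -> BleachTrace:
    """Background-subtracted mean-intensity trace of one cell, normalized.

    Per frame: mean over the cell footprint minus mean over the background
    region, then scaled so the first frame equals 100.
    """
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    footprint = labels == cell_id
    if not footprint.any():
        raise ValueError(f"cell {cell_id} not present in mask")
    if background_region is None:
        background_region = default_background_region(labels)
    if (background_region & (labels > 0)).any():
        raise ValueError("background region overlaps a cell")
    cell_mean = stack.frames[:, footprint].mean(axis=1)
    bg_mean = stack.frames[:, background_region].mean(axis=1)
    signal = cell_mean - bg_mean
    if signal[0] <= 0:
        raise ValueError(f"cell {cell_id}: frame-0 background-subtracted mean <= 0, cannot normalize")
    norm = 100.0 * signal / signal[0]
    norm[0] = 100.0
    return BleachTrace(int(cell_id), condition, stack.times.copy(), norm)


def _group_mean_curves(
    traces: list[BleachTrace],
) -> tuple[list[str], dict[str, np.ndarray], dict[str, np.ndarray], dict[str, int]]:
    order: list[str] = []
    times: dict[str, np.ndarray] = {}
    curves: dict[str, list[np.ndarray]] = {}
    for tr in traces:
        c = tr.condition
        if c not in curves:
            order.append(c)
            times[c] = tr.times
            curves[c] = []
        elif tr.times.shape != times[c].shape or not np.allclose(tr.times, times[c]):
            raise ValueError(f"traces of condition {c!r} are on different time grids")
        curves[c].append(tr.normalized_intensity)
    mean = {c: np.mean(np.stack(v), axis=0) for c, v in curves.items()}
    n = {c: len(v) for c, v in curves.items()}
    return order, times, mean, n


def _model(t: np.ndarray, a: float, k_fast: float, k_slow: float) -> np.ndarray:
    return a * np.exp(-k_fast * t) + (100.0 - a) * np.exp(-k_slow * t)


def fit_photobleach_global(
    traces: list[BleachTrace],
    n_starts: int = 7,
    target: str = "mean",
) -> dict[str, BleachFit]:
    """Global constrained two-phase exponential fit across conditions.

    Each condition's field-mean curve (``target="mean"``, the default) is
    fitted jointly with a shared fast rate; ``target="pooled"`` fits all
    per-cell traces simultaneously instead.  The slow rate is parameterized
    as ``K_c = k_fast * r_c`` with ``r_c`` in [0, 1], which enforces
    K <= k_fast.  Bounded nonlinear least squares with multiple log-spaced
    starting fast rates guards against local minima.  SEM of K comes from
    the Jacobian-based covariance at the optimum (delta method for the
    product); R² is computed per condition on its mean curve.
    """
    if not traces:
        raise ValueError("no traces to fit")
    if target not in ("mean", "pooled"):
        raise ValueError("target must be 'mean' or 'pooled'")
    order, times, mean, n_cells = _group_mean_curves(traces)
    for c in order:
        if times[c].size < 5:
            raise ValueError(f"condition {c!r} has fewer than 5 time points")
    n_cond = len(order)
    pooled = {c: [tr for tr in traces if tr.condition == c] for c in order}

    def residuals(x: np.ndarray) -> np.ndarray:
        kf = x[0]
        out = []
        for i, c in enumerate(order):
            a, r = x[1 + i], x[1 + n_cond + i]
            model = _model(times[c], a, kf, kf * r)
            if target == "mean":
                out.append(model - mean[c])
            else:
                out.extend(model - tr.normalized_intensity for tr in pooled[c])
        return np.concatenate(out)

    t_max = max(times[c][-1] for c in order)
    lb = np.concatenate([[1e-10], np.zeros(n_cond), np.zeros(n_cond)])
    ub = np.concatenate([[np.inf], np.full(n_cond, 100.0), np.ones(n_cond)])
    kf_starts = np.geomspace(0.5 / t_max, 100.0 / t_max, n_starts)
    best = None
    failures = []
    for kf0 in kf_starts:
        x0 = np.concatenate([[kf0], np.full(n_cond, 50.0), np.full(n_cond, 0.1)])
        try:
            res = least_squares(
                residuals, x0, bounds=(lb, ub), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000,
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append((kf0, str(exc)))
            continue
        if not res.success and res.status <= 0:
            failures.append((kf0, res.message))
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError(
            "two-phase fit failed to converge from any start; starts tried: "
            + ", ".join(f"k_fast={kf:.4g} ({msg})" for kf, msg in failures)
        )

    x = best.x
    kf = float(x[0])
    m = best.fun.size
    p = x.size
    dof = max(m - p, 1)
    s2 = 2.0 * best.cost / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * s2

    fits: dict[str, BleachFit] = {}
    for i, c in enumerate(order):
        a, r = float(x[1 + i]), float(x[1 + n_cond + i])
        k_slow = kf * r
        # delta method: K = k_fast * r
        grad = np.zeros(p)
        grad[0] = r
        grad[1 + n_cond + i] = kf
        var_k = float(grad @ cov @ grad)
        fitted = _model(times[c], a, kf, k_slow)
        ss_res = float(np.sum((mean[c] - fitted) ** 2))
        ss_tot = float(np.sum((mean[c] - mean[c].mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        at_bound = bool(
            np.isclose(a, 0) or np.isclose(a, 100) or np.isclose(r, 0) or np.isclose(r, 1)
        )
        fits[c] = BleachFit(
            condition=c,
            K=k_slow,
            k_fast=kf,
            A_fast=a,
            SEM_K=float(np.sqrt(max(var_k, 0.0))),
            R2=r2,
            n=n_cells[c],
            at_bound=at_bound,
            times=times[c],
            mean_curve=mean[c],
            fitted_curve=fitted,
        )
    return fits


def compare_conditions(
    fits: dict[str, BleachFit] | list[BleachFit],
    reference: str | None = None,
) -> pd.DataFrame:
    """Rank conditions by fitted slow rate K (smaller K ⇒ faster diffusion).

    Returns a table of K ± SEM per condition, the ratio to the reference
    condition (the first one by default) and a diffusion verdict.
    """
    fit_list = list(fits.values()) if isinstance(fits, dict) else list(fits)
    if len(fit_list) < 2:
        raise ValueError("need at least 2 fits to compare")
    grids = [f.times for f in fit_list if f.times is not None]
    if grids and any(g.shape != grids[0].shape or not np.allclose(g, grids[0]) for g in grids[1:]):
        raise ValueError("fits are on mismatched time grids")
    if reference is None:
        reference = fit_list[0].condition
    ref = next((f for f in fit_list if f.condition == reference), None)
    if ref is None:
        raise ValueError(f"reference condition {reference!r} not among fits")

    rows = []
    for f in fit_list:
        ratio = f.K / ref.K if ref.K > 0 else np.inf
        se = np.hypot(f.SEM_K, ref.SEM_K)
        delta = f.K - ref.K
        if f.condition == reference:
            verdict = "reference"
        elif delta == 0 or (se > 0 and abs(delta) < 2 * se):
            verdict = "no change"
        elif delta < 0:
            verdict = "faster diffusion"
        else:
            verdict = "slower diffusion"
        rows.append(
            {
                "condition": f.condition,
                "K": f.K,
                "SEM_K": f.SEM_K,
                "k_fast": f.k_fast,
                "A_fast": f.A_fast,
                "R2": f.R2,
                "n": f.n,
                "K_ratio_to_ref": ratio,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows)


# ---- trace CSV round trip ---------------------------------------------------

def write_traces_csv(traces: list[BleachTrace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": tr.times,
                    "cell_id": tr.cell_id,
                    "condition": tr.condition,
                    "intensity": tr.normalized_intensity,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_traces_csv(path) -> list[BleachTrace]:
    df = pd.read_csv(path)
    traces = []
    for (cond, cid), grp in df.groupby(["condition", "cell_id"], sort=True):
        grp = grp.sort_values("time_s")
        traces.append(
            BleachTrace(
                cell_id=int(cid),
                condition=str(cond),
                times=grp["time_s"].to_numpy(),
                normalized_intensity=grp["intensity"].to_numpy(),
            )
        )
    return traces


def fits_to_frame(fits: dict[str, BleachFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition": f.condition,
                "K": f.K,
                "SEM_K": f.SEM_K,
                "R2": f.R2,
                "n": f.n,
                "k_fast": f.k_fast,
                "A_fast": f.A_fast,
                "at_bound": f.at_bound,
            }
            for f in fits.values()
        ]
    )
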