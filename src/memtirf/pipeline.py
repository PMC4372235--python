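"""End-to-end experiment orchestration: simulate → render → analyze.

An experiment is a set of named conditions, each binding simulation and
optics parameters (usually via a preset), analyzed with the line-scan,
kymogram and photobleaching modules and summarized in one cross-condition
report.  Everything is a pure function of (config, master seed).

Preset conditions encode the interpretive model under study: "untreated"
carries substrate sites that cluster particles into foci and slow their
diffusion, "rifampicin" removes the sites, "fixed" freezes all dynamics and
"control_protein" has no clustering under either label.  The mapping lives
only here — the analysis modules know nothing about conditions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bleachfit, kymo, linescan
from .optics import OpticsConfig, render_stack
from .sim import CellGeometry, ConfigError, SimConfig, Trajectory, simulate_membrane_dynamics

__all__ = [
    "SIM_PRESETS",
    "ExperimentConfig",
    "ConditionSpec",
    "ExperimentResult",
    "run_experiment",
    "simulate_field",
    "field_geometries",
]

log = logging.getLogger("memtirf.pipeline")

# Per-condition simulation parameter presets (overridable per experiment).
# Clustering strength and D values are chosen so that foci hold roughly half
# of the particles at steady state in the "untreated" condition.
SIM_PRESETS: dict[str, dict] = {
    "untreated": dict(
        D_free=0.02, D_bound=0.0005, n_sites=60, site_capacity=10,
        capture_radius=0.08, k_on=30.0, k_off=0.25,
    ),
    "rifampicin": dict(
        D_free=0.02, D_bound=0.0, n_sites=0, site_capacity=1, k_on=0.0, k_off=0.0,
    ),
    "fixed": dict(
        D_free=0.0, D_bound=0.0, n_sites=0, site_capacity=1, k_on=0.0, k_off=0.0,
    ),
    "control_protein": dict(
        D_free=0.02, D_bound=0.0, n_sites=0, site_capacity=1, k_on=0.0, k_off=0.0,
    ),
}

_DEFAULT_SIM = dict(n_particles=1200)

_DEFAULT_OPTICS = dict(
    evanescent_depth=0.05,
    photons_per_fluorophore=150.0,
    psf_sigma=0.1,
    pixel_size=0.08,
    camera_offset=100.0,
    read_noise_sd=2.0,
)


@dataclass(frozen=True)
class ConditionSpec:
    """One condition: a preset name plus parameter overrides."""

    preset: str = "untreated"
    sim: dict = field(default_factory=dict)
    optics: dict = field(default_factory=dict)

    def sim_params(self) -> dict:
        if self.preset not in SIM_PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}; available: {sorted(SIM_PRESETS)}")
        params = dict(_DEFAULT_SIM)
        params.update(SIM_PRESETS[self.preset])
        params.update(self.sim)
        return params

    def optics_params(self) -> dict:
        params = dict(_DEFAULT_OPTICS)
        params.update(self.optics)
        return params


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of a multi-condition experiment."""

    conditions: dict[str, ConditionSpec]
    out_dir: str
    master_seed: int = 0
    n_cells: int = 12
    analyses: tuple[str, ...] = ("linescan", "kymo", "bleachfit")
    # bleaching acquisition
    bleach_frames: int = 61
    bleach_frame_interval: float = 0.1  # s
    bleach_coefficient: float = 1.0  # 1/s at weight 1
    # kymogram acquisition (bleach-free TIRF video, sparse labelling)
    kymo_frames: int = 91
    kymo_frame_interval: float = 1.0 / 30.0  # s
    kymo_n_particles: int = 100
    burn_in_s: float = 20.0  # binding equilibration before acquisition
    save_tiffs: bool = False
    save_plots: bool = False

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):  # pragma: no cover
            raise ConfigError("condition names must be unique")
        if not self.conditions:
            raise ConfigError("at least one condition required")
        for name in self.analyses:
            if name not in ("linescan", "kymo", "bleachfit"):
                raise ConfigError(f"unknown analysis {name!r}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        conditions = {
            name: ConditionSpec(**(spec or {})) for name, spec in raw.pop("conditions").items()
        }
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        return cls(conditions=conditions, **raw)


@dataclass
class ExperimentResult:
    """In-memory bundle of everything a run produced."""

    config: ExperimentConfig
    out_dir: Path
    field_summaries: dict[str, linescan.FieldSummary]
    persistence: dict[str, dict[str, float]]
    fits: dict[str, bleachfit.BleachFit]
    comparison: "object"  # pandas DataFrame
    manifest: dict


def _seed_int(*key: int) -> int:
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0])


def field_geometries(
    n_cells: int, seed: int, pixel_size: float, spacing_um: float = 5.0
) -> tuple[list[CellGeometry], tuple[int, int]]:
    """Lay rod-shaped cells on a jittered grid; return geometries + image shape.

    Grid spacing exceeds the cell length so masks never overlap, keeping
    every line scan usable (adjacency exclusion still applies near the
    jittered extremes).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    n_cols = int(np.ceil(np.sqrt(n_cells)))
    n_rows = int(np.ceil(n_cells / n_cols))
    geometries = []
    for i in range(n_cells):
        r, c = divmod(i, n_cols)
        cx = (c - (n_cols - 1) / 2.0) * spacing_um + rng.uniform(-0.3, 0.3)
        cy = (r - (n_rows - 1) / 2.0) * spacing_um + rng.uniform(-0.3, 0.3)
        geometries.append(
            CellGeometry(
                length=float(rng.uniform(2.6, 3.4)),
                radius=0.4,
                center_xy=(cx, cy),
                orientation=float(rng.uniform(0, np.pi)),
            )
        )
    margin = 3.0  # µm beyond the outermost grid point
    w_px = int(np.ceil((n_cols * spacing_um + margin) / pixel_size))
    h_px = int(np.ceil((n_rows * spacing_um + margin) / pixel_size))
    return geometries, (h_px, w_px)


def simulate_field(
    spec: ConditionSpec,
    n_cells: int,
    seed: int,
    dt: float,
    n_steps: int,
    burn_in_steps: int = 0,
    spacing_um: float = 5.0,
) -> tuple[list[Trajectory], tuple[int, int]]:
    """Simulate ``n_cells`` independent cells of one condition.

    Returns burn-in-trimmed trajectories plus the image shape that fits the
    whole field.
    """
    params = spec.sim_params()
    pixel_size = spec.optics_params()["pixel_size"]
    geometries, shape = field_geometries(n_cells, seed, pixel_size, spacing_um)
    trajs = []
    for i, geom in enumerate(geometries):
        cfg = SimConfig(
            dt=dt,
            n_steps=n_steps + burn_in_steps,
            seed=_seed_int(seed, i),
            geometry=geom,
            **params,
        )
        traj = simulate_membrane_dynamics(cfg)
        trajs.append(traj.trimmed(burn_in_steps) if burn_in_steps else traj)
    return trajs, shape


def _write_csv(df, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run every condition end to end and write the result bundle.

    Per condition: simulate a field of cells, render an epifluorescence
    snapshot (line scans), a bleach-free TIRF video (kymograms) and a TIRF
    photobleaching stack (decay traces); then fit all conditions jointly
    with a shared fast rate and write the comparison report.  Outputs are
    deterministic functions of (config, master_seed).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"master_seed": cfg.master_seed, "conditions": {}, "files": []}
    field_summaries: dict[str, linescan.FieldSummary] = {}
    persistence: dict[str, dict[str, float]] = {}
    all_traces: list[bleachfit.BleachTrace] = []

    for ci, (name, spec) in enumerate(cfg.conditions.items()):
        t0 = time.perf_counter()
        stage = f"{name}:simulate"
        try:
            cond_seed = _seed_int(cfg.master_seed, ci)
            opt = spec.optics_params()
            # burn-in lets binding reach steady state before acquisition
            has_sites = spec.sim_params()["n_sites"] > 0
            kymo_dt = cfg.kymo_frame_interval

            # epifluorescence snapshot: full labelling, one frame
            burn_epi = int(round(cfg.burn_in_s / 0.05)) if has_sites else 0
            trajs_e, shape = simulate_field(
                spec, cfg.n_cells, cond_seed, dt=0.05,
                n_steps=0, burn_in_steps=burn_epi,
            )
            # kymogram video: sparse labelling resolves individual clusters
            kymo_spec = dataclasses.replace(
                spec, sim=dict(spec.sim, n_particles=cfg.kymo_n_particles)
            )
            burn_kymo = int(round(cfg.burn_in_s / kymo_dt)) if has_sites else 0
            trajs_k, _ = simulate_field(
                kymo_spec, cfg.n_cells, _seed_int(cond_seed, 1), dt=kymo_dt,
                n_steps=cfg.kymo_frames - 1, burn_in_steps=burn_kymo,
            )
            # photobleaching stack: binding resolved at half the frame rate
            bleach_dt = cfg.bleach_frame_interval / 2.0
            burn_bleach = int(round(cfg.burn_in_s / bleach_dt)) if has_sites else 0
            trajs_b, _ = simulate_field(
                spec, cfg.n_cells, _seed_int(cond_seed, 2), dt=bleach_dt,
                n_steps=2 * (cfg.bleach_frames - 1), burn_in_steps=burn_bleach,
            )

            stage = f"{name}:render"
            optics_common = dict(opt, image_shape=shape)
            epi_optics = OpticsConfig(
                mode="epifluorescence", bleach_coefficient=0.0,
                exposure=0.05, frame_interval=0.05,
                seed=_seed_int(cond_seed, 3), **optics_common,
            )
            epi_stack, mask = render_stack(trajs_e, epi_optics, n_frames=1)
            kymo_optics = OpticsConfig(
                mode="tirf", bleach_coefficient=0.0,
                exposure=kymo_dt, frame_interval=kymo_dt,
                seed=_seed_int(cond_seed, 4), **optics_common,
            )
            kymo_stack, kymo_mask = render_stack(trajs_k, kymo_optics)
            bleach_optics = OpticsConfig(
                mode="tirf", bleach_coefficient=cfg.bleach_coefficient,
                exposure=cfg.bleach_frame_interval, frame_interval=cfg.bleach_frame_interval,
                seed=_seed_int(cond_seed, 5), **optics_common,
            )
            bleach_stack, bleach_mask = render_stack(trajs_b, bleach_optics)

            cond_files: dict[str, str] = {}
            if cfg.save_tiffs:
                for tag, stk in (("epi", epi_stack), ("kymo", kymo_stack), ("bleach", bleach_stack)):
                    p = out / f"{name}_{tag}.tif"
                    stk.save_tiff(p)
                    cond_files[f"{tag}_tiff"] = str(p)
                mask.save_tiff(out / f"{name}_mask.tif")
                cond_files["mask_tiff"] = str(out / f"{name}_mask.tif")

            if "linescan" in cfg.analyses:
                stage = f"{name}:linescan"
                scans = linescan.extract_perimeter_scans(
                    epi_stack.frames[0], mask, epi_optics.pixel_size
                )
                stats = [linescan.scan_stats(s) for s in scans]
                summary = linescan.field_summary(stats)
                field_summaries[name] = summary
                p = out / f"{name}_linescans.csv"
                _write_csv(summary.table, p)
                cond_files["linescans_csv"] = str(p)

            if "kymo" in cfg.analyses:
                stage = f"{name}:kymo"
                scores: dict[str, float] = {}
                for axis in ("long", "short"):
                    kg = kymo.build_kymogram(kymo_stack, kymo_mask, cell_id=1, axis=axis)
                    p = out / f"{name}_kymogram_{axis}.tsv"
                    np.savetxt(p, kg.matrix, delimiter="\t", fmt="%.6g")
                    cond_files[f"kymogram_{axis}_tsv"] = str(p)
                    lag = 1.0 if kg.n_frames * kg.frame_interval > 1.5 else kg.frame_interval
                    res = kymo.persistence_score(kg, lag)
                    scores[f"{axis}_persistence_lag{res.lag:g}s"] = res.score
                    scores[f"{axis}_ridge_slope_px_per_frame"] = kymo.ridge_slope(kg)
                    if cfg.save_plots:
                        _save_heatmap(kg, out / f"{name}_kymogram_{axis}.png")
                persistence[name] = scores

            if "bleachfit" in cfg.analyses:
                stage = f"{name}:bleachtrace"
                bg = bleachfit.default_background_region(bleach_mask)
                for cid in bleach_mask.cell_ids:
                    all_traces.append(
                        bleachfit.cell_trace(
                            bleach_stack, bleach_mask, int(cid), bg, condition=name
                        )
                    )

            manifest["conditions"][name] = {
                "seed": cond_seed,
                "preset": spec.preset,
                "files": cond_files,
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }
            log.info("condition %s done in %.1fs", name, time.perf_counter() - t0)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    fits: dict[str, bleachfit.BleachFit] = {}
    comparison = None
    if all_traces:
        bleachfit.write_traces_csv(all_traces, out / "bleach_traces.csv")
        manifest["files"].append(str(out / "bleach_traces.csv"))
        fits = bleachfit.fit_photobleach_global(all_traces)
        _write_csv(bleachfit.fits_to_frame(fits), out / "bleach_fits.csv")
        manifest["files"].append(str(out / "bleach_fits.csv"))
        if len(fits) >= 2:
            comparison = bleachfit.compare_conditions(fits)
            _write_csv(comparison, out / "condition_comparison.csv")
            manifest["files"].append(str(out / "condition_comparison.csv"))

    if persistence:
        import pandas as pd

        rows = [{"condition": c, **scores} for c, scores in persistence.items()]
        _write_csv(pd.DataFrame(rows), out / "kymo_persistence.csv")
        manifest["files"].append(str(out / "kymo_persistence.csv"))
    if field_summaries:
        import pandas as pd

        rows = [
            {
                "condition": c,
                "n_cells": s.n_cells,
                "n_scans": s.n_scans,
                "median_mean_intensity": s.median_mean_intensity,
                "median_variance": s.median_variance,
            }
            for c, s in field_summaries.items()
        ]
        _write_csv(pd.DataFrame(rows), out / "linescan_summary.csv")
        manifest["files"].append(str(out / "linescan_summary.csv"))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return ExperimentResult(
        config=cfg,
        out_dir=out,
        field_summaries=field_summaries,
        persistence=persistence,
        fits=fits,
        comparison=comparison,
        manifest=manifest,
    )


def _save_heatmap(kg: kymo.Kymogram, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(figsize=(4, 3))
    axes.imshow(kg.normalized(), aspect="auto", cmap="inferno", origin="upper")
    axes.set_xlabel("position (px)")
    axes.set_ylabel("frame")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
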