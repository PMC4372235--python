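"""Brownian dynamics of membrane-anchored fluorophores on a rod-shaped cell.

Particles diffuse on the lateral (cylindrical) wall of a rod-shaped cell,
parameterized by an axial coordinate ``s`` in [0, length] and an azimuth
``theta`` in [0, 2*pi).  The cylinder is intrinsically flat, so free
diffusion is simulated exactly on the unrolled surface: raw (unwrapped)
coordinates follow a free 2-D Brownian walk; the physical coordinates are
obtained by reflecting ``s`` at the cell poles and wrapping the
circumferential arc.  Immobile "substrate sites" capture nearby particles
with first-order kinetics, which is how transient membrane foci are
modelled: a site holds up to ``site_capacity`` particles that then move
with the (typically much smaller) bound diffusion coefficient.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi

__all__ = [
    "ConfigError",
    "CellGeometry",
    "SimConfig",
    "ParticleState",
    "Trajectory",
    "simulate_membrane_dynamics",
    "ensemble_msd",
]


class ConfigError(ValueError):
    """Raised for invalid simulation or optics configuration."""


@dataclass(frozen=True)
class CellGeometry:
    """Idealized rod-shaped cell: a cylinder of given length and radius.

    The cell rests on the coverslip plane; the membrane height above the
    coverslip at azimuth ``theta`` is ``radius * (1 - cos(theta))`` with
    ``theta = 0`` at the bottom of the cell.

    Parameters
    ----------
    length : float
        Length of the cylindrical section, µm.
    radius : float
        Cell radius, µm.
    center_xy : tuple of float
        Position of the cell center in the image plane, µm.
    orientation : float
        In-plane angle of the long axis, radians.
    """

    length: float
    radius: float
    center_xy: tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.length) and self.length > 0):
            raise ConfigError(f"length must be positive and finite, got {self.length}")
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise ConfigError(f"radius must be positive and finite, got {self.radius}")

    @property
    def circumference(self) -> float:
        return TWO_PI * self.radius

    def height_above_coverslip(self, theta: np.ndarray | float) -> np.ndarray | float:
        """Membrane height z above the coverslip at azimuth ``theta`` (µm)."""
        return self.radius * (1.0 - np.cos(theta))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the membrane dynamics simulation.

    Rates are per second, lengths in µm, diffusion coefficients in µm²/s.
    ``n_sites = 0`` disables clustering entirely (substrate-depleted
    condition).
    """

    D_free: float
    dt: float
    n_steps: int
    n_particles: int
    geometry: CellGeometry
    D_bound: float = 0.0
    n_sites: int = 0
    site_capacity: int = 1
    capture_radius: float = 0.1
    k_on: float = 0.0
    k_off: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        scalars = {
            "D_free": self.D_free,
            "D_bound": self.D_bound,
            "capture_radius": self.capture_radius,
            "k_on": self.k_on,
            "k_off": self.k_off,
        }
        for name, value in scalars.items():
            if not np.isfinite(value) or value < 0:
                raise ConfigError(f"{name} must be finite and non-negative, got {value}")
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise ConfigError(f"dt must be positive, got {self.dt}")
        for name, value in {
            "n_steps": self.n_steps,
            "n_particles": self.n_particles,
            "n_sites": self.n_sites,
            "site_capacity": self.site_capacity,
        }.items():
            if int(value) != value or value < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {value}")
        if self.n_particles == 0:
            raise ConfigError("n_particles must be at least 1")
        # Binding is resolved once per tick, so the step size must not jump
        # over the capture zone.  Irrelevant without sites (diffusion on the
        # unrolled cylinder is exact at any dt).
        if self.n_sites > 0 and self.k_on > 0:
            step = np.sqrt(4.0 * self.D_free * self.dt)
            if step >= self.capture_radius:
                warnings.warn(
                    f"per-step displacement {step:.3g} µm exceeds capture_radius "
                    f"{self.capture_radius:.3g} µm; binding kinetics will be "
                    "under-resolved — reduce dt",
                    stacklevel=2,
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"]["center_xy"] = list(d["geometry"]["center_xy"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        g = dict(d.pop("geometry"))
        g["center_xy"] = tuple(g.get("center_xy", (0.0, 0.0)))
        return cls(geometry=CellGeometry(**g), **d)


@dataclass(frozen=True)
class ParticleState:
    """Snapshot of a single particle (convenience accessor, not storage)."""

    s: float
    theta: float
    bound_site: int | None
    bleached: bool


def _reflect(x: np.ndarray, length: float) -> np.ndarray:
    """Fold unbounded coordinates into [0, length] (reflecting boundaries)."""
    y = np.mod(x, 2.0 * length)
    return np.where(y > length, 2.0 * length - y, y)


@dataclass
class Trajectory:
    """Per-frame particle states of one simulated cell.

    Raw (unwrapped) coordinates are stored; wrapped physical coordinates are
    derived on demand.  ``bleached`` starts all-False and is filled in by the
    renderer, which owns the photophysics.
    """

    s_raw: np.ndarray  # (n_frames, n_particles) axial, unreflected
    arc_raw: np.ndarray  # (n_frames, n_particles) circumferential arc, unwrapped
    bound_site: np.ndarray  # (n_frames, n_particles) int, -1 = free
    bleached: np.ndarray  # (n_frames, n_particles) bool
    site_positions: np.ndarray  # (n_sites, 2): columns (s, theta)
    config: SimConfig

    @property
    def n_frames(self) -> int:
        return self.s_raw.shape[0]

    @property
    def n_particles(self) -> int:
        return self.s_raw.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.config.dt

    @property
    def s(self) -> np.ndarray:
        """Axial coordinate reflected into [0, length]."""
        return _reflect(self.s_raw, self.config.geometry.length)

    @property
    def theta(self) -> np.ndarray:
        """Azimuth wrapped to [0, 2*pi)."""
        return np.mod(self.arc_raw / self.config.geometry.radius, TWO_PI)

    def particle(self, frame: int, index: int) -> ParticleState:
        b = int(self.bound_site[frame, index])
        return ParticleState(
            s=float(self.s[frame, index]),
            theta=float(self.theta[frame, index]),
            bound_site=None if b < 0 else b,
            bleached=bool(self.bleached[frame, index]),
        )

    def trimmed(self, start: int) -> "Trajectory":
        """Trajectory with the first ``start`` frames dropped (burn-in)."""
        if not 0 <= start < self.n_frames:
            raise ValueError(f"start {start} out of range")
        cfg = dataclasses.replace(self.config, n_steps=self.config.n_steps - start)
        return Trajectory(
            s_raw=self.s_raw[start:],
            arc_raw=self.arc_raw[start:],
            bound_site=self.bound_site[start:],
            bleached=self.bleached[start:],
            site_positions=self.site_positions,
            config=cfg,
        )

    def bound_fraction(self) -> np.ndarray:
        """Fraction of particles bound, per frame."""
        return np.mean(self.bound_site >= 0, axis=1)

    def occupancy(self, frame: int) -> np.ndarray:
        """Occupant count per site at one frame."""
        occ = np.zeros(len(self.site_positions), dtype=int)
        bound = self.bound_site[frame]
        np.add.at(occ, bound[bound >= 0], 1)
        return occ

    # ---- serialization -------------------------------------------------
    def to_tsv(self, path, config_path=None) -> None:
        """Write (frame, particle, s, theta, bound_site, bleached) TSV.

        A JSON config sidecar is written to ``config_path`` (defaults to
        ``<path>.config.json``).
        """
        t, n = self.n_frames, self.n_particles
        frames = np.repeat(np.arange(t), n)
        particles = np.tile(np.arange(n), t)
        df = pd.DataFrame(
            {
                "frame": frames,
                "particle": particles,
                "s": self.s.ravel(),
                "theta": self.theta.ravel(),
                "bound_site": self.bound_site.ravel(),
                "bleached": self.bleached.ravel().astype(int),
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.9g")
        if config_path is None:
            config_path = str(path) + ".config.json"
        sidecar = {
            "config": self.config.to_dict(),
            "site_positions": self.site_positions.tolist(),
        }
        with open(config_path, "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def from_tsv(cls, path, config_path=None) -> "Trajectory":
        if config_path is None:
            config_path = str(path) + ".config.json"
        with open(config_path) as fh:
            sidecar = json.load(fh)
        config = SimConfig.from_dict(sidecar["config"])
        sites = np.asarray(sidecar["site_positions"], dtype=float).reshape(-1, 2)
        df = pd.read_csv(path, sep="\t")
        t = int(df["frame"].max()) + 1
        n = int(df["particle"].max()) + 1
        shape = (t, n)
        df = df.sort_values(["frame", "particle"])
        return cls(
            s_raw=df["s"].to_numpy().reshape(shape),
            arc_raw=df["theta"].to_numpy().reshape(shape) * config.geometry.radius,
            bound_site=df["bound_site"].to_numpy().reshape(shape).astype(np.int32),
            bleached=df["bleached"].to_numpy().reshape(shape).astype(bool),
            site_positions=sites,
            config=config,
        )


def _particle_stream(seed: int, index: int) -> np.random.Generator:
    # Counter-keyed substream: particle i's path is independent of how many
    # other particles exist.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, index)))


def _site_stream(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))


def simulate_membrane_dynamics(config: SimConfig) -> Trajectory:
    """Run the surface Brownian dynamics and return the full trajectory.

    Per tick: every particle takes a Gaussian step of per-axis variance
    ``2*D*dt`` (D depending on its bound state); bound particles unbind with
    probability ``1 - exp(-k_off*dt)``; free particles within
    ``capture_radius`` of an unsaturated site bind with probability
    ``1 - exp(-k_on*dt)`` (nearest unsaturated site wins, ties broken by
    lowest site index; a particle that unbound this tick may not rebind
    until the next).  Fully reproducible from ``config.seed``.
    """
    g = config.geometry
    n, t = config.n_particles, config.n_steps
    m = config.n_sites
    circ = g.circumference

    # Per-particle substreams: initial position, then normal steps, then
    # uniforms for the binding/unbinding bernoulli draws.
    s_cur = np.empty(n)
    arc_cur = np.empty(n)
    steps = np.empty((t, n, 2)) if t else np.empty((0, n, 2))
    needs_u = m > 0 and (config.k_on > 0 or config.k_off > 0)
    uniforms = np.empty((t, n)) if (t and needs_u) else None
    for i in range(n):
        rng = _particle_stream(config.seed, i)
        s_cur[i] = rng.uniform(0.0, g.length)
        arc_cur[i] = rng.uniform(0.0, circ)
        if t:
            steps[:, i, :] = rng.standard_normal((t, 2))
            if needs_u:
                uniforms[:, i] = rng.random(t)

    site_rng = _site_stream(config.seed)
    if m:
        site_s = site_rng.uniform(0.0, g.length, m)
        site_theta = site_rng.uniform(0.0, TWO_PI, m)
        site_arc = site_theta * g.radius
        site_positions = np.column_stack([site_s, site_theta])
    else:
        site_positions = np.empty((0, 2))

    s_out = np.empty((t + 1, n))
    arc_out = np.empty((t + 1, n))
    bound_out = np.full((t + 1, n), -1, dtype=np.int32)

    s_out[0] = s_cur
    arc_out[0] = arc_cur
    bound = np.full(n, -1, dtype=np.int32)
    occ = np.zeros(m, dtype=np.int64)

    sig_free = np.sqrt(2.0 * config.D_free * config.dt)
    sig_bound = np.sqrt(2.0 * config.D_bound * config.dt)
    p_off = -np.expm1(-config.k_off * config.dt)
    p_on = -np.expm1(-config.k_on * config.dt)
    cap2 = config.capture_radius**2

    for k in range(t):
        sigma = np.where(bound >= 0, sig_bound, sig_free)
        s_cur = s_cur + steps[k, :, 0] * sigma
        arc_cur = arc_cur + steps[k, :, 1] * sigma

        if needs_u:
            u = uniforms[k]
            # unbinding first; a freshly unbound particle sits out this tick
            just_unbound = (bound >= 0) & (u < p_off)
            if just_unbound.any():
                np.subtract.at(occ, bound[just_unbound], 1)
                bound[just_unbound] = -1
            if p_on > 0:
                candidates = np.flatnonzero((bound < 0) & ~just_unbound & (u < p_on))
                if candidates.size:
                    s_w = _reflect(s_cur[candidates], g.length)
                    arc_w = np.mod(arc_cur[candidates], circ)
                    ds = s_w[:, None] - site_s[None, :]
                    darc = arc_w[:, None] - site_arc[None, :]
                    darc -= circ * np.round(darc / circ)  # shortest arc
                    dist2 = ds * ds + darc * darc
                    # All candidates see the occupancy at the start of the
                    # tick; nearest open site wins (argmin → lowest site
                    # index on ties).  If a site would overfill, the
                    # lowest-index particles are admitted and the rest stay
                    # free until the next tick.
                    open_cols = occ < config.site_capacity
                    dist2[:, ~open_cols] = np.inf
                    dist2[dist2 > cap2] = np.inf
                    nearest = np.argmin(dist2, axis=1)
                    has_site = np.isfinite(dist2[np.arange(candidates.size), nearest])
                    free_slots = config.site_capacity - occ
                    for row in np.flatnonzero(has_site):
                        j = nearest[row]
                        if free_slots[j] > 0:
                            free_slots[j] -= 1
                            bound[candidates[row]] = j
                            occ[j] += 1

        s_out[k + 1] = s_cur
        arc_out[k + 1] = arc_cur
        bound_out[k + 1] = bound

    return Trajectory(
        s_raw=s_out,
        arc_raw=arc_out,
        bound_site=bound_out,
        bleached=np.zeros((t + 1, n), dtype=bool),
        site_positions=site_positions,
        config=config,
    )


def ensemble_msd(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble mean squared displacement versus time.

    Uses the unwrapped surface coordinates, so reflections at the poles and
    azimuthal wrap-around do not bias the estimate.  For free 2-D diffusion
    the expectation is ``MSD(t) = 4*D*t``.
    """
    ds = traj.s_raw - traj.s_raw[0]
    da = traj.arc_raw - traj.arc_raw[0]
    return traj.times, np.mean(ds * ds + da * da, axis=1)
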