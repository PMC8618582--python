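"""Conformations, Langevin dynamics and conformational ensembles.

The chain is integrated with a BAOAB Langevin scheme at kT = 1 (internal
units) with friction 0.1 per ps and an effective bead mass chosen so that
the Lennard-Jones time ``tau = d sqrt(m/kT)`` equals its physical value
(~6.3 ps for 100 amu beads of 1 nm).  Connectivity is a harmonic bond of
rest length d and stiffness 200 kT/d^2, which keeps bond-length
fluctuations below 0.1 d.  The default time step of 0.1 ps resolves the
bond period comfortably and is stable against excluded-volume collisions
over multi-million-step runs.

A production ensemble is generated in three phases, mirroring the protocol
used to fit chromosome contact maps: grow a self-avoiding coil inside an
impenetrable spherical cage, equilibrate it with excluded volume only
until the radius of gyration plateaus, then switch on the pair attractions,
drop the cage and sample conformations along the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import _kernels
from .chromosome import ChromosomeSpec, ScaleMap
from .potentials import PairPotentialField

_SCALE = ScaleMap()

#: default integrator parameters (internal units)
DEFAULT_DT_PS = 0.1
DEFAULT_GAMMA_PER_PS = 0.1
DEFAULT_BOND_K = 200.0
DEFAULT_CAGE_K = 100.0
_NOISE_CHUNK = 2000


@dataclass
class Conformation:
    """One spatial conformation: bead positions in units of d."""

    positions: np.ndarray
    time_stamp: float | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_subunits(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "Conformation":
        return Conformation(self.positions.copy(), self.time_stamp)


@dataclass
class ConformationEnsemble:
    """K conformations of one chain plus generation provenance."""

    positions: np.ndarray  # (K, N, 3)
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("ensemble positions must be (K, N, 3)")
        if self.positions.shape[0] < 1:
            raise ValueError("an ensemble needs at least one member")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def __getitem__(self, k: int) -> Conformation:
        return Conformation(self.positions[k])

    @property
    def n_subunits(self) -> int:
        return self.positions.shape[1]


@dataclass
class Trajectory:
    """Frames sampled from one dynamics run."""

    positions: np.ndarray  # (F, N, 3)
    times_ps: np.ndarray  # (F,)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


@dataclass
class DynamicsConfig:
    """Integrator settings shared by all simulation phases."""

    dt_ps: float = DEFAULT_DT_PS
    gamma_per_ps: float = DEFAULT_GAMMA_PER_PS
    kT: float = 1.0
    mass: float = _SCALE.mass_internal
    bond_k: float = DEFAULT_BOND_K
    cage_k: float = DEFAULT_CAGE_K

    @classmethod
    def for_field(cls, field: PairPotentialField | None) -> "DynamicsConfig":
        """Config with the time step scaled to the strongest coupling.

        Collision velocities in deep attraction wells grow with the well
        depth, so the stable step shrinks like ``1/sqrt(u_max)``; the
        default 0.1 ps is calibrated for couplings of order kT.
        """
        if field is None:
            return cls()
        u_max = max(1.0, float(field.u0_attr.max()) if field.u0_attr.size
                    else 1.0, field.u0_ev)
        return cls(dt_ps=DEFAULT_DT_PS / np.sqrt(u_max))


def radius_of_gyration(positions: np.ndarray) -> float:
    pos = np.asarray(positions, float)
    com = pos.mean(axis=0)
    return float(np.sqrt(((pos - com) ** 2).sum(axis=1).mean()))


def build_initial_conformation(spec: ChromosomeSpec, seed: int,
                               max_retries: int = 1000,
                               max_restarts: int = 100) -> Conformation:
    """Grow a self-avoiding coil inside the spherical cage.

    Chain growth: each bead is placed at distance d from its predecessor in
    a random direction, rejected if it leaves the cage or approaches any
    non-bonded bead closer than d.  After ``max_retries`` rejections for one
    bead the growth restarts with an incremented seed; deterministic for a
    given seed.
    """
    n = spec.n_subunits
    d = spec.diameter
    cage = spec.cage_radius * d
    for restart in range(max_restarts):
        rng = np.random.default_rng(seed + restart)
        pos = np.empty((n, 3))
        # start near the centre so long chains have room in every direction
        pos[0] = rng.uniform(-1.0, 1.0, 3) * 0.25 * cage
        ok = True
        for b in range(1, n):
            placed = False
            for _ in range(max_retries):
                v = rng.normal(size=3)
                v *= d / np.linalg.norm(v)
                cand = pos[b - 1] + v
                if np.linalg.norm(cand) > cage:
                    continue
                if b >= 2:
                    dist2 = ((pos[: b - 1] - cand) ** 2).sum(axis=1)
                    if np.any(dist2 < d * d):
                        continue
                pos[b] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return Conformation(pos, time_stamp=0.0)
    raise RuntimeError(
        f"self-avoiding growth did not converge after {max_restarts} restarts")


def _integrate(pos: np.ndarray, vel: np.ndarray, n_steps: int,
               rng: np.random.Generator, cfg: DynamicsConfig,
               field: PairPotentialField, d: float,
               cage_r: float) -> None:
    """Run ``n_steps`` BAOAB steps in place, chunking the noise arrays."""
    n = pos.shape[0]
    f = np.empty_like(pos)
    _kernels.compute_forces(pos, f, d, cfg.bond_k, field.u0_ev,
                            field.u0_attr, field.r_cut, cage_r, cfg.cage_k)
    done = 0
    while done < n_steps:
        m = min(_NOISE_CHUNK, n_steps - done)
        if cfg.kT > 0:
            noise = rng.standard_normal((m, n, 3))
        else:
            noise = np.zeros((m, n, 3))
        _kernels.baoab_chunk(pos, vel, f, noise, cfg.dt_ps, cfg.gamma_per_ps,
                             cfg.mass, cfg.kT, d, cfg.bond_k, field.u0_ev,
                             field.u0_attr, field.r_cut, cage_r, cfg.cage_k)
        done += m
        if not np.all(np.isfinite(pos)):
            raise RuntimeError(f"coordinate overflow at step {done}")


@dataclass
class EquilibrationResult:
    conformation: Conformation
    rg_trace: np.ndarray
    converged: bool


def equilibrate(conf: Conformation, potentials: PairPotentialField,
                config: DynamicsConfig | None = None, *, seed: int = 0,
                cage_radius: float | None = 14.0,
                window_steps: int = 10_000, rel_tol: float = 0.01,
                max_windows: int = 60) -> EquilibrationResult:
    """Relax a conformation until the radius of gyration plateaus.

    The gyration radius is averaged over consecutive windows of
    ``window_steps`` integrator steps; the run stops when the windowed mean
    changes by less than ``rel_tol`` (relative) between two consecutive
    windows, or flags non-convergence after ``max_windows`` windows.
    """
    cfg = config or DynamicsConfig.for_field(potentials)
    pos = conf.positions.copy()
    vel = np.zeros_like(pos)
    rng = np.random.default_rng(seed)
    cage = -1.0 if cage_radius is None else float(cage_radius)
    means = []
    trace = []
    converged = False
    sub = max(1, window_steps // 10)
    for _ in range(max_windows):
        vals = []
        for _ in range(window_steps // sub):
            _integrate(pos, vel, sub, rng, cfg, potentials, 1.0, cage)
            r = radius_of_gyration(pos)
            vals.append(r)
            trace.append(r)
        means.append(float(np.mean(vals)))
        if len(means) >= 2:
            prev, cur = means[-2], means[-1]
            if abs(cur - prev) < rel_tol * abs(prev):
                converged = True
                break
    return EquilibrationResult(Conformation(pos, time_stamp=0.0),
                               np.asarray(trace), converged)


def simulate_dynamics(conf: Conformation, potentials: PairPotentialField,
                      n_steps: int, seed: int, *,
                      config: DynamicsConfig | None = None,
                      stride: int = 100,
                      cage_radius: float | None = None) -> Trajectory:
    """Langevin trajectory from an (equilibrated) conformation.

    Frames are stored every ``stride`` steps, including the initial state;
    the cage is off by default (production phase).  Seeded and
    bit-reproducible on one platform.
    """
    cfg = config or DynamicsConfig.for_field(potentials)
    pos = conf.positions.copy()
    vel = np.zeros_like(pos)
    rng = np.random.default_rng(seed)
    cage = -1.0 if cage_radius is None else float(cage_radius)
    frames = [pos.copy()]
    times = [0.0]
    done = 0
    while done < n_steps:
        m = min(stride, n_steps - done)
        _integrate(pos, vel, m, rng, cfg, potentials, 1.0, cage)
        done += m
        frames.append(pos.copy())
        times.append(done * cfg.dt_ps)
    return Trajectory(np.asarray(frames), np.asarray(times))


def sample_ensemble(spec: ChromosomeSpec, field: PairPotentialField,
                    k_members: int, seed: int, *,
                    config: DynamicsConfig | None = None,
                    burn_in_ps: float = 4000.0, stride_ps: float = 50.0,
                    equil_window_steps: int = 5000,
                    start: Conformation | None = None) -> ConformationEnsemble:
    """Generate an ensemble of K conformations under a potential field.

    If ``start`` is None the full protocol runs: self-avoiding coil in the
    cage, excluded-volume equilibration, then attractions on / cage off
    with a collapse burn-in before sampling.  Passing a pre-equilibrated
    ``start`` skips the coil phase (used by the iterative fit, which reuses
    one equilibrated coil and fresh noise seeds per iteration).
    """
    cfg = config or DynamicsConfig.for_field(field)
    rng = np.random.default_rng(seed)
    if start is None:
        coil = build_initial_conformation(spec, seed)
        ev_only = PairPotentialField(field.u0_ev,
                                     np.zeros_like(field.u0_attr),
                                     field.r_cut)
        eq = equilibrate(coil, ev_only, cfg, seed=seed + 1,
                         cage_radius=spec.cage_radius,
                         window_steps=equil_window_steps)
        start = eq.conformation
    pos = start.positions.copy()
    vel = np.zeros_like(pos)
    burn_steps = int(round(burn_in_ps / cfg.dt_ps))
    stride_steps = max(1, int(round(stride_ps / cfg.dt_ps)))
    _integrate(pos, vel, burn_steps, rng, cfg, field, 1.0, -1.0)
    members = np.empty((k_members, spec.n_subunits, 3))
    for k in range(k_members):
        _integrate(pos, vel, stride_steps, rng, cfg, field, 1.0, -1.0)
        members[k] = pos
    prov = {"seed": seed, "k": k_members, "field_checksum": field.checksum(),
            "burn_in_ps": burn_in_ps, "stride_ps": stride_ps}
    return ConformationEnsemble(members, prov)


def msd_curve(traj: Trajectory, locus: int,
              scale: ScaleMap | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Time-origin-averaged mean squared displacement of one locus.

    Returns lag times in real hours and MSD in nm^2, using the physical
    bead size (225 nm) and the ps-to-hour conversion of ``scale``.
    """
    scale = scale or ScaleMap()
    if traj.n_frames < 2:
        raise ValueError("trajectory needs at least 2 frames")
    if not (0 <= locus < traj.positions.shape[1]):
        raise IndexError("locus out of range")
    x = traj.positions[:, locus, :]
    nf = x.shape[0]
    lags = np.arange(1, nf)
    msd = np.empty(nf - 1)
    for li, lag in enumerate(lags):
        disp = x[lag:] - x[:-lag]
        msd[li] = (disp ** 2).sum(axis=1).mean()
    dt_frame = float(traj.times_ps[1] - traj.times_ps[0])
    lag_hours = lags * dt_frame / scale.ps_per_real_hour
    return lag_hours, msd * scale.d_real_nm ** 2
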