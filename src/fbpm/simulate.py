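"""Synthetic mobility-biosensing experiments.

Generates particle trajectories with ground-truth binding states for sandwich
and competition assays.  Each particle performs free Brownian motion above
the substrate — lateral steps with a wall-hindered diffusivity that depends
on the instantaneous gap height, the height itself evolving by overdamped
sedimentation-plus-thermal dynamics with a reflecting wall — and switches
between unbound and bound states as a continuous-time Markov process.  While
bound, motion is confined: an Ornstein-Uhlenbeck tether around the anchor
point with stationary standard deviation ``confine_um``.  Localization noise
is added to every reported position.

The binding channel is an *effective* association rate: hit rate, binder
densities, and molecular affinity are folded into one concentration-dependent
rate (Hill-shaped mapping).  Sandwich assays bind faster with more target;
competition assays bind slower because the target blocks the particle-side
binders.  Short-lived non-specific sticking and an optional long-lived
multivalent bound tier are also modelled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .motion import Trajectory, TrajectorySet
from .physics import (
    DEFAULT_HINDRANCE_FLOOR,
    HeightModel,
    ParticleSpec,
    height_model_for,
    stokes_einstein_d0,
)

__all__ = [
    "KineticScenario",
    "SimConfig",
    "GroundTruth",
    "FovGroundTruth",
    "STATE_NAMES",
    "effective_on_rate",
    "simulate_particle",
    "simulate_fov",
    "brownian_trajectory",
    "render_frames",
]

# ground-truth state codes
UNBOUND, BOUND_SPECIFIC, BOUND_NONSPECIFIC, BOUND_MULTIVALENT = 0, 1, 2, 3
STATE_NAMES = {
    UNBOUND: "unbound",
    BOUND_SPECIFIC: "bound_specific",
    BOUND_NONSPECIFIC: "bound_nonspecific",
    BOUND_MULTIVALENT: "bound_multivalent",
}


@dataclass(frozen=True)
class KineticScenario:
    """Concentration → switching-rate mapping for one assay design.

    The effective association rate at target concentration C is

        sandwich:     k_ns + k_on_max · Cⁿ / (C_halfⁿ + Cⁿ)
        competition:  k_ns + k_on_max · C_halfⁿ / (C_halfⁿ + Cⁿ)

    Defaults put the specific bond lifetime at 4 s (k_off = 0.25/s, the scale
    measured for single molecular bonds) and non-specific sticking at a rare,
    short-lived channel (k_ns = 0.002/s, lifetime 1 s).  ``p_multi`` is the
    per-second probability of a second bond forming while specifically bound,
    promoting the dwell to a slower-dissociating multivalent tier.
    """

    mode: str = "sandwich"  # "sandwich" | "competition"
    k_on_max: float = 0.02  # 1/s
    c_half: float = 50.0  # concentration units (e.g. pM)
    n_mol: float = 1.0
    k_off: float = 0.25  # 1/s  (specific bond: 4 s lifetime)
    k_ns: float = 0.002  # 1/s  (non-specific association)
    k_off_ns: float = 1.0  # 1/s  (non-specific bonds live ~1 s)
    p_multi: float = 0.0  # 1/s while bound_specific
    k_off_multi: float = 0.02  # 1/s
    binding_reach_um: float | None = None  # None: height-independent binding

    def __post_init__(self) -> None:
        if self.mode not in ("sandwich", "competition"):
            raise ValueError(f"mode must be 'sandwich' or 'competition', got {self.mode!r}")
        for name in ("k_on_max", "k_off", "k_ns", "k_off_ns", "k_off_multi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_multi:
            raise ValueError("p_multi must be >= 0")
        if self.p_multi > 0 and self.k_off_multi >= self.k_off:
            raise ValueError("multivalent dissociation must be slower than k_off")
        if self.c_half <= 0 or self.n_mol <= 0:
            raise ValueError("c_half and n_mol must be > 0")


@dataclass(frozen=True)
class SimConfig:
    """Recording and integration parameters.

    The defaults emulate the standard acquisition protocol: 60 Hz video in
    blocks of 5 minutes, hundreds of particles per field of view, with
    ~20 nm localization noise and a ~30 nm bound-state confinement length so
    bound-state effective diffusivities fall well below the published
    cutoffs.
    """

    frame_rate: float = 60.0  # Hz
    block_s: float = 300.0
    n_blocks: int = 1
    n_particles: int = 500
    confine_um: float = 0.03  # stationary SD of the bound-state tether
    tau_confine_s: float = 0.05  # OU relaxation time of the tether
    sigma_loc_um: float = 0.02  # localization noise
    substeps: int = 10  # integration substeps per frame
    fov_um: tuple[float, float] = (706.0, 530.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.block_s <= 0:
            raise ValueError("frame rate and block duration must be > 0")
        if self.sigma_loc_um < 0 or self.confine_um <= 0:
            raise ValueError("need sigma_loc >= 0 and confine_um > 0")
        if self.substeps < 1 or self.n_blocks < 1 or self.n_particles < 1:
            raise ValueError("substeps, n_blocks, n_particles must be >= 1")

    @property
    def frames_per_block(self) -> int:
        return int(round(self.frame_rate * self.block_s))

    @property
    def n_frames(self) -> int:
        return self.frames_per_block * self.n_blocks

    @property
    def total_s(self) -> float:
        return self.block_s * self.n_blocks

    @property
    def block_bounds(self) -> list[tuple[float, float]]:
        """(start, end) times of each recording block, in seconds."""
        return [(i * self.block_s, (i + 1) * self.block_s) for i in range(self.n_blocks)]


@dataclass
class GroundTruth:
    """Exact simulated state of one particle: per-frame labels, the event
    list (state, start, end in s), and the gap-height track."""

    particle_id: int
    states: np.ndarray  # int8 per frame, codes in STATE_NAMES
    events: pd.DataFrame  # columns: state, t_start_s, t_end_s
    heights_um: np.ndarray | None = None

    @property
    def bound(self) -> np.ndarray:
        return self.states > 0

    @property
    def labels(self) -> np.ndarray:
        return np.array([STATE_NAMES[int(s)] for s in self.states])

    @property
    def n_binding_events(self) -> int:
        """Number of distinct bound episodes (consecutive bound_* events with
        no intervening unbound event count once)."""
        b = (self.events["state"] != "unbound").to_numpy()
        if b.size == 0:
            return 0
        return int(np.sum(b & ~np.concatenate(([False], b[:-1]))))


@dataclass
class FovGroundTruth:
    """Ground truth for a whole field of view."""

    per_particle: dict[int, GroundTruth] = field(default_factory=dict)

    def __getitem__(self, pid: int) -> GroundTruth:
        return self.per_particle[pid]

    @property
    def events(self) -> pd.DataFrame:
        frames = []
        for pid, gt in self.per_particle.items():
            df = gt.events.copy()
            df.insert(0, "particle_id", pid)
            frames.append(df)
        return (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["particle_id", "state", "t_start_s", "t_end_s"])
        )

    def to_frame(self, frame_rate: float = 60.0) -> pd.DataFrame:
        rows = []
        for pid, gt in self.per_particle.items():
            rows.append(
                pd.DataFrame(
                    {
                        "particle_id": pid,
                        "frame": np.arange(len(gt.states)),
                        "true_state": gt.labels,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path, frame_rate: float = 60.0) -> None:
        self.to_frame(frame_rate).to_csv(path, index=False)


def effective_on_rate(concentration, scenario: KineticScenario):
    """Total association rate (specific + non-specific) at a concentration.

    Monotone increasing in C for sandwich mode, decreasing for competition.
    Accepts scalars or arrays.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    cn = c**scenario.n_mol
    chn = scenario.c_half**scenario.n_mol
    if scenario.mode == "sandwich":
        frac = np.where(cn + chn > 0, cn / (chn + cn), 0.0)
    else:
        frac = chn / (chn + cn)
    out = scenario.k_ns + scenario.k_on_max * frac
    return float(out) if np.isscalar(concentration) else out


# ---------------------------------------------------------------------------
# core integrator: one particle, substep resolution
# ---------------------------------------------------------------------------

def _kernel(
    n_frames,
    substeps,
    dt,
    x0,
    y0,
    h0,
    d0,
    a,
    inv_hb,
    floor,
    k_on_spec,
    k_ns,
    k_off,
    k_off_ns,
    p_multi,
    k_off_multi,
    reach,
    ell_c,
    rho_ou,
    sig_ou,
    normals,
    uniforms,
    x_out,
    y_out,
    h_out,
    state_out,
    sub_states,
):
    x, y, h = x0, y0, h0
    ax, ay = x, y
    state = 0
    x_out[0], y_out[0], h_out[0] = x, y, h
    state_out[0] = 0
    i = 0
    for f in range(1, n_frames):
        for _ in range(substeps):
            n1 = normals[i, 0]
            n2 = normals[i, 1]
            n3 = normals[i, 2]
            u = uniforms[i]
            if state == 0:
                # height: overdamped sedimentation + thermal noise with
                # height-dependent perpendicular mobility (Itô drift
                # correction keeps the barometric stationary law exact)
                num = 6.0 * h * h + 2.0 * a * h
                den = 6.0 * h * h + 9.0 * a * h + 2.0 * a * a
                fperp = num / den
                dnum = 12.0 * h + 2.0 * a
                dden = 12.0 * h + 9.0 * a
                dfperp = (dnum * den - num * dden) / (den * den)
                dperp = d0 * fperp
                h = h + (-dperp * inv_hb + d0 * dfperp) * dt + math.sqrt(2.0 * dperp * dt) * n3
                if h < 0.0:
                    h = -h
                # lateral free diffusion, wall-hindered
                b = a / (a + h)
                fpar = (
                    1.0
                    - 0.5625 * b
                    + 0.125 * b * b * b
                    - 0.17578125 * b * b * b * b
                    - 0.0625 * b * b * b * b * b
                )
                if fpar < floor:
                    fpar = floor
                s = math.sqrt(2.0 * d0 * fpar * dt)
                x += s * n1
                y += s * n2
                gate = reach < 0.0 or h < reach
                if gate:
                    p1 = k_on_spec * dt
                    p2 = k_ns * dt
                    if u < p1:
                        state = 1
                        ax, ay = x, y
                    elif u < p1 + p2:
                        state = 2
                        ax, ay = x, y
            else:
                # tethered (confined) motion around the anchor
                x = ax + (x - ax) * rho_ou + sig_ou * n1
                y = ay + (y - ay) * rho_ou + sig_ou * n2
                if state == 1:
                    if u < k_off * dt:
                        state = 0
                    elif u < (k_off + p_multi) * dt:
                        state = 3
                elif state == 2:
                    if u < k_off_ns * dt:
                        state = 0
                else:
                    if u < k_off_multi * dt:
                        state = 0
            sub_states[i] = state
            i += 1
        x_out[f], y_out[f], h_out[f] = x, y, h
        state_out[f] = state


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _kernel = njit(cache=True)(_kernel)
except Exception:  # numba unavailable: same code runs as plain Python
    pass


def _check_rates(scenario: KineticScenario, k_on_spec: float, dt: float) -> None:
    worst = max(k_on_spec, scenario.k_ns, scenario.k_off, scenario.k_off_ns, scenario.p_multi)
    if worst * dt > 0.1:
        warnings.warn(
            f"fastest rate {worst:.3g}/s is coarse for substep {dt:.2g} s "
            f"(k·Δt = {worst * dt:.2g} > 0.1); increase substeps",
            stacklevel=3,
        )


def simulate_particle(
    spec: ParticleSpec,
    scenario: KineticScenario,
    config: SimConfig,
    seed,
    concentration: float = 0.0,
    particle_id: int = 0,
    x0: float | None = None,
    y0: float | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one particle; returns its Trajectory and exact GroundTruth.

    All randomness flows from ``seed`` (int, Generator, or SeedSequence);
    identical inputs give bit-identical outputs.
    """
    rng = np.random.default_rng(seed)
    model = height_model_for(spec)
    d0 = stokes_einstein_d0(spec)
    n_frames = config.n_frames
    substeps = config.substeps
    dt = 1.0 / (config.frame_rate * substeps)
    n_sub = (n_frames - 1) * substeps

    k_total = effective_on_rate(concentration, scenario)
    k_on_spec = k_total - scenario.k_ns
    _check_rates(scenario, k_on_spec, dt)

    if x0 is None:
        x0 = float(rng.uniform(0, config.fov_um[0]))
    if y0 is None:
        y0 = float(rng.uniform(0, config.fov_um[1]))
    h0 = float(rng.exponential(model.mean_height_um))

    normals = rng.standard_normal((n_sub, 3))
    uniforms = rng.random(n_sub)
    loc_noise = rng.standard_normal((n_frames, 2)) * config.sigma_loc_um

    x_out = np.empty(n_frames)
    y_out = np.empty(n_frames)
    h_out = np.empty(n_frames)
    state_out = np.empty(n_frames, dtype=np.int8)
    sub_states = np.empty(n_sub, dtype=np.int8)

    rho_ou = math.exp(-dt / config.tau_confine_s)
    sig_ou = config.confine_um * math.sqrt(1.0 - rho_ou * rho_ou)
    reach = -1.0 if scenario.binding_reach_um is None else scenario.binding_reach_um

    _kernel(
        n_frames,
        substeps,
        dt,
        x0,
        y0,
        h0,
        d0,
        spec.radius_um,
        1.0 / model.mean_height_um,
        DEFAULT_HINDRANCE_FLOOR,
        k_on_spec,
        scenario.k_ns,
        scenario.k_off,
        scenario.k_off_ns,
        scenario.p_multi,
        scenario.k_off_multi,
        reach,
        config.confine_um,
        rho_ou,
        sig_ou,
        normals,
        uniforms,
        x_out,
        y_out,
        h_out,
        state_out,
        sub_states,
    )

    frames = np.arange(n_frames)
    traj = Trajectory(
        particle_id=particle_id,
        frame=frames,
        t_s=frames / config.frame_rate,
        x_um=x_out + loc_noise[:, 0],
        y_um=y_out + loc_noise[:, 1],
    )

    # event list from the substep-resolution state sequence
    full = np.concatenate(([0], sub_states)).astype(np.int8)
    change = np.flatnonzero(np.diff(full))
    bounds = np.concatenate(([0], change + 1, [len(full)]))
    ev_state = [STATE_NAMES[int(full[b])] for b in bounds[:-1]]
    events = pd.DataFrame(
        {
            "state": ev_state,
            "t_start_s": [b * dt for b in bounds[:-1]],
            # final event ends at the recording end, not one substep past it
            "t_end_s": [min(b, n_sub) * dt for b in bounds[1:]],
        }
    )
    gt = GroundTruth(particle_id, state_out, events, heights_um=h_out)
    return traj, gt


def simulate_fov(
    spec: ParticleSpec,
    scenario: KineticScenario,
    config: SimConfig,
    concentration: float = 0.0,
    seed=None,
) -> tuple[TrajectorySet, FovGroundTruth]:
    """Simulate an independent ensemble (one field of view).

    Per-particle seeds are spawned deterministically from the master seed
    (``config.seed`` unless ``seed`` is given), so runs are bit-reproducible
    and any single particle can be regenerated in isolation.
    """
    master = config.seed if seed is None else seed
    children = np.random.SeedSequence(master).spawn(config.n_particles)
    trajs, gts = [], {}
    for pid, child in enumerate(children):
        traj, gt = simulate_particle(
            spec, scenario, config, child, concentration=concentration, particle_id=pid
        )
        trajs.append(traj)
        gts[pid] = gt
    return TrajectorySet(trajs), FovGroundTruth(gts)


def brownian_trajectory(
    d_um2_s: float,
    n_frames: int,
    frame_rate: float = 60.0,
    sigma_loc_um: float = 0.0,
    seed=None,
    particle_id: int = 0,
    x0: float = 0.0,
    y0: float = 0.0,
) -> Trajectory:
    """Plain free 2D Brownian motion at a fixed diffusivity (no walls, no
    binding) — the reference input for estimator-consistency checks."""
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    step = math.sqrt(2.0 * d_um2_s * dt)
    xy = np.cumsum(rng.standard_normal((n_frames, 2)) * step, axis=0)
    xy[:, 0] += x0 - xy[0, 0]
    xy[:, 1] += y0 - xy[0, 1]
    if sigma_loc_um > 0:
        xy = xy + rng.standard_normal((n_frames, 2)) * sigma_loc_um
    frames = np.arange(n_frames)
    return Trajectory(particle_id, frames, frames * dt, xy[:, 0], xy[:, 1])


def render_frames(
    trajset: TrajectorySet,
    psf_sigma_px: float = 1.3,
    pixel_size_um: float = 0.345,
    shape: tuple[int, int] = (256, 256),
    background: float = 100.0,
    photon_scale: float = 5000.0,
    seed=None,
    poisson_noise: bool = True,
) -> np.ndarray:
    """Render trajectories into a synthetic image stack (frames, H, W) uint16.

    Each particle is drawn as an integrated 2D Gaussian spot of total flux
    ``photon_scale`` at its true position; Poisson shot noise is applied on
    top of the constant background.  Positions outside the image are clipped
    to the border with a warning.
    """
    rng = np.random.default_rng(seed)
    trajs = trajset.trajectories
    if not trajs:
        raise ValueError("empty trajectory set")
    n_frames = max(len(t) for t in trajs)
    H, W = shape
    stack = np.full((n_frames, H, W), background, dtype=float)
    half = max(3, int(np.ceil(4 * psf_sigma_px)))
    clipped = False
    for t in trajs:
        px = t.x_um / pixel_size_um
        py = t.y_um / pixel_size_um
        if np.any(px < 0) or np.any(px > W - 1) or np.any(py < 0) or np.any(py > H - 1):
            clipped = True
            px = np.clip(px, 0, W - 1)
            py = np.clip(py, 0, H - 1)
        for k, f in enumerate(t.frame):
            cx, cy = px[k], py[k]
            ix, iy = int(round(cx)), int(round(cy))
            x_lo, x_hi = max(0, ix - half), min(W, ix + half + 1)
            y_lo, y_hi = max(0, iy - half), min(H, iy + half + 1)
            xs = np.arange(x_lo, x_hi)
            ys = np.arange(y_lo, y_hi)
            gx = np.exp(-((xs - cx) ** 2) / (2 * psf_sigma_px**2))
            gy = np.exp(-((ys - cy) ** 2) / (2 * psf_sigma_px**2))
            spot = np.outer(gy, gx) * (photon_scale / (2 * np.pi * psf_sigma_px**2))
            stack[int(f), y_lo:y_hi, x_lo:x_hi] += spot
    if clipped:
        warnings.warn("some particle positions fell outside the image and were clipped",
                      stacklevel=2)
    if poisson_noise:
        stack = rng.poisson(stack).astype(float)
    return np.clip(stack, 0, 65535).astype(np.uint16)
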