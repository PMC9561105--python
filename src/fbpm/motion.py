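"""Trajectory containers, windowed-MSD diffusivity traces, two-state
segmentation, and ensemble quality-control filtering.

The analysis chain mirrors how mobility-based biosensing experiments are
processed: particle centre positions per video frame → sliding-window
mean-squared-displacement (MSD) estimate of the effective diffusivity D(t) →
threshold/hysteresis segmentation of D(t) into unbound (free Brownian) and
bound (confined) states → exclusion of stuck, hyperactive, and colliding
particles before ensemble statistics are computed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "TrajectorySet",
    "DiffusivityTrace",
    "SegmentationConfig",
    "StateTrace",
    "QCReport",
    "msd",
    "diffusivity_trace",
    "segment_states",
    "qc_filter",
]

TRAJECTORY_COLUMNS = ["particle_id", "frame", "t_s", "x_um", "y_um", "valid"]
STATE_COLUMNS = ["particle_id", "frame", "t_s", "D_um2_s", "state"]


@dataclass
class Trajectory:
    """Time-stamped 2D positions of one particle.

    Frames are strictly increasing; ``t_s = frame / frame_rate``.  Positions
    at frames flagged invalid (gap fills from the linker) are excluded from
    MSD estimation.
    """

    particle_id: int
    frame: np.ndarray
    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.frame), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.frame) > 1 and np.any(np.diff(self.frame) <= 0):
            raise ValueError(f"particle {self.particle_id}: frame indices must strictly increase")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def frame_rate(self) -> float:
        if len(self) < 2:
            return float("nan")
        dt = np.median(np.diff(self.t_s) / np.diff(self.frame))
        return 1.0 / dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "particle_id": self.particle_id,
                "frame": self.frame,
                "t_s": self.t_s,
                "x_um": self.x_um,
                "y_um": self.y_um,
                "valid": self.valid.astype(int),
            }
        )


@dataclass
class TrajectorySet:
    """An ensemble of trajectories from one field of view / recording."""

    trajectories: list[Trajectory] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, i) -> Trajectory:
        return self.trajectories[i]

    @property
    def particle_ids(self) -> list[int]:
        return [t.particle_id for t in self.trajectories]

    def to_frame(self) -> pd.DataFrame:
        if not self.trajectories:
            return pd.DataFrame(columns=TRAJECTORY_COLUMNS)
        return pd.concat([t.to_frame() for t in self.trajectories], ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrajectorySet":
        trajs = []
        for pid, g in df.groupby("particle_id", sort=True):
            g = g.sort_values("frame")
            valid = g["valid"].to_numpy().astype(bool) if "valid" in g else None
            trajs.append(
                Trajectory(
                    particle_id=int(pid),
                    frame=g["frame"].to_numpy(),
                    t_s=g["t_s"].to_numpy(),
                    x_um=g["x_um"].to_numpy(),
                    y_um=g["y_um"].to_numpy(),
                    valid=valid,
                )
            )
        return cls(trajs)

    @classmethod
    def from_csv(cls, path) -> "TrajectorySet":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class DiffusivityTrace:
    """Windowed effective diffusivity D(t) of one particle.

    One value per sliding window of ``window`` frames (step 1 frame), stamped
    at the window-centre time; length = trajectory length − window + 1.
    Negative least-squares slopes (possible at the static-noise floor) are
    clipped to 0 and counted in ``n_clipped``.
    """

    particle_id: int
    window: int
    center_frame: np.ndarray
    t_s: np.ndarray
    D_um2_s: np.ndarray
    n_clipped: int = 0

    def __len__(self) -> int:
        return len(self.D_um2_s)


@dataclass(frozen=True)
class SegmentationConfig:
    """Hysteresis thresholds for two-state segmentation of D(t).

    ``d_hi`` is the field's published free-motion cutoff (0.15 μm²/s for 1 μm
    particles, 0.05 μm²/s for 2.8 μm particles); the bound-entry threshold
    ``d_lo`` sits below it to suppress chatter.  Dwells shorter than
    ``min_dwell`` trace samples are merged into their surroundings; the
    default of 90 samples (three 0.5 s windows at 60 Hz) exceeds the
    correlation length of the sliding-window estimator, so noise excursions
    cannot masquerade as binding events, while staying well below the ~4 s
    single-bond lifetime.
    """

    d_hi: float
    d_lo: float
    min_dwell: int = 90

    def __post_init__(self) -> None:
        if not (0 <= self.d_lo < self.d_hi):
            raise ValueError(f"need 0 <= d_lo < d_hi, got d_lo={self.d_lo}, d_hi={self.d_hi}")
        if self.min_dwell < 1:
            raise ValueError("min_dwell must be >= 1")

    @classmethod
    def for_cutoff(cls, cutoff: float, lo_fraction: float = 0.6, min_dwell: int = 90):
        """Build from a single published cutoff: d_hi=cutoff, d_lo=0.6·cutoff."""
        return cls(d_hi=cutoff, d_lo=lo_fraction * cutoff, min_dwell=min_dwell)


@dataclass
class StateTrace:
    """Per-frame unbound/bound segmentation of one particle.

    ``bound`` covers every analysed frame; ``transitions`` is a list of
    (direction, time) with direction +1 for binding (unbound→bound) and −1
    for unbinding, strictly alternating.
    """

    particle_id: int
    frame: np.ndarray
    t_s: np.ndarray
    bound: np.ndarray
    transitions: list[tuple[int, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    @property
    def bound_fraction(self) -> float:
        return float(np.mean(self.bound))

    def to_frame(self, trace: DiffusivityTrace | None = None) -> pd.DataFrame:
        d = np.full(len(self), np.nan)
        if trace is not None:
            idx = np.searchsorted(self.frame, trace.center_frame)
            d[idx] = trace.D_um2_s
        return pd.DataFrame(
            {
                "particle_id": self.particle_id,
                "frame": self.frame,
                "t_s": self.t_s,
                "D_um2_s": d,
                "state": np.where(self.bound, "bound", "unbound"),
            }
        )


def msd(traj: Trajectory, max_lag: int) -> np.ndarray:
    """Time-averaged MSD(τ) for τ = 1..max_lag frames, using all overlapping
    valid pairs.  Returns an array of length max_lag in μm².
    """
    n = len(traj)
    if max_lag >= n:
        raise ValueError(f"max_lag={max_lag} must be < trajectory length {n}")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    x, y, v = traj.x_um, traj.y_um, traj.valid
    out = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        ok = v[lag:] & v[:-lag]
        dx = x[lag:] - x[:-lag]
        dy = y[lag:] - y[:-lag]
        sq = dx[ok] ** 2 + dy[ok] ** 2
        out[lag - 1] = sq.mean() if sq.size else np.nan
    return out


def _windowed_msd(x, y, valid, window, lag):
    """Mean squared displacement at one lag inside every sliding window.

    Returns an array of length n−window+1; windows are W consecutive frames,
    pairs (i, i+lag) with both endpoints valid.
    """
    n = len(x)
    dx = x[lag:] - x[:-lag]
    dy = y[lag:] - y[:-lag]
    sq = dx**2 + dy**2
    ok = (valid[lag:] & valid[:-lag]).astype(float)
    sq = np.where(ok > 0, sq, 0.0)
    m = window - lag  # pairs per full window
    csq = np.concatenate(([0.0], np.cumsum(sq)))
    cok = np.concatenate(([0.0], np.cumsum(ok)))
    n_win = n - window + 1
    s = csq[m : m + n_win] - csq[:n_win]
    c = cok[m : m + n_win] - cok[:n_win]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(c > 0, s / np.maximum(c, 1), np.nan)


def diffusivity_trace(
    traj: Trajectory,
    window: int = 30,
    fit_lags: int = 5,
    frame_rate: float | None = None,
) -> DiffusivityTrace:
    """Sliding-window effective diffusivity from short-lag MSD slopes.

    For each window of ``window`` frames the MSD over lags 1..``fit_lags`` is
    fitted with an origin-constrained least-squares line MSD(τ) = m·τ; the
    effective diffusivity is D = m/(4Δt) (2D diffusion).  The short-lag,
    origin-constrained fit keeps the estimator responsive to state switches
    at the cost of a static-noise floor ∝ σ_loc².
    """
    if not (window > fit_lags >= 1):
        raise ValueError(f"need window > fit_lags >= 1, got {window}, {fit_lags}")
    n = len(traj)
    if n < window:
        warnings.warn(
            f"particle {traj.particle_id}: trajectory ({n} frames) shorter than "
            f"window ({window}); empty diffusivity trace",
            stacklevel=2,
        )
        empty = np.empty(0)
        return DiffusivityTrace(traj.particle_id, window, empty.astype(int), empty, empty)
    if frame_rate is None:
        frame_rate = traj.frame_rate
    dt = 1.0 / frame_rate
    lags = np.arange(1, fit_lags + 1, dtype=float)
    denom = float(np.sum(lags**2))
    num = np.zeros(n - window + 1)
    for lag in range(1, fit_lags + 1):
        num += lag * _windowed_msd(traj.x_um, traj.y_um, traj.valid, window, lag)
    slope = num / denom  # μm² per lag-frame
    d = slope / (4.0 * dt)
    n_clipped = int(np.sum(d < 0))
    d = np.clip(d, 0.0, None)
    if n_clipped:
        logger.debug("particle %s: clipped %d negative D values", traj.particle_id, n_clipped)
    centers = np.arange(n - window + 1) + window // 2
    return DiffusivityTrace(
        particle_id=traj.particle_id,
        window=window,
        center_frame=traj.frame[centers],
        t_s=traj.t_s[centers],
        D_um2_s=d,
        n_clipped=n_clipped,
    )


def _merge_short_runs(states: np.ndarray, min_len: int) -> np.ndarray:
    """Debounce a boolean state sequence: repeatedly absorb the shortest run
    below ``min_len`` into its neighbours until none remain."""
    s = states.copy()
    while True:
        change = np.flatnonzero(np.diff(s.astype(np.int8)))
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [len(s)]))
        lengths = ends - starts
        if len(starts) <= 1:
            return s
        short = np.flatnonzero(lengths < min_len)
        # never erase the whole sequence: only flip interior/edge runs that
        # have a neighbour to merge into
        if short.size == 0:
            return s
        k = short[np.argmin(lengths[short])]
        s[starts[k] : ends[k]] = ~s[starts[k]]
    return s


def segment_states(
    trace: DiffusivityTrace,
    cfg: SegmentationConfig,
    full_frames: np.ndarray | None = None,
    full_times: np.ndarray | None = None,
) -> StateTrace:
    """Hysteresis segmentation of a D(t) trace into unbound/bound states.

    The particle enters the bound state when D drops below ``d_lo`` and
    leaves it when D rises above ``d_hi``; values in between keep the current
    state.  Dwells shorter than ``min_dwell`` samples are merged away.  When
    ``full_frames``/``full_times`` are given (the underlying trajectory's
    frames), window-centre states are extended to cover every frame.
    """
    d = trace.D_um2_s
    n = len(d)
    if n == 0:
        return StateTrace(trace.particle_id, np.empty(0, int), np.empty(0), np.empty(0, bool))
    bound = np.empty(n, dtype=bool)
    state = bool(d[0] < cfg.d_lo)
    for i in range(n):
        if state:
            if d[i] > cfg.d_hi:
                state = False
        else:
            if d[i] < cfg.d_lo:
                state = True
        bound[i] = state
    if cfg.min_dwell > 1:
        bound = _merge_short_runs(bound, cfg.min_dwell)

    if full_frames is None:
        frames, times = trace.center_frame, trace.t_s
        states_full = bound
    else:
        frames = np.asarray(full_frames)
        times = np.asarray(full_times) if full_times is not None else frames / 60.0
        # extend window-centre states to the trajectory edges
        idx = np.searchsorted(trace.center_frame, frames, side="right") - 1
        idx = np.clip(idx, 0, n - 1)
        states_full = bound[idx]

    change = np.flatnonzero(np.diff(bound.astype(np.int8)))
    transitions = [
        (1 if bound[c + 1] else -1, float(trace.t_s[c + 1])) for c in change
    ]
    return StateTrace(
        particle_id=trace.particle_id,
        frame=frames,
        t_s=times,
        bound=states_full,
        transitions=transitions,
    )


@dataclass
class QCReport:
    """Per-rule exclusion counts from the ensemble quality filter."""

    n_total: int
    stuck: list[int]
    hyperactive: list[int]
    colliding: list[int]

    @property
    def excluded_ids(self) -> set[int]:
        return set(self.stuck) | set(self.hyperactive) | set(self.colliding)

    @property
    def excluded_fraction(self) -> float:
        return len(self.excluded_ids) / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_stuck": len(self.stuck),
            "n_hyperactive": len(self.hyperactive),
            "n_colliding": len(self.colliding),
            "excluded_fraction": self.excluded_fraction,
            "stuck": sorted(self.stuck),
            "hyperactive": sorted(self.hyperactive),
            "colliding": sorted(self.colliding),
        }


def qc_filter(
    trajset: TrajectorySet,
    traces: list[DiffusivityTrace],
    state_traces: list[StateTrace],
    stuck_d: float = 0.01,
    hyperactive_sd: float = 4.0,
    collision_dist_um: float = 0.7,
    collision_run_s: float = 1.0,
    warn_fraction: float = 0.10,
):
    """Exclude stuck, hyperactive, and colliding particles.

    Rules (all thresholds configurable):

    i.   stuck: time-averaged D below ``stuck_d`` (default 0.01 μm²/s);
    ii.  hyperactive: switching-event count above the ensemble mean by more
         than ``hyperactive_sd`` standard deviations (default 4);
    iii. colliding: a pair of particles closer than ``collision_dist_um``
         (default 0.7 μm, ≈2 px) for an uninterrupted run longer than
         ``collision_run_s`` — both members excluded.

    Returns ``(filtered TrajectorySet, filtered traces, filtered state
    traces, QCReport)``.  Warns when the excluded fraction reaches 10%, the
    level above which published ensembles flag a problem.
    """
    n = len(trajset)
    if n == 0:
        raise ValueError("empty trajectory set")
    by_id = {t.particle_id: k for k, t in enumerate(trajset)}

    stuck = [
        tr.particle_id for tr in traces if len(tr) and float(np.mean(tr.D_um2_s)) < stuck_d
    ]

    counts = np.array([st.n_transitions for st in state_traces], dtype=float)
    mu, sd = counts.mean(), counts.std()
    hyperactive = [
        st.particle_id
        for st, c in zip(state_traces, counts)
        if sd > 0 and c > mu + hyperactive_sd * sd
    ]

    colliding: set[int] = set()
    trajs = trajset.trajectories
    means = np.array([[t.x_um.mean(), t.y_um.mean()] for t in trajs])
    spans = np.array(
        [np.hypot(t.x_um.max() - t.x_um.min(), t.y_um.max() - t.y_um.min()) for t in trajs]
    )
    for i in range(n):
        for j in range(i + 1, n):
            # cheap prefilter: bounding circles must come close
            gap = np.hypot(*(means[i] - means[j])) - (spans[i] + spans[j]) / 2
            if gap > collision_dist_um:
                continue
            ti, tj = trajs[i], trajs[j]
            common, ia, ja = np.intersect1d(ti.frame, tj.frame, return_indices=True)
            if common.size < 2:
                continue
            dist = np.hypot(ti.x_um[ia] - tj.x_um[ja], ti.y_um[ia] - tj.y_um[ja])
            close = dist < collision_dist_um
            if not close.any():
                continue
            fr = ti.frame_rate
            run_frames = max(2, int(np.ceil(collision_run_s * (fr if np.isfinite(fr) else 60.0))))
            # longest run of consecutive close frames
            best = run = 0
            for k in range(common.size):
                run = run + 1 if close[k] and (k == 0 or common[k] == common[k - 1] + 1) else (
                    1 if close[k] else 0
                )
                best = max(best, run)
            if best > run_frames:
                colliding.update((ti.particle_id, tj.particle_id))

    report = QCReport(n, stuck, hyperactive, sorted(colliding))
    excluded = report.excluded_ids
    if len(excluded) == n:
        raise ValueError("quality filter excluded every particle")
    if report.excluded_fraction >= warn_fraction:
        warnings.warn(
            f"{report.excluded_fraction:.0%} of particles excluded by quality filter "
            f"(threshold {warn_fraction:.0%})",
            stacklevel=2,
        )
    keep = [t.particle_id not in excluded for t in trajs]
    return (
        TrajectorySet([t for t, k in zip(trajs, keep) if k]),
        [tr for tr, k in zip(traces, keep) if k],
        [st for st, k in zip(state_traces, keep) if k],
        report,
    )
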