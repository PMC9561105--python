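"""Single-molecule switching statistics from state traces.

State dwell times are the primary observable of mobility-based biosensing:
the unbound-state lifetime encodes the effective association rate (and hence
the analyte concentration) while the bound-state lifetime encodes the
molecular dissociation rate.  Dwells truncated by the start or end of a
recording block give only a lower bound on the true duration and are flagged
right-censored; the exponential fit handles them by maximum likelihood
(total exposure over complete-event count).  A "naive" mode that treats
censored dwells as complete is also provided: it reproduces the apparent
saturation of measured lifetimes at the recording-window scale when the true
lifetime far exceeds the measurement duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .motion import StateTrace

__all__ = [
    "LifetimeSet",
    "SurvivalCurve",
    "ExponentialFit",
    "extract_lifetimes",
    "extract_lifetimes_ensemble",
    "survival_curve",
    "fit_exponential",
    "fit_biexponential",
    "switching_activity",
    "bound_fraction",
]


@dataclass
class LifetimeSet:
    """Dwell times of one state with censoring flags.

    ``censored[i]`` is True when dwell i abuts a recording-block boundary
    (either edge), in which case ``durations_s[i]`` is only the observed
    part of the dwell.  ``right_censored[i]`` marks the subset that is
    truncated by the block *end*: those dwells never end in an observed
    transition, so they contribute exposure but no event to the exponential
    likelihood.  A dwell merely clipped at the block *start* but ending in a
    transition still ends in an observed event; by memorylessness of the
    exponential its observed duration is a valid draw from the same
    distribution.
    """

    state: str  # "unbound" | "bound"
    durations_s: np.ndarray
    censored: np.ndarray
    right_censored: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.right_censored is None:
            self.right_censored = self.censored.copy()
        else:
            self.right_censored = np.asarray(self.right_censored, dtype=bool)
        if self.durations_s.shape != self.censored.shape:
            raise ValueError("durations and censored flags must align")
        if self.right_censored.shape != self.censored.shape:
            raise ValueError("right_censored flags must align")
        if np.any(self.right_censored & ~self.censored):
            raise ValueError("right-censored dwells must also be flagged censored")
        if np.any(self.durations_s <= 0):
            raise ValueError("durations must be > 0")

    def __len__(self) -> int:
        return len(self.durations_s)

    @property
    def n_complete(self) -> int:
        """Dwells bounded by two observed transitions (no edge contact)."""
        return int(np.sum(~self.censored))

    @property
    def n_events(self) -> int:
        """Dwells ending in an observed transition (complete or only
        start-clipped); the event count of the exponential likelihood."""
        return int(np.sum(~self.right_censored))

    @property
    def complete(self) -> np.ndarray:
        return self.durations_s[~self.censored]

    def merged(self, other: "LifetimeSet") -> "LifetimeSet":
        if other.state != self.state:
            raise ValueError("cannot merge lifetime sets of different states")
        return LifetimeSet(
            self.state,
            np.concatenate([self.durations_s, other.durations_s]),
            np.concatenate([self.censored, other.censored]),
            np.concatenate([self.right_censored, other.right_censored]),
        )


@dataclass
class SurvivalCurve:
    """Empirical survival S(t) = 1 − CDF of complete dwell times."""

    times_s: np.ndarray
    survival: np.ndarray
    n_censored_excluded: int = 0

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times_s, t, side="right") - 1
        return self.survival[np.clip(idx, 0, len(self.survival) - 1)]


@dataclass
class ExponentialFit:
    """Fitted characteristic lifetime(s) of a dwell-time distribution.

    Single-exponential by default; ``tau2_s``/``weight2`` are set for a
    two-component mixture (short-lived monovalent + long-lived multivalent
    bonds), with components ordered tau_s < tau2_s.
    """

    tau_s: float
    se_s: float
    n_complete: int
    n_censored: int
    mode: str = "censored"  # censoring handling: "censored" | "naive"
    tau2_s: float | None = None
    weight2: float | None = None
    degenerate: bool = False

    @property
    def is_biexponential(self) -> bool:
        return self.tau2_s is not None

    def to_dict(self) -> dict:
        d = {
            "tau_s": self.tau_s,
            "se_s": self.se_s,
            "n_complete": self.n_complete,
            "n_censored": self.n_censored,
            "mode": self.mode,
        }
        if self.is_biexponential:
            d.update(tau2_s=self.tau2_s, weight2=self.weight2)
        return d


def _dwells_in_block(transitions, bound0: bool, t0: float, t1: float):
    """Dwells of one particle inside one recording block [t0, t1]."""
    times = [t for _, t in transitions if t0 < t < t1]
    # state at block start
    state = bound0
    for d, t in transitions:
        if t <= t0:
            state = d > 0
    edges = [t0] + times + [t1]
    out = []  # (state_is_bound, duration, censored, right_censored)
    s = state
    for i in range(len(edges) - 1):
        dur = edges[i + 1] - edges[i]
        cens = (i == 0) or (i == len(edges) - 2)
        rcens = i == len(edges) - 2
        if dur > 0:
            out.append((s, dur, cens, rcens))
        s = not s
    return out


def extract_lifetimes(
    trace: StateTrace,
    block_bounds: list[tuple[float, float]],
) -> dict[str, LifetimeSet]:
    """Dwell times per state from one particle's state trace.

    ``block_bounds`` are the (start, end) times of the recording blocks in
    seconds; a dwell that abuts a block edge is flagged censored.  Passing a
    single merged (start, end) treats contiguous blocks as one uninterrupted
    recording.  Returns ``{"unbound": ..., "bound": ...}``.
    """
    if not block_bounds:
        raise ValueError("at least one recording block is required")
    bound0 = bool(trace.bound[0]) if len(trace) else False
    per_state = {"unbound": ([], [], []), "bound": ([], [], [])}
    for t0, t1 in block_bounds:
        for is_bound, dur, cens, rcens in _dwells_in_block(trace.transitions, bound0, t0, t1):
            key = "bound" if is_bound else "unbound"
            per_state[key][0].append(dur)
            per_state[key][1].append(cens)
            per_state[key][2].append(rcens)
    return {
        k: LifetimeSet(
            k,
            np.array(v[0]),
            np.array(v[1], dtype=bool),
            np.array(v[2], dtype=bool),
        )
        for k, v in per_state.items()
    }


def extract_lifetimes_ensemble(
    traces: list[StateTrace],
    block_bounds: list[tuple[float, float]],
) -> dict[str, LifetimeSet]:
    """Pooled dwell times over an ensemble of particles."""
    pooled: dict[str, LifetimeSet] | None = None
    for tr in traces:
        sets = extract_lifetimes(tr, block_bounds)
        pooled = sets if pooled is None else {k: pooled[k].merged(sets[k]) for k in pooled}
    if pooled is None:
        raise ValueError("no state traces given")
    return pooled


def survival_curve(lifetimes: LifetimeSet) -> SurvivalCurve:
    """Empirical 1 − CDF over the complete (uncensored) dwells.

    S(0) = 1 and S is non-increasing; censored dwells are excluded and their
    count is reported on the curve.
    """
    if len(lifetimes) == 0:
        raise ValueError("empty lifetime set")
    comp = np.sort(lifetimes.complete)
    if comp.size == 0:
        raise ValueError("no complete dwells (all censored)")
    n = comp.size
    times = np.concatenate(([0.0], comp))
    surv = np.concatenate(([1.0], 1.0 - np.arange(1, n + 1) / n))
    return SurvivalCurve(times, surv, n_censored_excluded=len(lifetimes) - n)


def fit_exponential(
    lifetimes: LifetimeSet,
    mode: str = "censored",
    min_complete: int = 10,
) -> ExponentialFit:
    """Maximum-likelihood exponential lifetime with right-censoring.

    censored mode (correct):  τ̂ = Σ(all observed durations) / n_events,
    where events are dwells ending in an observed transition — dwells
    truncated by a block end contribute exposure but no event.  This
    total-time-over-events estimator is invariant under subdividing an
    uninterrupted recording into blocks.
    naive mode (fidelity to finite-window measurements): every dwell is
    treated as complete, so τ̂ saturates at the recording-window scale when
    the true lifetime exceeds it.

    Standard error is τ̂/√n_events.
    """
    if mode not in ("censored", "naive"):
        raise ValueError(f"mode must be 'censored' or 'naive', got {mode!r}")
    n_complete = lifetimes.n_complete
    n_cens = len(lifetimes) - n_complete
    if mode == "censored":
        n_events = lifetimes.n_events
        if n_events == 0:
            raise ValueError("all dwells censored: lifetime unidentifiable in censored mode")
        if n_events < min_complete:
            raise ValueError(
                f"{n_events} observed events < required minimum {min_complete}"
            )
        tau = float(lifetimes.durations_s.sum() / n_events)
        se = tau / np.sqrt(n_events)
    else:
        n_all = len(lifetimes)
        if n_all < max(1, min_complete):
            raise ValueError(f"{n_all} dwells < required minimum {min_complete}")
        tau = float(lifetimes.durations_s.mean())
        se = tau / np.sqrt(n_all)
    return ExponentialFit(tau, se, n_complete, n_cens, mode=mode)


def _biexp_em(t: np.ndarray, tau1: float, tau2: float, w2: float, n_iter: int = 500):
    """EM for a two-component exponential mixture on complete dwells."""
    for _ in range(n_iter):
        p1 = (1 - w2) * np.exp(-t / tau1) / tau1
        p2 = w2 * np.exp(-t / tau2) / tau2
        r2 = p2 / (p1 + p2)
        w2_new = r2.mean()
        tau1_new = np.sum((1 - r2) * t) / max(np.sum(1 - r2), 1e-300)
        tau2_new = np.sum(r2 * t) / max(np.sum(r2), 1e-300)
        if (
            abs(tau1_new - tau1) < 1e-10 * tau1
            and abs(tau2_new - tau2) < 1e-10 * tau2
            and abs(w2_new - w2) < 1e-12
        ):
            tau1, tau2, w2 = tau1_new, tau2_new, w2_new
            break
        tau1, tau2, w2 = tau1_new, tau2_new, w2_new
    return tau1, tau2, w2


def fit_biexponential(
    lifetimes: LifetimeSet,
    min_complete: int = 50,
) -> ExponentialFit:
    """Two-component exponential mixture fit (EM on complete dwells).

    Models coexisting short-lived (monovalent) and long-lived (multivalent)
    bond populations.  Falls back to the single-exponential fit with a
    degenerate-fit warning when the components are not identifiable
    (τ₂/τ₁ < 2 or a component weight pinned near 0/1).
    """
    comp = lifetimes.complete
    if comp.size < min_complete:
        raise ValueError(f"{comp.size} complete dwells < required minimum {min_complete}")
    med = np.median(comp)
    tau1, tau2, w2 = _biexp_em(comp, med / 2.0, 4.0 * med, 0.3)
    if tau2 < tau1:
        tau1, tau2, w2 = tau2, tau1, 1.0 - w2
    if tau2 / max(tau1, 1e-300) < 2.0 or w2 < 0.02 or w2 > 0.98:
        warnings.warn(
            "bi-exponential fit degenerate (components not identifiable); "
            "falling back to single exponential",
            stacklevel=2,
        )
        single = fit_exponential(lifetimes, min_complete=1)
        single.degenerate = True
        return single
    se = tau1 / np.sqrt(comp.size)
    return ExponentialFit(
        tau_s=float(tau1),
        se_s=float(se),
        n_complete=int(comp.size),
        n_censored=len(lifetimes) - comp.size,
        tau2_s=float(tau2),
        weight2=float(w2),
    )


def switching_activity(
    traces: list[StateTrace],
    duration_s: float,
    per: str = "min",
) -> tuple[float, float]:
    """Average switching activity: binding plus unbinding events per particle
    per unit time (default per minute), with SEM over particles.
    """
    if not traces:
        raise ValueError("at least one particle required")
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    scale = {"s": 1.0, "min": 60.0}[per]
    rates = np.array([tr.n_transitions / duration_s * scale for tr in traces])
    sem = rates.std(ddof=1) / np.sqrt(len(rates)) if len(rates) > 1 else 0.0
    return float(rates.mean()), float(sem)


def bound_fraction(traces: list[StateTrace]) -> tuple[float, float]:
    """Time-averaged bound fraction per particle, averaged over particles,
    with SEM over particles."""
    if not traces:
        raise ValueError("at least one particle required")
    fracs = np.array([tr.bound_fraction for tr in traces])
    sem = fracs.std(ddof=1) / np.sqrt(len(fracs)) if len(fracs) > 1 else 0.0
    return float(fracs.mean()), float(sem)
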