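"""Sensor-level calibration and monitoring.

Dose-response readouts (switching activity, bound fraction, state lifetimes)
are fitted with the four-parameter sigmoid

    y(x) = y_min + (y_max − y_min) · xⁿ / (EC50ⁿ + xⁿ)

to extract the EC50, the concentration of half-maximal response.  Decreasing
responses (competition assays) are handled by y_max < y_min.  Monitoring
experiments — a concentration-time profile analysed block by block — relax
exponentially after a concentration step; the relaxation time is fitted with
y(t) = y_∞ + (y_0 − y_∞)·exp(−t/τ).

This module also hosts the end-to-end analysis pipeline (quality filter →
diffusivity traces → state segmentation → switching statistics) that the
command-line tool wraps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import t as student_t

from . import kinetics, motion
from .kinetics import ExponentialFit, LifetimeSet
from .motion import DiffusivityTrace, QCReport, SegmentationConfig, StateTrace, TrajectorySet

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "RelaxationFit",
    "MonitorSeries",
    "AnalysisConfig",
    "AnalysisResult",
    "analyze_ensemble",
    "fit_hill",
    "fit_relaxation",
    "build_dose_response",
    "run_monitoring",
]


class UnidentifiableFitError(RuntimeError):
    """The data cannot constrain the requested fit (flat response)."""


@dataclass
class DoseResponseCurve:
    """One readout versus analyte concentration, with uncertainties."""

    readout: str  # activity | bound_fraction | unbound_lifetime | bound_lifetime
    concentrations: np.ndarray
    values: np.ndarray
    uncertainties: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.uncertainties is not None:
            self.uncertainties = np.asarray(self.uncertainties, dtype=float)
            if self.uncertainties.shape != self.values.shape:
                raise ValueError("uncertainty length mismatch")
        if self.concentrations.shape != self.values.shape:
            raise ValueError("concentration/value length mismatch")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")


def hill(x, y_min, y_max, n, ec50):
    """The four-parameter sigmoid y_min + (y_max − y_min)·xⁿ/(EC50ⁿ + xⁿ)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        xn = np.where(x > 0, x, np.nan) ** n
        f = np.where(x > 0, xn / (ec50**n + xn), 0.0)
    return y_min + (y_max - y_min) * f


@dataclass
class HillFit:
    """Fitted sigmoid parameters with a 95% confidence interval on EC50."""

    y_min: float
    y_max: float
    n: float
    ec50: float
    ec50_ci: tuple[float, float]
    se_log_ec50: float
    residuals: np.ndarray
    ci_method: str = "covariance"

    def __post_init__(self) -> None:
        lo, hi = self.ec50_ci
        if not (lo <= self.ec50 <= hi):
            raise ValueError("EC50 confidence interval must contain the point estimate")

    def __call__(self, x):
        return hill(x, self.y_min, self.y_max, self.n, self.ec50)

    def to_dict(self) -> dict:
        return {
            "y_min": self.y_min,
            "y_max": self.y_max,
            "n": self.n,
            "ec50": self.ec50,
            "ec50_ci95": list(self.ec50_ci),
            "ci_method": self.ci_method,
        }


def _hill_log(x, y_min, y_max, log_n, log_ec50):
    return hill(x, y_min, y_max, np.exp(log_n), np.exp(log_ec50))


def fit_hill(
    curve: DoseResponseCurve,
    ci_method: str = "auto",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> HillFit:
    """Weighted least-squares sigmoid fit extracting the EC50.

    Positivity of EC50 and n is enforced by fitting on a log scale
    internally; weights are inverse-variance with the per-point uncertainty
    floored at the median uncertainty.  Zero-concentration (blank) points do
    not participate.  The 95% EC50 interval comes from the linearized
    covariance of log EC50; a seeded percentile bootstrap is used as
    fallback when the covariance is unusable (``ci_method="auto"``) or on
    request (``ci_method="bootstrap"``).
    """
    pos = curve.concentrations > 0
    x = curve.concentrations[pos]
    y = curve.values[pos]
    if x.size < 4:
        raise ValueError(f"need >= 4 positive concentrations, got {x.size}")
    if curve.uncertainties is not None:
        u = curve.uncertainties[pos].astype(float)
        floor = np.median(u)
        sigma = np.maximum(u, floor if floor > 0 else 1.0)
    else:
        sigma = None
    dyn = np.ptp(y)
    noise_scale = np.median(sigma) if sigma is not None else 0.0
    if dyn == 0 or (noise_scale > 0 and dyn < 2.0 * noise_scale):
        raise UnidentifiableFitError(
            f"flat dose-response: dynamic range {dyn:.3g} < 2x median uncertainty"
        )

    def _attempt(p0):
        # supplied uncertainties are real SEMs -> absolute; otherwise the
        # residual scale is estimated from the fit itself
        return curve_fit(
            _hill_log, x, y, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
            maxfev=20000,
        )

    p0s = [
        np.array([y[0], y[-1], 0.0, np.log(g)])
        for g in (np.exp(np.mean(np.log(x))), x[len(x) // 2], x[1], x[-2])
    ]
    popt = pcov = None
    errors = []
    for p0 in p0s:
        try:
            popt, pcov = _attempt(p0)
            break
        except Exception as e:  # noqa: BLE001 - collected for diagnostics
            errors.append(str(e))
    if popt is None:
        raise RuntimeError(
            "sigmoid fit did not converge after restarts: " + "; ".join(errors)
        )
    y_min, y_max, log_n, log_ec50 = popt
    ec50 = float(np.exp(log_ec50))
    resid = y - _hill_log(x, *popt)
    se_log = float(np.sqrt(pcov[3, 3])) if np.all(np.isfinite(pcov)) else np.inf
    dof = x.size - 4

    method = ci_method
    if ci_method == "auto":
        usable = np.isfinite(se_log) and (sigma is not None or dof > 0)
        method = "covariance" if usable else "bootstrap"
    if method == "covariance":
        if not np.isfinite(se_log) or (sigma is None and dof <= 0):
            raise RuntimeError("covariance-based CI requested but covariance is unusable")
        if sigma is not None:
            q = 1.96  # absolute uncertainties: normal quantile
        else:
            # residual variance estimated on few dof: Student-t quantile
            q = float(student_t.ppf(0.975, dof))
        ci = (float(np.exp(log_ec50 - q * se_log)), float(np.exp(log_ec50 + q * se_log)))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, x.size, x.size)
            if np.unique(x[idx]).size < 4:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pb, _ = curve_fit(
                        _hill_log,
                        x[idx],
                        y[idx],
                        p0=popt,
                        sigma=None if sigma is None else sigma[idx],
                        maxfev=5000,
                    )
                boots.append(np.exp(pb[3]))
            except Exception:  # noqa: BLE001
                continue
        if len(boots) < max(20, n_bootstrap // 10):
            raise RuntimeError("bootstrap CI failed: too few successful resamples")
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (float(min(lo, ec50)), float(max(hi, ec50)))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return HillFit(
        y_min=float(y_min),
        y_max=float(y_max),
        n=float(np.exp(log_n)),
        ec50=ec50,
        ec50_ci=ci,
        se_log_ec50=se_log,
        residuals=resid,
        ci_method=method,
    )


@dataclass
class RelaxationFit:
    """Exponential relaxation y(t) = y_∞ + (y_0 − y_∞)·exp(−t/τ)."""

    tau: float
    se: float
    y0: float
    y_inf: float
    residuals: np.ndarray

    def __call__(self, t):
        return self.y_inf + (self.y0 - self.y_inf) * np.exp(-np.asarray(t) / self.tau)


def fit_relaxation(times, values) -> RelaxationFit:
    """Least-squares exponential-decay fit of a post-step readout series.

    ``times`` in minutes (any consistent unit works; τ is returned in the
    same unit).  The fit is invariant to adding a constant to all values
    (absorbed in y_∞).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError(f"need >= 4 time points, got {t.size}")
    if np.ptp(y) == 0:
        raise UnidentifiableFitError("constant readout: relaxation time unidentifiable")
    t0 = t[0]

    def model(tt, y_inf, y0, tau):
        return y_inf + (y0 - y_inf) * np.exp(-(tt - t0) / tau)

    span = max(t[-1] - t[0], 1e-12)
    popt, pcov = curve_fit(
        model,
        t,
        y,
        p0=[y[-1], y[0], span / 3.0],
        bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    resid = y - model(t, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0 and 1 - ss_res / ss_tot < 0.5:
        warnings.warn(
            f"poor relaxation fit (R²={1 - ss_res / ss_tot:.2f}); residual range "
            f"[{resid.min():.3g}, {resid.max():.3g}]",
            stacklevel=2,
        )
    se = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else np.inf
    return RelaxationFit(tau=float(popt[2]), se=se, y0=float(popt[1]),
                         y_inf=float(popt[0]), residuals=resid)


# ---------------------------------------------------------------------------
# analysis pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisConfig:
    """End-to-end analysis parameters.

    ``cutoff`` is the free-motion diffusivity threshold for the particle
    size in use (0.05 μm²/s for 2.8 μm beads, 0.15 μm²/s for 1 μm beads).
    """

    cutoff: float = 0.05
    lo_fraction: float = 0.6
    min_dwell: int = 90
    window: int = 30
    fit_lags: int = 5
    frame_rate: float = 60.0
    qc: bool = True
    censoring_mode: str = "censored"
    min_complete: int = 10

    @property
    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig.for_cutoff(self.cutoff, self.lo_fraction, self.min_dwell)


@dataclass
class AnalysisResult:
    """Everything the pipeline derives from one recording at one
    concentration."""

    trajset: TrajectorySet
    traces: list[DiffusivityTrace]
    state_traces: list[StateTrace]
    qc_report: QCReport | None
    activity: tuple[float, float]  # events/particle/min, SEM
    bound_frac: tuple[float, float]
    lifetimes: dict[str, LifetimeSet]
    fits: dict[str, ExponentialFit | None]
    duration_s: float

    def summary(self) -> dict:
        out = {
            "n_particles": len(self.trajset),
            "duration_s": self.duration_s,
            "activity_per_min": self.activity[0],
            "activity_sem": self.activity[1],
            "bound_fraction": self.bound_frac[0],
            "bound_fraction_sem": self.bound_frac[1],
        }
        for state, fit in self.fits.items():
            out[f"{state}_lifetime"] = fit.to_dict() if fit is not None else None
        if self.qc_report is not None:
            out["qc"] = self.qc_report.to_dict()
        return out


def analyze_ensemble(
    trajset: TrajectorySet,
    config: AnalysisConfig = AnalysisConfig(),
    block_bounds: list[tuple[float, float]] | None = None,
) -> AnalysisResult:
    """Run the full chain on one recording: diffusivity traces → state
    segmentation → quality filter → switching statistics and lifetime fits.
    """
    if len(trajset) == 0:
        raise ValueError("empty trajectory set")
    traces = [
        motion.diffusivity_trace(t, config.window, config.fit_lags, config.frame_rate)
        for t in trajset
    ]
    seg = config.segmentation
    state_traces = [
        motion.segment_states(tr, seg, full_frames=t.frame, full_times=t.t_s)
        for t, tr in zip(trajset, traces)
    ]
    qc_report = None
    if config.qc:
        trajset, traces, state_traces, qc_report = motion.qc_filter(
            trajset, traces, state_traces
        )
    t_lo = min(t.t_s[0] for t in trajset)
    t_hi = max(t.t_s[-1] for t in trajset)
    duration = t_hi - t_lo + 1.0 / config.frame_rate
    if block_bounds is None:
        block_bounds = [(t_lo, t_hi)]
    lifetimes = kinetics.extract_lifetimes_ensemble(state_traces, block_bounds)
    fits: dict[str, ExponentialFit | None] = {}
    for state, ls in lifetimes.items():
        try:
            fits[state] = kinetics.fit_exponential(
                ls, mode=config.censoring_mode, min_complete=config.min_complete
            )
        except ValueError as e:
            logger.info("no %s lifetime fit: %s", state, e)
            fits[state] = None
    return AnalysisResult(
        trajset=trajset,
        traces=traces,
        state_traces=state_traces,
        qc_report=qc_report,
        activity=kinetics.switching_activity(state_traces, duration),
        bound_frac=kinetics.bound_fraction(state_traces),
        lifetimes=lifetimes,
        fits=fits,
        duration_s=duration,
    )


def build_dose_response(
    analyses: list[tuple[float, AnalysisResult]],
    units: str = "",
) -> dict[str, DoseResponseCurve]:
    """Assemble per-readout dose-response curves from per-concentration
    analyses.  Duplicate concentrations are merged by inverse-variance
    pooling (logged)."""
    if len(analyses) < 2:
        raise ValueError("need >= 2 concentrations")
    per_readout: dict[str, dict[float, list[tuple[float, float]]]] = {
        "activity": {}, "bound_fraction": {}, "unbound_lifetime": {}, "bound_lifetime": {}
    }
    for conc, res in analyses:
        per_readout["activity"].setdefault(conc, []).append(res.activity)
        per_readout["bound_fraction"].setdefault(conc, []).append(res.bound_frac)
        for state, key in (("unbound", "unbound_lifetime"), ("bound", "bound_lifetime")):
            fit = res.fits.get(state)
            if fit is not None:
                per_readout[key].setdefault(conc, []).append((fit.tau_s, fit.se_s))
    curves = {}
    for readout, by_conc in per_readout.items():
        concs = sorted(by_conc)
        vals, uncs = [], []
        for c in concs:
            entries = by_conc[c]
            if len(entries) > 1:
                logger.info("merging %d replicates at concentration %g (%s)",
                            len(entries), c, readout)
            v = np.array([e[0] for e in entries])
            u = np.array([max(e[1], 1e-12) for e in entries])
            w = 1.0 / u**2
            vals.append(float(np.sum(w * v) / np.sum(w)))
            uncs.append(float(1.0 / np.sqrt(np.sum(w))))
        if len(concs) >= 2:
            curves[readout] = DoseResponseCurve(
                readout, np.array(concs), np.array(vals), np.array(uncs), units=units
            )
    return curves


@dataclass
class MonitorSeries:
    """Block-by-block readout of a monitoring experiment."""

    times_min: np.ndarray  # block midpoints
    concentrations: np.ndarray  # applied concentration per block
    activity: np.ndarray
    activity_sem: np.ndarray
    bound_fraction: np.ndarray
    bound_fraction_sem: np.ndarray
    missing: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.missing is None:
            self.missing = np.zeros(len(self.times_min), dtype=bool)


def run_monitoring(
    blocks: list[tuple[float, TrajectorySet]],
    config: AnalysisConfig = AnalysisConfig(),
    block_s: float | None = None,
) -> tuple[MonitorSeries, dict]:
    """Analyse a concentration-time profile block by block.

    ``blocks`` is a time-ordered list of (applied concentration, trajectory
    set); particle ids need not persist across blocks.  Blocks whose
    analysis fails (e.g. no surviving particles) are flagged missing and the
    pipeline continues.  Returns the MonitorSeries plus a full JSON-ready
    report.
    """
    if not blocks:
        raise ValueError("no blocks given")
    times, concs = [], []
    act, act_sem, bf, bf_sem, missing = [], [], [], [], []
    reports = []
    t_cursor = 0.0
    for conc, trajset in blocks:
        if block_s is None:
            dur = (
                max(t.t_s[-1] for t in trajset) - min(t.t_s[0] for t in trajset)
                + 1.0 / config.frame_rate
                if len(trajset)
                else 0.0
            )
        else:
            dur = block_s
        times.append((t_cursor + dur / 2.0) / 60.0)
        concs.append(conc)
        t_cursor += dur
        try:
            res = analyze_ensemble(trajset, config)
            act.append(res.activity[0])
            act_sem.append(res.activity[1])
            bf.append(res.bound_frac[0])
            bf_sem.append(res.bound_frac[1])
            missing.append(False)
            reports.append(res.summary())
        except ValueError as e:
            logger.warning("block at %.1f min failed: %s", times[-1], e)
            act.append(np.nan)
            act_sem.append(np.nan)
            bf.append(np.nan)
            bf_sem.append(np.nan)
            missing.append(True)
            reports.append({"error": str(e)})
    series = MonitorSeries(
        np.array(times),
        np.array(concs),
        np.array(act),
        np.array(act_sem),
        np.array(bf),
        np.array(bf_sem),
        np.array(missing, dtype=bool),
    )
    report = {
        "blocks": [
            {"t_mid_min": float(t), "concentration": float(c), **r}
            for t, c, r in zip(series.times_min, series.concentrations, reports)
        ]
    }
    return series, report
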