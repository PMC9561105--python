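"""Imaging front-end: spot detection, phasor subpixel localization, linking.

The phasor method localizes a spot from the phase of the first Fourier
coefficient of its region of interest along each axis: for a spot at position
x0 inside an N-pixel window the coefficient is ≈ A·exp(−2πi·x0/N), so
x0 = −angle·N/(2π).  It is insensitive to a constant background (which only
contributes to the DC term) and needs no iterative fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .motion import Trajectory, TrajectorySet

__all__ = [
    "SpotDetection",
    "detect_spots",
    "phasor_localize",
    "localize_frame",
    "link_trajectories",
    "track_stack",
]


@dataclass
class SpotDetection:
    """One detected spot: integer pixel position plus subpixel refinement."""

    frame: int
    px: int  # column (x)
    py: int  # row (y)
    x_px: float = np.nan  # subpixel, pixels
    y_px: float = np.nan
    intensity: float = 0.0


def detect_spots(
    frame: np.ndarray,
    k_mad: float = 5.0,
    min_separation_px: int = 4,
    frame_index: int = 0,
) -> list[SpotDetection]:
    """Local-maxima detection above a robust background threshold.

    Pixels must exceed ``median + k_mad·MAD`` and be the maximum within a
    ``min_separation_px`` neighbourhood; brighter spots suppress dimmer ones
    closer than the separation.
    """
    img = np.asarray(frame, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.dtype.kind in "ui" and np.any(frame == np.iinfo(frame.dtype).max):
        warnings.warn("saturated pixels in frame", stacklevel=2)
    med = np.median(img)
    mad = np.median(np.abs(img - med))
    thresh = med + k_mad * max(mad, 1e-12)
    size = 2 * min_separation_px + 1
    local_max = img == ndimage.maximum_filter(img, size=size, mode="nearest")
    ys, xs = np.nonzero(local_max & (img > thresh))
    if ys.size == 0:
        return []
    order = np.argsort(img[ys, xs])[::-1]
    kept: list[tuple[int, int]] = []
    out = []
    for o in order:
        y, x = int(ys[o]), int(xs[o])
        if any((y - ky) ** 2 + (x - kx) ** 2 < min_separation_px**2 for ky, kx in kept):
            continue
        kept.append((y, x))
        out.append(SpotDetection(frame_index, x, y, intensity=float(img[y, x])))
    return out


def phasor_localize(roi: np.ndarray) -> tuple[float, float]:
    """Subpixel offset (dx, dy) in pixels from the ROI centre.

    Uses the phase of the first discrete Fourier coefficient of the ROI's
    marginal sums along each axis.  Requires an odd ROI size ≥ 5 and
    non-constant intensities.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or roi.shape[0] != roi.shape[1]:
        raise ValueError("ROI must be square")
    n = roi.shape[0]
    if n < 5 or n % 2 == 0:
        raise ValueError(f"ROI size must be odd and >= 5, got {n}")
    if np.ptp(roi) == 0:
        raise ValueError("constant ROI: position undefined")
    offsets = []
    for axis in (1, 0):  # x then y
        marg = roi.sum(axis=0 if axis == 1 else 1)
        c1 = np.fft.fft(marg)[1]
        if abs(c1) == 0:
            raise ValueError("zero first Fourier coefficient: position undefined")
        pos = (-np.angle(c1) * n / (2 * np.pi)) % n  # position in [0, n)
        off = pos - (n - 1) / 2.0
        # wrap into the ROI
        if off > n / 2:
            off -= n
        offsets.append(off)
    return offsets[0], offsets[1]


def localize_frame(
    frame: np.ndarray,
    roi_size: int = 7,
    frame_index: int = 0,
    **detect_kwargs,
) -> list[SpotDetection]:
    """Detect and phasor-localize all spots of one frame (positions in px)."""
    half = roi_size // 2
    H, W = frame.shape
    img = np.asarray(frame, dtype=float)
    dets = detect_spots(frame, frame_index=frame_index, **detect_kwargs)
    out = []
    for d in dets:
        if d.px < half or d.px >= W - half or d.py < half or d.py >= H - half:
            continue  # too close to the border to cut an ROI
        roi = img[d.py - half : d.py + half + 1, d.px - half : d.px + half + 1]
        bg = np.median(roi)
        try:
            dx, dy = phasor_localize(roi - bg)
        except ValueError:
            continue
        d.x_px = d.px + dx
        d.y_px = d.py + dy
        out.append(d)
    return out


def link_trajectories(
    detections: list[list[SpotDetection]],
    max_disp_um: float,
    pixel_size_um: float = 0.345,
    max_gap: int = 0,
    frame_rate: float = 60.0,
) -> TrajectorySet:
    """Frame-by-frame nearest-neighbour linking of detections into tracks.

    Each new frame is assigned to the open track heads by solving the
    bipartite minimum-total-displacement problem (Hungarian algorithm) over
    candidate pairs within ``max_disp_um``; ties resolve deterministically
    towards the lower track id.  Unmatched detections seed new tracks; a
    track missing for more than ``max_gap`` frames is closed.  Gap frames
    are filled by linear interpolation and flagged invalid.
    """
    tracks: list[dict] = []  # each: frames[], x[], y[], last_frame, open
    big = 1e9  # cost sentinel for forbidden (too-distant) pairs
    for fi, dets in enumerate(detections):
        pos = np.array([[d.x_px * pixel_size_um, d.y_px * pixel_size_um] for d in dets])
        active = [
            k
            for k, tr in enumerate(tracks)
            if tr["open"] and fi - tr["last_frame"] <= max_gap + 1
        ]
        used_dets: set[int] = set()
        if active and len(dets):
            heads = np.array([[tracks[k]["x"][-1], tracks[k]["y"][-1]] for k in active])
            dist = np.hypot(
                heads[:, None, 0] - pos[None, :, 0], heads[:, None, 1] - pos[None, :, 1]
            )
            cost = np.where(dist <= max_disp_um, dist, big)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] >= big:
                    continue
                k, j = active[r], int(c)
                tr = tracks[k]
                tr["frames"].append(fi)
                tr["x"].append(pos[j, 0])
                tr["y"].append(pos[j, 1])
                tr["last_frame"] = fi
                used_dets.add(j)
        for k, tr in enumerate(tracks):
            if tr["open"] and fi - tr["last_frame"] > max_gap:
                tr["open"] = False
        for j in range(len(dets)):
            if j not in used_dets:
                tracks.append(
                    {
                        "frames": [fi],
                        "x": [pos[j, 0]],
                        "y": [pos[j, 1]],
                        "last_frame": fi,
                        "open": True,
                    }
                )
    trajs = []
    for pid, tr in enumerate(tracks):
        frames = np.array(tr["frames"])
        x = np.array(tr["x"])
        y = np.array(tr["y"])
        full = np.arange(frames[0], frames[-1] + 1)
        valid = np.isin(full, frames)
        xi = np.interp(full, frames, x)
        yi = np.interp(full, frames, y)
        trajs.append(
            Trajectory(
                particle_id=pid,
                frame=full,
                t_s=full / frame_rate,
                x_um=xi,
                y_um=yi,
                valid=valid,
            )
        )
    return TrajectorySet(trajs)


def track_stack(
    stack: np.ndarray,
    roi_size: int = 7,
    max_disp_um: float = 2.0,
    pixel_size_um: float = 0.345,
    max_gap: int = 0,
    frame_rate: float = 60.0,
    min_track_length: int = 1,
    **detect_kwargs,
) -> TrajectorySet:
    """Full front-end: detect + localize every frame, then link into tracks.

    ``min_track_length`` drops stub tracks (spurious shot-noise detections
    rarely persist across frames); surviving tracks are renumbered.
    """
    dets = [
        localize_frame(stack[f], roi_size=roi_size, frame_index=f, **detect_kwargs)
        for f in range(stack.shape[0])
    ]
    ts = link_trajectories(
        dets,
        max_disp_um=max_disp_um,
        pixel_size_um=pixel_size_um,
        max_gap=max_gap,
        frame_rate=frame_rate,
    )
    if min_track_length > 1:
        kept = [t for t in ts if t.valid.sum() >= min_track_length]
        for pid, t in enumerate(kept):
            t.particle_id = pid
        ts = TrajectorySet(kept)
    return ts
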