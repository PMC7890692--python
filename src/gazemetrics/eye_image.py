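"""Synthetic eye-frame rendering and circular-Hough pupil detection.

The detector is a gradient-edge circular Hough transform: an edge map is
obtained by thresholding the intensity-gradient magnitude, every edge pixel
votes for all candidate centers at each radius on an integer radius grid, and
the global accumulator peak (normalized by ring size) is the detection.
Ties are broken deterministically: smallest radius first, then smallest
(y, x) center.  Frames where the peak support falls below the detection
threshold (blink / away frames, degenerate images) yield ``found=False``.

Coordinates are 0-based with origin at the top-left corner, x rightward and
y downward.  The pupil size handed downstream is the *diameter* in pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.signal import detrend as _sp_detrend
from scipy.stats import pearsonr

from .simulate import (
    STATUS_AWAY,
    STATUS_BLINK,
    STATUS_MISSING,
    STATUS_VALID,
    GazeTrace,
)

__all__ = [
    "EyeFrame",
    "PupilDetection",
    "render_eye_frame",
    "detect_pupil",
    "hough_accumulate",
    "frames_to_trace",
    "illumination_pupil_correlation",
    "read_frame",
    "write_frame",
]

# rendering intensity bands (pre-illumination scaling)
_PUPIL_LEVEL = 30.0
_IRIS_LEVEL = 120.0
_SCLERA_LEVEL = 200.0
_LID_LEVEL = 170.0


@dataclass
class EyeFrame:
    """One grayscale frame: float intensities in [0, 255]."""

    pixels: np.ndarray
    t: float = 0.0

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def validate(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("EyeFrame.pixels must be 2-D")
        if self.height < 32 or self.width < 32:
            raise ValueError("EyeFrame must be at least 32x32 pixels")


@dataclass
class PupilDetection:
    """Detected circle: center (x, y), radius, accumulator support in [0,1]."""

    center: tuple[float, float]
    radius: float
    score: float
    found: bool

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


def render_eye_frame(
    pupil_center: tuple[float, float],
    pupil_radius: float,
    iris_radius: float,
    eyelid_closure: float = 0.0,
    illumination_level: float = 1.0,
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (96, 96),
    t: float = 0.0,
    rng: np.random.Generator | None = None,
) -> EyeFrame:
    """Render a schematic eye: dark pupil disc inside a lighter iris annulus
    on bright sclera, optionally occluded from the top by the eyelid.

    ``eyelid_closure`` in [0, 1] sweeps the lid from the top of the iris
    (0 = fully open) down past its bottom (1 = fully closed).  Mean intensity
    scales multiplicatively with ``illumination_level``.
    """
    h, w = shape
    cx, cy = pupil_center
    if not (0 < pupil_radius < iris_radius):
        raise ValueError("require 0 < pupil_radius < iris_radius")
    if iris_radius >= min(h, w) / 2:
        raise ValueError("iris_radius must fit inside the frame")
    if not (0.0 <= eyelid_closure <= 1.0):
        raise ValueError("eyelid_closure must be in [0, 1]")
    if illumination_level <= 0:
        raise ValueError("illumination_level must be > 0")

    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(xx - cx, yy - cy)
    img = np.full((h, w), _SCLERA_LEVEL)
    img[d <= iris_radius] = _IRIS_LEVEL
    img[d <= pupil_radius] = _PUPIL_LEVEL
    if eyelid_closure > 0:
        lid_y = (cy - iris_radius) + eyelid_closure * 2.0 * iris_radius
        img[yy <= lid_y] = _LID_LEVEL
    img = img * illumination_level
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return EyeFrame(pixels=np.clip(img, 0.0, 255.0), t=t)


def _edge_map(pixels: np.ndarray, gradient_threshold: float) -> np.ndarray:
    gy, gx = np.gradient(pixels.astype(float))
    return (np.hypot(gx, gy) > gradient_threshold).astype(np.int64)


def _ring_offsets(r: int) -> np.ndarray:
    """Integer offsets (dy, dx) whose distance from the origin is within 0.5
    of ``r`` — the width-1 annulus used for voting and normalization."""
    rng_ = np.arange(-r - 1, r + 2)
    dy, dx = np.meshgrid(rng_, rng_, indexing="ij")
    d = np.hypot(dy, dx)
    mask = np.abs(d - r) <= 0.5
    return np.stack([dy[mask], dx[mask]], axis=1)


def hough_accumulate(
    edges: np.ndarray, radii: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vote accumulation: returns ``(votes, ring_sizes)`` where
    ``votes[i, y, x]`` counts edge pixels whose distance from center (x, y)
    is within 0.5 px of ``radii[i]``."""
    h, w = edges.shape
    ey, ex = np.nonzero(edges)
    votes = np.zeros((len(radii), h, w), dtype=np.int64)
    ring_sizes = np.empty(len(radii), dtype=np.int64)
    for i, r in enumerate(radii):
        offs = _ring_offsets(int(r))
        ring_sizes[i] = len(offs)
        if len(ey) == 0:
            continue
        cy = ey[:, None] + offs[None, :, 0]
        cx = ex[:, None] + offs[None, :, 1]
        ok = (cy >= 0) & (cy < h) & (cx >= 0) & (cx < w)
        np.add.at(votes[i], (cy[ok], cx[ok]), 1)
    return votes, ring_sizes


def detect_pupil(
    frame: EyeFrame,
    radius_range: tuple[int, int],
    detection_threshold: float = 0.35,
    gradient_threshold: float = 20.0,
) -> PupilDetection:
    """Single-peak circular Hough detection on the frame's edge map.

    ``radius_range`` is an inclusive integer interval; the accumulator peak is
    normalized by the ring pixel count so ``score`` lies in [0, 1].  Constant
    or edge-free frames return ``found=False`` rather than raising.
    """
    frame.validate()
    rmin, rmax = int(radius_range[0]), int(radius_range[1])
    if not (1 <= rmin <= rmax):
        raise ValueError("radius_range must satisfy 1 <= rmin <= rmax")
    if rmax >= min(frame.height, frame.width) / 2:
        raise ValueError("radius_range exceeds frame geometry")
    edges = _edge_map(frame.pixels, gradient_threshold)
    radii = np.arange(rmin, rmax + 1)
    votes, ring_sizes = hough_accumulate(edges, radii)

    best = PupilDetection(center=(np.nan, np.nan), radius=np.nan, score=0.0, found=False)
    best_score = -1.0
    for i, r in enumerate(radii):  # ascending radius: smallest r wins ties
        v = votes[i]
        peak = int(v.max())
        score = peak / ring_sizes[i]
        if score > best_score + 1e-12:
            y, x = np.argwhere(v == peak)[0]  # row-major: smallest (y, x)
            best_score = score
            best = PupilDetection(
                center=(float(x), float(y)), radius=float(r), score=float(score),
                found=False,
            )
    if best_score >= detection_threshold:
        best.found = True
    else:
        best = PupilDetection(
            center=(np.nan, np.nan), radius=np.nan, score=float(max(best_score, 0.0)),
            found=False,
        )
    return best


def frames_to_trace(
    frames: list[EyeFrame],
    radius_range: tuple[int, int],
    participant_id: str = "P00",
    blink_max_s: float = 0.5,
    away_min_s: float = 2.0,
    detection_threshold: float = 0.35,
    gradient_threshold: float = 20.0,
    nominal_rate: float = 30.0,
) -> GazeTrace:
    """Run the detector on a time-ordered frame sequence and classify
    not-found runs by duration: shorter than ``blink_max_s`` -> blink, at
    least ``away_min_s`` -> away, in between -> missing.

    Every frame maps to exactly one sample.
    """
    if not frames:
        raise ValueError("frames must be nonempty")
    t = np.array([f.t for f in frames], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("frames must be strictly time-ordered")
    pupil = np.full(len(frames), np.nan)
    found = np.zeros(len(frames), dtype=bool)
    for i, f in enumerate(frames):
        det = detect_pupil(f, radius_range, detection_threshold, gradient_threshold)
        if det.found:
            pupil[i] = det.diameter
            found[i] = True
    status = np.full(len(frames), STATUS_VALID, dtype="<U8")
    i = 0
    n = len(frames)
    dt = np.median(np.diff(t)) if n > 1 else 1.0 / nominal_rate
    while i < n:
        if found[i]:
            i += 1
            continue
        j = i
        while j < n and not found[j]:
            j += 1
        run_dur = (t[j - 1] - t[i]) + dt  # run length in time, inclusive
        if run_dur < blink_max_s:
            status[i:j] = STATUS_BLINK
        elif run_dur >= away_min_s:
            status[i:j] = STATUS_AWAY
        else:
            status[i:j] = STATUS_MISSING
        i = j
    trace = GazeTrace(
        participant_id=participant_id, t=t, pupil=pupil, status=status,
        nominal_rate=nominal_rate,
    )
    trace.validate()
    return trace


def illumination_pupil_correlation(
    pupil_series: np.ndarray,
    illumination_series: np.ndarray,
    detrend_mode: str = "linear",
) -> float:
    """Pearson correlation between pupil size and scene illumination after
    detrending (``"linear"`` removes a least-squares line, ``"diff"`` uses
    first differences, ``"none"`` skips detrending).

    Pairs where either series is non-finite are dropped.  Returns NaN (with a
    warning) when either detrended series has zero variance.
    """
    x = np.asarray(pupil_series, dtype=float)
    y = np.asarray(illumination_series, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 pairwise-valid samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("undefined correlation: a series has zero variance")
        return float("nan")
    scale_x, scale_y = np.std(x), np.std(y)
    if detrend_mode == "linear":
        x = _sp_detrend(x, type="linear")
        y = _sp_detrend(y, type="linear")
    elif detrend_mode == "diff":
        x = np.diff(x)
        y = np.diff(y)
    elif detrend_mode != "none":
        raise ValueError("detrend_mode must be 'linear', 'diff' or 'none'")
    # detrending a pure trend/constant leaves only float residue: still flag
    if np.std(x) < 1e-12 * max(1.0, scale_x) or np.std(y) < 1e-12 * max(1.0, scale_y):
        warnings.warn("undefined correlation: a series has zero variance")
        return float("nan")
    return float(pearsonr(x, y)[0])


def write_frame(path: str | Path, frame: EyeFrame) -> None:
    """Write a frame as 8-bit grayscale PNG/TIFF."""
    iio.imwrite(Path(path), np.clip(frame.pixels, 0, 255).astype(np.uint8))


def read_frame(path: str | Path, t: float = 0.0) -> EyeFrame:
    """Read an 8-bit grayscale PNG/TIFF frame."""
    px = np.asarray(iio.imread(Path(path)), dtype=float)
    if px.ndim == 3:  # collapse any color axis
        px = px.mean(axis=-1)
    frame = EyeFrame(pixels=px, t=t)
    frame.validate()
    return frame
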