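"""Synthetic video front end: render marker frames, detect them, and
recover the deflection trace.

The video-optical recording stage watches two dark marker squares at the
tips of the silicone posts.  Contraction pulls the posts toward each
other, so the inter-marker separation shrinks by the total deflection
delta(t).  The renderer draws the two squares with sub-pixel (area
coverage) anti-aliasing plus optional Gaussian pixel noise; the tracker
segments dark components with an automatic (Otsu) threshold and takes
intensity-weighted centroids, giving sub-pixel separation estimates.  The
resting separation is estimated as the upper decile of per-frame
separations (diastole dominates a recording), and
delta(t) = rest_separation - separation(t) converted through the camera
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .trace import ContractionTrace

__all__ = [
    "CameraModel",
    "FrameStack",
    "render_frames",
    "detect_markers",
    "track_deflection",
]

#: percentile of per-frame separations taken as the diastolic rest level
REST_PERCENTILE = 90.0
#: largest tolerable fraction of lost frames
MAX_LOST_FRACTION = 0.05


@dataclass(frozen=True)
class CameraModel:
    """Camera/optics description for the synthetic recording rig."""

    pixels_per_mm: float = 20.0
    frame_rate: float = 100.0          # Hz; must match the trace grid
    frame_shape: tuple = (64, 48)      # (rows, cols)
    marker_size_px: float = 6.0        # square edge length
    marker_separation_px: float = 32.0 # resting centre-to-centre distance
    background: float = 200.0
    foreground: float = 50.0
    noise_sd: float = 0.0              # intensity units

    def __post_init__(self) -> None:
        if self.pixels_per_mm <= 0 or self.frame_rate <= 0:
            raise ValueError("pixels_per_mm and frame_rate must be positive")
        if self.foreground >= self.background:
            raise ValueError("markers must be darker than the background")


@dataclass
class FrameStack:
    """Grayscale frames with uniform timestamps."""

    frames: np.ndarray      # (n_frames, rows, cols) float
    timestamps: np.ndarray  # s

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n, rows, cols)")
        if self.frames.shape[0] != self.timestamps.size:
            raise ValueError("one timestamp per frame required")


def _coverage_1d(n: int, lo: float, hi: float) -> np.ndarray:
    """Fraction of each unit pixel [i, i+1) covered by the interval [lo, hi]."""
    edges = np.arange(n + 1, dtype=float)
    return np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo),
                   0.0, 1.0)


def render_frames(trace: ContractionTrace, camera: CameraModel,
                  seed: int = 0) -> FrameStack:
    """Render a deflection trace as a synthetic marker movie.

    ``trace`` must be in deflection units.  Both markers move toward the
    frame centre by delta/2 each, so their separation shrinks by the full
    deflection.  Raises if a marker would leave the frame.
    """
    if trace.is_force:
        raise ValueError("render_frames expects a deflection trace")
    if abs(trace.sample_rate - camera.frame_rate) > 0.01 * camera.frame_rate:
        raise ValueError("camera frame_rate must match the trace sample rate")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    delta_px = trace.in_unit("mm").value * camera.pixels_per_mm
    rows, cols = camera.frame_shape
    cx = cols / 2.0
    cy0 = rows / 2.0 - camera.marker_separation_px / 2.0
    cy1 = rows / 2.0 + camera.marker_separation_px / 2.0
    half = camera.marker_size_px / 2.0

    frames = np.empty((delta_px.size, rows, cols), dtype=float)
    col_cov = _coverage_1d(cols, cx - half, cx + half)
    contrast = camera.background - camera.foreground
    for i, d in enumerate(delta_px):
        ca = cy0 + d / 2.0   # top marker moves down
        cb = cy1 - d / 2.0   # bottom marker moves up
        if ca - half < 0 or cb + half > rows or ca >= cb:
            raise ValueError(f"marker leaves the frame at sample {i}")
        row_cov = _coverage_1d(rows, ca - half, ca + half) + \
            _coverage_1d(rows, cb - half, cb + half)
        frames[i] = camera.background - contrast * np.outer(row_cov, col_cov)
    if camera.noise_sd > 0:
        frames += rng.normal(0.0, camera.noise_sd, size=frames.shape)
    return FrameStack(frames=frames, timestamps=trace.time.copy())


def detect_markers(frame: np.ndarray) -> np.ndarray | None:
    """Centroids of the two dark markers in one frame, or None if lost.

    Otsu threshold -> two largest dark components (each grown by one pixel
    to pick up anti-aliased edges) -> darkness-weighted centroids.
    Returns a (2, 2) array of (row, col) ordered by row.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.max() == frame.min():
        return None
    thresh = threshold_otsu(frame)
    mask = frame < thresh
    labels, n = ndimage.label(mask)
    if n < 2:
        return None
    sizes = ndimage.sum_labels(np.ones_like(frame), labels, range(1, n + 1))
    order = np.argsort(sizes)[::-1]
    background = float(np.median(frame[~mask])) if (~mask).any() else frame.max()
    centroids = []
    for lab in (order[0] + 1, order[1] + 1):
        comp = ndimage.binary_dilation(labels == lab)
        weights = np.clip(background - frame, 0.0, None) * comp
        total = weights.sum()
        if total <= 0:
            return None
        rr, cc = np.mgrid[0:frame.shape[0], 0:frame.shape[1]]
        # pixel centres are at index + 0.5
        centroids.append(((rr + 0.5) * weights).sum() / total)
        centroids.append(((cc + 0.5) * weights).sum() / total)
    pts = np.asarray(centroids).reshape(2, 2)
    return pts[np.argsort(pts[:, 0])]


def track_deflection(stack: FrameStack, camera: CameraModel,
                     well_id: str = "well") -> ContractionTrace:
    """Deflection trace (um) from per-frame marker separations.

    Lost frames (detection failure) are linearly interpolated and flagged;
    more than MAX_LOST_FRACTION lost frames is an error.
    """
    n = stack.frames.shape[0]
    separations = np.full(n, np.nan)
    for i in range(n):
        pts = detect_markers(stack.frames[i])
        if pts is not None:
            separations[i] = np.hypot(*(pts[1] - pts[0]))
    lost = ~np.isfinite(separations)
    if lost.mean() > MAX_LOST_FRACTION:
        raise ValueError(f"{lost.sum()} of {n} frames lost "
                         f"(> {MAX_LOST_FRACTION:.0%})")
    flags = []
    if lost.any():
        good = np.flatnonzero(~lost)
        separations = np.interp(np.arange(n), good, separations[good])
        flags.append(f"interpolated_{int(lost.sum())}_lost_frames")
    rest = np.percentile(separations, REST_PERCENTILE)
    delta_um = (rest - separations) / camera.pixels_per_mm * 1e3
    return ContractionTrace(time=stack.timestamps, value=delta_um,
                            unit="um", well_id=well_id, flags=flags)
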