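"""Bead detection, subpixel localization, linking and drift correction.

The tracking chain mirrors the standard high-throughput bead-tracking
recipe: a discoidal averaging filter amplifies spots over background,
an intensity threshold plus local-maximum test detects candidate beads,
an isotropic 2-D Gaussian least-squares fit refines each position to
subpixel accuracy, and a per-frame nearest-neighbour radius search (on
a KD-tree) links detections into tracks.  Stage drift is estimated from
immobile reference beads and subtracted.

Coordinates are 0-based with the pixel-center convention; ``x`` is the
flow axis (columns), ``y`` the orthogonal fluctuation axis (rows are
``y``).  The theoretical localization precision follows the familiar
photon-statistics formula

    sigma^2 = s^2/N + a^2/(12 N) + 8 pi s^4 b^2 / (a^2 N^2)

with photon count N, pixel size a, background s.d. b and spot width s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.spatial import cKDTree


class TrackingError(ValueError):
    pass


class GaussianFitError(RuntimeError):
    """Raised when a spot fit fails to converge or is degenerate."""


@dataclass
class PeakFit:
    """Subpixel localization of one spot in one frame."""

    frame: int
    x: float          # pixels, column axis
    y: float          # pixels, row axis
    amplitude: float
    sigma: float      # pixels
    baseline: float
    photons: float    # 2*pi*A*s^2 (gain 1)


@dataclass
class Track:
    """One bead followed through the stack (positions in pixels)."""

    track_id: int
    peaks: list[PeakFit] = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([p.frame for p in self.peaks], dtype=int)

    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions."""
        return np.array([[p.x, p.y] for p in self.peaks], dtype=float)


# ----------------------------------------------------------------------
def _disk_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy * yy + xx * xx) <= radius * radius + 1e-9


def discoidal_filter(img: np.ndarray, r_inner: int = 2, r_outer: int = 5) -> np.ndarray:
    """Discoidal averaging: disk mean minus surrounding annulus mean.

    output(p) = mean(I over disk r<=r_inner) - mean(I over r_inner<r<=r_outer),
    both centered at p.  Near edges the kernels are truncated to
    in-bounds pixels (no padding), so a constant image maps to exactly
    zero everywhere.  The operator is linear.
    """
    if not (0 < r_inner < r_outer):
        raise TrackingError("require 0 < r_inner < r_outer")
    img = np.asarray(img, dtype=float)
    disk = _disk_offsets(r_inner).astype(float)
    big = _disk_offsets(r_outer).astype(float)
    pad = (big.shape[0] - disk.shape[0]) // 2
    annulus = big.copy()
    annulus[pad:pad + disk.shape[0], pad:pad + disk.shape[1]] -= disk
    ones = np.ones_like(img)

    def local_mean(kernel: np.ndarray) -> np.ndarray:
        num = ndimage.convolve(img, kernel, mode="constant", cval=0.0)
        den = ndimage.convolve(ones, kernel, mode="constant", cval=0.0)
        return num / den

    return local_mean(disk) - local_mean(annulus)


def detect_peaks(filtered: np.ndarray, threshold: float, min_separation: int = 3) -> list[tuple[int, int]]:
    """Integer (row, col) peak candidates above threshold.

    A pixel qualifies if it exceeds ``threshold`` and equals the local
    maximum within ``min_separation``.  Candidates closer than
    ``min_separation`` (Euclidean) are suppressed greedily by descending
    intensity, ties broken by smaller row then column.
    """
    if threshold <= 0:
        raise TrackingError("threshold must be positive")
    filtered = np.asarray(filtered, dtype=float)
    foot = _disk_offsets(min_separation)
    local_max = ndimage.maximum_filter(filtered, footprint=foot, mode="nearest")
    cand = np.argwhere((filtered > threshold) & (filtered >= local_max))
    if len(cand) == 0:
        return []
    vals = filtered[cand[:, 0], cand[:, 1]]
    order = np.lexsort((cand[:, 1], cand[:, 0], -vals))
    accepted: list[tuple[int, int]] = []
    for idx in order:
        r, c = int(cand[idx, 0]), int(cand[idx, 1])
        if all((r - ar) ** 2 + (c - ac) ** 2 >= min_separation**2 for ar, ac in accepted):
            accepted.append((r, c))
    return accepted


def fit_gaussian_2d(patch: np.ndarray, init: PeakFit | None = None,
                    max_iter: int = 200, rtol: float = 1e-8,
                    weights: np.ndarray | str | None = None) -> PeakFit:
    """Isotropic 2-D Gaussian least-squares fit on an image patch.

    Model: I(x, y) = B + A * exp(-((x-x0)^2 + (y-y0)^2) / (2 s^2)).
    Position is reported in patch coordinates (pixel centers).  Photons
    are estimated as 2*pi*A*s^2 assuming unit gain.

    ``weights="photon"`` weights residuals by the inverse expected
    per-pixel noise (shot noise plus background variance estimated from
    the patch border), bringing the variance of the estimate close to
    the information bound in photon-limited images; an explicit weight
    array may also be given.

    Raises
    ------
    GaussianFitError
        On non-convergence, non-positive amplitude, or a position
        outside the patch.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or min(patch.shape) < 5:
        raise TrackingError("patch must be 2-D and at least 5x5")
    ny, nx = patch.shape
    yy, xx = np.mgrid[0:ny, 0:nx]

    if isinstance(weights, str):
        if weights != "photon":
            raise TrackingError(f"unknown weighting scheme {weights!r}")
        border = np.concatenate([patch[0], patch[-1], patch[:, 0], patch[:, -1]])
        bg_var = max(np.var(border), 1e-12)
        shot = np.clip(patch - np.median(border), 0.0, None)
        weights = 1.0 / np.sqrt(shot + bg_var)

    if init is None:
        b0 = float(patch.min())
        a0 = float(patch.max() - b0)
        if a0 <= 0:
            raise GaussianFitError("flat patch: no amplitude to fit")
        w = np.clip(patch - b0, 0, None)
        tot = w.sum()
        x0 = float((w * xx).sum() / tot)
        y0 = float((w * yy).sum() / tot)
        s0 = max(1.0, math.sqrt(((w * ((xx - x0) ** 2 + (yy - y0) ** 2)).sum() / tot) / 2.0))
        p0 = [b0, a0, x0, y0, s0]
    else:
        p0 = [init.baseline, init.amplitude, init.x, init.y, init.sigma]

    w = np.ones_like(patch) if weights is None else np.asarray(weights, dtype=float)

    def resid(p):
        b, a, x0, y0, s = p
        model = b + a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * s * s))
        return ((model - patch) * w).ravel()

    try:
        res = least_squares(resid, p0, method="lm", xtol=rtol, ftol=rtol, max_nfev=max_iter * 6)
    except Exception as exc:  # pragma: no cover - scipy internal failure
        raise GaussianFitError(f"fit failed: {exc}") from exc
    b, a, x0, y0, s = res.x
    s = abs(float(s))
    if not res.success or a <= 0 or not (0 <= x0 <= nx - 1) or not (0 <= y0 <= ny - 1):
        raise GaussianFitError("fit did not converge to a valid peak")
    return PeakFit(frame=0, x=float(x0), y=float(y0), amplitude=float(a),
                   sigma=s, baseline=float(b),
                   photons=float(2.0 * math.pi * a * s * s))


def localize_frame(img: np.ndarray, threshold: float, min_separation: int = 3,
                   r_inner: int = 2, r_outer: int = 5, patch_radius: int = 4,
                   frame: int = 0) -> list[PeakFit]:
    """Filter, detect and subpixel-fit every bead in one frame."""
    filt = discoidal_filter(img, r_inner, r_outer)
    fits: list[PeakFit] = []
    ny, nx = img.shape
    for r, c in detect_peaks(filt, threshold, min_separation):
        r0, r1 = max(0, r - patch_radius), min(ny, r + patch_radius + 1)
        c0, c1 = max(0, c - patch_radius), min(nx, c + patch_radius + 1)
        patch = np.asarray(img[r0:r1, c0:c1], dtype=float)
        if min(patch.shape) < 5:
            continue
        try:
            pk = fit_gaussian_2d(patch)
        except GaussianFitError:
            continue  # peak dropped
        pk.frame = frame
        pk.x += c0
        pk.y += r0
        fits.append(pk)
    return fits


def link_trajectories(detections: list[list[PeakFit]], radius: float,
                      max_gap: int = 0) -> list[Track]:
    """Greedy mutual-nearest linking of per-frame detections.

    For each frame, candidate links between active track ends and new
    detections within ``radius`` are sorted by ascending distance (ties
    by detection index) and assigned greedily so each track and each
    detection is used at most once.  Unmatched detections seed new
    tracks; a track survives up to ``max_gap`` frames without a match.
    """
    if radius <= 0:
        raise TrackingError("radius must be positive")
    tracks: list[Track] = []
    active: list[tuple[Track, int]] = []  # (track, last frame seen)
    next_id = 0
    for fi, dets in enumerate(detections):
        new_active: list[tuple[Track, int]] = []
        used = np.zeros(len(dets), dtype=bool)
        if active and dets:
            ends = np.array([[tr.peaks[-1].x, tr.peaks[-1].y] for tr, _ in active])
            pts = np.array([[d.x, d.y] for d in dets])
            tree = cKDTree(pts)
            pairs = []
            for ti, end in enumerate(ends):
                for di in tree.query_ball_point(end, radius):
                    d = float(np.hypot(*(end - pts[di])))
                    pairs.append((d, di, ti))
            pairs.sort()
            track_used = np.zeros(len(active), dtype=bool)
            for d, di, ti in pairs:
                if used[di] or track_used[ti]:
                    continue
                tr, _ = active[ti]
                tr.peaks.append(dets[di])
                used[di] = True
                track_used[ti] = True
                new_active.append((tr, fi))
            for ti, (tr, last) in enumerate(active):
                if not track_used[ti] and fi - last <= max_gap:
                    new_active.append((tr, last))
        else:
            for tr, last in active:
                if fi - last <= max_gap:
                    new_active.append((tr, last))
        for di, det in enumerate(dets):
            if not used[di]:
                tr = Track(track_id=next_id, peaks=[det])
                next_id += 1
                new_active.append((tr, fi))
                tracks.append(tr)
        active = new_active
    return tracks


def estimate_drift(stuck_tracks: list[Track], n_frames: int,
                   window_frames: int = 1) -> np.ndarray:
    """Per-frame (x, y) drift from immobile reference beads.

    Drift is the mean displacement of each stuck bead from its own first
    position, averaged over beads and smoothed with a centered moving
    average of ``window_frames`` samples.  Frames not covered by any
    stuck bead get the nearest covered value.
    """
    if not stuck_tracks:
        raise TrackingError("no stuck tracks: skip drift correction")
    disp = np.full((n_frames, 2), np.nan)
    counts = np.zeros(n_frames)
    acc = np.zeros((n_frames, 2))
    for tr in stuck_tracks:
        pos = tr.positions()
        frames = tr.frames
        ref = pos[0]
        for f, p in zip(frames, pos):
            if 0 <= f < n_frames:
                acc[f] += p - ref
                counts[f] += 1
    covered = counts > 0
    if not covered.any():
        raise TrackingError("stuck tracks cover no frames")
    disp[covered] = acc[covered] / counts[covered, None]
    # fill gaps by nearest covered frame
    idx = np.arange(n_frames)
    cov_idx = idx[covered]
    nearest = cov_idx[np.searchsorted(cov_idx, np.clip(idx, cov_idx[0], cov_idx[-1]))
                      .clip(0, len(cov_idx) - 1)]
    disp = disp[nearest]
    if window_frames > 1:
        kernel = np.ones(window_frames) / window_frames
        pad = window_frames // 2
        padded = np.pad(disp, ((pad, pad), (0, 0)), mode="edge")
        disp = np.column_stack([
            np.convolve(padded[:, 0], kernel, mode="valid")[:n_frames],
            np.convolve(padded[:, 1], kernel, mode="valid")[:n_frames],
        ])
    return disp


def correct_drift(tracks: list[Track], stuck_tracks: list[Track],
                  frame_rate: float = 1.0, window_s: float = 300.0) -> list[Track]:
    """Subtract stuck-bead drift (smoothed over ``window_s``) from all tracks.

    Returns new Track objects; inputs are not modified.  Relative
    distances between beads in the same frame are unchanged.
    """
    n_frames = 1 + max(int(tr.frames.max()) for tr in tracks)
    window_frames = max(1, int(round(window_s * frame_rate)))
    drift = estimate_drift(stuck_tracks, n_frames, window_frames)
    out: list[Track] = []
    for tr in tracks:
        peaks = []
        for p in tr.peaks:
            q = PeakFit(frame=p.frame, x=p.x - drift[p.frame, 0], y=p.y - drift[p.frame, 1],
                        amplitude=p.amplitude, sigma=p.sigma, baseline=p.baseline,
                        photons=p.photons)
            peaks.append(q)
        out.append(Track(track_id=tr.track_id, peaks=peaks))
    return out


# ----------------------------------------------------------------------
def localization_precision(photons: float, pixel_size: float,
                           background_sd: float, spot_sd: float) -> float:
    """Theoretical localization precision (same length units as inputs).

    sigma = sqrt(s^2/N + a^2/(12 N) + 8 pi s^4 b^2 / (a^2 N^2)).
    """
    n, a, b, s = photons, pixel_size, background_sd, spot_sd
    if min(n, a, b, s) <= 0:
        raise TrackingError("all precision inputs must be strictly positive")
    return math.sqrt(s * s / n + a * a / (12.0 * n)
                     + 8.0 * math.pi * s**4 * b * b / (a * a * n * n))


def estimate_fov(n_px_x: int, n_px_y: int, pixel_pitch_um: float,
                 magnification: float) -> tuple[float, float]:
    """Field of view (width, height) in um from sensor and magnification."""
    if min(n_px_x, n_px_y) <= 0 or pixel_pitch_um <= 0 or magnification <= 0:
        raise TrackingError("all field-of-view inputs must be positive")
    return (n_px_x * pixel_pitch_um / magnification,
            n_px_y * pixel_pitch_um / magnification)
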