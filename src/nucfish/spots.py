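"""Spot detection and subpixel 2D Gaussian localization.

Diffraction-limited FISH puncta are detected per z-plane as local maxima of a
band-pass (Laplacian-of-Gaussian) filtered image and then refined by fitting an
isotropic 2D Gaussian on the plane where the filtered response peaks.  The fit
is strictly two-dimensional: the axial (z) index is attached to the spot but
never optimized, matching the common practice for widefield stacks whose axial
sampling is too coarse for a meaningful 3D PSF fit.

Coordinate convention: arrays are indexed (channel, z, y, x); subpixel centers
are reported as (x, y) in pixels, 0-based, with pixel centers at integer
coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize


@dataclass(frozen=True)
class ImageStack:
    """Multi-channel 3D fluorescence stack.

    Parameters
    ----------
    voxels
        Nonnegative float array indexed (channel, z, y, x).
    pixel_size_nm
        Lateral physical pixel size in nanometres.
    channel_names
        Ordered channel labels, e.g. ``("dapi", "exon", "intron")``.
    """

    voxels: np.ndarray
    pixel_size_nm: float = 144.0
    channel_names: tuple[str, ...] = ("dapi", "exon", "intron")

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 4:
            raise ValueError(f"voxels must be 4D (c, z, y, x); got shape {v.shape}")
        if any(s < 1 for s in v.shape):
            raise ValueError(f"all stack dimensions must be >= 1; got {v.shape}")
        if v.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{v.shape[0]} channels but {len(self.channel_names)} channel names"
            )
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if not np.all(np.isfinite(v)):
            raise ValueError("voxel intensities must be finite")
        if v.min() < 0:
            raise ValueError("voxel intensities must be nonnegative")
        object.__setattr__(self, "voxels", v)

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel_index(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"unknown channel {channel!r}; available: {self.channel_names}"
            ) from None

    def channel(self, channel: str) -> np.ndarray:
        """Return the (z, y, x) volume for one named channel."""
        return self.voxels[self.channel_index(channel)]


@dataclass
class Spot:
    """One fitted fluorescent punctum."""

    spot_id: int
    channel: str
    z_plane: int
    center_xy: tuple[float, float]  # (x, y), 0-based, pixel centers at integers
    amplitude: float  # fitted peak height above local background
    sigma_px: float
    background: float
    residual_norm: float  # RMS fit residual / fitted amplitude
    nucleus_id: Optional[int] = None  # filled by segmentation.assign_spots_to_nuclei

    @property
    def x(self) -> float:
        return self.center_xy[0]

    @property
    def y(self) -> float:
        return self.center_xy[1]


@dataclass(frozen=True)
class Rejection:
    """A candidate that failed the Gaussian fit acceptance filters."""

    candidate: tuple[int, int, int]  # (z, y, x)
    reason: str  # border | no_convergence | flat | sigma_out_of_band | high_residual | out_of_window


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the detect-then-fit pipeline.

    ``threshold`` fixes the detection threshold on the band-pass response;
    when ``None`` the threshold is mean + ``threshold_k`` standard deviations
    of the filtered channel (robust, parameter-light default).
    """

    log_sigma_px: float = 1.3
    threshold: Optional[float] = None
    threshold_k: float = 5.0
    min_separation_px: float = 3.0
    fit_window_px: int = 4  # half-width; fit region is (2w+1) x (2w+1)
    min_sigma_px: float = 0.4
    max_sigma_px: float = 5.0
    max_residual: float = 1.0

    def __post_init__(self) -> None:
        if self.log_sigma_px <= 0:
            raise ValueError("log_sigma_px must be positive")
        if self.min_separation_px <= 0:
            raise ValueError("min_separation_px must be positive")
        if self.fit_window_px < 1:
            raise ValueError("fit_window_px must be >= 1")
        if not (0 < self.min_sigma_px < self.max_sigma_px):
            raise ValueError("need 0 < min_sigma_px < max_sigma_px")
        if self.max_residual < 0:
            raise ValueError("max_residual must be nonnegative")
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be positive")


def bandpass_response(volume: np.ndarray, log_sigma_px: float) -> np.ndarray:
    """Per-plane negated Laplacian-of-Gaussian response of a (z, y, x) volume.

    Bright blobs of scale ~``log_sigma_px`` give large positive responses.
    The scale-normalized response (multiplied by sigma^2) is returned so
    thresholds are comparable across scales.
    """
    vol = np.asarray(volume, dtype=float)
    out = np.empty_like(vol)
    for z in range(vol.shape[0]):
        out[z] = -ndimage.gaussian_laplace(vol[z], sigma=log_sigma_px) * log_sigma_px**2
    return out


def _resolve_threshold(response: np.ndarray, params: DetectionParams) -> float:
    if params.threshold is not None:
        return float(params.threshold)
    return float(response.mean() + params.threshold_k * response.std())


def detect_candidates(
    stack: ImageStack, channel: str, params: DetectionParams
) -> list[tuple[int, int, int]]:
    """Detect candidate puncta as in-plane local maxima of the band-pass response.

    A voxel is a candidate when its filtered response strictly exceeds the
    threshold and is >= all its 8 in-plane neighbours.  Candidates closer than
    ``min_separation_px`` in-plane (at any z) are reduced to the one with the
    strongest response, so each retained candidate carries the z-plane on which
    its response is maximal.  Returned positions are (z, y, x) integers sorted
    lexicographically.
    """
    vol = stack.channel(channel)
    resp = bandpass_response(vol, params.log_sigma_px)
    thr = _resolve_threshold(resp, params)

    # in-plane 3x3 plateau-tolerant local maxima above threshold
    footprint = np.zeros((1, 3, 3), dtype=bool)
    footprint[0] = True
    is_max = resp >= ndimage.maximum_filter(resp, footprint=footprint, mode="nearest")
    zz, yy, xx = np.nonzero(is_max & (resp > thr))
    if zz.size == 0:
        return []

    order = sorted(
        range(zz.size),
        key=lambda i: (-resp[zz[i], yy[i], xx[i]], int(zz[i]), int(yy[i]), int(xx[i])),
    )
    accepted: list[tuple[int, int, int]] = []
    min_sep2 = params.min_separation_px**2
    for i in order:
        z, y, x = int(zz[i]), int(yy[i]), int(xx[i])
        if all((y - ay) ** 2 + (x - ax) ** 2 >= min_sep2 for _, ay, ax in accepted):
            accepted.append((z, y, x))
    accepted.sort()
    return accepted


def _gaussian2d(params_vec: np.ndarray, xg: np.ndarray, yg: np.ndarray) -> np.ndarray:
    b, a, x0, y0, s = params_vec
    return b + a * np.exp(-((xg - x0) ** 2 + (yg - y0) ** 2) / (2.0 * s * s))


def fit_gaussian_2d(
    stack: ImageStack,
    channel: str,
    candidate: tuple[int, int, int],
    params: DetectionParams,
) -> Spot | Rejection:
    """Least-squares fit of ``b + A exp(-r^2 / 2 sigma^2)`` around a candidate.

    The fit runs on the candidate's own z-plane within a square window of
    half-width ``fit_window_px``, clipped at image borders; windows clipped by
    more than half their area are rejected with reason ``"border"``.  Accepted
    fits must have positive amplitude, sigma inside the acceptance band, the
    center inside the window, and an RMS-residual-to-amplitude ratio at most
    ``max_residual``.
    """
    z, yc, xc = candidate
    vol = stack.channel(channel)
    nz, ny, nx = vol.shape
    if not (0 <= z < nz and 0 <= yc < ny and 0 <= xc < nx):
        raise ValueError(f"candidate {candidate} outside stack shape {(nz, ny, nx)}")

    w = params.fit_window_px
    y0, y1 = max(0, yc - w), min(ny, yc + w + 1)
    x0, x1 = max(0, xc - w), min(nx, xc + w + 1)
    full_area = (2 * w + 1) ** 2
    if (y1 - y0) * (x1 - x0) < 0.5 * full_area:
        return Rejection(candidate, "border")

    patch = vol[z, y0:y1, x0:x1]
    yg, xg = np.mgrid[y0:y1, x0:x1].astype(float)

    bg0 = float(patch.min())
    amp0 = float(patch[yc - y0, xc - x0] - bg0)
    if amp0 <= 0:
        amp0 = max(float(patch.max() - bg0), 1e-6)
    p0 = np.array([bg0, amp0, float(xc), float(yc), params.log_sigma_px])

    def residuals(p: np.ndarray) -> np.ndarray:
        return (_gaussian2d(p, xg, yg) - patch).ravel()

    try:
        sol = optimize.least_squares(residuals, p0, method="lm", max_nfev=500)
    except Exception:
        return Rejection(candidate, "no_convergence")
    if not sol.success or not np.all(np.isfinite(sol.x)):
        return Rejection(candidate, "no_convergence")

    bg, amp, fx, fy, sig = sol.x
    sig = abs(float(sig))  # model depends on sigma^2 only
    flat_floor = max(1e-9, 1e-6 * abs(bg))
    if amp <= flat_floor:
        return Rejection(candidate, "flat")
    if not (params.min_sigma_px <= sig <= params.max_sigma_px):
        return Rejection(candidate, "sigma_out_of_band")
    if not (x0 - 0.5 <= fx <= x1 - 0.5 and y0 - 0.5 <= fy <= y1 - 0.5):
        return Rejection(candidate, "out_of_window")
    rms = math.sqrt(float(np.mean(sol.fun**2)))
    residual_norm = rms / amp
    if residual_norm > params.max_residual:
        return Rejection(candidate, "high_residual")

    return Spot(
        spot_id=-1,  # assigned by call_spots
        channel=channel,
        z_plane=int(z),
        center_xy=(float(fx), float(fy)),
        amplitude=float(amp),
        sigma_px=sig,
        background=float(bg),
        residual_norm=float(residual_norm),
    )


def call_spots(
    stack: ImageStack,
    channel: str,
    params: DetectionParams | None = None,
    return_rejections: bool = False,
):
    """Detect, fit and filter puncta in one channel.

    Fitted spots whose subpixel centers land within ``min_separation_px`` of a
    brighter accepted spot are collapsed onto the brighter one.  Spot ids are
    sequential in (z, y, x) order of the fitted centers, so identical input
    yields identical ids.
    """
    if params is None:
        params = DetectionParams()
    candidates = detect_candidates(stack, channel, params)
    spots: list[Spot] = []
    rejections: list[Rejection] = []
    for cand in candidates:
        result = fit_gaussian_2d(stack, channel, cand, params)
        if isinstance(result, Spot):
            spots.append(result)
        else:
            rejections.append(result)

    # collapse near-duplicate fits, keeping the brighter spot
    spots.sort(key=lambda s: (-s.amplitude, s.z_plane, s.y, s.x))
    kept: list[Spot] = []
    min_sep2 = params.min_separation_px**2
    for s in spots:
        if all((s.y - k.y) ** 2 + (s.x - k.x) ** 2 >= min_sep2 for k in kept):
            kept.append(s)

    kept.sort(key=lambda s: (s.z_plane, s.y, s.x))
    out = [replace(s, spot_id=i) for i, s in enumerate(kept)]
    if return_rejections:
        return out, rejections
    return out
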