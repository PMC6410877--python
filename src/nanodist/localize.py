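"""Spot detection, Gaussian MLE localization, aperture photometry, and
per-spot localization-variance prediction.

Single fluorophores image as diffraction-limited spots well described by a
symmetric 2D Gaussian over a constant background, with Poisson photon noise.
Fitting maximizes the Poisson likelihood of an integrated-Gaussian model
(pixel-area integrals of the PSF, not point samples), initialized from the
standard starting conditions: centroid position, a width of 0.9 pixels, the
mean of the outermost ROI pixels as the background, and the ROI sum minus the
background contribution as the intensity.

The per-axis localization variance fed into the distance-error budget is the
Cramer-Rao lower bound of this same imaging model (Gaussian PSF, pixelation,
constant Poisson background), evaluated from the model's Fisher information;
maximum-likelihood fits are statistically efficient here, so the bound tracks
the empirically measured fit-to-fit variance.  The intensity and background
that enter it come from aperture photometry rather than from the MLE fit
values, which agrees better with measured variances in practice; the MLE
photometry is kept as a diagnostic.

Pixel units are used inside this module; positions and widths convert to nm
via the camera pixel size (159 nm by default) at the output boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, optimize

from .simulate import _pixel_fractions

__all__ = [
    "CameraModel",
    "LocalizationRecord",
    "counts_to_photons",
    "detect_spots",
    "aperture_photometry",
    "fit_spot_mle",
    "localization_variance",
]

DEFAULT_PIXEL_NM = 159.0
#: starting width of the Gaussian fit, in pixels
INIT_WIDTH_PX = 0.9


@dataclass(frozen=True)
class CameraModel:
    """Camera calibration: conversion in e-/count, offset in counts, read
    noise in e- RMS, pixel size in nm."""

    conversion: float = 1.0
    offset: float = 0.0
    read_noise: float = 0.0
    pixel_size: float = DEFAULT_PIXEL_NM

    def __post_init__(self) -> None:
        if self.conversion <= 0 or self.pixel_size <= 0:
            raise ValueError("conversion and pixel_size must be > 0")


@dataclass(frozen=True)
class LocalizationRecord:
    """One fitted spot; positions/widths in nm, photometry in photons.

    ``sigma_loc_sq`` is the predicted per-axis localization variance (nm^2),
    None until computed.  ``mle_intensity``/``mle_background`` hold the raw
    fit photometry (diagnostic); ``intensity``/``background`` are the
    aperture values used downstream.
    """

    x: float
    y: float
    width: float
    intensity: float
    background: float
    sigma_loc_sq: Optional[float] = None
    frame: int = 0
    channel: int = 1
    flags: tuple[str, ...] = ()
    mle_intensity: Optional[float] = None
    mle_background: Optional[float] = None

    @property
    def ok(self) -> bool:
        return not self.flags


def counts_to_photons(image, camera: CameraModel) -> np.ndarray:
    """(counts - offset) * conversion, clipped at zero."""
    image = np.asarray(image, dtype=float)
    return np.clip((image - camera.offset) * camera.conversion, 0.0, None)


def _ring_mean(roi: np.ndarray) -> float:
    """Mean of the outermost pixel ring."""
    ring = np.concatenate([roi[0, :], roi[-1, :], roi[1:-1, 0], roi[1:-1, -1]])
    return float(ring.mean())


def detect_spots(image, noise_tolerance: float, box_size: int) -> list[tuple[int, int]]:
    """Local maxima exceeding the local background by noise_tolerance.

    ``image`` is in photons.  Candidates are strict local maxima within a
    box_size window whose peak value exceeds the mean of the surrounding ROI
    ring plus ``noise_tolerance``; overlapping candidates are resolved
    greedily by brightness.  Returns (x, y) integer pixel centers of
    non-overlapping ROIs; maxima too close to the image edge for a full ROI
    are dropped.
    """
    if box_size < 5 or box_size % 2 == 0:
        raise ValueError("box_size must be odd and >= 5")
    image = np.asarray(image, dtype=float)
    h = box_size // 2
    footprint = np.ones((box_size, box_size), dtype=bool)
    is_max = (image == ndimage.maximum_filter(image, footprint=footprint))
    ys, xs = np.nonzero(is_max)
    candidates = []
    for y, x in zip(ys, xs):
        if y < h or x < h or y >= image.shape[0] - h or x >= image.shape[1] - h:
            continue
        roi = image[y - h : y + h + 1, x - h : x + h + 1]
        if image[y, x] > _ring_mean(roi) + noise_tolerance:
            candidates.append((float(image[y, x]), int(x), int(y)))
    candidates.sort(reverse=True)
    accepted: list[tuple[int, int]] = []
    for _, x, y in candidates:
        if all(max(abs(x - ax), abs(y - ay)) >= box_size for ax, ay in accepted):
            accepted.append((x, y))
    return accepted


def aperture_photometry(roi) -> tuple[float, float]:
    """(intensity, background) by the aperture method.

    Background is the mean of the outermost pixel ring (photons/pixel);
    intensity is the ROI sum minus the background contribution, floored at 0.
    """
    roi = np.asarray(roi, dtype=float)
    bg = _ring_mean(roi)
    intensity = max(float(roi.sum()) - bg * roi.size, 0.0)
    return intensity, bg


def _expected(params: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    x0, y0, s, N, b = params
    fx = _pixel_fractions(shape[1], x0, s)
    fy = _pixel_fractions(shape[0], y0, s)
    return N * np.outer(fy, fx) + b


def fit_spot_mle(roi, camera: Optional[CameraModel] = None,
                 frame: int = 0, channel: int = 1) -> Optional[LocalizationRecord]:
    """Poisson MLE of a symmetric integrated-Gaussian spot over a flat
    background.

    ``roi`` is a square, odd-sided photon array.  Returns None for an all-zero
    ROI; a fit that fails to converge or lands within one pixel of the ROI
    edge is returned flagged.  The record carries aperture photometry as its
    intensity/background and the MLE values as diagnostics.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or roi.shape[0] != roi.shape[1] or roi.shape[0] % 2 == 0:
        raise ValueError("roi must be square with odd side")
    if camera is None:
        camera = CameraModel()
    if not np.any(roi > 0):
        return None
    n = roi.shape[0]

    # starting conditions: centroid of the background-subtracted ROI,
    # width 0.9 px, ring-mean background, sum-minus-background intensity
    b0 = _ring_mean(roi)
    excess = np.clip(roi - b0, 0.0, None)
    tot = excess.sum()
    yy, xx = np.mgrid[0:n, 0:n]
    if tot > 0:
        x0 = float((xx * excess).sum() / tot)
        y0 = float((yy * excess).sum() / tot)
    else:
        x0 = y0 = (n - 1) / 2.0
    N0 = max(float(roi.sum() - b0 * roi.size), 1.0)

    def nll(p: np.ndarray) -> float:
        mu = _expected(p, roi.shape)
        mu = np.clip(mu, 1e-12, None)
        return float(np.sum(mu - roi * np.log(mu)))

    res = optimize.minimize(
        nll,
        x0=np.array([x0, y0, INIT_WIDTH_PX, N0, max(b0, 1e-3)]),
        method="L-BFGS-B",
        bounds=[(0.0, n - 1.0), (0.0, n - 1.0), (0.25, n), (1e-3, None), (0.0, None)],
    )
    xf, yf, sf, Nf, bf = res.x
    flags = []
    if not res.success:
        flags.append("not_converged")
    if min(xf, yf) < 1.0 or max(xf, yf) > n - 2.0:
        flags.append("edge")
    ap_intensity, ap_background = aperture_photometry(roi)
    px = camera.pixel_size
    return LocalizationRecord(
        x=xf * px,
        y=yf * px,
        width=sf * px,
        intensity=ap_intensity,
        background=ap_background,
        frame=frame,
        channel=channel,
        flags=tuple(flags),
        mle_intensity=float(Nf),
        mle_background=float(bf),
    )


def localization_variance(intensity: float, background: float, width: float,
                          camera: CameraModel) -> float:
    """Predicted per-axis localization variance, in nm^2.

    Fisher-information (Cramer-Rao) bound of the pixelated Gaussian-PSF model
    with constant Poisson background: the spot is placed at a pixel center on
    a lattice wide enough to hold all its mass, and

        var(x) = 1 / sum_k (d mu_k / d x)^2 / mu_k

    with mu_k the expected photons in pixel k.  Decreases with intensity,
    increases with background.  ``width`` in nm (Gaussian sigma), intensity in
    photons, background in photons/pixel.
    """
    if intensity <= 0:
        raise ValueError("intensity must be > 0")
    if width <= 0:
        raise ValueError("width must be > 0")
    a = camera.pixel_size
    s = width / a  # sigma in pixels
    sa = math.sqrt(s**2 + 1.0 / 12.0)
    half = int(math.ceil(4.0 * sa)) + 2
    n = 2 * half + 1
    c = float(half)  # spot centered on the middle pixel
    fx = _pixel_fractions(n, c, s)
    fy = _pixel_fractions(n, c, s)
    # d/dx of the pixel-integrated 1D Gaussian: difference of edge densities
    edges = np.arange(n + 1) - 0.5
    phi = np.exp(-((edges - c) ** 2) / (2.0 * s**2)) / (math.sqrt(2.0 * math.pi) * s)
    dfx = phi[:-1] - phi[1:]
    mu = intensity * np.outer(fy, fx) + background
    dmu = intensity * np.outer(fy, dfx)
    info = float(np.sum(dmu**2 / mu))
    return a**2 / info
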