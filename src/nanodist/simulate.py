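"""Monte Carlo generators for two-color distance data, spot images, and
fiducial fields.

``simulate_pairs`` is the generator behind every benchmark in this package:
each particle gets a true separation vector d*x_hat plus an isotropic 2D
Gaussian conformational displacement with per-axis SD sigma_con, so the true
distance is ||(d + g1, g2)|| — non-negative by construction, with an SD close
to sigma_con whenever sigma_con is small against d.  The isotropic model is
what makes population averaging work: vector-averaged distances of a
heterogeneous sample are then exactly the measured-distance distribution with
location d and scale sqrt(sigma_con^2 + sigma_vec^2), so the population
center d remains identifiable no matter how heterogeneous the sample is.  (A
scalar truth floored at zero destroys that structure and the population
average with it.)  Each frame and channel draws its own
localization *variance* from a Gamma distribution (mean sigma_loc^2, spread
controlled by sigma_sigma_loc), and the observed positions are the true
positions plus iid per-axis Gaussian noise of that variance.  Registration
error enters the channel-2 observation as per-axis Gaussian noise with SD
sigma_reg, so the per-axis separation error budget is exactly
sigma_reg^2 + sigma_loc1^2 + sigma_loc2^2.  An optional fraction of
observations is replaced by background outliers with distances uniform on
[0, outlier_range_max].

The Gamma parameterization is a convention (the variance distribution only
needs matched mean and spread): mean m = sigma_loc^2 and
SD s = 2 * sigma_loc * sigma_sigma_loc, giving shape (m/s)^2 and scale s^2/m.

``simulate_spot_image`` and ``simulate_fiducial_field`` provide forward models
for the localization and registration stages: integrated-Gaussian spots under
Poisson noise with a simple camera model, and two-channel bead fields related
by an affine map or a smooth nonlinear warp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterator, Optional

import numpy as np
from scipy import special

from .distfit import PairObservation, ParticleTrack, VectorDistance

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_pairs",
    "simulate_spot_image",
    "simulate_fiducial_field",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the two-color distance generator (nm units).

    ``sigma_sigma_loc*`` control the spread of the per-frame localization-
    variance distribution; zero means every frame has exactly sigma_loc^2.
    ``outlier_range_max`` defaults to 5 * d when None.  A seed is mandatory.
    """

    d: float = 10.0
    sigma_con: float = 0.0
    sigma_loc1: float = 1.0
    sigma_loc2: float = 1.0
    sigma_sigma_loc1: float = 0.0
    sigma_sigma_loc2: float = 0.0
    sigma_reg: float = 0.0
    n_particles: int = 100
    n_frames: int = 1
    outlier_fraction: float = 0.0
    outlier_range_max: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("d", "sigma_con", "sigma_loc1", "sigma_loc2",
                     "sigma_sigma_loc1", "sigma_sigma_loc2", "sigma_reg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.outlier_fraction < 1.0):
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.n_particles < 1 or self.n_frames < 1:
            raise ValueError("n_particles and n_frames must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is required")

    @property
    def sigma_d_nominal(self) -> float:
        """Nominal combined distance uncertainty (nm) at mean variances."""
        return math.sqrt(self.sigma_reg**2 + self.sigma_loc1**2 + self.sigma_loc2**2)


@dataclass(frozen=True)
class SimulatedDataset:
    """Arrays of shape (n_particles, n_frames); ``truth`` is per-particle.

    ``sigma_loc1_sq``/``sigma_loc2_sq`` are the drawn per-axis localization
    variances (nm^2).  Views as tracks, vector distances, or flat arrays are
    derived on demand.
    """

    dx: np.ndarray
    dy: np.ndarray
    r: np.ndarray
    sigma_loc1_sq: np.ndarray
    sigma_loc2_sq: np.ndarray
    truth: np.ndarray
    config: SimulationConfig

    @property
    def n_particles(self) -> int:
        return self.dx.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dx.shape[1]

    @property
    def sigma_d(self) -> np.ndarray:
        """Per-observation combined distance uncertainty (nm)."""
        return np.sqrt(
            self.config.sigma_reg**2 + self.sigma_loc1_sq + self.sigma_loc2_sq
        )

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """(r, sigma_d) flattened over particles and frames."""
        return self.r.ravel(), self.sigma_d.ravel()

    def vector_distances(self) -> list[VectorDistance]:
        """Vector-averaged distance per particle (mean dx, mean dy, norm)."""
        rv = np.hypot(self.dx.mean(axis=1), self.dy.mean(axis=1))
        sig = np.sqrt(np.mean(self.sigma_d**2, axis=1) / self.n_frames)
        tiny = np.finfo(float).tiny
        return [
            VectorDistance(particle_id=i, r_vec=float(rv[i]),
                           n_frames=self.n_frames,
                           sigma_d_vec=float(max(sig[i], tiny)))
            for i in range(self.n_particles)
        ]

    def r_vec(self) -> np.ndarray:
        """Vector-averaged distances as a plain array (fast path)."""
        return np.hypot(self.dx.mean(axis=1), self.dy.mean(axis=1))

    def tracks(self) -> Iterator[ParticleTrack]:
        sreg = self.config.sigma_reg
        for i in range(self.n_particles):
            obs = tuple(
                PairObservation(
                    dx=float(self.dx[i, j]), dy=float(self.dy[i, j]),
                    r=float(self.r[i, j]),
                    sigma_loc1_sq=float(self.sigma_loc1_sq[i, j]),
                    sigma_loc2_sq=float(self.sigma_loc2_sq[i, j]),
                    sigma_reg=sreg, frame=j, particle_id=i,
                )
                for j in range(self.n_frames)
            )
            yield ParticleTrack(particle_id=i, observations=obs)


def _gamma_variances(rng, mean_sd: float, spread: float, shape: tuple) -> np.ndarray:
    """Per-frame localization variances: Gamma with mean mean_sd^2."""
    m = mean_sd**2
    if m == 0.0:
        return np.zeros(shape)
    s = 2.0 * mean_sd * spread
    if s == 0.0:
        return np.full(shape, m)
    k = (m / s) ** 2
    theta = s**2 / m
    return rng.gamma(k, theta, size=shape)


def simulate_pairs(config: SimulationConfig) -> SimulatedDataset:
    """Draw a two-color distance dataset; reproducible given config.seed."""
    rng = np.random.default_rng(config.seed)
    P, F = config.n_particles, config.n_frames

    if config.sigma_con > 0:
        # isotropic conformational displacement of the separation vector
        con = rng.normal(scale=config.sigma_con, size=(P, 2))
        sep_true = np.column_stack([config.d + con[:, 0], con[:, 1]])
    else:
        sep_true = np.column_stack([np.full(P, float(config.d)), np.zeros(P)])
    truth = np.hypot(sep_true[:, 0], sep_true[:, 1])

    v1 = _gamma_variances(rng, config.sigma_loc1, config.sigma_sigma_loc1, (P, F))
    v2 = _gamma_variances(rng, config.sigma_loc2, config.sigma_sigma_loc2, (P, F))

    # channel 1 at the origin, channel 2 at (truth, 0); noise is isotropic so
    # the orientation of the separation vector is irrelevant
    n1 = rng.normal(size=(P, F, 2)) * np.sqrt(v1)[..., None]
    n2 = rng.normal(size=(P, F, 2)) * np.sqrt(v2)[..., None]
    reg = rng.normal(scale=config.sigma_reg, size=(P, F, 2)) \
        if config.sigma_reg > 0 else 0.0

    obs = sep_true[:, None, :] + n2 + reg - n1
    dx, dy = obs[..., 0], obs[..., 1]

    if config.outlier_fraction > 0:
        mask = rng.random((P, F)) < config.outlier_fraction
        rmax = config.outlier_range_max
        if rmax is None:
            rmax = 5.0 * config.d
        u = rng.uniform(0.0, rmax, size=(P, F))
        theta = rng.uniform(0.0, 2.0 * np.pi, size=(P, F))
        dx = np.where(mask, u * np.cos(theta), dx)
        dy = np.where(mask, u * np.sin(theta), dy)

    r = np.hypot(dx, dy)
    return SimulatedDataset(
        dx=dx, dy=dy, r=r, sigma_loc1_sq=v1, sigma_loc2_sq=v2,
        truth=truth, config=config,
    )


# ---------------------------------------------------------------------------
# spot-image forward model
# ---------------------------------------------------------------------------


def _pixel_fractions(n: int, center: float, sigma: float) -> np.ndarray:
    """Fraction of a unit-integral 1D Gaussian falling in each pixel.

    Pixel i spans [i-0.5, i+0.5] in the continuous coordinate convention
    (center of pixel 0 at 0.0).
    """
    edges = np.arange(n + 1) - 0.5
    c = special.erf((edges - center) / (math.sqrt(2.0) * sigma))
    return 0.5 * (c[1:] - c[:-1])


def expected_spot_image(x: float, y: float, width: float, intensity: float,
                        background: float, shape: tuple[int, int]) -> np.ndarray:
    """Noise-free expected photons/pixel of an integrated-Gaussian spot.

    ``x``/``y``/``width`` in pixels (x along columns, y along rows),
    ``intensity`` total photons, ``background`` photons/pixel.
    """
    ny, nx = shape
    fx = _pixel_fractions(nx, x, width)
    fy = _pixel_fractions(ny, y, width)
    return intensity * np.outer(fy, fx) + background


def simulate_spot_image(x, y, width, intensity, background, shape, camera,
                        seed) -> np.ndarray:
    """Noisy camera image (counts) of one spot.

    Photon shot noise is Poisson; the camera adds its offset, divides by the
    photon conversion factor (e-/count), and adds Gaussian read noise.
    """
    rng = np.random.default_rng(seed)
    expected = expected_spot_image(x, y, width, intensity, background, shape)
    photons = rng.poisson(expected).astype(float)
    counts = camera.offset + photons / camera.conversion
    if camera.read_noise > 0:
        counts = counts + rng.normal(
            scale=camera.read_noise / camera.conversion, size=shape
        )
    return counts


# ---------------------------------------------------------------------------
# fiducial-field generator
# ---------------------------------------------------------------------------


def quadratic_warp(amplitude: float, field_size: float) -> Callable[[np.ndarray], np.ndarray]:
    """A smooth nonlinear distortion of the given peak amplitude (nm).

    Quadratic in the normalized field coordinates, so no single global affine
    can undo it, but any small neighborhood is locally affine to high order.
    """

    def warp(pts: np.ndarray) -> np.ndarray:
        u = pts[:, 0] / field_size
        v = pts[:, 1] / field_size
        out = pts.copy()
        out[:, 0] += amplitude * (u**2 + 0.5 * u * v)
        out[:, 1] += amplitude * (v**2 - 0.5 * u * v)
        return out

    return warp


def simulate_fiducial_field(n_beads: int, field_size: float, distortion,
                            jitter_sd: float, seed):
    """Two-channel bead field: channel 2 = distortion(channel 1) + jitter.

    ``distortion`` may be None (identity), an AffineTransform, or any callable
    mapping an (N, 2) array to an (N, 2) array.  Returns two PointSets in nm.
    """
    from .register import AffineTransform, PointSet  # local import, no cycle at module load

    rng = np.random.default_rng(seed)
    ch1 = rng.uniform(0.0, field_size, size=(n_beads, 2))
    if distortion is None:
        ch2 = ch1.copy()
    elif isinstance(distortion, AffineTransform):
        ch2 = distortion.apply(ch1)
    else:
        ch2 = np.asarray(distortion(ch1), dtype=float)
    if jitter_sd > 0:
        ch2 = ch2 + rng.normal(scale=jitter_sd, size=ch2.shape)
    return (
        PointSet(points=ch1, channel=1),
        PointSet(points=ch2, channel=2),
    )
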