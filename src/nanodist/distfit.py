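"""Distance estimators for two-color single-molecule separations.

Four estimators of the true fluorophore separation are provided:

``P2D``
    Two-parameter maximum-likelihood fit of the measured-distance
    distribution (mu and sigma_d both free).  Included mainly as the
    reference method: it collapses toward mu = 0 whenever sigma_d is
    comparable to or larger than the distance, because the distribution
    becomes nearly independent of mu in that regime.
``Sigma-P2D``
    One-parameter MLE of mu with the distance uncertainty sigma_d fixed to
    its experimentally measured value per pair,
    sigma_d = sqrt(sigma_reg^2 + sigma_loc1^2 + sigma_loc2^2).
``Vector``
    Per-particle vector averaging of the separations over frames (mean dx,
    mean dy, then the Euclidean norm), followed by a Gaussian fit of the
    averaged distances.
``Vector-P2D``
    Vector averaging followed by a two-parameter fit of the measured-distance
    distribution to the empirical CDF by nonlinear least squares, which is
    considerably more robust to background outliers than MLE.

SEMs come from the observed Fisher information for the MLE methods and from a
particle-level bootstrap for the vector methods.

Numerical policy: the Gaussian approximation of the density is substituted
for the exact form whenever the current sigma_d estimate is smaller than half
the current mu estimate (the regime where it is accurate to <2%); the exact
log-space form is used everywhere else.  Both fitters are multi-started on a
coarse grid because the likelihood is bimodal at large sigma_d/mu (a basin at
the true distance and one at zero); ties are broken toward the highest
likelihood, then the smallest mu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import integrate, optimize

from .distributions import _logpdf, _logpdf_approx

__all__ = [
    "PairObservation",
    "ParticleTrack",
    "VectorDistance",
    "DistanceFitResult",
    "combine_sigma_d",
    "fit_p2d",
    "fit_sigma_p2d",
    "vector_average",
    "fit_vector",
    "fit_vector_p2d",
    "sem_fisher",
    "sem_bootstrap",
]

# number of coarse-grid points scanned before local polishing; the grid spans
# [0, 2 * 99th percentile of r] so it is exactly scale-covariant
_GRID_N = 61
_DEFAULT_N_BOOT = 1000


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairObservation:
    """One matched two-channel observation of a molecule in one frame.

    Separations are channel2 - channel1 in nm; ``sigma_loc1_sq`` and
    ``sigma_loc2_sq`` are the per-axis localization *variances* (nm^2) of the
    two spots and ``sigma_reg`` the registration error (nm).
    """

    dx: float
    dy: float
    r: float
    sigma_loc1_sq: float
    sigma_loc2_sq: float
    sigma_reg: float
    frame: int = 0
    particle_id: int = 0

    def __post_init__(self) -> None:
        if abs(self.r - math.hypot(self.dx, self.dy)) > 1e-9:
            raise ValueError("r must equal hypot(dx, dy) within 1e-9 nm")
        if self.sigma_loc1_sq < 0 or self.sigma_loc2_sq < 0 or self.sigma_reg < 0:
            raise ValueError("variances and sigma_reg must be >= 0")

    @property
    def sigma_d(self) -> float:
        """Combined per-pair distance uncertainty (nm)."""
        return math.sqrt(
            self.sigma_reg**2 + self.sigma_loc1_sq + self.sigma_loc2_sq
        )


@dataclass(frozen=True)
class ParticleTrack:
    """All observations of one molecule, ordered by frame."""

    particle_id: int
    observations: tuple[PairObservation, ...]

    def __post_init__(self) -> None:
        if len(self.observations) < 1:
            raise ValueError("a track needs at least one observation")
        if any(o.particle_id != self.particle_id for o in self.observations):
            raise ValueError("all observations must share the track's particle_id")


@dataclass(frozen=True)
class VectorDistance:
    """Vector-averaged separation of one particle over its frames."""

    particle_id: int
    r_vec: float
    n_frames: int
    sigma_d_vec: float

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.sigma_d_vec <= 0:
            raise ValueError("sigma_d_vec must be > 0")


@dataclass(frozen=True)
class DistanceFitResult:
    """Outcome of one distance fit.

    ``sigma_d_hat`` is None for Sigma-P2D (fixed, not fitted); ``sem`` is None
    when SEM computation was explicitly skipped (n_boot=0).  ``objective`` is
    the final log-likelihood (MLE methods) or the residual sum of squares
    (NLLSQ methods).
    """

    mu_hat: float
    sigma_d_hat: Optional[float]
    sem: Optional[float]
    method: str
    n_used: int
    converged: bool
    objective: float


# ---------------------------------------------------------------------------
# error composition
# ---------------------------------------------------------------------------


def combine_sigma_d(sigma_reg, sigma_loc1, sigma_loc2):
    """Combined distance uncertainty sqrt(reg^2 + loc1^2 + loc2^2), in nm.

    All inputs are standard deviations in nm and must be non-negative;
    broadcasts over arrays.
    """
    sigma_reg = np.asarray(sigma_reg, dtype=float)
    sigma_loc1 = np.asarray(sigma_loc1, dtype=float)
    sigma_loc2 = np.asarray(sigma_loc2, dtype=float)
    if np.any(sigma_reg < 0) or np.any(sigma_loc1 < 0) or np.any(sigma_loc2 < 0):
        raise ValueError("error components must be >= 0")
    out = np.sqrt(sigma_reg**2 + sigma_loc1**2 + sigma_loc2**2)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# likelihood internals
# ---------------------------------------------------------------------------


def _switched_logpdf(r, mu, sigma):
    """Per-observation log-density with the approximation switch.

    Uses the Gaussian approximation for observations whose sigma_d is smaller
    than half the current mu estimate, the exact form otherwise.
    """
    exact = _logpdf(r, mu, sigma)
    if mu <= 0:
        return exact
    use_approx = np.asarray(sigma) < 0.5 * mu
    if not np.any(use_approx):
        return exact
    approx = _logpdf_approx(r, mu, sigma)
    return np.where(use_approx, approx, exact)


def _loglik_mu(r: np.ndarray, sigma: np.ndarray) -> Callable[[float], float]:
    def ll(mu: float) -> float:
        return float(np.sum(_switched_logpdf(r, mu, sigma)))

    return ll


def _loglik_mu_exact(r: np.ndarray, sigma: np.ndarray) -> Callable[[float], float]:
    """Exact-form log-likelihood, smooth in mu.

    The per-observation approximation switch makes the fitting objective
    (negligibly) discontinuous in mu; curvature-based SEMs must therefore be
    taken on the exact form, which the log-space evaluation keeps finite
    everywhere.
    """

    def ll(mu: float) -> float:
        return float(np.sum(_logpdf(r, mu, sigma)))

    return ll


def _maximize_1d(
    ll: Callable[[float], float],
    r: np.ndarray,
    extra_starts: Sequence[float],
) -> tuple[float, float, bool]:
    """Grid scan + bounded polish of a 1D log-likelihood in mu.

    Returns (mu_hat, loglik, converged).  Scale-covariant by construction:
    the grid and all tolerances derive from the data scale.
    """
    scale = float(np.quantile(r, 0.99))
    if scale <= 0:
        scale = float(np.max(r)) if np.max(r) > 0 else 1.0
    hi = 2.0 * scale
    grid = np.linspace(0.0, hi, _GRID_N)
    cand = np.unique(np.clip(np.r_[grid, extra_starts], 0.0, 10.0 * np.max(r) + hi))
    vals = np.array([ll(m) for m in cand])
    if not np.any(np.isfinite(vals)):
        return float(np.median(r)), -np.inf, False

    order = np.argsort(vals)[::-1]
    step = grid[1] - grid[0]
    best_mu, best_ll, converged = float(cand[order[0]]), float(vals[order[0]]), False
    # polish the two best basins (the likelihood can be bimodal)
    polished: list[tuple[float, float, bool]] = []
    seen: list[float] = []
    for idx in order:
        m0 = float(cand[idx])
        if any(abs(m0 - s) < 1.5 * step for s in seen):
            continue
        seen.append(m0)
        lo_b = max(0.0, m0 - 2.0 * step)
        hi_b = m0 + 2.0 * step
        res = optimize.minimize_scalar(
            lambda m: -ll(m),
            bounds=(lo_b, hi_b),
            method="bounded",
            options={"xatol": 1e-10 * (scale + 1e-300)},
        )
        polished.append((float(res.x), float(-res.fun), bool(res.success)))
        if len(seen) == 2:
            break
    # highest likelihood wins; ties (within numerical noise) go to smaller mu
    polished.sort(key=lambda t: (-t[1], t[0]))
    if polished:
        best_mu, best_ll, converged = polished[0]
    return best_mu, best_ll, converged


def _fisher_sem_mu(ll: Callable[[float], float], mu_hat: float, scale: float):
    """SEM from the observed Fisher information (numeric 2nd derivative).

    Returns (sem, ok); ok is False when the curvature is non-positive (flat or
    pathological likelihood), in which case callers fall back to a bootstrap.
    """
    h = max(1e-4 * scale, 1e-4 * (abs(mu_hat) + 1e-12))
    m0 = max(mu_hat, h)  # keep the stencil inside the domain
    d2 = (ll(m0 + h) - 2.0 * ll(m0) + ll(m0 - h)) / h**2
    info = -d2
    if not np.isfinite(info) or info <= 0:
        return None, False
    return float(1.0 / math.sqrt(info)), True


def _extract_r_sigma(observations) -> tuple[np.ndarray, np.ndarray]:
    """Accept PairObservation lists, (r, sigma_d) pairs, or a pair of arrays."""
    if isinstance(observations, tuple) and len(observations) == 2:
        r = np.asarray(observations[0], dtype=float)
        sigma = np.broadcast_to(
            np.asarray(observations[1], dtype=float), r.shape
        ).astype(float)
        return r, sigma
    observations = list(observations)
    if not observations:
        raise ValueError("no observations")
    if isinstance(observations[0], PairObservation):
        r = np.array([o.r for o in observations])
        sigma = np.array([o.sigma_d for o in observations])
    else:
        r = np.array([float(o[0]) for o in observations])
        sigma = np.array([float(o[1]) for o in observations])
    return r, sigma


# ---------------------------------------------------------------------------
# MLE fitters
# ---------------------------------------------------------------------------


def fit_p2d(distances, init: Optional[tuple[float, float]] = None) -> DistanceFitResult:
    """Two-parameter MLE of (mu, sigma_d) from measured distances.

    ``init`` optionally seeds the optimizer with (mu0, sigma0); a coarse grid
    and the standard starts (median(r), and mean(r) minus the sample SD,
    clipped at zero) are always scanned as well.
    """
    r = np.asarray(distances, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 distances")
    if np.any(r < 0):
        raise ValueError("distances must be >= 0")
    sd = float(np.std(r))
    if sd == 0.0:
        # zero-variance input: the scale parameter is degenerate
        return DistanceFitResult(
            mu_hat=float(r[0]), sigma_d_hat=0.0, sem=None, method="P2D",
            n_used=int(r.size), converged=False, objective=-np.inf,
        )

    rmax = float(np.max(r))
    scale = float(np.quantile(r, 0.99)) or rmax

    def nll(p: np.ndarray) -> float:
        mu, sigma = p
        if sigma <= 0:
            return np.inf
        return -float(np.sum(_switched_logpdf(r, mu, sigma)))

    mu_grid = np.linspace(0.0, 2.0 * scale, 25)
    sigma_grid = sd * np.array([0.25, 0.5, 1.0, 1.5, 2.0])
    starts = [(float(np.median(r)), sd), (max(float(np.mean(r)) - sd, 0.0), sd)]
    if init is not None:
        starts.append((float(init[0]), float(init[1])))
    best_grid = min(
        ((m, s) for m in mu_grid for s in sigma_grid), key=lambda p: nll(np.array(p))
    )
    starts.append(best_grid)

    results = []
    for mu0, s0 in starts:
        res = optimize.minimize(
            nll,
            x0=np.array([mu0, max(s0, 1e-6 * scale)]),
            method="Nelder-Mead",
            options={
                "xatol": 1e-8 * scale,
                "fatol": 1e-10 * max(1.0, r.size),
                "maxiter": 2000,
                "initial_simplex": np.array(
                    [
                        [mu0, max(s0, 1e-6 * scale)],
                        [mu0 + 0.1 * scale, max(s0, 1e-6 * scale)],
                        [mu0, max(s0, 1e-6 * scale) + 0.1 * scale],
                    ]
                ),
            },
        )
        mu_hat = float(np.clip(res.x[0], 0.0, 10.0 * rmax))
        s_hat = float(np.clip(res.x[1], 1e-12 * scale, 10.0 * rmax))
        results.append((mu_hat, s_hat, -float(res.fun), bool(res.success)))
    results.sort(key=lambda t: (-t[2], t[0]))
    mu_hat, s_hat, ll_hat, ok = results[0]

    ll_mu = _loglik_mu_exact(r, np.full_like(r, s_hat))  # profile at sigma_hat
    sem, sem_ok = _fisher_sem_mu(ll_mu, mu_hat, scale)
    if not sem_ok:
        sem = None
    return DistanceFitResult(
        mu_hat=mu_hat, sigma_d_hat=s_hat, sem=sem, method="P2D",
        n_used=int(r.size), converged=ok, objective=ll_hat,
    )


def fit_sigma_p2d(observations) -> DistanceFitResult:
    """One-parameter MLE of mu with per-pair sigma_d fixed to measured values.

    ``observations`` may be PairObservation records, (r, sigma_d) pairs, or a
    tuple of arrays (r, sigma_d).  The likelihood is the product over
    observations of the measured-distance density evaluated at each pair's own
    sigma_d, which reduces to the pooled form when sigma_d is constant.
    """
    r, sigma = _extract_r_sigma(observations)
    if r.size < 1:
        raise ValueError("need at least 1 observation")
    if np.any(sigma <= 0):
        raise ValueError("every observation needs sigma_d > 0")
    if np.any(r < 0):
        raise ValueError("distances must be >= 0")

    ll = _loglik_mu(r, sigma)
    pooled = float(np.sqrt(np.mean(sigma**2)))
    starts = [float(np.median(r)), max(float(np.mean(r)) - pooled, 0.0)]
    mu_hat, ll_hat, ok = _maximize_1d(ll, r, starts)
    scale = float(np.quantile(r, 0.99)) or float(np.max(r)) or 1.0
    sem, sem_ok = _fisher_sem_mu(_loglik_mu_exact(r, sigma), mu_hat, scale)
    if not sem_ok:
        sem = None
    return DistanceFitResult(
        mu_hat=mu_hat, sigma_d_hat=None, sem=sem, method="SigmaP2D",
        n_used=int(r.size), converged=ok, objective=ll_hat,
    )


# ---------------------------------------------------------------------------
# vector averaging and the population-average fitters
# ---------------------------------------------------------------------------


def vector_average(track: ParticleTrack) -> VectorDistance:
    """Average the separation vector over frames, then take its norm.

    Cancels localization noise coherently (unlike frame-by-frame distance
    averaging, which rectifies it): the averaged point has an effective
    uncertainty of RMS(per-frame sigma_d) / sqrt(n_frames).
    """
    dx = np.array([o.dx for o in track.observations])
    dy = np.array([o.dy for o in track.observations])
    sig = np.array([o.sigma_d for o in track.observations])
    n = dx.size
    r_vec = float(np.hypot(dx.mean(), dy.mean()))
    sigma_vec = float(np.sqrt(np.mean(sig**2) / n))
    return VectorDistance(
        particle_id=track.particle_id,
        r_vec=r_vec,
        n_frames=int(n),
        sigma_d_vec=max(sigma_vec, np.finfo(float).tiny),
    )


def _extract_rvec(vdists) -> np.ndarray:
    if isinstance(vdists, np.ndarray):
        return np.asarray(vdists, dtype=float)
    vdists = list(vdists)
    if vdists and isinstance(vdists[0], VectorDistance):
        return np.array([v.r_vec for v in vdists])
    return np.asarray(vdists, dtype=float)


def fit_vector(vdists, *, n_boot: int = _DEFAULT_N_BOOT, seed: Optional[int] = None) -> DistanceFitResult:
    """Gaussian fit of the vector-averaged distances: mu_hat = sample mean.

    SEM by particle-level bootstrap (``seed`` required unless n_boot=0).
    """
    rv = _extract_rvec(vdists)
    if rv.size < 3:
        raise ValueError("need at least 3 vector distances")
    mu_hat = float(np.mean(rv))
    sigma_hat = float(np.std(rv))
    sem = None
    if n_boot:
        sem = sem_bootstrap(
            rv, lambda d: DistanceFitResult(
                float(np.mean(d)), None, None, "Vector", d.size, True, 0.0
            ),
            n_boot=n_boot, seed=_require_seed(seed),
        )
    return DistanceFitResult(
        mu_hat=mu_hat, sigma_d_hat=sigma_hat, sem=sem, method="Vector",
        n_used=int(rv.size), converged=True,
        objective=float(np.sum((rv - mu_hat) ** 2)),
    )


def _cdf_on_sorted(points: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Model CDF at sorted sample points via cumulative Simpson on a fine grid.

    Grid resolution is sigma/10 (capped between 400 and 8000 nodes), fine
    enough that quadrature error is negligible against ECDF noise.
    """
    rmax = points[-1]
    n = int(np.clip(math.ceil(rmax / (sigma / 10.0)), 400, 8000)) | 1
    grid = np.linspace(0.0, rmax, n)
    with np.errstate(over="ignore"):
        pdf = np.exp(_logpdf(grid, mu, sigma))
    pdf[0] = 0.0
    cdf = integrate.cumulative_simpson(pdf, x=grid, initial=0.0)
    return np.interp(points, grid, np.clip(cdf, 0.0, 1.0))


def fit_vector_p2d(
    vdists,
    *,
    n_boot: int = _DEFAULT_N_BOOT,
    seed: Optional[int] = None,
    cutoff: Optional[float] = None,
) -> DistanceFitResult:
    """Two-parameter NLLSQ fit of the measured-distance CDF to the ECDF.

    The model CDF (numeric integration of the density) is evaluated at every
    sorted sample point — no histogram, hence no bin-size choices — and
    (mu, sigma_d) minimize the unweighted sum of squared CDF differences.
    Robust to background outliers; an optional high distance ``cutoff`` may
    drop gross outliers, and can safely be set to several times the expected
    distance.  SEM by particle-level bootstrap.
    """
    rv = _extract_rvec(vdists)
    if cutoff is not None:
        rv = rv[rv <= cutoff]
    if rv.size < 3:
        raise ValueError("need at least 3 vector distances")
    return _fit_p2d_nllsq(rv, n_boot=n_boot, seed=seed)


def _fit_p2d_nllsq(rv: np.ndarray, *, n_boot: int, seed: Optional[int]) -> DistanceFitResult:
    pts = np.sort(rv)
    n = pts.size
    ecdf = (np.arange(1, n + 1) - 0.5) / n  # Hazen plotting positions
    rmax = float(pts[-1])
    scale = float(np.quantile(pts, 0.99)) or rmax or 1.0
    sd = float(np.std(pts))
    if sd == 0.0:
        return DistanceFitResult(
            mu_hat=float(pts[0]), sigma_d_hat=0.0, sem=None, method="VectorP2D",
            n_used=n, converged=False, objective=np.inf,
        )

    def residuals(p: np.ndarray) -> np.ndarray:
        mu, sigma = p
        return _cdf_on_sorted(pts, mu, sigma) - ecdf

    lo = np.array([0.0, 1e-9 * scale])
    hi = np.array([10.0 * rmax, 10.0 * rmax])
    # coarse grid scan picks the starting basin: the cost surface is nearly
    # flat in mu below the scale of sigma_d, and a single local start can
    # stall on the wrong side of that plateau
    mu_grid = np.linspace(0.0, 1.5 * scale, 13)
    sig_grid = sd * np.array([0.5, 0.8, 1.0, 1.3])
    grid_best = min(
        ((m, s) for m in mu_grid for s in sig_grid),
        key=lambda p: float(np.sum(residuals(np.array(p)) ** 2)),
    )
    starts = [
        np.array(grid_best),
        np.array([float(np.median(pts)), max(sd, 1e-6 * scale)]),
        np.array([max(float(np.mean(pts)) - sd, 1e-3 * scale), max(1.5 * sd, 1e-6 * scale)]),
    ]
    fits = []
    for x0 in starts:
        try:
            res = optimize.least_squares(
                residuals, x0=np.clip(x0, lo, hi), bounds=(lo, hi),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        fits.append((float(res.x[0]), float(res.x[1]), float(res.cost), res.status > 0))
    if not fits:
        return DistanceFitResult(
            mu_hat=float(np.median(pts)), sigma_d_hat=sd, sem=None,
            method="VectorP2D", n_used=n, converged=False, objective=np.inf,
        )
    fits.sort(key=lambda t: (t[2], t[0]))
    mu_hat, s_hat, cost, ok = fits[0]
    sem = None
    if n_boot:
        sem = sem_bootstrap(
            rv, lambda d: _fit_p2d_nllsq(d, n_boot=0, seed=None),
            n_boot=n_boot, seed=_require_seed(seed),
        )
    return DistanceFitResult(
        mu_hat=mu_hat, sigma_d_hat=s_hat, sem=sem, method="VectorP2D",
        n_used=n, converged=ok, objective=2.0 * cost,
    )


# ---------------------------------------------------------------------------
# SEM estimation
# ---------------------------------------------------------------------------


def sem_fisher(result: DistanceFitResult, data) -> float:
    """SEM of mu from the observed Fisher information at the fitted mu.

    ``data`` is whatever the fitter consumed (observations with per-pair
    sigma_d for Sigma-P2D; for P2D the fitted sigma_d_hat is held fixed).
    Falls back to a particle-naive bootstrap when the numeric curvature is
    non-positive.
    """
    r, sigma = _extract_r_sigma(
        data if not isinstance(data, np.ndarray) else (data, result.sigma_d_hat)
    )
    if result.method == "P2D" and result.sigma_d_hat:
        sigma = np.full_like(r, result.sigma_d_hat)
    ll = _loglik_mu_exact(r, sigma)
    scale = float(np.quantile(r, 0.99)) or float(np.max(r)) or 1.0
    sem, ok = _fisher_sem_mu(ll, result.mu_hat, scale)
    if ok:
        return sem
    return sem_bootstrap(
        list(zip(r, sigma)), lambda obs: fit_sigma_p2d(obs), n_boot=200, seed=0
    )


def _require_seed(seed: Optional[int]) -> int:
    if seed is None:
        raise ValueError("a seed is required for bootstrap SEMs")
    return int(seed)


def sem_bootstrap(data, fitter, n_boot: int, seed: int) -> float:
    """SD of mu_hat over particle-level resamples with replacement.

    ``data`` is a sequence (or array) of per-particle records; ``fitter`` maps
    a resample to a DistanceFitResult.  Deterministic given ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(int(seed))
    data_arr = np.asarray(data, dtype=object) if not isinstance(data, np.ndarray) else data
    n = len(data_arr)
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = data_arr[idx]
        estimates[b] = fitter(sample).mu_hat
    return float(np.std(estimates))
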