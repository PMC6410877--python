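"""Two-channel registration: global affine, piecewise-affine refinement, and
target-registration-error (TRE) statistics.

Chromatic aberration and camera distortions leave a smooth but spatially
varying offset field between the two color channels.  A single global affine
transform removes the bulk of it and brings fiducials close enough for
automated pairing; a second, *piecewise* affine stage then corrects each
location using only nearby control fiducials (a nearest-neighbor search with
a minimum/maximum point count and a search radius), which a global fit cannot
do.  Registration quality is judged on fiducials not used to build the map:
the residual means mu_x, mu_y define the registration error
sigma_reg = sqrt(mu_x^2 + mu_y^2), and datasets are conventionally accepted
for distance analysis only when sigma_reg < 1 nm.

All coordinates are in nm; origin at the image top-left, x right, y down,
with the center of pixel (0, 0) at (0.0, 0.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointSet",
    "AffineTransform",
    "PiecewiseAffineModel",
    "RegistrationModel",
    "RegistrationQuality",
    "UncorrectableRegionError",
    "fit_affine",
    "pair_fiducials",
    "piecewise_transform",
    "compute_tre",
    "build_registration",
]

#: default piecewise-affine neighbor-search parameters
DEFAULT_MIN_POINTS = 10
DEFAULT_MAX_POINTS = 100
DEFAULT_MAX_DIST_NM = 2000.0
#: registration acceptance threshold on sigma_reg (nm)
SIGMA_REG_ACCEPT_NM = 1.0
#: a query closer than this to a control point is treated as that control
#: point and excluded from its own local fit (leave-self-out, needed for TRE)
_SELF_EPS_NM = 1e-6


class UncorrectableRegionError(ValueError):
    """Raised when a query has fewer than min_points control points in range.

    Carries ``n_found``, the number of control points that were within the
    search radius.
    """

    def __init__(self, n_found: int, min_points: int):
        self.n_found = n_found
        self.min_points = min_points
        super().__init__(
            f"uncorrectable region: {n_found} control points within radius, "
            f"need {min_points}"
        )


@dataclass(frozen=True)
class PointSet:
    """Fiducial or spot coordinates of one channel, in nm."""

    points: np.ndarray
    channel: int = 1
    frame: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, PointSet):
        return obj.points
    pts = np.asarray(obj, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    return pts


@dataclass(frozen=True)
class AffineTransform:
    """p -> A @ p + t with a non-singular 2x2 linear part."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        t = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(A)) <= 1e-12:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "matrix", A)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(2), np.zeros(2))

    def apply(self, pts) -> np.ndarray:
        pts = _as_points(pts)
        return pts @ self.matrix.T + self.translation


def _lstsq_affine(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    # center both sets first: raw field coordinates (tens of um in nm) make
    # the ones-column design ill-conditioned enough to cost ~8 digits
    c_src = src.mean(axis=0)
    c_dst = dst.mean(axis=0)
    design = np.column_stack([src - c_src, np.ones(len(src))])
    sol, _, rank, _ = np.linalg.lstsq(design, dst - c_dst, rcond=None)
    if rank < 3:
        raise ValueError("control points are collinear (rank-deficient fit)")
    A = sol[:2].T
    t = sol[2] + c_dst - A @ c_src
    return AffineTransform(matrix=A, translation=t)


def fit_affine(src, dst, pairs: Optional[Sequence[tuple[int, int]]] = None) -> AffineTransform:
    """Least-squares affine mapping src onto dst.

    ``pairs`` are (src_index, dst_index) correspondences; by default points
    are matched by position in the arrays.  Needs >= 3 non-collinear pairs;
    exact (to rounding) when the true mapping is affine and noise-free.
    """
    s = _as_points(src)
    d = _as_points(dst)
    if pairs is not None:
        pairs = np.asarray(list(pairs), dtype=int)
        s = s[pairs[:, 0]]
        d = d[pairs[:, 1]]
    if len(s) != len(d):
        raise ValueError("src and dst must have the same number of points")
    if len(s) < 3:
        raise ValueError("need at least 3 point pairs")
    return _lstsq_affine(s, d)


def pair_fiducials(ch1, ch2_transformed, max_pairing_dist: float) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbor pairs closer than max_pairing_dist (nm).

    Returns (index_in_ch1, index_in_ch2) pairs; every point appears in at
    most one pair.  Raises if no pair is found.
    """
    p1 = _as_points(ch1)
    p2 = _as_points(ch2_transformed)
    if len(p1) == 0 or len(p2) == 0:
        raise ValueError("both point sets must be non-empty")
    t1, t2 = cKDTree(p1), cKDTree(p2)
    d12, j12 = t2.query(p1, distance_upper_bound=max_pairing_dist)
    _, j21 = t1.query(p2, distance_upper_bound=max_pairing_dist)
    pairs = [
        (i, int(j))
        for i, (dist, j) in enumerate(zip(d12, j12))
        if np.isfinite(dist) and j < len(p2) and j21[j] == i
    ]
    if not pairs:
        raise ValueError("no fiducial pairs found within the pairing distance")
    return pairs


@dataclass(frozen=True)
class PiecewiseAffineModel:
    """Control-point pairs (after the global affine) plus search parameters.

    For each query, the nearest control points within ``max_dist`` (at most
    ``max_points``, ties broken by index) define a local affine transform; a
    query with fewer than ``min_points`` neighbors lies in an uncorrectable
    region.
    """

    src: np.ndarray
    dst: np.ndarray
    min_points: int = DEFAULT_MIN_POINTS
    max_points: int = DEFAULT_MAX_POINTS
    max_dist: float = DEFAULT_MAX_DIST_NM
    _tree: cKDTree = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        src = np.asarray(self.src, dtype=float)
        dst = np.asarray(self.dst, dtype=float)
        if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
            raise ValueError("src and dst must be matching (N, 2) arrays")
        if self.min_points > self.max_points:
            raise ValueError("min_points must be <= max_points")
        if self.max_dist <= 0:
            raise ValueError("max_dist must be > 0")
        if len(src) < self.min_points:
            raise ValueError("fewer control points than min_points")
        object.__setattr__(self, "src", src)
        object.__setattr__(self, "dst", dst)
        object.__setattr__(self, "_tree", cKDTree(src))


def _local_affine(model: PiecewiseAffineModel, q: np.ndarray) -> AffineTransform:
    idx = model._tree.query_ball_point(q, model.max_dist)
    if idx:
        d = np.linalg.norm(model.src[idx] - q, axis=1)
        order = np.lexsort((idx, d))  # nearest first, ties by index
        idx = [idx[k] for k in order]
        # leave-self-out: a coincident control point must not vote on itself
        idx = [k for k in idx if np.linalg.norm(model.src[k] - q) > _SELF_EPS_NM]
    if len(idx) < model.min_points:
        raise UncorrectableRegionError(len(idx), model.min_points)
    idx = idx[: model.max_points]
    return _lstsq_affine(model.src[idx], model.dst[idx])


def piecewise_transform(model: PiecewiseAffineModel, query) -> np.ndarray:
    """Apply the local affine correction at each query point.

    Accepts a single (x, y) or an (N, 2) array; raises
    UncorrectableRegionError where the neighbor count is insufficient.
    """
    q = np.asarray(query, dtype=float)
    single = q.ndim == 1
    pts = q[None, :] if single else q
    out = np.empty_like(pts)
    for i, p in enumerate(pts):
        out[i] = _local_affine(model, p).apply(p)[0]
    return out[0] if single else out


@dataclass(frozen=True)
class RegistrationModel:
    """Global affine plus optional piecewise refinement, channel 2 -> 1."""

    affine: AffineTransform
    piecewise: Optional[PiecewiseAffineModel] = None

    def transform(self, pts) -> np.ndarray:
        out = self.affine.apply(_as_points(pts))
        if self.piecewise is not None:
            out = piecewise_transform(self.piecewise, out)
        return out


def build_registration(
    ch1,
    ch2,
    *,
    max_pairing_dist: float = 500.0,
    min_points: int = DEFAULT_MIN_POINTS,
    max_points: int = DEFAULT_MAX_POINTS,
    max_dist: float = DEFAULT_MAX_DIST_NM,
    piecewise: bool = True,
) -> RegistrationModel:
    """Build a channel-2 -> channel-1 registration from one bead acquisition.

    Fits the global affine on mutual-nearest-neighbor pairs (pre-paired with
    the identity transform, then refined once after the first affine), and
    anchors the piecewise stage on the affine-corrected pairs.
    """
    p1 = _as_points(ch1)
    p2 = _as_points(ch2)
    pairs = pair_fiducials(p1, p2, max_pairing_dist)
    idx2 = [j for _, j in pairs]
    idx1 = [i for i, _ in pairs]
    affine = _lstsq_affine(p2[idx2], p1[idx1])
    # re-pair after the global affine: catches pairs the raw offset missed
    pairs = pair_fiducials(p1, affine.apply(p2), max_pairing_dist)
    idx2 = [j for _, j in pairs]
    idx1 = [i for i, _ in pairs]
    affine = _lstsq_affine(p2[idx2], p1[idx1])
    # robust rejection: a handful of wrong correspondences (close neighbors
    # mutually nearest by accident) would otherwise leverage the global fit;
    # iterate because the contaminated fit inflates every residual at first
    for _ in range(5):
        resid = np.linalg.norm(p1[idx1] - affine.apply(p2[idx2]), axis=1)
        keep = resid <= 5.0 * np.median(resid) + 1e-9
        if np.all(keep) or np.sum(keep) < 3:
            break
        idx1 = [i for i, k in zip(idx1, keep) if k]
        idx2 = [j for j, k in zip(idx2, keep) if k]
        affine = _lstsq_affine(p2[idx2], p1[idx1])
    pw = None
    if piecewise:
        pw = PiecewiseAffineModel(
            src=affine.apply(p2[idx2]),
            dst=p1[idx1],
            min_points=min_points,
            max_points=max_points,
            max_dist=max_dist,
        )
    return RegistrationModel(affine=affine, piecewise=pw)


def transform_points(model: RegistrationModel, pts) -> tuple[np.ndarray, np.ndarray]:
    """Apply a registration point-wise, masking uncorrectable regions.

    Returns (mapped, ok): rows of ``mapped`` where ``ok`` is False could not
    be piecewise-corrected (too few control points in range) and hold the
    global-affine result instead.
    """
    p = _as_points(pts)
    mapped = model.affine.apply(p)
    ok = np.ones(len(p), dtype=bool)
    if model.piecewise is not None:
        for i in range(len(p)):
            try:
                mapped[i] = piecewise_transform(model.piecewise, mapped[i])
            except UncorrectableRegionError:
                ok[i] = False
    return mapped, ok


@dataclass(frozen=True)
class RegistrationQuality:
    """Residual statistics of a registration evaluated on test fiducials.

    sigma_reg = sqrt(mu_x^2 + mu_y^2) of the mean residuals; ``accepted`` is
    the conventional sigma_reg < 1 nm gate for distance analysis.
    """

    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    sigma_reg: float
    n_fiducials: int
    accepted: bool

    def __post_init__(self) -> None:
        expected = math.hypot(self.mu_x, self.mu_y)
        if not math.isclose(self.sigma_reg, expected, rel_tol=0.0, abs_tol=1e-12):
            raise ValueError("sigma_reg must equal hypot(mu_x, mu_y)")


def compute_tre(
    model: RegistrationModel,
    test_src,
    test_dst,
    pairs: Optional[Sequence[tuple[int, int]]] = None,
) -> RegistrationQuality:
    """Target registration error on an independent fiducial acquisition.

    ``test_src`` are channel-2 test fiducials, ``test_dst`` the matching
    channel-1 positions; residuals are dst - transform(src).  When the test
    points coincide with control points (single-acquisition use), the
    piecewise stage's leave-self-out rule makes this a leave-one-out TRE.
    Test fiducials falling in uncorrectable regions (too few control points
    within the search radius, typically at the field edges) are excluded
    from the statistics; it is an error if no correctable fiducial remains.
    """
    s = _as_points(test_src)
    d = _as_points(test_dst)
    if pairs is not None:
        pairs = np.asarray(list(pairs), dtype=int)
        s = s[pairs[:, 0]]
        d = d[pairs[:, 1]]
    if len(s) == 0 or len(s) != len(d):
        raise ValueError("need matching, non-empty test point sets")
    mapped = np.empty_like(s)
    keep = np.ones(len(s), dtype=bool)
    for i, p in enumerate(s):
        try:
            mapped[i] = model.transform(p)
        except UncorrectableRegionError:
            keep[i] = False
    if not np.any(keep):
        raise ValueError("all test fiducials lie in uncorrectable regions")
    resid = d[keep] - mapped[keep]
    mu_x = float(np.mean(resid[:, 0]))
    mu_y = float(np.mean(resid[:, 1]))
    sigma_reg = math.hypot(mu_x, mu_y)
    return RegistrationQuality(
        mu_x=mu_x,
        mu_y=mu_y,
        sigma_x=float(np.std(resid[:, 0])),
        sigma_y=float(np.std(resid[:, 1])),
        sigma_reg=sigma_reg,
        n_fiducials=int(len(s)),
        accepted=sigma_reg < SIGMA_REG_ACCEPT_NM,
    )
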