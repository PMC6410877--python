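"""Benchmarking harness: distance-discrepancy grids and the reliability
criterion.

Each benchmark cell fixes an estimator, a ratio of distance uncertainty to
true distance (sigma_d/d), a particle count, and a frame count; for the cell
we simulate ``n_reps`` independent datasets, fit every requested method on the
*same* datasets (so method comparisons are paired), and aggregate the
normalized distance discrepancy (measured - expected) / expected.  A
discrepancy of -1.0 means the estimator returned 0 nm.  A cell is reliable
when the mean discrepancy is within 20% of the true distance and its SD below
30% — the conventional accuracy gate for these methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import distfit
from .simulate import SimulationConfig, SimulatedDataset, simulate_pairs

__all__ = [
    "BenchmarkCell",
    "distance_discrepancy",
    "is_reliable",
    "config_for_ratio",
    "fit_dataset",
    "benchmark_grid",
    "cells_to_dataframe",
]

RELIABLE_MEAN = 0.20
RELIABLE_SD = 0.30
#: a cell with more than this fraction of failed fits is flagged
FAILURE_FLAG_FRACTION = 0.20

METHODS = ("P2D", "SigmaP2D", "Vector", "VectorP2D")


def distance_discrepancy(measured: float, expected: float) -> float:
    """(measured - expected) / expected; expected must be positive."""
    if expected <= 0:
        raise ValueError("expected distance must be > 0")
    return (measured - expected) / expected


def is_reliable(mean_disc: float, sd_disc: float) -> bool:
    """|mean| < 20% and SD < 30% of the true distance."""
    return abs(mean_disc) < RELIABLE_MEAN and sd_disc < RELIABLE_SD


@dataclass(frozen=True)
class BenchmarkCell:
    """Aggregated discrepancies of one method under one simulated condition.

    ``mean_discrepancy`` is the signed mean over repeats (the benchmark
    metric); ``mean_abs_discrepancy`` the mean of absolute values, kept as a
    diagnostic of per-dataset scatter.  ``n_failed`` counts non-converged
    fits, which are excluded from the aggregates; ``flagged`` marks cells
    where more than 20% of fits failed.
    """

    method: str
    ratio: float
    n_particles: int
    n_frames: int
    n_reps: int
    mean_discrepancy: float
    sd_discrepancy: float
    mean_abs_discrepancy: float
    reliable: bool
    n_failed: int = 0
    flagged: bool = False


def config_for_ratio(base: SimulationConfig, ratio: float, n_particles: int,
                     n_frames: int, seed: int) -> SimulationConfig:
    """Derive a config whose nominal sigma_d equals ratio * d.

    The localization errors of the two channels are set equal and sized so
    that sqrt(sigma_reg^2 + 2 sigma_loc^2) = ratio * d; the *relative* spread
    of the localization-variance distribution (sigma_sigma_loc / sigma_loc)
    is inherited from the base config, so heterogeneity scales with the
    error level.
    """
    target = ratio * base.d
    if target < base.sigma_reg:
        raise ValueError("ratio * d must be >= sigma_reg")
    sigma_loc = math.sqrt((target**2 - base.sigma_reg**2) / 2.0)
    rel1 = base.sigma_sigma_loc1 / base.sigma_loc1 if base.sigma_loc1 > 0 else 0.0
    rel2 = base.sigma_sigma_loc2 / base.sigma_loc2 if base.sigma_loc2 > 0 else 0.0
    return replace(
        base, sigma_loc1=sigma_loc, sigma_loc2=sigma_loc,
        sigma_sigma_loc1=rel1 * sigma_loc, sigma_sigma_loc2=rel2 * sigma_loc,
        n_particles=n_particles, n_frames=n_frames, seed=seed,
    )


def fit_dataset(ds: SimulatedDataset, method: str) -> distfit.DistanceFitResult:
    """Fit one simulated dataset with one estimator (no SEM, for speed)."""
    if method == "P2D":
        return distfit.fit_p2d(ds.r.ravel())
    if method == "SigmaP2D":
        return distfit.fit_sigma_p2d(ds.flat())
    if method == "Vector":
        return distfit.fit_vector(ds.r_vec(), n_boot=0)
    if method == "VectorP2D":
        return distfit.fit_vector_p2d(ds.r_vec(), n_boot=0)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def benchmark_grid(
    methods: Sequence[str],
    ratios: Sequence[float],
    n_particles_list: Sequence[int],
    n_frames_list: Sequence[int],
    n_reps: int,
    base_config: SimulationConfig,
    seed: int,
) -> list[BenchmarkCell]:
    """Simulate and fit every cell of the grid; deterministic given seed.

    Per-repeat sub-seeds are spawned reproducibly from ``seed``; within a
    cell all methods see the same datasets.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 to estimate an SD")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    root = np.random.SeedSequence(seed)
    cells: list[BenchmarkCell] = []
    for ratio in ratios:
        for n_particles in n_particles_list:
            for n_frames in n_frames_list:
                cell_ss = root.spawn(1)[0]
                rep_seeds = [
                    int(s.generate_state(1)[0] % (2**31))
                    for s in cell_ss.spawn(n_reps)
                ]
                discs: dict[str, list[float]] = {m: [] for m in methods}
                failed = {m: 0 for m in methods}
                for rep_seed in rep_seeds:
                    cfg = config_for_ratio(
                        base_config, ratio, n_particles, n_frames, rep_seed
                    )
                    ds = simulate_pairs(cfg)
                    for m in methods:
                        fit = fit_dataset(ds, m)
                        if not fit.converged:
                            failed[m] += 1
                            continue
                        discs[m].append(
                            distance_discrepancy(fit.mu_hat, base_config.d)
                        )
                for m in methods:
                    arr = np.asarray(discs[m])
                    if arr.size == 0:
                        mean = sd = mean_abs = float("nan")
                    else:
                        mean = float(arr.mean())
                        sd = float(arr.std())
                        mean_abs = float(np.abs(arr).mean())
                    cells.append(
                        BenchmarkCell(
                            method=m, ratio=float(ratio),
                            n_particles=int(n_particles),
                            n_frames=int(n_frames), n_reps=int(n_reps),
                            mean_discrepancy=mean, sd_discrepancy=sd,
                            mean_abs_discrepancy=mean_abs,
                            reliable=bool(arr.size and is_reliable(mean, sd)),
                            n_failed=failed[m],
                            flagged=failed[m] > FAILURE_FLAG_FRACTION * n_reps,
                        )
                    )
    return cells


def cells_to_dataframe(cells: Sequence[BenchmarkCell]) -> pd.DataFrame:
    """Tidy table of benchmark cells (one row per method x condition)."""
    return pd.DataFrame([vars(c) for c in cells])
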