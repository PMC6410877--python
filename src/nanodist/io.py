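"""File formats and run configuration.

Everything on disk is in nm and plain text: localization tables are
comma-delimited with an exact header, registration maps and fit results are
JSON, benchmark grids are tidy CSV.  Run configurations are nested JSON/YAML
documents validated strictly (unknown keys rejected, explicit seeds wherever
randomness exists).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .distfit import DistanceFitResult
from .register import (  # noqa: F401
    AffineTransform,
    PiecewiseAffineModel,
    RegistrationModel,
)

__all__ = [
    "LOCALIZATION_COLUMNS",
    "SchemaError",
    "read_localization_table",
    "write_localization_table",
    "save_registration_model",
    "load_registration_model",
    "fit_result_to_dict",
    "save_fit_result",
    "RunConfig",
    "load_run_config",
    "config_hash",
]

#: required columns of a localization table; particle_id is optional
LOCALIZATION_COLUMNS = (
    "frame",
    "channel",
    "x_nm",
    "y_nm",
    "width_nm",
    "intensity_photons",
    "background_photons",
    "sigma_loc_nm",
)
OPTIONAL_COLUMNS = ("particle_id",)
_INT_COLUMNS = ("particle_id", "frame", "channel")


class SchemaError(ValueError):
    """A table or config violates its schema."""


def read_localization_table(path) -> pd.DataFrame:
    """Read and validate a localization table (comma-delimited, header row)."""
    df = pd.read_csv(path)
    missing = [c for c in LOCALIZATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    unknown = [
        c for c in df.columns
        if c not in LOCALIZATION_COLUMNS and c not in OPTIONAL_COLUMNS
    ]
    if unknown:
        raise SchemaError(f"unknown column(s): {', '.join(unknown)}")
    for col in df.columns:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise SchemaError(
                f"non-numeric or missing value in column {col!r} at row {bad[0] + 1}"
            )
    for col in _INT_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(np.int64)
    if not df["channel"].isin([1, 2]).all():
        row = int(df.index[~df["channel"].isin([1, 2])][0]) + 1
        raise SchemaError(f"channel must be 1 or 2 (row {row})")
    return df


def write_localization_table(df: pd.DataFrame, path) -> None:
    """Write a localization table; fixed 6-decimal format (1e-6 nm lossless)."""
    cols = [c for c in OPTIONAL_COLUMNS if c in df.columns] + list(LOCALIZATION_COLUMNS)
    missing = [c for c in LOCALIZATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    df[cols].to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# registration maps
# ---------------------------------------------------------------------------


def save_registration_model(model: RegistrationModel, path) -> None:
    doc = {
        "affine": {
            "matrix": model.affine.matrix.tolist(),
            "translation": model.affine.translation.tolist(),
        },
        "piecewise": None,
    }
    if model.piecewise is not None:
        pw = model.piecewise
        doc["piecewise"] = {
            "src": pw.src.tolist(),
            "dst": pw.dst.tolist(),
            "min_points": pw.min_points,
            "max_points": pw.max_points,
            "max_dist": pw.max_dist,
        }
    Path(path).write_text(json.dumps(doc))


def load_registration_model(path) -> RegistrationModel:
    doc = json.loads(Path(path).read_text())
    affine = AffineTransform(
        matrix=np.array(doc["affine"]["matrix"]),
        translation=np.array(doc["affine"]["translation"]),
    )
    pw = None
    if doc.get("piecewise") is not None:
        p = doc["piecewise"]
        pw = PiecewiseAffineModel(
            src=np.array(p["src"]), dst=np.array(p["dst"]),
            min_points=int(p["min_points"]), max_points=int(p["max_points"]),
            max_dist=float(p["max_dist"]),
        )
    return RegistrationModel(affine=affine, piecewise=pw)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------


def fit_result_to_dict(result: DistanceFitResult) -> dict:
    return {
        "method": result.method,
        "mu_hat": result.mu_hat,
        "sigma_d_hat": result.sigma_d_hat,
        "sem": result.sem,
        "n_used": result.n_used,
        "converged": result.converged,
        "objective": result.objective,
    }


def save_fit_result(result: DistanceFitResult, path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(result), indent=2))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_SECTION_FIELDS = {
    "camera": {"conversion", "offset", "read_noise", "pixel_size"},
    "detection": {"noise_tolerance", "box_size"},
    "registration": {"min_points", "max_points", "max_dist", "max_pairing_dist",
                     "sigma_reg_accept"},
    "fitting": {"method", "sigma_reg", "n_boot", "cutoff", "seed"},
    "simulation": {"d", "sigma_con", "sigma_loc1", "sigma_loc2",
                   "sigma_sigma_loc1", "sigma_sigma_loc2", "sigma_reg",
                   "n_particles", "n_frames", "outlier_fraction",
                   "outlier_range_max", "seed"},
}
_SEEDED_SECTIONS = ("fitting", "simulation")

_DEFAULTS = {
    "camera": {"conversion": 1.0, "offset": 0.0, "read_noise": 0.0,
               "pixel_size": 159.0},
    "detection": {"noise_tolerance": 10.0, "box_size": 11},
    "registration": {"min_points": 10, "max_points": 100, "max_dist": 2000.0,
                     "max_pairing_dist": 500.0, "sigma_reg_accept": 1.0},
    "fitting": {"method": "sigma-p2d", "sigma_reg": 0.0, "n_boot": 1000,
                "cutoff": None, "seed": None},
    "simulation": {"d": 10.0, "sigma_con": 0.0, "sigma_loc1": 1.0,
                   "sigma_loc2": 1.0, "sigma_sigma_loc1": 0.0,
                   "sigma_sigma_loc2": 0.0, "sigma_reg": 0.0,
                   "n_particles": 100, "n_frames": 1, "outlier_fraction": 0.0,
                   "outlier_range_max": None, "seed": None},
}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated nested configuration for the pipeline stages."""

    camera: dict
    detection: dict
    registration: dict
    fitting: dict
    simulation: dict

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        unknown = set(doc) - set(_SECTION_FIELDS)
        if unknown:
            raise SchemaError(f"unknown config section(s): {sorted(unknown)}")
        sections = {}
        for name, allowed in _SECTION_FIELDS.items():
            given = doc.get(name, {})
            if not isinstance(given, dict):
                raise SchemaError(f"section {name!r} must be a mapping")
            bad = set(given) - allowed
            if bad:
                raise SchemaError(f"unknown key(s) in {name!r}: {sorted(bad)}")
            merged = dict(_DEFAULTS[name])
            merged.update(given)
            sections[name] = merged
        for name in _SEEDED_SECTIONS:
            if name in doc and sections[name].get("seed") is None:
                raise SchemaError(f"section {name!r} requires an explicit seed")
        return cls(**sections)


def load_run_config(path) -> RunConfig:
    """Load a JSON (.json) or YAML (.yml/.yaml) run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise SchemaError("config root must be a mapping")
    return RunConfig.from_dict(doc)


def config_hash(config: RunConfig) -> str:
    """Stable hash of a config, for structured logs."""
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
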