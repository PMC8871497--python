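"""File formats: long-format curve CSVs, scalar CSVs, JSON fit serialization.

Curves travel as long-format CSV with columns (subject_id, functional_id,
t, value); every (subject, functional) pair must share one common grid.
Fitted models and run configurations are stored as JSON at full double
precision, stamped with a schema version, the package version and a config
hash so runs can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fkmr import FKMRRegressor

__all__ = ["read_curves", "write_curves", "read_scalars", "write_scalars",
           "save_fit", "load_fit", "write_manifest", "FormatError"]

FIT_SCHEMA_VERSION = 1
CURVE_COLUMNS = ("subject_id", "functional_id", "t", "value")


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


def write_curves(path, curves: list[np.ndarray], grid: np.ndarray,
                 functional_ids: list[str] | None = None,
                 subject_ids: list | None = None) -> None:
    """Write per-functional curve matrices as one long-format CSV."""
    n, m = curves[0].shape
    if functional_ids is None:
        functional_ids = [f"Z{i + 1}" for i in range(len(curves))]
    if subject_ids is None:
        subject_ids = [f"s{i + 1}" for i in range(n)]
    frames = []
    for fid, mat in zip(functional_ids, curves):
        frames.append(pd.DataFrame({
            "subject_id": np.repeat(subject_ids, m),
            "functional_id": fid,
            "t": np.tile(grid, n),
            "value": np.asarray(mat, dtype=float).ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curves(path):
    """Read a long-format curve CSV into per-functional n x m matrices.

    Returns (curves, grid, functional_ids, subject_ids).  Subjects keep
    their file order; a ragged or inconsistent grid raises
    :class:`FormatError` naming the offending subject.
    """
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"curves file is missing columns {missing}")
    functional_ids = list(pd.unique(df["functional_id"]))
    subject_ids = list(pd.unique(df["subject_id"]))
    grid = None
    curves = []
    # t values are compared positionally in file order: a clipped jittered
    # grid may carry tied boundary points, so sorting/deduplication would
    # corrupt the curve matrices.
    for fid in functional_ids:
        sub = df[df["functional_id"] == fid]
        mats = []
        for sid in subject_ids:
            rec = sub[sub["subject_id"] == sid]
            tvals = rec["t"].to_numpy(dtype=float)
            if tvals.size >= 2 and np.any(np.diff(tvals) < 0):
                raise FormatError(
                    f"subject {sid!r} / functional {fid!r}: time points are "
                    "not sorted")
            if grid is None:
                grid = tvals
                if grid.size < 2:
                    raise FormatError("fewer than two time points per curve")
            elif tvals.shape != grid.shape or not np.allclose(tvals, grid):
                raise FormatError(
                    f"subject {sid!r} / functional {fid!r} does not share "
                    "the common time grid")
            mats.append(rec["value"].to_numpy(dtype=float))
        curves.append(np.vstack(mats))
    return curves, grid, functional_ids, subject_ids


def write_scalars(path, x: np.ndarray, y: np.ndarray,
                  subject_ids: list | None = None) -> None:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(y):
        x = x.T
    if subject_ids is None:
        subject_ids = [f"s{i + 1}" for i in range(len(y))]
    data = {"subject_id": subject_ids}
    for j in range(x.shape[1]):
        data[f"x{j + 1}"] = x[:, j]
    data["y"] = np.asarray(y, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False)


def read_scalars(path):
    """Returns (X covariate matrix, y, subject_ids); y column optional."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise FormatError("scalars file is missing 'subject_id'")
    xcols = [c for c in df.columns if c.startswith("x")]
    X = df[xcols].to_numpy(dtype=float) if xcols else np.empty((len(df), 0))
    y = df["y"].to_numpy(dtype=float) if "y" in df.columns else None
    return X, y, list(df["subject_id"])


def _config_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()[:16]


def save_fit(path, model: FKMRRegressor) -> None:
    """Serialize a fitted FKMRRegressor to JSON at full double precision."""
    params = model.get_params()
    state = {
        "beta": model.beta_.tolist(),
        "alpha": model.alpha_.tolist(),
        "gamma": model.gamma_.tolist(),
        "lambda1": model.lambda1_,
        "lambda2": model.lambda2_,
        "tau": model.tau_,
        "sigma2": model.sigma2_,
        "objective_trace": model.objective_trace_.tolist(),
        "selected_features": model.selected_features_.tolist(),
        "selected_groups": model.selected_groups_.tolist(),
        "n_outer_iterations": model.n_outer_iterations_,
        "converged": bool(model.converged_),
        "Z_train": np.asarray(model.Z_train_).tolist(),
        "q": model._q_,
    }
    payload = {
        "schema_version": FIT_SCHEMA_VERSION,
        "package_version": __version__,
        "config_hash": _config_hash(params),
        "params": params,
        "state": state,
    }
    Path(path).write_text(json.dumps(payload))


def load_fit(path) -> FKMRRegressor:
    """Reconstruct a fitted FKMRRegressor; predictions match to 1e-12."""
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != FIT_SCHEMA_VERSION:
        raise FormatError(
            f"fit schema version {payload.get('schema_version')!r} is not "
            f"supported (expected {FIT_SCHEMA_VERSION})")
    required = ["beta", "alpha", "gamma", "Z_train", "lambda1", "lambda2"]
    state = payload.get("state", {})
    missing = [k for k in required if k not in state]
    if missing:
        raise FormatError(f"fit file is missing fields {missing}")
    model = FKMRRegressor(**payload["params"])
    from .kernels import KernelSpec
    model.beta_ = np.asarray(state["beta"], dtype=float)
    model.alpha_ = np.asarray(state["alpha"], dtype=float)
    model.gamma_ = np.asarray(state["gamma"], dtype=float)
    model.lambda1_ = state["lambda1"]
    model.lambda2_ = state["lambda2"]
    model.tau_ = state.get("tau")
    model.sigma2_ = state.get("sigma2")
    model.objective_trace_ = np.asarray(state.get("objective_trace", []))
    model.selected_features_ = np.asarray(state.get("selected_features", []),
                                          dtype=int)
    model.selected_groups_ = np.asarray(state.get("selected_groups", []),
                                        dtype=int)
    model.n_outer_iterations_ = state.get("n_outer_iterations", 0)
    model.converged_ = state.get("converged", False)
    model.Z_train_ = np.asarray(state["Z_train"], dtype=float)
    model._q_ = state["q"]
    model._kspec_ = KernelSpec(float(model.Z_train_.shape[1]))
    return model


def write_manifest(path, config: dict, seed: int | None = None) -> None:
    """Drop a manifest (config, seed, version, hash) enabling exact re-runs."""
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": _config_hash(config),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
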