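"""CSV input, result serialization, and the trace document.

Points come in as a rectangular numeric CSV (rows = observations), distance
matrices as a square numeric CSV.  Results go out as a labels CSV
(1-based row indices and cluster labels, input order preserved) and a JSON
trace documenting every iteration: k before/after, the penalty eta, the
optimal permutation (1-based image list), its cycles, and the attained
objective.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ClusteringResult, Config
from .geometry import DistanceMatrix, PointSet

TRACE_SCHEMA_VERSION = 1


def read_points_csv(
    path: str | Path,
    has_header: bool = False,
    id_column: str | int | None = None,
) -> PointSet:
    """Read an observations-by-features table into a :class:`PointSet`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, header=0 if has_header else None)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    ids = None
    if id_column is not None:
        col = id_column if has_header else int(id_column)
        if col not in df.columns:
            raise ValueError(f"{path}: id column {col!r} not found")
        ids = tuple(str(v) for v in df[col])
        df = df.drop(columns=[col])
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no coordinate columns")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.argmax((bad | df[col].isna()).to_numpy()))
            raise ValueError(f"{path}: non-numeric or missing value at row {row + 1}, "
                             f"column {col!r}")
    return PointSet(coords=df.to_numpy(dtype=float), ids=ids)


def read_distance_csv(path: str | Path) -> DistanceMatrix:
    """Read and validate a square symmetric distance matrix.

    Asymmetries up to 1e-9 (relative) are symmetrized away; tiny negative
    entries within -1e-9 are clipped to zero; the diagonal must be zero
    within 1e-9.
    """
    path = Path(path)
    try:
        values = pd.read_csv(path, header=None).to_numpy(dtype=float)
    except (ValueError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"{path}: not a numeric matrix ({exc})") from None
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: distance matrix must be square, got {values.shape}")
    scale = max(1.0, float(np.max(np.abs(values), initial=0.0)))
    if np.max(np.abs(values - values.T)) > 1e-9 * scale:
        raise ValueError(f"{path}: matrix asymmetric beyond tolerance 1e-9")
    values = 0.5 * (values + values.T)
    if np.any(values < -1e-9 * scale):
        raise ValueError(f"{path}: negative distances")
    values = np.maximum(values, 0.0)
    if np.any(np.abs(np.diag(values)) > 1e-9 * scale):
        raise ValueError(f"{path}: nonzero diagonal")
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(values=values, metric_name="precomputed")


def trace_document(result: ClusteringResult) -> dict:
    """Serializable record of a run: settings plus the per-iteration trace."""
    return {
        "schema_version": TRACE_SCHEMA_VERSION,
        "settings": asdict(result.settings),
        "final_k": int(result.k),
        "converged": bool(result.converged),
        "iterations": [
            {
                "iteration": r.iteration,
                "k_before": r.k_before,
                "k_after": r.k_after,
                "eta": r.eta,
                "permutation": list(r.permutation.mapping),
                "cycles": [list(c) for c in r.cycles.cycles],
                "objective": r.objective,
            }
            for r in result.trace
        ],
    }


def write_result(
    result: ClusteringResult,
    labels_path: str | Path,
    trace_path: str | Path | None = None,
) -> None:
    """Write the labels CSV (and optionally the JSON trace).

    The labels file has columns ``row_index`` (1-based, input order),
    ``id`` (only when the input carried ids), and ``cluster`` (1-based).
    """
    n = len(result.labels)
    data: dict[str, object] = {"row_index": np.arange(1, n + 1)}
    if result.ids is not None:
        data["id"] = list(result.ids)
    data["cluster"] = result.labels
    pd.DataFrame(data).to_csv(labels_path, index=False)
    if trace_path is not None:
        Path(trace_path).write_text(json.dumps(trace_document(result), indent=1) + "\n")


def read_labels_csv(path: str | Path) -> np.ndarray:
    """Read back a labels CSV written by :func:`write_result` (1-based labels)."""
    df = pd.read_csv(path)
    if "cluster" not in df.columns:
        raise ValueError(f"{path}: missing 'cluster' column")
    order = np.argsort(df["row_index"].to_numpy())
    return df["cluster"].to_numpy(dtype=int)[order]
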