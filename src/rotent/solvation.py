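"""Solvation application layer.

Connects orientation samples to solvation thermodynamics in the spirit of
inhomogeneous fluid solvation theory (IFST): orientation records tagged with
positions are assigned to cubic voxels of a Cartesian analysis grid, a
relative orientational entropy is estimated per voxel, and each voxel's
contribution to the molar solvation free energy is

    -T dS_orient = -T k N_A n_bar H_rel     [kcal/mol]

where ``n_bar`` is the mean number of molecules in the voxel per frame and
``H_rel <= 0`` the relative orientational entropy, so orientational ordering
always costs free energy. Only the solute-water orientational term is
treated here; translational and water-water terms are out of scope.

File format: delimited text with a header; columns ``frame`` then either
``qw qx qy qz`` (quaternion) or ``alpha beta gamma`` (ZYZ Euler, radians),
optionally preceded by ``x y z`` positions in Angstroms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entropy import EntropyEstimate, HistogramSpec, histogram_entropy, knn_entropy_relative
from .metrics import Metric, MetricSpec
from .rotations import (
    SymmetryMode,
    euler_to_quaternion,
    normalize_quaternion,
    quaternion_to_euler,
)

__all__ = [
    "ThermoConstants",
    "VoxelGrid",
    "VoxelizedSample",
    "read_orientation_table",
    "write_orientation_table",
    "voxelize",
    "molar_contribution",
    "grid_entropy_report",
]

logger = logging.getLogger(__name__)

QUAT_COLS = ["qw", "qx", "qy", "qz"]
EULER_COLS = ["alpha", "beta", "gamma"]
POS_COLS = ["x", "y", "z"]

#: parsed quaternions may deviate from unit norm by at most this much
PARSE_NORM_TOL = 1e-6


@dataclass(frozen=True)
class ThermoConstants:
    """Temperature and molar gas constant used in the free-energy conversion."""

    temperature: float = 298.0  # K
    gas_constant: float = 1.9872e-3  # k * N_A, kcal/(mol K)


@dataclass(frozen=True)
class VoxelGrid:
    """Cubic Cartesian analysis grid (10 x 10 x 10 cells of 0.5 A by default)."""

    center: tuple = (0.0, 0.0, 0.0)
    n_cells: int = 10
    resolution: float = 0.5  # Angstrom

    @property
    def edge(self) -> float:
        return self.n_cells * self.resolution

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.center, float) - self.edge / 2.0

    @property
    def n_voxels(self) -> int:
        return self.n_cells**3


@dataclass
class VoxelizedSample:
    """Per-voxel orientation assignments of a position-tagged sample."""

    grid: VoxelGrid
    voxel_of_record: np.ndarray  # flat voxel index per record, -1 = out of grid
    counts: np.ndarray  # (n_voxels,) in-grid record counts
    n_frames: int
    n_out_of_grid: int
    frame: np.ndarray = field(repr=False)
    quaternions: np.ndarray = field(repr=False)

    @property
    def n_bar(self) -> np.ndarray:
        """Mean number of molecules per frame in each voxel."""
        return self.counts / self.n_frames

    def voxel_orientations(self, flat_index: int) -> np.ndarray:
        return self.quaternions[self.voxel_of_record == flat_index]


def read_orientation_table(path, fmt: str = "auto") -> pd.DataFrame:
    """Read a delimited orientation table into a validated DataFrame.

    Returns columns ``frame``, optional ``x y z``, and ``qw qx qy qz``
    (Euler input is converted). Non-unit quaternions beyond ``PARSE_NORM_TOL``
    and malformed rows raise ``ValueError`` with the offending location.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as err:
        raise ValueError(f"cannot parse orientation table {path}: {err}") from err
    df.columns = [str(c).strip().lower() for c in df.columns]
    if fmt == "auto":
        if set(QUAT_COLS) <= set(df.columns):
            fmt = "quaternion"
        elif set(EULER_COLS) <= set(df.columns):
            fmt = "euler"
        else:
            raise ValueError(
                f"{path}: header must contain {QUAT_COLS} or {EULER_COLS}"
            )
    need = QUAT_COLS if fmt == "quaternion" else EULER_COLS
    missing = [c for c in ["frame"] + need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        logger.warning("%s: empty data section", path)
        return pd.DataFrame(columns=["frame"] + POS_COLS + QUAT_COLS)
    for c in ["frame"] + need + [c for c in POS_COLS if c in df.columns]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    bad = df[need].isna().any(axis=1) | df["frame"].isna()
    if bad.any():
        raise ValueError(f"{path}: malformed row at line {int(bad.idxmax()) + 2}")
    if not df["frame"].is_monotonic_increasing:
        raise ValueError(f"{path}: frame indices must be non-decreasing")

    out = pd.DataFrame({"frame": df["frame"].astype(int)})
    if set(POS_COLS) <= set(df.columns):
        for c in POS_COLS:
            out[c] = df[c].astype(float)
    if fmt == "quaternion":
        q = df[QUAT_COLS].to_numpy(float)
        norm = np.linalg.norm(q, axis=1)
        off = np.abs(norm - 1.0) > PARSE_NORM_TOL
        if off.any():
            raise ValueError(
                f"{path}: non-unit quaternion at line {int(np.flatnonzero(off)[0]) + 2}"
            )
        q = normalize_quaternion(q)
    else:
        q = euler_to_quaternion(df[EULER_COLS].to_numpy(float))
    out[QUAT_COLS] = q
    return out


def write_orientation_table(df: pd.DataFrame, path, fmt: str = "quaternion") -> None:
    """Write an orientation table as TSV (quaternion or Euler columns)."""
    cols = ["frame"] + [c for c in POS_COLS if c in df.columns]
    out = df[cols].copy()
    if fmt == "quaternion":
        out[QUAT_COLS] = df[QUAT_COLS].to_numpy(float)
    elif fmt == "euler":
        out[EULER_COLS] = quaternion_to_euler(df[QUAT_COLS].to_numpy(float))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def voxelize(records: pd.DataFrame, grid: VoxelGrid) -> VoxelizedSample:
    """Assign position-tagged orientation records to grid voxels.

    Voxel intervals are half-open ``[low, high)`` per axis (boundary samples
    go to the higher-index voxel); records outside the grid are counted and
    excluded. ``n_frames`` is the number of distinct frame indices.
    """
    if not set(POS_COLS) <= set(records.columns):
        raise ValueError("records carry no positions (x, y, z)")
    pos = records[POS_COLS].to_numpy(float)
    q = records[QUAT_COLS].to_numpy(float)
    frame = records["frame"].to_numpy(int)
    idx = np.floor((pos - grid.origin) / grid.resolution).astype(int)
    inside = np.all((idx >= 0) & (idx < grid.n_cells), axis=1)
    flat = np.full(len(records), -1, dtype=int)
    flat[inside] = (
        idx[inside, 0] * grid.n_cells + idx[inside, 1]
    ) * grid.n_cells + idx[inside, 2]
    counts = np.bincount(flat[inside], minlength=grid.n_voxels).astype(float)
    n_frames = int(len(np.unique(frame))) if len(records) else 0
    return VoxelizedSample(
        grid=grid,
        voxel_of_record=flat,
        counts=counts,
        n_frames=n_frames,
        n_out_of_grid=int((~inside).sum()),
        frame=frame,
        quaternions=q,
    )


def molar_contribution(
    h_rel: float, n_bar: float, constants: ThermoConstants = ThermoConstants()
) -> float:
    """Molar free-energy contribution ``-T dS_orient`` of one voxel, kcal/mol.

    Positive when ``h_rel < 0``: orientational ordering costs free energy.
    """
    if n_bar < 0:
        raise ValueError("mean occupancy must be >= 0")
    return -constants.temperature * constants.gas_constant * n_bar * h_rel


def grid_entropy_report(
    vox: VoxelizedSample,
    estimator: str = "knn",
    k: int = 1,
    spec: MetricSpec = MetricSpec(Metric.D3, SymmetryMode.C2V),
    constants: ThermoConstants = ThermoConstants(),
    min_samples: int | None = None,
) -> pd.DataFrame:
    """Per-voxel entropy and free-energy table; grid totals are the column sums.

    Voxels with fewer samples than ``min_samples`` (default ``k + 1`` for the
    KNN estimator, 1 for the histogram) get NaN entropy and a zero
    free-energy contribution.
    """
    if min_samples is None:
        min_samples = (k + 1) if estimator == "knn" else 1
    rows = []
    for v in range(vox.grid.n_voxels):
        qv = vox.voxel_orientations(v)
        n_v = qv.shape[0]
        if n_v >= max(min_samples, 2 if estimator == "knn" else 1):
            if estimator == "knn":
                est: EntropyEstimate = knn_entropy_relative(qv, k=k, spec=spec)
            elif estimator == "histogram":
                est = histogram_entropy(
                    quaternion_to_euler(qv), spec.symmetry, HistogramSpec()
                )
            else:
                raise ValueError(f"unknown estimator {estimator!r}")
            h = est.h_rel
            dg = molar_contribution(h, vox.n_bar[v], constants)
        else:
            h, dg = np.nan, 0.0
        rows.append(
            {
                "voxel": v,
                "n_samples": n_v,
                "n_bar": vox.n_bar[v],
                "h_rel": h,
                "minus_T_dS": dg,
            }
        )
    return pd.DataFrame(rows)
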