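"""Reading and writing thermographic frame stacks and measurement tables.

A recording of one sealing event is stored as a directory of per-frame CSV
matrices (``frame_000.csv``, ``frame_001.csv``, ...) holding temperatures in
degrees Celsius, plus a single JSON sidecar ``metadata.json`` with the spatial
calibration and geometry:

.. code-block:: json

    {
      "calibration_um_per_px": 100.0,
      "branch_band": [76, 83],
      "column_roi": [8, 39],
      "timestamps_s": [0.0, 0.5, 1.0]
    }

``branch_band`` is the inclusive row interval occupied by the closed
instrument branches; row 0 is the top of the image, so "above the branches"
means rows < ``r_top`` and "below" means rows > ``r_bottom``.  ``column_roi``
is the inclusive column interval across which transects are taken.  The
calibration is a single isotropic µm-per-pixel scalar and is always an
explicit input — it is never inferred from optics.

Necrosis/zone measurements travel as a TSV with one row per
(instrument, sample, side); see :data:`MEASUREMENT_COLUMNS`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

#: Plausible temperature range enforced on load (°C).  Anything outside is
#: treated as a corrupted or mis-scaled recording, not as data.
TEMPERATURE_RANGE_C = (-50.0, 400.0)

SIDES = ("above", "below")

#: Canonical column order of a measurement table.
MEASUREMENT_COLUMNS = (
    "instrument_id",
    "sample_id",
    "side",
    "critical_extent_um",
    "necrosis_extent_um",
    "frontier_temp_C",
)

_SIDECAR_NAME = "metadata.json"
_FRAME_RE = re.compile(r"^frame_(\d+)\.csv$")


@dataclass(frozen=True)
class ThermalFrameStack:
    """Time-ordered stack of 2D temperature grids for one sealing event.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, n_rows, n_cols)``, temperatures in °C.
    timestamps_s
        Seconds from recording start, strictly increasing, one per frame.
    calibration_um
        Isotropic spatial calibration, µm per pixel, > 0.
    branch_band
        Inclusive row interval ``(r_top, r_bottom)`` occupied by the closed
        instrument branches.
    column_roi
        Inclusive column interval ``(c_first, c_last)`` over which transects
        are taken.
    """

    frames: np.ndarray
    timestamps_s: np.ndarray
    calibration_um: float
    branch_band: tuple[int, int]
    column_roi: tuple[int, int]

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        ts = np.asarray(self.timestamps_s, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "timestamps_s", ts)
        object.__setattr__(self, "branch_band", tuple(int(v) for v in self.branch_band))
        object.__setattr__(self, "column_roi", tuple(int(v) for v in self.column_roi))
        object.__setattr__(self, "calibration_um", float(self.calibration_um))

        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValidationError(
                f"frames must be a non-empty (n_frames, rows, cols) array, got shape {frames.shape}"
            )
        if not np.all(np.isfinite(frames)):
            raise ValidationError("frames contain non-finite temperatures")
        lo, hi = TEMPERATURE_RANGE_C
        if frames.min() < lo or frames.max() > hi:
            raise ValidationError(
                f"temperatures outside plausible range [{lo}, {hi}] °C "
                f"(observed [{frames.min():.1f}, {frames.max():.1f}])"
            )
        if ts.shape != (frames.shape[0],):
            raise ValidationError(
                f"timestamps length {ts.shape} does not match {frames.shape[0]} frames"
            )
        if frames.shape[0] > 1 and not np.all(np.diff(ts) > 0):
            raise ValidationError("timestamps must be strictly increasing")
        if not self.calibration_um > 0:
            raise ValidationError("calibration_um must be > 0")
        r_top, r_bottom = self.branch_band
        n_rows, n_cols = frames.shape[1:]
        if not (0 <= r_top <= r_bottom < n_rows):
            raise ValidationError(
                f"branch_band {self.branch_band} not within 0..{n_rows - 1}"
            )
        c0, c1 = self.column_roi
        if not (0 <= c0 <= c1 < n_cols):
            raise ValidationError(
                f"column_roi {self.column_roi} not within 0..{n_cols - 1}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def grid_shape(self) -> tuple[int, int]:
        return tuple(self.frames.shape[1:])


def _parse_frame_csv(path: Path, frame_index: int) -> np.ndarray:
    try:
        return np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
    except ValueError:
        # Slow path: locate the offending cell so the error is actionable.
        for i, line in enumerate(path.read_text().splitlines()):
            for j, cell in enumerate(line.split(",")):
                try:
                    float(cell)
                except ValueError:
                    raise ParseError(
                        f"non-numeric cell {cell!r} in frame {frame_index}, "
                        f"row {i}, column {j} ({path.name})"
                    ) from None
        raise ParseError(f"malformed CSV in frame {frame_index} ({path.name})") from None


def read_frame_stack(directory: str | Path) -> ThermalFrameStack:
    """Read a frame-stack directory (per-frame CSVs + JSON sidecar).

    Frames are ordered by their zero-padded index in the file name.
    """
    directory = Path(directory)
    sidecar = directory / _SIDECAR_NAME
    if not sidecar.is_file():
        raise FormatError(f"missing sidecar {_SIDECAR_NAME} in {directory}")
    meta = json.loads(sidecar.read_text())
    for key in ("calibration_um_per_px", "branch_band", "column_roi", "timestamps_s"):
        if key not in meta:
            raise FormatError(f"sidecar is missing field {key!r}")

    frame_files: dict[int, Path] = {}
    for p in directory.iterdir():
        m = _FRAME_RE.match(p.name)
        if m:
            frame_files[int(m.group(1))] = p
    if not frame_files:
        raise FormatError(f"no frame_*.csv files found in {directory}")
    indices = sorted(frame_files)
    if indices != list(range(len(indices))):
        raise FormatError(f"frame indices are not contiguous from 0: {indices}")

    frames = []
    shape = None
    for idx in indices:
        grid = _parse_frame_csv(frame_files[idx], idx)
        if shape is None:
            shape = grid.shape
        elif grid.shape != shape:
            raise FormatError(
                f"frame {idx} has shape {grid.shape}, expected {shape} "
                f"({frame_files[idx].name})"
            )
        frames.append(grid)

    return ThermalFrameStack(
        frames=np.stack(frames),
        timestamps_s=np.asarray(meta["timestamps_s"], dtype=float),
        calibration_um=float(meta["calibration_um_per_px"]),
        branch_band=tuple(meta["branch_band"]),
        column_roi=tuple(meta["column_roi"]),
    )


def write_frame_stack(stack: ThermalFrameStack, directory: str | Path) -> None:
    """Write a stack as per-frame CSVs (6 decimals) plus the JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(stack.n_frames - 1)))
    for idx in range(stack.n_frames):
        np.savetxt(
            directory / f"frame_{idx:0{width}d}.csv",
            stack.frames[idx],
            delimiter=",",
            fmt="%.6f",
        )
    meta = {
        "calibration_um_per_px": stack.calibration_um,
        "branch_band": list(stack.branch_band),
        "column_roi": list(stack.column_roi),
        "timestamps_s": [float(t) for t in stack.timestamps_s],
    }
    (directory / _SIDECAR_NAME).write_text(json.dumps(meta, indent=1))


def read_frame_stack_tiff(tiff_path: str | Path, sidecar_path: str | Path) -> ThermalFrameStack:
    """Read a multi-page 32-bit float TIFF (one page per frame) + JSON sidecar.

    Bulk alternative to the CSV directory layout; the sidecar schema is
    identical.
    """
    import tifffile

    meta = json.loads(Path(sidecar_path).read_text())
    frames = np.asarray(tifffile.imread(str(tiff_path)), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    return ThermalFrameStack(
        frames=frames,
        timestamps_s=np.asarray(meta["timestamps_s"], dtype=float),
        calibration_um=float(meta["calibration_um_per_px"]),
        branch_band=tuple(meta["branch_band"]),
        column_roi=tuple(meta["column_roi"]),
    )


def write_frame_stack_tiff(stack: ThermalFrameStack, tiff_path: str | Path,
                           sidecar_path: str | Path) -> None:
    """Write a stack as a multi-page float32 TIFF plus the JSON sidecar."""
    import tifffile

    tifffile.imwrite(str(tiff_path), stack.frames.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "calibration_um_per_px": stack.calibration_um,
        "branch_band": list(stack.branch_band),
        "column_roi": list(stack.column_roi),
        "timestamps_s": [float(t) for t in stack.timestamps_s],
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a measurement table in place and return it.

    Enforces: the six canonical columns present; ``side`` in {above, below};
    extents ≥ 0; necrosis extent never exceeds the critical extent when both
    are positive (the necrosis zone lies inside the >50 °C zone); unique
    (instrument_id, sample_id, side) keys.  Extra columns are preserved.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"measurement table is missing columns {missing}")
    df = df.copy()
    for col in ("critical_extent_um", "necrosis_extent_um", "frontier_temp_C"):
        df[col] = pd.to_numeric(df[col])
    bad_side = ~df["side"].isin(SIDES)
    if bad_side.any():
        raise ValidationError(
            f"side must be one of {SIDES}; offending rows: {df.index[bad_side].tolist()}"
        )
    if (df["critical_extent_um"] < 0).any() or (df["necrosis_extent_um"] < 0).any():
        raise ValidationError("extents must be >= 0")
    both_pos = (df["critical_extent_um"] > 0) & (df["necrosis_extent_um"] > 0)
    exceeds = both_pos & (df["necrosis_extent_um"] > df["critical_extent_um"])
    if exceeds.any():
        first = df.loc[exceeds].iloc[0]
        raise ValidationError(
            "necrosis_extent_um exceeds critical_extent_um for "
            f"({first['instrument_id']}, {first['sample_id']}, {first['side']})"
        )
    keys = df[["instrument_id", "sample_id", "side"]]
    dup = keys.duplicated()
    if dup.any():
        first = keys.loc[dup].iloc[0]
        raise ValidationError(
            f"duplicate (instrument_id, sample_id, side) key: {tuple(first)}"
        )
    return df


def read_measurements(tsv_path: str | Path) -> pd.DataFrame:
    """Read and validate a measurement table from a TSV file."""
    df = pd.read_csv(tsv_path, sep="\t")
    return validate_measurements(df)


def write_measurements(df: pd.DataFrame, tsv_path: str | Path) -> None:
    """Write a validated measurement table as TSV ('.' decimal separator)."""
    df = validate_measurements(df)
    cols = list(MEASUREMENT_COLUMNS) + [c for c in df.columns if c not in MEASUREMENT_COLUMNS]
    df[cols].to_csv(tsv_path, sep="\t", index=False)
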