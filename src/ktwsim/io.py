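"""Readers and writers: snapshot TSV, trajectory TSV, JSON sidecar.

All on-disk formats are plain text.  Snapshots are long-format TSV
(``col``, ``row``, ``species_id``) listing occupied sites only;
trajectories are one TSV row per step.  Every run writes a JSON
metadata sidecar with the fully resolved configuration, the seed and
the package version, sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .config import RunConfig, config_from_dict
from .hexlattice import HexLattice

SNAPSHOT_COLUMNS = ("col", "row", "species_id")


def write_snapshot(lattice: HexLattice, path: str | Path) -> None:
    """Write occupied sites as ``col<TAB>row<TAB>species_id`` rows."""
    sites = np.flatnonzero(lattice.occ)
    frame = pd.DataFrame(
        {
            "col": sites % lattice.width,
            "row": sites // lattice.width,
            "species_id": lattice.occ[sites],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_snapshot(
    path: str | Path, width: int | None = None, height: int | None = None
) -> HexLattice:
    """Read a snapshot TSV; dimensions default to the occupied bounding size.

    Pass ``width``/``height`` explicitly when the lattice is larger than
    the extent of its occupied sites (e.g. sparse states).
    """
    frame = pd.read_csv(path, sep="\t")
    if tuple(frame.columns) != SNAPSHOT_COLUMNS:
        raise ValueError(
            f"snapshot must have columns {SNAPSHOT_COLUMNS}, got {tuple(frame.columns)}"
        )
    if width is None:
        width = int(frame["col"].max()) + 1 if len(frame) else 0
    if height is None:
        height = int(frame["row"].max()) + 1 if len(frame) else 0
    lattice = HexLattice.empty(width, height)
    if ((frame["col"] >= width) | (frame["row"] >= height)).any():
        raise ValueError("snapshot contains sites outside the stated dimensions")
    idx = frame["row"].to_numpy() * width + frame["col"].to_numpy()
    lattice.occ[idx] = frame["species_id"].to_numpy()
    return lattice


def write_trajectory(trajectory: pd.DataFrame, path: str | Path) -> None:
    """Write a trajectory as TSV (full float precision, exact round-trip)."""
    trajectory.to_csv(path, sep="\t", index=False)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if "penalized" in frame.columns:
        frame["penalized"] = frame["penalized"].astype(bool)
    return frame


def write_sidecar(config: RunConfig, path: str | Path, **extra: Any) -> None:
    """Write the resolved config + version as a JSON metadata sidecar."""
    from . import __version__

    payload = {"config": config.to_dict(), "version": __version__, **extra}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_sidecar(path: str | Path) -> RunConfig:
    """Rebuild a :class:`RunConfig` from a sidecar written by this package."""
    payload = json.loads(Path(path).read_text())
    return config_from_dict(payload["config"])
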