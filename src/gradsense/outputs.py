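"""Plain-text output writers: observable CSVs and XYZ particle snapshots."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = ["write_xyz_frame", "write_xyz_trajectory"]

# element tags: L free ligand, B bound receptor, U unbound receptor
_TAGS = ("L", "B", "U")


def write_xyz_frame(fh, state, comment: str = "") -> None:
    """Append one XYZ frame for the current state to an open text handle."""
    lig = state.ligands
    rec = state.receptors
    bound = state.bound
    n = lig.shape[0] + rec.shape[0]
    fh.write(f"{n}\n")
    header = f"t={state.time:.6f}s"
    if comment:
        header += f" {comment}"
    fh.write(header + "\n")
    for tag, pts in (
        ("L", lig),
        ("B", rec[bound]),
        ("U", rec[~bound]),
    ):
        for x, y, z in pts:
            fh.write(f"{tag} {x:.6f} {y:.6f} {z:.6f}\n")


def write_xyz_trajectory(path: str | Path, states: Iterable) -> None:
    """Write a sequence of states as a multi-frame XYZ file."""
    with open(path, "w") as fh:
        for state in states:
            write_xyz_frame(fh, state)
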