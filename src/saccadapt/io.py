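"""Serialization of grids and population maps.

Maps are stored as compressed binary arrays (``.npz``) with a JSON sidecar
recording the grid geometry and provenance, and can be exported to tidy CSV
``(x, y, value)`` for inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grid import FieldGrid, PopulationMap

__all__ = ["save_map", "load_map", "map_to_csv"]


def save_map(pop: PopulationMap, path: str | Path, provenance: str = "") -> None:
    path = Path(path)
    np.savez_compressed(path, activity=pop.activity)
    sidecar = {
        "half_extent": pop.grid.half_extent,
        "step": pop.grid.step,
        "package": "saccadapt",
        "version": __version__,
        "provenance": provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_map(path: str | Path) -> PopulationMap:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    grid = FieldGrid(sidecar["half_extent"], sidecar["step"])
    with np.load(path) as data:
        return PopulationMap(data["activity"], grid)


def map_to_csv(pop: PopulationMap, path: str | Path) -> None:
    X, Y = pop.grid.mesh()
    pd.DataFrame(
        {"x": X.ravel(), "y": Y.ravel(), "value": pop.activity.ravel()}
    ).to_csv(path, index=False)
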