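"""Small deterministic fixtures for tests and documentation.

All fixtures are generated programmatically (nothing shipped on disk):
a 30-cell hand-checkable table, a two-blob segregated tissue, scaled-down
self-/cross-preference cohort pairs, and one cluster-infiltration image.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cell_table import CellTable, write_cells
from .simulate import (
    ClusterSpec,
    InfiltrationParams,
    SimParams,
    cohort_to_table,
    make_scaffolds,
    preset_spec,
    simulate_cohort,
    simulate_infiltration,
)

#: scaled-down simulator settings used by fixtures (small field -> fast)
SMALL_SIM = SimParams(f=400.0, t=200.0, iterations=100, swaps=30)


def thirty_cell_table(seed: int = 7) -> CellTable:
    """30 random cells, 3 types, one image; hand-checkable size."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 100, size=(30, 2))
    types = rng.choice(["A", "B", "C"], size=30)
    return CellTable(pd.DataFrame({
        "cell_id": np.arange(30), "x": pts[:, 0], "y": pts[:, 1],
        "cell_type": types, "image_id": "fix30",
    }))


def two_blob_tissue(n_per_blob: int = 200, seed: int = 5, gap: float = 60.0) -> CellTable:
    """Two spatially segregated Gaussian blobs of types A and B."""
    rng = np.random.default_rng(seed)
    a = rng.normal([0.0, 0.0], 10.0, size=(n_per_blob, 2))
    b = rng.normal([gap, 0.0], 10.0, size=(n_per_blob, 2))
    pts = np.vstack([a, b])
    return CellTable(pd.DataFrame({
        "cell_id": np.arange(len(pts)), "x": pts[:, 0], "y": pts[:, 1],
        "cell_type": ["A"] * n_per_blob + ["B"] * n_per_blob,
        "image_id": "blobs",
    }))


def infiltrated_blob_tissue(seed: int = 9, n_b: int = 260, n_a: int = 40) -> CellTable:
    """A blob of type B with a few infiltrating A cells scattered inside:
    the canonical asymmetric fixture (every A sits among B, but most B
    never touch an A)."""
    rng = np.random.default_rng(seed)
    b = rng.uniform(0, 100, size=(n_b, 2))
    a = rng.uniform(30, 70, size=(n_a, 2))
    pts = np.vstack([b, a])
    return CellTable(pd.DataFrame({
        "cell_id": np.arange(len(pts)), "x": pts[:, 0], "y": pts[:, 1],
        "cell_type": ["B"] * n_b + ["A"] * n_a,
        "image_id": "infil",
    }))


def mini_cohort_pair(kind: str, levels=("random", "strong"), n_images: int = 12,
                     seed: int = 0, params: SimParams = SMALL_SIM):
    """Scaled-down cohort pair on shared scaffolds; returns
    {level: list[SimulatedTissue]}."""
    scaffolds = make_scaffolds(n_images, params, seed)
    return {
        level: simulate_cohort(
            preset_spec(kind, level), n_images, params, seed, scaffolds=scaffolds
        )
        for level in levels
    }


def small_infiltration_image(seed: int = 3) -> CellTable:
    """Down-scaled scenario-II-style image (fast to pack)."""
    params = InfiltrationParams(
        width=800.0, height=800.0, n_background=900, min_d=10.0,
        clusters=(
            ClusterSpec("purple", 120, (250.0, 250.0), semi_axes=(180.0, 120.0),
                        infiltration=0.3, infiltrating_type="green"),
            ClusterSpec("green", 110, (560.0, 560.0), semi_axes=(180.0, 120.0)),
        ),
    )
    return simulate_infiltration(params, seed, image_id="mini_scenarioII")


def write_fixture_set(outdir: Path, seed: int = 0) -> dict:
    """Write the full fixture set as CSV files; returns a manifest of
    file -> cell count."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}

    def _put(name: str, table: CellTable):
        path = outdir / name
        write_cells(table, path)
        manifest[name] = table.n_cells

    _put("thirty_cells.csv", thirty_cell_table(seed + 7))
    _put("two_blobs.csv", two_blob_tissue(seed=seed + 5))
    _put("infiltrated_blob.csv", infiltrated_blob_tissue(seed=seed + 9))
    for kind in ("self", "cross"):
        cohorts = mini_cohort_pair(kind, n_images=6, seed=seed)
        for level, tissues in cohorts.items():
            _put(f"{kind}_{level}.csv", cohort_to_table(tissues))
    _put("mini_scenarioII.csv", small_infiltration_image(seed + 3))
    return manifest
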