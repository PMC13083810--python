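"""Cell tables and score tables: the shared data model and its I/O.

A *cell table* is the universal input: one row per cell with 2-D
coordinates, a categorical cell-type label and an image (sample)
identifier.  Coordinates are unitless reals; the unit (pixels vs µm) is
metadata only, and every graph parameter (e.g. a radius ``r``) is
expressed in the same unit as the coordinates.

Score tables are long-format: one row per (image, ordered type pair,
score name).  Non-directional scores (CPscore) are stored once per
unordered pair with ``index_type <= neighbor_type``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, SchemaError, ValidationError

#: canonical column names of a cell table
CELL_COLUMNS = ("cell_id", "x", "y", "cell_type", "image_id")

#: the score family a run may emit
SCORE_NAMES = ("cozi_z", "total_z", "sigval_classic", "sigval_histocat", "cpscore")

#: canonical column order of a long-format score table
SCORE_COLUMNS = (
    "image_id",
    "index_type",
    "neighbor_type",
    "score_name",
    "score_value",
    "ccr",
    "n_perm",
    "seed",
    "n_cells",
)


@dataclass
class CellTable:
    """Validated per-cell table plus its declared cell-type label set.

    The label set defines K, the number of types every K×K score matrix
    is indexed by; it may contain types absent from individual images.
    """

    df: pd.DataFrame
    label_set: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        df = self.df
        missing = [c for c in CELL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"cell table is missing column(s): {', '.join(missing)}")
        if len(df) == 0:
            raise EmptyInputError("cell table contains no cells")
        df = df.loc[:, list(CELL_COLUMNS)].copy()
        df["x"] = pd.to_numeric(df["x"], errors="coerce")
        df["y"] = pd.to_numeric(df["y"], errors="coerce")
        bad = df.index[~(np.isfinite(df["x"]) & np.isfinite(df["y"]))]
        if len(bad):
            raise ValidationError(
                f"non-finite coordinates in row(s) {list(bad[:10])}", rows=bad
            )
        df["cell_type"] = df["cell_type"].astype(str)
        df["image_id"] = df["image_id"].astype(str)
        dup = df.duplicated(subset=["image_id", "cell_id"])
        if dup.any():
            raise ValidationError(
                f"duplicate cell_id within an image at row(s) {list(df.index[dup][:10])}",
                rows=df.index[dup],
            )
        observed = tuple(sorted(df["cell_type"].unique()))
        if self.label_set is None:
            self.label_set = observed
        else:
            self.label_set = tuple(str(t) for t in self.label_set)
            unknown = set(observed) - set(self.label_set)
            if unknown:
                raise ValidationError(
                    f"cell types not in declared label set: {sorted(unknown)}"
                )
        self.df = df

    @property
    def n_cells(self) -> int:
        return len(self.df)

    @property
    def k_types(self) -> int:
        return len(self.label_set)

    def image_ids(self) -> list[str]:
        """Image identifiers in first-appearance order."""
        return list(dict.fromkeys(self.df["image_id"]))

    def image(self, image_id: str) -> "CellTable":
        """Sub-table of one image, keeping the full label set."""
        sub = self.df[self.df["image_id"] == str(image_id)]
        if len(sub) == 0:
            raise EmptyInputError(f"no cells for image {image_id!r}")
        return CellTable(sub.reset_index(drop=True), label_set=self.label_set)

    def coordinates(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        """Integer-coded cell types, indexing into ``label_set``."""
        lut = {t: i for i, t in enumerate(self.label_set)}
        return self.df["cell_type"].map(lut).to_numpy(dtype=np.intp)

    def drop_label(self, token: str) -> "CellTable":
        """Remove cells carrying an exclusion token (e.g. ``"exclude"``)."""
        keep = self.df["cell_type"] != token
        labels = tuple(t for t in self.label_set if t != token)
        return CellTable(self.df[keep].reset_index(drop=True), label_set=labels)


def _sniff_delimiter(path) -> str:
    with open(path, "r", newline="") as fh:
        sample = fh.read(8192)
    if not sample.strip():
        raise EmptyInputError(f"{path}: file is empty")
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_cells(
    path,
    column_map: dict | None = None,
    delimiter: str | None = None,
    label_set=None,
) -> CellTable:
    """Read a delimited-text cell table.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    column_map
        Mapping from canonical names (``x``, ``y``, ``cell_type``,
        ``image_id``, ``cell_id``) to the file's column names.  Unmapped
        names default to themselves.  ``cell_id`` and ``image_id`` are
        synthesized (row number / ``"image0"``) when absent.
    delimiter
        Field delimiter; auto-detected when ``None``.
    label_set
        Declared cell-type universe; inferred from the data when ``None``.
    """
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    column_map = dict(column_map or {})
    rename = {}
    for canonical in CELL_COLUMNS:
        src = column_map.get(canonical, canonical)
        if src in df.columns:
            rename[src] = canonical
        elif canonical == "cell_id":
            df["cell_id"] = np.arange(len(df))
        elif canonical == "image_id":
            df["image_id"] = "image0"
        else:
            raise SchemaError(
                f"{path}: required column {src!r} (for {canonical!r}) not found; "
                f"available: {list(df.columns)}"
            )
    df = df.rename(columns=rename)
    return CellTable(df, label_set=label_set)


def write_cells(table: CellTable, path) -> None:
    """Write a cell table as CSV (inverse of :func:`read_cells`)."""
    table.df.to_csv(path, index=False)


def empty_scores() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        SCORE_COLUMNS,
        [str, str, str, str, float, float, int, int, int],
    )})


def sort_scores(scores: pd.DataFrame) -> pd.DataFrame:
    return scores.sort_values(
        ["image_id", "index_type", "neighbor_type", "score_name"],
        kind="mergesort",
    ).reset_index(drop=True)


def write_scores(scores: pd.DataFrame, path) -> None:
    """Write a long-format score table as CSV in deterministic row order.

    Floats are serialized with repr-level fidelity so a write/read round
    trip is bit-stable.
    """
    out = scores.loc[:, list(SCORE_COLUMNS)]
    sort_scores(out).to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    """Read a score table written by :func:`write_scores`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"score table missing column(s): {missing}")
    bad_sig = df["score_name"].str.startswith("sigval") & ~df["score_value"].isin(
        [-1.0, 0.0, 1.0]
    )
    if bad_sig.any():
        raise ValidationError("sigval values must be in {-1, 0, 1}", rows=df.index[bad_sig])
    ccr = df["ccr"].dropna()
    if ((ccr < 0) | (ccr > 1)).any():
        raise ValidationError("ccr outside [0, 1]")
    return df
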