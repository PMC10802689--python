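"""Localization-table I/O.

The pipeline's lingua franca is a flat table of 2D single-molecule
localizations with fixed columns and units (nanometres, milliseconds):

    x_nm, y_nm, t_ms, frame, traj_id, photons, precision_nm

``x_nm`` is the axial coordinate along the nucleocytoplasmic transport axis
(negative = cytoplasmic side), ``y_nm`` the transverse coordinate.  Tables
are exchanged as tab-delimited text with a header row.
"""

from __future__ import annotations

import pandas as pd

TABLE_COLUMNS = ["x_nm", "y_nm", "t_ms", "frame", "traj_id", "photons", "precision_nm"]


def empty_table() -> pd.DataFrame:
    """Return an empty localization table with the canonical columns."""
    return pd.DataFrame(
        {
            "x_nm": pd.Series(dtype=float),
            "y_nm": pd.Series(dtype=float),
            "t_ms": pd.Series(dtype=float),
            "frame": pd.Series(dtype=int),
            "traj_id": pd.Series(dtype=object),
            "photons": pd.Series(dtype=float),
            "precision_nm": pd.Series(dtype=float),
        }
    )


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the canonical column set and per-trajectory frame ordering.

    Raises ``ValueError`` on missing columns, non-increasing frames within a
    trajectory, or non-positive precisions; returns the table unchanged.
    """
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"localization table missing columns: {missing}")
    if len(table):
        for tid, grp in table.groupby("traj_id", sort=False):
            frames = grp["frame"].to_numpy()
            if len(frames) > 1 and not (frames[1:] > frames[:-1]).all():
                raise ValueError(f"frames not strictly increasing in trajectory {tid!r}")
        prec = table["precision_nm"]
        if (prec.dropna() <= 0).any():
            raise ValueError("precision_nm must be positive where present")
    return table


def read_table(path) -> pd.DataFrame:
    """Read a tab-delimited localization table, validating its structure."""
    table = pd.read_csv(path, sep="\t", comment="#")
    return validate_table(table)


def write_table(table: pd.DataFrame, path) -> None:
    """Write a localization table as tab-delimited text with a header row."""
    validate_table(table)
    table.to_csv(path, sep="\t", index=False, columns=TABLE_COLUMNS)
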