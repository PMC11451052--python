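"""Localization-table container and file I/O.

A localization table holds the super-resolved coordinates of one imaging
round (one target protein): x/y in nanometers, the camera frame each blink
was detected in, an optional per-localization precision, and -- for
simulated data only -- a provenance flag saying whether the row came from a
labeled site, a false positive, or carryover from an incompletely erased
previous round.

Two on-disk dialects are supported and round-trip losslessly:

* ``csv`` -- comma-separated with a header row; columns ``x_nm``, ``y_nm``,
  ``frame`` and, when present, ``precision_nm`` and ``origin_flag``.
* ``hdf5`` -- one group per channel under ``/channels/<target_id>``, with one
  dataset per column, same names as the CSV dialect.

Coordinates may be stored in camera pixels; pass ``unit="pixel"`` together
with the effective pixel size (108 nm for the instrument emulated here) to
convert on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "LocalizationTable",
    "SchemaError",
    "read_localizations",
    "write_localizations",
    "read_dataset",
    "write_dataset",
]

#: flag values allowed in the provenance column of simulated tables
ORIGIN_FLAGS = ("true_site", "false_positive", "carryover")

_CORE_COLUMNS = ("x_nm", "y_nm", "frame")
_OPTIONAL_COLUMNS = ("precision_nm", "origin_flag")


class SchemaError(ValueError):
    """An input table is missing a required column or violates an invariant."""


@dataclass
class LocalizationTable:
    """Localizations of one channel (one imaging round / one target).

    Parameters
    ----------
    data:
        Frame with columns ``x_nm``, ``y_nm``, ``frame`` and optionally
        ``precision_nm`` and ``origin_flag``.
    channel:
        Target identifier (e.g. ``"GM130"``).
    round_index:
        Zero-based position of this channel in the acquisition sequence.
    """

    data: pd.DataFrame
    channel: str = ""
    round_index: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in _CORE_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"localization table missing column(s): {', '.join(missing)}")
        xy = self.data[["x_nm", "y_nm"]].to_numpy(float)
        if xy.size and not np.isfinite(xy).all():
            raise SchemaError("localization coordinates must be finite")
        frames = self.data["frame"].to_numpy()
        if frames.size and (frames < 0).any():
            raise SchemaError("frame indices must be non-negative")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) float array of coordinates in nm."""
        return self.data[["x_nm", "y_nm"]].to_numpy(float)

    def translated(self, dx: float, dy: float) -> "LocalizationTable":
        """Return a copy rigidly shifted by (dx, dy) nm."""
        data = self.data.copy()
        data["x_nm"] = data["x_nm"] + dx
        data["y_nm"] = data["y_nm"] + dy
        return LocalizationTable(data, channel=self.channel, round_index=self.round_index)

    def copy(self) -> "LocalizationTable":
        return LocalizationTable(self.data.copy(), self.channel, self.round_index)

    @classmethod
    def from_arrays(
        cls,
        x_nm: Iterable[float],
        y_nm: Iterable[float],
        frame: Iterable[int] | None = None,
        precision_nm: Iterable[float] | None = None,
        origin_flag: Iterable[str] | None = None,
        channel: str = "",
        round_index: int = 0,
    ) -> "LocalizationTable":
        x = np.asarray(list(x_nm), float)
        y = np.asarray(list(y_nm), float)
        cols: dict = {
            "x_nm": x,
            "y_nm": y,
            "frame": np.zeros(len(x), dtype=np.int64)
            if frame is None
            else np.asarray(list(frame), np.int64),
        }
        if precision_nm is not None:
            cols["precision_nm"] = np.asarray(list(precision_nm), float)
        if origin_flag is not None:
            cols["origin_flag"] = np.asarray(list(origin_flag), object)
        return cls(pd.DataFrame(cols), channel=channel, round_index=round_index)


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    if path.suffix.lower() in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    return "csv"


def _finalize_frame(
    df: pd.DataFrame,
    unit: str,
    pixel_size: float | None,
    column_map: Mapping[str, str] | None,
) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns=dict(column_map))
    # tolerate bare x/y headers from foreign tables
    for bare, canon in (("x", "x_nm"), ("y", "y_nm")):
        if canon not in df.columns and bare in df.columns:
            df = df.rename(columns={bare: canon})
    for col in ("x_nm", "y_nm"):
        if col not in df.columns:
            raise SchemaError(f"input table lacks required column '{col}'")
    if unit == "pixel":
        if pixel_size is None or pixel_size <= 0:
            raise ValueError("pixel-unit input requires a positive pixel_size (nm)")
        df = df.copy()
        df["x_nm"] = df["x_nm"] * pixel_size
        df["y_nm"] = df["y_nm"] * pixel_size
        if "precision_nm" in df.columns:
            df["precision_nm"] = df["precision_nm"] * pixel_size
    elif unit != "nm":
        raise ValueError(f"unknown unit '{unit}' (expected 'nm' or 'pixel')")
    if "frame" not in df.columns:
        df = df.assign(frame=np.int64(0))
    df["frame"] = df["frame"].astype(np.int64)
    keep = [c for c in (*_CORE_COLUMNS, *_OPTIONAL_COLUMNS) if c in df.columns]
    return df[keep].reset_index(drop=True)


def read_localizations(
    path: str | Path,
    dialect: str | None = None,
    unit: str = "nm",
    pixel_size: float | None = None,
    channel: str | None = None,
    round_index: int = 0,
    column_map: Mapping[str, str] | None = None,
) -> LocalizationTable:
    """Read one channel's localization table from disk.

    For the HDF5 dialect ``channel`` selects the group under ``/channels``;
    it may be omitted when the file holds exactly one channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dia = _infer_dialect(path, dialect)
    if dia == "csv":
        df = pd.read_csv(path)
        df = _finalize_frame(df, unit, pixel_size, column_map)
        return LocalizationTable(df, channel=channel or path.stem, round_index=round_index)
    if dia == "hdf5":
        with h5py.File(path, "r") as fh:
            group = fh["channels"]
            names = list(group.keys())
            if channel is None:
                if len(names) != 1:
                    raise ValueError(
                        f"file holds channels {names}; pass channel= to select one"
                    )
                channel = names[0]
            if channel not in group:
                raise KeyError(f"channel '{channel}' not in file (has {names})")
            df = _read_h5_group(group[channel])
        df = _finalize_frame(df, unit, pixel_size, column_map)
        return LocalizationTable(df, channel=channel, round_index=round_index)
    raise ValueError(f"unknown dialect '{dia}'")


def _read_h5_group(grp: h5py.Group) -> pd.DataFrame:
    cols = {}
    for name in grp:
        arr = grp[name][()]
        if arr.dtype.kind in ("S", "O"):
            arr = np.asarray([v.decode() if isinstance(v, bytes) else v for v in arr], object)
        cols[name] = arr
    return pd.DataFrame(cols)


def write_localizations(
    table: LocalizationTable, path: str | Path, dialect: str | None = None
) -> Path:
    """Write one channel to disk; see :func:`read_localizations` for dialects."""
    path = Path(path)
    dia = _infer_dialect(path, dialect)
    if dia == "csv":
        table.data.to_csv(path, index=False)
    elif dia == "hdf5":
        with h5py.File(path, "w") as fh:
            _write_h5_group(fh.require_group("channels"), table)
    else:
        raise ValueError(f"unknown dialect '{dia}'")
    return path


def _write_h5_group(channels: h5py.Group, table: LocalizationTable) -> None:
    name = table.channel or "channel"
    if name in channels:
        del channels[name]
    grp = channels.create_group(name)
    grp.attrs["round_index"] = table.round_index
    for col in table.data.columns:
        values = table.data[col].to_numpy()
        if values.dtype.kind == "O":
            values = np.asarray([str(v).encode() for v in values])
        grp.create_dataset(col, data=values)


def write_dataset(
    dataset: Mapping[str, LocalizationTable], path: str | Path, dialect: str | None = None
) -> Path:
    """Write a multi-channel dataset.

    CSV dialect writes one ``<target_id>.csv`` per channel into the directory
    ``path``; HDF5 writes all channels into one file.
    """
    path = Path(path)
    dia = _infer_dialect(path, dialect)
    if dia == "csv":
        path.mkdir(parents=True, exist_ok=True)
        for name, table in dataset.items():
            table.data.to_csv(path / f"{name}.csv", index=False)
    elif dia == "hdf5":
        with h5py.File(path, "w") as fh:
            grp = fh.require_group("channels")
            for table in dataset.values():
                _write_h5_group(grp, table)
    else:
        raise ValueError(f"unknown dialect '{dia}'")
    return path


def read_dataset(
    path: str | Path,
    dialect: str | None = None,
    unit: str = "nm",
    pixel_size: float | None = None,
    column_map: Mapping[str, str] | None = None,
    round_order: Iterable[str] | None = None,
) -> dict[str, LocalizationTable]:
    """Read a multi-channel dataset written by :func:`write_dataset`.

    ``round_order`` fixes the channel ordering (and round indices); by
    default channels are ordered by name (CSV) or file order (HDF5).
    """
    path = Path(path)
    tables: dict[str, LocalizationTable] = {}
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise FileNotFoundError(f"no .csv channel tables in {path}")
        for f in files:
            tables[f.stem] = read_localizations(
                f, "csv", unit=unit, pixel_size=pixel_size, column_map=column_map
            )
    else:
        dia = _infer_dialect(path, dialect)
        if dia != "hdf5":
            table = read_localizations(
                path, dia, unit=unit, pixel_size=pixel_size, column_map=column_map
            )
            tables[table.channel] = table
        else:
            with h5py.File(path, "r") as fh:
                for name in fh["channels"]:
                    df = _read_h5_group(fh["channels"][name])
                    df = _finalize_frame(df, unit, pixel_size, column_map)
                    tables[name] = LocalizationTable(df, channel=name)
    order = list(round_order) if round_order is not None else list(tables)
    missing = [c for c in order if c not in tables]
    if missing:
        raise KeyError(f"round_order names channels absent from data: {missing}")
    out: dict[str, LocalizationTable] = {}
    for i, name in enumerate(order):
        t = tables[name]
        out[name] = LocalizationTable(t.data, channel=name, round_index=i)
    return out
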