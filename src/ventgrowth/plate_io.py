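"""Plate-table IO and blank subtraction.

The on-disk plate table is long-format CSV, one row per (well, day):

    well_id, organism, salinity, pH, temperature, replicate, role, day, od630

``role`` is "inoculated" or "control".  The rate table produced by the
fitting stage is CSV with columns

    organism, salinity, pH, temperature, replicate,
    a, k, d, xc, rate, growth_flag, fit_ok, rss

Both formats are comma-separated, header row, UTF-8, full-precision
floats, no missing values (wells without a usable fit store 0.0 for the
curve parameters with fit_ok = False).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PLATE_COLUMNS = [
    "well_id", "organism", "salinity", "pH", "temperature",
    "replicate", "role", "day", "od630",
]
RATE_COLUMNS = [
    "organism", "salinity", "pH", "temperature", "replicate",
    "a", "k", "d", "xc", "rate", "growth_flag", "fit_ok", "rss",
]


class PlateParseError(ValueError):
    """Raised for malformed plate tables."""


class PairingError(ValueError):
    """Raised when an inoculated well cannot be matched to controls."""


@dataclass(frozen=True)
class WellSeries:
    """One well's daily OD readings plus its factor labels."""

    well_id: str
    organism: str
    salinity: float
    ph: float
    temperature: float
    replicate: int
    role: str                 # inoculated | control | blank_subtracted
    times: np.ndarray         # days, strictly increasing
    od: np.ndarray            # OD630, same length as times

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise PlateParseError(
                f"well {self.well_id}: times and od must be equal-length 1-d"
            )
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise PlateParseError(f"well {self.well_id}: times not strictly increasing")
        if not np.all(np.isfinite(y)):
            raise PlateParseError(f"well {self.well_id}: non-finite OD values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", y)

    @property
    def treatment(self) -> tuple[float, float, float]:
        return (self.salinity, self.ph, self.temperature)


def wells_to_frame(wells: Iterable[WellSeries]) -> pd.DataFrame:
    """Flatten a collection of series into the long plate table."""
    records = []
    for w in wells:
        for day, od in zip(w.times, w.od):
            records.append(
                (w.well_id, w.organism, w.salinity, w.ph, w.temperature,
                 w.replicate, w.role, day, od)
            )
    return pd.DataFrame(records, columns=PLATE_COLUMNS)


def write_plate_table(wells: Iterable[WellSeries], sink) -> None:
    # %.17g guarantees exact float round-trips through the text format
    wells_to_frame(wells).to_csv(sink, index=False, float_format="%.17g")


def read_plate_table(source) -> list[WellSeries]:
    """Read a long-format plate CSV into validated per-well series.

    Rows within a well are sorted by day.  Raises
    :class:`PlateParseError` on a missing column, a duplicated
    (well, day) pair, or a non-numeric OD value, naming the offender.
    """
    df = pd.read_csv(source, float_precision="round_trip")
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateParseError(f"missing column(s): {', '.join(missing)}")
    dup = df.duplicated(subset=["well_id", "day"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise PlateParseError(
            f"duplicate (well, day) pair: ({row['well_id']}, {row['day']})"
        )
    for col in ("salinity", "pH", "temperature", "day", "od630"):
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any() and not df[col].isna().any():
            bad = df.loc[converted.isna()].index[0]
            raise PlateParseError(f"non-numeric value in {col} at row {bad}")
        if converted.isna().any():
            raise PlateParseError(f"missing value in {col}")
        df[col] = converted

    wells: list[WellSeries] = []
    for well_id, grp in df.groupby("well_id", sort=False):
        grp = grp.sort_values("day")
        first = grp.iloc[0]
        wells.append(
            WellSeries(
                well_id=str(well_id),
                organism=str(first["organism"]),
                salinity=float(first["salinity"]),
                ph=float(first["pH"]),
                temperature=float(first["temperature"]),
                replicate=int(first["replicate"]),
                role=str(first["role"]),
                times=grp["day"].to_numpy(dtype=float),
                od=grp["od630"].to_numpy(dtype=float),
            )
        )
    return wells


def blank_subtract(
    inoculated: WellSeries, controls: Sequence[WellSeries]
) -> WellSeries:
    """Subtract the per-day mean control OD from an inoculated well.

    Controls must share the well's (salinity, pH, temperature) treatment
    and time grid; the organism label is ignored, so one control set per
    treatment serves every organism.  Negative values are retained:
    clamping at zero would bias early-time noise upward before fitting.
    """
    matching = [
        c for c in controls
        if c.role == "control" and c.treatment == inoculated.treatment
    ]
    if not matching:
        raise PairingError(
            f"no control wells for treatment {inoculated.treatment}"
        )
    for c in matching:
        if len(c.times) != len(inoculated.times) or not np.array_equal(
            c.times, inoculated.times
        ):
            raise PairingError(
                f"control {c.well_id} time grid does not match {inoculated.well_id}"
            )
    mean_control = np.mean([c.od for c in matching], axis=0)
    return replace(
        inoculated,
        role="blank_subtracted",
        od=inoculated.od - mean_control,
    )


def write_rate_table(table: pd.DataFrame, sink) -> None:
    """Write a growth-rate table as CSV with a stable column order."""
    missing = [c for c in RATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"rate table missing column(s): {', '.join(missing)}")
    table[RATE_COLUMNS].to_csv(sink, index=False, float_format="%.17g")


def read_rate_table(source) -> pd.DataFrame:
    df = pd.read_csv(source, float_precision="round_trip")
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rate table missing column(s): {', '.join(missing)}")
    for col in ("salinity", "pH", "temperature", "a", "k", "d", "xc", "rate", "rss"):
        df[col] = df[col].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    df["growth_flag"] = df["growth_flag"].astype(bool)
    df["fit_ok"] = df["fit_ok"].astype(bool)
    return df
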