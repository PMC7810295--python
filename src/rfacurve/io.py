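"""Reading RFA equipment logs and cohort tables; writing result tables.

RFA generators log one row per sample with time ``t`` [s], voltage ``V``
[V], current ``I`` [mA] and power ``P`` [W] in delimited text.  The
impedance channel ``Z`` [ohm] is either logged directly or derived from
Ohm's law, ``Z = V / (I * 1e-3)`` for current in milliamps.

Column names vary between machines, so :func:`read_rfa_log` accepts an
explicit column map and otherwise matches common aliases
case-insensitively.  Rows with missing values, non-positive current or
negative voltage are dropped (generator cut-out artifacts) and counted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ValidationError
from .reference import GROUP_FACTORS

__all__ = [
    "ImpedanceCurve",
    "CohortTable",
    "read_rfa_log",
    "read_cohort_table",
    "write_results",
    "read_results",
]

# Case-insensitive aliases for each logical channel.
_CHANNEL_ALIASES: dict[str, tuple[str, ...]] = {
    "t": ("t", "time", "time_s", "t_s", "tempo", "seconds"),
    "V": ("v", "voltage", "volt", "tensao", "v_v"),
    "I": ("i", "current", "corrente", "i_ma", "current_ma"),
    "P": ("p", "power", "potencia", "p_w", "watts"),
    "Z": ("z", "impedance", "imp", "impedancia", "z_ohm", "ohms"),
}


@dataclass
class ImpedanceCurve:
    """One ablation's impedance time series with optional raw channels.

    Times are stored as seconds from the start of the log: if the first
    timestamp of the source is nonzero the whole series is shifted so that
    ``t[0] == 0`` (every landmark time is a duration).
    """

    sample_id: str
    t: np.ndarray
    Z: np.ndarray
    V: np.ndarray | None = None
    I: np.ndarray | None = None
    P: np.ndarray | None = None
    source_path: str = ""
    dropped_rows: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        for ch in ("V", "I", "P"):
            v = getattr(self, ch)
            if v is not None:
                setattr(self, ch, np.asarray(v, dtype=float))
        if self.t.ndim != 1 or self.t.shape != self.Z.shape:
            raise DataError("t and Z must be 1-D arrays of equal length")
        if len(self.t) < 3:
            raise DataError(
                f"curve {self.sample_id!r}: need at least 3 samples, got {len(self.t)}"
            )
        if np.any(np.diff(self.t) <= 0):
            raise DataError(f"curve {self.sample_id!r}: time not strictly increasing")
        if self.t[0] != 0.0:
            self.t = self.t - self.t[0]
        if np.any(self.Z <= 0):
            raise DataError(f"curve {self.sample_id!r}: non-positive impedance present")
        if self.V is not None and self.I is not None:
            derived = self.V / (self.I * 1e-3)
            if not np.allclose(self.Z, derived, rtol=1e-9, atol=0.0):
                raise DataError(
                    f"curve {self.sample_id!r}: Z inconsistent with V / (I * 1e-3)"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1])


@dataclass
class CohortTable:
    """Sample -> (group, factor levels, ablation volume) mapping.

    Wraps a DataFrame with columns ``sample_id``, ``group``, ``solution``,
    ``temperature`` and ``volume`` (cm^3, NaN when not measured).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = {"sample_id", "group"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
        df["sample_id"] = df["sample_id"].astype(str)
        df["group"] = df["group"].astype(str).str.upper().str.strip()
        unknown = sorted(set(df["group"]) - set(GROUP_FACTORS))
        if unknown:
            raise ValidationError(
                f"unknown group labels {unknown}; allowed: {sorted(GROUP_FACTORS)}"
            )
        dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
        if dupes:
            raise ValidationError(f"duplicate sample_id values: {sorted(set(dupes))}")
        factors = df["group"].map(GROUP_FACTORS)
        derived_sol = factors.str[0]
        derived_temp = factors.str[1]
        for col, derived in (("solution", derived_sol), ("temperature", derived_temp)):
            if col in df.columns:
                given = df[col].astype(str).str.lower().str.strip()
                bad = df.loc[given != derived, "sample_id"].tolist()
                if bad:
                    raise ValidationError(
                        f"{col} inconsistent with group for samples {bad}"
                    )
            df[col] = derived
        if "volume" in df.columns:
            df["volume"] = pd.to_numeric(df["volume"], errors="coerce")
            if (df["volume"].dropna() < 0).any():
                raise ValidationError("negative ablation volume")
        else:
            df["volume"] = np.nan
        self.data = df[["sample_id", "group", "solution", "temperature", "volume"]]

    def __len__(self) -> int:
        return len(self.data)

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())


def _resolve_columns(
    columns: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map logical channel names to actual column names; explicit map wins."""
    lowered = {str(c).lower().strip(): c for c in columns}
    resolved: dict[str, str] = {}
    if column_map:
        for channel, name in column_map.items():
            if channel not in _CHANNEL_ALIASES:
                raise FormatError(f"unknown channel {channel!r} in column map")
            if name not in columns:
                raise FormatError(f"mapped column {name!r} not found in file")
            resolved[channel] = name
    for channel, aliases in _CHANNEL_ALIASES.items():
        if channel in resolved:
            continue
        for alias in aliases:
            if alias in lowered:
                resolved[channel] = lowered[alias]
                break
    return resolved


def read_rfa_log(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    current_unit: str = "mA",
    *,
    sample_id: str | None = None,
    delimiter: str = ",",
    decimal: str = ".",
) -> ImpedanceCurve:
    """Read one equipment log into a validated :class:`ImpedanceCurve`.

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    column_map:
        Optional mapping from logical channels (``t``, ``V``, ``I``, ``P``,
        ``Z``) to column names in the file; unmapped channels are matched
        by common aliases.
    current_unit:
        ``"mA"`` (equipment default) or ``"A"``; controls the Ohm's-law
        conversion when the impedance channel has to be derived.
    delimiter, decimal:
        CSV dialect.  Brazilian exports often use ``;`` with ``,`` decimals.
    """
    path = Path(path)
    if current_unit not in ("mA", "A"):
        raise ValueError("current_unit must be 'mA' or 'A'")
    if not path.exists():
        raise FormatError(f"log file not found: {path}")
    df = pd.read_csv(path, sep=delimiter, decimal=decimal)
    cols = _resolve_columns(df.columns, column_map)
    if "t" not in cols:
        raise FormatError(f"{path.name}: no time column found among {list(df.columns)}")
    has_z = "Z" in cols
    has_vi = "V" in cols and "I" in cols
    if not has_z and not has_vi:
        raise FormatError(
            f"{path.name}: need either an impedance column or both voltage "
            f"and current columns; found {list(df.columns)}"
        )

    use = {ch: cols[ch] for ch in cols}
    frame = pd.DataFrame(
        {ch: pd.to_numeric(df[name], errors="coerce") for ch, name in use.items()}
    )
    n_raw = len(frame)
    needed = ["t"] + (["Z"] if has_z else []) + (["V", "I"] if has_vi else [])
    valid = frame[needed].notna().all(axis=1)
    valid &= frame["t"].notna() & (frame["t"] >= 0)
    if has_vi:
        valid &= (frame["I"] > 0) & (frame["V"] >= 0)
    if has_z:
        valid &= frame["Z"] > 0
    frame = frame[valid]
    dropped = n_raw - len(frame)
    if len(frame) < 3:
        raise DataError(f"{path.name}: fewer than 3 valid rows after cleaning")
    if np.any(np.diff(frame["t"].to_numpy()) <= 0):
        raise DataError(f"{path.name}: time not strictly increasing after cleaning")

    if has_vi:
        current_ma = frame["I"].to_numpy()
        if current_unit == "A":
            current_ma = current_ma * 1e3
    if has_z:
        z = frame["Z"].to_numpy()
    else:
        z = frame["V"].to_numpy() / (current_ma * 1e-3)

    return ImpedanceCurve(
        sample_id=sample_id if sample_id is not None else path.stem,
        t=frame["t"].to_numpy(),
        Z=z,
        V=frame["V"].to_numpy() if "V" in frame else None,
        I=current_ma if has_vi else None,
        P=frame["P"].to_numpy() if "P" in frame else None,
        source_path=str(path),
        dropped_rows=int(dropped),
    )


def read_cohort_table(path: str | Path, sheet: int | str = 0) -> CohortTable:
    """Read a cohort table from XLSX or delimited text.

    Factor levels are derived from the group label; the volume column is
    optional.  Column names are matched case-insensitively.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cohort table not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path)
    rename = {}
    for c in df.columns:
        key = str(c).lower().strip()
        if key in ("sample_id", "sample", "id", "amostra"):
            rename[c] = "sample_id"
        elif key in ("group", "grupo", "arm"):
            rename[c] = "group"
        elif key in ("solution", "solucao"):
            rename[c] = "solution"
        elif key in ("temperature", "temp", "temperatura"):
            rename[c] = "temperature"
        elif key in ("volume", "volume_cm3", "vol"):
            rename[c] = "volume"
    return CohortTable(df.rename(columns=rename))


def _record_to_dict(record) -> dict:
    if dataclasses.is_dataclass(record) and not isinstance(record, type):
        return dataclasses.asdict(record)
    if isinstance(record, Mapping):
        return dict(record)
    raise TypeError(f"cannot serialize record of type {type(record).__name__}")


def write_results(
    records: Iterable | pd.DataFrame, path: str | Path, format: str = "csv"
) -> Path:
    """Write result records (dataclasses, dicts or a DataFrame) losslessly.

    CSV floats are written with 17 significant digits so that a re-read
    reproduces every value bit-for-bit; JSON keeps native float precision.
    Empty record sets are an error, never an empty file.
    """
    path = Path(path)
    if format not in ("csv", "json"):
        raise ValueError("format must be 'csv' or 'json'")
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [_record_to_dict(r) for r in records]
        df = pd.DataFrame(rows)
    if df.empty:
        raise DataError("refusing to write an empty result set")
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1) + "\n")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path, float_precision="round_trip")
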