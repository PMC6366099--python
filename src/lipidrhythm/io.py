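"""Long-table schema, readers/writers, normalisation, imputation, stacking.

The canonical in-memory container is a tidy :class:`pandas.DataFrame` with
columns ``subject, group, time_h, analyte, value`` (one measurement per
row; missing measurements are rows with NaN value, never dropped rows).
Times are absolute hours since midnight of the admission day; samples
taken after midnight on day 2 are unwrapped into [24, 48) so that the
periodic kernel — not any data folding — handles circadian wrap-around.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("lipidrhythm")

__all__ = [
    "REQUIRED_COLUMNS",
    "LongTableError",
    "AnalyteSeries",
    "read_long_table",
    "write_long_table",
    "validate_long_table",
    "parse_time",
    "normalize",
    "impute_missing",
    "stack_series",
]

REQUIRED_COLUMNS = ("subject", "group", "time_h", "analyte", "value")

#: default mapping from canonical column names to file column names
DEFAULT_DIALECT = {c: c for c in REQUIRED_COLUMNS}


class LongTableError(ValueError):
    """Raised for schema violations in a long-format measurement table."""


@dataclass
class AnalyteSeries:
    """All observations of one analyte in one group, stacked across subjects.

    ``t``, ``y`` and ``subject_idx`` are aligned vectors ordered by
    (subject, time); ``subject_idx`` maps each observation to ``subjects``.
    """

    analyte: str
    group: str
    t: np.ndarray
    y: np.ndarray
    subject_idx: np.ndarray
    subjects: list = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def __len__(self) -> int:
        return self.t.size


def parse_time(value) -> float:
    """Parse a clock time as decimal hours; accepts ``HH:MM`` or numbers."""
    if isinstance(value, str) and ":" in value:
        hh, mm = value.split(":")
        return float(hh) + float(mm) / 60.0
    return float(value)


def _unwrap_times(hours: np.ndarray) -> np.ndarray:
    """Unwrap one midnight crossing: once the clock time decreases, add 24 h."""
    out = np.array(hours, dtype=float)
    offset = 0.0
    for i in range(1, out.size):
        if out[i] + offset < out[i - 1]:
            offset = 24.0
        out[i] += offset
    return out


def validate_long_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise LongTableError(f"missing required columns: {missing}")
    if not np.all(np.isfinite(table["time_h"].to_numpy(dtype=float))):
        raise LongTableError("non-finite time_h values")
    dup = table.duplicated(subset=["subject", "time_h", "analyte"])
    if dup.any():
        row = table.loc[dup.idxmax()]
        raise LongTableError(
            "duplicate (subject, time_h, analyte) key: "
            f"({row['subject']}, {row['time_h']}, {row['analyte']})"
        )
    n_groups = table.groupby("subject", observed=True)["group"].nunique()
    bad = n_groups[n_groups > 1]
    if len(bad):
        raise LongTableError(f"subject in multiple groups: {list(bad.index)}")
    return table


def read_long_table(path, dialect=None) -> pd.DataFrame:
    """Read and validate a tidy CSV/TSV of long-format measurements.

    Parameters
    ----------
    path : str or Path
        CSV (or TSV, by extension) file with one measurement per row.
    dialect : dict or str or Path, optional
        Mapping from canonical column names (``subject, group, time_h,
        analyte, value``) to the file's column names, or a path to a YAML
        file holding that mapping.

    Times may be given as ``HH:MM`` strings or decimal hours; within each
    (subject, analyte) trace, a clock time that does not increase is taken
    to lie after midnight and is unwrapped into [24, 48).
    """
    if dialect is None:
        dialect = DEFAULT_DIALECT
    elif not isinstance(dialect, dict):
        with open(dialect) as fh:
            dialect = {**DEFAULT_DIALECT, **(yaml.safe_load(fh) or {})}
    else:
        dialect = {**DEFAULT_DIALECT, **dialect}

    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep)
    missing = [v for v in dialect.values() if v not in raw.columns]
    if missing:
        raise LongTableError(f"{path}: missing columns {missing}")
    table = raw.rename(columns={v: k for k, v in dialect.items()})[list(REQUIRED_COLUMNS)]

    times = np.empty(len(table))
    for i, (row_no, v) in enumerate(table["time_h"].items()):
        try:
            times[i] = parse_time(v)
        except (TypeError, ValueError) as exc:
            raise LongTableError(f"{path}: unparseable time {v!r} at row {row_no}") from exc
    table = table.assign(time_h=times)
    table["time_h"] = (
        table.groupby(["subject", "analyte"], sort=False, observed=True)["time_h"]
        .transform(lambda s: _unwrap_times(s.to_numpy()))
    )
    table["value"] = pd.to_numeric(table["value"], errors="coerce")
    return validate_long_table(table.reset_index(drop=True))


def write_long_table(table: pd.DataFrame, path) -> None:
    """Write a long table as tidy CSV (round-trips bit-identically)."""
    cols = [c for c in table.columns if c in REQUIRED_COLUMNS + ("imputed",)]
    table[cols].to_csv(path, index=False)


def normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Centre and scale every (subject, analyte) stratum to mean 0, SD 1.

    The sample SD uses the n-1 denominator and is computed over observed
    (non-missing) values only; missing cells are untouched.  Strata with
    zero variance cannot be normalised: their rows are excluded from the
    returned table (a warning is logged and the dropped strata are listed
    in ``table.attrs["excluded_strata"]``).  Idempotent on observed cells.
    """
    table = table.copy()
    excluded = []
    grouped = table.groupby(["subject", "analyte"], observed=True)["value"]
    mean = grouped.transform("mean")
    sd = grouped.transform("std")  # ddof=1, NaN-aware
    constant = sd.fillna(0.0) < 1e-12
    if constant.any():
        for key in (
            table.loc[constant, ["subject", "analyte"]].drop_duplicates().itertuples(index=False)
        ):
            excluded.append((key.subject, key.analyte))
            logger.warning(
                "excluding constant stratum subject=%s analyte=%s from rhythm analysis",
                key.subject, key.analyte,
            )
        warnings.warn(f"excluded {len(excluded)} constant (subject, analyte) strata")
    table["value"] = (table["value"] - mean) / sd
    table = table.loc[~constant].reset_index(drop=True)
    table.attrs["excluded_strata"] = excluded
    return table


def impute_missing(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing values by linear interpolation in time, per stratum.

    Within every (subject, analyte) trace the missing values are linearly
    interpolated between the neighbouring observed timepoints; missing
    boundary values carry the nearest observed value.  Deterministic given
    the input.  Imputed cells are flagged in a boolean ``imputed`` column.

    Strata with fewer than 2 observed timepoints cannot be interpolated;
    subjects whose every stratum is that sparse are dropped with a warning.
    """
    table = table.sort_values(["subject", "analyte", "time_h"], kind="stable").reset_index(
        drop=True
    )
    table["imputed"] = table["value"].isna()
    drop_idx = []
    for (subject, analyte), idx in table.groupby(["subject", "analyte"], observed=True).groups.items():
        idx = np.asarray(idx)
        t = table.loc[idx, "time_h"].to_numpy(dtype=float)
        y = table.loc[idx, "value"].to_numpy(dtype=float)
        obs = np.isfinite(y)
        if obs.all():
            continue
        if obs.sum() < 2:
            logger.warning(
                "dropping stratum subject=%s analyte=%s: <2 observed timepoints", subject, analyte
            )
            drop_idx.extend(idx.tolist())
            continue
        # np.interp clamps outside the observed range = boundary carry
        table.loc[idx[~obs], "value"] = np.interp(t[~obs], t[obs], y[obs])
    if drop_idx:
        dropped_subjects = set(table.loc[drop_idx, "subject"]) - set(
            table.drop(index=drop_idx)["subject"]
        )
        if dropped_subjects:
            warnings.warn(f"subjects dropped (too few observed visits): {sorted(dropped_subjects)}")
        table = table.drop(index=drop_idx).reset_index(drop=True)
    assert not table["value"].isna().any()
    return table


def stack_series(table: pd.DataFrame, analyte: str, group: str) -> AnalyteSeries:
    """Stack all observations of one analyte in one group into vectors.

    Ordering is canonical (subject, then time), so permuting input rows
    yields an identical series.  Missing (NaN) values are excluded.
    """
    sel = table[
        (table["analyte"] == analyte) & (table["group"] == group) & table["value"].notna()
    ]
    if sel.empty:
        raise LongTableError(f"no observations for analyte={analyte!r} group={group!r}")
    sel = sel.sort_values(["subject", "time_h"], kind="stable")
    subjects = sorted(sel["subject"].unique().tolist())
    index = {s: i for i, s in enumerate(subjects)}
    return AnalyteSeries(
        analyte=analyte,
        group=group,
        t=sel["time_h"].to_numpy(dtype=float),
        y=sel["value"].to_numpy(dtype=float),
        subject_idx=sel["subject"].map(index).to_numpy(dtype=int),
        subjects=subjects,
    )
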