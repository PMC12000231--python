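"""Trial-level data container, validation, and long-format file I/O.

The package operates on long-format trial records: one row per trial with a
participant identifier, a stimulus identifier, up to two binary condition
factors (e.g., stimulus category and response direction in an
approach-avoidance task), and a positive reaction time.  A presentation
index records the order of the trial within the participant's session; when
the input file has none, file order within participant is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TrialTable",
    "DataError",
    "ConfigError",
    "read_trials",
    "write_trials",
    "exclude_trials",
]

#: canonical internal column names
PARTICIPANT, STIMULUS, RT, PRESENTATION = "participant", "stimulus", "rt", "presentation"


class DataError(ValueError):
    """A data file or table violates the trial-table contract."""


class ConfigError(ValueError):
    """A column mapping or option refers to something that does not exist."""


@dataclass(frozen=True)
class TrialTable:
    """Validated long-format trial records.

    Parameters
    ----------
    df:
        DataFrame with columns ``participant``, ``stimulus``, ``rt``,
        ``presentation`` plus one column per condition factor.
    factors:
        Names of the (at most two) binary condition-factor columns.
    """

    df: pd.DataFrame
    factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.df
        required = [PARTICIPANT, STIMULUS, RT, PRESENTATION, *self.factors]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ConfigError(f"missing columns: {missing}")
        if len(self.factors) > 2:
            raise ConfigError("at most two condition factors are supported")
        if len(df) == 0:
            raise DataError("trial table is empty")
        rt = df[RT].to_numpy()
        if not np.issubdtype(rt.dtype, np.number):
            raise DataError("rt column is not numeric")
        bad = ~np.isfinite(rt) | (rt <= 0)
        if bad.any():
            rows = df.index[bad][:10].tolist()
            raise DataError(
                f"{int(bad.sum())} trials have non-finite or non-positive RT "
                f"(first offending rows: {rows})"
            )
        dup = df.duplicated(subset=[PARTICIPANT, PRESENTATION])
        if dup.any():
            raise DataError(
                "presentation index is not unique within participant "
                f"(e.g., row {df.index[dup][0]})"
            )
        for f in self.factors:
            n_levels = df[f].nunique()
            if n_levels > 2:
                raise DataError(f"factor {f!r} has {n_levels} levels, at most 2 supported")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def participants(self) -> np.ndarray:
        return np.asarray(pd.unique(self.df[PARTICIPANT]))

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def factor_levels(self, factor: str) -> tuple:
        levels = sorted(pd.unique(self.df[factor]))
        return tuple(levels)

    def subset(self, mask: np.ndarray) -> "TrialTable":
        """Row-subset sharing the original presentation indices."""
        return TrialTable(self.df.loc[np.asarray(mask)].copy(), self.factors)

    def cell_counts(self) -> pd.DataFrame:
        """Trials per participant x factor-level combination."""
        keys = [PARTICIPANT, *self.factors]
        return self.df.groupby(keys, observed=True).size().rename("n_trials").reset_index()


def read_trials(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    factors: Iterable[str] = (),
    sep: str | None = None,
) -> TrialTable:
    """Read a long-format CSV/TSV of trials into a validated TrialTable.

    ``column_map`` maps canonical names (``participant``, ``stimulus``,
    ``rt``, ``presentation`` and factor names) to the file's column names;
    canonical names already present in the file need no entry.  When the
    file has no presentation column, indices are assigned by file order
    within participant.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such file: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep)
    column_map = dict(column_map or {})
    factors = tuple(factors)

    rename = {}
    for canonical in (PARTICIPANT, STIMULUS, RT, PRESENTATION, *factors):
        source = column_map.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
        elif canonical in (PARTICIPANT, STIMULUS, RT) or canonical in factors:
            raise ConfigError(
                f"column {source!r} (for {canonical!r}) not found in {path.name}; "
                f"available: {list(raw.columns)}"
            )
    df = raw.rename(columns=rename)

    rt_numeric = pd.to_numeric(df[RT], errors="coerce")
    bad = rt_numeric.isna() & df[RT].notna() | df[RT].isna()
    if bad.any():
        row = int(df.index[bad][0])
        raise DataError(
            f"non-numeric or missing RT in row {row} of {path.name} "
            f"(value: {df[RT].iloc[row]!r})"
        )
    df[RT] = rt_numeric.astype(float)

    if PRESENTATION not in df.columns:
        df[PRESENTATION] = df.groupby(PARTICIPANT).cumcount() + 1
    keep = [PARTICIPANT, STIMULUS, RT, PRESENTATION, *factors]
    return TrialTable(df[keep].reset_index(drop=True), factors)


def write_trials(table: TrialTable, path: str | Path, sep: str | None = None) -> None:
    """Write a TrialTable back to long-format CSV/TSV (lossless round-trip)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table.df.to_csv(path, sep=sep, index=False)


def exclude_trials(
    table: TrialTable, predicate: Callable[..., bool]
) -> tuple[TrialTable, pd.DataFrame]:
    """Drop trials for which ``predicate(trial)`` is true.

    ``predicate`` receives one trial at a time as a named tuple with fields
    ``participant``, ``stimulus``, ``rt``, ``presentation`` and the factor
    columns, and must be a pure function of those fields.  Returns the
    filtered table and a per-participant report of removed counts.  A
    warning names any participant for whom a whole factor-level cell was
    emptied; exclusions are applied before splitting.
    """
    remove = np.fromiter(
        (bool(predicate(row)) for row in table.df.itertuples(index=False)),
        dtype=bool,
        count=len(table.df),
    )
    report = (
        pd.DataFrame(
            {PARTICIPANT: table.df[PARTICIPANT], "removed": remove.astype(int)}
        )
        .groupby(PARTICIPANT, observed=True)["removed"]
        .sum()
        .reset_index(name="n_removed")
    )
    if remove.all():
        raise DataError("predicate removed every trial")
    kept = table.subset(~remove)
    if remove.any() and table.factors:
        before = table.df.groupby([PARTICIPANT, *table.factors], observed=True).size()
        after = kept.df.groupby([PARTICIPANT, *table.factors], observed=True).size()
        emptied = before.index.difference(after.index)
        for key in emptied:
            warnings.warn(
                f"exclusion emptied cell {key[1:]} for participant {key[0]!r}",
                stacklevel=2,
            )
    return kept, report
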