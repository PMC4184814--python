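"""Reading, validation and preprocessing of community time-series tables.

The expected table dialect is one age column (years BP, present = AD 1950)
followed by one numeric column per species holding percent abundances
(0–100, computed relative to the total count in each sample, so rows need
not sum exactly to 100 when rare taxa were excluded).  Records are stored
oldest-first internally, i.e. ages strictly decrease along the row index.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTimeSeries",
    "FormatError",
    "read_community_table",
    "preprocess",
    "write_series_table",
    "read_series_table",
]

#: slack on the <=100 row-sum check; real tables carry rounding error.
ROW_SUM_TOLERANCE = 0.5


class FormatError(ValueError):
    """Raised when an input table violates the community-table dialect."""


@dataclass
class CommunityTimeSeries:
    """A community record: ages plus a [time step x species] percent matrix.

    Parameters
    ----------
    ages
        Age of each time step in years BP, strictly decreasing (oldest
        first) after preprocessing; weakly decreasing runs of equal ages
        are tolerated before preprocessing.
    species_names
        Taxon label per column of ``abundance``; order preserved from the
        source table.
    abundance
        Percent abundances, shape ``(n_steps, n_species)``.  NaN marks a
        barren (no-data) time step prior to preprocessing.
    meta
        Free-form provenance record (source path, input age order,
        preprocessing counts, ...).
    """

    ages: np.ndarray
    species_names: list[str]
    abundance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        self.species_names = list(self.species_names)
        if self.abundance.ndim != 2:
            raise FormatError("abundance must be a 2-D matrix")
        n_steps, n_species = self.abundance.shape
        if n_steps == 0 or n_species == 0:
            raise FormatError("community table must have >=1 step and >=1 species")
        if len(self.ages) != n_steps:
            raise FormatError(
                f"{len(self.ages)} ages but {n_steps} abundance rows"
            )
        if len(self.species_names) != n_species:
            raise FormatError(
                f"{len(self.species_names)} names but {n_species} species columns"
            )

    @property
    def n_steps(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_species(self) -> int:
        return self.abundance.shape[1]

    def validate(self, strict_ages: bool = True) -> None:
        """Check the record invariants; raise :class:`FormatError` if violated.

        With ``strict_ages=False`` consecutive equal ages are tolerated
        (the raw state before :func:`preprocess` collapses them).
        """
        if np.isnan(self.ages).any():
            raise FormatError("ages contain missing values")
        d = np.diff(self.ages)
        if strict_ages:
            if not (d < 0).all():
                raise FormatError("ages must strictly decrease (oldest first)")
        elif not (d <= 0).all():
            raise FormatError("ages must be monotonic non-increasing")
        finite = self.abundance[~np.isnan(self.abundance)]
        if (finite < 0).any():
            raise FormatError("negative abundance values")
        row_ok = ~np.isnan(self.abundance).any(axis=1)
        sums = self.abundance[row_ok].sum(axis=1)
        if (sums > 100.0 + ROW_SUM_TOLERANCE).any():
            i = int(np.argmax(sums > 100.0 + ROW_SUM_TOLERANCE))
            raise FormatError(
                f"row sum {sums[i]:.4f} exceeds 100 (+{ROW_SUM_TOLERANCE})"
            )
        if strict_ages and np.isnan(self.abundance).any():
            raise FormatError("missing abundance values after preprocessing")

    def to_frame(self, age_column: str = "age") -> pd.DataFrame:
        df = pd.DataFrame(self.abundance, columns=self.species_names)
        df.insert(0, age_column, self.ages)
        return df


def _sniff_delimiter(header_line: str) -> str:
    counts = {sep: header_line.count(sep) for sep in (",", "\t", ";")}
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        raise FormatError("could not detect a delimiter (comma/tab/semicolon)")
    return best


def read_community_table(
    path: str | Path, age_column: str | None = None
) -> CommunityTimeSeries:
    """Read a delimited community table into a :class:`CommunityTimeSeries`.

    The first column is taken as the age column unless ``age_column`` names
    another one.  The delimiter is auto-detected among comma, tab and
    semicolon.  Ages may run young-to-old or old-to-young in the file; the
    returned record is normalized to oldest-first and the input order noted
    in ``meta['input_age_order']``.

    Raises
    ------
    FormatError
        On a missing age column, duplicate species names, an empty table,
        non-numeric species cells, or a blank cell in a row that is not
        entirely blank (entirely blank rows are legitimate no-data steps
        that :func:`preprocess` removes).
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: empty table")
    sep = _sniff_delimiter(lines[0])
    header = [h.strip() for h in lines[0].split(sep)]
    if age_column is None:
        age_column = header[0]
    if age_column not in header:
        raise FormatError(f"{path}: missing age column {age_column!r}")
    species = [h for h in header if h != age_column]
    if not species:
        raise FormatError(f"{path}: no species columns")
    dup = {s for s in species if species.count(s) > 1}
    if dup:
        raise FormatError(f"{path}: duplicate species names {sorted(dup)}")

    df = pd.read_csv(_io.StringIO(text), sep=sep)
    df.columns = header
    ages = pd.to_numeric(df[age_column], errors="coerce")
    if ages.isna().any():
        row = int(ages.index[ages.isna()][0])
        raise FormatError(f"{path}: non-numeric age in data row {row}")

    mat = np.empty((len(df), len(species)), dtype=float)
    for j, name in enumerate(species):
        col = df[name]
        num = pd.to_numeric(col, errors="coerce")
        bad = num.isna() & col.notna() & (col.astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.index[bad][0])
            raise FormatError(
                f"{path}: non-numeric value {col[row]!r} in row {row}, "
                f"column {name!r}"
            )
        mat[:, j] = num.to_numpy()

    # blank cells: allowed only when the whole row is blank (barren step)
    nan_mask = np.isnan(mat)
    partial = nan_mask.any(axis=1) & ~nan_mask.all(axis=1)
    if partial.any():
        row = int(np.argmax(partial))
        col = species[int(np.argmax(nan_mask[row]))]
        raise FormatError(
            f"{path}: blank cell in data row {row}, column {col!r} "
            "(row is not entirely blank)"
        )

    age_arr = ages.to_numpy(dtype=float)
    d = np.diff(age_arr)
    if (d <= 0).all():
        order = "old_to_young"
    elif (d >= 0).all():
        order = "young_to_old"
        age_arr = age_arr[::-1]
        mat = mat[::-1]
    else:
        raise FormatError(f"{path}: ages are not monotonic")

    cts = CommunityTimeSeries(
        ages=age_arr,
        species_names=species,
        abundance=mat,
        meta={
            "source": str(path),
            "age_column": age_column,
            "input_age_order": order,
            "n_steps_raw": len(age_arr),
        },
    )
    cts.validate(strict_ages=False)
    return cts


def preprocess(
    raw: CommunityTimeSeries,
    average_equal_ages: bool = True,
    drop_empty: bool = True,
) -> CommunityTimeSeries:
    """Drop barren steps and collapse consecutive equal-age steps.

    Rows whose species values are entirely missing, or entirely zero, are
    removed (poor-preservation steps).  Consecutive runs of rows sharing an
    identical age are collapsed to a single row of column-wise arithmetic
    means.  The result has strictly decreasing ages and no missing values;
    the operation is idempotent.

    Raises
    ------
    FormatError
        If duplicate ages occur non-consecutively (ambiguous collapse) or
        if every row is removed.
    """
    ages = raw.ages.copy()
    mat = raw.abundance.copy()

    if drop_empty:
        empty = np.isnan(mat).all(axis=1) | (np.nan_to_num(mat) == 0).all(axis=1)
        ages, mat = ages[~empty], mat[~empty]
    if len(ages) == 0:
        raise FormatError("preprocessing removed every time step")
    if np.isnan(mat).any():
        i, j = np.argwhere(np.isnan(mat))[0]
        raise FormatError(
            f"missing value at step {i}, species {raw.species_names[j]!r}"
        )

    if average_equal_ages:
        # consecutive runs of equal age -> one averaged row
        boundary = np.concatenate(([True], np.diff(ages) != 0))
        group = np.cumsum(boundary) - 1
        n_groups = group[-1] + 1
        out_ages = np.empty(n_groups)
        out_mat = np.empty((n_groups, mat.shape[1]))
        for g in range(n_groups):
            sel = group == g
            out_ages[g] = ages[np.argmax(sel)]
            out_mat[g] = mat[sel].mean(axis=0)
        ages, mat = out_ages, out_mat

    if len(np.unique(ages)) != len(ages):
        vals, counts = np.unique(ages, return_counts=True)
        raise FormatError(
            f"non-consecutive duplicate ages {vals[counts > 1].tolist()}"
        )

    meta = dict(raw.meta)
    meta["n_steps_raw"] = meta.get("n_steps_raw", raw.n_steps)
    meta["n_steps"] = len(ages)
    meta["preprocessed"] = True
    out = CommunityTimeSeries(ages, raw.species_names, mat, meta)
    out.validate(strict_ages=True)
    return out


def write_series_table(series, path: str | Path) -> None:
    """Write any named-column tabular result as full-precision TSV.

    ``series`` may be a :class:`pandas.DataFrame` or any object exposing a
    ``to_frame()`` method (e.g. :class:`CommunityTimeSeries`,
    :class:`~regimeshift.fisher.FISeries`).  Round-trips through
    :func:`read_series_table` to float precision 1e-12.
    """
    if not isinstance(series, pd.DataFrame):
        series = series.to_frame()
    series.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_series_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_series_table`."""
    return pd.read_csv(path, sep="\t")
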