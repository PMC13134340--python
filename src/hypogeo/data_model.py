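"""Tabular data model for eDNA incidence surveys.

The pipeline starts from two plain-text tables:

* a **sample table** describing each pooled soil sample (location in the
  national sampling grid, host tree genus, and numerical environmental
  covariates), and
* an **incidence table** giving, for every fungal phylotype and sample, the
  number of distinct amplicon sequence variants (ASV types) observed.  ASV
  *type* counts — not read counts — are the occurrence currency throughout;
  read counts may ride along for relative-abundance summaries only.

Both tables are TSV/CSV with a header row; ``#``-prefixed lines are treated
as comments so result files can carry provenance headers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Host",
    "SampleRecord",
    "SampleTable",
    "IncidenceTable",
    "GenusTable",
    "ValidationError",
    "read_samples",
    "read_incidence",
    "write_samples",
    "write_incidence",
    "relative_abundance",
    "collapse_to_genus",
    "filter_genera_min_grids",
]

#: Sample-table columns that are not environmental covariates.
RESERVED_COLUMNS = ("sample_id", "site_id", "grid_id", "host", "latitude", "longitude")

#: Covariates the nationwide survey records; extra columns are kept as-is.
STANDARD_COVARIATES = ("MAT", "MAP", "altitude", "pH", "TOC", "TN", "NH4+", "NO3-", "TP")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


class Host(enum.Enum):
    """Host tree genus associated with a pooled soil sample."""

    PINUS = "PINUS"
    QUERCUS = "QUERCUS"
    OTHER = "OTHER"

    @classmethod
    def parse(cls, label: object) -> "Host":
        """Map a free-text host label onto the enum, case-insensitively.

        Anything that is not recognisably *Pinus* or *Quercus* becomes
        ``OTHER`` and is excluded from host-preference testing downstream.
        """
        text = str(label).strip().upper()
        if text.startswith("PINUS"):
            return cls.PINUS
        if text.startswith("QUERCUS"):
            return cls.QUERCUS
        return cls.OTHER


@dataclass(frozen=True)
class SampleRecord:
    """One pooled soil sample with its design identifiers and covariates.

    ``covariates`` maps variable name to a float; a missing measurement is
    stored as ``nan`` (never silently zero).
    """

    sample_id: str
    site_id: str
    grid_id: str
    host: Host
    latitude: float
    longitude: float
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(
                f"sample {self.sample_id!r}: latitude {self.latitude} outside [-90, 90]"
            )
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(
                f"sample {self.sample_id!r}: longitude {self.longitude} outside [-180, 180]"
            )


class SampleTable:
    """Ordered collection of :class:`SampleRecord` with unique ids."""

    def __init__(self, records: Iterable[SampleRecord]):
        self.records: list[SampleRecord] = list(records)
        seen: dict[str, int] = {}
        dupes = []
        for rec in self.records:
            if rec.sample_id in seen:
                dupes.append(rec.sample_id)
            seen[rec.sample_id] = 1
        if dupes:
            raise ValidationError(f"duplicate sample_id values: {sorted(set(dupes))}")
        self._by_id = {rec.sample_id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, sample_id: str) -> SampleRecord:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    @property
    def sample_ids(self) -> list[str]:
        return [rec.sample_id for rec in self.records]

    def covariate_names(self) -> list[str]:
        names: list[str] = []
        for rec in self.records:
            for key in rec.covariates:
                if key not in names:
                    names.append(key)
        return names

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a DataFrame (one covariate per column, NaN = missing)."""
        rows = []
        for rec in self.records:
            row = {
                "sample_id": rec.sample_id,
                "site_id": rec.site_id,
                "grid_id": rec.grid_id,
                "host": rec.host.value,
                "latitude": rec.latitude,
                "longitude": rec.longitude,
            }
            row.update(rec.covariates)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class IncidenceTable:
    """Phylotype × sample matrix of distinct-ASV counts.

    ``asv_types[i, j]`` is the number of ASV types of phylotype ``i``
    observed in sample ``j``.  ``genera[i]`` labels phylotype ``i``; an
    empty string means unassigned.  ``reads`` is an optional parallel
    matrix of read counts used only for relative abundance.
    """

    phylotype_ids: list[str]
    genera: list[str]
    sample_ids: list[str]
    asv_types: np.ndarray
    reads: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.asv_types = np.asarray(self.asv_types)
        p, s = len(self.phylotype_ids), len(self.sample_ids)
        if self.asv_types.shape != (p, s):
            raise ValidationError(
                f"asv_types shape {self.asv_types.shape} != ({p} phylotypes, {s} samples)"
            )
        if len(self.genera) != p:
            raise ValidationError("genera list length does not match phylotypes")
        _check_counts(self.asv_types, "asv_types")
        self.asv_types = self.asv_types.astype(np.int64)
        if self.reads is not None:
            self.reads = np.asarray(self.reads)
            if self.reads.shape != (p, s):
                raise ValidationError("reads matrix shape mismatch")
            _check_counts(self.reads, "reads")
            self.reads = self.reads.astype(np.int64)

    @property
    def n_phylotypes(self) -> int:
        return len(self.phylotype_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, phylotype_id: str) -> np.ndarray:
        return self.asv_types[self.phylotype_ids.index(phylotype_id)]

    def genus_of(self, phylotype_id: str) -> str:
        return self.genera[self.phylotype_ids.index(phylotype_id)]

    def check_joinable(self, samples: SampleTable) -> None:
        missing = [s for s in self.sample_ids if s not in samples]
        if missing:
            raise ValidationError(f"incidence sample ids not in sample table: {missing}")

    def to_long(self) -> pd.DataFrame:
        """Long-format view (phylotype, genus, sample, asv_types[, reads]);
        zero cells are omitted — long layout is the canonical output form."""
        rows = []
        for i, pid in enumerate(self.phylotype_ids):
            for j, sid in enumerate(self.sample_ids):
                if self.asv_types[i, j] == 0 and (
                    self.reads is None or self.reads[i, j] == 0
                ):
                    continue
                row = {
                    "phylotype": pid,
                    "genus": self.genera[i],
                    "sample": sid,
                    "asv_types": int(self.asv_types[i, j]),
                }
                if self.reads is not None:
                    row["reads"] = int(self.reads[i, j])
                rows.append(row)
        cols = ["phylotype", "genus", "sample", "asv_types"]
        if self.reads is not None:
            cols.append("reads")
        return pd.DataFrame(rows, columns=cols)


@dataclass
class GenusTable:
    """Genus × sample count matrix (phylotype rows summed within genus)."""

    genera: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genera), len(self.sample_ids)):
            raise ValidationError("genus count matrix shape mismatch")
        _check_counts(self.counts, "counts")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_genera(self) -> int:
        return len(self.genera)

    def row(self, genus: str) -> np.ndarray:
        return self.counts[self.genera.index(genus)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genera, columns=self.sample_ids)


def _check_counts(matrix: np.ndarray, name: str) -> None:
    arr = np.asarray(matrix)
    if arr.size == 0:
        return
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError(f"{name}: non-numeric entries")
    bad = np.argwhere(~np.isfinite(arr.astype(float)) | (arr < 0) | (arr != np.floor(arr)))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"{name}: invalid count {arr[i, j]!r} at row {i}, column {j} "
            "(counts must be non-negative integers)"
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    if delimiter is None:
        # sniff: TSV if the header line has tabs, else comma
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                if line.strip() and not line.startswith("#"):
                    delimiter = "\t" if "\t" in line else ","
                    break
            else:
                delimiter = "\t"
    return pd.read_csv(path, sep=delimiter, comment="#", dtype=str, skip_blank_lines=True)


def read_samples(path: str | Path, delimiter: str | None = None) -> SampleTable:
    """Read a sample metadata table.

    Required columns: sample_id, site_id, grid_id, host, latitude,
    longitude.  Every other column is treated as a named numerical
    covariate; empty cells become NaN (missing).
    """
    df = _read_table(path, delimiter)
    missing_cols = [c for c in RESERVED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing required columns {missing_cols}")
    covar_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]

    records = []
    for idx, row in df.iterrows():
        try:
            lat = float(row["latitude"])
            lon = float(row["longitude"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path}: unparseable coordinate in data row {idx}: "
                f"latitude={row['latitude']!r} longitude={row['longitude']!r}"
            ) from exc
        covars = {}
        for c in covar_cols:
            cell = row[c]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
                covars[c] = float("nan")
            else:
                try:
                    covars[c] = float(cell)
                except ValueError:
                    covars[c] = float("nan")
        try:
            records.append(
                SampleRecord(
                    sample_id=str(row["sample_id"]),
                    site_id=str(row["site_id"]),
                    grid_id=str(row["grid_id"]),
                    host=Host.parse(row["host"]),
                    latitude=lat,
                    longitude=lon,
                    covariates=covars,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: data row {idx}: {exc}") from exc
    return SampleTable(records)


def write_samples(samples: SampleTable, path: str | Path, *, header_comments: Sequence[str] = ()) -> None:
    df = samples.to_frame()
    _write_with_comments(df, path, header_comments)


_LONG_REQUIRED = {"phylotype", "sample"}


def read_incidence(path: str | Path, delimiter: str | None = None, layout: str = "auto") -> IncidenceTable:
    """Read an incidence table in long or wide layout.

    Long layout has columns ``phylotype, sample, asv_types`` (or ``count``)
    plus optional ``genus`` and ``reads``; absent pairs are zero.  Wide
    layout has one row per phylotype (column ``phylotype``, optional
    ``genus``) and one column per sample.  If no genus column is present,
    a ``Genus|rest`` convention in the phylotype id is used.
    """
    df = _read_table(path, delimiter)
    cols = set(df.columns)
    if layout == "auto":
        layout = "long" if _LONG_REQUIRED <= cols else "wide"
    if layout == "long":
        return _incidence_from_long(df)
    return _incidence_from_wide(df)


def _genus_from_id(pid: str) -> str:
    return pid.split("|", 1)[0] if "|" in pid else ""


def _incidence_from_long(df: pd.DataFrame) -> IncidenceTable:
    count_col = "asv_types" if "asv_types" in df.columns else "count"
    if count_col not in df.columns:
        raise ValidationError("long incidence table needs an 'asv_types' or 'count' column")
    pids = list(dict.fromkeys(df["phylotype"].astype(str)))
    sids = list(dict.fromkeys(df["sample"].astype(str)))
    pidx = {p: i for i, p in enumerate(pids)}
    sidx = {s: j for j, s in enumerate(sids)}
    asv = np.zeros((len(pids), len(sids)), dtype=np.int64)
    reads = np.zeros_like(asv) if "reads" in df.columns else None
    genera = {p: _genus_from_id(p) for p in pids}
    for rownum, row in df.iterrows():
        p, s = str(row["phylotype"]), str(row["sample"])
        val = _parse_count(row[count_col], rownum, count_col)
        asv[pidx[p], sidx[s]] = val
        if reads is not None:
            reads[pidx[p], sidx[s]] = _parse_count(row["reads"], rownum, "reads")
        if "genus" in df.columns and str(row["genus"]).strip() not in ("", "nan"):
            genera[p] = str(row["genus"]).strip()
    return IncidenceTable(pids, [genera[p] for p in pids], sids, asv, reads)


def _incidence_from_wide(df: pd.DataFrame) -> IncidenceTable:
    if "phylotype" not in df.columns:
        raise ValidationError("wide incidence table needs a 'phylotype' column")
    meta = ["phylotype"] + (["genus"] if "genus" in df.columns else [])
    sample_cols = [c for c in df.columns if c not in meta]
    pids = [str(p) for p in df["phylotype"]]
    if "genus" in df.columns:
        genera = [str(g).strip() if str(g).strip() != "nan" else "" for g in df["genus"]]
    else:
        genera = [_genus_from_id(p) for p in pids]
    asv = np.zeros((len(pids), len(sample_cols)), dtype=np.int64)
    for i, (_, row) in enumerate(df.iterrows()):
        for j, c in enumerate(sample_cols):
            asv[i, j] = _parse_count(row[c], i, c)
    return IncidenceTable(pids, genera, list(sample_cols), asv)


def _parse_count(cell: object, rownum: object, col: str) -> int:
    if cell is None or str(cell).strip() in ("", "nan"):
        return 0
    try:
        val = float(cell)
    except ValueError as exc:
        raise ValidationError(f"row {rownum}, column {col!r}: non-numeric count {cell!r}") from exc
    if val < 0 or val != int(val):
        raise ValidationError(
            f"row {rownum}, column {col!r}: count {cell!r} is negative or non-integer"
        )
    return int(val)


def write_incidence(table: IncidenceTable, path: str | Path, *, layout: str = "long",
                    header_comments: Sequence[str] = ()) -> None:
    """Write an incidence table (long layout is canonical)."""
    if layout == "long":
        df = table.to_long()
    elif layout == "wide":
        df = pd.DataFrame(table.asv_types, columns=table.sample_ids)
        df.insert(0, "genus", table.genera)
        df.insert(0, "phylotype", table.phylotype_ids)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    _write_with_comments(df, path, header_comments)


def _write_with_comments(df: pd.DataFrame, path: str | Path, comments: Sequence[str]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# summaries and filters
# ---------------------------------------------------------------------------

def relative_abundance(table: IncidenceTable, taxon: str, basis: str = "asv_types") -> float:
    """Relative abundance of one phylotype, in percent.

    Computed as the taxon's total count divided by the grand total over all
    phylotypes and samples, × 100.  ``basis`` selects the ASV-type matrix
    (default) or the read matrix.
    """
    if basis == "asv_types":
        matrix = table.asv_types
    elif basis == "reads":
        if table.reads is None:
            raise ValidationError("no read matrix present")
        matrix = table.reads
    else:
        raise ValueError(f"unknown basis {basis!r}")
    grand = matrix.sum()
    if grand == 0:
        raise ValidationError("grand total is zero; relative abundance undefined")
    i = table.phylotype_ids.index(taxon)
    return float(matrix[i].sum()) / float(grand) * 100.0


def collapse_to_genus(table: IncidenceTable) -> GenusTable:
    """Sum phylotype ASV-type counts within genus, per sample.

    Genus order is lexicographic (stable across runs).  Every phylotype
    must carry a genus label.
    """
    unlabeled = [p for p, g in zip(table.phylotype_ids, table.genera) if not g]
    if unlabeled:
        raise ValidationError(f"phylotypes without genus label: {unlabeled}")
    genera = sorted(set(table.genera))
    gidx = {g: i for i, g in enumerate(genera)}
    counts = np.zeros((len(genera), table.n_samples), dtype=np.int64)
    for i, g in enumerate(table.genera):
        counts[gidx[g]] += table.asv_types[i]
    return GenusTable(genera, list(table.sample_ids), counts)


def filter_genera_min_grids(
    table: GenusTable, samples: SampleTable, min_grids: int = 2
) -> tuple[GenusTable, list[str]]:
    """Drop genera detected in fewer than ``min_grids`` distinct grids.

    Returns the filtered table and the list of excluded genera.  A genus
    restricted to a single sampling grid cannot support range-wide
    preference statistics and is excluded from the preference analysis.
    """
    grid_of = {}
    for sid in table.sample_ids:
        if sid not in samples:
            raise ValidationError(f"sample {sid!r} not found in sample table")
        grid_of[sid] = samples[sid].grid_id
    keep, excluded = [], []
    for i, genus in enumerate(table.genera):
        grids = {grid_of[sid] for j, sid in enumerate(table.sample_ids) if table.counts[i, j] > 0}
        (keep if len(grids) >= min_grids else excluded).append(genus)
    rows = [table.genera.index(g) for g in keep]
    return GenusTable(keep, list(table.sample_ids), table.counts[rows]), excluded
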