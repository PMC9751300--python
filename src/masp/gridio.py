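"""Grid and abundance-matrix data model plus delimited-text readers/writers.

The micro-scaffold compartmentalizes a tissue slice into a lattice of
micro-wells; each occupied well yields one micro-specimen, which becomes one
sample (one column of the abundance matrix).  :class:`SpatialGrid` records the
lattice geometry and the specimen ↔ (row, col) bijection; :class:`QuantMatrix`
holds log2 protein (or peptide) abundances with explicit missingness; and
:class:`QCSet` groups the pooled-reference (QC) runs injected periodically
through the acquisition to monitor drift.

All on-disk formats are plain TSV/CSV.  Floats are written with 6 significant
digits, missing cells as ``NA`` (empty cells are also accepted on read), and
metadata travels in ``#``-prefixed header lines.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"
FLOAT_FORMAT = "%.6g"

#: legal scale tags in their canonical transition order (zscore reachable
#: from any of the first three)
SCALE_TAGS = ("log2_raw", "log2_tic", "log2_ref", "zscore")

Well = tuple[int, int]


def _fmt(x: float) -> str:
    return MISSING_TOKEN if x is None or (isinstance(x, float) and np.isnan(x)) else FLOAT_FORMAT % x


def _sniff_delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpatialGrid:
    """The micro-well lattice and the specimen ↔ well bijection.

    Coordinates are 0-based with row 0 at the top and column 0 at the left
    (image raster convention).
    """

    n_rows: int
    n_cols: int
    resolution_um: float
    specimen_wells: dict[str, Well]  # specimen id -> (row, col)
    _well_to_specimen: dict[Well, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.resolution_um <= 0:
            raise ValueError("resolution_um must be positive")
        if not self.specimen_wells:
            raise ValueError("grid holds no micro-specimens (empty wells set)")
        inv: dict[Well, str] = {}
        for sid, (r, c) in self.specimen_wells.items():
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(
                    f"specimen {sid!r} at ({r}, {c}) is outside the "
                    f"{self.n_rows}x{self.n_cols} grid"
                )
            if (r, c) in inv:
                raise ValueError(
                    f"well ({r}, {c}) assigned to both {inv[(r, c)]!r} and {sid!r}"
                )
            inv[(r, c)] = sid
        object.__setattr__(self, "_well_to_specimen", inv)

    @property
    def wells(self) -> frozenset[Well]:
        return frozenset(self._well_to_specimen)

    @property
    def n_wells(self) -> int:
        return len(self.specimen_wells)

    def sorted_wells(self) -> list[Well]:
        """Occupied wells in row-major order (the canonical vectorization order)."""
        return sorted(self._well_to_specimen)

    def specimen_at(self, well: Well) -> str:
        return self._well_to_specimen[well]

    def well_of(self, specimen_id: str) -> Well:
        return self.specimen_wells[specimen_id]


class QuantMatrix:
    """Log2 abundances for m features across n samples, with explicit missingness.

    Internally a samples × features :class:`pandas.DataFrame` of floats where
    NaN marks a missing measurement.  ``scale_tag`` records where the matrix
    sits in the normalization chain (raw → TIC → reference → z-score).
    """

    def __init__(self, values: pd.DataFrame, scale_tag: str = "log2_raw"):
        if scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {scale_tag!r}; expected one of {SCALE_TAGS}")
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        self.values = values.astype(float)
        self.scale_tag = scale_tag

    # -- introspection ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def with_values(self, values: pd.DataFrame, scale_tag: str | None = None) -> "QuantMatrix":
        return QuantMatrix(values, scale_tag or self.scale_tag)

    def subset_samples(self, sample_ids: Iterable[str]) -> "QuantMatrix":
        return QuantMatrix(self.values.loc[list(sample_ids)], self.scale_tag)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"QuantMatrix(n_samples={self.n_samples}, n_features={self.n_features}, "
            f"scale_tag={self.scale_tag!r}, n_missing={self.n_missing})"
        )


@dataclass
class QCSet:
    """Pooled-reference (QC) runs plus their position in the acquisition order.

    ``run_index`` gives each QC run's slot in the injection sequence;
    ``batch_of_specimen`` assigns every tissue specimen to its temporally
    nearest QC run (ties broken toward the earlier run), which is the QC run
    used for reference normalization of that specimen.
    """

    quant: QuantMatrix
    run_index: dict[str, int]  # qc sample id -> acquisition slot
    batch_of_specimen: dict[str, str] = field(default_factory=dict)  # specimen -> qc id

    def __post_init__(self) -> None:
        if set(self.run_index) != set(self.quant.sample_ids):
            raise ValueError("run_index keys must match the QC sample ids exactly")
        idx = sorted(self.run_index.values())
        if len(set(idx)) != len(idx):
            raise ValueError("QC run_index values must be unique")
        for spec, qc in self.batch_of_specimen.items():
            if qc not in self.run_index:
                raise ValueError(f"specimen {spec!r} assigned to unknown QC run {qc!r}")

    @property
    def n_runs(self) -> int:
        return self.quant.n_samples

    def assign_specimens(self, specimen_run_index: Mapping[str, int]) -> "QCSet":
        """Map each specimen to its nearest QC run by acquisition slot.

        Ties (a specimen equidistant from two QC runs) go to the earlier run.
        """
        qc_ids = sorted(self.run_index, key=lambda q: self.run_index[q])
        qc_pos = np.array([self.run_index[q] for q in qc_ids])
        mapping = {}
        for spec, pos in specimen_run_index.items():
            d = np.abs(qc_pos - pos)
            mapping[spec] = qc_ids[int(np.argmin(d))]  # argmin takes the earliest on ties
        return QCSet(self.quant, dict(self.run_index), mapping)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sniff_delimiter(path),
        index_col=0,
        comment="#",
        dtype=str,
        keep_default_na=False,
    )
    return df


def read_quant_matrix(path: str | Path, rows_are_features: bool = True) -> QuantMatrix:
    """Read a delimited abundance table into a :class:`QuantMatrix`.

    The file carries one header row of ids and one leading id column.  With
    ``rows_are_features=True`` (the default layout) rows are features and
    columns are samples; pass ``False`` for the transposed orientation.
    Empty cells and the token ``NA`` denote missing values; anything else
    must parse as a number.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    with open(path) as fh:  # pandas mangles duplicate header names; check raw
        for line in fh:
            if not line.startswith("#"):
                header_ids = line.rstrip("\n").split(sep)[1:]
                break
        else:
            raise ValueError(f"empty file {path}")
    dup_hdr = pd.Index(header_ids)
    if dup_hdr.duplicated().any():
        raise ValueError(
            f"duplicate column header id {dup_hdr[dup_hdr.duplicated()][0]!r} in {path}"
        )
    raw = _read_table(path)
    axis0 = raw.index
    axis1 = raw.columns
    for name, ids in (("row", axis0), ("column header", axis1)):
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate {name} id {dup[0]!r} in {path}")
    values = np.empty(raw.shape, dtype=float)
    for i, rid in enumerate(axis0):
        for j, cid in enumerate(axis1):
            cell = raw.iat[i, j].strip()
            if cell == "" or cell == MISSING_TOKEN:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell {cell!r} at row {rid!r}, column {cid!r} in {path}"
                    ) from None
    df = pd.DataFrame(values, index=axis0, columns=axis1)
    if rows_are_features:
        df = df.T  # -> samples x features
    df.index.name = "sample_id"
    df.columns.name = "feature_id"
    return QuantMatrix(df, scale_tag="log2_raw")


def write_quant_matrix(
    q: QuantMatrix,
    path: str | Path,
    rows_are_features: bool = True,
    header_lines: Iterable[str] = (),
) -> None:
    """Write a :class:`QuantMatrix` as delimited text (6 significant digits)."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = q.values.T if rows_are_features else q.values
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"# scale_tag={q.scale_tag}; precision=6g; missing={MISSING_TOKEN}\n")
        fh.write(sep.join([df.index.name or "id", *map(str, df.columns)]) + "\n")
        for rid, row in zip(df.index, df.to_numpy()):
            fh.write(sep.join([str(rid), *(_fmt(v) for v in row)]) + "\n")


_GRID_META_RE = re.compile(r"(n_rows|n_cols|resolution_um)\s*=\s*([0-9.eE+-]+)")


def read_grid(
    path: str | Path,
    n_rows: int | None = None,
    n_cols: int | None = None,
    resolution_um: float | None = None,
) -> SpatialGrid:
    """Read a grid-layout table (columns ``specimen_id, row, col``).

    Grid geometry comes from ``#``-prefixed header lines of the form
    ``# n_rows=30 n_cols=30 resolution_um=400`` or from the keyword
    arguments (arguments win).
    """
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for key, val in _GRID_META_RE.findall(line):
                meta[key] = float(val)
    n_rows = int(n_rows if n_rows is not None else meta.get("n_rows", 0))
    n_cols = int(n_cols if n_cols is not None else meta.get("n_cols", 0))
    resolution_um = float(
        resolution_um if resolution_um is not None else meta.get("resolution_um", 0)
    )
    if not (n_rows and n_cols and resolution_um):
        raise ValueError(
            f"grid geometry missing: declare n_rows/n_cols/resolution_um in the "
            f"header of {path} or pass them as arguments"
        )
    df = pd.read_csv(path, sep=_sniff_delimiter(path), comment="#")
    required = {"specimen_id", "row", "col"}
    if not required.issubset(df.columns):
        raise ValueError(f"grid file {path} must have columns {sorted(required)}")
    dup = df["specimen_id"][df["specimen_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate specimen id {dup.iloc[0]!r} in {path}")
    wells = {
        str(row.specimen_id): (int(row.row), int(row.col)) for row in df.itertuples()
    }
    return SpatialGrid(n_rows, n_cols, resolution_um, wells)


def write_grid(g: SpatialGrid, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    path = Path(path)
    sep = _sniff_delimiter(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            f"# n_rows={g.n_rows} n_cols={g.n_cols} resolution_um={FLOAT_FORMAT % g.resolution_um}\n"
        )
        fh.write(sep.join(["specimen_id", "row", "col"]) + "\n")
        for sid, (r, c) in sorted(g.specimen_wells.items(), key=lambda kv: kv[1]):
            fh.write(sep.join([sid, str(r), str(c)]) + "\n")


def write_map_table(m, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Write one protein map as a ``row, col, value`` table (missing → ``NA``)."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            f"# protein_id={m.protein_id}; scale_tag={m.scale_tag}; "
            f"n_rows={m.grid.n_rows}; n_cols={m.grid.n_cols}; "
            f"resolution_um={FLOAT_FORMAT % m.grid.resolution_um}; precision=6g\n"
        )
        fh.write(sep.join(["row", "col", "value"]) + "\n")
        for (r, c) in m.grid.sorted_wells():
            fh.write(sep.join([str(r), str(c), _fmt(m.cell_values[(r, c)])]) + "\n")


def read_map_table(path: str | Path) -> tuple[dict[Well, float], dict[str, str]]:
    """Read a map table back; returns (cell values, header metadata)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for part in line.lstrip("# ").strip().split(";"):
                if "=" in part:
                    k, v = part.split("=", 1)
                    meta[k.strip()] = v.strip()
    df = pd.read_csv(path, sep=_sniff_delimiter(path), comment="#", dtype=str, keep_default_na=False)
    cells: dict[Well, float] = {}
    for row in df.itertuples():
        val = row.value.strip()
        cells[(int(row.row), int(row.col))] = (
            np.nan if val in ("", MISSING_TOKEN) else float(val)
        )
    return cells, meta


def match_samples(q: QuantMatrix, g: SpatialGrid) -> QuantMatrix:
    """Restrict a matrix to the grid's specimens, in grid (row-major) order.

    Samples in the matrix that are not on the grid (e.g. QC runs sharing the
    matrix) and grid specimens absent from the matrix are reported with a
    logged warning and excluded rather than raising; downstream maps treat
    absent specimens as fully missing wells.
    """
    grid_ids = [g.specimen_at(w) for w in g.sorted_wells()]
    present = [sid for sid in grid_ids if sid in set(q.sample_ids)]
    missing_on_grid = sorted(set(grid_ids) - set(present))
    extra_in_matrix = sorted(set(q.sample_ids) - set(grid_ids))
    if missing_on_grid:
        logger.warning(
            "%d grid specimen(s) absent from the matrix (e.g. %s); their wells "
            "will be fully missing",
            len(missing_on_grid),
            missing_on_grid[:3],
        )
    if extra_in_matrix:
        logger.warning(
            "%d matrix sample(s) not on the grid excluded (e.g. %s)",
            len(extra_in_matrix),
            extra_in_matrix[:3],
        )
    return q.subset_samples(present)
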