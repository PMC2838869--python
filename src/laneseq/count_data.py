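"""Gene x lane count matrices and per-lane metadata.

The central object is :class:`CountMatrix`: a dense matrix of non-negative
integer read counts with one row per gene and one column per sequencing lane,
optionally annotated with per-gene region lengths (base pairs).  Counts stay
integral end-to-end — the exact and likelihood-based tests downstream consume
integer counts, and quantile normalization rounds back to integers.

:class:`LaneInfo` carries the per-lane design variables: the biological
condition assayed in the lane, the flow-cell the lane belongs to, the library
preparation, and the lane's total mapped-read count (its sequencing depth).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from laneseq.errors import FormatError, ValidationError

_LENGTH_COL = "length"


def _check_unique(labels: Sequence[str], what: str) -> None:
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dup = next(x for x in labels if x in seen or seen.add(x))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} label: {dup!r}")


@dataclass
class CountMatrix:
    """Read counts for ``len(gene_ids)`` genes across ``len(lane_ids)`` lanes.

    Parameters
    ----------
    gene_ids, lane_ids
        Unique row / column labels.
    counts
        Integer array of shape ``(n_genes, n_lanes)``; every cell >= 0.
    gene_lengths
        Optional per-gene region length in bp (>= 1).  Required only by
        length-aware operations (RPKM-style measures, length weighting).
    """

    gene_ids: list[str]
    lane_ids: list[str]
    counts: np.ndarray
    gene_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.lane_ids = [str(l) for l in self.lane_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError(f"counts must be 2-D, got shape {counts.shape}")
        if counts.shape != (len(self.gene_ids), len(self.lane_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.lane_ids)} lanes"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.lane_ids, "lane")
        if counts.size:
            if not np.issubdtype(counts.dtype, np.integer):
                if np.issubdtype(counts.dtype, np.floating):
                    if np.any(~np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                        i, j = self._first_bad(~np.isfinite(counts) | (counts != np.floor(counts)))
                        raise ValidationError(
                            f"non-integer count for gene {self.gene_ids[i]!r} "
                            f"in lane {self.lane_ids[j]!r}: {counts[i, j]!r}"
                        )
                else:
                    raise ValidationError(f"counts dtype {counts.dtype} is not numeric-integral")
            counts = counts.astype(np.int64)
            if np.any(counts < 0):
                i, j = self._first_bad(counts < 0)
                raise ValidationError(
                    f"negative count for gene {self.gene_ids[i]!r} "
                    f"in lane {self.lane_ids[j]!r}: {counts[i, j]}"
                )
        else:
            counts = counts.astype(np.int64)
        self.counts = counts
        if self.gene_lengths is not None:
            lengths = np.asarray(self.gene_lengths)
            if lengths.shape != (len(self.gene_ids),):
                raise ValidationError(
                    f"gene_lengths shape {lengths.shape} does not match {len(self.gene_ids)} genes"
                )
            if lengths.size and (np.any(lengths < 1) or np.any(lengths != np.floor(lengths))):
                bad = int(np.argmax((lengths < 1) | (lengths != np.floor(lengths))))
                raise ValidationError(
                    f"gene length for {self.gene_ids[bad]!r} must be a positive "
                    f"integer, got {lengths[bad]!r}"
                )
            self.gene_lengths = lengths.astype(np.int64)

    @staticmethod
    def _first_bad(mask: np.ndarray) -> tuple[int, int]:
        i, j = np.argwhere(mask)[0]
        return int(i), int(j)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_lanes(self) -> int:
        return len(self.lane_ids)

    def lane_totals(self) -> np.ndarray:
        """Column sums: total mapped reads per lane."""
        return self.counts.sum(axis=0)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
                          columns=self.lane_ids)
        if self.gene_lengths is not None:
            df.insert(0, _LENGTH_COL, self.gene_lengths)
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        if self.gene_ids != other.gene_ids or self.lane_ids != other.lane_ids:
            return False
        if not np.array_equal(self.counts, other.counts):
            return False
        if (self.gene_lengths is None) != (other.gene_lengths is None):
            return False
        if self.gene_lengths is not None:
            return bool(np.array_equal(self.gene_lengths, other.gene_lengths))
        return True


@dataclass
class LaneInfo:
    """Per-lane design metadata.

    ``table`` is indexed by lane_id with columns ``condition``, ``flow_cell``,
    ``library_prep`` and ``total_count``.  ``total_count`` is checked against
    the column sums of an associated :class:`CountMatrix` by :func:`validate_against`.
    """

    table: pd.DataFrame = field(repr=False)

    COLUMNS = ("condition", "flow_cell", "library_prep", "total_count")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"lane table missing columns: {missing}")
        if df.index.has_duplicates:
            raise ValidationError("duplicate lane ids in lane table")
        tc = df["total_count"]
        if tc.isna().any() or (tc < 0).any() or (tc != tc.astype(np.int64)).any():
            raise ValidationError("total_count must be non-negative integers")
        self.table = df.assign(total_count=tc.astype(np.int64))
        self.table.index = self.table.index.astype(str)
        self.table.index.name = "lane_id"

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str, str, int]]) -> "LaneInfo":
        """Build from ``(lane_id, condition, flow_cell, library_prep, total_count)`` tuples."""
        df = pd.DataFrame.from_records(
            list(records), columns=["lane_id", *cls.COLUMNS]
        ).set_index("lane_id")
        return cls(df)

    @property
    def lane_ids(self) -> list[str]:
        return list(self.table.index)

    def conditions(self) -> list[str]:
        """Distinct condition labels in sorted order."""
        return sorted(self.table["condition"].unique())

    def column(self, name: str) -> pd.Series:
        if name == "lane_id":
            return pd.Series(self.table.index, index=self.table.index, name="lane_id")
        if name not in self.table.columns:
            raise ValidationError(f"unknown lane attribute {name!r}")
        return self.table[name]

    def with_totals(self, matrix: CountMatrix) -> "LaneInfo":
        """Copy with total_count refreshed from a (re-derived) count matrix."""
        if list(self.table.index) != matrix.lane_ids:
            raise ValidationError("lane ids of metadata and count matrix differ")
        return LaneInfo(self.table.assign(total_count=matrix.lane_totals()))

    def validate_against(self, matrix: CountMatrix) -> None:
        """Check lane ids and stored totals against a count matrix."""
        if list(self.table.index) != matrix.lane_ids:
            raise ValidationError("lane ids of metadata and count matrix differ")
        totals = matrix.lane_totals()
        stored = self.table["total_count"].to_numpy()
        if not np.array_equal(stored, totals):
            bad = int(np.argmax(stored != totals))
            raise ValidationError(
                f"total_count for lane {matrix.lane_ids[bad]!r} is {stored[bad]} "
                f"but column sum is {totals[bad]}"
            )


# ---------------------------------------------------------------------------
# Delimited I/O.  Tab-separated; counts are plain integers, never decimals.
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, dialect: str = "tsv") -> CountMatrix:
    """Read a gene x lane count table.

    ``dialect='tsv'``: tab-separated with a header of lane ids, gene ids in the
    first column, and an optional ``length`` column.  ``dialect='mtx'``:
    MatrixMarket file with sidecar ``<path>.genes.txt`` / ``<path>.lanes.txt``
    label files (one label per line).
    """
    path = Path(path)
    if dialect == "mtx":
        return _read_count_mtx(path)
    if dialect != "tsv":
        raise FormatError(f"unknown dialect {dialect!r} (expected 'tsv' or 'mtx')")
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise FormatError(f"cannot parse count table {path}: {exc}") from exc
    if df.index.name is None and df.columns.size == 0:
        raise FormatError(f"count table {path} has no lane columns")
    gene_ids = [str(g) for g in df.index]
    lengths = None
    if _LENGTH_COL in df.columns:
        lengths = pd.to_numeric(df.pop(_LENGTH_COL), errors="coerce").to_numpy()
    lane_ids = [str(c) for c in df.columns]
    counts = np.empty((len(gene_ids), len(lane_ids)), dtype=np.int64)
    for j, lane in enumerate(lane_ids):
        col = pd.to_numeric(df[lane], errors="coerce")
        bad = col.isna() | (col < 0) | (col != np.floor(col))
        if bad.any():
            gene = gene_ids[int(np.argmax(bad.to_numpy()))]
            raise ValidationError(
                f"invalid count for gene {gene!r} in lane {lane!r}: "
                f"{df[lane][bad].iloc[0]!r}"
            )
        counts[:, j] = col.to_numpy(dtype=np.int64)
    return CountMatrix(gene_ids, lane_ids, counts, gene_lengths=lengths)


def write_count_table(matrix: CountMatrix, path: str | Path, dialect: str = "tsv") -> None:
    """Write a count table; byte-stable for a fixed input (rows/columns as given)."""
    path = Path(path)
    if dialect == "mtx":
        _write_count_mtx(matrix, path)
        return
    if dialect != "tsv":
        raise FormatError(f"unknown dialect {dialect!r} (expected 'tsv' or 'mtx')")
    buf = io.StringIO()
    header = ["gene_id"]
    if matrix.gene_lengths is not None:
        header.append(_LENGTH_COL)
    header.extend(matrix.lane_ids)
    buf.write("\t".join(header) + "\n")
    for i, gene in enumerate(matrix.gene_ids):
        row = [gene]
        if matrix.gene_lengths is not None:
            row.append(str(int(matrix.gene_lengths[i])))
        row.extend(str(int(c)) for c in matrix.counts[i])
        buf.write("\t".join(row) + "\n")
    path.write_text(buf.getvalue())


def _read_count_mtx(path: Path) -> CountMatrix:
    from scipy.io import mmread

    try:
        mat = mmread(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
    genes = Path(str(path) + ".genes.txt").read_text().splitlines()
    lanes = Path(str(path) + ".lanes.txt").read_text().splitlines()
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    return CountMatrix(genes, lanes, dense)


def _write_count_mtx(matrix: CountMatrix, path: Path) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    mmwrite(str(path), coo_matrix(matrix.counts))
    Path(str(path) + ".genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
    Path(str(path) + ".lanes.txt").write_text("\n".join(matrix.lane_ids) + "\n")


def read_lane_table(path: str | Path) -> LaneInfo:
    """Read lane metadata from a TSV with columns lane_id, condition, flow_cell, library_prep, total_count."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse lane table {path}: {exc}") from exc
    if "lane_id" not in df.columns:
        raise FormatError(f"lane table {path} is missing a lane_id column")
    df = df.set_index("lane_id")
    if "total_count" in df.columns:
        df["total_count"] = pd.to_numeric(df["total_count"], errors="coerce")
    return LaneInfo(df)


def write_lane_table(lane_info: LaneInfo, path: str | Path) -> None:
    lane_info.table.to_csv(path, sep="\t")


def pool_lanes(matrix: CountMatrix, lane_info: LaneInfo, group_by: str = "condition") -> CountMatrix:
    """Sum counts across lanes within groups of a lane attribute.

    Pooling by summation is justified when lane counts are Poisson with
    lane-specific depths: the pooled count is sufficient for the group rate.
    Output columns are the sorted group labels.
    """
    groups = lane_info.column(group_by)
    if list(groups.index) != matrix.lane_ids:
        raise ValidationError("lane ids of metadata and count matrix differ")
    labels = sorted(groups.unique())
    pooled = np.zeros((matrix.n_genes, len(labels)), dtype=np.int64)
    for k, label in enumerate(labels):
        cols = np.flatnonzero((groups == label).to_numpy())
        pooled[:, k] = matrix.counts[:, cols].sum(axis=1)
    return CountMatrix(list(matrix.gene_ids), [str(l) for l in labels], pooled,
                       gene_lengths=None if matrix.gene_lengths is None
                       else matrix.gene_lengths.copy())
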