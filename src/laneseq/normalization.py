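"""Between-lane normalization of read counts.

Lanes differ in sequencing depth, so gene counts must be put on a common
scale before expression can be compared across lanes.  All but one of the
procedures here are *global*: a single positive factor ``d_i`` scales the
counts of lane ``i`` and enters the downstream tests as an offset
(``log d_i`` in the Poisson log-linear model, or the reference column of a
2x2 table for the exact tests).

Three global factor choices are provided:

* **total-count** — the lane's total mapped reads (the convention underlying
  RPKM).  Dominated by the handful of most highly expressed genes, which in
  skewed transcriptomes can carry half of all reads; if those genes are
  differentially expressed the factors are biased.
* **housekeeping** — the lane's count for a single reference gene assumed
  constant across conditions (e.g. POLR2A).
* **upper-quartile** — the 75th percentile of the lane's gene counts after
  excluding genes with zero reads in every lane.  Robust to the extreme
  upper tail, informative despite the preponderance of zero/low counts
  (which makes the median useless).

Each raw factor vector is rescaled so the factors sum to the grand total of
reads over all lanes; ratios between lanes are unchanged but normalized
expression measures stay on the familiar counts-per-lane scale.

The one non-global procedure, :func:`quantile_normalize`, forces every
lane's count distribution onto a common reference (the per-rank median of
the lane-wise sorted count vectors) and rounds back to integers so the
count-based tests still apply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from laneseq.count_data import CountMatrix
from laneseq.errors import ValidationError

__all__ = [
    "NormalizationFactors",
    "rescale_factors",
    "total_count_factors",
    "housekeeping_factors",
    "upper_quartile_factors",
    "quantile_normalize",
    "per_length_measure",
]


@dataclass
class NormalizationFactors:
    """Per-lane positive scale factors ``d_i`` with the method that produced them."""

    lane_ids: list[str]
    d: np.ndarray
    method: str

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.lane_ids),):
            raise ValidationError("factor vector length does not match lane ids")
        if np.any(~np.isfinite(d)) or np.any(d <= 0):
            bad = int(np.argmax(~np.isfinite(d) | (d <= 0)))
            raise ValidationError(
                f"normalization factor for lane {self.lane_ids[bad]!r} must be "
                f"positive and finite, got {d[bad]!r}"
            )
        self.d = d

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.lane_ids, self.d))


def read_factors_table(path) -> NormalizationFactors:
    """Read per-lane factors from a two-column TSV (lane_id, d)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=0)
    if not {"lane_id", "d"}.issubset(df.columns):
        raise ValidationError(f"factors table {path} needs columns lane_id and d")
    method = str(df["method"].iloc[0]) if "method" in df.columns and len(df) else "custom"
    return NormalizationFactors([str(l) for l in df["lane_id"]],
                                df["d"].to_numpy(dtype=float), method)


def write_factors_table(factors: NormalizationFactors, path) -> None:
    with open(path, "w") as fh:
        fh.write("lane_id\td\tmethod\n")
        for lane, d in zip(factors.lane_ids, factors.d):
            fh.write(f"{lane}\t{d:.10g}\t{factors.method}\n")


def rescale_factors(raw: np.ndarray, lane_totals: np.ndarray,
                    lane_ids: list[str] | None = None,
                    method: str = "custom") -> NormalizationFactors:
    """Rescale raw per-lane factors so their sum equals the grand total count.

    ``d = raw * sum(lane_totals) / sum(raw)``; pairwise ratios are preserved.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(~np.isfinite(raw)) or np.any(raw <= 0):
        raise ValidationError("raw factors must be positive and finite")
    totals = np.asarray(lane_totals, dtype=float)
    if lane_ids is None:
        lane_ids = [f"lane{i}" for i in range(len(raw))]
    d = raw * (totals.sum() / raw.sum())
    return NormalizationFactors(list(lane_ids), d, method)


def total_count_factors(matrix: CountMatrix) -> NormalizationFactors:
    """Factors proportional to each lane's total read count.

    After grand-total rescaling the factors *are* the lane totals.
    """
    totals = matrix.lane_totals()
    if np.any(totals == 0):
        bad = int(np.argmax(totals == 0))
        raise ValidationError(f"lane {matrix.lane_ids[bad]!r} has zero total count")
    return rescale_factors(totals, totals, matrix.lane_ids, method="total")


def housekeeping_factors(matrix: CountMatrix, gene_id: str) -> NormalizationFactors:
    """Factors proportional to one reference gene's per-lane counts."""
    row = matrix.counts[matrix.gene_index(gene_id)]
    if np.any(row == 0):
        bad = int(np.argmax(row == 0))
        raise ValidationError(
            f"housekeeping gene {gene_id!r} has zero count in lane "
            f"{matrix.lane_ids[bad]!r}"
        )
    return rescale_factors(row, matrix.lane_totals(), matrix.lane_ids,
                           method="housekeeping")


def _nonzero_gene_mask(counts: np.ndarray) -> np.ndarray:
    """Genes with reads in at least one lane."""
    return counts.sum(axis=1) > 0


def upper_quartile_factors(matrix: CountMatrix) -> NormalizationFactors:
    """Factors proportional to each lane's 75th percentile of gene counts.

    Genes with zero reads across *all* lanes are excluded first; a gene with
    zero reads in some lanes but not others keeps its zeros in the lanes
    where it has none.  The quantile uses linear interpolation between order
    statistics (R's default "type 7").
    """
    keep = _nonzero_gene_mask(matrix.counts)
    retained = matrix.counts[keep]
    if retained.shape[0] < 4:
        raise ValidationError(
            f"only {retained.shape[0]} genes with nonzero counts; "
            "need at least 4 for an upper quartile"
        )
    uq = np.percentile(retained, 75, axis=0, method="linear")
    if np.any(uq <= 0):
        bad = int(np.argmax(uq <= 0))
        raise ValidationError(
            f"upper quartile of lane {matrix.lane_ids[bad]!r} is zero; "
            "count distribution too degenerate for quantile scaling"
        )
    return rescale_factors(uq, matrix.lane_totals(), matrix.lane_ids,
                           method="upper_quartile")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (fixed rule for bit-stable integer output)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def quantile_normalize(matrix: CountMatrix, ties: str = "first") -> CountMatrix:
    """Force every lane onto a common count distribution.

    For each rank ``r`` the reference value is the median across lanes of
    the ``r``-th smallest retained count; each lane's ``r``-th smallest
    count is replaced by that reference.  The result is rounded
    half-away-from-zero so downstream count-based tests remain applicable.
    Genes with zero reads in every lane are left at zero and excluded from
    the rank computation.

    ``ties`` controls how equal counts within a lane are assigned.  The
    default ``'first'`` gives each tied entry its own rank's reference value
    (ranks broken by input order, deterministic) so normalized lanes share
    the sorted reference vector exactly.  ``'mean'`` gives all members of a
    tie run the mean reference over their ranks — symmetric, but long tie
    runs then deviate from the common reference distribution.
    """
    if matrix.n_lanes < 2:
        raise ValidationError("quantile normalization needs at least 2 lanes")
    if ties not in ("first", "mean"):
        raise ValidationError(f"ties must be 'first' or 'mean', got {ties!r}")
    keep = _nonzero_gene_mask(matrix.counts)
    sub = matrix.counts[keep].astype(float)
    n, m = sub.shape
    if n == 0:
        return CountMatrix(list(matrix.gene_ids), list(matrix.lane_ids),
                           matrix.counts.copy(),
                           gene_lengths=None if matrix.gene_lengths is None
                           else matrix.gene_lengths.copy())
    reference = np.median(np.sort(sub, axis=0), axis=1)
    out = np.empty_like(sub)
    for j in range(m):
        col = sub[:, j]
        order = np.argsort(col, kind="stable")
        assigned = reference.copy()
        if ties == "mean":
            sorted_col = col[order]
            start = 0
            while start < n:
                stop = start
                while stop + 1 < n and sorted_col[stop + 1] == sorted_col[start]:
                    stop += 1
                if stop > start:
                    assigned[start:stop + 1] = reference[start:stop + 1].mean()
                start = stop + 1
        out[order, j] = assigned
    result = matrix.counts.astype(float).copy()
    result[keep] = out
    result = _round_half_away(result).astype(np.int64)
    return CountMatrix(list(matrix.gene_ids), list(matrix.lane_ids), result,
                       gene_lengths=None if matrix.gene_lengths is None
                       else matrix.gene_lengths.copy())


def per_length_measure(matrix: CountMatrix, factors: NormalizationFactors) -> np.ndarray:
    """Reads per kilobase of gene model per million (rescaled) reads.

    ``value[i, j] = count / (d_j / 1e6) / (length_i / 1e3)`` — linear in the
    count, so a doubled factor halves the measure.
    """
    if matrix.gene_lengths is None:
        raise ValidationError("per-length measures require gene_lengths")
    if factors.lane_ids != matrix.lane_ids:
        raise ValidationError("factor lane ids do not match matrix lanes")
    d = factors.d[None, :]
    lengths = matrix.gene_lengths[:, None].astype(float)
    return matrix.counts / (d / 1e6) / (lengths / 1e3)
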