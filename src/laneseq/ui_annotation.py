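"""Union-intersection (UI) gene models and read counting.

Summarizing expression at the whole-gene level requires a gene region that
is unambiguous under alternative splicing and overlapping annotation.  A
*constitutive exon* is a maximal run of exonic bases present in every
isoform of a gene; the *UI gene* is the union of a gene's constitutive
exons minus the coding exons of all other genes.  Reads are then counted
over UI regions, strands pooled, each read counted at most once per gene.

Coordinates are 0-based half-open internally; GTF (1-based inclusive) is
converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from laneseq.count_data import CountMatrix
from laneseq.errors import AnnotationError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "UIGene",
    "AlignedRead",
    "constitutive_exons",
    "build_ui_genes",
    "count_reads",
    "sample_fixed_length",
    "read_gtf",
    "read_bed_alignments",
    "read_sam_alignments",
    "write_bed",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValidationError(f"need start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One isoform: its exons (sorted, non-overlapping) with per-exon coding flags."""

    gene_id: str
    transcript_id: str
    exons: list[GenomicInterval]
    coding: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id!r} has no exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise AnnotationError(
                f"transcript {self.transcript_id!r} spans chromosomes {sorted(chroms)}"
            )
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping exons in transcript {self.transcript_id!r}"
                )
        if not self.coding:
            self.coding = [False] * len(self.exons)
        if len(self.coding) != len(self.exons):
            raise ValidationError("coding flags must match number of exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom


@dataclass
class UIGene:
    """Disjoint sorted regions forming the gene-level region of interest."""

    gene_id: str
    regions: list[GenomicInterval]
    length: int = 0

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: (r.start, r.end))
        for a, b in zip(self.regions, self.regions[1:]):
            if b.start < a.end:
                raise ValidationError(f"UI regions of {self.gene_id!r} overlap")
        total = sum(r.width for r in self.regions)
        if self.length == 0:
            self.length = total
        elif self.length != total:
            raise ValidationError(
                f"stated length {self.length} != total region width {total}"
            )

    @property
    def chrom(self) -> str:
        return self.regions[0].chrom


@dataclass(frozen=True)
class AlignedRead:
    """Minimal alignment record: location, source lane and uniqueness flag."""

    chrom: str
    start: int
    end: int
    lane_id: str
    unique: bool = True


# ---------------------------------------------------------------------------
# Interval set arithmetic on (start, end) pair lists (half-open, sorted)
# ---------------------------------------------------------------------------

def _merge(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals as maximal disjoint sorted intervals."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(pairs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intersection of two disjoint sorted interval lists."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set difference a \\ b for disjoint sorted interval lists."""
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            if b[k][0] > cur:
                out.append((cur, b[k][0]))
            cur = max(cur, b[k][1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def constitutive_exons(transcripts: list[TranscriptModel]) -> list[GenomicInterval]:
    """Base-level intersection of exonic coverage across all isoforms of a gene.

    Returns maximal disjoint intervals — the bases (portions of or entire
    exons) present in every isoform.  A single isoform yields its own exons.
    """
    if not transcripts:
        raise ValidationError("need at least one transcript")
    chroms = {t.chrom for t in transcripts}
    if len(chroms) > 1:
        raise AnnotationError(
            f"transcripts of gene {transcripts[0].gene_id!r} span chromosomes "
            f"{sorted(chroms)}"
        )
    chrom = transcripts[0].chrom
    common = _merge([(e.start, e.end) for e in transcripts[0].exons])
    for t in transcripts[1:]:
        common = _intersect(common, _merge([(e.start, e.end) for e in t.exons]))
        if not common:
            break
    return [GenomicInterval(chrom, s, e) for s, e in common]


def build_ui_genes(transcripts: list[TranscriptModel],
                   chromosomes: list[str] | None = None) -> list[UIGene]:
    """Build UI genes: constitutive exons minus other genes' coding exons.

    Genes whose resulting region is empty are omitted.  Genes whose
    transcripts span multiple chromosomes are reported and skipped.
    ``chromosomes`` optionally restricts to an allow-list (default: all).
    Output is sorted by gene id.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)

    # per gene: chromosome + merged coding exon intervals
    coding_by_chrom: dict[str, dict[str, list[tuple[int, int]]]] = {}
    const: dict[str, list[GenomicInterval]] = {}
    for gene_id in sorted(by_gene):
        ts = by_gene[gene_id]
        try:
            ce = constitutive_exons(ts)
        except AnnotationError as exc:
            logger.warning("skipping gene %s: %s", gene_id, exc)
            continue
        chrom = ts[0].chrom
        if chromosomes is not None and chrom not in chromosomes:
            continue
        const[gene_id] = ce
        coding = [(e.start, e.end)
                  for t in ts for e, c in zip(t.exons, t.coding) if c]
        coding_by_chrom.setdefault(chrom, {})[gene_id] = _merge(coding)

    out: list[UIGene] = []
    for gene_id in sorted(const):
        ce = const[gene_id]
        if not ce:
            continue
        chrom = ce[0].chrom
        others = _merge([iv
                         for g, ivs in coding_by_chrom.get(chrom, {}).items()
                         if g != gene_id for iv in ivs])
        regions = _subtract([(r.start, r.end) for r in ce], others)
        if not regions:
            continue
        out.append(UIGene(gene_id, [GenomicInterval(chrom, s, e) for s, e in regions]))
    return out


def count_reads(alignments, ui_genes: list[UIGene],
                lane_ids: list[str] | None = None) -> CountMatrix:
    """Count unique-mapping reads overlapping UI regions, per gene and lane.

    A read is assigned to a UI gene when its alignment overlaps the gene's
    regions by at least one base (strands pooled); each read counts at most
    once per gene, but a read overlapping UI regions of two different genes
    increments both (logged as ambiguous).  Reads on chromosomes absent
    from the annotation are tallied as unassigned and logged.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for gi, gene in enumerate(ui_genes):
        for r in gene.regions:
            trees.setdefault(r.chrom, IntervalTree())[r.start:r.end] = gi

    counts: dict[str, np.ndarray] = {}
    if lane_ids is not None:
        for lane in lane_ids:
            counts[lane] = np.zeros(len(ui_genes), dtype=np.int64)
    unassigned = 0
    ambiguous = 0
    for read in alignments:
        if not read.unique:
            continue
        col = counts.get(read.lane_id)
        if col is None:
            if lane_ids is not None:
                raise ValidationError(f"read from unexpected lane {read.lane_id!r}")
            col = counts.setdefault(read.lane_id, np.zeros(len(ui_genes), dtype=np.int64))
        tree = trees.get(read.chrom)
        if tree is None:
            unassigned += 1
            continue
        genes = {iv.data for iv in tree.overlap(read.start, read.end)}
        if not genes:
            unassigned += 1
            continue
        if len(genes) > 1:
            ambiguous += 1
        for gi in genes:
            col[gi] += 1
    if unassigned:
        logger.info("%d reads unassigned (no overlapping UI region)", unassigned)
    if ambiguous:
        logger.info("%d reads ambiguous (overlap UI regions of several genes)", ambiguous)
    lanes = lane_ids if lane_ids is not None else sorted(counts)
    mat = (np.column_stack([counts[l] for l in lanes]) if lanes
           else np.zeros((len(ui_genes), 0), dtype=np.int64))
    return CountMatrix([g.gene_id for g in ui_genes], list(lanes), mat,
                       gene_lengths=np.array([g.length for g in ui_genes], dtype=np.int64)
                       if ui_genes else None)


def sample_fixed_length(ui_gene: UIGene, L: int, seed: int) -> UIGene:
    """Pick a random contiguous ``L``-base window of a UI gene.

    The window is contiguous in UI coordinate space (along the concatenated
    UI bases), with its start uniform over the valid positions, so it may
    map back to more than one genomic interval.  Deterministic for a fixed
    seed.  Genes shorter than ``L`` are ineligible.
    """
    if L < 1:
        raise ValidationError("window length must be >= 1")
    if ui_gene.length < L:
        raise ValidationError(
            f"gene {ui_gene.gene_id!r} is ineligible: UI length {ui_gene.length} < {L}"
        )
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, ui_gene.length - L + 1))
    return _ui_window(ui_gene, start, L)


def _ui_window(ui_gene: UIGene, ui_start: int, L: int) -> UIGene:
    """Map a UI-coordinate window [ui_start, ui_start+L) back to genomic intervals."""
    remaining = L
    pos = 0
    out: list[GenomicInterval] = []
    for r in ui_gene.regions:
        if remaining == 0:
            break
        if pos + r.width <= ui_start:
            pos += r.width
            continue
        offset = max(0, ui_start - pos)
        take = min(r.width - offset, remaining)
        out.append(GenomicInterval(r.chrom, r.start + offset, r.start + offset + take,
                                   r.strand))
        remaining -= take
        pos += r.width
    return UIGene(ui_gene.gene_id, out)


# ---------------------------------------------------------------------------
# File format boundaries
# ---------------------------------------------------------------------------

def read_gtf(path: str) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    Requires ``exon`` features with ``gene_id``/``transcript_id`` attributes;
    ``CDS`` features mark the coding portions (an exon's coding flag is set
    when it overlaps a CDS of the same transcript).  GTF's 1-based inclusive
    coordinates are converted to the internal 0-based half-open convention.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            disable_infer_genes=True, disable_infer_transcripts=True)
    exons: dict[tuple[str, str], list[GenomicInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    for feat in db.features_of_type("CDS"):
        tid = feat.attributes["transcript_id"][0]
        cds.setdefault(tid, []).append((feat.start - 1, feat.end))
    for feat in db.features_of_type("exon"):
        gid = feat.attributes["gene_id"][0]
        tid = feat.attributes["transcript_id"][0]
        strand = feat.strand if feat.strand in ("+", "-") else "."
        exons.setdefault((gid, tid), []).append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand))
    out = []
    for (gid, tid), ivs in sorted(exons.items()):
        cds_merged = _merge(cds.get(tid, []))
        ivs = sorted(ivs, key=lambda e: (e.start, e.end))
        coding = [bool(_intersect([(e.start, e.end)], cds_merged)) for e in ivs]
        out.append(TranscriptModel(gid, tid, ivs, coding))
    return out


def read_bed_alignments(path: str, lane_id: str | None = None):
    """Yield :class:`AlignedRead` from a BED6 file.

    Convention: the name field carries the lane id (overridden by
    ``lane_id``), and a score of 1 marks a unique-mapping read (0 = not
    unique).  Missing name/score columns default to ``lane_id`` / unique.
    """
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            lane = lane_id or (fields[3] if len(fields) > 3 else "lane0")
            unique = True if len(fields) < 5 else fields[4] not in ("0", "0.0")
            yield AlignedRead(chrom, start, end, lane, unique)


def read_sam_alignments(path: str, lane_id: str | None = None, unique=None):
    """Yield :class:`AlignedRead` from a SAM/BAM file via pysam.

    ``unique`` is a predicate on the pysam record deciding the uniqueness
    flag; the default accepts primary alignments with mapping quality > 0.
    The lane id is taken from the read group (RG tag) unless overridden.
    """
    import pysam

    if unique is None:
        def unique(rec):  # noqa: ANN001
            return (not rec.is_secondary and not rec.is_supplementary
                    and rec.mapping_quality > 0)
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            lane = lane_id
            if lane is None:
                lane = rec.get_tag("RG") if rec.has_tag("RG") else "lane0"
            yield AlignedRead(rec.reference_name, rec.reference_start,
                              rec.reference_end, str(lane), bool(unique(rec)))


def write_bed(ui_genes: list[UIGene], path: str) -> None:
    """Write UI regions as BED6, one line per region, name = gene id."""
    with open(path, "w") as fh:
        for gene in ui_genes:
            for r in gene.regions:
                strand = r.strand if r.strand in ("+", "-") else "."
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{gene.gene_id}\t0\t{strand}\n")
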