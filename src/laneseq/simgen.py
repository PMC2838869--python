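"""Seeded synthetic data with the statistical structure the methods assume.

The generator emulates a two-condition, multi-lane sequencing experiment:

* per-lane counts are Poisson with mean ``d_i * lambda_{a(i),j} * theta_i``,
  where ``d_i`` is a lane depth multiplier, ``lambda`` the condition-level
  expression and ``theta_i`` optional multiplicative flow-cell and
  library-prep effects shared across genes;
* baseline expression is heavy-tailed log-normal.  The default log-scale
  sd of 1.65 makes the top 5% of genes carry about half of the expected
  total count (for a log-normal, the expected-count share of the top 5%
  is Phi(sigma - 1.645), which is 1/2 at sigma = 1.645) — the skew that
  makes total-count normalization fragile;
* a configurable fraction of genes is differentially expressed, optionally
  concentrated in the highest-expression genes and in one direction (the
  regime in which total-count factors absorb the DE of a few dominant
  genes and bias everything else);
* gene lengths are log-uniform, and a noisy gold standard mimics an
  independent qRT-PCR-style log-ratio measurement.

The default layout mirrors a two-flow-cell design with seven lanes per
condition and library preparation confounded with condition.  All draws
come from one seeded generator in a fixed substream order (lengths,
expression, DE assignment, lane effects, counts, then gold/reads), so every
bundle is reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from laneseq.count_data import CountMatrix, LaneInfo
from laneseq.errors import ValidationError
from laneseq.ui_annotation import UIGene

__all__ = [
    "LaneSpec",
    "SimConfig",
    "SimTruth",
    "simulate_counts",
    "simulate_gold",
    "simulate_reads",
    "resample_fixed_length_counts",
    "scenario_null",
    "scenario_basic_de",
    "scenario_highcount_bias",
    "scenario_length_bias",
    "default_lanes",
]


@dataclass(frozen=True)
class LaneSpec:
    lane_id: str
    condition: str
    flow_cell: str
    library_prep: str
    depth: float  # relative sequencing-depth multiplier, > 0


def default_lanes(depth_spread: float = 0.2) -> list[LaneSpec]:
    """Seven lanes per condition over two flow-cells, prep confounded with condition.

    Depths are fixed (not drawn) on an even grid spanning
    ``1 +/- depth_spread`` so that depth recovery has a known target.
    """
    lanes = []
    layout = [("A", "F1", 4), ("B", "F1", 3), ("A", "F2", 3), ("B", "F2", 4)]
    idx = {"A": 0, "B": 0}
    n_total = sum(k for _, _, k in layout)
    depths = np.linspace(1 - depth_spread, 1 + depth_spread, n_total)
    i = 0
    for cond, fc, k in layout:
        for _ in range(k):
            idx[cond] += 1
            lanes.append(LaneSpec(f"{cond}{idx[cond]}", cond, fc, f"prep{cond}",
                                  float(depths[i])))
            i += 1
    return lanes


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions used throughout.

    ``mean_count`` sets the expected reads per gene per unit-depth lane
    (the log-normal expression law is shifted to hit it); with the default
    2,000 genes this gives lane totals around 10^5 — a scaled-down lane.
    ``de_lfc_sd`` is the log-fold-change spread of DE genes (natural log).
    ``highcount_de_bias`` makes the top-expression 5% of genes DE in one
    direction (log-fold-change ``bias_lfc``) instead of symmetric DE.
    """

    n_genes: int = 2000
    lanes: list[LaneSpec] = field(default_factory=default_lanes)
    mean_count: float = 50.0
    expression_sigma: float = 1.65
    de_fraction: float = 0.1
    de_lfc_sd: float = 1.5
    de_lfc_magnitude: float | None = None  # if set: lfc = +/- magnitude, random sign
    reads_per_bp: float | None = None  # if set: expression proportional to length
    highcount_de_bias: bool = False
    bias_fraction: float = 0.05
    bias_lfc: float = 1.0
    flowcell_effect_sd: float = 0.0
    libprep_effect_sd: float = 0.0
    length_min: int = 200
    length_max: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or not self.lanes:
            raise ValidationError("need at least one gene and one lane")
        if any(l.depth <= 0 for l in self.lanes):
            raise ValidationError("lane depths must be positive")
        for frac in (self.de_fraction, self.bias_fraction):
            if not 0 <= frac <= 1:
                raise ValidationError("fractions must lie in [0, 1]")
        if self.expression_sigma < 0 or self.de_lfc_sd < 0:
            raise ValidationError("scale parameters must be non-negative")
        if self.flowcell_effect_sd < 0 or self.libprep_effect_sd < 0:
            raise ValidationError("effect sds must be non-negative")
        if not 1 <= self.length_min <= self.length_max:
            raise ValidationError("need 1 <= length_min <= length_max")


@dataclass
class SimTruth:
    """Ground truth behind a simulated bundle."""

    genes: pd.DataFrame       # gene_id, length, lambda_<cond>..., lfc, is_de
    lane_effects: pd.DataFrame  # lane_id, depth, theta (multiplicative)
    conditions: list[str]


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, LaneInfo, SimTruth]:
    """Draw a gene x lane Poisson count matrix plus metadata and ground truth.

    ``X_ij ~ Poisson(d_i * lambda_{a(i),j} * theta_i)`` with the structure
    described in the module docstring.  ``lfc`` is the log-fold-change of
    the second sorted condition relative to the first (matching the
    direction convention of the DE tests).
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    conditions = sorted({l.condition for l in config.lanes})
    if len(conditions) not in (1, 2):
        raise ValidationError("the generator models one or two conditions")

    # substream order: lengths, expression, DE assignment, lane effects, counts
    lengths = np.exp(rng.uniform(np.log(config.length_min),
                                 np.log(config.length_max), G)).astype(np.int64)
    lengths = np.clip(lengths, config.length_min, config.length_max)

    if config.reads_per_bp is not None:
        # expression proportional to length: longer transcripts shed more
        # sequencible fragments at the same molar abundance
        lam = config.reads_per_bp * lengths.astype(float)
    else:
        sigma = config.expression_sigma
        lam = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=G)
        lam *= config.mean_count  # E[lambda] = mean_count

    def draw_lfc(n: int) -> np.ndarray:
        if config.de_lfc_magnitude is not None:
            # sign-balanced fixed magnitude: leaves count quantiles unchanged
            # in expectation, unlike a log-normal effect law
            return config.de_lfc_magnitude * rng.choice([-1.0, 1.0], size=n)
        return rng.normal(0.0, config.de_lfc_sd, n)

    lfc = np.zeros(G)
    is_de = np.zeros(G, dtype=bool)
    if config.highcount_de_bias:
        n_bias = int(round(config.bias_fraction * G))
        top = np.argsort(lam)[::-1][:n_bias]
        is_de[top] = True
        lfc[top] = config.bias_lfc
        others = np.flatnonzero(~is_de)
        n_de = int(round(config.de_fraction * len(others)))
        pick = rng.choice(others, size=n_de, replace=False)
        is_de[pick] = True
        lfc[pick] = draw_lfc(n_de)
    else:
        n_de = int(round(config.de_fraction * G))
        pick = rng.choice(G, size=n_de, replace=False)
        is_de[pick] = True
        lfc[pick] = draw_lfc(n_de)

    fcs = sorted({l.flow_cell for l in config.lanes})
    lps = sorted({(l.flow_cell, l.library_prep) for l in config.lanes})
    fc_eff = dict(zip(fcs, np.exp(rng.normal(0.0, config.flowcell_effect_sd, len(fcs)))))
    lp_eff = dict(zip(lps, np.exp(rng.normal(0.0, config.libprep_effect_sd, len(lps)))))

    # split the effect symmetrically: lam is the geometric mean across
    # conditions, so sign-balanced DE perturbs both count distributions
    # identically and cancels from between-condition quantile ratios
    if len(conditions) == 2:
        lam_by_cond = {conditions[0]: lam * np.exp(-lfc / 2),
                       conditions[1]: lam * np.exp(lfc / 2)}
    else:
        lfc = np.zeros(G)
        is_de[:] = False
        lam_by_cond = {conditions[0]: lam}
    counts = np.empty((G, len(config.lanes)), dtype=np.int64)
    theta = np.empty(len(config.lanes))
    for i, lane in enumerate(config.lanes):
        theta[i] = fc_eff[lane.flow_cell] * lp_eff[(lane.flow_cell, lane.library_prep)]
        mu = lane.depth * theta[i] * lam_by_cond[lane.condition]
        counts[:, i] = rng.poisson(mu)

    gene_ids = [f"g{k:05d}" for k in range(G)]
    matrix = CountMatrix(gene_ids, [l.lane_id for l in config.lanes], counts,
                         gene_lengths=lengths)
    lane_info = LaneInfo.from_records(
        [(l.lane_id, l.condition, l.flow_cell, l.library_prep, int(t))
         for l, t in zip(config.lanes, matrix.lane_totals())])
    gene_cols = {"gene_id": gene_ids, "length": lengths}
    for c in conditions:
        gene_cols[f"lambda_{c}"] = lam_by_cond[c]
    gene_cols["lfc"] = lfc
    gene_cols["is_de"] = is_de
    genes = pd.DataFrame(gene_cols).set_index("gene_id")
    lane_effects = pd.DataFrame({
        "lane_id": [l.lane_id for l in config.lanes],
        "depth": [l.depth for l in config.lanes],
        "theta": theta,
    }).set_index("lane_id")
    return matrix, lane_info, SimTruth(genes, lane_effects, conditions)


def simulate_gold(truth: SimTruth, noise_sd: float, seed: int) -> pd.DataFrame:
    """Noisy gold-standard log-ratios: true log-fold-change + Gaussian noise."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    lr = truth.genes["lfc"].to_numpy() + rng.normal(0.0, noise_sd, len(truth.genes))
    return pd.DataFrame({"log_ratio": lr}, index=truth.genes.index)


def simulate_reads(ui_genes: list[UIGene], expected_counts: np.ndarray,
                   lane_id: str, seed: int, read_length: int = 35) -> list[tuple]:
    """Place Poisson numbers of fixed-length reads uniformly on UI genes.

    Returns sorted BED-style records ``(chrom, start, end, lane_id, 1)``;
    each read starts uniformly over the gene's UI bases and is truncated at
    the enclosing region boundary so that it never strays off the gene.
    Genes whose UI length is below the read length are skipped.
    """
    import warnings

    rng = np.random.default_rng(seed)
    records = []
    for gene, mu in zip(ui_genes, np.asarray(expected_counts, dtype=float)):
        if gene.length < read_length:
            warnings.warn(f"gene {gene.gene_id!r} shorter than read length; skipped")
            continue
        n = rng.poisson(mu)
        if n == 0:
            continue
        starts = rng.integers(0, gene.length - read_length + 1, size=n)
        bounds = np.cumsum([0] + [r.width for r in gene.regions])
        for s in starts:
            ridx = int(np.searchsorted(bounds, s, side="right") - 1)
            region = gene.regions[ridx]
            gstart = region.start + (int(s) - int(bounds[ridx]))
            gend = min(gstart + read_length, region.end)
            records.append((region.chrom, gstart, gend, lane_id, 1))
    records.sort()
    return records


def resample_fixed_length_counts(matrix: CountMatrix, L: int, seed: int) -> CountMatrix:
    """Restrict each gene's counts to a fixed-length subregion by thinning.

    Under uniform read placement along a gene, the reads falling in an
    ``L``-base window are a binomial thinning of the gene's count with
    probability ``L / length``; this reproduces a fixed-length reanalysis
    without re-simulating reads.  All genes must be at least ``L`` bp.
    """
    if matrix.gene_lengths is None:
        raise ValidationError("fixed-length resampling requires gene_lengths")
    if np.any(matrix.gene_lengths < L):
        raise ValidationError(f"all genes must be at least {L} bp for resampling")
    rng = np.random.default_rng(seed)
    p = (L / matrix.gene_lengths.astype(float))[:, None]
    thinned = rng.binomial(matrix.counts, np.broadcast_to(p, matrix.counts.shape))
    return CountMatrix(list(matrix.gene_ids), list(matrix.lane_ids), thinned,
                       gene_lengths=np.full(matrix.n_genes, L, dtype=np.int64))


# ---------------------------------------------------------------------------
# Canned scenarios
# ---------------------------------------------------------------------------

def _bundle(config: SimConfig, gold_noise_sd: float):
    matrix, lane_info, truth = simulate_counts(config)
    gold = simulate_gold(truth, gold_noise_sd, seed=config.seed + 1)
    return {"counts": matrix, "lanes": lane_info, "truth": truth,
            "gold": gold, "config": config}


def scenario_null(seed: int, n_genes: int = 2000) -> dict:
    """No DE, no batch effects: pure depth differences."""
    return _bundle(SimConfig(n_genes=n_genes, de_fraction=0.0, seed=seed),
                   gold_noise_sd=0.05)


def scenario_basic_de(seed: int, n_genes: int = 2000) -> dict:
    """Symmetric DE in 10% of genes, no high-count bias."""
    return _bundle(SimConfig(n_genes=n_genes, seed=seed), gold_noise_sd=0.05)


def scenario_length_bias(seed: int, n_genes: int = 1000) -> dict:
    """Counts proportional to gene length, small effects everywhere.

    Expected per-condition pooled count roughly equals the gene length in
    bp (reads_per_bp then lane pooling), lengths log-uniform on
    [250, 5000] bp; every gene carries a small length-independent effect
    (log-fold-change sd 0.3), mimicking data in which no gene is exactly
    null.  In this regime the unweighted t statistics rank long genes as
    more significant; dividing by sqrt(length) removes the association, as
    does restricting every gene to a fixed 250 bp subregion.
    """
    lanes = default_lanes()
    n_per_cond = sum(1 for l in lanes if l.condition == "A")
    config = SimConfig(n_genes=n_genes, lanes=lanes, de_fraction=1.0,
                       de_lfc_sd=0.3, reads_per_bp=1.0 / n_per_cond,
                       length_min=250, length_max=5000, seed=seed)
    return _bundle(config, gold_noise_sd=0.05)


def scenario_highcount_bias(seed: int, n_genes: int = 2000, bias: bool = True) -> dict:
    """A few dominant genes DE in one direction, carrying ~half the counts.

    The top 5% of genes by expression are over-expressed in the second
    condition (log-fold-change 1.0), so total-count factors absorb their DE
    and bias the estimated log-ratios of the majority of (null) genes,
    while upper-quartile factors do not.  A further 10% of the remaining
    genes carry sign-balanced DE of magnitude 2.5 to populate the gold
    standard's DE classes without shifting the count quantiles.
    """
    config = SimConfig(n_genes=n_genes, highcount_de_bias=bias,
                       de_lfc_magnitude=2.5, seed=seed)
    return _bundle(config, gold_noise_sd=0.05)
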