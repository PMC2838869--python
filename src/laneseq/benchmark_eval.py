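"""Benchmarking DE calls against a gold standard, and model diagnostics.

The evaluation mirrors a qRT-PCR benchmark: genes assayed by an independent
platform are split into non-DE, DE+ and DE- classes from their absolute
log-fold-change (below ``a`` / above ``b``; the interval ``[a, b]`` is a
"no-call" buffer that is ignored).  ROC curves are *direction-aware*: a
true positive requires calling the gene DE **and** agreeing with the gold
standard on the direction; a DE call in the wrong direction on a gold-DE
gene is a false positive.

Also here: a per-gene Pearson chi-square goodness-of-fit check of the
offset-only Poisson model across replicate lanes (for QQ display against
the chi-square reference), and the (FMM-FPM)/FMM read-category proxy for
the sequencing error rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from laneseq.count_data import CountMatrix, LaneInfo
from laneseq.de_testing import design_matrix, fit_poisson_glm
from laneseq.errors import ValidationError
from laneseq.normalization import NormalizationFactors

__all__ = [
    "ConfusionCounts",
    "classify_gold",
    "confusion_at_threshold",
    "roc_curve",
    "poisson_gof",
    "error_rate_proxy",
    "plot_roc",
    "plot_gof_qq",
]

CLASS_NON_DE = "nonDE"
CLASS_DE_UP = "DE+"
CLASS_DE_DOWN = "DE-"
CLASS_NO_CALL = "no-call"


@dataclass
class ConfusionCounts:
    """Direction-aware confusion counts against the gold standard."""

    TP: int
    FP: int
    TN: int
    FN: int
    P: int  # gold-standard DE genes
    N: int  # gold-standard non-DE genes

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN", "P", "N"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.TP > self.P or self.TN > self.N:
            raise ValidationError("TP <= P and TN <= N must hold")

    @property
    def tpr(self) -> float:
        return self.TP / self.P if self.P else math.nan

    @property
    def fpr(self) -> float:
        return self.FP / self.N if self.N else math.nan


def classify_gold(log_ratios: pd.Series | dict, a: float = 0.2, b: float = 2.0) -> pd.DataFrame:
    """Split gold-standard genes into nonDE / DE+ / DE- / no-call classes.

    A gene is non-DE if its absolute log-ratio is below ``a``, DE (with the
    sign of the ratio) if above ``b``, and a no-call if it falls in
    ``[a, b]``.  The default thresholds are ``a = 0.2`` and ``b = 2.0``.
    """
    if not (0 <= a < b):
        raise ValidationError(f"need 0 <= a < b, got a={a}, b={b}")
    lr = pd.Series(log_ratios, dtype=float)
    cls = np.where(np.abs(lr) < a, CLASS_NON_DE,
                   np.where(np.abs(lr) > b,
                            np.where(lr > 0, CLASS_DE_UP, CLASS_DE_DOWN),
                            CLASS_NO_CALL))
    return pd.DataFrame({"log_ratio": lr, "gold_class": cls})


def _check_gold(gold: pd.DataFrame) -> pd.DataFrame:
    if "gold_class" not in gold.columns:
        raise ValidationError("gold standard must have a 'gold_class' column "
                              "(use classify_gold)")
    return gold[gold["gold_class"] != CLASS_NO_CALL]


def confusion_at_threshold(calls: pd.DataFrame, gold: pd.DataFrame) -> ConfusionCounts:
    """Count TP/FP/TN/FN for a fixed set of signed DE calls.

    ``calls`` is indexed by gene_id with columns ``de`` (bool) and
    ``direction`` (-1/0/+1).  The cell mapping: a DE call is a TP only when
    the gold class is DE in the *same* direction; a DE call on a gold-DE
    gene in the wrong direction is an FP, as is any DE call on a gold
    non-DE gene; a non-DE call on a gold-DE gene is an FN.  Genes in the
    calls but not in the (non-no-call) gold are ignored.
    """
    gold = _check_gold(gold)
    shared = calls.index.intersection(gold.index)
    g = gold.loc[shared, "gold_class"]
    de = calls.loc[shared, "de"].astype(bool)
    direction = calls.loc[shared, "direction"].astype(int)
    P = int((gold["gold_class"].isin([CLASS_DE_UP, CLASS_DE_DOWN])).sum())
    N = int((gold["gold_class"] == CLASS_NON_DE).sum())

    gold_up = g == CLASS_DE_UP
    gold_down = g == CLASS_DE_DOWN
    gold_non = g == CLASS_NON_DE
    call_up = de & (direction > 0)
    call_down = de & (direction < 0)
    call_de = call_up | call_down

    TP = int((gold_up & call_up).sum() + (gold_down & call_down).sum())
    FP = int((gold_non & call_de).sum()
             + (gold_up & call_down).sum() + (gold_down & call_up).sum())
    FN = int(((gold_up | gold_down) & ~call_de).sum())
    TN = int((gold_non & ~call_de).sum())
    return ConfusionCounts(TP, FP, TN, FN, P, N)


def roc_curve(p_values: pd.Series, directions: pd.Series, gold: pd.DataFrame) -> pd.DataFrame:
    """Direction-aware ROC sweep over the observed p-values.

    At each threshold, genes with ``p <= threshold`` are called DE with their
    estimated direction.  TPR = TP / (number of gold DE genes); FPR = FP /
    (number of gold non-DE genes).  The returned points are sorted by FPR
    and include the (0, 0) origin and the everything-called endpoint.
    """
    gold = _check_gold(gold)
    shared = gold.index.intersection(p_values.index)
    p = p_values.loc[shared].astype(float)
    d = directions.loc[shared].astype(int)
    g = gold.loc[shared, "gold_class"]
    P = int(g.isin([CLASS_DE_UP, CLASS_DE_DOWN]).sum())
    N = int((g == CLASS_NON_DE).sum())
    if P == 0 or N == 0:
        raise ValidationError(f"ROC undefined: P={P}, N={N} gold genes")

    order = np.argsort(p.to_numpy(), kind="stable")
    p_sorted = p.to_numpy()[order]
    g_sorted = g.to_numpy()[order]
    d_sorted = d.to_numpy()[order]

    # genes with direction 0 are never counted as positive calls
    de_called = d_sorted != 0
    tp_step = (((g_sorted == CLASS_DE_UP) & (d_sorted > 0))
               | ((g_sorted == CLASS_DE_DOWN) & (d_sorted < 0)))
    fp_step = de_called & ~tp_step
    fp_nonde_step = (g_sorted == CLASS_NON_DE) & de_called
    tp_cum = np.cumsum(tp_step)
    fp_cum = np.cumsum(fp_step)
    fp_nonde_cum = np.cumsum(fp_nonde_step)

    # collapse ties in p: threshold sweep over distinct observed p-values
    distinct = np.flatnonzero(np.diff(p_sorted, append=np.inf) != 0)
    rows = [(np.nan, 0, 0, N, P, 0.0, 0.0)]
    for i in distinct:
        tp, fp = int(tp_cum[i]), int(fp_cum[i])
        # a wrong-direction call on a gold-DE gene is an FP, not an FN
        fn = P - tp - (fp - int(fp_nonde_cum[i]))
        tn = N - int(fp_nonde_cum[i])
        rows.append((p_sorted[i], tp, fp, tn, fn, fp / N, tp / P))
    out = pd.DataFrame(rows, columns=["threshold", "TP", "FP", "TN", "FN", "FPR", "TPR"])
    return out.sort_values(["FPR", "TPR"], kind="stable").reset_index(drop=True)


def roc_auc(roc: pd.DataFrame) -> float:
    """Trapezoidal area under a ROC point list (clipped to FPR in [0, 1])."""
    fpr = roc["FPR"].to_numpy()
    tpr = roc["TPR"].to_numpy()
    return float(np.trapezoid(tpr, fpr))


def interpolate_tpr(roc: pd.DataFrame, fpr_grid: np.ndarray) -> np.ndarray:
    """Step-interpolate TPR of a ROC curve at given FPR values (best TPR at or below)."""
    fpr = roc["FPR"].to_numpy()
    tpr = roc["TPR"].to_numpy()
    out = np.zeros_like(np.asarray(fpr_grid, dtype=float))
    for i, x in enumerate(fpr_grid):
        ok = fpr <= x + 1e-12
        out[i] = tpr[ok].max() if ok.any() else 0.0
    return out


def poisson_gof(matrix: CountMatrix, lane_info: LaneInfo,
                factors: NormalizationFactors, design_spec: str = "null",
                statistic: str = "pearson") -> pd.DataFrame:
    """Per-gene goodness-of-fit of the offset Poisson model across lanes.

    For each gene the model is fit (closed form for the offset-only model:
    fitted mean ``mu_i = d_i * lambda_hat``) and the Pearson statistic
    ``sum_i (x_i - mu_i)^2 / mu_i`` is returned with ``df = lanes - params``
    together with matched chi-square theoretical quantiles for a QQ plot.
    Under replicate lanes of one condition the statistics should follow the
    chi-square law with ``lanes - 1`` df if counts are Poisson with
    lane-proportional means.  Genes with all-zero counts are excluded.
    ``statistic='deviance'`` substitutes the deviance.
    """
    if matrix.n_lanes < 2:
        raise ValidationError("goodness-of-fit needs at least 2 lanes")
    if factors.lane_ids != matrix.lane_ids:
        raise ValidationError("factor lane ids do not match matrix lanes")
    X, _, _, _ = design_matrix(lane_info, design_spec)
    n_params = X.shape[1]
    df = matrix.n_lanes - n_params
    if df < 1:
        raise ValidationError("no residual degrees of freedom for goodness-of-fit")
    nz = matrix.counts.sum(axis=1) > 0
    counts = matrix.counts[nz].astype(float)
    d = factors.d

    if design_spec == "null":
        lam = counts.sum(axis=1) / d.sum()
        mu = lam[:, None] * d[None, :]
    else:
        mu = np.empty_like(counts)
        for g in range(counts.shape[0]):
            fit = fit_poisson_glm(counts[g], lane_info, factors, design_spec)
            mu[g] = np.exp(fit.design @ fit.coefficients) * d
    if statistic == "pearson":
        gof = ((counts - mu) ** 2 / mu).sum(axis=1)
    elif statistic == "deviance":
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(counts > 0, counts * np.log(counts / mu), 0.0)
        gof = 2.0 * (term - (counts - mu)).sum(axis=1)
    else:
        raise ValidationError(f"unknown statistic {statistic!r}")

    out = pd.DataFrame({
        "gene_id": np.array(matrix.gene_ids, dtype=object)[nz],
        "statistic": gof,
        "df": df,
    })
    ranks = stats.rankdata(gof, method="ordinal")
    out["theoretical_quantile"] = stats.chi2.ppf((ranks - 0.5) / len(gof), df)
    return out


def error_rate_proxy(fmm: float, fpm: float) -> float | None:
    """Rough sequencing error-rate estimate from read categories.

    ``fmm`` counts purity-filtered reads mapping with up to two mismatches;
    ``fpm`` the perfectly matching subset.  The excess ``(fmm - fpm)/fmm``
    estimates the fraction of reads carrying sequencing errors (assuming no
    SNPs).  Returns ``None`` when ``fmm`` is 0 (undefined).
    """
    if fmm < 0 or fpm < 0:
        raise ValidationError("read counts must be non-negative")
    if fpm > fmm:
        raise ValidationError(f"fpm ({fpm}) cannot exceed fmm ({fmm})")
    if fmm == 0:
        return None
    return (fmm - fpm) / fmm


# ---------------------------------------------------------------------------
# Optional static plots
# ---------------------------------------------------------------------------

def plot_roc(curves: dict[str, pd.DataFrame], path: str) -> None:
    """Save a ROC comparison plot (one labelled curve per entry)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, roc in curves.items():
        ax.step(roc["FPR"], roc["TPR"], where="post", label=label)
    ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_gof_qq(gof: pd.DataFrame, path: str) -> None:
    """Save a chi-square QQ plot of goodness-of-fit statistics."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    srt = np.sort(gof["statistic"].to_numpy())
    thq = np.sort(gof["theoretical_quantile"].to_numpy())
    ax.scatter(thq, srt, s=4, alpha=0.5)
    lim = max(thq.max(), srt.max())
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8)
    ax.set_xlabel("chi-square quantile")
    ax.set_ylabel("goodness-of-fit statistic")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
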