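"""Per-gene differential-expression statistics for lane-based count data.

All tests model the read count ``X_ij`` of gene ``j`` in lane ``i`` as
Poisson with log-mean ``log d_i + log lambda_{a(i),j} (+ technical terms)``,
where ``d_i`` is the lane's normalization factor entering as a known offset
and ``a(i)`` is the biological condition assayed in lane ``i``.

Four test families are provided:

* **likelihood-ratio** tests between nested Poisson log-linear fits
  (:func:`fit_poisson_glm`, :func:`lr_test`) — the most general, and the
  only family usable with nuisance effects (flow-cell, library prep);
* **t statistics** from the same GLM, using the observed-information
  covariance (:func:`t_statistic_glm`) or the delta-method variance
  ``1/xA + 1/xB`` of a log count ratio (:func:`t_statistic_delta`).  Both
  break down when one condition has zero counts: the standard error blows
  up and the p-value is pinned near 1 no matter how many reads the other
  condition has;
* **Fisher's exact test** comparing the gene's count split across the two
  conditions to the split of the normalization factors
  (:func:`fisher_exact_de`);
* the **Cochran-Mantel-Haenszel** stratified extension combining one 2x2
  table per stratum, typically per flow-cell (:func:`mantel_haenszel_de`).

LR and Fisher p-values remain informative for zero-count genes — they
decrease continuously in the nonzero condition's count — which is the
practically important difference between the families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from laneseq.count_data import CountMatrix, LaneInfo, pool_lanes
from laneseq.errors import ValidationError
from laneseq.normalization import NormalizationFactors

__all__ = [
    "GLMFit",
    "TestResult",
    "design_matrix",
    "fit_poisson_glm",
    "lr_test",
    "t_statistic_glm",
    "t_statistic_delta",
    "fisher_exact_de",
    "fisher_pvalues_for_margins",
    "mantel_haenszel_de",
    "weight_by_length",
    "filter_low_count",
    "run_de",
]

DESIGN_SPECS = ("null", "condition", "condition+flowcell", "libprep_within_flowcell")

_MAX_ITER = 50
_COEF_TOL = 1e-10
_DIVERGE_BOUND = 30.0  # |log-scale coefficient| beyond this means a zero-count cell


@dataclass
class GLMFit:
    """Maximum-likelihood Poisson fit for one gene."""

    gene_id: str
    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    converged: bool
    design_labels: list[str]
    design_spec: str
    design: np.ndarray = field(repr=False)
    condition_levels: list[str] = field(default_factory=list)
    condition_cols: list[int] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.coefficients)


@dataclass
class TestResult:
    """One test statistic for one gene."""

    gene_id: str
    statistic: float
    df: float
    p_value: float
    direction: int  # sign of estimated log-fold-change: -1, 0, +1
    method: str
    flag: str = ""


def design_matrix(lane_info: LaneInfo, design_spec: str):
    """Build the design matrix for one of the supported model structures.

    ``null``
        intercept only (a single common expression level).
    ``condition``
        one log-expression parameter per biological condition (cell-means
        coding; sorted condition order).
    ``condition+flowcell``
        condition cell means plus flow-cell contrasts (first sorted
        flow-cell is the reference).
    ``libprep_within_flowcell``
        flow-cell cell means plus library-preparation contrasts nested
        within each flow-cell (first sorted prep per flow-cell is the
        reference) — library effects are nested within flow-cells.

    Returns ``(X, labels, condition_levels, condition_cols)``.
    """
    n = len(lane_info.lane_ids)
    cond = lane_info.column("condition").to_numpy()
    fc = lane_info.column("flow_cell").to_numpy()
    lp = lane_info.column("library_prep").to_numpy()
    cols: list[np.ndarray] = []
    labels: list[str] = []
    condition_levels: list[str] = []
    condition_cols: list[int] = []

    if design_spec == "null":
        cols.append(np.ones(n))
        labels.append("intercept")
    elif design_spec in ("condition", "condition+flowcell"):
        condition_levels = sorted(set(cond))
        for c in condition_levels:
            condition_cols.append(len(cols))
            cols.append((cond == c).astype(float))
            labels.append(f"condition[{c}]")
        if design_spec == "condition+flowcell":
            for f in sorted(set(fc))[1:]:
                cols.append((fc == f).astype(float))
                labels.append(f"flow_cell[{f}]")
    elif design_spec == "libprep_within_flowcell":
        for f in sorted(set(fc)):
            cols.append((fc == f).astype(float))
            labels.append(f"flow_cell[{f}]")
        for f in sorted(set(fc)):
            preps = sorted(set(lp[fc == f]))
            for p in preps[1:]:
                cols.append(((fc == f) & (lp == p)).astype(float))
                labels.append(f"library_prep[{f}:{p}]")
    else:
        raise ValidationError(
            f"unknown design_spec {design_spec!r}; expected one of {DESIGN_SPECS}"
        )
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(f"design {design_spec!r} is rank-deficient for these lanes")
    return X, labels, condition_levels, condition_cols


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(mu), 0.0)
    return float(np.sum(term - mu - gammaln(y + 1)))


def fit_poisson_glm(gene_counts: np.ndarray, lane_info: LaneInfo,
                    factors: NormalizationFactors, design_spec: str = "condition",
                    gene_id: str = "") -> GLMFit:
    """Fit the Poisson log-linear model with offset ``log d_i`` by IRLS.

    For the null and plain condition designs the MLE has a closed form (the
    group count sum over the group offset sum); the iterative fit agrees
    with it to high precision and is also used for designs with nuisance
    effects, where no closed form exists.

    A gene with zero counts in a cell that has its own parameter drives that
    coefficient to minus infinity; the fit is flagged ``converged=False``
    (the coefficient is clamped on the log scale) rather than raising.
    """
    y = np.asarray(gene_counts, dtype=float)
    if y.shape != (len(lane_info.lane_ids),):
        raise ValidationError("gene_counts length does not match number of lanes")
    if factors.lane_ids != lane_info.lane_ids:
        raise ValidationError("factor lane ids do not match lane metadata")
    X, labels, cond_levels, cond_cols = design_matrix(lane_info, design_spec)
    offset = np.log(factors.d)

    # IRLS (Newton scoring for the canonical log link)
    beta = np.linalg.lstsq(X, np.log(y + 0.5) - offset, rcond=None)[0]
    converged = False
    for _ in range(_MAX_ITER):
        eta = X @ beta + offset
        mu = np.exp(eta)
        z = eta - offset + (y - mu) / mu
        XtW = X.T * mu
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if np.any(np.abs(beta) > _DIVERGE_BOUND):
            beta = np.clip(beta, -_DIVERGE_BOUND, _DIVERGE_BOUND)
            break
        if step < _COEF_TOL:
            converged = True
            break
    mu = np.exp(X @ beta + offset)
    info = (X.T * mu) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
    return GLMFit(
        gene_id=gene_id,
        coefficients=beta,
        covariance=cov,
        log_likelihood=_poisson_loglik(y, mu),
        converged=converged,
        design_labels=labels,
        design_spec=design_spec,
        design=X,
        condition_levels=cond_levels,
        condition_cols=cond_cols,
    )


def _is_nested(X_null: np.ndarray, X_full: np.ndarray) -> bool:
    """Column space of the null design contained in that of the full design."""
    if X_null.shape[1] >= X_full.shape[1]:
        return False
    joint = np.column_stack([X_full, X_null])
    return np.linalg.matrix_rank(joint) == np.linalg.matrix_rank(X_full)


def _condition_direction(fit: GLMFit) -> int:
    """Sign of the second-vs-first sorted-condition log-fold-change."""
    if len(fit.condition_cols) != 2:
        return 0
    delta = fit.coefficients[fit.condition_cols[1]] - fit.coefficients[fit.condition_cols[0]]
    return int(np.sign(delta))


def lr_test(fit_full: GLMFit, fit_null: GLMFit) -> TestResult:
    """Likelihood-ratio test between nested Poisson fits.

    Statistic ``2 (l_full - l_null)`` referred to chi-square with df equal
    to the difference in parameter count.  Direction is the sign of the
    estimated condition contrast of the full fit (0 if not a two-condition
    design).
    """
    if fit_full.gene_id != fit_null.gene_id:
        raise ValidationError("fits are for different genes")
    if fit_full.design.shape[0] != fit_null.design.shape[0]:
        raise ValidationError("fits use different lane sets")
    if not _is_nested(fit_null.design, fit_full.design):
        raise ValidationError(
            f"design {fit_null.design_spec!r} is not nested in {fit_full.design_spec!r}"
        )
    stat = 2.0 * (fit_full.log_likelihood - fit_null.log_likelihood)
    if stat < 0:
        if stat < -1e-8 * max(1.0, abs(fit_full.log_likelihood)):
            warnings.warn(f"negative LR statistic {stat:.3g}; fit did not converge")
        stat = 0.0
    df = fit_full.n_params - fit_null.n_params
    p = float(stats.chi2.sf(stat, df))
    flag = "" if (fit_full.converged and fit_null.converged) else "nonconverged"
    return TestResult(fit_full.gene_id, float(stat), df, p,
                      _condition_direction(fit_full), "lr", flag)


def t_statistic_glm(fit_full: GLMFit, contrast: np.ndarray | None = None) -> TestResult:
    """Wald t statistic for a coefficient contrast of a Poisson GLM fit.

    The variance comes from the observed-information covariance of the fit.
    By default the contrast is second minus first sorted condition.  When a
    condition has zero counts its coefficient estimate diverges and the
    standard error becomes enormous, so the statistic collapses toward 0 and
    the p-value toward 1 (flagged ``zero_count``).
    """
    if contrast is None:
        if len(fit_full.condition_cols) != 2:
            raise ValidationError("default contrast needs a two-condition design")
        contrast = np.zeros(fit_full.n_params)
        contrast[fit_full.condition_cols[1]] = 1.0
        contrast[fit_full.condition_cols[0]] = -1.0
    contrast = np.asarray(contrast, dtype=float)
    est = float(contrast @ fit_full.coefficients)
    var = float(contrast @ fit_full.covariance @ contrast)
    if not np.isfinite(var) or var <= 0:
        raise ValidationError("contrast is not estimable from this fit")
    t = est / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(t)))
    flag = "" if fit_full.converged else "zero_count"
    return TestResult(fit_full.gene_id, float(t), np.nan, p,
                      int(np.sign(est)), "t_glm", flag)


def t_statistic_delta(xA: int, xB: int, dA: float, dB: float,
                      gene_id: str = "") -> TestResult:
    """Delta-method t statistic on pooled condition counts.

    ``t = [log(xA/dA) - log(xB/dB)] / sqrt(1/xA + 1/xB)`` — the variance of
    a log Poisson count to first order.  If either count is zero the
    standard error is infinite: the statistic is reported as 0 with p = 1
    and the ``zero_count`` flag set.
    """
    if xA < 0 or xB < 0 or dA <= 0 or dB <= 0:
        raise ValidationError("counts must be >= 0 and offsets > 0")
    if xA == 0 or xB == 0:
        direction = int(np.sign(xA / dA - xB / dB))
        return TestResult(gene_id, 0.0, np.nan, 1.0, direction, "t_delta", "zero_count")
    est = np.log(xA / dA) - np.log(xB / dB)
    t = est / np.sqrt(1.0 / xA + 1.0 / xB)
    p = float(2.0 * stats.norm.sf(abs(t)))
    return TestResult(gene_id, float(t), np.nan, p, int(np.sign(est)), "t_delta")


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------

def fisher_pvalues_for_margins(N: int, K: int, n: int,
                               logfact: np.ndarray | None = None):
    """Two-sided Fisher p-values for every table with fixed margins.

    For the hypergeometric family with population ``N``, successes ``K`` and
    draws ``n``, returns ``(k, p)`` where ``k`` spans the support and
    ``p[i]`` is the two-sided p-value of observing ``k[i]``: the sum of all
    point probabilities not exceeding the observed one (the
    minimum-likelihood rule, with the customary ``1 + 1e-7`` relative slack
    on the tie comparison).

    ``logfact`` may supply a precomputed ``gammaln(0..N+1)`` table
    (``logfact[m] = log m!``); otherwise it is computed on the fly.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"inconsistent margins N={N}, K={K}, n={n}")
    lo = max(0, n + K - N)
    hi = min(n, K)
    k = np.arange(lo, hi + 1)
    if logfact is None:
        lf = lambda m: gammaln(np.asarray(m, dtype=float) + 1.0)  # noqa: E731
    else:
        lf = lambda m: logfact[m]  # noqa: E731
    logpmf = (lf(K) - lf(k) - lf(K - k)
              + lf(N - K) - lf(n - k) - lf(N - K - n + k)
              - (lf(N) - lf(n) - lf(N - n)))
    pmf = np.exp(logpmf)
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    idx = np.searchsorted(pmf[order], pmf * (1 + 1e-7), side="right")
    p = np.where(idx > 0, csum[np.clip(idx - 1, 0, len(csum) - 1)], 0.0)
    return k, np.minimum(p, 1.0)


def fisher_exact_de(xA: int, xB: int, dA: float, dB: float,
                    gene_id: str = "") -> TestResult:
    """Fisher's exact test of the gene's count split against the factor split.

    The 2x2 table is ``[[xA, xB], [round(dA) - xA, round(dB) - xB]]``: the
    gene's pooled counts per condition against the remainder of the
    (rounded) normalization-factor totals.  Under the null of no
    differential expression the gene's counts split across conditions in
    the same proportions as ``d``.  Two-sided p by the minimum-likelihood
    rule under the hypergeometric null.
    """
    rA, rB = int(round(dA)), int(round(dB))
    if xA < 0 or xB < 0:
        raise ValidationError("counts must be non-negative")
    if rA - xA < 0 or rB - xB < 0:
        raise ValidationError(
            f"normalization totals ({rA}, {rB}) smaller than gene counts "
            f"({xA}, {xB}); factors inconsistent with counts"
        )
    N = rA + rB
    K = xA + xB          # gene-row margin
    n = rA               # condition-A column margin
    k, p = fisher_pvalues_for_margins(N, K, n)
    pval = float(p[int(xA) - int(k[0])])
    with np.errstate(divide="ignore"):
        direction = int(np.sign(xA / dA - xB / dB))
    return TestResult(gene_id, pval, np.nan, pval, direction, "fisher")


def mantel_haenszel_de(per_stratum_tables, gene_id: str = "") -> TestResult:
    """Cochran-Mantel-Haenszel chi-square test across 2x2 strata.

    ``per_stratum_tables`` is an iterable of 2x2 arrays
    ``[[xA, xB], [dA - xA, dB - xB]]``, one per stratum (typically one per
    flow-cell).  The statistic is the 1-df CMH chi-square without continuity
    correction; the common direction is the sign of the Mantel-Haenszel
    pooled odds ratio.  Strata with a zero margin carry no information and
    are dropped with a warning.
    """
    a = e = v = num = den = 0.0
    used = 0
    for t_idx, table in enumerate(per_stratum_tables):
        tab = np.asarray(table, dtype=float)
        if tab.shape != (2, 2) or np.any(tab < 0):
            raise ValidationError(f"stratum {t_idx}: not a non-negative 2x2 table")
        r1, r2 = tab.sum(axis=1)
        c1, c2 = tab.sum(axis=0)
        n_tot = tab.sum()
        if min(r1, r2, c1, c2) == 0 or n_tot <= 1:
            warnings.warn(f"stratum {t_idx} has a zero margin; dropped")
            continue
        used += 1
        a += tab[0, 0]
        e += r1 * c1 / n_tot
        v += r1 * r2 * c1 * c2 / (n_tot ** 2 * (n_tot - 1))
        num += tab[0, 0] * tab[1, 1] / n_tot
        den += tab[0, 1] * tab[1, 0] / n_tot
    if used == 0:
        raise ValidationError("all strata dropped (zero margins); CMH undefined")
    if v == 0:
        stat = 0.0
    else:
        stat = (a - e) ** 2 / v
    p = float(stats.chi2.sf(stat, 1))
    if num > 0 and den > 0:
        direction = int(np.sign(np.log(num / den)))
    elif num == den:
        direction = 0
    else:
        direction = 1 if num > den else -1
    return TestResult(gene_id, float(stat), 1.0, p, direction, "mh")


def weight_by_length(result: TestResult, length: float) -> TestResult:
    """Scale a t-family statistic by ``1/sqrt(length)``.

    The unweighted t statistics grow with read count and hence gene length
    for a fixed underlying effect, biasing top lists toward long genes;
    dividing by the square root of length yields a length-independent
    ranking.  The p-value is recomputed from the normal reference and the
    method label marks the statistic as length-weighted.
    """
    if length is None or not np.isfinite(length) or length < 1:
        raise ValidationError(f"need a length >= 1 to weight, got {length!r}")
    if not result.method.startswith("t_"):
        raise ValidationError("length weighting applies to t-family statistics")
    stat = result.statistic / np.sqrt(length)
    p = float(2.0 * stats.norm.sf(abs(stat)))
    if result.flag == "zero_count":
        p = 1.0
    return TestResult(result.gene_id, float(stat), result.df, p, result.direction,
                      result.method + "_lw", result.flag)


def filter_low_count(matrix: CountMatrix, lane_info: LaneInfo,
                     threshold: int = 20) -> np.ndarray:
    """Boolean mask keeping genes with >= ``threshold`` pooled reads in both conditions.

    Genes with fewer than ``threshold`` reads in *either* condition are
    masked out; removing them rescues the sensitivity of the t statistics,
    which cannot handle low-count genes.
    """
    conds = lane_info.conditions()
    if len(conds) != 2:
        raise ValidationError(f"low-count filter needs exactly 2 conditions, got {len(conds)}")
    pooled = pool_lanes(matrix, lane_info, "condition")
    return (pooled.counts[:, 0] >= threshold) & (pooled.counts[:, 1] >= threshold)


# ---------------------------------------------------------------------------
# Batch driver
# ---------------------------------------------------------------------------

def _condition_sums(matrix: CountMatrix, lane_info: LaneInfo,
                    factors: NormalizationFactors):
    conds = lane_info.conditions()
    if len(conds) != 2:
        raise ValidationError(f"two-group tests need exactly 2 conditions, got {len(conds)}")
    cond = lane_info.column("condition").to_numpy()
    maskA = cond == conds[0]
    maskB = cond == conds[1]
    xA = matrix.counts[:, maskA].sum(axis=1).astype(float)
    xB = matrix.counts[:, maskB].sum(axis=1).astype(float)
    dA = float(factors.d[maskA].sum())
    dB = float(factors.d[maskB].sum())
    return conds, xA, xB, dA, dB


def _xlogx(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(x > 0, x * np.log(x), 0.0)


def _lr_two_group(xA, xB, dA, dB):
    """Vectorized closed-form LR statistic for the plain two-condition design.

    By sufficiency, lanes of a condition pool: the group MLE is the group
    count sum over the group offset sum, and the offset and factorial terms
    cancel in the log-likelihood difference.
    """
    x = xA + xB
    d = dA + dB
    ll_full = _xlogx(xA) - xA * np.log(dA) + _xlogx(xB) - xB * np.log(dB)
    ll_null = _xlogx(x) - x * np.log(d)
    return np.maximum(2.0 * (ll_full - ll_null), 0.0)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    if ok.any():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return adj


def run_de(matrix: CountMatrix, lane_info: LaneInfo, factors: NormalizationFactors,
           method: str = "lr", *, design: str = "condition", null_design: str = "null",
           filter_min: int | None = None, weight_length: bool = False,
           strata: str = "flow_cell", adjust: bool = True) -> pd.DataFrame:
    """Run one DE test on every gene of a matrix.

    Returns a DataFrame in input gene order with columns ``gene_id``,
    ``statistic``, ``df``, ``p_value``, ``direction`` (-1/0/+1),
    ``p_adj`` (Benjamini-Hochberg) and ``flag``.  Genes removed by the
    optional low-count filter get NaN statistics and the ``filtered`` flag.
    Per-gene failures are flagged, never abort the batch.

    Direction convention (all methods): sign of the estimated log-fold-change
    of the *second* sorted condition relative to the first.
    """
    if method not in ("lr", "t_glm", "t_delta", "fisher", "mh"):
        raise ValidationError(f"unknown method {method!r}")
    lane_info.validate_against(matrix)
    if factors.lane_ids != matrix.lane_ids:
        raise ValidationError("factor lane ids do not match matrix lanes")
    G = matrix.n_genes
    keep = np.ones(G, dtype=bool)
    if filter_min is not None:
        keep = filter_low_count(matrix, lane_info, filter_min)

    stat = np.full(G, np.nan)
    df_col = np.full(G, np.nan)
    pval = np.full(G, np.nan)
    direction = np.zeros(G, dtype=np.int8)
    flags = np.array(["filtered" if not k else "" for k in keep], dtype=object)

    if method in ("lr", "t_glm", "t_delta") and design == "condition":
        conds, xA, xB, dA, dB = _condition_sums(matrix, lane_info, factors)
        if method == "lr":
            s = _lr_two_group(xA, xB, dA, dB)
            stat[keep] = s[keep]
            df_col[keep] = 1.0
            pval[keep] = stats.chi2.sf(s, 1)[keep]
            direction[keep] = np.sign(xB / dB - xA / dA).astype(np.int8)[keep]
        else:
            zero = (xA == 0) | (xB == 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (np.log(xB / dB) - np.log(xA / dA)) / np.sqrt(1.0 / xA + 1.0 / xB)
            t = np.where(zero, 0.0, t)
            p = np.where(zero, 1.0, 2.0 * stats.norm.sf(np.abs(t)))
            stat[keep] = t[keep]
            pval[keep] = p[keep]
            direction[keep] = np.sign(xB / dB - xA / dA).astype(np.int8)[keep]
            flags[keep & zero] = "zero_count"
        mlabel = method
        if weight_length and method in ("t_glm", "t_delta"):
            if matrix.gene_lengths is None:
                raise ValidationError("length weighting requires gene_lengths")
            w = np.sqrt(matrix.gene_lengths.astype(float))
            stat = stat / w
            nz = np.isfinite(stat)
            pval[nz] = 2.0 * stats.norm.sf(np.abs(stat[nz]))
            pval[(flags == "zero_count")] = 1.0
            mlabel += "_lw"
    elif method == "lr":
        # designs with nuisance effects: per-gene IRLS fits
        for g in range(G):
            if not keep[g]:
                continue
            try:
                full = fit_poisson_glm(matrix.counts[g], lane_info, factors,
                                       design, gene_id=matrix.gene_ids[g])
                null = fit_poisson_glm(matrix.counts[g], lane_info, factors,
                                       null_design, gene_id=matrix.gene_ids[g])
                res = lr_test(full, null)
            except (ValidationError, np.linalg.LinAlgError) as exc:
                flags[g] = f"error:{exc}"
                continue
            stat[g], df_col[g], pval[g] = res.statistic, res.df, res.p_value
            direction[g] = res.direction
            if res.flag:
                flags[g] = res.flag
        mlabel = "lr"
    elif method == "fisher":
        conds, xA, xB, dA, dB = _condition_sums(matrix, lane_info, factors)
        for g in range(G):
            if not keep[g]:
                continue
            try:
                res = fisher_exact_de(int(xA[g]), int(xB[g]), dA, dB,
                                      gene_id=matrix.gene_ids[g])
            except ValidationError as exc:
                flags[g] = f"error:{exc}"
                continue
            # direction convention: second sorted condition over first
            stat[g], pval[g] = res.statistic, res.p_value
            direction[g] = -res.direction
        mlabel = "fisher"
    elif method == "mh":
        strata_vals = lane_info.column(strata)
        cond = lane_info.column("condition").to_numpy()
        conds = lane_info.conditions()
        if len(conds) != 2:
            raise ValidationError("Mantel-Haenszel needs exactly 2 conditions")
        for g in range(G):
            if not keep[g]:
                continue
            tables = []
            for s in sorted(strata_vals.unique()):
                in_s = (strata_vals == s).to_numpy()
                mA = in_s & (cond == conds[0])
                mB = in_s & (cond == conds[1])
                xa = int(matrix.counts[g, mA].sum())
                xb = int(matrix.counts[g, mB].sum())
                da = int(round(factors.d[mA].sum()))
                db = int(round(factors.d[mB].sum()))
                tables.append([[xa, xb], [da - xa, db - xb]])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = mantel_haenszel_de(tables, gene_id=matrix.gene_ids[g])
            except ValidationError as exc:
                flags[g] = f"error:{exc}"
                continue
            stat[g], df_col[g], pval[g] = res.statistic, res.df, res.p_value
            direction[g] = -res.direction
        mlabel = "mh"
    else:
        raise ValidationError(f"method {method!r} does not support design {design!r}")

    out = pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "statistic": stat,
        "df": df_col,
        "p_value": pval,
        "direction": direction,
        "flag": flags.astype(str),
    })
    out.attrs["method"] = mlabel
    if adjust:
        out["p_adj"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out
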