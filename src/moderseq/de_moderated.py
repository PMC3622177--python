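"""Intensity-moderated variance test for differential expression.

The test treats the per-gene log2-expression variance as a smooth function
of average intensity.  A tricube-weighted local linear regression estimates
that trend, either from absolute between-sample log-differences
(``trend_only`` mode, usable without replicates) or from log sample
variances on the Fisher's-Z scale (``moderated`` mode).  In moderated mode
the trend acts as an empirical-Bayes prior: the prior degrees of freedom
``d0`` are recovered from the excess spread of log sample variances around
the trend via the trigamma moment equation, and each gene's variance is
shrunk toward the intensity-matched prior,

    s~^2_g = (d0 * s0^2(A_g) + d_g * s^2_g) / (d0 + d_g).

z-scores on condition-mean differences, normal or t reference p-values,
Benjamini-Hochberg FDR, and threshold calls complete the screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .io_formats import ExpressionMatrix

HALF_NORMAL_FACTOR = float(np.sqrt(np.pi / 2.0))  # E|N(0, s^2)| = s * sqrt(2/pi)
SIGMA_FLOOR = 1e-4
NEG_LOG10_P_CAP = 320.0


@dataclass
class LogExpression:
    """log2(RPKM + pseudocount) per gene/sample with the sample design."""

    x: pd.DataFrame
    A: pd.Series
    design: pd.Series
    pseudocount: float

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.design:
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.design.items() if c == condition]


@dataclass
class VarianceModel:
    """Fitted intensity->variance trend plus empirical-Bayes prior.

    In ``moderated`` mode ``trend`` is on the log-variance (Fisher's-Z
    location) scale and ``s0_sq`` maps intensity to the prior variance; in
    ``trend_only`` mode ``trend`` predicts the absolute log-difference and
    ``s0_sq`` the implied per-observation variance sigma_d^2 / 2.
    """

    mode: Literal["trend_only", "moderated"]
    trend: Callable[[np.ndarray], np.ndarray]
    d0: float
    s0_sq: Callable[[np.ndarray], np.ndarray]
    d_g: float
    s_g_sq: np.ndarray | None = None


def log_transform(expr: ExpressionMatrix, pseudocount: float = 0.25) -> LogExpression:
    """x = log2(rpkm + pseudocount); A = per-gene mean of x over samples."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = np.log2(expr.rpkm + pseudocount)
    return LogExpression(x, x.mean(axis=1).rename("A"), expr.design, pseudocount)


def pairwise_log_differences(le: LogExpression) -> tuple[np.ndarray, list[tuple[str, str, str]]]:
    """All unordered between-sample differences x_s - x_s' per gene.

    Returns (differences of shape (n_genes, n_pairs), pair metadata as
    (sample, sample, 'within'|'between') tuples).
    """
    samples = list(le.x.columns)
    if len(samples) < 2:
        raise ValueError("need at least two samples to form differences")
    xv = le.x.to_numpy()
    cols, meta = [], []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            cols.append(xv[:, i] - xv[:, j])
            kind = "within" if le.design.iloc[i] == le.design.iloc[j] else "between"
            meta.append((samples[i], samples[j], kind))
    return np.column_stack(cols), meta


def loess_smooth(x: np.ndarray, y: np.ndarray, span: float = 0.4,
                 iterations: int = 2) -> Callable[[np.ndarray], np.ndarray]:
    """Tricube-weighted local linear regression with robustness iterations.

    Returns a predictor that linearly interpolates the fit (constant beyond
    the observed range).
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    delta = 0.01 * (x.max() - x.min()) if x.size > 200 else 0.0
    fit = _sm_lowess(y, x, frac=span, it=iterations, delta=delta, return_sorted=True)
    xs, idx = np.unique(fit[:, 0], return_index=True)
    ys = fit[idx, 1]
    if xs.size == 1:
        const = float(ys[0])
        return lambda a: np.full_like(np.asarray(a, float), const)
    return lambda a: np.interp(np.asarray(a, float), xs, ys)


def fit_abs_diff_trend(A: np.ndarray, d: np.ndarray, span: float = 0.4,
                       pair_kinds: Sequence[str] | None = None,
                       within_only: bool = False) -> Callable[[np.ndarray], np.ndarray]:
    """Fit sigma_d(A): local regression of |log-difference| on intensity.

    ``d`` has one column per sample pair; by default all pairs feed the fit
    (justified when few genes are truly DE), ``within_only`` restricts to
    within-condition pairs.  The fitted E|d| is converted to a
    difference-scale standard deviation via sigma_d = E|d| * sqrt(pi/2)
    (exact when d is centered normal) and floored at 1e-4.
    """
    A = np.asarray(A, float)
    d = np.atleast_2d(np.asarray(d, float))
    if d.shape[0] != A.size:
        d = d.T
    if A.size < 50:
        raise ValueError("insufficient data for local regression (need >= 50 genes)")
    cols = np.arange(d.shape[1])
    if within_only:
        if pair_kinds is None:
            raise ValueError("within_only requires pair_kinds metadata")
        cols = np.array([i for i, k in enumerate(pair_kinds) if k == "within"])
        if cols.size == 0:
            raise ValueError("no within-condition pairs available")
    xx = np.repeat(A, cols.size)
    yy = np.abs(d[:, cols]).ravel()
    smooth = loess_smooth(xx, yy, span=span)

    def sigma_d(a: np.ndarray) -> np.ndarray:
        return np.maximum(smooth(a) * HALF_NORMAL_FACTOR, SIGMA_FLOOR)

    return sigma_d


def per_gene_variance(le: LogExpression) -> tuple[np.ndarray, float]:
    """Pooled within-condition sample variance with d_g = n1 + n2 - 2."""
    conds = le.conditions
    if len(conds) != 2:
        raise ValueError("per_gene_variance expects exactly two conditions")
    g1, g2 = (le.x[le.samples_of(c)].to_numpy() for c in conds)
    n1, n2 = g1.shape[1], g2.shape[1]
    d_g = n1 + n2 - 2
    if d_g < 1 or max(n1, n2) < 2:
        raise ValueError("no replicated condition: pooled variance undefined; "
                         "use trend_only mode")
    ss1 = ((g1 - g1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((g2 - g2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return (ss1 + ss2) / d_g, float(d_g)


def trigamma_inverse(y: float, max_iter: int = 50, tol: float = 1e-10) -> float:
    """Solve psi'(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive; no solution for y <= 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            return float(x)
    raise RuntimeError(f"trigamma_inverse did not converge for y={y!r} "
                       f"(last x={x!r}, step={dif!r})")


def fit_variance_model(le: LogExpression, s_g_sq: np.ndarray, d_g: float,
                       span: float = 0.4) -> VarianceModel:
    """Empirical-Bayes variance prior on the Fisher's-Z scale.

    e_g = log(s_g^2) - psi(d_g/2) + log(d_g/2) is an unbiased estimate of
    log sigma_g^2 under normality.  Its local-regression trend on intensity
    gives the prior location; the moment equation
    mean[(e_g - e^(A_g))^2] - psi'(d_g/2) = psi'(d0/2) gives the prior
    degrees of freedom (d0 = +inf when the residual spread does not exceed
    the sampling variance psi'(d_g/2)).  Genes with zero sample variance are
    excluded from fitting and reinstated at shrinkage time.
    """
    if d_g < 1:
        raise ValueError("moderated mode needs residual degrees of freedom >= 1")
    s_g_sq = np.asarray(s_g_sq, float)
    A = le.A.to_numpy()
    ok = s_g_sq > 0
    if ok.sum() < 50:
        raise ValueError("insufficient data for local regression (need >= 50 genes "
                         "with positive variance)")
    e = np.log(s_g_sq[ok]) - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    trend = loess_smooth(A[ok], e, span=span)
    resid_var = float(np.mean((e - trend(A[ok])) ** 2)) - float(special.polygamma(1, d_g / 2.0))
    if resid_var <= 0:
        d0 = np.inf
    else:
        d0 = 2.0 * trigamma_inverse(resid_var)

    def s0_sq(a: np.ndarray) -> np.ndarray:
        offset = 0.0 if np.isinf(d0) else float(special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        return np.exp(trend(a) + offset)

    return VarianceModel("moderated", trend, float(d0), s0_sq, float(d_g), s_g_sq)


def trend_only_model(le: LogExpression, span: float = 0.4,
                     within_only: bool = False) -> VarianceModel:
    """Variance model from the |log-difference| trend alone (no replicates needed)."""
    d, meta = pairwise_log_differences(le)
    kinds = [m[2] for m in meta]
    sigma_d = fit_abs_diff_trend(le.A.to_numpy(), d, span=span,
                                 pair_kinds=kinds, within_only=within_only)
    # a difference of two observations carries twice the per-observation variance
    s0 = lambda a: sigma_d(a) ** 2 / 2.0
    return VarianceModel("trend_only", sigma_d, np.inf, s0, 0.0, None)


def moderate_variance(s_g_sq: np.ndarray | None, d_g: float, model: VarianceModel,
                      A: np.ndarray) -> np.ndarray:
    """Posterior variance s~^2 for each gene at intensity A."""
    prior = model.s0_sq(np.asarray(A, float))
    if model.mode == "trend_only":
        return prior
    s_g_sq = np.asarray(s_g_sq, float)
    if np.isinf(model.d0):
        return prior
    if model.d0 == 0:
        return s_g_sq
    return (model.d0 * prior + d_g * s_g_sq) / (model.d0 + d_g)


def z_test(le: LogExpression, s_tilde_sq: np.ndarray, model: VarianceModel,
           reference: str = "normal") -> pd.DataFrame:
    """z = (mean2 - mean1) / sqrt(s~^2 (1/n1 + 1/n2)); two-sided p-values.

    ``reference='normal'`` uses the standard normal tail; ``'t'`` uses a t
    distribution with d0 + d_g degrees of freedom.  Zero posterior variance
    is flagged degenerate (p = 0 if the means differ, else 1).
    """
    if reference not in ("normal", "t"):
        raise ValueError("reference must be 'normal' or 't'")
    c1, c2 = le.conditions[:2]
    x1 = le.x[le.samples_of(c1)].to_numpy()
    x2 = le.x[le.samples_of(c2)].to_numpy()
    n1, n2 = x1.shape[1], x2.shape[1]
    diff = x2.mean(axis=1) - x1.mean(axis=1)
    s_tilde_sq = np.asarray(s_tilde_sq, float)
    degenerate = s_tilde_sq <= 0
    se = np.sqrt(np.where(degenerate, np.nan, s_tilde_sq) * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore"):
        z = diff / se
    df = model.d0 + model.d_g
    if reference == "normal" or np.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        p = 2.0 * stats.t.sf(np.abs(z), df)
    z = np.where(degenerate,
                 np.where(diff > 0, np.inf, np.where(diff < 0, -np.inf, 0.0)), z)
    p = np.where(degenerate, np.where(diff != 0, 0.0, 1.0), p)
    return pd.DataFrame({"z": z, "p": p, "degenerate": degenerate}, index=le.x.index)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, mapped back to the
    input order with a stable sort so ties share their treatment.
    """
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_de(results: pd.DataFrame, fc_threshold: float = 2.0,
            fdr_threshold: float = 0.05, rpkm_floor: float = 0.1) -> pd.DataFrame:
    """Set call in {up, down, ns} by strict q, fold-change and RPKM cuts."""
    lfc_cut = np.log2(fc_threshold)
    max_mean = results[["mean_rpkm_cond1", "mean_rpkm_cond2"]].max(axis=1)
    q = results["q"].to_numpy()
    sig = pd.notna(results["q"]) & (q < fdr_threshold) & (max_mean > rpkm_floor)
    call = np.where(sig & (results["log2fc"] > lfc_cut), "up",
                    np.where(sig & (results["log2fc"] < -lfc_cut), "down", "ns"))
    out = results.copy()
    out["call"] = call
    return out


def de_test(
    expr: ExpressionMatrix,
    mode: str = "auto",
    span: float = 0.4,
    pseudocount: float = 0.25,
    reference: str = "normal",
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    rpkm_floor: float = 0.1,
    within_only: bool = False,
) -> pd.DataFrame:
    """Run the full moderated differential-expression screen.

    Multiple testing is filter-then-test: only genes whose larger
    condition-mean RPKM exceeds ``rpkm_floor`` enter the BH adjustment
    (others keep their p but q = NA, call = ns).  Fold changes are
    log2((mean_cond2 + c) / (mean_cond1 + c)) on the RPKM scale; the
    reverse-direction column is emitted as well to keep signs unambiguous.
    """
    le = log_transform(expr, pseudocount)
    conds = le.conditions
    if len(conds) != 2:
        raise ValueError("de_test expects exactly two conditions")
    n1, n2 = (len(le.samples_of(c)) for c in conds)
    if mode == "auto":
        mode = "moderated" if max(n1, n2) >= 2 else "trend_only"
    if mode == "moderated":
        s_g_sq, d_g = per_gene_variance(le)
        model = fit_variance_model(le, s_g_sq, d_g, span=span)
    elif mode == "trend_only":
        s_g_sq, d_g = None, 0.0
        model = trend_only_model(le, span=span, within_only=within_only)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    A = le.A.to_numpy()
    s_tilde = moderate_variance(s_g_sq, d_g, model, A)
    zt = z_test(le, s_tilde, model, reference=reference)

    m1 = expr.rpkm[le.samples_of(conds[0])].mean(axis=1)
    m2 = expr.rpkm[le.samples_of(conds[1])].mean(axis=1)
    log2fc = np.log2((m2 + pseudocount) / (m1 + pseudocount))
    results = pd.DataFrame({
        "gene_id": expr.rpkm.index,
        "A": A,
        "mean_rpkm_cond1": m1.to_numpy(),
        "mean_rpkm_cond2": m2.to_numpy(),
        "log2fc": log2fc.to_numpy(),
        "log2fc_reverse": -log2fc.to_numpy(),
        "s_tilde_sq": s_tilde,
        "z": zt["z"].to_numpy(),
        "p": zt["p"].to_numpy(),
    })
    passing = results[["mean_rpkm_cond1", "mean_rpkm_cond2"]].max(axis=1) > rpkm_floor
    q = np.full(len(results), np.nan)
    if passing.any():
        q[passing.to_numpy()] = bh_adjust(results.loc[passing, "p"].to_numpy())
    results["q"] = q
    results = call_de(results, fc_threshold, fdr_threshold, rpkm_floor)
    results.attrs["mode"] = mode
    results.attrs["d0"] = model.d0
    results.attrs["d_g"] = d_g
    return results


def rank_top_expressed(expr: ExpressionMatrix, k: int = 20,
                       pseudocount: float = 0.25) -> pd.DataFrame:
    """Top-k genes by mean RPKM across all samples (ties broken by gene_id)."""
    mean_rpkm = expr.rpkm.mean(axis=1)
    df = pd.DataFrame({
        "gene_id": mean_rpkm.index,
        "mean_rpkm": mean_rpkm.to_numpy(),
        "mean_log2_rpkm": np.log2(mean_rpkm.to_numpy() + pseudocount),
    })
    df = df.sort_values(["mean_rpkm", "gene_id"], ascending=[False, True],
                        kind="stable").head(k)
    return df.reset_index(drop=True)


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plotting-ready volcano columns; -log10(p) capped at 320."""
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(results["p"].to_numpy())
    return pd.DataFrame({
        "gene_id": results["gene_id"],
        "log2fc": results["log2fc"],
        "log2fc_reverse": results["log2fc_reverse"],
        "neg_log10_p": np.minimum(neg_log10_p, NEG_LOG10_P_CAP),
        "call": results["call"],
    })
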