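"""Differential expression with empirical-Bayes moderated t-statistics.

The engine is a self-contained two-group implementation of the
moderated t: per-gene two-sample linear models give a mean difference
(the log2 fold change), a pooled residual variance s_g^2 on
d_g = n_A + n_B - 2 degrees of freedom, and an unscaled variance
v_g = 1/n_A + 1/n_B.  A scaled inverse-chi-square prior
sigma_g^2 ~ d0 * s0^2 / chi^2_{d0} is estimated across genes by
matching the moments of log s_g^2 to a scaled F distribution
(digamma/trigamma moment equations); the posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

yields the moderated statistic t~_g = diff_g / sqrt(s~_g^2 * v_g) on
d0 + d_g degrees of freedom.  d0 = 0 recovers the ordinary two-sample
t; d0 = infinity the normal-theory limit with variance s0^2.

Also houses BH FDR adjustment, the DEG filter (FDR-adjusted p <= 0.05
and |log2FC| >= 1, both inclusive), and the summary-level clinical
group comparisons (pooled two-sample t from printed mean/SD/n, and the
2x2 Pearson chi-square without continuity correction).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from fibrostrat.io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_FDR_MAX = 0.05
DEFAULT_LFC_MIN = 1.0


# ---------------------------------------------------------------------------
# Per-gene two-group models
# ---------------------------------------------------------------------------


@dataclass
class GeneModelFit:
    """Per-gene two-group summaries for one contrast (A vs B)."""

    genes: list[str]
    diff: np.ndarray  # mean(A) - mean(B), log2 scale
    s2: np.ndarray  # pooled residual variance
    df: float  # residual degrees of freedom, n_A + n_B - 2
    v: float  # unscaled variance of the difference, 1/n_A + 1/n_B


def fit_gene_models(
    m: ExpressionMatrix,
    groups: pd.Series,
    contrast: tuple[str, str],
) -> GeneModelFit:
    """Fit gene-wise two-group models for ``contrast = (A, B)``.

    Returns the mean difference A - B, the pooled residual variance and
    its degrees of freedom, and the unscaled variance of the
    difference.  Both groups need at least two samples.
    """
    group_a, group_b = contrast
    samples_a = groups.index[groups == group_a].intersection(m.data.columns)
    samples_b = groups.index[groups == group_b].intersection(m.data.columns)
    n_a, n_b = len(samples_a), len(samples_b)
    if n_a < 2 or n_b < 2:
        raise ValueError(
            f"contrast {contrast}: need >=2 samples per group, got {n_a} and {n_b}"
        )
    xa = m.data[list(samples_a)].to_numpy()
    xb = m.data[list(samples_b)].to_numpy()
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    df = float(n_a + n_b - 2)
    return GeneModelFit(
        genes=m.gene_ids,
        diff=mean_a - mean_b,
        s2=ss / df,
        df=df,
        v=1.0 / n_a + 1.0 / n_b,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes prior
# ---------------------------------------------------------------------------


@dataclass
class EBPrior:
    """Variance-prior hyperparameters: prior df (may be inf; 0 is the
    no-moderation limit giving the ordinary t) and prior variance s0^2
    toward which gene variances are shrunk."""

    df_prior: float
    var_prior: float

    def __post_init__(self) -> None:
        if not (self.df_prior >= 0):
            raise ValueError("prior df must be >= 0")
        if not (self.var_prior > 0 and math.isfinite(self.var_prior)):
            raise ValueError("prior variance must be positive and finite")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs x > 0")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def estimate_eb_prior(s2: np.ndarray, df: float | np.ndarray) -> EBPrior:
    """Method-of-moments estimate of (d0, s0^2) from gene variances.

    Given s_g^2 | sigma_g^2 ~ sigma_g^2 chi^2_d / d and the scaled
    inverse-chi-square prior, log s_g^2 follows a location-shifted
    log-F; its mean and variance identify the prior through digamma /
    trigamma relations.  If the empirical variance of log s_g^2 does
    not exceed the sampling component trigamma(d/2), the prior df is
    infinite and s0^2 is the geometric-mean-consistent constant.
    """
    s2 = np.asarray(s2, dtype=float)
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = (s2 > 0) & (df_arr >= 1)
    n_zero = int(((s2 <= 0) & (df_arr >= 1)).sum())
    if ok.sum() < 10:
        raise ValueError("need >=10 genes with positive variance and df >= 1")
    if n_zero:
        logger.warning("estimate_eb_prior: dropped %d genes with zero variance", n_zero)
    z = np.log(s2[ok])
    d = df_arr[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2.0).mean())
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return EBPrior(df_prior=d0, var_prior=s0_sq)


def moderated_t(
    diff: np.ndarray,
    s2: np.ndarray,
    df: float | np.ndarray,
    v: float | np.ndarray,
    prior: EBPrior,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t, two-sided p, and total df for each gene.

    Posterior variance (d0 s0^2 + d s^2)/(d0 + d); total df d0 + d.
    d0 = inf uses s0^2 with the normal limit; d0 -> 0 recovers the
    ordinary t.
    """
    diff = np.atleast_1d(np.asarray(diff, dtype=float))
    s2 = np.atleast_1d(np.asarray(s2, dtype=float))
    v_arr = np.broadcast_to(np.asarray(v, dtype=float), diff.shape)
    d_arr = np.broadcast_to(np.asarray(df, dtype=float), diff.shape)
    if (v_arr <= 0).any():
        raise ValueError("unscaled variance v must be positive")
    d0, s0_sq = prior.df_prior, prior.var_prior
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0_sq + d_arr * s2) / (d0 + d_arr)
        df_total = d0 + d_arr
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(s2_post * v_arr)
    t = np.where(np.isnan(t) & (diff == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p, df_total


# ---------------------------------------------------------------------------
# BH adjustment and DEG calls
# ---------------------------------------------------------------------------


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def de_table(
    m: ExpressionMatrix,
    groups: pd.Series,
    contrasts: list[tuple[str, str]],
    prior: EBPrior | None = None,
    fdr_max: float = DEFAULT_FDR_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
    adjust: str = "per-contrast",
) -> pd.DataFrame:
    """Moderated-t differential expression for a list of contrasts.

    The prior is estimated from the first contrast's residual variances
    unless supplied.  BH is applied per contrast by default
    (``adjust='global'`` pools all contrasts).  Returns one row per
    gene per contrast with columns gene, contrast, lfc, t, p, q, deg,
    direction.
    """
    if adjust not in ("per-contrast", "global"):
        raise ValueError("adjust must be 'per-contrast' or 'global'")
    frames = []
    for contrast in contrasts:
        fit = fit_gene_models(m, groups, contrast)
        contrast_prior = prior if prior is not None else estimate_eb_prior(fit.s2, fit.df)
        t, p, _ = moderated_t(fit.diff, fit.s2, fit.df, fit.v, contrast_prior)
        frames.append(
            pd.DataFrame(
                {
                    "gene": fit.genes,
                    "contrast": f"{contrast[0]}_vs_{contrast[1]}",
                    "lfc": fit.diff,
                    "t": t,
                    "p": p,
                }
            )
        )
    de = pd.concat(frames, ignore_index=True)
    if adjust == "global":
        de["q"] = bh_adjust(de["p"].to_numpy())
    else:
        de["q"] = de.groupby("contrast", sort=False)["p"].transform(
            lambda col: bh_adjust(col.to_numpy())
        )
    de["deg"] = (de["q"] <= fdr_max) & (de["lfc"].abs() >= lfc_min)
    de["direction"] = np.where(de["lfc"] >= 0, "up", "down")
    return de


def call_degs(
    de: pd.DataFrame,
    fdr_max: float = DEFAULT_FDR_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> dict[str, dict[str, str]]:
    """DEG sets per contrast with direction.

    Thresholds are inclusive: q <= fdr_max and |lfc| >= lfc_min.
    Returns {contrast: {gene: 'up'|'down'}}.
    """
    if "q" not in de.columns:
        raise ValueError("DE table lacks adjusted p-values")
    passing = de[(de["q"] <= fdr_max) & (de["lfc"].abs() >= lfc_min)]
    out: dict[str, dict[str, str]] = {c: {} for c in de["contrast"].unique()}
    for row in passing.itertuples():
        out[row.contrast][row.gene] = "up" if row.lfc >= 0 else "down"
    return out


# ---------------------------------------------------------------------------
# Clinical group-comparison statistics
# ---------------------------------------------------------------------------


def pooled_t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Two-sided pooled-variance Student t from printed summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        t = 0.0 if m1 == m2 else math.inf * math.copysign(1, m1 - m2)
    else:
        t = (m1 - m2) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, float(df), p


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (df = 1, no continuity correction) for the
    2x2 table [[a, b], [c, d]]."""
    for count in (a, b, c, d):
        if count < 0 or int(count) != count:
            raise ValueError("counts must be nonnegative integers")
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if any(mg == 0 for mg in margins):
        raise ValueError("all table margins must be positive")
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
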