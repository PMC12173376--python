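"""Two-group differential expression with empirical-Bayes variance moderation.

The model is the standard hierarchical one for gene-wise variances: the
residual variance s2_g of gene g on d_g degrees of freedom is distributed as
s2_g | sigma2_g ~ sigma2_g * chi2(d_g)/d_g with the gene-wise true variances
drawn from a scaled inverse-chi-square prior with d0 degrees of freedom and
scale s0^2.  The posterior variance

    s2_tilde_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

replaces s2_g in the t statistic, which then has d0 + d_g degrees of freedom.
(d0, s0^2) are estimated by closed-form moment matching of log s2_g against a
scaled F distribution, using digamma/trigamma identities.

Only the two-group design is supported (all contrasts in this package are
stage-vs-control or exposed-vs-unexposed): no covariates, no sample weights,
no mean-variance trend — a deliberate subset of the general linear-model
formulation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .annotation_io import ExpressionStudy
from .enrichment import bh_adjust

logger = logging.getLogger("proteosig.diffexp")


@dataclass(frozen=True)
class ModerationPrior:
    """Prior degrees of freedom d0 (may be +inf) and prior variance s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0 (may be inf)")
        if not (self.s0_sq >= 0):
            raise ValueError("s0_sq must be >= 0")


@dataclass
class TwoGroupFit:
    """Per-gene ordinary least-squares summary of a two-group contrast."""

    genes: list[str]
    log2fc: np.ndarray      # mean(a) - mean(b)
    s2: np.ndarray          # pooled residual variance
    df_residual: int        # n_a + n_b - 2
    u: float                # unscaled SD of the effect, sqrt(1/n_a + 1/n_b)
    n_a: int
    n_b: int


def fit_two_group(study: ExpressionStudy, contrast: tuple[str, str]) -> TwoGroupFit:
    """Fit gene-wise mean difference ``contrast[0] - contrast[1]``.

    Requires >= 2 samples per condition and a log2-scale matrix.
    """
    cond_a, cond_b = contrast
    for c in (cond_a, cond_b):
        if c not in study.conditions:
            raise ValueError(f"condition {c!r} absent from sample metadata")
    sa = study.samples_for(cond_a)
    sb = study.samples_for(cond_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(f"need >=2 samples per condition; got {len(sa)} vs {len(sb)}")
    A = study.matrix[sa].to_numpy(float)
    B = study.matrix[sb].to_numpy(float)
    na, nb = A.shape[1], B.shape[1]
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    ssa = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((B - B.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = na + nb - 2
    s2 = (ssa + ssb) / df
    return TwoGroupFit(genes=list(study.matrix.index), log2fc=log2fc, s2=s2,
                       df_residual=df, u=math.sqrt(1 / na + 1 / nb), n_a=na, n_b=nb)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_prior(s2, df_residual: int, min_genes: int = 10) -> ModerationPrior:
    """Moment-match (d0, s0^2) from observed gene-wise variances.

    With e_g = log s2_g - digamma(d/2) + log(d/2), the between-gene excess of
    var(e) over trigamma(d/2) equals trigamma(d0/2); when the excess is <= 0
    there is no detectable gene-to-gene variance dispersion and d0 = +inf with
    s0^2 = the geometric mean of the s2_g.  Genes with s2 = 0 are excluded
    from estimation (log undefined).  Fewer than ``min_genes`` positive
    variances also triggers the d0 = +inf fallback.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size == 0 or np.all(s2 <= 0):
        raise ValueError("cannot estimate a variance prior: all variances are zero")
    d = float(df_residual)
    if d <= 0:
        raise ValueError("df_residual must be positive")
    pos = s2[s2 > 0]
    e = np.log(pos) - special.digamma(d / 2) + math.log(d / 2)
    ebar = float(e.mean())
    if pos.size < min_genes:
        logger.warning("only %d positive variances; falling back to d0=inf", pos.size)
        return ModerationPrior(d0=math.inf, s0_sq=float(np.exp(ebar)))
    G = pos.size
    evar = float(((e - ebar) ** 2).mean() * G / (G - 1)) - float(special.polygamma(1, d / 2))
    if evar <= 0:
        # no between-gene dispersion beyond chance: exp(ebar) is the d0->inf
        # limit of exp(ebar + digamma(d0/2) - log(d0/2)) and is consistent for
        # the shared variance (the raw log-mean of s2 would be biased low)
        return ModerationPrior(d0=math.inf, s0_sq=float(np.exp(ebar)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(ebar + special.digamma(d0 / 2) - math.log(d0 / 2)))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def moderated_t(fit: TwoGroupFit, prior: ModerationPrior,
                direction_alpha: float = 0.05) -> pd.DataFrame:
    """Moderated t-statistics, two-sided p, BH adjustment and direction calls.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``s2``,
    ``s2_post``, ``df_total``, ``t``, ``p``, ``adj_p``, ``direction``.
    ``direction`` is sign(log2fc) where adj_p < ``direction_alpha``, else 0.
    d0 = 0 reduces to the ordinary pooled t; d0 = +inf to the shared-variance
    z-form (normal reference distribution).
    """
    d0, s0 = prior.d0, prior.s0_sq
    d = fit.df_residual
    genes = list(fit.genes)
    log2fc = np.asarray(fit.log2fc, float)
    s2 = np.asarray(fit.s2, float)
    if math.isinf(d0):
        if s0 <= 0:
            raise ValueError("d0=inf with s0_sq=0: no usable variance")
        s2_post = np.full_like(s2, s0)
        df_total = math.inf
    else:
        s2_post = (d0 * s0 + d * s2) / (d0 + d) if d0 > 0 else s2.copy()
        df_total = d0 + d

    keep = s2_post > 0
    if not np.all(keep):
        logger.warning("dropping %d gene(s) with zero posterior variance",
                       int((~keep).sum()))
    genes = [g for g, k in zip(genes, keep) if k]
    log2fc, s2, s2_post = log2fc[keep], s2[keep], s2_post[keep]

    t = log2fc / (fit.u * np.sqrt(s2_post))
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    adj = np.asarray(bh_adjust(p.tolist()))
    direction = np.where(adj < direction_alpha, np.sign(log2fc), 0.0).astype(int)
    return pd.DataFrame({
        "log2fc": log2fc, "s2": s2, "s2_post": s2_post,
        "df_total": df_total, "t": t, "p": p, "adj_p": adj,
        "direction": direction}, index=pd.Index(genes, name="gene"))


def de_table(study: ExpressionStudy, contrast: tuple[str, str],
             direction_alpha: float = 0.05) -> pd.DataFrame:
    """Convenience: fit, estimate the prior, and moderate in one call."""
    fit = fit_two_group(study, contrast)
    prior = estimate_prior(fit.s2, fit.df_residual)
    return moderated_t(fit, prior, direction_alpha=direction_alpha)
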