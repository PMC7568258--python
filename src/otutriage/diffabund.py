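"""Differential abundance via an empirical-Bayes moderated t-test with BH FDR.

Relative abundances are floored (default 0.1 %, matching the published
pseudo-abundance convention) and log2-transformed.  Per-OTU residual
variances are shrunk toward a prior fitted across OTUs by the classic
log-moment method for a scaled-F model of variances (Smyth 2004): the prior
is described by degrees of freedom ``d0`` and scale ``s0_sq``, the posterior
variance is the df-weighted blend ``(d0*s0_sq + d*s2) / (d0 + d)``, and the
moderated t statistic gains ``d0`` degrees of freedom.  p-values receive
Benjamini-Hochberg adjustment, and an OTU is called significant when the
fold change of floored group means reaches ``fc_min`` (either direction) at
``q <= fdr_max`` — the published call criterion (fold >= 1.2, FDR 0.05).

This screen operates on relative abundances; it belongs to the same
statistical family as the count-level limma-voom analysis but does not
reproduce voom's precision weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceTable


@dataclass(frozen=True)
class ModeratedVariancePrior:
    """Scaled inverse-chi-square prior on per-OTU variances.

    ``d0`` may be +inf, in which case every posterior variance collapses to
    ``s0_sq`` (complete shrinkage).
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("prior degrees of freedom must be positive")
        if not self.s0_sq > 0:
            raise ValueError("prior variance must be positive")


@dataclass(frozen=True)
class DifferentialResult:
    """Per-OTU differential-abundance evidence for one two-group comparison."""

    otu_id: str
    log2_fold_change: float  # group A over group B, floored means
    t_statistic: float
    p_value: float
    q_value: float
    significant: bool


def log_transform(table: AbundanceTable, floor: float = 0.1) -> pd.DataFrame:
    """log2(max(value, floor)) per cell; same shape/labels as the table."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    return np.log2(table.data.clip(lower=floor))


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def fit_variance_prior(
    residual_variances, residual_df: float
) -> ModeratedVariancePrior:
    """Moment fit of the variance prior from across-OTU residual variances.

    Models each sample variance as ``s0_sq * F(d, d0)`` and matches the mean
    and variance of log variances (digamma/trigamma moments).  Exactly-zero
    variances are offset to 1e-5 of the median positive variance before
    taking logs.  When the log variances show no excess dispersion the fit
    degenerates to ``d0 = +inf`` with ``s0_sq`` the mean variance.
    """
    x = np.asarray(residual_variances, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 residual variances to fit a prior")
    if residual_df <= 0:
        raise ValueError("residual df must be positive")
    if (x < 0).any():
        raise ValueError("variances must be non-negative")
    m = np.median(x)
    if m == 0:
        m = 1.0
    x = np.maximum(x, 1e-5 * m)
    d = float(residual_df)
    z = np.log(x)
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar > 0 and np.isfinite(evar):
        d0 = 2.0 * _trigamma_inverse(evar)
        if np.isfinite(d0):
            s0 = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
            return ModeratedVariancePrior(d0=d0, s0_sq=s0)
    return ModeratedVariancePrior(d0=math.inf, s0_sq=float(x.mean()))


def moderated_t(
    group_a, group_b, prior: ModeratedVariancePrior | None = None
) -> tuple[float, float, float]:
    """Moderated two-sample t-test on log2 values.

    With no prior (or ``d0 = 0`` passed explicitly via a prior constructed
    with a vanishing d0 limit) this reduces to the ordinary pooled t-test.
    Returns ``(t, p, total_df)``; ``total_df = d0 + nA + nB - 2``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 samples")
    d = na + nb - 2
    s2 = (a.var(ddof=1) * (na - 1) + b.var(ddof=1) * (nb - 1)) / d
    if prior is None:
        d0, s0 = 0.0, 0.0
    else:
        d0, s0 = prior.d0, prior.s0_sq
    if math.isinf(d0):
        s2_post, df_total = s0, math.inf
    else:
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d0 + d
    diff = a.mean() - b.mean()
    se = math.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    if se == 0:
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        t = diff / se
    p = float(2.0 * stats.t.sf(abs(t), df_total)) if np.isfinite(t) else 0.0
    return float(t), min(p, 1.0), df_total


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_otus(
    table: AbundanceTable,
    group_field: str,
    group_a: str | None = None,
    group_b: str | None = None,
    fc_min: float = 1.2,
    fdr_max: float = 0.05,
    floor: float = 0.1,
) -> list[DifferentialResult]:
    """Screen every OTU for differential abundance between two groups.

    ``group_field`` names a metadata column; with more than two levels,
    ``group_a`` / ``group_b`` select the comparison.  The per-OTU pipeline:
    floored log2 transform, pooled residual variance, shared variance prior
    across OTUs, moderated t, BH adjustment.  Fold change is the ratio of
    floored group means (direction-symmetric); ``significant`` requires the
    ratio in either direction to reach ``fc_min`` and ``q <= fdr_max``.
    """
    if group_field not in table.metadata.columns:
        raise ValueError(f"unknown metadata field {group_field!r}")
    levels = table.metadata[group_field].astype(str)
    present = sorted(levels.unique())
    if group_a is None or group_b is None:
        if len(present) != 2:
            raise ValueError(
                f"{group_field!r} has levels {present}; specify group_a and group_b"
            )
        group_a, group_b = present
    for g in (group_a, group_b):
        if g not in present:
            raise ValueError(f"group {g!r} not found in {group_field!r}")
    logm = log_transform(table, floor=floor)
    ia = levels.index[levels == group_a]
    ib = levels.index[levels == group_b]
    na, nb = len(ia), len(ib)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 samples")
    la = logm.loc[ia].to_numpy()
    lb = logm.loc[ib].to_numpy()
    d = na + nb - 2
    s2 = (la.var(axis=0, ddof=1) * (na - 1) + lb.var(axis=0, ddof=1) * (nb - 1)) / d
    prior = fit_variance_prior(s2, d)
    mean_a = table.data.loc[ia].mean(axis=0).clip(lower=floor)
    mean_b = table.data.loc[ib].mean(axis=0).clip(lower=floor)
    results = []
    tps = [moderated_t(la[:, j], lb[:, j], prior) for j in range(logm.shape[1])]
    qs = bh_fdr([p for _, p, _ in tps])
    log2_fc_min = math.log2(fc_min) if np.isfinite(fc_min) else math.inf
    for j, otu in enumerate(logm.columns):
        l2fc = math.log2(mean_a.iloc[j] / mean_b.iloc[j])
        t, p, _ = tps[j]
        sig = bool(abs(l2fc) >= log2_fc_min and qs[j] <= fdr_max)
        results.append(
            DifferentialResult(
                otu_id=str(otu),
                log2_fold_change=l2fc,
                t_statistic=t,
                p_value=p,
                q_value=float(qs[j]),
                significant=sig,
            )
        )
    return results


def results_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    """Differential results as a DataFrame (otu, log2FC, t, p, q, significant)."""
    df = pd.DataFrame(
        {
            "otu_id": [r.otu_id for r in results],
            "log2_fold_change": [r.log2_fold_change for r in results],
            "t_statistic": [r.t_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
    return df.set_index("otu_id")
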