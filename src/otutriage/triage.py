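"""Candidate-OTU triage: extreme stratification, correlation panel, consensus.

Three lines of evidence classify each OTU as *provocative* (tracking with
worse ileitis), *beneficial_or_opportunistic* (enriched where pathology is
low, whether protective or merely filling a vacated niche), or
*indeterminate*:

1. Cured-vs-sick extreme screen — DKO mice with overall pathology score at
   or below ``cured_max`` (default 1) versus at or above ``sick_min``
   (default 5); per OTU the ratio of floored mean abundances
   (cured / sick), a pairwise t-test, and a family-wise adjusted p.
2. Marker-correlation panel — Pearson correlation of each OTU's abundance
   with the five pathology markers across all DKO mice, sign-harmonized so
   a positive coefficient always means "more abundance, more pathology"
   (the Paneth-fraction coefficient is flipped), then averaged.
3. Genotype shift — differential abundance of untreated DKO versus non-DKO
   mice (expansion/contraction), used as corroborating annotation.

A provocative verdict demands concordant positive evidence from both
pathology-linked analyses: cured/sick ratio < 1 with pairwise p <= alpha
*and* harmonized mean correlation at or above the moderate threshold
(default 0.3).  A genotype expansion alone is not sufficient — pathology
itself reshapes the community, so a DKO-enriched OTU may be a passenger.
The beneficial/opportunistic call is looser, mirroring the "suggestive
signs" standard: any two concordant negative signals (ratio > 1, harmonized
r <= -threshold, or genotype contraction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceTable
from .diffabund import DifferentialResult
from .pathology import MARKER_DIRECTIONS, MARKER_NAMES

VERDICTS = ("provocative", "beneficial_or_opportunistic", "indeterminate")


@dataclass(frozen=True)
class ExtremeGroups:
    """Sample ids at the pathology extremes (disjoint; DKO mice only)."""

    cured_ids: tuple[str, ...]
    sick_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.cured_ids) & set(self.sick_ids):
            raise ValueError("cured and sick groups overlap")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation plus the least-squares line behind it."""

    r: float
    n: int
    slope: float
    intercept: float
    degenerate: bool = False

    @property
    def r_squared(self) -> float:
        return self.r * self.r


@dataclass
class TriageRecord:
    """Accumulated per-OTU evidence and the consensus verdict."""

    otu_id: str
    ratio_cured_over_sick: float | None = None
    pairwise_p: float | None = None
    adjusted_p: float | None = None
    per_marker_r: dict = field(default_factory=dict)
    harmonized_mean_r: float | None = None
    dko_log2_fold: float | None = None
    dko_q: float | None = None
    verdict: str = "indeterminate"


def stratify_extremes(
    scores: Mapping[str, float],
    cured_max: float = 1.0,
    sick_min: float = 5.0,
) -> ExtremeGroups:
    """Split mice into cured (score <= cured_max) and sick (score >= sick_min).

    ``scores`` should already be restricted to eligible (DKO) mice.  Emits a
    warning when either extreme is empty.
    """
    if cured_max >= sick_min:
        raise ValueError("cured_max must be below sick_min")
    cured = tuple(s for s, v in scores.items() if v <= cured_max)
    sick = tuple(s for s, v in scores.items() if v >= sick_min)
    if not cured or not sick:
        warnings.warn(
            f"extreme stratification found {len(cured)} cured and {len(sick)} sick mice",
            stacklevel=2,
        )
    return ExtremeGroups(cured_ids=cured, sick_ids=sick)


def cured_sick_screen(
    table: AbundanceTable,
    groups: ExtremeGroups,
    floor: float = 0.1,
    alpha: float = 0.05,
    method: str = "bonferroni",
    family: str | int = "candidates",
) -> pd.DataFrame:
    """Per-OTU cured/sick abundance ratio, pairwise t-test, adjusted p.

    The ratio divides floored mean abundance in cured mice by that in sick
    mice: ratio < 1 marks a possibly provocative OTU, > 1 a possibly
    beneficial or opportunistic one.  The t-test is an ordinary two-sample
    pairwise test on the raw abundances.  The multiplicity family is
    configurable because the published correction implies a family smaller
    than all OTUs: ``"candidates"`` (default) corrects, per direction, over
    the OTUs passing the pairwise test at ``alpha``; ``"all"`` corrects over
    every OTU; an integer fixes the family size directly.  ``method`` is
    ``bonferroni``, ``holm`` or ``fdr_bh``.
    """
    if not groups.cured_ids or not groups.sick_ids:
        raise ValueError("both extreme groups must be non-empty")
    cured = table.data.loc[list(groups.cured_ids)]
    sick = table.data.loc[list(groups.sick_ids)]
    mean_c = cured.mean(axis=0).clip(lower=floor)
    mean_s = sick.mean(axis=0).clip(lower=floor)
    ratio = mean_c / mean_s
    with np.errstate(invalid="ignore"):
        tt = stats.ttest_ind(cured.to_numpy(), sick.to_numpy(), axis=0, equal_var=True)
    p = np.where(np.isnan(tt.pvalue), 1.0, tt.pvalue)
    direction = np.where(
        ratio < 1, "provocative", np.where(ratio > 1, "beneficial_or_opportunistic", "none")
    )
    adjusted = np.ones_like(p)
    if isinstance(family, int):
        adjusted = np.minimum(p * family, 1.0) if method == "bonferroni" else _adjust(p, method)
    elif family == "all":
        adjusted = _adjust(p, method)
    elif family == "candidates":
        # per-direction family of pairwise-significant candidates
        for dirn in ("provocative", "beneficial_or_opportunistic"):
            mask = (direction == dirn) & (p <= alpha)
            if mask.any():
                adjusted[mask] = _adjust(p[mask], method)
    else:
        raise ValueError(f"unknown family {family!r}")
    out = pd.DataFrame(
        {
            "ratio_cured_over_sick": ratio,
            "p_value": p,
            "adjusted_p": adjusted,
            "direction": direction,
        },
        index=table.data.columns,
    )
    out.index.name = "otu_id"
    return out


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method not in ("bonferroni", "holm", "fdr_bh"):
        raise ValueError(f"unknown multiplicity method {method!r}")
    return multipletests(p, method=method)[1]


def pearson_fit(x, y) -> CorrelationResult:
    """Pearson r with the fitted line; degenerate (zero-variance) inputs give r = 0."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("length mismatch")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return CorrelationResult(r=0.0, n=xa.size, slope=0.0, intercept=float(ya.mean()), degenerate=True)
    fit = stats.linregress(xa, ya)
    return CorrelationResult(
        r=float(fit.rvalue), n=xa.size, slope=float(fit.slope), intercept=float(fit.intercept)
    )


def marker_correlation_panel(
    table: AbundanceTable, markers: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r of each OTU's abundance against each of the five markers.

    ``markers`` is indexed by sample_id with the five marker columns; the
    correlation uses the samples present in both inputs (all DKO mice across
    the control and antibiotic sets).  Degenerate correlations are reported
    as 0; a parallel boolean column marks them.
    """
    missing = set(MARKER_NAMES) - set(markers.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    shared = [s for s in table.sample_ids if s in markers.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 mice with both abundance and marker data")
    abund = table.data.loc[shared]
    mk = markers.loc[shared]
    rows = {}
    for otu in abund.columns:
        rec = {}
        for name in MARKER_NAMES:
            res = pearson_fit(abund[otu], mk[name])
            rec[name] = res.r
            rec[f"{name}_degenerate"] = res.degenerate
        rows[otu] = rec
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "otu_id"
    return out


def harmonized_average(
    per_marker_r: Mapping[str, float], directions: Mapping[str, bool] | None = None
) -> float:
    """Direction-harmonized mean of the five marker correlations.

    Coefficients for markers where higher values mean better health (the
    Paneth fraction) are sign-flipped before averaging, so the result's sign
    reads as "positive = associated with more pathology".
    """
    if directions is None:
        directions = MARKER_DIRECTIONS
    missing = set(directions) - set(per_marker_r)
    if missing:
        raise ValueError(f"missing marker correlations: {sorted(missing)}")
    vals = [
        per_marker_r[name] if higher_is_worse else -per_marker_r[name]
        for name, higher_is_worse in directions.items()
    ]
    return float(np.mean(vals))


def combined_correlation(
    table: AbundanceTable, otus: Sequence[str], marker_values: pd.Series
) -> CorrelationResult:
    """Correlate the summed abundance of several OTUs with one marker."""
    missing = set(otus) - set(table.otu_ids)
    if missing:
        raise ValueError(f"unknown OTUs: {sorted(missing)}")
    shared = [s for s in table.sample_ids if s in marker_values.index]
    combined = table.data.loc[shared, list(otus)].sum(axis=1)
    return pearson_fit(combined, marker_values.loc[shared])


def dilution_adjust(target: float, diluter: float) -> float:
    """Renormalize an abundance as a share of the community excluding a diluter.

    A blooming OTU (e.g. Escherichia/Shigella after vancomycin) mechanically
    dilutes every other OTU's share of classified reads; closing the
    composition without the diluter — ``target / (100 - diluter) * 100`` —
    removes that artifact.  ``diluter`` must be below 100.
    """
    if not 0 <= diluter < 100:
        raise ValueError("diluter abundance must lie in [0, 100)")
    if target < 0:
        raise ValueError("target abundance must be non-negative")
    return target / (100.0 - diluter) * 100.0


def consensus_classify(
    records: Mapping[str, TriageRecord] | Sequence[TriageRecord],
    dko_vs_nondko: Sequence[DifferentialResult] | None = None,
    corr_threshold: float = 0.3,
    alpha: float = 0.05,
    fc_min: float = 1.2,
) -> dict[str, str]:
    """Consensus verdict per OTU from the three evidence lines.

    provocative: cured/sick ratio < 1 with pairwise p <= alpha AND
    harmonized mean r >= corr_threshold (two concordant pathology-positive
    signals; the genotype shift is annotation, not sufficient evidence).
    beneficial_or_opportunistic: at least two of {ratio > 1,
    harmonized r <= -corr_threshold, significant DKO contraction at fc_min}.
    Everything else: indeterminate.  Verdicts are written back onto the
    records and returned as a mapping.
    """
    if not isinstance(records, Mapping):
        records = {r.otu_id: r for r in records}
    dko_fold = {}
    if dko_vs_nondko is not None:
        for r in dko_vs_nondko:
            dko_fold[r.otu_id] = r
    log2_fc_min = math.log2(fc_min)
    verdicts = {}
    for otu, rec in records.items():
        if dko_vs_nondko is not None and otu in dko_fold:
            rec.dko_log2_fold = dko_fold[otu].log2_fold_change
            rec.dko_q = dko_fold[otu].q_value
        hmr = rec.harmonized_mean_r
        ratio = rec.ratio_cured_over_sick
        p = rec.pairwise_p
        cs_positive = ratio is not None and p is not None and ratio < 1 and p <= alpha
        corr_positive = hmr is not None and hmr >= corr_threshold
        cs_negative = ratio is not None and ratio > 1
        corr_negative = hmr is not None and hmr <= -corr_threshold
        dko_contracted = (
            rec.dko_log2_fold is not None
            and rec.dko_q is not None
            and rec.dko_log2_fold <= -log2_fc_min
            and rec.dko_q <= alpha
        )
        if cs_positive and corr_positive:
            verdict = "provocative"
        elif sum((cs_negative, corr_negative, dko_contracted)) >= 2:
            verdict = "beneficial_or_opportunistic"
        else:
            verdict = "indeterminate"
        rec.verdict = verdict
        verdicts[otu] = verdict
    return verdicts


def triage_study(
    table: AbundanceTable,
    markers: pd.DataFrame,
    cured_max: float = 1.0,
    sick_min: float = 5.0,
    floor: float = 0.1,
    alpha: float = 0.05,
    corr_threshold: float = 0.3,
    fc_min: float = 1.2,
    fdr_max: float = 0.05,
    multiplicity_method: str = "bonferroni",
    multiplicity_family: str | int = "candidates",
) -> dict[str, TriageRecord]:
    """Run the full triage on one study: screen, panel, genotype shift, verdicts.

    ``markers`` covers the DKO mice (indexed by sample_id).  The genotype
    comparison uses untreated (Splenda) DKO mice versus non-DKO mice when
    both are present.
    """
    from .diffabund import differential_otus  # local import to avoid cycle

    dko = table.dko_samples()
    scores = markers.loc[[s for s in dko.sample_ids if s in markers.index], "overall_score"]
    groups = stratify_extremes(dict(scores), cured_max=cured_max, sick_min=sick_min)
    records = {otu: TriageRecord(otu_id=otu) for otu in table.otu_ids}

    if groups.cured_ids and groups.sick_ids:
        screen = cured_sick_screen(
            table, groups, floor=floor, alpha=alpha,
            method=multiplicity_method, family=multiplicity_family,
        )
        for otu, row in screen.iterrows():
            records[otu].ratio_cured_over_sick = float(row["ratio_cured_over_sick"])
            records[otu].pairwise_p = float(row["p_value"])
            records[otu].adjusted_p = float(row["adjusted_p"])

    panel = marker_correlation_panel(dko, markers)
    for otu in table.otu_ids:
        per_marker = {name: float(panel.loc[otu, name]) for name in MARKER_NAMES}
        records[otu].per_marker_r = per_marker
        records[otu].harmonized_mean_r = harmonized_average(per_marker)

    meta = table.metadata
    is_ctrl_dko = (meta["genotype"] == "DKO") & (meta["treatment"] == "splenda")
    is_nondko = meta["genotype"] == "nonDKO"
    dko_results = None
    if is_ctrl_dko.sum() >= 2 and is_nondko.sum() >= 2:
        sub = table.subset(list(map(str, meta.index[is_ctrl_dko | is_nondko])))
        dko_results = differential_otus(
            sub, "genotype", group_a="DKO", group_b="nonDKO",
            fc_min=fc_min, fdr_max=fdr_max, floor=floor,
        )
    consensus_classify(
        records, dko_results, corr_threshold=corr_threshold, alpha=alpha, fc_min=fc_min
    )
    return records


def records_frame(records: Mapping[str, TriageRecord]) -> pd.DataFrame:
    """Triage records as a flat DataFrame (one row per OTU)."""
    rows = {}
    for otu, rec in records.items():
        row = {
            "ratio_cured_over_sick": rec.ratio_cured_over_sick,
            "pairwise_p": rec.pairwise_p,
            "adjusted_p": rec.adjusted_p,
            "harmonized_mean_r": rec.harmonized_mean_r,
            "dko_log2_fold": rec.dko_log2_fold,
            "dko_q": rec.dko_q,
            "verdict": rec.verdict,
        }
        for name in MARKER_NAMES:
            row[f"r_{name}"] = rec.per_marker_r.get(name)
        rows[otu] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "otu_id"
    return df
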