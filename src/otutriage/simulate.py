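"""Synthetic ileal communities with linked pathology markers.

The generator emulates the study design: four DKO treatment groups (Splenda
control, metronidazole, vancomycin, streptomycin; 8 mice each) plus 6
non-DKO littermates, 24 OTUs whose group-mean profiles default to the
published group means.  Each mouse's composition is a Dirichlet draw whose
mean is its group profile and whose concentration parameter controls
mouse-to-mouse scatter; the draw is scaled to a classified-read total drawn
uniformly from [75, 98] percent, so rows never sum to 100 — as in the real
tables, where part of the reads stay unclassified.

Pathology is tied to the community through a latent severity:

    l = beta0 + beta1 * (summed abundance of the provocative OTUs) + N(0, sigma^2)

The overall score is ``l`` clipped to [0, 10] and rounded to the 0.5 grid;
exfoliation, crypt abscesses and apoptosis are increasing saturating
(logistic) functions of ``l`` plus small observation noise, while the
Paneth-cell fraction decreases with ``l``.  Only this monotone co-variation
is asserted by the analysis — the link shapes themselves are a modelling
convenience.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import datasets
from .abundance import AbundanceTable

#: Classified-read row-total range (percent), mirroring the published totals.
ROW_TOTAL_RANGE = (75.0, 98.0)

# Marker observation-noise amplitudes and link shapes (fixed; the latent
# noise scale `sigma` is the tunable knob).
_MARKER_NOISE = {
    "exfoliation_fraction": 0.02,
    "paneth_fraction": 0.04,
    "abscesses_per_field": 0.05,
    "apoptosis_per_crypt": 0.02,
}


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _default_profiles() -> dict[str, pd.Series]:
    table = datasets.group_mean_table()
    return {g: table[g] for g in datasets.GROUPS}


def _default_n() -> dict[str, int]:
    return {
        "splenda": 8,
        "metronidazole": 8,
        "vancomycin": 8,
        "streptomycin": 8,
        "nonDKO": 6,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic study.

    beta0/beta1 place the latent severity scale: with the default published
    profiles the combined Lactobacillus + Clostridiaceae-1 abundance runs
    from ~2 % (streptomycin) to ~71 % (Splenda control), so beta0 = 1.0 and
    beta1 = 0.062 span scores ~1 (cured-like) to ~5.5 (sick-like), matching
    the observed score range under treatment.  sigma = 0.8 leaves the
    abundance signal dominant but not deterministic.  concentration = 50
    gives realistic mouse-to-mouse scatter (the dominant OTU varies by
    roughly +/- 7 percentage points between cage mates).
    """

    group_profiles: Mapping[str, pd.Series] = field(default_factory=_default_profiles)
    n_per_group: Mapping[str, int] = field(default_factory=_default_n)
    concentration: float = 50.0
    provocative_otus: tuple[str, ...] = ("Lactobacillus", "Clostridiaceae-1")
    beta0: float = 1.0
    beta1: float = 0.062
    sigma: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {g!r}: need at least 2 mice per group, got {n}")
        for g, prof in self.group_profiles.items():
            if (np.asarray(prof, dtype=float) < 0).any():
                raise ValueError(f"group {g!r}: negative profile values")
        if set(self.n_per_group) - set(self.group_profiles):
            raise ValueError("n_per_group names groups without profiles")


@dataclass(frozen=True)
class SyntheticStudy:
    """A generated study: abundance table, marker panels, and the truth record."""

    table: AbundanceTable
    markers: pd.DataFrame
    truth: dict


def sample_compositions(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> AbundanceTable:
    """Draw per-mouse compositions for every group in the configuration."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    frames, meta_rows = [], []
    otus = None
    for group in config.n_per_group:
        profile = pd.Series(config.group_profiles[group], dtype=float)
        if otus is None:
            otus = list(profile.index)
        profile = profile.reindex(otus).fillna(0.0)
        n = config.n_per_group[group]
        p = profile.to_numpy()
        total = p.sum()
        if total <= 0:
            raise ValueError(f"group {group!r}: profile sums to zero")
        alpha = p / total * config.concentration
        pos = alpha > 0
        comps = np.zeros((n, len(alpha)))
        comps[:, pos] = rng.dirichlet(alpha[pos], size=n)
        row_totals = rng.uniform(*ROW_TOTAL_RANGE, size=n)
        values = comps * row_totals[:, None]
        ids = [f"{group}_{i + 1:02d}" for i in range(n)]
        frames.append(pd.DataFrame(values, index=ids, columns=otus))
        genotype = "nonDKO" if group == "nonDKO" else "DKO"
        treatment = "splenda" if group == "nonDKO" else group
        for i, sid in enumerate(ids):
            meta_rows.append(
                {"sample_id": sid, "genotype": genotype, "treatment": treatment,
                 "sex": "M" if i % 2 == 0 else "F"}
            )
    data = pd.concat(frames)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return AbundanceTable(data, meta)


def generate_markers(
    table: AbundanceTable,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pathology markers for every mouse in the table, linked to abundance.

    Returns a DataFrame indexed by sample_id with the five marker columns.
    Latent severity gets the full Gaussian noise ``sigma``; each marker adds
    small fixed-amplitude observation noise on top of its link function.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    missing = set(config.provocative_otus) - set(table.otu_ids)
    if missing:
        raise ValueError(f"provocative OTUs absent from table: {sorted(missing)}")
    n = len(table.sample_ids)
    combined = table.data[list(config.provocative_otus)].sum(axis=1).to_numpy()
    latent = config.beta0 + config.beta1 * combined
    if config.sigma > 0:
        latent = latent + rng.normal(0.0, config.sigma, size=n)
    score = np.clip(latent, 0.0, 10.0)
    score = np.round(score * 2.0) / 2.0
    noise = {k: rng.normal(0.0, v, size=n) for k, v in _MARKER_NOISE.items()}
    markers = pd.DataFrame(
        {
            "overall_score": score,
            "exfoliation_fraction": np.clip(
                0.45 * _logistic((latent - 4.5) / 1.3) + noise["exfoliation_fraction"], 0.0, 1.0
            ),
            "paneth_fraction": np.clip(
                1.0 - 0.92 * _logistic((latent - 3.0) / 1.0) + noise["paneth_fraction"], 0.0, 1.0
            ),
            "abscesses_per_field": np.clip(
                1.6 * _logistic((latent - 5.0) / 1.2) + noise["abscesses_per_field"], 0.0, None
            ),
            "apoptosis_per_crypt": np.clip(
                0.05 + 0.35 * _logistic((latent - 3.0) / 1.5) + noise["apoptosis_per_crypt"],
                0.0, None,
            ),
        },
        index=table.data.index,
    )
    markers.index.name = "sample_id"
    return markers


def make_study(config: SimulationConfig, out_dir: Path | str | None = None) -> SyntheticStudy:
    """Compose compositions and markers into one reproducible study.

    With ``out_dir`` set, writes ``abundance.tsv``, ``metadata.csv``,
    ``markers.csv`` and ``truth.json`` in the formats the pipeline reads.
    """
    rng = np.random.default_rng(config.seed)
    table = sample_compositions(config, rng)
    markers = generate_markers(table, config, rng)
    truth = {
        "beta0": config.beta0,
        "beta1": config.beta1,
        "sigma": config.sigma,
        "seed": config.seed,
        "concentration": config.concentration,
        "provocative_otus": list(config.provocative_otus),
    }
    study = SyntheticStudy(table=table, markers=markers, truth=truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.write(out / "abundance.tsv", out / "metadata.csv")
        markers.to_csv(out / "markers.csv")
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return study


def calibrate_slope(
    config: SimulationConfig, r_squared: float, center_score: float = 5.0
) -> SimulationConfig:
    """Set beta1 so the latent abundance/severity R-squared hits a target.

    With ``l = beta0 + beta1*A + e``, the latent R-squared is
    ``beta1^2 Var(A) / (beta1^2 Var(A) + sigma^2)``; solving for beta1 uses
    the *expected* abundance variance of the combined provocative OTUs
    across the DKO design (a large analytic draw at the configured
    concentration).  beta0 is then chosen to center the mean DKO score at
    ``center_score`` so clipping at the scale ends stays rare.  Score
    rounding attenuates the realized R-squared slightly below the target.
    """
    if not 0 < r_squared < 1:
        raise ValueError("r_squared must lie in (0, 1)")
    if config.sigma <= 0:
        raise ValueError("calibration needs sigma > 0")
    # analytic expected variance of combined provocative abundance over DKO groups
    rng = np.random.default_rng(987654321)  # internal, fixed: estimates a design constant
    probe = replace(config, seed=0)
    dko_groups = [g for g in config.n_per_group if g != "nonDKO"]
    sums = []
    for g in dko_groups:
        prof = pd.Series(config.group_profiles[g], dtype=float)
        p = prof.to_numpy() / prof.sum()
        alpha = p * config.concentration
        pos = alpha > 0
        comp = np.zeros((2000, p.size))
        comp[:, pos] = rng.dirichlet(alpha[pos], size=2000)
        totals = rng.uniform(*ROW_TOTAL_RANGE, size=2000)
        idx = [list(prof.index).index(o) for o in config.provocative_otus]
        sums.append((comp[:, idx].sum(axis=1) * totals))
    weights = np.repeat(
        [config.n_per_group[g] for g in dko_groups],
        [len(s) for s in sums],
    )
    pooled = np.concatenate(sums)
    var_a = float(np.cov(pooled, aweights=weights)[()])
    mean_a = float(np.average(pooled, weights=weights))
    beta1 = config.sigma * np.sqrt(r_squared / (1.0 - r_squared)) / np.sqrt(var_a)
    beta0 = center_score - beta1 * mean_a
    return replace(probe, beta1=float(beta1), beta0=float(beta0), seed=config.seed)
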