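"""Composite ileum histopathology scoring and the five-marker panel.

Blinded H&E evaluation of the distal small intestine yields per-mouse raw
observations: apoptotic figures per crypt, the fraction of crypts retaining
Paneth cells, crypt density per 10x field, inflammation foci per field, peak
inflammation intensity, crypt exfoliation (anoikis) and crypt abscess counts.
Five rubric subscores are derived from these and summed into an overall
score on [0, 10]; a separate five-marker panel (overall score, exfoliation,
Paneth incidence, abscesses, apoptosis) feeds the abundance-correlation
screen, each marker flagged with whether larger values mean worse disease.

Bin edges are the published empirical cut points.  The published bins leave
narrow gaps between rounded edges (e.g. Paneth 0.59-0.6) and do not define
scores beyond the worst printed bin; here each lower bin extends up to the
next edge and out-of-range inputs clamp to the worst defined subscore, so
the rubric is total on its domain.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd


class IntensityGrade(str, enum.Enum):
    """Peak inflammation damage seen in the section."""

    NONE = "none"
    SMALL_ABSCESS = "small_abscess"
    LARGE_ABSCESS = "large_abscess"
    EROSION = "erosion"


@dataclass(frozen=True)
class HistologyObservation:
    """Raw per-mouse histology measurements feeding the rubric."""

    apoptosis_per_crypt: float
    paneth_fraction: float
    crypt_density: float
    foci_per_field: float
    intensity_grade: IntensityGrade
    exfoliation_fraction: float = 0.0
    abscesses_per_field: float = 0.0

    def __post_init__(self) -> None:
        for name in ("apoptosis_per_crypt", "crypt_density", "foci_per_field", "abscesses_per_field"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("paneth_fraction", "exfoliation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not isinstance(self.intensity_grade, IntensityGrade):
            object.__setattr__(self, "intensity_grade", IntensityGrade(self.intensity_grade))


@dataclass(frozen=True)
class PathologySubscores:
    """The five rubric subscores and their sum (overall in [0, 10])."""

    apoptosis_sub: float
    paneth_sub: float
    density_sub: float
    foci_sub: float
    intensity_sub: float

    @property
    def overall(self) -> float:
        return (
            self.apoptosis_sub
            + self.paneth_sub
            + self.density_sub
            + self.foci_sub
            + self.intensity_sub
        )


#: Marker name -> True when larger values indicate worse disease.
MARKER_DIRECTIONS: dict[str, bool] = {
    "overall_score": True,
    "exfoliation_fraction": True,
    "paneth_fraction": False,
    "abscesses_per_field": True,
    "apoptosis_per_crypt": True,
}

MARKER_NAMES = tuple(MARKER_DIRECTIONS)


@dataclass(frozen=True)
class MarkerPanel:
    """The five pathology markers for one mouse, with direction flags."""

    overall_score: float
    exfoliation_fraction: float
    paneth_fraction: float
    abscesses_per_field: float
    apoptosis_per_crypt: float

    @property
    def values(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MARKER_NAMES}

    @property
    def directions(self) -> dict[str, bool]:
        return dict(MARKER_DIRECTIONS)


def score_apoptosis(x: float) -> float:
    """1 when apoptotic figures per crypt exceed 0.1 (strictly), else 0."""
    if x < 0:
        raise ValueError("apoptosis figures/crypt must be non-negative")
    return 1.0 if x > 0.1 else 0.0


def score_paneth(f: float) -> float:
    """Subscore for the fraction of crypts retaining Paneth cells.

    [0.8, 1] -> 0; [0.6, 0.8) -> 0.5; [0.34, 0.6) -> 1; [0.15, 0.34) -> 1.5;
    [0, 0.15) -> 2.  Bins are closed at the healthier edge.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("Paneth fraction must lie in [0, 1]")
    if f >= 0.8:
        return 0.0
    if f >= 0.6:
        return 0.5
    if f >= 0.34:
        return 1.0
    if f >= 0.15:
        return 1.5
    return 2.0


def score_density(d: float) -> float:
    """Subscore for crypts per 10x field (one side): >=39.1 -> 0;
    [33.6, 39.1) -> 1; below -> 2 (values under the worst printed bin clamp)."""
    if d < 0:
        raise ValueError("crypt density must be non-negative")
    if d >= 39.1:
        return 0.0
    if d >= 33.6:
        return 1.0
    return 2.0


def score_foci(f: float) -> float:
    """Subscore for inflammation foci per 10x field (both sides): 0 -> 0;
    (0, 0.2] -> 1; above -> 2 (counts beyond the worst printed bin clamp)."""
    if f < 0:
        raise ValueError("foci per field must be non-negative")
    if f == 0:
        return 0.0
    if f <= 0.2:
        return 1.0
    return 2.0


_INTENSITY_SUB = {
    IntensityGrade.NONE: 0.0,
    IntensityGrade.SMALL_ABSCESS: 1.0,
    IntensityGrade.LARGE_ABSCESS: 2.0,
    IntensityGrade.EROSION: 3.0,
}


def score_intensity(g: IntensityGrade | str) -> float:
    """Subscore for peak inflammation intensity (none/small/large/erosion)."""
    return _INTENSITY_SUB[IntensityGrade(g)]


def overall_score(obs: HistologyObservation) -> PathologySubscores:
    """All five subscores for one mouse; overall is their sum."""
    return PathologySubscores(
        apoptosis_sub=score_apoptosis(obs.apoptosis_per_crypt),
        paneth_sub=score_paneth(obs.paneth_fraction),
        density_sub=score_density(obs.crypt_density),
        foci_sub=score_foci(obs.foci_per_field),
        intensity_sub=score_intensity(obs.intensity_grade),
    )


def marker_panel(obs: HistologyObservation, subs: PathologySubscores | None = None) -> MarkerPanel:
    """Assemble the five-marker panel for one mouse."""
    if subs is None:
        subs = overall_score(obs)
    return MarkerPanel(
        overall_score=subs.overall,
        exfoliation_fraction=obs.exfoliation_fraction,
        paneth_fraction=obs.paneth_fraction,
        abscesses_per_field=obs.abscesses_per_field,
        apoptosis_per_crypt=obs.apoptosis_per_crypt,
    )


# -- tabular I/O -----------------------------------------------------------

_OBS_COLUMNS = (
    "apoptosis_per_crypt",
    "paneth_fraction",
    "crypt_density",
    "foci_per_field",
    "intensity_grade",
    "exfoliation_fraction",
    "abscesses_per_field",
)


def read_histology(path: Path | str) -> dict[str, HistologyObservation]:
    """Read a histology CSV (one row per mouse, sample_id + observation columns)."""
    df = pd.read_csv(path)
    missing = set(_OBS_COLUMNS) - set(df.columns)
    if "sample_id" not in df.columns or missing:
        raise ValueError(f"histology CSV missing columns: {sorted(missing | {'sample_id'} - set(df.columns))}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["sample_id"])] = HistologyObservation(
            apoptosis_per_crypt=float(row["apoptosis_per_crypt"]),
            paneth_fraction=float(row["paneth_fraction"]),
            crypt_density=float(row["crypt_density"]),
            foci_per_field=float(row["foci_per_field"]),
            intensity_grade=IntensityGrade(row["intensity_grade"]),
            exfoliation_fraction=float(row["exfoliation_fraction"]),
            abscesses_per_field=float(row["abscesses_per_field"]),
        )
    return out


def score_table(observations: dict[str, HistologyObservation]) -> pd.DataFrame:
    """Subscores, overall score and marker panel for a set of mice.

    Returns a DataFrame indexed by sample_id with one column per subscore,
    the overall score, and the five marker columns.
    """
    rows = {}
    for sid, obs in observations.items():
        subs = overall_score(obs)
        panel = marker_panel(obs, subs)
        rows[sid] = {
            "apoptosis_sub": subs.apoptosis_sub,
            "paneth_sub": subs.paneth_sub,
            "density_sub": subs.density_sub,
            "foci_sub": subs.foci_sub,
            "intensity_sub": subs.intensity_sub,
            **panel.values,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def read_marker_table(path: Path | str) -> pd.DataFrame:
    """Read a marker CSV (sample_id + the five marker columns)."""
    df = pd.read_csv(path).set_index("sample_id")
    missing = set(MARKER_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"marker CSV missing columns: {sorted(missing)}")
    return df[list(MARKER_NAMES)].astype(float)
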