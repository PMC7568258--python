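"""OTU relative-abundance tables: I/O, validation, filtering and summaries.

The central container is :class:`AbundanceTable`: a samples x OTUs matrix of
relative abundances in percent of classified reads, paired with per-sample
metadata (genotype, treatment, sex).  Row totals need not reach 100 because
unclassified reads are excluded upstream; published group totals range from
75 to 98 percent.  Values are stored exactly as read — any abundance floor
(the 0.1 % pseudo-abundance convention visible throughout the published
table) is applied only inside log/ratio computations downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("DKO", "nonDKO")
TREATMENTS = ("splenda", "metronidazole", "vancomycin", "streptomycin", "none")
SEXES = ("M", "F", "unknown")

#: Slack allowed above 100 % for row totals (rounding of published values).
ROW_TOTAL_TOLERANCE = 0.5


class AbundanceTableError(ValueError):
    """Raised when a table or its metadata violates the format contract."""


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one mouse's ileal sample."""

    sample_id: str
    genotype: str
    treatment: str
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise AbundanceTableError(
                f"sample {self.sample_id!r}: unknown genotype {self.genotype!r}"
            )
        if self.treatment not in TREATMENTS:
            raise AbundanceTableError(
                f"sample {self.sample_id!r}: unknown treatment {self.treatment!r}"
            )
        if self.sex not in SEXES:
            raise AbundanceTableError(
                f"sample {self.sample_id!r}: unknown sex {self.sex!r}"
            )
        if self.genotype == "nonDKO" and self.treatment not in ("splenda", "none"):
            raise AbundanceTableError(
                f"sample {self.sample_id!r}: non-DKO mice were not antibiotic-treated "
                f"(treatment {self.treatment!r})"
            )


@dataclass(frozen=True)
class GroupProfile:
    """Mean abundance profile (percent) for one group of mice."""

    group_label: str
    mean_abundance: pd.Series

    def __post_init__(self) -> None:
        if (self.mean_abundance < 0).any():
            bad = self.mean_abundance.index[self.mean_abundance < 0][0]
            raise AbundanceTableError(
                f"profile {self.group_label!r}: negative mean for OTU {bad!r}"
            )


@dataclass
class AbundanceTable:
    """Samples x OTUs relative abundances (percent) plus sample metadata.

    ``data`` is indexed by sample_id with one column per OTU; ``metadata`` is
    indexed by sample_id with columns genotype / treatment / sex, aligned
    row-for-row with ``data``.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0:
            raise AbundanceTableError("no samples")
        self.data.index = self.data.index.astype(str).rename("sample_id")
        self.data.columns = self.data.columns.rename(None)
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise AbundanceTableError(f"duplicate OTU name {dup!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise AbundanceTableError(f"duplicate sample id {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            row, col = np.argwhere(~np.isfinite(values))[0]
            raise AbundanceTableError(
                f"non-finite abundance for sample {self.data.index[row]!r}, "
                f"OTU {self.data.columns[col]!r}"
            )
        if (values < 0).any():
            row, col = np.argwhere(values < 0)[0]
            raise AbundanceTableError(
                f"negative abundance for sample {self.data.index[row]!r}, "
                f"OTU {self.data.columns[col]!r}"
            )
        totals = values.sum(axis=1)
        if (totals > 100 + ROW_TOTAL_TOLERANCE).any():
            bad = self.data.index[int(np.argmax(totals))]
            raise AbundanceTableError(
                f"sample {bad!r}: row total {totals.max():.2f} exceeds 100 %"
            )
        if self.metadata is None:
            self.metadata = pd.DataFrame(
                {"genotype": "DKO", "treatment": "none", "sex": "unknown"},
                index=self.data.index,
            )
        self.metadata.index = self.metadata.index.astype(str).rename("sample_id")
        missing = self.data.index.difference(self.metadata.index)
        if len(missing) > 0:
            raise AbundanceTableError(
                f"samples missing from metadata: {sorted(map(str, missing))}"
            )
        extra = self.metadata.index.difference(self.data.index)
        if len(extra) > 0:
            warnings.warn(
                f"metadata rows without abundance data ignored: {sorted(map(str, extra))}",
                stacklevel=2,
            )
        self.metadata = self.metadata.loc[self.data.index]
        for sid, row in self.metadata.iterrows():
            SampleRecord(str(sid), row["genotype"], row["treatment"], row.get("sex", "unknown"))

    # -- convenience -------------------------------------------------------

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(map(str, self.data.index))

    @property
    def samples(self) -> list[SampleRecord]:
        return [
            SampleRecord(str(sid), r["genotype"], r["treatment"], r.get("sex", "unknown"))
            for sid, r in self.metadata.iterrows()
        ]

    def subset(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        """Restrict to the given samples (order preserved)."""
        ids = list(sample_ids)
        missing = set(ids) - set(self.sample_ids)
        if missing:
            raise AbundanceTableError(f"unknown sample ids: {sorted(missing)}")
        return AbundanceTable(self.data.loc[ids].copy(), self.metadata.loc[ids].copy())

    def dko_samples(self) -> "AbundanceTable":
        """The DKO mice only (all treatment groups)."""
        keep = self.metadata.index[self.metadata["genotype"] == "DKO"]
        return self.subset(list(map(str, keep)))

    def write(self, table_path: Path | str, metadata_path: Path | str) -> None:
        """Write the abundance TSV and metadata CSV in the on-disk formats."""
        self.data.rename_axis("sample_id").to_csv(table_path, sep="\t")
        self.metadata.rename_axis("sample_id").to_csv(metadata_path)


# -- readers ---------------------------------------------------------------


def _read_delimited(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError:
        raise AbundanceTableError("no samples") from None
    return df


def read_metadata(path: Path | str) -> pd.DataFrame:
    """Read the sample-metadata CSV (columns sample_id, genotype, treatment, sex)."""
    meta = pd.read_csv(path)
    required = {"sample_id", "genotype", "treatment"}
    if not required.issubset(meta.columns):
        raise AbundanceTableError(
            f"metadata must have columns {sorted(required)}; got {list(meta.columns)}"
        )
    if "sex" not in meta.columns:
        meta["sex"] = "unknown"
    return meta.set_index("sample_id")


def read_abundance_table(path: Path | str, metadata_path: Path | str | None = None) -> AbundanceTable:
    """Read a delimited abundance table (samples as rows, OTUs as columns, percent).

    The header row carries OTU names and the first column sample ids.  When
    ``metadata_path`` is given, rows are aligned to the metadata; samples
    without metadata are rejected and metadata rows without samples are
    reported with a warning.
    """
    df = _read_delimited(path)
    if df.shape[0] == 0:
        raise AbundanceTableError("no samples")
    meta = read_metadata(metadata_path) if metadata_path is not None else None
    return AbundanceTable(df.astype(float), meta)


def read_mothur_shared(path: Path | str, metadata_path: Path | str | None = None) -> AbundanceTable:
    """Read a mothur ``.shared`` count file, converting counts to percent.

    Expected columns: label, Group, numOtus, then one count column per OTU.
    Counts become percent of each sample's row total, so rows sum to 100
    (no unclassified fraction exists in a shared file).
    """
    df = pd.read_csv(path, sep="\t")
    expected = {"label", "Group", "numOtus"}
    if not expected.issubset(df.columns):
        raise AbundanceTableError(
            f"not a mothur shared file: missing columns {sorted(expected - set(df.columns))}"
        )
    counts = df.drop(columns=["label", "numOtus"]).set_index("Group").astype(float)
    counts.index.name = "sample_id"
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        zero = counts.index[totals == 0][0]
        raise AbundanceTableError(f"sample {zero!r}: zero total count")
    percent = counts.div(totals, axis=0) * 100.0
    meta = read_metadata(metadata_path) if metadata_path is not None else None
    return AbundanceTable(percent, meta)


# -- operations ------------------------------------------------------------


def filter_otus(
    table: AbundanceTable, min_percent: float = 0.5, min_samples: int = 1
) -> AbundanceTable:
    """Keep OTUs whose abundance exceeds ``min_percent`` in >= ``min_samples`` samples.

    The published pipeline retained genera with abundance greater than 0.5 %
    in at least one sample.  The threshold is strict (> not >=); the sample
    set is unchanged and the result may have zero OTUs.
    """
    hits = (table.data > min_percent).sum(axis=0)
    keep = table.data.columns[hits >= min_samples]
    return AbundanceTable(table.data[keep].copy(), table.metadata.copy())


def group_means(table: AbundanceTable, group_by: str | Sequence[str]) -> list[GroupProfile]:
    """Arithmetic mean abundance per OTU within each metadata group.

    ``group_by`` names one or more metadata columns; every sample belongs to
    exactly one group.  Group labels join the level values with '/'.
    """
    cols = [group_by] if isinstance(group_by, str) else list(group_by)
    for c in cols:
        if c not in table.metadata.columns:
            raise AbundanceTableError(f"unknown metadata field {c!r}")
    labels = table.metadata[cols].astype(str).agg("/".join, axis=1)
    profiles = []
    for label, idx in sorted(labels.groupby(labels).groups.items()):
        means = table.data.loc[idx].mean(axis=0)
        profiles.append(GroupProfile(str(label), means))
    return profiles


def total_classified(profile: GroupProfile) -> float:
    """Sum of all OTU means — the classified fraction of reads, in percent."""
    if len(profile.mean_abundance) == 0:
        raise AbundanceTableError("empty profile")
    return float(profile.mean_abundance.sum())


def core_microbiota(
    dko: GroupProfile,
    nondko: GroupProfile,
    per_otu_p: Mapping[str, float] | None = None,
    fold_max: float = 2.0,
    p_min: float = 0.09,
    min_mean: float = 0.2,
) -> set[str]:
    """OTUs shared at similar abundance by diseased and control mice.

    An OTU belongs to the core when its between-group fold difference
    ``max(a, b) / min(a, b)`` is below ``fold_max``, its differential-
    abundance p-value exceeds ``p_min`` (no significant shift), and its mean
    is at least ``min_mean`` percent in *both* groups.  The mean floor keeps
    trace OTUs — whose fold ratio is meaningless at pseudo-abundance level —
    out of the core.  Symmetric in the two profiles.
    """
    a, b = dko.mean_abundance, nondko.mean_abundance
    if set(a.index) != set(b.index):
        only = set(a.index).symmetric_difference(b.index)
        raise AbundanceTableError(f"OTUs present in only one profile: {sorted(only)}")
    b = b.loc[a.index]
    core: set[str] = set()
    for otu in a.index:
        x, y = float(a[otu]), float(b[otu])
        if min(x, y) < min_mean:
            continue
        lo, hi = min(x, y), max(x, y)
        fold = 1.0 if hi == 0 else (np.inf if lo == 0 else hi / lo)
        if fold >= fold_max:
            continue
        p = 1.0 if per_otu_p is None else float(per_otu_p.get(otu, 1.0))
        if p <= p_min:
            continue
        core.add(str(otu))
    return core
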