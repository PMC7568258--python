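"""Published summary data for the Gpx1/2-DKO ileum microbiome study.

The study profiled the ileal fecal-stream microbiota (V3-V4 16S, genus-level
OTUs) of Gpx1/2 double-knockout (DKO) mice developing ileitis, their
pathology-free non-DKO littermates, and DKO mice treated with one of three
antibiotics (metronidazole, vancomycin, streptomycin) in Splenda-sweetened
drinking water.  This module holds the published group-mean relative
abundances (percent of classified reads) for the 24 OTUs that passed the
0.5 %-in-at-least-one-sample filter, together with the published harmonized
pathology-correlation column and the named eight-OTU core microbiota.

These are printed summary values, not the per-mouse deposited data; they
anchor fixtures, the synthetic-community generator and the arithmetic
acceptance checks.
"""

from __future__ import annotations

import pandas as pd

#: Treatment-group column order: Splenda-control DKO, non-DKO littermates,
#: then the three antibiotic-treated DKO groups.
GROUPS = ("splenda", "nonDKO", "metronidazole", "vancomycin", "streptomycin")

# OTU -> (splenda, nonDKO, metronidazole, vancomycin, streptomycin) mean %.
_MEAN_ABUNDANCE = {
    "Lactobacillus":        (44.6,  39.54,  55.97, 43.4,    1.77),
    "Clostridiaceae-1":     (26.37, 25.05,  12.8,   0.1,    0.11),
    "Ureaplasma":           (6.3,    0.64,   2.19,  0.107, 32.38),
    "Sporacetigenium":      (3.76,   0.68,   0.1,   0.1,    0.1),
    "Bacteroides":          (1.81,   0.45,   0.1,   0.349,  4.4),
    "Helicobacter":         (1.22,   0.14,   0.11,  0.11,   0.17),
    "Escherichia/Shigella": (0.949,  0.11,  10.62, 44.9,    0.1),
    "Parasutterella":       (0.656,  0.46,   6.12,  1.23,  11.73),
    "Streptococcus":        (0.507,  0.26,   0.33,  0.1,    0.133),
    "Turicibacter":         (0.477,  0.32,   0.2,   0.1,    0.1),
    "Dorea":                (0.465,  0.34,   0.1,   0.1,    0.113),
    "Staphylococcus":       (0.417,  1.34,   0.14,  0.19,   0.159),
    "Roseburia":            (0.39,   0.1,    0.1,   0.1,    0.1),
    "Barnesiella":          (0.33,   8.33,   0.348, 0.1,    1.4),
    "Lachnospiraceae":      (0.266,  0.27,   0.1,   0.1,    0.104),
    "Pasteurellaceae":      (0.26,   0.1,    0.1,   0.1,    0.1),
    "Alistipes":            (0.21,   0.28,   0.0,   0.0,    0.001),
    "Ruminococcaceae":      (0.19,   0.44,   0.1,   0.1,    0.1),
    "Allobaculum":          (0.16,   0.03,   0.07,  0.0,   20.63),
    "Desulfovibrio":        (0.11,   1.31,   0.0,   0.0,    0.0002),
    "Porphyromonadaceae":   (0.11,   1.17,   0.0,   0.0,    0.58),
    "Bifidobacteriaceae":   (0.11,   0.016,  5.86,  0.0,    0.79),
    "Enterococcus":         (0.1,    0.01,   2.65,  0.00065, 0.044),
    "Akkermansia":          (0.0,    0.0003, 0.25,  0.0,    0.0),
}

#: Published harmonized average correlation of each OTU's abundance with the
#: five pathology markers across all DKO mice (sign: + = more pathology).
PATHOLOGY_CORRELATION = pd.Series(
    {
        "Lactobacillus": 0.506,
        "Clostridiaceae-1": 0.455,
        "Ureaplasma": -0.294,
        "Sporacetigenium": 0.343,
        "Bacteroides": -0.227,
        "Helicobacter": 0.378,
        "Escherichia/Shigella": -0.224,
        "Parasutterella": -0.266,
        "Streptococcus": 0.403,
        "Turicibacter": 0.308,
        "Dorea": 0.088,
        "Staphylococcus": 0.144,
        "Roseburia": 0.085,
        "Barnesiella": -0.178,
        "Lachnospiraceae": 0.183,
        "Pasteurellaceae": 0.435,
        "Alistipes": 0.174,
        "Ruminococcaceae": 0.139,
        "Allobaculum": -0.314,
        "Desulfovibrio": 0.175,
        "Porphyromonadaceae": -0.299,
        "Bifidobacteriaceae": 0.099,
        "Enterococcus": 0.044,
        "Akkermansia": 0.122,
    },
    name="pathology_correlation",
)

#: The eight-OTU core microbiota shared by DKO and non-DKO ilea (< 2-fold
#: between-genotype difference, non-significant).
CORE_OTUS = frozenset(
    {
        "Lactobacillus",
        "Clostridiaceae-1",
        "Streptococcus",
        "Lachnospiraceae",
        "Turicibacter",
        "Parasutterella",
        "Dorea",
        "Alistipes",
    }
)


def group_mean_table() -> pd.DataFrame:
    """Published group-mean abundance table (24 OTUs x 5 groups, percent).

    Rows are OTUs ranked by Splenda-control abundance; columns follow
    :data:`GROUPS`.
    """
    df = pd.DataFrame.from_dict(_MEAN_ABUNDANCE, orient="index", columns=list(GROUPS))
    df.index.name = "otu_id"
    return df


def otu_ids() -> list[str]:
    """OTU identifiers in published (abundance-ranked) order."""
    return list(_MEAN_ABUNDANCE)
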