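# Methods

## Setting

The pipeline analyzes ileal fecal-stream microbiota of Gpx1/2-DKO mice
(spontaneous ileitis on a B6 background), their pathology-free non-DKO
littermates, and DKO mice given metronidazole, vancomycin or streptomycin in
Splenda-sweetened water from weaning. Inputs are genus-level OTU
relative-abundance tables in percent of classified reads (row totals below
100 are normal and preserved — statistics never renormalize rows), sample
metadata (genotype, treatment, sex), and per-mouse histology.

## Abundance handling

**Floor.** Published tables show many entries at exactly 0.1 %, consistent
with a reporting/pseudo-abundance floor. Raw tables are stored as read;
a configurable floor (default 0.1 %) is applied only inside log and ratio
computations (log₂ transform, fold changes, cured/sick ratios). This
preserves data fidelity while keeping ratios of trace OTUs finite and
consistent with the published convention. The differential screen and the
cured/sick screen share the same floor default (cross-checked by a test).

**Filter.** OTUs are retained when abundance exceeds 0.5 % (strictly) in at
least one sample. The filter is idempotent and never changes the sample set.

**Core microbiota.** An OTU is "core" (shared by diseased and control mice)
when the between-genotype fold difference max(a,b)/min(a,b) is below 2, its
differential p-value exceeds 0.09, and its mean is at least 0.2 % in both
groups. The 0.2 % mean floor is this package's addition: without it,
floor-valued trace OTUs (e.g. a 0 vs 0.0003 pair) pass the fold test
spuriously. With it, the published group means yield exactly the eight
named core OTUs. The rule is symmetric in the two profiles.

## Histopathology rubric

Five subscores: apoptosis (>0.1 figures/crypt → 1, else 0), Paneth-cell
incidence ([0.8, 1] → 0; [0.6, 0.8) → 0.5; [0.34, 0.6) → 1; [0.15, 0.34) →
1.5; [0, 0.15) → 2), crypt density (≥39.1/field → 0; [33.6, 39.1) → 1;
below → 2), inflammation foci (0 → 0; (0, 0.2] → 1; >0.2 → 2), and peak
intensity (none/small abscess/large abscess/erosion → 0/1/2/3). The overall
score is their sum, always in [0, 10] on the 0.5 grid.

Two interpretive choices were needed because the published bin edges are
rounded empirical cut points: (i) narrow gaps between bins (e.g. Paneth
0.59–0.6, density 39–39.1) are closed by extending the lower (worse) bin
upward, and the overlapping Paneth bin "0–0.79 → 0.5" is read as
[0.6, 0.8) — the only non-overlapping reading consistent with its
neighbors; (ii) inputs beyond the worst printed bin (density below 27.8,
foci above 0.5) clamp to that bin's subscore, since no worse subscore is
defined and observed maxima are consistent with clamping. Any positive
focus count scores at least 1.

The marker panel per mouse is (overall score, exfoliation fraction, Paneth
fraction, crypt abscesses per field, apoptosis per crypt) with fixed
direction flags: all higher-is-worse except the Paneth fraction.

## Ordination

The between-sample distance is the Jaccard family on abundance vectors.
Default is the quantitative (Ružička) form 1 − Σmin/Σmax, chosen because the
source analysis computed distances on abundance *values*; binary Jaccard on
presence calls (default threshold 0.5 %) is available. Ružička is a true
metric on the non-negative orthant (verified by property test), with two
all-zero vectors at distance 0.

"Distance-based PCA" is implemented as classical principal-coordinates
analysis: square and double-center the distances, eigendecompose, scale
eigenvectors by √eigenvalue. Negative eigenvalues (non-Euclidean input) are
reported unchanged, excluded from the explained-fraction denominator, and
not corrected (no Cailliez/Lingoes); axes with non-positive eigenvalues get
zero coordinates. For Euclidean-consistent input the embedding reproduces
the distances to 1e-8. An independent cross-check against scikit-bio's PCoA
is part of the suite.

## Differential abundance

Counts are not available to this pipeline, so the screen operates on
floored log₂ relative abundances with an empirical-Bayes moderated t-test —
the same statistical family as the count-level limma-voom analysis, without
voom's mean–variance precision weights. Per-OTU pooled residual variances
s² (df d = nA + nB − 2) are shrunk toward a scaled inverse-chi-square prior
(d₀, s₀²) fitted across OTUs by the log-moment method (digamma/trigamma
matching of the scaled-F model; zero variances are offset to 1e-5 of the
median before the log). The posterior variance is
(d₀s₀² + d·s²)/(d₀ + d); the t statistic uses d + d₀ degrees of freedom.
When the log variances show no excess dispersion the fit degenerates to
d₀ = ∞ (all variances collapse to the mean variance). The implementation
agrees with R limma's `fitFDist`/`eBayes` to ~1e-9 on a shared matrix
(oracle test) and reduces exactly to the ordinary pooled t-test without a
prior.

p-values receive Benjamini–Hochberg adjustment; an OTU is *significant*
when the ratio of floored group means reaches 1.2 in either direction and
q ≤ 0.05. Under identical group profiles at the study's sample sizes, fewer
than 10 % of simulated studies produce any call; an 8-fold planted shift is
detected in well over 80 %.

Only two-group comparisons are implemented; the original design matrix
(litter pairing, sex) is unknown and out of scope.

## Candidate triage

**Extreme screen.** DKO mice with overall score ≤ 1 are "cured", ≥ 5
"sick". Per OTU: ratio of floored mean abundances (cured/sick), ordinary
pairwise t-test, and a family-wise adjusted p. The published correction
implies a family smaller than all 24 OTUs, so the family is configurable:
the default corrects, per direction, over the OTUs passing the pairwise
test (the named candidates), with Holm/BH and fixed-size options. Ratio
below 1 marks a possibly provocative OTU; above 1 possibly beneficial or
opportunistic.

**Correlation panel.** Pearson correlation (the reported quantities are
R² values from line fits) of each OTU's abundance with each of the five
markers across all DKO mice. Degenerate (zero-variance) inputs return r = 0
with an explicit flag rather than NaN. The harmonized average flips the
Paneth coefficient's sign and averages the five, so positive always means
"more abundance, more pathology". Combined-abundance correlations sum the
listed OTUs per mouse first; the dilution adjustment renormalizes a target
OTU to the community excluding a blooming diluter,
target/(100 − diluter) × 100 — a closed-composition interpretation, kept in
one function so alternatives can be swapped.

**Consensus.** Three evidence lines per OTU: (i) genotype shift (untreated
DKO vs non-DKO differential), (ii) cured/sick direction and pairwise
significance, (iii) harmonized correlation against a moderate threshold
(default |r| ≥ 0.3). The *provocative* verdict requires both
pathology-linked signals: ratio < 1 with pairwise p ≤ 0.05 **and**
harmonized r ≥ 0.3. A genotype expansion is recorded but is not sufficient
evidence — pathology itself reshapes the community, so DKO-enriched taxa
may be passengers (the study's own reasoning for reclassifying Ureaplasma,
which is DKO-enriched yet anti-correlated with pathology). This
asymmetry also gives the null-control guarantee: with no abundance–
pathology link, real genotype differences alone cannot generate provocative
calls. The *beneficial_or_opportunistic* verdict is deliberately looser
("suggestive signs" standard): any two concordant negatives among ratio > 1,
harmonized r ≤ −0.3, and significant genotype contraction. Everything else
is *indeterminate*. All thresholds live in `PipelineConfig`.

## Synthetic-data generator

Compositions are Dirichlet draws with mean equal to the group profile
(defaults: the five published group-mean columns) and a concentration
parameter (default 50, giving the dominant OTU a realistic ±7-percentage-
point mouse-to-mouse scatter); each row is scaled to a classified total
drawn uniformly from [75, 98] %, mimicking the published range. Default
design: 8 mice per DKO treatment group, 6 non-DKO, 24 OTUs.

Markers derive from the latent severity ℓ = β₀ + β₁·A + N(0, σ²), where A
is the summed abundance of the designated provocative OTUs (default
Lactobacillus + Clostridiaceae-1). Defaults β₀ = 1.0, β₁ = 0.062, σ = 0.8
place the Splenda-control group near score 5.5 and the streptomycin group
near 1, matching the observed treated score range (0.5–8). The overall
score is ℓ clipped to [0, 10] and rounded to the 0.5 grid; exfoliation,
abscesses and apoptosis are increasing logistic functions of ℓ, the Paneth
fraction a decreasing one, each with small fixed observation noise. The
link shapes are a modelling convenience — analyses rely only on the
monotone co-variation. `calibrate_slope` sets β₁ analytically from σ and
the design's abundance variance to hit a target latent R², centering β₀ so
clipping stays rare.

What the generator does *not* emulate: litter/cage effects, sequencing
noise and compositional count error, zero inflation beyond the Dirichlet's
own, antibiotic pharmacokinetics, and any OTU–OTU interaction. Passing
recovery tests therefore show the pipeline's statistical machinery is
sound under the assumed generative structure, not that real data meet that
structure.

## Problem sizes and numerical choices

Seeded replicate counts in tests and the acceptance script (100 replicates
for recovery/null properties, 200 for the differential null and power
checks, 60/50 in the acceptance script) keep full runs in the minutes
range while leaving comfortable margins over the asserted rates. Jaccard
distance matrices are vectorized over pairs; PCoA symmetrizes the centered
matrix before `eigh` and zeroes eigenvalues below 1e-10. The trigamma
inverse uses limma's Newton iteration. Ties at bin edges in the rubric are
resolved by the closed-at-healthier-edge convention above. Degenerate
inputs (all-zero samples, zero-variance OTUs, empty extreme groups) are
handled explicitly: validated errors where the operation is undefined,
flagged zeros where a neutral value is well-defined.

## Known limitations

- The moderated-t screen approximates, not replicates, a count-level
  limma-voom analysis; supplementary fold/FDR tables are approximation
  targets only.
- The exact multiplicity family behind the published corrected p-values is
  unstated; the default ("candidates") reproduces their magnitude but is
  one of several defensible choices, hence configurable.
- Replication of the per-mouse supplementary statistics requires the
  deposited per-mouse data; without those files the corresponding
  acceptance test fails by design with instructions.
- Verdicts are associational; no causal claim is made, and genus/family
  OTUs may hide species-level heterogeneity.
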