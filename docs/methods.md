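# Methods

This note documents the models and conventions behind each pipeline stage,
the synthetic-cohort generator that stands in for patient data, the
numerical choices made where the underlying assay conventions leave room,
and what the tests do and do not establish about real data.

## Pathologic and radiographic response

pTR is percent *regression*: `100 × (1 − Σviable/Σbed)`, pooled over all
slides of a specimen before dividing, which is exactly the bed-area-weighted
mean of per-slide viable percentages. Response-class conventions state
cutoffs both as percent residual viable tumor and as pTR; the
implementation standardizes on the regression scale (pCR = 100, MPR ≥ 90,
pPR ≥ 50, NR < 50) so that all cutoffs, the PR flag (pTR ≥ 50) and
waterfall ordering share one axis. Rounding is half-away-from-zero to the
nearest integer percent, the convention that makes printed small-cohort
rates (5/14 → 36%) come out as published tallies do. One score per slide is
accepted; adjudication between multiple pathologists is out of scope.

Patients whose pretreatment-suspicious nodes prove pathologically negative
are flagged `possible_ln_cr`. They count as a 100% nodal response for the
>20-point discordance rule, but enter the any-site PR tally only in the
"speculative" variant — the report carries both the confirmed and the
speculative rate.

Radiographic volume is the product of the longest perpendicular
bidimensional measurements (mm²); multi-lesion sites sum volumes before
computing percent change. Measurements are normalized to length ≥ width on
ingest.

## MIF quantification

Cell tables carry boolean marker states per segmented cell; phenotype
gates are required-positive/required-negative marker sets, checked for
pairwise mutual exclusivity (two gates overlap iff neither requires
positive a marker the other requires negative — that check is exact, not
heuristic). Unmatched cells are retained as "other" so stromal-fraction
denominators stay honest.

Numerical conventions:

* **H-score.** Marker-negative cells count as intensity 0; marker-positive
  cells recorded in bin 0 are promoted to 1+ (a positive call with minimal
  intensity), keeping the score consistent with its 0–300 range.
* **Zero guard for fold changes.** log₂ fold changes and CD8/Treg ratios
  add a pseudocount of 1 (one cell/mm² or one H-score point) *only when
  either value is exactly zero*; nonzero measurements are never perturbed.
  The pseudocount is an explicit argument for sensitivity analyses.
* **Stromal immune fraction.** CK⁻, roundness ≥ 0.8 and diameter ≤ 15 µm.
  The roundness cutoff operationalizes a qualitative morphology criterion
  and is configurable; 0.8 cleanly separates the generator's immune
  (≈0.9) from fibroblast-like (≈0.55) populations.
* Duplicated rows are dropped before counting (double-imported cells must
  not inflate densities); tumor + stroma counts add up to whole-slide
  counts by construction.

Intensity thresholds that map raw fluorescence to bins are treated as
fixed within a patient's pre/post pair and are outside the package: the
cell table is already binned.

## Spatial proximity

Two modes are exposed because the two figure-level statistics phrase the
quantity differently: `pairwise` (all T cell–Treg pairs within the radius;
the default for mean-distance and shift statistics) and `nearest` (each T
cell's distance to its nearest Treg, if within the radius; the default for
distance-probability curves). The radius default is 100 µm. The
accelerated path uses a KD-tree only to *find* candidate neighbors; every
reported distance is recomputed with the same numpy expression a
brute-force implementation would use, and the tree radius carries a 1e−9
relative slack with the final ≤ r filter applied on the recomputed
distance — this is what makes the results bit-identical to the exhaustive
O(n·m) oracle, which the tests verify on hundreds of random instances.
Ties in nearest-Treg distance are resolved by taking the minimum distance
(the value is identical; the identity of the Treg is not reported).

No edge correction is applied by default (whole-slide analysis); an
optional flag drops T cells within one radius of the field border for
simulation studies. A slide with no Tregs yields an explicit empty result
(n_pairs = 0, mean NaN), not an exception, and the pre/post shift of an
empty side is NaN.

Expected effect sizes under the generator: within a 100 µm cap, the mean
pairwise distance of an unconstrained pattern is ≈ 2R/3 ≈ 66.7 µm, while a
40 µm exclusion gives ≈ (R³−r³)/(1.5(R²−r²)) ≈ 74.3 µm — so collapsing the
exclusion produces a log₂ shift of ≈ −0.16. The planted-recovery tests are
thresholded from this calculation, not fitted to runs.

## Variant consensus

Variant identity is the exact (chrom, pos, ref, alt) key after
normalization: shared prefix bases are trimmed first (advancing pos), then
shared suffix bases, always keeping at least one base per allele. Without
a reference genome full left-alignment is impossible; prefix-then-suffix
trimming collapses the common caller representational differences (padded
alleles, anchor-base conventions) so the voting rule is well defined.
SNVs need ≥3 of the 4 callers, indels ≥2 of 3 (MuSE calls no indels);
consensus is monotone in support by construction. VAF is taken from
Mutect2 when it supports the variant, otherwise the mean across
supporters. Ingest is PASS-only by default with a flag to include
everything. Expression uses log₂(TPM + 1).

## Neoepitope selection

"All possible 9-mers derived from a variant" is implemented as all sliding
windows over the mutant protein that overlap at least one altered residue
— for an interior missense exactly nine windows; fewer near the termini
(min(p, 9, L−8, L−p+1)). Windows identical to any wild-type 9-mer of the
same protein are removed (they are not neoepitopes), deduplicated
preserving leftmost-first order. Frameshifts translate the novel tail to
the first stop and mark every residue from the shift onward; a variant
creating an immediate stop yields an empty context.

Ranking keys are RNA expression and variant allele frequency; the combiner
`rank_score = log₂(TPM+1) × VAF` is a package choice (monotone in both
keys) and is configurable. Ties break by ascending IC50, then peptide.
Each peptide is scored against every patient HLA class I allele and keeps
its best (lowest) IC50. Selection applies the three synthesis criteria —
present pretreatment, IC50 ≤ 200 nM, TPM ≥ 4 (raw TPM by default; a flag
switches the threshold to the log scale) — and truncates to
`max_per_patient` (default 12; the generator uses 9, which makes a
12-patient cohort test ≈108 peptides).

Binding prediction itself is out of scope: the `BindingPredictor`
interface takes (peptide, allele) → IC50 nM. Two implementations ship: a
file/dict-backed lookup table, and a hash-seeded synthetic stand-in (a
fixed fraction of pairs are strong binders, IC50 ∈ (10, 200]; the rest
log-uniform up to 50 µM) that reproduces only the distributional role of a
predictor — a controllable strong-binder rate — with none of its biology.

## ELISpot calling

Means of technical duplicates are computed before any thresholding.
Detected means mean > 0; positive means post-treatment mean ≥ 5;
increased means post − pre difference in means > 5 (strict). Positivity is
evaluated on post-treatment TILs, matching how responses are tallied. No
background subtraction by default (raw means are reported); optional
no-peptide-well subtraction floors at zero. Per-patient aggregates count
positive neoepitope conditions and sum post-treatment means over all
neoepitope conditions; the CEF viral pool is tracked separately and never
counted as a neoepitope.

## Cohort statistics

Mann-Whitney U is two-sided, exact when both groups have ≤8 untied
observations and tie-corrected normal approximation otherwise; Wilcoxon
signed-rank drops zero differences (all-zero pairs give a NaN sentinel);
the one-sample t test of fold changes returns 1.0 for a zero-variance
sample at the null mean and 0.0 for a zero-variance sample away from it
(the degenerate limits, documented rather than raised); regression is OLS
with the F test of slope ≠ 0. p < 0.05 is called significant, no
multiple-testing correction is applied, and the report records how many
tests it ran.

## The synthetic cohort generator

The generator's defaults define the study conditions: 14 patients with a
5/14 responder fraction (assignment is a seeded permutation, so the count
is exact), TIL/ELISpot data for 12 of them, 1-year recurrence risk 0.22
for non-responders and 0 for responders.

**Slides.** A 1.5 × 1.5 mm analysis field with 4 tumor nests (random discs,
radius 280 ± 60 µm, clipped to the field); compartment is
point-in-nest-union. Published sources do not state per-slide cell counts,
so densities were chosen once as realistic for inflamed carcinoma fields:
tumor cells 1500/mm² of parenchyma; stromal densities (cells/mm²)
CD8 200, CD4 150, Treg 80, PMN 150, macrophage 120 plus 200
fibroblast-like cells; intratumoral densities several-fold lower. Counts
are Poisson draws at density × compartment area; positions are uniform by
rejection within the compartment, giving ≈3000 cells per slide. Ki67 is
Bernoulli per cell (T cells 0.25, tumor 0.5), PD-L1 likewise (myeloid 0.5,
tumor 0.3); intensity bins are drawn from a 4-vector of probabilities;
diameters and roundness are clipped normals per population (immune 9 ± 1.5
µm, round; tumor 14 ± 2.5 µm; fibroblast-like 18 ± 3 µm, not round).

**Treg exclusion.** The generator plants Treg avoidance of proliferating
T cells: after placing all T cells, any Treg within
`treg_exclusion_radius_um` (default 40 µm) of a Ki67⁺ FoxP3⁻ T cell is
resampled within its compartment, up to 100 attempts, then dropped.
Replacing only violating draws approximately preserves marginal densities;
radius 0 reduces to complete spatial randomness between the populations.

**Planted responder effects** (what the cohort-level tests recover):
responders get pTR drawn in [50, 70] (non-responders [3, 49]; a constant
viable fraction across a patient's slides makes the pooled pTR exactly the
drawn target), a 4× post-treatment intratumoral CD8 influx with stromal
Treg loss, post-treatment collapse of the exclusion radius to 0, lower
pretreatment stromal myeloid density (110 vs 360 cells/mm²), and a higher
immunogenic fraction among synthesized peptides (0.45 vs 0.05).

**Variants and expression.** A shared 60-gene proteome (random sequences,
100–400 aa); per patient ≈60 mutations (Poisson), 10% synonymous, 8%
frameshift, the rest missense; VAF ~ Beta(2, 5); TPM log-normal; 95% of
variants present pretreatment. Caller call sets are the truth thinned by
per-caller sensitivity (0.92–0.97) plus Poisson-mean private false calls
with low VAFs; MuSE never emits indels. The synthetic binding predictor
assigns 25% of peptide–allele pairs IC50 ≤ 200 nM.

**ELISpot.** Duplicate counts are negative binomial (shape 4).
Immunogenic peptides get post-treatment mean 25 spots and are detectable
pretreatment (mean 3) with probability 0.5; non-immunogenic wells sit at a
0.5-spot baseline. CEF is positive in half the patients (mean 25); a
positive-control well (mean 60) and a no-peptide background well (mean
0.2) complete the plate. The two unassayed patients are taken from the
non-responders, matching a 5-vs-7 PR split among assayed patients.

All randomness flows from one root seed through spawned child streams per
patient and modality, so any sub-object is reproducible in isolation and
the same seed yields byte-identical cohort directories.

**What the generator does not emulate.** Pixel-level image content,
segmentation error, spectral bleed-through, batch effects between slides,
read-level sequencing noise (caller errors are modeled at the call level,
not the read level), linkage between mutational processes and expression,
germline HLA structure, or survival times. Passing tests therefore show
that the *computations* are correct and that planted effects of realistic
size are recovered — not that the biological effects exist or have these
sizes in patients.

## Problem sizes used by the test and acceptance suites

Unit and acceptance tests shrink the field to 0.8 × 0.8 mm (≈900 cells per
slide) and the variant load to ≈12 mutations over 20 genes where full size
adds nothing to the property under test; the end-to-end recovery test runs
the full 14-patient default cohort. The spatial oracle comparison uses 200
random instances of up to 500 cells; consensus recall uses 10,000
simulated variants against the closed-form binomial P(≥3 of 4 at 0.9) =
0.9477; type-I control of the responder association test uses 200
zero-effect ELISpot cohorts (the cheapest correlate path through the
generator, chosen so that repeated-seed calibration is practical).

## Known limitations

* Indel normalization is reference-free; representations that require
  genuine left-shifting across repeat tracts will not be unified.
* The proximity analysis is 2D and ignores slide-edge truncation unless
  the exclusion flag is set; absolute distance distributions near the
  field border are biased accordingly (identically pre and post).
* The Mann-Whitney exact path is restricted to untied samples; heavily
  tied small-sample correlates (e.g., counts) use the tie-corrected
  normal approximation, which is approximate at n = 14.
* `stop_gained`/truncating variants yield no candidate peptides even when
  the truncation junction could, in principle, create one spanning window;
  junction peptides are modeled only for indels and frameshifts.
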