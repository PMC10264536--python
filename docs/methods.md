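# Methods

## Statistical model and procedure

The pipeline treats a cohort as a patient × analyte matrix of serum
abundances (pg/ml for multiplex analytes; the dimensionless
kynurenine/tryptophan ratio for IDO activity) with a binary
cumulative-toxicity label per patient (1 = more than one immune-related
adverse event of any grade). Five stages run in sequence.

**Log transform.** Abundances are natural-log transformed. The choice of
base is immaterial downstream — every subsequent statistic is
rank-based — and is fixed at *e* for definiteness. Zero and negative
values are treated as below-detection-limit missingness rather than
offset-imputed: an arbitrary pseudo-count would manufacture ties in rank
statistics, whereas missingness is handled exactly. Each analyte's
missing count is recorded; analytes with more than 50 % missing raise a
warning, and analytes left with fewer than three observed values in
either toxicity group are flagged unusable for group tests.

**Univariate stage.** Each usable analyte is compared between toxicity
groups with a two-sided Mann–Whitney U test on log-levels; U is reported
for group 1 versus group 0. The exact null distribution is used when
n₀·n₁ ≤ 400 and the pooled sample is tie-free; otherwise the normal
approximation with tie and continuity corrections. A fully tied sample
returns p = 1 with a degeneracy flag. P-values are
Benjamini–Hochberg-adjusted over the family of analytes tested in the
same run (m ≤ 34), and a direction (up/down in toxicity) is assigned
when the adjusted p ≤ 0.05, from the group medians on the log scale.
Shapiro–Wilk normality is computed per analyte on pooled log-values as a
descriptive record only; the nonparametric test is used throughout,
never switched by normality.

**Connectivity.** Connectivity between two analytes is the Spearman
correlation of their log-abundance profiles, i.e. the Pearson
correlation of average (tie-aware) ranks, on pairwise-complete
observations (≥ 4 required; constant vectors are flagged undefined and
excluded, never coerced to 0). Two-sided p-values use the t
approximation with n − 2 degrees of freedom at all study-relevant n; an
exact full-enumeration permutation p is available behind a flag for
n ≤ 10. The analyte-versus-toxicity association is the Spearman
correlation with the 0/1 indicator (equivalent to the rank-biserial
correlation up to a positive factor). Each surface is its own
multiple-testing family, adjusted independently: the ≤ 34 analyte
associations form one family; each group matrix's C(34,2) = 561 pairs
form another. This family choice is the central interpretive decision of
the multiple-testing setup and is deliberately per-heatmap; merging
families would couple the two groups' discoveries.

**Networks.** The edge rule is conjunctive: |ρ| strictly greater than
the threshold AND adjusted p ≤ α (default 0.05). The threshold defaults
to the 85th linear-interpolation percentile of the pooled off-diagonal
|ρ| values of *both* group matrices (each unordered pair counted once
per matrix); a fixed manual threshold (e.g. 0.6) may be supplied instead
to reproduce a known operating point. Strictness at the boundary is
deliberate, since boundary ties are possible on small cohorts. All panel
analytes remain as nodes, so isolated nodes are preserved and degree
distributions are comparable across groups.

**Comparison.** Edge identity for matching across groups is the
unordered analyte pair; magnitudes and signs are ignored, so a pair
positive in one group and negative in the other counts as shared
(sign-sensitive matching is available as a flag, in which case such a
pair appears in both specific sets). Shared = intersection, specific =
set differences; the identities |E₀| = |shared| + |specific₀| and
|E₁| = |shared| + |specific₁| are asserted at construction on every run.
In the exported edge lists, shared rows carry the group-0 network's
ρ and adjusted p.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not any particular dataset. Per toxicity group, log-abundances are drawn
multivariate normal with a common mean (default 4.0 log-units, ≈ 55
pg/ml) and standard deviation `noise_sd_log`, under a block-constant
correlation matrix; abundances are `exp` of these draws, giving
log-normal marginals — positive, right-skewed, as serum concentrations
are. Group 1 adds `shift_log_units` to the mean of each elevated
analyte. Finally `lod_censor_fraction` of the lowest values per analyte
(pooled over groups) is set to exactly 0, emulating below-detection
readouts and exercising the missing-value path; censoring is applied
after the correlated draw so planted correlations are attenuated the way
a detection limit attenuates real ones.

Defaults define the generator's reference condition:

| parameter | default | rationale |
|---|---|---|
| n_group0 / n_group1 | 52 / 27 | the target study's group sizes |
| panel | 34 analytes | 12 cytokines, 5 chemokines, 13 soluble checkpoints, 3 adhesion molecules, IDO activity |
| elevated_analytes | IP10, IL8, sLAG3, sPDL2, sHVEM, sCD137, sCD27, sICAM1 | the 8 markers reported toxicity-elevated |
| shift_log_units | 0.8 | a moderate effect (e^0.8 ≈ 2.2× median) — a synthetic choice, not an estimate of the study's unreported effect sizes |
| noise_sd_log | 0.7 | geometric SD ≈ 2, typical within-group dispersion of serum cytokine panels |
| block correlation | 0.9 | strong planted co-expression, clearly above the ≈ 0.3–0.6 thresholds the percentile rule produces |
| lod_censor_fraction | 0.02 | occasional below-LOD values without degrading usable n |
| base_log_mean | 4.0 | ≈ 55 pg/ml, a mid-range multiplex concentration |

The default correlation blocks plant the differential-connectivity
phenomenon directly: a 9-cytokine core block (IL-10, IL-13, IL-6,
IL-1α, IL-1β, GM-CSF, TNF-α, IFN-α, IFN-γ) present in **both** groups
(its C(9,2) = 36 pairs should be recovered as shared edges); a
5-chemokine block and the sCD137/sCD27/sCD28 trio present **only
without toxicity** (10 + 3 pairs, specific to group 0); and an
sPD-L2-coupled block (sPD-L2, IL-17A, IL-4, IL-12p70) present **only
with toxicity** (6 pairs, specific to group 1). Blocks within one group
must be disjoint — overlapping block-constant specifications would be
ambiguous — and each group's correlation matrix is verified positive
semidefinite at construction; a violating configuration is an error,
never silently repaired. Draws use one integer seed via a split
`SeedSequence` (one stream per group) in canonical sorted-analyte order,
so cohorts are bit-reproducible and independent of panel column order.

What the generator does *not* model: per-analyte heterogeneity of means
and variances, heavier-than-log-normal tails, batch/plate effects,
assay-specific detection limits per analyte, negative planted
correlations, and any dependence between toxicity grade class and the
abundance distribution beyond the mean shift. Passing tests therefore
demonstrate that the pipeline recovers planted structure under an
idealized but fair data model — they do not certify performance on real
sera, where effect sizes and dependence structure are unknown.

## Numerical choices and degenerate inputs

- Adjusted p-values are computed with the step-up formula
  q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j capped at 1 and returned in input order. Note
  BH is not idempotent: re-adjusting already-adjusted values can inflate
  them further (the step-up minimum shifts), so adjusted values are
  computed exactly once per family.
- Spearman p at |ρ| = 1 is set to 0 (the t statistic diverges).
- Percentile thresholds use linear interpolation
  (h = (n−1)·q between order statistics), matching `numpy.percentile`'s
  default.
- The pipeline validates its configuration up front (exactly one input
  source), tags every stage failure with the stage name, and removes
  partial outputs on abort. The manifest records the full configuration,
  seed and threshold; a manifest replay reproduces every output
  bit-identically (no timestamps are embedded).
- Patient and analyte identifiers are case-sensitive exact tokens; a
  bundled alias map normalizes common spelling variants of panel
  analytes (e.g. `HEVM` → `sHVEM`, `GM-CSF` → `GMCSF`) at load time.

## File formats

- **Abundance**: CSV/TSV, first column `patient_id`, remaining columns
  analyte ids; empty cell = missing; decimal point `.`.
- **Panel**: CSV/TSV with `analyte_id`, `display_name`,
  `functional_group` ∈ {cytokine, chemokine, soluble_immune_checkpoint,
  adhesion_molecule, ido_activity}.
- **Toxicity**: CSV/TSV with `patient_id`, `cumulative_toxicity` ∈
  {0, 1}, optional `grade_class` ∈ {G0G1, G2G3}.
- **Edge lists**: five TSVs (per-group networks, shared, two specific
  sets) with `analyte_a`, `analyte_b`, `rho`, `p_adjusted`, rows in
  alphabetical pair order; also available as a five-sheet spreadsheet
  and per-network GraphML.

## Problem sizes in the test and acceptance runs

Monte-Carlo checks run at the reference condition (79 × 34): 200
replicates for univariate sensitivity and null false-flag rate in the
test suite (100 each in the acceptance script), 60 (40) replicates for
group-specific edge recovery. At these sizes the Monte-Carlo standard
error of each estimated rate is well below the margins being checked
(e.g. sensitivity ≈ 0.98 against a 0.9 requirement).

## Known limitations

- The toxicity-association stage uses the binary cumulative-toxicity
  indicator; graded severity scores are not modeled.
- IDO activity is included among the correlated analytes by default and
  can be excluded (`--exclude-ido`) where the kyn/trp readout is deemed
  unreliable.
- No covariate adjustment (age, sex, tumor type), partial correlations,
  community detection or centralities beyond degree: the pipeline
  reproduces a deliberately simple marginal-plus-pairwise analysis.
- With ~80 patients split 52/27, correlation estimates in the smaller
  group are noisy; the percentile threshold adapts to the pooled
  distribution, so thresholds are not comparable across cohorts of very
  different size or signal density.
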