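# Methods

## Trait model

The target phenotype is qualitative: presence or absence of a fruit
volatile (γ-decalactone) controlled by a single dominant locus.  The
working model throughout is a **hemizygous deletion**: non-producers
physically lack the causal gene, so its transcript, its PCR amplicon, a
tightly linked SSR allele and the volatile are absent together.  The
producer parent is modelled as **simplex** (one functional copy in the
octoploid genome) because the observed segregation in producer ×
non-producer F1 populations is approximately 1:1; higher dosage is not
modelled.  Under simplex inheritance the expected carrier fraction is 0.5
in the F1 and in a backcross to the null parent, and 0.75 in a backcross
of a carrier F1 to the simplex carrier parent (1 − 0.5·0.5).  The 0.75
figure is a modelling choice exposed in configuration: segregation ratios
for that cross are not separately constrained by data, only cosegregation.

## Volatile phenotyping

Peak areas are normalized to the internal standard (3-hexanone spiked at a
fixed concentration before blending): response = target area / IS area, a
unitless ratio invariant to common scaling.  Technical replicates
(default 2) are averaged per harvest; the replicate SD is retained for
reports.

**Producer calling.** A genotype is a PRODUCER if any harvest mean exceeds
the noise floor; a NONPRODUCER only if all harvest means are at or below
the floor **and** at least three harvests were observed; otherwise
INSUFFICIENT_DATA.  The three-harvest rule reflects the strong
environmental lability of the trait: a producer can be silent in a
non-inductive harvest.  The noise floor is a configuration parameter; for
real data the helper `noise_floor_from_blanks` supplies the conventional
mean + 3·SD of blank (or known-null) responses.  No universal numeric
detection limit is hard-coded, because it is instrument-specific.

**Trend classes.** With exactly three harvest means (v1, v2, v3), a
genotype-season is assigned one of five classes: NONPRODUCER, PEAK
(mid-season maximum), VALLEY, DECREASE (high early, then flat-low) and
INCREASE (monotone rise).  Two values count as different when they differ
by more than `rel_tol` (default 0.2) times the seasonal maximum; using the
global maximum as the scale keeps all comparisons mutually consistent.
Rules are checked in the order above; producer profiles where no rule
fires (near-flat) fall through to a weak-maximum tie-break with priority
PEAK > DECREASE > INCREASE.  The classifier is total and single-valued
over all orderings (property-tested exhaustively).

**Quantification.** Concentration is estimated from an OLS standard curve
of baseline-corrected response on spiked concentration (spikes 0.005–0.3
mM into half-ripe fruit puree, which mimics the ripe-fruit matrix;
baseline = unspiked puree response).  Inversion clips at 0 mM; estimates
outside the calibrated spike range are returned but flagged, and
sub-range values render as "< 0.005 mM (below calibration)".

## RPKM and the candidate filter

RPKM[g,s] = counts[g,s] · 10⁹ / (library_sizes[s] · gene_lengths[g]).
Whether library sizes are supplied explicitly or derived from count column
sums is an I/O option, since "total mapped reads" vs "reads assigned to
genes" is a data-dependent choice.

Detection is RPKM strictly greater than `detect_threshold` (default 1
RPKM).  The parental comparison considers transcripts with RPKM > 10 in at
least one parent and reports parent-unique sets (detected in one parent,
undetected in the other) and overexpressed sets (detected in both, ≥5-fold
higher).  Thresholds follow the "strictly greater" reading of ">10" and
the "at least" reading of "5 times or more".

The core filter is **pairwise**: gene g survives iff
(RPKM[g,p] + c)/(RPKM[g,q] + c) > F for every producer p and non-producer
q, computed as (min over producers + c)/(max over non-producers + c) > F.
Defaults: F = 4 (the strictest end of the 2–4-fold range; the pipeline
also reports counts at 2 and 3), pseudocount c = 0.1 RPKM.  The
pseudocount keeps folds finite for the expected zero-RPKM deletion
signature without reordering genes; the filter is monotone in F and, for
genes with all-zero non-producer RPKM, monotone in c.  A pool-mean mode
exists for sensitivity analysis but is not the default, because pairwise
semantics are what make a single discordant genotype fatal.  Survivors
then pass the **presence screen**: detected in all producers, undetected
in all non-producers — no exceptions, matching the deletion model.

## SNP filter

A genotype supports a site iff depth ≥ 10 and non-reference read fraction
≥ 0.95 (both inclusive, per "10 or greater" and "95% minimum"); a site is
emitted iff ≥ 2 genotypes support it.  "Present in at least two datasets"
is interpreted as the per-genotype criteria passing in ≥ 2 genotypes, not
mere coverage.  The fraction is compared after division (19/20 and the
literal 0.95 round to the same binary float) so the inclusive boundary is
exact.  One alternate allele per site; no genotype likelihoods.  Output is
minimal VCF 4.2 with INFO `NPASS` and a per-sample `PF` pass flag,
round-trip-verified against an independent VCF parser in tests.

## Validation statistics

**ΔΔCT.** ΔCT = mean CT(target) − mean CT(housekeeping) per condition;
ΔΔCT = ΔCT(sample) − ΔCT(calibrator); fold = 2^−ΔΔCT at assumed 100%
efficiency.  SD is propagated on the sample ΔCT as √(sd_t² + sd_h²) and
reported both in cycles and as the fold interval 2^−(ΔΔCT±SD), because the
two scales are not interchangeable.  Target reactions that never amplify
yield fold 0 with a flag — under the deletion model this is absence, not
low expression, so no max-cycle CT is imputed.

**Segregation and cosegregation.** Goodness-of-fit is Pearson chi-square
against the stated ratio (df = categories − 1).  Marker concordance is the
fraction of genotypes where amplicon presence ⇔ producer status, excluding
failed PCR controls and INSUFFICIENT_DATA genotypes, with the 2×2
cosegregation test attached.  A perfectly cosegregating table with both
phenotype classes present is diagonal and has no zero margin, so Pearson
chi-square (no continuity correction) applies; tables with a zero margin
(marker or phenotype constant) instead report the exact probability
0.5^(n−1) that an independent fair presence/absence marker would be
perfectly concordant or anti-concordant.  No multiple-testing correction
anywhere: these are single-locus confirmatory tests, and per-allele SSR
rows are reported unadjusted with exact integer fragment sizes.

## The synthetic-data generator

The generator emulates the study design so every stage is testable without
sequencing data; its defaults are the study conditions, not tuning knobs.

* **Panel**: both parents plus F1 progeny selected to a fixed composition
  (default 11 producers / 5 non-producers, 16 genotypes), mirroring how a
  sequencing panel is assembled from a phenotyped population.
* **Expression**: negative-binomial counts, per-gene mean log-uniform over
  5–500 (shared across genotypes), dispersion 0.1, lognormal per-cell
  noise (σ = 0.2); per-genotype expected totals scaled to library sizes
  drawn uniformly from 300k–850k reads (the study's ~3–8.5 M per genotype,
  scaled down tenfold to keep simulation cheap).  The causal gene is fixed
  at 1,500 bp (a typical desaturase transcript) and calibrated to ~50 RPKM
  in ripe carrier fruit; stage factors 1/21 : 1 : 21 for green : blushing
  : ripe give the configured 21-fold ripening induction.  Non-carriers get
  strictly zero causal counts.  50 of 2,000 genes are decoys whose
  presence per genotype is an independent fair coin, emulating
  homoeolog-segregation noise; iid assignment matches the 2·0.5¹⁶
  spurious-cosegregation probability used in the recovery analysis.
* **Volatiles**: non-carriers draw uniform background on
  [0, volatile_baseline] (so the baseline, default 0.01, is their exact
  noise ceiling and the natural default noise floor in simulate mode);
  carriers emit signal 1.0 shaped per trend class over harvests
  (PEAK 1:3:1, VALLEY 3:1:3, DECREASE 3:1:1, INCREASE 1:2:4), times 11 in
  harvests labelled inductive, with lognormal noise (σ = 0.1), two
  technical replicates.  Trend classes among carriers are sampled
  8:5:3:1 (peak : valley : decrease : increase), the observed class
  proportions in a ~35-progeny season.
* **Markers**: amplicon and SSR allele 205 present iff carrier; allele 209
  monomorphic; 215/219 independent fair coins.
* **Pileups**: Poisson(30) depth, Binomial(depth, 0.05) background
  non-reference counts (which essentially never reach a 95% fraction); 30%
  of sites planted to pass in exactly two genotypes.
* **qPCR**: Gaussian CT noise (σ = 0.05 cycles), triplicates, true folds
  configured; non-carrier targets never amplify.
* **Environment** modulates the volatile and qPCR layers; expression
  tables take a developmental stage but no environment label — modelling
  env-modulated expression would duplicate the ripening-factor machinery
  without adding testable structure.

All randomness flows from one master seed through named SeedSequence
substreams (one per operation), so a configuration is byte-reproducible
and operations are independently stable.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level artefacts (mapping bias across
subgenomes, multi-mapping, 3′ bias), correlated expression between genes,
partial deletions or expression-silenced (rather than deleted) null
alleles, genotype-by-environment interaction beyond a scalar fold,
phenotyping error (the simulated noise floor exactly separates classes),
and linkage structure beyond one causal locus with one linked SSR.  On
real data the presence screen can fail through a single mis-phenotyped
genotype, which the simulation's clean separation never exercises.

## Problem sizes and numerics

Simulated studies use 2,000 genes × 16 genotypes, chosen to preserve the
filter's statistical structure (decoy false-survival odds ≈ 50 · 0.5¹⁶
per run) while keeping a full discovery run under a second.  Segregation
checks use n = 10,000 progeny (binomial 3-SD band ±1.5 points).  Fold
comparisons are strict inequalities; detection is strict; SNP thresholds
inclusive.  Concentration-range flags tolerate 1e-9 relative round-off at
the calibration edges so exact inversions of the boundary spikes are not
flagged.  Degenerate inputs (empty pools, < 3 spike levels, zero library
sizes, nonref > depth, unsorted VCF input, failed internal standards)
raise errors naming the offending item rather than propagating NaNs.

## Known limitations

Single alt allele per variant site; 100%-efficiency ΔΔCT (no standard-curve
efficiency correction); trend classes defined only for three-harvest
seasons (longer seasons interpolate generator shapes but are not
classified); the pairwise filter is deterministic thresholding and supplies
no error control — it is a screen, and its output is expected to be
validated by qPCR and markers, as the pipeline's validation stage does.
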