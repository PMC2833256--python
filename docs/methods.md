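# Methods

`respcrit` implements CT-based early-response evaluation of metastatic renal
cell cancer (mRCC) under an anti-angiogenic tyrosine kinase inhibitor such as
sunitinib. These drugs cause tumour necrosis — visible on contrast-enhanced
CT as a drop in lesion attenuation (Hounsfield units, HU) — often with little
shrinkage, so size-only criteria (RECIST 1.0) can miss real responses that
attenuation-aware criteria (Choi) capture. The package provides the whole
chain needed to study that dissociation: ROI measurement, target-lesion
eligibility, response classification, survival-endpoint derivation, the
statistical comparison, and a synthetic cohort generator so the pipeline is
testable end to end without patient data.

## Response models

**RECIST 1.0.** Per patient, the sum of longest diameters (SLD) over target
lesions. At each evaluation: new lesions → PD; all lesions vanished and no
new lesions → CR; SLD change from baseline ≤ −30% → PR; SLD change from the
nadir (smallest SLD recorded since treatment start, equal to baseline at the
first evaluation) ≥ +20% → PD; otherwise SD. Checks run in the order
new-lesions, CR, PR, PD, SD.

**Choi.** Two per-patient quantities at each evaluation: the SLD percent
change over Choi-eligible lesions, and the percent change of the unweighted
mean of per-lesion mean HU over attenuation-evaluable lesions. PR is a size
decrease ≥ 10% **or** an attenuation decrease ≥ 15% (inclusive thresholds);
the attenuation PR overrides a size increase. PD is a size increase ≥ 10%
without the attenuation PR, or new lesions, or obvious progression of
non-measurable disease (taken as an input flag and mapped to PD — the flag's
only printed role is to veto PR, and progression of non-measurable disease
is progression). CR and SD as in RECIST. Single-criterion variants
(`size_only`, `attenuation_only`) dichotomise on one condition each, with
new lesions forcing PD.

The Choi size criterion is applied to the *sum* of diameters, parallel to
RECIST, rather than per-lesion: the sum is the only size aggregation the
criteria family defines, and the attenuation side is explicitly
mean-then-change. This is switchable in principle but shipped as the single
supported aggregation.

Classification always uses unrounded percent changes. Display rounding is
half-away-from-zero to integers (so −39.25% → −39, −18.75% → −19),
months to one decimal.

## Eligibility

Bone and brain metastases and the primary tumour are never target lesions.
Baseline diameter < 10 mm excludes a lesion entirely; 10 mm ≤ d < 15 mm is
measurable by RECIST but below the Choi floor; cavitation or a
beam-hardening artefact at evaluation removes the lesion from the Choi set
(this matches the lesion-accounting convention in which those are
Choi-only exclusions). A separate per-lesion flag, `attenuation_evaluable`,
keeps a Choi lesion in the *size* analysis while dropping it from the
*attenuation* analysis when it shrinks below 15 mm at evaluation, cavitates,
shows an artefact, or vanishes. Caps of 10 target lesions per patient and 5
per organ are applied after the rule filters, keeping the largest baseline
diameters (ties broken by input order — target-lesion practice is to pick
the largest lesions). Boundaries are inclusive exactly as printed: 15.0 mm
is Choi-eligible. A patient with no Choi-eligible baseline lesion is flagged
not-evaluable by Choi rather than dropped.

## Endpoints and censoring

All times are months from the first treatment day; the 12-week window is the
exact constant 84 days / 30.4375 days·month⁻¹ ≈ 2.76 months. Keeping months
as the single internal unit (rather than converting through days) avoids
unit drift; the constant is exact either way.

PFS event = earliest of radiological PD (RECIST assessment), clear clinical
PD, or death attributed to progression within 12 weeks of the last response
evaluation. Otherwise censored: at last follow-up when no progression is
recorded, or at the last adequate tumour assessment when a PD-attributed
death falls more than 12 weeks after the last evaluation (the PD date is
then unknown). OS event = death of any cause; otherwise censored at
last-known-alive. Clinical benefit = CR or PR at best response, or SD with
PFS ≥ 12 weeks.

## Statistical layer

* **Kaplan–Meier** via lifelines; the median is the smallest time with
  S(t) ≤ 0.5 (undefined if the curve never reaches 0.5 — alternatives
  differ only when S plateaus exactly at 0.5). Events precede censorings at
  tied times.
* **Log-rank** (two groups, 1 df) via lifelines; tests verify it against a
  hand-coded hypergeometric O−E computation to 1e−10.
* **Wilcoxon signed-rank** implemented in-package: zero differences dropped,
  average ranks for tied magnitudes, W⁺ reported. For n ≤ 25 the exact null
  distribution of W⁺ is built by dynamic programming over the doubled-rank
  multiset (average ranks are half-integers, so doubling gives integers);
  this reproduces exhaustive sign enumeration including ties, which scipy's
  exact method does not handle. For n > 25 a tie-corrected normal
  approximation is used. Two-tailed p = 2·min(P(W⁺≤w), P(W⁺≥w)), capped
  at 1.
* **Spearman** rho from scipy rankdata + Pearson on ranks; for n ≤ 9 the
  p-value is exact over all n! permutations (vectorised), otherwise the
  usual t approximation. Constant inputs raise rather than return NaN.

All p-values are two-tailed, α = 0.05.

## ROI measurement

A polygon ROI on a 2-D HU grid selects the pixels whose centres fall inside
(or exactly on the edge of) the polygon; the mean of those pixels is the
lesion's mean attenuation and the area is pixel count × pixel area.
Coordinates are continuous millimetres with the origin at the centre of
pixel (0,0). Membership uses shapely's boundary-inclusive predicate;
self-intersecting or zero-area polygons are rejected, so the even-odd vs
winding distinction never arises. Display window settings play no role in
measurement. Fixtures round-trip as 16-bit PNG plus a JSON sidecar carrying
the HU offset/scale and pixel spacing (scale 1 whenever the HU range fits
16 bits, so integer-valued grids round-trip exactly).

## Synthetic cohort generator

The generator's defaults (shipped as `data/default_cohort_config.json`,
versioned) encode the study conditions the pipeline is meant to reproduce:

* 55 patients, responder fraction 36/55, first evaluation uniform in
  1.1–3.4 months, administrative censoring at 45 months (accrual-to-closure
  span of a late-2000s retrospective series).
* Site mix proportional to the published per-site lesion counts (including
  the excluded bone/brain/primary lesions); per-site log-normal baseline
  diameters anchored at the published medians (sizes are positive and the
  published ranges are right-skewed) and clipped-normal baseline HU at the
  published medians (ranges roughly symmetric). Bone, brain and primary
  parameters and the lesion-count distribution (uniform 1–8, giving ≈4.5
  lesions/patient as in the published lesion totals) are not printed
  anywhere and are field-realistic choices fixed once.
* Effects: a patient-level percent change drawn per phenotype (responders
  −20% size / −35% HU on average; non-responders +8% / −3%) with per-lesion
  noise on top, applied multiplicatively; the mixture reproduces the
  published cohort-level medians (≈ −11% size, ≈ −24% HU). Effects deepen
  40% per later evaluation so slow responders cross thresholds late,
  mirroring patients who reach PR only at best response.
* Survival: PFS exponential with phenotype medians 14.5 / 3.2 months;
  OS = PFS + an independent exponential post-progression time whose median
  is the published OS−PFS median gap, guaranteeing OS ≥ PFS per patient.
  OS is floored just above the first-evaluation time because the cohort is
  conditioned on having a first-evaluation scan, as the eligibility
  criteria require. Deaths observed before the administrative horizon are
  attributed to progression.
* Nuisance processes: lung lesions cavitate at evaluation with
  probability 0.08, any lesion shows a beam-hardening artefact with 0.025,
  non-responders develop new lesions at first evaluation with 0.25 —
  rates matching the published exclusion and new-lesion counts.

A single seed drives everything through per-patient `SeedSequence`
sub-streams, so a cohort is a prefix of any larger cohort with the same
seed, and identical (config, seed) gives byte-identical CSVs.

What the generator does **not** emulate: measurement error between repeated
ROI placements, inter-observer variability, contrast-phase differences
between scans, non-exponential (e.g. cure-fraction) survival, correlated
lesion effects within organs beyond the patient-level effect, and
non-PD deaths. Passing tests therefore show that the pipeline's logic and
statistics behave correctly under the stated generative model — not that
the criteria would perform identically on real imaging data.

## Problem sizes and numerical choices

Distribution-recovery checks use 2 000 patients (sampling error of a
median at that n is well under the 10% check band); survival-parameter
recovery uses 500 per phenotype; the log-rank null calibration uses 1 000
simulations of 50 + 50 patients, where the binomial standard error of the
rejection rate is ≈ 0.7%. The Choi classifier is verified against a
literal nested-if transcription of its rule table over the full integer
grid [−100, 200]² × all flag combinations (362 404 cases). Degenerate
inputs fail loudly: empty lesion sets raise not-evaluable errors, zero
baselines are rejected before division, all-zero Wilcoxon differences
return p = 1 by convention.

## Known limitations

* RECIST 1.1 rules (short-axis nodes, two-lesion cap) are out of scope; the
  implementation is RECIST 1.0 as used alongside the Choi criteria.
* The nadir is tracked as the smallest positive SLD; regrowth after a
  complete response is signalled by new lesions rather than a percent
  change from zero.
* No hazard-ratio or multivariable survival modelling; the comparison layer
  is deliberately the Cox-free KM + log-rank analysis.
* Patient-level vs lesion-level exclusion bookkeeping (a patient whose only
  lesion is the primary tumour) is handled by the not-evaluable flag, not
  by dropping patients silently.
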