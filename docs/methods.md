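# Methods

## Quantification model

Each cultured slice contributes annotation measurements: one perimeter
length, and per morphology class the summed length of cancer-cell outgrowth
along that perimeter (µm); cultures whose tumors do not form outgrowth are
instead annotated with viable and severely damaged tumor areas within the
slice (µm²).  The morphology vocabulary is closed — flat, cubic,
cylindrical and clear outgrowth count as viable; swollen and
necro-apoptotic as damaged — and unknown classes are rejected at ingest
rather than silently dropped, because the viable/damaged grouping drives
every downstream readout.

Per-slice readouts:

- per-class % of perimeter = 100 · class length / perimeter;
- outgrowth % = viable % + damaged % (the six classes are exhaustive);
- viability % = 100 · viable / (viable + damaged), over lengths
  (outgrowth mode) or areas (area mode);
- TVI = 3 · viable % + 1 · damaged %, hence bounded by 1× and 3× the
  outgrowth % and linear in the class composition.  The weights are
  configurable; 3 / 1 are the operational defaults of the assay.

Degenerate slices: zero outgrowth gives outgrowth % = 0 and TVI = 0 (the
index is length-weighted) but an undefined viability ratio, recorded as
missing with a logged warning.  A missing or zero perimeter in outgrowth
mode is a data error, not a readout.  Quantification mode is a per-culture
attribute auto-detected from which record kinds are present and can be
overridden.

Duplicate slices are arithmetic-averaged per culture × condition, ignoring
missing values and recording the n used.  Matrices are culture × condition;
per-condition medians are taken over cultures, and the pooled-selenite
median pools the duplicate-averaged condition summaries of all selenite
doses (pooling summaries, not raw slices, was the open design choice; it
matches how the per-condition values are defined).

Evans regression grades map damaged % (= 100 − viability %) to
I (<10), IIa (10–50), IIb (>50–90), III (>90) and IV (= 100).  Only the
>90% ⇒ III–IV anchor is assay-defined; the inner band edges follow the
published Evans scheme and are configurable.

## Inference

**Exact Wilcoxon signed-rank.**  Differences d = x − y; zeros are discarded
before ranking (Wilcoxon's original convention; Pratt's zero-ranking is
available behind `drop_zeros=False`); |d| is ranked with midranks under
ties; W = sum of positive-difference ranks.  For n_eff ≤ 12 (≤ 4096 sign
vectors) the two-sided p is exact: the full distribution of W under random
signs is enumerated and p = min(1, 2·min(P(W* ≤ W), P(W* ≥ W))).  The
doubled-smaller-tail rule is stated explicitly so values reproduce
bit-for-bit.  Beyond n_eff = 12 a normal approximation with tie and
continuity corrections is used; the study scale (n = 8) always stays exact.

**Benjamini–Hochberg.**  Step-up, p̃₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j capped at 1,
applied across the declared comparison family.  The default family is the
four treatment-vs-control comparisons per readout; the family is
configurable because study descriptions rarely state it.

**Friedman / Kendall's W.**  Within-block midranks; χ² with the standard
tie correction; p from χ²(k−1); effect size W = χ²/(n(k−1)) ∈ [0, 1],
equal to 1 iff all blocks rank the treatments identically.  Blocks with a
missing cell are dropped with a logged count.  At n = 8, k = 4 the χ²
approximation is compared in the test suite against a 10,000-draw
within-block permutation null; agreement is asserted to 0.05 absolute,
a band fixed in advance to cover Monte-Carlo noise plus the discreteness
of the permutation distribution at this block count.

**Normality screening** (Shapiro–Wilk) is delegated to `scipy.stats` and
reported descriptively only; it merely motivates the nonparametric choice.

## Differential-expression filter

The module consumes a finished DE results table (gene, aligned read count,
log2FC, raw and adjusted p) and never refits anything.  Stage one flags
adjusted p ≤ 0.05 and |log2FC| ≥ 1 (both inclusive; "±1 fold change" is
read as a magnitude threshold, since point equality would be vacuous) with
an up/down direction.  Stage two keeps raw p ≤ 1e-4 and ≥ 350 reads —
raw p is the default cut variable (configurable), the reading adopted
where the description is ambiguous.  The strict list is ordered by
ascending p, then descending |log2FC|, then gene id, so "top gene" output
is deterministic.

## Synthetic cohort generator

The generator emulates the study conditions, not any particular dataset:

| parameter | default | rationale |
|---|---|---|
| n_patients | 8 | cohort size of the assay design |
| conditions | control 72 h; selenite 5/15/30 µM; gemcitabine 1 µM | treatment arms |
| duplicates_per_condition | 2 | duplicate slices averaged per condition |
| v0 ~ Beta(8, 2) | mean 0.8 | control viability ≈ 80% |
| emax, ec50, hill | 0.99, 7 µM, 4 | minimal effect at 5 µM, >90% damage at 15–30 µM |
| outgrowth0 | 0.55 | control outgrowth ≈ 55% of perimeter |
| outgrowth_decline | 0.7 | control TVI ≈ 150 falling to ≈ 17 at 30 µM |
| noise_sd | 0.3 (logit) | duplicate-slice variability; a free choice, as no duplicate variance is published |
| gem_responder_prob | 1/8 | gemcitabine effective in ~1 of 8 tumors |
| area_mode_patients | 2 | cultures quantified within-slice by area |
| perimeter_mean_um | 20 000 | ~6–10 mm slices |

Viable fraction follows v(d) = v0·(1 − emax·dᵸ/(dᵸ + ec50ᵸ)); the
outgrowth fraction declines with the same Hill term scaled by
`outgrowth_decline`.  Gemcitabine is a per-patient Bernoulli responder
flag: responders receive the maximal-effect reduction (the simplest
one-parameter choice), non-responders are unchanged.  Slice noise is
normal on the logit scale so fractions stay in (0, 1); with noise_sd = 0
the per-slice values equal the expectations, which is what makes exact
parameter recovery testable.  Class compositions are symmetric-Dirichlet
and the last component is computed as a residual, so class lengths
partition the group totals to full floating precision.  Per-patient RNG
substreams are spawned as `SeedSequence([seed, patient_index])`, so
enlarging the cohort never reshuffles earlier patients.

What the generator does **not** emulate: spatial structure within slices,
inter-slice depth gradients, annotation error of the pathologist,
classifier segmentation noise, or any transcriptome-to-morphology
coupling (the DE table is generated independently).  Passing tests
therefore demonstrate correctness of the quantification and inference
machinery under the assumed statistical structure, not biological
validity on real cohorts.

## Numerical choices

- Exact-test tail comparisons use a 1e-9 absolute tolerance because
  midranks make the enumerated W non-integer under ties.
- "Exact" parameter recovery is asserted at 1e-9 relative: values
  round-trip through length products, so bit-equality is not meaningful.
- Readout CSVs are written with 17 significant digits and read back with
  round-trip float parsing, so write→read is lossless.
- The config hash in the run manifest excludes the output directory,
  which does not affect bundle content.
- Percentages are rendered to one decimal in reports; machine outputs
  keep full precision.

## Problem sizes

The test suite uses the cohort sizes of the design itself (8 cultures ×
5 conditions × 2 duplicates): 200 enumeration-oracle datasets at n ≤ 10,
500 random p-vectors for the BH oracle, 10,000 permutations for the
Friedman null, 200 seeds for the dose-damage Monte-Carlo check and 500
replicate null cohorts for the type-I calibration — sizes at which the
Monte-Carlo margins quoted in the tests are meaningful.

## Known limitations

- The normal-approximation branch is untested territory for the assay
  scale; it exists for larger cohorts only.
- Area-mode cultures contribute no outgrowth % or TVI, so those matrices
  carry missing rows (n = 6 of 8 by default) and the Friedman test drops
  them; this mirrors the assay, but reduces power for those readouts.
- GeoJSON ingestion assumes planar pixel coordinates and a single
  µm-per-unit scale; the classification property key is configurable but
  only string or `{"name": ...}` values are recognised.
- The DE filter treats thresholds as universal constants of the
  procedure; they are configurable arguments, not fitted quantities.
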