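# slicequant

Quantitative drug-response analysis for *ex vivo* organotypic tumor
tissue-slice cultures, built for pancreatic ductal adenocarcinoma (PDAC)
slice experiments but generic over any annotation-measurement cohort.

Precision-cut tissue slices (~350 µm) cultured on inserts develop a layer of
cancer-cell outgrowth on their cut surface.  Pathologist annotations of that
outgrowth — lengths of six morphology classes along the slice perimeter, or
viable/damaged tumor areas within the slice for cultures that do not form
outgrowth — are exported from whole-slide software as tables of lengths (µm)
and areas (µm²).  `slicequant` turns those tables into per-slice readouts,
duplicate-averaged culture × condition matrices, Evans regression grades and
paired small-sample nonparametric inference, and applies a two-stage
significance filter to companion differential-expression results.

## The readouts

Outgrowth morphologies are grouped into **viable** (flat, cubic,
cylindrical, clear) and severely **damaged** (swollen, necro-apoptotic).
Per slice, with perimeter length *P* and summed class lengths *ℓᵢ*:

- per-class % of perimeter: 100·ℓᵢ/P; **outgrowth %** = Σᵢ 100·ℓᵢ/P
- **viability %** = 100·viable/(viable + damaged), lengths for
  outgrowth-mode cultures, areas for area-mode cultures
- **tumor viability index** (TVI):
  TVI = Σ_{i ∈ {viable, damaged}} (% outgrowth length)ᵢ · wᵢ with
  w_viable = 3, w_damaged = 1, so TVI ∈ [0, 300]

Readouts are averaged over duplicate slices per culture × condition.
Damage > 90% maps to Evans tumor-regression grades III–IV.

## The inference

With n = 8 cultures, asymptotics are inappropriate: each treatment is
compared against the untreated control with a paired Wilcoxon signed-rank
test whose two-sided p-value comes from **exact enumeration of all 2ⁿ sign
assignments** (doubled smaller tail, capped at 1), with Benjamini–Hochberg
correction across the comparison family.  A Friedman test with Kendall's
W = χ²/(n(k−1)) measures the global dose effect across conditions.

A synthetic-cohort generator (Emax/Hill dose response on the viable
fraction, logit-normal duplicate-slice noise, Bernoulli gemcitabine
responder flag, Dirichlet morphology composition) provides ground-truthed
data for every stage.

## Worked example

```
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_quantify_readouts.py
python analysis/03_paired_inference.py
python analysis/04_filter_de.py --seed 1
```

prints (abridged):

```
generated 460 annotation records over 80 slices
area-mode cultures: ['DT7', 'DT8']; gemcitabine responders: none
viability_pct: medians control_72h=86.7, se5=69.7, se15=4.5, se30=1.0, gem1=85.2; pooled selenite 4.5
tvi: medians control_72h=140.7, se5=104.6, se15=18.0, se30=17.0, gem1=136.7; pooled selenite 19.0
Evans III-IV (>90% damaged) in se30: 8 cultures
viability_pct: significant vs control (BH p<=0.05): ['se5_vs_control_72h', 'se15_vs_control_72h', 'se30_vs_control_72h', 'gem1_vs_control_72h']; Friedman p = 2.7e-06, Kendall's W = 0.978
```

Median cancer-cell viability falls from 86.7% untreated to 4.5% pooled over
the selenite doses, every culture crosses the >90%-damage (Evans III–IV)
threshold at 15–30 µM, the three selenite comparisons reach the minimal
attainable BH-adjusted exact p at n = 8 (4/3 · 2/256 ≈ 0.0104), and the
Friedman test confirms a strong dose-concordant effect (W = 0.978).  At this
seed the gemcitabine arm is also flagged — by chance, not by construction:
no culture drew the responder flag, and the suite verifies the exact test's
type-I error stays at or below nominal over 500 null cohorts.

The same pipeline runs end to end behind a CLI:

```
slicequant run --out results/run --seed 1
slicequant simulate --seed 1 --out results/sim
slicequant stats --matrix results/readouts/matrix_viability_pct.csv --control control_72h
```

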