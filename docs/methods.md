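# Methods

## Simulation model

The generator draws gene-by-sample counts for a full-factorial
donor × time × dose design. The log2 mean of gene *g* in sample *s* is

    η_gs = β0_g + u_{g,d(s)} + s_g·1[female donor]
         + γ_g·1[late timepoint] + δ_g·f(dose_s) + φ_g·f(dose_s)·1[late]

and counts are negative binomial, X ~ NB(μ = L_s·2^η, α_g) with
var = μ + α_g μ² (gamma–Poisson mixture). Dispersion α_g is lognormal
(median 0.05, log-sd 0.5, a typical bulk RNA-seq range); baselines
β0_g ~ N(5, 2²) on log2 so that mean counts span ~1–10⁴; library-size
factors L_s are lognormal (log-sd 0.2) and divided by their geometric
mean so the design stays identifiable against size-factor estimation.
α_g = 0 is implemented as the deterministic limit (counts =
round(μ)): it gives bitwise-constant replicates, which makes contract
tests exact; genuinely Poisson-like genes are represented by small
positive α instead.

Default effect structure, chosen once to emulate the whole-blood
irradiation study design the package targets:

| parameter | default | what it encodes |
| --- | --- | --- |
| donors | D1 ♂, D2 ♂, D3 ♀ | 3 donors, two male, one female |
| doses | 0, 0.5, 1, 2, 4 Gy | graded X-ray series incl. sham |
| times | 2 h, 6 h | ex vivo incubation |
| `frac_dose_responsive` | 0.05 | ~100 / 2000 genes respond to dose |
| `slope_mean/sd` | 0.7 / 0.2 log2 per Gy | gives per-donor \|r\| ≈ 0.9+ at 6 h |
| `slope_pos_frac` | 0.6 | upregulation dominates the dose response |
| `interaction_scale` | 0.5 | φ = 0.5 δ: stronger response at 6 h |
| `frac_time_responsive` | 0.30 | broad time-in-culture drift |
| `time_effect_mean/sd` | 1.3 / 0.4 log2 | time separates on a leading PC |
| `donor_sd` | 0.4 log2 | per-gene-per-donor offsets |
| `sex_effect_sd` | 0.9 log2 | shared offset of the female donor's samples |

The sex term is deliberately larger than the per-donor term: in this
kind of data the female donor's samples sit farther from both male
donors than the male donors do from each other (mostly reflecting
blood cell composition, which the generator abstracts into offsets
rather than mixing cell-type profiles). With these defaults PCA of the
top-500 variable genes shows donor/sex and time as the leading axes —
the structure real data of this design exhibit — with positive
silhouettes for both factors on PC1–PC2. Dose never dominates the
leading components, which is exactly why the within-donor screen
exists.

Randomness is split per gene from the master seed
(`SeedSequence(entropy=(seed, stage), spawn_key=(gene,))`), so a run
with fewer genes is a strict prefix of a longer run, and every
downstream result is reproducible bit-for-bit from one integer.

What the generator does **not** model: cell-type mixtures (donor
differences are offsets, not deconvolvable compositions), read-level
artifacts, gene–gene correlation beyond what shared factors induce,
GC/length biases, and outlier samples. Tests passing on this generator
therefore validate the statistics under an idealized NB world; they do
not certify behavior on data with, e.g., correlated co-regulated
modules or composition shifts.

## The dose-correlation screen

Expression is filtered (mean raw count ≥ 10), normalized by
median-of-ratios size factors, and log2(x + 1)-transformed (the
transform feeding the correlation is selectable; log2 is the default
because variance is more nearly dose-stable there). Per donor and
timepoint the Pearson correlation with dose (identity dose scale by
default; log1p optional) is Fisher-transformed with variance
1/(n−3); n = 5 dose points gives 0.5 per donor. Donors with constant
expression for a gene are dropped (constancy is detected with a 1e-12
relative tolerance, since normalization leaves float jitter on
constant rows); genes with < 2 usable donors are flagged `untestable`
rather than aborting the screen.

Pooling uses the unweighted mean of z (with equal nᵢ this coincides
with inverse-variance weighting). Two variance schemes are exposed:

- **default, `include_between=False`**: T = W̄/m, standard-normal
  reference. This is the common-effect ("fixed-effects") estimator.
- **`include_between=True`**: T = W̄ + (1 + 1/m)B with Student-t
  reference at Barnard–Rubin degrees of freedom
  ν = (m−1)(1 + W̄/((1+1/m)B))², falling back to normal when B = 0.

The default was chosen on power and calibration grounds, verified by
simulation at the design scale (m = 3 donors, n = 5 doses): with
donor correlations at \|r\| = 0.9 the common-effect test has ~95%
power at α = 0.05 while the B-inclusive combination has ~15% (its
total variance is dominated by a between-donor term estimated from
three values, and its adjusted df collapse toward 2); under the null
the common-effect test is nearly exact (type-I ≈ 0.050) while the
B-inclusive variant is essentially never significant. With three
donors there is no information to estimate donor heterogeneity, so
charging it to the variance destroys the test; the conservative
variant remains available for designs with more donors. Published
within-donor dose screens of this 3 × 5 design print confidence
intervals consistent with the common-effect scheme.

Classification defaults to raw p < 0.05 with the sign of the pooled r;
BH q-values are always emitted and `classify_on="q"` switches the
call to FDR control. Degenerate r = ±1 is clamped at 1 − 10⁻⁶ before
atanh.

### Known miscalibration at n = 5

The Fisher variance 1/(n−3) = 0.5 slightly overstates the exact null
variance of atanh(r) at n = 5 (≈ 0.466), so null p-values are mildly
conservative: the empirical type-I error at nominal 0.05 is ~0.04–0.05,
but a Kolmogorov–Smirnov uniformity test on thousands of null genes
resolves the deviation (D ≈ 0.03) and rejects. This is intrinsic to
the classical transform at few dose points, not a defect of the
implementation; the conservatism is harmless for screening (it loses
a little power, never inflates false positives).

## Contrasts

The paired stage computes per-donor log2 fold changes between two
(dose, time) conditions and tests their mean with a one-sample t
(df = m−1). With `moderation="shrink"` each gene's variance is shrunk
toward the across-gene mean variance with weight prior_df/(prior_df +
df), prior_df = 4, and df increases accordingly — an empirical-Bayes
style stabilization without which df = 2 t-statistics are so
heavy-tailed that null genes swamp rankings (AUC for recovering true
time-responsive genes rises from ~0.89 to ~0.95 with moderation, which
is why the pipeline default is `shrink`; the unmoderated test remains
the function default for transparency). A gene with zero LFC variance
and nonzero mean is tested against the moderated variance alone; zero
variance and zero mean gives p = 1. This stage is deliberately a
simple paired t on log2 values, standing in for count-model
differential expression: it feeds DEG lists and readout vectors to
enrichment and TF inference, and makes no claim to model dispersion.

## TF activity (ULM)

For each TF, a regressor x over *all* readout genes (signed regulon
weight for targets, 0 otherwise) is fit to the readout y by OLS with
intercept; the slope's t-value is the activity, equivalently
t = r√(n−2)/√(1−r²) for the x–y Pearson correlation, hence invariant
to scaling and shifting of the readout. TFs with fewer than
`min_targets = 5` targets among the readout genes are excluded and
listed. The default readout is the contrast t vector (moderated in the
pipeline); the log2 fold change works as well. Zero residual variance
caps the activity at ±10⁶ with a flag. Significance is BH-adjusted
across TFs within each readout.

## ORA

The over-representation p-value is the hypergeometric upper tail
P(X ≥ k) — the ≥ convention, stated explicitly because the off-by-one
variant P(X > k) is a classic source of cross-tool discrepancies —
with N the number of *expressed* genes (the post-filter universe), not
the whole annotation. Sets are intersected with the universe first;
sets outside the size bounds (5, 500) are excluded and listed. Query
genes outside the universe are dropped with a warning.

## Numerical and interface choices

- Row z-scores use the sample sd (n−1); constant rows map to zeros.
- PCA centers but does not scale genes; variance ties at the top-n
  boundary break lexicographically by gene id, making gene selection
  deterministic.
- All output tables are TSV (UTF-8, NA for missing) with a leading
  `#` provenance line (version, seed, config hash); counts round-trip
  losslessly through TSV and MatrixMarket triplets.
- Every pipeline run writes its fully resolved configuration next to
  its outputs; re-running the same config and seed is byte-identical.
- The bundled `toy_synthetic_network.tsv` / `toy_synthetic_sets.gmt`
  are randomly generated fixtures over the simulated gene namespace
  for tests and demos; they are not curated biological resources.

## Problem sizes

The validation suite runs at the study's own design scale: 2,000-gene
simulations (≈100 dose-responsive) for recovery, aggregated over 100
replicates; 5,000 null genes for calibration; 100 spike-in runs
against a 60-TF network for ULM recovery; full enumeration of all
hypergeometric configurations up to N = 30. These sizes keep every
check to seconds-to-a-minute on one core while leaving Monte-Carlo
error well below the margins being asserted.
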