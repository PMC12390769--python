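# Methods

This note documents the models, numerical choices and limitations of
`proteoconnect`, in the spirit of a statistical-methods appendix.

## Study layout

All analyses run over a fixed panel of 13 language-related Brodmann areas
sampled bilaterally (26 ROIs, canonical order `BA44_L … BA9_L, BA44_R …
BA9_R`). The proteome is an LFQ intensity matrix (proteins × samples) with
one sample per donor × region × hemisphere; zero intensity means
"not detected". The connectome consists of per-subject ROI time series and
a symmetric streamline-count table with ROI surface areas. The cohort table
has one row per subject with `gmv_<ROI>` columns and language scores.

## Preprocessing

**Detection filter.** A protein is usable in a region × hemisphere group iff
it is detected in ≥ `min_donors` (default 5) donors of that group. The mask
depends only on the zero-pattern. Filtering precedes normalization; the
order is configurable.

**Normalization.** log2 transform of nonzero entries; each sample column is
shifted so its median equals the global median of column medians. This
removes per-sample loading differences and is robust to the heavy tails of
LFQ data. Missing values stay missing (NaN) — they are excluded from
differential expression and summaries, and imputed (per-protein minimum)
only for PCA.

**Batch correction.** Per protein, log2 abundance is regressed on donor
indicators (sum-to-zero coded) plus region × hemisphere indicators, and the
fitted donor contribution is subtracted after centring it within each
region × hemisphere group. The centring step guarantees that every
condition-mean contrast is preserved to machine precision even when
missingness unbalances the per-protein design; with a balanced design it
coincides with standard residualisation. Proteins are grouped by
missingness pattern so each distinct design matrix is factorised once.
Confounded (rank-deficient) designs raise an error. The procedure is the
least-squares analogue of standard batch-removal tools, without
empirical-Bayes shrinkage, so its contract is exactly testable.

## Variability and stability

The coefficient of variation is computed per protein and region over
detected donors on the normalised **linear** scale (CV of log values is not
scale-free); V_inter is the median across regions with ≥ 2 detections. Note
the sample CV at n = 10 donors is slightly biased below the asymptotic
lognormal value √(exp(s²) − 1); tests freeze the small-sample value from a
simulation oracle.

Differential stability ΔS is the mean over donor pairs of the Pearson
correlation between the two donors' regional profiles (default scope: the
13 regions of one hemisphere; bilateral scope available). Pairs sharing
fewer than 3 detected regions are skipped. ΔS is invariant to per-donor
affine rescaling.

## Spin test

Spatial-permutation nulls are built by uniform random 3-D rotations
(QR of Gaussian matrices with sign and determinant fixes) of the ROI
centroids on the unit sphere; each rotated ROI is reassigned to the nearest
original ROI one-to-one, greedily by increasing arc distance, so the null
is a proper permutation. When maps span both hemispheres the mirrored
rotation (conjugation by diag(−1, 1, 1)) is applied to the right
hemisphere and assignment stays within hemisphere. The p-value is
two-sided with the +1 correction: p = (1 + #{|null| ≥ |obs|}) / (1 + n_rot).
With only 13 ROIs rotations are coarse, so a plain label-permutation null
(`null="permute"`) is provided as a fallback. Empirical type-I error at
α = .05 is ≈ .04 over 1000 null replicates (slightly conservative, as
expected for a discrete permutation null).

**Detection limit.** The null SD of a Spearman correlation over 13 regions
is 1/√12 ≈ .29. Consequently couplings of |ρ| ≲ .6 cannot reliably pass a
two-sided test plus FDR across thousands of genes; the class-recovery tests
and the default pipeline plant |ρ| = .95, where recovery exceeds 95% per
class. Weaker planted couplings are faithfully generated but land in the
Uncoupled class — a property of the statistic at this ROI count, not a bug.

The mRNA generator uses a Gaussian copula on the normalized regional
protein profile with ρ_pearson = 2 sin(πρ_s/6), so the population Spearman
equals the planted value; the sample Spearman at n = 13 shows the usual
small-sample attenuation (planted .9 → observed ≈ .88 on average).

## Differential expression

Default test: two-sided Wilcoxon rank-sum, exact whenever both groups have
≤ 10 samples and the data are tie-free. The exact null distribution of the
Mann–Whitney U is built by the Gaussian-binomial recurrence and cached per
group-size pair, which lets the 325-pair DEP matrix be computed vectorised
across proteins; tied or larger samples fall back to the tie-corrected
normal approximation. A Welch-t option exists. The exact path is validated
against exhaustive enumeration of all C(20,10) rank assignments.

DEP rule: p < .05 and |avg_log2FC| > .1, strict inequalities, with
avg_log2FC = mean(log2 A) − mean(log2 B) over detected donors;
|avg_log2FC| ≥ 5 entries are flagged "highlighted". DEP counts per pair use
raw p (per the figure-legend convention); a q-based variant is available.
BH-FDR is computed within each pairwise comparison, not pooled across
pairs. Donor pairing is not exploited (detection masks differ per region);
a paired option is out of scope.

## Connectome

Subject FC = Pearson correlation of ROI time series; group FC = entrywise
Fisher-z mean (r = ±1 clipped to 1 − 10⁻⁷ before atanh), with an
arithmetic-mean option. Node strength = mean off-diagonal r over all 25
partners (default) or the 12 ipsilateral partners. Streamline density =
counts / mean of the two ROI surface areas. Negative FC is retained in
strength computations.

## Coupling statistics

DEP–connectivity coupling is the plain Pearson correlation over the 325
upper-triangle pairs with a two-sided t-test on n − 2 df, reported pooled
(pairs additionally annotated left/right/cross for per-class summaries).
The pair observations are not independent (each ROI participates in 25
pairs); the p-value follows the field's convention and should be read
accordingly. Correlations use FC r-values, not Fisher-z (configurable
upstream). Hierarchical clustering uses average linkage on 1 − correlation
(or 1 − normalised connectivity) distances; dendrograms export to Newick.

## E/I balance

E/I ratio per region × hemisphere = Σ excitatory / Σ inhibitory region-mean
**linear** intensities (sums of log values are not meaningful); the default
sets are AMPA (GRIA1–4) + NMDA (GRIN1, GRIN2A, GRIN2B, GRIN2C) vs GABA-A
(GABRA1–5, GABRB1–3, GABRG1–3), kept exactly as conventionally printed
(GRIN2C rather than the more common GRIN2D). Hemispheric FC–E/I
correlations (n = 13 regions each) are dependent because regions are
matched pairs; they are compared with Steiger's Z using the Pearson–Filon
covariance of the Fisher z's with mean-r pooling. Monte-Carlo null
calibration gives type-I ≈ .049 at α = .05 (n = 13). The independent-sample
Fisher-z comparison is the fallback when cross-correlations are
unavailable. Gene-driver profiling reports per-gene hemispheric
correlations, Fisher ΔZ with Steiger p, and the leave-one-out change in the
set-aggregate ΔZ.

## Cohort analysis

ROI GMV group comparisons use the pooled-variance Student t (the variant
consistent with published summary statistics; Welch optional) with BH-FDR
over 26 ROIs. GMV–score associations are partial Pearson correlations after
least-squares residualisation on covariates (default age + sex; always
recorded), with t-based p on n − 2 − k df. Summary-statistic helpers
reproduce printed cohort tables: pooled t from means/SDs/ns and Pearson χ²
without continuity correction (Yates' correction would zero the small
printed statistics). Cohort tables are validated with warnings rather than
errors so published tables with minor internal inconsistencies can be
reproduced verbatim.

## Synthetic generator: what it emulates and what it does not

Per-protein log2 abundance = baseline (N(22, 2²)) + sparse region signature
(5% of proteins per region, N(0, 1)) + sparse left–right shift (2%,
N(0, .8²)) + donor offset (global N(0, .6²) plus protein-specific
N(0, .3²) — the part median alignment cannot remove) + N(0, .5²) noise,
exponentiated to intensities; missingness is MCAR at 5% by default (an
abundance-dependent mechanism is available; which one matches real LFQ
detection is deliberately left open). Excitatory genes additionally carry a
lateralised profile ± slope × gradient (slope ±.9 on GRIA1/GRIA4, 0.3× on
other excitatory genes), calibrated so realized FC–E/I correlation
magnitudes fall in the .65–.79 range reported for such data.

Connectivity: each ROI pair shares a latent signal with weight
w = base + slope × rank(proteomic similarity) + boost × homotopic +
γ(g_i + g_j), entering both ROIs' time series on top of unit private noise,
so every subject FC is a valid correlation matrix with population
r_ij = w_ij/√(d_i d_j). Streamline counts are negative-binomial with
log-link mean in w (many near-zero pairs, homotopic motor pairs in the
thousands). Defaults are study-scale: 4415 proteins × 10 donors × 26
regions, 90 subjects, 52 patients vs 30 controls.

Not emulated: raw spectra and peptide-level data, haemodynamics and fMRI
preprocessing artefacts, spatial autocorrelation of cortical maps beyond
the mirrored geometry, tractography biases, realistic score distributions.
Passing recovery tests therefore demonstrates estimator correctness under
the stated generative model, not robustness to all real-data pathologies.

## Problem sizes used in tests and the acceptance script

Recovery and calibration loops run scaled-down replicates chosen to keep
the statistical properties intact: proteome recovery 200 proteins × 6
donors × 6 subjects (200 seeds), E/I recovery 60 proteins × 10 donors × 20
subjects (200 seeds), spin calibration 1000 replicates × 199 rotations,
Steiger calibration 2000 replicates, null-FDR 200 replicates × 300
proteins, homotopic property 30 subjects × 200 time points (5 seeds).
Generator defaults remain at full study scale.

## Known limitations

- Exact Wilcoxon p-values are discrete; at n = 10 + 10 the smallest
  two-sided p is ≈ 1.1 × 10⁻⁵, and null rejection rates sit slightly below
  nominal α.
- The spin null with 13 ROIs is coarse (at most 13! permutations, far fewer
  realised); the label-permutation fallback is statistically equivalent
  here because generated maps carry no residual spatial autocorrelation.
- The coupling p-value ignores pair non-independence (convention).
- Batch correction assumes additive donor effects on the log2 scale.
- The GMV power of a 1-SD single-ROI effect at the 52/30 cohort size is
  ≈ .87 after BH correction — planted effects near that size are detected
  most but not all of the time.
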