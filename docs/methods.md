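# Methods notes

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions that were genuinely open.

## Plate normalization and Bliss synergy

Viability is raw luminescence divided by the mean of solvent-only control
wells matched within the same plate, experiment and solvent. Controls are
never pooled across plates: plate-to-plate luminescence offsets are the
dominant nuisance in ATP-proxy assays, and within-plate matching makes every
downstream score invariant to rescaling a plate's signals by any constant.
Viabilities are not clipped at 1; treated wells can legitimately outgrow
controls and clipping would bias Bliss expectations downward.

The Bliss expectation is Y_AB(E) = Y_A · Y_B and the synergy score is
Y_AB(E) / Y_AB(O). Boundary semantics follow the category definitions
literally: scores in the closed interval [2, 5] are "synergistic", strictly
above 5 "strongly synergistic", and the replication rule counts experiments
with score strictly greater than 2. For n experiments the rule generalizes
to a strict majority, ceil((n+1)/2), which reduces to 2-of-3 for the
standard triplicate design. The aggregate score is the median across
experiments, reported with the (min, max) range; the median was chosen over
the mean because experiment-level scores are ratio statistics with heavy
right tails. Observed viabilities are floored at 1e-4 before division (and
flagged) so that near-complete eradication yields a large finite score
rather than an infinity; the floor corresponds to a 0.01% residual signal,
below typical luminescence background.

The plate generator plants an interaction as a divisor of the Bliss-expected
combination viability, so the true synergy score equals the planted factor
by construction, and applies multiplicative log-normal noise with unit mean.
A log-normal was chosen because luminescence error is multiplicative and
viability cannot go negative. The default noise CV of 0.1 reflects typical
well-to-well variability of organoid ATP assays; it is a free parameter of
the generator, not an estimate from any dataset. Default design: 4 replicate
wells per condition, 3 independent experiments. With these settings,
planting factors between 2 and 113 is recovered with a median relative
error of about 5–7% (see the acceptance script), comfortably inside the 25%
band used for validation.

## Colony detection

The pipeline is rolling-ball background subtraction (ball radius 115 px) →
Gaussian blur (σ 2 px) → global threshold → 8-connected labeling →
hole-filling → feature filter (area ≥ 5000 µm² and circularity ≥ 0.5).
Choices worth recording:

* **Rolling ball at large radii.** The ball rolls on a shrunken copy of the
  image (shrink factor 2/4/8 for radii above 10/30/100 px) and the
  background is bilinearly resized back. This mirrors the classic ImageJ
  optimization and makes the cost independent of the radius; the smooth
  background loses only sub-pixel accuracy.
* **Thresholding.** The method was an open choice; Otsu's global threshold
  on the blurred, background-subtracted image is the default (parameter-free
  and standard in macro-style pipelines), with a fixed-value alternative
  exposed. Otsu alone will happily split a colony-free residual image into
  two classes, so the applied threshold is max(Otsu, median + 6 robust SDs)
  of the residual; for any image actually containing colonies the Otsu value
  dominates, while blank wells yield zero detections.
* **Circularity.** 4π·area/perimeter² with the Crofton perimeter estimator,
  which keeps digitized disks near circularity 1; a tolerance of 0.1 above 1
  absorbs the remaining discretization. The "± 50 cells" gloss sometimes
  attached to the 5000 µm² cutoff is biological context, not a second filter.
* **Merged colonies** are not watershed-split; overlaps are flagged in the
  synthetic ground truth instead.

Surviving fractions use the standard clonogenic definitions (PE at 0 Gy;
SF(d) normalized to PE). The linear-quadratic fit SF = exp(−αD − βD²) by
least squares on log SF is provided as a convenience extension, not part of
the per-dose quantification.

The image generator renders hard-edged disks on a linear illumination ramp
with optional Gaussian noise, written as 16-bit TIFF. It does not emulate
ragged colony borders, density-dependent colony size, or vignetting; passing
detection tests therefore demonstrate the pipeline's correctness on
well-separated, disk-like objects, not robustness to confluent cultures.

## Sub-G1 analysis

Landmarks are local maxima of a Gaussian-KDE density (Silverman bandwidth,
1024-point grid); among all mode pairs with position ratio in [1.7, 2.3] the
pair with the largest combined density is taken as (2N, 4N). KDE mode-finding
was preferred over histogram peaks because it has no bin-edge artifacts, and
Silverman's rule keeps the estimate scale-equivariant, so the sub-G1 fraction
is invariant under global intensity rescaling when landmarks are
auto-detected.

No numeric sub-G1 gate is standard, so the gate is gate_factor × 2N-mode
with default 0.80: for peak CVs up to ~8% the G1 peak's lower 2.5-SD shoulder
stays above the gate, while fragmented-DNA events fall well below it. The
generator draws sub-G1 events uniformly on [0.25, 0.75] × the 2N mode,
G1/G2M as Gaussians (G2M centred at exactly twice the 2N mode), and S-phase
uniformly between the peaks. Inputs are assumed debris/doublet-gated
upstream; scatter gating and S-phase deconvolution (Dean–Jett–Fox style) are
out of scope. Group comparisons of fold changes use the pooled two-sided
Student's t test.

## Expression layer

**TMM.** The reference sample is the one whose upper-quartile count fraction
is closest to the mean; factors are precision-weighted means of M-values
after trimming 30% on M and 5% on A, rescaled to geometric mean 1. The
implementation agrees with Bioconductor edgeR's `calcNormFactors` to ~1e-6
relative on matrices with composition bias (this is asserted in the test
suite via Rscript).

**Differential expression** is equal-variance t tests on TMM-normalized
log2-CPM (pseudocount 0.5) with BH step-up control at FDR 1%. This is a
deliberate simplification of a moderated linear-model analysis: it keeps
error control (null false-positive proportions stay well under the nominal
level) but gives up the shrinkage power that empirical-Bayes moderation
brings at 3-vs-3 designs. Concretely, a 4-fold shift at n = 3 per group and
dispersion 0.1 is detected at raw p < 0.01 for most genes but rarely clears
BH at 1% with only 4 degrees of freedom; at n = 8 per group recovery at FDR
1% exceeds 95%. The test suite encodes both behaviours. Default
low-expression filter: CPM ≥ 1 in ≥ 3 samples.

**Gene-set scores.** The per-sample score is the set's mean expression rank,
z-scaled under the exact finite-population null: for m members among G genes,
E[r̄] = (G+1)/2 and Var[r̄] = (G−m)(G+1)/(12m). This replaces KS-style
per-sample enrichment estimators with a self-contained statistic whose null
is analytic (mean 0, variance 1 for random sets, verified by permutation in
the tests); scores are not numerically comparable to GSVA output, though
they order samples similarly for coherently shifted sets. Sets with under
50% of members present are dropped with a warning. Set-level contrasts reuse
the t-test + BH machinery; the response rate is −log10(P_adj) × log2(fold
change) with a *linear* fold-change input, making the statistic antisymmetric
under fold-change inversion. It is computed per gene set by default; the same
function applies per gene.

**Graph.** Nodes are the significant sets (direction-annotated); an edge
joins two sets sharing at least `min_shared` genes (default 1) with the
intersection size as weight. Layout is intentionally excluded: GraphML
output leaves force-directed rendering to any downstream tool. Category tags
are user-supplied keyword lists matched against set names, since no
principled automatic categorization exists.

**Count generator.** Negative-binomial (gamma-Poisson) counts with log-normal
per-gene baselines around a mean of 200, dispersion 0.1, and three samples
per group — a deliberately small bulk design with planted log2 effects
applied to member genes in group 2 plus decoy sets for null calibration. It
does not emulate gene–gene correlation, length/GC bias, or outlier samples,
so passing tests demonstrate statistical calibration, not robustness to those
real-data artifacts.

## Determinism and problem sizes

Every generator draws from one explicit `numpy.random.Generator`; pipeline
runs write a manifest (seed, parameters, versions, SHA-256 of inputs and
outputs) sufficient to re-execute them exactly. Validation sizes — 100
null screens, 30 screens per planted factor, 50 images per noise level,
10,000 flow events, 50 null count simulations — were chosen so that every
Monte-Carlo estimate has sampling error well below the tolerance it is
compared against while the whole validation completes in well under a
minute of compute; all of them are function arguments and scale up freely.

## Known limitations

* Synergy is Bliss-only by design; Loewe, ZIP or HSA models are out of scope.
* The DE layer's power at triplicate designs is limited without variance
  moderation (see above); interpret FDR-1% gene lists from n = 3 accordingly.
* Colony detection assumes grayscale images and does not split touching
  colonies.
* Flow analysis requires both 2N and 4N populations to be present; pure-G1
  samples need manual gates.
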