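# Methods

This note documents the models implemented in `splitomics`, the design
choices made where several defensible options existed, the synthetic
data the package uses to validate itself, and what the validation does
and does not demonstrate.

## Statistical core

**Hypergeometric tail.** All enrichment questions (term
over-representation of a DEG list; over-connectivity of a gene's
interaction partners to a query set) reduce to the one-sided
over-representation tail P(X ≥ k) of a hypergeometric distribution. The
tail is summed in log space (log-PMF + log-sum-exp), so probabilities
down to the smallest positive double (~1e-308) are computed without
underflow of intermediate terms; the exhaustive-enumeration oracle in
the test suite checks every valid configuration with N ≤ 12 to 1e-12.
One-sided was chosen because the depletion direction is never of
interest in the enrichment context here.

**Two-group test.** The per-gene test is the Welch (unequal-variance)
t-test on log2 intensities. This is a deliberate default, not a claim
about optimality: it requires no variance-pooling assumption and is a
documented swap-in point. Moderated (empirical-Bayes) variance models
are out of scope. Degenerate zero-variance genes get p = 1 when group
means are equal and p = 0 otherwise.

**Multiplicity.** Benjamini–Hochberg (step-up with monotonicity
enforcement) is the default for enrichment and connectivity families;
Šidák (1 − (1−p)^m) and Bonferroni (min(1, m·p)) serve the post-hoc
pairwise comparisons of spectral integrals. The family size `m` may be
set larger than the supplied vector when only part of a comparison
family is passed in. Šidák post-hoc tests are implemented as adjustment
of named pairwise Welch comparisons, not as a studentized-range
procedure: the comparison set is an explicit argument, matching how
figure-style group-pair annotations are made.

**Critical correlation.** The significance filter for loadings is
r\* = t\*/√(t\*² + n − 2), the exact two-tailed threshold for a zero
correlation test at df = n − 2. r\* is always derived from the actual
model sample count; no numeric constant is hard-coded (the conventional
|r| > 0.49 corresponds to n ≈ 16–17 at α = 0.05).

## Transcriptome arm

**DEG calling.** A gene is significant when its (raw or BH-adjusted,
caller's choice) p-value is below `p_threshold` and its symmetric
linear fold change max(FC, 1/FC) is at least `fc_threshold` (defaults
0.05 and 1.5). Fold change is treated-minus-reference on the log2
scale; significant genes split into `up`/`down` by the sign of the log2
FC, and the three direction classes partition the gene universe. Both
raw and adjusted p are always reported because both conventions are
common; the gate is configurable. Inputs are assumed to be one row per
gene — probe summarisation and normalisation are upstream
responsibilities.

**Term enrichment and the dichotomy.** Terms are trimmed to the
explicit background (the full assay universe, not the annotated subset)
before testing, so K counts only background members; records need a
minimum overlap (default 2) to be emitted; BH is applied over the
emitted family. The `term_dichotomy` summary counts terms passing a
threshold for the up-query only, the down-query only, and both — a
fully polarised response has an empty intersection. Plain
hypergeometric is used, not the EASE-style (k − 1) variant; GO graph
structure (parent–child propagation) is not modelled.

**Connectivity enrichment.** For each candidate gene g with at least
one interaction partner in the background, the partner set is the union
of in- and out-neighbours (direction and sign ignored, multiplicity
collapsed — the hypergeometric requires distinct draws), intersected
with the background and excluding g itself; the population likewise
excludes g, so a gene can never count itself. Separate runs against the
all-DEG, up and down query sets reproduce the usual
regulator-of-which-arm table structure. Components of the DEG-induced
subnetwork are weakly connected (display convention); hub ranking is by
total degree with lexicographic tie-break; the bipartite annotation
reports d = out-degree (downstream targets) and u = in-degree (upstream
regulators), with Σd = Σu = |edges| as a conserved check.

## Chemometrics arm

**Scaling.** Columns (bins) are mean-centred and unit-variance scaled
(sd with one delta degree of freedom). Zero-variance bins are dropped
and recorded; the inverse transform restores them from their means, so
scale→unscale round-trips exactly. Cross-validation refits the scaler
on each training fold — scaling is part of the model, not of the data.

**O-PLS (single response).** The predictive weight is w ∝ Xᵀy (y
centred), which is exactly the first NIPALS PLS1 weight. Each
orthogonal component takes the current predictive loading p, removes
its projection on w (wₒ ∝ p − (wᵀp)w), and deflates X by the resulting
score/loading pair. Because w ∝ Xᵀy, the orthogonal scores satisfy
tₒᵀy = 0 identically — the defining constraint — and deflation
conserves X: orthogonal reconstruction + predictive reconstruction +
residual equals the input to machine precision. With `n_orth = 0` the
model is bit-for-bit NIPALS PLS1. One predictive component is fitted
(two classes admit one discriminant direction); `n_orth` defaults to 1,
the near-universal choice for two-class NMR data, with the usual
rule-of-thumb of stopping when Q²Y starts decreasing. The class dummy
is a single −1/+1 column (a two-column one-hot for two classes is rank
one anyway).

**Q²Y and permutation.** Q²Y = 1 − PRESS/SS over stratified, seeded
k-fold cross-validation (default 8 folds), with per-fold refits of
scaler and model; SS is the total centred sum of squares of the dummy.
Stratification guarantees both classes in every training fold. The
permutation test permutes y B times (default 1000) and recomputes the
full cross-validated Q²Y each time; p = (1 + #{Q²ₚₑᵣₘ ≥ Q²ₒᵦₛ})/(B + 1),
which cannot return zero. Both quantities are bit-reproducible given
the seed.

**Correlation loadings.** Interpretation is done against the *raw*
(unscaled) bins: r = corr(bin, predictive score), back-scaled
coefficient = r·sd(bin) (covariance shape). Back-scaling by the bin's
own standard deviation restores spectral line shapes and signs, so the
loading trace reads like a spectrum with signed peaks. The significance
flag is |r| > r\*(n, α). The filter is on |r|, not r²: an r² > 0.49
threshold would equal |r| > 0.7, which is not a critical-correlation
value at these sample sizes, so the |r| reading is used and the flag is
exposed. Zero-variance bins get r = 0 and are never significant.

**Integration and group tests.** Region integrals are trapezoidal over
the ppm interval (descending axis handled; areas reported positive);
adjacent regions split at a shared grid point are exactly additive.
Group comparison is omnibus one-way ANOVA followed by named pairwise
Welch tests, Šidák- (default) or Bonferroni-adjusted over the named
family. A total-area normalisation utility exists for dilution-style
nuisance but is off by default; alignment, baseline correction and
other spectral pre-treatment are out of scope upstream of the bin
matrix.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their parameters and a seed, and
every generator returns a truth sidecar so predictions can be joined to
the planted structure.

**Expression.** Gene baselines are uniform on [6, 12] log2 units (a
typical microarray intensity range; fold changes are scale-free against
it). Planted up/down genes shift by ±`effect_log2` in group B; noise is
i.i.d. Gaussian on the log2 scale. Defaults — 2000 genes, 8 vs 8
samples, 100 up + 100 down planted genes, effect 1.5 log2 units, noise
sd 0.25 — describe a strong, clean intervention signature: per-gene
effects of several residual sd, the regime in which a two-stage
p-and-fold-change filter is expected to approach complete recovery.
What is *not* modelled: mean–variance dependence, probe-level effects,
batch structure, correlated genes. Recovery results therefore
demonstrate the pipeline's correctness, not its power on noisy designs.

**Gene sets.** Up-terms draw a fraction `purity` (default 0.9) of their
20 members from the planted up genes and the rest from nulls,
symmetrically for down-terms; null terms sample the whole universe.
Planted up- and down-term cores are disjoint by construction, which is
what makes the empty enriched-term intersection a recoverable truth.

**Network.** Planted regulators (default 8) are drawn from the null
genes; 80% of each regulator's 20 targets come from the planted DEG
sets (the 0.8 target purity is a fixed design constant: strong
preferential targeting with a realistic minority of off-list targets),
the rest from other genes. Background edges are uniform ordered pairs
at density 5e-4 (~2000 edges over a 2000-gene universe — sparse, like
curated interactomes). Signs are drawn 0.45/0.45/0.10
activation/inhibition/unspecified. Degree distributions, edge
multiplicity by mechanism and literature-curation biases are not
modelled.

**Spectra.** Each sample is dilution × (baseline + Σ concentration ×
line shape) + Gaussian noise. Line shapes are Lorentzian by default
(the physical NMR line shape; Gaussian is available — the choice
affects realism, not the statistics under test). The default panel is a
faecal/intestinal-extract-like set of nine metabolites with multiplets
placed at approximately their real chemical shifts over a 9.0–0.5 ppm
axis of 400 bins. The default discriminatory species is a
bile-acid-like metabolite whose signals — steroid methyl singlets near
0.7/0.9 ppm, CH/CH₂ envelopes at 1.6–2.3 ppm, a conjugate triplet at
3.08 ppm — are spread across the spectrum, as bile-acid signals are in
real extracts; its concentration doubles in class 2. Concentrations are
log-normal across samples (log-sd 0.2, ~20% biological CV); dilution is
uniform on [0.8, 1.2] per sample (the dominant nuisance of faecal
extracts, and what the orthogonal component and the optional total-area
normalisation exist for); noise sd 0.05 is 5% of the unit peak-height
scale. A flat baseline of 0.3 keeps off-peak bins non-negative at
documented noise levels (non-negativity is guaranteed for noise sd up
to ~1% of the minimum peak height and holds with large margin at the
defaults). Truth masks for "a metabolite's bins" use bins carrying at
least 25% of that metabolite's maximum clean amplitude: at the unit
scale a doubled concentration moves such bins by ≥ 5× the noise sd, so
the mask contains exactly the bins where an effect is detectable in
principle; line tails below that level are excluded from both the
sensitivity numerator and the false-flag denominator (a 2% mask is used
to exclude tails when counting null bins). Not modelled: peak-position
jitter (misalignment), J-coupling fine structure beyond fixed
multiplets, baseline roll, correlated metabolite panels, water/urea
artefacts. Passing recovery tests on these spectra shows the
chemometric chain is implemented correctly and calibrated under clean
conditions; it does not certify performance on misaligned or heavily
overlapped real spectra.

## Numerical and procedural choices

- Enrichment and connectivity tables are sorted by raw p (stable sort;
  connectivity ties broken by gene id); output order of p-adjustment
  always matches input order.
- Hub ranking ties break lexicographically by node id, so rankings are
  deterministic.
- Duplicate network edges collapse keeping the first sign; the collapse
  count is recorded on the graph. Self-loops are rejected at build
  time.
- Cross-validation folds are stratified by class and seeded; fold seeds
  and permutation seeds are explicit arguments everywhere, and no
  global RNG state is used anywhere in the package.
- The permutation estimator (b + 1)/(B + 1) is used because it is
  never zero and has the correct exchangeability guarantee.
- Gene identifiers are case-sensitive opaque strings; symbol
  normalisation is the caller's concern.
- PCA is computed by singular value decomposition (via scikit-learn)
  and verified in the tests against an independent
  covariance-eigendecomposition oracle; the O-PLS implementation is
  verified against an independent NIPALS PLS1 oracle and its own
  definitional identities.

## Problem sizes used in validation

The validation suite and the reproduction script use: 2000 genes × 16
samples for the expression arm; 40-term collections of 20 genes each;
2000-node networks with ~2100 edges; 20 × 400 spectra for the planted
effect (B = 1000 permutations in the reproduction script; B = 200 in
the test suite) and 20 replicates of 16 × 300 no-effect spectra at
B = 200 for null calibration. These sizes were chosen so the whole
suite exercises every claim at full statistical strength while
remaining comfortable on a single CPU.

## Known limitations

- The Welch test is the only expression test; count-based or moderated
  models must be applied upstream or swapped in.
- Connectivity enrichment counts *distinct* interactors; an
  edge-multiplicity variant (counting parallel interactions) is a noted
  possible extension, not implemented.
- Multi-class discrimination (beyond two classes) is out of scope for
  O-PLS-DA; the ANOVA/post-hoc path covers k-group questions for
  integrals only.
- The synthetic spectra omit misalignment, so the critical-r filter's
  behaviour under peak-position jitter is untested.
- Whether a raw or an adjusted p-value gate "should" be used for DEG
  calling is design-dependent; both are exposed and reported, and no
  default claim is made beyond raw-p gating with BH columns always
  present.
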