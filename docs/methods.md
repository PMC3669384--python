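# Methods

This note documents the models, conventions and numerical choices behind
`metabodiv`, in the order the pipeline runs. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Peak lists and alignment

A sample is a list of `(m/z, intensity, S/N)` peaks from direct-infusion
ESI(+) FT-ICR-MS. On read, peaks below the S/N floor (default 1, the export
threshold of such acquisitions) or outside the acquisition window (default
150–2000 m/z) are dropped; both are configurable. The S/N column is
optional — absent means the list was thresholded upstream.

Direct-infusion data have no retention axis, so alignment is pure mass
binning: all peaks from all samples are pooled, sorted, and the sorted
sequence is cut wherever the gap between consecutive masses exceeds
`tol_ppm × mean(adjacent masses) / 1e6`. This single-linkage rule is
deterministic, order-independent, and equivalent to the transitive closure
of the all-pairs within-tolerance relation (asserted against a union-find
oracle in the tests). The default tolerance of 1 ppm is a safe envelope for
an instrument calibrated below 0.1 ppm: features 2 ppm apart stay separate
while per-sample mass errors of ±0.3 ppm still co-bin. A feature's
consensus m/z is the intensity-weighted mean of its member peaks. If one
sample contributes two peaks to a bin, the more intense (tie: lighter) is
kept and the discard logged.

## Formula assignment

Ion masses are neutralized as [M+H]⁺ / [M−H]⁻ only (proton mass
1.007276466 Da); multiply charged ions and other adducts are out of scope.
Candidate CHNOS formulas for a neutral mass M are enumerated by looping over
the (C, N, O, S) sub-lattice and solving for the hydrogen count from the
mass residual — at sub-ppm tolerances at most one H value can fit, so the
search is exhaustive (verified exactly against a brute-force five-element
grid for 1000 random masses below 500 Da).

Validation rules, in the order reported on failure:

* element bounds C ≤ 100, 0 ≤ O ≤ 80, N ≤ 5, S ≤ 1, C ≥ 1;
* O/C ≤ 1.0 (the conventional upper bound for biomolecular CHNOS
  filtering; configurable);
* RDBE = C − H/2 + N/2 + 1 within [0, 40];
* hydrogen valence cap H ≤ 2C + N + 2;
* nitrogen rule: the parity of the nominal (integer) mass must equal the
  parity of N — for CHNOS this is the same constraint as RDBE integrality.

The assignment tolerance defaults to 0.5 ppm, the usual node-validity
criterion for downstream network analysis. Each feature gets its
lowest-|error| candidate; features with ≥ 2 in-tolerance candidates carry an
`ambiguous` flag. Above roughly 800–1000 Da isobaric CHNOS alternatives
within 0.5 ppm become common and no exact-mass method can separate them;
the flag is the honest statement of that limit.

¹³C isotopologue satellites are removed before assignment: a feature is
discarded when a lighter feature sits 1.0033548 Da below it (±0.001 Da),
the median heavy/light intensity ratio over co-occurring samples is below
1.2 × C × 0.0107 (C from the light feature's formula when available, else
the constraint bound), and — when ≥ 3 samples share both peaks — the two
intensity patterns correlate with Pearson r ≥ 0.5. The ratio cap follows
natural ¹³C abundance with 20 % slack; the correlation floor operationalizes
"co-varies with its parent" and is a package choice (no ratio/correlation
recipe is standard).

## Networks

**Mass-difference network.** Nodes are features with an accepted formula
(|error| < 0.5 ppm). An edge labeled with a transformation (H₂O, CH₂, CO₂,
SO₃, hexose, …) connects two nodes whose mass difference matches that
transformation's exact delta within 0.1 ppm; the ppm denominator is the
larger of the two node masses (a choice that had to be made; configurable).
The shipped list of ~50 transformations has deltas computed from the
monoisotopic element masses, so in noise-free (theoretical-mass) mode edges
are reproducible from formulas alone. All edge sets are verified against an
all-pairs oracle.

**Correlation network.** Samples are nodes; an edge carries Pearson r
between two intensity profiles when r > 0.90 (strictly positive
correlations only). Zero-variance profiles stay isolated with a warning.
A 10×-frequency rule labels features specific to a sample class (a feature
is `specific_to` a class when its occurrence frequency there is ≥ 10× the
mean over other classes).

Raising the edge-formation tolerance never removes mass-difference edges;
raising the correlation threshold never adds edges — both monotonicity
properties are asserted in tests.

## Multivariate modeling and discriminative-metabolite selection

Intensities are modeled on the log₁₀(1 + x) scale: ion counts are
log-normal, and log transformation keeps per-feature variances comparable
across the several orders of magnitude an FT-ICR intensity scale spans.
Before a supervised fit the pipeline (a) keeps only features present in at
least half the samples — direct-infusion data are full of single-sample
chemical-noise peaks that would otherwise dominate the covariance scale —
and (b) imputes remaining zeros as half the feature's minimum positive
intensity, the conventional below-detection-limit treatment. Columns are
then mean-centered and Pareto-scaled (divide by √sd; unit-variance
scaling available).

PLS-DA is NIPALS PLS1 on a ±1 class vector. OPLS-DA removes `n_orth`
(default 1) Y-orthogonal components from X by orthogonal-signal-correction
deflation and then fits one predictive PLS component; with `n_orth = 0` it
reproduces 1-component PLS-DA to machine precision (asserted). The
predictive score's covariance and correlation with each (preprocessed)
feature give the S-plot profiles.

Three selection rules are intersected to call a feature discriminative:

* **VIP ≥ 1** with VIP_j = √(p · Σ_a w²_ja SSY_a / Σ_a SSY_a), which
  satisfies Σ_j VIP²_j = p identically;
* **S-plot rule**: |cov| and |corr| each scaled so their maximum is 100 %;
  keep features with both strictly above 50 %;
* **Wilcoxon** two-sided rank-sum p < 0.05 on raw p — q-values
  (Benjamini–Hochberg) are reported alongside but selection follows the
  raw-p convention to match common chemometric practice for these designs.

The sign of cov(t₁, x_j) (after orienting t₁ to correlate positively with
the class code) splits selected features into "elevated in group A" vs
"elevated in group B".

Statistical support for a partition of samples is assessed by 7-fold
cross-validated Q² of a 1-component PLS-DA predicting the partition labels
(supported when Q² ≥ 0.4) together with a 200-permutation test (p < 0.05,
+1 rule); multi-cluster partitions are tested one-vs-rest and the weakest
contrast decides. No standard criterion exists for "statistically supported
clustering"; these thresholds are the package's documented choice and are
configurable.

## Metabotype OTUs and diversity

Strain profiles (one cellular fraction at a time, preprocessed as above)
are clustered by Ward's minimum-variance method. Merge heights are the
increase in within-cluster error sum of squares (ESS); SciPy's `ward`
linkage reports √(2·ΔESS), so heights are transformed h → h²/2 — a
monotone map that changes neither topology nor relative cuts. The
exhaustive greedy-ESS oracle in the tests pins down this convention
(two 1-D points at distance 2 merge at cost 2).

Cutting the dendrogram at `pct`/100 × (maximal merge distance) yields the
m-OTU partition at that percentage; partitions are nested across
thresholds. Per partition: Shannon–Weiner H = −Σ p_i ln p_i (natural log),
Good's coverage C = 1 − n₁/N (n₁ = singleton m-OTUs, N = strains — strains
play the role of individuals, m-OTUs of species), and analytical
rarefaction E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)] computed with exact
integer combinatorics so that E[S₁] = 1 and E[S_N] = S hold to machine
precision. Along any coarsening grid H is non-increasing and C
non-decreasing; the diversity-profile routine asserts both on every call.
The default report grid is 5–100 % in 5 % steps.

## Fingerprint dendrograms

PFGE band patterns and MALDI-TOF peak lists are position sets compared
under a 1 % relative match tolerance (an FPQuest-style band tolerance;
greedy one-to-one matching of sorted positions). Dice similarity
2|A∩B|/(|A|+|B|) with UPGMA agglomeration is the PFGE default; matched-peak
percentage |A∩B|/max(|A|,|B|) with single linkage is the MALDI default.
Dendrogram heights are dissimilarities 100 − S, verified against a
brute-force average-linkage oracle.

## Synthetic data generator

The generator plants a metabolome with the statistical structure the
analysis assumes and emits peak lists the I/O layer reads like real data.

* **Formulas** are rejection-sampled from the valid CHNOS lattice: carbon
  6 + Gamma(2.2, 8) capped at 70 — a right-skewed small-metabolite profile
  (median composition ≈ C20, ≈ 400 Da) with a lipid/oligomer tail, matching
  typical ESI(+) metabolome mass distributions; hydrogen is set as
  H = 2C + 2 + N − 2·RDBE with RDBE drawn 0–20, which makes every draw
  satisfy the nitrogen rule by construction; N is drawn 0–5 (weighted
  toward 0), S present in 8 % of formulas, O uniform up to the O/C bound.
  Every formula passes the default constraint set and lands inside the
  150–2000 m/z window after protonation.
* **Design**: a shared core metabolome plus per-group accessory formulas
  whose mean intensity is elevated by `effect_size_sd` (default 2) noise
  standard deviations in that group's strains. The default truth sizes
  mirror the intracellular old-vs-new contrast of the motivating study
  design: 5332 core + 274 "old"-elevated + 136 "new"-elevated = 5742
  formulas; cluster designs use group-proportional accessory sets. The
  default study layout is two sites of new isolates plus shared reference
  strains, three cellular fractions.
* **Noise**: observed m/z = (M + m_proton)(1 + ε) with
  ε ~ N(0, 0.1 ppm) (calibration below 100 ppb); intensities log-normal
  with CV 5 % (routine intensity repeatability); core features drop out
  per strain with probability 0.02; 50 spurious peaks per sample, uniform
  in the window but ≥ 3 ppm from any truth mass; optional ¹³C satellites
  at +1.0033548 Da with ratio 0.0107 · C.
* **Reference table**: 15 % of formulas receive synthetic
  metabolite/pathway/class labels drawn from a six-class vocabulary with a
  configurable skew (lipid metabolism heaviest by default).

All randomness flows from one `numpy` seed; identical seeds reproduce
identical truth sets and peak lists bit for bit.

**What the generator does not emulate** — and what passing tests therefore
do not establish about real data: correlated (batch/drift) mass error,
intensity covariance between metabolites of one pathway, adduct and
in-source-fragment chemistry beyond ±H, detector saturation, and
presence/absence structure richer than independent dropout. Recovery rates
on synthetic data are upper bounds for instrument data.

## Problem sizes in the shipped checks

The acceptance script and tests run the pipeline at sizes chosen to
exercise the full design while keeping runs interactive: the old-vs-new
recovery at the full 5742-feature / 40-strain design, formula recovery at
500 formulas × 4 strains, m-OTU recovery at 998 features × 24 strains in
4 planted clusters, enumeration-oracle agreement at 1000 random masses
below 500 Da, networks at ≈ 100 nodes. The published feature tallies from
the motivating study derive from unreleased instrument data; the package
reproduces their percentage arithmetic from the printed counts and
validates everything else by construction on synthetic truth.

## Known limitations

* Exact-mass annotation cannot separate isobars/isomers; multi-isomer
  annotations are all retained and flagged rather than resolved.
* OPLS-DA handles two classes; multi-class contrasts are run pairwise or
  one-vs-rest.
* The Wilcoxon selection follows the raw p < 0.05 convention; with
  thousands of features this admits false positives by design, which is
  why selection intersects three rules.
* Ward clustering input metric (Euclidean on preprocessed log intensities)
  is a convention; other metrics change m-OTU boundaries.
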