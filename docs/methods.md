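# Methods

This note documents the models, defaults and design choices behind
`mzsift`, the way a simulation or statistics package documents its
internals: what each stage assumes, which knobs matter, what the synthetic
data does and does not emulate, and where the genuinely open choices were
made.

## Study design being emulated

An in vitro metabolism experiment with pooled human liver microsomes:
three incubation groups at 0 µM (Blank), 12.5 µM (Low) and 25 µM (High)
substrate, five replicates each. A pooled QC sample (equal aliquots of all
fifteen incubations) is injected five times at the start of the analytical
sequence and once after every fifth sample to track instrument
sensitivity. A separate pair of duplicate control incubations supports
feature identification: a *substrate blank* (microsomes, no substrate) and
an *enzyme blank* (substrate, no microsomes). Injection order of the
non-QC samples is randomized.

## Mass arithmetic (`chem`)

Monoisotopic masses are sums of lightest-isotope IUPAC masses (NIST table
via pyteomics, ≥ 6 decimals). Ion m/z uses the proton mass 1.00727646 Da
for protonation and deprotonation alike and neglects electron mass — for
singly charged small molecules this stays well inside the 5 ppm matching
tolerance used everywhere downstream (Orbitrap data printed to 4 decimals
is typically good to ~2 ppm). Charge states above 1, isotope fine
structure and MS² prediction are out of scope.

The biotransformation catalogue stores signed element deltas, never bare
mass numbers; each rule's mass delta is recomputed from its delta on
demand, so catalogue and masses cannot drift apart. Metabolic shifts:
dihydro- (+H₂, carbonyl reduction), HO- (+O), di-HO- (+2O), oxo-
(+O −H₂, lactam formation), dihydro-HO-, dihydro-oxo- (net +O), oxo-HO-,
N,N-dealkyl- (−C₄H₆, pyrrolidine ring loss). Non-metabolic shifts seen in
electrospray work: dehydro- (−H₂), water loss (−H₂O), imido- (+NH −O),
and cyano- (+CN −H, acetonitrile chemistry). Note that dihydro-oxo- and
HO- are mass-degenerate (+O); disambiguation is evidence-based, not
mass-based (see Annotation).

Feature names follow the "M" + rounded m/z + "T" + retention time in
seconds convention. Rounding is half-up; the convention's source only says
"rounded", and the single printed example does not discriminate, so
half-up was chosen and is stated here.

## Synthetic data (`simulate`)

Each planted species contributes a Gaussian chromatographic profile whose
intensity integrates to the planted abundance (area units), sampled on a
uniform scan grid (default 0.5 s over 0–700 s, so the 60–600 s retention
filter is exercised on both sides). Per species: ¹³C isotopologues at
+k × 1.003355/z with M+1/M = n_C × 0.0107 and a binomial M+2 term;
centroid m/z jitter ~ Normal(0, 1 ppm); a linear multiplicative
sensitivity drift (1 + rate × injection index, default −0.4 %/injection,
matching the linear model the correction stage fits); biological
variability (log-normal, CV 5%) on incubation replicates and technical
variability (CV 2%) on every injection.

The default scenario plants an alpha-PBP-like parent (C₁₄H₁₉NO, [M+H]⁺
218.1539, RT 216 s, base area 5 × 10⁶) with dose multipliers 0/1/2×; five
metabolites at catalogued shifts (4–15% of the parent's abundance) with
multipliers 0/1/1.8× — the sub-proportional High response emulates mildly
saturating metabolite formation; a co-eluting dehydro in-source artifact
and a chloride dimer adduct [2M+2H+Cl]⁺ that track the parent; a dehydro
impurity eluting elsewhere (present wherever the powder is, including the
enzyme blank); and 200 dose-independent background species (log-normal
areas, median 8 × 10³ — the parent exceeds every background species by
well over 100×). The pooled QC's composition is the arithmetic mean of the
three group multipliers, so QC ≈ Low for dose-responsive species.

Noise has three components: (i) additive noise centroids at uniform random
m/z (Poisson 15/scan, log-normal intensities around 30); (ii) m/z jitter;
and (iii) a *carryover/chemical-background* term — faint centroids at
every analyte ion channel in every run (Bernoulli 0.25/scan). Component
(iii) is what gap-filling integrates in samples that genuinely lack an
analyte; without it a 5 ppm reintegration window in a blank would almost
never contain a uniform-random noise centroid and blank abundances would
be structurally zero, which real reintegration-based pipelines do not
show. The area-equivalent noise floor is defined as the noise intensity
integrated over a nominal 10 s window (default 300 area units).

Not emulated: retention-time shifts between runs (so no RT warping is
needed or provided), profile-mode peak shapes, chimeric MS², detector
saturation, and any real retention model — RT values are free parameters.
Consequently, passing tests demonstrate the *logic* of the workflow
(filter correctness, drift removal, annotation reasoning), not robustness
to chromatographic misalignment or matrix effects in real data. Raw
intensity scales are arbitrary; no instrument publishes its units either.

## Peak detection (`peaks`)

The picker is a deliberately transparent stand-in for externally optimized
tooling, with every parameter in the configuration: greedy ROI tracing (a
centroid joins an open ROI within 5 ppm of its running mean m/z; ROIs idle
for > 5 scans close; ROIs with < 5 occupied scans are dropped), Gaussian
smoothing (σ = 1.5 s), local-maxima detection with SNR ≥ 5 against a
robust baseline (1.4826 × MAD of the smoothing residual — a plain MAD of
an ROI trace would be biased because the trace is mostly peak), peak
bounds at the nearest local minima or where the trace falls to 0.5% of the
apex (long near-zero tails are not width), width within [2, 60] s,
trapezoidal areas.

Features are single-linkage groups of per-sample peaks, implemented as
sequential gap-splitting: sort by m/z and split where neighbours are more
than 5 ppm apart, then within each m/z block sort by RT and split at gaps
over 10 s. This is exactly single linkage with per-axis thresholds,
deterministic (peaks are pre-sorted by sample id and apex RT) and
O(n log n). Per-sample duplicates keep the larger area. Name collisions
after rounding (two features both rounding to "M218T216") get a numeric
suffix.

Gap-filling integrates each feature's consensus RT window in every sample
without a member peak and flags the value as filled. In blanks this
integrates carryover/background — deliberately, since that reintegration
behaviour is what makes blank groups highly variable downstream.

## Statistics (`stats`)

Order of operations is fixed and deliberate: fold changes and Welch
t-tests are computed on **raw** abundances (zeros included), the filter is
applied, and only then are zeros replaced and abundances log₁₀-transformed
— the transformation step follows filtering in the procedure being
reproduced. Whether the original tests ran on raw or log abundances is
not stated there; raw follows from the stated ordering and a config
switch covers the alternative.

Signed fold change: r = mean_b/mean_a reported as r if r ≥ 1 else −1/r, so
"< −1.5 or > 1.5" is symmetric. Degenerate cases: both means 0 → NaN
(never passes); a = 0, b > 0 → +∞ (passes any FC threshold; the p-value
still gates); b = 0 → −∞. A feature survives if |FC| > 1.5 **and**
p < 0.001 in the *same* comparison ("a corresponding p-value"), and its RT
lies in [60, 600] s inclusive (the exclusion wording removes only strict
violations). The filter is monotone in both thresholds by construction.

Welch's test uses the unequal-variance statistic with Welch–Satterthwaite
degrees of freedom (scipy); the test suite checks it against a literal
transcription of the formulas to 1e-10 and verifies the empirical type-I
rate at α = 0.001 over 100,000 null draws. No multiple-testing correction
is applied by default — the raw p < 0.001 gate is the procedure being
reproduced; Benjamini–Hochberg is available behind an off-by-default
flag. Zero replacement uses the single global minimum positive abundance
of the table (surrogate LOD), not per-feature minima.

## Drift correction (`drift`)

For every feature detected (pre-fill, nonzero) in *all* QC injections, an
ordinary least-squares line of log₁₀ abundance on injection index is
fitted on the QC samples only, and the fitted trend is subtracted from all
samples ("extrapolating" the QC trend across the sequence), then
re-anchored at the QC mean so values keep their scale. Features failing
the every-QC criterion pass through bit-identical. The source wording
("linear model to extrapolate its abundance drift between QC samples") is
ambiguous between one global line and segment-wise interpolation between
QC pairs; both are implemented, the single line is the default. QC
injections with gross sensitivity loss (total intensity beyond 5× from the
median QC) are flagged by the diagnostics and can be excluded manually via
configuration — exclusion is flag-driven, never automatic, mirroring how
such runs are handled in practice.

## Multivariate diagnostics (`mva`)

PCA is the SVD of the column-centered samples × features matrix, full
rank, variance percentages summing to 100, component signs fixed by making
each component's largest-magnitude loading positive (for testability).
The multivariate stage operates on the statistical sequence only
(incubation replicates + QCs); the blank identification runs are evidence
for annotation, not part of the pattern analysis. t-SNE uses perplexity 5
(≈ group size), PCA initialization and a fixed seed — the reference
workflow reports none of its hyperparameters, so only qualitative
reproduction is claimed (group separation; QC embedding near the Low
group because the pool approximates the mean composition). Hierarchical
clustering z-scores each feature across samples (dropping zero-variance
features with a record), then applies complete-linkage Euclidean
agglomeration to samples and features; distance and linkage are exposed in
the configuration since the source does not state them.

On the default scenario these diagnostics reproduce the expected
phenomenology: PC1 carries > 95% of the variance (all significant features
track the dominant parent, i.e. high collinearity), blanks form their own
cluster, and their within-group variance for substrate-derived features
exceeds the dosed groups' (gap-filled noise).

## Annotation (`annotate`)

Precedence: isotopes > adducts > blank-evidence classes > metabolite >
isomer linking — so a ¹³C satellite can never be claimed by a
transformation rule. Isotope satellites require the +k × 1.003355 spacing
within 5 ppm (k ≤ 2), co-elution within 5 s, lower mean abundance than
the anchor, and, when the anchor's carbon count is known, an M+1/M ratio
within a factor 2 of n_C × 0.0107. Remaining features are matched against
the adduct catalogue (applied to the parent's neutral mass) and the
transformation catalogue (applied to the parent ion); the best |ppm| wins
and a second rule within 1 ppm is reported as ambiguous — the
mass-degenerate HO-/dihydro-oxo- pair always ties and is flagged.

Origin ladder for transformation-matched features, ties resolved in this
order: (1) co-elutes with the parent (|ΔRT| ≤ 5 s) → in-source artifact;
(2) present in the enzyme blank but not the substrate blank → powder
impurity; (3) present in the substrate blank → contaminant/background;
(4) absent from both blanks and dose-responsive → metabolite. "Present"
means mean blank abundance above 3× the noise floor (configurable);
"dose-responsive" means passing the significance filter with a positive
Blank→High fold change. Missing blank runs yield "undetermined", never a
guess. Features matching the same rule at retention times more than 10 s
apart are cross-linked as isomers, numbered by ascending RT; this single
mechanism covers positional isomers, diastereomers and parent conformers,
since distinguishing them properly needs MS², which is out of scope.

## Numerical and engineering choices

- Default tolerances: 5 ppm m/z everywhere, 10 s RT for grouping/ledger
  matching, 5 s for co-elution claims.
- All randomness flows from a single seed: the study seed derives per-run
  generator seeds; t-SNE has its own fixed seed in config. Identical
  configuration gives byte-identical CSV outputs.
- CSVs are comma-separated UTF-8 with "." decimals; report tables print
  m/z to 4 decimals (table style of the field) while full precision is
  retained internally.
- Degenerate inputs are rejected loudly: empty scan grids, all-zero
  tables, < 3 QCs, missing groups (named in the error), zero ion charge,
  unknown element symbols (offending symbol named), malformed width
  bounds, too-large perplexity.
- Problem sizes: the default synthetic study (27 runs × 1401 scans,
  ~200 background + ~30 analyte ion species per run) runs the full
  pipeline in well under a minute on one CPU; the test suite completes in
  a few minutes.

## Known limitations

- The peak picker is intentionally simple; it does not reproduce any
  specific external picker's parameterization, and its recall guarantees
  are demonstrated only on the synthetic scenario.
- One mass-degenerate transformation pair (HO- vs dihydro-oxo-) cannot be
  resolved without MS² or retention modelling; the annotation reports the
  ambiguity rather than resolving it.
- The isotope ratio gate assumes a known carbon count only for features
  linked to the parent; background features carry no formula.
- Negative-mode chemistry is representable (deprotonated species) but the
  default scenario is positive-mode only, as the bulk of the reference
  observations are.
- The M+2 satellite of chlorine-containing adducts is dominated by ³⁷Cl
  (+1.99705 Da), not ¹³C₂ (+2.00671 Da). The isotope annotator models ¹³C
  spacing only (as does the simulator), so a real ³⁷Cl satellite would
  fall outside the ¹³C₂ tolerance and remain unknown rather than be
  mislabeled. The chemistry module exposes the ³⁷Cl spacing constant for
  mass checks.
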