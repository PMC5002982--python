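# Methods

## Stimulus geometry

Stimuli live in CIE 1976 (u′, v′) chromaticity space. The monitor gamut
is a triangle with CRT-like primaries (configurable); the adapting gray
point defaults to D65. Hue is the four-quadrant angle of
(u′ − gray_u, v′ − gray_v), kept in [0, 360); all angular differences
are wrapped to (−180, 180].

Two saturation measures are attached to each stimulus. The CIELUV
ratio divides the gray-to-stimulus distance by the gray-to-spectrum-
locus distance along the same ray; the locus is a coarse 15-vertex
polyline approximating the published shape of the u′v′ spectral locus
(only the ratio matters, and unit tests use synthetic loci). The
cone-opponent measure is the Euclidean distance from gray after a
linear map of (u′, v′) offsets; an exact CIE→MB-DKL conversion needs
the monitor primaries' spectra, so the matrix is a configuration input
with a documented qualitative default.

The generated default set holds 45 hues per luminance class (0.62,
3.05, 7.8 cd/m², classes low/equi/high), all on the gamut boundary.
Base angles carry a mild irregularity — gaps shrink toward the
primaries — but keep a floor of twice (filler offset + triplet
tolerance), ~7.2°. Seventeen designated anchor hues are reproduced in
every class within ±0.9°; the remaining hues are displaced by slightly
more than the 3° triplet tolerance, with opposite signs in the low and
high classes. This makes the hue-matched triplet search return exactly
the 17 anchors, provably, for any seed. Real stimulus sets oversample
the primaries much more strongly; the floor is the price of a
deterministic triplet count, and the saturation confound (which is
what drives the interesting model behavior) is carried entirely by the
triangle geometry, not by the sampling density.

The 21-hue "evenly spaced" subsample is chosen per class by a globally
greedy assignment of stimuli to 21 equally spaced target angles
(smallest circular deviation first, no stimulus reused). Hue-matched
triplets are found greedily by ascending anchor hue, taking the
tightest available completion; each stimulus joins at most one triplet.

## Tuning model and fitting

The tuning curve is a truncated raised cosine:
r(θ) = fmin + fmax·cos²(π·Δ/(2w)) for |Δ| < w, else fmin, with
Δ = θ − α wrapped circularly. The half-maximum falls exactly at
Δ = w/2, so w is the FWHM; w = 180° is a linear (cosine) cell. The
printed-form ambiguity of the truncation condition is resolved by
treating the FWHM identity as normative.

Responses at the 21 subsampled hues are optionally smoothed by a
3-point circular boxcar (±1 stimulus; the narrower 2-point reading of
"across one stimulus" is rejected because it shifts the curve by half
a bin). Fitting is bounded nonlinear least squares (trust-region
reflective) with a deterministic multi-start grid — an α start at each
sampled angle plus width starts {60, 100, 180, 300} at the empirical
argmax — so fits involve no RNG. Bounds: w ∈ [36°, 360°] (the lower
bound, two inter-stimulus gaps, prevents delta-like overfits),
fmax ≥ 0. R² is 1 − SSres/SStot against the (smoothed) responses.
Flat response vectors are returned as fmax = 0 fits flagged
unreliable rather than errors.

Response windows for trial-level data follow a latency rule: the
window opens at the first time bin exceeding baseline + 2.5 SD and
closes when the rate falls back below that threshold or at
stimulus duration − latency/4, whichever is earlier.

## Synthetic populations

Three generator kinds emulate the recorded cell classes' phenomenology;
their defaults are the package's standing study conditions:

* glob — widths ~N(95°, 20°) clipped to [50, 200] (median fitted width
  ≈ 90–105°), cross-luminance peak jitter SD 4°, balanced mean gains
  across luminance classes, drive fmax ∈ [20, 45] Hz over baseline
  fmin ∈ [1, 5] Hz;
* interglob — widths ~N(125°, 30°), peak jitter SD 25°, mean gains
  favoring luminance contrast (1.25, 0.7, 1.25 for low/equi/high), and
  deliberately weak modulation (fmax ∈ [8, 20] Hz over fmin ∈ [4, 10]
  Hz). The weak modulation, not the width alone, is what degrades this
  population's tuning-fit quality and representational geometry — a
  noiseless broad cosine population actually correlates near-perfectly
  with angular distance;
* lgn — width exactly 180°, peaks 28% uniform / 72% within ±5° of the
  cardinal angles.

Every kind draws per-neuron multiplicative gain jitter (SD 0.3, LGN 0)
per luminance class, so individual cells can prefer any class even when
population gains balance; this is what makes luminance decodable from
glob-like populations while their mean AUC stays at chance. Model-cell
responses are the tuning curve evaluated at the stimulus hues,
multiplied by stimulus saturation, min-max normalized. Trial noise is
Poisson on spike counts in a 200 ms window (Gaussian and noiseless
options exist for analytic tests). All generators are deterministic
under their seed.

What the generator does not emulate: real spike-train dynamics
(latency, adaptation, OFF responses), correlated noise across neurons,
eye movements, rod intrusion at mesopic luminance, and the much
stronger primary-oversampling of real maximally saturated stimulus
sets. Passing tests therefore validate the analysis chain, not claims
about any animal's cortex.

## Narrowness × uniformity grid search

For each grid cell (width, fraction-uniform), model populations are
simulated repeatedly: peaks drawn uniformly over integer degrees with
probability fraction-uniform, otherwise within ±5° of a family angle
(cardinal or unique-hue). Model cells and the recorded population are
each rank-ordered by peak response angle (ties broken by neuron index)
and compared pairwise by R², by default the squared Pearson correlation
between the model cell's normalized 45-hue tuning function and the
recorded neuron's raw 45-hue responses (a regression-R² variant is
available; min-max normalization leaves the Pearson form unchanged).
The cell statistic is the median R² over iterations × pairs. When the
recorded population is larger than the model count, it is re-subsampled
per iteration. Negative R² values (possible under the regression
definition) are retained raw and floored at zero only for heat-map
display.

Identifiability limits, found empirically and worth knowing:

* With saturation scaling on, broad model cells (w ≳ 120°) collapse
  their peak responses onto the high-saturation gamut apices regardless
  of α. Rank-ordering then ties massively, pairing degrades, and the
  uniformity fraction of a planted population is not recoverable — an
  all-cardinal model can outscore the planted all-uniform one. This is
  the same saturation confound the model exists to illustrate.
  Parameter-recovery tests therefore run in the saturation-ablated
  regime (saturation ≡ 1 for both populations), where recovery is clean.
* A planted 28%-uniform cardinal population is indistinguishable from
  0%-uniform by the median statistic at n = 60 (the median pair is
  cardinal either way); recovery tests span fractions upward from the
  planted value. Width recovery is unaffected by either limit.
* Desk-scale grids (5 × 4 cells, 50 iterations, 60 neurons) are used
  throughout the tests; they recover planted cells reliably while a
  full grid (24 widths × 5 fractions × 1000 iterations) remains
  available through the library and CLI.

## Luminance statistics

AUC is computed by the rank identity (normalized Mann–Whitney U, ties
counted ½), mathematically equal to criterion sweeping. Rates are
z-scored per neuron over the full 135-stimulus set first. Significance:
2000 label shuffles, cell significant at p < 0.05 when its AUC leaves
the null's 2.5–97.5 percentile band. Calibration of this rule's type-I
error (and of the warm/cool test below) is asserted at 3–7% in the
test suite.

Peak angles from different luminance classes are compared after
aligning the second peak to within a half turn of the first
(e.g. reference 10°, other 355° → −5). Pearson correlations of aligned
peaks are bootstrapped over random halves of the population drawn
without replacement (the with/without choice is undocumented in the
field; without replacement avoids duplicated cells in a half-sample).
Note an inherent property of align-then-correlate: independent uniform
peaks yield r → 1/√2, not 0, because alignment bounds each difference
to ±180°; the procedure is meaningful for comparing populations, not
as an absolute null. Population comparisons t-test the Fisher-z
transforms of two bootstrap distributions, reporting the median p over
replicates with percentile CIs; because bootstrap halves of one
population are not independent samples, even small true differences
produce extreme p values — an inflation inherent to the procedure.
Per-hue-bin peak shifts (8 bins of 45°, binned by the brighter class's
peak) use Mann–Whitney U on aligned values over 2000 bootstraps of 90%
of cells, reporting mean p per bin; bins under 3 cells are skipped.

## Representational geometry

Neural RDMs are 1 − Pearson correlation between stimulus response
vectors after per-neuron z-scoring (full-set or per-luminance-set
convention as required); stimuli whose vectors have zero variance
across neurons are dropped listwise. The reference RDM is circular
hue-angle distance (∈ [0, 180]).

MDS minimizes Sammon stress, Σ(d−δ)²/d normalized by Σd over pairs,
with analytic gradients under L-BFGS-B, starting from the classical
(Torgerson) solution plus seeded random restarts; zero off-diagonal
dissimilarities are floored at a small epsilon to keep the weights
finite. Metric Sammon minimization was chosen over a rank-order
variant because the error function is named explicitly in the
tradition this follows; convergence uses scipy defaults with
ftol 1e-12. Embeddings are compared only through their distance
matrices (rotation/translation invariant).

RSA correlates the lower triangles of a neural and reference RDM after
intersecting labels; the p-value is two-tailed on z = atanh(r) with
SE 1/√(m−3) over m retained pairs. Paired population comparisons
t-test atanh-transformed bootstrap correlation distributions.

## Decoding

Responses are z-scored per neuron jointly across the 51 hue-matched
stimuli (the per-class variant exists behind the same surface). Hue
generalization: for each of the C(17,2) = 136 hue pairs, a linear SVM
(scikit-learn LinearSVC, C = 1, squared hinge) trains on the 4 points
of two luminance classes and is tested on the held-out class's 2
points. Luminance generalization: train on 15 hues × 2 classes (30
points), test the held-out hue pair's 4 points. No additional scaling
is fit per problem. Chance is 50% by construction; the permutation
null shuffles training labels only (within-problem, preserving class
balance and the generalization structure) and reports the add-one p,
floored near 1/n_perm. Population-size effects use random neuron
subsamples; paired accuracy comparisons use McNemar's exact two-tailed
test on discordant counts.

## Selectivity and warm/cool bias

Selectivity (1 − min/max) and sparseness
([1 − (Σr/n)²/(Σr²/n)]/(1 − 1/n)) are computed on raw mean rates to
the 17 hue-matched stimuli of the low- and high-luminance sets. Gates
are strict: selectivity > 0.6 on either set to be retained, sparseness
> 0.3 on either set for "sharp", else "broad". The warm arc defaults
to hue angles 320°–90° (pink through yellow) and the cool arc to
100°–300° (green through violet); the Munsell boundary hues are not
printed as CIELUV angles anywhere authoritative, so both arcs are
configuration constants. The permutation null assigns each cell one of
the 45 stimulus angles uniformly; p is the fraction of null
populations whose warm:cool ratio reaches the bootstrap population's,
averaged over 2000 bootstraps of 90% of cells, floored at 1/n_perm;
a cool count of zero switches the comparison to warm counts.

## Pipeline and reproducibility

`pipeline.run_all` derives a deterministic child seed per stage from
the master seed (SHA-256 of "seed:stage"), so any stage can be rerun in
isolation and the full bundle is byte-identical under a fixed
configuration. Outputs carry the config hash and seed. Desk-scale
defaults (120 neurons, 50 grid iterations, 500 permutations) complete
in minutes on one core; full-scale counts (300/181 neurons, 1000
iterations, 2000 permutations) are plain configuration changes.
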