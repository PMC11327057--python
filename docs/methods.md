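# Methods

## The model

`qppdyn` analyzes resting-state BOLD recordings as superpositions of a few
large-scale quasiperiodic patterns (QPPs): recurring whole-brain events in
which regions activate and deactivate cyclically with systematic timing
offsets (propagation). The decomposition used is complex PCA of the analytic
signal. Each location's demeaned series x(v, t) is lifted to

    a(v, t) = x(v, t) + i · H[x(v, ·)](t),

with H the Hilbert transform computed in the frequency domain (negative
bins zeroed, positive bins doubled, DC and Nyquist untouched). The SVD
X = U S Vᴴ of the timepoints × locations complex matrix yields, per
component, a spatial loading whose modulus is the pattern's magnitude map
and whose argument is a per-location phase lag (the propagation structure),
and a temporal score U·S whose modulus is the pattern's instantaneous
strength and whose argument is the position in the pattern's cycle.
Explained-variance ratios are s²ₖ / Σ s². Scores are defined as U·S rather
than U so that |score| carries amplitude, which the downstream magnitude
statistics require.

Because each component's global phase is indeterminate, it is fixed so that
the largest-magnitude loading entry is real and positive; results are then
reproducible bit-for-bit.

### Varimax rotation

After extraction the components are rotated toward simple structure by
maximizing the varimax criterion evaluated on squared loading magnitudes,

    f(R) = Σₖ Var_v( |(L R)(v, k)|² ),   R unitary,

using pairwise Kaiser-style sweeps. The pair rotation is a planar *unitary*
rotation — a real angle θ plus a relative phase δ between the two columns.
The phase freedom is not a refinement but a necessity: between
near-degenerate singular values the SVD mixes components with an arbitrary
complex phase, and a purely real rotation cannot undo a complex mixing (on
planted data, real-rotation varimax left sparse pattern pairs visibly mixed
— loading correlation ≈ 0.92 and envelope correlation as low as 0.53 —
where the unitary rotation recovers ≥ 0.99 and ≥ 0.8). For any fixed δ the
squared magnitudes |a cosθ + e^{iδ} b sinθ|² depend on θ exactly as in
classical real varimax with u = |a|² − |b|² and v = 2 Re(a·conj(b)·e^{−iδ}),
so Kaiser's closed-form optimal angle applies; δ is searched on a grid with
local refinement, and δ = 0 is always a candidate, so the procedure reduces
to the textbook pairwise algorithm for real loadings. A pair rotation is
applied only if it improves the criterion, so the rotated solution never
scores below the unrotated one. An earlier design computed the rotation by
running real varimax on the stacked real/imaginary parts; that optimizes a
different objective (variance of squared stacked entries), offers no
non-decrease guarantee for the magnitude criterion, and shares the real
rotation's inability to unmix complex-phase mixings.

By default the criterion is evaluated on variance-weighted loadings —
columns scaled by their squared singular values, i.e. by component
variance. Unweighted varimax treats every orthonormal loading column
equally, and a spatially flat high-variance component — precisely the
global-signal pattern — is then dismantled into other directions because
flat columns minimize the simplicity criterion. Amplitude weighting
(singular values to the first power) proved insufficient: on roughly half
of the simulated cohorts the rotation still tilted the global pattern into
noise directions (planted-map correlations down to 0.72). Variance
weighting suppresses that quartically while leaving pairs of comparable
strength — the ones that genuinely need unmixing — unaffected, and
restored planted-map correlations ≥ 0.99 across all seeds tested. It is
configurable (`weight_by_variance=False` gives the unweighted criterion,
which the rotation-recovery tests use).

Scores are rotated with the same unitary matrix, so scores·loadingsᴴ is
unchanged; components are re-sorted by rotated-score variance and
re-phase-fixed.

### Retention and states

The number of retained components comes either from an explicit override
(the human analyses in this literature fix k = 3) or from a scree elbow
rule: the point of maximum perpendicular distance to the chord joining the
first and last scree points, ties toward smaller k. Each timepoint is then
labelled with the retained component of largest score magnitude (ties to
the lower index). With the "all" dominance pool, timepoints won by a
non-retained component are labelled "other", which makes per-state
incidences sum below one — the behavior consistent with published cluster
incidence tables that do not reach 100%. Incidence = fraction of timepoints
per state; carpet matrices, first/last segment magnitude summaries, paired
t-tests, k-means subject clustering (silhouette-selected k), Bonferroni
correction and one-way within-subject repeated-measures ANOVA complete the
statistical layer. The RM-ANOVA uses the standard decomposition
SS_total = SS_subjects + SS_conditions + SS_error with
F = MS_cond/MS_error on (c−1, (c−1)(s−1)) degrees of freedom and no
sphericity correction.

## Preprocessing

Nuisance regression and bandpass are one projection, mirroring AFNI
3dTProject semantics: Legendre polynomials of order 0..polort, the six
motion parameters when provided (no derivatives), and a sine/cosine pair
for every DFT frequency strictly outside the passband (cosine only at
Nyquist) are orthonormalized, and the data are replaced by the projection
residual. This makes filtering idempotent and residuals exactly orthogonal
to everything removed — testable contracts an IIR filter does not provide.
Band edges are inclusive. Defaults: passband 0.01–0.1 Hz for the human-like
path (TR 0.72 s), 0.01–0.25 Hz for the rodent-like path (TR 2 s),
polort = 2.

Optional Gaussian spatial smoothing operates on a rectangular grid
embedding with symmetric boundaries (mean-preserving); it defaults to off
for matrix inputs. Per-location z-scoring to unit variance is the default
for the human-path workflow (standard practice before PCA); the rodent-path
workflow runs on raw amplitudes, matching preprocessing chains that apply
only motion regression and bandpass. This is not cosmetic: z-scoring
rescales each location by its total SD, so for patterns with disjoint
spatial supports it equalizes amplitudes across patterns and distorts
dominance in low-noise data (see "What the generator shows" below).

QC measures follow the conventional definitions: tSNR = temporal mean /
temporal SD per location (meaningful only on un-demeaned data; a warning is
raised otherwise), global signal = frame-wise mean over the mask, and
framewise displacement FD(t) = Σ|Δtrans| + r·Σ|Δrot| with default head
radius 50 mm (human) or 5 mm (rodent) — radii are conventions, not
measurements, and are configurable.

## The synthetic generator

Real HCP and rodent recordings cannot be redistributed, so every claim the
tests make is established on synthetic data with planted ground truth. The
signal model is the family complex PCA is designed to recover:

    y(v, t) = Σₖ aₖ(t) · mₖ(v) · cos(2π fₖ t + φₖ(v)) + ε(v, t).

* `make_pattern_library` plants K patterns: pattern 1 near-uniform positive
  with a shallow linear phase gradient (the global-signal analogue);
  patterns 2..K are pairs of narrow anti-phase blocks (offset π, linear
  phase gradient inside each block) on mutually disjoint supports. Because
  magnitude maps are nonnegative, near-orthogonality against a uniform map
  forces sparsity: block supports cover ~2.4% of locations, giving pairwise
  |cosine| ≤ 0.2 by construction. Maps are unit L2-norm so envelopes
  directly set score amplitudes.
* Carriers default to 0.03/0.05/0.08 Hz (0.03/0.07/0.11 Hz for TR 2 s),
  distinct and inside the analysis band, making components spectrally
  separable. The sinusoidal carrier is a modeling choice — real QPPs are
  only quasi-periodic; nothing downstream depends on exact periodicity
  beyond the narrowband assumption under which |score| tracks the envelope.
* Envelopes are constant, linear ramps, or piecewise-constant. The
  two-group cohort plants the within-scan drift design: group "ramp" has
  the global pattern's envelope rising 0.5→1.5 at pattern 2's expense
  (1.5→0.5); group "constant" keeps a fixed graded mixture (1.2/1.0/0.8).
  A 5% multiplicative per-subject amplitude jitter creates between-subject
  variability. SNR (planted-signal variance / noise variance) defaults
  to 1; noise is white by default, with a 1/f-shaped option.
* Condition recordings translate per-condition mixture weights into
  dominance-block envelopes: the scan is cut into 20-frame blocks, each
  assigned a dominant pattern (amplitude 1.5 vs 0.5) by largest-remainder
  quota with randomized tie-breaking — a deterministic tie rule would bias
  block counts toward pattern 1 and plant a spurious condition effect
  under equal weights. Realized dominance fractions are within one block
  of the requested weights.
* `add_nuisance` plants removable confounds: shared polynomial drift, a
  global respiration-like oscillation (warned about if inside the analysis
  passband, where it would not be removable), and a smoothed random-walk
  six-parameter motion trace with motion-coupled signal.

### What the generator shows — and what it does not

Passing tests establish that the implementation recovers exactly the
structure the model plants: amplitude-modulated narrowband travelling
waves with near-orthogonal spatial supports, white/pink noise, and
removable nuisance. Real BOLD differs in ways the generator does not
emulate: hemodynamic response shape and its regional variability,
non-sinusoidal and non-stationary pattern waveforms, spatially correlated
physiological noise, overlapping pattern supports, and real motion/field
interactions. Recovery numbers here are therefore upper bounds on, not
estimates of, performance on real recordings.

Two generator-driven findings shaped the defaults. First, per-location
z-scoring erases amplitude dominance when patterns have disjoint supports
and noise is low (each pattern's locations are rescaled by that pattern's
own amplitude), which is why the rodent-path workflow and the noise-free
validation run on raw amplitudes. Second, the projection filter has edge
transients whenever its regressors are not exactly orthogonal to the
planted signal — both for carriers off the scan's DFT grid (leakage into
the stopband pairs) and for the Legendre detrending columns (never
orthogonal to a finite cosine); the transients are a few frames wide but
can flip the state argmax at scan boundaries. The noise-free
exact-recovery validation therefore places carriers on the DFT grid inside
the passband and uses polort = 0 (noise-free data has no drift to remove),
making the projection exactly the identity on the planted signal. At
SNR ≈ 1 neither effect is material.

## Workflows and numerical choices

Workflow A (within-scan drift): preprocess each subject → concatenate along
time → decompose (10 components, varimax, retain 3) → per-timepoint states
→ incidence, first/last segment summaries (defaults 200/200 frames) →
paired t per component → k-means on 2K subject features (per-component
magnitude mean and SD, in that order), silhouette-selected k over {2, 3, 4},
50 restarts, features z-scored (means and SDs live on different scales).
Workflow B (cross-condition): preprocess each subject × condition recording
→ concatenate everything so all conditions share one pattern definition →
decompose → split scores per cell → subject × condition × component
incidence and mean magnitude → RM-ANOVA per component and
Bonferroni-corrected paired t between two named conditions.

The analytic signal is computed per recording before concatenation, so the
frequency-domain Hilbert construction never wraps across recording
boundaries; boundaries are recorded so scores split back exactly.
Per-recording standardization before stacking is configurable (on for
workflow A, off for workflow B, as above). Degenerate inputs fail loudly:
zero-variance locations inside the mask, missing repeated-measures cells,
zero-variance paired differences, rank-deficient projection bases and
components beyond numerical rank all raise errors naming the offender.

Validation experiment sizes (chosen as the package's own reduced designs):
pattern recovery on 20 subjects × 600 frames × 90 locations at SNR 1;
drift power on 100 replicates of 10+10 subjects × 400 frames × 60
locations; condition contrast on 8 subjects × 3 conditions with weights
(0.50, 0.20, 0.30) / (0.25, 0.45, 0.30) / (0.40, 0.30, 0.30) and unequal
durations (240/320/280 frames), 100 replicates; the null calibration uses
equal weights *and equal durations* (unequal durations make per-condition
incidence variances heterogeneous — a sphericity violation that measurably
inflates the RM-ANOVA type-I rate even with no planted effect) over 400
replicates; QC contrast on 20 seeded clean/nuisance twin pairs.

## Known limitations

* The rotation's equivalence to any specific published complex-PCA
  implementation is not claimed; what is guaranteed is the optimization
  contract (criterion non-decrease, exact pairwise optima) and planted
  recovery.
* The scree elbow rule is a convention; on shallow scree curves the
  maximum-distance point is ambiguous, which is why an explicit k override
  exists and is used by the study-shaped workflows.
* The RM-ANOVA applies no sphericity correction and ignores unequal
  per-subject data volumes; both follow the analysis this package
  operationalizes and are noted there as limitations too.
* Incidence statistics treat states as hard labels; soft definitions based
  on relative magnitudes are out of scope.
* Ragged (unequal-length) recordings are kept ragged; carpet sorting
  across time requires equal lengths and refuses otherwise.
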