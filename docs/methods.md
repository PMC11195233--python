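# Methods

## Stimulus and paradigm

The chirp stimulus is synthesized as `carrier(t) · (1 − d/2 + (d/2)·sin Φ(t))`
with modulator phase `Φ(t) = 2π (f₀ t + (f₁−f₀) t² / 2D)` (f₀ = 0 Hz,
f₁ = 100 Hz, D = 2 s), modulation depth d = 1 by default. The carrier is
pink noise made by spectral shaping (amplitude ∝ f^(−1/2) over 1 Hz to
0.4·fs) of white Gaussian noise; the synthesis method is a package choice,
as is the depth. The paradigm places 200 onsets with offset-to-onset gaps
drawn uniformly from 1500–2000 ms (the gap anchor convention is a package
choice).

Instantaneous frequency is estimated from the analytic-signal phase
derivative. Near series boundaries the discrete Hilbert transform rings, so
the boundary value (`edge_instantaneous_frequency`) is taken from a local
quadratic fit to the unwrapped phase — exact for a linear chirp — over the
trailing 128 samples.

## Time-frequency decomposition

Complex Morlet atoms with temporal SD `σ_t = cycles(f) / (2πf)`,
`cycles(f)` linear from 1 at 2 Hz to 30 at 120 Hz, truncated at ±3σ_t and
amplitude-normalized so a unit sinusoid at the centre frequency yields
|coefficient| = 1 at every frequency. Convolution is FFT-based; output is
decimated to 5-ms steps by default (memory), configurable. Samples whose
wavelet support crosses an epoch edge are **flagged invalid** rather than
zero-padded — the 1-cycle 2-Hz atom spans ±239 ms, most of the baseline —
and all downstream consumers honour the flags.

* **ITPC**: resultant length of unit phase vectors across trials. The
  trial-count bias correction subtracts `r_critical = sqrt(−ln 0.5 / n)`,
  the Rayleigh critical value at α = 0.5 (the null median of the resultant
  length); the printed source formula is typographically garbled, and the
  un-rooted variant is available (`sqrt=False`) for sensitivity analysis.
  Corrected values may be negative and are preserved.
* **STP**: trial-mean of `10·log10(|coef|² + ε)`, ε = 10⁻³⁰ of the unit
  scale (keeps dB finite on silent input without distorting real values).
  The dB convention is adopted; the absolute offset is unit-dependent and
  not matched to any particular acquisition chain.
* **ERSP**: the trial-mean log power is referenced to its mean over the
  valid baseline samples (−500–0 ms) per frequency, i.e. a geometric-mean
  baseline. This makes the baseline window average to exactly 0 dB by
  construction; an arithmetic-mean power baseline would differ only by a
  Jensen gap (< 0.1 dB for stationary inputs) but not satisfy the exactness
  property. Frequencies with a fully invalid baseline raise, naming the
  frequency.

## Feature windows and regions

The frequency bands are onset/offset 2–13 Hz, alpha 8–12 Hz, gamma1
30–57 Hz, gamma2 63–100 Hz. The protocol specifies bands only; time windows
are derived from the chirp law f(t) = 50·t (gamma1: 600–1140 ms, gamma2:
1260–2000 ms) with onset 0–500 ms and offset 2000–2500 ms bracketing the
evoked transients; power windows span 0–2000 ms. All windows are
config-overridable; extraction is the mean over the rectangular window
(no ridge-following in v1).

The 68 Desikan-Killiany nodes map onto 14 left/right lobar regions through
a versioned YAML config following standard lobar assignments; the temporal
region includes the banks of the superior temporal sulcus and the
transverse temporal gyrus, and the insula is grouped with the cingulate
("deep source") region since the reference grouping table is unavailable.
Nodes are retained as replicates for modeling; a region-mean view exists
for reporting.

## SA ratio

Gamma1 STP is min-max normalized onto [0, cap] where cap defaults to the
analysis set's own maximum gamma1 ITPC (the historical constant 0.0164 is
exposed as `PROTOCOL_STP_CAP` for exact-protocol mode, but is data-specific).
Normalization pools **all** subjects × nodes of the analysis set: pooling
only the temporal nodes would pin some temporal node at exactly 0 and make
its subject's ratio explode; with the full set pooled, the global minimum
virtually always lies outside the (gamma-elevated) temporal region and
temporal values stay interior. Normalized values at or below 10⁻⁶·cap are
clipped to that floor and flagged. The ratio gamma1 ITPC / normalized STP is
computed per temporal node and averaged within each temporal lobe per
subject. It is strictly increasing in ITPC and strictly decreasing in
normalized STP.

## Transfer entropy

Each trial's raw broadband series is discretized by its own 5%/95%
quantiles into 3 symbols (per-trial symbolization; session-level quantiles
are a documented alternative the protocol leaves open). Rényi transfer
entropy of order q (default 0.5, logged in every output; q is not fixed by
the protocol) with target/source Markov orders k = l = 3 uses the plug-in
escort-distribution estimator in bits (base-2 logs); at q = 1 it dispatches
to the exact Shannon plug-in limit. Per-trial significance resamples the
source in contiguous blocks of k + 1 = 4 samples, n_boot = 300, with the
add-one convention p = (1 + #{TE_b ≥ TE_obs})/(n_boot + 1), ties counted as
≥, so p > 0 always. TE% = percentage of artifact-free trials with p ≤ .01
per directed pair; the default pairs are the three right frontal nodes
(caudal middle frontal, pars triangularis, rostral middle frontal) × the
left/right superior temporal gyrus, both directions.

The plug-in Rényi estimator has a large positive finite-sample bias at
q < 1 (≈ 0.44 bits for independent 3-symbol streams of epoch length); the
bootstrap p-value calibrates significance against exactly that bias, which
is why raw TE values are never thresholded directly.

## Statistics

ITPC responses are variance-stabilized by the signed cube root of the log,
`sign(ln x)·|ln x|^{1/3}` on (0, 1]; corrected ITPC is re-mapped to the raw
domain by adding `r_critical` before the transform. The alternative
reading `(1/3)·log` is available as `transform="third_log"`.

The region model is a documented two-stage contract: node replicates are
collapsed to subject × region means (making the fit invariant to verbatim
replicate duplication), then a linear mixed model with Group × Sex × Region
fixed effects and a subject random intercept is fit (statsmodels MixedLM)
and Wald F statistics are reported per term with a residual large-sample
denominator df — the Pinheiro-Bates containment df is deliberately not
replicated; the contract is recorded in the fit metadata. Post-hoc
cell contrasts per region are pooled-SD t tests with Benjamini-Hochberg
adjustment at 5% within each response's family and Cohen's d from cell
means and pooled SD. Clinical associations are Spearman correlations
(average ranks for ties) with BH at 10% across the declared family. SA
group comparisons use a two-sample rank-sum test — the cells are
independent groups, so the original "signed-ranks" label is treated as a
misnomer, noted in the output metadata — with the rank-biserial correlation
as effect size and Holm adjustment across sides × cell pairs (exact null
distribution for untied samples up to n = 25 per cell).

## Synthetic cohorts

Each epoch is a sum of independent components: a 6-Hz Gabor onset burst
peaking 100 ms post-onset (and a half-amplitude offset burst 100 ms after
stimulus end), phase-jittered per trial by von Mises(0, κ_onset); the
chirp-following oscillation at the modulation frequency (the acoustic
carrier itself is not modelled in neural epochs), constant amplitude,
phase-jittered by von Mises(0, κ_chirp); 30–100 Hz background gamma noise;
8–12 Hz alpha; and a 1/f background spanning 1–150 Hz so every analysis
frequency carries incoherent noise (otherwise coherent spectral leakage
above 100 Hz would dominate ITPC there). Component random streams derive
from (seed, node, component), so components are additive under a fixed seed
and every output is bit-reproducible.

Group effects are designed on latent per-subject traits (one standard
normal per component): a designed standardized effect shifts the trait mean
of its group/sex cell at nodes of the targeted regions. Traits map
monotonically to generator parameters — phase-locking targets through the
inverse von Mises mean resultant length (κ = A⁻¹(r)), amplitudes on a dB
scale (between-subject SD 1.5 dB) — so standardized feature differences
match the design in expectation on the latent scale. Measured Cohen's d is
attenuated by trial-count measurement noise (≈ 20% at 60 trials for gamma1
ITPC, shrinking with more trials); the default study conditions are 60
trials and the default effect pattern mirrors the headline phenotype
(reduced temporal gamma locking and elevated background gamma in affected
males, enhanced frontal/cingulate onset response in both sexes). Temporal
regions carry a +2.5 dB baseline gamma offset (auditory cortex under
auditory drive), which also keeps the SA normalization minimum outside the
temporal lobe. Clinical scores use a Gaussian copula on within-group
feature ranks (latent Pearson `2·sin(π·ρ/6)` for a designed Spearman ρ),
calibrated to the catalogued group means and SDs.

What the generator does **not** emulate: volume conduction and field
spread, inter-node correlation structure, non-stationary artifacts,
heavy-tailed noise, or realistic source-current units. Passing tests
therefore demonstrate the estimators' correctness and calibration under
controlled conditions, not performance on recorded EEG.

## Problem sizes in the test suite

The acceptance-level checks run at the stated sizes (2000 Monte-Carlo
nulls; 500 bootstrap trials; 20 cohort draws at 20 subjects per male cell).
Cohort-level checks use a reduced analysis set — four temporal exemplar
nodes plus two occipital reference nodes, a 3-Hz gamma1 grid and 60 trials —
chosen as the smallest set that preserves the pooled-normalization geometry
the SA ratio depends on; the full 68-node, 1-Hz configuration is a config
switch.

## Known limitations

* Rectangular feature windows (no ridge-aligned extraction).
* The mixed-model denominator df is approximate; exact containment df can
  shift borderline p values.
* Whether ITPC should be transformed before or after trial-count
  correction is left open by the protocol; the transform here receives
  corrected values re-mapped by `r_critical`.
* The cingulate grouping stands in for deeper sources that a cortical-only
  parcellation cannot represent.
* TE is computed on raw broadband epochs; optional band-restriction is a
  config choice, and continuous (kernel/KSG) estimators are out of scope.
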