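# Methods

## Scope and model

`lfpnet` analyzes multi-channel local field potential (LFP) recordings
around a systemic drug injection (t = 0) with two complementary measures:

1. **Aperiodic spectral parameterization.** The non-oscillatory part of the
   LFP power spectrum is modeled as a power law

       S(f) = 10^A / f^B        [uV^2/Hz],  f in 1-300 Hz

   where the offset `A` (log10 power scale) is read as a proxy for overall
   population activity and the exponent `B` (spectral slope) as an index of
   excitation-inhibition balance.  Spectra are estimated on **bipolar
   derivations** (differences between electrode pairs within the same
   anatomical structure), which cancel any far-field or common-mode
   contribution algebraically.

2. **Functional connectivity via Gaussian-copula mutual information
   (GCMI).** Raw monopolar signals, down-sampled to 1 kHz, are analyzed in
   non-overlapping 2-s windows; each margin is rank-transformed to an exact
   standard-normal copula and MI is computed parametrically from covariance
   determinants.  The per-epoch summary is the median of the per-window MI
   values (a 15-min epoch yields exactly 450 of them), and the drug effect
   per electrode pair is the post/baseline ratio of these medians.

Baseline-vs-drug contrasts use two-sided nonparametric tests (Wilcoxon
signed-rank for paired values, rank-sum for independent groups) with a
Kolmogorov-Smirnov normality check that documents non-normality; the
pipeline is nonparametric regardless of its outcome.  Significance is
declared at p <= 0.05, uncorrected by default (a Benjamini-Hochberg flag
exists).

## Synthetic generator and its ground truth

Because every stage must be verifiable by parameter recovery, the package
ships a generator that emulates the structure of such recordings:

* **Aperiodic background** by frequency-domain spectral shaping: white
  Gaussian noise is transformed with an rFFT, scaled by `sqrt(S(f) fs / 2)`,
  and inverse-transformed, so the expected one-sided PSD equals
  `10^A / f^B` exactly.  The DC bin is zeroed; fits start at 1 Hz, so this
  is invisible downstream.
* **Coupling** through shared latent 1/f sources: one global source loading
  on every channel plus one source per structure.  With per-channel private
  noise pre-scaled by `sqrt(1 - S)` (S = total shared variance fraction),
  each channel's PSD equals its target exactly and the correlation between
  channels equals the loading product.  Default loadings (global^2 = 0.45,
  structure^2 = 0.115) put the baseline within-structure mean MI about 70%
  above the between-structure mean, matching the contrast reported for such
  recordings.
* **Oscillations** (e.g. 130-160 Hz high-frequency humps) as band-pass
  filtered noise with a given in-band RMS, drawn independently per channel
  so they survive bipolar differencing, as they do in real recordings.
* **Common-mode artifact**: one colored-noise trace added identically to
  all channels (cancelled exactly by bipolar derivation).
* **Drug step at t = 0** with three parameters: offset change dA, exponent
  change dB, and a coupling scale g that multiplies every source loading by
  sqrt(g).  No pharmacokinetic ramp is modeled: analysis epochs sit tens of
  minutes from the injection, so the transition shape is irrelevant to the
  contracts being tested.

**Coupling changes leave bipolar spectra invariant.**  The coupling scale
rescales only the shared-source loadings; private noise keeps its baseline
amplitude.  Since equal-loading shared sources cancel in bipolar pairs,
the spectral stage sees exactly dA and dB, unconfounded by the
connectivity manipulation.  The price is that the *monopolar* total power
shifts by `log10(1 - S(1-g))`; the ground-truth object records this
per-channel, per-epoch.  Connectivity is insensitive to it (GCMI is scale
invariant).

## Numerical choices

* **Welch estimation**: Hann windows, 50% overlap, density scaling, no
  detrending (a constant signal keeps its DC power).  The **aperiodic
  stage uses 8-s windows**: at 0.125-Hz resolution the 1-Hz lower fit
  bound sits eight bins from DC, so spectral-kernel smoothing of steep
  spectra is negligible (B = 4 recovered within 0.03; with 2-s windows the
  same fit is biased by +0.4).  MI windows are 2 s, per the connectivity
  protocol.
* **Median spectra and the chi-square factor**: per-window PSD bins of
  Gaussian signals are ~chi^2 with 2 dof, so the across-window median sits
  at ln 2 ~ 0.693 of the underlying PSD.  `median_spectrum(..., debias=True)`
  divides by ln 2 — robustness of the median to transients is kept, the
  absolute scale is restored.  Epoch *differences* (dA, dB) are unaffected
  either way; the spectral pipeline uses the debiased form so absolute
  offsets are interpretable.
* **Power-law fit**: ordinary least squares of log10 power on log10 f after
  resampling onto 100 log-spaced frequencies (linear interpolation in
  log-log coordinates), giving each decade equal leverage.  On a noiseless
  power law the fit is exact to machine precision on any grid.
* **Periodic separation**: iterative — fit, flag contiguous bins whose
  positive log-residual exceeds 2.5 SD, mask, refit; at most 5 passes.
  Mains (50 Hz) and harmonics are masked unconditionally (+/- 2 Hz).  If
  more than half of the fit range ends up masked a warning is logged and
  the fit is still returned.
* **GCMI**: copula via average ranks (deterministic under ties) and
  `ndtri(rank/(n+1))`; MI from covariance determinants with an analytic
  small-sample bias correction (half-integer digamma terms per entropy
  estimate), on by default.  Near-singular joint covariance (|rho| -> 1)
  returns `inf` with a warning.  Units default to bits.
* **Ratio floor**: post/baseline MI ratios are undefined for pairs whose
  baseline median MI is below 0.001 bits (ratios explode on near-zero
  denominators); such pairs are flagged and excluded from ratio summaries.
  Negative bias-corrected window values are clamped to 0 before medians.
* **Downsampling**: polyphase resampling (Kaiser window) with > 40 dB
  stopband attenuation above the new Nyquist; output length is
  floor(n fs'/fs).
* **Epochs**: half-open sample intervals, seconds relative to injection,
  0-based channels.  Out-of-range epoch requests raise rather than clip.
  Stage-specific protocol defaults (-32..-2 / 30..60 min for spectra,
  -20..-5 / 45..60 min for MI) are plain config fields, since published
  protocols vary window placement between stages.

## Statistical design

The statistical unit is the electrode pair, pooled within a region — which
raises a pseudo-replication concern: pairs sharing an electrode have
correlated (A, B) estimates, and pooled rank tests over them are
anticonservative.  Two mitigations are available: the "neighbors" bipolar
mode on a pair-isolated array geometry yields electrode-disjoint pairs
whose estimates are independent (the per-structure signed-rank then attains
its exact size, 2/64 ~ 3.1% at six pairs), and the report carries the
caveat.  The default mode remains all-within-structure pairs for spectral
estimation fidelity.

With three structures tested at alpha = 0.05 without correction, the
familywise false-positive probability across structure-level tests is
~9-14% by construction; the packaged dissociation check therefore asks the
directional question (no structure with a *significant positive* offset
change under a null offset), not blanket non-significance.

## Scaled-down study conditions

The packaged drug studies (`lfpnet.study`) run 3 structures x 12 channels
at 1 kHz with 150 s on each side of the injection and 120-s analysis
epochs; bipolar pairs come from the "neighbors" mode (6 electrode-disjoint
pairs per structure), and connectivity uses all 630 monopolar pairs with
60 MI windows per epoch.  Stylized effects: "ketamine-like"
(dA = +0.3, coupling x0.7) and "LSD-like" (dB = -0.4, coupling x0.8).
These sizes keep a full study at a few seconds of compute while leaving
every recovered quantity well-resolved (offset to ~0.02, exponent to
~0.01, ratios to a few percent).

## What the generator does and does not emulate

Passing recovery tests show the pipeline is correct *for data matching the
generator's assumptions*: Gaussian 1/f-plus-sources signals, stationary
within epochs, instantaneous (zero-lag) coupling, a step drug effect, and
gapless single-session recordings.  Real recordings add non-Gaussian
transients (movement, chewing), lagged and frequency-specific coupling,
pharmacokinetic ramps, electrode drift, and between-animal variability —
none of which are modeled.  In particular the generator cannot validate
the physiological *interpretation* of A and B, only their estimation.

## Known limitations

* GCMI is a lower bound on MI and captures only monotone-marginal,
  copula-Gaussian dependence; lagged or higher-order dependence is invisible.
* MI window samples are autocorrelated for 1/f signals, so per-window MI
  values are noisier than the iid bias theory assumes; medians over windows
  absorb most of this, and ratio summaries are unaffected by the common
  scale.
* Absolute exponent estimates above B ~ 4 would need still longer Welch
  windows than the 8-s default.
* The region inclusion rule (>= 6 recordings from >= 3 animals) is relaxed
  to single-animal settings in simulated studies via config, since one
  simulated session is one animal.
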