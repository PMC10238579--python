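# Methods

## The pipeline

1. **Epoching.** A single-channel EEG recording at a fixed sampling rate is
   cut into consecutive 30-s epochs (7680 samples at 256 Hz, 3840 at 128 Hz);
   a trailing partial epoch is dropped.  Epochs flagged as artifacts (flags
   are an input — artifact *detection* is out of scope) are removed, with the
   original epoch indices retained so depth series stay alignable with the
   hypnogram.

2. **Recording z-scoring.** All retained samples of a recording are z-scored
   with one pooled mean and standard deviation.  This suppresses amplitude
   differences between subjects, devices and montages while keeping the
   relative stage-to-stage variation within a night.  Statistics are computed
   *after* artifact removal so outliers do not contaminate them.

3. **Spectral vectors.** Each epoch is Fourier transformed (plain FFT of the
   z-scored samples; no taper, no per-epoch detrend — the per-recording
   z-score is the only normalization).  The modulus is raised to the scaling
   exponent γ and truncated: the DC bin is excluded and bins 1…F are kept
   with F = floor(f_max · 30); the default cutoff f_max = 35 Hz gives
   F = 1050 at the 1/30 Hz resolution of a 30-s epoch.  The unnormalized FFT
   convention is used (moduli scale with epoch length); only relative
   spectral structure matters downstream.  γ compresses the heavy-tailed
   amplitude distribution; γ = 1/2 is the default and exponents below 1/2
   trigger a warning because overly aggressive compression degrades the
   later cluster analysis.

4. **PCA.** A PCA (mean-centering only, no per-bin variance scaling) over the
   pooled spectral vectors gives orthonormal *eigenspectra* ΔV_i(f), indexed
   from zero in order of decreasing explained variance, and per-epoch scores
   C_i(k).  Any spectrum is reconstructed as
   V(f) = V_mean(f) + Σ C_i·ΔV_i(f).

5. **Sign orientation.** PCA leaves eigenvector signs free.  Each
   eigenspectrum is flipped, if necessary, so that its summed loading above
   3 Hz minus the summed loading at or below 3 Hz is non-negative (exact
   ties: the largest-magnitude loading is made positive).  The 3 Hz split is
   the delta/rest boundary; after orientation a *larger* C1 always means
   relatively more fast activity, i.e. *shallower* sleep, with no labels
   involved.

6. **Sleep depth.** The depth variable is the oriented score of component
   index 1 of the γ = 1/2 spectral vectors.  Component 0 typically absorbs
   broadband amplitude fluctuations; component 1 is the slow-vs-fast
   contrast that tracks depth.  Agreement with a hypnogram is measured as
   |Pearson r| against the numeric stage mapping Wake = 0, REM = −1,
   N1 = −2, N2 = −3, N3 = −4 (the modulus, because the sign is a
   convention).

7. **Selection.** The GDV (below) is evaluated for every single component
   and component pair of the first three, for γ ∈ {1.0, 0.7, 0.5}; the
   spectra and the PCA are recomputed per γ.  The most negative cell wins.
   Only subsets of size ≤ 2 are scanned by default (larger subsets rarely
   help: non-separating dimensions dilute the GDV).

8. **Harmonization.** For two devices recording the same subject at the same
   rate, the filter function A(f) is the per-bin ratio of the reference
   device's epoch-averaged spectrum to the target's.  Multiplying each
   target epoch spectrum by A(f) makes the two epoch-averaged spectra equal
   — an algebraic identity, property-tested.  One PCA fitted on the
   reference only is used for both devices.  Zero bins in the target average
   are an error, not epsilon-patched: silent patching would corrupt A(f).
   Start-time offsets are recovered by scanning integer epoch shifts
   (default ±120 epochs = ±1 h) and maximizing |Pearson| on the overlap;
   ties prefer the smallest |shift|, then negative shifts.

## The GDV

For N labeled points in D dimensions, each dimension is z-scored (population
convention, divisor N) and multiplied by 1/2; on the rescaled points the GDV
is the mean intra-class Euclidean distance (unordered pairs) minus the mean
inter-class distance (all cross-pairs, averaged over class pairs), times
1/√D.  The prefactors fix the scale: 0 means no clustering, −1 is already
very strong separation, and values are comparable across dimensionalities.
Classes with fewer than two members are an error (the intra-class mean is
undefined), not silently skipped.  Pair sums run in fixed index order so
floating-point results are reproducible.  The implementation is exact
O(N²) (vectorized pairwise distances); callers subsample if needed — the
selection grid exposes a seeded per-stage subsampling argument for that.

## The synthetic generator

Real scored polysomnography is not distributable, so the generator emulates
the features the method relies on, no more:

* **Hypnogram**: a first-order Markov chain over {W, REM, N1, N2, N3}
  starting in Wake; the default transition matrix gives geometric dwell
  times of minutes-scale, a plausible night architecture at 30-s resolution.
* **EEG**: per epoch, stationary colored Gaussian noise synthesized in the
  frequency domain; its power profile is a 1/f background (default slope 1)
  plus flat band bumps (delta 0.5–3, theta 3–8, alpha 8–12, sigma 12–16,
  beta 16–35 Hz) weighted by a stage table.  Delta power rises
  monotonically over W < N1 < N2 < N3; REM's profile sits near N1's and
  breaks the ordering in the other bands, as in real sleep.
* **Continuous descent** (default on): after a switch to a deeper stage the
  delta weight climbs linearly toward the deeper target (full range in 20
  epochs ≈ 10 min) while switches to shallower stages jump immediately —
  awakenings are abrupt, deepening is gradual.
* **Per-epoch broadband gain** (log-normal, sd 0.4 in log-amplitude): the
  arousal-like amplitude fluctuation that gives the PCA a dominant
  amplitude component C0 ahead of the depth contrast C1, as observed in
  real spectra.
* **Between-subject variability**: per-subject log-normal jitter on every
  band weight (sd 0.2), a uniform ×[0.5, 2] broadband amplitude factor
  (exactly what the recording z-score must suppress), and jittered gain-sd.
* **Second device**: the same underlying signal passed through a smooth
  positive spectral gain curve, recorded with an integer epoch offset;
  ground truth is returned for recovery tests.

Defaults (960 epochs = 8 h at 128 Hz) were fixed once, on plausibility
grounds, so that the planted structure is clear but not caricatural; with
them the pipeline reaches per-subject hypnogram correlations around 0.85–0.95
and the selection grid reproduces the qualitative findings (γ = 1/2, single
component C1 best; GDV argmin = hypnogram-correlation argmax).  What passing
tests on this generator shows is that the *pipeline* recovers planted
structure of the kind real sleep EEG exhibits; it does not certify
performance on clinical data, which has non-stationary epochs, artifacts,
spindle/K-complex morphology and inter-rater label noise that the generator
deliberately omits.

## Numerical choices

* FFT bookkeeping: bin f ↔ frequency f/30 Hz; F = floor(f_max·30); DC always
  excluded.  At 256 Hz a 30-s epoch yields 3840 non-redundant amplitudes, of
  which 1050 are kept at the 35 Hz cutoff (1000 in the cross-device CLI
  preset, whose cutoff is the 1000th bin ≈ 33.3 Hz).
* PCA uses a full SVD (deterministic); explained variances follow the
  sample-covariance (N−1) convention and sum to the total variance.
* Eigenspectrum orientation as above; the rule is applied at fit time and
  recorded in the model file.
* Alignment correlations use only the overlapping segment (no padding);
  overlaps shorter than 3 epochs are an error, constant overlaps give NaN
  cells in the curve.
* Model files, spectral-vector files and hypnograms are plain text; EDF
  recordings are written by a minimal built-in 16-bit writer (1-s records,
  microvolt units, symmetric physical range) and read through MNE.

## Design choices that were genuinely open

* **Component indexing** is zero-based: "component 1" is the second-largest
  variance direction.  This matches the role separation observed in pooled
  spectra (C0 = amplitude, C1 = depth) and keeps the eigenspectrum sum
  starting at i = 0.
* **Global vs local fitting**: the PCA is fitted on pooled recordings by
  default; per-recording ("local") fitting is available but produces more
  weak outcomes, because a single night may not constrain the component
  order — the package exposes both so the comparison is reproducible.
* **Pooled correlation** is computed over concatenated epochs when a cohort
  is summarized by one number; per-recording distributions are the primary
  view.
* **Error policy**: degenerate inputs (constant signals/columns, singleton
  classes, all-flagged recordings, zero filter bins) raise errors naming the
  offender; cohort-level routines degrade per item (NaN) instead of
  aborting.

## Known limitations

* The depth variable is only calibrated for γ = 1/2; other exponents emit a
  warning and shift which component carries the depth contrast.
* No artifact detection, no resampling, no multi-channel fusion, and no
  discrete stage classifier on top of C1 — deliberately out of scope.
* O(N²) GDV: for very long pooled cohorts use the per-stage subsampling
  argument.
* The EDF writer covers the single-channel, integer-rate case needed for
  fixtures; it is not a general-purpose EDF+ implementation.
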