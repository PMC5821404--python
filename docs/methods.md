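# Methods

This note documents the models and procedures implemented in `alphacrit`,
the parameter choices that matter, what the synthetic-data generators do
and do not emulate, and the numerical decisions taken where the design was
genuinely open.

## Detrended fluctuation analysis

DFA estimates the strength of long-range temporal correlations as the
power-law growth of detrended fluctuations with window length. The
implementation follows the classic first-order (linear-detrend) procedure:

1. cumulative sum of the demeaned signal, X(t) = Σ_{t'≤t}(x(t') − ⟨x⟩);
2. segmentation into k = ⌊(T − N)/(0.5 N)⌋ segments of length N at 50%
   overlap, anchored at the start of the record; a trailing remainder
   shorter than N is discarded;
3. least-squares linear detrend within each segment; RMS residual per
   segment; mean over segments gives ⟨F_N⟩;
4. ordinary least squares of log₁₀⟨F_N⟩ on log₁₀N over all retained
   windows (equal weights) gives the scaling exponent α.

Window lengths are logarithmically spaced (15 values, 3–50 s by default;
5–30 s for the model analyses), rounded to integer samples with duplicates
removed. Windows that yield no complete segment are dropped with a warning;
a window with zero fluctuation (constant input) raises instead of silently
producing −∞ in the fit.

**Small-window bias.** With linear detrending, windows below ~10 samples
are biased: iid noise reads α ≈ 0.62 rather than 0.50 when the window grid
is 3–50 *samples* (the R-R interval setting, where windows count
heartbeats). This deviation is intrinsic to first-order DFA, independent of
record length, and affects any implementation of this procedure; tests of
the R-R analyses therefore compare against an iid-noise reference computed
with the same windows. At 3–50 *seconds* on signals sampled at hundreds of
Hz (windows of ≥750 samples) the bias is negligible — white noise reads
α = 0.50 within ±0.01.

**Spectral counterpart.** The envelope power spectrum follows
P(f) ∝ f^−β with β = 2α − 1 for power-law decaying autocorrelations. β is
reported as the *positive decay exponent* (the log-log OLS slope negated),
so a flat spectrum has β = 0 and 1/f noise has β = 1; α = (β + 1)/2 holds
on this convention.

## Band-pass filtering, envelopes, multitaper spectra

Band-pass filtering uses a Hamming-window FIR kernel of 3 cycles of the
band's low edge (rounded up to odd length), applied by centred convolution
so the output is zero-phase and length-preserving. Three cycles balances
transition width against edge loss; for the 8–12 Hz band the in-band gain
is 1.000 and a tone at 2 Hz is attenuated by ~58 dB. One filter length at
each edge is discarded before envelope statistics — filter and Hilbert
transients otherwise bias the smallest DFA windows.

The amplitude envelope is the magnitude of the analytic (Hilbert) signal of
the band-limited trace.

Multitaper spectra average periodograms over discrete prolate spheroidal
(Slepian) tapers and over 50%-overlapping windows. `smoothing_hz` is the
spectral concentration half-bandwidth W; a T-second window admits
2·T·W − 1 tapers (5 s, 2 Hz → 19). The one-sided density is normalized so
its integral equals the signal variance (verified to 10% on stationary
noise).

**Oscillatory peak detection.** Population spectra superimpose an
aperiodic 1/f-like background and oscillatory bumps. `spectral_peak`
therefore returns the most *prominent* local maximum of log power within a
frequency range rather than the absolute maximum, which the background
would always place at the lowest frequency.

## Source-space projection with session-unbiased orientation

Comparisons of source-level power or envelopes across sessions are biased
if each session picks its own dipole orientation. The implemented scheme
fixes a common orientation per source: the session-mean source-level
cross-spectral matrix C(r,f) = (1/S) Σ_i A_iᴴ C_i A_i (conjugate transpose,
so the result is Hermitian for complex CSDs) is eigendecomposed and the
leading eigenvector u₁ — the orientation maximizing session-averaged
projected power — is applied to every session's filter, B_i = A_i u₁.
Envelopes are |H_i(f,t)·B_i| and per-session power is Re(B_iᴴ C_i B_i).

Numerical conventions: the eigenvector's sign/phase is arbitrary, so the
global phase is rotated to make the largest-magnitude component real and
positive (reproducible envelopes); near-degenerate leading eigenvalues are
resolved by the deterministic ordering of the symmetric eigensolver. No
post-hoc normalization (e.g. unit-noise-gain) is applied to B. Spatial
filters are *inputs* — inverse-model (eLORETA/leadfield) computation is out
of scope.

## The E/I lattice model

2,500 probabilistic integrate-and-fire units on a 50×50 lattice, 75%
excitatory, with directed local connectivity: each unit selects
round(pct/100 × neighbourhood) distinct targets within its 7×7
neighbourhood with probability ∝ exp(−d/λ) in Euclidean lattice distance.
Defaults: 42.5% (excitatory units) and 75% (inhibitory units) of the
neighbourhood.

Per 1-ms step, in this order:

1. I_i ← I_i + Σ_j N_ij W_ij S_j  (spikes S_j from the previous step);
2. Euler decay τ_I dI/dt = I₀ − I with τ_I = 9 ms, I₀ = 0;
3. P_i ← P_i + I_i;
4. Euler decay τ_P dP/dt = P₀ − P with τ_P = 6 ms (exc.) / 12 ms (inh.),
   background P₀ = 10⁻⁶ ms⁻¹ (exc.) / 0 (inh.);
5. spike with probability clip(P_i·dt, 0, 1) — P is a per-ms hazard, so
   with dt = 1 ms the raw P value is the spike probability (no double
   scaling);
6. spikers reset P to P_r = −2 ms⁻¹ (exc.) / −20 ms⁻¹ (inh.), producing a
   much longer effective refractory period for inhibitory units.

Weights (receiving kind first): W_EE = W_IE = 0.0085, W_EI = −0.569,
W_II = −2. Gain factors N (unity at baseline) multiply weights by the
receiving/sending kind pair and implement neuromodulatory scaling of
synaptic efficacy. The decay recursions are evaluated in multiplier form
(x ← x·(1 − dt/τ) + dt·x₀/τ), algebraically identical to the explicit
Euler step.

Open design points, fixed as follows and exposed in `NetworkConfig`:

- **Distance-decay constant λ = 2 lattice units** — keeps the exponential
  selection probability meaningful across the 7×7 window.
- **Open boundaries** (edge units have truncated neighbourhoods): a local
  cortical patch has edges; a toroidal option exists.
- **E/I identity by uniform random permutation** at build time.
- **LFP proxy = summed spikes** per step across all units (the summed
  synaptic input is available as an alternative).

At the baseline working point the LFP shows an alpha-band (≈9–10 Hz)
spectral peak above the aperiodic background, envelope DFA (8–12 Hz,
5–30-s windows) of α ≈ 0.8, and κ ≈ 0.9 — the jointly critical regime.
Emergent numbers vary by a few hundredths across connectome/spiking seeds;
reported values are seed averages.

**Performance and problem sizes.** The stepper is a numba kernel;
a 1,000-s simulation of the full lattice runs in tens of seconds. The
sweep utilities default to the published protocol (2.5% structural spacing,
10 seeds, 1,000 s per cell); the test suite exercises a reduced 5×5 gain
grid at 400-s simulations with one seed per cell, which is sufficient to
resolve the qualitative phenomenology (κ monotone in excitatory gain,
non-monotonic α along the E/I-ratio axis).

## Avalanches and the kappa index

Population activity is binned (default 1 ms, the integration step); the
threshold is a percentile (default 50th) of the *nonzero* bin counts, or an
explicit absolute value (0 segments runs of nonzero bins bounded by
silence, the classic spike-avalanche definition). An avalanche is a
maximal run of bins whose activity strictly exceeds the threshold; its size
is the total spike count within the run. Strict exceedance matters: an
inclusive comparison with a median-of-nonzero threshold counts every
typical bin as part of an avalanche, which flattens the kappa differences
between excitation- and inhibition-dominant regimes that the adaptive
threshold is meant to expose.

κ = 1 + (1/m) Σ_k [F_ref(β_k) − F_emp(β_k)] at m = 10 logarithmically
spaced sizes β_k across the support, with F_ref the CDF of the *discrete*
truncated power law with exponent −1.5 on the observed (or given) support.
κ = 1 at the critical reference; heavier tails (excitation-dominant) give
κ > 1, lighter tails (inhibition-dominant) κ < 1. κ depends only on the
empirical CDF (duplicating the sample leaves it unchanged).

## Group statistics

**Bayes factors** are reported as BF₁₀ (values < 1 favour the null). The
paired-t conversion is the JZS default (Cauchy prior on effect size, scale
√2/2), evaluated by quadrature over the g-prior mixture. The correlation
conversion uses the JZS linear-model integral in r and n; at r = 0,
n = 28 it yields BF ≈ 0.146.

**Cluster-based permutation test** (two-sided, family-wise error
controlled): per-voxel paired t; voxels with p < 0.05 are kept only if at
least two of their spatial neighbours are also significant;
positively- and negatively-signed voxels form separate clusters via
connected components of the adjacency; clusters are scored by summed t.
Under each of N permutations (within-subject condition relabeling = sign
flips of the paired differences; the observed labeling is included, so
p ≥ 1/N), the maximum and minimum cluster scores are recorded; observed
clusters outside the 2.5th–97.5th percentiles of those extreme-score
distributions are significant. Synthetic voxel maps use 4-connected
lattice adjacency.

The test is conservative on very small maps: with few voxels, the
two-significant-neighbours rule rarely forms clusters under the null, so
the family-wise error rate falls below nominal. Calibration is therefore
assessed at the realistic map size (3,000 voxels), where the empirical
rate over 200 null replicates × 1,000 permutations is ≈ 0.065 — consistent
with the nominal 0.05.

## Peripheral signals

R-peaks: rolling-window (2-s) maximum threshold at 0.6× with a 250-ms
refractory constraint — scale-invariant and robust for the clean synthetic
fixtures in scope; real-ECG noise/ectopy handling is a non-goal. Heart
rate is peak count over duration. R-R DFA reuses the `lrtc` implementation
verbatim with 3–50-beat windows. EOG events: third-order Butterworth
1–5 Hz (zero-phase), z-scored, threshold 4; contiguous suprathreshold
samples merge into one event for counting.

## Synthetic data: what it does and does not emulate

Every generator is a pure function of its arguments including the seed
(NumPy PCG64; the algorithm name is recorded in HDF5 metadata), and each
plants a ground truth recovered by the matching analysis within documented
tolerance:

- **Colored noise** by spectral synthesis — deterministic amplitude law
  f^(−β/2), uniform random phases — has an exactly power-law periodogram by
  construction (unlike AR filtering).
- **Scale-free oscillations**: a carrier multiplied by a nonnegative
  envelope built from colored noise with β = 2α − 1. Nonnegativity by
  *shifting* (minimum plus a small offset), not rectification — absolute
  value would distort the autocorrelation exponent.
- **Avalanche sizes** by inverse-CDF sampling of the truncated discrete
  power law.
- **Toy sensor sets**: per-session orthonormal sensor frames (mutually
  orthogonal across sources, hence the n_sensors ≥ 3·n_sources
  requirement) with planted unit orientations plus isotropic noise — the
  planted orientation is exactly recoverable as noise → 0. Not a forward
  model: no realistic leadfields, correlated noise, or cross-source
  leakage.
- **Synthetic ECG**: 10-ms triangular QRS spikes at 10× the baseline noise
  SD (an unambiguous detection target), R-R intervals with CV 0.05 and a
  planted DFA exponent. No P/T waves, baseline wander, or artifacts.
- **Paired voxel maps**: condition A standard normal; condition B adds
  unit-variance paired noise plus a standardized effect on a voxel subset;
  4-connected lattice adjacency. No spatial autocorrelation of the noise —
  real MEG source maps are spatially smooth, which changes cluster sizes
  but not the validity of the max-statistic calibration.

Passing tests on these fixtures demonstrates that the analysis chain is
correct and self-consistent; it does not certify performance on real
recordings with artifacts, nonstationarity, or sensor noise structure the
generators omit.

## Known limitations

- First-order DFA only (no multifractal or higher-order detrending).
- The lattice model has no long-range connections and no conductance-based
  dynamics; automated weight optimization is out of scope (the published
  optimized weights are taken as given).
- The avalanche bin size and threshold are free parameters; κ values
  shift by a few hundredths across reasonable choices.
- Group statistics cover paired designs only (no mixed models, no
  parametric FWE/FDR).
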