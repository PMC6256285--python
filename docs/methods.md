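# Methods

This note documents the models, estimators and numerical conventions behind
synaptoquant, and what its synthetic benchmarks do and do not demonstrate
about real data.

## Conventions

Coordinates are 0-based, ordered (z, y, x) (or (y, x) in 2D), with half-open
pixel/voxel ranges and voxel size (dz, dy, dx) in micrometres; the defaults
(0.3, 0.1, 0.1) µm approximate Nyquist-sampled spinning-disk confocal data
through a high-NA objective. Currents are stored signed (inward negative);
event amplitudes are reported as positive magnitudes. All randomness flows
through `numpy.random.default_rng(seed)`: same arguments + seed ⇒
bit-identical output.

## Synthetic data: what is emulated

**Dendrite stacks.** Puncta are isotropic 3D Gaussians (σ = radius/2,
default radius 0.4 µm) placed with a minimum separation of 4 radii inside a
shaft-shaped volume, convolved with a Gaussian PSF (default σ 0.2 µm = 2 px
laterally), then corrupted by optional Poisson noise and additive Gaussian
read noise clipped at zero. A punctum's `amplitude` is defined as its
*post-PSF* peak (the generator pre-compensates the Gaussian-on-Gaussian
attenuation), so amplitude/noise-SD is the peak SNR by construction; the
brightest rendered voxel can sit below the continuum peak by up to ~25%
when the sub-voxel center falls between z-planes (axial σ ≈ 0.7 voxel).
Channel coincidence is exact: `round(coincidence · N_A)` channel-A puncta
are placed within one voxel of a distinct B partner; all other A puncta keep
≥ 3 radii from every B punctum, so ground-truth coincidence is unambiguous.
Not emulated: optical aberrations, stage drift, bleaching, autofluorescent
background structure. Passing recovery tests therefore shows the chain is
correct under the stated noise model, not that thresholds transfer to any
particular microscope.

**mEPSC traces.** Events occur at Poisson times (default 1 Hz over 60 s at
20 kHz) with lognormal amplitudes (median 20 pA, log-SD 0.15 in the
benchmark conditions, which keeps essentially all events above 3.5× the
3 pA noise SD) and unit-peak difference-of-exponential waveforms
(rise τ 0.5 ms, decay τ 5 ms), on additive Gaussian noise. No overlapping-
event correlations, seal instabilities or line noise.

**Evoked I/V families.** Conductance follows a sigmoidal outward-block
model, g(V) = g0·(1 − d/(1 + exp(−(V − v_half)/k))), with reversal potential
+3 mV; the noiseless peak current at V is exactly g(V)·(V − v_rev) scaled
onto a fixed EPSC template. Each stored sweep is the average of three noisy
trials, the standard evoked-EPSC protocol. The default block depth 0.55
yields a true slope-ratio RI of 2.89 over the −60…+60 mV protocol, inside
the range reported for young (GluA2-poor) neurons; with full block (d = 1)
the outward branch becomes non-monotone and its OLS slope turns negative,
so RI is only a meaningful rectification summary for block depths up to
roughly 0.8 under this protocol.

**Spine time-lapses.** Frames every 40–60 s (default 50 s): 5 min baseline
at F0, a 150 s stimulus plateau at F0·(1 + transient/100), a 60 s linear
return, then washout exactly at F0, with i.i.d. Gaussian frame noise
(default 5% of F0). Real indicator data additionally show drift, bleaching
and focal-plane changes that this generator deliberately omits.

## Analysis conventions and numerical choices

**Thresholding.** The default per-channel threshold is a robust background
threshold: median + 5 robust SDs, where the SD is estimated from the spread
between the median and the 85th percentile (valid when background noise is
clipped at zero, and insensitive to a sparse bright foreground). A pooled
Otsu threshold is also provided but collapses onto the noise floor when the
foreground occupies only a few percent of voxels, which is the normal regime
for synaptic puncta. Thresholds are chosen once per experiment and frozen
across conditions; every result records the threshold used.

**Segmentation.** Optional unsharp-mask sharpening (Gaussian σ 1 px, amount
0.6) affects segmentation geometry only; all intensity statistics are read
from the raw image so intensities stay comparable across conditions.
Components smaller than 4 voxels are discarded (the 3D analog of the
4-pixel rule used in 2D detection). Watershed separation is marker-based:
markers at local maxima of the σ = 1 px smoothed image within each
above-threshold component, flooding the inverted intensity; it can split but
never merge threshold-connected components, and mask voxels left unlabeled
(flat plateaus) keep their component identity as new labels. 2D detection
uses 8-connectivity, the 2D analog of 26-connectivity.

**Colocalization.** Object overlap requires ≥ 1 shared voxel with a single
partner punctum (configurable); both directional fractions are always
computed with their own denominators, and an empty denominator yields a
missing value, never 0. "Non-overlapping" sets are the exact complement, so
overlap + complement partition each channel.

**Mini detection.** Noise SD is MAD × 1.4826 of the high-frequency residual
(raw − 1 kHz low-pass). Detection runs on the low-pass trace after global
median subtraction (hence DC-invariant), requiring both height and
*prominence* above threshold — the prominence requirement stops bumps riding
a decay arm from being re-detected — with a 5 ms refractory distance. Decay
τ is fitted from one time-to-peak past the trough (where the rising
exponential has decayed) out to 5 guessed τ (37%-crossing guess); the
37%-crossing time is emitted alongside as a fit-free statistic. Charge
integrates to the first return to baseline or the window end; windows are
truncated at the next detected event.

**Rectification.** The peak-measurement window is anchored once, on the
sweep with the largest response, and reused across all sweeps of a family
(the common shaded window across traces in standard I/V figures); each peak
is the mean over ±1.5 ms around that anchor, constrained to the 3–6 ms
post-stimulus band when a stimulus time is recorded. Per-sweep anchoring is
available but noise-dominated sweeps near reversal then anchor on noise
extremes and bias the flat-branch slope. The reversal potential is the
interpolated zero crossing; the branch split happens at that estimate (not
at 0 mV), with an on-reversal point joining the negative branch. Command
potentials are corrected by the 18 mV liquid junction potential before
analysis. QC: a cell fails if series resistance rises > 20% over its first
reading.

**ΔF/F.** Background subtraction precedes ΔF/F (which is not
offset-invariant — a fixture in the test suite demonstrates the shift).
F0 is the mean over all pre-stimulus frames (window boundaries are
half-open, so the frame at stimulus onset is a stimulus frame). The
transient is the *mean* ΔF/F over the stimulus window extended to the first
post-stimulus frame: a max-based reading would carry an extreme-value noise
bias of about +5 points at 5% frame noise. Reversibility = |mean washout
ΔF/F| ≤ 2 baseline SDs; the population-level paired test is the primary
reversibility assessment, this flag is a per-ROI convenience.

**Cohort statistics.** Cohorts draw exactly n values per cell without
replacement (with-replacement behind a flag); cells are visited in sorted-id
order so a seed fully determines the cohort. KS uses α = 0.005, all other
tests α = 0.05, both module constants. Dunn's post hoc z-tests use pooled
mean ranks with tie correction and a Bonferroni factor over the number of
pairs, two-sided. The factorial path is a type-II two-way ANOVA with
Šidák-corrected within-genotype contrasts (paired t when a `cell` column
aligns the levels).

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` run on: 60-puncta/channel
dendrites (60 µm, SNR 8, PSF 2 px) for colocalization recovery; a 60 s,
1 Hz, 20 kHz trace for detection recall/FDR; 7-potential sweep families
(200 noisy replicates for the consistency check); 17 ROIs at 5% noise for
ΔF/F; 2000 null replicates of 600-value cohorts for the KS calibration; and
a 6-dendrite-per-condition end-to-end experiment. These sizes give stable
statistics in seconds on one CPU while matching the per-experiment scale of
the emulated protocols.

## Known limitations

- Rolling-ball background subtraction runs per 2D plane (the ImageJ
  semantics); the radius is interpreted in pixels.
- Richardson–Lucy deconvolution with a Gaussian PSF is a stand-in for
  commercial CMLE deconvolution — same likelihood fixed point, different PSF
  model and regularisation, so restored intensities are not expected to
  match any specific commercial output. It is off by default and no shipped
  analysis depends on it.
- The mini detector is a documented replacement for unpublished lab
  software, not a reproduction of it; its parameters are exposed.
- Spine/shaft and ROI analyses take user-supplied boxes; automated spine
  detection is out of scope.
- Object-based colocalization only; pixel-correlation coefficients
  (Pearson/Manders) are deliberately not provided.
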