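"""Ground-truthed synthetic data generators.

Every downstream stage of the package (puncta segmentation, colocalization,
mini detection, rectification, dF/F) is testable against exact ground truth
produced here. Generators are deterministic given a seed and never estimate
anything: the returned ground truth is what was rendered, by construction.

What is emulated (and what is not): dendritic image stacks carry Gaussian
puncta on a dark background with Gaussian-PSF blur and Poisson+Gaussian
camera noise, but no optical aberrations, drift or bleaching; mEPSC traces
are difference-of-exponential events on Gaussian noise, without channel-level
kinetics; evoked sweeps follow a sigmoidal outward-block conductance model
of polyamine rectification; spine time-lapses are plateau transients with a
linear return to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dynamics import RoiSeries
from .ephys import Trace
from .images import ImageStack

DEFAULT_VOXEL_SIZE = (0.3, 0.1, 0.1)  # (dz, dy, dx) um


# ---------------------------------------------------------------------------
# Ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthPuncta:
    """Exact puncta ground truth for one channel of a synthetic stack."""

    centers_vox: np.ndarray   # (N, 3) float voxel coordinates (z, y, x)
    amplitudes: np.ndarray    # post-PSF peak intensity per punctum
    radii_um: np.ndarray
    channel: str
    coincident_with: np.ndarray  # partner-channel punctum index, -1 if none
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if np.any(self.amplitudes <= 0):
            raise ValueError("amplitudes must be positive")

    def __len__(self) -> int:
        return self.centers_vox.shape[0]

    @property
    def centers_um(self) -> np.ndarray:
        return self.centers_vox * np.asarray(self.voxel_size)

    @property
    def n_coincident(self) -> int:
        return int(np.sum(self.coincident_with >= 0))


@dataclass
class GroundTruthEvents:
    """Exact event ground truth for a synthetic mEPSC trace."""

    onset_times_s: np.ndarray
    amplitudes_pa: np.ndarray
    rise_tau_ms: float
    decay_tau_ms: float

    def __post_init__(self) -> None:
        self.onset_times_s = np.asarray(self.onset_times_s, dtype=float)
        self.amplitudes_pa = np.asarray(self.amplitudes_pa, dtype=float)
        if self.onset_times_s.size and np.any(np.diff(self.onset_times_s) <= 0):
            raise ValueError("onset times must be strictly increasing")
        if np.any(self.amplitudes_pa <= 0):
            raise ValueError("amplitudes must be positive")
        if not (self.decay_tau_ms > self.rise_tau_ms > 0):
            raise ValueError("require decay_tau > rise_tau > 0")

    def __len__(self) -> int:
        return self.onset_times_s.size


@dataclass
class RectificationModel:
    """Sigmoidal outward-block conductance model of AMPAR rectification.

    g(V) = g0 * (1 - block_depth / (1 + exp(-(V - v_half)/k_block)))

    With block_depth = 0 the I/V relation is ohmic; with deep block at
    positive potentials the outward branch flattens, mimicking polyamine
    block of GluA2-lacking receptors, and the slope-ratio RI rises above 1.
    """

    g0_ns: float = 1.0
    v_rev_mv: float = 3.0
    v_half_mv: float = 20.0
    k_block_mv: float = 10.0
    block_depth: float = 0.55

    def __post_init__(self) -> None:
        if self.k_block_mv <= 0:
            raise ValueError("k_block must be positive")
        if not 0.0 <= self.block_depth <= 1.0:
            raise ValueError("block_depth must lie in [0, 1]")
        if self.g0_ns <= 0:
            raise ValueError("g0 must be positive")

    def conductance_ns(self, v_mv) -> np.ndarray:
        v = np.asarray(v_mv, dtype=float)
        return self.g0_ns * (
            1.0 - self.block_depth / (1.0 + np.exp(-(v - self.v_half_mv) / self.k_block_mv))
        )

    def peak_current_pa(self, v_mv) -> np.ndarray:
        v = np.asarray(v_mv, dtype=float)
        return self.conductance_ns(v) * (v - self.v_rev_mv)

    def true_slopes_ns(self, potentials_mv) -> tuple[float, float]:
        """Closed-form OLS slopes of the noiseless peak I/V on each branch."""
        v = np.asarray(potentials_mv, dtype=float)
        i = self.peak_current_pa(v)
        neg = v <= self.v_rev_mv
        pos = v > self.v_rev_mv
        if neg.sum() < 2 or pos.sum() < 2:
            raise ValueError("potentials must provide >= 2 points on each side of v_rev")

        def slope(vv, ii):
            vm, im = vv.mean(), ii.mean()
            return float(np.sum((vv - vm) * (ii - im)) / np.sum((vv - vm) ** 2))

        return slope(v[neg], i[neg]), slope(v[pos], i[pos])

    def true_ri(self, potentials_mv) -> float:
        s_neg, s_pos = self.true_slopes_ns(potentials_mv)
        return s_neg / s_pos


# ---------------------------------------------------------------------------
# Dendrite stacks
# ---------------------------------------------------------------------------

def _epsc_kernel(t_s: np.ndarray, rise_tau_ms: float, decay_tau_ms: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials kernel (positive-going)."""
    if decay_tau_ms <= rise_tau_ms:
        raise ValueError("decay_tau must exceed rise_tau")
    tr, td = rise_tau_ms * 1e-3, decay_tau_ms * 1e-3
    k = np.exp(-t_s / td) - np.exp(-t_s / tr)
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    return k / peak


def _place_points(
    rng: np.ndarray,
    n: int,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    min_sep: float,
    avoid: np.ndarray | None = None,
    avoid_sep: float = 0.0,
    max_tries: int = 400,
) -> np.ndarray:
    """Rejection-sample n points (um) with pairwise and avoidance separations."""
    pts: list[np.ndarray] = []
    span = bounds_hi - bounds_lo
    if np.any(span <= 0):
        raise ValueError("geometry too small for the requested puncta")
    for _ in range(n):
        for attempt in range(max_tries):
            p = bounds_lo + rng.random(3) * span
            ok = all(np.linalg.norm(p - q) >= min_sep for q in pts)
            if ok and avoid is not None and avoid.size:
                ok = np.min(np.linalg.norm(avoid - p, axis=1)) >= avoid_sep
            if ok:
                pts.append(p)
                break
        else:
            raise ValueError(
                f"geometry too small: could not place {n} puncta with separation {min_sep:.2f} um"
            )
    return np.asarray(pts).reshape(n, 3)


def gen_dendrite_stack(
    length_um: float = 30.0,
    n_puncta: tuple[int, int] = (40, 40),
    coincidence: float = 0.5,
    amplitude: tuple[float, float] = (80.0, 80.0),
    radius_um: float = 0.4,
    psf_sigma_um: float = 0.2,
    noise_sd: float = 10.0,
    poisson: bool = False,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    shaft_halfwidth_um: float = 2.0,
    margin_um: float = 0.5,
    min_separation_um: float | None = None,
    channel_names: tuple[str, str] = ("A", "B"),
    seed: int | None = None,
) -> tuple[ImageStack, tuple[GroundTruthPuncta, GroundTruthPuncta]]:
    """Render a two-channel dendrite stack with a controlled coincidence fraction.

    Puncta are 3D Gaussians (sigma = radius/2) placed along a dendrite shaft,
    blurred by a Gaussian PSF, then corrupted by optional Poisson noise and
    additive Gaussian noise. ``amplitude`` is the post-PSF peak intensity of
    a punctum, so amplitude/noise_sd is the peak SNR. Exactly
    ``round(coincidence * n_puncta[0])`` channel-A puncta are placed within
    one voxel of a channel-B partner; the remaining A puncta are kept at
    least three radii from every B punctum so ground-truth coincidence is
    unambiguous.
    """
    if not 0.0 <= coincidence <= 1.0:
        raise ValueError("coincidence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dz, dy, dx = voxel_size
    vox = np.asarray(voxel_size)

    z_extent = 4.0
    y_extent = 2.0 * (shaft_halfwidth_um + margin_um)
    x_extent = length_um
    shape = tuple(int(np.ceil(e / s)) for e, s in zip((z_extent, y_extent, x_extent), vox))

    lo = np.array([margin_um, margin_um, margin_um])
    hi = np.array([z_extent - margin_um, y_extent - margin_um, x_extent - margin_um])
    min_sep = min_separation_um if min_separation_um is not None else 4.0 * radius_um

    n_a, n_b = n_puncta
    n_coinc = int(round(coincidence * n_a))
    if n_coinc > min(n_a, n_b):
        raise ValueError("coincidence fraction demands more pairs than puncta available")

    centers_b = _place_points(rng, n_b, lo, hi, min_sep)
    partners = rng.choice(n_b, size=n_coinc, replace=False)
    jitter_um = (rng.random((n_coinc, 3)) * 2.0 - 1.0) * vox  # <= 1 voxel per axis
    coinc_a = centers_b[partners] + jitter_um
    coinc_a = np.clip(coinc_a, lo, hi)
    free_a = _place_points(
        rng, n_a - n_coinc, lo, hi, min_sep, avoid=centers_b, avoid_sep=3.0 * radius_um
    )
    centers_a = np.concatenate([coinc_a, free_a]) if n_a else np.zeros((0, 3))
    # interleave so coincident puncta are not positionally ordered
    order = rng.permutation(n_a)
    centers_a = centers_a[order]
    coincident_with_a = np.full(n_a, -1, dtype=int)
    coincident_with_b = np.full(n_b, -1, dtype=int)
    inv = np.argsort(order)
    for k, j in enumerate(partners):
        ai = int(inv[k])
        coincident_with_a[ai] = int(j)
        coincident_with_b[int(j)] = ai

    sigma_um = radius_um / 2.0
    psf_vox = psf_sigma_um / vox if psf_sigma_um > 0 else np.zeros(3)
    sigma_vox = sigma_um / vox
    # pre-compensate Gaussian-on-Gaussian peak attenuation so the rendered
    # post-PSF peak equals the requested amplitude
    atten = float(np.prod(sigma_vox / np.sqrt(sigma_vox**2 + psf_vox**2)))

    def render(centers_um: np.ndarray, amp: float) -> np.ndarray:
        img = np.zeros(shape)
        for c_um in centers_um:
            c = c_um / vox
            lo_i = np.maximum(0, np.floor(c - 3 * sigma_vox).astype(int))
            hi_i = np.minimum(shape, np.ceil(c + 3 * sigma_vox).astype(int) + 1)
            grids = np.meshgrid(
                *[np.arange(a, b, dtype=float) for a, b in zip(lo_i, hi_i)], indexing="ij"
            )
            d2 = sum(((g - cc) / s) ** 2 for g, cc, s in zip(grids, c, sigma_vox))
            img[tuple(slice(a, b) for a, b in zip(lo_i, hi_i))] += (
                amp / atten * np.exp(-0.5 * d2)
            )
        if psf_sigma_um > 0:
            img = ndimage.gaussian_filter(img, sigma=psf_vox)
        return img

    chan_a = render(centers_a, amplitude[0])
    chan_b = render(centers_b, amplitude[1])
    voxels = np.stack([chan_a, chan_b])
    if poisson:
        voxels = rng.poisson(np.clip(voxels, 0, None)).astype(float)
    if noise_sd > 0:
        voxels = voxels + rng.normal(0.0, noise_sd, voxels.shape)
    voxels = np.clip(voxels, 0.0, None)

    stack = ImageStack(voxels, voxel_size, list(channel_names), bit_depth=16)
    gt_a = GroundTruthPuncta(
        centers_vox=centers_a / vox,
        amplitudes=np.full(n_a, amplitude[0]),
        radii_um=np.full(n_a, radius_um),
        channel=channel_names[0],
        coincident_with=coincident_with_a,
        voxel_size=voxel_size,
    )
    gt_b = GroundTruthPuncta(
        centers_vox=centers_b / vox,
        amplitudes=np.full(n_b, amplitude[1]),
        radii_um=np.full(n_b, radius_um),
        channel=channel_names[1],
        coincident_with=coincident_with_b,
        voxel_size=voxel_size,
    )
    return stack, (gt_a, gt_b)


# ---------------------------------------------------------------------------
# Miniature EPSC traces
# ---------------------------------------------------------------------------

def gen_mepsc_trace(
    duration_s: float = 60.0,
    rate_hz: float = 1.0,
    amp_median_pa: float = 20.0,
    amp_sigma: float = 0.3,
    rise_tau_ms: float = 0.5,
    decay_tau_ms: float = 5.0,
    noise_sd_pa: float = 3.0,
    fs: float = 20000.0,
    seed: int | None = None,
) -> tuple[Trace, GroundTruthEvents]:
    """Synthesize a voltage-clamp trace of miniature EPSCs on Gaussian noise.

    Events occur at Poisson times with lognormal amplitudes
    (median ``amp_median_pa``, log-sd ``amp_sigma``) and are rendered as
    negative-going (inward) unit-peak difference-of-exponential waveforms
    scaled to each event's amplitude.
    """
    if decay_tau_ms <= rise_tau_ms:
        raise ValueError("decay_tau must exceed rise_tau")
    if rate_hz < 0:
        raise ValueError("rate must be nonnegative")
    if fs <= 2.0 / (rise_tau_ms * 1e-3):
        raise ValueError("sampling rate too low to resolve the rise time")
    rng = np.random.default_rng(seed)
    n_samp = int(round(duration_s * fs))
    trace = np.zeros(n_samp)

    n_ev = rng.poisson(rate_hz * duration_s)
    onsets = np.sort(rng.random(n_ev) * duration_s)
    onsets = np.unique(onsets)  # enforce strictly increasing
    amps = amp_median_pa * np.exp(amp_sigma * rng.standard_normal(onsets.size))

    kern_len = int(round(8 * decay_tau_ms * 1e-3 * fs))
    kern = _epsc_kernel(np.arange(kern_len) / fs, rise_tau_ms, decay_tau_ms)
    for on, amp in zip(onsets, amps):
        i0 = int(round(on * fs))
        i1 = min(n_samp, i0 + kern_len)
        if i0 < n_samp:
            trace[i0:i1] -= amp * kern[: i1 - i0]
    if noise_sd_pa > 0:
        trace = trace + rng.normal(0.0, noise_sd_pa, n_samp)

    gt = GroundTruthEvents(
        onset_times_s=onsets,
        amplitudes_pa=amps,
        rise_tau_ms=rise_tau_ms,
        decay_tau_ms=decay_tau_ms,
    ) if onsets.size else GroundTruthEvents(
        onset_times_s=np.empty(0),
        amplitudes_pa=np.empty(0),
        rise_tau_ms=rise_tau_ms,
        decay_tau_ms=decay_tau_ms,
    )
    return Trace(samples=trace, fs=fs, holding_potential=-60.0), gt


# ---------------------------------------------------------------------------
# Evoked I/V sweep families
# ---------------------------------------------------------------------------

def gen_iv_sweeps(
    model: RectificationModel,
    potentials_mv=(-60, -40, -20, 0, 20, 40, 60),
    rise_tau_ms: float = 1.0,
    decay_tau_ms: float = 8.0,
    noise_sd_pa: float = 0.0,
    n_trials: int = 3,
    sweep_duration_s: float = 0.05,
    stim_time_s: float = 0.01,
    fs: float = 20000.0,
    seed: int | None = None,
) -> tuple[dict[float, Trace], float]:
    """Evoked EPSC sweeps at several holding potentials, plus the true RI.

    Each sweep is the unit-peak EPSC template scaled to the model's peak
    current at that potential (so the noiseless peak equals
    g(V)·(V − v_rev) exactly), stored as the average of ``n_trials`` noisy
    trials (the usual evoked-EPSC protocol); the true RI is the closed-form
    ratio of the noiseless peak I/V regression slopes on the two branches.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    v = np.asarray(potentials_mv, dtype=float)
    if np.all(v <= model.v_rev_mv) or np.all(v >= model.v_rev_mv):
        raise ValueError("potentials must span both sides of the reversal potential")
    rng = np.random.default_rng(seed)
    n_samp = int(round(sweep_duration_s * fs))
    i_stim = int(round(stim_time_s * fs))
    kern = _epsc_kernel(np.arange(n_samp - i_stim) / fs, rise_tau_ms, decay_tau_ms)
    sweeps: dict[float, Trace] = {}
    for pot in v:
        sw = np.zeros(n_samp)
        sw[i_stim:] = float(model.peak_current_pa(pot)) * kern
        if noise_sd_pa > 0:
            sw = sw + rng.normal(0.0, noise_sd_pa, (n_trials, n_samp)).mean(axis=0)
        sweeps[float(pot)] = Trace(
            samples=sw, fs=fs, holding_potential=float(pot), stim_time_s=stim_time_s
        )
    return sweeps, model.true_ri(v)


# ---------------------------------------------------------------------------
# Spine time-lapses
# ---------------------------------------------------------------------------

def gen_spine_timelapse(
    n_spines: int = 17,
    baseline_f0: float = 100.0,
    transient_pct: float = 50.0,
    baseline_s: float = 300.0,
    stim_s: float = 150.0,
    return_s: float = 60.0,
    wash_s: float = 300.0,
    frame_interval_s: float = 50.0,
    noise_sd_frac: float = 0.05,
    seed: int | None = None,
) -> tuple[list[RoiSeries], dict]:
    """Spine fluorescence time-lapses with a stimulus-locked plateau transient.

    The protocol mirrors high-K+ depolarization imaging: a baseline period,
    a stimulus window during which fluorescence sits at
    F0·(1 + transient_pct/100), a linear return to F0 over ``return_s``, and
    a washout at exactly F0. Frames are captured every ``frame_interval_s``
    (40-60 s); i.i.d. Gaussian noise of SD ``noise_sd_frac``·F0 is added.
    """
    if not 40.0 <= frame_interval_s <= 60.0:
        raise ValueError("frame interval must lie in [40, 60] s")
    total = baseline_s + stim_s + return_s + wash_s
    stim_window = (baseline_s, baseline_s + stim_s)
    if stim_window[1] + return_s > total:
        raise ValueError("stimulus window (with return) outside the recording")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, total + 1e-9, frame_interval_s)
    plateau = baseline_f0 * (1.0 + transient_pct / 100.0)
    f = np.full_like(t, baseline_f0)
    in_stim = (t >= stim_window[0]) & (t <= stim_window[1])
    f[in_stim] = plateau
    in_ret = (t > stim_window[1]) & (t < stim_window[1] + return_s)
    frac = (t[in_ret] - stim_window[1]) / return_s
    f[in_ret] = plateau + (baseline_f0 - plateau) * frac

    wash_window = (stim_window[1] + return_s, float(t[-1]))
    series = []
    for k in range(n_spines):
        noise = rng.normal(0.0, noise_sd_frac * baseline_f0, t.size) if noise_sd_frac > 0 else 0.0
        series.append(
            RoiSeries(
                roi_id=f"spine{k}",
                frame_times=t,
                mean_intensity=np.clip(f + noise, 0.0, None),
                baseline_window=(0.0, stim_window[0]),
                stim_window=stim_window,
                wash_window=wash_window,
            )
        )
    truth = {
        "f0": baseline_f0,
        "plateau": plateau,
        "transient_pct": transient_pct,
        "stim_window": stim_window,
        "wash_window": wash_window,
    }
    return series, truth
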