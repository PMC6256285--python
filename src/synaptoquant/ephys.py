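"""Miniature-EPSC detection/kinetics and evoked I/V rectification analysis.

Sign convention: inward (excitatory, at negative holding potential) currents
are negative in storage; reported event amplitudes are positive magnitudes.

The mini detector is a documented stand-in for unpublished lab software:
noise is estimated robustly from the high-frequency residual
(MAD x 1.4826), and events are negative-going deflections of the low-pass-
filtered trace exceeding ``threshold_sd`` noise SDs, separated by a refractory
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats


@dataclass
class Trace:
    """A current recording: samples in pA at a fixed sampling rate."""

    samples: np.ndarray
    fs: float
    holding_potential: float | None = None  # mV
    cell_id: str | None = None
    condition: str | None = None
    stim_time_s: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class MiniEvent:
    """One detected synaptic event with its kinetic measurements."""

    onset_s: float
    peak_amplitude_pa: float          # positive magnitude of the inward peak
    rise_time_10_90_ms: float | None
    decay_tau_ms: float | None
    decay_t37_ms: float | None        # time from peak to 37% of amplitude
    charge_pa_ms: float | None
    baseline_pa: float


@dataclass
class IVAnalysis:
    """Current-voltage analysis of evoked EPSC peak responses.

    ``ri`` is the rectification index: the ratio of the I/V regression slope
    over the branch negative to the reversal potential to the slope over the
    positive branch. RI > 1 signals inward rectification (GluA2-lacking,
    polyamine-blocked AMPA receptors).
    """

    potentials_mv: np.ndarray
    peak_currents_pa: np.ndarray
    v_rev_est_mv: float
    slope_neg_ns: float | None
    slope_pos_ns: float | None
    ri: float | None
    normalized_currents: np.ndarray = field(default=None)


# ---------------------------------------------------------------------------
# Miniature EPSC detection
# ---------------------------------------------------------------------------

def _lowpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    sos = signal.butter(4, cutoff_hz / (fs / 2.0), btype="low", output="sos")
    return signal.sosfiltfilt(sos, x)


def estimate_noise_sd(trace: Trace, lp_cutoff_hz: float = 1000.0) -> float:
    """Robust noise SD: MAD x 1.4826 of the high-pass residual."""
    low = _lowpass(trace.samples, trace.fs, lp_cutoff_hz)
    resid = trace.samples - low
    return float(stats.median_abs_deviation(resid, scale="normal"))


def detect_minis(
    trace: Trace,
    threshold_sd: float = 3.5,
    min_interval_ms: float = 5.0,
    lp_cutoff_hz: float = 1000.0,
) -> list[float]:
    """Detect miniature EPSC onsets (seconds) in a voltage-clamp trace.

    Events are negative-going deflections of the low-pass-filtered,
    median-baselined trace whose trough exceeds ``threshold_sd`` times the
    robust noise SD; troughs closer than ``min_interval_ms`` are merged.
    The onset is placed where the deflection last crossed 10% of the trough
    depth before the trough. Detection is invariant to a DC offset.
    """
    if trace.fs < 2.0 * lp_cutoff_hz:
        raise ValueError("sampling rate must be at least twice the low-pass cutoff")
    if trace.duration_s < 1.0:
        raise ValueError("trace must be >= 1 s for noise estimation")
    low = _lowpass(trace.samples, trace.fs, lp_cutoff_hz)
    noise_sd = estimate_noise_sd(trace, lp_cutoff_hz)
    depth = -(low - np.median(low))  # positive-going event depth
    thr = threshold_sd * noise_sd
    if thr <= 0:  # noiseless trace: any deflection at all counts
        thr = max(1e-9, 1e-6 * max(1.0, np.max(np.abs(depth))))
    distance = max(1, int(round(min_interval_ms * 1e-3 * trace.fs)))
    # prominence rather than height: a bump riding a decaying arm must climb
    # the threshold itself, so one event is not re-detected during its decay
    peaks, _ = signal.find_peaks(depth, height=thr, prominence=thr, distance=distance)
    onsets: list[float] = []
    for p in peaks:
        level = 0.1 * depth[p]
        i = p
        while i > 0 and depth[i] > level:
            i -= 1
        onsets.append(i / trace.fs)
    return onsets


def event_kinetics(
    trace: Trace,
    onset_s: float,
    window_ms: float = 50.0,
    baseline_ms: float = 3.0,
    next_onset_s: float | None = None,
) -> MiniEvent:
    """Measure amplitude, 10-90% rise, decay tau, 37% decay time and charge.

    * amplitude: baseline minus trough (reported as positive pA);
    * rise: interpolated 10->90% crossing times on the falling edge;
    * decay: single-exponential tau fitted from one time-to-peak past the
      trough (where the rising exponential has died away) to 5 guessed taus,
      the guess being the 37%-of-amplitude crossing; fit failure leaves the
      tau missing but keeps the event;
    * charge: integral of (baseline - I) from onset to return-to-baseline or
      the window end, in pA.ms.
    """
    fs = trace.fs
    x = trace.samples
    i_on = int(round(onset_s * fs))
    if not (0 <= i_on < x.size):
        raise ValueError("onset outside trace")
    i_end = min(x.size, i_on + int(round(window_ms * 1e-3 * fs)))
    if next_onset_s is not None:  # truncate at the following event
        i_end = min(i_end, int(round(next_onset_s * fs)))
    n_base = int(round(baseline_ms * 1e-3 * fs))
    b0 = max(0, i_on - n_base)
    baseline = float(np.mean(x[b0:i_on])) if i_on > b0 else float(x[i_on])
    seg = baseline - x[i_on:i_end]  # positive-going deflection
    if seg.size < 3:
        raise ValueError("event window too short")
    i_pk = int(np.argmax(seg))
    amp = float(seg[i_pk])

    def _cross(level: float, lo: int, hi: int, rising: bool) -> float | None:
        """Interpolated index where seg crosses `level` in [lo, hi)."""
        for i in range(lo, hi - 1):
            a, b = seg[i], seg[i + 1]
            if (rising and a < level <= b) or (not rising and a >= level > b):
                return i + (level - a) / (b - a)
        return None

    t10 = _cross(0.1 * amp, 0, i_pk + 1, rising=True)
    t90 = _cross(0.9 * amp, 0, i_pk + 1, rising=True)
    rise_ms = (t90 - t10) / fs * 1e3 if (t10 is not None and t90 is not None) else None

    t37 = _cross(np.exp(-1.0) * amp, i_pk, seg.size, rising=False)
    decay_t37_ms = (t37 - i_pk) / fs * 1e3 if t37 is not None else None

    decay_tau_ms = None
    if decay_t37_ms is not None and decay_t37_ms > 0:
        tau_guess = decay_t37_ms
        # start one time-to-peak after the trough so the rising exponential
        # no longer contaminates the single-exponential fit
        start = min(seg.size - 3, i_pk + max(1, i_pk - 0))
        stop = min(seg.size, i_pk + int(round(5 * tau_guess * 1e-3 * fs)))
        if stop - start >= 3:
            t = (np.arange(start, stop) - i_pk) / fs * 1e3  # ms from peak
            y = seg[start:stop]
            try:
                popt, _ = optimize.curve_fit(
                    lambda tt, a, tau: a * np.exp(-tt / tau),
                    t,
                    y,
                    p0=(amp, tau_guess),
                    maxfev=2000,
                )
                if popt[1] > 0:
                    decay_tau_ms = float(popt[1])
            except RuntimeError:
                decay_tau_ms = None

    # charge: onset to first return to baseline after the trough
    i_ret = None
    for i in range(i_pk, seg.size):
        if seg[i] <= 0:
            i_ret = i
            break
    stop_q = i_ret if i_ret is not None else seg.size
    charge = float(np.trapezoid(seg[:stop_q], dx=1.0 / fs) * 1e3)  # pA.ms

    return MiniEvent(
        onset_s=i_on / fs,
        peak_amplitude_pa=amp,
        rise_time_10_90_ms=rise_ms,
        decay_tau_ms=decay_tau_ms,
        decay_t37_ms=decay_t37_ms,
        charge_pa_ms=charge,
        baseline_pa=baseline,
    )


def analyze_minis(trace: Trace, **detect_kwargs) -> list[MiniEvent]:
    """Detect events then measure kinetics for each, truncating at neighbors."""
    onsets = detect_minis(trace, **detect_kwargs)
    events = []
    for k, on in enumerate(onsets):
        nxt = onsets[k + 1] if k + 1 < len(onsets) else None
        try:
            events.append(event_kinetics(trace, on, next_onset_s=nxt))
        except ValueError:  # window fully truncated by a neighbor: unmeasurable
            continue
    return events


def ensemble_average(
    trace: Trace,
    onsets_s: list[float],
    pre_ms: float = 5.0,
    post_ms: float = 50.0,
) -> np.ndarray:
    """Pointwise mean of baseline-subtracted snippets aligned at onset.

    Snippets running past either end of the trace are dropped.
    """
    if len(onsets_s) < 1:
        raise ValueError("need at least one event")
    fs = trace.fs
    n_pre = int(round(pre_ms * 1e-3 * fs))
    n_post = int(round(post_ms * 1e-3 * fs))
    snips = []
    for on in onsets_s:
        i = int(round(on * fs))
        if i - n_pre < 0 or i + n_post > trace.samples.size:
            continue
        snip = trace.samples[i - n_pre : i + n_post].astype(float)
        base = np.mean(snip[:n_pre]) if n_pre > 0 else snip[0]
        snips.append(snip - base)
    if not snips:
        raise ValueError("no event fits inside the trace")
    return np.mean(snips, axis=0)


# ---------------------------------------------------------------------------
# Evoked I/V rectification
# ---------------------------------------------------------------------------

def correct_junction_potential(command_potentials_mv, ljp_mv: float = 18.0):
    """Liquid-junction-potential correction: V_corrected = V_command - LJP."""
    v = np.asarray(command_potentials_mv, dtype=float)
    out = v - ljp_mv
    return float(out) if out.ndim == 0 else out


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xm, ym = x.mean(), y.mean()
    return float(np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2))


def measure_peak_current(
    trace: Trace,
    window_half_ms: float = 1.5,
    post_stim_band_ms: tuple[float, float] = (3.0, 6.0),
    anchor: str = "peak",
) -> float:
    """Signed peak current (pA) of an evoked sweep, baseline-subtracted.

    The peak is the extremum of |I - baseline| after the stimulus; the
    returned value averages samples around it. Two window conventions are
    provided for the "within 3-6 ms of peak current" rule:

    * ``anchor='peak'`` (default): mean over peak +/- ``window_half_ms``,
      constrained to the 3-6 ms post-stimulus band when a stimulus time is
      recorded on the trace;
    * ``anchor='after_peak'``: mean over [peak, peak + 2*window_half_ms].
    """
    x = trace.samples
    fs = trace.fs
    if trace.stim_time_s is not None:
        i_stim = int(round(trace.stim_time_s * fs))
    else:
        i_stim = 0
    baseline = float(np.mean(x[:i_stim])) if i_stim > 1 else 0.0
    dev = x[i_stim:] - baseline
    i_pk = i_stim + int(np.argmax(np.abs(dev)))
    half = int(round(window_half_ms * 1e-3 * fs))
    if anchor == "peak":
        lo, hi = i_pk - half, i_pk + half + 1
    elif anchor == "after_peak":
        lo, hi = i_pk, i_pk + 2 * half + 1
    else:
        raise ValueError("anchor must be 'peak' or 'after_peak'")
    if trace.stim_time_s is not None:
        band_lo = i_stim + int(round(post_stim_band_ms[0] * 1e-3 * fs))
        band_hi = i_stim + int(round(post_stim_band_ms[1] * 1e-3 * fs)) + 1
        lo, hi = max(lo, band_lo), min(hi, band_hi)
    lo = max(lo, 0)
    hi = min(hi, x.size)
    if hi <= lo:
        lo, hi = i_pk, i_pk + 1
    return float(np.mean(x[lo:hi]) - baseline)


def rectification_analysis(
    sweeps: dict[float, Trace] | list[Trace],
    window_half_ms: float = 1.5,
    anchor: str = "peak",
) -> IVAnalysis:
    """Rectification index from a family of evoked sweeps across potentials.

    Peak currents are measured per sweep, the reversal potential estimated by
    linear interpolation of the I/V zero crossing, and separate OLS slopes
    fitted to the branches below and above it. RI = slope_neg / slope_pos.
    The normalized I/V divides by |I| at the most negative potential.
    """
    if isinstance(sweeps, dict):
        items = sorted(sweeps.items())
        potentials = np.array([v for v, _ in items], dtype=float)
        traces = [t for _, t in items]
    else:
        traces = sorted(sweeps, key=lambda t: t.holding_potential)
        potentials = np.array([t.holding_potential for t in traces], dtype=float)
    if potentials.size < 2:
        raise ValueError("need sweeps at >= 2 holding potentials")
    # The peak window is anchored once, on the sweep with the largest
    # response, and reused for every sweep (the common shaded measurement
    # window across traces): near-reversal and strongly blocked sweeps are
    # noise-dominated and would otherwise anchor their window on noise.
    def _dev(t: Trace) -> np.ndarray:
        i_stim = int(round((t.stim_time_s or 0.0) * t.fs))
        base = float(np.mean(t.samples[:i_stim])) if i_stim > 1 else 0.0
        return t.samples[i_stim:] - base, i_stim, base

    ref = max(traces, key=lambda t: np.max(np.abs(_dev(t)[0])))
    ref_dev, ref_stim, _ = _dev(ref)
    pk_offset = int(np.argmax(np.abs(ref_dev)))  # samples after stimulus
    peaks = np.empty(potentials.size)
    for k, t in enumerate(traces):
        dev, i_stim, base = _dev(t)
        fs = t.fs
        half = int(round(window_half_ms * 1e-3 * fs))
        if anchor == "peak":
            lo, hi = pk_offset - half, pk_offset + half + 1
        elif anchor == "after_peak":
            lo, hi = pk_offset, pk_offset + 2 * half + 1
        else:
            raise ValueError("anchor must be 'peak' or 'after_peak'")
        if t.stim_time_s is not None:
            band_lo = int(round(3.0e-3 * fs))
            band_hi = int(round(6.0e-3 * fs)) + 1
            lo, hi = max(lo, band_lo), min(hi, band_hi)
        lo = max(lo, 0)
        hi = min(hi, dev.size)
        if hi <= lo:
            lo, hi = pk_offset, pk_offset + 1
        peaks[k] = float(np.mean(dev[lo:hi]))

    # reversal potential: interpolated zero crossing of the I/V relation
    v_rev = None
    for i in range(potentials.size - 1):
        a, b = peaks[i], peaks[i + 1]
        if a == 0:
            v_rev = potentials[i]
            break
        if a * b < 0:
            v_rev = potentials[i] - a * (potentials[i + 1] - potentials[i]) / (b - a)
            break
    if v_rev is None:
        raise ValueError("I/V relation does not cross zero; reversal potential undefined")

    neg = potentials < v_rev
    pos = potentials > v_rev
    # the on-reversal point (if any potential equals v_rev) joins the negative branch
    on_rev = potentials == v_rev
    neg = neg | on_rev
    slope_neg = _ols_slope(potentials[neg], peaks[neg]) if neg.sum() >= 2 else None
    slope_pos = _ols_slope(potentials[pos], peaks[pos]) if pos.sum() >= 2 else None
    ri = (
        slope_neg / slope_pos
        if (slope_neg is not None and slope_pos is not None and slope_pos != 0)
        else None
    )
    i_min = int(np.argmin(potentials))
    denom = abs(peaks[i_min])
    normalized = peaks / denom if denom > 0 else np.full_like(peaks, np.nan)
    return IVAnalysis(
        potentials_mv=potentials,
        peak_currents_pa=peaks,
        v_rev_est_mv=float(v_rev),
        slope_neg_ns=slope_neg,
        slope_pos_ns=slope_pos,
        ri=ri,
        normalized_currents=normalized,
    )


def qc_series_resistance(rs_mohm) -> bool:
    """Series-resistance QC: fail (False) if Rs rose > 20% above its first value."""
    rs = np.asarray(rs_mohm, dtype=float)
    if rs.size < 2:
        raise ValueError("need >= 2 series-resistance readings")
    if np.any(rs <= 0):
        raise ValueError("series resistance must be positive")
    return bool(np.max(rs) / rs[0] <= 1.20)
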