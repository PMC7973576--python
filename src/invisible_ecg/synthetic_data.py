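"""Synthetic paired two-device ECG recordings with full ground truth.

The generator stands in for the study-style data this pipeline analyses:
one device carries a gel-electrode reference ECG (Lead-I-like morphology)
plus an LED synchronization channel; the second device carries one or more
dry-electrode experimental ECG channels plus a luminosity channel that sees
the same LED pulses delayed by a configurable inter-device offset.

Everything downstream needs ground truth to be testable, so the generator
returns exact R-peak times, the NN-interval series, saturation windows and
the true offset alongside the two :class:`~.acquisition_io.RawRecording`\\ s.

RR model
--------
NN intervals follow a stationary AR(1) process. Its two parameters are
fixed in closed form by the requested SDNN and SDSD:

    phi      = 1 - SDSD^2 / (2 SDNN^2)
    var(eps) = SDNN^2 (1 - phi^2)

since for AR(1) ``var = var(eps)/(1-phi^2)`` and the successive-difference
variance is ``2 var (1 - phi)``. This is the simplest process for which both
targets are exactly attainable.

Artifact model
--------------
Dry-electrode contact loss is modelled as episodes during which the
experimental channel is clamped at an ADC rail (0 or full scale), the way a
saturated front end reports it. Band-limited Gaussian noise and sinusoidal
baseline wander emulate measurement noise and respiration/motion drift.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .acquisition_io import (
    ChannelRole,
    ChannelSpec,
    RawRecording,
    millivolts_to_adc,
)
from .errors import ParameterError


@dataclass
class SynthConfig:
    """Generator configuration.

    Parameters
    ----------
    duration : float
        Recording length in seconds (study sessions were 5 min).
    fs : float
        Sampling frequency, Hz.
    hr_mean : float
        Mean heart rate, BPM. Default 75, mid resting band (60-100 BPM).
    sdnn_target, sdsd_target : float
        Target SDNN / SDSD of the NN series, ms. Feasibility requires
        ``sdsd_target <= 2 * sdnn_target``.
    noise_rms : float
        RMS of additive Gaussian measurement noise, mV at the electrode.
    wander_amp, wander_freq : float
        Amplitude (mV) and frequency (Hz) of sinusoidal baseline wander.
    sat_rate : float
        Contact-loss episodes per minute on each experimental channel.
    sat_dur : float
        Duration of each saturation episode, seconds.
    sync_offset : int
        Device-B-minus-device-A delay in samples.
    n_sync_pulses : int
        Number of LED pulses.
    pulse_width : float or None
        Pulse width in seconds; ``None`` sizes pulses so they occupy about
        8% of the recording, keeping the pulse level visible to the
        percentile-based onset threshold.
    ecg_amp : float
        R-peak amplitude, mV at the electrode. The front end's full-scale
        range is +/-VCC/(2G) = +/-0.15 mV, so the default 0.1 mV uses about
        two thirds of the ADC range without clipping.
    n_exp_channels : int
        Number of experimental (dry-electrode) ECG channels on device B.
    seed : int
        Fixes all randomness.
    """

    duration: float = 300.0
    fs: float = 1000.0
    hr_mean: float = 75.0
    sdnn_target: float = 50.0
    sdsd_target: float = 30.0
    noise_rms: float = 0.003
    wander_amp: float = 0.01
    wander_freq: float = 0.3
    sat_rate: float = 0.0
    sat_dur: float = 1.0
    sync_offset: int = 250
    n_sync_pulses: int = 5
    pulse_width: float | None = None  # None: auto, ~8% duty cycle
    ecg_amp: float = 0.1
    n_exp_channels: int = 1
    adc_bits: int = 10
    vcc: float = 3.3
    gain: float = 11000.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise ParameterError("duration and fs must be positive")
        if not 20 <= self.hr_mean <= 240:
            raise ParameterError(f"hr_mean {self.hr_mean} BPM is not physiological")
        if self.sdnn_target < 0 or self.sdsd_target < 0:
            raise ParameterError("sdnn_target and sdsd_target must be >= 0")
        if self.sdnn_target > 0 and self.sdsd_target > 2 * self.sdnn_target:
            raise ParameterError(
                f"infeasible HRV targets: sdsd {self.sdsd_target} > 2*sdnn "
                f"{2 * self.sdnn_target} (AR(1) requires sdsd <= 2 sdnn)"
            )
        if self.n_exp_channels < 1:
            raise ParameterError("need at least one experimental channel")
        n_episodes = int(round(self.sat_rate * self.duration / 60.0))
        if n_episodes * self.sat_dur > 0.5 * self.duration:
            raise ParameterError(
                f"saturation episodes ({n_episodes} x {self.sat_dur}s) would cover "
                f"more than half of the {self.duration}s recording"
            )
        if abs(self.sync_offset) >= self.duration * self.fs / 2:
            raise ParameterError("sync_offset too large for this duration")


@dataclass
class GroundTruth:
    """Exact generation truth accompanying a synthetic pair.

    Times are seconds on each device's own clock: ``r_times_exp`` =
    ``r_times_ref`` + offset/fs. ``sat_windows`` maps experimental channel
    name to a list of (start, end) second pairs on device B's clock.
    """

    r_times_ref: list[float]
    r_times_exp: list[float]
    nn_ms: list[float]
    sat_windows: dict[str, list[tuple[float, float]]]
    true_offset: int
    pulse_times: list[float]

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), sort_keys=True), encoding="utf-8")
        return path


def generate_nn_series(
    hr_mean: float,
    sdnn_target: float,
    sdsd_target: float,
    n_beats: int,
    seed=None,
) -> np.ndarray:
    """Stationary AR(1) NN-interval series (ms) hitting SDNN/SDSD targets.

    ``seed`` may be an int or an existing :class:`numpy.random.Generator`.
    Population moments converge to the targets as ``n_beats`` grows; the
    first sample is drawn from the stationary distribution so the whole
    series is stationary.
    """
    if n_beats < 2:
        raise ParameterError(f"n_beats must be >= 2, got {n_beats}")
    if hr_mean <= 0:
        raise ParameterError("hr_mean must be positive")
    mean_ms = 60000.0 / hr_mean
    if sdnn_target < 0 or sdsd_target < 0:
        raise ParameterError("variability targets must be >= 0")
    if sdnn_target == 0:
        if sdsd_target != 0:
            raise ParameterError("sdsd_target must be 0 when sdnn_target is 0")
        return np.full(n_beats, mean_ms)
    phi = 1.0 - sdsd_target**2 / (2.0 * sdnn_target**2)
    if not -1.0 < phi <= 1.0:
        raise ParameterError(
            f"infeasible targets (AR coefficient {phi:.3f} outside (-1, 1]): "
            "require sdsd < 2 sdnn"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    innov_sd = sdnn_target * np.sqrt(max(1.0 - phi**2, 0.0))
    nn = np.empty(n_beats)
    nn[0] = mean_ms + rng.normal(0.0, sdnn_target)
    eps = rng.normal(0.0, innov_sd, size=n_beats - 1)
    for k in range(1, n_beats):
        nn[k] = mean_ms + phi * (nn[k - 1] - mean_ms) + eps[k - 1]
    # physiological floor; with default targets this never engages
    return np.maximum(nn, 250.0)


def beat_template(fs: float, amp: float = 0.1) -> tuple[np.ndarray, int]:
    """Fixed P-QRS-T beat waveform sampled at ``fs``.

    Returns ``(waveform_mV, r_offset)`` where ``r_offset`` is the sample
    index of the R maximum within the waveform. The shape is a sum of
    Gaussians with resting-ECG proportions: P and T waves, a dominant R
    spike, and small Q/S deflections — smooth, with a sharp R, which is all
    the Hamilton detector relies on.
    """
    t = np.arange(int(round(-0.25 * fs)), int(round(0.45 * fs))) / fs
    components = [  # (center s, width s, relative amplitude)
        (-0.17, 0.025, 0.12),  # P
        (-0.025, 0.010, -0.12),  # Q
        (0.0, 0.012, 1.00),  # R
        (0.030, 0.010, -0.22),  # S
        (0.22, 0.060, 0.30),  # T
    ]
    wave = np.zeros_like(t)
    for c, w, a in components:
        wave += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    wave *= amp
    r_offset = int(np.argmax(wave))
    return wave, r_offset


def _render_ecg(r_times: np.ndarray, n: int, fs: float, amp: float) -> np.ndarray:
    """Clean ECG in mV: the beat template stamped at each R time."""
    wave, r_off = beat_template(fs, amp)
    sig = np.zeros(n)
    for t in r_times:
        start = int(round(t * fs)) - r_off
        lo, hi = max(start, 0), min(start + wave.size, n)
        if hi > lo:
            sig[lo:hi] += wave[lo - start : hi - start]
    return sig


def _sat_windows(
    rng: np.random.Generator, duration: float, rate_per_min: float, sat_dur: float
) -> list[tuple[float, float]]:
    """Non-overlapping contact-loss windows: one per equal time slot.

    Placing one episode uniformly inside each of ``n`` equal slots keeps the
    episode count exact and windows disjoint without rejection sampling.
    """
    n = int(round(rate_per_min * duration / 60.0))
    if n == 0:
        return []
    slot = duration / n
    if sat_dur >= slot:
        raise ParameterError(
            f"sat_dur {sat_dur}s does not fit in the {slot:.1f}s episode slots"
        )
    starts = [i * slot + rng.uniform(0, slot - sat_dur) for i in range(n)]
    return [(s, s + sat_dur) for s in starts]


def _pulse_channel(
    n: int, fs: float, pulse_times: np.ndarray, width: float, adc_max: int
) -> np.ndarray:
    """Rectangular sync pulses as ADC counts: low floor, high plateau."""
    low, high = int(0.1 * adc_max), int(0.9 * adc_max)
    sig = np.full(n, low, dtype=np.int64)
    w = int(round(width * fs))
    for t in pulse_times:
        i = int(round(t * fs))
        if 0 <= i < n:
            sig[i : min(i + w, n)] = high
    return sig


def generate_pair(cfg: SynthConfig) -> tuple[RawRecording, RawRecording, GroundTruth]:
    """Generate the (reference device, experimental device, truth) triple.

    Device A holds ``ECG_REF`` + ``LED``; device B holds ``A1..An``
    experimental channels + ``LUX``, all delayed by ``cfg.sync_offset``
    samples. The clean waveform is shared between devices (same heart);
    measurement noise is drawn independently per channel, and saturation
    episodes affect only the experimental channels.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    offset = int(cfg.sync_offset)

    # --- ground-truth beat times ------------------------------------------
    n_beats_max = int(cfg.duration * cfg.hr_mean / 60.0 * 1.5) + 10
    nn_all = generate_nn_series(
        cfg.hr_mean, cfg.sdnn_target, cfg.sdsd_target, n_beats_max, rng
    )
    r_times = 0.5 + np.cumsum(np.concatenate([[0.0], nn_all])) / 1000.0
    r_times = r_times[r_times < cfg.duration - 0.5]
    nn_ms = np.diff(r_times) * 1000.0

    clean = _render_ecg(r_times, n, cfg.fs, cfg.ecg_amp)
    t_axis = np.arange(n) / cfg.fs
    wander_phase = rng.uniform(0, 2 * np.pi)
    wander = cfg.wander_amp * np.sin(2 * np.pi * cfg.wander_freq * t_axis + wander_phase)
    base = clean + wander

    # --- sync pulses -------------------------------------------------------
    pulse_width = (
        cfg.pulse_width
        if cfg.pulse_width is not None
        else max(0.2, 0.08 * cfg.duration / cfg.n_sync_pulses)
    )
    margin = 1.0 + pulse_width
    if cfg.n_sync_pulses == 1:
        pulse_times = np.array([cfg.duration / 2.0])
    else:
        pulse_times = np.linspace(margin, cfg.duration - margin, cfg.n_sync_pulses)
        pulse_times = pulse_times + rng.uniform(-0.2, 0.2, size=cfg.n_sync_pulses)
    pulse_times = np.sort(pulse_times)

    spec_kw = dict(adc_bits=cfg.adc_bits, vcc=cfg.vcc, gain=cfg.gain)
    ref_spec = ChannelSpec("ECG_REF", ChannelRole.ECG_REF, **spec_kw)
    led_spec = ChannelSpec("LED", ChannelRole.LED, **spec_kw)
    adc_max = ref_spec.adc_max

    # --- device A: reference ----------------------------------------------
    ref_mv = base + (rng.normal(0, cfg.noise_rms, n) if cfg.noise_rms > 0 else 0.0)
    dev_a = RawRecording(
        channels=[ref_spec, led_spec],
        samples=np.column_stack(
            [
                millivolts_to_adc(ref_mv, ref_spec),
                _pulse_channel(n, cfg.fs, pulse_times, pulse_width, adc_max),
            ]
        ),
        fs=cfg.fs,
        device_id="deviceA",
        meta={"seed": cfg.seed},
    )

    # --- device B: experimental, delayed by `offset` samples ---------------
    # sample k of device B shows the instant (k - offset)/fs of device A
    def shift(sig_mv: np.ndarray) -> np.ndarray:
        out = np.zeros(n)
        if offset >= 0:
            out[offset:] = sig_mv[: n - offset]
        else:
            out[: n + offset] = sig_mv[-offset:]
        return out

    base_b = shift(base)
    exp_cols = []
    exp_specs = []
    sat_windows: dict[str, list[tuple[float, float]]] = {}
    for c in range(cfg.n_exp_channels):
        spec = ChannelSpec(f"A{c + 1}", ChannelRole.ECG_EXP, **spec_kw)
        mv = base_b + (rng.normal(0, cfg.noise_rms, n) if cfg.noise_rms > 0 else 0.0)
        counts = millivolts_to_adc(mv, spec)
        windows = _sat_windows(rng, cfg.duration, cfg.sat_rate, cfg.sat_dur)
        for w_start, w_end in windows:
            i0, i1 = int(round(w_start * cfg.fs)), int(round(w_end * cfg.fs))
            rail = adc_max if rng.random() < 0.5 else 0
            counts[i0:i1] = rail
        sat_windows[spec.name] = windows
        exp_cols.append(counts)
        exp_specs.append(spec)

    lux_times = pulse_times + offset / cfg.fs
    lux_spec = ChannelSpec("LUX", ChannelRole.LUMINOSITY, **spec_kw)
    dev_b = RawRecording(
        channels=exp_specs + [lux_spec],
        samples=np.column_stack(
            exp_cols
            + [_pulse_channel(n, cfg.fs, lux_times, pulse_width, adc_max)]
        ),
        fs=cfg.fs,
        device_id="deviceB",
        meta={"seed": cfg.seed},
    )

    truth = GroundTruth(
        r_times_ref=[float(t) for t in r_times],
        r_times_exp=[float(t + offset / cfg.fs) for t in r_times],
        nn_ms=[float(v) for v in nn_ms],
        sat_windows=sat_windows,
        true_offset=offset,
        pulse_times=[float(t) for t in pulse_times],
    )
    return dev_a, dev_b, truth
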