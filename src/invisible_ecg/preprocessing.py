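"""Digital conditioning and beat segmentation.

Three stages: a linear-phase FIR band-pass (order 300, 3-45 Hz, Hamming
window — the conventional conditioning for dry-electrode ECG, removing
baseline drift and mains/EMG noise while keeping QRS energy), Hamilton's
adaptive-threshold QRS detector, and fixed-window beat-template extraction
around each R peak.

The filter is applied forward-backward (zero phase) so that R-peak
latencies are not biased by the filter's group delay; the hardware analog
band [0.5; 40] Hz is assumed already applied upstream of these files.

Hamilton detector
-----------------
The detector follows the open-source Hamilton rules: band-limited
differentiation, rectification and an 80 ms moving-average integration
produce a detection function whose local maxima are classified QRS or noise
by an adaptive threshold ``noise + 0.3125 (peak - noise)`` maintained from
running medians of the last eight QRS and noise peak heights. A 200 ms
refractory period suppresses double fires, peaks within 360 ms of the last
QRS whose maximal slope is under half of the preceding QRS slope are
rejected as T waves, and if no QRS is found within 1.5x the running mean RR
a search-back pass re-examines rejected peaks at half threshold. Detected
events are finally snapped to the R maximum of the conditioned signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, ParameterError


class BeatLabel(str, Enum):
    NORMAL = "normal"
    OUTLIER = "outlier"


@dataclass(frozen=True)
class FilterSpec:
    """Linear-phase FIR band-pass description. ``order`` is taps - 1, even."""

    order: int = 300
    band: tuple[float, float] = (3.0, 45.0)
    window: str = "hamming"

    def __post_init__(self):
        if self.order % 2 != 0:
            raise ParameterError(f"order must be even (type-I FIR), got {self.order}")
        low, high = self.band
        if not 0 < low < high:
            raise ParameterError(f"need 0 < low < high, got band {self.band}")


@dataclass
class BeatSeries:
    """R-peak sample indices for one channel, with per-beat normality labels."""

    r_indices: np.ndarray
    fs: float
    labels: list[BeatLabel] = field(default_factory=list)

    def __post_init__(self):
        self.r_indices = np.asarray(self.r_indices, dtype=np.int64)
        if not self.labels:
            self.labels = [BeatLabel.NORMAL] * self.r_indices.size
        if len(self.labels) != self.r_indices.size:
            raise ParameterError("labels and r_indices length mismatch")
        if self.r_indices.size > 1 and np.any(np.diff(self.r_indices) <= 0):
            raise ParameterError("r_indices must be strictly increasing")

    @property
    def r_times(self) -> np.ndarray:
        """Beat times in seconds."""
        return self.r_indices / self.fs

    @property
    def n_beats(self) -> int:
        return self.r_indices.size


@dataclass
class BeatTemplateSet:
    """Fixed-length beat waveforms cut around each R peak.

    ``templates`` is (n_beats, window_samples) in mV. ``r_indices`` are the
    R positions of the *kept* beats (edge-truncated beats are dropped and
    listed in ``dropped_r_indices``). The distance/TP fields are filled by
    the morphology stage.
    """

    templates: np.ndarray
    window_ms: tuple[float, float]
    fs: float
    r_indices: np.ndarray
    dropped_r_indices: np.ndarray
    distances: np.ndarray | None = None
    mu_d: float | None = None
    sigma_d: float | None = None
    tp_percent: np.ndarray | None = None
    labels: list[BeatLabel] | None = None

    @property
    def n_beats(self) -> int:
        return self.templates.shape[0]

    @property
    def mean_template(self) -> np.ndarray:
        return self.templates.mean(axis=0)

    def kept_mask(self) -> np.ndarray:
        if self.labels is None:
            return np.ones(self.n_beats, dtype=bool)
        return np.array([lb == BeatLabel.NORMAL for lb in self.labels])


def design_bandpass(spec: FilterSpec, fs: float) -> np.ndarray:
    """FIR band-pass taps (``order + 1`` symmetric coefficients).

    The windowed design's transition band (~3.3 fs / taps, about 11 Hz for
    301 taps at 1 kHz) is wider than the 3 Hz lower edge, which would leak a
    few percent of DC and drift through; the taps are therefore re-centred
    to sum exactly to zero, which nulls DC while preserving symmetry and
    leaving the passband essentially untouched.
    """
    low, high = spec.band
    if high >= fs / 2:
        raise ParameterError(
            f"band {spec.band} exceeds Nyquist ({fs / 2} Hz) at fs={fs}"
        )
    taps = sps.firwin(
        spec.order + 1, [low, high], pass_zero=False, window=spec.window, fs=fs
    )
    return taps - taps.mean()


def apply_filter(x, taps) -> np.ndarray:
    """Zero-phase (forward-backward) FIR filtering; output length == input length."""
    x = np.asarray(x, dtype=float)
    taps = np.asarray(taps, dtype=float)
    if x.size <= taps.size:
        raise InsufficientDataError(
            f"signal ({x.size} samples) must be longer than the filter ({taps.size} taps)"
        )
    padlen = min(3 * taps.size, x.size - 1)
    return sps.filtfilt(taps, [1.0], x, padlen=padlen)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_rpeaks_hamilton(signal, fs: float) -> np.ndarray:
    """R-peak sample indices via Hamilton's adaptive-threshold rules.

    Expects a band-passed mV trace and ``fs >= 100`` Hz. A flat or empty
    signal yields an empty result (not an error). R peaks are assumed
    positive-dominant (Lead-I convention); each detection is refined to the
    maximum of ``signal`` within +/-100 ms of the detection-function peak.
    """
    x = np.asarray(signal, dtype=float)
    if fs < 100:
        raise ParameterError(f"fs must be >= 100 Hz, got {fs}")
    if x.size < int(0.5 * fs) or np.ptp(x) == 0:
        return np.array([], dtype=np.int64)

    slope = np.abs(np.diff(x, prepend=x[0]))
    detfun = _moving_average(slope, max(1, int(round(0.08 * fs))))

    cand, _ = sps.find_peaks(detfun, distance=max(1, int(round(0.05 * fs))))
    if cand.size == 0:
        return np.array([], dtype=np.int64)

    refractory = int(round(0.2 * fs))
    twave_win = int(round(0.36 * fs))
    slope_win = int(round(0.05 * fs))

    def max_slope(i: int) -> float:
        lo, hi = max(0, i - slope_win), min(slope.size, i + slope_win + 1)
        return float(slope[lo:hi].max())

    # initial estimates from the first two seconds of the detection function
    head = detfun[: int(2 * fs)]
    qrs_heights = [float(head.max())]
    noise_heights = [float(np.median(head))]
    qrs_idx: list[int] = []
    rejected: list[tuple[int, float]] = []  # (index, height) noise peaks
    rr_hist: list[float] = []
    mean_rr = fs  # prior: 60 BPM until measured

    def threshold() -> float:
        npk = float(np.median(noise_heights[-8:]))
        spk = float(np.median(qrs_heights[-8:]))
        return npk + 0.3125 * (spk - npk)

    def accept(i: int, height: float) -> None:
        nonlocal mean_rr
        if qrs_idx:
            rr_hist.append(i - qrs_idx[-1])
            mean_rr = float(np.mean(rr_hist[-8:]))
        qrs_idx.append(i)
        qrs_heights.append(height)

    for i in cand:
        h = float(detfun[i])
        if qrs_idx and i - qrs_idx[-1] < refractory:
            continue
        is_qrs = h > threshold()
        if (
            is_qrs
            and qrs_idx
            and i - qrs_idx[-1] < twave_win
            and max_slope(i) < 0.5 * max_slope(qrs_idx[-1])
        ):
            is_qrs = False  # T wave: close to previous QRS, much gentler slope
        if is_qrs:
            accept(i, h)
        else:
            noise_heights.append(h)
            rejected.append((i, h))
        # search-back: no QRS for 1.5x the running mean RR
        if qrs_idx and rr_hist and i - qrs_idx[-1] > 1.5 * mean_rr:
            window = [
                (j, hj)
                for j, hj in rejected
                if qrs_idx[-1] + refractory <= j <= i
            ]
            if window:
                j, hj = max(window, key=lambda p: p[1])
                if hj > 0.5 * threshold():
                    accept(j, hj)
                    qrs_idx.sort()
                    rejected = [(k, hk) for k, hk in rejected if k != j]

    if not qrs_idx:
        return np.array([], dtype=np.int64)

    # snap each detection to the R maximum of the conditioned trace
    half = int(round(0.1 * fs))
    refined = []
    for i in qrs_idx:
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(np.asarray(refined, dtype=np.int64))

    # enforce the refractory on the refined indices, keeping the taller peak
    final: list[int] = []
    for i in refined:
        if final and i - final[-1] < refractory:
            if x[i] > x[final[-1]]:
                final[-1] = int(i)
        else:
            final.append(int(i))
    return np.asarray(final, dtype=np.int64)


def extract_templates(
    signal,
    r_indices,
    fs: float,
    window_ms: tuple[float, float] = (200.0, 400.0),
) -> BeatTemplateSet:
    """Cut fixed windows (default 200 ms before R, 400 ms after) per beat.

    Beats whose window would run off either end of the signal are dropped
    and reported via ``dropped_r_indices``.

    Raises
    ------
    InsufficientDataError
        If no beat has full window support.
    """
    x = np.asarray(signal, dtype=float)
    r = np.asarray(r_indices, dtype=np.int64)
    pre = int(round(window_ms[0] * fs / 1000.0))
    post = int(round(window_ms[1] * fs / 1000.0))
    keep = (r - pre >= 0) & (r + post <= x.size)
    kept, dropped = r[keep], r[~keep]
    if kept.size == 0:
        raise InsufficientDataError("no beat has full template-window support")
    templates = np.stack([x[i - pre : i + post] for i in kept])
    return BeatTemplateSet(
        templates=templates,
        window_ms=window_ms,
        fs=fs,
        r_indices=kept,
        dropped_r_indices=dropped,
    )
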