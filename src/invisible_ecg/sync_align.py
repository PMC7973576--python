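"""Optical synchronization: pulse detection and inter-device alignment.

The two acquisition devices are electrically decoupled; an LED on device A
is observed by a luminosity sensor on device B, so the same rectangular
pulses appear in both streams separated by the (unknown) inter-device
offset. Alignment is a two-step estimate: detect pulse onsets per device,
then take the median of matched onset differences. The median is robust to
a missed or spurious pulse, which cross-correlating the full channels would
not be (the channels are otherwise unrelated signals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition_io import RawRecording
from .errors import AlignmentError

#: Minimum spacing between accepted pulse onsets (s).
REFRACTORY_S = 0.1


@dataclass
class SyncEvents:
    """Pulse onsets per device and the resulting offset estimate."""

    onsets_a: np.ndarray
    onsets_b: np.ndarray
    estimated_offset: int
    residual_jitter: float


def detect_pulses(signal, fs: float) -> np.ndarray:
    """Rising-edge pulse onsets in a sync channel.

    The threshold is the midpoint between the 5th and 95th percentile of the
    channel, which is insensitive to the duty cycle of the pulses. Onsets
    closer than 100 ms to the previous accepted onset are suppressed.

    Raises
    ------
    AlignmentError
        If the channel is flat (95th percentile equals 5th): no pulses.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise AlignmentError("signal too short for pulse detection")
    p5, p95 = np.percentile(x, [5, 95])
    if p95 <= p5:
        raise AlignmentError("flat sync channel: no pulses detectable")
    theta = 0.5 * (p5 + p95)
    above = x > theta
    rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        rising = np.concatenate([[0], rising])
    refractory = int(round(REFRACTORY_S * fs))
    onsets = []
    last = -np.inf
    for i in rising:
        if i - last >= refractory:
            onsets.append(i)
            last = i
    if not onsets:
        raise AlignmentError("no pulse onsets found above threshold")
    return np.asarray(onsets, dtype=np.int64)


def estimate_offset(onsets_a, onsets_b) -> tuple[int, float]:
    """Device-B-minus-device-A offset from matched pulse onsets.

    Onsets are matched greedily by smallest absolute time difference, each
    onset used at most once; the offset is the median of matched ``b - a``
    differences and the jitter their median absolute deviation.
    """
    a = np.sort(np.asarray(onsets_a, dtype=np.int64))
    b = np.sort(np.asarray(onsets_b, dtype=np.int64))
    if a.size == 0 or b.size == 0:
        raise AlignmentError("need at least one pulse onset per device")
    # all candidate pairs ranked by |difference|; greedy accept
    diffs = b[None, :] - a[:, None]
    order = np.argsort(np.abs(diffs), axis=None, kind="stable")
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for flat in order:
        i, j = divmod(int(flat), b.size)
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append(diffs[i, j])
        if len(matched) == min(a.size, b.size):
            break
    if not matched:
        raise AlignmentError("zero matched pulse pairs")
    matched = np.asarray(matched)
    offset = float(np.median(matched))
    jitter = float(np.median(np.abs(matched - offset)))
    return int(round(offset)), jitter


def sync_devices(rec_a: RawRecording, rec_b: RawRecording,
                 led_channel: str = "LED", lux_channel: str = "LUX") -> SyncEvents:
    """Detect pulses on both sync channels and estimate the offset."""
    onsets_a = detect_pulses(rec_a.channel(led_channel), rec_a.fs)
    onsets_b = detect_pulses(rec_b.channel(lux_channel), rec_b.fs)
    offset, jitter = estimate_offset(onsets_a, onsets_b)
    return SyncEvents(onsets_a, onsets_b, offset, jitter)


def align(rec_a: RawRecording, rec_b: RawRecording,
          offset: int) -> tuple[RawRecording, RawRecording]:
    """Trim both recordings to their common time support.

    ``offset`` is B minus A in samples: sample ``k`` of device B shows the
    same instant as sample ``k - offset`` of device A. The trimmed outputs
    have equal length and index ``i`` refers to the same instant in both.
    """
    na, nb = rec_a.n_samples, rec_b.n_samples
    i0 = max(0, -offset)           # first valid A index
    i1 = min(na, nb - offset)      # one past last valid A index
    if i1 <= i0:
        raise AlignmentError(
            f"no temporal overlap between devices for offset {offset}"
        )
    trimmed_a = RawRecording(
        channels=rec_a.channels,
        samples=rec_a.samples[i0:i1],
        fs=rec_a.fs,
        device_id=rec_a.device_id,
        meta=dict(rec_a.meta),
    )
    trimmed_b = RawRecording(
        channels=rec_b.channels,
        samples=rec_b.samples[i0 + offset : i1 + offset],
        fs=rec_b.fs,
        device_id=rec_b.device_id,
        meta=dict(rec_b.meta),
    )
    return trimmed_a, trimmed_b
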