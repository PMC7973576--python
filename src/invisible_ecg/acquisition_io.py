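"""Plain-text acquisition format I/O and ADC unit conversion.

The on-disk format is an OpenSignals-style dialect: three ``#``-prefixed
header lines (the middle one a JSON object) followed by a tab-separated
integer body, one column per channel::

    # BEGIN HEADER
    # {"fs": 1000, "bits": 10, "channels": [{"name": "ECG_REF", "role": "ecg_ref"}], ...}
    # END HEADER
    512	498
    513	501

Samples are raw ADC counts. The count-to-millivolt mapping follows the
symmetric single-supply convention

    mV = ((c / 2^n) - 0.5) * VCC / G * 1000

with VCC = 3.3 V and gain G = 11000 by default, so mid-scale maps to 0 mV.
The hardware this emulates amplifies the electrode signal 11,000x and
digitizes at 10 bit / 1 kHz; the full-scale input range is therefore
+/- VCC / (2 G) = +/-0.15 mV referred to the electrodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .errors import FormatError, ValidationError


class ChannelRole(str, Enum):
    """What a channel carries: reference ECG, experimental ECG, or a sync channel."""

    ECG_REF = "ecg_ref"
    ECG_EXP = "ecg_exp"
    LED = "led"
    LUMINOSITY = "luminosity"


#: Default supply voltage of the acquisition front end (V).
DEFAULT_VCC = 3.3
#: Default analog front-end gain (dimensionless).
DEFAULT_GAIN = 11000.0
#: Default ADC resolution (bits).
DEFAULT_BITS = 10


@dataclass(frozen=True)
class ChannelSpec:
    """Static description of one acquisition channel.

    Parameters
    ----------
    name : str
        Channel label, e.g. ``"A4"`` or ``"ECG_REF"``.
    role : ChannelRole
        Signal type carried by the channel.
    adc_bits : int
        ADC resolution in bits; counts live in ``[0, 2**adc_bits - 1]``.
    vcc : float
        Supply voltage in volts.
    gain : float
        Analog front-end gain.
    """

    name: str
    role: ChannelRole
    adc_bits: int = DEFAULT_BITS
    vcc: float = DEFAULT_VCC
    gain: float = DEFAULT_GAIN

    def __post_init__(self):
        if self.adc_bits < 1:
            raise ValidationError(f"adc_bits must be >= 1, got {self.adc_bits}")
        if self.gain <= 0:
            raise ValidationError(f"gain must be > 0, got {self.gain}")
        if self.vcc <= 0:
            raise ValidationError(f"vcc must be > 0, got {self.vcc}")

    @property
    def adc_max(self) -> int:
        return 2**self.adc_bits - 1


@dataclass
class RawRecording:
    """One device's multichannel integer acquisition.

    ``samples`` is an ``(n_samples, n_channels)`` integer array of ADC counts;
    column order matches ``channels``.
    """

    channels: list[ChannelSpec]
    samples: np.ndarray
    fs: float
    device_id: str = "device"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.int64)
        if self.samples.ndim == 1:
            self.samples = self.samples.reshape(-1, 1)
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if self.samples.shape[1] != len(self.channels):
            raise ValidationError(
                f"sample matrix has {self.samples.shape[1]} columns "
                f"but {len(self.channels)} channels declared"
            )
        for j, ch in enumerate(self.channels):
            col = self.samples[:, j]
            if col.size and (col.min() < 0 or col.max() > ch.adc_max):
                bad = int(np.argmax((col < 0) | (col > ch.adc_max)))
                raise ValidationError(
                    f"ADC value {col[bad]} out of range [0, {ch.adc_max}] "
                    f"at row {bad}, channel '{ch.name}'"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        for j, ch in enumerate(self.channels):
            if ch.name == name:
                return j
        raise KeyError(f"no channel named '{name}' in device '{self.device_id}'")

    def channel(self, name: str) -> np.ndarray:
        """Return the ADC count column for a named channel."""
        return self.samples[:, self.channel_index(name)]

    def channels_by_role(self, role: ChannelRole) -> list[str]:
        return [ch.name for ch in self.channels if ch.role == role]

    def __eq__(self, other) -> bool:
        if not isinstance(other, RawRecording):
            return NotImplemented
        return (
            self.channels == other.channels
            and self.fs == other.fs
            and self.device_id == other.device_id
            and self.samples.shape == other.samples.shape
            and bool(np.array_equal(self.samples, other.samples))
        )


def read_recording(path) -> RawRecording:
    """Parse a plain-text acquisition file into a :class:`RawRecording`.

    Round-trips bit-exactly with :func:`write_recording`.

    Raises
    ------
    FormatError
        If the header is missing or not valid JSON.
    ValidationError
        If a sample is outside the ADC range of its channel.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().split("\n")
    if len(lines) < 3 or not lines[0].startswith("#"):
        raise FormatError(f"{path}: missing '#'-prefixed header")
    header = None
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        stripped = line.lstrip("#").strip()
        if stripped.startswith("{"):
            try:
                header = json.loads(stripped)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}: header JSON invalid: {exc}") from exc
    else:
        body_start = len(lines)
    if header is None:
        raise FormatError(f"{path}: no JSON header line found")
    for key in ("fs", "bits", "channels"):
        if key not in header:
            raise FormatError(f"{path}: header missing key '{key}'")

    bits = int(header["bits"])
    vcc = header.get("vcc", DEFAULT_VCC)
    gain = header.get("gain", DEFAULT_GAIN)
    vccs = vcc if isinstance(vcc, list) else [vcc] * len(header["channels"])
    gains = gain if isinstance(gain, list) else [gain] * len(header["channels"])
    try:
        channels = [
            ChannelSpec(
                name=str(c["name"]),
                role=ChannelRole(c["role"]),
                adc_bits=bits,
                vcc=float(v),
                gain=float(g),
            )
            for c, v, g in zip(header["channels"], vccs, gains, strict=True)
        ]
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: bad channel entry in header: {exc}") from exc

    rows = [line for line in lines[body_start:] if line.strip()]
    if rows:
        try:
            samples = np.array(
                [[int(v) for v in row.split("\t")] for row in rows], dtype=np.int64
            )
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer sample value: {exc}") from exc
        if samples.shape[1] != len(channels):
            raise FormatError(
                f"{path}: {samples.shape[1]} columns but {len(channels)} channels declared"
            )
    else:
        samples = np.empty((0, len(channels)), dtype=np.int64)

    meta = {
        k: v
        for k, v in header.items()
        if k not in ("fs", "bits", "channels", "device_id", "vcc", "gain")
    }
    return RawRecording(
        channels=channels,
        samples=samples,
        fs=float(header["fs"]),
        device_id=str(header.get("device_id", "device")),
        meta=meta,
    )


def write_recording(rec: RawRecording, path) -> Path:
    """Write ``rec`` to ``path`` in the plain-text format; deterministic bytes."""
    path = Path(path)
    fs = rec.fs
    header = {
        "fs": int(fs) if float(fs).is_integer() else fs,
        "bits": rec.channels[0].adc_bits if rec.channels else DEFAULT_BITS,
        "channels": [{"name": ch.name, "role": ch.role.value} for ch in rec.channels],
        "device_id": rec.device_id,
        "vcc": [ch.vcc for ch in rec.channels],
        "gain": [ch.gain for ch in rec.channels],
    }
    header.update({k: rec.meta[k] for k in sorted(rec.meta)})
    out = ["# BEGIN HEADER", "# " + json.dumps(header, sort_keys=True), "# END HEADER"]
    for row in rec.samples:
        out.append("\t".join(str(int(v)) for v in row))
    path.write_text("\n".join(out) + "\n", encoding="utf-8")
    return path


def adc_to_millivolts(counts, spec: ChannelSpec) -> np.ndarray:
    """Convert ADC counts to millivolts at the electrode (pre-gain).

    ``mV = ((c / 2^n) - 0.5) * VCC / G * 1000`` — strictly monotone in counts,
    mid-scale (``c = 2^(n-1)``) maps to exactly 0 mV.
    """
    counts = np.asarray(counts)
    if counts.size and (counts.min() < 0 or counts.max() > spec.adc_max):
        raise ValidationError(
            f"counts outside ADC range [0, {spec.adc_max}] for channel '{spec.name}'"
        )
    return (counts / 2.0**spec.adc_bits - 0.5) * spec.vcc / spec.gain * 1000.0


def millivolts_to_adc(mv, spec: ChannelSpec) -> np.ndarray:
    """Quantize a millivolt waveform through the inverse transfer function.

    Rounds to the nearest count and clips at the ADC rails, i.e. models the
    quantization (and saturation) a real front end applies.
    """
    mv = np.asarray(mv, dtype=float)
    counts = np.rint((mv / 1000.0 * spec.gain / spec.vcc + 0.5) * 2.0**spec.adc_bits)
    return np.clip(counts, 0, spec.adc_max).astype(np.int64)


def stream_rate(fs: float, frame_bytes: int) -> float:
    """Streaming throughput in kbit/s for ``frame_bytes``-byte frames at ``fs`` Hz.

    1 kHz x 7 bytes -> 56 kbit/s, the full four-channel configuration.
    """
    if fs <= 0:
        raise ValidationError(f"fs must be > 0, got {fs}")
    if frame_bytes <= 0:
        raise ValidationError(f"frame_bytes must be > 0, got {frame_bytes}")
    return fs * frame_bytes * 8.0 / 1000.0
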