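"""Synthetic two-channel gyroscope recordings of repetitive leg motions.

Emulates the acquisition chain of a body-worn pair of single-axis rate
gyroscopes (one above, one below the knee): limb angular rate -> analog
output voltage (affine, saturating at the rate limit) -> 8-bit ADC ->
decimation to the working sample rate -> fixed-length labeled segments.

Eight motion classes are modeled as quasi-periodic burst trains: each
repetition of a motion produces one amplitude-normalized swing burst per
channel, with class-specific peak rates and oscillatory content.  Class 1
is quiet standing (sensor noise only); classes 2 and 8 drive mainly the
below-knee channel; classes 4/5 and 2/8 are deliberately similar pairs,
mirroring motions that differ mostly in direction — a distinction that
energy-based features cannot see.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CHANNELS = ("above_knee", "below_knee")

__all__ = [
    "CHANNELS",
    "Harmonic",
    "ChannelTemplate",
    "MotionClass",
    "MOTION_CLASSES",
    "get_motion",
    "GyroSpec",
    "RecordingProtocol",
    "SignalSegment",
    "LabeledDataset",
    "generate_rate_signal",
    "rate_to_voltage",
    "voltage_to_rate",
    "quantize_adc",
    "adc_code",
    "downsample",
    "build_dataset",
    "save_dataset",
    "load_dataset",
]


# --------------------------------------------------------------------------
# motion templates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Harmonic:
    """One oscillatory component gated by the repetition envelope."""

    freq_hz: float
    weight: float


@dataclass(frozen=True)
class ChannelTemplate:
    """Per-channel motion parameters.

    ``amplitude`` is the peak angular rate of one repetition burst in deg/s
    (bursts are normalized to unit peak before scaling, so this is an exact
    bound up to amplitude jitter).  ``harmonics`` add class-specific
    oscillations on top of the single swing cycle of each burst.
    """

    amplitude: float
    harmonics: tuple[Harmonic, ...] = ()


@dataclass(frozen=True)
class MotionClass:
    id: int
    name: str
    channels: tuple[ChannelTemplate, ChannelTemplate]  # (above knee, below knee)


def _tmpl(amp: float, *harmonics: tuple[float, float]) -> ChannelTemplate:
    return ChannelTemplate(amp, tuple(Harmonic(f, w) for f, w in harmonics))


# Peak rates stay below the 90 deg/s sensor limit even with amplitude jitter.
# Classes 4/5 share both channels and nearby spectra (straight-leg swings
# forward/backward); classes 2/8 are below-knee dominant with nearby spectra
# (lower-leg swings back/up).  These are the confusable pairs by design.
MOTION_CLASSES: dict[int, MotionClass] = {
    1: MotionClass(1, "standing still", (_tmpl(0.0), _tmpl(0.0))),
    2: MotionClass(2, "lower leg backward", (_tmpl(6.0), _tmpl(55.0, (3.0, 0.30)))),
    3: MotionClass(3, "whole leg forward, knee bent",
                   (_tmpl(45.0, (2.0, 0.25)), _tmpl(65.0, (4.5, 0.30)))),
    4: MotionClass(4, "straight leg forward",
                   (_tmpl(50.0, (2.5, 0.20)), _tmpl(48.0, (2.5, 0.20)))),
    5: MotionClass(5, "straight leg backward",
                   (_tmpl(43.0, (2.6, 0.22)), _tmpl(45.0, (2.6, 0.22)))),
    6: MotionClass(6, "leg sideways",
                   (_tmpl(55.0, (1.5, 0.15)), _tmpl(28.0, (1.5, 0.15)))),
    7: MotionClass(7, "squat",
                   (_tmpl(70.0, (3.6, 0.35), (6.5, 0.15)),
                    _tmpl(72.0, (3.6, 0.35), (6.5, 0.15)))),
    8: MotionClass(8, "lower leg up, sitting", (_tmpl(8.0), _tmpl(60.0, (3.2, 0.28)))),
}


def get_motion(motion_id: int) -> MotionClass:
    try:
        return MOTION_CLASSES[int(motion_id)]
    except (KeyError, ValueError, TypeError):
        raise ValueError(
            f"unknown motion id {motion_id!r}; valid ids are 1..8"
        ) from None


# --------------------------------------------------------------------------
# sensor / acquisition model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GyroSpec:
    """Rate-gyro plus acquisition-chain parameters.

    Defaults model a piezoelectric vibratory gyro with a ±90 deg/s range
    mapped affinely onto 0.5–4.5 V around a 2.5 V zero-rate output,
    digitized by an 8-bit ADC over 0–5 V at 2,668 Hz and decimated by 20.
    """

    rate_max: float = 90.0
    v_zero: float = 2.5
    v_min: float = 0.5
    v_max: float = 4.5
    adc_bits: int = 8
    adc_range: tuple[float, float] = (0.0, 5.0)
    fs_raw: float = 2668.0
    downsample_factor: int = 20

    def __post_init__(self) -> None:
        if not (self.v_min < self.v_zero < self.v_max):
            raise ValueError("require v_min < v_zero < v_max")
        if self.rate_max <= 0:
            raise ValueError("rate_max must be positive")
        if self.adc_bits < 1:
            raise ValueError("adc_bits must be >= 1")
        if self.adc_range[1] <= self.adc_range[0]:
            raise ValueError("adc_range must be increasing")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")

    @property
    def fs_out(self) -> float:
        """Effective sample rate after decimation (Hz)."""
        return self.fs_raw / self.downsample_factor

    @property
    def volts_per_rate(self) -> float:
        return (self.v_max - self.v_zero) / self.rate_max


def rate_to_voltage(rate, spec: GyroSpec = GyroSpec()):
    """Affine rate -> voltage map with saturation at the rate limit.

    0 deg/s maps to ``v_zero``; ±``rate_max`` map to ``v_max``/``v_min``;
    rates beyond the limit saturate at the corresponding rail.
    """
    v = spec.v_zero + np.asarray(rate, dtype=float) * spec.volts_per_rate
    return np.clip(v, spec.v_min, spec.v_max)


def voltage_to_rate(voltage, spec: GyroSpec = GyroSpec()):
    """Inverse of :func:`rate_to_voltage` on the linear (unsaturated) range."""
    return (np.asarray(voltage, dtype=float) - spec.v_zero) / spec.volts_per_rate


def adc_code(voltage, spec: GyroSpec = GyroSpec()):
    """Integer ADC code: uniform mid-tread quantizer, half-way rounds up."""
    lo, hi = spec.adc_range
    n_codes = 2 ** spec.adc_bits - 1
    step = (hi - lo) / n_codes
    v = np.clip(np.asarray(voltage, dtype=float), lo, hi)
    return np.floor((v - lo) / step + 0.5).astype(np.int64)


def quantize_adc(voltage, spec: GyroSpec = GyroSpec()):
    """Reconstructed voltage of the nearest ADC code."""
    lo, hi = spec.adc_range
    step = (hi - lo) / (2 ** spec.adc_bits - 1)
    return lo + adc_code(voltage, spec) * step


def downsample(signal, factor: int):
    """Keep every ``factor``-th sample starting at index 0."""
    if int(factor) != factor or factor < 1:
        raise ValueError(f"downsample factor must be an integer >= 1, got {factor!r}")
    return np.asarray(signal)[..., :: int(factor)]


# --------------------------------------------------------------------------
# rate-signal synthesis
# --------------------------------------------------------------------------

def _burst(tau: np.ndarray, burst_dur: float, template: ChannelTemplate,
           phases: np.ndarray) -> np.ndarray:
    """Unit-peak repetition burst: Hann envelope times one swing cycle
    plus the template's gated harmonics."""
    env = 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / burst_dur))
    wave = np.sin(2.0 * np.pi * tau / burst_dur)
    for harm, phi in zip(template.harmonics, phases):
        wave = wave + harm.weight * np.sin(2.0 * np.pi * harm.freq_hz * tau + phi)
    out = env * wave
    peak = np.max(np.abs(out))
    if peak > 0:
        out = out / peak
    return out


def generate_rate_signal(
    motion: MotionClass | int,
    duration_s: float,
    fs: float,
    seed: int | np.random.Generator = 0,
    *,
    snr_db: float = 20.0,
    noise_floor: float = 0.5,
    amp_jitter: float = 0.10,
) -> np.ndarray:
    """Synthesize one two-channel angular-rate recording (deg/s).

    The motion repeats quasi-periodically: the repetition period is drawn
    once per call from U(5, 7) s, each repetition gets independent amplitude
    jitter (truncated Gaussian, relative sd ``amp_jitter``), small timing
    jitter and random harmonic phases.  Both channels share repetition
    timing (the leg moves as a whole).  Additive white Gaussian noise with
    standard deviation ``max(noise_floor, amplitude * 10**(-snr_db/20))``
    deg/s is added per channel; quiet channels get the noise floor only.

    Returns an array of shape ``(2, round(duration_s * fs))``, channel 0
    above the knee, channel 1 below.  Deterministic given the seed.
    """
    if not isinstance(motion, MotionClass):
        motion = get_motion(motion)
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = int(round(duration_s * fs))
    x = np.zeros((2, n))
    period = rng.uniform(5.0, 7.0)
    n_reps = int(math.floor(duration_s / period))
    burst_dur = 0.8 * period

    # Draw per-repetition randomness in a channel-independent order so the
    # two channels stay aligned.
    for r in range(n_reps):
        jit = float(np.clip(rng.normal(0.0, amp_jitter), -2.5 * amp_jitter,
                            2.5 * amp_jitter))
        t0 = r * period + 0.1 * period + rng.uniform(-0.05, 0.05) * period
        i0 = int(round(t0 * fs))
        i1 = min(n, i0 + int(round(burst_dur * fs)))
        if i1 <= i0:
            continue
        tau = (np.arange(i0, i1) - i0) / fs
        for ch, template in enumerate(motion.channels):
            phases = rng.uniform(0.0, 2.0 * np.pi, size=len(template.harmonics))
            if template.amplitude <= 0:
                continue
            x[ch, i0:i1] += template.amplitude * (1.0 + jit) * _burst(
                tau, burst_dur, template, phases)

    for ch, template in enumerate(motion.channels):
        sigma = max(noise_floor, template.amplitude * 10.0 ** (-snr_db / 20.0))
        x[ch] += rng.normal(0.0, sigma, size=n)
    return x


# --------------------------------------------------------------------------
# recording protocol and dataset assembly
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RecordingProtocol:
    """How much data is recorded and how it is cut into segments."""

    n_motions: int = 8
    intervals_per_motion: int = 8
    interval_s: float = 72.0
    segments_per_interval: int = 6
    segment_len: int = 1600
    n_channels: int = 2

    def __post_init__(self) -> None:
        if not (1 <= self.n_motions <= len(MOTION_CLASSES)):
            raise ValueError("n_motions must be in 1..8")
        if self.n_channels not in (1, 2):
            raise ValueError("n_channels must be 1 or 2")
        for name in ("intervals_per_motion", "segments_per_interval", "segment_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def segments_per_motion_per_channel(self) -> int:
        return self.intervals_per_motion * self.segments_per_interval

    @property
    def n_segments(self) -> int:
        """Total single-channel segment count."""
        return (self.n_motions * self.intervals_per_motion
                * self.segments_per_interval * self.n_channels)

    @property
    def n_patterns(self) -> int:
        """Number of multi-channel patterns (one per (motion, interval, segment))."""
        return self.n_motions * self.intervals_per_motion * self.segments_per_interval


@dataclass(frozen=True)
class SignalSegment:
    """One fixed-length single-channel segment with its labels."""

    samples: np.ndarray
    channel: str
    motion: int
    interval_index: int
    segment_index: int


@dataclass
class LabeledDataset:
    """Paired two-channel segments with one shared motion label per pattern.

    ``pairs`` has shape (n_patterns, n_channels, segment_len) in deg/s after
    the full acquisition round trip; ``meta`` has one row per pattern with
    motion_id / interval_index / segment_index.
    """

    pairs: np.ndarray
    labels: np.ndarray
    meta: pd.DataFrame
    protocol: RecordingProtocol
    spec: GyroSpec
    seed: int
    snr_db: float

    @property
    def n_patterns(self) -> int:
        return self.pairs.shape[0]

    @property
    def n_segments(self) -> int:
        return self.pairs.shape[0] * self.pairs.shape[1]

    def counts(self) -> pd.DataFrame:
        """Single-channel segment counts by motion and channel."""
        rows = []
        for motion_id in sorted(set(self.labels.tolist())):
            n = int((self.labels == motion_id).sum())
            for ch in range(self.pairs.shape[1]):
                rows.append({"motion_id": motion_id, "channel": CHANNELS[ch],
                             "n_segments": n})
        return pd.DataFrame(rows)

    def segments(self):
        """Iterate over single-channel :class:`SignalSegment` records."""
        for i in range(self.n_patterns):
            row = self.meta.iloc[i]
            for ch in range(self.pairs.shape[1]):
                yield SignalSegment(
                    samples=self.pairs[i, ch],
                    channel=CHANNELS[ch],
                    motion=int(row["motion_id"]),
                    interval_index=int(row["interval_index"]),
                    segment_index=int(row["segment_index"]),
                )


def build_dataset(
    protocol: RecordingProtocol = RecordingProtocol(),
    spec: GyroSpec = GyroSpec(),
    seed: int = 0,
    *,
    snr_db: float = 20.0,
    noise_floor: float = 0.5,
) -> LabeledDataset:
    """Run the full acquisition chain and segment the result.

    For every (motion, interval): synthesize the raw-rate recording at
    ``fs_raw``, convert to voltage (with saturation), quantize with the ADC,
    decimate, convert back to rate, and cut into ``segments_per_interval``
    segments of ``segment_len`` samples.  All randomness derives from
    ``seed`` through per-(motion, interval) substreams, so the result is
    byte-identical across runs with the same arguments.
    """
    raw_needed = (protocol.segments_per_interval * protocol.segment_len
                  * spec.downsample_factor)
    capacity = int(round(protocol.interval_s * spec.fs_raw))
    if raw_needed > capacity * 1.01:
        raise ValueError(
            f"interval of {protocol.interval_s} s provides {capacity} raw samples "
            f"but {raw_needed} are required for "
            f"{protocol.segments_per_interval} x {protocol.segment_len} samples "
            f"at decimation {spec.downsample_factor}"
        )

    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(protocol.n_motions * protocol.intervals_per_motion)

    pairs, labels, meta_rows = [], [], []
    k = 0
    for motion_id in range(1, protocol.n_motions + 1):
        motion = get_motion(motion_id)
        for interval in range(protocol.intervals_per_motion):
            rng = np.random.default_rng(children[k])
            k += 1
            raw = generate_rate_signal(
                motion, protocol.interval_s, spec.fs_raw, rng,
                snr_db=snr_db, noise_floor=noise_floor,
            )[: protocol.n_channels, :raw_needed]
            volts = quantize_adc(rate_to_voltage(raw, spec), spec)
            rate = voltage_to_rate(downsample(volts, spec.downsample_factor), spec)
            for s in range(protocol.segments_per_interval):
                seg = rate[:, s * protocol.segment_len: (s + 1) * protocol.segment_len]
                pairs.append(seg)
                labels.append(motion_id)
                meta_rows.append({"motion_id": motion_id, "interval_index": interval,
                                  "segment_index": s})

    return LabeledDataset(
        pairs=np.stack(pairs),
        labels=np.asarray(labels, dtype=int),
        meta=pd.DataFrame(meta_rows),
        protocol=protocol,
        spec=spec,
        seed=int(seed),
        snr_db=snr_db,
    )


# --------------------------------------------------------------------------
# plain-text persistence
# --------------------------------------------------------------------------

def save_dataset(dataset: LabeledDataset, directory: str | Path) -> Path:
    """Write one CSV row per single-channel segment plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    seg_len = dataset.pairs.shape[2]
    cols = [f"s{i:04d}" for i in range(seg_len)]
    rows = []
    index = []
    for i in range(dataset.n_patterns):
        m = dataset.meta.iloc[i]
        for ch in range(dataset.pairs.shape[1]):
            index.append((int(m["motion_id"]), CHANNELS[ch],
                          int(m["interval_index"]), int(m["segment_index"])))
            rows.append(dataset.pairs[i, ch])
    frame = pd.DataFrame(np.asarray(rows), columns=cols)
    head = pd.DataFrame(index, columns=["motion_id", "channel",
                                        "interval_index", "segment_index"])
    pd.concat([head, frame], axis=1).to_csv(
        directory / "segments.csv", index=False, float_format="%.10g")
    sidecar = {
        "protocol": dataclasses.asdict(dataset.protocol),
        "spec": dataclasses.asdict(dataset.spec),
        "seed": dataset.seed,
        "snr_db": dataset.snr_db,
    }
    (directory / "dataset.json").write_text(json.dumps(sidecar, indent=2))
    return directory / "segments.csv"


def load_dataset(directory: str | Path) -> LabeledDataset:
    """Inverse of :func:`save_dataset`."""
    directory = Path(directory)
    sidecar = json.loads((directory / "dataset.json").read_text())
    sidecar["spec"]["adc_range"] = tuple(sidecar["spec"]["adc_range"])
    protocol = RecordingProtocol(**sidecar["protocol"])
    spec = GyroSpec(**sidecar["spec"])
    table = pd.read_csv(directory / "segments.csv")
    sample_cols = [c for c in table.columns if c.startswith("s") and c[1:].isdigit()]
    pairs, labels, meta_rows = [], [], []
    keys = ["motion_id", "interval_index", "segment_index"]
    for key, grp in table.groupby(keys, sort=True):
        grp = grp.sort_values("channel", key=lambda s: s.map(
            {name: i for i, name in enumerate(CHANNELS)}))
        pairs.append(grp[sample_cols].to_numpy())
        labels.append(int(key[0]))
        meta_rows.append(dict(zip(keys, (int(v) for v in key))))
    return LabeledDataset(
        pairs=np.stack(pairs),
        labels=np.asarray(labels, dtype=int),
        meta=pd.DataFrame(meta_rows),
        protocol=protocol,
        spec=spec,
        seed=int(sidecar["seed"]),
        snr_db=float(sidecar["snr_db"]),
    )
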