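"""Synthetic lung-sound simulator.

Generates digital-stethoscope-like recordings of vesicular breath sounds with
injected adventitious events — crackles and wheezes — together with
ground-truth annotations and a cohort manifest, so that every downstream
stage (preprocessing, detection, agreement evaluation) can be exercised and
tested without clinical audio.

The acoustic models are deliberately simple and parameter-transparent:

* A **crackle** is a transient: a brief unidirectional initial deflection
  (half-sine pulse) followed by an exponentially damped sinusoid.  The damping
  constant is chosen so the envelope reaches 10% of peak exactly at the
  event's total duration, which makes "total duration width" a measurable
  quantity.  Default parameter draws keep the two-cycle duration under 20 ms
  and the total duration under 25 ms, the classical waveform criteria for
  crackles.

* A **wheeze** (pooled with rhonchi) is a tonal segment: a windowed sinusoid
  with optional weaker harmonics, longer than 25 ms, with a dominant
  frequency above 100 Hz.

* **Vesicular breath noise** is band-limited (100–1000 Hz) Gaussian noise
  amplitude-modulated by a periodic inspiratory/expiratory envelope.

Recordings are rendered once at a high master rate and then observed through
per-device profiles (resampling + bit-depth quantization), emulating a paired
two-device study design: a high-fidelity device at 44100 Hz / 32-bit float
and a low-fidelity device at 4000 Hz / 16-bit PCM.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .errors import InvalidParameterError

__all__ = [
    "Waveform",
    "DeviceProfile",
    "HIFI_PROFILE",
    "LOFI_PROFILE",
    "CrackleParams",
    "WheezeParams",
    "AcousticEvent",
    "RecordingRecord",
    "EventModelConfig",
    "CohortConfig",
    "Cohort",
    "synth_crackle",
    "synth_wheeze",
    "breath_envelope",
    "synth_breath_noise",
    "render_recording",
    "apply_device_profile",
    "quantize",
    "generate_cohort",
    "write_wav",
]

GROUPS = ("normal", "wheeze_only", "crackles_pm_wheeze", "cf_clear")
#: Posterior-thorax auscultation sites (left/right × upper/lower quadrant).
QUADRANTS = ("LUQ", "RUQ", "LLQ", "RLQ")


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class Waveform:
    """A mono sampled acoustic signal.

    Parameters
    ----------
    samples
        Amplitudes, dimensionless, nominal range [-1, 1].
    sample_rate_hz
        Sampling rate in Hz.
    bit_depth
        16 (PCM), 32 (IEEE float) or ``"continuous"`` for an idealized,
        un-quantized signal (the master render).
    """

    samples: np.ndarray
    sample_rate_hz: float
    bit_depth: int | str = "continuous"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise InvalidParameterError("waveform must be 1-D with >= 1 sample")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("waveform contains non-finite samples")
        if self.sample_rate_hz <= 0:
            raise InvalidParameterError("sample_rate_hz must be positive")
        if self.bit_depth not in (16, 32, "continuous"):
            raise InvalidParameterError(f"unsupported bit depth {self.bit_depth!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz


@dataclass(frozen=True)
class DeviceProfile:
    """Acquisition characteristics of a digital stethoscope."""

    name: str
    sample_rate_hz: int
    bit_depth: int | str


#: High-fidelity device profile (44100 Hz, 32-bit float).
HIFI_PROFILE = DeviceProfile("hifi", 44100, 32)
#: Low-fidelity device profile (4000 Hz, 16-bit PCM).
LOFI_PROFILE = DeviceProfile("lofi", 4000, 16)

BUILTIN_PROFILES = {p.name: p for p in (HIFI_PROFILE, LOFI_PROFILE)}


@dataclass
class CrackleParams:
    """Morphological parameters of a single crackle.

    ``two_cycle_duration_ms`` is fixed by the oscillation frequency
    (two periods = 2000 / f ms); it is stored for convenience and checked for
    consistency if supplied.
    """

    onset_s: float
    oscillation_freq_hz: float
    total_duration_ms: float
    initial_deflection_fraction: float = 0.2
    amplitude: float = 1.0
    two_cycle_duration_ms: float | None = None

    def __post_init__(self) -> None:
        if self.oscillation_freq_hz <= 0:
            raise InvalidParameterError("oscillation_freq_hz must be > 0")
        if self.amplitude <= 0:
            raise InvalidParameterError("amplitude must be > 0")
        if self.onset_s < 0:
            raise InvalidParameterError("onset_s must be >= 0")
        if not 0 < self.initial_deflection_fraction < 1:
            raise InvalidParameterError("initial_deflection_fraction must be in (0,1)")
        nominal = 2000.0 / self.oscillation_freq_hz
        if self.two_cycle_duration_ms is None:
            self.two_cycle_duration_ms = nominal
        elif not math.isclose(self.two_cycle_duration_ms, nominal, rel_tol=1e-6):
            raise InvalidParameterError(
                "two_cycle_duration_ms inconsistent with oscillation frequency"
            )
        if self.total_duration_ms <= self.two_cycle_duration_ms:
            raise InvalidParameterError(
                "total_duration_ms must exceed two_cycle_duration_ms"
            )


@dataclass
class WheezeParams:
    """Parameters of a single wheeze/rhonchus segment."""

    onset_s: float
    dominant_freq_hz: float
    duration_ms: float
    amplitude: float = 1.0
    n_harmonics: int = 0

    def __post_init__(self) -> None:
        if self.dominant_freq_hz <= 0:
            raise InvalidParameterError("dominant_freq_hz must be > 0")
        if self.duration_ms <= 0:
            raise InvalidParameterError("duration_ms must be > 0")
        if self.amplitude <= 0:
            raise InvalidParameterError("amplitude must be > 0")
        if self.onset_s < 0:
            raise InvalidParameterError("onset_s must be >= 0")
        if self.n_harmonics < 0:
            raise InvalidParameterError("n_harmonics must be >= 0")


@dataclass
class AcousticEvent:
    """A ground-truth (or detected) adventitious event."""

    kind: str  # "crackle" | "wheeze"
    onset_s: float
    duration_s: float
    params: CrackleParams | WheezeParams

    def __post_init__(self) -> None:
        if self.kind not in ("crackle", "wheeze"):
            raise InvalidParameterError(f"unknown event kind {self.kind!r}")

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "onset_s": self.onset_s, "duration_s": self.duration_s}
        d["params"] = {
            k: v for k, v in vars(self.params).items() if not k.startswith("_")
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcousticEvent":
        cls_p = CrackleParams if d["kind"] == "crackle" else WheezeParams
        return cls(
            kind=d["kind"],
            onset_s=d["onset_s"],
            duration_s=d["duration_s"],
            params=cls_p(**d["params"]),
        )


@dataclass
class RecordingRecord:
    """One row of the cohort manifest plus its ground-truth events."""

    recording_id: str
    participant_id: str
    group: str
    quadrant: str
    device: str
    duration_s: float = 20.0
    excluded: bool = False
    exclusion_reason: str = ""
    truth_events: list[AcousticEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidParameterError(f"unknown group {self.group!r}")
        if self.excluded and not self.exclusion_reason:
            raise InvalidParameterError("excluded recordings need an exclusion_reason")
        kinds = {e.kind for e in self.truth_events}
        if self.group in ("normal", "cf_clear") and kinds:
            raise InvalidParameterError(f"{self.group} recordings must be event-free")
        if self.group == "wheeze_only" and "crackle" in kinds:
            raise InvalidParameterError("wheeze_only recordings cannot contain crackles")
        for e in self.truth_events:
            if e.onset_s + e.duration_s > self.duration_s + 1e-9:
                raise InvalidParameterError("event extends past end of recording")


# ---------------------------------------------------------------------------
# Event synthesis
# ---------------------------------------------------------------------------

def synth_crackle(params: CrackleParams, sample_rate_hz: float) -> Waveform:
    """Synthesize one crackle transient.

    The waveform is a brief unidirectional half-sine deflection of width
    ``initial_deflection_fraction × two_cycle_duration`` followed by a
    sinusoid at ``oscillation_freq_hz`` whose exponential envelope decays to
    10% of the peak amplitude at ``total_duration_ms`` (measured from the
    deflection onset).
    """
    fs = float(sample_rate_hz)
    if fs < 4 * params.oscillation_freq_hz:
        raise InvalidParameterError(
            "sample rate must be at least 4x the crackle oscillation frequency"
        )
    a = params.amplitude
    f = params.oscillation_freq_hz
    t_total = params.total_duration_ms / 1000.0
    t_defl = params.initial_deflection_fraction * (params.two_cycle_duration_ms / 1000.0)
    n = int(round(t_total * fs)) + 1
    t = np.arange(n) / fs
    out = np.zeros(n)
    head = t < t_defl
    out[head] = a * np.sin(np.pi * t[head] / t_defl)
    # decay constant: envelope hits 0.1*peak exactly at total duration
    lam = math.log(10.0) / (t_total - t_defl)
    tail = ~head
    tt = t[tail] - t_defl
    # negative leading phase so the tail swings away from the deflection
    out[tail] = -a * np.exp(-lam * tt) * np.sin(2 * np.pi * f * tt)
    return Waveform(out, fs)


def synth_wheeze(params: WheezeParams, sample_rate_hz: float) -> Waveform:
    """Synthesize one wheeze: a Tukey-windowed sinusoid plus weak harmonics.

    Harmonic ``h`` (1-based overtone) has relative amplitude ``0.3**h``;
    overtones at or above Nyquist are dropped.  The fundamental must itself be
    below Nyquist.  A short taper (Tukey alpha = 0.1) keeps the RMS of a
    harmonic-free wheeze within a few percent of ``amplitude / sqrt(2)``.
    """
    fs = float(sample_rate_hz)
    if params.dominant_freq_hz >= fs / 2:
        raise InvalidParameterError("dominant frequency must be below Nyquist")
    n = max(2, int(round(params.duration_ms / 1000.0 * fs)))
    t = np.arange(n) / fs
    out = np.sin(2 * np.pi * params.dominant_freq_hz * t)
    for h in range(1, params.n_harmonics + 1):
        f_h = (h + 1) * params.dominant_freq_hz
        if f_h >= fs / 2:
            break
        out += (0.3 ** h) * np.sin(2 * np.pi * f_h * t)
    out *= params.amplitude * signal.windows.tukey(n, alpha=0.1)
    return Waveform(out, fs)


def breath_envelope(duration_s: float, cycle_period_s: float,
                    sample_rate_hz: float, floor: float = 0.25) -> np.ndarray:
    """Periodic inspiratory/expiratory amplitude envelope.

    ``floor + (1 - floor) * sin^2(pi t / T)`` — one complete cycle per
    ``cycle_period_s``.
    """
    t = np.arange(int(round(duration_s * sample_rate_hz))) / sample_rate_hz
    return floor + (1.0 - floor) * np.sin(np.pi * t / cycle_period_s) ** 2


def synth_breath_noise(duration_s: float, cycle_period_s: float,
                       sample_rate_hz: float, seed: int,
                       rms: float = 0.02) -> Waveform:
    """Vesicular background: band-limited noise with breath-cycle modulation.

    White Gaussian noise is band-passed to 100–1000 Hz (4th-order Butterworth,
    zero-phase), modulated by :func:`breath_envelope`, and scaled to the
    requested overall RMS.  Fully reproducible from ``seed``.
    """
    if duration_s <= 0:
        raise InvalidParameterError("duration_s must be > 0")
    if cycle_period_s <= 0:
        raise InvalidParameterError("cycle_period_s must be > 0")
    fs = float(sample_rate_hz)
    if fs <= 2000:
        raise InvalidParameterError("breath-noise synthesis needs fs > 2000 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    sos = signal.butter(4, [100.0, 1000.0], btype="bandpass", fs=fs, output="sos")
    shaped = signal.sosfiltfilt(sos, white)
    shaped *= breath_envelope(duration_s, cycle_period_s, fs)
    shaped *= rms / max(np.sqrt(np.mean(shaped**2)), 1e-300)
    return Waveform(shaped, fs)


def _synth_event(event: AcousticEvent, fs: float) -> np.ndarray:
    if event.kind == "crackle":
        return synth_crackle(event.params, fs).samples
    return synth_wheeze(event.params, fs).samples


def render_recording(events: Sequence[AcousticEvent], noise: Waveform,
                     snr_db: float = 25.0,
                     ) -> tuple[Waveform, list[AcousticEvent]]:
    """Mix events into background noise at a controlled event-to-noise ratio.

    Each event is scaled so that, over the event's own time support, the ratio
    of event power to background power equals ``snr_db``.  If the mix peak
    exceeds 1 the whole mix is rescaled (ratios are unaffected).  Returns the
    mixed waveform and the events as ground truth.
    """
    fs = noise.sample_rate_hz
    n = noise.samples.size
    mix = noise.samples.copy()
    for ev in events:
        i0 = int(round(ev.onset_s * fs))
        seg = _synth_event(ev, fs)
        i1 = i0 + seg.size
        if i0 < 0 or i1 > n:
            raise InvalidParameterError(
                f"{ev.kind} at {ev.onset_s:.3f}s extends past recording end"
            )
        p_noise = float(np.mean(noise.samples[i0:i1] ** 2))
        p_event = float(np.mean(seg**2))
        scale = math.sqrt(p_noise * 10.0 ** (snr_db / 10.0) / p_event)
        mix[i0:i1] += scale * seg
    peak = float(np.max(np.abs(mix)))
    if peak > 1.0:
        mix *= 0.99 / peak
    return Waveform(mix, fs), list(events)


# ---------------------------------------------------------------------------
# Device observation
# ---------------------------------------------------------------------------

def quantize(samples: np.ndarray, bit_depth: int | str) -> np.ndarray:
    """Quantize to the device grid.

    16-bit uses the PCM convention (multiples of 2^-15, so the round-trip
    through an int16 WAV is exact); 32-bit truncates to IEEE float32;
    ``"continuous"`` is a no-op.
    """
    if bit_depth == "continuous":
        return np.asarray(samples, dtype=np.float64)
    if bit_depth == 16:
        ints = np.clip(np.round(samples * 32768.0), -32768, 32767)
        return ints / 32768.0
    if bit_depth == 32:
        return samples.astype(np.float32).astype(np.float64)
    raise InvalidParameterError(f"unsupported bit depth {bit_depth!r}")


def apply_device_profile(w: Waveform, profile: DeviceProfile) -> Waveform:
    """Observe a master render through a device: anti-aliased resampling to
    the device rate followed by bit-depth quantization.

    Only downsampling (or rate-preserving) profiles are allowed: the
    simulator always renders at the highest rate first.
    """
    if profile.sample_rate_hz > w.sample_rate_hz:
        raise InvalidParameterError(
            "device profile requests upsampling; render the master at a rate "
            ">= every device rate"
        )
    if profile.sample_rate_hz == w.sample_rate_hz:
        out = w.samples
    else:
        ratio = Fraction(int(profile.sample_rate_hz), int(w.sample_rate_hz))
        out = signal.resample_poly(w.samples, ratio.numerator, ratio.denominator)
    out = np.clip(out, -1.0, 1.0)
    return Waveform(quantize(out, profile.bit_depth),
                    profile.sample_rate_hz, profile.bit_depth)


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a mono WAV: PCM16 for 16-bit waveforms, IEEE float32 otherwise."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if w.bit_depth == 16:
        ints = np.clip(np.round(w.samples * 32768.0), -32768, 32767).astype(np.int16)
        wavfile.write(path, int(w.sample_rate_hz), ints)
    else:
        wavfile.write(path, int(w.sample_rate_hz), w.samples.astype(np.float32))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class EventModelConfig:
    """Distributions from which per-recording event parameters are drawn.

    The ranges guarantee the classical waveform criteria by construction:
    crackle oscillation frequencies in [150, 800] Hz give two-cycle durations
    of 2.5–13.3 ms (< 20 ms) and total durations capped below 25 ms; wheeze
    durations of 80–2000 ms and dominant frequencies of 150–900 Hz comfortably
    exceed the > 25 ms / > 100 Hz thresholds while staying inside the
    100–1000 Hz analysis band.
    """

    crackle_rate: float = 6.0          # mean crackles per recording (Poisson)
    wheeze_rate: float = 2.0           # mean wheeze segments per recording
    crackle_freq_range: tuple[float, float] = (150.0, 800.0)
    crackle_total_factor_range: tuple[float, float] = (1.4, 1.8)
    crackle_deflection_range: tuple[float, float] = (0.1, 0.3)
    wheeze_freq_range: tuple[float, float] = (150.0, 900.0)
    wheeze_duration_range_ms: tuple[float, float] = (80.0, 2000.0)
    wheeze_max_harmonics: int = 2
    snr_db: float = 25.0
    breath_cycle_s: float = 3.0
    wheeze_in_crackle_group_prob: float = 0.5


@dataclass
class CohortConfig:
    """Shape of the simulated study cohort.

    Defaults mirror the study design: 25 participants in four groups
    (9 normal, 5 wheeze-only, 5 crackles ± wheeze, 6 CF with a clear chest),
    four posterior-thorax quadrants each, two devices, 20-second recordings,
    and four aberrant recordings excluded per device.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: {
        "normal": 9, "wheeze_only": 5, "crackles_pm_wheeze": 5, "cf_clear": 6,
    })
    quadrants: tuple[str, ...] = QUADRANTS
    devices: tuple[DeviceProfile, ...] = (HIFI_PROFILE, LOFI_PROFILE)
    exclusions_per_device: int = 4
    duration_s: float = 20.0
    master_rate_hz: int = 44100
    events: EventModelConfig = field(default_factory=EventModelConfig)
    female_fraction: float = 0.28

    def __post_init__(self) -> None:
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise InvalidParameterError(f"unknown groups {sorted(unknown)}")
        if sum(self.group_sizes.values()) <= 0:
            raise InvalidParameterError("group sizes must sum to a positive count")

    @property
    def n_participants(self) -> int:
        return sum(self.group_sizes.values())


_EXCLUSION_REASONS = (
    "aberrant recording: inadequate chest wall contact",
    "aberrant recording: cable connection failure",
)


def _draw_events(cfg: CohortConfig, group: str,
                 rng: np.random.Generator) -> list[AcousticEvent]:
    """Draw ground-truth events for one master recording of a given group."""
    ev_cfg = cfg.events
    events: list[AcousticEvent] = []
    want_crackles = group == "crackles_pm_wheeze"
    want_wheeze = group == "wheeze_only" or (
        group == "crackles_pm_wheeze"
        and rng.random() < ev_cfg.wheeze_in_crackle_group_prob
    )
    if want_crackles:
        for _ in range(rng.poisson(ev_cfg.crackle_rate)):
            f = rng.uniform(*ev_cfg.crackle_freq_range)
            two_cd = 2000.0 / f
            total = two_cd * rng.uniform(*ev_cfg.crackle_total_factor_range)
            onset = rng.uniform(0.2, cfg.duration_s - 0.2)
            p = CrackleParams(
                onset_s=onset,
                oscillation_freq_hz=f,
                total_duration_ms=total,
                initial_deflection_fraction=rng.uniform(*ev_cfg.crackle_deflection_range),
            )
            events.append(AcousticEvent("crackle", onset, total / 1000.0, p))
    if want_wheeze:
        for _ in range(rng.poisson(ev_cfg.wheeze_rate)):
            dur_ms = rng.uniform(*ev_cfg.wheeze_duration_range_ms)
            onset = rng.uniform(0.2, cfg.duration_s - 0.2 - dur_ms / 1000.0)
            p = WheezeParams(
                onset_s=onset,
                dominant_freq_hz=rng.uniform(*ev_cfg.wheeze_freq_range),
                duration_ms=dur_ms,
                n_harmonics=int(rng.integers(0, ev_cfg.wheeze_max_harmonics + 1)),
            )
            events.append(AcousticEvent("wheeze", onset, dur_ms / 1000.0, p))
    events.sort(key=lambda e: e.onset_s)
    return events


def _aberrant_master(kind: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """A technically failed recording: near-silence (poor chest contact) or a
    hard-clipped, dropout-ridden signal (cable failure)."""
    if kind % 2 == 0:
        return 1e-4 * rng.standard_normal(n)
    x = np.clip(5.0 * rng.standard_normal(n), -1.0, 1.0)
    x[:: max(1, n // 40)] = 0.0
    return x


@dataclass
class Cohort:
    """A generated study cohort.

    Audio is rendered lazily and deterministically: each (participant,
    quadrant) master has its own seed spawned from the cohort seed, so a
    single recording can be re-rendered bit-identically without materializing
    the whole cohort in memory.
    """

    config: CohortConfig
    seed: int
    manifest: pd.DataFrame
    participants: pd.DataFrame
    records: dict[str, RecordingRecord]
    _master_seeds: dict[str, int]          # (participant|quadrant) key -> seed
    _aberrant: dict[str, int]              # recording_id -> aberrant kind

    def render_master(self, participant_id: str, quadrant: str) -> Waveform:
        """Re-render the continuous master mix for one auscultation site."""
        cfg = self.config
        key = f"{participant_id}|{quadrant}"
        seed = self._master_seeds[key]
        any_dev = cfg.devices[0].name
        rec = self.records[f"{participant_id}_{quadrant}_{any_dev}"]
        noise = synth_breath_noise(cfg.duration_s, cfg.events.breath_cycle_s,
                                   cfg.master_rate_hz, seed)
        mix, _ = render_recording(rec.truth_events, noise, cfg.events.snr_db)
        return mix

    def render_recording_audio(self, recording_id: str) -> Waveform:
        """Render one device observation (the per-device WAV content)."""
        rec = self.records[recording_id]
        profile = next((d for d in self.config.devices if d.name == rec.device),
                       None) or BUILTIN_PROFILES[rec.device]
        if recording_id in self._aberrant:
            n = int(round(self.config.duration_s * self.config.master_rate_hz))
            rng = np.random.default_rng(self._master_seeds[f"ab|{recording_id}"])
            master = Waveform(_aberrant_master(self._aberrant[recording_id], n, rng),
                              self.config.master_rate_hz)
        else:
            master = self.render_master(rec.participant_id, rec.quadrant)
        return apply_device_profile(master, profile)

    def iter_recordings(self, include_excluded: bool = True,
                        ) -> Iterator[tuple[RecordingRecord, Waveform]]:
        for rec_id, rec in self.records.items():
            if rec.excluded and not include_excluded:
                continue
            yield rec, self.render_recording_audio(rec_id)

    def write(self, out_dir: str | Path, write_audio: bool = True) -> None:
        """Write manifest CSV, per-recording truth JSON, and (optionally) WAVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.manifest.to_csv(out / "manifest.csv", index=False)
        self.participants.to_csv(out / "participants.csv", index=False)
        ann = out / "annotations"
        ann.mkdir(exist_ok=True)
        for rec_id, rec in self.records.items():
            with open(ann / f"{rec_id}.json", "w") as fh:
                json.dump([e.to_dict() for e in rec.truth_events], fh, indent=1)
        if write_audio:
            audio = out / "audio"
            for rec_id in self.records:
                write_wav(audio / f"{rec_id}.wav",
                          self.render_recording_audio(rec_id))


def _draw_participants(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Demographics table: group labels plus sex / age / weight covariates.

    The female count is fixed at ``round(female_fraction * n)`` so cohort
    percentages are stable; ages follow a log-normal with median ~6.7 years
    and weights a linear pediatric weight-for-age rule with noise.
    """
    rows = []
    idx = 0
    for group in GROUPS:
        for _ in range(cfg.group_sizes.get(group, 0)):
            rows.append({"participant_id": f"P{idx:03d}", "group": group})
            idx += 1
    n = len(rows)
    n_female = int(round(cfg.female_fraction * n))
    sex = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sex)
    age = np.clip(6.7 * np.exp(rng.normal(0.0, 0.55, size=n)), 0.5, 18.0)
    weight = np.clip(2.4 * age + 8.0 + rng.normal(0.0, 2.0, size=n), 3.0, 90.0)
    df = pd.DataFrame(rows)
    df["sex"] = sex
    df["age_years"] = np.round(age, 1)
    df["weight_kg"] = np.round(weight, 1)
    return df


def generate_cohort(config: CohortConfig | None = None, seed: int = 0,
                    out_dir: str | Path | None = None,
                    write_audio: bool = True) -> Cohort:
    """Generate the full synthetic cohort.

    Draws participants, per-site ground-truth events, and per-device exclusion
    flags; audio is rendered lazily from per-site seeds (and written to
    ``out_dir/audio`` if requested).  Identical ``(config, seed)`` pairs
    produce bit-identical manifests, annotations and WAVs.
    """
    cfg = config or CohortConfig()
    root = np.random.SeedSequence(seed)
    ss_demo, ss_events, ss_excl, ss_masters, ss_aberrant = root.spawn(5)
    rng_demo = np.random.default_rng(ss_demo)
    rng_events = np.random.default_rng(ss_events)
    rng_excl = np.random.default_rng(ss_excl)

    participants = _draw_participants(cfg, rng_demo)

    records: dict[str, RecordingRecord] = {}
    master_seeds: dict[str, int] = {}
    site_index = 0
    n_sites = len(participants) * len(cfg.quadrants)
    master_children = ss_masters.spawn(n_sites)
    for _, p in participants.iterrows():
        for q in cfg.quadrants:
            events = _draw_events(cfg, p["group"], rng_events)
            key = f"{p['participant_id']}|{q}"
            master_seeds[key] = int(
                master_children[site_index].generate_state(1)[0] % (2**31)
            )
            site_index += 1
            for dev in cfg.devices:
                rec_id = f"{p['participant_id']}_{q}_{dev.name}"
                records[rec_id] = RecordingRecord(
                    recording_id=rec_id,
                    participant_id=p["participant_id"],
                    group=p["group"],
                    quadrant=q,
                    device=dev.name,
                    duration_s=cfg.duration_s,
                    truth_events=events,
                )

    # per-device aberrant exclusions
    aberrant: dict[str, int] = {}
    ab_children = ss_aberrant.spawn(len(cfg.devices) * cfg.exclusions_per_device)
    ab_i = 0
    for dev in cfg.devices:
        dev_ids = [r for r in records if records[r].device == dev.name]
        n_excl = min(cfg.exclusions_per_device, len(dev_ids))
        for rec_id in rng_excl.choice(dev_ids, size=n_excl, replace=False):
            kind = ab_i % 2
            aberrant[rec_id] = kind
            records[rec_id].excluded = True
            records[rec_id].exclusion_reason = _EXCLUSION_REASONS[kind]
            master_seeds[f"ab|{rec_id}"] = int(
                ab_children[ab_i].generate_state(1)[0] % (2**31)
            )
            ab_i += 1

    manifest = pd.DataFrame(
        [
            {
                "recording_id": r.recording_id,
                "participant_id": r.participant_id,
                "group": r.group,
                "quadrant": r.quadrant,
                "device": r.device,
                "duration_s": r.duration_s,
                "excluded": r.excluded,
                "exclusion_reason": r.exclusion_reason,
            }
            for r in records.values()
        ]
    )
    cohort = Cohort(cfg, seed, manifest, participants, records,
                    master_seeds, aberrant)
    if out_dir is not None:
        cohort.write(out_dir, write_audio=write_audio)
    return cohort
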