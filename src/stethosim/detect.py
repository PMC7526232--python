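"""Rule-based crackle and wheeze detection.

The classical waveform criteria define what a crackle or a wheeze *is*:

* crackle — a short initial deflection from baseline followed by a longer,
  dampening sinusoidal wave with two-cycle duration < 20 ms and total
  duration width < 25 ms;
* wheeze/rhonchus — a rapid periodic (sinusoidal) waveform of total length
  > 25 ms with a dominant frequency > 100 Hz.

They do not define how to *search* for candidates, so this module pairs each
criterion with a conventional candidate stage:

* crackles: an amplitude-envelope transient detector (envelope exceeding
  ``k`` × a rolling-median baseline) proposes windows; each window is then
  measured — two-cycle duration via baseline crossings from the deflection
  onset, total duration via the point where the fine envelope falls below
  10% of the candidate peak — and accepted only if both thresholds hold;
* wheezes: a spectrogram tonality detector (per-frame spectral peak
  prominence over the frame median) proposes frames; consecutive tonal
  frames with stable peak frequency are merged and the segment's time
  support is refined in the time domain before the duration and frequency
  thresholds are applied.

Per-recording continuous scores (the probability-raster analog of an opaque
classifier) are then derived: a saturating exponential in the accepted
crackle count, and the fraction of the recording covered by wheeze segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .errors import InvalidParameterError
from .simulate import Waveform

__all__ = [
    "DetectorConfig",
    "TransientWindow",
    "CrackleCandidate",
    "WheezeSegment",
    "Spectrogram",
    "ScorePair",
    "RecordingLabel",
    "find_transients",
    "validate_crackle",
    "spectrogram",
    "find_wheeze_segments",
    "detect_events",
    "score_from_counts",
    "score_recording",
    "label_recording",
]


@dataclass(frozen=True)
class DetectorConfig:
    """All detector tunables in one place.

    ``envelope_ms`` is the short-time amplitude-envelope window; the
    rolling-median baseline uses the much longer ``baseline_ms`` so that it
    tracks the breath cycle but not individual transients.
    """

    # transient (crackle candidate) stage; the envelope window is kept
    # comparable to the shortest in-criterion crackle (~5 ms total duration)
    # so short transients are not diluted below the detection threshold
    k_threshold: float = 4.0
    envelope_ms: float = 5.0
    baseline_ms: float = 1000.0
    pre_ms: float = 10.0            # window extent before the candidate peak
    post_ms: float = 40.0           # window extent after the peak
    # crackle morphology criteria
    max_two_cycle_ms: float = 20.0
    max_total_ms: float = 25.0
    envelope_floor_fraction: float = 0.1   # "total duration" decay threshold
    # spectrogram / wheeze stage
    frame_ms: float = 50.0
    hop_ms: float = 12.5
    prominence_threshold: float = 6.0
    min_wheeze_freq_hz: float = 100.0
    max_wheeze_freq_hz: float = 1000.0   # top of the analysis band
    min_wheeze_ms: float = 25.0
    freq_continuity: float = 0.2    # max relative peak-frequency jump
    # score mapping
    crackle_score_scale: float = 4.0


@dataclass
class TransientWindow:
    """A candidate transient proposed by the envelope detector."""

    start_s: float
    end_s: float
    peak_time_s: float
    peak_amplitude: float


@dataclass
class CrackleCandidate:
    """A measured (and possibly rejected) crackle candidate."""

    peak_time_s: float
    measured_two_cycle_ms: float
    measured_total_ms: float
    peak_amplitude: float
    accepted: bool
    rejection_reason: str = ""


@dataclass
class WheezeSegment:
    start_s: float
    end_s: float
    dominant_freq_hz: float
    tonality: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ScorePair:
    """Continuous per-recording scores in [0, 1], one per sound type."""

    crackle_score: float
    wheeze_score: float

    def __post_init__(self) -> None:
        for v in (self.crackle_score, self.wheeze_score):
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError("scores must lie in [0, 1]")


@dataclass(frozen=True)
class RecordingLabel:
    crackle_present: bool
    wheeze_present: bool


# ---------------------------------------------------------------------------
# Crackle candidate stage
# ---------------------------------------------------------------------------

def _short_time_envelope(x: np.ndarray, fs: float, win_ms: float) -> np.ndarray:
    n = max(1, int(round(win_ms / 1000.0 * fs)))
    return ndimage.uniform_filter1d(np.abs(x), size=n, mode="nearest")


def _rolling_median_baseline(env: np.ndarray, fs: float,
                             baseline_ms: float) -> np.ndarray:
    # median on a ~200 Hz decimated envelope, then held back to full rate
    step = max(1, int(round(fs / 200.0)))
    dec = env[::step]
    size = max(3, int(round(baseline_ms / 1000.0 * fs / step)))
    med = ndimage.median_filter(dec, size=size, mode="nearest")
    return np.repeat(med, step)[: env.size]


def find_transients(w: Waveform, config: DetectorConfig | None = None,
                    ) -> list[TransientWindow]:
    """Propose candidate crackle windows.

    A sample is flagged where the short-time envelope exceeds
    ``k_threshold`` times the rolling-median baseline; contiguous flagged
    runs become candidates, each windowed ``pre_ms`` before to ``post_ms``
    after its rectified-amplitude peak.  Overlapping windows are resolved by
    keeping the larger peak.
    """
    cfg = config or DetectorConfig()
    x = w.samples
    fs = w.sample_rate_hz
    env = _short_time_envelope(x, fs, cfg.envelope_ms)
    base = _rolling_median_baseline(env, fs, cfg.baseline_ms)
    floor = 1e-8 + 0.05 * float(np.median(env))
    hot = env > cfg.k_threshold * np.maximum(base, floor)
    if not hot.any():
        return []
    labels, n_regions = ndimage.label(hot)
    pre = int(round(cfg.pre_ms / 1000.0 * fs))
    post = int(round(cfg.post_ms / 1000.0 * fs))
    cands: list[TransientWindow] = []
    for sl in ndimage.find_objects(labels):
        region = sl[0]
        peak_idx = region.start + int(np.argmax(np.abs(x[region])))
        i0 = max(0, peak_idx - pre)
        i1 = min(x.size, peak_idx + post)
        cands.append(TransientWindow(i0 / fs, i1 / fs, peak_idx / fs,
                                     float(abs(x[peak_idx]))))
    # non-overlap: greedy by descending peak
    cands.sort(key=lambda c: -c.peak_amplitude)
    kept: list[TransientWindow] = []
    for c in cands:
        if all(c.end_s <= k.start_s or c.start_s >= k.end_s for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: c.peak_time_s)
    return kept


def _fine_envelope(x: np.ndarray, fs: float) -> np.ndarray:
    # Hilbert (analytic) envelope, lightly smoothed: unlike a moving maximum
    # it does not widen the transient, so duration measurements stay unbiased
    env = np.abs(signal.hilbert(x))
    return ndimage.uniform_filter1d(env, size=max(1, int(round(0.001 * fs))),
                                    mode="nearest")


def validate_crackle(window: TransientWindow, w: Waveform,
                     config: DetectorConfig | None = None) -> CrackleCandidate:
    """Measure a candidate window against the crackle waveform criteria.

    Two-cycle duration: time from the deflection onset (last point before
    the peak where the fine envelope is below 10% of peak) to the fifth
    baseline crossing after onset — the initial deflection returns to
    baseline once, then two full oscillation cycles contribute four more
    crossings.  Total duration: time from onset until the fine envelope
    stays below ``envelope_floor_fraction`` × peak for at least 3 ms.
    Accepts iff two-cycle < 20 ms and total < 25 ms.
    """
    cfg = config or DetectorConfig()
    fs = w.sample_rate_hz
    i0 = max(0, int(round(window.start_s * fs)))
    i1 = min(w.samples.size, int(round(window.end_s * fs)))
    x = w.samples[i0:i1]
    if x.size < 8:
        return CrackleCandidate(window.peak_time_s, np.nan, np.nan,
                                window.peak_amplitude, False,
                                "window too short to measure")
    env = _fine_envelope(x, fs)
    peak_idx = int(np.argmax(np.abs(x)))
    peak = float(abs(x[peak_idx]))
    thresh = cfg.envelope_floor_fraction * peak

    # onset of the initial deflection
    below = np.nonzero(env[:peak_idx] < thresh)[0]
    onset = int(below[-1]) if below.size else 0

    # baseline crossings after onset
    s = np.sign(x[onset:])
    s[s == 0] = 1
    crossings = np.nonzero(np.diff(s) != 0)[0] + 1 + onset
    if crossings.size < 5:
        return CrackleCandidate(window.peak_time_s, np.nan, np.nan,
                                window.peak_amplitude, False,
                                "fewer than two oscillation cycles in window")
    two_cycle_ms = (crossings[4] - onset) / fs * 1000.0

    # total duration: sustained envelope decay below the floor fraction
    run = max(1, int(round(0.003 * fs)))
    below_after = (env[peak_idx:] < thresh).astype(int)
    if below_after.size >= run:
        run_sums = np.convolve(below_after, np.ones(run, dtype=int), mode="valid")
        hits = np.nonzero(run_sums == run)[0]
    else:
        hits = np.array([], dtype=int)
    if hits.size:
        total_ms = (peak_idx + hits[0] - onset) / fs * 1000.0
    else:
        total_ms = (x.size - 1 - onset) / fs * 1000.0

    if two_cycle_ms >= cfg.max_two_cycle_ms:
        return CrackleCandidate(window.peak_time_s, two_cycle_ms, total_ms,
                                peak, False, "two-cycle duration >= 20 ms")
    if total_ms >= cfg.max_total_ms:
        return CrackleCandidate(window.peak_time_s, two_cycle_ms, total_ms,
                                peak, False, "total duration >= 25 ms")
    if total_ms < two_cycle_ms:
        # measurement inconsistency (e.g. envelope dip mid-transient)
        return CrackleCandidate(window.peak_time_s, two_cycle_ms, total_ms,
                                peak, False, "inconsistent duration measurements")
    return CrackleCandidate(window.peak_time_s, two_cycle_ms, total_ms,
                            peak, True)


# ---------------------------------------------------------------------------
# Wheeze stage
# ---------------------------------------------------------------------------

@dataclass
class Spectrogram:
    """Short-time Fourier magnitude with Hann windowing."""

    freqs_hz: np.ndarray
    times_s: np.ndarray
    magnitude: np.ndarray     # shape (n_freqs, n_frames)
    frame_s: float
    hop_s: float
    sample_rate_hz: float


def spectrogram(w: Waveform, frame_ms: float = 50.0,
                hop_ms: float = 12.5) -> Spectrogram:
    """Hann-windowed short-time Fourier magnitude.

    The 50 ms default frame gives <= 25 Hz frequency resolution even at the
    low-fidelity 4000 Hz rate.
    """
    if frame_ms < 10:
        raise InvalidParameterError("frame_ms must be >= 10 ms")
    fs = w.sample_rate_hz
    nperseg = int(round(frame_ms / 1000.0 * fs))
    hop = max(1, int(round(hop_ms / 1000.0 * fs)))
    if nperseg > w.samples.size:
        raise InvalidParameterError("frame longer than the signal")
    sft = signal.ShortTimeFFT(signal.windows.hann(nperseg), hop=hop, fs=fs,
                              scale_to="magnitude")
    mag = np.abs(sft.stft(w.samples))
    times = sft.t(w.samples.size)
    return Spectrogram(sft.f, times, mag, nperseg / fs, hop / fs, fs)


def _refine_segment_support(x: np.ndarray, fs: float, t0: float, t1: float,
                            f_dom: float) -> tuple[float, float]:
    """Refine a merged tonal region to its time-domain support.

    The region is narrow-band filtered around the dominant frequency and the
    support is the span where the band envelope exceeds half its maximum —
    this keeps a 20 ms burst from inheriting the full width of the analysis
    frames that contain it.
    """
    pad = 0.05
    i0 = max(0, int((t0 - pad) * fs))
    i1 = min(x.size, int((t1 + pad) * fs))
    seg = x[i0:i1]
    lo, hi = 0.75 * f_dom, min(1.25 * f_dom, 0.49 * fs)
    if seg.size < 16 or lo >= hi:
        return t0, t1
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    band = signal.sosfiltfilt(sos, seg)
    env = ndimage.uniform_filter1d(np.abs(band),
                                   size=max(1, int(0.005 * fs)), mode="nearest")
    # contiguous run above half-max that contains the envelope peak; a
    # first-to-last crossing span would bridge unrelated noise excursions
    above = env > 0.5 * env.max()
    peak = int(np.argmax(env))
    lo_i = peak
    while lo_i > 0 and above[lo_i - 1]:
        lo_i -= 1
    hi_i = peak
    while hi_i < above.size - 1 and above[hi_i + 1]:
        hi_i += 1
    return (i0 + lo_i) / fs, (i0 + hi_i + 1) / fs


def find_wheeze_segments(S: Spectrogram, w: Waveform | None = None,
                         config: DetectorConfig | None = None,
                         ) -> list[WheezeSegment]:
    """Segment tonal (wheezy) stretches of a spectrogram.

    A frame is tonal when its spectral peak magnitude exceeds
    ``prominence_threshold`` times the frame's median magnitude and the peak
    frequency is above 100 Hz.  Consecutive tonal frames whose peak frequency
    varies by less than 20% are merged; when the source waveform is supplied
    the merged region's boundaries are refined in the time domain.  Only
    segments longer than 25 ms are returned, with the mean tonal-frame peak
    frequency as the dominant frequency.
    """
    cfg = config or DetectorConfig()
    # tonality is judged within the analysis band only: outside it the
    # band-pass has already emptied the spectrum, which would deflate the
    # median and make every frame look tonal
    band = (S.freqs_hz >= cfg.min_wheeze_freq_hz) & \
           (S.freqs_hz <= cfg.max_wheeze_freq_hz)
    if not band.any():
        return []
    freqs = S.freqs_hz[band]
    mag = S.magnitude[band, :]
    n_frames = mag.shape[1]
    peak_bins = np.argmax(mag, axis=0)
    peak_mags = mag[peak_bins, np.arange(n_frames)]
    medians = np.median(mag, axis=0)
    peak_freqs = freqs[peak_bins]
    with np.errstate(divide="ignore", invalid="ignore"):
        prominence = np.where(medians > 0, peak_mags / medians,
                              np.where(peak_mags > 0, np.inf, 0.0))
    tonal = (prominence > cfg.prominence_threshold) & \
            (peak_freqs > cfg.min_wheeze_freq_hz)

    segments: list[WheezeSegment] = []
    i = 0
    while i < n_frames:
        if not tonal[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n_frames and tonal[j + 1]
               and abs(peak_freqs[j + 1] - peak_freqs[j])
               < cfg.freq_continuity * peak_freqs[j]):
            j += 1
        frames = slice(i, j + 1)
        f_dom = float(np.mean(peak_freqs[frames]))
        t0 = float(S.times_s[i] - S.frame_s / 2)
        t1 = float(S.times_s[j] + S.frame_s / 2)
        if w is not None:
            t0, t1 = _refine_segment_support(w.samples, w.sample_rate_hz,
                                             t0, t1, f_dom)
        if (t1 - t0) * 1000.0 > cfg.min_wheeze_ms and f_dom > cfg.min_wheeze_freq_hz:
            tonality = float(np.clip(
                np.mean(np.log10(np.maximum(prominence[frames], 1.0)))
                / np.log10(100.0), 0.0, 1.0))
            segments.append(WheezeSegment(t0, t1, f_dom, tonality))
        i = j + 1
    return segments


# ---------------------------------------------------------------------------
# Per-recording scoring
# ---------------------------------------------------------------------------

def detect_events(w: Waveform, config: DetectorConfig | None = None,
                  ) -> tuple[list[CrackleCandidate], list[WheezeSegment]]:
    """Run both detectors on a preprocessed waveform.

    Returns the accepted crackle candidates and the wheeze segments.
    """
    cfg = config or DetectorConfig()
    crackles = [
        c for c in (validate_crackle(win, w, cfg)
                    for win in find_transients(w, cfg))
        if c.accepted
    ]
    S = spectrogram(w, cfg.frame_ms, cfg.hop_ms)
    wheezes = find_wheeze_segments(S, w, cfg)
    return crackles, wheezes


def score_from_counts(n_crackles: int, wheeze_time_s: float,
                      duration_s: float,
                      config: DetectorConfig | None = None) -> ScorePair:
    """Map event counts/coverage to [0, 1] scores.

    crackle_score = 1 - exp(-n / scale) (scale defaults to 4, so four
    accepted crackles score ~0.632); wheeze_score = wheeze coverage fraction,
    capped at 1.  Both are monotone in their inputs.
    """
    cfg = config or DetectorConfig()
    c = 1.0 - float(np.exp(-n_crackles / cfg.crackle_score_scale))
    s = min(1.0, max(0.0, wheeze_time_s / duration_s))
    return ScorePair(c, s)


def score_recording(w: Waveform, config: DetectorConfig | None = None,
                    ) -> ScorePair:
    """Detect events and map them to the per-recording score pair."""
    cfg = config or DetectorConfig()
    crackles, wheezes = detect_events(w, cfg)
    wheeze_time = sum(s.duration_s for s in wheezes)
    return score_from_counts(len(crackles), wheeze_time, w.duration_s, cfg)


def label_recording(s: ScorePair, crackle_cutoff: float = 0.0,
                    wheeze_cutoff: float = 0.0) -> RecordingLabel:
    """Threshold scores into presence labels.

    Presence requires the score to *strictly* exceed the cutoff, matching
    the "> 0.00" maximum-sensitivity convention: a score of exactly 0 is
    never called present.
    """
    for c in (crackle_cutoff, wheeze_cutoff):
        if not 0.0 <= c <= 1.0:
            raise InvalidParameterError("cutoffs must lie in [0, 1]")
    return RecordingLabel(s.crackle_score > crackle_cutoff,
                          s.wheeze_score > wheeze_cutoff)
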