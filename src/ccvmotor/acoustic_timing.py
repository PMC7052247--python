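"""Phonatory timing variables from CCV audio.

Four quantities are extracted from a mono recording of one uttered CCV:

* the vocal onset — appearance of the spectral signature of the initial
  consonant (sustained fundamental-frequency energy for voiced
  plosives, sustained broadband noise for fricatives);
* the utterance duration T;
* the consonantal transition tau, bounded by two acoustic landmarks
  whose nature depends on the cluster type (plosive release bursts are
  broadband transients; fricatives are sustained noise spots);
* the normalized transition tau' = tau / T, which washes out speech-rate
  differences between speakers.

Landmarks are located on zero-phase band-limited energy envelopes
(bursts in the 1–8 kHz band, voicing in the 75–300 Hz band), so the
estimates carry no filter delay. All detector settings live in
:class:`DetectorConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import signal

__all__ = [
    "PhonatoryMeasures",
    "DetectorConfig",
    "NoOnsetError",
    "NoTransitionError",
    "detect_vocal_onset",
    "detect_transition",
    "measure_utterance",
    "normalize_transition",
    "onset_delay",
    "extract_phonatory",
]


class NoOnsetError(RuntimeError):
    """No sustained supra-threshold energy found: no vocal onset."""


class NoTransitionError(RuntimeError):
    """Fewer than two landmarks found: transition undefined."""


@dataclass(frozen=True)
class DetectorConfig:
    """Landmark-detector settings (times in s, frequencies in Hz)."""

    voiced_band: tuple[float, float] = (75.0, 300.0)
    burst_band: tuple[float, float] = (1000.0, 8000.0)
    onset_smooth: float = 0.010   # envelope moving-average window
    burst_smooth: float = 0.005
    sustain: float = 0.030        # minimum supra-threshold run for onsets
    onset_rel_threshold: float = 0.25   # fraction of (peak - floor)
    floor_factor: float = 4.0     # noise-floor multiplier for onsets
    burst_min_separation: float = 0.030
    burst_rel_height: float = 0.25      # fraction of the strongest burst
    fricative_sustain: float = 0.050    # minimum duration of a noise spot
    pre_onset_margin: float = 0.020     # landmark search starts this early


@dataclass(frozen=True)
class PhonatoryMeasures:
    """Per-trial phonatory timing (all times in seconds)."""

    delta: float | None  # first-fixation onset to vocal onset
    T: float             # utterance duration
    tau: float           # consonantal transition
    tau_norm: float      # tau / T
    landmarks: tuple[tuple[str, float], ...]


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    n = max(1, n)
    kernel = np.ones(n) / n
    return signal.fftconvolve(x, kernel, mode="same")


def _band_envelope(
    wave: np.ndarray, sample_rate: float, band: tuple[float, float], smooth: float
) -> np.ndarray:
    """Zero-phase band-pass magnitude envelope."""
    nyq = sample_rate / 2.0
    hi = min(band[1], 0.99 * nyq)
    sos = signal.butter(4, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    filtered = signal.sosfiltfilt(sos, wave)
    return _moving_average(np.abs(filtered), int(round(smooth * sample_rate)))


def _first_sustained_crossing(
    env: np.ndarray, threshold: float, sustain_samples: int
) -> int | None:
    above = env > threshold
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= sustain_samples:
            return i - run + 1
    return None


def _validate_wave(wave, sample_rate) -> np.ndarray:
    wave = np.asarray(wave, dtype=float)
    if wave.ndim != 1:
        raise ValueError("waveform must be mono (1-D)")
    if wave.size < int(0.1 * sample_rate):
        raise ValueError("waveform shorter than 0.1 s")
    return wave


def detect_vocal_onset(
    wave, sample_rate: float, voiced: bool = True, config: DetectorConfig = DetectorConfig()
) -> float:
    """Time (s) of the earliest sustained supra-threshold energy in the
    onset band: the fundamental-frequency band for voiced initial
    consonants, the broadband noise band for fricative initials.

    The threshold adapts to the record: noise floor (median envelope)
    times ``floor_factor``, or ``onset_rel_threshold`` of the dynamic
    range above the floor, whichever is larger.
    """
    wave = _validate_wave(wave, sample_rate)
    band = config.voiced_band if voiced else config.burst_band
    env = _band_envelope(wave, sample_rate, band, config.onset_smooth)
    floor = float(np.percentile(env, 10))  # silence occupies the record edges
    peak = float(env.max())
    if peak <= 0 or peak < 10 * np.finfo(float).tiny:
        raise NoOnsetError("record contains no energy")
    threshold = max(
        config.floor_factor * floor, floor + config.onset_rel_threshold * (peak - floor)
    )
    idx = _first_sustained_crossing(
        env, threshold, int(round(config.sustain * sample_rate))
    )
    if idx is None:
        raise NoOnsetError("no sustained supra-threshold energy found")
    return idx / sample_rate


def _phonation_offset(
    wave: np.ndarray, sample_rate: float, onset: float, config: DetectorConfig
) -> float:
    """Last time any band (voicing or broadband) stays above threshold."""
    total = np.zeros_like(wave)
    for band, smooth in (
        (config.voiced_band, config.onset_smooth),
        (config.burst_band, config.burst_smooth),
    ):
        env = _band_envelope(wave, sample_rate, band, smooth)
        total = np.maximum(total, env / max(env.max(), np.finfo(float).tiny))
    threshold = 0.05
    above = np.nonzero(total > threshold)[0]
    if above.size == 0:
        raise NoOnsetError("no energy above the offset threshold")
    return above[-1] / sample_rate


def _burst_landmarks(
    wave: np.ndarray, sample_rate: float, after: float, config: DetectorConfig
) -> list[float]:
    """Times of broadband release bursts (envelope peaks) after ``after``."""
    env = _band_envelope(wave, sample_rate, config.burst_band, config.burst_smooth)
    start = max(0, int(round(after * sample_rate)))
    seg = env[start:]
    if seg.size == 0 or seg.max() <= 0:
        return []
    peaks, _ = signal.find_peaks(
        seg,
        height=config.burst_rel_height * seg.max(),
        distance=max(1, int(round(config.burst_min_separation * sample_rate))),
        prominence=0.5 * config.burst_rel_height * seg.max(),
    )
    return [(start + p) / sample_rate for p in peaks]


def _noise_spot(
    wave: np.ndarray, sample_rate: float, after: float, config: DetectorConfig
) -> tuple[float, float] | None:
    """(start, end) of the first sustained broadband noise region."""
    env = _band_envelope(wave, sample_rate, config.burst_band, config.onset_smooth)
    start = max(0, int(round(after * sample_rate)))
    seg = env[start:]
    if seg.size == 0:
        return None
    threshold = 0.3 * seg.max()
    above = seg > threshold
    run_start, run = None, 0
    need = int(round(config.fricative_sustain * sample_rate))
    for i, a in enumerate(above):
        if a:
            if run == 0:
                run_start = i
            run += 1
        else:
            if run >= need:
                break
            run = 0
    if run < need or run_start is None:
        return None
    run_end = run_start + run
    return (start + run_start) / sample_rate, (start + run_end) / sample_rate


def detect_transition(
    wave,
    sample_rate: float,
    cluster_type: str,
    vocal_onset: float | None = None,
    config: DetectorConfig = DetectorConfig(),
) -> tuple[float, list[tuple[str, float]]]:
    """Consonantal transition tau (s) and its two labelled landmarks.

    Rules per cluster type:

    * ``plosive-plosive`` — from the release burst of the first plosive
      to the release burst of the second one into the vowel;
    * ``plosive-fricative`` — from the brief broadband plosive burst to
      the start of the purely noisy fricative spot;
    * ``fricative-plosive`` — from the abrupt end of the fricative noise
      to the release burst of the plosive into the vowel;
    * ``fricative-fricative`` — unsupported (no landmark rule).
    """
    wave = _validate_wave(wave, sample_rate)
    if cluster_type == "fricative-fricative":
        raise ValueError("no transition rule for fricative-fricative clusters")
    if vocal_onset is None:
        vocal_onset = detect_vocal_onset(
            wave, sample_rate, voiced=cluster_type.startswith("plosive"), config=config
        )
    search_from = vocal_onset - config.pre_onset_margin

    if cluster_type == "plosive-plosive":
        bursts = _burst_landmarks(wave, sample_rate, search_from, config)
        if len(bursts) < 2:
            raise NoTransitionError(
                f"found {len(bursts)} release burst(s); need 2"
            )
        t1, t2 = bursts[0], bursts[1]
        landmarks = [("release_1", t1), ("release_2", t2)]
    elif cluster_type == "plosive-fricative":
        bursts = _burst_landmarks(wave, sample_rate, search_from, config)
        if not bursts:
            raise NoTransitionError("no plosive burst found")
        t1 = bursts[0]
        spot = _noise_spot(wave, sample_rate, t1 + 0.02, config)
        if spot is None:
            raise NoTransitionError("no fricative noise spot found")
        t2 = spot[0]
        landmarks = [("release_1", t1), ("fricative_start", t2)]
    elif cluster_type == "fricative-plosive":
        spot = _noise_spot(wave, sample_rate, search_from, config)
        if spot is None:
            raise NoTransitionError("no fricative noise spot found")
        t1 = spot[1]
        bursts = _burst_landmarks(wave, sample_rate, t1 + 0.005, config)
        if not bursts:
            raise NoTransitionError("no plosive burst after the fricative")
        t2 = bursts[0]
        landmarks = [("fricative_end", t1), ("release_2", t2)]
    else:
        raise ValueError(f"unknown cluster type {cluster_type!r}")

    tau = t2 - t1
    if tau <= 0:
        raise NoTransitionError("landmarks are not ordered in time")
    return tau, landmarks


def measure_utterance(
    wave, sample_rate: float, voiced: bool = True, config: DetectorConfig = DetectorConfig()
) -> tuple[float, float]:
    """(onset, T): vocal onset and utterance duration in seconds."""
    wave = _validate_wave(wave, sample_rate)
    onset = detect_vocal_onset(wave, sample_rate, voiced=voiced, config=config)
    offset = _phonation_offset(wave, sample_rate, onset, config)
    if offset <= onset:
        raise NoOnsetError("phonation offset precedes onset")
    return onset, offset - onset


def normalize_transition(tau: float, T: float) -> float:
    """tau' = tau / T; the rate-normalized consonantal transition."""
    if T <= 0:
        raise ValueError("utterance duration T must be positive")
    if tau < 0 or tau > T:
        raise ValueError("tau must lie within [0, T]")
    if tau == T:
        warnings.warn("tau equals T: degenerate transition spanning the utterance")
    return tau / T


def onset_delay(
    first_fixation_onset: float | None, vocal_onset: float | None
) -> float | None:
    """Delay between the first fixation on a CCV and its voice onset.

    Both timestamps must be on the same clock. Negative values (voice
    before fixation) are returned as-is; quality control flags them
    downstream. Missing timestamps yield None (trial later excluded).
    """
    if first_fixation_onset is None or vocal_onset is None:
        return None
    return vocal_onset - first_fixation_onset


def extract_phonatory(
    wave,
    sample_rate: float,
    cluster_type: str,
    first_fixation_onset: float | None = None,
    voiced_initial: bool = True,
    config: DetectorConfig = DetectorConfig(),
) -> PhonatoryMeasures:
    """Full phonatory extraction for one trial's audio record."""
    onset, T = measure_utterance(wave, sample_rate, voiced=voiced_initial, config=config)
    tau, landmarks = detect_transition(
        wave, sample_rate, cluster_type, vocal_onset=onset, config=config
    )
    tau = min(tau, T)  # guard against envelope-tail overshoot
    return PhonatoryMeasures(
        delta=onset_delay(first_fixation_onset, onset),
        T=T,
        tau=tau,
        tau_norm=normalize_transition(tau, T),
        landmarks=tuple([("vocal_onset", onset)] + landmarks),
    )
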