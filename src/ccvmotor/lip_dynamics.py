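"""Lip-accelerometer processing: rectified envelopes, trace alignment,
and the oral/silent articulation amplitude comparison.

Lip movement is the accessible proxy for whole-tract articulation
during reading. Traces are rectified and smoothed with a 140-ms moving
window, aligned either at the vocal onset (oral block) or at their
maximum (both blocks, when no vocal reference exists), and the oral
versus silent articulation ranges are compared as a ratio of aligned
peak magnitudes — accelerometer units are uncalibrated, so only ratios
are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

__all__ = [
    "LipTrace",
    "envelope",
    "align_traces",
    "modality_amplitude_ratio",
]


@dataclass(frozen=True)
class LipTrace:
    """Uniformly sampled lip acceleration (arbitrary units)."""

    samples: np.ndarray
    rate: float  # Hz
    t0: float = 0.0
    modality: str = "oral"  # oral | silent
    vocal_onset: float | None = None  # s, same clock as t0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate


def envelope(trace: LipTrace, window: float = 140.0) -> np.ndarray:
    """Centred moving average of |samples| over ``window`` ms.

    Edges shrink the averaging window to the available samples (no zero
    padding), so a constant input maps to a constant output.
    """
    n = int(round(window * 1e-3 * trace.rate))
    if n < 1:
        raise ValueError("window must cover at least one sample period")
    x = np.abs(trace.samples)
    if n > x.size:
        raise ValueError("window longer than the trace")
    half_lo = (n - 1) // 2
    half_hi = n // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(x.size)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, x.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _reference_index(trace: LipTrace, env: np.ndarray, mode: str) -> int:
    if mode == "vocal_onset":
        if trace.vocal_onset is None:
            raise ValueError("trace has no vocal onset reference")
        return int(round((trace.vocal_onset - trace.t0) * trace.rate))
    if mode == "maximum":
        peak = env.max()
        hits = np.nonzero(env == peak)[0]
        if hits.size > 1:
            warnings.warn("maximum not unique; using the earliest one")
        return int(hits[0])
    raise ValueError(f"unknown alignment mode {mode!r}")


def align_traces(
    traces: list[LipTrace], mode: str = "vocal_onset", window: float = 140.0
) -> tuple[np.ndarray, np.ndarray]:
    """Align smoothed envelopes so each trace's reference sits at t = 0.

    Returns (matrix, time_axis): one row per trace on a common axis,
    NaN where a trace has no samples. Relative timing within each trace
    is preserved; all traces must share one sampling rate.
    """
    if not traces:
        raise ValueError("no traces to align")
    rate = traces[0].rate
    if any(t.rate != rate for t in traces):
        raise ValueError("all traces must share one sampling rate")
    envs = [envelope(t, window) for t in traces]
    refs = [_reference_index(t, e, mode) for t, e in zip(traces, envs)]
    left = max(refs)
    right = max(e.size - r for e, r in zip(envs, refs))
    width = left + right
    matrix = np.full((len(traces), width), np.nan)
    for row, (e, r) in enumerate(zip(envs, refs)):
        matrix[row, left - r : left - r + e.size] = e
    time_axis = (np.arange(width) - left) / rate
    return matrix, time_axis


def modality_amplitude_ratio(
    oral_peaks, silent_peaks
) -> tuple[float, bool]:
    """Ratio of median aligned-peak magnitudes, oral / silent.

    Returns (ratio, finite_flag); an all-zero silent median yields
    (inf, False). The ratio is invariant to any common gain applied to
    both modalities.
    """
    oral_peaks = np.asarray(oral_peaks, dtype=float)
    silent_peaks = np.asarray(silent_peaks, dtype=float)
    if oral_peaks.size == 0 or silent_peaks.size == 0:
        raise ValueError("need at least one peak per modality")
    oral_med = float(np.median(oral_peaks))
    silent_med = float(np.median(silent_peaks))
    if silent_med == 0.0:
        return float("inf"), False
    return oral_med / silent_med, True


def aligned_peaks(traces: list[LipTrace], window: float = 140.0) -> np.ndarray:
    """Peak envelope magnitude of each trace (maximum-aligned peaks)."""
    return np.array([envelope(t, window).max() for t in traces])
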