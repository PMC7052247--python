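"""Calibrated synthetic CCV reading experiments.

Generates every input the analysis consumes, with the study's design
and group structure built in:

* the trial design — 72 CCVs (ordered pairs of 9 consonants, no
  repeated consonant), 6 per screen, 30 screens per block, two blocks
  (oral / silent), the 15 voiced-initial plosive-plosive CCVs repeated
  three times per block and the other 57 two or three times (135
  repetitions), 180 stimuli per block;
* trial-level timing draws calibrated to the measured subgroup means of
  the normalized transition tau' (fully voiced 0.373/0.390 by place
  ordering; devoiced 0.413), the positive Delta–tau' and silent
  FFD–tau' couplings, and negative repetition slopes on FPRT/TFT;
* fixation-event streams that round-trip exactly through the gaze
  pipeline;
* CCV audio with planted burst landmarks for the acoustic detectors;
* lip-accelerometer traces with oral/silent amplitudes separated by two
  orders of magnitude.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .effort import FRICATIVES, PLOSIVES, VOICED_PLOSIVES, analysis_ccvs, ccv_from_string
from .gaze_metrics import FixationEvent, OcularMeasures, ScreenLayout, N_AOIS
from .lip_dynamics import LipTrace
from .qc_filter import bin_frequency

__all__ = [
    "CalibrationTable",
    "DesignSpec",
    "SynthAudio",
    "ccv_inventory",
    "load_frequency_table",
    "build_design",
    "simulate_timing",
    "realize_fixations",
    "synthesize_ccv_audio",
    "simulate_lip_trace",
]

CONSONANTS = tuple(PLOSIVES) + tuple(FRICATIVES)

SACCADE_GAP = 0.030  # s between successive fixations
FIXATION_SLOT = 0.450  # nominal reading time budget per AOI, s


def ccv_inventory() -> list[str]:
    """All 72 CCV labels: ordered consonant pairs, same-consonant pairs
    excluded, ending in the vowel a."""
    return [
        f"{c1}{c2}a" for c1 in CONSONANTS for c2 in CONSONANTS if c1 != c2
    ]


def load_frequency_table() -> pd.DataFrame:
    """Packaged synthetic intra-word frequency table (ccv, f)."""
    with resources.files("ccvmotor.data").joinpath(
        "ccv_frequency_synthetic.csv"
    ).open() as fh:
        return pd.read_csv(fh, comment="#")


# ---------------------------------------------------------------------------
# calibration

@dataclass(frozen=True)
class CalibrationTable:
    """Trial-level generative parameters.

    ``ccv_stats`` holds per-CCV tau' and T moments for the 15
    plosive-plosive analysis CCVs; other CCVs fall back to the default
    moments. Couplings: Delta = delta_intercept + delta_slope * tau'
    (s); silent-block FFD = ffd_intercept + ffd_slope * tau'_ccv (ms);
    FPRT/TFT are built from FFD plus non-negative gap draws whose means
    decrease with repetition number (ms per repetition).
    """

    ccv_stats: pd.DataFrame
    delta_intercept: float = 0.25
    delta_slope: float = 0.50
    delta_sd: float = 0.15
    ffd_intercept: float = -70.0
    ffd_slope: float = 700.0
    ffd_sd: float = 40.0
    ffd_oral_mean: float = 210.0
    fprt_gap: float = 60.0
    fprt_rep_slope: float = -20.0
    fprt_gap_sd: float = 40.0
    tft_gap: float = 45.0
    tft_rep_slope: float = -10.0
    tft_gap_sd: float = 35.0
    default_tau_mean: float = 0.40
    default_tau_sd: float = 0.065
    default_T_mean: float = 0.490
    default_T_sd: float = 0.050
    p_unfixated: float = 0.02
    p_mispronounced: float = 0.04
    p_multi_attempt: float = 0.015

    @classmethod
    def default(cls) -> "CalibrationTable":
        with resources.files("ccvmotor.data").joinpath(
            "ccv_calibration.csv"
        ).open() as fh:
            stats = pd.read_csv(fh, comment="#")
        return cls(ccv_stats=stats)

    @classmethod
    def from_file(cls, path: str | Path, **couplings) -> "CalibrationTable":
        return cls(ccv_stats=pd.read_csv(path, comment="#"), **couplings)

    def zero_couplings(self) -> "CalibrationTable":
        """Null calibration: all tau' couplings and repetition slopes 0,
        per-CCV tau' means collapsed to the grand mean."""
        stats = self.ccv_stats.copy()
        grand = float(stats["tau_norm_mean"].mean())
        stats["tau_norm_mean"] = grand
        return replace(
            self,
            ccv_stats=stats,
            delta_intercept=self.delta_intercept + self.delta_slope * grand,
            delta_slope=0.0,
            ffd_intercept=self.ffd_intercept + self.ffd_slope * grand,
            ffd_slope=0.0,
            fprt_rep_slope=0.0,
            tft_rep_slope=0.0,
        )

    def tau_mean(self, ccv: str) -> float:
        row = self.ccv_stats[self.ccv_stats["ccv"] == ccv]
        if row.empty:
            return self.default_tau_mean
        return float(row["tau_norm_mean"].iloc[0])

    def _moments(self, ccv: str) -> tuple[float, float, float, float]:
        row = self.ccv_stats[self.ccv_stats["ccv"] == ccv]
        if row.empty:
            return (
                self.default_tau_mean,
                self.default_tau_sd,
                self.default_T_mean,
                self.default_T_sd,
            )
        r = row.iloc[0]
        return (
            float(r["tau_norm_mean"]),
            float(r["tau_norm_sd"]),
            float(r["T_mean"]),
            float(r["T_sd"]),
        )

    def validate(self) -> None:
        """Check the calibrated subgroup ordering invariants."""
        m = {r["ccv"]: r["tau_norm_mean"] for _, r in self.ccv_stats.iterrows()}
        canonical = np.mean([m["bda"], m["bga"], m["dga"]])
        interchanged = np.mean([m["dba"], m["gba"], m["gda"]])
        voiced = np.mean([m[c] for c in ("bda", "bga", "dba", "dga", "gba", "gda")])
        devoiced = np.mean(
            [m[f"{c1}{c2}a"] for c1 in "bdg" for c2 in "ptc"]
        )
        if not canonical < interchanged:
            raise ValueError("calibration must order canonical < interchanged")
        if not voiced < devoiced:
            raise ValueError("calibration must order voiced < devoiced")


# ---------------------------------------------------------------------------
# design

@dataclass(frozen=True)
class DesignSpec:
    """Experimental design: subjects x blocks x screens of 6 CCVs."""

    n_subjects: int = 30
    n_screens: int = 30
    core_repetitions: int = 3   # the 15 analysis CCVs, per block
    filler_triples: int = 21    # fillers shown 3x (the rest are shown 2x)

    @property
    def stimuli_per_block(self) -> int:
        return self.n_screens * N_AOIS

    def filler_counts(self) -> tuple[int, int]:
        """(n shown 3x, n shown 2x) among the 57 non-core CCVs."""
        n_fillers = 72 - 15
        triples = self.filler_triples
        doubles = n_fillers - triples
        return triples, doubles


def _block_stimuli(spec: DesignSpec, rng: np.random.Generator) -> list[str]:
    core = [c.label for c in analysis_ccvs()]
    fillers = [c for c in ccv_inventory() if c not in core]
    triples, doubles = spec.filler_counts()
    total = spec.core_repetitions * len(core) + 3 * triples + 2 * doubles
    if total != spec.stimuli_per_block:
        raise ValueError(
            f"repetition scheme yields {total} stimuli, need {spec.stimuli_per_block}"
        )
    chosen = rng.permutation(len(fillers))[:triples]
    stimuli = core * spec.core_repetitions
    for i, f in enumerate(fillers):
        stimuli += [f] * (3 if i in set(chosen) else 2)
    order = rng.permutation(len(stimuli))
    return [stimuli[i] for i in order]


def build_design(spec: DesignSpec = DesignSpec(), seed: int = 0) -> pd.DataFrame:
    """Trial table: one row per presented CCV.

    Columns: subject, block, screen, position, ccv, cluster_type, f,
    freq_level, repetition (occurrence index within subject x block).
    Deterministic given (spec, seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    freq = load_frequency_table().set_index("ccv")["f"]
    rows = []
    for subject in range(1, spec.n_subjects + 1):
        blocks = ["oral", "silent"] if rng.random() < 0.5 else ["silent", "oral"]
        for block in blocks:
            stimuli = _block_stimuli(spec, rng)
            seen: dict[str, int] = {}
            for idx, ccv in enumerate(stimuli):
                seen[ccv] = seen.get(ccv, 0) + 1
                f = float(freq.get(ccv, 0.0))
                rows.append(
                    {
                        "subject": subject,
                        "block": block,
                        "screen": idx // N_AOIS,
                        "position": idx % N_AOIS,
                        "ccv": ccv,
                        "cluster_type": ccv_from_string(ccv).cluster_type,
                        "f": f,
                        "freq_level": bin_frequency(f),
                        "repetition": seen[ccv],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# timing simulation

def simulate_timing(
    design: pd.DataFrame,
    calibration: CalibrationTable | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-trial timing variables onto a design table.

    Oral trials receive phonatory variables (tau', T, tau, Delta and a
    vocal onset); both blocks receive the ocular triple FFD <= FPRT <=
    TFT and QC flags. FFD carries the tau' coupling in the silent block
    only; FPRT/TFT decrease in expectation with repetition number.
    """
    calibration = calibration if calibration is not None else CalibrationTable.default()
    cal = calibration
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    df = design.copy()
    n = len(df)

    moments = np.array([cal._moments(c) for c in df["ccv"]])
    tau_mu, tau_sd, T_mu, T_sd = moments.T
    oral = (df["block"] == "oral").to_numpy()
    rep = df["repetition"].to_numpy()

    tau_norm = np.clip(rng.normal(tau_mu, tau_sd), 0.02, 0.95)
    T = np.clip(rng.normal(T_mu, T_sd), 0.25, None)
    delta = cal.delta_intercept + cal.delta_slope * tau_norm + rng.normal(
        0.0, cal.delta_sd, n
    )

    # ocular variables (ms); the articulatory coupling acts through the
    # CCV's calibrated mean tau', not the trial's own oral draw
    ccv_tau = tau_mu
    ffd_mean = np.where(
        oral, cal.ffd_oral_mean, cal.ffd_intercept + cal.ffd_slope * ccv_tau
    )
    ffd = np.maximum(rng.normal(ffd_mean, cal.ffd_sd), 30.0)
    gap1 = np.maximum(
        rng.normal(cal.fprt_gap + cal.fprt_rep_slope * (rep - 1), cal.fprt_gap_sd),
        0.0,
    )
    gap2 = np.maximum(
        rng.normal(cal.tft_gap + cal.tft_rep_slope * (rep - 1), cal.tft_gap_sd),
        0.0,
    )
    fprt = ffd + gap1
    tft = fprt + gap2

    unfixated = rng.random(n) < cal.p_unfixated
    mispronounced = oral & (rng.random(n) < cal.p_mispronounced)
    multi_attempt = oral & (rng.random(n) < cal.p_multi_attempt)

    # nominal clocks: screens start every 6 reading slots
    screen_start = (
        df.groupby(["subject", "block", "screen"]).ngroup().to_numpy()
        * (N_AOIS * FIXATION_SLOT + 2.0)
    )
    first_fix_onset = screen_start + df["position"].to_numpy() * FIXATION_SLOT

    df["ffd"] = ffd
    df["fprt"] = fprt
    df["tft"] = tft
    df["unfixated"] = unfixated
    df["first_fix_onset"] = np.where(unfixated, np.nan, first_fix_onset)
    df["tau_norm"] = np.where(oral, tau_norm, np.nan)
    df["T"] = np.where(oral, T, np.nan)
    df["tau"] = np.where(oral, tau_norm * T, np.nan)
    df["delta"] = np.where(oral, delta, np.nan)
    df["vocal_onset"] = np.where(oral & ~unfixated, first_fix_onset + delta, np.nan)
    df["mispronounced"] = mispronounced
    df["multi_attempt"] = multi_attempt
    df.loc[unfixated, ["ffd", "fprt", "tft"]] = np.nan
    return df


# ---------------------------------------------------------------------------
# fixation realization (inverse of the gaze pipeline)

def realize_fixations(
    trial_measures: list[OcularMeasures],
    layout: ScreenLayout = ScreenLayout(),
    screen_start: float = 0.0,
) -> list[FixationEvent]:
    """Fixation stream for one 6-AOI screen whose forward gaze measures
    reproduce ``trial_measures`` exactly.

    First pass visits fixated AOIs left to right (FFD fixation, then a
    remainder fixation when FPRT > FFD); a second pass adds one re-read
    fixation per AOI with TFT > FPRT. Raises when a measure triple is
    internally inconsistent, or when the only re-read belongs to the
    last fixated AOI (no intervening AOI could end its first pass).
    """
    if len(trial_measures) != N_AOIS:
        raise ValueError(f"expected {N_AOIS} measures, got {len(trial_measures)}")
    for m in trial_measures:
        if m.fixated and not (0 < m.ffd <= m.fprt <= m.tft):
            raise ValueError("inconsistent measures: need 0 < FFD <= FPRT <= TFT")
    fixated = [i for i, m in enumerate(trial_measures) if m.fixated]
    rereads = [
        i for i in fixated if trial_measures[i].tft > trial_measures[i].fprt
    ]
    if rereads and fixated and rereads == [fixated[-1]]:
        raise ValueError(
            "inconsistent measures: a re-read on the last fixated AOI only "
            "cannot terminate its first pass"
        )
    events: list[FixationEvent] = []
    clock = screen_start

    def emit(aoi: int, duration_ms: float) -> None:
        nonlocal clock
        x, y = layout.aoi_center(aoi)
        events.append(
            FixationEvent(onset=clock, duration=duration_ms, x=x, y=y)
        )
        clock += duration_ms / 1000.0 + SACCADE_GAP

    for i in fixated:
        m = trial_measures[i]
        emit(i, m.ffd)
        if m.fprt > m.ffd:
            emit(i, m.fprt - m.ffd)
    for i in rereads:
        emit(i, trial_measures[i].tft - trial_measures[i].fprt)
    return events


# ---------------------------------------------------------------------------
# audio synthesis

@dataclass(frozen=True)
class SynthAudio:
    """Synthetic CCV waveform with its planted ground truth."""

    wave: np.ndarray
    sample_rate: float
    onset: float
    landmarks: tuple[float, ...]
    T: float


def _bandpassed_noise(
    n: int, sample_rate: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    nyq = sample_rate / 2.0
    sos = signal.butter(
        4, [band[0] / nyq, min(band[1], 0.99 * nyq) / nyq], btype="band", output="sos"
    )
    return signal.sosfilt(sos, rng.standard_normal(n))


def synthesize_ccv_audio(
    landmark_times,
    T: float = 0.490,
    sample_rate: float = 16000.0,
    onset: float | None = None,
    voiced: bool = True,
    fricative_spans=None,
    snr_db: float = 30.0,
    amplitude: float = 1.0,
    seed: int = 0,
) -> SynthAudio:
    """Synthetic CCV record for the landmark detectors.

    A low-frequency buzz (fundamental + harmonics) runs from the vocal
    onset to the end of the utterance (voiced CCVs); broadband 10-ms
    release bursts are planted at each landmark time; a vowel-like
    periodic component follows the last landmark; optional sustained
    noise spans emulate fricatives. White background noise is scaled to
    ``snr_db`` relative to the clean signal. Not naturalistic speech —
    a ground-truth fixture, bit-reproducible per seed.
    """
    landmarks = tuple(float(t) for t in np.atleast_1d(landmark_times))
    onset = float(onset) if onset is not None else (landmarks[0] - 0.05 if landmarks else 0.1)
    end = onset + T
    if any(not (onset <= t <= end) for t in landmarks):
        raise ValueError("landmarks must lie within the utterance [onset, onset+T]")
    if list(landmarks) != sorted(landmarks):
        raise ValueError("landmarks must be increasing")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    n = int(round((end + 0.15) * sample_rate))
    t = np.arange(n) / sample_rate
    wave = np.zeros(n)

    in_utterance = (t >= onset) & (t <= end)
    if voiced:
        buzz = np.zeros(n)
        for k, f0 in enumerate((120.0, 240.0), start=1):
            buzz += (0.3 / k) * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        wave += buzz * in_utterance

    burst_len = int(round(0.010 * sample_rate))
    window = np.hanning(burst_len)
    for tk in landmarks:
        center = int(round(tk * sample_rate))
        lo = center - burst_len // 2
        burst = _bandpassed_noise(burst_len, sample_rate, (1000.0, 8000.0), rng)
        burst = window * burst / max(np.abs(burst).max(), 1e-12)
        hi = min(lo + burst_len, n)
        if lo < 0 or hi <= lo:
            continue
        wave[lo:hi] += burst[: hi - lo]

    if landmarks:  # vowel-like tail after the final release
        tail = (t >= landmarks[-1]) & (t <= end)
        wave += 0.2 * np.sin(2 * np.pi * 700.0 * t) * tail

    for span in fricative_spans or []:
        lo = int(round(span[0] * sample_rate))
        hi = int(round(span[1] * sample_rate))
        frick = _bandpassed_noise(hi - lo, sample_rate, (2000.0, 6000.0), rng)
        ramp = np.minimum(1.0, np.minimum(np.arange(hi - lo), np.arange(hi - lo)[::-1]) / (0.005 * sample_rate))
        wave[lo:hi] += 0.5 * ramp * frick / max(np.abs(frick).max(), 1e-12)

    wave *= amplitude
    rms = float(np.sqrt(np.mean(wave**2)))
    if rms > 0:
        noise_rms = rms / (10 ** (snr_db / 20.0))
        wave = wave + rng.standard_normal(n) * noise_rms
    return SynthAudio(
        wave=wave, sample_rate=sample_rate, onset=onset, landmarks=landmarks, T=T
    )


# ---------------------------------------------------------------------------
# lip traces

def simulate_lip_trace(
    modality: str,
    vocal_onset: float,
    seed: int = 0,
    rate: float = 1000.0,
    silent_scale: float = 1e-2,
    activity: str = "low",
    noise_floor: float = 5e-4,
) -> LipTrace:
    """Synthetic lip-accelerometer trace.

    The oral profile ramps up over the half second before phonation,
    peaks at the vocal onset, and decays afterwards. Silent traces are
    the same profile scaled down two orders of magnitude
    (``activity='low'``) or pure sensor noise (``activity='null'``).
    """
    if modality not in ("oral", "silent"):
        raise ValueError(f"unknown modality {modality!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    duration = vocal_onset + 0.45
    t = np.arange(int(round(duration * rate))) / rate
    rise, fall = 0.5, 0.45
    profile = np.zeros_like(t)
    up = (t >= vocal_onset - rise) & (t < vocal_onset)
    profile[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - vocal_onset + rise) / rise))
    down = (t >= vocal_onset) & (t < vocal_onset + fall)
    profile[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - vocal_onset) / fall))
    carrier = np.sin(2 * np.pi * 7.0 * t + rng.uniform(0, 2 * np.pi))
    carrier = 0.8 * carrier + 0.2 * rng.standard_normal(t.size)

    scale = 1.0
    if modality == "silent":
        scale = 0.0 if activity == "null" else silent_scale
    samples = scale * profile * carrier + noise_floor * rng.standard_normal(t.size)
    return LipTrace(
        samples=samples, rate=rate, t0=0.0, modality=modality, vocal_onset=vocal_onset
    )
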