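"""Total vocal effort of a plosive-plosive CCV.

Effort is modelled as the sum of a laryngeal devoicing term and the
integrated deformation of the vocal tract away from its neutral shape:

    E = E0 + int_0^T int_0^L |A(x, t) - A_Omega(x)| dx dt

E0 > 0 is paid whenever a phoneme of the CCV is devoiced (the glottis
must be actively abducted to stop vocal-fold vibration); the double
integral accumulates the elastic cost of reshaping the tract over the
utterance. Units: cm^2 * s (area deviation integrated over cm and s).

E0 itself has no published value. When not supplied it is calibrated so
that the devoiced-group mean effort exceeds the fully-voiced-group mean
by the same ratio as the measured normalized-transition group means
(41.3 / 38.2) — a calibration, not a measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tract_model import (
    AreaField,
    OcclusionGesture,
    TractGeometry,
    VowelGesture,
    area_function,
    default_geometry,
    neutral_area,
)

__all__ = [
    "CCVSpec",
    "EffortResult",
    "EffortConfig",
    "ccv_from_string",
    "analysis_ccvs",
    "devoicing_term",
    "tract_effort",
    "ccv_effort",
    "effort_table",
    "effort_sweep",
    "calibrate_e0",
]

VOICED_PLOSIVES = ("b", "d", "g")
UNVOICED_PLOSIVES = ("p", "t", "c")  # c = /k/ as spelled in the stimuli
PLOSIVES = VOICED_PLOSIVES + UNVOICED_PLOSIVES
FRICATIVES = ("s", "f", "j")

# occlusion place as a fraction of tract length; voiced/unvoiced pairs
# share their place of articulation (lips, alveolar ridge, velum)
OCCLUSION_PLACE_FRAC = {
    "b": 1.00, "p": 1.00,   # bilabial: at the mouth exit
    "d": 0.85, "t": 0.85,   # alveolar
    "g": 0.60, "c": 0.60,   # velar
}

# ratio of the printed devoiced-group to voiced-group mean normalized
# transitions, used to calibrate the default E0
DEVOICED_TO_VOICED_TAU_RATIO = 41.3 / 38.2


class UnsupportedClusterError(ValueError):
    """Raised for CCVs whose effort the occlusion model cannot express."""


def _cluster_type(c1: str, c2: str) -> str:
    a = "plosive" if c1 in PLOSIVES else "fricative"
    b = "plosive" if c2 in PLOSIVES else "fricative"
    return f"{a}-{b}"


@dataclass(frozen=True)
class CCVSpec:
    """One consonant-consonant-vowel trigram and its attributes."""

    c1: str
    c2: str
    vowel: str = "a"
    f: float = 0.0  # intra-word frequency, appearances per million words

    def __post_init__(self) -> None:
        for c in (self.c1, self.c2):
            if c not in PLOSIVES + FRICATIVES:
                raise ValueError(f"unknown consonant {c!r}")
        if self.c1 == self.c2:
            raise ValueError("CCVs repeating the same consonant are excluded")

    @property
    def label(self) -> str:
        return f"{self.c1}{self.c2}{self.vowel}"

    @property
    def voiced1(self) -> bool:
        return self.c1 in VOICED_PLOSIVES

    @property
    def voiced2(self) -> bool:
        return self.c2 in VOICED_PLOSIVES

    @property
    def cluster_type(self) -> str:
        return _cluster_type(self.c1, self.c2)

    @property
    def devoiced(self) -> bool:
        """True when any consonant is an unvoiced plosive."""
        return self.c1 in UNVOICED_PLOSIVES or self.c2 in UNVOICED_PLOSIVES

    def occlusion_places(self, L: float) -> tuple[float, float]:
        if self.cluster_type != "plosive-plosive":
            raise UnsupportedClusterError(
                f"{self.label}: no occlusion model for fricatives"
            )
        return (
            L * OCCLUSION_PLACE_FRAC[self.c1],
            L * OCCLUSION_PLACE_FRAC[self.c2],
        )


def ccv_from_string(label: str, f: float = 0.0) -> CCVSpec:
    """Parse a three-letter label like ``'bda'`` into a CCVSpec."""
    if len(label) != 3:
        raise ValueError(f"CCV label must have 3 characters, got {label!r}")
    return CCVSpec(c1=label[0], c2=label[1], vowel=label[2], f=f)


def analysis_ccvs() -> list[CCVSpec]:
    """The 15 CCVs analysed: a voiced plosive followed by any other
    plosive (voiced first consonants give a clean spectrogram onset)."""
    return [
        CCVSpec(c1=c1, c2=c2)
        for c1 in VOICED_PLOSIVES
        for c2 in PLOSIVES
        if c2 != c1
    ]


@dataclass(frozen=True)
class EffortResult:
    ccv: CCVSpec
    E_tract: float
    E0: float
    dt_closure: float

    @property
    def E_total(self) -> float:
        return self.E_tract + self.E0


@dataclass(frozen=True)
class EffortConfig:
    """Parameters of the effort computation.

    T : utterance duration in s (mean measured CCV duration).
    dt_closure : interval between the two closures in s.
    t1 : time of the first closure in s.
    E0_value : laryngeal devoicing effort (cm^2 s); None = calibrate.
    q1_target, q2_target : vowel /a/ mode coefficients.
    time_step : integration step in s.
    """

    T: float = 0.490
    dt_closure: float = 0.200
    t1: float = 0.100
    E0_value: float | None = None
    q1_target: float = 0.48
    q2_target: float = 0.38
    sigma: float = 1.0
    w: float = 0.120
    time_step: float = 0.001


def devoicing_term(ccv: CCVSpec, E0_value: float) -> float:
    """E0 if any consonant of the CCV is devoiced, else 0."""
    if E0_value < 0:
        raise ValueError("E0_value must be non-negative")
    return float(E0_value) if ccv.devoiced else 0.0


def tract_effort(field: AreaField) -> float:
    """Integrated tract deformation: trapezoidal quadrature of
    |A(x,t) - A_Omega(x)| over x then t (cm^2 s)."""
    if field.x_grid.size < 2 or field.t_grid.size < 2:
        raise ValueError("need at least 2 points per axis to integrate")
    dev = np.abs(field.area - field.neutral[:, None])
    inner = np.trapezoid(dev, field.x_grid, axis=0)
    return float(np.trapezoid(inner, field.t_grid))


def _build_field(
    ccv: CCVSpec, geometry: TractGeometry, config: EffortConfig
) -> AreaField:
    if config.dt_closure >= config.T:
        raise ValueError("closure interval dt_closure must be < T")
    x1, x2 = ccv.occlusion_places(geometry.L)
    vowel = VowelGesture(config.q1_target, config.q2_target, config.T)
    occl = [
        OcclusionGesture(x_k=x1, t_k=config.t1, sigma=config.sigma, w=config.w),
        OcclusionGesture(
            x_k=x2, t_k=config.t1 + config.dt_closure, sigma=config.sigma, w=config.w
        ),
    ]
    n_t = int(round(config.T / config.time_step)) + 1
    t_grid = np.linspace(0.0, config.T, n_t)
    return area_function(geometry, vowel, occl, t_grid)


def ccv_effort(
    ccv: CCVSpec,
    geometry: TractGeometry | None = None,
    config: EffortConfig = EffortConfig(),
    E0_value: float | None = None,
) -> EffortResult:
    """Total effort of one plosive-plosive CCV.

    Builds the two occlusion gestures riding the linear vowel
    trajectory, integrates the tract deformation, and adds the
    laryngeal term. ``E0_value`` overrides ``config.E0_value``; if both
    are None, E0 is calibrated (see :func:`calibrate_e0`).
    """
    geometry = geometry if geometry is not None else default_geometry()
    e0 = E0_value if E0_value is not None else config.E0_value
    if e0 is None:
        e0 = calibrate_e0(geometry, config)
    e_tract = tract_effort(_build_field(ccv, geometry, config))
    return EffortResult(
        ccv=ccv,
        E_tract=e_tract,
        E0=devoicing_term(ccv, e0),
        dt_closure=config.dt_closure,
    )


def effort_table(
    ccvs: list[CCVSpec] | None = None,
    geometry: TractGeometry | None = None,
    config: EffortConfig = EffortConfig(),
) -> pd.DataFrame:
    """Effort of each CCV under one configuration (order-preserving).

    Columns: ccv, E_tract, E0, E_total, dt_closure.
    """
    ccvs = ccvs if ccvs is not None else analysis_ccvs()
    geometry = geometry if geometry is not None else default_geometry()
    e0 = config.E0_value
    if e0 is None:
        e0 = calibrate_e0(geometry, config)
    rows = []
    for ccv in ccvs:
        try:
            res = ccv_effort(ccv, geometry, config, E0_value=e0)
        except Exception as exc:  # attach the CCV label to the failure
            raise type(exc)(f"{ccv.label}: {exc}") from exc
        rows.append(
            {
                "ccv": ccv.label,
                "E_tract": res.E_tract,
                "E0": res.E0,
                "E_total": res.E_total,
                "dt_closure": res.dt_closure,
            }
        )
    return pd.DataFrame(rows)


def effort_sweep(
    dt_values=None,
    ccvs: list[CCVSpec] | None = None,
    geometry: TractGeometry | None = None,
    config: EffortConfig = EffortConfig(),
) -> pd.DataFrame:
    """Effort tables over a range of inter-closure intervals.

    The sweep explores every plausible degree of overlap between the
    two plosive gestures; default grid 100–300 ms in 25-ms steps.
    """
    if dt_values is None:
        dt_values = np.arange(0.100, 0.301, 0.025)
    frames = []
    for dt in np.asarray(dt_values, dtype=float):
        tab = effort_table(ccvs, geometry, replace(config, dt_closure=float(dt)))
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def calibrate_e0(
    geometry: TractGeometry | None = None, config: EffortConfig = EffortConfig()
) -> float:
    """Calibrate the laryngeal term E0.

    Solves  mean(E_tract,devoiced) + E0 = r * mean(E_tract,voiced)
    with r = 41.3 / 38.2, the ratio of the measured devoiced- to
    voiced-group mean normalized transitions, over the 15 analysis
    CCVs. Floored at 0 (E0 must be non-negative).
    """
    geometry = geometry if geometry is not None else default_geometry()
    cfg = replace(config, E0_value=0.0)
    tab = effort_table(analysis_ccvs(), geometry, cfg)
    devoiced = tab["ccv"].map(lambda s: ccv_from_string(s).devoiced)
    mean_voiced = tab.loc[~devoiced, "E_tract"].mean()
    mean_devoiced = tab.loc[devoiced, "E_tract"].mean()
    return float(max(0.0, DEVOICED_TO_VOICED_TAU_RATIO * mean_voiced - mean_devoiced))
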