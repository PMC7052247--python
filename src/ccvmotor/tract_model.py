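"""Time-varying vocal-tract area function for vowel + plosive gestures.

The tract is described by its cross-sectional area A(x, t) along the
distance x from the glottal entrance (x = 0) to the mouth exit (x = L).
A vowel substrate is built from a neutral diameter profile Omega(x)
deformed along two spatial modes phi1(x), phi2(x) with time-varying
coefficients q1(t), q2(t); each plosive consonant multiplies the field
by an occlusion factor [1 - c_k(x) m(t - t_k)] that drives the area to
zero at its place and time of closure:

    A(x, t) = (pi/4) [Omega(x) + q1(t) phi1(x) + q2(t) phi2(x)]^2
              * prod_k [1 - c_k(x) m(t - t_k)]

The packaged default geometry is a smooth parametric stand-in for
anatomical decompositions derived from MRI data (which are not
redistributable): Omega is a positive sinusoidal bulge and the modes are
the first two cosine harmonics on [0, L]. Users with empirical profiles
can load their own tables with :func:`load_geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TractGeometry",
    "VowelGesture",
    "OcclusionGesture",
    "AreaField",
    "default_geometry",
    "load_geometry",
    "neutral_area",
    "occlusion_activation",
    "occlusion_profile",
    "vowel_trajectory",
    "area_function",
]


class InvalidGeometryError(ValueError):
    """Raised when a tract geometry violates its invariants."""


@dataclass(frozen=True)
class TractGeometry:
    """Spatial description of the vocal tract.

    Parameters
    ----------
    x_grid : array of positions in cm, strictly increasing over [0, L].
    omega : neutral diameter profile Omega(x) in cm, strictly positive.
    phi1, phi2 : dimensionless deformation modes sampled on ``x_grid``.
    """

    x_grid: np.ndarray
    omega: np.ndarray
    phi1: np.ndarray
    phi2: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x_grid, dtype=float)
        object.__setattr__(self, "x_grid", x)
        for name in ("omega", "phi1", "phi2"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != x.shape:
                raise InvalidGeometryError(f"{name} must match x_grid in length")
        if x.ndim != 1 or x.size < 2:
            raise InvalidGeometryError("x_grid must be 1-D with at least 2 points")
        if not np.all(np.diff(x) > 0) or x[0] != 0:
            raise InvalidGeometryError("x_grid must be strictly increasing from 0")
        if np.any(self.omega <= 0):
            raise InvalidGeometryError("Omega(x) must be strictly positive")

    @property
    def L(self) -> float:
        """Tract length in cm."""
        return float(self.x_grid[-1])


@dataclass(frozen=True)
class VowelGesture:
    """Linear evolution of the mode coefficients from neutral to a vowel.

    q1 and q2 start at 0 (neutral tract) and reach their targets at the
    end of the utterance, t = T (seconds).
    """

    q1_target: float
    q2_target: float
    T: float

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("utterance duration T must be positive")


@dataclass(frozen=True)
class OcclusionGesture:
    """One plosive closure: place x_k (cm), time t_k (s), spatial
    half-width sigma (cm) and activation duration w (s)."""

    x_k: float
    t_k: float
    sigma: float = 1.0
    w: float = 0.120

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.w <= 0:
            raise ValueError("sigma and w must be positive")


@dataclass(frozen=True)
class AreaField:
    """A(x, t) in cm^2 on x_grid x t_grid, with its neutral reference."""

    x_grid: np.ndarray
    t_grid: np.ndarray
    area: np.ndarray  # shape (len(x_grid), len(t_grid))
    neutral: np.ndarray  # A_Omega(x), shape like x_grid

    def __post_init__(self) -> None:
        if self.area.shape != (self.x_grid.size, self.t_grid.size):
            raise ValueError("area must have shape (n_x, n_t)")
        if self.neutral.shape != self.x_grid.shape:
            raise ValueError("neutral profile must be sampled on x_grid")

    def to_frame(self) -> pd.DataFrame:
        """Dense export with x positions as index and times as columns."""
        return pd.DataFrame(self.area, index=self.x_grid, columns=self.t_grid)


# ---------------------------------------------------------------------------
# geometry construction

def default_geometry() -> TractGeometry:
    """The packaged parametric geometry (L = 17.5 cm, 101 points)."""
    with resources.files("ccvmotor.data").joinpath("default_tract.csv").open() as fh:
        return _geometry_from_frame(pd.read_csv(fh, comment="#"))


def load_geometry(path: str | Path) -> TractGeometry:
    """Load a geometry table (columns x, omega, phi1, phi2) from CSV."""
    return _geometry_from_frame(pd.read_csv(path, comment="#"))


def _geometry_from_frame(df: pd.DataFrame) -> TractGeometry:
    required = {"x", "omega", "phi1", "phi2"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidGeometryError(f"geometry table missing columns {sorted(missing)}")
    return TractGeometry(
        x_grid=df["x"].to_numpy(),
        omega=df["omega"].to_numpy(),
        phi1=df["phi1"].to_numpy(),
        phi2=df["phi2"].to_numpy(),
    )


def parametric_geometry(L: float = 17.5, n: int = 101) -> TractGeometry:
    """Construct the default parametric geometry analytically.

    Omega(x) = 1.5 + 0.4 sin(pi x / L)    (cm, positive everywhere)
    phi1(x)  = cos(pi x / L)
    phi2(x)  = cos(2 pi x / L)
    """
    x = np.linspace(0.0, L, n)
    return TractGeometry(
        x_grid=x,
        omega=1.5 + 0.4 * np.sin(np.pi * x / L),
        phi1=np.cos(np.pi * x / L),
        phi2=np.cos(2 * np.pi * x / L),
    )


# ---------------------------------------------------------------------------
# operations

def neutral_area(geometry: TractGeometry) -> np.ndarray:
    """Neutral area profile A_Omega(x) = (pi/4) Omega(x)^2 in cm^2."""
    return 0.25 * np.pi * geometry.omega**2


def occlusion_activation(g: OcclusionGesture, t) -> np.ndarray | float:
    """Temporal activation m(t) of an occlusion: raised cosine of total
    width ``g.w`` centred at ``g.t_k``; 1 at the closure time, 0 outside."""
    t = np.asarray(t, dtype=float)
    u = (t - g.t_k) / g.w  # support |u| < 1/2
    m = np.where(np.abs(u) < 0.5, 0.5 * (1.0 + np.cos(2 * np.pi * u)), 0.0)
    return m if m.ndim else float(m)


def occlusion_profile(g: OcclusionGesture, x) -> np.ndarray | float:
    """Spatial profile c_k(x): Gaussian bump of half-width sigma at x_k."""
    x = np.asarray(x, dtype=float)
    c = np.exp(-((x - g.x_k) ** 2) / (2.0 * g.sigma**2))
    return c if c.ndim else float(c)


def vowel_trajectory(v: VowelGesture, t) -> tuple[np.ndarray, np.ndarray]:
    """Mode coefficients (q1, q2) at time(s) t: linear from 0 to target."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > v.T):
        raise ValueError("t outside the utterance interval [0, T]")
    frac = t / v.T
    return v.q1_target * frac, v.q2_target * frac


def area_function(
    geometry: TractGeometry,
    vowel: VowelGesture,
    occlusions: list[OcclusionGesture],
    t_grid,
) -> AreaField:
    """Evaluate A(x, t) on ``geometry.x_grid`` x ``t_grid``.

    The product over occlusion factors is clamped so that c_k * m stays
    <= 1, keeping every factor (and hence the area) non-negative.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    for g in occlusions:
        if not (0.0 <= g.x_k <= geometry.L):
            raise ValueError(f"occlusion place {g.x_k} outside [0, {geometry.L}]")
    q1, q2 = vowel_trajectory(vowel, t_grid)
    diam = (
        geometry.omega[:, None]
        + q1[None, :] * geometry.phi1[:, None]
        + q2[None, :] * geometry.phi2[:, None]
    )
    area = 0.25 * np.pi * diam**2
    for g in occlusions:
        cm = occlusion_profile(g, geometry.x_grid)[:, None] * occlusion_activation(
            g, t_grid
        )[None, :]
        area = area * (1.0 - np.minimum(cm, 1.0))
    return AreaField(
        x_grid=geometry.x_grid,
        t_grid=t_grid,
        area=area,
        neutral=neutral_area(geometry),
    )
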