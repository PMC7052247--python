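"""Fixation bookkeeping: areas of interest and reading-time measures.

Each screen shows six CCVs in a monospaced font (24 px per character,
three characters per CCV, four blank spaces between CCVs). Fixation
events are assigned to CCV areas of interest (AOIs) and the three
standard reading-time measures are computed per AOI:

* FFD  — first fixation duration;
* FPRT — first-pass reading time: sum of the fixations on the CCV from
  first entry until any other CCV is fixated;
* TFT  — total fixation time: sum of all fixations on the CCV.

The first and last CCVs of every screen are discarded to avoid
screen-edge effects on the ocular variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FixationEvent",
    "ScreenLayout",
    "OcularMeasures",
    "NOT_FIXATED",
    "assign_fixations",
    "compute_measures",
    "screen_measures",
    "discard_edges",
]

N_AOIS = 6


@dataclass(frozen=True)
class FixationEvent:
    """One fixation: onset (s), duration (ms), gaze position (px)."""

    onset: float
    duration: float
    x: float
    y: float
    screen_id: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("fixation duration must be positive")


@dataclass(frozen=True)
class ScreenLayout:
    """Geometry of one 6-CCV screen.

    AOI boxes are the 3-character boxes expanded horizontally by
    ``h_margin`` px on each side and vertically by ``v_margin`` px; the
    default margin of one blank-space width (24 px) leaves the centre
    of each 4-space gap unassigned.
    """

    resolution: tuple[int, int] = (1024, 768)
    char_width: int = 24
    chars_per_ccv: int = 3
    gap_spaces: int = 4
    h_margin: float = 24.0
    v_margin: float = 24.0  # about +-1 degree of visual angle

    @property
    def ccv_width(self) -> int:
        return self.char_width * self.chars_per_ccv

    @property
    def gap_width(self) -> int:
        return self.char_width * self.gap_spaces

    @property
    def aois(self) -> list[tuple[float, float, float, float]]:
        """Six (left, right, top, bottom) boxes in px, left to right."""
        total = N_AOIS * self.ccv_width + (N_AOIS - 1) * self.gap_width
        left0 = (self.resolution[0] - total) / 2.0
        y_mid = self.resolution[1] / 2.0
        line_half = self.char_width / 2.0  # text line half-height
        boxes = []
        for i in range(N_AOIS):
            left = left0 + i * (self.ccv_width + self.gap_width)
            boxes.append(
                (
                    left - self.h_margin,
                    left + self.ccv_width + self.h_margin,
                    y_mid - line_half - self.v_margin,
                    y_mid + line_half + self.v_margin,
                )
            )
        return boxes

    def aoi_center(self, i: int) -> tuple[float, float]:
        left, right, top, bottom = self.aois[i]
        return (left + right) / 2.0, (top + bottom) / 2.0


@dataclass(frozen=True)
class OcularMeasures:
    """Reading-time measures for one CCV (ms); invariant FFD<=FPRT<=TFT."""

    ffd: float
    fprt: float
    tft: float
    fixated: bool
    first_fixation_onset: float | None

    def __post_init__(self) -> None:
        if self.fixated and not (0 <= self.ffd <= self.fprt <= self.tft):
            raise ValueError("measures must satisfy 0 <= FFD <= FPRT <= TFT")


NOT_FIXATED = OcularMeasures(0.0, 0.0, 0.0, False, None)


def assign_fixations(
    fixations: list[FixationEvent], layout: ScreenLayout
) -> list[int | None]:
    """AOI index (0-5) for each fixation, or None for fixations landing
    in gaps or margins. Boxes do not overlap, so each fixation maps to
    at most one AOI."""
    boxes = layout.aois
    if not boxes:
        raise ValueError("layout has no AOIs")
    out: list[int | None] = []
    for fx in fixations:
        hit = None
        for i, (left, right, top, bottom) in enumerate(boxes):
            if left <= fx.x <= right and top <= fx.y <= bottom:
                hit = i
                break
        out.append(hit)
    return out


def compute_measures(
    fixations: list[FixationEvent],
    aoi_labels: list[int | None],
    target_aoi: int,
    stimulus_onset: float = 0.0,
) -> OcularMeasures:
    """FFD / FPRT / TFT for one AOI from a screen's fixation sequence.

    The sequence must be in temporal order. A first fixation that
    starts before stimulus onset is clipped to stimulus onset (its
    pre-stimulus portion does not count as reading time).
    """
    if len(fixations) != len(aoi_labels):
        raise ValueError("fixations and labels must align")
    durations = []  # on-target durations in sequence order
    on_target = []
    for fx, label in zip(fixations, aoi_labels):
        dur = fx.duration
        onset = fx.onset
        if label == target_aoi and onset < stimulus_onset:
            clipped = (stimulus_onset - onset) * 1000.0
            dur = max(0.0, dur - clipped)
            onset = stimulus_onset
        durations.append((onset, dur))
        on_target.append(label == target_aoi)
    if not any(on_target):
        return NOT_FIXATED

    first_idx = on_target.index(True)
    ffd = durations[first_idx][1]
    # first pass: consecutive target fixations until another AOI is hit
    fprt = 0.0
    for i in range(first_idx, len(fixations)):
        label = aoi_labels[i]
        if on_target[i]:
            fprt += durations[i][1]
        elif label is not None:
            break  # another AOI fixated: first pass over
    tft = sum(d for (_, d), hit in zip(durations, on_target) if hit)
    return OcularMeasures(
        ffd=ffd,
        fprt=fprt,
        tft=tft,
        fixated=True,
        first_fixation_onset=durations[first_idx][0],
    )


def screen_measures(
    fixations: list[FixationEvent],
    layout: ScreenLayout,
    stimulus_onset: float = 0.0,
) -> list[OcularMeasures]:
    """Measures for all six AOIs of one screen, left to right."""
    labels = assign_fixations(fixations, layout)
    return [
        compute_measures(fixations, labels, i, stimulus_onset)
        for i in range(N_AOIS)
    ]


def discard_edges(measures: list) -> list:
    """Drop the first and last CCVs of a 6-AOI screen (edge effects),
    preserving left-to-right order of the four interior ones."""
    if len(measures) != N_AOIS:
        raise ValueError(f"expected {N_AOIS} AOIs, got {len(measures)}")
    return list(measures[1:-1])
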