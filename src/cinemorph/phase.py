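"""End-systole / end-diastole frame selection from chamber-size extrema.

Each frame's chamber size is estimated as its 2D labelled area (pixel count
times pixel area); the frame of maximal LV area is taken as end-diastole and
the minimal one as end-systole. When the LV is missing or degenerate the left
atrium serves as fallback with the mapping inverted (the LA is largest at
ventricular end-systole, when the ventricle has emptied into the atria).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .masks import CineSeries, MaskError

#: Chamber regions smaller than this (pixels) are treated as absent.
MIN_CHAMBER_PIXELS = 10


class PhaseSelectionError(MaskError):
    """Neither the LV nor the LA supports phase selection."""


@dataclass
class PhaseSelection:
    """Chosen cardiac-phase frames and the area series behind them."""

    systole_index: int
    diastole_index: int
    basis: str  # "LV" or "LA"
    areas_mm2: list[Optional[float]]
    warnings: list[str] = field(default_factory=list)


def chamber_area_series(series: CineSeries, chamber: str) -> list[Optional[float]]:
    """Per-frame 2D chamber area in mm^2; None where the chamber is absent."""
    areas: list[Optional[float]] = []
    any_present = False
    for frame in series:
        if chamber in frame.label_map:
            n = int(np.count_nonzero(frame.region(chamber)))
        else:
            n = 0
        if n == 0:
            areas.append(None)
        else:
            any_present = True
            areas.append(n * frame.pixel_area_mm2)
    if not any_present:
        raise MaskError(f"chamber {chamber!r} absent in every frame")
    return areas


def _usable(series: CineSeries, chamber: str) -> bool:
    """Chamber usable when present with >= MIN_CHAMBER_PIXELS in > half of frames."""
    ok = 0
    for frame in series:
        if chamber in frame.label_map and (
            int(np.count_nonzero(frame.region(chamber))) >= MIN_CHAMBER_PIXELS
        ):
            ok += 1
    return ok > len(series) / 2


def _extrema(areas: list[Optional[float]]) -> tuple[int, int, bool]:
    """(argmin, argmax, tied) over defined entries; earliest frame on ties."""
    vals = [(a, i) for i, a in enumerate(areas) if a is not None]
    amin = min(vals, key=lambda t: (t[0], t[1]))
    amax = max(vals, key=lambda t: (t[0], -t[1]))
    tied = sum(1 for a, _ in vals if a == amin[0]) > 1 or (
        sum(1 for a, _ in vals if a == amax[0]) > 1
    )
    return amin[1], amax[1], tied


def select_phases(series: CineSeries) -> PhaseSelection:
    """Pick the end-systolic and end-diastolic frames of a cine series.

    Basis LV: diastole = argmax LV area, systole = argmin. Fallback basis LA
    (LV absent or under :data:`MIN_CHAMBER_PIXELS` in more than half the
    frames): the mapping inverts — the largest LA marks ventricular
    end-systole. Ties go to the earliest frame and are flagged.
    """
    if len(series) < 2:
        raise MaskError("phase selection needs at least 2 frames")
    warnings: list[str] = []
    if _usable(series, "LV"):
        basis = "LV"
        areas = chamber_area_series(series, "LV")
        argmin, argmax, tied = _extrema(areas)
        systole, diastole = argmin, argmax
    elif _usable(series, "LA"):
        basis = "LA"
        warnings.append("lv_unusable_la_fallback")
        areas = chamber_area_series(series, "LA")
        argmin, argmax, tied = _extrema(areas)
        systole, diastole = argmax, argmin  # inverted mapping
    else:
        raise PhaseSelectionError("neither LV nor LA usable for phase selection")
    if tied:
        warnings.append("extremum_tie")
    return PhaseSelection(
        systole_index=systole,
        diastole_index=diastole,
        basis=basis,
        areas_mm2=areas,
        warnings=warnings,
    )
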