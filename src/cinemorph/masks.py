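"""Core raster containers: a single labelled cine frame and an ordered series.

A :class:`LabelMask` is one 2D integer raster in which each cardiac chamber
(LV, LA, RV, RA) is painted with a distinct positive code and background is 0.
Physical pixel spacing is carried as (row_mm, col_mm) and is never averaged:
anisotropic acquisitions stay anisotropic all the way to the millimetre
measurements. Coordinates throughout the package are (row, col), 0-based,
pixel-centre convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

#: Default chamber encoding. The codes are arbitrary but must be consistent
#: across a series; override via any function's ``label_map`` argument.
DEFAULT_LABEL_MAP: dict[str, int] = {"LV": 1, "LA": 2, "RV": 3, "RA": 4}

#: Canonical chamber names.
CHAMBERS: tuple[str, ...] = ("LV", "LA", "RV", "RA")

#: Chamber pairs measured by the pipeline, keyed by the semantic name of the
#: resulting linear measurement.
MEASUREMENT_PAIRS: dict[str, tuple[str, str]] = {
    "mitral_annulus": ("LA", "LV"),
    "tricuspid_annulus": ("RA", "RV"),
    "interventricular_septum": ("LV", "RV"),
    "atrial_septum": ("LA", "RA"),
}

#: Valve name for an unordered atrium-ventricle pair; septa have no valve.
VALVE_BY_PAIR: dict[frozenset, str] = {
    frozenset(("LA", "LV")): "mitral_annulus",
    frozenset(("RA", "RV")): "tricuspid_annulus",
}


class MaskError(ValueError):
    """Raised when a raster violates the label-mask contract."""


@dataclass
class LabelMask:
    """One cine frame: integer chamber raster plus physical spacing.

    Parameters
    ----------
    grid:
        2D integer array, background 0, chambers coded per ``label_map``.
    spacing:
        (row_mm_per_px, col_mm_per_px); both strictly positive.
    label_map:
        Chamber name -> integer code. Every nonzero grid value must appear
        among the codes.
    frame_index:
        Ordinal position of this frame in the cine cycle.
    """

    grid: np.ndarray
    spacing: tuple[float, float]
    label_map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise MaskError(f"grid must be 2D, got shape {self.grid.shape}")
        if self.grid.shape[0] < 2 or self.grid.shape[1] < 2:
            raise MaskError(f"grid must be at least 2x2, got {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            if np.issubdtype(self.grid.dtype, np.floating) and np.all(
                self.grid == np.round(self.grid)
            ):
                self.grid = self.grid.astype(np.int32)
            else:
                raise MaskError(f"grid must be integer-valued, dtype {self.grid.dtype}")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise MaskError(f"spacing must be strictly positive, got {self.spacing}")
        self.label_map = dict(self.label_map)
        codes = set(int(c) for c in self.label_map.values())
        present = set(int(v) for v in np.unique(self.grid)) - {0}
        unknown = present - codes
        if unknown:
            raise MaskError(
                f"grid contains codes {sorted(unknown)} absent from label_map "
                f"{self.label_map}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def pixel_area_mm2(self) -> float:
        """Physical area of one pixel in mm^2."""
        return self.spacing[0] * self.spacing[1]

    def code(self, chamber: str) -> int:
        try:
            return int(self.label_map[chamber])
        except KeyError:
            raise MaskError(f"chamber {chamber!r} not in label_map {self.label_map}")

    def region(self, chamber: str) -> np.ndarray:
        """Boolean raster of one chamber's pixels."""
        return self.grid == self.code(chamber)

    def has_chamber(self, chamber: str) -> bool:
        return chamber in self.label_map and bool(np.any(self.region(chamber)))

    def chamber_area_mm2(self, chamber: str) -> float:
        """Labelled pixel count x pixel area."""
        return float(np.count_nonzero(self.region(chamber))) * self.pixel_area_mm2

    def replace_grid(self, grid: np.ndarray) -> "LabelMask":
        return LabelMask(grid, self.spacing, self.label_map, self.frame_index)


@dataclass
class CineSeries:
    """Ordered frames of one subject's 4-chamber acquisition.

    All frames must share grid shape, spacing and label map; frame indices run
    0..n-1 in order.
    """

    frames: Sequence[LabelMask]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.frames = list(self.frames)
        if not self.frames:
            raise MaskError("CineSeries requires at least one frame")
        first = self.frames[0]
        for i, f in enumerate(self.frames):
            if f.shape != first.shape:
                raise MaskError("all frames must share grid shape")
            if f.spacing != first.spacing:
                raise MaskError("all frames must share spacing")
            if dict(f.label_map) != dict(first.label_map):
                raise MaskError("all frames must share label_map")
            if f.frame_index != i:
                raise MaskError(
                    f"frame_index must increase from 0; frame {i} has "
                    f"index {f.frame_index}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[LabelMask]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> LabelMask:
        return self.frames[i]

    @property
    def spacing(self) -> tuple[float, float]:
        return self.frames[0].spacing

    @property
    def label_map(self) -> Mapping[str, int]:
        return self.frames[0].label_map
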