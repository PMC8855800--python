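"""Reading and writing label masks, cine stacks, spacing metadata and tables.

Masks travel as integer PNG/TIFF images or NIfTI volumes; physical pixel
spacing comes either from an explicit (row_mm, col_mm) pair, from the NIfTI
header, or from the PixelSpacing attribute (tag 0028,0030) of an accompanying
DICOM file. Measurement tables are plain CSV with a header row.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .masks import DEFAULT_LABEL_MAP, CineSeries, LabelMask, MaskError

_NIFTI_SUFFIXES = (".nii", ".nii.gz")

MEASUREMENT_COLUMNS = [
    "subject_id",
    "frame_index",
    "phase",
    "name",
    "length_mm",
    "length_px",
    "endpoint_1_row",
    "endpoint_1_col",
    "endpoint_2_row",
    "endpoint_2_col",
    "flags",
]


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def read_mask(
    path: str | os.PathLike,
    label_map: Mapping[str, int] | None = None,
    spacing: tuple[float, float] | None = None,
    frame_index: int = 0,
) -> LabelMask:
    """Read one 2D label raster from PNG/TIFF/NIfTI.

    ``spacing`` must be supplied for raster images; for NIfTI it defaults to
    the header pixdim of the first two axes. Unknown nonzero codes raise
    :class:`MaskError` rather than being silently relabelled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    label_map = dict(label_map) if label_map is not None else dict(DEFAULT_LABEL_MAP)
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise MaskError(f"{path}: expected a single 2D frame, got shape {data.shape}")
        if spacing is None:
            zooms = img.header.get_zooms()[:2]
            spacing = (float(zooms[0]), float(zooms[1]))
        grid = data
    else:
        grid = iio.imread(path)
        if grid.ndim == 3 and grid.shape[2] in (3, 4):
            # palette-expanded PNG: accept only if all channels agree
            if not (grid[..., 0] == grid[..., 1]).all() or not (
                grid[..., 0] == grid[..., 2]
            ).all():
                raise MaskError(f"{path}: colour image is not a label raster")
            grid = grid[..., 0]
        if grid.ndim != 2:
            raise MaskError(f"{path}: expected 2D raster, got shape {grid.shape}")
        if spacing is None:
            raise MaskError(
                f"{path}: spacing must be given explicitly or recovered via "
                "spacing_from_dicom for raster images"
            )
    if not np.issubdtype(np.asarray(grid).dtype, np.integer):
        raise MaskError(f"{path}: non-integer pixel data ({np.asarray(grid).dtype})")
    return LabelMask(np.asarray(grid), spacing, label_map, frame_index)


def write_mask(mask: LabelMask, path: str | os.PathLike) -> None:
    """Write a mask as integer PNG/TIFF or NIfTI (spacing goes to the header)."""
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        affine = np.diag([mask.spacing[0], mask.spacing[1], 1.0, 1.0])
        img = nib.Nifti1Image(mask.grid.astype(np.int16), affine)
        img.header.set_zooms((mask.spacing[0], mask.spacing[1]))
        nib.save(img, str(path))
        return
    maxcode = int(mask.grid.max(initial=0))
    dtype = np.uint8 if maxcode < 256 else np.uint16
    iio.imwrite(path, mask.grid.astype(dtype))


def read_series(
    paths: Sequence[str | os.PathLike],
    label_map: Mapping[str, int] | None = None,
    spacing: tuple[float, float] | None = None,
    subject_id: str = "",
) -> CineSeries:
    """Read an ordered list of frame files into a :class:`CineSeries`.

    Frames are taken in the order given; sort the paths upstream (the CLI
    sorts by filename).
    """
    frames = [
        read_mask(p, label_map=label_map, spacing=spacing, frame_index=i)
        for i, p in enumerate(paths)
    ]
    return CineSeries(frames, subject_id=subject_id)


def spacing_from_dicom(dicom_path: str | os.PathLike) -> tuple[float, float]:
    """Physical pixel spacing (row_mm, col_mm) from DICOM tag (0028,0030).

    Values are returned exactly as stored, in DICOM's (row, column) order,
    with no rescaling or averaging.
    """
    import pydicom

    ds = pydicom.dcmread(str(dicom_path), stop_before_pixels=True, force=True)
    if "PixelSpacing" not in ds:
        raise KeyError(f"{dicom_path}: DICOM file lacks PixelSpacing (0028,0030)")
    values = ds.PixelSpacing
    if len(values) != 2:
        raise ValueError(f"{dicom_path}: PixelSpacing has {len(values)} entries")
    try:
        row_mm, col_mm = float(values[0]), float(values[1])
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{dicom_path}: non-numeric PixelSpacing {values}") from exc
    if row_mm <= 0 or col_mm <= 0:
        raise ValueError(f"{dicom_path}: non-positive PixelSpacing {values}")
    return (row_mm, col_mm)


def measurements_frame(records: Iterable[Mapping]) -> pd.DataFrame:
    """Normalise measurement record dicts into the canonical column order."""
    df = pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("no measurement records to write")
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    extra = [c for c in df.columns if c not in MEASUREMENT_COLUMNS]
    return df[MEASUREMENT_COLUMNS + extra]


def write_measurements(records: Iterable[Mapping], path: str | os.PathLike) -> pd.DataFrame:
    """Write per-(subject, frame, measurement) rows to CSV.

    One row per (subject, frame/phase, measurement name); millimetre values
    are written with 9 decimals so a read-back reproduces them to 1e-9.
    """
    df = measurements_frame(records)
    df.to_csv(path, index=False, float_format="%.9f")
    return df


def read_measurements(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
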