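"""Synthetic 4-chamber cine phantoms with exact ground truth.

The phantom rasterizes four axis-aligned rectangular chambers in 4-chamber
topology: atria above their ventricles, left and right heart separated by a
one-pixel septal gap column, the LA-LV and RA-RV pairs abutting along
straight horizontal valve planes. Chamber widths and heights follow sinusoids
over the cycle so that annular diameters and chamber areas are analytically
known per frame. Anatomical realism is deliberately traded for exactly
controllable geometry: the phantom exists to validate the measurement
pipeline, not to imitate myocardium.

By default the annular cycle is shifted half a period against the LV-area
cycle, so the annulus is widest at end-systole (when LV area is minimal) —
the physiological ordering in which systolic annular measurements exceed
diastolic ones.

Rasterization convention: for a true diameter D and column spacing s, the
shared chamber edge is drawn n = round(D/s) - 1 pixels wide. The radius-1
interface band then extends one pixel beyond each end of the shared edge, so
its extremal chord spans round(D/s) pixel steps and measures D up to the
half-pixel rounding of n — ground truth and measurement convention agree to
sub-pixel accuracy on noise-free frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import ndimage

from .masks import DEFAULT_LABEL_MAP, CineSeries, LabelMask
from .qc import SubjectRecord, bsa

_MARGIN = 4  # background border, px; must exceed adjacency radius + noise band


class GeometryError(ValueError):
    """Requested phantom geometry does not fit the grid."""


@dataclass
class PhantomParams:
    """Generating parameters of one phantom cine series.

    Diameters and areas are physical (mm, mm^2); the grid realises them at
    the given spacing. ``annulus_phase_frac`` is the fraction of a cycle by
    which the annular sinusoid is shifted against the LV-area sinusoid
    (default 0.5: annulus maximal when LV area minimal).
    """

    shape: tuple[int, int] = (224, 224)
    spacing: tuple[float, float] = (0.5, 0.5)
    n_frames: int = 20
    mitral_mean_mm: float = 30.0
    mitral_amp_mm: float = 3.0
    tricuspid_mean_mm: float = 33.0
    tricuspid_amp_mm: float = 3.0
    lv_area_mean_mm2: float = 1200.0
    lv_area_amp_mm2: float = 350.0
    la_area_mean_mm2: float = 800.0
    la_area_amp_mm2: float = 200.0
    rv_area_mean_mm2: float = 1100.0
    rv_area_amp_mm2: float = 300.0
    ra_area_mean_mm2: float = 750.0
    ra_area_amp_mm2: float = 180.0
    annulus_phase_frac: float = 0.5
    boundary_noise_sd_px: float = 0.0
    rotation_quarter_turns: int = 0
    seed: int = 0
    label_map: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    subject_id: str = "phantom"

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for name in ("mitral", "tricuspid"):
            amp = getattr(self, f"{name}_amp_mm")
            mean = getattr(self, f"{name}_mean_mm")
            if amp < 0:
                raise ValueError(f"{name} amplitude must be >= 0")
            if mean - amp <= 0:
                raise ValueError(f"{name} diameter cycle reaches <= 0")
        if self.boundary_noise_sd_px < 0:
            raise ValueError("boundary_noise_sd_px must be >= 0")
        if self.rotation_quarter_turns % 4 and self.spacing[0] != self.spacing[1]:
            # quarter-turn rotation swaps axes; spacing is swapped alongside,
            # so anisotropy is supported, but keep the check explicit
            pass


@dataclass
class PhantomTruth:
    """Exact per-frame geometry of a generated phantom.

    Annular diameters are the generating sinusoids; septal arcs and chamber
    areas are the exact values of the rasterized geometry (the discrete
    generating functions), so truth areas equal labelled-pixel counts times
    pixel area on noise-free frames.
    """

    mitral_diameter_mm: np.ndarray
    tricuspid_diameter_mm: np.ndarray
    iv_septum_mm: np.ndarray
    atrial_septum_mm: np.ndarray
    areas_mm2: dict[str, np.ndarray]  # chamber -> per-frame area
    systole_index: int
    diastole_index: int
    params: PhantomParams
    seed: int

    def frame_table(self) -> pd.DataFrame:
        n = len(self.mitral_diameter_mm)
        return pd.DataFrame(
            {
                "frame_index": np.arange(n),
                "mitral_diameter_mm": self.mitral_diameter_mm,
                "tricuspid_diameter_mm": self.tricuspid_diameter_mm,
                "iv_septum_mm": self.iv_septum_mm,
                "atrial_septum_mm": self.atrial_septum_mm,
                **{f"area_{c}_mm2": v for c, v in self.areas_mm2.items()},
            }
        )


def _width_px(diameter_mm: float, col_mm: float) -> int:
    """Shared-edge width realising a given annular diameter (see module doc)."""
    n = int(round(diameter_mm / col_mm)) - 1
    if n < 2:
        raise GeometryError(
            f"diameter {diameter_mm} mm too small for spacing {col_mm} mm/px"
        )
    return n


def _height_px(area_mm2: float, width_px: int, pixel_area: float) -> int:
    return max(3, int(round(area_mm2 / pixel_area / width_px)))


def generate_phantom_series(
    params: PhantomParams,
) -> tuple[CineSeries, PhantomTruth]:
    """Rasterize one phantom cine series and its exact ground truth.

    Identical params (including seed) give bit-identical output. Raises
    :class:`GeometryError` when the requested diameters/areas cannot fit the
    grid with the mandatory background margin.
    """
    rows, cols = params.shape
    s_r, s_c = params.spacing
    px_area = s_r * s_c
    n = params.n_frames
    theta = 2 * np.pi * np.arange(n) / n
    # LV-area cycle: maximal at frame 0 (end-diastole), minimal mid-cycle
    lv_area = params.lv_area_mean_mm2 + params.lv_area_amp_mm2 * np.cos(theta)
    rv_area = params.rv_area_mean_mm2 + params.rv_area_amp_mm2 * np.cos(theta)
    # atria fill in counter-phase with the ventricles
    la_area = params.la_area_mean_mm2 - params.la_area_amp_mm2 * np.cos(theta)
    ra_area = params.ra_area_mean_mm2 - params.ra_area_amp_mm2 * np.cos(theta)
    ann_phase = theta + 2 * np.pi * params.annulus_phase_frac
    mitral = params.mitral_mean_mm + params.mitral_amp_mm * np.cos(ann_phase)
    tricuspid = params.tricuspid_mean_mm + params.tricuspid_amp_mm * np.cos(ann_phase)

    dims = []
    for f in range(n):
        n_m = _width_px(mitral[f], s_c)
        n_t = _width_px(tricuspid[f], s_c)
        dims.append(
            {
                "n_m": n_m,
                "n_t": n_t,
                "h_lv": _height_px(lv_area[f], n_m, px_area),
                "h_la": _height_px(la_area[f], n_m, px_area),
                "h_rv": _height_px(rv_area[f], n_t, px_area),
                "h_ra": _height_px(ra_area[f], n_t, px_area),
            }
        )
    h_atria_max = max(max(d["h_la"], d["h_ra"]) for d in dims)
    h_vent_max = max(max(d["h_lv"], d["h_rv"]) for d in dims)
    n_t_max = max(d["n_t"] for d in dims)
    n_m_max = max(d["n_m"] for d in dims)
    r_valve = _MARGIN + h_atria_max  # last atrial row; ventricles start below
    c_gap = _MARGIN + n_t_max  # background septal gap column
    if r_valve + h_vent_max + _MARGIN > rows:
        raise GeometryError(
            f"grid of {rows} rows cannot hold atria {h_atria_max} + "
            f"ventricles {h_vent_max} px plus margins"
        )
    if c_gap + 1 + n_m_max + _MARGIN > cols:
        raise GeometryError(
            f"grid of {cols} cols cannot hold chamber widths "
            f"{n_t_max}+{n_m_max} px plus margins"
        )

    lm = params.label_map
    rng = np.random.default_rng(params.seed)
    frames = []
    for f, d in enumerate(dims):
        grid = np.zeros((rows, cols), dtype=np.uint8)
        # left heart (image right of the gap): LA above LV
        grid[r_valve - d["h_la"] + 1 : r_valve + 1, c_gap + 1 : c_gap + 1 + d["n_m"]] = lm["LA"]
        grid[r_valve + 1 : r_valve + 1 + d["h_lv"], c_gap + 1 : c_gap + 1 + d["n_m"]] = lm["LV"]
        # right heart (image left of the gap): RA above RV, right-aligned
        grid[r_valve - d["h_ra"] + 1 : r_valve + 1, c_gap - d["n_t"] : c_gap] = lm["RA"]
        grid[r_valve + 1 : r_valve + 1 + d["h_rv"], c_gap - d["n_t"] : c_gap] = lm["RV"]
        mask = LabelMask(grid, (s_r, s_c), lm, frame_index=f)
        if params.boundary_noise_sd_px > 0:
            mask = perturb_mask(
                mask,
                params.boundary_noise_sd_px,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        frames.append(mask)

    spacing_out = (s_r, s_c)
    k = params.rotation_quarter_turns % 4
    if k:
        if k % 2 == 1:
            spacing_out = (s_c, s_r)
        frames = [
            LabelMask(np.rot90(m.grid, k).copy(), spacing_out, lm, frame_index=i)
            for i, m in enumerate(frames)
        ]

    truth = PhantomTruth(
        mitral_diameter_mm=mitral,
        tricuspid_diameter_mm=tricuspid,
        iv_septum_mm=np.array(
            [(min(d["h_lv"], d["h_rv"]) + 1) * s_r for d in dims]
        ),
        atrial_septum_mm=np.array(
            [(min(d["h_la"], d["h_ra"]) + 1) * s_r for d in dims]
        ),
        areas_mm2={
            "LV": np.array([d["h_lv"] * d["n_m"] * px_area for d in dims]),
            "LA": np.array([d["h_la"] * d["n_m"] * px_area for d in dims]),
            "RV": np.array([d["h_rv"] * d["n_t"] * px_area for d in dims]),
            "RA": np.array([d["h_ra"] * d["n_t"] * px_area for d in dims]),
        },
        systole_index=int(np.argmin(lv_area)),
        diastole_index=int(np.argmax(lv_area)),
        params=params,
        seed=params.seed,
    )
    return CineSeries(frames, subject_id=params.subject_id), truth


def perturb_mask(
    mask: LabelMask, boundary_noise_sd_px: float, seed: int = 0
) -> LabelMask:
    """Erode/dilate label noise confined to a band around chamber boundaries.

    The band is every pixel whose Chebyshev distance to a differently
    labelled pixel is at most ceil(2 * sd). Each band pixel independently,
    with probability min(0.45, sd/2), takes the label of a uniformly chosen
    8-neighbour. Pixels outside the band — chamber interiors and far
    background — are untouched. sd = 0 is the identity; fixed seeds give
    identical output.
    """
    if boundary_noise_sd_px < 0:
        raise ValueError("boundary_noise_sd_px must be >= 0")
    if boundary_noise_sd_px == 0:
        return mask.replace_grid(mask.grid.copy())
    b = math.ceil(2 * boundary_noise_sd_px)
    size = 2 * b + 1
    grid = mask.grid
    band = ndimage.maximum_filter(grid, size=size) != ndimage.minimum_filter(
        grid, size=size
    )
    p = min(0.45, boundary_noise_sd_px / 2.0)
    rng = np.random.default_rng(seed)
    coin = rng.random(grid.shape) < p
    flip = band & coin
    # pull the label of a random 8-neighbour through an edge-padded view
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    choice = rng.integers(0, len(offsets), size=grid.shape)
    padded = np.pad(grid, 1, mode="edge")
    out = grid.copy()
    rr, cc = np.nonzero(flip)
    offs = np.asarray(offsets)[choice[rr, cc]]
    out[rr, cc] = padded[rr + 1 + offs[:, 0], cc + 1 + offs[:, 1]]
    return mask.replace_grid(out)


def generate_cohort(
    n_subjects: int,
    mitral_systole_mean: float = 33.0,
    mitral_systole_sd: float = 3.5,
    mitral_diastole_mean: float = 28.0,
    mitral_diastole_sd: float = 3.5,
    outlier_fraction: float = 0.0,
    manual_bias: float = 0.0,
    manual_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Draw a synthetic measurement cohort for QC and validation testing.

    Diameters are normal per phase; each subject independently becomes a
    gross outlier (its systolic value displaced by at least 6 SD) with
    probability ``outlier_fraction``. Covariates: age uniform over the
    imaging-cohort range 40-70 y, sex Bernoulli(1/2), height and weight
    normal around population means, BSA by Mosteller. Paired "manual" values
    are auto/(1 + manual_bias) with multiplicative noise of SD
    ``manual_noise_sd``, so the automated-vs-manual percentage difference has
    expectation ~ manual_bias.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not 0 <= outlier_fraction < 1:
        raise ValueError("outlier_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    pair_rows = []
    for i in range(n_subjects):
        sid = f"S{i:05d}"
        sysd = rng.normal(mitral_systole_mean, mitral_systole_sd)
        diad = rng.normal(mitral_diastole_mean, mitral_diastole_sd)
        if rng.random() < outlier_fraction:
            sign = 1 if rng.random() < 0.5 else -1
            sysd = mitral_systole_mean + sign * (6.0 + abs(rng.normal())) * mitral_systole_sd
        age = float(rng.uniform(40, 70))
        sex = int(rng.random() < 0.5)
        height = float(np.clip(rng.normal(169, 9), 140, 210))
        weight = float(np.clip(rng.normal(76, 13), 40, 160))
        rec = SubjectRecord(
            subject_id=sid,
            mitral_systole_mm=float(sysd),
            mitral_diastole_mm=float(diad),
            age=age,
            sex=sex,
            height_cm=height,
            weight_kg=weight,
            bsa=bsa(height, weight),
        )
        records.append(rec)
        for phase, value in (("systole", sysd), ("diastole", diad)):
            noise = rng.normal(0.0, manual_noise_sd) if manual_noise_sd > 0 else 0.0
            manual = value / (1.0 + manual_bias) * (1.0 + noise)
            pair_rows.append(
                {
                    "subject_id": sid,
                    "phase": phase,
                    "auto_mm": float(value),
                    "manual_mm": float(manual),
                    "age": age,
                    "sex": sex,
                    "bsa": rec.bsa,
                    "plane_deviation": float(rng.normal(0.0, 1.0)),
                }
            )
    return records, pd.DataFrame(pair_rows)
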