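"""Reproducible benchmark experiments over the phantom suite.

These functions re-run the full pipeline on freshly generated phantoms and
report aggregate accuracy; nothing is cached or looked up. They back both the
validation tests and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .phantom import PhantomParams, generate_phantom_series
from .pipeline import measure_series


def mitral_accuracy_suite(
    n_phantoms: int = 100,
    seed: int = 0,
    spacing_mm: float = 0.5,
    boundary_noise_sd_px: float = 0.5,
    n_frames: int = 20,
    diameter_range_mm: tuple[float, float] = (25.0, 40.0),
    amplitude_mm: float = 3.0,
) -> dict:
    """Measured-vs-true mitral diameter error over a seeded phantom suite.

    Each phantom draws a mean mitral diameter so that the cyclic diameter
    stays inside ``diameter_range_mm``; the pipeline selects end-diastole by
    LV area and the phase-selected mitral diameter is compared with the
    ground truth of the selected frame.

    Returns mean relative error (percent), mean absolute error (mm), and the
    per-phantom error arrays.
    """
    rng = np.random.default_rng(seed)
    lo, hi = diameter_range_mm
    rel_err, abs_err = [], []
    for _ in range(n_phantoms):
        mean = rng.uniform(lo + amplitude_mm, hi - amplitude_mm)
        params = PhantomParams(
            spacing=(spacing_mm, spacing_mm),
            n_frames=n_frames,
            mitral_mean_mm=float(mean),
            mitral_amp_mm=amplitude_mm,
            boundary_noise_sd_px=boundary_noise_sd_px,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        series, truth = generate_phantom_series(params)
        result = measure_series(series)
        idx = result.phases.diastole_index
        measured = result.diastole.measurements["mitral_annulus"].length_mm
        true = float(truth.mitral_diameter_mm[idx])
        abs_err.append(abs(measured - true))
        rel_err.append(abs(measured - true) / true)
    return {
        "n_phantoms": n_phantoms,
        "mean_relative_error_pct": float(100.0 * np.mean(rel_err)),
        "mean_absolute_error_mm": float(np.mean(abs_err)),
        "max_absolute_error_mm": float(np.max(abs_err)),
        "relative_errors": np.asarray(rel_err),
        "absolute_errors_mm": np.asarray(abs_err),
    }
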