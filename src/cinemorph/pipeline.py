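"""Series-level orchestration: measure a cine series and tag cardiac phases."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .masks import CineSeries
from .morphometry import FrameMeasurements, measure_frame
from .phase import PhaseSelection, select_phases


@dataclass
class SeriesMeasurements:
    """Phase-selected measurements for one subject's cine acquisition."""

    subject_id: str
    phases: PhaseSelection
    systole: FrameMeasurements
    diastole: FrameMeasurements
    flags: list[str] = field(default_factory=list)


def measure_series(
    series: CineSeries,
    adjacency_radius_px: int = 1,
    orientation_qc: bool = True,
) -> SeriesMeasurements:
    """Select end-systole/end-diastole and measure those two frames.

    Phase selection scans every frame's chamber area (cheap pixel counts);
    the full geometric measurement runs only on the two selected frames.
    """
    phases = select_phases(series)
    out = {}
    for phase_name, idx in (
        ("systole", phases.systole_index),
        ("diastole", phases.diastole_index),
    ):
        fm = measure_frame(
            series[idx],
            adjacency_radius_px=adjacency_radius_px,
            orientation_qc=orientation_qc,
        )
        fm.measurements = {
            k: replace(m, phase=phase_name) for k, m in fm.measurements.items()
        }
        out[phase_name] = fm
    return SeriesMeasurements(
        subject_id=series.subject_id,
        phases=phases,
        systole=out["systole"],
        diastole=out["diastole"],
        flags=list(phases.warnings),
    )


def series_records(result: SeriesMeasurements) -> list[dict]:
    """Flatten a series result into CSV-ready measurement rows."""
    rows = []
    for fm in (result.systole, result.diastole):
        for m in fm.measurements.values():
            rows.append(
                {
                    "subject_id": result.subject_id,
                    "frame_index": m.frame_index,
                    "phase": m.phase,
                    "name": m.name,
                    "length_mm": m.length_mm,
                    "length_px": m.length_px,
                    "endpoint_1_row": m.endpoint_1[0],
                    "endpoint_1_col": m.endpoint_1[1],
                    "endpoint_2_row": m.endpoint_2[0],
                    "endpoint_2_col": m.endpoint_2[1],
                    "flags": ";".join(m.flags + fm.flags),
                }
            )
    return rows
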