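"""The measuring function: medial axes, chamber orientation, annulus and septum.

Given a cleaned 4-chamber label mask the pipeline proceeds in two steps. The
long axis of each chamber is traced along its medial axis (skeleton), and the
skeleton endpoint nearer the paired chamber across the atrioventricular valve
is designated the base (the other the apex); this orients the chamber and
serves as a QC check. The annulus itself is located from the band of pixels
where an atrium and its ventricle meet: the pair of band pixels at maximal
physical (mm-scaled) distance defines the annular diameter. Septal lengths
are measured as arc length along the LV-RV and LA-RA interface bands.

All millimetre distances are computed from anisotropically scaled coordinate
deltas, never from a pixel count times an average spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import cdist
from skimage.morphology import skeletonize

from .masks import MEASUREMENT_PAIRS, VALVE_BY_PAIR, LabelMask, MaskError

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element

MEASUREMENT_NAMES = tuple(MEASUREMENT_PAIRS)


class ChamberMissingError(MaskError):
    """A required chamber has no pixels in the mask."""


class InterfaceNotFoundError(MaskError):
    """Two chambers are not adjacent within the requested radius."""


@dataclass
class MedialPath:
    """Longest geodesic path along one chamber's skeleton.

    ``points`` are (row, col) pixel coordinates, consecutive points
    8-adjacent. ``base_point``/``apex_point`` are set by
    :func:`classify_base_apex`.
    """

    points: list[tuple[int, int]]
    chamber: str
    base_point: Optional[tuple[int, int]] = None
    apex_point: Optional[tuple[int, int]] = None
    flags: list[str] = field(default_factory=list)

    @property
    def endpoints(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return self.points[0], self.points[-1]


@dataclass
class InterfaceSegment:
    """Band of pixels where two chamber regions meet.

    ``pixels`` is an (N, 2) array of (row, col) positions lying within the
    adjacency radius (Chebyshev) of both chambers; ``endpoint_1``/
    ``endpoint_2`` are the band pixels at maximal mm-scaled Euclidean
    distance.
    """

    pixels: np.ndarray
    chamber_a: str
    chamber_b: str
    endpoint_1: tuple[int, int]
    endpoint_2: tuple[int, int]
    valve: str
    spacing: tuple[float, float]
    flags: list[str] = field(default_factory=list)

    @property
    def endpoint_distance_mm(self) -> float:
        (r1, c1), (r2, c2) = self.endpoint_1, self.endpoint_2
        return float(
            np.hypot((r1 - r2) * self.spacing[0], (c1 - c2) * self.spacing[1])
        )


@dataclass
class LinearMeasurement:
    """A named anatomical distance on one frame.

    ``length_px`` is the isotropic-equivalent pixel length and is only set
    when spacing is isotropic; ``length_mm`` always comes from mm-scaled
    coordinate deltas.
    """

    name: str
    endpoint_1: tuple[int, int]
    endpoint_2: tuple[int, int]
    length_mm: float
    length_px: Optional[float]
    frame_index: int
    phase: str = "unassigned"
    flags: list[str] = field(default_factory=list)


@dataclass
class FrameMeasurements:
    """All linear measurements and chamber areas for one frame."""

    measurements: dict[str, LinearMeasurement]
    areas_mm2: dict[str, float]
    frame_index: int
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# mask cleanup
# ---------------------------------------------------------------------------

def clean_mask(mask: LabelMask) -> LabelMask:
    """Keep each chamber's largest 8-connected component and fill its holes.

    Small satellite components of a label are erased to background; fully
    enclosed background holes inside the surviving component are assigned to
    that label. Other labels' pixels are never reassigned. Idempotent.
    """
    grid = mask.grid.copy()
    # pass 1: drop satellite components
    for chamber, code in mask.label_map.items():
        binary = grid == code
        if not binary.any():
            continue
        labels, n = ndimage.label(binary, structure=_EIGHT)
        if n > 1:
            sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
            grid[(labels > 0) & (labels != keep)] = 0
    # pass 2: fill background holes enclosed by the surviving component
    for chamber, code in mask.label_map.items():
        binary = grid == code
        if not binary.any():
            continue
        filled = ndimage.binary_fill_holes(binary)
        grid[filled & (grid == 0)] = code
    return mask.replace_grid(grid)


# ---------------------------------------------------------------------------
# medial axis
# ---------------------------------------------------------------------------

def _skeleton_graph(coords: np.ndarray) -> csr_matrix:
    """Sparse 8-adjacency graph over skeleton pixels, Euclidean px weights."""
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}
    rows, cols, weights = [], [], []
    for i, (r, c) in enumerate(coords):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = index.get((int(r) + dr, int(c) + dc))
                if j is not None and j > i:
                    rows.append(i)
                    cols.append(j)
                    weights.append(float(np.hypot(dr, dc)))
    n = len(coords)
    return csr_matrix((weights, (rows, cols)), shape=(n, n))


def _farthest(dist: np.ndarray, coords: np.ndarray) -> int:
    """Index of the farthest reachable node; ties broken lexicographically."""
    finite = np.isfinite(dist)
    best = dist[finite].max()
    cand = np.flatnonzero(finite & (dist >= best - 1e-12))
    order = np.lexsort((coords[cand, 1], coords[cand, 0]))
    return int(cand[order[0]])


def medial_axis_path(mask: LabelMask, chamber: str) -> MedialPath:
    """Longest geodesic path between endpoints of a chamber's skeleton.

    The binary chamber region is thinned to its medial axis and the longest
    shortest path on the skeleton graph is found by a double farthest-point
    sweep (exact on trees, which thinning yields in practice). If the
    skeleton degenerates to a single pixel the path is that pixel duplicated
    and flagged.
    """
    region = mask.region(chamber)
    if not region.any():
        raise ChamberMissingError(f"chamber {chamber!r} empty in frame {mask.frame_index}")
    skel = skeletonize(region)
    coords = np.argwhere(skel)
    if len(coords) == 0:  # pragma: no cover - skeletonize keeps >=1 px
        coords = np.argwhere(region)[:1]
    # sort for deterministic start and tie-breaks
    coords = coords[np.lexsort((coords[:, 1], coords[:, 0]))]
    if len(coords) == 1:
        p = (int(coords[0, 0]), int(coords[0, 1]))
        return MedialPath([p, p], chamber, flags=["degenerate_skeleton"])
    graph = _skeleton_graph(coords)
    d0 = dijkstra(graph, directed=False, indices=0)
    u = _farthest(d0, coords)
    d1, pred = dijkstra(graph, directed=False, indices=u, return_predecessors=True)
    v = _farthest(d1, coords)
    path_idx = [v]
    while path_idx[-1] != u:
        path_idx.append(int(pred[path_idx[-1]]))
    path_idx.reverse()  # runs u -> v
    points = [(int(coords[i, 0]), int(coords[i, 1])) for i in path_idx]
    flags = []
    if len(points) < 2:
        points = points * 2
        flags.append("degenerate_skeleton")
    return MedialPath(points, chamber, flags=flags)


def classify_base_apex(
    path: MedialPath, mask: LabelMask, paired_chamber: str
) -> MedialPath:
    """Designate the path endpoint facing the paired chamber as the base.

    Of the two skeleton-path endpoints, the one with smaller mm-scaled
    Euclidean distance to the nearest pixel of the chamber across the
    atrioventricular valve is the base; the other is the apex. A distance tie
    is resolved by row-major order of the endpoints and flagged.
    """
    paired = np.argwhere(mask.region(paired_chamber))
    if len(paired) == 0:
        raise ChamberMissingError(
            f"paired chamber {paired_chamber!r} absent; cannot orient {path.chamber}"
        )
    scale = np.asarray(mask.spacing)
    tree = cKDTree(paired * scale)
    e1, e2 = path.endpoints
    d1, _ = tree.query(np.asarray(e1) * scale)
    d2, _ = tree.query(np.asarray(e2) * scale)
    flags = list(path.flags)
    if np.isclose(d1, d2):
        flags.append("base_apex_tie")
        base, apex = sorted((e1, e2))
    elif d1 < d2:
        base, apex = e1, e2
    else:
        base, apex = e2, e1
    return replace(path, base_point=base, apex_point=apex, flags=flags)


# ---------------------------------------------------------------------------
# atrium-ventricle interface
# ---------------------------------------------------------------------------

def _max_distance_pair(
    pixels: np.ndarray, spacing: tuple[float, float]
) -> tuple[tuple[int, int], tuple[int, int], float]:
    """Pixel pair at maximal mm-scaled Euclidean distance.

    Candidates are restricted to convex-hull vertices of the mm-scaled point
    cloud (the diametral pair always lies on the hull); degenerate clouds
    fall back to the full set. Ties are broken by lexicographic order of the
    sorted coordinate pair, so the result is deterministic and matches a
    brute-force search.
    """
    pts = np.asarray(pixels, dtype=float)
    scaled = pts * np.asarray(spacing)
    cand = np.arange(len(pts))
    if len(pts) > 8:
        try:
            hull = ConvexHull(scaled)
            cand = np.asarray(hull.vertices)
        except QhullError:
            pass  # collinear or tiny cloud: brute force everything
    sub = scaled[cand]
    dmat = cdist(sub, sub)
    best = dmat.max()
    ii, jj = np.nonzero(dmat >= best - 1e-12)
    pairs = []
    for i, j in zip(ii, jj):
        if i >= j:
            continue
        a = (int(pixels[cand[i], 0]), int(pixels[cand[i], 1]))
        b = (int(pixels[cand[j], 0]), int(pixels[cand[j], 1]))
        pairs.append(tuple(sorted((a, b))))
    if not pairs:  # single pixel
        p = (int(pixels[0, 0]), int(pixels[0, 1]))
        return p, p, 0.0
    p1, p2 = min(pairs)
    d = float(
        np.hypot((p1[0] - p2[0]) * spacing[0], (p1[1] - p2[1]) * spacing[1])
    )
    return p1, p2, d


def av_interface(
    mask: LabelMask,
    chamber_a: str,
    chamber_b: str,
    adjacency_radius_px: int = 1,
) -> InterfaceSegment:
    """Locate the band of pixels where two chambers meet.

    Interface pixels are grid positions within ``adjacency_radius_px``
    (Chebyshev) of pixels of *both* chambers; its two extremal pixels (maximal
    mm-scaled mutual distance) are the interface endpoints. For an
    atrium-ventricle pair the band houses the valve annulus.
    """
    if adjacency_radius_px < 1:
        raise ValueError("adjacency_radius_px must be >= 1")
    ra = mask.region(chamber_a)
    rb = mask.region(chamber_b)
    if not ra.any():
        raise ChamberMissingError(f"chamber {chamber_a!r} empty")
    if not rb.any():
        raise ChamberMissingError(f"chamber {chamber_b!r} empty")
    size = 2 * adjacency_radius_px + 1
    foot = np.ones((size, size), dtype=bool)
    band = ndimage.binary_dilation(ra, structure=foot) & ndimage.binary_dilation(
        rb, structure=foot
    )
    pixels = np.argwhere(band)
    if len(pixels) == 0:
        raise InterfaceNotFoundError(
            f"chambers {chamber_a!r} and {chamber_b!r} are not adjacent within "
            f"radius {adjacency_radius_px}"
        )
    e1, e2, dist = _max_distance_pair(pixels, mask.spacing)
    flags = []
    if dist == 0.0:
        flags.append("degenerate_interface")
    valve = VALVE_BY_PAIR.get(frozenset((chamber_a, chamber_b)), "none")
    return InterfaceSegment(
        pixels=pixels,
        chamber_a=chamber_a,
        chamber_b=chamber_b,
        endpoint_1=e1,
        endpoint_2=e2,
        valve=valve,
        spacing=mask.spacing,
        flags=flags,
    )


def _length_px_if_isotropic(
    length_mm: float, spacing: tuple[float, float]
) -> Optional[float]:
    if np.isclose(spacing[0], spacing[1]):
        return length_mm / spacing[0]
    return None


def annulus_diameter(
    interface: InterfaceSegment,
    spacing: tuple[float, float],
    frame_index: int = 0,
) -> LinearMeasurement:
    """Annular diameter: mm-scaled chord between the interface endpoints."""
    (r1, c1), (r2, c2) = interface.endpoint_1, interface.endpoint_2
    length_mm = float(np.hypot((r1 - r2) * spacing[0], (c1 - c2) * spacing[1]))
    flags = list(interface.flags)
    if length_mm == 0.0 and "degenerate_interface" not in flags:
        flags.append("degenerate_interface")
    name = interface.valve if interface.valve != "none" else (
        f"{interface.chamber_a}_{interface.chamber_b}_chord"
    )
    return LinearMeasurement(
        name=name,
        endpoint_1=interface.endpoint_1,
        endpoint_2=interface.endpoint_2,
        length_mm=length_mm,
        length_px=_length_px_if_isotropic(length_mm, spacing),
        frame_index=frame_index,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# septal arc length
# ---------------------------------------------------------------------------

def _is_simple_curve(band: np.ndarray) -> bool:
    """True when every band pixel has at most two 8-neighbours in the band."""
    counts = ndimage.convolve(
        band.astype(np.int8), np.ones((3, 3), np.int8), mode="constant"
    )
    return bool(np.all(counts[band] <= 3))  # self + <=2 neighbours


def _chain_length_mm(
    pixels: np.ndarray,
    start: tuple[int, int],
    spacing: tuple[float, float],
) -> tuple[float, bool]:
    """Nearest-neighbour chaining from ``start``; returns (arc mm, ok)."""
    scale = np.asarray(spacing)
    pts = np.asarray(pixels, dtype=float)
    remaining = {(int(r), int(c)) for r, c in pixels}
    cur = start
    remaining.discard(cur)
    total = 0.0
    while remaining:
        cand = np.array(sorted(remaining))
        deltas = (cand - np.asarray(cur)) * scale
        dists = np.hypot(deltas[:, 0], deltas[:, 1])
        k = int(np.argmin(dists))  # sorted() above makes ties lexicographic
        step_px = np.max(np.abs(cand[k] - np.asarray(cur)))
        if step_px > 2:
            return total, False  # disconnected band
        total += float(dists[k])
        cur = (int(cand[k, 0]), int(cand[k, 1]))
        remaining.discard(cur)
    return total, True


def septal_length(
    mask: LabelMask,
    chamber_a: str,
    chamber_b: str,
    spacing: tuple[float, float] | None = None,
    adjacency_radius_px: int = 1,
    frame_index: int | None = None,
) -> LinearMeasurement:
    """Arc length of the septal interface between two same-side chambers.

    The interface band (LV-RV for the interventricular septum, LA-RA for the
    atrial septum) is thinned to a one-pixel curve where necessary, ordered by
    nearest-neighbour chaining from its extremal endpoint, and the sum of
    mm-scaled steps between consecutive chained pixels is returned. A
    disconnected band falls back to the endpoint chord, flagged.
    """
    spacing = spacing if spacing is not None else mask.spacing
    frame_index = frame_index if frame_index is not None else mask.frame_index
    interface = av_interface(mask, chamber_a, chamber_b, adjacency_radius_px)
    band = np.zeros(mask.shape, dtype=bool)
    band[interface.pixels[:, 0], interface.pixels[:, 1]] = True
    flags = list(interface.flags)
    if not _is_simple_curve(band):
        thin = skeletonize(band)
        if thin.any():
            band = thin
            flags.append("interface_thinned")
    pixels = np.argwhere(band)
    e1, e2, _ = _max_distance_pair(pixels, spacing)
    arc, ok = _chain_length_mm(pixels, e1, spacing)
    if not ok:
        arc = float(
            np.hypot((e1[0] - e2[0]) * spacing[0], (e1[1] - e2[1]) * spacing[1])
        )
        flags.append("chain_failed_chord_fallback")
    name = (
        "interventricular_septum"
        if frozenset((chamber_a, chamber_b)) == frozenset(("LV", "RV"))
        else "atrial_septum"
        if frozenset((chamber_a, chamber_b)) == frozenset(("LA", "RA"))
        else f"{chamber_a}_{chamber_b}_septum"
    )
    return LinearMeasurement(
        name=name,
        endpoint_1=e1,
        endpoint_2=e2,
        length_mm=arc,
        length_px=_length_px_if_isotropic(arc, spacing),
        frame_index=frame_index,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# whole-frame measurement
# ---------------------------------------------------------------------------

def measure_frame(
    mask: LabelMask,
    adjacency_radius_px: int = 1,
    orientation_qc: bool = True,
) -> FrameMeasurements:
    """Measure every available annulus, septum and chamber area on one frame.

    Runs :func:`clean_mask`, then the mitral (LA-LV) and tricuspid (RA-RV)
    annular diameters, the interventricular (LV-RV) and atrial (LA-RA) septal
    arc lengths, and per-chamber areas. Chamber pairs that are missing or not
    adjacent yield absent measurements (with a frame flag), never zeros.

    With ``orientation_qc`` each atrium's medial-axis orientation is checked
    against its valve interface: the base endpoint must lie no farther from
    the interface band than the apex endpoint does (thinning retracts
    skeleton endpoints by about half the local chamber width, so an absolute
    pixel threshold would be shape-dependent). Frames violating the ordering
    are flagged.
    """
    mask = clean_mask(mask)
    present = [c for c in mask.label_map if mask.has_chamber(c)]
    if not present:
        raise ChamberMissingError(f"no chambers present in frame {mask.frame_index}")
    measurements: dict[str, LinearMeasurement] = {}
    flags: list[str] = []
    interfaces: dict[str, InterfaceSegment] = {}
    for name, (a, b) in MEASUREMENT_PAIRS.items():
        if not (mask.has_chamber(a) and mask.has_chamber(b)):
            flags.append(f"missing_pair:{name}")
            continue
        try:
            if name in ("mitral_annulus", "tricuspid_annulus"):
                iface = av_interface(mask, a, b, adjacency_radius_px)
                interfaces[name] = iface
                measurements[name] = annulus_diameter(
                    iface, mask.spacing, mask.frame_index
                )
            else:
                measurements[name] = septal_length(
                    mask, a, b, adjacency_radius_px=adjacency_radius_px
                )
        except InterfaceNotFoundError:
            flags.append(f"non_adjacent_pair:{name}")
    areas = {c: mask.chamber_area_mm2(c) for c in present}
    if orientation_qc:
        for atrium, name in (("LA", "mitral_annulus"), ("RA", "tricuspid_annulus")):
            if name not in interfaces or not mask.has_chamber(atrium):
                continue
            ventricle = MEASUREMENT_PAIRS[name][1]
            try:
                path = classify_base_apex(
                    medial_axis_path(mask, atrium), mask, ventricle
                )
            except (ChamberMissingError, MaskError):
                continue
            iface = interfaces[name]
            scale = np.asarray(mask.spacing)
            band = iface.pixels * scale

            def _to_band(pt):
                d = band - np.asarray(pt, dtype=float) * scale
                return float(np.min(np.hypot(d[:, 0], d[:, 1])))

            if _to_band(path.base_point) > _to_band(path.apex_point) + 1e-9:
                flags.append(f"base_far_from_interface:{atrium}")
    return FrameMeasurements(
        measurements=measurements,
        areas_mm2=areas,
        frame_index=mask.frame_index,
        flags=flags,
    )
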