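# Methods

## The measurement model

`cinemorph` treats a 4-chamber cine acquisition as an ordered stack of 2D
integer label masks, one code per chamber (defaults LV=1, LA=2, RV=3, RA=4),
background 0, with physical pixel spacing (row_mm, col_mm) carried
separately per axis. All geometry uses (row, col), 0-based, pixel-centre
coordinates; millimetre lengths are always computed from anisotropically
scaled coordinate deltas, so anisotropic acquisitions are handled without
averaging the spacing.

The per-frame measuring function has two geometric primitives.

**Medial-axis orientation.** Each chamber's binary region is thinned with a
connectivity-preserving skeletonization and the chamber's long axis is the
longest geodesic path between skeleton endpoints, found by a double
farthest-point sweep over the 8-adjacent skeleton graph with Euclidean step
weights (1 and √2). The sweep is exact on trees; thinning yields trees on
all shapes we generate, and an exhaustive all-pairs search serves as the
test oracle. Of the path's endpoints, the one nearer (mm-scaled) to the
paired chamber across the valve is the *base*, the other the *apex*.
Distance ties are resolved by row-major endpoint order and flagged.

**Interface band and annulus.** The interface of two chambers is the set of
grid positions within a Chebyshev adjacency radius (default 1 px,
configurable) of pixels of both chambers. For an atrium–ventricle pair this
band straddles the valve plane; the band pixel pair at maximal mm-scaled
Euclidean distance defines the annular diameter (the chord between them).
Production code restricts the pair search to convex-hull vertices of the
scaled band (the diametral pair of a finite point set lies on its hull;
strict convexity of squared distance along a segment excludes edge-interior
points), with a brute-force fallback for degenerate clouds; ties are broken
by lexicographic order of the sorted coordinate pair so results are
deterministic and identical to exhaustive search.

The base/apex construction and the interface construction both localise the
valve; the interface chord is the quantity reported as the diameter, because
it is the only construct that yields a diameter directly. The medial-axis
result is used for orientation QC instead: a frame is flagged when an
atrium's base endpoint lies farther from its valve interface band than the
apex endpoint does. An absolute distance threshold was rejected here —
thinning retracts skeleton endpoints by roughly half the local chamber
width, so any fixed pixel threshold would fire on perfectly healthy
geometry; the relative base-vs-apex ordering is shape-independent.

**Septal lengths** (LV–RV, LA–RA) are arc lengths, not chords: a septum is
curved in general and a chord would systematically underestimate. The
interface band is thinned to a one-pixel curve when it is not already a
simple curve (chaining a two-pixel-wide band directly would double-count),
ordered by nearest-neighbour chaining from its extremal endpoint, and the
mm-scaled steps between consecutive chained pixels are summed. A
disconnected band (a chaining step of more than 2 px) falls back to the
endpoint chord, flagged.

**Cleanup.** Before measurement each chamber keeps only its largest
8-connected component and fully enclosed background holes are filled with
the surrounding label; other labels are never reassigned. Degenerate
single-pixel interfaces yield zero-length flagged measurements rather than
errors, so batch runs do not abort.

## Phase selection

Per-frame chamber size is the 2D labelled area (pixel count × pixel area).
Only single-slice 4-chamber masks exist in this pipeline, so the 2D area
stands in for a volume estimate; this assumption is recorded in the output
metadata (`basis` column). End-diastole is the frame of maximal LV area,
end-systole of minimal LV area. When the LV is absent or under 10 px in
more than half the frames, the left atrium is used with the mapping
inverted — atrial and ventricular filling are reciprocal, so the largest LA
marks ventricular end-systole. Ties take the earliest frame and are flagged.

## QC and validation

Population QC z-scores each measurement across the cohort with the sample
(n−1) SD and excludes |z| > k. Both k = 3 and k = 2.5 are in circulation as
exclusion conventions; k = 3.0 is the default and 2.5 ships as a named
preset (`K_SD_STRICT`) rather than being silently chosen. Under a normal
cohort k = 3 removes ≈ 0.27% of draws, which the tests verify by
simulation. Body surface area uses Mosteller √(h·w/3600) by default (Du
Bois selectable); BSA enters validation as a raw covariate.

Automated-vs-manual validation reports mean(auto − manual) in mm and
mean((auto − manual)/manual) as a fraction, and regresses the percentage
difference on the supplied covariates (age, BSA, sex, imaging-plane
deviation, cardiac phase) by OLS with intercept, via statsmodels.
Rank-deficient designs and under-determined fits are flagged with
coefficients absent rather than raising.

## The phantom: what it emulates and what it does not

The phantom rasterizes four axis-aligned rectangles in 4-chamber topology:
atria above ventricles, left and right heart separated by a one-pixel
background gap column (so the septal interface bands are clean single-width
curves), valve planes horizontal. Widths track the annular-diameter
sinusoids, heights the area sinusoids; the annular cycle is shifted half a
period against the LV-area cycle by default so the annulus is widest at
end-systole, the physiologically expected ordering. A given true diameter D
at column spacing s is realised as a shared edge of round(D/s) − 1 px: the
radius-1 interface band extends one pixel beyond each end of the shared
edge, so its extremal chord spans round(D/s) pixel steps and equals D up to
half-pixel rounding. Truth diameters are the generating sinusoids; truth
septal arcs and areas are the exact values of the rasterized (integer)
geometry, so areas match labelled pixel counts exactly on clean frames.

Boundary noise emulates segmentation jitter: within a band of ±⌈2·sd⌉ px
around every label boundary, each pixel independently takes the label of a
random 8-neighbour with probability min(0.45, sd/2). Interiors and far
background are untouched, and all randomness is a pure function of the
seed. Quarter-turn rotations (with spacing swapped on odd turns) support
the invariance tests; arbitrary-angle rotation is not offered because label
resampling at arbitrary angles has no exact raster ground truth.

What passing on phantoms does **not** show: real chambers are curved,
oblique and non-convex; real segmentation errors are spatially correlated,
not i.i.d. boundary flips; real valve planes tilt. The phantom validates
the geometric correctness and noise robustness of the measurement operators,
not anatomical fidelity.

Default phantom conditions: 224×224 grid at 0.5 mm/px, 20 frames, mitral
30 ± 3 mm, tricuspid 33 ± 3 mm, LV 1200 ± 350 mm², LA 800 ± 200 mm² (right
heart slightly smaller). The diameters sit in the adult CMR range; the
areas are scaled to keep all four chambers on one grid while preserving the
LV/LA size ordering and counter-phase filling. The accuracy benchmark
(examples/noise_robustness.py, scripts/acceptance.py) uses 100 phantoms
with per-phantom mean diameters drawn uniformly so cyclic diameters span
25–40 mm, 0.5 px boundary noise — 100 phantoms gives sub-0.1 mm standard
error on the mean error while the whole suite runs in seconds.

The synthetic cohort generator draws per-phase diameters (33 ± 3.5 mm
systole, 28 ± 3.5 mm diastole, systole > diastole on average), covariates
from plausible adult imaging-cohort ranges (age 40–70 y, height 169 ± 9 cm,
weight 76 ± 13 kg), gross outliers at ≥ 6 SD with a configurable rate, and
paired "manual" values auto/(1+b)·(1+ε) for a configured bias b — noise-free
recovery of b by `compare_to_manual` is exact by construction.

## Numerical choices and edge cases

- Tie-breaks everywhere are lexicographic on (row, col) so every operation
  is deterministic; extremum ties in phase selection take the earliest
  frame.
- `length_px` is reported only under isotropic spacing (it is ill-defined
  otherwise); `length_mm` is always authoritative.
- SD = 0 cohorts z-score to 0 and exclude nothing; cohorts smaller than
  p + 2 rows skip regression with a flag (and note that sample z-scores are
  bounded by (n−1)/√n, so k = 3 needs n ≳ 11 to flag anything).
- CSV/TSV writers use 9 decimals; round-trips reproduce values to 1e-9.
- Measurement tables, phase tables and phenotype exports have fixed,
  documented column orders.

## Known limitations

- Single-slice 2D only: no multi-slice volumetry, no 3D annulus or
  saddle-shape reconstruction, and no leaflet or regurgitation assessment.
- The annular diameter is the in-plane interface chord; through-plane tilt
  of the valve is invisible to it.
- Septal arc length depends mildly on the thinning of wide interface bands
  (endpoints can retract by a pixel).
- The LA-fallback phase mapping assumes reciprocal atrial/ventricular
  filling; pathologies that break it (e.g. severe mitral regurgitation)
  would mislabel phases.
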