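# cinemorph

Automated morphometry of the atrioventricular valve annuli from 4-chamber
cardiac cine segmentation masks.

Population imaging studies extract valve phenotypes — above all the
anterior–posterior **mitral annular diameter** — from tens of thousands of
cardiac MRI exams, far beyond what manual annotation can cover. `cinemorph`
implements the measurement stage of such a pipeline: it takes per-frame
integer label masks of the four cardiac chambers (LV, LA, RV, RA), as
produced by any segmentation model, and turns them into phase-resolved
millimetre phenotypes ready for downstream association analyses. It is aimed
at imaging-genetics and cardiology groups who have chamber segmentations and
need reproducible annular and septal measurements with quality control.

## Method

For each frame the measuring function:

1. **cleans** the mask (largest 8-connected component per chamber, enclosed
   background holes filled);
2. traces each chamber's long axis along its **medial axis** (skeleton),
   taking the longest geodesic path between skeleton endpoints; the endpoint
   nearer the paired chamber across the valve is the chamber **base**, the
   other the **apex** (used for orientation QC);
3. finds the **atrium–ventricle interface**: the band of pixels within a
   Chebyshev adjacency radius (default 1) of both chambers. The pair of band
   pixels at maximal physical distance defines the annulus, and the annular
   diameter is

   &nbsp;&nbsp;&nbsp;&nbsp;D = √((Δrow · s_row)² + (Δcol · s_col)²)

   with pixel spacing (s_row, s_col) in mm/px taken from DICOM PixelSpacing
   (0028,0030) or given explicitly — never averaged across axes;
4. measures the **interventricular and atrial septa** as arc length along
   the LV–RV and LA–RA interface bands, and chamber **areas** as pixel count
   × pixel area.

End-diastole and end-systole are selected per subject as the frames of
maximal and minimal LV area (left-atrial fallback with inverted mapping when
the LV is unusable). Cohort QC excludes measurements beyond k sample
standard deviations (default k = 3, with a 2.5 preset), and
`compare_to_manual` summarises automated-vs-manual agreement as the mean
percentage difference (auto − manual)/manual with an OLS regression on age,
body surface area (Mosteller, √(height·weight/3600)), sex and acquisition
covariates.

A **phantom generator** rasterizes 4-chamber cine series with exact per-frame
ground truth (annular diameters, septal arcs, areas) and seeded boundary
noise, so the entire pipeline is testable without any imaging data.

## Worked example

```sh
python examples/measure_phantom.py
```

```
frames: 20  spacing: (0.5, 0.5) mm/px
selected systole=frame 10, diastole=frame 0 (basis LV)

systole (frame 10):
  mitral annulus    33.004 mm  (truth  33.000)
  tricuspid annulus  36.003 mm  (truth  36.000)
  IV septum         23.000 mm  (truth  23.000)
  LV area            845.00 mm^2 (truth   845.00)

diastole (frame 0):
  mitral annulus    27.005 mm  (truth  27.000)
  ...
mitral systole - diastole: +5.999 mm
```

On a noise-free phantom the measured diameters agree with ground truth to a
few microns, areas and septal arcs exactly; the systolic mitral diameter
exceeds the diastolic one because the annulus deforms with ventricular
contraction. The other examples cover noise robustness
(`noise_robustness.py`), cohort outlier QC (`qc_cohort.py`) and
automated-vs-manual validation (`manual_validation.py`).

A thin CLI wraps the same library for batch runs:

```sh
cinemorph phantom --out subjects/P01 --seed 5 --noise-sd 0.5
cinemorph measure --masks subjects --spacing 0.5,0.5 --out results
cinemorph qc --measurements results/measurements.csv --out results/qc.csv
```

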