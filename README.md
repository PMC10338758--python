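# epidtrack

In-vivo quality assurance of marker-based **dynamic tumor tracking (DTT)**
from portal images.

During a tracked liver SBRT delivery on a gimballed linac, the MLC-shaped
beam follows the tumor through the breathing cycle while the electronic
portal imaging device (EPID) behind the patient passively records cine
frames of the treatment beam (2 Hz, 1024 × 1024 panel, 0.18 mm/px
de-magnified to the isocenter plane).  Each frame therefore shows two
things at once: the radiation aperture the machine actually delivered, and
the shadows of the implanted gold seeds (3 mm × 1 mm) that stand in for
the tumor.  `epidtrack` measures how well the one followed the other, and
turns the residual into a planning-target-volume (PTV) margin number.

The pipeline, per cine series (one treatment beam):

1. **Normalize** raw frames to grayscale in [0, 1] (0 = white/open beam,
   1 = black/blocked).
2. **LoG-filter** each frame (Laplacian of Gaussian, σ matched to the
   seed's projected half-width) to make marker shadows compact extrema.
3. **Trace the field edge** of the MLC aperture with a Moore-neighbor
   chain-code follower (Freeman 8-codes) and take the area centroid as the
   aperture center.
4. **Detect markers** by robust thresholding + connected-component
   labeling inside the aperture, with plausibility filters (area,
   elongation, distance to the field edge); the unweighted mean of the
   marker centroids is the target's center of mass (COM).
5. **Tracking error.**  Per frame *i*, the offset is the COM minus
   aperture center in mm at isocenter; with frame 1 as baseline,

   E_T,pan(i) = |pan(i) − pan(1)|,  E_T,tilt(i) = |tilt(i) − tilt(1)|,
   E_T,2D(i) = √(E_T,pan² + E_T,tilt²).

6. **Statistics.**  Mean/SD/90th-percentile/max per field; frame-weighted
   pooling per patient; then across patients

   Σ = SD(per-patient means)  (systematic),
   σ = RMS(per-patient SDs)   (random),
   PTV-margin contribution = 2.5 Σ + 0.7 σ  (Van Herk, 90 % of patients /
   95 % CTV coverage).

A synthetic-scene generator with exact ground truth (moving polygonal
aperture, elliptical seed shadows, respiratory trace, injected tracking
offset, noise, optional MLC occlusion) makes every stage testable without
clinical images.

## Worked example

Render a short synthetic beam with a constant 0.4 / −0.2 mm (pan/tilt)
tracking offset and analyze it:

```bash
epidtrack simulate --output-dir sim --n-frames 8 --matrix-size 512 \
    --offset-pan 0.4 --offset-tilt -0.2 --seed 3
printf 'geometry:\n  matrix_size: 512\n' > geom.yaml
epidtrack analyze sim --config geom.yaml --output-dir out --patient-id P01
```

```
analyzed 8/8 frames -> out/offsets.csv
```

`out/offsets.csv` starts:

```
patient_id,fraction_id,field_id,index,time_s,n_markers,pan_mm,tilt_mm,et_pan_mm,et_tilt_mm,et_2d_mm,included
P01,1,1,1,0.00000,3,0.40474,-0.19899,0.00000,0.00000,0.00000,True
P01,1,1,2,0.50000,3,0.40503,-0.23462,0.00029,0.03563,0.03563,True
```

The measured per-frame offsets (0.405, −0.199 mm …) recover the injected
(0.4, −0.2) mm to a few hundredths of a millimetre — about a tenth of a
pixel — and the baseline-referenced E_T columns start at exactly zero on
frame 1.  The small nonzero E_T on later frames is the localization noise
of the detector grid as the aperture and seeds move.

Per-patient statistics pool frames across fields/fractions
(`epidtrack aggregate out/offsets.csv ...`), and the margin step consumes
any per-patient table.  A reference cohort of eight liver SBRT patients
ships with the package:

```bash
epidtrack margin --reference-cohort
```

```
"2d": {
  "Sigma_mm": 0.2013,
  "sigma_mm": 0.7932,
  "margin_mm": 1.0585,
  "margin_rounded_mm": 1.1
}
```

Reading: across the cohort, the frame-to-frame (random) 2D tracking error
is σ = 0.79 mm, the patient-to-patient (systematic) component is
Σ = 0.20 mm, and the resulting DTT contribution to the PTV margin is
**1.1 mm**.

## Layout

| module | role |
| --- | --- |
| `epid_io` | raw/TIFF/PNG frame + series reading, grayscale convention, offsets CSV |
| `preprocessing` | LoG kernel/filter, robust response threshold |
| `field_aperture` | field segmentation, chain-code tracing, aperture centroid |
| `marker_detection` | candidate labeling, plausibility filters, marker COM |
| `tracking_analysis` | offsets, E_T, field/patient statistics |
| `margins` | Σ, σ, Van Herk margin, reference cohort |
| `synthetic` | ground-truth scene generator, populations |
| `cli` | `analyze` / `aggregate` / `margin` / `simulate` |

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
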