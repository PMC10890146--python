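# ppmval

Validation toolkit for projection-mapped optical tissue measurements:
depth-camera **base-plane calibration**, camera-to-projector **rigid
transform estimation**, mutual-information-driven **deformable registration**
of specimen snapshots to histology images, and **label transfer** of
probe-sized measurement areas into annotated histology space to produce
per-measurement tissue-class percentages.

No study data ships with the package; a synthetic-phantom module generates
every fixture (inclined noisy depth planes, checkerboard point pairs under a
known rigid transform, specimen/histology image pairs related by a known
smooth deformation) together with its ground truth.

## Package layout

| module | contents |
|---|---|
| `ppmval.plane_calibration` | depth-frame averaging, least-squares plane fit `a·x + b·y + z + c = 0`, tilt correction `z_new = z + a·x + b·y + c` |
| `ppmval.projector_calibration` | rigid (rotation + translation) fit from 3-D point pairs via closed-form Procrustes/Kabsch, optional simplex polish, RMSE report |
| `ppmval.preprocessing` | HSV-saturation and Rec.-709 luminance conversion, resize to the fixed 256×192 registration grid, Otsu foreground masks |
| `ppmval.registration` | hard-binned mutual information (bits), Dice score, backward bilinear warping, and the dense-displacement-field estimator (coarse-to-fine control grid, partial-volume MI gradient ascent with diffusion penalty and monotone line search) |
| `ppmval.label_extraction` | projected-dot detection by image differencing, probe-disk rasterization, nearest-neighbor mask warping, per-disk tissue percentages |
| `ppmval.synthetic_data` | seeded phantom generators with attached ground truth |
| `ppmval.pipeline` / `ppmval.cli` | end-to-end orchestration, cohort summaries, `ppm` CLI |

### Conventions

* Pixel coordinates are 0-based `(x, y)` = (column, row); pixel centers at
  integer positions. Plane slopes are per-pixel unless coordinates are
  rescaled by the caller.
* Displacement fields use **backward mapping**:
  `out(x, y) = moving(x + u(x, y), y + v(x, y))`; POI masks are warped with
  the same convention (nearest-neighbor, label codes preserved).
* Depth PNGs are 16-bit grayscale, 1 count = 0.1 mm, 0 = invalid pixel;
  delimited-text depth frames are in mm.
* Displacement fields are stored as 2-plane float32 TIFF (u, v) with a JSON
  sidecar; rigid transforms as JSON `{R: 9 row-major values, T: 3 values}`.

## CLI

```bash
ppm make-phantom --preset depth    --seed 1 --out scratch/depth
ppm make-phantom --preset calib    --seed 1 --out scratch/calib
ppm make-phantom --preset specimen --seed 1 --out scratch/case

ppm calibrate-plane     --frames 'scratch/depth/frame_*.csv' --samples 10000 --seed 0 --out plane.json
ppm calibrate-projector --pairs scratch/calib/pairs.csv --out transform.json --report rmse
ppm register            --fixed scratch/case/HO.png --moving scratch/case/SO.png \
                        --out ddf.tif --metrics metrics.json --bins 32 --lambda 0.05
ppm extract-labels      --spoi scratch/case/SPOI.png --so scratch/case/SO.png --ddf ddf.tif \
                        --annotation scratch/case/HA.png --legend scratch/case/legend.json \
                        --radius 6 --out labels.csv

# or everything at once, then summarize a cohort:
ppm run --so scratch/case/SO.png --spoi scratch/case/SPOI.png --ho scratch/case/HO.png \
        --annotation scratch/case/HA.png --legend scratch/case/legend.json --out scratch/run1
ppm evaluate scratch/run1 --out cohort.csv
```

`ppm run` writes the preprocessed images, the DDF, Dice/MI metrics before
and after registration, the warped measurement-area mask, the tissue-label
report (CSV + JSON), an overlay figure, and a JSON log of all parameters.
A failing stage aborts with a non-zero exit code naming the stage.

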