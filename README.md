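# dermspec

RGB-to-hyperspectral narrow-band imaging and detection evaluation for
dermoscopy images.

The package converts 8-bit RGB dermoscopy-style images into 401-channel
reflectance cubes (380–780 nm at 1 nm) via a PCA spectral basis and a
polynomial regression from XYZ color coordinates, synthesizes narrow-band
pseudo-color images from the 405–435 nm and 525–555 nm hemoglobin
absorption windows, prepares annotated datasets (Pascal-VOC XML → YOLO
txt, stratified 80/20 split), and evaluates object detections through an
extended confusion matrix with background false-positive/false-negative
entries plus the five standard summary metrics (precision, recall,
specificity, F1, accuracy). Reference implementations of the GIoU,
confidence, and classification loss terms are included as pure numeric
functions. A fully seeded synthetic module generates class-specific
lesion spectra, rendered scenes with ground-truth boxes and cubes,
calibration spectra, and detection sets that materialize any target
confusion matrix — so every stage is testable without real data.

## CLI

One entry point with subcommands; `--config config.yaml` and `--seed N`
are global, flags override config values:

```sh
dermspec --seed 1134 simulate --out runs/sim          # synthetic annotated scene
dermspec prepare runs/voc --out runs/prep --size 640 --split 0.8
dermspec convert runs/sim/scene.png --out runs/conv   # RGB -> 401-band cube
dermspec nbi runs/conv/scene.cube.npz --out runs/nbi --windows 405:435,525:555
dermspec bands runs/spectra.csv --out runs/bands --n 2 --width 31
dermspec evaluate --detections dets.csv --ground-truth gts.csv --out runs/eval \
    --iou 0.45 --conf 0.25 --precision-convention exclude-background
dermspec losses --fixture assignments.json
```

Every subcommand writes a `*.provenance.json` sidecar (config digest,
seed, version) so runs are replayable.

## Colorimetric tables

`src/dermspec/data/` holds the observer and illuminant tables (CSV,
401 rows each): CIE 1931 2° curves from the Wyman–Sloan–Shirley analytic
fit and a smooth 6504 K daylight illuminant constrained to the D65 white
chromaticity. `python scripts/make_color_tables.py` regenerates both
deterministically and prints the derived linear RGB↔XYZ matrix.
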