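# lesionplan

Surface-based detection of focal cortical lesions and its integration with
stereoelectroencephalography (sEEG) implantation planning.

The package covers the full analysis chain on triangulated cortical
hemisphere surfaces:

- **surface_io** — FreeSurfer binary surfaces, curv/MGH per-vertex overlays,
  NIfTI/MGH volumes, Slicer FCSV / CSV electrode contact files, 4×4 text
  affines, and the cohort outcome table (a 34-patient table ships as package
  data).
- **features** — per-vertex feature channels (cortical thickness, gray-white
  contrast, mean curvature, sulcal depth, intrinsic curvature, six
  cortical/subcortical intensity depth samples): vertex areas, angle-deficit
  Gaussian curvature, trilinear depth sampling, area-weighted geodesic
  Gaussian smoothing, within-/between-subject z-normalization against a
  control cohort, and interhemispheric asymmetry channels.
- **classifier** — one-hidden-layer sigmoidal network over the 22-column
  vertex design matrix; hidden width chosen as the number of principal
  components explaining >99% of control variance; per-subject balanced
  lesional/contralateral training sampling; Youden-index decision threshold;
  leave-one-out cross-validation; control-cohort specificity.
- **clustering** — edge-connected suprathreshold clusters with a 50 mm²
  area filter, ranking by mean prediction.
- **seeg** — contact transforms, minimum cluster-contact Euclidean
  distances, strict <10 mm SOZ colocalization calls, per-patient
  concordance classification.
- **planning** — pre-planning cluster exclusions (contralateral / artifact /
  top-3), extra-electrode counting, and the minimum-cohort power
  calculation (seeded Monte-Carlo over 1000 simulated cohorts, with the
  exact binomial tail as an independent oracle).
- **synthetic_data** — mirror-symmetric deformed-icosphere hemisphere pairs,
  control feature fields, geodesic lesion patches, linear electrode
  trajectories; everything reproducible from one seed.
- **reporting / cli** — cohort summary tallies and an end-to-end pipeline
  driver.

## CLI

```sh
lesionplan simulate --out sim/ --seed 1          # write a synthetic cohort
lesionplan loocv --seed 1                        # LOOCV on a synthetic cohort
lesionplan train --seed 1 --model-out model.json
lesionplan predict --model model.json --matrix matrix.csv --out scores.mgh
lesionplan cluster --surface lh.white --scores scores.mgh --threshold 0.6 --out clusters.csv
lesionplan colocalize --surface lh.white --scores scores.mgh --threshold 0.6 \
    --contacts contacts.fcsv --affine affine.txt
lesionplan power --p 0.382 --target 10 --confidence 0.9 --cohorts 1000 --seed 1
lesionplan report --json                         # tallies of the packaged table
lesionplan pipeline --seed 1 --out run/          # full synthetic end-to-end run
```

## Conventions

Coordinates are millimetres in scanner RAS; vertex indices are 0-based;
affines act on column vectors with a homogeneous coordinate appended.
Cluster score thresholds are strict (`score > t`); colocalization uses a
strict `< 10 mm` distance rule; cluster areas below 50 mm² are discarded.
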