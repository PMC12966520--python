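# calciscore

Quantification of abdominal-artery calcification from contrast-enhanced CT
angiography (CTA). The package consumes two externally produced NIfTI
segmentations — an artery label map (0 background, 1 aorta, 2 iliac,
3 mesenteric, 4 renal) and a binary calcification mask — plus the CTA HU
volume, and provides:

- **`volumes_io`** — NIfTI read/write with spacing/affine handling and
  resampling to an isotropic working grid (nearest-neighbour for label maps,
  trilinear for HU volumes).
- **`shortening`** — vessel-tree length standardization: side arteries are
  trimmed to 2.5 cm measured geodesically from their aortic stump (the
  intersection with a twice-dilated aorta, grown by 25 masked single-voxel
  dilations on a 1 mm grid), and the aorta is truncated 1 cm above the
  highest retained side artery. 6-connectivity throughout.
- **`calc_threshold`** — the two threshold-based segmentation baselines: an
  idealized per-case search over 101 global thresholds (1% intensity
  intervals) maximizing Dice against ground truth, and the clinically
  realistic fixed threshold (default 470 HU).
- **`seg_metrics`** — Dice, Jaccard, volumetric similarity, sensitivity and
  precision, per binary mask or per artery region.
- **`burden`** — volume-normalized calcification burden score (calcified
  volume / artery volume, bounded in [0, 1]) per artery group plus a
  volume-pooled combined score, with 6-connected cluster counts and mean
  cluster sizes in mm³.
- **`agreement_stats`** — Pearson r, R², OLS regression, Bland-Altman bias
  and ±1.96 SD limits of agreement, paired t-test; Bland-Altman and
  bootstrap-banded regression plots.
- **`phantom`** — synthetic CTA phantoms (HU + artery labels + calcification)
  with controllable geometry, HU bands and noise, plus randomized cohorts
  with construction-derived truth tables, so the entire pipeline is testable
  without clinical data.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes independent brute-force oracles (pure-Python flood fill,
BFS geodesic distance, exhaustive threshold re-sweeps) and a
`tests/test_acceptance.py` implementing the acceptance criteria.

## CLI

```bash
calciscore phantom --out-dir demo/ --seed 1
calciscore shorten --in demo/arteries.nii.gz --out demo/shortened.nii.gz
calciscore threshold --hu demo/hu.nii.gz --roi demo/arteries.nii.gz --fixed 470 --out demo/calc470.nii.gz
calciscore threshold --hu demo/hu.nii.gz --roi demo/arteries.nii.gz --optimal --gt demo/calc.nii.gz --out demo/calcopt.nii.gz --trace demo/sweep.csv
calciscore score --arteries demo/shortened.nii.gz --calc demo/calc.nii.gz --out demo/scores.csv
calciscore evaluate --pred demo/shortened.nii.gz --gt demo/shortened.nii.gz --mode arteries --out demo/metrics.csv
calciscore agree --in pairs.csv --out agree.csv --plots-dir plots/
calciscore run --config run.json        # full workflow, JSON-configured
```

`run.json` keys: `arteries` (required), `calc` or `hu` (+ `threshold_hu`),
optional `gt_arteries` / `gt_calc`, `shortening` (dict of
`ShorteningConfig` fields) and `out_dir`.

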