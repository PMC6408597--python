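# camosim

A tested pipeline for studying how disruptive coloration (edge-enhancement
camouflage) interacts with binocular depth information during visual search:

1. **`camosim.palette`** — forest-like colour palettes (synthetic generator
   or CSV loader) and selection of two mid-luminance, saturated base
   colours from the 10–45 and 55–90 value-centile bands.
2. **`camosim.texture`** — procedural snake textures: uniform noise →
   Gaussian smoothing (σ = 33 px) → binarisation at 0.5 → two-colour
   composition, optionally with a ±0.25 linear luminance ramp over the
   0–10 px band around every region boundary (light side lighter, dark
   side darker).
3. **`camosim.scene`** — metric (cm) leaf-litter scenes: a Bezier-outline
   leaf mesh dropped 4500× onto a brown ground plane via a deterministic
   height-field stacking model (stack cap 1.5 cm), plus an
   elliptical-cross-section snake (4.00° × 0.40° × 0.02° at 57 cm) resting
   on the litter. Layouts serialize to JSON.
4. **`camosim.render`** — a z-buffer rasterizer producing stereo pairs
   (6.5 cm camera separation, 57 cm viewing distance, 39.64° × 28.74°
   field) under ambient or collimated illumination (45° elevation, 350°
   azimuth, cast shadows), with ground-truth snake masks, per-pixel depth,
   signed disparity maps (crossed positive), and red/green anaglyphs.
5. **`camosim.experiment`** — the 2 × 2 × 2 × 4 × 10 factorial session
   (320 trials) and a synthetic observer producing reaction times with
   subject random intercepts/slopes, right-skewed trial noise, lapses,
   errors and a 20 s timeout.
6. **`camosim.stats`** — the analysis pipeline: participant exclusion at
   4 s.d. error rate, removal of no-response/incorrect trials, reciprocal
   transform with a pooled 3 s.d. outlier screen, collapse to cell means,
   fully-within 2 × 2 × 2 repeated-measures ANOVA, generalized eta
   squared, and paired simple-effects t-tests with Cohen's d.

## Command line

```sh
camosim palette  --seed 1 --out palette.csv
camosim texture  --seed 1 --enhanced --out texture.png
camosim scene    --seed 1 --leaves 500 --quadrant TR --out layout.json
camosim render   --layout layout.json --light directional --out-dir renders/
camosim simulate --participants 29 --seed 1 --out trials.csv
camosim analyze  --data trials.csv --out results.json --report report.txt
```

## Notes on modelling choices

* The rigid-body physics drop of the original stimuli is replaced by a
  deterministic sequential stacking model (elements rest flat at the
  running height-field maximum under their footprint); nominal drop
  heights are kept as metadata only.
* Rendering uses an off-axis stereo projection through the shared screen
  plane, so the 57 cm plane carries exactly zero disparity; pixels are
  linear in visual angle, making pixel→degree conversion exact.
* Cast shadows are tested against per-cell occupancy slabs (top/underside
  of the topmost element), so a leaf raised by *h* casts its shadow
  *h*/tan(elevation) from its footprint, opposite the light azimuth.
* Azimuth convention: degrees clockwise from +Y (screen up) viewed from
  above; 350° puts the source slightly left of up.
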