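# spermtopo

Chromosome-topology analysis of decondensed sperm nuclei from FISH/IF
microscopy, built around the classical linear (a/m/b) and radial (D/L, H/L)
centromere-positioning scheme:

* **geometry** — the nuclear coordinate model: longitudinal-axis construction,
  axial fractions, linear zone assignment (basal/middle/apical thirds),
  normalized radial coordinates with mirror folding, shape QC on L/l, and
  inter-centromere distances.
* **imaging** — segmentation of elliptical nuclei from the nuclear-stain
  channel (Otsu + moment ellipse fit), FISH spot detection with sub-pixel
  centroids, and background-subtracted per-nucleus IF intensities.
* **epimarks** — 5mC/5hmC positive/negative classification (fixed-threshold
  or Otsu), hyper/hypo/mixed strata, and chromatin-class (protamination /
  AO / TUNEL) frequency tables.
* **topology** — per chromosome × fraction × epistate summaries (zone
  frequencies, mean ± SE radial coordinates), repositioning-direction calls,
  Ward chromocenter clustering with Newick export, convex-hull chromocenter
  areas, and distance summaries with fold changes.
* **stats** — the testing policy: Shapiro–Wilk-gated Welch-t / Mann–Whitney,
  Kruskal–Wallis + Dunn (Bonferroni), and the summary/fold/percent-change
  arithmetic.
* **synthetic** / **render** — a fully seeded population generator
  (coordinate tables and rendered multi-channel 16-bit TIFF scenes) whose
  default presets equal published per-fraction summary values, so every
  pipeline stage is testable as a parameter-recovery experiment without any
  external data.

## CLI

```sh
spermtopo simulate --seed 1 --cells 100 --out run/pop        # coordinate tables
spermtopo render   --seed 1 --out run/scene                  # TIFF + sidecars
spermtopo measure  --coords run/pop/coordinates.csv --d-mode euclidean --out run/signals.csv
spermtopo classify --cells run/pop/cells.csv --method otsu --out run/cells_classified.csv
spermtopo aggregate --signals run/signals.csv --out run/agg  # summary CSVs + Newick
spermtopo stats    --signals run/signals.csv --out run/stats.csv
spermtopo run-all  --seed 1 --cells 100 --out run/full       # everything + manifest
```

Exit codes: 0 success, 2 configuration error, 3 data error.  `--d-mode`
selects how D is measured (`euclidean`: literal signal→basal distance;
`axial`: projection on the axis, so D/L is the axial fraction); simulation
presets are axial-mode means, so recovery runs should measure in axial mode.

## Data formats

* Coordinate CSV: `nucleus_id, case, fraction, chromosome, x_um, y_um,
  basal_x_um, basal_y_um, apex_x_um, apex_y_um, L_um, l_um`.
* Image scenes: C×H×W uint16 TIFF + channel-map JSON
  (`nuclear`, `fish:<chromosome>`, `if:5mC`, `if:5hmC`) + ground-truth CSV.
* Aggregates: tidy CSVs (zone frequencies, radial means ± SE, distances,
  repositioning calls) and one Newick dendrogram per fraction.
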