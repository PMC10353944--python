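# nichemech

Quantification toolkit for neural-stem-cell (NSC) niche mechanics: how
strongly cells grip their substrate, how fast they move, and where they sit
in the subventricular-zone (SVZ) neurogenic niche.

Adult NSCs live along the lateral-ventricle wall; their activated progeny
normally migrate out of the niche, along the rostral migratory stream (RMS),
to the olfactory bulb (OB). With age, activated NSCs/progenitors become more
adhesive and less motile, and this package implements the bespoke image- and
data-analysis procedures used to quantify that phenotype:

- **FRET tension-sensor force maps** (`nichemech.fret`) — cells plated on
  RGD molecular tension sensors pull on integrin-bound sensor molecules;
  stretching separates the donor/acceptor dye pair, so force lowers the FRET
  efficiency *E*. Per pixel, the sensitized-emission proximity ratio
  `E = A′ / (A′ + γ·D′)` (with background subtraction and optional donor
  bleed-through β) is inverted through a monotone force→efficiency
  calibration to a force map in pN. Force-producing adhesions are segmented
  by thresholding plus watershed splitting, and summarized per cell
  (adhesion count, pixel- or adhesion-weighted mean force, total area) and
  per animal group (Mann–Whitney on animal means; Fisher exact on the
  proportion of force-producing cells).
- **Assay quantification** (`nichemech.image_quant`) — particle counting
  with explicit thresholds and optional watershed splitting; size-normalized
  masked intensity (RawIntDen / area); enzyme-detachment percent remaining
  (`100 × after/before` with a border-margin ROI); centrifugation assay area
  fraction inside a circular crop; Matrigel dispersion distance (maximum
  Euclidean reach beyond the initial spotting perimeter).
- **Migration tracking** (`nichemech.tracking`) — mutual-nearest-neighbor
  detection linking with gap bridging, and track velocity as mean path speed
  (path length / duration), summarized per animal.
- **Niche geometry** (`nichemech.niche`) — Euclidean distance from nucleus
  centers to a hand-traced ventricle-border polyline, the 200-µm analysis
  band (excludes striatal astrocytes), marker-panel cell classification
  (GFAP/Ki67, S100a6/Ki67, EdU/Ki67/DCX), point-in-polygon region counts
  along the SVZ→RMS→OB path, and EdU labeling efficiency (EdU⁺/Ki67⁺).
- **Single-cell signatures** (`nichemech.signatures`) — CP10K
  log-normalization `ln(1 + 10⁴·c/total)`, cumulative gene-set scores (e.g.
  GO:0007155 "cell adhesion"), seeded group downsampling, and
  promoter-accessibility/expression decile binning.
- **Exact statistics** (`nichemech.stats`) — two-tailed Mann–Whitney U,
  two-sided Fisher exact, and Wilcoxon matched-pairs signed-rank tests with
  exact enumeration branches for small samples, plus normalization of values
  to a reference-group mean per experiment block.
- **Synthetic data** (`nichemech.synth`) — seeded generators with exact
  ground truth for every stage: Poisson-noise two-channel sensor images,
  Ornstein–Uhlenbeck persistent random walks, Bernoulli retention,
  distance-shifted niche sections, and negative-binomial count matrices.
- **Workflow** (`nichemech.workflow` / `nichemech run`) — a TOML-configured
  demonstration pipeline chaining the generators into every analysis stage,
  emitting a byte-stable reproducibility report.

## Worked example

Simulate a small tension-sensor field of view and recover per-cell forces:

```python
from nichemech.fret import (CalibrationCurve, compute_efficiency,
                            force_from_efficiency, segment_adhesions,
                            profile_cell)
from nichemech.synth import SimConfig, simulate_tension_images

cal = CalibrationCurve.default_synthetic()   # 0 pN -> E 0.90 ... 10 pN -> E 0.15
cfg = SimConfig(seed=42)                     # 512x512 px, 0.16 um/px,
                                             # 2000 signal / 100 bg photons
imgs = simulate_tension_images(cfg, n_cells=6, adhesions_per_cell=3,
                               force_distribution=lambda rng: rng.uniform(2, 8))

emap = compute_efficiency(imgs.donor, imgs.acceptor,
                          bg_donor=100, bg_acceptor=100,
                          intensity_floor=1000, pixel_size=cfg.pixel_size)
fmap = force_from_efficiency(emap, cal)
adhesions = segment_adhesions(fmap, imgs.cell_mask,
                              force_threshold=float(cal.force_at(0.80)),
                              min_area=0.5)
print(f"{len(adhesions)} adhesions detected ({len(imgs.ground_truth)} simulated)")
for cid in sorted(adhesions.cell_ids):
    p = profile_cell(adhesions, cid)
    print(f"cell {p.cell_id}: {p.n_adhesions} adhesions, "
          f"mean force {p.average_force_pN:.2f} pN, area {p.total_area_um2:.2f} um^2")
```

```
18 adhesions detected (18 simulated)
cell 1: 3 adhesions, mean force 5.94 pN, area 5.04 um^2
cell 2: 3 adhesions, mean force 5.42 pN, area 5.04 um^2
cell 3: 3 adhesions, mean force 5.09 pN, area 3.79 um^2
cell 4: 3 adhesions, mean force 4.31 pN, area 3.48 um^2
cell 5: 3 adhesions, mean force 5.63 pN, area 3.64 um^2
cell 6: 3 adhesions, mean force 4.27 pN, area 4.53 um^2
```

Every adhesion was found, and each cell's mean force is the pixel-weighted
average over its adhesions — under shot noise at these photon budgets the
recovered forces sit within a few percent of the simulated ground truth.

A command-line interface mirrors the library
(`nichemech fret | track | niche | score | detach | spin | disperse | count |
intensity | test | run`); see `nichemech --help`.

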