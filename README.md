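# fcquant

Focal-contact segmentation and quantification for fluorescence microscopy of
mechanically stretched podocytes — with a synthetic, ground-truthed scene
generator that makes the whole pipeline testable without any microscope.

## The problem

Podocytes — the terminally differentiated epithelial cells of the kidney
filtration barrier — respond to cyclic mechanical stretch by reorganizing
their actin cytoskeleton into radial stress fibers converging on an
actin-rich center (ARC), and their attachment depends on integrin-based
focal adhesions (FAs, marked by talin-1). Quantifying how a perturbation
(here: siRNA knockdown of the actin-bundling protein fascin-1) changes FA
number and size per cell requires segmenting hundreds of small, elongated,
diffraction-blurred puncta per cell and attributing each to a cell. This
package implements that measurement chain:

1. **Detection** — gradient-seeded adaptive local threshold: a pixel is
   foreground iff it exceeds `local mean + k·local sd` in a circular window
   *and* its connected region contains a strong Sobel-gradient seed.
2. **Specificity** — each candidate's eroded-core mean divided by the mean
   of a ring just outside it must reach a contrast ratio; small or flat
   candidates are dropped.
3. **Separation** — slightly connected contacts are split by marker-based
   watershed on the negated distance transform (h-maxima markers).
4. **Cell context** — seed-point (semi-automatic) watershed cell
   segmentation; each contact is assigned to the cell containing its
   centroid, with its distance to the cell edge.
5. **Quantification** — moment-based shape parameters (area, axes,
   eccentricity, orientation) and fluorescence activities per contact;
   per-cell count / mean area / total area; LoG-based nucleus counting for
   adhesion assays.
6. **Statistics** — mean ± SD/SEM, percent reduction
   `100 − 100·test/control`, unpaired t-test (pooled or Welch) and
   Mann-Whitney U (exact for n ≤ 12, tie-corrected normal otherwise),
   fiber-profile aggregation (per-bin mean ± SEM).

The synthetic generator renders cells with known contacts (anisotropic
Gaussian spots whose half-peak ellipse has analytic area π·a·b), radial or
transversal stress fibers carrying linear intensity gradients, nuclei
fields, and a Poisson + Gaussian camera noise model — all bit-reproducible
from a single seed. See `docs/methods.md` for the model and every default.

## Worked example

The numbered scripts under `analysis/` run the study end to end; each is a
thin driver over the library. Step 02 simulates both conditions at reduced
size (20 cells/group) and pushes every scene through the full pipeline:

```text
$ python analysis/02_focal_adhesion_recovery.py
control  : contacts/cell 191.9 (truth 193.7), area 1.36 µm² (truth 1.49)
knockdown: contacts/cell 127.0 (truth 126.1), area 1.28 µm² (truth 1.19)
count reduction: detected 33.9 % (truth 34.9 %), t-test p = 3.97e-20
```

Reading: the generator drew control cells with on average 193.7 contacts of
1.49 µm² and knockdown cells with 126.1 contacts of 1.19 µm²; blind
re-detection recovered 191.9 and 127.0 contacts per cell (≈1% error) and a
33.9% count reduction against the 34.9% actually generated, significant by
unpaired t-test. Step 03 prints the same comparison plus the worked-example
reductions computed from the published per-cell group means
(196 → 125 contacts = 36.2%, 1.48 → 1.19 µm² = 19.6%,
304 → 154 µm² = 49.3%); step 04 profiles 75 radial fibers and confirms the
opposite actin/fascin gradients are recovered (slope error < 0.5%); step 05
runs the adhesion assay:

```text
$ python analysis/05_adhesion_counts.py
counted means: control 45.8, test 37.1 (true 45.8 / 37.1)
estimated loss: 19.0 ± 2.9 % (true 17 %)
```

There is also a `fcquant` CLI (`simulate`, `segment`, `cells`, `quantify`,
`profile`, `adhesion`, `compare`, `run`) for operating on TIFF/CSV files
directly; `analysis/01_simulate_example_scenes.py` writes example scenes to
run it on.

## Layout

```
src/fcquant/     library: synthetic, image, segmentation, cells, quantify,
                 profiles, stats, config, pipeline, experiments, cli
analysis/        numbered narrative drivers (simulate → quantify → compare)
tests/           pytest suite incl. brute-force oracle battery
scripts/         acceptance.py (reproduction script)
docs/methods.md  models, parameters, assumptions, limitations
```
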