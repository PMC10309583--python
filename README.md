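# mitomorph

Single-neuron mitochondrial morphometry from calibrated fluorescence
microscopy stacks — with a synthetic-neuron simulator that provides exact
ground truth for every metric the pipeline computes.

## The problem

Adult-born hippocampal granule neurons build their mitochondrial network as
they mature: a dense, interconnected network in the soma and discrete
rod-shaped mitochondria distributed along the dendritic arbor.  Quantifying
how that architecture changes between genotypes or treatments requires a
reproducible chain of measurements on confocal z-stacks of single labeled
neurons (e.g. mitoDsRed with a cytoplasmic YFP fill):

- **compartment occupancy** — the percentage of the soma, primary-dendrite or
  arbor area covered by thresholded mitochondrial signal;
- **per-mitochondrion morphometry** — counts, tip-to-tip lengths and the four
  morphological classes (fragmented < 1 µm, elongated 1–2 µm, medium/large
  2–3 µm, tubular > 3 µm);
- **linear metrics** — mitochondria per µm of dendrite (linear density) and
  the percentage of dendritic length covered by signal (linear occupancy);
- **skeleton network metrics** for the somatic network — footprint, mean
  branch length, mean summed branch length and branches per independent
  structure;
- **fluorescence intensity** — corrected total cell fluorescence
  `CTCF = integrated density − (ROI size × mean background)`, and CTMF, the
  same quantity computed over the mitochondrial mask and normalized to its
  area (intensity per µm² of mitochondria);
- **colocalization** — mask-overlap area fractions and Manders' M1/M2 for
  lysosome/mitochondria co-labeling;
- **spatial distribution** — centrifugal branch orders (primary dendrite =
  I), a 0–1 proximo-distal position score per mitochondrion, branch-order
  fractions, spine density (spines/10 µm), and the regression of
  mitochondrion count on dendritic length;
- **group statistics** with the field's standard decision logic: Shapiro–Wilk
  or D'Agostino–Pearson normality testing, F-test of variances, Student's or
  Welch's t-test, Mann–Whitney, Kolmogorov–Smirnov on cumulative length
  distributions, Kruskal–Wallis with Dunn's post-hoc for fold changes.

Binarization everywhere uses Tsai's moment-preserving ("Moments") threshold:
the cut gray level is chosen so that a bilevel image preserves the first
three gray-level moments of the input histogram.  Co-stain channels
(MFN2/OPA1/OxPhos-style immunostains) are first passed through the standard
enhancement chain — unsharp mask (radius 2, weight 0.4), rolling-ball
background subtraction (radius 50), CLAHE (block 9, 256 bins, slope 4),
median filter (radius 1).

Because every stage is easy to get subtly wrong, the package ships a
first-class synthetic data module: it generates 2D neuron geometries (soma +
branched arbor + placed rod mitochondria with known lengths, orders and
positions), renders them into calibrated multi-channel stacks with PSF blur,
Poisson shot noise, Gaussian read noise and an illumination gradient, and
records the exact truth for every quantity, so the whole pipeline is tested
as a measurement instrument.

## Worked example

```python
import json
import mitomorph as mm

spec = mm.NeuronSpec(mito_linear_density_per_um=0.30)
dataset = mm.generate_cohort(
    n_cells=3,
    spec_by_group={"ctrl": spec},
    cfg=mm.RenderConfig(seed=0),
    seed=42,
    out_dir="demo_cohort",
)
config = mm.RunConfig(analyses=("soma", "arbor", "network", "distribution"))
result = mm.analyze_cell(config, dataset.path[0])
for k in ("soma_occupancy_pct", "dendritic_mito_count", "linear_density_per_um",
          "linear_occupancy_pct", "mean_mito_length_um", "pct_fragmented",
          "pct_elongated", "mito_footprint_um2", "mean_network_branches"):
    print(f"{k:28s} {result['metrics'][k]:.3f}")
truth = json.load(open(dataset.path[0] + "/meta.json"))["truth"]
print("true count:", truth["n_mito"], " true linear density: %.3f" % truth["linear_density_per_um"])
```

prints

```
soma_occupancy_pct           70.036
dendritic_mito_count         89.000
linear_density_per_um        0.304
linear_occupancy_pct         43.514
mean_mito_length_um          1.433
pct_fragmented               29.213
pct_elongated                48.315
mito_footprint_um2           54.654
mean_network_branches        69.000
true count: 89  true linear density: 0.304
```

The analyzed cell carries 89 dendritic mitochondria and the pipeline — max
projection, Moments threshold, ROI cleaning, 8-connected components —
recovers all 89, a linear density of 0.304/µm against a ground truth of
0.304/µm, and a length distribution dominated by fragmented and elongated
mitochondria, as configured.  The soma occupancy (70.0%) runs a few points
above the geometric fill fraction because the PSF widens structures; the
skeleton of the somatic network resolves 69 branches in one connected
structure.

The same objects are available from the command line:

```sh
mitomorph simulate --out demo_cohort --n-cells 3 --seed 42 --groups ctrl --density 0.30
mitomorph analyze-cell demo_cohort/ctrl_000 --enable soma --enable arbor
mitomorph analyze-cohort demo_cohort --out results/
```

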