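# clonoscope

Analysis pipeline for **combinatorial-fluorophore clonal labeling** (CLoNe-style
lineage tracing) in laminated cerebral cortex. In these experiments each
labeled progenitor passes a fixed combination of up to four fluorophores to
its progeny, so the cells of one clone share a multichannel color signature.
`clonoscope` turns multichannel 8-bit fluorescence images (or pre-extracted
cell tables) into clone partitions and the spatial statistics used to
describe them, and ships a fully ground-truthed synthetic-data generator so
every stage is testable without microscopy data.

Intended users: developmental neuroscientists and image-analysis people who
quantify clonal dispersion and laminar composition of lineage-labeled cortex.

## What it computes

**Segmentation — multilevel histogram thresholding with PSNR model
selection.** Each channel is segmented by *n* intensity thresholds computed
iteratively from its histogram (each intensity interval, visited in order of
pixel mass, splits at μ ± w·σ of its occupancy-weighted distribution). The
piecewise-constant reconstruction replaces every pixel by its segment mean
and is scored by

PSNR = 20·log₁₀(255 / RMSE) [dB].

The optimal *n* is the smallest one whose PSNR gain over *n* − 1 drops below
ε dB (elbow rule); 7–12 thresholds are typical for multichannel fluorescence
material. Cells are connected components of the above-threshold foreground;
each cell gets a centroid (μm) and a mean intensity per channel.

**Clone decoding — intensity quantization into cell codes.** Each channel
mean is quantized into 5 levels of 51 intensity points each
(level = ⌊I/51⌋, with I = 255 clamped into the top level). The ordered
level tuple is the *cell code*; cells sharing a code within a section form a
clone; the all-zero code means "unlabeled". Clone sizes are binned 1–8 /
8–16 / 16–32 and unrepresented sizes are reported.

**Spatial statistics.** All cell pairs are classified related/unrelated ×
same/different layer, with Euclidean distances in μm; category dispersion is
summarized as mean ± SD and compared with Mann–Whitney tests (exact by
enumeration for small samples, tie-corrected normal approximation
otherwise). Per-layer replicate counts are compared with Welch *t*-tests
under Sidák correction (p_adj = 1 − (1 − p)^m), laminar contribution
fractions are aggregated supra-/infragranularly, and the bookkeeping
`excitatory_fraction(f_all, p_neuron, p_interneuron) =
f_all / (p_neuron · (1 − p_interneuron))` converts a label fraction of all
cells into a fraction of excitatory neurons.

**Synthetic data.** Clones with configurable size distributions and
code space are placed in a six-layer cortical slab with controllable
same-layer (default 36.8 ± 20.5 μm) and cross-layer (142.1 ± 76.8 μm)
separations, rendered as filled somata with Gaussian edges into 4-channel
8-bit TIFFs, with exact ground truth for every cell.

## Worked example

```python
from clonoscope import (mouse_s1_model, SimulationParams, simulate_clones,
                        render_image, RenderConfig, detect_cells, encode_table,
                        group_clones, pair_distances, summarize_dispersion)

model = mouse_s1_model()
params = SimulationParams(n_clones=60, clone_size_distribution={2: 0.5, 3: 0.5},
                          noise_sd=0.0, min_cell_separation=20.0, seed=11)
cells, truth = simulate_clones(model, params)
image = render_image(cells, (model.cortical_thickness, model.slab_width),
                     RenderConfig())
detected, searches = detect_cells(image)
detected["layer"] = model.layer_of(detected["y_um"].to_numpy())
coded = encode_table(detected)
groups = group_clones(coded)
coded["clone_id"] = coded["cell_id"].map(
    {c: g.clone_id for g in groups for c in g.cell_ids})
summary = summarize_dispersion(pair_distances(coded))
print(summary.table.round(1))
```

prints (abridged):

```
simulated 149 cells in 60 clones; detected 149 cells
channel 1 selected n = 5, thresholds = (8, 38, 73, 199, 226)
recovered 60 clones (ground truth: 60)
                             n  mean_um  sd_um
relatedness layer_class
related     same            68     52.7   37.9
            different       50    161.8   68.2
unrelated   same          1989    218.4  129.4
            different     8919    367.6  157.2
related vs unrelated (different layers): p = 3.48e-21
```

Every simulated cell is re-detected from the rendered image, the 60-clone
partition is recovered exactly from the decoded cell codes, and clonally
related cells in different layers are far closer than unrelated ones
(Mann–Whitney p ≪ 0.001). Related-pair means sit above the configured
36.8/142.1 μm here because the example enforces a 20 μm separation floor so
that rendered somata never touch.

A command-line interface mirrors the library
(`clonoscope simulate | segment | decode | stats | run`); `clonoscope run
config.yaml` chains all stages and writes a manifest with checksums for
reproducibility.

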