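# Methods

## Problem setting

Combinatorial-fluorophore clonal labeling marks each labeled progenitor with
one combination of up to four fluorophores; its progeny inherit the
combination, so a clone is operationally the set of cells sharing one
multichannel color signature within a tissue section. The pipeline has four
stages: (1) segment each channel of a multichannel 8-bit image by multilevel
histogram thresholding and extract per-cell mean channel intensities;
(2) quantize intensities into discrete *cell codes* and partition cells into
clones by code identity; (3) summarize clone sizes; (4) compute spatial
dispersion and laminar statistics. A synthetic-data generator provides
ground-truthed inputs for all of it.

## Segmentation

**Threshold rule.** The multilevel thresholding literature describes a family
of iterative histogram-subdivision schemes without a single canonical
variant; ours is chosen to be fully deterministic. A worklist of intensity
intervals starts with the occupied range. The interval with the largest
pixel mass is split by emitting thresholds at μ − w·σ and μ + w·σ of its
occupancy-weighted intensity distribution (just μ when w = 0; default
w = 1), clipped inside the interval and shifted up by one intensity unit on
collision; the *outer* sub-intervals re-enter the worklist. This repeats
until n thresholds exist or no interval holds two distinct occupied values.

**Reconstruction and model selection.** Segment k holds pixels with
t_k < I ≤ t_{k+1}; its representative is the segment *mean* (not the interval
midpoint) because the mean minimizes RMSE for fixed thresholds, which makes
"adding a threshold never increases RMSE" a provable invariant rather than a
heuristic. PSNR = 20·log₁₀(255/RMSE); a lossless reconstruction is reported
as `math.inf`, which orders above every finite PSNR. The number of
thresholds is chosen by an elbow rule — the smallest n whose PSNR gain over
n − 1 falls below ε (default ε = 1.0 dB, chosen so that typical fluorescence
material selects mid-range n rather than saturating the search) — because
PSNR increases monotonically with n and has no interior maximum. The search
also stops at a lossless reconstruction or when the histogram saturates.

**Cell extraction.** Foreground is the union over channels of pixels
strictly above each channel's lowest threshold; 8-connected components of at
least `min_area` pixels (default 10) become cells, with the unweighted pixel
centroid converted to μm. Mean channel intensities are measured over the
cell's *half-max core*: the component pixels at or above half of the cell's
maximum across channels. The core, unlike the full above-threshold support,
has a brightness-independent extent (the full support of a bright cell
reaches much deeper into the dim blob fringe than that of a faint cell,
deflating its mean by a brightness-dependent factor that scrambles the
downstream quantizer). Over the half-max core the measured/nominal intensity
ratio is ≈ 0.92 for every cell, which the 51-point quantizer bins absorb
without level crossings. Touching cells are not split (no watershed); inputs
are expected to resolve individual somata.

## Clone decoding

Each channel mean is quantized as level = ⌊I/51⌋ into five levels of 51
intensity points (0–50, 51–101, 102–152, 153–203, 204–254); intensity 255 —
the one gray value 5 × 51 leaves over — is clamped into the top level. The
all-zero code is reserved for "unlabeled" (no fluorophore) and excluded from
clones. Same-code cells within one section form one clone; clones are never
merged across sections (cross-section continuity of a code is ambiguous),
and an optional `max_link_distance` splits same-code cells by single-linkage
clustering as a sensitivity check for accidental code collisions. Clone
sizes are binned 1–8 / 8–16 / 16–32 (half-open on the right) and integer
sizes absent from the observed spectrum are reported.

## Spatial statistics

Related pairs are all within-clone pairs; unrelated pairs default to all
cross-clone pairs within a section, with an option to subsample them to the
related-pair count (the original analysis does not state its sampling).
Pairs are classed same/different layer and distances are Euclidean over all
supplied coordinate dimensions. Dispersion is reported per category as
mean ± SD with pooled "total" rows (pooled over layer classes, weighted by
pair counts).

Mann–Whitney comparisons use exact enumeration over all label assignments
for joint sample sizes ≤ 12 (ties counted with midrank ½; the two-sided p is
the probability of a U at least as far from n_a·n_b/2 as observed) and the
tie-corrected normal approximation with continuity correction otherwise.
Layer-count comparisons use Welch's unequal-variance t-test — replicate
counts come from very few brains with no reason to assume equal variances —
with Sidák adjustment 1 − (1 − p)^m across the layers tested, and percent
change (mean₂ − mean₁)/mean₁. All tests are two-sided by default.

`laminar_contribution` divides labeled by total counts per layer and
aggregates supragranular (L2/3, L4), infragranular (L5, L6, SP) and total
fractions as count-weighted means. `excitatory_fraction` rescales a label
fraction measured against all cells into a fraction of excitatory neurons,
f_all / (p_neuron · (1 − p_interneuron)); with the study's printed inputs
(0.30, 0.64, 0.25) this is 30/48 = 62.5%. Note the study's abstract quotes
67.5% of glutamatergic cells while its discussion computes 30/48 = 62.5%;
the package implements the explicit 30/48 arithmetic and records both
figures here without adjudicating between them.

## Synthetic-data generator

**Geometry.** A six-layer S1-like slab (L1 0–100, L2/3 100–320, L4 320–420,
L5 420–560, L6 560–720, SP 720–780 μm; width 600 μm) with half-open layer
intervals, origin at the pia, depth increasing toward white matter. 2-D by
default; an optional section thickness adds a z coordinate (serial sections
of 100–150 μm are typical for cleared-tissue stacks).

**Codes and intensities.** Each clone draws one non-zero code; by default
codes are drawn *without replacement*, because the zero-noise round-trip
guarantee (decoding recovers the simulated partition exactly) requires
distinct codes — 50 iid draws from the 624-code space would collide with
probability ≈ 0.87. `allow_code_collisions=True` restores iid draws for
collision-rate studies. Channel intensity = bin center (51·level + 25, the
margin-maximizing point of each bin) + N(0, noise_sd), clipped to [0, 255];
default noise_sd = 5, comfortably inside the 25-point margin. The intensity
model is a stand-in: the real copy-number/expression distribution of
integrated cassettes is not characterized.

**Placement.** The observed dispersion summaries (same-layer related pairs
36.8 ± 20.5 μm, different-layer 142.1 ± 76.8 μm, different-layer share
19/42 of related pairs) are generator defaults, but no placement *law* is
published, so one is defined: the clone anchor is uniform in the slab; every
mate sits at an exact separation r from the anchor, with r drawn from a
zero-truncated normal whose location is solved (Brent) so the truncated mean
equals the configured category mean. Mate designations and separations are
drawn before the anchor, and the anchor is rejection-sampled so every
designated cross-layer separation can reach another layer — conditioning the
anchor rather than the separation keeps the configured distance
distributions exact. Same-layer mates move tangentially with a small
(5 μm SD) reflected depth jitter; cross-layer mates land uniformly in the
reachable depth range of a random other layer. Distances between two
*mates* of larger clones are anchor-mediated and therefore wider than the
configured means; the pairwise calibration is exact for clone size 2, which
matches how the source pairs were measured. An optional minimum cell
separation (for rendering fixtures whose somata must not touch) truncates
the separation distribution below.

Unrelated-pair dispersion is a property of slab geometry, not a sampled
parameter; `scaled_model_for_unrelated_mean` rescales the slab (expected
distance between uniform points scales linearly with geometry) so that
unrelated different-layer pairs average a target (e.g. 294.9 μm), computed
by deterministic quadrature over the different-layer |Δdepth| distribution.

**Clone sizes.** Default distribution: bins 1–8 / 9–16 / 17–32 with
probabilities 0.25 / 0.35 / 0.40, uniform within bins — encoding the
reported ordering (sizes 8–16 about twice as frequent as 1–8, >16 most
frequent) since only two bin frequencies (19.7 vs 10.8) and the ordering are
published. Any explicit pmf or a fixed size can be substituted.

**Rendering.** Cells are filled somata: a flat disk (radius 5 μm ≈ a real
soma) at the cell's channel intensity with a Gaussian edge (σ = 1 μm),
summed onto a uniform background (default 8, well below the lowest non-zero
bin center) and quantized to 8-bit. All channels share the spatial profile,
so channel ratios — the basis of the cell code — are preserved across the
blob. Not modeled: point-spread anisotropy, photobleaching,
autofluorescence, or partial-volume mixing of touching cells. Blobs clipped
by the field border shift their unweighted centroid inward by a few μm;
interior blobs localize to within one pixel.

**What passing tests show.** The synthetic data exercise the full
segmentation → decoding → statistics chain against exact ground truth, but
real material differs in ways the generator deliberately omits: non-Gaussian
and spatially correlated noise, intensity gradients with depth, touching
somata, and an unknown cassette-expression distribution. Passing round
trips demonstrate internal consistency of the pipeline, not field accuracy
on microscopy data.

## Numerical choices and problem sizes

- Degenerate (constant) channels yield the single-segment n = 0 result with
  a warning rather than an error; empty segments take interval midpoints.
- Threshold ties resolve by a +1 intensity shift; thresholds live in
  (0, 255).
- Decoding accuracy at noise_sd = 10 is bounded by per-channel Gaussian
  boundary crossings: interior levels miss with probability
  P(|N(0, 10)| > 25.5) ≈ 1.1% and the clamped end levels with ≈ 0.5–0.6%,
  so a four-channel code is recovered for ≈ 96–97% of cells; the test suite
  asserts agreement with this analytic prediction rather than an
  unattainable higher figure.
- Test and acceptance fixtures use 60-clone rendered slabs (~150 cells,
  780 × 600 px × 4 channels) and 500–1000-cell tables; the whole suite runs
  in well under a minute. These sizes were chosen so every statistical
  tolerance (3 SE recovery bands, binomial accuracy bands) is meaningful at
  desk scale.
- All randomness flows from one master seed through `numpy.random.SeedSequence`
  substreams (codes / placement / intensity noise / background cells), so
  tables are bit-reproducible.
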