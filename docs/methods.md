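# Methods

## Scoring model

The assay quantifies lysosomal positioning as an intensity-ratio statistic.
Per microscope field (multi-page TIFF; nuclear stain, γ-tubulin/MTOC marker,
lysosomal marker, optional aggregate channel; pixel size in µm mandatory):

1. **Nuclei** — Gaussian smoothing (σ = 2 px) of the nuclear channel, Otsu
   threshold, 4-connected labelling, removal of objects below a minimum
   area (default 3 µm²).  A constant or empty image yields an empty mask.
2. **Cells** — nucleus-seeded watershed on the smoothed lysosome+tubulin
   composite.  Cytoplasmic support is the suprathreshold region of the
   composite under a *triangle* threshold.  Otsu was the natural first
   choice here, but on dark-background fluorescence composites the
   histogram is trimodal (background, dim cytoplasm, bright organelle
   clusters) and Otsu — like multi-Otsu and Li — cuts above the dim
   cytoplasm mode, truncating cells to their organelle clusters; the
   triangle method takes the foot of the dominant background peak, keeps
   the full cell body, and is invariant to positive rescaling.  Every
   support pixel is assigned to exactly one cell; each cell contains its
   seed nucleus; numbering follows the nuclei.
3. **MTOC** — per field: percentile contrast normalisation to [0, 1]
   (defaults 1st/99.9th; the ceiling must sit above the diffuse
   cytoplasmic pool, which a centrosomal spot of ~0.1 % pixel share
   requires — a 99th-percentile ceiling lands inside the pool and
   compresses spot contrast below noise), light Gaussian denoising
   (σ = 1 px; morphological opening applied to raw shot noise takes its
   low envelope and floods the top-hat with spurious response), then
   rolling-ball background subtraction implemented as a white top-hat
   with a disk footprint of physical radius 5 µm.  Per cell: data-driven
   threshold (Otsu default) on the within-cell values, 4-connected
   components, the component with the largest integrated intensity wins
   (ties: higher peak, then scan order), position = intensity-weighted
   centroid.  Exactly one MTOC per cell; cells without suprathreshold
   signal are flagged undetected and excluded from scoring.
4. **Clustering ratio** — lysosomal intensity inside the 7 µm circle on
   the MTOC over the whole-cell intensity.  The numerator region is
   circle ∩ cell (configurable), which guarantees a ratio in [0, 1] and
   excludes bleed-through from neighbours; the denominator includes the
   nucleus (literal whole-cell reading; configurable to exclude it).
   Exclusions — undetected MTOC, border-touching cell, zero lysosomal
   signal — are recorded with reasons, never silently dropped.
5. **Clustering value** — per-well summary (mean by default; median
   available) divided by the pooled control-well summary; a control well
   therefore scores 1 against its own pool by construction.

Hit calling is strictly `fold_change > threshold` with threshold 1.1; a
boundary-equal value is not a hit.  The cascade ledger chains primary hit
calling, secondary (RFP/GFP flux) hit calling at the same rule,
autofluorescence exclusion (annotation input — no detection is attempted),
and an optional confirmation stage recorded from annotations.  Primary hits
missing from the secondary table are recorded as excluded rather than
shrinking the stage's input count, so `output_k = input_{k+1}` always holds.

Flow-cytometry gating keeps events with DAPI ≤ dapi_max (live) and
RFP ≥ rfp_min (reporter-positive); the per-event RFP/GFP ratio is
summarised by the median by default (robust to the heavy right tail of
ratio distributions).  Gate defaults (dapi_max = 1000, rfp_min = 100) are
declared configuration calibrated to the synthetic event generator, not
instrument values.  Densitometry starts from band-intensity tables; lane
and band detection from gel images is out of scope.

## Geometry conventions

Coordinates are 0-based (row, col) pixel indices; geometric centres are
real-valued; conversion to µm uses the pixel size (default 0.325 µm/px,
typical of a 20× high-content objective, making the 7 µm circle ≈ 21.5 px
across).  A pixel belongs to a circle when its centre lies within the
radius; a circle smaller than one pixel spacing keeps its nearest in-bounds
pixel so an in-bounds centre never yields an empty mask.  The central
region of a cell is computed by iterated binary erosion with a 3×3 cross,
stopping at the last iterate whose area is still ≥ fraction × cell area
(default fraction 0.70); the peripheral region is the set difference.  A
cell "has peripheral lysosomes" when more than half of its lysosomal
intensity lies in the peripheral region — the underlying assay reports a
percentage of such cells without defining the per-cell criterion, so the
0.5 intensity fraction is this package's declared choice, exposed in
configuration.

## Synthetic data: what it emulates

`SyntheticCellSpec` renders fields of non-overlapping cells on a jittered
grid (the generator refuses geometries that cannot fit the requested cell
count): a nuclear disk (radius 4 µm), one bright Gaussian MTOC spot
adjacent to the nucleus (offset 1.5 µm from the nuclear edge), a dim
diffuse cytoplasmic pool in the tubulin channel, and `n_puncta` (60)
lysosomal puncta of σ = 0.3 µm per cell.  Each punctum lands, with
probability κ (the *clustered fraction*), uniformly inside the 7 µm circle
about the MTOC, otherwise uniformly in the cytoplasmic annulus.  Because
puncta have finite size, centres keep a 3σ margin from the circle edge and
the cell edge so a punctum's rendered intensity stays inside its region;
the per-cell circle-to-cytoplasm area fraction *a* is computed in closed
form on the actual placement region and stored in the ground truth.  The
expected in-circle intensity fraction is then exactly

    E[r] = κ + (1 − κ)·a

Noise is photon-limited (Poisson applied to the clean image).  Gaussian
read noise is available but defaults to 0: the simulated background is
exactly dark, so summed clipped read noise would add a pedestal to the
whole-cell denominator that real images fold into their background — with
it on, the ratio is biased toward the area fraction by the pedestal share.
All generators are pure functions of (spec, seed) via `SeedSequence`
sub-streams per cell; fixed seeds give bit-identical output.

What the generator does **not** emulate — and hence what passing tests do
not certify on real data: nonzero/structured backgrounds and shading,
touching or overlapping cells, irregular (non-disk) cell and nucleus
shapes, out-of-focus light, vesicle substructure, multi-centrosome cells,
channel cross-talk, and spectral autofluorescence (auto-fluorescent
compounds are handled purely as annotations).

Screen tables plant hits explicitly: non-hits are centred at fold change 1
(Gaussian noise, sd 0.01, clipped at the threshold so planted labels are
exact); hits draw `threshold + margin + Exp(0.15)` with margin 0.05.  Flow
events plant exact category counts (dead above the DAPI gate, RFP-negative
below the RFP gate) and give live reporter-positive events log-normal
per-event ratios with the stated median.

## Numerical choices and tolerances

* Thresholds: Otsu for spot/aggregate picking, triangle for cytoplasmic
  support, fixed-percentile available everywhere; all scale-invariant.
* Ties in MTOC component selection break deterministically (integrated
  intensity, then peak, then scan order); a weighted centroid that falls
  outside the owning cell (possible for non-convex components) snaps to
  the component's brightest pixel so the reported position is always
  inside the cell.
* Degenerate inputs have defined conventions: constant images normalise
  to zero; flat images background-subtract to zero; empty masks propagate
  as empty results; zero denominators yield recorded exclusions or NaN
  with a warning, never exceptions mid-plate.
* Parameter-recovery comparisons use tolerance `3·SE + 1e-3`, SE being the
  standard error of the measured mean.  The 1e-3 term is an a-priori bound
  on the deterministic raster-rendering residue (Gaussian punctum tail
  beyond the 3σ sampling margin, uint16 quantisation, pixel-centre circle
  discretisation): at κ = 1 the placement variance vanishes while this
  residue (order 1e-4) does not, so a pure 3·SE bound is unattainable for
  any finite-size punctum model.  The residue does not scale with sample
  size, which is why it enters as an additive constant.
* Problem sizes in the validation experiments — 200 cells per κ point,
  50 positive-control replicates of one 9-cell field per arm, 1200-compound
  tables — were chosen as the smallest sizes at which the binomial standard
  errors make the comparisons meaningful; they complete in about a minute
  on one CPU.

## Design choices on genuinely open points

* Whether the measurement circle is clipped to the cell and whether the
  denominator excludes the nucleus are not specified by the assay
  description; both are configuration, defaulting to clipped circle and
  nucleus-inclusive denominator.
* The per-well summary statistic defaults to the mean (assay reports are
  mean ± SD); the flow summary defaults to the median.
* FCS files are not parsed; flow events enter as plain per-event CSV,
  which keeps the core dependency-light.  The screening CLI consumes the
  same tables.
* Cell-boundary delineation is a nucleus-seeded watershed stand-in: the
  underlying assay never states its cell-segmentation method.

## Known limitations

* 2-D only; no z-stacks, tracking, or deconvolution.
* One MTOC per cell by construction; genuinely multi-centrosomal cells
  would be scored at their brightest centrosome.
* The synthetic fields are far cleaner than real high-content images;
  absolute localisation and recovery figures quoted by the validation
  experiments are upper bounds on real-data performance.
* Control normalisation is the only plate-effect correction (no B-score
  or spatial detrending); dose–response modelling is out of scope.
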