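# Methods

This note records the models, defaults and design choices behind
`nucleoscreen`, and what the synthetic emulation does and does not show
about real screening data.

## The screen being emulated

The target experiment is a 384-well imaging screen for inhibitors of
ribosome biogenesis in a human cancer cell line.  Four readouts are scored
per compound: immunofluorescence of the shuttling 40S assembly factor ENP1
without LMB (nucleolar at steady state; disperses to the nucleoplasm when
rRNA transcription stops) and with LMB (nucleoplasmic in controls; retained
in nucleoli when nucleolar pre-40S assembly fails), and two
tetracycline-inducible ribosomal-protein reporters, RPS2-YFP and RPL29-GFP
(cytoplasmic in controls; nuclear/nucleolar when subunit maturation is
blocked).  Each well is imaged as a 3×3 montage at 10× with a Hoechst
channel for nuclei and one reporter channel; each cell is assigned to one
of eight phenotype classes; hit rates, z′ quality scores and a 5-SD hit
list follow.

## Synthetic-data generator

The generator reproduces the screen's statistical structure, not its
optics in detail.

**Plate layout.** 16 rows × 24 columns; columns 1 and 23 carry the solvent
(DMSO) control, columns 2 and 24 cycle through the six positive-control
compounds, the 20 inner columns hold library compounds one well each.
Four plates hold a 1172-compound library with 108 empty library wells.

**Class mixture.** Each well's cells are multinomial draws from
`p = (1 − a)·p_ctrl + a·p_act`, where `a ∈ [0, 1]` is the compound's
activity on that readout.  Published sources do not report per-class
baseline frequencies in DMSO wells, so the defaults are stipulated: 82% of
cells fall in the four scoreable interphase classes, with the remaining 18%
split over mitotic (5%), apoptotic (3%), signal-free (5%) and missegmented
(5%) cells; the interphase portion is concentrated on the class a healthy
control shows for that readout (nucleolar for −LMB ENP1, nucleoplasmic for
+LMB ENP1, cytoplasmic for the RP reporters), with a small baseline hit-class
frequency (~2%) so the DMSO hit rate is small but nonzero.  `p_act` moves
that mass onto the readout's hit classes.

**Per-well jitter.** Every well's activity receives an additive
Beta-distributed jitter, `a_eff = a + j(1 − a)` with `j ~ Beta(2, 98)`
(mean 0.02).  This gives the DMSO null nonzero between-well variance — the
5-SD threshold would otherwise collapse onto binomial noise alone.

**Cell numbers.** A seeded well holds ~2000 cells of which the 3×3 montage
images roughly one ninth; table mode uses a Poisson mean of 360 cells per
well, image mode a Poisson mean of 40 cells per site.  Both are config
fields; desk-scale analyses in the tests and acceptance script use ~120
cells per well (~100 classified) to keep runtimes in seconds.

**Rendering.** Cells are disks (nucleus radius ~5 ± 0.5 µm) placed by dart
throwing with a packing tolerance; 2–4 nucleoli sub-disks (radius 1–1.7 µm)
lie inside each interphase nucleus.  The reporter channel uses a fixed
class-conditional level table (nucleoli / nucleoplasm / cytoplasm-ring
relative intensities): nucleolar 1.0/0.25/0.2, nucleolar-nucleoplasmic
1.0/0.8/0.2, nucleoplasmic 0.3/0.9/0.2, cytoplasmic 0.5/0.3/1.0; mitotic
cells are condensed bright Hoechst blobs with uniform reporter, apoptotic
cells fragment into four small Hoechst blobs, signal-free cells have
Hoechst only, and missegmented cells render two fused nuclei under one
label.  The published material shows these phenotypes only as example
images; the table is chosen to make the classes separable at the default
signal-to-noise and is configurable.  Pixel size defaults to 0.65 µm
(typical 10×), field 256×256 px, background 20, intensity scale 600.

**Vignette and noise.** A radially symmetric multiplicative gain (30% fall
at the field corner) plus a constant additive camera term (10), then
Poisson shot noise and Gaussian read noise (SD 2).  A custom gain field can
be injected for forward-model tests.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: nuclei are circular with sharp edges (real
chromatin texture, clumping and debris are absent); there is no point-spread
blur, photobleaching, cell-cycle structure, plate-edge biology or
well-to-well staining drift; classes are rendered from a fixed intensity
table, so classifier accuracy here is an upper bound on what manually
annotated real cells would support.

## Illumination correction

Model: `observed = gain(x) · scene(x) + offset`, with a smooth
multiplicative vignette over a spatially uniform camera term.  Estimation
uses the per-pixel low quantile (default q = 0.05) of a stack of ≥ 50 site
images: because the scene background is spatially uniform, this
background-dominated field equals `gain · background + offset` and is
robust to cells crossing any pixel.  The quantile sits `z_q` noise SDs
below the local background; assuming shot-noise scaling (SD ≈ √level) this
bias is removed by a three-step fixed-point iteration before the field is
smoothed (Gaussian, σ = 2% of image width), the scalar dark level
subtracted, and the result normalized to mean 1.

Pixelwise regression-style estimators (fitting gain and offset per pixel
from the image-to-image variation) were evaluated and rejected: at
desk-scale stacks (~100 images) the per-pixel signal is dominated by
whether a cell happens to cover the pixel, and no amount of smoothing
recovers a 30% vignette to the required fidelity.  The background-quantile
estimator is identifiable precisely because the scene background is flat;
it cannot separate a *spatially varying* additive term from the gain, which
is why the offset is modeled as a scalar (obtainable from dark frames in a
real instrument; configurable here).

Because the gain is normalized to mean 1, corrected intensities carry a
global scale of `mean(gain_true)` relative to the unvignetted scene; all
downstream statistics are scale-free (rates, ratios, relative thresholds),
so this convention is harmless.

Focus filtering scores each image by the variance of its Laplacian and
rejects images below 0.2× the batch median — a relative rule, so exposure
changes do not shift the decision.  A single image is always retained.

## Segmentation and features

Nuclei: Gaussian pre-smooth (σ = 1 px; 0 disables), Otsu threshold, hole
filling, distance-transform watershed with peak markers at least
(expected radius / 2) apart, then a 30–800 µm² size filter; labels are
renumbered 1..N and border-touching labels flagged.  The cytoplasm ring
dilates each nucleus by `round(6.5 µm / pixel size)` pixels; contested
pixels go to the nearest nucleus with ties to the lower label (implemented
as a per-label distance transform with strict-improvement updates, so the
tie rule is exact).

The 15 per-cell features are: nucleus area (µm²), eccentricity, solidity;
nuclear mean/integrated/SD intensity per channel; ring mean/integrated
reporter intensity; mean of the top-decile nuclear reporter pixels and its
ratio to the nuclear median (nucleolar contrast); a white-top-hat spot
count; and the nuclear/ring reporter ratio.  Ratio features are set to 0
and flagged when their denominator is below ε = 1e-6.  The spot counter
uses only relative rules — the top-hat peak must exceed the masked median
intensity, and spots are pixels above 0.5× (features) or 0.3×
(counter-assay foci) of that peak — so counts are invariant under constant
rescaling of a channel.

## Classifier

A random forest (300 trees, fixed seed, single-threaded for
reproducibility) on the 15-feature table.  Training labels come from
simulator ground truth extracted on true masks — the stand-in for the
manual annotation that seeds interactive classification in a real screen.
Posteriors are reported in the canonical class order and argmax ties break
toward the earlier class.  The contract is behavioral (held-out accuracy
≥ 0.85 on synthetic labels); no fidelity to any particular historical
learner is claimed.  On the default synthetic conditions held-out accuracy
is effectively 1.0, which reflects the generator's clean class geometry
(see the generator caveats above).

## Screen statistics

Sample standard deviations (n − 1) are used everywhere; control-well group
sizes are small.  Hit-rate denominators follow the hit/non-hit table of
the assay definitions; for the −LMB ENP1 readout the published description
is internally ambiguous, so the denominator is selectable
(`methods_table` default: non-hit = nucleolar + nucleolar/nucleoplasmic;
`results_text`: nucleolar only; `all_interphase`: all four interphase
classes).  z′ is computed per (readout, replicate, positive control) with
control wells pooled across the four plates (per-plate z′ is a grouping
away in the rates table); it is undefined (NaN) when the group means
coincide and errors for groups of fewer than two wells.  Thresholds are
per (readout, replicate): DMSO mean + 5 sample SDs.  A compound must
exceed its replicate threshold in at least k = 2 of N = 3 replicates
(both configurable); undefined rates never count as above-threshold, and a
compound missing any replicate is logged incomplete and excluded.  The
screen-level hit list is the union over readouts.  Wells pool their sites'
cells before any rate is computed; each compound occupies one well per
replicate.  Border-touching cells keep their features but are excluded
from image-mode class counts.

In place of the manual "visual confirmation" step of interactive screening,
hits should be reviewed from the exported per-well rate tables and raw
images; no algorithmic stand-in is provided deliberately.

## Counter assays

DNA damage: a nucleus is positive when its focal spot count reaches 5 OR —
when a calibrated threshold is supplied (control mean + 3 SD) — its
nuclear marker mean exceeds it.  The rule replaces manual counting with an
explicit, reproducible criterion; both arms are relative, so the reported
fraction is invariant to channel rescaling when the threshold is
recalibrated on the same data.  Degron reporter: per-nucleus integrated
GFP with the extranuclear median subtracted (camera background must not
scale with nuclear area); condition summary is the median and, with a
threshold calibrated from a negative condition, the GFP-positive fraction;
the degradation readout is the ratio of condition medians
(+auxin / −auxin), ≈ 0.1 under the simulated 90% degradation.

## Orchestration and reproducibility

One `ScreenConfig` drives either mode: `tables` (multinomial class counts
through the statistics stage; the full four-readout screen runs in
seconds) or `images` (render → correct → focus-filter → segment → extract
→ classify → statistics; demo-scale subsets run in tens of seconds).  All
randomness descends from the single config seed through spawned
`SeedSequence` streams; outputs embed the config hash and seed, and an
unchanged config reproduces every artifact byte for byte.  Image-mode
illumination models are fitted per channel per (readout, replicate, plate)
batch from that batch's own site images.

## Known limitations

- The illumination model assumes a uniform scene background and a scalar
  camera offset; strongly structured backgrounds or spatially varying
  offsets are out of scope.
- Ring-based cytoplasm approximation double-counts neighboring cells'
  cytoplasm where rings abut and says nothing about true cell boundaries.
- The eight-class vocabulary is fixed; partial phenotypes are forced into
  the nearest class.
- Table mode treats the classifier as a per-cell confusion matrix,
  ignoring within-well correlations of classification errors.
- Synthetic realism bounds what green tests prove about real screens; see
  the generator caveats above.
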