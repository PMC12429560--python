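# Methods

`striocompart` quantifies molecular expression differences between the two
neurochemical compartments of the striatum — the MOR1-rich striosomes and the
surrounding matrix — the way compartmental densitometry studies of
Huntington's-disease model mice do: striosome borders are delineated on a
MOR1 reference channel by a residual U-Net, the target molecule's
immunolabeling is averaged per compartment and caudoputamen segment, and
group differences are summarized as relative-intensity ratios, striosome-to-
matrix predominance indices, and rank-test statistics with Cohen's r effect
sizes. Because real whole-slide material is large and not redistributable,
the package ships a synthetic section generator with known ground truth;
everything downstream treats synthetic and real inputs identically.

## Synthetic sections

A section is a two-channel gray-level image (default 8-bit, stored float32):
the MOR1 reference channel and a target-molecule channel. Geometry is drawn
once per section from a seeded generator:

- **Territory.** An ellipse (~42% x 45% of the frame half-extents) with mild
  low-order radial modulation — a convex-ish caudoputamen profile with a
  background margin ("slide glass") on all sides.
- **Striosomes.** White noise filtered with a difference of Gaussians at
  scale `striosome_scale_px` (default 32 px) and thresholded at the quantile
  that yields `striosome_area_fraction` (default 0.10) of striatal pixels.
  This produces elongated, labyrinthine minority blobs — a deliberate
  caricature of striosome morphology with an exactly controllable area
  fraction, not an anatomical model.
- **Excluded structures.** Elliptical fiber bundles and thin vessel tracks
  are carved out of the tissue before the striosome quantile is taken, so
  the striosome fraction is exact over the remaining striatal pixels.

Intensities come from an *effect table*: one mean gray level per (molecule,
genotype, age, segment, compartment). The default table constrains only the
effect directions to the study design being emulated — MOR1 up in Q175KI
striosomes, progressively with age; PDE10A, Gα_olf, Drd1, Drd2 and A2A
down; wildtype PDE10A slightly striosome-predominant — with magnitudes that
are configuration, not ground truth. All means exceed the background level
(default 10); fiber/vessel pixels render at a distinct low level (40).

Noise is additive i.i.d. Gaussian (default sd 25 gray levels), clipped to
the bit-depth range — the simplest model for which standard-error
predictions hold. Between-animal and staining-batch variability enters as a
per-(sample, channel, compartment) multiplicative log-normal offset with
mean 1 and CV `between_animal_cv` (default 0.08) applied to the amplitude
above background, so group comparisons are statistically nontrivial while
background subtraction still recovers offsets exactly. What the generator
does *not* emulate: chromogenic (DAB) optics, spatially correlated texture,
intensity gradients across the section, registration error between the two
channels, and real anatomical segment boundaries. Tests passing on this
material therefore validate the measurement and inference chain, not
robustness to those real-data effects.

Seeding: every cohort derives per-section seeds from the root seed through
`SeedSequence(entropy=seed, spawn_key=(counter,))`, so identical configs are
bit-identical and extending a cohort never reshuffles existing sections.

## Segmentation

The model is a residual U-Net over the single MOR1 channel: per resolution
level one residual block (two 3x3 convolutions with group normalization and
an identity/1x1 shortcut), 2x2 max pooling down, nearest-neighbour
upsampling with skip concatenation up, a 1x1 head to two classes
(striosome vs rest). Defaults: depth 4, base 16 channels (~500k
parameters). The layers are implemented directly on numpy in NHWC layout
with convolutions lowered to one BLAS GEMM per call; gradients are
hand-derived and verified by finite differences in the test suite. Group
normalization (8 groups) was chosen over batch statistics for batch-size
independence and bitwise determinism.

Training follows the protocol of the emulating study: sections are tiled on
a non-overlapping grid with reflective edge padding; tiles without striatal
tissue may be dropped for training, never for inference; augmentation is
either vertical flip only (probability 0.5, applied to image and labels
together) or vertical flip plus photometric jitter of the image only
(brightness ±20%; hue ±0.05 cycles and saturation ±20% where tiles are
color). The loss is unweighted pixel-wise cross-entropy; the optimizer is
Adam at learning rate 1e-3 (2e-3 in the desk-scale benchmark). "Training
rate 0.85" is read as the train/held-out split fraction — 0.85 is
implausible as a learning rate — and the split is by section where sections
are available, otherwise by tile. The checkpoint returned is the epoch with
the minimum held-out cross-entropy, not the last one; ties go to the
earlier epoch. For desk-scale budgets an epoch is `steps_per_epoch` batches
drawn from a seeded permutation stream over the training tiles, and the
per-epoch held-out loss is estimated on a fixed seeded subsample of
held-out tiles (`eval_tiles`, default 32); final metrics are always
computed on full held-out sections.

Inference tiles the section, stitches the probability maps over the exact
half-open crop windows, and binarizes at 0.5 with ties assigned to
striosome. Because group normalization uses per-tile statistics, tiled and
whole-image inference agree per-pixel rather than bitwise; disagreement off
tile seams is under 1% of pixels on a trained model, and the seam margin is
2^(depth-1) px. Otsu thresholding within the tissue region is provided as
the annotation aid it was in the original workflow and doubles as the weak
baseline: on noiseless renders it is near-perfect (Dice >= 0.99), at the
default noise level it falls well below the U-Net.

Evaluation metrics (IoU, Dice, precision, recall, accuracy) are computed
from striosome-vs-rest confusion counts, by default within the striatal
region; whole-tile accuracy (background included) is reported for the
training-diagnostic accuracy. Macro averaging (mean of per-image scores) is
the default reporting mode, with pooled counts available; the algebraic
identities dice = 2·iou/(1+iou) and dice = harmonic mean(precision, recall)
hold exactly in pooled mode only. Zero-denominator conventions: two empty
masks score 1.0, any other empty denominator 0.0.

## Densitometry

Segments: the striatal mask is split about its centroid into dorsomedial,
dorsolateral, ventromedial and ventrolateral quadrants (dorsal = top of the
image; the medial side is a per-hemisphere flag), with WH their union. This
deterministic quadrant rule is a surrogate for the manual segment drawing
of the real workflow; user-supplied segment masks can replace it.

Per (segment, compartment) the mean gray level of the target channel is
taken over compartment pixels minus fiber/vessel exclusions, and referenced
to background. The background reference is the *median* of the out-of-tissue
region: near the bottom of the detector range the clipped noise
distribution loses its lower tail, which biases the sample mean upward
(about +5.7 gray at background 10 and noise sd 25) and would systematically
inflate compartment ratios; the median is unbiased as long as under half
the background mass clips. Subtraction (rather than recording background
separately) makes every record invariant to a constant shift of the image.
Cells with no remaining pixels are flagged `qc_excluded`, mirroring the
visual QC exclusion of poorly stained segments. Higher gray level means
stronger immunoreactivity (fluorescence polarity); a DAB-style inversion is
left to input preprocessing.

Two indices summarize compartment effects:

- **RI** (relative intensity) = mean intensity of the mutant group / mean
  intensity of the wildtype group, per (molecule, age, segment,
  compartment). This is a ratio of group means — not a mean of per-sample
  ratios — matching the index's definition as a group-level ratio.
- **ISMP** (index of striosome-to-matrix predominance) = striosome / matrix
  intensity *per sample*, then summarized as group mean ± SEM. The
  asymmetry (RI at group level, ISMP at sample level) follows how the two
  indices are reported: RI as a heatmap of group ratios, ISMP as group
  distributions.

On noiseless renders the pipeline recovers every configured RI and ISMP
exactly (the synthetic means are exactly representable and the estimator
chain is linear); with noise and offsets, recovery is within sampling error
(3 SE at n = 8 mice per group in the acceptance suite).

## Statistics

The sampling unit is the caudoputamen (animal x hemisphere; 16 per group at
n = 8 mice), treated as independent. Group comparisons use Kruskal-Wallis
omnibus tests followed by pairwise two-sided Mann-Whitney U tests with
Bonferroni correction; the family size is an explicit parameter whose
defaults reproduce the conventional adjusted thresholds 0.05/10 = 0.005 and
0.05/3 ≈ 0.0167. The U test uses the exact null distribution for tie-free
combined samples up to n = 20 and the tie- and continuity-corrected normal
approximation otherwise; single-observation-per-group comparisons are
returned degenerate with p = 1. Cohen's r = |Z|/sqrt(N) uses the
tie-corrected Z *without* continuity correction (the conventional effect-
size definition), binned at 0.1/0.3/0.5 into small/medium/large. Report
tables are molecule x (age, segment) matrices of RI, Cohen's r and
significance flags (missing cells explicit NA), plus per-molecule ISMP
group summaries; heatmap figures mirror the tables.

## Problem sizes and numerical choices

The desk-scale segmentation benchmark uses 54 sections of 512x512 px
(46 train / 8 held-out at the 0.85 split), 64-px training tiles, batch 32,
12 epochs of 6 steps, learning rate 2e-3 — sizes chosen so the whole
benchmark (generation, training, evaluation) completes in minutes on one
CPU core while leaving the protocol (tiling, augmentation arms, checkpoint
selection, macro evaluation) fully exercised. Parameter-recovery and
type-I-error checks run on 160x224 px cohorts with the full 6-molecule,
2-genotype, 3-age design. Floating point: activations and parameters are
float32; reductions (means, losses) accumulate in float64; training is
bit-reproducible for a fixed seed and BLAS thread count.

## Known limitations

- The generator's homogeneous per-compartment means make segmentation
  easier than real MOR1 histology; the benchmark's margins over the
  reference scores should be read accordingly.
- The quadrant segment rule ignores real anatomical boundaries.
- Group normalization trades exact stitching locality for determinism.
- The default effect table is a direction-constrained invention; magnitudes
  carry no biological meaning.
- No atlas registration, no per-cell analysis, no multi-class
  (fiber/vessel) prediction head — fibers and vessels are excluded via
  ground-truth or user-supplied masks.
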