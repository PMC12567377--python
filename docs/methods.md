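# Methods

## Signal model and features

EEG windows are modelled per channel and band as zero-mean Gaussian. The
differential entropy of a window is computed in closed form,
h = ½ ln(2πe σ̂²) nats, with σ̂² the biased (1/n) sample variance — the
maximum-likelihood estimator under the Gaussian model, chosen so the
amplitude-scaling law (scaling a signal by c adds exactly ln|c| nats) and
the agreement with numerical quadrature of −∫ f ln f hold to machine
precision and can be asserted exactly in tests. Natural logarithms are
used throughout; all DE values are in nats.

Band decomposition uses 4th-order Butterworth band-pass filters applied
forward-backward (zero phase), so filtering never shifts window
boundaries; the five bands are δ 1–4, θ 4–8, α 8–12, β 12–30 and
γ 30–50 Hz. Zero-phase filtering squares the magnitude response, which
makes each filter's half-power point fall at its band edge; the band
outputs consequently sum back to a 1–50 Hz band-limited input with
relative L2 error below 0.1, which is verified rather than assumed.

A zero-variance window would make the entropy −∞; the extractor returns a
flagged sentinel and clamps stored features to a floor of −10 nats
(configurable) so degenerate synthetic edge cases cannot poison training.

Face frames are center-cropped to a square, bilinearly resized, and
min-max normalized per feature (pixel × channel) within each subject,
mapping each feature to [0, 1]; constant features map to 0. An optional
signed rescale (2x − 1) is available for users who prefer a symmetric
range; the unsigned form is the default because it is the form whose
endpoints are directly checkable.

## Topographic rasterization

Electrode positions come from an azimuthal-equidistant projection of
standard extended 10-20 template positions (62 channels; the two
cerebellar sites sometimes present in 62-channel caps are represented by
the posterior pair PO9/PO10, which exist in the standard template). The
unit disc of electrode coordinates is mapped to the central 200/224 box of
the raster, pixel centers at half-integer coordinates; both conventions
are recorded in the feature-file attributes.

Bilinear interpolation is defined on scattered electrodes as follows: for
each pixel, take the nearest electrode in each of the four open quadrants
(NW/NE/SW/SE) around it; weight each by the product of the coordinate
distances to its x- and y-opposite stencil members; normalize weights to
sum to one. On a rectangular electrode grid this reduces exactly to
textbook bilinear interpolation, which is the sense in which the classical
four-point formula is honoured. Pixels lacking an electrode in some
quadrant — the border outside the electrode hull margin — are exactly
zero. A pixel within ε = 1e-6 of an electrode takes that electrode's
value. Degenerate collinear stencils (all four area products zero) fall
back to the nearest electrode; this can only occur for pixels exactly on
a line through all four stencil electrodes. Because weights are convex,
maps never overshoot the electrode value range.

The per-pixel stencils depend only on the layout and raster size, so they
are precomputed once into a (pixels × electrodes) matrix; rasterizing any
number of DE vectors is then a single matrix product.

## Encoders and fusion

The EEG encoder (EFEM) is a small convolutional network: a 3×3/stride-2
stem with BatchNorm and GELU, a second 3×3 conv, then MBConv stages — each
block max-pools, reduces channels 1×1, applies two depthwise-separable
convolutions, reweights channels by squeeze-excitation (reduction ratio
0.25), and adds a residual when input and output shapes match. By default
each band map is encoded separately with shared weights, so every token
carries a known band identity; this is what makes per-band attention
attribution well defined. (A joint 5-channel mode exists for users who do
not need attribution.)

The face encoder (FEFEM) is a residual network: 7×7/stride-2 stem,
3×3/stride-2 max-pool, then bottleneck (1×1–3×3–1×1) residual stages with
stride-2 first blocks; a basic-block (3×3–3×3) variant is available by
configuration and is also the architecture of the 18-layer 1000-class
baseline used for complexity comparison.

Both encoders end in a token projection (1×1 conv to a projection width,
then a linear map to d_model). Fusion prepends a learned class token,
adds learned modality-type embeddings (no intra-modality positional
encoding, so class logits are invariant to token permutations within a
modality), runs pre-LN transformer blocks, and classifies from the class
token. Attention weights of every block are recorded.

**Reference configuration.** d_model 256, 8 heads, 2 blocks, MLP ratio 4;
EFEM stem 32, stage widths (32, 64, 128, 256), 2 blocks/stage, expansion
4; FEFEM depth-18 bottleneck with widths (64, 128, 256, 512). Two values
were fixed by calibrating the model's parameter count to the published
complexity budget of 15.2 M: the bottleneck output expansion is 2 (with
the conventional expansion 4 the encoders alone exceed the budget), and
the token-projection width is 2128, giving 15.195 M parameters. The
complexity counter reproduces the standard 18-layer residual baseline
exactly (11,689,512 parameters, 1.814 G MACs at 3×224×224) using the
conv/matmul-only MAC convention with 1 MAC = 1 FLOP. A printed depthwise
parameter formula that includes spatial dimensions circulates in the
literature; the counter implements standard convolution algebra (k²·d for
a depthwise kernel, d·d_j for the pointwise map), under which depthwise
separation gives its usual parameter saving.

**Scaled configuration.** For desk-scale synthetic studies (64×64 maps
and faces): d_model 32, 4 heads, 1 block, MLP ratio 2; EFEM stem 4,
widths (4, 8, 16); FEFEM widths (8, 16, 32), 1 block/stage, expansion 2.
These widths were chosen once so a full five-method comparison trains in
minutes on one CPU core with the numpy engine; the dataset conditions
(below) are not reduced further.

## Training protocol

Cross-entropy loss, batch size 32, AdamW (Table-style hyperparameter
lists name the decoupled variant; plain Adam is available) at
η_max = 1e-3 with cosine annealing
η_t = η_min + ½(η_max−η_min)(1 + cos(π T_cur/T_max)), updated once per
epoch with T_max equal to the epoch budget; a per-batch option exists.
Weight decay 1e-4 (AdamW only). Weight initialisation is fan-in-scaled
and fully seeded: identical seed and data give bit-identical trained
weights. Decisions are argmax with lowest-index tie-break.

Splits are clip-wise and stratified: within each subject every fold
receives one clip of each emotion, so all windows of a clip share a fold
and clip leakage is structurally impossible; the assertion is re-run on
every experiment. Leave-one-subject-out splits are provided for
subject-independent evaluation. The paired t-test across subjects is
two-sided; zero-variance difference vectors are flagged as undefined
rather than silently returning a value.

Attention attribution takes the class-token row of the last block's
attention, averages over heads and evaluation windows, sums the mass
within each EEG band (known from per-band token construction) and each
facial region (a named partition of the face-token grid: forehead, eyes,
cheeks, mouth, other), and renormalizes within the EEG group and the face
group separately, so each group's weights sum to one.

## Synthetic data generator

The generator emulates the structure of a 62-channel/200 Hz multimodal
emotion corpus: n subjects × (4 emotions × clips-per-emotion) clips of
fixed duration, one face frame per 1 s window, balanced labels.

EEG background is independent Gaussian noise shaped into the five bands
with equal unit variance per band (each band component is filtered white
noise renormalized to unit variance). Class signal is injected as a
variance multiplier m on one (band, scalp-region) pair per emotion —
defaults: happy → (β, parietal), sad → (δ, frontal), fear → (γ,
occipital), calm → (θ, central), all with m = 4 — loosely following the
affective-EEG literature's posterior-fast/frontal-slow emphases without
claiming physiological fidelity. Because the Gaussian assumption of the
DE closed form is exactly true here, the expected DE offset of targeted
entries is analytic: ½ ln m (0.693 nats at m = 4), with tolerance
shrinking as windows accumulate. Scalp regions are defined by coordinate
rules on the montage (frontal/central/temporal/parietal/occipital
partition). Subject effects are log-normal per-channel gains (σ = 0.1)
drawn once per subject, which exercise per-subject normalization and the
subject-dependent protocol.

Faces are procedurally drawn (ellipse head, eye and mouth primitives)
with emotion-dependent geometric deformations — mouth curvature up/down
for happy/sad, mouth opening and widened eyes for fear, neutral for calm
— scaled by a signature-strength parameter (default 1.0), plus per-frame
geometric jitter and pixel noise (σ = 0.02 in [0,1] units). Pixel values
are snapped to the 8-bit grid at generation time so PNG round-trips are
lossless. With strength 0 the classes are exchangeable; with large
strength and zero noise a nearest-centroid classifier on raw pixels is
perfect — both ends are tested.

What the generator does **not** emulate: volume conduction and realistic
cross-channel covariance, artifacts (blinks, EMG), non-stationarity
within clips, facial identity variation, temporal dynamics across frames.
Passing tests therefore demonstrate that the pipeline recovers the kind
of band-localized variance structure and geometric face cues it is built
to detect — not performance on real recordings.

## Scaled-down synthetic studies

The end-to-end study uses 4 subjects, 5 clips per emotion, 20 s clips
(1600 windows), 64×64 maps and faces, the scaled configuration, 10
epochs, and one clip-wise fold (1280 training / 320 validation windows).
All five methods (EEG-only, face-only, attention fusion, concatenation,
decision fusion) must beat the 25% chance level at binomial p < 0.01, and
attention fusion must be within one standard error of (or above) the best
unimodal branch. The label-shuffled control re-runs the same pipeline
with permuted labels and requires every method to stay inside the 99%
binomial interval around chance; it trains 5 epochs, since shuffled
labels carry no recoverable signal at any epoch count. Published
real-data accuracies for this model family are not reproduced here: the
underlying corpus is restricted, and the synthetic study is a correctness
check, not a benchmark.

## Numerical and implementation notes

The autodiff engine is reverse-mode on numpy arrays in float32 (float64
in oracle tests); every op's gradient is validated against central
differences. Convolution is im2col + GEMM with a specialized shifted
multiply-add path for depthwise kernels; max-pool backward scatters
through argmax indices. BatchNorm uses batch statistics during training
(momentum 0.1 running stats for evaluation); LayerNorm is used inside the
fusion blocks, matching the BatchNorm-in-encoders / LayerNorm-in-
transformer split. GELU is exact (erf-based). Softmax subtracts the row
maximum before exponentiation.

Known limitations: no GPU path (numpy only), no pretrained weights, EDF
is read but not written (raw float32 + JSON header is the native EEG
format), no artifact rejection or re-referencing, and no face detection —
frames are assumed pre-cropped to the face.
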