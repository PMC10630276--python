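# Methods

This note documents the models and procedures implemented in `synthct`,
the parameters that matter, the design decisions taken where the design
was genuinely open, and what the phantom-based tests do and do not show.

## The synthesis model

The core is a conditional GAN for semantic image synthesis with three
networks:

**Generator.** A latent code `z` (default 64 dimensions at desk scale) is
mapped by a fully-connected layer to a 4×4 feature grid and upsampled
through `n_upsample_stages` stages (4 for 64×64, 7 for 512×512). Every
stage applies spatially-adaptive normalization (SPADE): features are
instance-normalized, then re-scaled and re-shifted per pixel by γ(m) and
β(m) maps predicted from the one-hot annotation map `m` resized to the
stage's resolution. Because the semantic layout is re-injected at every
stage, the output cannot drift away from the map — this is what makes
annotation edits (nodule removal, insertion, relocation, resizing)
propagate faithfully into the image. The modulation heads are 1×1
convolutions on top of a 3×3 shared convolution: spatial context comes
from the shared layer, and the 1×1 heads keep SPADE affordable at full
resolution on CPU. The output head is a sigmoid, so synthetic images are
produced in [0, 1] and mapped back to the HU window.

**Style encoder.** A strided-convolution encoder produces `(μ, log σ²)`
of a diagonal Gaussian posterior over `z`; training samples by
reparameterization, inference from a guide image uses the posterior mean
(example-guided synthesis). Three deliberate choices make the style path
work at small training scales, where we found the textbook layout learns
nothing about style:

1. the encoder is normalization-free — instance norms would strip the
   global-intensity information that distinguishes scanners;
2. the global mean intensity of the input is appended (scaled) to the
   flattened features feeding the latent heads, since overall brightness
   is the single strongest scanner cue;
3. the generator adds a scalar pre-activation output bias predicted from
   `z`, with latent unit 0 wired at initialization to read the brightness
   shortcut positively. Training refines this pathway instead of having
   to discover its sign within a few hundred steps.

With these in place, guiding the desk-profile model with a +80 HU
brighter copy of an image raises the synthetic body-region mean by
+20–30 HU consistently across seeds; without them the response was ~0 HU
with random sign.

**Discriminators.** Two patch discriminators score (image, map) pairs at
full and half resolution (three strided 4×4 convolutions plus a 1-channel
head each). Their intermediate activations provide the feature-matching
loss.

**Losses.** Discriminator: hinge on real/fake. Generator:
`L_hinge + λ_FM·L_FM + λ_KL·KL + λ_rec·L1`, with λ_FM = 10 and
λ_KL = 0.05 (the conventional SPADE weighting) and λ_rec = 10. The
pixel-space L1 reconstruction term replaces the usual pretrained-network
perceptual loss, which is off by default because it requires external
weights (a hook accepts any user-supplied feature extractor). The L1 term
is load-bearing at desk scale: without direct supervision the rare, small
nodule label (tens of pixels, ~17% of slices) never renders distinctly
within the step budget.

**Optimization and initialization.** Adam with β = (0, 0.999) and the
two-timescale rule (discriminator faster than generator). The desk
profile uses 1e-3/2e-3; the full profile the conventional 1e-4/4e-4 —
with few hundred steps the conventional rates leave the network
effectively at initialization. Weights are He-initialized
(sd = √(2/fan_in)). A single config seed controls initialization, data
shuffling and latent sampling; runs are bit-reproducible on one machine
with a fixed BLAS thread count, but cross-platform bit-exactness is not
promised — stochastic tests use statistical tolerances and majority
votes over three seeds.

The networks run on a small reverse-mode automatic-differentiation engine
over numpy arrays written for this package (`synthct.nn`), with
convolution implemented as per-tap batched GEMMs. Analytic gradients are
verified against central finite differences in the test suite.

## Phantoms

The phantom generator produces 2D chest-like slices where every pixel's
label is known by construction: an elliptical body with a fat/skin rim
(body label, −200 ± 25 HU), soft-tissue interior (+40 ± 20), a dense
vertebral body (+700 ± 150), two lung ellipses (−800 ± 60) carrying 2–4
bright Bézier "vessels" at soft-tissue HU (1 px wide at 64×64, 2 px at
512), optional nodules (−50 ± 40, diameter ~8–16% of the image side,
irregular boundary), exterior air at −1000 HU, and global Gaussian noise
(sd 20 HU). All HU values are config-overridable; their ordering
(lung < nodule ≤ soft < dense) is enforced.

Corpora are organized into scans: each scan samples a base geometry once
(slices jitter ≤ 5% per axis), a nodule Bernoulli draw per slice
(default prevalence 0.17, matching the fraction of nodule-bearing slices
in typical screening chest-CT collections), and a per-scan scanner style
(intensity offset uniform in ±60 HU, occasional gantry ring and table
pad, extra noise). The per-scan style is what gives the style encoder a
real signal to learn.

Phantoms deliberately omit projection physics — no partial-volume
averaging, beam hardening or reconstruction filters — and ignore slice
spacing. Passing tests therefore demonstrate that the pipeline's
machinery behaves correctly on data with the right label-vs-HU structure;
they do not certify image quality on clinical CT, which additionally
varies in texture, artefacts and anatomy far beyond these phantoms.

## Preprocessing

Slices are harmonized by clipping to the lung window [−1350, 150] HU and
normalized affinely to [0, 1]. Splits are made at the *scan* level
(neighbouring slices of one scan are near-duplicates; slice-level splits
would leak), while the degraded-control subsets (defaults 2% and 0.3%)
are drawn uniformly at the *slice* level from the training pool, since
they represent fractions of the training material, not of the patients.
Subset sizes use round-half-away-from-zero with a floor of one item
(logged when the floor engages). DICOM reading applies rescale
slope/intercept and treats missing rescale tags as an explicit metadata
error.

## Annotation maps

Maps use six codes: exterior 0 plus the five anatomical labels — body 1,
soft tissue 2, dense tissue 3, lung area 4, nodule area 5. The exterior
code exists so one-hot conditioning covers every pixel; statements about
"five labels" exclude it.

Segmentation runs on raw HU (the display window's 150 HU ceiling would
saturate bone): body = largest 8-connected component above −500 HU with
holes filled; lung = components below −320 HU inside the body, closed
over thin bright vessels, hole-filled, and area-filtered (≥ 50 px at
512², scaled by (side/512)²); dense = above +150 HU; soft = above
−120 HU; the body label keeps the remaining fat/skin band. Priority on
overlap: nodule > lung > dense > soft > body. The soft-tissue threshold
is this package's own addition — with soft defined purely as "body
remainder" the body label could never appear in a segmented map, and the
five-label output would collapse to four. All thresholds are
config-overridable and are declared substitutes for whatever the original
segmentation used, not reconstructions of it. Nodules come from supplied
masks (manual annotation in real data, ground truth in phantoms) and are
rejected if less than half the mask overlaps lung.

Editing operations preserve anatomical plausibility: insertion rasterizes
an irregular disk (radius perturbed by seeded angular harmonics) and
keeps only parts contiguous with lung (pleura contact allowed,
free-floating islands discarded); relocation translates the component
rigidly by the integer offset moving its centroid to the target;
resizing inverse-maps the binary mask about its centroid with bilinear
interpolation and a 0.5 threshold (half-pixel boundary accuracy, which
matters for few-pixel nodules) and refuses to shrink below a 2 px
equivalent diameter.

## Evaluation

SSIM uses the literature-standard parameterization — 11×11 Gaussian
window, σ = 1.5, K₁ = 0.01, K₂ = 0.03 — on [0, 1]-normalized images
(L = 1), via scikit-image. Evaluation is *paired*: each test original
guides its own synthetic image through the encoder's posterior mean, so
the pairwise comparison SSIM presumes is meaningful. MSE and PSNR are
reported alongside as generic secondary metrics. Aggregates are
mean ± sd with normal-approximation 95% CIs, recomputable from the
per-pair rows.

The model family (primary, control 1 at 2%, control 2 at 0.3%) is
trained with identical configuration and seed discipline, differing only
in the training subset; manifests record the fractions. The SSIM
distributions of the three sets are compared by one-way ANOVA with
Tukey's HSD post hoc (scipy); reader scores are modelled by a
proportional-odds cumulative-logit ordinal regression (statsmodels), with
non-convergence or extreme effects flagged explicitly as likely complete
separation.

The quartet harness assembles blinded trials of one original plus the
three synthetic renderings of the same annotation map, permutes positions
uniformly per quartet, exports windowed 8-bit PNGs under opaque names and
keeps the unblinding key in a separate file that is only read at scoring
time. Scoring handles partial completion (a reader answering only some
quartets) and reports, per set, the percentage chosen as original and the
mean ± sd of the 1–4 scores.

## Problem sizes

The default experiment — 300 phantom slices at 64×64, training fractions
(1.0, 0.02, 0.003), 3 epochs, batch 8, 50 held-out pairs, repeated for
three seeds in the test suite and one seed in the acceptance script — is
sized so the whole study runs in minutes on a single CPU core while still
exhibiting the qualitative behaviors of interest: trained ≫ untrained
SSIM, primary ≥ control 2, strong lung/soft contrast, and near-total
nodule-removal adherence.

## Known limitations

- 2D only; no 3D synthesis or volumetric consistency.
- Desk-scale models are far below publication scale; their SSIM values
  characterize the miniature study, not clinical image quality.
- Phantom realism is structural, not textural; perceptual conclusions
  about radiologist-facing quality cannot be drawn from phantom runs.
- The SSIM of control 1 (2%) is not reliably separated from control 2
  (0.3%) at desk scale; only the robust primary-vs-control-2 comparison
  is asserted.
- Bit-exact reproducibility holds per machine/BLAS, not across platforms.
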