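# Methods

This note documents the models, parameters and numerical choices behind
`cbctrepair`, and what the synthetic phantoms do and do not establish about
clinical data.

## Thorax phantom generator

Phantoms are analytic: an elliptical body with a fat rim (outer 10% of the
body ellipse), two lung ellipses, bone discs (vertebral body, sternum, six
rib cross-sections) and a full-width couch slab whose top edge sits at a
configurable row. Intensities are exact HU levels (air −1000, lung −750,
fat −90, soft tissue +40, bone +700, couch +100), rasterised at
pixel-centre resolution with optional 1-px Gaussian edge smoothing
(default off, so every mask has an exact analytic oracle).

Cohort variability: one uniform jitter draw per structure per patient
(±3% of each size/position parameter by default), plus a smooth sinusoidal
per-slice drift of amplitude 1% emulating cranio-caudal change. These
scales were chosen once as a plausible inter-patient spread for thoracic
anatomy at this level of abstraction; the generator is deterministic per
(spec, seed).

What the phantom does **not** emulate: CT noise and beam-hardening, soft
tissue texture, true 3D cone-beam geometry (the whole pipeline is
slice-wise), scatter physics, or anatomical topology beyond gross thorax
structure. Passing tests therefore demonstrate that the pipeline's
*mechanics* (simulation geometry, training dynamics, freezing, metrics
bookkeeping) are correct and reproducible — not that the models reach
clinical image quality. The tabled SSIM/MAE values from the clinical study
are deliberately not reproduced: they require the patient data.

## Synthetic CBCT simulation

Per slice: (1) elastic deformation — per-node displacements uniform in
±`deform_max_disp` (default 15 px at 512-px scale, 4 px at 128) on a coarse
grid (spacing 64 px at 512), bilinearly upsampled and applied with edge
clamping; (2) radon transform of both the clean and distorted slice after
shifting intensities by +1024 HU so air carries ≈ 0 attenuation (projecting
negative HU would be physically meaningless); (3) entry-wise sinogram
replacement: a fraction f ~ U(0, 0.10) is drawn per image and round(f·N)
entry positions chosen uniformly without replacement are copied from the
distorted sinogram (a view-wise mode replacing whole projection rows is
available behind `entrywise=False`); (4) ramp-filtered back-projection with
linear interpolation over 180 angles in [0°, 180°) (90 at desk scale),
offset removed, values clamped to [−1024, 3071] HU; (5) isocentre rejection
sampling uniformly over the body mask (pixels > −500 HU, largest connected
component) until ≥ 5% of body pixels lie beyond the field-of-view radius,
with an explicit "cannot truncate" error after 1000 attempts; (6) circular
truncation: pixels farther than `fov_radius` from the isocentre are set to
stored intensity 0 — not −1024 HU — and the image is neither recentred nor
cropped. The normalisation layer maps stored 0 through the same affine as
real HU, so the network sees the exterior as a distinct flat level.

Numerical consequences to be aware of: the measured "replaced fraction" in
terms of *differing* sinogram entries is lower than the drawn f, because
rays that miss the deformed anatomy replace values with identical ones;
FBP round-trip error on the 128-px phantom is ≈ 38 HU interior MAE at 90
angles (the fixture tolerance is frozen at 60 HU), so even f = 0
simulations differ from the masked CT by this reconstruction floor.

## Preprocessing of paired volumes

CBCT slices are zero-padded centrally to the target grid; the CT is
registered onto the padded CBCT with a 2D rigid + isotropic-scale
(similarity) transform, correlation metric evaluated **only over the
nonzero field-of-view mask** (otherwise the padding dominates), multi-
resolution (shrink 4/2/1) regular-step gradient descent. Known rigid
perturbations up to 5° / 10 px are recovered with median error well below
0.5 px / 0.5°. Couch removal sets every row strictly below the detected
couch surface to −1024 HU; the surface is the first row below the body's
lowest extent whose above-air (> −900 HU) run spans ≥ 60% of the width,
with a configurable fallback row. "Below" means larger row index (supine,
head-first display convention). Pairing is index-aligned and refuses
volumes with differing slice thickness, since slice correspondence is
otherwise undefined. For phantom-simulated CBCT the two grids coincide by
construction, so pipeline configs may disable registration
(`{"registration": False}`); the registration path is validated separately
by the recovery tests.

## Translation model

Generator: U-Net with stride-2 4×4 convolutions, batch normalisation from
the second encoder stage, leaky-ReLU (slope 0.2) activations throughout,
and decoder stages of transposed convolution → batch norm → (dropout 0.5 in
the four innermost stages) → leaky ReLU → depth concatenation with the
mirrored encoder activation. Channel widths follow the standard doubling
capped at 8× base filters. The full-scale profile (512 px input, 64 base
filters, depth 8) flattens to exactly 61 layers; the final decoder stage
concatenates with the input image (the only full-resolution tensor) and a
3×3 convolution maps back to one channel, followed by tanh to match the
[−1, 1] intensity normalisation (a linear-output switch exists). The
desk-scale profile used in tests is 32–128 px, 2–16 filters, depth chosen
so the bottleneck stays ≥ 1 px.

Discriminator: conditional patch classifier on the channel-concatenated
(input, candidate) pair, C64–C128–C256 stride 2 then two stride-1 4×4
convolutions — a 70-px receptive field per output unit.

Losses and optimisation: non-saturating adversarial loss (binary
cross-entropy on logits) plus λ·L1 with λ = 100 in normalised units; Adam
with lr 2·10⁻⁴, β₁ 0.5, β₂ 0.999; batch size 1. Batch normalisation always
uses batch statistics (instance-style at batch 1), also at inference, which
is the behaviour of the canonical recipe; dropout is disabled at inference
so prediction is deterministic. All stochastic elements (weight
initialisation N(0, 0.02), dropout masks, data order) draw from one seeded
generator; training is bit-reproducible on fixed thread settings.

The engine is pure NumPy (im2col convolution; transposed convolution
implemented as the exact adjoint of the strided convolution, sharing the
same primitives), with correctness pinned by adjoint-identity and
finite-difference tests.

## Transfer learning

"Retraining the final two layers" is interpreted as the final two
*weight-bearing* layers in topological order — the last decoder stage's
batch normalisation and the terminal convolution — since activation,
dropout and concatenation layers carry no weights. The freeze mask is
exposed as `n_trainable_param_layers` (default 2) so stratified base-model
libraries or deeper fine-tuning remain possible. Frozen layers are
verified bit-identical (per-layer SHA-256 checksums over parameters)
before vs after transfer; the discriminator remains fully trainable during
transfer, since the adversarial signal must keep adapting. Transfer
returns a new model; the base model is never mutated.

## Evaluation

SSIM: Gaussian-windowed (11×11, σ 1.5), K1 = 0.01, K2 = 0.03, with
`data_range` fixed at 4095 (the full HU span) so values are comparable
across slices. Metrics are computed over the full padded frame including
the zero exterior — near-unity SSIM for raw partial CBCT against ground
truth is only explicable under that protocol, and the package follows it —
while masked variants can be built from the body-mask utilities. MAE is in
HU over all pixels. Volume reports aggregate per-slice values with mean and
sample standard deviation (n−1). Difference maps are ground truth minus
output, rendered on a symmetric diverging scale about 0 HU.

## Study orchestration and scale

Study A trains the streak-removal and imputation models sequentially; the
imputation model's training inputs are byte-identical to the streak model's
outputs (asserted by fingerprint). Study B trains one combined model on the
base cohort (the transfer patient is excluded by a leakage guard) and
derives patient-specific models 1 and 2 from one or two CBCT sets.
Manifests record seeds, cohort composition, per-slice SHA-256 fingerprints
and configs; train/test fingerprint sets are disjoint by construction.

Problem sizes in the shipped tests and the acceptance script are chosen for
single-CPU reproducibility: 32–128-px phantoms, 45–90 projection angles,
2–16 base filters, and trainings of 1–30 epochs (400 for the one-image
overfit check); the full-scale profile (512 px / 180 angles / 64 filters /
200- and 500-epoch schedules) is exercised structurally (architecture,
geometry, couch removal) but not trained. The patient-specific trend
experiment (3 seeds, 3 base patients + 1 transfer patient, 6 slices each at
64 px) reproduces the orderings reported for the clinical cohort — model
output beats raw partial CBCT in MAE and two transfer sets are on average
at least as good as one — without claiming the clinical values.

## Known limitations

- Slice-wise 2D simulation; no cone-beam (FDK) geometry, scatter or
  beam-hardening physics, no metal artifacts.
- Registration is 2D rigid + isotropic scale; deformable or 6-DOF motion is
  out of scope.
- At batch size 1 the bottleneck batch-norm output collapses to its bias —
  an inherited property of the recipe, harmless in practice because of the
  skip connections.
- The NumPy engine targets desk-scale reproducibility, not throughput;
  full-scale 512-px training is out of its intended envelope.
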