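# Methods

This note documents the models, conventions and numerical choices behind
`nasometry`, and what its synthetic-data experiments do and do not show.

## Coordinate model

All 3D landmark coordinates live in a face-mounted frame with its origin at
the glabella: x to the subject's right, y superior, z anterior.  The three
photographic views are modelled as orthographic projections of this frame —
the capture protocol fixes the camera-to-subject distance, so perspective
effects are absorbed into the calibration constants rather than modelled
explicitly:

* frontal image plane carries (x, y);
* lateral (right-profile) plane carries (z, y);
* mental (basal) plane carries (x, w), where w is the coordinate along the
  g→prn direction within the midsagittal plane.

The mental convention deserves a word.  A basal photograph is aimed from
below the chin, perpendicular to the glabella–pronasale line; its in-image
vertical is therefore the g→prn axis, not the raw z axis.  Under this
convention the g–prn segment appears at its true length when the head is
posed correctly, and any residual head tilt φ shortens it by exactly cos φ —
which is what makes the tilt coefficient T = d(g–prn)_mental /
d(g–prn)_lateral a direct estimate of cos φ, and is the reason the glabella
is included in the basal view's landmark set.  The two simpler alternative
plane assignments remain selectable in the aggregation policy.

Measured coordinates that no view observes are stored as NaN with a
provenance tag, never as zero.  Two optional fill-in policies exist: midline
points unseen frontally (kyphion, rhinion) may take x = 0, and the depth of
a far-side bilateral point may be mirrored from its near-side twin — exact
for a symmetric face, an approximation otherwise, and off by default.

## Measurements

Each linear measurement is a 2D Euclidean distance in one source view
(widths frontal; profile lengths lateral; nasal-base widths mental — the
assignment is configurable).  Angles are computed with atan2 on the cross
and dot products rather than arccos of the normalized dot product: the two
are identical in exact arithmetic, but the atan2 form keeps full precision
near 0° and 180°, where the straightened-dorsum check (kyphion angle → 180°
after hump removal) operates.

The nostril axis, needed for the interaxial (g9) and nostril-axis (g10)
angles, is not uniquely determined by any standard landmark definition.  The
default here is the directed line from the subalare through the soft
triangle (sbal → c′) of each side; a principal-axis fit over the four basal
landmarks {sbal, c′, cw, c} is available as an alternative.  g10 is reported
as the left/right mean with per-side values attached.  Note that g10 is
referenced to the image horizontal, so unlike every other angle it is not
invariant to rotating the photograph — it co-rotates with the frame, which
the tests assert explicitly.

Pixel-to-millimetre conversion follows the three view formulas quoted in the
README.  The scale factor D is an even polynomial in the radial distance of
the measured segment's midpoint from the optical centre — the standard
radial-distortion model; with the default distortion list [1] it reduces to
the constant α.  The tilt coefficient has two modes: the default "ratio"
mode takes the mental/lateral reference ratio itself as cos(tilt) (the
dimensionally coherent reading); a "literal" mode computes cos(ratio) with
the ratio read as radians, retained for fidelity with sources that print
that form.  Ratios marginally above 1 (float noise at zero tilt) clamp
silently; materially above 1 clamps with a warning, since a projection
cannot exceed the true length.

## Canons and bridge classification

Canon satisfaction is |lhs − t·rhs| ≤ τ·t·rhs with a relative tolerance τ
(default 5%) plus a 1e-9-relative absolute guard so that exactly-constructed
proportions register as satisfied even at τ = 0 despite binary rounding of
constants like 0.43.  Raw observed ratios are always reported so users can
apply their own criterion.  Canons 5–8 reference points outside the
23-landmark model (gnathion, supra-/sub-aurale, pupil centre); these are
accepted as optional extra annotation fields and the affected canons report
"not evaluable" when they are absent.

The bridge class is a total function of the signed perpendicular deviation
δ of the rhinion from the n–prn line, measured in the lateral plane with
anterior positive: straight for |δ| ≤ 1 mm, convex for δ > 1, concave for
−5 ≤ δ < −1, broken for δ < −5.  The boundary ties (exactly 1.0 and exactly
−5.0 mm) resolve to the milder class; both thresholds are configurable.  If
a dense dorsal profile polyline is supplied, the deviation is evaluated at
the profile point nearest the annotated rhinion.

## Detector

The landmark regressor is a six-convolution network — (32, 5×5), (32, 3×3),
(64, 3×3), (64, 3×3), (128, 3×3), (256, 3×3), all stride 1 with 'same'
padding — with batch normalization and ReLU after every convolution, 2×2/2
max pooling after conv blocks 2, 4 and 6 (VGG-style pairing), and three
fully connected layers (1024, 512, 2·K) whose linear outputs are the (u, v)
positions of the view's K landmarks normalized by the input size.  One model
is trained per view; the views share the architecture and differ only in K.
Training minimizes MSE on normalized coordinates with Adam at learning rate
0.001 (batch 32, seeded 80/20 train/validation split, no early stopping).
The output bias of the final layer is initialized to the mean training
target — a standard regression-head warm start that removes the slow
whole-scale drift Adam's step-size cap would otherwise impose, so the
optimizer spends its budget on image-dependent residuals.

Two further training-schedule options matter in short runs.  Adam's first
steps are sign-normalized (every weight moves by a full learning rate
regardless of gradient magnitude); through the ~65k-fan-in first dense
layer this coherently kicks the outputs by tens of normalized units, a
transient that vanishes in long trainings but dominates runs of a few
hundred steps.  ``zero_init_head`` (final-layer weights start at zero, so
predictions begin exactly at the warm-started bias) and ``warmup_steps``
(linear ramp of the learning rate to its target, letting the second-moment
statistics accumulate first) remove it.  A related effect sets the noise
floor late in training: Adam's per-weight steps stay near the full learning
rate whenever gradients are minibatch-noise dominated, which through the
same fan-in keeps the outputs jittering far above the attainable error.
``lr_schedule="cosine"`` anneals the rate to zero over the run so short
trainings settle.  All three options are off by default and enabled in the
package's own scaled-down experiments, where augmentation is also disabled:
its ±10° coordinate jitter is a regularizer aimed at photographic
variability, and at a few hundred steps it injects target noise an order of
magnitude above the residual scale being learned.

The network is implemented directly on numpy in NHWC layout: convolutions
are a single BLAS sgemm over an im2col patch matrix, backprop is written by
hand, and all initialization and shuffling descend from one seed, making
training bit-reproducible.  Augmentation (rotation ±10°, scale 0.9–1.1,
horizontal flip with left/right identity swap — never for the lateral view,
whose mirror would show the other body side) is applied on the preprocessed
model-space pairs.  Preprocessing removes the green studio background by
chroma threshold, converts to grayscale, and resizes aspect-preserving with
centre padding, recording the affine map so predictions return in original
pixel coordinates.

Memory note: at the reference 416×416 input the first dense layer holds
~690k×1024 weights (≈2.8 GB in float32), which is buildable but not
practical to train on a small machine; the package's own experiments run the
identical architecture at 128×128 (≈68 M parameters), where an epoch over
160 training images takes on the order of a minute on one CPU core.

## Synthetic faces

The generator starts from a 37-point 3D template (plus the four optional
canon points) with anthropometrically plausible dimensions (nasal width
34 mm, nasal height ≈45 mm, intercanthal width 34 mm, bizygomatic width
134 mm).  Per participant it adds a mirror-symmetric Gaussian shape
perturbation (sd 1.5 mm) plus a small asymmetric term (sd 0.4 mm), and
scales the nasal subset by width/height/protrusion factors drawn around 1
(sd 0.05–0.07).  The bridge deviation is drawn from N(0, 2 mm) clipped to
[−7.5, 5.5] unless overridden; the rhinion is placed at 45% of the n→prn
chord displaced by exactly that deviation, and a kyphion appears at 30% of
the chord whenever a hump is present (hump ⇔ deviation > 1 mm unless
forced).  Rendering draws a skin-coloured dilated convex hull on the green
background with dark feature polylines passing exactly through the
landmarks, plus Gaussian pixel noise (sd 2 grey levels); the mm-per-pixel
scale defaults to 0.5 at 416 px and scales inversely with the frame so the
face fills any requested resolution.  The default mental-view tilt is 0°
(the rig poses the head; nonzero tilts are exercised separately when
validating the tilt coefficient).

Ground truth is the projected landmark set itself, so measurement round
trips are exact by construction and rasterization plays no role.  What the
generator does *not* emulate: photographic texture, lighting, lens blur,
occlusion, demographic shape variation beyond independent Gaussian jitter,
and perspective foreshortening.  Detector results on these images therefore
demonstrate that the architecture, losses, augmentation and coordinate
plumbing are implemented correctly and can localize schematic features —
they say nothing about accuracy on clinical photographs.

## Experiment sizes

The test suite trains the full architecture at 128×128 on 200 synthetic
frontal images for 8 epochs (held-out NME checked against a 5% bound,
batch 32, no augmentation, zero-initialized head, 10 warmup steps with
cosine decay) and
drives a 10-image run at 64×64 for 200 epochs as an overfitting check
(2% bound; it converges well below, past the level a constant mean-landmark
predictor can reach).  These sizes were chosen as the smallest that
exercise every training-path component while keeping the whole suite
comfortably CPU-runnable; the frontal view stands for all three since the
architecture and code path are shared and only K differs.

## Known limitations

* The mental-view w-axis convention makes basal measurements exact only at
  zero head tilt; at nonzero tilt the T correction rescales the whole view
  although tilt foreshortens only the w component, so width-like basal
  measurements acquire a cos-φ-order bias.  This mirrors the global form of
  the printed conversion formulas rather than a per-axis correction.
* NME normalization defaults to the ground-truth landmark bounding box per
  view; image-dimension normalization is available and gives smaller
  percentages.  The printed (un-rooted) "literal" NME form is implemented
  for fidelity but is dimensional and not comparable across image sizes.
* The canon checker evaluates frontal-plane proportions; canon verdicts on
  strongly rotated heads would need pose normalization first.
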