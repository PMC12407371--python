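# Methods

## Problem and pipeline

Ultrasonic leaf clips measure a transmit–receive voltage amplitude
(V_TRx, mV) across a leaf blade. As the blade dries, less of the
acoustic energy is absorbed by water and V_TRx rises, so the voltage is
an inverse, non-linear proxy for relative water content,

    RWC = 100 · (m_fresh − m_dry) / (m_turgid − m_dry)   [%].

There is no universal V_TRx→RWC calibration: every leaf has its own
*characteristic curve*, acquired destructively by a stepwise
oven-drying loop (10 readings of mass and voltage, then a 24-h dry mass).
The pipeline implemented here replaces that destructive calibration for
new leaves with a generative model: a per-cultivar conditional
variational autoencoder (CVAE), conditioned on five easily measured
morphometric features — area A (cm²), perimeter P (cm), their ratio A/P
(cm), caliper thickness T (µm) and shape skewness S — generates the
10-point curve for an unseen leaf; a cubic polynomial fitted to that
curve then translates device voltages into RWC, for single "one-shot"
readings or whole time series.

## Synthetic study design

The real three-cultivar sweet-potato library (100 Honey, 50 Japanese,
50 Orange leaves) is not publicly archived, so a synthetic module
reproduces its statistical structure and serves as ground truth for
every test:

* **Features** are sampled uniformly per cultivar within ranges whose
  relative spreads (max−min)/min match the per-cultivar percentages of
  the study design (e.g. Honey: A 155%, P 91%, T 173%, S 125%); A/P is
  always recomputed from A and P, never drawn.
* **Truth curves** follow a two-endpoint power law
  V(rwc) = v_max − (v_max − v_min)(rwc/100)^γ — the simplest family
  that is strictly decreasing in RWC, non-linear, and pinned at the
  turgid (v_min) and dry (v_max) voltages. The endpoints and exponent
  are fixed affine+logistic functions of the normalized features
  (coefficients shipped as documented constants), which makes
  "recover the curve from the features" a well-posed task. γ defaults
  to the range (0.5, 1.5): it spans convex through concave shapes while
  the inverse map remains within reach of a 10-point cubic transfer
  fit (worst-case round-trip residual 1.4 RWC points at γ = 1.5,
  rising beyond 2.5 points past γ ≈ 1.8).
* **Honey bimodality**: Honey mixes two equally weighted amplitude
  groups scaling v_max by 1× (≈300 mV) and 2× (≈600 mV). Group
  membership is drawn independently of the features. A direct
  consequence: no feature-conditioned model can resolve a held-out
  Honey leaf's group, so held-out *voltage* RMSE for Honey is dominated
  by the ≈300 mV group separation; held-out *RWC* prediction is
  unaffected. This is a property of the modelled design, not of the
  learner.
* **Drying loop**: water mass decays geometrically over the 10
  iterations from the turgid amount to a per-leaf final RWC fraction
  (2–10%, a smooth function of thickness and area, so that the RWC
  grid itself is predictable from features). Masses come from a simple
  tissue model (dry matter 0.35 g cm⁻³ of blade volume, turgid water
  fraction 0.8).
* **Noise**: additive Gaussian on V_TRx (sd 3 mV) and on RWC
  (sd 1 point, clamped to [0, 100]). These defaults keep the hold-out
  RMSE targets of the design attainable while remaining realistic for
  a charge-amplified MEMS readout and a 0.1-mg balance workflow.
* **Renderer**: for morphometrics tests, leaves are rasterized as
  tapered ellipses, half-width w(u) = b√(1−u²)(1−su) along the major
  axis. The taper s is solved in closed form from the requested
  skewness (the projected density's third standardized moment is
  (s/16 − s³/32)/(1/4 − s²/16)^{3/2}), the area πab is independent of
  s, and the stored ground truth (pixel-count area, quadrature
  perimeter of the continuous outline, direct-moment skewness) is
  computed independently of the measurement code. Realizable
  |skewness| tops out near 0.385, so cultivar skewness ranges are
  capped at 0.36. The renderer does not honor a requested perimeter —
  an area and a perimeter drawn independently are generally not
  jointly realizable by one smooth blade — so perimeter accuracy is
  validated against analytic shapes (circle, square, Ramanujan
  ellipse) instead.

What the synthetic data does *not* emulate: vein/midrib structure and
multi-lobed outlines, drying-zone spatial dynamics within a blade,
sensor drift and re-attachment variability, and any correlation between
Honey's amplitude group and morphology. Passing tests therefore show
that the pipeline recovers curves *when the features determine them up
to noise*; they do not certify accuracy on real leaves.

## Morphometrics

Segmentation assumes the high-contrast leaf-on-white-paper protocol:
Otsu's global threshold (dark side by default; the "bright" policy
reflects intensities first, so a pure contrast inversion yields the
identical mask), largest connected component, hole filling. Area is the
foreground pixel count over (px/cm)². Perimeter traces the 0.5-level
marching-squares contour of a lightly smoothed mask (Gaussian, σ = 1 px)
and sums polyline segment lengths; the smoothing suppresses the
staircase bias that makes raw pixel-edge counting overestimate smooth
boundaries by up to ~27%, at the cost of slightly rounding sharp
corners (all analytic-shape errors stay within 3%). Skewness is the
third standardized moment of foreground pixels projected on the major
principal axis; the axis orientation is fixed deterministically
(positive column component) so the sign is reproducible and negates
under mirror reflection. Thickness is a pass-through caliper value.

## The CVAE

Each cultivar's master model holds two independent slave CVAEs — one
for the 10-point voltage vector, one for the 10-point RWC vector — both
conditioned on the same feature vector. Encoder and decoder are
fully connected tanh networks (default two hidden layers of 64 units);
the encoder emits the mean µ and log-variance of a diagonal Gaussian
over a 2-D latent z, and the decoder maps (z, c) back to the curve.
Curves and features are min–max normalized per column with the stats
stored in the generator. The loss is the β-ELBO with mean-squared-error
reconstruction (β = 1); KL uses the closed form for diagonal Gaussians
and is non-negative by construction. Reconstruction losses are also
reported de-normalized (mV², %²).

Training is full-batch Adam (lr 10⁻³) with inverse-time learning-rate
decay lr/(1 + 3·t/T); without the decay, late-phase Adam jitter on the
near-zero plateau produces visible upward excursions of the smoothed
loss. Epoch schedule: 20 000 (Honey) / 10 000 (Japanese, Orange) for
the full profile; the analysis scripts, tests and acceptance runs use
2 000 (noisy libraries) and 5 000 (noiseless recovery), past the loss
plateau at these library sizes — a 100-leaf library trains in a few
seconds per slave on one CPU core. Everything is seeded: weight
initialization (Glorot uniform), the per-epoch reparameterization draws
and the slave sub-seeds all derive from the config seed, so identical
inputs give identical weights and traces.

Prediction decodes z = 0 (the prior mean) in deterministic mode or
z ~ N(0, I) in sampled mode. With β = 1 on these small, feature-determined
curves the posterior collapses toward the prior and the decoder relies
on the condition — which is precisely the use case: curves for unseen
leaves from features alone. One consequence worth noting: the mean of
many sampled-mode curves differs from the deterministic curve by a
small O(σ_z²) curvature bias of the nonlinear decoder (observed
≲ 0.1% of signal), which no number of samples removes; the generative
consistency test bounds it at 0.1% of the signal on top of the
Monte-Carlo standard error.

## Transfer function and evaluation

The predicted curve is fitted with a least-squares polynomial
RWC = f(V_TRx), degree 3 by default (configurable 1–5, always below the
point count). Numerically the fit uses a scaled-domain polynomial basis
to keep the Vandermonde system well conditioned at mV magnitudes.
Outside the source curve's voltage range the polynomial is never
extrapolated: inputs clamp to the nearest range endpoint and outputs
clamp to [0, 100]; out-of-range events are logged. Non-monotone fits
are logged, never silently inverted.

Hold-out evaluation predicts deterministic curves for unseen leaves
(disjointness enforced by leaf id) and scores per-leaf V_TRx and RWC
RMSE; reports carry the minimum ("best", an optimistic summary labeled
as such) and the mean. The scaled-down study design evaluates
best-of-10/5/5 leaves for Honey/Japanese/Orange.

## Degenerate inputs and tie-breaks

Fresh masses marginally outside [dry, turgid] (balance noise) clamp RWC
to the boundary with a warning; turgid ≤ dry is an error. Curves with
mixed lengths are rejected rather than resampled. Multi-region voltage
readings are averaged before curve assembly. Duplicate voltages with
conflicting RWC trigger an ill-conditioning warning. Single-pixel masks
have undefined moments and raise. Library CSVs are written at 9
significant digits; write→read→write reproduces the text byte for byte.

## Known limitations

* Honey hold-out voltage accuracy is bounded by the feature-independent
  amplitude groups (see above); reports include it, bounds do not.
* The feature→curve maps are smooth and low-dimensional by
  construction; real leaves may carry curve variation that the five
  features do not explain, which would raise hold-out RMSE in ways the
  synthetic tests cannot probe.
* Automatic ruler detection is out of scope: the pixel scale comes from
  configuration or image metadata.
* The CVAE is a plain numpy implementation: small networks, full-batch
  training, CPU only. It is not meant for images or large latent
  spaces.
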