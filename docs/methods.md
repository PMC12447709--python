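# Methods

## Dose model

Dose is computed with the AAPM TG-43 formalism.  Each dwell position
contributes `Sk · Λ · G(r,θ)/G(r0,θ0) · g(r) · φan(r)` cGy/h at a voxel, with
the reference point at r0 = 10 mm on the transverse axis.  The default source
model is a point source with 1-D anisotropy, which is accurate at the 5–80 mm
distances a cervix implant evaluates; a line-source geometry factor with the
3.5 mm active length is available (`SourceModel(mode="line")`) and uses the
local channel tangent at each dwell as the source axis.  The embedded radial
dose function and anisotropy tables follow the published mHDR-v2 consensus
data; `g(r)` is interpolated log-linearly and clamped at the table edges.
Nominal air-kerma strength is 40,800 U (≈ 10 Ci), and dose-influence entries
are stored in Gy per second so dwell times in seconds produce Gy directly.

Matrices are dense and kept per structure (rows = retained voxels, columns =
dwell positions).  Voxels within the applicator-exclusion radius (default
2 mm, at least the 1 mm channel radius) of any channel centerline are removed
from the structure masks before matrix construction, so no evaluation point
sits inside hardware and every source–voxel distance is strictly positive.
Channel centerlines are natural cubic splines through the control points,
reparameterized by arc length and sampled at 1 mm; dwell positions sit every
5 mm of arc (the standard afterloader step).

## DVH metrics

Dx uses the order-statistic convention without interpolation: the k-th
smallest dose with k = ⌈(1 − x/100)·N⌉.  This makes exactly one voxel carry
each metric, which is what the optimizer differentiates through.  Vx is a
plain voxel count fraction.  D2cc takes the n-th highest dose with
n = round(2000 mm³ / voxel volume), minimum 1; structures smaller than 2 cm³
fall back to their minimum dose and log a warning (a deliberate, conservative
degenerate-input rule — the metric is then the whole-structure near-maximum
region anyway).  Target metrics are expressed in percent of the structure's
prescription and OAR metrics as p_s = 100·D2cc/threshold before they reach
the loss, the score or the RL state.

## Dwell-time optimization

The composite loss (intermediate-risk coverage, high-risk hot-spot control,
quadratic OAR sparing, and hard penalties `100·|D90_HR − 100| +
Σ 10·w_s·max(p_s − 100, 0)`) is minimized over `u = log d` with Adam
(learning rate 0.01, β = (0.9, 0.999)), which makes positivity structural and
conditions the problem well.  The hot-spot terms are the ratio form
`(D50/150)²`, `(D20/200)²`; a deviation form `((D50−150)/150)²` is available
behind `OptimizerConfig(hotspot_form="deviation")` for users who want the
terms to vanish at the guideline values rather than merely penalize
magnitude.  Gradients are analytic subgradients: each order-statistic metric
routes its derivative through the single voxel that realizes it, and the
absolute-value kink uses sign(0) = 0.

Initialization is uniform dwell times scaled so the mean CTV_HR dose equals
the prescription.  Early stopping uses a patience of 500 iterations with a
minimum significant improvement ΔL = 0.1 (defaults; the RL loop uses a
cheaper 800-iteration/150-patience configuration, see below).  The best
iterate is tracked and returned, so the final loss never exceeds the initial
one even though Adam steps across the penalty kink are not monotone.  The
whole procedure is deterministic for fixed inputs.

For reporting (not inside the loss loop), plans are rescaled so D90 of the
high-risk CTV is exactly 100% of prescription; dose linearity makes this a
single global factor.

## Plan score

Each scored metric has a goal, tolerance, weight and direction; scores ramp
linearly inside the tolerance window so the total score
`R = (ΣS_i + ΣBonus_s)/(Σw_i + Bonus_max) × 100` is continuous and bounded in
[0, 100].  OARs earn a bonus linear in their sparing margin below threshold,
capped at b·w.  Defaults: D90 of both CTVs target-centered at 100 ± 5 with
weight 2; V150 ≤ 50% and V200 ≤ 20% (tolerance 10, weight 1); every
p_s ≤ 100% (tolerance 10, weight 1) with bonus coefficient b = 0.2.  These
goal/tolerance/weight values are design choices exposed in `ScoreConfig`;
clinics tune them to local protocol.  The score is kept on the 0–1 fractional
scale inside the environment and reported in percent, so "reward = 100 ×
score improvement" and "R scaled 0–100" are one consistent convention.

## Environment and agent

An episode samples a patient, draws the 8 planning weights log-uniformly
within [0.01, 100] (the natural measure given multiplicative actions; a
linear-uniform draw would start nearly every episode at large weights), runs
the inner optimization, and then lets the agent take up to 5 actions:
multiply or divide one weight by 1.5, or stop.  An update that would leave
the bounds changes nothing and costs a fixed penalty of 1 reward unit.  The
first do-nothing action terminates the episode.  Rewards excluding boundary
penalties telescope to 100 × (final − initial fractional score) by
construction.

The agent is a DQN: a 2 × 128 ReLU Q-network over the 20-dimensional state
(12 scaled metrics ‖ 8 log-scaled weights), uniform replay (capacity 30,000),
batch 512, learning rate 1e-4, discount 0.99, target-network sync every 500
steps, and ε-greedy exploration decaying linearly 1.0 → 0.05 over the first
half of training.  The network, backprop and Adam are implemented directly on
numpy arrays, which keeps training single-threaded and bit-reproducible under
a fixed seed.  The full protocol is 40,000 timesteps; the package default is
a desk-scale 4,000.

## Synthetic phantoms

The generator emulates the geometry of a tandem-plus-needles cervix implant:
CTV_HR is an ellipsoid (semi-axes 12–18 mm laterally, 15–22 mm cranially)
centred on the tandem tip, CTV_IR its 4–7 mm margin expansion, the bladder an
anterior sphere, rectum a posterior tube, sigmoid a superior-posterior tube,
and the bowels superior structures; 2–4 straight needles accompany the curved
tandem.  Prescriptions are sampled within the published clinical ranges
(CTV_HR 3.23–6.20 Gy/fx, CTV_IR 2.13–4.99 Gy/fx over 5 fractions) and
per-OAR thresholds within the corresponding published per-organ ranges.  The
default grid is 2 mm isotropic, 80³ voxels (2 cc ≈ 250 voxels, enough for a
stable D2cc).

What the phantoms do **not** emulate: real contour irregularity, applicator
library shapes, inter-fraction anatomical change, and the correlation
structure between tumour size, prescriptions and prior external-beam dose.
Passing tests therefore demonstrate the correctness and behaviour of the
planning machinery under realistic geometry and magnitudes, not clinical
plan-quality statistics; clinical numbers require a real cohort ingested
through the `PatientCase` contract.

## Problem sizes

The test suite and the learning check run at a documented desk scale chosen
as a deliberate package choice for iteration speed: 2.5 mm voxels on a 64³
grid with the phantom geometry at 75% scale (a few thousand structure voxels,
~40–50 dwells), the inner optimizer at 800 iterations with patience 150, and
DQN training at 2,000 timesteps over 3 phantoms with greedy/random evaluation
over 20 episodes.  At this scale an occasional sigmoid or small-bowel section
falls below 2 cc and triggers the documented D2cc fallback.

## Known limitations

- No scatter/heterogeneity corrections (TG-186) or shielded applicators.
- Channel volume is modelled by centerline distance only; the swept cylinder
  cross-section is not rasterized.
- The D2cc subgradient moves a single voxel per iteration; plateaus between
  order statistics can slow convergence near ties.
- DICOM-RT ingestion is out of scope; `PatientCase` is the integration point.
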