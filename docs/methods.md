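# Methods

This note documents the models and procedures implemented in `cardiovae`,
the assumptions behind them, and the numerical and design choices a user
should know before trusting or extending the results.

## Synthetic biventricular anatomy

The generator (`cardiovae.synthetic_anatomy`) emulates a population of 3D
biventricular anatomies as multi-class point clouds with three substructures
— LV endocardium (label 1), LV epicardium (label 2), RV endocardium
(label 3) — at end-diastole (ED) and end-systole (ES).

**Shape model.** Each surface is a truncated prolate ellipsoid with an open
base. At scale 1 the LV endocardial long semi-axis is 62 mm with a 25 mm
short semi-axis, truncated at 30% of the long semi-axis above center, giving
an apex-to-base length near 90 mm and an ED LV cavity volume near 115 mL —
anatomically ordinary values, chosen so that errors measured in mm are
physiologically interpretable. The LV epicardium adds `wall_thickness` to
both semi-axes. The RV endocardium is a laterally offset ellipsoid clipped
to the exterior of the LV epicardial quadric, which produces the septally
attached crescent without modelling valves. The basal cut plane can tilt
(`basal_tilt`, degrees) about the anterior-posterior axis.

**Generative factors.** Six interpretable factors drive inter-subject
variability (unitless multipliers unless noted): `scale`, `elongation`
(volume-preserving axis stretch), `basal_tilt` (deg), `wall_thickness`
(mm), `rv_size`, and `ef_target` (LV ejection fraction). Controls draw
`ef_target` ~ N(0.60, 0.05), `wall_thickness` ~ N(9.0, 1.0) mm,
`scale` ~ N(1.00, 0.06); the myocardial-infarction (MI) subpopulation is
shifted toward lower ejection fraction N(0.44, 0.06), thinner walls
N(7.2, 1.0) mm and mild dilation N(1.07, 0.07), so that disease is
recoverable from shape and downstream classifiers have planted signal. All
distributions are clipped to physiologic ranges.

**ES transform.** ES surfaces contract radially toward the LV long axis
with 5% longitudinal shortening; the radial factor is solved by 1-D
bisection on the analytic truncated-ellipsoid volume so the LV cavity loses
exactly `ef_target` of its ED volume, and the ES epicardium is re-derived
under conservation of myocardial volume, which reproduces systolic wall
thickening. Parameter combinations that would make "contraction" an
expansion (ejection fraction below the longitudinal shortening) or place
the ES epicardium inside the endocardium are rejected.

**Sampling.** Surface points are drawn area-uniformly (sphere-direction
proposals accepted with probability proportional to the local area stretch
of the ellipsoid map), then filtered by the basal and septal clips; each
class receives exactly the requested count. All randomness flows through
`numpy` generators seeded per call; cohorts are exactly reproducible.

**Survival labels.** Incident-MI event times follow an exponential
proportional-hazards model with rate `baseline_hazard * exp(gamma *
risk_score)` per day and administrative right-censoring at the follow-up
horizon (default 10 years, baseline hazard 1e-4/day, gamma 1). The latent
`risk_score` is a noisy linear combination of the MI-shifted factors, so
hazard is correlated with shape. The generating coefficients are returned
alongside the labels for recovery tests. Subjects flagged as prevalent MI
(disease before imaging) carry no incident event time and are excluded
from survival analyses, mirroring the usual cohort convention.

**What the generator does not emulate.** Real cine-MRI anatomies have
regional wall-motion abnormalities, trabeculation, papillary muscles,
acquisition noise, and segmentation bias; the synthetic family is smooth
and six-dimensional by construction. Passing results therefore demonstrate
that the pipeline's machinery is correct and well-calibrated on a
controlled population — not that the learned representation transfers to
clinical data.

## Point-cloud variational autoencoder

`cardiovae.point_vae` implements the multi-class Point VAE.

**Input.** One subject enters as a (2n) x 4 tensor: the ED and ES clouds
concatenated along the point axis, with columns x, y, z (centered at the
subject's joint centroid and scaled by 1/50 inside the network) and a
label column. The label encodes phase and substructure jointly,
(class - 2) + 3 * phase, so the per-point features can separate ED from
ES points; with a class-only label the encoder would have to infer the
phase of every point from geometry alone, which measurably degrades how
well systolic function is captured in the latent space.

**Encoder.** Two PointNet-style blocks — shared per-point MLP, symmetric
max-pool, global feature concatenated back to every point — with an
additive residual connection between the blocks, followed by an MLP head
that outputs the 16-D posterior mean and log-variance. The symmetric
pooling makes the encoding exactly permutation-invariant. The standard
deviation is `exp(0.5 * logvar)`, which is positive by construction.

**Decoder.** A coarse stage maps the latent vector through an MLP to an
m x 3 x (2*3) tensor of anchor points (m = 128 by default; channels are
phase-major, class-minor: ED classes 1-3, then ES classes 1-3). A folding
stage places a 4 x 4 grid patch around every anchor and deforms it with a
shared MLP conditioned on the latent vector, the anchor position, the
patch coordinates and a channel one-hot, yielding p = 16 m dense points
per channel as anchor + learned offset.

**Loss.** `L_total = L_reconstruction + beta * L_KL` with beta = 0.2. The
KL term is the closed-form divergence of the diagonal Gaussian posterior
from N(0, I), summed over latent dimensions (so beta has a fixed meaning)
and averaged over the batch. The reconstruction term sums, over the six
(phase, class) channels, the symmetric Chamfer distance of the coarse
channel to the matching input subset plus alpha times that of the dense
channel. Chamfer terms inside the loss use squared Euclidean distances in
mm^2 (coordinates are compared at physical scale, which keeps the
reconstruction/KL balance independent of the internal normalisation);
reported evaluation distances use the plain Euclidean convention of
`shape_metrics.chamfer_distance`, comparable to a voxel size in mm. Alpha
ramps linearly from 0.1 to 1.0 over the first half of training and stays
constant after — low early weight lets the coarse stage settle the global
shape before local detail is refined.

**Training.** Adam (batch size 4) on a tape-based reverse-mode autodiff
engine written on numpy (`cardiovae.nn`; float32, gradient-checked against
finite differences in the test suite). Two stochastic estimators keep the
per-step cost compatible with CPU-only training, and both affect the
training loss only — inference and all reported evaluations use every
point exactly:

* encoder point dropout — each step feeds a random subset (default 512 of
  1024) of each class-phase block to the encoder; max-pooling makes the
  pooled features insensitive to this (measured posterior-mean shift
  ~1% of its scale);
* Chamfer mini-batching — each Chamfer direction is estimated from a
  random subset of at most 512 query points per step (an unbiased
  mini-batch of the point sums), with exact nearest neighbours over the
  full opposite set via KD-trees.

Three further optimisation choices matter at desk scale: the learning
rate (default 2e-3) decays linearly to 5% over the second half of
training; the Chamfer query subsample doubles over the last fifth of the
steps (lower gradient noise near convergence); and the weights are
Polyak-averaged (EMA, decay 0.999) over the second half, with the
averaged weights used for inference. Desk-scale defaults (600-subject
cohorts, 5,000 steps, folding width 80) train in roughly a quarter hour
on one CPU core; every size is exposed in `PointVAEConfig` for larger
budgets. Divergence (non-finite loss) aborts with the offending step
index. Checkpoints store the JSON config plus all weights in one `.npz`
archive and reload bit-identically.

**Inference-time patch refinement.** The folding stage is a continuous
parametric map of the patch coordinates, so at inference each learned
patch is sampled on an 8 x 8 grid (p = 64 m points per channel) instead
of the 4 x 4 training grid. Training is unchanged; the denser sampling
simply represents the same learned surface with more points, which
empirically improves the measured Chamfer distance of every channel (the
fold does not wiggle off-surface between training samples).

**Irreducible Chamfer floor.** Because evaluation compares two *sampled*
point sets, the expected Chamfer distance between a perfect surface
reconstruction and a 1024-point input sample is bounded away from zero by
sampling sparsity. Measured empirically with fresh resamplings of the
true surfaces, the floor for the largest surface (ED LV epicardium,
~1.7e4 mm^2) is 1.74 mm at a 2048-point reconstruction and ~1.5 mm at
8192 points. Reported reconstruction errors should be read against this
floor, not against zero.

## Shape metrics

* **Chamfer distance** — symmetric mean nearest-neighbour distance,
  0.5 * (mean_{P1} min_{P2} d + mean_{P2} min_{P1} d), exact KD-tree
  search (approximate search is deliberately not used); `squared=True`
  gives the loss convention.
* **Cavity volume** — an open-base surface cloud is closed by a
  star-shaped triangulation about its centroid (the convex hull of unit
  directions), which spans the basal opening with its chordal cap; the
  enclosed volume is the sum of radial tetrahedra. The centroid of any
  cloud lying on a convex shell is a valid star center, which covers the
  clipped RV crescent. Validated against analytic spheres, scaling laws
  and rigid motions; the estimator is a declared convention, since no
  canonical cloud-to-volume rule exists.
* **LV mass** — (epicardial volume - endocardial volume) x 1.05 g/mL,
  the standard myocardial density.
* **Gaussian-kernel MMD** — biased V-statistic, so identical populations
  score exactly zero; bandwidth defaults to the median pairwise distance
  of the pooled sample (median heuristic), overridable.

## Latent tools

Component traversal holds all latent components at the dataset's mean
posterior value and sweeps one component by +-2 SD of its posterior means
(the SD-multiple convention is a default, not a claim). The per-component
effect size is the Euclidean Chamfer distance between the -2 SD and +2 SD
decodes, averaged over the six channels.

Virtual populations sample the latent space and decode. The default draws
z from a Gaussian moment-matched to a reference dataset's aggregate
posterior (mean and covariance of the posterior means plus the mean
posterior variance); pure prior sampling z ~ N(0, I) remains available.
The reason for this default is empirical: at desk-scale training budgets
the aggregate posterior is much narrower than the prior (the KL term has
not yet pulled them together), so prior samples land in latent regions
the decoder never saw and decode to collapsed shapes, while
aggregate-posterior samples reproduce the training population's clinical
metrics to within a few percent. At large training budgets the two
distributions converge and the distinction disappears.

## MI prediction and survival

Classification uses balanced (equal-count, seeded) control/MI subsets,
standardised features, weak-L2 logistic regression and stratified 10-fold
cross-validation; accuracy, AUROC, F1, precision and recall are averaged
unweighted across folds. Clinical baselines are logistic models on LV EF,
RV EF, or both, with ejection fractions computed from the clouds by the
cavity-volume estimator.

The Cox proportional-hazards model maximises the Breslow partial
likelihood by Newton iterations with step halving to a gradient norm below
1e-8; rank deficiency, separation and non-convergence raise errors with
diagnostics. Harrell's concordance uses the strict indicator definition —
usable pairs are (i, j) with an observed event for i and t_i < t_j, the
numerator counts risk_i > risk_j, and risk ties score zero; the common
ties = 0.5 convention is an explicit option, never a silent default.
Survival times are in days with imaging at t = 0.

## Electrophysiology pipeline

**Surface reconstruction** projects a substructure's points onto unit
directions about their centroid, triangulates via the convex hull of
directions, and prunes triangles whose longest edge exceeds 2.5x the
median, which re-opens the basal cut. This star-shaped method is exact for
the surfaces this package produces (all are subsets of convex shells); an
alpha-complex boundary is available as a fallback for clouds that violate
that assumption. The RV epicardium — unresolvable at cine-MRI resolution —
is the RV endocardium offset 3 mm along per-vertex normals (with a
normal-smoothing retry if the offset folds any triangle).

**Assembly** closes each surface by the same star closure with vertices
beyond the basal plane projected onto it (flat basal cap). The outer shell
is the union of the LV and RV epicardial solids (each surface's vertices
kept where not inside the other, re-closed about the joint centroid); the
LV cavity is the closed endocardium; the RV cavity closes the RV
endocardium together with the facing septal patch of the LV epicardium, so
the septum is not carved out of the myocardium. The result is three closed
genus-0 shells (Euler characteristic 6, zero boundary edges); the solid
myocardium is inside the outer shell and outside both cavities. Membership
tests are exact ray casts against the star-shaped shells (Moller-Trumbore
against KD-tree candidate faces).

**Tetrahedralization** fills the myocardium with a jittered cubic lattice
at the target edge length (desk default 3 mm; 1.5 mm available), adds all
shell vertices, takes the scipy Delaunay complex, and keeps tetrahedra
whose centroid is myocardial, then the largest connected component. This
replaces a named frontal-Delaunay/TetGen toolchain with an equivalent
contract: conforming positive-volume tetrahedra, median edge within
[0.5, 2]x the target, boundary within one target edge of the input
surfaces. Nodes are tagged lv_endo / rv_endo / epi / base by shell
provenance and basal-plane proximity. The apex-base coordinate is the
normalized long-axis fraction; the transmural coordinate is the
endo-to-epi distance ratio d_endo / (d_endo + d_epi) — a cheaper, robust
alternative to a harmonic (Laplace) interpolation that agrees with it to
within a few percent on wall-like geometries.

**Fibers** follow the standard rule-based helix: the sheet (transmural)
direction is the per-element gradient of the transmural coordinate, and
the fiber lies in the wall plane at a helix angle varying linearly from
+60 deg at the endocardium to -60 deg at the epicardium; the frame is
orthonormal to 1e-6 by construction.

**Eikonal activation** uses conduction velocities 0.67 / 0.30 / 0.17 m/s
along the fiber / transmural / normal directions with a 1.20 m/s fast
endocardial layer, and seven root nodes (LV mid-septum, LV basal anterior
paraseptal, two LV mid-posterior; RV mid-septum, two RV free-wall),
selected as the endocardial nodes nearest rule-based anatomical targets;
all onsets are 0 ms (the onset pattern is configurable). Each element's
anisotropic metric is mapped to an isotropic one by a linear transform, so
local updates reduce to the classical face solution (closed-form
characteristic through the opposite face, with edge and vertex fallbacks);
Jacobi-style sweeps with scatter-min iterate to convergence (tolerance
1e-7 ms). The fast endocardial layer is realised as 1-D shortcut
relaxations along endocardial surface edges at the endocardial velocity —
a declared convention, since the interaction of the fast layer with 3-D
anisotropy is not uniquely defined. Accuracy on an isotropic slab is ~1.5%
mean against d/v beyond the near-source zone; an independent graph
shortest-path oracle (mesh edges, optionally second-ring chords to reduce
direction quantisation) is used for cross-checks only. Disconnected
components keep infinite activation times and are reported, not hidden.

**Pseudo-ECG.** The activation-to-ECG map is not uniquely determined by an
Eikonal solution; this package uses the standard dipole-density integral
phi_e(t) = sum_elements grad(Vm) . grad(1/r) * V_element with a fixed
sigmoidal transmembrane upstroke of ~1 ms rise time centered at each
node's activation time, electrodes at deterministic torso-scale offsets
around the heart (RA, LA, LL, V1-V6 in an anteriorly ordered precordial
arc), limb leads I = LA-RA and II = LL-RA, and V1-V6 referenced to the
Wilson central terminal. Amplitudes are arbitrary normalized units; only
the time structure (QRS morphology and duration) is asserted in tests.
The trace spans [min activation - 5 ms, max activation + 20 ms] at a 1 ms
default step. Population comparisons resample all traces onto a common
onset-aligned grid and compute per-lead Gaussian-kernel MMD, alongside the
gold-standard score from a seeded half-split of the reference population.

## Problem sizes used in the shipped tests

Unit and property tests run on 40-120 subject cohorts with 256 points per
class and briefly trained models; the acceptance suite trains once at the
full desk scale (600 subjects, 1024 points per class per phase, 5,000
steps) and shares that model across the reconstruction, classification and
population-realism checks; electrophysiology tests use ~1e4-tetrahedron
meshes (3.5-4.5 mm edges for heart meshes, 1.5-2.5 mm slabs). These sizes
are the package's own desk-scale study conditions; every one of them is a
config argument, and the 1.5 mm element size and 300k-step training budget
of a full-scale study remain available through the same interfaces.

## Known limitations

* The synthetic family is smooth and low-dimensional; none of the results
  here certify performance on clinical reconstructions.
* The cavity-volume estimator is validated against analytic shapes only;
  its absolute accuracy on strongly non-star-shaped clouds is not
  characterised (the RV crescent it is used on is star-shaped from its
  centroid by construction).
* Single beat, depolarization only: no repolarization/T-wave, no
  pathology-specific conduction changes, fixed root nodes and velocities.
* The torso is a fixed synthetic electrode layout, not an image-derived
  torso model; ECG amplitudes are therefore only meaningful relative to
  each other.
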