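# Methods

This note documents the models, parameters and numerical choices behind
`cuffsim`, and what its synthetic benchmark does and does not show about
real nerve-cuff recordings.

## Volume-conductor model

Tissue voltages obey the quasi-static Poisson equation ∇·(σ∇V) = −I with
purely resistive, frequency-independent conductivities and an insulating
outer boundary.  Materials and defaults (S/m):

| material | σ | notes |
|---|---|---|
| endoneurium (longitudinal) | 0.5710 | along the nerve axis |
| endoneurium (transverse) | 0.0826 | in-plane |
| perineurium | 0.0021 | thin resistive sheath per fascicle |
| epineurium | 0.0826 | isotropic |
| saline | 2 | 11 mm cylinder around nerve + cuff |
| cuff | 1 × 10⁻⁷ | effectively a perfect insulator |

Endoneurium is the only anisotropic material; its tensor is diagonal with
the longitudinal value along z.  Capacitive effects, frequency dependence
and electrode–electrolyte interface impedance are out of scope.

**Discretization.** The volume is a voxel grid built by extruding the 2-D
cross-section: one potential unknown per conducting voxel, 7-point
finite-volume stencil, face conductances from the harmonic mean of the
adjoining voxel conductivities.  This is the lowest-order finite-element
equivalent of the same PDE; a tetrahedral mesh is an implementation
vehicle, not part of the model's contract.  The default in-plane pitch for
solver grids is 0.15 mm with 0.75 mm axially over a 24 mm extent
(≥ the 20 mm cuff); the cross-section renderer guarantees every
perineurium sheath is at least one voxel thick, and extrusion rejects any
slice where the sheath ring is broken.  At 0.15 mm the rendered sheath is
thicker than the anatomical ~3%-of-diameter value; this exaggerates
inter-fascicle shielding somewhat and is the main fidelity cost of the
coarse desk grid.

**Insulator cutoff.** Voxels whose conductivity is below 10⁻⁶ S/m (the
cuff, and everything outside the saline cylinder) carry no unknown and
are treated as perfect insulators.  The alternative — keeping 10⁻⁷ S/m
cuff voxels in the system — adds a ~10⁷ conductance contrast that stalls
conjugate gradients while changing the solution by less than one part in
10⁶.  The cuff's corners protrude slightly beyond the 11 mm saline
cylinder; the cylinder truncates them, which is electrically
indistinguishable from cuff insulation.

**Solver.** Jacobi-preconditioned conjugate gradients on the SPD system;
default relative tolerance 10⁻⁸ (10⁻⁶ in the desk profile, which leaves
leadfield entries accurate to far better than the noise floor of any
simulated recording).  The gauge is fixed by pinning one boundary saline
voxel during the solve and re-zeroing the mean over boundary saline
nodes afterwards; any fixed gauge is acceptable because the tripolar
montage removes constants.

**Leadfield.** For each contact (versus a fixed reference contact, by
default contact 0) a balanced unit source/sink pair is injected and
solved once; by reciprocity, the axial derivative ∂φ/∂z of that solution
at a source voxel is the channel's sensitivity to a unit axial dipole
(V per A·mm) there.  Source degrees of freedom are *all* endoneurium
voxels at all interior axial slabs; dipoles are restricted to the axial
direction, matching the dominant current flow of a propagating action
potential.  M = 56 channels therefore cost 55 solves.  Contacts are
points snapped to the nearest conducting voxel on the cuff's inner face.
The choice of reference pair does not matter: the tripolar montage
(subtracting the mean of the two outer contact rings) maps all
consistent references to the same result, and it commutes with
`D = L·J` because both are linear row operations.

## Synthetic cross-section

The generator emulates an oblong human median-nerve slice held in a FINE:
an elliptical epineurium (default semi-axes 4.5 × 2.0 mm) containing 17
quasi-elliptical fascicles (semi-axis range 0.15–0.45 mm, aspect
0.65–1.0, random orientation), each wrapped in a perineurium annulus of
thickness 3% of its equivalent diameter (at least one pixel).

Seventeen fascicles with a ≥ 1 mm centroid separation floor inside this
oblong sit close to the hexagonal packing limit, so independent rejection
sampling of centroids essentially never succeeds.  Centroids are instead
drawn from a jittered hexagonal lattice whose spacing and jitter bound
guarantee the separation floor by construction; per-site radii are capped
by the distance to the epineurium boundary and to neighboring sites so
endoneurium plus sheath never collide.  Everything is driven by one seed
and is bit-reproducible.

The rendered grayscale image (bright fascicles on a darker
connective-tissue background) feeds the same Otsu-threshold segmentation
pipeline that a histology image would, so the mask pipeline is exercised
end to end.  What the synthetic slice does *not* emulate: irregular
fascicle shapes, stain gradients and imaging artifacts, blood vessels
(beyond the minimum-area filter they motivate, default 0.01 mm²), and
FINE-induced nerve reshaping — the cross-section is kept undeformed.

## nCAP simulation

* **Waveform bank** — 1000 templates × 100 samples at 30 kHz.  The base
  shape is a biphasic difference of Gaussians (depolarization lobe
  σ = 0.10 ms; repolarization lobe σ = 0.25 ms, delayed 0.25 ms, relative
  amplitude 0.55), peak-normalized, with seeded amplitude jitter
  Uniform(0.9, 1.1) and time-offset jitter Uniform(−3, +3) samples applied
  by linear interpolation.  The shape is pluggable; no claim is made that
  it matches any specific fiber population, only the morphology of an
  extracellular nCAP.
* **Propagation** — one event per recording (overlapping nCAPs are out of
  scope).  The event's source chain occupies its cross-section node at
  every axial slab, thinned to a node-of-Ranvier spacing of 1.0 mm (large
  myelinated fiber convention; the desk grid's 0.75 mm slab spacing gives
  an effective 0.75 mm).  Each node's row is the template delayed by
  z / v · fs samples (v = 60 m/s), quantized with floor(x + 0.5) so that
  a travel time of exactly one sample per node stays exactly one sample
  (round-half-to-even would alternate).  The onset is aligned so the peak
  passes the cuff center at sample 50.
* **Noise** — i.i.d. Gaussian per channel and sample with
  std = n × max|noiseless D| (n ∈ {0.05, 0.10, 0.15}).  A variance-based
  reading (var = n × max|D|) is selectable via `noise_mode="variance"`;
  the amplitude reading is the default because the noise level is
  described as a percentage of signal amplitude in the in vivo
  calibration it mimics.  Noise is injected after the tripolar montage
  (per referenced channel).
* **Normalization** — division by the global maximum absolute value, so
  classifiers see relative spatiotemporal patterns, never absolute
  voltages.

## Signatures

SE and TE are the same 56 × 100 voltage image under two fixed row
orders: SE groups the 8 contacts of each layer (edge A positions 1–4,
then edge B), layer 1 through 7; TE groups the 7 layers of each axial
contact column (edge A columns first).  The canonical channel order is
`layer·8 + edge·4 + position`; the two permutation tables derived from
the electrode layout are the ordering contract between dataset generation
and classification — any fixed consistent order would do, and the order
used here may differ from other implementations' row order.

## Classifiers

All backbones share the two-stream arrangement: one feature extractor per
signature type, features concatenated into a dense softmax head.

* `escape` — per stream: conv 5×5 (64·w filters) → maxpool 2×2 →
  conv 3×3 (128·w) → maxpool 2×2 → dense (1024·w) with dropout 0.5 after
  the dense layer and before the head.  At w = 1 the parameter count is
  ≈ 92 M, dominated by the dense layer.
* `residual` — conv stem, 1×1 widening, identity-skip blocks
  (two 3×3 convs each), global average pooling; ≈ 19 M at full width.
* `mobile` — inverted bottlenecks (1×1 expand ×6 → depthwise 3×3 → 1×1
  project) with skip-adds wherever input and output widths match;
  ≈ 0.5 M at full width.  The ranking escape > residual > mobile mirrors
  the complexity ordering of the corresponding published families.

The layer dimensions themselves are this package's own design (the
benchmark protocol fixes the training recipe, not the layer sizes).
Training uses SGD with learning rate 10⁻³, learning-rate decay 10⁻⁶ per
update (Keras-legacy convention `lr/(1+decay·t)`; a separate weight-decay
field exists and defaults to 0), momentum 10⁻⁹ — reproduced as stated,
i.e. effectively zero — batch 128, a stratified seeded 20% validation
split, early stopping on validation loss with patience 15 epochs
(`escape`) or 40 (`residual`, `mobile`), restoring best-validation
weights.  Layers are NumPy with numba kernels for the convolutions and
pooling; gradients are verified against finite differences (note that at
exact ReLU kinks — zero-initialized biases meeting exactly-zero
activations — the analytic subgradient and a finite difference
legitimately differ, so the checks nudge parameters off the kink first).

## Evaluation design

12 conditions (classes 3/5/7/10 × noise 5/10/15%), each repeated with a
fresh uniform fascicle selection and fresh dataset seeds; every dataset
is exactly class-balanced (per-class count = ⌊size/c⌋, remainder
dropped); stratified threefold cross-validation; accuracy is the sole
headline metric.  Per-condition results are reported as mean ± SD of the
per-repetition fold means, SD across repetitions.  The two-way
fixed-effects ANOVA (classes × noise, with interaction) uses one value
per repetition; the full design gives the interaction test F(6, 108).
The fascicle-distance analysis pairs each repetition's mean pairwise
selected-centroid distance with its mean accuracy (Pearson r; a
zero-variance input is reported as explicitly undefined rather than
NaN).  Run seeds derive from the master seed through `SeedSequence`
spawn keys, collision-free and below 2³¹.

### Desk profile

The published-scale design (30,000-sample datasets, 10 repetitions,
full-width networks) is impractical on one CPU, so the default `desk`
profile keeps every protocol *ratio* intact and shrinks sizes: 6,000
samples per dataset, 3 repetitions, width multiplier 1/16, batch size 48
with at most 12 training epochs, solver grid 0.15 mm/0.75 mm at
tolerance 10⁻⁶.  The smaller desk batch matters: with the stated
learning rate of 10⁻³ and effectively zero momentum, convergence is
governed by the number of SGD updates, and a 4,000-sample training fold
at batch 128 provides too few of them within a single-CPU epoch budget —
batch 48 triples the update count at identical FLOPs.  The
early-stopping patience (15) rarely binds inside 12 epochs.  The `full`
profile restores the benchmark numbers (30,000 samples, 10 repetitions,
full width, batch 128, 50-epoch ceiling) for anyone with the compute.

What desk-scale passing results show: the geometry → leadfield →
signature → CNN chain is internally consistent, the easiest condition
(3 classes, 5% noise, well-separated fascicles) is nearly perfectly
classifiable, and accuracy degrades with noise.  What they do not show:
absolute accuracies for real cadaveric geometry, the behavior of
full-width networks (e.g. overfitting instabilities of very large
backbones), or robustness to structured noise (EMG, movement artifacts),
none of which the white-noise model emulates.

## Numerical details and edge cases

* All simulation randomness flows through `numpy.random.Generator` seeded
  explicitly; datasets, banks and training are bit-reproducible per seed.
* Degenerate inputs fail loudly: single-intensity images ("no threshold
  found"), zero fascicles after filtering, infeasible packings,
  unbalanced current injections, all-zero recordings, single-class
  training labels, sub-voxel perineurium.
* Max-pooling resolves ties to the first maximum; pooling crops odd
  trailing rows/columns.
* Recordings are stored float32; solver and leadfield arithmetic is
  float64.
* `F1` scores are deliberately not reported: with exactly balanced
  classes they add nothing over accuracy.
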