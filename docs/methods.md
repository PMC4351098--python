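# Methods

`ortrack` reimplements, at desk scale on synthetic phantoms, a complete
optic-radiation (OR) tractography analysis: multi-tensor DWI simulation,
fiber-orientation estimation by constrained spherical deconvolution (CSD)
and by a ball-and-stick (B&S) posterior sampler, probabilistic streamline
tractography under atlas-style mask logic, streamline-density images, and a
voxel-wise ROC / landmark-distance evaluation comparing the two models.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Coordinates and conventions

All world coordinates are NIfTI-style RAS+ millimetres; +y is anterior, so
"N mm posterior to the temporal pole (TP)" means world-y = TP_y − N. Voxel
indices are 0-based, and voxel (i, j, k) is centred at `affine @ (i, j, k, 1)`.
Streamlines and landmarks are stored in world mm.

## The phantom

No public data exist for the original clinical analysis (patient DWI and
the population atlas registrations are not distributed), so the package
generates its own ground truth. The phantom emulates the anatomy that makes
the OR hard to track:

* a **bent fan**: a bundle of cubic-spline tubes from a thalamic seed
  region (LGN analogue) running anteriorly into a sharp hairpin
  (Meyer's-loop analogue; total turning ≈ 180°) and fanning posteriorly to
  a cortical target (V1 analogue);
* an optional **crossing tract**, a straight left-right tube through the
  fan body, giving voxels with two fiber populations;
* an **atlas surrogate**: the binary tract mask blurred with a Gaussian
  (σ = 1 voxel) and max-normalized to [0, 1], standing in for a
  probabilistic population atlas; thresholding it at probability > 0.1
  yields the gold-standard mask;
* recorded **landmarks**: TP, occipital pole (OP) and the centerline loop
  apex. The default layout puts the apex 27 mm posterior to the TP
  (the classic dissection estimate of the Meyer's-loop-to-TP distance)
  with a TP-OP span of ~119 mm, on a 40×50×20 grid at 2.5 mm isotropic
  voxels (the clinical voxel size, reduced field of view). All geometric
  defaults are artifact choices, chosen once; they are configurable
  (`PhantomConfig`) but not calibrated to any dataset.

Tissue parameters: fiber compartments are axially symmetric tensors with
eigenvalues (1.7, 0.3, 0.3)×10⁻³ mm²/s; free water has an isotropic
diffusivity of 3.0×10⁻³ mm²/s; the anisotropic volume fraction inside the
tract is 0.8 (split 0.4/0.4 in crossing voxels). These are standard
white-matter/CSF literature values.

### Signal simulation

Per voxel the noiseless signal is the multi-tensor forward model

    S(g, b) = S0 [ f_iso e^(−b d_iso) + Σ_k f_k e^(−b gᵀ D_k g) ]

and Rician noise is applied as |S + ε₁ + i ε₂| with ε ~ N(0, σ²),
σ = S0/SNR referenced to the b = 0 signal (default SNR 30). The default
acquisition is 30 unique gradient directions at b = 3000 s/mm² plus one
b = 0 volume, matching a clinically practical high-b protocol. Directions
are generated by antipodally symmetrized electrostatic-repulsion descent
from a seeded random start; for 30 directions the minimum pairwise angle
exceeds 25°.

What the generator does **not** emulate: EPI artifacts (eddy currents,
susceptibility distortion, motion), partial-volume T2 effects, anatomy
beyond the tract system, and inter-subject anatomical variability —
pipeline "subjects" are independent noise realizations of one geometry.
Passing tests therefore demonstrate correctness of the algorithms under
controlled conditions, not robustness to real-scanner artifacts or to
registration error.

## Tensor fitting

Weighted linear least squares on the log-signal: an OLS pass followed by
two reweighting passes with weights equal to the squared predicted signal.
Intensities ≤ 0 (possible only under extreme noise) are floored to the
smallest positive intensity in the voxel's series before the log. Negative
fitted eigenvalues are clamped to zero before the FA formula, so FA ∈ [0, 1]
always. On noiseless single-tensor voxels the fit recovers the tensor to
machine precision.

## CSD

The DW signal is modelled as the spherical convolution of an axially
symmetric single-fiber response with the FOD. In the real symmetric
even-order spherical-harmonic basis (orthonormal; coefficients ordered by
ascending l, m from −l to +l) the convolution is diagonal:
`s_lm = sqrt(4π/(2l+1)) r_l f_lm`. Defaults: lmax = 6 (28 coefficients),
signals normalized by the voxel's mean b = 0 intensity.

**Response estimation**: voxels with FA > 0.7 are reoriented so the
principal eigenvector maps to +z (each signal is re-fit at the rotated
gradient directions), and the m = 0 coefficients are averaged. Reconvolving
the response with a delta at +z reproduces the mean aligned signal to
within 2% RMS.

**Constraint**: after an (ridge-stabilized) unconstrained deconvolution,
amplitudes on a 300-direction Fibonacci grid below τ = 0.1 × mean initial
amplitude are penalized with weight λ = 1 and the normal equations
re-solved until the constrained set stabilizes (cap 50 iterations). A
single soft set at λ = 1 leaves residual ringing lobes of −12…−16% of the
mean amplitude regardless of λ (raising λ collapses the solution, because
the penalty Gram is full rank, and merges crossing peaks), so a second,
heavier penalty (λ_neg = 3) is applied to directions whose amplitude is
strictly negative. With the two-tier constraint the worst negative lobe
over 20 noise realizations is −5% of the mean amplitude, delta recovery is
0.01°, and a 90° crossing at SNR 30 is resolved in 12/12 realizations.

A note on angular resolution: a 45° crossing lies below the resolution of
the lmax = 6 basis at any b-value; the property test showing better
crossing resolution at b = 3000 than b = 1000 uses lmax = 8 (14/24 vs 2/24
realizations resolved). The pipeline default remains lmax = 6.

## Ball-and-stick

The multi-compartment model

    S = S0 [ (1 − Σ_k f_k) e^(−b d) + Σ_k f_k e^(−b d (gᵀv_k)²) ]

is sampled by blockwise Metropolis-Hastings under a Gaussian noise
likelihood, all masked voxels in parallel. Parameter blocks per sweep: S0,
d, each f_k, each orientation v_k (tangent-space Gaussian perturbation,
renormalized), and a conjugate inverse-gamma Gibbs update of the noise
variance (Jeffreys prior). Priors: d uniform on (0, 0.01] mm²/s, fractions
uniform on the simplex Σf_k ≤ 1, orientations uniform on the sphere.
Proposal scales adapt per voxel and block during burn-in toward a 0.3–0.5
acceptance rate. Chains are initialized from the tensor fit.

Sampling S0 matters: with S0 fixed at the measured b = 0 mean, its ~3%
measurement error (one b = 0 volume at SNR 30) propagates into f as a
per-dataset offset the posterior cannot see, and 90% credible intervals
cover the truth in only ~62% of repeats; with S0 sampled, coverage is 82%
and the posterior width matches the frequentist spread. The sampler was
cross-checked against a brute-force importance-sampled exact posterior on
a single-voxel dataset.

Schedules: the library default is the conventional 1000 burn-in / 50 kept
samples at thinning 25. The pipeline configuration uses a shorter
desk-scale schedule (300 burn-in, 50 kept, thinning 5) chosen so a full
five-subject, two-model experiment completes in minutes; recovery and
acceptance rates are indistinguishable between the two schedules on the
phantom. Known limitation: the Gaussian likelihood ignores the Rician
noise floor, which biases f slightly downward when the perpendicular
stick signal approaches zero (b·d ≳ 5).

## Tracking

Fixed-step Euler integration (0.2 mm, far below the voxel size), grown
bidirectionally from uniformly jittered intra-voxel seed positions, 100
streamlines per seed voxel in the desk-scale configuration (5000 in the
protocol-faithful configuration). The 0.3 mm radius-of-curvature cutoff is
enforced as a per-step cone via the arc-chord relation
θ_max = 2 arcsin(step/(2R)) ≈ 38.9°. The first step of each half follows
the sampled seed direction exactly so the two halves join without a kink;
every subsequent turn is bounded by the cone.

Per-step direction sampling: for CSD, the FOD (trilinearly interpolated SH
coefficients) is evaluated on a fixed 500-direction sphere restricted to
the curvature cone, amplitudes below the cutoff (0.1, with b0-normalized
signals) are zeroed, and a direction is drawn with probability
proportional to amplitude — the exact distribution that rejection sampling
of the discretized FOD targets; if no admissible direction remains the
streamline terminates. For B&S, one posterior sample is drawn at the
nearest voxel and the stick nearest the incoming direction among sticks
with posterior-mean fraction ≥ 0.05 is followed, or the streamline
terminates if it falls outside the cone. Streamlines also terminate on
leaving the FA > 0.1 inclusion mask, leaving the grid, or exceeding 200 mm.

Mask logic: retained streamlines must visit the waypoint (OR-mask voxels
on the coronal slice 60 mm posterior to the TP) and the target, and never
the exclusion plane (full ipsilateral coronal plane 20 mm posterior to the
TP); they are truncated at the midline sagittal termination plane. The
streamline-density image (SDI) counts the fraction of retained streamlines
visiting each voxel, each streamline contributing at most once per voxel.

## Evaluation

With gold mask G (atlas surrogate > 0.1) and search volume S (inclusion ∪
G; the original analysis is ambiguous between the inclusion mask and a
tract-union search volume, so the search mask is an explicit argument),
TPR(t) = |{SDI > t} ∩ G|/|G| and FPR(t) = |{SDI > t} ∩ (S∖G)|/|S∖G| are
swept over all distinct SDI values; TPR is interpolated linearly onto 1000
equally spaced FPR points anchored at (0,0) and (1,1); AUC is the
trapezoid area and Youden's J = max(TPR − FPR) over swept thresholds. The
AUC equals brute-force pairwise concordance to 0.01 on all small
instances. Per-subject SDI thresholds are set at FPR ≤ 2.1% (lowest such
distinct value) and the cross-subject median per model binarizes every
SDI; volumes are voxel counts × voxel volume.

Landmarks: the anterior tip of the loop (MLA) is read automatically as the
centroid of tract voxels on the most anterior occupied coronal slice — a
proxy for expert identification; MLA-TP, MLA-OP and TP-OP are
anterior-posterior (|Δy|) distances, the axis along which dissection
studies report them. The anterior-tip *error* compares the MLA of the
final tract with the MLA of the ground-truth mask read by the same rule
(comparing a tract-surface reading against the centerline apex would
penalize a model by the tube radius for reconstructing the full loop).

Paired statistics: two-sided Wilcoxon signed-rank (zero differences
dropped, average ranks for ties; exact null by full enumeration for
n ≤ 15, normal approximation with tie correction beyond) and paired
t-tests. The exact signed-rank p matches enumeration of all 2ⁿ sign
assignments.

**Direction subsampling**: energy-minimal subsets of the gradient scheme
(greedy electrostatic removal) re-run the CSD pipeline; the subsampled
final tract is scored against the full-data final tract (sensitivity,
specificity, Dice, and FPR at the full-data threshold).

## Problem sizes and reproducibility

The default experiment (40×50×20 grid, ~23 seed voxels, 100
streamlines/seed, five noise realizations, both models) runs in about six
minutes on one CPU core; the test suite uses a further-reduced 24×40×12
phantom for end-to-end tests. Every stochastic stage derives its seed from
the global seed as `(seed × 1_000_003 + stage_code) mod 2³¹`, so stages
can be re-run in isolation bit-reproducibly.

## Known limitations

* The evaluation's false-positive rates on the phantom are far lower than
  in clinical data (the background contains no adjacent tracts to leak
  into), so the 2.1%-FPR threshold typically resolves to a very small SDI
  value; the mechanism is exercised, but its numerical value is not
  comparable to the clinical setting.
* Affine registration is resampling-only; estimating the affine is out of
  scope.
* The B&S likelihood is Gaussian, not Rician (see above).
* The MLA reading is a fixed geometric rule; inter-rater variability of
  expert readings is not modelled.
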