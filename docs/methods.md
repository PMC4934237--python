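# Methods

## Kinematic model and conventions

The hand state is a vector of 19 joint angles in degrees: thumb abduction
(TA), rotation (TR) and metacarpal flexion (TM), and for each finger F ∈
{I, M, R, L} the abduction (FA), metacarpal-phalangeal flexion (FM),
proximal interphalangeal flexion (FP) and distal interphalangeal flexion
(FD). The canonical serialization order is the thumb block followed by the
per-finger (A, M, P, D) blocks; any consistent order is mathematically
equivalent, this one is fixed for deterministic file formats. Flexion and
abduction are positive; no anatomical range limits are imposed, and raw
minimum-variance estimates are reported unclamped.

Distal flexions are not independent DOFs: they follow the proximal joints
through θ_D = (2/3)·θ_P, a standard interphalangeal coupling, leaving 15
free DOFs. The thumb carries no derived distal joint. Coupling consistency
is a checkable predicate, not an enforced constraint, because an estimator
fusing arbitrary measurements need not return exactly coupled values at
unmeasured joints.

## Synergy prior

Grasp postures concentrate along a few inter-joint covariation directions
(postural synergies). The prior is the Gaussian summary of a pose ensemble
X (19 × N): μ_o the row means, P_o the sample covariance with denominator
N − 1 (taken literally from the defining formula; no shrinkage). The
covariance is symmetrized as (P + Pᵀ)/2 to kill round-off asymmetry before
eigen/solve routines. Because ensembles are built with distal joints already
coupled, P_o has rank ≤ 15; this is deliberate and the estimator must (and
does) tolerate it. Estimation is performed over the full 19 DOFs after
coupling, not over 15 DOFs and lifted — the construction order implied by
how the coupled model is assembled.

## Minimum-variance estimation

Given y = Hx + ν with canonical-row H and noise covariance R, the posterior
under the prior N(μ_o, P_o) is computed in the innovation form

x̂ = μ_o − P_o Hᵀ S⁻¹ (H μ_o − y),  P_p = P_o − P_o Hᵀ S⁻¹ H P_o,
S = H P_o Hᵀ + R,

implemented with a symmetric linear solve (never an explicit inverse) and
exploiting that H is a row selection: H P_o Hᵀ is an index slice, and the
full m × 19 matrices are never formed. S must have reciprocal condition
number above 10⁻¹²; below that a `SingularMeasurementError` names the joint
subset, which with R = 0 signals a sensor on a (numerically) zero-variance
or linearly dependent joint set — e.g. measuring both a PIP joint and its
slaved DIP joint. The information form
x̂ = (P_o⁻¹ + HᵀR⁻¹H)⁻¹(HᵀR⁻¹y + P_o⁻¹μ_o) is kept as a secondary route; it
requires P_o and R nonsingular and exists chiefly as an independent
algebraic cross-check.

With R = 0 the estimator interpolates: H x̂ = y exactly and the measured
rows/columns of P_p vanish. R = 0 is the default operating point because the
glove's sensor noise (sub-degree over a hold) is negligible against postural
variability; a nonzero R is accepted everywhere for sensitivity studies.

Raw sensor windows are reduced by the arithmetic mean (no outlier
rejection) after per-sensor conversion to angles; a 10-second hold at
typical sampling rates gives ~1000 samples, so 0.8° sensor noise leaves
≈ 0.025° standard error on the averaged measurement.

## Optimal sensor placement

The design cost of a joint subset is ‖P_p‖²_F (degrees⁴) at that subset; 0
for a full measurement, ‖P_o‖²_F for none. The reference search is exact
exhaustive enumeration — C(19, 5) = 11,628 subsets evaluate in seconds —
with ties broken lexicographically in canonical joint order. Greedy forward
selection (largest cost decrease per added joint) is the documented
approximation: optimal for diagonal priors, an upper bound in general.
Infeasible subsets (singular S with R = 0) score +∞ and cannot be selected.
The five-joint optimum depends on the prior; the original glove study's
motion-capture prior gave {TA, MM, RP, LA, LM}, reported here as the
reference answer for users supplying their own prior rather than as a
property of every synergy prior.

## Goniometer model and calibration

A double-layer knitted-piezoresistive-fabric goniometer outputs the
resistance difference ΔR between its layers, affine in the flexion angle:
ΔR = s_θ·θ + ΔR₀ (the ideal identical-layer case ΔR = k·θ is ΔR₀ = 0).
Two-point calibration at known angles (default 0° flat and 90° bent) solves
the inverse map θ = α₁ΔR + α₂ exactly: α₁ = (θ₂−θ₁)/(ΔR₂−ΔR₁),
α₂ = θ₁ − α₁ΔR₁. Equal outputs at both positions are a degenerate-
calibration error. Measurement noise is injected in the angle domain
(default sd 0.8°, the observed resting-noise bound; one shared default
across sensors since no per-sensor figures exist), equivalent to
resistance-domain noise scaled by s_θ. Resistance-difference units are
arbitrary — only the affine relation matters. Electrical front-end
behaviour (four-point measurement, amplification, filtering, digitization)
and hysteresis/drift are out of scope; the model starts at ΔR.

## Grasp recognition

Recognition is unsupervised: K-means under the squared Euclidean distance
d(x, c) = (x−c)(x−c)′ on full 19-DOF reconstructed poses, k = one cluster
per grasp type. The protocol is leave-one-subject-out: the held-out
subject's per-grasp mean poses seed the centroids (cluster j inherits grasp
identity j and is never re-ordered), and the remaining subjects' poses are
clustered. Where the protocol is underspecified, the choices are:
convergence = unchanged assignment vector, with a max-iteration bound of
100; an emptied cluster keeps its previous centroid (preserving the
identity the confusion-table semantics require); distance ties go to the
lowest-indexed centroid. Full Lloyd iteration is the default, with a
nearest-centroid (no-update) variant exposed for comparison. Accuracies are
the per-type diagonal fraction (relative) and overall diagonal fraction
(absolute) of the confusion matrix, rounded half-up to two decimals to
match conventional percentage reporting.

Note that a converged Lloyd solution is a fixed point — each sample with
its nearest centroid, centroids at cluster means — but not necessarily
stable against single-sample moves *with* centroid recomputation
(Hartigan-style moves can still improve it); the tests assert the former,
which is what the algorithm guarantees.

## Synthetic data

No public grasp-ensemble dataset accompanies the method, so the generator
produces the statistical structure it relies on. A pose's 15 free DOFs are
drawn as mu + B w + ε with unit-norm synergy directions B (random
orthonormal by default), w ~ N(0, diag(σ_syn²)), ε ~ N(0, σ_res²I), then
lifted through the coupling. Defaults: k = 5 synergies with geometrically
decaying σ_syn = (20, 12, 7, 4, 2)°, σ_res = 1°, ensemble size N = 2000 —
values chosen once to produce a strongly low-rank, realistically scaled
postural covariance; all are config-overridable. The choice of five
synergies matches the five-sensor design point.

Labeled panels emulate the recognition experiment: 8 grasp types × 5
subjects × 3 repetitions (120 trials). Grasp-type means are drawn from the
same synergy model and rescaled so their minimum pairwise distance is a
chosen multiple ("separation") of the total within-label spread
(within-grasp synergy sd (2, 1.5, 1, 0.7, 0.5)°, residual 0.5°, plus
per-subject isotropic jitter, default 1.5°, applied as one offset per
subject). Separation 10 models cleanly distinct grasps; 3 models realistic
overlap between similar grasps. What the generator does *not* model:
biomechanically realistic per-object grasp shapes, joint-limit saturation,
sensor sliding or cross-talk artifacts, or pathological (non-physiological)
synergy patterns — so perfect synthetic recognition demonstrates protocol
correctness, not field performance on real hands.

All sampling uses one explicit NumPy Generator per call, seeded at the call
site; there is no hidden global RNG state.

## Numerical and I/O choices

Reciprocal-condition threshold 10⁻¹² for innovation solves; PSD checks
allow eigenvalues down to −10⁻⁸ × the largest (round-off); percentages
rounded half-up via decimal arithmetic. Pose/panel CSVs store degrees with
shortest-round-trip float formatting and are read with round-trip float
parsing, so write→read is exact; the prior serializes to JSON. Pipeline
outputs carry a config-hash + seed provenance comment and are byte-identical
across reruns of the same config and seed.

## Problem sizes

Default validation sizes: 1000 random instances for the estimator-form
identity, 200 for interpolation checks, 50 random priors against the
independent design enumerator, 5000 draws for parameter recovery (sampling
error on the MSE/trace ratio ≈ 2%, against a 10% band), 6000 draws for the
goniometer noise recovery, and the full 11,628-subset design search. These
run in seconds on one core.

## Known limitations

The estimator is static — no temporal filtering across a movement; the
prior encodes grasping synergies of unimpaired hands and transfers poorly
to tasks with different coordination patterns or to pathological synergies;
the optimal subset is only as good as the supplied prior; and the linear
Gaussian machinery cannot represent multimodal posture distributions.
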