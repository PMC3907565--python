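# Methods

`fdtica` implements an unsupervised analysis of Frequency Doubling Technology
(FDT) Matrix 24-2 visual fields: a variational Bayesian independent component
analysis mixture model (VB-ICA-MM) that clusters 53-dimensional field vectors
(52 threshold sensitivities plus age), discovers per-cluster sets of
statistically independent defect axes, and generates graded defect patterns
along those axes.  Because no clinical cohort ships with the package, a
calibrated synthetic-field generator supplies data with the statistical
structure the analysis assumes.

## The model

Each observation x (a standardized field vector, dimension D) is assigned to
one of K clusters with mixing proportions π.  Within cluster k,

    x = μ_k + A_k s + ε,        ε ~ N(0, diag(ψ_k)⁻¹)

where A_k is a D×L mixing matrix, s an L-vector of latent sources, and ψ_k
per-dimension noise precisions (diagonal, not isotropic: perimetry points
have heterogeneous variability).  Each source s_l is a mixture of m
univariate Gaussians with weights w_kl, means η_klj and precisions β_klj —
the non-Gaussianity that makes the axes identifiable as independent
components rather than an arbitrary rotation of a factor subspace.

Conjugate priors complete the model: Dirichlet on π and on each w_kl;
Gaussian on μ_k and η_klj; Gamma on ψ, β, and on per-column automatic
relevance determination (ARD) precisions α_kl governing A's columns,
A_·l ~ N(0, α_kl⁻¹ I).  When a column carries no structure its posterior α
grows and the column shrinks to zero — this is how the number of axes per
cluster is discovered without a model-evidence scan over L.

## Inference

Structured mean-field variational inference:

    q = q(z) q(s|z) q(c|z) q(A) q(μ) q(α) q(ψ) q(π) q(w) q(η) q(β),

with q(s|z=k) a full-covariance Gaussian per observation and c the per-source
mixture-component indicators.  Every update in a sweep is the exact
conditional optimum, in a fixed order (responsibilities; source posteriors;
component responsibilities; A; α; μ; ψ; w, η, β; π), so the evidence lower
bound (ELBO) is non-decreasing sweep over sweep up to round-off.  The test
suite enforces `ELBO_t ≥ ELBO_{t−1} − 10⁻⁶·|ELBO_{t−1}|` on every fitted
trace; a violation indicates an implementation bug, not a modeling choice.

Numerical notes: cluster responsibilities and component responsibilities are
computed with log-sum-exp; source-posterior precision matrices are symmetric
positive definite by construction (ARD/β diagonals are strictly positive);
argmax ties in hard assignments resolve to the lowest cluster index; a
non-finite intermediate raises an error naming the update step.

### Initialization

Defaults (`init="kmeans"`): cluster means from a seeded k-means partition
(with a small seed-dependent jitter so distinct seeds give distinct starts);
each cluster's mixing matrix from the principal directions of its member
set, scaled by the singular values, plus random jitter; source-component
means spread over standard-normal quantiles.  A pure random start
(`init="random"`: random rows as means, small random mixing entries) is kept
as an option but recovers in-subspace rotations much less reliably: with
small random mixing matrices the posterior often lands in a basin where one
bimodal source is shared across two axes (Amari distance ≈ 0.7 on the L=2
recovery oracle, vs ≈ 0.001 for the PCA-seeded start).  Restarts are still
required — the selection protocol fits every configuration from multiple
seeds and keeps the best — but the PCA-seeded start makes each restart far
more likely to land in an identifiable basin.

Priors default to broad Gamma(10⁻², 10⁻²) for ψ and α, Gamma(1, 1) for β,
unit-precision Gaussians for η, concentration 1 Dirichlets, and
N(0, 10²·I)-scale (κ₀ = 10⁻²) cluster means — all on standardized data, where
unit scales are natural.  Training runs up to 500 sweeps (the protocol's cap)
with early stopping at a relative ELBO change of 10⁻⁸.

### Identifiability caveat

With sources whose joint distribution is rotation-symmetric (e.g. two
identical bimodal sources behind mixing columns of exactly equal norm), the
in-subspace rotation is not identifiable: a 45°-rotated basis with trimodal
marginals explains the data equally well.  The recovery oracles therefore use
mixing matrices with distinct column norms; on real perimetric data exact
symmetry has measure zero.

## Model selection

The candidate grid crosses K ∈ {2,3,4,5}, L_max ∈ {10,20}, m ∈ {3,6,8} and 30
restarts (720 fits); seeds are stable hashes of (master seed, K, L_max, m,
restart), so the grid is reproducible and restartable.  FDT labels never
enter fitting — `fit_vbica_mm` receives only the data matrix — and are used
post hoc to score each candidate: clusters are labeled normal when >50% of
their argmax-assigned members are FDT-normal (ties and empty clusters →
glaucoma, the conservative screening choice), specificity is the fraction of
FDT-normal fields in normal clusters, sensitivity the fraction of
FDT-abnormal fields in glaucoma clusters.  Selection is lexicographic:
among candidates with specificity ≥ 0.90, maximal sensitivity; if none
qualifies, maximal specificity; ties broken by higher ELBO, then lower K,
then lower candidate index.  The trade-off is stated as a goal rather than a
formula in the protocol this mirrors; the lexicographic reading plus
deterministic tie-breaks makes selection a pure function of the candidate
table.

## Axis pruning, orientation and patterns

Axis magnitude = ‖E[A]_·l‖₂ × the responsibility-weighted posterior SD of
source l over the cluster's members — the data-space spread the axis
carries.  The sorted magnitude curve is cut at its knee (interior position
of maximum discrete second difference); a manual override is first-class
because axis counts were chosen by eye in the clinical protocol this
follows.  Pruning drops the weakest columns and retrains warm-started from
the pruned posterior with L fixed (preserving the selected basin rather than
refitting cold).

Axes are unit-normalized and oriented so that +direction means greater
abnormality: the mean projection of a cluster's abnormal-labeled members
must exceed that of its normal-labeled members; a cluster with a single
label class falls back to the geometric rule that +direction decreases mean
simulated sensitivity.  For contrast axes inside a glaucoma cluster (e.g.
separating superior-defect from inferior-defect members) no sign can lower
both hemifields relative to the cluster mean, so the label rule is the
defining convention and the geometric rule only the fallback.

A pattern at k SD along an axis is x = μ_N + k·σ_proj·d in standardized
space — anchored at the NORMAL cluster centroid μ_N for every cluster's axes
(an own-centroid flag exists for exploration) — mapped back to dB and
reported as deviations from the de-standardized μ_N: a simulated
total-deviation plot plus a generated age.  σ_proj is the SD of the member
fields' projections (not the source-posterior SD), so "±2 SD" spans the
spread of actual fields along the axis; projection SDs are computed over
cluster members, not all fields.  Deviations are not clipped at 0 dB (they
are deviations, not thresholds).  Severity of any field along an axis is
((z − μ_N)·d)/σ_proj, making severity(pattern(k)) = k an exact identity.
Fields are partitioned among a cluster's axes by largest |cosine| between
the cluster-centered field and the axis direction.

## The synthetic generator

What it emulates: a 1,190 + 786 eye screening cohort.  Normal fields are a
smooth radial hill of vision (31 − 0.12·eccentricity dB, ≈30.5 dB centrally)
plus a per-eye global offset ~ N(−1.0, 2.75²) dB and iid per-point noise
~ N(0, 2.0²) dB, clipped at 0 dB.  The −1.0 dB offset encodes that study
normals sit slightly below the normative surface, matching a mean MD of
−1.00 dB; 2.75² + 2.0²/52 gives an MD SD of ≈2.77 dB against the reported
2.80 dB.  Abnormal fields subtract severity × a defect template from the
same normal model.  Templates (non-positive, per unit severity) follow the
classic glaucomatous morphologies on the 24-2 grid: superior/inferior
altitudinal (loss −1 in one hemifield, −0.25 diffuse in the other),
superior/inferior nasal steps, their "arrowhead" union, diffuse loss, and
diffuse-superior loss; weights favor altitudinal defects, mirroring the
dominant clinical patterns.  Severity is Gamma(shape 2, per-archetype scale)
with the scale solved in closed form so every archetype contributes −4.57 dB
of expected MD, putting the abnormal arm's mean MD at −5.57 dB.  Shape 2 was
chosen as realistic for a GHT/PSD-screened abnormal group (little mass at
zero severity); it implies an MD SD of ≈4.3 dB, somewhat below the reported
5.09 dB — a documented compromise, since only the means are calibration
targets.  Ages are truncated normals (50.0 ± 14.7 normal, 55.9 ± 15.3
abnormal, bounds [18, 95]; truncation shifts means by <1 year); reliability
indices are Beta draws matching the reported mean rates and capped at the
0.33 reliability criterion.

What it does not emulate: spatial noise correlation, test–retest structure,
learning and fatigue effects, floor-effect variability growth, multi-modal
real-world severity distributions, or between-eye correlation (both eyes of
a subject are treated as exchangeable records — a caveat the clinical cohort
shares).  Passing tests therefore demonstrate that the pipeline recovers
structure of this assumed form, not that it would reach the same operating
point on clinical data.

A generic `sample_ica_mixture` oracle (known means, mixing matrices,
mixture-of-Gaussian sources, diagonal noise) backs the recovery tests:
cluster recovery by adjusted Rand index, mixing recovery by Amari distance,
and the m=1 Gaussian limit against the principal subspace.

## Problem sizes and defaults in the shipped analyses

The numbered drivers under `analysis/` use the full synthetic cohort (1,976
fields) with a reduced demo grid — K ∈ {2,3,4}, L_max = 10, m = 3, 5
restarts, 150 sweeps — chosen so the complete search runs in a few minutes
on one CPU while exercising the same selection, pruning and pattern
machinery as the full 720-model protocol.  The age ablation reruns the
pipeline with age held constant; the constant column is dropped before
standardization (a zero-variance input cannot be z-scored), which is the
intended semantics of removing age's influence.

## Known limitations

- The VB update equations follow the package's own conjugate formulation of
  the mixture-of-ICA model; published analyses of this kind cite software
  whose exact priors and updates are not printed, so numerical equality with
  any particular historical implementation is not claimable.
- Mean deviation is the unweighted mean of pointwise deviations; the
  instrument's eccentricity weighting is proprietary.  Generator calibration
  targets use the same statistic, so they are self-consistent.
- Knee detection by maximum curvature can be brittle on nearly flat
  magnitude curves (it warns and keeps all axes when the curve is flat);
  the manual override exists for exactly that reason.
- Selection consumes labels post hoc; with few candidates or small cohorts
  the specificity goal may be infeasible and the fallback (max specificity)
  applies.
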