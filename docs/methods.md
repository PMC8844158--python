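# Methods

## The analysis

`hemigrad` quantifies hemispheric specialisation through the geometry of
intrinsic-connectivity gradients. The pipeline assumes parcelwise BOLD
time-series that have already been denoised; no preprocessing (confound
regression, filtering, scrubbing) is performed here.

**Connectivity.** For each participant, a P×P Pearson correlation matrix
over parcels; `z = atanh(r)` applied off-diagonally before any averaging so
that the group matrix is a mean of variance-stabilised values. The diagonal
is set to 0 after the transform: self-connections carry no information and
would otherwise always survive row sparsification. The group matrix stays in
Fisher-Z space and is passed directly to the embedding; individual-level
gradients are computed from each participant's own Fisher-Z matrix with
identical parameters.

**Embedding.** Each row keeps its `ceil((1−s)·P)` largest entries
(sparsity `s = 0.9`, i.e. the top 10% of connections, ties broken by first
index); affinity between parcels is the normalized angle
`a(i,j) = 1 − arccos(cos(row_i, row_j))/π ∈ [0, 1]` computed on the
sparsified rows, diagonal zeroed. Diffusion-map embedding of the affinity
`W`: with `D = diag(W·1)`, form `W' = D^−α W D^−α` (α = 0.5, the
anisotropic normalization that removes the influence of sampling density),
then the row-stochastic operator `P = D'^−1 W'`. Eigenpairs are obtained
through the symmetric conjugate `D'^−1/2 W' D'^−1/2`; the trivial constant
eigenvector (λ = 1) is dropped; gradient k is `ψ_k · λ_k/(1 − λ_k)`
(diffusion time t = 0, the regularised multi-scale weighting; `λ_k^t` for
t > 0). Ten gradients are retained by default. Variance explained is each
retained eigenvalue's share of the nonnegative part of the retained
spectrum. Sign is fixed per gradient (largest-magnitude entry positive) so
repeated runs are bit-identical; sign indeterminacy is the only
nondeterminism of the eigensolver.

Note that a gradient's *orientation* (which end is "heteromodal") is still
a convention. In a real study it is inherited from alignment to a canonical
reference; in the synthetic setting the acceptance script anchors the
template against the planted coordinate before aligning individuals.

**Alignment.** Orthogonal Procrustes (`argmin_Q ‖T − S·Q‖`, reflections
permitted) aligns each individual gradient set to a template; iteration
re-estimates the template as the mean of the previously aligned sets, ten
rounds by default (a `fixed_template` switch repeats alignment to the
original template instead — the iterative variant is the default because it
also stabilises the template itself). No centering and no scaling by
default: the lateralization statistic consumes gradient magnitudes, and
uniform scaling is available behind a flag. Gradient columns are matched by
index after rotation; the rotation absorbs sign flips and component
reordering of individual solutions.

**Lateralization.** Per participant, the chosen gradient is min–max
normalized to 0–100 across *all* parcels of both hemispheres jointly —
per-hemisphere normalization would erase exactly the global offset under
study, so it is not offered. Network summaries are unweighted means of the
parcels in each network × hemisphere cell (hemispheres contribute unequal
parcel counts; no weighting is applied). The difference score is
`LH mean − RH mean` per network and participant. Inference:

* *Global test*: per-participant global hemisphere means (mean of network
  means), paired t, plus the fraction of participants with L > R.
* *ANOVA*: 2 (hemisphere) × N (network) within-subject ANOVA on the network
  means, computed in orthonormal-contrast space; Greenhouse–Geisser epsilon
  `tr(S)²/(q·tr(S²))` from the contrast-score covariance, with the F tested
  on (ε·df1, ε·df2); partial eta squared `SS_eff/(SS_eff+SS_err)`. A
  per-participant covariate of no interest (e.g. the global L−R value) is
  partialled out by residualizing each contrast variable on the centered
  covariate, charging one error df per contrast variable. The no-covariate
  path reproduces `pingouin.rm_anova` exactly (verified in the test suite).
* *Permutation tests*: under H0 the hemisphere labels are exchangeable
  within participant, so each difference score is symmetric about zero. The
  null for each network's mean difference is built by sign-flipping
  participants' scores: exhaustively (all 2^n patterns,
  p = count/2^n, observed pattern included) whenever 2^n does not exceed
  the requested resamples, else Monte-Carlo with the add-one convention
  `(1+count)/(B+1)` (B = 5000 by default). Two-sided; Bonferroni over the
  number of networks tested. Sign-flipping was chosen over a participant
  bootstrap because it is exact under the stated exchangeability null and
  admits an enumeration oracle.
* *Network-pair distances*: per participant and hemisphere, the signed
  gradient distance `mean_b − mean_a`; paired t of LH vs RH distances,
  Bonferroni over the declared family of pairs.

The z-scored difference map standardises the per-network group means across
networks (population SD) — over networks rather than participants, since
its purpose is to flag the networks with the most extreme differences.

**Behaviour.** Condition efficiency `−RT/accuracy` (s; higher = better)
controls speed–accuracy trade-offs. PCA on the correlation matrix of
condition scores retains components with eigenvalue > 1 (Kaiser) and
applies varimax with Kaiser row-normalization when two or more survive;
factor scores use the regression method `Z·R⁻¹·Λ`. Outliers are handled by
z-scoring and replacing |z| > 2.5 with 0 — the mean of a z-scored variable;
imputing the raw mean and re-z-scoring would perturb every other
participant's value. Outlier detection is applied to the final factor/EV
scores (matching the order of operations in the scoring procedure); a
pre-PCA variant can be composed from the same primitives. Regressions are
one OLS fit per network of the difference score on all EVs jointly, betas
standardized by z-scoring DV and EVs; by default only explicitly selected
networks (e.g. those passing the permutation screen) are modelled.

## The synthetic cohort

The generator plants exactly the structure the analysis assumes and nothing
else:

* Each parcel has a latent coordinate `g ∈ [0, 1]`. Latent signals are
  zero-mean unit-variance Gaussian with correlation
  `exp(−|g_i − g_j|/τ)` — the Ornstein–Uhlenbeck kernel, positive
  semidefinite for any coordinate set, whose leading nontrivial diffusion
  eigenvector orders parcels by `g`. Independent Gaussian observation noise
  (SD `noise_sd`) is added, attenuating all correlations by
  `1/(1+noise_sd²)` without reordering them.
* Networks are spread evenly along [0, 1] in canonical principal-gradient
  order (visual lowest, default-mode highest), and the parcels of a network
  tile `±within_network_spread` around the network position. The spread
  mirrors within-network heterogeneity of real parcellations and keeps the
  sparsified affinity graph a single ordered chain: exactly coincident
  parcel coordinates create duplicate-row cliques, and strongly clustered
  network positions fragment the rank-local graph into weakly coupled blobs
  whose localized eigenmodes displace the global gradient. (The canonical
  clustered positions remain available via `canonical_coordinates()` for
  experiments on exactly this failure mode.)
* Hemispheric asymmetry: each network has a population LH−RH offset
  (defaults follow the canonical pattern: control/default/attention networks
  shifted toward the heteromodal end on the left, the ventral
  anterior-temporal limbic network reversed, sensorimotor networks near
  zero); each participant draws their own offset from
  `Normal(mean, asymmetry_sd)`, applied to left-hemisphere parcels only, so
  LH−RH is interpretable as the planted offset.
* Behaviour: the target score is `r·z(asymmetry) + √(1−r²)·noise` for the
  chosen network; all other scores are independent standard normals.
* Reproducibility: every participant has an RNG stream keyed on
  `(seed, participant_index)`, so cohorts are bit-identical regardless of
  generation order; `truth.json` stores every planted parameter.

Defaults and why: `τ = 0.3` (correlation between gradient extremes
`e^(−1/0.3·range) ≈ 0.1`, giving realistic long-range decay while keeping
neighbouring networks strongly coupled); `noise_sd = 0.5` (sample
correlations attenuated to 80% of latent, comparable to short-scan
reliability); `within_network_spread = 0.02` (≈ one third of the
inter-network spacing); `asymmetry_sd = 0.03` (between-subject SD of the
offset on the coordinate scale — effects of the planted magnitudes are
detectable at cohorts of a few dozen without being deterministic);
`n_timepoints = 200` and 80 parcels in 17 networks (unequal L/R counts by
construction) for the reference cohort.

What the generator does **not** emulate: haemodynamics, autocorrelated
noise, motion or physiological artefacts, spatial maps (no volumes or
surfaces), non-Gaussian tails, and any asymmetry mechanism other than a
coordinate shift. Consequently, passing tests establish that the pipeline
recovers planted gradient geometry and planted asymmetries under the
model's own assumptions — they do not certify performance on real scans.

A further honest caveat established by the package's own end-to-end runs:
at the reference scale (80 parcels, T = 200), *individual-level* gradients
are noisy (median planted-coordinate correlation ≈ 0.8), and the min–max
anchoring plus the rank-local nature of the sparsified embedding distort
small network offsets; only the large planted asymmetries are recovered
with reliable sign at the per-network level, while the group-level gradient
itself is recovered almost perfectly (|ρ| ≈ 0.99). Inference-layer
properties (type-I calibration, power, regression recovery) are therefore
validated on difference scores sampled directly from the generator's
implied distribution, which isolates the statistical machinery from
embedding noise.

## Numerical choices

* Fisher-Z clips off-diagonal |r| ≥ 1−1e−7 (duplicate parcels) with a
  logged warning instead of producing infinities.
* Sparsification uses a stable descending sort, so threshold ties keep the
  first index — deterministic and oracle-checkable.
* The normalized-angle kernel clips cosines into [−1, 1] before `arccos`
  and clamps the affinity into [0, 1] (float round-off near the ends);
  symmetry of the kernel output is asserted, not forced.
* The embedding refuses disconnected affinity graphs (reporting component
  sizes) and `n_components ≥ P`. Transition-operator eigenvalues may be
  slightly negative for generic affinities; they are retained (the
  spectrum's ordering is what matters) and excluded from variance-explained.
* Exhaustive sign-flip enumeration includes the identity pattern, so the
  exact p can never be 0; the Monte-Carlo branch uses the add-one
  convention for the same reason.
* Degenerate cases raise rather than guess: constant gradient columns
  (min–max), zero variance across networks (z-map), zero-variance
  difference with nonzero mean (global test reports p → 0 with a warning),
  singular correlation matrices (PCA), rank-deficient designs (OLS, with
  the collinear EV pair named).

## Limitations

* No vertex/surface-level analysis and no homotopic parcel-level inference;
  the network level is the unit of analysis by design.
* The covariate-adjusted repeated-measures ANOVA uses residualization with
  a df charge per contrast variable — a pragmatic partialling scheme, not a
  full mixed-model ANCOVA; the no-covariate path is exactly standard.
* Only the normalized-angle kernel and diffusion-map embedding are
  implemented (pluggable, but alternatives are out of scope).
* Bonferroni is the only multiplicity correction offered for the network
  screen, matching the analysis the package implements.
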