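# Methods

`signedconn` implements a sign-aware analysis of developmental change in
functional connectomes: signed graph construction, per-node age-effect
estimation with penalized-spline mixed models, and spatial alignment testing
against the sensorimotor-association (SA) cortical axis. Because the kind of
longitudinal imaging cohort this analysis targets is rarely shareable, the
package ships a synthetic cohort generator with planted, recoverable ground
truth; every stage is validated against it.

## Connectivity and strength

Session connectivity is the Pearson correlation matrix of regional time
series (columns z-scored; the diagonal is removed and represented as NaN —
the package-wide convention for "absent entry"). Matrices are Fisher
z-transformed entrywise (`atanh`, correlations clipped at 1 − 1e−7 with a
warning to keep the transform finite).

Node strength is computed on the full (unthresholded) Fisher-z matrix after
the short-range exclusion, in three variants: positive (Σ max(w, 0)),
negative (Σ max(−w, 0), reported as a magnitude so "stronger negative
connectivity" reads monotonically), and absolute (their sum). Sum is the
primary definition; a mean-over-present-edges option exists because the
distance exclusion removes different numbers of edges per node, which makes
sum and mean non-equivalent even for rank-based downstream statistics.

## Signed graphs

Graph construction is ordered: (1) exclude node pairs closer than 30 mm —
Euclidean distance on volume coordinates, since no cortical surface is in
scope; (2) apply the edge-sign treatment: absolute value `|w|` or
positive-only rectification `max(w, 0)`; (3) proportional thresholding
retaining the top 25% of *eligible* (non-excluded) edges by weight, so every
session's graph has identical density. Exclusion precedes thresholding so
short-range leakage edges cannot consume the density budget; both the order
and the density are configurable for sensitivity analyses. Ties at the
density cut are broken deterministically (weight descending, then node-pair
lexicographic). Exactly ⌊density × n_eligible⌋ edges are retained, weights
unchanged (weighted graphs, never binarized). Negative-only graphs are not
constructed: at realistic negative-edge fractions they are too sparse to
threshold meaningfully.

Three node metrics are computed:

* **Onnela clustering** C_i = (k_i(k_i−1))⁻¹ Σ_{j,h} (ŵ_ij ŵ_jh ŵ_hi)^{1/3},
  with binary degree k_i over retained edges and weights max-normalized
  (ŵ = w / max w) so C_i ∈ [0, 1]. Nodes with k_i ≤ 1 get 0.
* **Weighted local efficiency**: for node i, the mean over ordered neighbor
  pairs of 1/d_jk, where d_jk is the weighted shortest path (edge length
  1/ŵ, max-normalized weights) inside the subgraph induced by i's
  neighbors; unreachable pairs contribute 0; nodes with < 2 neighbors get 0.
  With max-normalization all three metrics are invariant to a global
  positive rescaling of weights.
* **Participation coefficient** P_i = 1 − Σ_m (k_im / k_i)² over weighted
  module strengths; nodes with zero strength get 0.

All three are verified against independent brute-force enumerations (triple
loops, hand-rolled Floyd-Warshall) to 1e−10, and clustering additionally
against networkx's weighted clustering.

## Per-node age models

For each node and metric the full model is

    y_ij = β0 + f(age_ij) + β1 sex_i + β2 alcohol_ij + β3 cannabis_ij
           + β4 FD_ij + u_i + ε_ij,

with f a penalized cubic spline and u_i ~ N(0, σ_u²) a subject random
intercept; the null model drops f entirely and keeps everything else. The
smooth is a cubic B-spline basis of dimension 5 with a second-order
difference penalty (a P-spline). Five basis functions is deliberately small:
with three visit waves per subject the age design cannot identify more, and
the P-spline at this dimension spans the same function class as a
thin-plate-type basis while staying well conditioned. The penalty is handled
through the mixed-model representation — the penalty null space (the linear
age trend) joins the fixed effects and the wiggle coefficients become an iid
variance component — so REML estimation of the two variance ratios performs
smoothness selection. Likelihood evaluations use the Woodbury/Henderson
form, with cross-products cached per design, so per-node model grids over
hundreds of nodes cost milliseconds per fit. The fitter is cross-checked in
the test suite against statsmodels MixedLM configured to the identical
variance-component model; agreement is to ~1e−3 on fixed effects and
variance components.

The age-effect size is ΔR² = R²_adj(full) − R²_adj(null). "Adjusted R² of a
mixed model" is ambiguous, so the package defines it on the marginal (fixed
effects + smooth) fitted values — the subject BLUPs are excluded from the
fit, so the random intercept contributes to neither model and cancels in the
difference. The degrees-of-freedom adjustment counts the smooth's effective
degrees of freedom (edf), computed from the Henderson ridge-system hat
diagonal (linear age column plus shrunk wiggle columns). Slightly negative
ΔR² values are retained — they carry the overfit penalty's information, and
the rank-based downstream statistics are insensitive to them.

The smooth's p-value is a maximum-likelihood likelihood-ratio test of the
age terms (linear coefficient and wiggle variance jointly zero) against the
boundary mixture 0.5·χ²(1) + 0.5·χ²(2). Under an all-noise cohort of 300
sessions this is near-calibrated with mild conservatism in the far tail,
which is the safe direction for the Benjamini-Hochberg flags (q = 0.05
across nodes) built on it. Nodes whose fits fail or do not converge are
logged, excluded from the FDR set, and reported; more than 20% failures
aborts the map.

## SA-axis alignment and the spin test

Alignment is the Spearman correlation between a per-node ΔR² map and the SA
ranks. Significance uses a parcel-spin permutation null: random rotations
drawn uniformly from SO(3) are applied to the right-hemisphere spherical
coordinates and their x-mirror to the left (preserving hemispheric
symmetry); each node receives the SA rank of the nearest original
same-hemisphere node. The reassignment may duplicate ranks — the standard
parcel-spin convention. The SA map is the vector spun (the ΔR² map stays
fixed); spinning the data map instead is available behind a flag. The
two-sided p-value is (1 + #{|ρ_null| ≥ |ρ_obs|}) / (n_perm + 1), so p is
never zero and never below 1/(n_perm+1).

On spatially autocorrelated maps that are independent of the SA axis by
construction (randomly rotated multi-scale surfaces), the empirical type-I
error at α = 0.05 is at the nominal rate, while a naive label shuffle on
the same maps rejects more than half the time — the contrast that motivates
the spin null. Known limitation: for maps dominated by a single
low-frequency (dipole-like) gradient, the nearest-neighbor parcel spin is
mildly conservative in the far tail (rotated dipoles stay correlated, and
assignment duplicates widen the null slightly).

## Synthetic cohort generator

The generator is an explicit latent-correlation model on the Fisher-z
scale; `tanh` maps back to correlations, so entries stay in (−1, 1) and no
positive-definiteness repair is needed in direct-matrix mode.

**Parcellation.** Nodes sit on two mirror-symmetric unit hemispheres
(jittered Fibonacci lattices; volume coordinates are sphere × 100 mm, so the
30 mm exclusion radius is meaningful). Modules are contiguous angular
sectors assigned on the right hemisphere and copied to the mirror. The SA
score is a fixed multi-scale smooth function of position plus node noise,
ranked to give a 1..P permutation; mixing low- and mid-frequency components
matters — a pure low-order gradient would leave the spin null spanning
nearly the full [−1, 1] range, giving the alignment test unrealistically low
power compared to how such tests behave on real cortical maps. Association
modules are the half of modules with the highest mean SA rank.

**Baseline structure.** Within-module mean r = 0.35, between-module
r = 0.12, and between association-module pairs a negative mean that is
solved analytically (Gaussian tail) so the expected fraction of negative
edges matches the configured target (default 16%). A between-module
baseline much below r ≈ 0.1 would spill negative edges everywhere once
realistic edge dispersion (static heterogeneity sd 0.06 + session noise sd
0.05) is added, making a minority-and-concentrated negative-edge regime
unreachable; that is why the between-module baseline is 0.12.

**Planted effects.** Positive-edge age slopes are graded by the SA axis:
slope(i,j) = s·(g_i + g_j)/2 with g linear from 1 (sensorimotor pole) to 0
(association pole) and s = 0.008 z/year by default; with ~100 incident
edges and subject intercept sd 0.025 this yields node-level ΔR² for
positive strength ranging from ~0.02 to ~0.15 across the hierarchy —
the magnitude regime such studies report. Negative-edge age effects deepen
the association-block edges uniformly (0.004 z/year by default). Subject
random intercepts, sex, zero-inflated age-increasing substance scores, and
lognormal framewise displacement shift all edges additively on the z scale;
FD is drawn independent of age so covariate-shielding checks have a clean
target. Ground truth (per-node expected slopes and the SA gradient) is
stored with every cohort, and the generator asserts at build time that the
planted positive gradient is perfectly rank-aligned with the SA axis.

**Reversal scenario** (`reversal_config`). Demonstrating that absolute-value
and positive-only constructions can disagree requires care, for two reasons
discovered while designing the generator: max-normalized clustering is
blind to globally coherent weight growth (only *relative* change moves it),
and proportional thresholding is zero-sum, so growth anywhere induces edge
churn concentrated at the opposite end of the hierarchy. The scenario
therefore plants: strong static within-module coupling in association
modules (r = 0.55, holding the normalizing maximum), growing within-module
coupling in sensorimotor modules (r = 0.30 baseline, SA-graded growth at
0.018 z/year at the pole; within-module edges sit far above the threshold
cut, so no churn), and anticorrelations between association modules that
start clearly negative (z = −0.30, no sign-crossing across ages 12-18, so
nothing leaks into positive-only graphs) and deepen uniformly at
0.035 z/year. Result: the clustering ΔR²-SA gradient is positive
(association-dominant) in absolute-value graphs and negative
(sensorimotor-dominant) in positive-only graphs.

**Cohort shape.** Subjects enter at a uniform baseline age early in the
window and return at roughly biennial follow-ups (ages strictly increasing,
compressed into the window when a draw overshoots); three timepoints by
default; optional missing-completely-at-random session dropout. Time-series
mode samples frames from the (eigenvalue-clipped, nearest-correlation
repaired) latent matrix and returns the empirical Pearson matrix, converging
entrywise to the latent correlation as the frame count grows.

**What the generator does not emulate:** BOLD hemodynamics, scanner noise
spectra, motion artifacts, preprocessing residuals, spatially varying
noise, non-random attrition, or realistic substance-use score
distributions. Passing tests therefore demonstrate the *statistical
machinery* — exact graph construction, calibrated nulls, unbiased effect
recovery, and the sign-treatment reversal mechanism — not fidelity to any
particular empirical cohort.

## Problem sizes and defaults

Demo-scale defaults (60 subjects × 3 visits, 100 nodes, 13 modules, 500
spin permutations) run the full nine-cell grid in a few minutes on one CPU;
the statistical validation suite uses 100-125 subjects and 100-150 nodes,
and 1000-permutation spin ensembles. Study scale (334 nodes, 10,000
permutations) is available through the same configs. Key tolerances:
metric-oracle agreement 1e−10; Fisher clipping at 1 − 1e−7; REML optimizer
Nelder-Mead on log variance ratios (xatol 1e−4, warm-started across nodes
with cold-start fallback); rank deficiency detected by pivoted QR with an
eps-scaled tolerance and reported with the offending column names.
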