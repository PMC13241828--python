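# signedconn

Sign-aware developmental connectomics: do conclusions about how brain
networks mature depend on how anticorrelated (negative) functional
connections are treated?

Resting-state functional connectivity (FC) contains a minority of negative
edges. Most graph-theoretical studies either take absolute values or discard
negatives before building networks, and the choice is rarely examined.
`signedconn` implements a longitudinal analysis pipeline that makes the
choice explicit and quantifies its consequences:

1. **Connectivity & strength** — Pearson FC from regional time series,
   Fisher z-transform, and sign-resolved node strength (positive / negative
   / absolute sums) on full matrices with short-range (< 30 mm) edges
   excluded.
2. **Signed graphs** — absolute-value vs positive-only weighted networks at
   matched density (proportional thresholding, top 25% of eligible edges),
   with three node metrics: Onnela weighted clustering
   C_i = (k_i(k_i−1))⁻¹ Σ (ŵ_ij ŵ_jh ŵ_hi)^{1/3}, weighted local efficiency
   (mean inverse shortest path among a node's neighbors), and the
   participation coefficient P_i = 1 − Σ_m (k_im/k_i)².
3. **Age effects** — per node, a penalized-spline mixed model
   y = β0 + s(age) + covariates + subject intercept + ε (REML, authored
   fitter validated against statsmodels MixedLM), contrasted with a null
   model without s(age); the effect size is
   ΔR² = R²_adj(full) − R²_adj(null), with Benjamini-Hochberg FDR over
   nodes.
4. **SA-axis alignment** — Spearman correlation of the ΔR² map with
   sensorimotor-association (SA) axis ranks, tested against a
   hemisphere-symmetric spin-permutation null (random SO(3) rotations,
   nearest-parcel reassignment).

Because longitudinal imaging cohorts of this kind are not generally
shareable, the package includes a first-class synthetic cohort generator
(`simulate_cohort`) with planted, recoverable ground truth: SA-graded
positive-edge age effects, association-concentrated negative edges at a
calibrated global fraction, subject random intercepts, and covariate
effects. A preset reversal scenario (`reversal_config`) plants
age-strengthening anticorrelations that make the two network constructions
genuinely disagree about where development concentrates.

The audience is researchers in network neuroscience / developmental
cognitive neuroscience who want a tested, reproducible implementation of the
sign-aware pipeline, or a sandbox for studying how edge-sign treatment,
thresholding, and spatial nulls interact.

## Worked example

```python
import signedconn as sc

# synthetic longitudinal cohort: 60 subjects x 3 visits, 100 nodes
ds = sc.simulate_cohort(sc.SimulationConfig(n_subjects=60, n_nodes=100,
                                            n_modules=13, seed=11))
mats, pheno, parc = ds.matrices(), ds.phenotypes(), ds.parcellation

# positive-strength panel -> per-node age effects -> SA alignment
strength = sc.NodeStrength(parcellation=parc, variant="positive").fit(mats)
amap = sc.age_effect_map(strength.transform(mats), pheno)
spin = sc.SpinAlignment(parcellation=parc, n_perm=1000, seed=11)
spin.fit(amap.delta_r2)
print(f"rho = {spin.rho_:.3f}, p_spin = {spin.p_spin_:.4f}, "
      f"mean dR2 = {amap.delta_r2.mean():.3f}")
```

This prints

```
rho = -0.898, p_spin = 0.0010, mean dR2 = 0.072
```

meaning: age explains on average ~7% of the variance in positive
connectivity strength, the per-node effects decrease strongly along the SA
axis (sensorimotor nodes change most, Spearman ρ = −0.90 against SA rank),
and no rotation of the SA map out of 1000 reproduces that alignment
(p at the permutation floor 1/(n_perm+1) ≈ 0.001) — the pipeline recovers
the gradient the generator planted.

The full nine-cell grid (three strength variants + three graph metrics × two
constructions) runs with one call or from the shell:

```bash
signedconn run-all --seed 11 --out demo_run       # writes demo_run/report.json
signedconn simulate --seed 3 --out cohort/        # stage-by-stage variants:
signedconn graph-metrics cohort/matrices.tsv cohort/parcellation.tsv \
    --treatment positive_only --out metrics.tsv
```

## Layout

| module | contents |
| --- | --- |
| `signedconn.parcellation` | mirrored spherical parcellations, modules, SA ranks |
| `signedconn.synthetic` | latent-correlation cohort generator, scenarios |
| `signedconn.connectivity` | Pearson FC, Fisher z, node strength (`NodeStrength`) |
| `signedconn.graphs` | exclusion, sign treatments, thresholding, metrics (`SignedGraphMetrics`) |
| `signedconn.gamm` | penalized-spline random-intercept REML fitter |
| `signedconn.age_models` | ΔR² maps, FDR (`AgeEffectMapper`) |
| `signedconn.spin` | spin ensembles, alignment tests (`SpinAlignment`) |
| `signedconn.pipeline` / `signedconn.cli` | orchestration, resumable runs, CLI |

Stage classes follow scikit-learn conventions (`fit`/`transform`,
`get_params`, fitted attributes with trailing underscores) and compose with
sklearn tooling; the module-level functions are thin wrappers for one-off
use. See `docs/methods.md` for the statistical details and design
decisions.
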