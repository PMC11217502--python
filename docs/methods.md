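# Methods

`metstab` analyses balanced multi-environment trials (MET): the same G
genotypes grown in each of E environments (here: crop seasons) in R
complete replicate blocks. Its motivating use case is the screening of
Spanish-type groundnut breeding lines for fresh seed dormancy — a trait
measured as *intensity of dormancy* (IOD, the percentage of freshly
harvested seeds not yet germinated at 15 or 21 days after sowing, in field
or petriplate assays) — together with economic traits (pod yield per plant,
hundred pod/kernel weight, shelling percentage), but every statistic is
generic MET methodology.

## Model and decomposition

### Pooled ANOVA

For a balanced RCBD repeated over environments,

    y_ijr = mu + e_j + rho_jr + g_i + (ge)_ij + eps_ijr

the corrected total SS decomposes exactly into ENV, REP(ENV), GEN, ENV:GEN
and Residuals with the familiar df (E−1, E(R−1), G−1, (G−1)(E−1),
E(G−1)(R−1)). Genotype and interaction are tested against the pooled
residual, environments against replicates-within-environments. Unbalanced
tables are rejected rather than approximated: the package targets the
designed trial, not observational data.

### Homogeneity of error variances

Pooling seasons into one ANOVA presumes homogeneous error variances. The
package tests this with Levene's statistic on the within-environment RCBD
errors. Raw RCBD residuals are *correlated* — each environment has G·R
residuals but only (G−1)(R−1) free dimensions — and feeding them straight
into Levene's F inflates the test badly (empirical size ≈ 0.16 at nominal
0.05 for G = 10, E = 3, R = 3). The default therefore first maps each
environment's residual space onto its (G−1)(R−1) orthonormal error
contrasts, which are iid normal under the null; Levene's mean-centred test
on the contrasts holds its size (measured 0.053) with good power (0.78 at
an error-SD ratio of 2). The raw-residual variant remains available as
`residual_method="pooled"`; median centring as `center="median"`.

### AMMI

The genotype × environment cell-means matrix is double-centered (row means,
column means out, grand mean back) and decomposed by SVD. With
λ_k = s_k² the interaction SS identity on the replicate scale is
R·Σλ_k = SS(ENV:GEN); each axis carries θ_k = 100·λ_k/Σλ_k percent of the
interaction. Scores are reported on the symmetric biplot scale
(eigenvector × √singular-value) so the k-th multiplicative term of a cell
is the product of the two k-th scores. Axis signs are fixed so the
largest-magnitude environment loading is positive — SVD output is otherwise
sign-arbitrary and biplots would flip between linear-algebra backends.

Each axis gets Gollob's F test: F_k = (R·λ_k/df_k)/MS_res with
df_k = G + E − 1 − 2k. The number of "significant" axes (minimum 1,
capped at 2 by default — the dominant-axis regime the package targets)
feeds the stability indices; the cap and α are parameters.

**Known limitation.** Gollob's test treats λ_1 as an ordinary sum of
squares although it is the largest eigenvalue of a noise matrix under the
null, so the PC1 test is anticonservative: measured size 0.103 at α = 0.05
(G = 10, E = 3, R = 3, 4000 null simulations), while the last axis's test
is conservative (0.003). Treat per-axis p-values as descriptive guidance,
not calibrated inference; this is a property of the conventional method,
reported here rather than patched.

### Signal/noise partition of the interaction

The interaction SS mixes a repeatable low-rank pattern with noise, whose
expected share is df(ENV:GEN)·MS_res. The package reports

    noise_SS  = df(ENV:GEN) x MS(Residuals)
    signal_SS = SS(ENV:GEN) - noise_SS   (clamped at 0, flagged)

and both as percentages of the interaction SS. A trait whose signal share
is large (≈ 90% for field dormancy intensity in the motivating trial) is
the regime where AMMI-based selection is informative.

## Selection statistics

- **ASI** (AMMI stability index): ASI_i = sqrt(Σ_k score_ik²·θ_k²) over the
  retained axes, with θ_k as *fractions* (0–1). Either the percent or the
  fraction convention preserves the ranking; fractions keep the index
  scale-free. Lower = more stable.
- **Ranks**: fractional average-rank ties (scipy `rankdata`), rank 1 =
  most stable for ASI, rank 1 = best mean for the trait (descending by
  default for every trait here, including IOD where more dormancy is
  better; direction is a parameter).
- **SSI** = rASI + rY, exactly. Least SSI = stable *and* high-performing.
- **YREM**: Y_ij = X_ij/max_i X_ij per environment; a genotype's
  across-environment average is 1 exactly when it is never beaten, and
  1 − avg is the share of attainable performance lost to crossover
  interaction. Scale-free per environment by construction.

## Mixed-model evaluation (BLUP / WAASB)

With genotype and g×e random, variance components come from the
expected-mean-squares identities of the balanced design (σ̂e² = MS_res,
σ̂ge² = (MS_ge − MS_res)/R, σ̂g² = (MS_gen − MS_ge)/(RE); negative estimates
clamped to zero and flagged). On balanced data these equal REML whenever
the estimates are interior — the test suite verifies this against a
numerically maximised restricted likelihood and against Henderson's
mixed-model equations solved directly.

Predicted genotype means shrink observed entry means toward the grand mean
by h = σ̂g²/(σ̂g² + σ̂ge²/E + σ̂e²/(ER)), which is also the entry-mean
broad-sense heritability H²; selection accuracy is As = √H², and
CV = 100·σ̂e/μ. WAASB is the weighted average of a genotype's absolute
IPCA scores from the SVD of the *shrunken* interaction matrix (the BLUPs of
the g×e deviations, i.e. the double-centered cell means times
σ̂ge²/(σ̂ge² + σ̂e²/R)), weights proportional to each axis's variance share,
summed over all axes. The mean × WAASB plane is cut at the two
across-genotype means into quadrants I–IV (IV = above-mean trait,
below-mean WAASB: productive and stable); points exactly on a threshold
resolve to the favourable side, so the double boundary case lands in IV —
a documented, configurable tie rule.

As = √H² is the accuracy of entry-mean selection; per-season variants of
As and CV can be computed by running the model per environment but are not
asserted against any external values.

## Dormancy screening

IOD pools germinated/total counts over replicates at the latest recorded
day ≤ the requested day (count-pooling, not averaging of percentages, so
unequal seed totals are weighted correctly). Classes: dormant if
IOD21 > 80, non-dormant if IOD21 < 20, else intermediate; both cut-offs are
parameters (20 is the operational non-dormant cut-off; 10 appears in some
screening protocols and can be configured). Marker concordance
cross-classifies allele-specific marker calls with the phenotypic class;
intermediate genotypes are untestable, and both discordance directions are
listed by name without interpreting them (recombinant vs assay failure is
not decidable from these data). The donor report requires, by default:
dormant class with min(IOD15, IOD21) ≥ 90 across assays (the operational
reading of "2–3 weeks of > 90% dormancy"), average YREM ≥ 0.95 on the
dormancy traits, and an SSI rank ≤ 10 for at least one economic trait;
every criterion's evidence is attached per genotype and thresholds only
ever shrink the selected set as they tighten.

## Synthetic trials

The generator draws y_ijr = mu + g_i + e_j + Σ_k √λ_k·α_ik·γ_jk + η_ij +
ε_ijr with random orthonormal α, γ orthogonal to the ones vector — the
planted term is therefore exactly a rank-k interaction with zero margins —
plus unstructured interaction noise η and plot error ε. The truth record
carries every realised effect, the implied signal share
R·Σλ/(R·Σλ + df·(σe² + R·ση²)) and the implied entry-mean H². Defaults
(G = 32, E = 3, R = 3, μ = 70, σg = 12, σε = 5, ση = 0.5, rank-1 λ = 4800,
seasonal shifts +4/−3/−1) emulate the motivating trial's high-signal
regime: genotype main effect dominating, one interaction axis at ≈ 90% of
the interaction SS, entry-mean H² ≈ 0.83, on an unbounded gram-like scale.
Percentage traits can be generated by clipping the latent scale to
[0, 100] (`percent=True`); clipping above ~5% of records triggers a warning
because the ANOVA algebra degrades, and no default analysis relies on
clipped data. "Donor" genotypes (optional) receive a genotype effect of
2.5 genotypic SDs and are excluded from the structured interaction axes:
stable, high-value truth for end-to-end selection checks.

Germination counts are cumulative binomial thinning of the still-dormant
pool, so counts are monotone in day by construction; class schedules
(dormant 0.97/0.95 still-dormant at days 15/21; non-dormant 0.15/0.05;
intermediate 0.60/0.45) put expected IOD21 above 90 for donors and below
20 for non-dormant lines. One integer seed drives every draw through a
single generator stream in a documented order.

What the generator does *not* emulate: the bounded, strongly bimodal
distribution of real dormancy percentages (dormant vs non-dormant lines
piling at 100 and 0), season-specific error variances, spatial field
trends, and unbalanced or missing plots. Passing recovery tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to those departures.

## Numerical choices and problem sizes

- SVD via LAPACK (`numpy.linalg.svd`); eigen-oracle comparisons in the
  tests use the cross-product eigendecomposition as the independent route.
- SS additivity and θ sums are maintained to ~1e−10 relative; tests assert
  at that level on ≤ 10×5 matrices.
- Published-table arithmetic is asserted exactly (noise SS, SSI) or at the
  printed-precision propagation bound (YREM averages recomputed from
  2-decimal season values: ±0.0101).
- Recovery suites use 200 simulated trials at the reference conditions and
  1000 null simulations at a reduced design (G = 10, E = 3, R = 3) for test
  calibration; these sizes give Monte-Carlo SEs well inside the asserted
  tolerances while keeping the default test run around a minute.
- Degenerate inputs: all-equal mean squares give zero variance components
  (flagged, not an error); σg² = 0 shrinks every predicted mean to μ;
  zero-interaction data give WAASB ≡ 0 and ASI ≡ 0.
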