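# metstab

Stability analysis of balanced multi-environment trials (MET) for plant
breeders, built around the workflow used to pick *stable fresh-seed-dormancy
donors* in Spanish-type groundnut: genotypes are evaluated over several crop
seasons and the question is which lines combine a high trait value (intensity
of dormancy, pod yield, seed weight, shelling %) with *consistency* across
seasons despite genotype × season interaction.

The package provides, as statsmodels-style model/results objects plus
functions:

- **Pooled ANOVA** over seasons (RCBD blocks nested in seasons) and a
  Levene homogeneity-of-error-variance test that licenses pooling;
- **AMMI**: SVD of the double-centered genotype × season means,
  y_ijr = μ + g_i + e_j + Σ_k √λ_k α_ik γ_jk + ε, with Gollob per-axis F
  tests, AMMI1 biplot coordinates, and the **signal/noise partition** of the
  interaction SS (noise = df_GE × MS_error);
- **Stability and selection indices**: ASI_i = √(Σ_k score²_ik θ²_k),
  fractional ranks, SSI = rASI + rY, and YREM (Y_ij = X_ij / max_i X_ij,
  the share of attainable performance kept under crossover interaction);
- **BLUP**: EMS variance components, shrunken predicted means, entry-mean
  H², selection accuracy √H², CV, **WAASB** stability scores (weighted
  absolute IPCA scores of the shrunken interaction) and mean × WAASB
  quadrants;
- **Dormancy screening**: intensity of dormancy from germination counts,
  dormant/non-dormant classification, marker–phenotype concordance and a
  combined donor report;
- a **synthetic-trial generator** with planted truth (signal share,
  heritability, donor genotypes) for validation, and a `metstab` CLI that
  runs any stage or the whole pipeline.

Bundled under `metstab.datasets` are the published *summary* tables of a
32-genotype × 3-season groundnut dormancy trial (ANOVA mean squares, rank
triples, YREM tables) used to verify all inter-table arithmetic.

## Worked example

```python
from metstab import AMMI, BLUP, SimConfig, simulate_met

table, truth = simulate_met(SimConfig(n_donors=5), seed=1)
res = AMMI(table, "yield").fit()
print(res.summary())
```

```
Interaction principal components (Gollob F tests)
     df          ss        ms        F       p  pct_gsi
pc
PC1  32  17280.3236  540.0101  23.8218  0.0000  97.4224
PC2  30    457.2038   15.2401   0.6723  0.9012   2.5776
significant axes retained: 1 (alpha = 0.05)

interaction SS 17737.53 = signal 16332.06 (92.08%) + noise 1405.46 (7.92%)
```

One interaction axis carries 97% of the genotype × season SS, and 92% of
that SS is repeatable signal above the noise floor df_GE × MS_error — the
regime in which AMMI-based selection is informative. The five planted
donor genotypes head the simultaneous selection index:

```python
print(res.stability_table().sort_values("SSI").head(4).round(3))
```

```
            ASI  rASI     mean   rY  SSI
genotype
G01       0.133   1.0  102.973  3.0  4.0
G02       0.153   3.0  107.375  1.0  4.0
G03       0.134   2.0  102.513  4.0  6.0
G05       0.317   4.0  103.047  2.0  6.0
```

Low ASI (stable: small interaction scores) plus a top mean rank gives the
smallest SSI. The mixed-model view agrees:

```python
blup = BLUP(table, "yield").fit()
print(f"H2={blup.heritability:.3f} As={blup.accuracy:.3f} CV={blup.cv:.2f}")
# H2=0.879 As=0.938 CV=6.42
```

Entry-mean heritability 0.88 (planted truth 0.83), so observed genotype
means are shrunk only mildly toward the grand mean, and selection accuracy
is √H² = 0.94. `blup.waasb` and `blup.quadrants` place each genotype in
the mean × stability plane (quadrant IV = productive and stable).

The same pipeline runs from the shell on any conforming long-format CSV
(`genotype,env,rep,trait,value`):

```sh
metstab simulate --out demo --seed 1
metstab report --input demo/met.csv --out demo_report
```

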