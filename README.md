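# diallelkit

Combining-ability analysis of spontaneous chromosome doubling in maize
haploids, built around Griffing's Method 1 (full diallel with parents and
reciprocal crosses), Model I (fixed effects).

Doubled-haploid (DH) maize breeding depends on making haploid plants
fertile so they can be self-pollinated.  A minority of genotypes do this
*spontaneously*, without colchicine or other mitosis inhibitors.  Two plot
traits quantify that ability:

* **HMF** — haploid male fertility: percent of haploid plants in a plot
  shedding pollen;
* **HF** — haploid fertility: percent of haploid plants setting seed on
  selfing (the operational success rate of a DH pipeline).

`diallelkit` takes plot-level haploid counts from a p × p diallel trial
(or pre-computed entry-mean tables) and produces the quantities a breeder
needs to decide whether these traits can be improved by selection: GCA,
SCA, reciprocal/maternal effect estimates with t tests, the
combining-ability ANOVA, descriptive variance components with Baker's
ratio and narrow/broad-sense heritabilities, and mid-parent / GCA-sum
hybrid prediction.  It ships the published summary tables of two
8-parent tropical diallel experiments as fixtures, plus a simulator that
generates study-sized trials (8 parents × 2 environments × 2 replicates ×
100 kernels per plot, binomial fertility counts) with known architecture.

## Model

Entry means over environments and replicates form a complete p × p grid
x_ij (mother i × father j; parents on the diagonal).  Method 1 decomposes

    x_ij = μ + g_i + g_j + s_ij + r_ij,      r_ij = (m_i − m_j) + n_ij

with Σ g_i = 0, s_ij = s_ji, Σ_j s_ij = 0, r_ij = −r_ji.  The closed-form
estimators (x_i. row sums, x_.i column sums, x.. total):

    ĝ_i  = (x_i. + x_.i)/2p − x../p²
    ŝ_ij = (x_ij + x_ji)/2 − (x_i. + x_.i + x_j. + x_.j)/2p + x../p²
    r̂_ij = (x_ij − x_ji)/2,   m̂_i = (x_i. − x_.i)/2p,   n̂_ij = r̂_ij − (m̂_i − m̂_j)

The decomposition is saturated (it reproduces every cell exactly), and its
components are orthogonal, so their sums of squares partition the genotype
sum of squares of the plot-level ANOVA

    y_ijkm = μ + g_ij + l_k + (gl)_ijk + r_mk + e_ijkm .

From the mean-square chain the package derives σ²_GCA, σ²_SCA, σ²_A =
2σ²_GCA, σ²_D = σ²_SCA, Baker's ratio 2σ²_GCA/(2σ²_GCA + σ²_SCA), the
GCA/SCA variance ratio, h² = σ²_A/σ²_P and H² = (σ²_A + σ²_D)/σ²_P.

## Worked example

Simulate a study-sized trial anchored to the Diallel I parents, analyze
both traits and predict hybrids from the published tables:

```sh
diallel report --experiment diallel1 --seed 7 --outdir out/
```

prints (and writes per-stage CSVs plus `report.txt` / `MANIFEST.json`):

```
HMF: Baker ratio 0.83, GCA/SCA 2.44, h2 0.78, H2 0.94
HF: Baker ratio 0.80, GCA/SCA 2.01, h2 0.74, H2 0.93
HMF published tables: r(MPV:F1P) 0.83, r(GCA:F1P) 0.86
HF published tables: r(MPV:F1P) 0.82, r(GCA:F1P) 0.89
```

The first two lines are variance-component summaries of the *simulated*
trial — Baker's ratios near 1 say additive (GCA) effects dominate, so mass
selection on parental performance should work.  The last two lines are
computed from the published parent means, hybrid BLUEs and GCA effects:
mid-parent values alone predict F1 performance at r ≈ 0.8, and summed GCA
effects slightly better.

The same stages are available piecemeal:

```sh
diallel simulate --seed 3 --out trial.csv          # 256-plot synthetic trial
diallel traits   --in trial.csv --out traits.csv   # append hmf/hf columns
diallel analyze  --in traits.csv --trait hmf --outdir out/
diallel predict  --experiment diallel1 --trait hmf --out pred.csv
```

or from Python:

```python
import diallelkit as dk

trial, truth = dk.simulate_paperlike("diallel1", seed=7)
trial = dk.add_trait_columns(trial)
means = dk.means_to_entry_table(trial, "hmf")
effects = dk.estimate_effects(means)          # ĝ, ŝ, r̂, m̂, n̂
```

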