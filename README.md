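# granulekit

Starch granule size-distribution deconvolution and pulldown-enrichment
statistics for wheat grain phenotyping.

Triticeae endosperm starch contains two granule populations: large,
discoid **A-type** granules initiated early in grain development, and
small, spherical **B-type** granules initiated around 15–20 days post
anthesis. Mutations in granule-initiation proteins shift how many
B-type granules form and how large they grow, and the standard readout
is a Coulter-counter particle-size distribution of purified starch.
granulekit implements the quantitative pipeline around that readout for
researchers phenotyping wheat (and other Triticeae) starch mutants:

- **I/O** for binned or raw particle-diameter CSVs and replicate
  protein-quantification tables (`granulekit.io`).
- **Size distributions**: number- and volume-weighted relative
  distributions, percent of granules below a diameter threshold, and
  absolute granule counts per mg fresh tissue from volumetric-mode
  counting (`granulekit.distributions`).
- **Mixture deconvolution**: the volume-weighted distribution is
  modelled as a one- or two-component log-normal mixture in
  ln-diameter,

  f(ln d) = w·N(ln d; μ_B, σ_B²) + (1−w)·N(ln d; μ_A, σ_A²),

  fitted by seeded multi-start bounded least squares on the volume-share
  density per unit ln d. The mixing weight *w* of the smaller-median
  component estimates the **B-type granule volume percentage**
  (100·w), and exp(μ + σ²/2) gives each component's volume-weighted
  mean diameter (`granulekit.mixture`).
- **Amylose colorimetry**: the empirical iodine calibration
  amylose% = 1.4935·exp(2.7029·A620/A535), plus starch content in
  glucose equivalents (`granulekit.colorimetry`).
- **Pulldown enrichment**: replicate abundance ratios (capped at 100),
  Welch t-tests on log abundances, Benjamini–Hochberg adjustment, and
  the ≥2-fold / P<0.05 enrichment filter (`granulekit.enrichment`);
  the published BGC1-pulldown reference list ships in
  `granulekit.datasets`.
- **Group statistics**: one-way ANOVA with Tukey HSD (Tukey–Kramer for
  unbalanced designs) and a compact letter display
  (`granulekit.groupstats`).
- **Synthetic data**: seeded generators for genotype-like granule
  populations (wild-type-, *phs1*- and *bgc1*-like presets, plus a
  developmental series) and spiked proteomics tables
  (`granulekit.simulate`).

## Worked example

Simulate a wild-type-like population of 100,000 particles (the B
component holds 30 % of starch volume with a 5 µm median; the A
component 70 % at 21 µm), then deconvolve it:

```python
import granulekit as gk

spec = gk.SyntheticSpec.from_preset("WT", seed=1)
data, truth = gk.simulate_granules(spec)

dist = gk.to_distribution(data, weighting="volume")
fit = gk.fit_mixture(dist, n_components=2, seed=1)
metrics = gk.derive_granule_metrics(fit)

print(round(metrics.b_volume_percent, 2))   # 29.46
print(round(metrics.mean_diameter_B, 2))    # 5.22
print(round(metrics.mean_diameter_A, 2))    # 21.6
print(round(gk.percent_small_granules(data), 2))  # 97.37
print(gk.qc_particle_count(data))           # pass
```

The fitted B-type volume percentage (29.46 %) recovers the generating
30 % within counting noise; the component mean diameters land on the
preset medians inflated by exp(σ²/2). Nearly all granules are below
10 µm *by number* (97.37 %) even though B-type granules hold only 30 %
of the volume — the expected signature of a bimodal A/B distribution.

The enrichment filter applied to the bundled BGC1-pulldown reference
list retains all 13 starch-metabolic proteins:

```python
result = gk.filter_enriched(gk.bgc1_pulldown_table(), fold=2.0, alpha=0.05)
print(result.n_retained)  # 13
```

And the amylose calibration maps an absorbance pair to an apparent
amylose content:

```python
gk.apparent_amylose(gk.AbsorbancePair(a535=0.521, a620=0.223))  # 4.75 %
```

The same pipeline is scriptable from the shell:

```sh
granulekit simulate --preset WT --seed 1 --out wt.csv
granulekit fit --input wt.csv --model 2 --seed 1
granulekit amylose --a535 1.0 --a620 0.0   # 1.4935
```

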