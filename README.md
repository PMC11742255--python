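# soilcue

Soil microbial **carbon use efficiency (CUE)** from ¹⁸O-H₂O stable-isotope
labeling, soil **stoichiometric C/N imbalance** from chloroform
fumigation–extraction, and **bacterial–fungal co-occurrence network
complexity** from SparCC-style compositional correlation inference — as one
tested, reproducible pipeline.

The package is aimed at soil microbial ecologists analysing ¹⁸O-qSIP
incubation experiments with a factorial field design (here: mycorrhizal type
AM/ECM × rhizosphere/non-rhizosphere position, replicated per tree species),
who want every derived quantity — growth, respiration, CUE, biomass
stoichiometry, diversity, network topology — computed by auditable code with
recovery tests against a synthetic study generator with known ground truth.

## The quantities at the core

**Growth from ¹⁸O incorporation.** Oxygen in newly synthesised DNA derives
from soil water, so labelling soil water to at%_final ¹⁸O makes the at% ¹⁸O
excess of DNA a measure of gross DNA production over the incubation:

    DNA_produced = O_total · (at%_excess / 100) · (100 / at%_final) · (100 / 31.21)
    Growth       = f_DNA · DNA_produced · 1000 / (DW · t)        [ng C g⁻¹ h⁻¹]

with O_total the O content (μg) of the DNA extract, 31.21 the mass % of O in
DNA, f_DNA = MBC / DNA content the biomass-to-DNA conversion, DW the dry soil
mass (g) and t the incubation time (h).

**Respiration from headspace CO₂** (blank-corrected mixing ratio R_S in ppm,
ideal gas law; p in kPa, V in L, n = 12.01 g mol⁻¹, R = 8.314 J mol⁻¹ K⁻¹):

    Respiration = R_S / (DW · t) · (p · n / (R · T)) · V · 1000  [ng C g⁻¹ h⁻¹]

**CUE** and microbial stoichiometry:

    CUE = Growth / (Growth + Respiration)
    MBC = ΔDOC / 0.45,   MBN = ΔTDN / 0.54
    imbalance = (DOC / TDN) / (MBC / MBN)

**Networks.** Bacterial and fungal OTU tables are rarefied, prevalence-filtered
(taxa in < 80% / < 50% of samples excluded), merged, and correlated with a
SparCC estimator (median of 20 Dirichlet-resampled log-ratio-variance
estimates; pseudo-P from 100 permutation bootstraps). Only robust (|r| > 0.65)
and significant (P < 0.05) pairs become edges; topology (avgK, density,
clustering, degree centralization, modularity, path metrics, …) is computed
per network for the four niches AM/ECM × rhizosphere/non-rhizosphere.

## Worked example

Rate equations on a single vial:

```python
from soilcue.isotope import dna_produced, growth_rate, respiration_rate, cue

d = dna_produced(O_total=10.0, atpct_labeled=5.2, atpct_control=0.2, atpct_final=20.0)
r = respiration_rate(Rs_ppm=1000.0, DW=1.0, t=24.0)
print(f"{d:.4f}")   # 8.0103  (ug DNA produced)
print(f"{r:.2f}")   # 380.97  (ng C g-1 h-1)
```

Full synthetic study from the shell:

```bash
soilcue simulate --seed 4 --out-dir study --noise-cv 0.15
soilcue all --config run.yaml        # paths to the study tables + seed
```

which logs one line per stage and writes the result bundle:

```
soilcue.pipeline: rates: 150 rows; chemistry: 150 rows
soilcue.pipeline: network ECM/non_rhizosphere: 35 samples, 73 taxa -> 24 nodes, 36 links
```

`rates.tsv` then holds one row per sample —

```
sample_id    growth  respiration  uptake  cue    ...
AM_sp01_N_1  95.97   279.60       375.57  0.256  ...
```

— i.e. this AM non-rhizosphere sample grew at ~96 ng C g⁻¹ h⁻¹ while
respiring ~280, allocating 25.6% of its C uptake to growth. The statistics
table reports the factorial tests (two-way type-II ANOVA when Shapiro–Wilk
accepts residual normality, Scheirer–Ray–Hare otherwise), e.g. for CUE the
mycorrhizal-type effect F = 88.5, p ≈ 1e−16 — the generator plants a 0.2
absolute CUE difference between ECM and AM non-rhizosphere soils, and the
pipeline recovers it. `topology.tsv` gives one column per niche network
(n = 24 nodes, L = 36 links, avgK = 3.0 for the planted 4-taxon co-abundance
blocks), and `network_ks.tsv` the pairwise Kolmogorov–Smirnov comparisons of
degree distributions.

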