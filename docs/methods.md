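# Methods

## Rate model and its assumptions

The ¹⁸O-qSIP growth calculation assumes (i) all oxygen in newly synthesised
DNA derives from soil water at the labelled at%_final, (ii) mortality of
newly labelled cells over the short (default 24 h) incubation is negligible,
and (iii) the biomass-to-DNA ratio f_DNA is constant within a sample over
the incubation. f_DNA is computed per sample from that sample's MBC and DNA
content rather than as a group mean, reading the conversion factor literally
as a per-sample property. A negative at% excess (control above labelled,
possible under measurement noise) is clipped to zero and flagged: net
negative DNA production contradicts assumption (ii) and is unphysical.

Respiration converts the blank-corrected headspace CO₂ mixing ratio to mass
of C with the ideal gas law. The CO₂ reading is taken from the labelled vial
only (the control vial's CO₂ is not used). Sample readings below the blank
mean are clipped to zero respiration with a logged warning. "Turnover rate"
is implemented as growth / MBC; the definition is recorded in the output
table metadata because the term is used loosely in the field.

Key defaults, all overridable through `IncubationConfig`:

| parameter | default | unit | rationale |
|---|---|---|---|
| pressure p | 101.325 | kPa | standard atmosphere |
| temperature T | 288.15 | K | 15 °C incubation |
| headspace V | 0.018 | L | 20 ml vial minus 2 ml sample bottle |
| O in DNA | 31.21 | mass % | elemental composition C₃₉H₄₄O₂₄N₁₅P₄ |
| at%_final | 20 | at% ¹⁸O | labelling level of soil water |
| control at% | 0.2 | at% ¹⁸O | natural ¹⁸O abundance |

Fumigation–extraction uses extraction efficiencies 0.45 (C) and 0.54 (N);
negative flush differences are clipped to zero with an audit flag. The
stoichiometric imbalance uses the *unfumigated* extract DOC/TDN as the
resource ratio; it is unit-free provided all concentrations share a μg g⁻¹
dry-soil basis (the pipeline requires and documents this).

## Community tables

Rarefaction is read-depth subsampling without replacement (multivariate
hypergeometric draw, seeded), to per-domain default depths of 20 981
(bacteria) and 8542 (fungi) reads per sample. Richness and Shannon diversity
(natural log) are computed on the rarefied tables. Prevalence filtering
keeps taxa present in **at least** the threshold fraction of samples
(inclusive boundary: exactly 80% presence survives the 0.8 bacterial
threshold), defaults 0.8 for bacteria and 0.5 for fungi.

## Correlation inference and networks

The SparCC-style estimator works from log-ratio variances
t_ij = Var[log(x_i/x_j)], which are invariant to per-sample closure. Basis
variances are solved from the row-sum linear system ((D−2)I + 𝟙𝟙ᵀ)ω² = T𝟙
under the sparsity assumption; the most strongly correlated pair exceeding
|ρ| = 0.1 is excluded from the system and the system re-solved, up to 10
rounds, with a guard that every taxon keeps at least two partners (and a
least-squares fallback for degenerate systems). The reported correlation is
the element-wise median of 20 estimates, each computed on a fraction matrix
drawn from the per-sample Dirichlet(counts + 1) posterior — the +1
pseudocount is also the zero-handling policy. Pseudo P-values use a
permutation null (each taxon's counts shuffled independently across
samples), 100 bootstrap re-estimates and the add-one rule
p = (1 + #{|r_b| ≥ |r_obs|})/(B + 1), so the smallest attainable p is
1/(B+1).

Edges require |r| > 0.65 **strictly** and p < 0.05 **strictly**; isolated
taxa are dropped before topology (node counts follow the convention of
counting connected OTUs). Networks are built per niche (AM/ECM ×
rhizosphere/non-rhizosphere) on that niche's samples only, with bacteria
and fungi prevalence-filtered separately and then merged into one count
table that the estimator renormalises jointly per sample.

Topology: density 2L/(n(n−1)); avgK 2L/n; clustering = mean local
clustering with 0 for degree < 2; Freeman degree centralization
Σ(k_max − k_i)/((n−1)(n−2)), undefined (NaN) below 3 nodes; weighted degree
uses |r| as edge weight. Diameter, average path length and mean eigenvector
centrality (leading eigenvector of the dense adjacency, L2-normalised) are
computed on the largest connected component — disconnected co-occurrence
networks are the norm, and this choice is recorded in the run manifest.
Communities and modularity come from greedy modularity maximisation, which
is deterministic; interactive layout-based tools are not bit-reproducible,
which is why a seeded/deterministic detector was chosen. Degree
distributions of two networks are compared with a two-sample
Kolmogorov–Smirnov test.

## Statistics

Responses are routed by a Shapiro–Wilk test on the residuals of the full
two-way OLS fit: normality accepted → two-way **type-II** ANOVA (type II
because the 8 AM vs 7 ECM species design is unbalanced); rejected but
response positive → re-test on the log scale; otherwise Scheirer–Ray–Hare.
The route and the Shapiro p-values are recorded in the output.

Scheirer–Ray–Hare runs the same type-II decomposition on mid-ranks and
refers H = SS_effect/(SS_total/(N−1)) to χ² with the effect df. Because the
denominator is the variance of the mid-ranks actually assigned, the
classical tie correction 1 − Σ(t³−t)/(N³−N) is built in, and the
single-factor case reduces *exactly* to tie-corrected Kruskal–Wallis.

Wilcoxon contrasts default to the unpaired rank-sum test (exact
distribution for n ≤ 25 without ties, otherwise normal approximation with
continuity correction); a paired signed-rank mode exists for designs paired
by tree individual, but pairing is not assumed. The Spearman screen reports
raw two-sided p-values without multiplicity correction, matching common
reporting practice for exploratory predictor screens; a Benjamini–Hochberg
step can be applied downstream. Network topology metrics exist once per
niche and are broadcast to that niche's samples for the screen, so within
one mycorrhizal type they take two distinct values — the screen's
correlations against topology are correspondingly coarse, and are reported
as such.

## Synthetic-data generator

The generator inverts the analysis: group-level true rates and pools for
each (mycorrhizal type, position) cell are converted into raw measurements,
so at zero noise every downstream stage recovers the truth exactly
(relative error < 1e−9 is asserted in tests; observed ≈ 1e−15). Defaults
emulate the study design: 8 AM + 7 ECM species × 2 positions × 5 replicates
= 150 samples. Planted contrasts: ECM non-rhizosphere CUE 0.45 vs AM
non-rhizosphere 0.25 (an absolute difference of 0.2, growth-driven); higher
respiration in ECM rhizosphere (CUE 0.30); higher MBC, MBN and DOC/TDN
under ECM; growth magnitudes inside the field-observed 16–390 ng C g⁻¹ h⁻¹
range. Per-sample truth equals the cell mean; all sampling variation enters
through measurement noise.

Noise is multiplicative log-normal with mean one (all measured quantities
are positive), applied independently to the O content of the extract, the
at% excess, the produced CO₂ and each fumigation extract concentration. The
measurement-error magnitude is not something desk work can pin down, so the
coefficient of variation is a config default (0.15) exposed everywhere.
Because recomputed growth is a product of two noisy readings, its CV at
noise_cv = 0.1 lands near 0.14, which the tests bound in [0.08, 0.18].
The fumigation-measured MBC (not the true MBC) is carried into the
incubation records, reproducing the real workflow's error propagation
through f_DNA.

OTU counts are multinomial reads over multivariate log-normal basis
abundances with a known basis correlation matrix — the generative model
under which SparCC is consistent. Study-scale defaults: 60 bacterial taxa at
depth 25 000 and 30 fungal taxa at depth 10 000 (rarefied downstream to
20 981 / 8542), each domain carrying three planted 4-taxon blocks of basis
ρ = 0.85 among the abundant taxa plus a rare tail that the prevalence
filters remove. What the generator does **not** emulate: taxon-specific
growth (the OTU tables are statistically independent of the planted rate
contrasts), sequencing error, chimeras, spatial or temporal autocorrelation,
and per-species random effects. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to every failure mode of real amplicon data.

## Problem sizes and numerical choices

The default pipeline run (150 samples, 4 networks, 20 SparCC iterations,
100 bootstraps) completes in well under a minute; the acceptance script's
recovery study uses 50 taxa × 200 samples at depth 50 000 and 1000 null
simulations for test calibration, sizes at which every Monte-Carlo check is
stable across seeds. Correlations are clipped to [−1, 1]; basis variances
floored at 1e−12; all randomness flows from explicit seeds, with per-stage
seeds derived from the master seed by hashing the stage name so stages stay
independent under one seed.

## Known limitations

- A null correlation estimated from n samples has sampling noise of sd
  ≈ 1/√(n−1); at n = 200 the mean absolute null estimate is therefore
  ≈ 0.056 for this (or any consistent) estimator. Claims that null pairs
  average below 0.05 at that sample size are not attainable and the test
  suite documents the floor rather than asserting past it.
- Rarefaction-based diversity and single-table SparCC are the study's
  workflow choices and are implemented as such; variance-stabilising or
  model-based alternatives are out of scope.
- The pipeline requires consistent μg g⁻¹ concentration inputs; it does not
  attempt unit inference.
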