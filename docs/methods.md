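# Methods

This note documents the models, conventions and numerical choices
behind `tcqe`, and what the synthetic-data validation does and does not
demonstrate.

## Network pharmacology arm

**Screens.** Compounds pass at oral bioavailability ≥ `ob_min` (30%)
AND drug-likeness ≥ `dl_min` (0.18), both inclusive; an allow-list
force-includes literature-supported compounds that fail the gate (the
canonical example being a pharmacopoeia index compound with poor
predicted bioavailability). Target predictions pass at probability
strictly > `prob_min` (0.1); duplicate (compound, target) pairs keep the
maximum probability. Disease genes pass at relevance strictly greater
than the median of *all* input scores, so at most half survive.

**Graph and centralities.** The compound–target–disease graph is
undirected, unweighted and simple — the sources give no direction or
weight semantics, and the conventions match what network-visualisation
tools report. Betweenness is normalised by (n−1)(n−2)/2; closeness uses
the component-scaled form (r−1)/(n−1) × (r−1)/Σd, where r is the size
of the node's reachable set, so values stay in [0, 1] on disconnected
graphs and isolated nodes score 0 on both.

**Key-target screen.** Survivors need degree strictly greater than
`degree_median_multiplier` (2) × median degree AND betweenness ≥ its
median AND closeness ≥ its median ("not lower than" is inclusive;
degree is strict). Medians are computed over target-role nodes only by
default — the screen's object is disease targets, and compound nodes
would distort the reference distribution — and isolated nodes are
excluded by default; both choices are configurable (`scope`,
`include_isolated`) because the underlying convention is genuinely
ambiguous in practice. Output is ranked by degree, ties broken by
closeness then node id.

## Metabolomics arm

**QC RSD filter.** Per feature, RSD% = sample SD (ddof 1)/mean × 100
over the pooled-QC injections; features are dropped only when RSD is
strictly above `qc_rsd_max` (30%), so a feature at exactly 30% is kept.
Features with zero QC mean are unquantifiable and dropped.

**LOESS drift correction.** Per feature, a locally weighted linear
regression (tricube weights, degree 1, span 0.75) of QC intensity on
injection order is evaluated at every sample's injection order by
linear interpolation, flat beyond the QC range. Each intensity is
divided by the local drift and rescaled by
median(QC)/median(QC/drift), which preserves the feature's QC median
*exactly* (a plain rescale by median(QC) preserves it only
approximately when the fitted drift varies along the run). When the
fitted drift is nonpositive anywhere the feature is left uncorrected
and flagged. The correction is exactly the identity when the QC
intensities are constant; with noisy QCs it necessarily smooths QC
noise as well as drift, so on a drift-free table it is only
approximately neutral — validation therefore checks exact identity on
constant-QC tables and RSD improvement on drifted ones.

**PCA.** Mean-centred SVD; unit-variance scaling by default (pareto and
none available); zero-variance features are dropped under unit-variance
scaling. Component signs follow a deterministic convention (the
largest-magnitude loading of each component is positive).

**OPLS-DA.** Classes are encoded ±1; X is mean-centred and
unit-variance scaled (the de-facto default of commercial discriminant-
analysis software; pareto available). Orthogonal components are removed
by the orthogonal-signal-correction sequence, then one predictive
component is fitted; predictive scores are orthogonal to every
orthogonal score by construction (checked to |cos| < 1e−8 on every
fit). R²X and R²Y come from the full fit. Q² uses k-fold
cross-validation (7 folds) with venetian-blind fold assignment:
within each class, samples sorted by injection order receive folds
0,1,…,k−1,0,… — consecutive injections never share a fold, and folds
are stratified by class. Each group needs ≥ 3 samples.

**VIP.** Computed over the predictive component; with a single
component VIP_j = √p · |w_j|/‖w‖, so mean(VIP²) = 1 identically
(asserted on every fit).

**Permutation test.** Class labels are shuffled with a seeded
generator; the model is refitted and R²Y/Q² recorded. Two diagnostics
are reported because the classical literature uses both: the empirical
p-value (1 + #{Q²_perm ≥ Q²_obs})/(1 + n_perm) with the pass flag
"max permuted Q² < observed Q²", and the regression intercept of
permuted Q² against the absolute label correlation. The pass flag uses
the max criterion.

**Differential screen.** log₂ fold change of raw group means (B vs A,
orientation declared per run — model-vs-control and treated-vs-model
are separate configured contrasts); two-sample Welch t-test on
log-transformed intensities (raw-scale testing available via config);
a feature is differential iff p < 0.05 and VIP > 1, both strict.
Positive/negative ionisation modes are processed as independent tables
and concatenated after QC filtering.

## Enrichment and integration

Over-representation is the one-sided hypergeometric upper tail with
Benjamini–Hochberg adjustment across tested sets; the default universe
is the union of all GMT members, an explicit universe overrides. No
attempt is made to reproduce any web service's modified statistic
(e.g. EASE); pathways are called enriched at adjusted p ≤ `enrich_p_max`
(0.05). The cross-omics step is an exact sorted intersection of the two
arms' pathway names; integrated targets are the ranked key targets that
belong to at least one common pathway.

## Biopotency arm

**From plate to probits.** Inhibition = 1 − (signal − blank)/(control −
blank), clipped to [0, 1]; replicate inhibitions are averaged per dose;
probits are Φ⁻¹(p) + 5. Inhibitions of exactly 0 or 1 are moved to
1/(4r) and 1 − 1/(4r) (r = replicates) — the standard continuity
adjustment for empirical probits. The probit line is unweighted OLS of
probit on log₁₀ dose — the classical *simple* probability-unit method;
a series needs ≥ 3 usable doses. The dose design is a descending
geometric series (default four levels at ratio 0.5).

**Parallel-line potency.** A common slope b is fitted to test and
reference with separate intercepts (pooled least squares). The log₁₀
potency ratio is M = (x̄_ref − x̄_test) + (ȳ_test − ȳ_ref)/b; potency =
10^M × reference potency. Confidence limits use Fieller's theorem with
the pooled residual variance (df = n_t + n_r − 3) and
g = t²s²/(b²S_xx): limits for M are
(x̄_r − x̄_t) + [m′ ± (ts/b)√((1−g)(1/n_t + 1/n_r) + m′²/S_xx)]/(1−g)
with m′ = (ȳ_t − ȳ_r)/b. g ≥ 1 means the slope is not significantly
nonzero and the assay is rejected as invalid rather than reported with
an unbounded interval. FL% = (high − low)/(2 × potency) × 100. A t-test
of the two separate slopes (pooled residual variance) reports the
parallelism p-value; p < 0.05 flags non-parallelism. The estimate is
scale-equivariant (multiplying all test doses by c divides potency by
c), and a reference assayed against itself scores exactly the assigned
reference potency.

**Unit conventions.** Two anchoring conventions coexist and are never
interconverted: a positive-control drug anchoring the plate at
100 U/mg, and a designated reference batch anchoring batch-to-batch
comparison at 1000 U/μg. The config (`reference_potency`,
`reference_potency_units`) names which scale a run uses.

**Method validation.** Precision/repeatability/stability are reported
as RSD% of replicate potency determinations with their n.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (spec, seed) and write a
`ground_truth.json` sufficient to score every downstream screen.

* **Network generator** — compounds straddle the OB/DL gate (half pass
  by default), prediction probabilities straddle 0.1, disease-gene
  relevance scores straddle their median. Background targets receive
  1–3 compound links, so the degree median is small and planted hubs
  (wired to 80% of active compounds by default) are the only nodes that
  can clear the 2×median screen — which is what makes exact
  ground-truth recovery a meaningful test.
* **Metabolomics generator** — feature baselines are lognormal
  (location 11.5, scale 1.0 on the log scale, i.e. ion-count-like
  intensities); replicate noise is multiplicative with CV 20%; planted
  features (default 20 at 2-fold) are perturbed in one group; QC
  injections are the pooled group mean with the same CV, interleaved
  every 4 runs plus lead-in and tail; drift is multiplicative in
  injection order (linear or sinusoidal), matching the ratio-based
  correction. The default table has 100 features: a realistic scale for
  an annotated metabolite table after QC filtering, and — because the
  screen uses a raw p < 0.05 with no multiplicity correction, so its
  expected false-call count grows linearly with the null count — the
  scale at which a 20-true-feature experiment keeps its false-discovery
  proportion near or below 20%. At, say, 200 features the same screen
  runs near 28% FDP; that is a property of raw-p screening, not of this
  implementation.
* **Assay generator** — true inhibition is Φ(b(log₁₀d − log₁₀ED50)),
  ED50_batch = ED50_ref/R; Gaussian noise (σ = 0.1 by default) is added
  on the probit scale per replicate, and signals are back-computed
  through the plate formula with fixed control/blank wells. Putting the
  noise on the probit scale keeps the generative model conjugate to the
  probit-line estimator while still exercising the readings→inhibition
  path; it does not model heteroscedastic fluorescence noise, plate
  edge effects, or non-parallel batches.

None of the generators simulate raw spectra, retention behaviour,
metabolite identities, or database idiosyncrasies, so passing tests
demonstrate correctness of the statistical machinery under its stated
assumptions — not robustness to the full messiness of real LC-MS or
plate data.

## Validation problem sizes

The acceptance checks run: potency recovery at R ∈ {0.25, 0.5, 1, 2, 4}
with σ = 0.1, 4 doses × 3 replicates over 200 seeded assays (median
recovery error and 95% Fieller coverage); metabolomics recovery over 50
seeded cohorts at the generator defaults; permutation behaviour over
10 signal and 10 noise cohorts at 30 permutations; centrality and
hypergeometric brute-force oracles over seeded sweeps of graphs with
≤ 12 nodes and draws with N ≤ 12; drift correction on a 0.01/injection
linear drift. These sizes give stable statistics at desk scale; all are
arguments, so larger studies are one call away.

## Known limitations

* The OPLS-DA implementation covers the two-class, single-predictive-
  component case used for pairwise contrasts; multi-class or
  multi-component variants are out of scope.
* LOESS drift correction assumes smooth multiplicative drift; abrupt
  batch steps need a changepoint-aware method.
* The hypergeometric ORA treats pathways as flat sets; topology-aware
  pathway impact scores are deliberately not implemented.
* Full maximum-likelihood probit regression (iteratively reweighted,
  response-count weighted) is not implemented; the simple unweighted
  method is the supported procedure, which is adequate when per-dose
  means are based on equal replicate counts.
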