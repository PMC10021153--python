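# Methods

## The analysis model

The pipeline treats multimorbidity as a pairwise-association network.
For one gender stratum of a cohort of respondents aged 45+, with binary
indicators for 16 chronic diseases, age in years and a sampling weight
per person:

* **Weighted prevalence** of disease *j* is Σwᵢxᵢⱼ/Σwᵢ.  Dyad
  prevalence (cell *j,k* of the co-occurrence matrix) is the weighted
  proportion with both indicators set; the 120 informative cells are
  the upper triangle of a symmetric 16×16 matrix and each cell is
  bounded above by the smaller of its two marginals (Fréchet bound,
  asserted by property test).
* **Pairwise association.** For each unordered pair the outcome disease
  is regressed on an intercept, the exposure indicator and age centered
  at 60, by logistic maximum likelihood (IRLS/Newton, canonical link, so
  expected and observed information coincide).  Convergence is declared
  when the largest coefficient update falls below 1e−8, capped at 50
  iterations; a coefficient passing ±15 on the logit scale is treated
  as (quasi-)separation and the pair flagged non-estimable rather than
  reported.  Sampling weights enter as frequency-style case weights by
  default; a sandwich (HC0) standard-error option exists because
  model-based SEs under expansion weights are anti-conservative.
  If age is constant in the stratum the age column is dropped (it is
  collinear with the intercept), making the adjustment vacuous and the
  estimate equal to the 2×2 cross-product ratio — which is also how the
  IRLS core is oracle-tested.
* **Symmetrization.** The source analyses report one age-adjusted OR
  per dyad without fixing which disease is the outcome, yet the final
  network is undirected.  The default rule fits both orientations and
  uses the geometric mean of the two adjusted ORs with the larger of
  the two p-values — symmetric and conservative.  `orientation="first"`
  reproduces a single-orientation analysis (outcome = codebook-later
  disease).  The reported `se_log_or` of a symmetrized pair is the
  larger of the two orientation SEs, again the conservative choice.
* **Edge rule.** A dyad becomes an edge iff `p < α` **and**
  `OR ≥ or_min`, defaults α = 0.05 and or_min = 1.2.  Boundary
  semantics are fixed: OR exactly 1.2 is in, p exactly 0.05 is out.
  No multiple-testing correction is applied by default, replicating the
  raw-p convention of the field; a Benjamini–Hochberg option is
  provided as a documented deviation and the report records the number
  of tests (120) either way.
* **Network metrics.** All 16 nodes are kept, isolates included.  Path
  metrics transform the OR weight into a distance, by default
  `d = 1/OR` (stronger association ⇒ shorter path); an `inverse_log`
  transform (`1/ln OR`, defined only for OR > 1) is available.
  Shortest paths are Dijkstra with an absolute tie tolerance of 1e−12;
  betweenness is Brandes' dependency accumulation over weighted
  geodesics, normalized by (n−1)(n−2)/2; closeness uses the
  Wasserman–Faust component correction ((r−1)/Σd scaled by
  (r−1)/(n−1)), so isolated nodes score 0 in both.  Diameter is the
  largest finite pairwise distance (i.e. of the largest component, 0
  for an edgeless graph); density is 2E/(n(n−1)).  Both centralities
  are reported raw and ×100, since published tables print them "in %"
  without documenting the scaling.

Strata are analysed strictly separately; no pooled model is ever
fitted.

## Known inconsistencies in published attribute tables

Published network-attribute tables for this design print a density of
0.50 for both gender networks, which is incompatible with the stated
definition ("actual connections divided by potential connections"):
35 and 25 edges over 16 nodes give 0.29 and 0.21.  Similarly the text
describes diameter as ranging in [0, 1] while printing 2.21 and 1.04,
and an isolated node is printed with nonzero closeness.  The package
implements the stated definitions (density 2E/(n(n−1)), diameter as the
largest geodesic, closeness 0 for isolates) and makes no claim of
numerical equivalence with those printed values; the degree columns and
edge counts, which *are* internally consistent via the handshake lemma,
are shipped as reference constants and checked.

## Synthetic cohorts

`generate_cohort` draws, per person, a 16-dimensional correlated
standard normal **z** with correlation matrix C (validated symmetric,
unit-diagonal, PSD to 1e−8); indicator *j* fires when zⱼ exceeds the
upper quantile of that person's marginal probability
pᵢⱼ = expit(logit(pⱼ) + slopeⱼ·(ageᵢ − 60)).  This Gaussian-copula
threshold model keeps every marginal calibrated (checked by Monte Carlo
at n = 50,000 within 3 standard errors) while a single matrix controls
all 120 pairwise associations; the 2×2 cell probabilities of a
correlated pair equal bivariate-normal orthant probabilities, which the
tests verify against numerical integration at n = 200,000.

Defaults (chosen once, as the package's stand-in for the restricted
survey): per-gender marginal prevalences set to the published
multimorbid-stratum values (e.g. hypertension 0.717 in women, 0.628 in
men); exchangeable latent correlation ρ = 0.15, which induces pairwise
ORs in the 1.2–2 range the edge filter targets; age slope 0.02 per year
for every disease; age truncated-normal(60, 10) with lower truncation
at 45 years; weights LogNormal(0, 0.5); n_per_gender = 10,000 — a
desk-scale stand-in for the published strata of 10,606 and 7,912.

What the generator does **not** emulate: cluster/strata structure in
the weights, state-level heterogeneity, disease-specific correlation
patterns, or item missingness.  Passing tests therefore demonstrate
correctness of the estimators and algorithms under a calibrated joint
distribution, not agreement with the restricted microdata's estimates.

`pair_logistic_cohort` is the second generator: exposure ~
Bernoulli(p), age ~ Uniform(45, 80), outcome ~ Bernoulli(expit(β₀ +
β₁·exposure + β₂·(age−60))), all other indicators 0.  Its true adjusted
OR is exp(β₁) exactly, which gives the recovery tests an analytic
truth: β₁ = log 2 at n = 50,000 must be recovered in [1.9, 2.1], and
under β₁ = 0 the edge-inclusion rate must sit in the binomial band of
the analytic rate P(N(0, se²) ≥ max(log 1.2, z₀.₉₇₅·se)) with
se² = 1/(n·p_out(1−p_out)·p_exp(1−p_exp)).

### Collider selection

Conditioning on multimorbidity (≥ 2 diseases) is conditioning on a
function of the indicators and distorts pairwise associations: two
independent diseases become negatively associated in the selected
subset.  A regression test asserts this effect exists (OR ≈ 1 before
selection, OR < 0.8 after).  Consequently all recovery tests run on
unselected cohorts, and analyses of multimorbid subsets — including the
worked example, where near-universal hypertension loses its edges after
selection — must be read as associations *within the multimorbid
population*, exactly as in the source design.

## Problem sizes and numerical choices

The heavy checks run at sizes chosen to make their Monte-Carlo bands
decisive on one CPU: marginal calibration at n = 50,000; orthant
probabilities at n = 200,000; null inclusion rate over 200 replicates
of n = 5,000; planted-edge recovery over 100 replicates of n = 100,000
(two pooled strata of 50,000 with identical margins), asserting the
planted ρ = 0.5 pair is the network's only edge in ≥ 95 replicates.
Graph metrics are verified against exhaustive geodesic enumeration on
100 random ≤ 10-node weighted graphs to 1e−9, and the IRLS core against
an independent optimizer (statsmodels GLM, tolerance tightened to
1e−12) to 1e−6 on 50 random cohorts.

Determinism: every generator takes an integer seed through
`numpy.random.default_rng`; identical config + seed yields
byte-identical cohorts, and the pipeline's `report.json` (including
SHA-256 checksums of all artifacts) is byte-identical across reruns.

## Limitations

* The regressions are marginal-pairwise, as in the source design; no
  conditional-independence graphical model (Ising, graphical lasso) is
  attempted, so an edge may reflect a shared neighbour.
* Survey weights are consumed as given; the multi-stage design
  (PSU/strata) is not replicated and no design-corrected variance is
  computed beyond the sandwich option.
* Directed networks are out of scope (age at diagnosis is unavailable
  in the source data).
* The χ² gender comparison defaults to plain Pearson on unweighted
  counts; published p-values for this design appear to use an
  undocumented, possibly design-corrected procedure, so only the
  statistic's definition — not published p-values — is checked.
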