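# morbnet — multimorbidity disease-network analysis

`morbnet` builds gender-specific disease co-occurrence networks from
person-level survey data, for epidemiologists studying multimorbidity
(the co-occurrence of two or more chronic conditions in one person).
It implements the full chain used in network analyses of the
Longitudinal Ageing Study in India (LASI) and similar ageing surveys:

1. **Cohort model** — a fixed codebook of 16 self-reported
   non-communicable diseases (`AS, CA, CB, CHD, COPD, CRF, DM, GD, HC,
   HYP, MKS, NPD, SD, ST, THY, UI`), binary-coded, with age, gender
   stratum and sampling weight per respondent; selection to the
   multimorbid subset (≥ 2 diseases).
2. **Descriptives** — survey-weighted prevalence per disease
   (Σwᵢxᵢ/Σwᵢ), Pearson χ² comparison of each disease between women and
   men, and the C(16,2) = 120-cell dyad co-occurrence matrix.
3. **Pairwise association** — for every unordered disease pair an
   age-adjusted binary logistic regression fitted by iteratively
   reweighted least squares (IRLS):
   `logit P(Y_j = 1) = β₀ + β₁ X_k + β₂ (age − 60)`,
   with the adjusted odds ratio `OR = exp(β₁)` and a Wald p-value.
   Both orientations are fitted and symmetrized (geometric-mean OR,
   larger p).
4. **Edge selection** — the inclusion rule `p < 0.05` and `OR ≥ 1.2`,
   keeping only statistically significant positive associations.
5. **Network metrics** — the weighted undirected disease network over
   all 16 nodes, with degree `K_i` (incident-edge count), closeness and
   betweenness centrality (Dijkstra / Brandes on distances `1/OR`,
   component-corrected for isolates), network diameter and density
   `2E/(n(n−1))`.

Because the underlying survey microdata are registration-gated, the
package ships a Gaussian-copula synthetic-cohort generator
(`morbnet.synthetic`) whose defaults emulate the study population's
structure — gendered marginal prevalences, positive pairwise latent
correlation, age-dependent disease odds, heterogeneous lognormal
weights — so the whole pipeline is testable end to end without any
data download.

## Worked example

```python
import morbnet as mn

cohort = mn.generate_cohort(mn.SyntheticConfig(n_per_gender=5000, seed=42))
women, men = mn.split_by_gender(cohort)
res = mn.DiseaseNetworkModel(women, multimorbid_only=True).fit()
print(res.summary())
```

prints (abridged):

```
Multimorbidity disease network
==============================
Records analysed:        3811  (selection=multimorbid)
Edge rule:               OR >= 1.2, p < 0.05
Orientation:             both-geomean
Nodes / edges:           16 / 27
Diameter (reciprocal):    3.1341
Density:                 0.2250

Top 5 dyads (weighted co-occurrence):
   HYP-MKS   48.58%
    GD-HYP   40.32%
    DM-HYP   38.19%
    GD-MKS   27.72%
    DM-MKS   26.53%
```

Reading this: 3,811 of the 5,000 simulated women carry ≥ 2 diseases;
27 of the 120 candidate dyads pass the `p < 0.05, OR ≥ 1.2` rule, giving
a network density of 27/120 = 0.225; the hypertension–musculoskeletal
dyad is the most frequent co-occurrence (48.6% of the multimorbid
stratum, weighted), matching the ordering reported for Indian older
adults.  `res.centrality` holds the per-disease degree, closeness and
betweenness (raw and ×100); `res.associations_frame()` is the full
120-row edges table.

The same analysis from the shell:

```bash
morbnet generate --n 5000 --seed 42 --out cohort.csv
morbnet run --input cohort.csv --out results/
morbnet report results/
```

`results/` then contains, per gender stratum, `prevalence.csv`,
`dyads.csv` (120 rows), `edges_all.csv` / `edges_included.csv`,
`nodes.csv`, `network.graphml`, `network_attributes.json`, and a
checksummed `report.json`.

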