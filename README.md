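# deepseep

Comparative metagenomics of the deep continental subsurface, packaged as a
tested Python library with seeded synthetic data generators. It targets the
question of how active and how fast microbial life is across subsurface
ecosystems — cold CO₂-driven geysers, mofettes, aquifers, mines — and what
shapes the biogeography of their key organisms (*Ca.* Altiarchaeota).

The package implements the analysis layer of such a study end to end:

* **In situ replication index** (`deepseep.replication`). Actively replicating
  bacteria carry replication forks running from the origin (*ori*) to the
  terminus (*ter*) of their circular chromosome, so sequencing coverage decays
  from *ori* to *ter*. With window coverages sorted ascending and trimmed, OLS
  of log₂ coverage on the rank fraction x ∈ [0, 1] gives the index
  *iRep* = 2^slope — the *ori*/*ter* coverage ratio. An index of 1.4 means
  40% of the population had an active fork at sampling time
  ((iRep − 1) × 100). QC gates on r², window retention, and an archaeal guard
  (archaea may replicate from multiple origins) follow the field's
  conventions. Exposed as `ReplicationIndexModel(...).fit()` returning a
  `ReplicationEstimate` with diagnostics and `summary()`.
* **Minimal generation time from codon-usage bias** (`deepseep.growth`).
  Translational selection biases the synonymous codon usage of constitutively
  expressed (ribosomal) genes in fast growers. The bias statistic is the mean
  over amino-acid families of half the L1 distance between the ribosomal and
  background codon-frequency vectors, mapped to hours through the log-linear
  calibration ln d = ln 40 − ln 100 · bias.
* **Majority-vote scaffold taxonomy** (`deepseep.taxonomy`): rank by rank from
  superkingdom down, a label is assigned when strictly more than 50% of the
  scaffold's proteins support it.
* **Chemolithoautotrophic pathway abundance** (`deepseep.pathways`): key-enzyme
  hits × scaffold coverage, normalized per Gbp sequenced, per-pathway
  selection of the most frequently hit enzyme, and row-wise Z-scaling;
  Shannon–Wiener diversity from rpS3 scaffold abundances.
* **Gene-sharing networks** (`deepseep.genenet`): all-vs-all alignment hits
  scored with similarity = alignment length × identity / query length; edges
  at thresholds 40–80%; connected components as gene families; families in
  ≤ 2 genomes exported as gene-loss/HGT candidates.
* **Biogeography** (`deepseep.biogeo`): WGS84 ellipsoidal geodesic distances,
  fragment-based average nucleotide identity (ANI), and the distance-decay
  Pearson test of ANI against km.
* **Geyser carbon budget** (`deepseep.carbon`): annual erupted inorganic
  carbon (CO₂ + HCO₃⁻), cell-bound carbon, and the fraction of degassing
  carbon fixed into biomass.
* **Statistics** (`deepseep.stats`): depth-trend correlations (per value and
  per ecosystem median), Welch-t / Mann–Whitney / Kruskal–Wallis, TOST
  equivalence with power-derived bounds, and the genome quality gate
  (≥ 70% completeness, ≤ 10% contamination).
* **Synthetic data** (`deepseep.synthetic_data`): seeded generators for
  circular genomes with known *ori*→*ter* coverage gradients, gene sets with
  tunable ribosomal codon bias, per-protein lineages, key-enzyme hits,
  multi-site panels with depth-dependent replication effects, and genome
  panels with distance-dependent ANI decay — ground truth for every estimator.

## Worked example

```python
from deepseep import synthetic_data as syn
from deepseep.replication import ReplicationIndexModel, fraction_replicating

profile = syn.simulate_coverage(250_000, mean_depth=50, true_ptr=1.4,
                                seed=7, noise="poisson")
est = ReplicationIndexModel(profile).fit()
print(est.summary())
print(f"replicating: {fraction_replicating(est.irep).percent:.1f}%")
```

```
Replication index estimate
----------------------------------------
genome            sim_250000
status            ok
iRep              1.3988
r^2               0.9991
windows (total)   50
retained fraction 0.920
QC pass           True
mismatch tol.     2% (input provenance)
replicating: 39.9%
```

The estimator recovers the simulated origin/terminus ratio of 1.4 (estimate 1.399) from
Poisson-noisy coverage, and the interpretation is that ~40% of this
population carried an active replication fork.

The full synthetic study — a 12-site panel spanning 0–3000 m with a negative
depth effect on replication, pathway matrices, a biogeography panel and the
carbon budget — runs from the command line:

```bash
deepseep demo --seed 7 --outdir demo
```

and reports, among other things, the negative depth trend of the estimated
replication indices (`depth_trend.json`, Pearson r = −0.56,
p = 3.5 × 10⁻⁵ at seed 7) and the carbon budget
(`carbon_budget.json`, 0.0018% of erupted carbon fixed into biomass for the
study's printed totals).

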