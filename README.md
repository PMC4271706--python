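# biomepool

How does a regional species pool — and the biome it occupies — assemble?
`biomepool` implements, as a tested and reusable pipeline, the phylogenetic
inference chain used to answer that question for clades spreading into a
focal region (the motivating system is a large Neotropical plant clade
dispersing from South America into Mexico and its seasonally dry tropical
forest):

1. **Historical biogeography.** Time-stratified
   dispersal–extinction–cladogenesis likelihoods with founder-event
   speciation (DEC, DEC+J, DIVALIKE, BAYAREALIKE variants) over bitmask
   range states, ML fitting, weighted-AIC model comparison, and marginal
   ancestral-range estimation. A lineage in range *R* gains area *a* at rate
   *d*·Σ_{b∈R} m_k[b,a] (epoch-*k* connectivity multipliers m_k ∈ [0,1]) and
   loses each occupied area at rate *e*; at speciation the parental range is
   partitioned by the cladogenesis distribution, with founder events
   (one daughter jumps to a new single area) weighted *j*.
2. **Dated range events.** Expansion (range gains the focal area) and
   restriction (range collapses to exactly the focal area) events per
   branch, dated at the stem node; dispersal rate = events/Myr over the
   event window; a rate inflection dated with geometric
   extremum-distance/extremum-surface estimators on the cumulative event
   curve, with before/after rates and fold change.
3. **Ancestral climate and evolutionary lag.** Per-species climate profiles
   (total annual precipitation, bio12; driest-quarter precipitation, bio17)
   from occurrence records; PGLS contrasts of endemic / widespread /
   non-focal groups; Brownian-motion ancestral reconstruction (ML and Gibbs
   MCMC); first threshold-crossing ages (e.g. bio12 ≤ 1800 mm yr⁻¹); and lag
   = crossing age − restriction age, classified pre-adapted / concurrent /
   in-situ.
4. **Diversification and phylogenetic diversity.** Constant-rate birth–death
   ML with incomplete-sampling fraction *f*, a two-regime AIC scan for rate
   shifts, dispersal-vs-diversification rate comparison, the χ²
   sampling-bias test, and mean pairwise patristic distance partitioned into
   within-introduction (in-situ) vs between-introduction (dispersal)
   components.

A synthetic-data module generates birth–death trees, range histories
simulated under exactly the kernels the likelihood uses (with a complete
ground-truth event log), BM climate traits with optional regime shifts,
noisy occurrence records, and jittered tree ensembles — so every stage is
testable against known truth without any download.

## Worked example

```python
import numpy as np
from biomepool import (SimulationConfig, PipelineConfig, run_pipeline,
                       BiogeoParams, EpochSchedule)

# connectivity between areas jumps 0.05 -> 1.0 at 24 Myr
schedule = EpochSchedule((200.0, 24.0, 0.0),
                         (np.full((4, 4), 0.05), np.ones((4, 4))))
sim = SimulationConfig(n_tips=150, birth_rate=0.08, death_rate=0.0,
                       biogeo_params=BiogeoParams(d=0.05, e=0.005, j=0.05),
                       epoch_schedule=schedule, max_range=2,
                       root_area="SA", seed=1)
report = run_pipeline(PipelineConfig(simulation=sim, focal_area="Me",
                                     n_trees=5, fit_models=("DEC", "DEC+J"),
                                     seed=1))
ev = report["stages"]["events"]
print(round(ev["expansions"]["mean"], 1),
      round(ev["inflection"]["mean"], 1),
      round(report["stages"]["fit_biogeo"]["d"], 3))
```

prints

```
8.2 24.2 0.05
```

— on average 8.2 independent expansions into the focal area per ensemble
tree, an inferred dispersal-rate inflection at 24.2 Myr (the simulation
planted the connectivity jump at 24 Myr), and a fitted dispersal rate
d ≈ 0.05 Myr⁻¹ (truth 0.05). The report also carries restriction counts,
before/after dispersal rates, evolutionary-lag tables and class counts,
net-diversification estimates, and the in-situ vs dispersal MPD partition,
each summarized across the tree ensemble with 95% quantile bands.

The same stages are available as CLI subcommands
(`biomepool simulate | fit-biogeo | ancestors | events | rates | climate |
lag | diversify | validate | all`).

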