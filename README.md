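# tigerscape

Landscape genetics for fragmented carnivore populations: from noisy
non-invasive microsatellite genotypes to individual identification,
population structure, migrant detection, detection-corrected occupancy,
habitat-corridor modeling, and Mantel-based validation of corridor models
against genetic differentiation.

The package is aimed at conservation geneticists and landscape ecologists
who work with (i) replicate scat/hair genotypes at 10–15 microsatellite
loci, (ii) replicated sign-survey detection histories with site
covariates, and (iii) landscape rasters — and who want the whole chain
from raw calls to "which corridor model explains gene flow" in one tested,
scriptable toolbox. A synthetic-data generator with a ground-truth ledger
makes every stage testable by parameter recovery.

## The core models

- **Identity**: consensus genotypes from replicate PCRs (heterozygotes
  ≥2 replicates, homozygotes ≥5), dropout-aware matching into unique
  individuals, and the sibling probability of identity
  PIsib = ¼ + ½Σp² + ½(Σp²)² − ¼Σp⁴ multiplied across loci.
- **Structure**: Weir–Cockerham θ (F_ST), allele-size R_ST, Phi_PT from
  squared-distance AMOVA, Rousset linearization d/(1−d), PCoA, and
  bottleneck tests (M-ratio k/(r+1), heterozygosity excess under SMM/TPM,
  mode shift).
- **Assignment**: admixture-model Gibbs sampler with Evanno ΔK;
  Rannala–Mountain likelihoods with Monte-Carlo exclusion
  (migrant ⇔ p < 0.01 and log₁₀ L_max/L_home ≥ 2, i.e. 100×);
  two-generation immigrant-ancestry posteriors aggregated into a recent
  migration matrix m; parentage LOD scores; and a conservative consensus
  rule labelling each candidate Migrant / Admixed / Resident.
- **Occupancy**: single-season likelihood
  P(history) = ψ·Πpʸ(1−p)¹⁻ʸ + (1−ψ)·1{no detections} with logit links,
  PCA+varimax covariate reduction (eigenvalue > 1), AIC model averaging
  (ΔAIC < 4), and parametric-bootstrap Ĉ with √Ĉ SE inflation.
- **Connectivity**: cost = 1 − ψ̂ on habitat, impermeable settlements;
  least-cost paths (8-connected Dijkstra) buffered by 1.5 km into
  corridors; circuit-theory effective resistance, current maps and
  corridor bottlenecks.
- **Validation**: Mantel and Freedman–Lane partial Mantel tests of
  linearized genetic distance against GGD, logGGD, LCPD, LCCD and RD,
  with a cluster-control matrix to separate isolation-by-distance from
  cluster structure.

## Worked example

Run the full synthetic study (landscape → surveys → occupancy → cost
surface → resistance-driven metapopulation → scat genotyping → structure,
migrants and Mantel comparison):

```python
from tigerscape import landgen, simdata

cfg = simdata.SimConfig(seed=3, grid_shape=(24, 24), samples_per_pop=25)
results = landgen.run_pipeline(cfg, "run_out")
print(open("run_out/report.txt").read())
```

which prints (seed 3):

```
tigerscape pipeline report
scat samples genotyped: 100
individuals identified: 90 (10 recaptures)
cumulative PI-sib: 1.646e-04
mean pairwise F_ST: 0.135
best K (delta-K): 4
first-generation migrants flagged: 1
naive occupancy: 19.1%
model occupancy: 37.1%
best spatial model: RD
```

Reading this: 100 simulated scat samples collapse to 90 unique tigers
(10 recaptures caught by genotype matching); the marker panel's
cumulative sibling probability of identity (1.6×10⁻⁴) means even full
sibs are almost surely distinguishable; pairwise F_ST averages 0.135
(moderate structure) and ΔK recovers the four simulated subpopulations;
detection-corrected occupancy (37%) roughly doubles the naive detected
fraction (19%) because per-survey detection is low; and resistance
distance (RD) — the model that actually generated gene flow in this
simulation — correlates best with linearized F_ST. Tables (diversity,
F_ST, migration rates, Mantel comparison), rasters and a manifest land in
`run_out/`.

The same stages are scriptable from the shell:

```bash
tigerscape --seed 3 --outdir out simulate --n-pops 5
tigerscape --seed 3 --outdir out genetics out/genotypes.gen
tigerscape --seed 3 --outdir out mantel out/fst.csv out/fst.csv
tigerscape --seed 3 --outdir out all
```

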