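# h2atlas

Partitioned SNP-heritability analysis across functional annotations, for
statistical geneticists who want to know *where* in the genome the polygenic
signal of a trait lives: multi-component GREML (AI-REML) on per-annotation
genetic relationship matrices, hierarchical SNP-to-annotation assignment,
enrichment Z-tests with delta-method standard errors, liability-scale totals
for case-control traits, inverse-variance meta-analysis and model selection,
functionally weighted multi-BLUP risk prediction, and a synthetic-cohort
simulation framework that validates the estimator end to end without any
external data.

## The model

The phenotype of N individuals is multivariate normal with one variance
component per annotation category plus an environmental term:

    y = Xb + Σᵢ gᵢ + e,   gᵢ ~ N(0, σ²ᵢ Kᵢ),   e ~ N(0, σ²ₑ I)

Kᵢ = WᵢWᵢᵀ/Mᵢ is the relationship matrix over the Mᵢ SNPs assigned to
component i (dosages standardized by in-sample allele frequency).  Every SNP
belongs to exactly one component of a priority hierarchy — coding > UTR >
promoter > annotation of interest > DHS > intron > other — so the components
partition the genome and each component's %SNPs is the null expectation for
its share of genetic variance.  σ² parameters are fitted by restricted
maximum likelihood with Average-Information updates; the heritability share
of component i, %h²g(i) = σ²ᵢ/Σ_genetic σ²ⱼ, gets a delta-method SE from the
inverse AI matrix, and enrichment is tested with Z = (%h²g − %SNPs)/SE.

## Worked example

```python
import numpy as np
from h2atlas import (SimScenario, simulate_cohort, fit_joint_model,
                     enriched_causal_source)

# a cohort of 1,000 samples and 10,000 unlinked SNPs; the focal annotation
# covers 3.22% of SNPs and is simulated to carry 50% of genetic variance
scen = SimScenario(
    n_samples=1000, n_snps=10000, n_causal=500, h2=0.5, seed=1,
    causal_source=lambda part: enriched_causal_source(part, "focal", 0.5),
)
sim = simulate_cohort(scen)
hp = fit_joint_model(sim.geno, sim.pheno, sim.partition)
i = hp.component_names.index("focal")
print(f"total h2          {hp.h2_total:.3f}")
print(f"focal %SNPs       {100 * hp.pct_snps[i]:.2f}")
print(f"focal %h2g        {100 * hp.pct_h2g[i]:.1f} (se {100 * hp.se_pct_h2g[i]:.1f})")
print(f"enrichment Z, p   {hp.z[i]:.2f}  {hp.p[i]:.2e}")
```

prints

```
total h2          0.602
focal %SNPs       3.22
focal %h2g        44.6 (se 9.8)
enrichment Z, p   4.22  2.40e-05
```

— the focal component was simulated to hold half the genetic variance in
3.2% of SNPs, and the joint seven-component fit recovers a ~14-fold
enrichment (44.6% of h²g vs the 3.22% null expectation, Z = 4.2).  A single
cohort is noisy (the total h² of 0.60 sits about one standard error above
the simulated 0.5); averaged over the 50 replicates of
`scripts/acceptance.py` the estimates centre on the simulation truth.

A thin CLI wraps the same pipeline:
`atlas simulate --scenario scenario.yaml --out dir/ --seed 42`,
`atlas qc`, `atlas joint --model selected8`, `atlas simulate-study`.

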