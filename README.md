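# dominet

Multi-site brain-network topology analysis centred on **DomiRank centrality**,
for researchers studying functional-connectivity alterations in ageing and
dementia cohorts (healthy controls, mild cognitive impairment, Alzheimer's
disease) collected across several acquisition sites.

## What it computes

Starting from per-subject regional time series (N regions × T time points,
e.g. a 246-region whole-brain parcellation), the pipeline:

1. **Network construction** — pairwise Pearson correlation → Fisher
   z-transform → proportional thresholding at a fixed density (default 4 %),
   with the maximum-weight spanning tree always retained so every subject's
   binary network is connected and has exactly `round(d·N(N−1)/2)` edges.
2. **DomiRank centrality** — the steady state of competition–relaxation
   dynamics on the adjacency matrix A,

   Γ̇ = αA(θ**1** − Γ) − βΓ  ⇒  Γ = θσ(σA + I)⁻¹A**1**,  σ = α/β,

   solved exactly as a linear system. σ trades local against global
   dominance and is feasible on (0, −1/λ_N), with λ_N the most negative
   adjacency eigenvalue; it is chosen by scanning 100 candidates and keeping
   the one whose DomiRank-targeted attack minimises the area under the
   largest-connected-component (LCC) curve. Seven classical centralities
   (betweenness, closeness, degree, eigenvector, harmonic, PageRank,
   strength) are computed alongside for comparison.
3. **Mega-analysis** — per-site covariate-adjusted group contrasts (linear
   model with age and sex), combined across sites with the √n-weighted
   Liptak–Stouffer formula z = Σwᵢzᵢ/√(Σwᵢ²), wᵢ = √nᵢ, and
   Benjamini–Hochberg FDR control over regions.
4. **Robustness** — targeted node-removal attacks ranked by any centrality,
   LCC curves and their areas, per subject and group-averaged.
5. **Prediction** — leave-one-site-out linear-SVM classification (ACC, SEN,
   SPE, AUC, Platt pseudoprobabilities) and support-vector regression of
   cognition scores (MMSE/MoCA), with strict training-fold-only
   standardization.
6. **Transcriptomic association** — PLS regression of the group-difference
   map on a regions × genes expression matrix, permutation significance of
   the first component, bootstrap gene-weight stability, top-gene ranking
   and hypergeometric gene-set enrichment (GMT input).

Because clinical imaging data are access-restricted, the package includes a
first-class **synthetic cohort generator**: a seven-site design with
realistic group sizes, site offsets, covariate effects, planted
connectivity effects in Fisher-z units and cognition scores coupled to
effect magnitude — so every stage can be verified against known ground
truth.

## Worked example

```python
import numpy as np
from dominet import (
    mcadi_like, generate_cohort, ThresholdConfig, mega_contrast,
)
from dominet.pipeline import build_networks, centrality_tables

# seven-site cohort with DomiRank hub attenuation (Δz = −0.5) in AD
# planted on 10 regions
planted = tuple(range(5, 246, 25))[:10]
cfg = mcadi_like(effect_regions=planted,
                 region_delta={"MCI": -0.25, "AD": -0.5}, seed=1)
cohort = generate_cohort(cfg)

ids = [s.subject_id for s in cohort.subjects]
nets = build_networks(cohort.time_series, ids, ThresholdConfig(density=0.04))
tables = centrality_tables(nets, ("DomiRank",))
mega = mega_contrast(tables["DomiRank"], cohort.subject_table(),
                     contrast=("HC", "AD"))
sig = set(np.flatnonzero(mega.significant).tolist())
print(f"{nets[0].n_edges} edges per network")
print(f"{len(sig)} FDR-significant regions; "
      f"{len(sig & set(planted))}/10 planted regions recovered")
```

prints

```
1205 edges per network
10 FDR-significant regions; 10/10 planted regions recovered
```

i.e. at 4 % density every 246-node network carries exactly 1205 edges, and
the mega-analysis recovers all ten planted hub attenuations with no false
positives in this run.

The same stages are available from the command line:
`dominet simulate | build | centrality | mega | attack | predict | pls |
report | sweep | run` (see `dominet --help`).

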