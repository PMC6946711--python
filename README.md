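# mycoassembly

Community-assembly inference for host-associated mycobiomes: null-model
detection of stochastic versus deterministic assembly, dissimilarity–
overlap universality analysis, richness-free turnover partitioning, and
the multivariate statistics that support them — plus a synthetic-data
generator that simulates fungal communities assembled under known
processes on a replicated compartment × week × treatment field design.

It is written for microbial ecologists who have an OTU table, sample
metadata, and a (rank-based) phylogeny, and want to ask: *was this
community pair shaped by selection, by dispersal, or by drift — and do
all the communities follow the same underlying dynamics?*

## The statistics at the core

For every pair of communities two standardized indices are computed
against explicit null models:

* **βNTI** — the z-score of the β mean nearest taxon distance (βMNTD)
  under a tip-shuffling null on the phylogeny.  βNTI ≤ −2 indicates
  phylogenetic clustering (homogeneous selection), βNTI ≥ +2
  overdispersion (variable selection).
* **RCI** — the Raup–Crick index, a quantile score in [−1, 1] of the
  observed shared-taxon count against richness-preserving,
  occupancy-weighted null assemblages.  RCI ≤ −0.95 flags homogenizing
  processes, RCI ≥ +0.95 dispersal limitation.

Pairs with |βNTI| < 2 and |RCI| < 0.95 are dominated by neither
selection nor dispersal; their compositional variance is attributed to
stochasticity (ecological drift and/or stochastic colonization).  The
fraction of such pairs per group, related to community size with a
mixed-effects model, tests the prediction that drift is strongest in
small communities.

Universality is assessed with the dissimilarity–overlap curve (DOC):
root Jensen–Shannon divergence over shared taxa against shared-taxon
overlap, LOWESS-smoothed, with a bootstrap change point and the
fraction of pairs in the negative-slope region (Fns).  Turnover free of
richness effects comes from the Sørensen partition
βsor = βsim + βsne.  Sequential PERMANOVA, Mantel tests, β dispersion,
PCoA, community Fst, CLR/Aitchison compositional tools, co-abundance
clustering and a random-forest community-age delay protocol round out
the toolkit.

## Worked example

Simulate two sets of 12 replicate communities from one 200-taxon
metacommunity — one set drifting neutrally, one under strong shared
trait selection — and recover the assembly process:

```python
import numpy as np
from mycoassembly import sample_metacommunity, AssemblyScenario, simulate_assembly
from mycoassembly.nullmodels import bnti, raup_crick, classify_processes

pool = sample_metacommunity(S=200, lognormal_sigma=1.0, seed=1)

for process, kw in [("drift", {}), ("homogeneous_selection", {"s": 100.0})]:
    scenario = AssemblyScenario(process=process, N=50, generations=50,
                                m=0.1, seed=1, **kw)
    table = simulate_assembly(pool, scenario, 12)
    b = bnti(table, pool.tree, reps=999, seed=1)
    r = raup_crick(table, reps=999, seed=2)
    pairs, summary = classify_processes(b, r)
    top = max(summary.fractions, key=summary.fractions.get)
    print(f"{process:>22}: mean betaNTI = {np.nanmean(b.score):+.2f}, "
          f"dominant class = {top} ({summary.fractions[top]:.0%} of 66 pairs)")
```

Output:

```
                 drift: mean betaNTI = -0.30, dominant class = stochastic_undominated (88% of 66 pairs)
 homogeneous_selection: mean betaNTI = -3.04, dominant class = homogeneous_selection (98% of 66 pairs)
```

The drift replicates sit inside both null envelopes (88% of pairs
undominated), while selection toward a shared, clade-restricted trait
optimum drives βNTI far below −2 for nearly every pair.

The same pipeline is available from the shell:

```bash
mycoassembly simulate --config scenario.yaml --out-dir sim/
mycoassembly nullmodel --tree sim/tree.nwk --reps 999 --seed 1 \
    --group-by week,compartment,treatment sim/table.tsv sim/metadata.tsv out/
mycoassembly doc --boot 1000 --seed 1 sim/table.tsv doc_out/
```

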