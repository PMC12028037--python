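# comstab

Co-occurrence network **com**plexity and **stab**ility analysis for microbial
communities.

Soil microbiome surveys routinely ask not just *who is there* (diversity) but
how tightly the community is wired (complexity) and how well that wiring
survives perturbation (stability). `comstab` implements the full analysis
chain used to compare such properties between sample groups — for example
fungal communities of clay-loam versus sandy mangrove soils — starting from a
samples × taxa feature table, a sample metadata table and an environmental
matrix:

1. **Diversity** — Shannon index (alpha), Bray–Curtis dissimilarity, PCoA
   ordination (beta), ANOSIM and Mantel permutation tests, WGS84 geodesic
   distance matrices.
2. **Networks** — signed Spearman co-occurrence networks per sample group
   with average degree ⟨k⟩ = (1/n) Σᵢ kᵢ = 2l/n, density 2l/(n(n−1)),
   Louvain modularity Q and within-module degree z-score hubs.
3. **Complexity** — per-sample cohesion
   C± = Σᵢ abundanceᵢ × connectednessᵢ±, where connectednessᵢ± is the mean
   retained positive (negative) correlation of taxon *i*; total cohesion is
   C⁺ + |C⁻|.
4. **Stability** — robustness: the proportion of species remaining after
   removing nodes (a random fraction, or the top module hubs) and iterating
   secondary extinctions — species *i* drops out when it loses all network
   edges or its abundance-weighted mean association
   Σ_{j≠i} bⱼ sᵢⱼ / Σ_{j≠i} bⱼ turns nonpositive.
5. **Drivers** — Spearman correlation tables (with significance stars and
   optional Benjamini–Hochberg correction) between environmental variables
   and diversity/cohesion/stability, plus simple linear regressions.
6. **PLS-PM** — partial least squares path modeling (Lohmöller algorithm,
   mode A, centroid scheme) relating soil properties, nutrients, geographic
   distance and alpha/beta diversity to complexity and stability, with
   direct/indirect/total effect decomposition and bootstrap significance.

A first-class synthetic-data module generates communities (Gaussian-copula
correlation blocks over negative-binomial counts), coordinates and
environmental matrices from latent path models with known ground truth, so
every stage is testable without any sequencing data.

## Worked example

```python
import numpy as np
from comstab import io_tables as io, network as nm, cohesion as coh
from comstab.synthetic import simulate_study

ft, meta, env = simulate_study(seed=1)          # two soil types, 30 samples each
groups = meta.column("soil_type")
for g in ("clay_loam", "sandy"):
    ids = [s for s, gv in zip(ft.sample_ids, groups) if gv == g]
    ft_g = io.filter_taxa(ft.select_samples(ids))
    rel_g = io.to_relative_abundance(ft_g)
    rho, p = nm.spearman_matrix(ft_g)
    net = nm.build_network(rho, p, ft_g)        # |rho| >= 0.6, BH q < 0.05
    report = nm.topology_report(net, seed=0)
    retained = coh.retained_correlation_matrix(ft_g, rho, p, net=net)
    conn_pos, conn_neg = coh.connectedness(retained)
    cdf = coh.cohesion_table(coh.cohesion(rel_g, conn_pos, conn_neg))
    idx = [ft_g.taxon_ids.index(t) for t in net.node_ids]
    strength = nm.pearson_matrix(ft_g)[np.ix_(idx, idx)]
    rob = coh.robustness(net, strength, parameter=0.5, n_iterations=499, seed=0)
    print(f"{g}: nodes={report.n_nodes} edges={report.n_edges} "
          f"density={report.density:.3f} modularity={report.modularity:.3f} "
          f"total_cohesion={cdf['total_cohesion'].mean():.3f} "
          f"robustness={rob.proportion_remaining:.3f}")
```

prints

```
clay_loam: nodes=46 edges=197 density=0.190 modularity=0.680 total_cohesion=0.679 robustness=0.426
sandy: nodes=19 edges=30 density=0.175 modularity=0.556 total_cohesion=0.261 robustness=0.309
```

The clay-loam community — generated with cooperative (positively correlated)
taxon blocks — forms the larger, denser network, carries the higher total
cohesion (more complexity) and retains more of its species under 50% random
node removal (more stability) than the sandy community, whose network
contains a substantial competitive block.

## Command line

The whole chain runs from one YAML configuration (every stochastic stage
needs an explicit seed; identical configs give byte-identical outputs):

```bash
comstab validate configs/demo.yaml     # normalize + show filled defaults
comstab all configs/demo.yaml -o runs/demo
```

The run directory contains TSV/JSON/GraphML outputs per stage plus a
`manifest.json` with the normalized config, every default that was filled
in, and a checksum per output file.

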