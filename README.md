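# littersuccession

Where do the microbes that decompose forest leaf litter come from — the
phyllosphere (the leaf's own surface and interior microbiota) or the
surrounding soil — and which ecological processes assemble their
communities as decomposition proceeds?

`littersuccession` is an analysis toolkit for amplicon (ASV) surveys of
decomposing litter and its candidate source habitats. It covers the four
computational stages such studies chain together, plus a synthetic-data
module that generates inputs with known ground truth so every stage is
testable without sequencing data:

1. **Microbial source tracking** (`littersuccession.sourcetrack`). Each
   litter ("sink") community is modelled as a convex mixture of the named
   source habitats plus an unknown pool:

       p_i = Σ_k α_k γ_ki + α_u γ_ui ,   Σ α = 1

   with sink counts multinomial over `p`. An expectation–maximization
   algorithm estimates the mixing weights `α`: the E-step computes per-taxon
   responsibilities `r_ik = α_k γ_ki / Σ_j α_j γ_ji`, the M-step updates the
   weights and the unknown profile `γ_u` (named source profiles stay fixed
   at their pseudocount-smoothed empirical frequencies). Includes seeded
   rarefaction (multivariate hypergeometric subsampling).
2. **Diversity statistics** (`littersuccession.diversity`). Shannon
   entropy, unweighted UniFrac (the fraction of observed branch length
   unique to one of two communities), principal-coordinate analysis with
   negative eigenvalues reported, pairwise PERMANOVA (Anderson's pseudo-F
   with permutation p-values, optionally exhaustive enumeration),
   Kruskal–Wallis, and the Mantel test.
3. **Co-occurrence networks and keystones** (`littersuccession.network`).
   A correlation network over the top-400 most abundant ASVs (|r| > 0.8,
   p < 0.01 by default); per-node leave-one-out impact scores
   `I_v = |Δ mean degree| + |Δ mean betweenness| + |Δ mean harmonic closeness|`;
   the top 10% of scores are keystone taxa, labelled by detection in the
   phyllosphere and soil tables; Pianka's niche overlap
   `O = Σ p q / √(Σ p² Σ q²)` compares origin groups over litter samples.
4. **Community assembly null models** (`littersuccession.assembly`).
   Phylogenetic binning by a greedy patristic-distance rule, then per bin
   and sample pair the abundance-weighted βMNTD z-score (βNTI) against a
   within-bin tip-shuffle null and the Raup–Crick metric on Bray–Curtis
   (RC_bray). βNTI < −2 → homogeneous selection (HoS), > +2 → heterogeneous
   selection (HeS); otherwise RC > 0.95 → dispersal limitation (DL),
   RC < −0.95 → homogenizing dispersal (HD), else drift (DR).
   Abundance-weighted process fractions aggregate the labels.

## Worked example

Estimate the origin of a litter community simulated as 55% phyllosphere,
30% soil and 15% unknown:

```python
import numpy as np
from littersuccession.synth import simulate_sources, simulate_sink
from littersuccession.sourcetrack import em_fit

sources, metadata, profiles = simulate_sources(
    n_sources=2, n_taxa=200, samples_per_source=6, seed=11, depth=20_000
)
rng = np.random.default_rng(99)
unknown = rng.dirichlet(np.full(200, 0.3))
sink, truth = simulate_sink(profiles, [0.55, 0.30, 0.15], unknown,
                            depth=20_000, seed=12)

model = em_fit(sink, profiles, source_names=("phyllosphere", "soil"))
for name, value in model.contributions().items():
    print(f"{name:13s} {value:.3f}")
print("converged:", model.converged, "iterations:", model.n_iterations)
```

prints

```
phyllosphere  0.552
soil          0.295
unknown       0.153
converged: True iterations: 40
```

i.e. the EM recovers the planted mixture to within half a percentage point
per component at this sequencing depth. The monotone log-likelihood trace
is available as `model.loglik_trace`.

## Command line

The full pipeline runs from one YAML config with a single seed:

```bash
littersuccession run --config config.yaml
littersuccession sourcetrack --sinks sinks.tsv --sources sources.tsv \
    --metadata meta.tsv --depth auto --seed 17 --out results.tsv
littersuccession diversity alpha --table table.tsv --out alpha.tsv
littersuccession network --table table.tsv --out-prefix net
littersuccession assembly --table table.tsv --tree tree.nwk --out-prefix asm
```

With no input paths configured, `run` generates the synthetic demo data
set (two source habitats, mixed litter sinks, a phylogeny) and runs all
four stages on it, writing per-stage TSV/JSON outputs and a run manifest.
Reruns with the same config and seed reproduce every result file
byte-for-byte (the manifest records wall-clock timings and is exempt).

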