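# rumennet

Reaction-centric metabolic-network analysis of two-diet rumen shotgun
metagenomes.

## The problem

Rumen microbes ferment feed into volatile fatty acids (VFAs) — acetate,
propionate and butyrate — which supply most of a ruminant's energy. When the
host's diet shifts from forage (FORG) to concentrate (CONC), the microbial
community reorganizes. `rumennet` analyzes that reorganization at the level
of *metabolic reactions* rather than taxa: translated shotgun reads are
mapped to enzyme sequences, enzymes to reactions, and reactions to nodes of
a shared-metabolite graph, so diets can be compared by where read mass sits
in metabolic-network space.

The package is aimed at microbiome researchers who want a tested, reusable
implementation of this pipeline, exercised end-to-end on synthetic data
with the statistical structure of a 8 + 8 animal two-diet study.

## The model

**Network.** Nodes are reactions (reactions with identical metabolite sets
merge); an undirected edge joins two nodes sharing a metabolite. Currency
metabolites — compounds occurring in ≥ 25, ≥ 50 or ≥ 100 reactions (networks
N25, N50, N100) — are excluded from edge formation. A host reaction graph is
joined to the microbial graph through *interface metabolites* (the three
VFAs; VFA + the 20 amino acids; or a larger absorbed-compound list), and
every node gets a *layer*: its within-subnetwork hop distance from the
interface frontier (interface-using nodes are layer 0).

**Read mapping.** Paired reads are quality-truncated, translated in six
frames, and ORFs ≥ 30 residues are aligned to enzymes by seeded
Smith–Waterman (two shared 7-mers, > 80% identity over > 80% of the ORF).
Hits whose reaction sets are identical or nested resolve to the minimal
set's node; conflicting mates or unrelated multi-hits are discarded.

**Statistics.** Node read densities per diet follow a three-state mixture —
a proportion p₀ of unobserved nodes, p₁ with one read, and a log-normal
(meanlog μ, sdlog σ) for the rest — compared between diets by likelihood
ratio. Per-node differences use exact Wilcoxon rank-sum tests with
Benjamini–Hochberg FDR. Structural contrasts (mean layer, carbon sum,
betweenness, degree, clustering) weight each node's statistic by its read
mass and are tested against a randomization null that pools all mapped
reads and redistributes each diet's total over nodes. Animal profiles are
compared as unit vectors vᵢ = rᵢ / √Σⱼ rⱼ² by Euclidean distance, with a
proportional-reassignment null. Finally, a simulated-annealing search asks
whether distinct read-to-node distributions can share one metabolite
("compound") profile: compound vectors Vᶜ are scaled to total 100,000 and
reads are moved singly (swap1) or in edge-constrained pairs (swap2) toward
a diet-average target.

## Worked example

```python
from rumennet.synthetic import ScenarioConfig, gen_reaction_db, gen_count_matrix
from rumennet.reaction_db import add_butyrate_pseudoreaction
from rumennet.network_build import build_graph, make_interface_set, merge_networks
from rumennet.diet_stats import mean_layer_test, fit_three_state_by_diet, per_node_tests

cfg = ScenarioConfig(seed=0)                      # 8+8 animals, 400 reactions
microbial, host = gen_reaction_db(cfg)
host = add_butyrate_pseudoreaction(host)          # butyrate -> butyryl-CoA uptake
merged = merge_networks(build_graph(host, 50), build_graph(microbial, 50),
                        make_interface_set("VFA_AA"))
cm, otus = gen_count_matrix(merged, cfg)

res = mean_layer_test(cm, merged.layer, n_rand=1000, seed=0)
print(f"mean-layer diff (FORG-CONC): {res.observed:.3f}  "
      f"max|null| {res.max_abs_null:.4f}  P {res.p_value:.4g}")
```

prints

```
mean-layer diff (FORG-CONC): 0.031  max|null| 0.0036  P 0.000999
```

The forage diet's reads sit on average 0.031 layers farther from the host
interface than the concentrate diet's — more than eight times the largest
difference seen in 1000 read randomizations, hence P < 0.001 (the add-one
permutation floor). Continuing,

```python
d = fit_three_state_by_diet(cm)
t = per_node_tests(cm)
```

reports per-diet mixture fits (`FORG: p0=0.268 meanlog=8.70 sdlog=1.87`,
`CONC: p0=0.265 meanlog=8.54 sdlog=1.70`: the concentrate diet concentrates
the same read mass on fewer, tighter nodes) and `55/303` nodes differentially
abundant at q < 0.05.

The same analyses are available from the shell:

```bash
rumennet synth --out study --seed 0
rumennet network build --db study/db_microbial --host-db study/db_host \
    --cutoff 50 --interface VFA_AA --out study/net
rumennet stats mean-layer --counts study/node_counts.tsv \
    --meta study/sample_metadata.tsv --layers study/net/nodes.tsv --seed 0
rumennet run --out results_full --seed 0      # the whole cutoff x interface grid
```

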