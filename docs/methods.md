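# Methods

## Network construction

A reaction database is three flat files: a metabolite table (id, name,
carbon count), a reaction table (id plus metabolite-id set) and an enzyme
FASTA whose description carries the catalyzed reaction ids. Reactions are
undirected — a reaction *is* its metabolite set — because edges are
shared-metabolite links with no substrate/product polarity. Reactions with
identical metabolite sets merge into one node named after the
lexicographically smallest member reaction id, which makes node identity
deterministic across runs.

Currency metabolites are defined by occurrence alone: a metabolite in
`cutoff` **or more** reactions (25, 50 or 100) forms no edges. Isolated
nodes are removed after currency filtering. Edge sets are therefore
monotone in the cutoff: N25 ⊆ N50 ⊆ N100.

The host graph is an input in the same schema; a butyrate → butyryl-CoA
pseudo-reaction (no enzyme) is added programmatically and idempotently,
reflecting the host's ability to absorb and activate microbial butyrate.
Pseudo-reaction metabolites count toward currency occurrence like any
other; at host-network scale two extra occurrences never cross a cutoff,
so the choice is immaterial in practice.

**Interface and layers.** Interface edges join each (host, microbial) node
pair that uses the *same* interface metabolite, evaluated on full
metabolite sets so currency status cannot sever the host–microbe link.
Interface sets: VFA = {acetate, propionate, butyrate}; VFA_AA adds the 20
universal amino acids (23 compounds); ALL extends VFA_AA with a
caller-supplied absorbed-compound list. Name → id mappings live in
configuration so synthetic databases may name compounds freely.

A node's layer is its within-subnetwork hop distance from the interface
frontier, computed by multi-source BFS (Dijkstra on unit weights): nodes
incident to an interface edge are layer 0 and distances grow outward. The
equivalent cross-network path length would be one hop larger (it counts the
interface edge itself); the frontier convention is used because it makes
"uses an interface metabolite ⇔ layer 0" exact. A node using an interface
metabolite that no node of the other subnetwork shares has no cross-network
path and carries the `None` sentinel, as does any node disconnected from
the frontier; such nodes keep their mapped reads for count statistics but
are excluded from all layer means and correlations.

## Read mapping

Each mate is truncated at the *start* of its first run of three bases with
phred < 15 (the run itself is removed — the conservative reading of
"truncated after the first run"; the run length and quality floor are
parameters). A pair is discarded if either truncated mate is shorter than
85 nt or has mean quality < 25. Both mates are translated in six frames;
ORFs are maximal stop-free runs and both mates must carry one of ≥ 30
residues.

Alignment is local affine-gap (Gotoh) dynamic programming with BLOSUM62,
gap open 11 / extend 1 — standard protein-search scoring; the thresholds
act on identity and coverage, not raw score, so the exact matrix matters
little. A candidate enzyme must share two distinct 7-mers with the ORF
anywhere (overlap allowed) before alignment; a hit then requires identity
> 0.80 computed over aligned columns with gap columns as mismatches, and
> 0.80 of the ORF's residues inside the aligned region. Both thresholds
are strict by default (`--gte` relaxes them). Ties in the traceback prefer
diagonal, then gap-in-query, then gap-in-target; the package aligner is
verified cell-for-cell against an independently coded quadratic oracle and
score-checked against Biopython's `PairwiseAligner`.

Per mate, the best-scoring ORF's hits are kept (ties break to the lower
ORF index, then the smaller enzyme id). The reaction sets of all kept hits
must form a chain under inclusion; the pair is assigned to the node(s) of
the minimal set — UNIQUE if one node, MULTI otherwise (tallied separately,
excluded from per-node counts). Mates with no common reaction are
discarded as discordant; incomparable sets as unrelated multi-hits. The
summary percentage of node-hit pairs uses valid-ORF pairs as denominator
(the published per-animal table's arithmetic fixes this choice); host-genome
contamination is reported from precomputed sample metadata, since
nucleotide-space host mapping is outside the method's core.

Mapper validation draws pseudo-read pairs — two 30-residue windows
separated by a 70-residue insert, uniform over (enzyme, offset) — and maps
them back with the source withheld, reporting mapped fraction,
unique:multi ratio and the incorrect-node fraction across an identity
grid. Alignments are computed once at the loosest threshold and
re-thresholded, so the sweep is monotone by construction.

## Count statistics

Counts are normalized to reads per node per 10⁶ mapped reads per animal.
The three-state read-density mixture defines its point masses on raw
integer counts (p₀ at zero, p₁ at one) and fits a log-normal truncated to
values > 1 by numerical MLE (Nelder–Mead on (μ, log σ), initialized at the
tail moments) to the normalized values of nodes with raw count ≥ 2. A
vector with no tail values degenerates cleanly to the point masses; one or
two distinct tail values is an error (the tail is unidentifiable). The
diet comparison refits the mixture on the two diets' observations
concatenated and uses 2(ℓ_F + ℓ_C − ℓ_pooled) ~ χ²; the nested parameter
difference is 4 (p₀, p₁, μ, σ per diet), the default df. A df = 5 flag is
provided for compatibility with the alternative counting convention, which
cannot be reconstructed from this parameterization.

Per-node tests are two-sided Wilcoxon rank-sum, exact whenever the pooled
sample has no ties (at 8 vs 8 the smallest attainable two-sided P is
2/12870), asymptotic otherwise, with BH-FDR at 5%.

**Randomization nulls.** All structural contrasts weight a per-node
statistic by read mass — the read-weighted mean Σwᵢsᵢ/Σwᵢ, i.e. the average
statistic experienced by a mapped read (an unnormalized mean-of-products
variant is selectable) — and compare the diet difference against a null
that pools per-node read masses across diets and redistributes each diet's
total multinomially over nodes (an exact without-replacement partition is
available behind a flag). P-values use the add-one estimator
(#{|null| ≥ |obs|} + 1)/(n_rand + 1) and are therefore in (0, 1]. This
null models read-sampling noise only: it is exactly calibrated when reads
are exchangeable given the pooled node masses (verified by simulation) and
is anticonservative under animal-level overdispersion, a property inherent
to the pooled-read design rather than an implementation artifact.
Betweenness is standard unnormalized betweenness centrality (fractional
counting over tied shortest paths); carbon sum is the total carbon count
of a node's metabolite set.

Presence/absence classifies nodes by diet-pooled observation; each
exclusive node's P is the probability that all of its reads land in one
diet when reassigned to animals proportional to mapped totals. The
per-node variance contrast compares the two diets' across-animal variances
of normalized counts with a node-paired Wilcoxon signed-rank (the variances
are paired by node, so the paired test is the appropriate form), repeated
on depth-equalized resamples (100,000 reads per animal without
replacement; shallower animals resample with replacement and are flagged).
VFA read fractions — the share of uniquely mapped reads on nodes using each
VFA — are correlated with measured concentrations by one-sided Spearman.

## Distances and the diet-shift simulation

Animal profiles are count vectors scaled to unit Euclidean norm; distances
between non-negative unit vectors lie in [0, √2]. The sampling null pools
reads within each diet and reassigns them to animals multinomially in
proportion to original mapped totals (expected-total conservation; an
exact per-animal partition is behind a flag), recomputing distances per
replicate. The node-versus-OTU distance correlation is Pearson over
within-diet pairs (all-pairs behind a flag) and is judged against the same
resampling null — important because diet-level heterogeneity alone can
produce high correlations between the two spaces.

Compound vectors sum each metabolite's read mass over the nodes using it
and are rescaled to total 100,000. The annealing objective is the
Euclidean distance between the state's scaled compound vector and the
(scaled) target (cosine distance selectable); states are integer read
counts, moves conserve total reads. swap1 moves one read from a node
chosen proportional to counts to a uniform node; swap2 picks a source edge
with reads on both endpoints and an independent destination edge, moving
one read along each pairing — both destination nodes must form an edge,
the reading most consistent with "another pair of connected nodes".
Metropolis acceptance exp(−Δ/T) with geometric cooling (T₀ = 1.0,
α = 0.9995, 200,000 iterations by default; all exposed in the config).
Each search runs independent restarts (default 10) from the same start
with sub-seeds derived deterministically from (seed, start label, restart
index) via CRC32, and keeps the restart whose *best-ever* state is closest
to the target. On instances small enough to enumerate, swap1 annealing
reaches the global optimum; swap2 can only do worse or equal on matched
seeds, since the edge constraint restricts the move set.

## Synthetic data

The generator emulates the study conditions, not real biology: 300 generic
metabolites plus the 24 named interface compounds, 400 microbial and 60
host reactions (metabolite sets of 2–6), one random-sequence enzyme per
microbial reaction (130–400 residues; 5% annotated to two reactions), and
16 animals (8 per diet) at 50,000 node-assigned reads each. A 15-compound
currency pool is reused in three frequency tiers targeting mean
occurrences of roughly 140, 60 and 32 of 400 reactions, so each cutoff
removes a different subset; each VFA is additionally pinned to one
reaction per side, since VFA production and uptake are obligatory in the
rumen.

Node intensities follow the three-state mixture with FORG parameters
p₀ = 0.25, p₁ = 0.08, μ = 3.0, σ = 1.703 (log-variance 2.9); the CONC
profile multiplies the shared base by exp(0.5 · (mean layer − layer)) —
tilting reads toward the interface — and tightens the spread to σ = 1.643
(log-variance 2.7), the two diets' printed log-variances. Animal columns
are multinomial draws of the intensity times log-normal animal dispersion
(0.25 FORG, 0.60 CONC); 5% of nodes are silenced in exactly one diet to
create diet-exclusive nodes; and three CONC animals share a degenerate
profile — Dirichlet(0.3) mass on 8 dominant nodes over a faint background
restricted to diet-expressed nodes — emulating the high-RFI phenotype. An
80-OTU table with its own diet effect accompanies the counts. Paired
100 bp reads are drawn from back-translated enzyme sequences (uniform
synonymous codons) with insert ~ N(309, 30) capped at 420 bp, so both
mates sit in a stop-free coding frame.

What the generator does *not* emulate: real sequence homology structure
(enzymes are uniform random peptides, so cross-mapping ambiguity is far
rarer than against a curated database), phylogenetic correlation between
OTUs and reactions, uneven per-animal sequencing depth, and host
contamination. Passing tests therefore demonstrate the pipeline's
correctness and calibration under its own model assumptions, not mapper
performance on real metagenomes.

## Problem sizes

The test suite and acceptance script run at desk scale as the package's
own sizing: FASTQ mapping on 2 animals × 150 pairs against a 40-enzyme
database; annealing oracles on ≤ 3-node, ≤ 8-read instances (3,000
iterations, 3 restarts); calibration over 200 simulated null datasets with
1,000 randomizations each; mixture recovery on 50 × 5,000-node
simulations; and the full-grid pipeline on a 150–200-reaction scenario.
Statistical conclusions at these sizes carry the usual Monte-Carlo
uncertainty, which the tests' tolerance bands reflect.

## Known limitations

- The pooled-read randomization null ignores animal-level overdispersion
  (see above); a label-permutation alternative would be calibrated under
  it but tests a different hypothesis.
- The df = 5 LRT convention is honored only as a flag; the default follows
  the parameter count.
- MULTI pairs are reported but not used downstream; no fractional
  assignment is attempted.
- Annealing move proposals and cooling are one concrete choice from a
  family the original description leaves open; all knobs are in
  `AnnealingConfig`.
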