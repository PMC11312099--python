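# paracong

Congruence analysis for **paired microbial communities** — e.g. the
endophyte community of a parasitic plant organ and the community of its
host's root or rhizosphere, sampled from the same biological units. The
package answers two questions:

1. **How congruent are the two communities?** Weighted UniFrac distances
   on a shared phylogeny → principal coordinates (PCoA) → symmetric
   Procrustes superimposition of the two sample configurations. The
   congruence statistic is the Procrustes correlation

   t₀ = √(1 − m²) ∈ [0, 1]

   (0 = complete disagreement, 1 = complete agreement), with permutation
   significance from PROTEST.

2. **Which taxa carry the congruence?** A leave-one-out analysis removes
   each taxonomic group (phylum by default) from both communities,
   recomputes UniFrac → PCoA → t₀′, and reports **Δt = t₀′ − t₀**.
   Negative Δt marks groups that support the agreement between the two
   communities; positive Δt marks groups that mask it.

Around this core the package provides the standard companion analyses of
amplicon surveys: alpha diversity (Chao1, Gini-Simpson, Pielou) and
rarefaction; co-occurrence networks from Spearman or basic-SparCC
correlations with permutation pseudo-p values, the strict |r| > 0.6 and
p < 0.05 edge filter, greedy (CNM) modularity, Zi/Pi node connectivity
and the four topological roles (peripheral / connector / module hub /
network hub); and a microbe–metabolite association screen (Spearman +
Fisher-Z test with `*`/`**` significance stars) plus the VIP > 1,
p < 0.05, |log2FC| ≥ 1 differential-metabolite filter.

A **synthetic-data module** generates paired communities whose
compositions share a latent factor of tunable strength λ, optionally
carried by a single designated phylum, plus metabolites with known
taxon–metabolite couplings — so every stage of the pipeline can be
validated against planted ground truth without downloading anything.
See `docs/methods.md` for the model and all numerical choices.

## Worked example

```python
import paracong as pc

# synthetic scenario: 30 taxa in 5 phyla, 20 paired samples,
# coupling lambda = 0.9 carried by the largest phylum
scenario = pc.generate_scenario(pc.ScenarioConfig(seed=1, carrier_phylum="auto"))
print(scenario["config"].carrier_phylum)   # Phylum02

loo = pc.leave_one_out_delta_t(
    scenario["table_a"], scenario["table_b"],
    scenario["tree"], scenario["taxonomy"], rank="phylum",
)
print(f"baseline t0 = {loo.baseline.t0:.3f}")
print(loo.table.round(3))
```

Output:

```
baseline t0 = 0.812
             t0_prime  delta_t  n_taxa_removed  skipped
taxon_group
Phylum01        0.811   -0.002               2    False
Phylum02        0.138   -0.674              32    False
Phylum03        0.725   -0.087              14    False
Phylum04        0.839    0.027               8    False
Phylum05        0.816    0.003               4    False
```

The two communities agree strongly overall (t₀ = 0.812). Removing the
carrier phylum (Phylum02, 16 taxa in each table, 32 rows removed in
total) collapses the congruence to t₀′ = 0.138 — Δt = −0.674, by far the
most negative value — while removing any other phylum barely moves t₀.
The leave-one-out statistic has correctly attributed the shared
structure to the phylum that was planted to carry it.

Significance of the baseline congruence:

```python
from paracong import weighted_unifrac, pcoa, protest

ord_a = pcoa(weighted_unifrac(scenario["table_a"], scenario["tree"]), n_axes=2)
ord_b = pcoa(weighted_unifrac(scenario["table_b"], scenario["tree"]), n_axes=2)
res = protest(ord_a.coordinates, ord_b.coordinates, n_permutations=999, seed=1)
print(f"t0 = {res.t0:.3f}, m2 = {res.m2:.3f}, p = {res.p_value:.3f}")
# t0 = 0.812, m2 = 0.340, p = 0.001
```

p = 0.001 is the smallest value attainable with 999 permutations: no
permuted sample matching came close to the observed congruence.

## Command line

The same pipeline is scriptable via the `paracong` entry point:

```bash
paracong simulate --seed 1 --out-dir demo/            # scenario files
paracong run --table-a demo/tableA.tsv --table-b demo/tableB.tsv \
    --tree demo/tree.nwk --taxonomy demo/taxonomy.tsv \
    --seed 1 --out-dir demo/results                   # unifrac→pcoa→protest→loo
paracong network demo/tableA.tsv --n-boot 1000 --seed 1 --out-dir demo/net
paracong associate demo/tableA.tsv demo/metabolites.tsv --out demo/assoc.tsv
```

Subcommands: `simulate`, `diversity`, `unifrac`, `pcoa`, `procrustes`,
`loo`, `network`, `associate`, `screen`, `run`. All inputs are TSV /
Newick; every output starts with a provenance header (version, seed,
config hash) and reruns with the same seed are byte-identical. Exit
codes: 0 success, 2 input error, 1 internal error.

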