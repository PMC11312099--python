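"""Synthetic paired-community generator with known ground truth.

Emulates the statistical object the congruence pipeline studies: two
sample-matched microbial communities (think endophyte compartment vs
host-root/rhizosphere compartment) whose compositions share a latent
factor structure of tunable strength, plus a metabolite matrix with
known taxon-metabolite couplings.

Generative model (all randomness from one integer seed):

* topology: Yule (pure-birth) tree over ``n_taxa`` leaves, exponential(1)
  branch lengths; phyla are monophyletic clades cut near the root.
* per sample j: shared factors f_j ~ N(0, I_K) and community-specific
  factors g_j^A, g_j^B ~ N(0, I_K).
* per taxon i: loadings w_i ~ N(0, 1/K) and baseline b_i ~ N(0, 1).
* log-propensity in community C:
      eta_ij^C = b_i + w_i . (lam * f_j + (1 - lam) * g_j^C) + eps,
  eps ~ N(0, sigma^2). If ``carrier_phylum`` is set, taxa OUTSIDE the
  carrier have their shared-factor term ``lam * f_j`` replaced by the
  community-specific term, i.e. eta = b_i + (1 - lam) * w_i . g_j^B +
  eps, in community B only — so only carrier taxa transmit the shared
  signal across communities.
* composition: softmax of eta over taxa; counts ~ Multinomial(N, p_j).
* metabolites: each coupled metabolite tracks
  alpha * log(rel. abundance of its taxon + 1e-6) plus Gaussian noise,
  with |alpha| ~ U(alpha_min, alpha_max) and random sign; uncoupled
  metabolites are pure N(0, 1). Intensities are shifted per metabolite
  to be non-negative (a monotone shift, so rank statistics are
  untouched).

The coupling lam in [0, 1] controls cross-community congruence: at
lam = 0 the two communities are independent given the shared taxon
baselines; at lam = 1 (and small sigma) they share their full factor
structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io import CommunityTable, MetaboliteTable, PhyloTree, TaxonomyMap

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "generate_tree",
    "assign_taxonomy",
    "generate_paired_tables",
    "generate_metabolite_table",
    "generate_scenario",
]


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic paired-community scenario.

    Defaults are the conditions of the carrier-phylum recovery scenario
    exercised throughout the test-suite: 30 taxa in 5 phyla, 20 paired
    samples, strong coupling (lam = 0.9) carried by one phylum,
    moderate noise (sigma = 0.5) and 5,000 reads per sample.
    """

    n_taxa: int = 30
    n_samples: int = 20
    n_phyla: int = 5
    n_factors: int = 1
    coupling: float = 0.9            # lam in [0, 1]
    carrier_phylum: str | None = None
    noise_sd: float = 0.5            # sigma > 0
    reads_per_sample: int = 5000     # N
    n_metabolites: int = 30
    n_coupled_metabolites: int = 5
    met_alpha_min: float = 1.5
    met_alpha_max: float = 2.0
    met_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if not 1 <= self.n_phyla <= self.n_taxa:
            raise ValueError("need 1 <= n_phyla <= n_taxa")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if self.n_coupled_metabolites > self.n_metabolites:
            raise ValueError("more coupled metabolites than metabolites")
        if not 0 < self.met_alpha_min <= self.met_alpha_max:
            raise ValueError("need 0 < met_alpha_min <= met_alpha_max")
        if self.met_noise_sd < 0:
            raise ValueError("met_noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream recovery tests."""

    coupling: float
    carrier_phylum: str | None
    loadings: pd.DataFrame | None = None      # taxa x factors
    couplings: list[tuple[str, str, float]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coupling": self.coupling,
            "carrier_phylum": self.carrier_phylum,
            "loadings": None if self.loadings is None
            else {t: list(map(float, row))
                  for t, row in self.loadings.iterrows()},
            "couplings": [
                {"taxon": t, "metabolite": m, "alpha": a}
                for t, m, a in self.couplings
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def _substream_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent integer sub-seeds (< 2**31) from one seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s >> 1) for s in state]


def generate_tree(n_taxa: int, seed: int) -> PhyloTree:
    """Yule (pure-birth) topology with exponential(1) branch lengths.

    Starts from a two-leaf cherry and repeatedly splits a uniformly
    chosen extant leaf until ``n_taxa`` leaves exist; every edge then
    receives an independent exponential(rate 1) length. Leaves are
    labelled ``t001, t002, ...`` in creation order. Deterministic given
    ``seed``.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    left = tree.seed_node.new_child()
    right = tree.seed_node.new_child()
    leaves = [left, right]
    while len(leaves) < n_taxa:
        parent = leaves.pop(int(rng.integers(len(leaves))))
        leaves.append(parent.new_child())
        leaves.append(parent.new_child())
    width = max(3, len(str(n_taxa)))
    for i, leaf in enumerate(leaves):
        taxon = taxon_namespace.new_taxon(f"t{i + 1:0{width}d}")
        leaf.taxon = taxon
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            node.edge.length = float(rng.exponential(1.0))
    return PhyloTree(tree)


def assign_taxonomy(tree: PhyloTree, n_phyla: int, seed: int) -> TaxonomyMap:
    """Cut the tree into ``n_phyla`` monophyletic clades -> phylum labels.

    Starting from the root clade, the splittable clade nearest the root
    (fewest edges from the root; ties broken by the seeded rng) is
    replaced by its child clades until ``n_phyla`` clades exist — the
    dendrogram-style cut through the deepest splits of the hierarchy.
    Phyla are labelled ``Phylum01, ...`` ordered by their smallest leaf.
    """
    n_leaves = tree.n_leaves
    if not 1 <= n_phyla <= n_leaves:
        raise ValueError(f"need 1 <= n_phyla <= {n_leaves}")
    rng = np.random.default_rng(seed)
    dtree = tree.to_dendropy()
    depth: dict[int, int] = {id(dtree.seed_node): 0}
    for node in dtree.preorder_node_iter():
        if node is not dtree.seed_node:
            depth[id(node)] = depth[id(node.parent_node)] + 1
    clades = [dtree.seed_node]
    while len(clades) < n_phyla:
        splittable = [c for c in clades if not c.is_leaf()]
        depths = np.array([depth[id(c)] for c in splittable])
        candidates = [c for c, d in zip(splittable, depths) if d == depths.min()]
        chosen = candidates[int(rng.integers(len(candidates)))]
        clades.remove(chosen)
        clades.extend(chosen.child_nodes())

    def clade_leaves(node) -> list[str]:
        return [str(l.taxon.label) for l in node.leaf_iter()]

    groups = sorted((sorted(clade_leaves(c)) for c in clades), key=lambda g: g[0])
    mapping: dict[str, dict[str, str]] = {}
    width = max(2, len(str(n_phyla)))
    for i, members in enumerate(groups):
        label = f"Phylum{i + 1:0{width}d}"
        for taxon in members:
            mapping[taxon] = {"kingdom": "Microbia", "phylum": label}
    return TaxonomyMap(mapping)


def generate_paired_tables(
    config: ScenarioConfig, tree: PhyloTree, taxonomy: TaxonomyMap
) -> tuple[CommunityTable, CommunityTable, GroundTruth]:
    """Sample-matched count tables A and B under the latent-factor model."""
    taxa = tree.leaf_labels
    if len(taxa) != config.n_taxa:
        raise ValueError("tree leaf count disagrees with config.n_taxa")
    if config.carrier_phylum is not None:
        carrier_taxa = [t for t in taxa
                        if taxonomy.get(t, "phylum") == config.carrier_phylum]
        if not carrier_taxa:
            raise ValueError(
                f"carrier phylum {config.carrier_phylum!r} has no taxa"
            )
    rng = np.random.default_rng(_substream_seeds(config.seed, 4)[2])
    n_t, n_s, k = config.n_taxa, config.n_samples, config.n_factors
    lam, sigma = config.coupling, config.noise_sd

    b = rng.normal(0.0, 1.0, size=n_t)
    w = rng.normal(0.0, 1.0 / np.sqrt(k), size=(n_t, k))
    f = rng.normal(size=(k, n_s))
    g_a = rng.normal(size=(k, n_s))
    g_b = rng.normal(size=(k, n_s))
    eps_a = rng.normal(0.0, sigma, size=(n_t, n_s))
    eps_b = rng.normal(0.0, sigma, size=(n_t, n_s))

    eta_a = b[:, None] + w @ (lam * f + (1 - lam) * g_a) + eps_a
    eta_b = b[:, None] + w @ (lam * f + (1 - lam) * g_b) + eps_b
    if config.carrier_phylum is not None:
        # non-carrier taxa keep only the community-specific term in B
        outside = np.array(
            [taxonomy.get(t, "phylum") != config.carrier_phylum for t in taxa]
        )
        eta_b[outside] = (b[outside, None]
                          + (1 - lam) * (w[outside] @ g_b)
                          + eps_b[outside])

    def to_counts(eta: np.ndarray) -> np.ndarray:
        p = np.exp(eta - eta.max(axis=0))
        p /= p.sum(axis=0)
        cols = [rng.multinomial(config.reads_per_sample, p[:, j])
                for j in range(n_s)]
        return np.array(cols).T

    samples = [f"s{j + 1:02d}" for j in range(n_s)]
    table_a = CommunityTable(pd.DataFrame(to_counts(eta_a), index=taxa, columns=samples))
    table_b = CommunityTable(pd.DataFrame(to_counts(eta_b), index=taxa, columns=samples))
    truth = GroundTruth(
        coupling=lam,
        carrier_phylum=config.carrier_phylum,
        loadings=pd.DataFrame(w, index=taxa,
                              columns=[f"factor{i + 1}" for i in range(k)]),
    )
    return table_a, table_b, truth


def generate_metabolite_table(
    config: ScenarioConfig, table_a: CommunityTable, seed: int
) -> tuple[MetaboliteTable, list[tuple[str, str, float]]]:
    """Metabolite intensities with the first ``n_coupled_metabolites``
    coupled to distinct randomly chosen taxa of community A.

    Coupled metabolite m follows alpha_m * log(relabund + 1e-6) plus
    N(0, met_noise_sd) noise; the rest are N(0, 1). Each metabolite is
    shifted to non-negative intensities.
    """
    if table_a.shape[0] == 0 or table_a.shape[1] == 0:
        raise ValueError("empty community table")
    rng = np.random.default_rng(seed)
    rel = table_a.relative_abundance()
    n_s = table_a.shape[1]
    width = max(2, len(str(config.n_metabolites)))
    met_ids = [f"m{i + 1:0{width}d}" for i in range(config.n_metabolites)]
    coupled_taxa = rng.choice(
        table_a.taxon_ids, size=config.n_coupled_metabolites, replace=False
    )
    couplings: list[tuple[str, str, float]] = []
    rows = np.empty((config.n_metabolites, n_s))
    for i, met in enumerate(met_ids):
        if i < config.n_coupled_metabolites:
            taxon = str(coupled_taxa[i])
            alpha = float(rng.uniform(config.met_alpha_min, config.met_alpha_max))
            alpha *= 1 if rng.random() < 0.5 else -1
            signal = alpha * np.log(rel.loc[taxon].to_numpy() + 1e-6)
            rows[i] = signal + rng.normal(0.0, config.met_noise_sd, size=n_s)
            couplings.append((taxon, met, alpha))
        else:
            rows[i] = rng.normal(0.0, 1.0, size=n_s)
    rows -= np.minimum(rows.min(axis=1, keepdims=True), 0.0)
    table = MetaboliteTable(
        pd.DataFrame(rows, index=met_ids, columns=table_a.sample_ids)
    )
    return table, couplings


def generate_scenario(config: ScenarioConfig) -> dict:
    """Full scenario bundle: tree, taxonomy, tables A/B, metabolites, truth.

    When ``config.carrier_phylum`` is the sentinel ``"auto"``, the
    largest phylum becomes the carrier.
    """
    tree_seed, tax_seed, _, met_seed = _substream_seeds(config.seed, 4)
    tree = generate_tree(config.n_taxa, tree_seed)
    taxonomy = assign_taxonomy(tree, config.n_phyla, tax_seed)
    if config.carrier_phylum == "auto":
        groups = taxonomy.groups_at_rank("phylum", tree.leaf_labels)
        carrier = max(sorted(groups), key=lambda g: len(groups[g]))
        config = ScenarioConfig(**{**asdict(config), "carrier_phylum": carrier})
    table_a, table_b, truth = generate_paired_tables(config, tree, taxonomy)
    metabolites, couplings = generate_metabolite_table(config, table_a, met_seed)
    truth.couplings = couplings
    return {
        "config": config,
        "tree": tree,
        "taxonomy": taxonomy,
        "table_a": table_a,
        "table_b": table_b,
        "metabolites": metabolites,
        "truth": truth,
    }
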