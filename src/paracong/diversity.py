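"""Alpha diversity, rarefaction, and the weighted UniFrac distance matrix.

Alpha diversity covers the three indices used throughout plant-microbiome
surveys: Chao1 richness (singleton/doubleton bias correction), the
Gini-Simpson diversity index 1 - sum p_i^2, and Pielou evenness
H / ln(S_obs) with natural-log Shannon entropy H.

Weighted UniFrac weights every branch of a rooted phylogeny by the
absolute difference in the relative abundance of its descendant leaves
between two samples:

    d_raw(A, B)  = sum_b  l_b * |P_b - Q_b|
    d_norm(A, B) = d_raw / sum_b l_b * (P_b + Q_b)

where l_b is the branch length and P_b (Q_b) the summed relative
abundance, in sample A (B), of leaves descending through branch b. The
normalized form is bounded in [0, 1] and is the default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import CommunityTable, DistanceMatrix, PhyloTree

logger = logging.getLogger(__name__)

__all__ = ["alpha_diversity", "rarefy", "weighted_unifrac"]


def alpha_diversity(table: CommunityTable) -> pd.DataFrame:
    """Per-sample Chao1, Gini-Simpson and Pielou indices.

    Counts must be (near-)integer: Chao1 needs exact singleton (F1) and
    doubleton (F2) tallies. Chao1 = S_obs + F1^2 / (2 F2) when F2 > 0,
    else the bias-corrected S_obs + F1 (F1 - 1) / 2. Pielou evenness is
    NaN for samples with a single observed taxon (ln S_obs = 0).

    Returns a DataFrame indexed by sample id with columns
    ``observed_taxa, chao1, simpson, pielou``.
    """
    counts = table.counts
    if not np.allclose(counts, np.round(counts), atol=1e-9):
        raise ValueError("alpha_diversity requires integer counts")
    counts = np.round(counts).astype(np.int64)
    records = {}
    for j, sample in enumerate(table.sample_ids):
        c = counts[:, j]
        total = int(c.sum())
        if total == 0:
            raise ValueError(f"all-zero sample: {sample!r}")
        present = c[c > 0]
        s_obs = present.size
        f1 = int((present == 1).sum())
        f2 = int((present == 2).sum())
        if f2 > 0:
            chao1 = s_obs + f1 * f1 / (2.0 * f2)
        else:
            chao1 = s_obs + f1 * (f1 - 1) / 2.0
        p = present / total
        simpson = 1.0 - float(np.sum(p * p))
        if s_obs > 1:
            shannon = -float(np.sum(p * np.log(p)))
            pielou = shannon / np.log(s_obs)
        else:
            pielou = np.nan
        records[sample] = {
            "observed_taxa": s_obs,
            "chao1": chao1,
            "simpson": simpson,
            "pielou": pielou,
        }
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "sample_id"
    return out


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning;
    if every sample falls below depth this is an error. Deterministic
    given ``seed`` (one multivariate-hypergeometric draw per kept sample,
    in sample order).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    counts = table.counts
    if not np.allclose(counts, np.round(counts), atol=1e-9):
        raise ValueError("rarefy requires integer counts")
    counts = np.round(counts).astype(np.int64)
    totals = counts.sum(axis=0)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if not keep.any():
        raise ValueError(f"all samples below rarefaction depth {depth}")
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    cols = {}
    for j, sample in enumerate(table.sample_ids):
        if not keep[j]:
            continue
        cols[sample] = rng.multivariate_hypergeometric(counts[:, j], depth)
    out = pd.DataFrame(cols, index=table.taxon_ids)
    return CommunityTable(out)


def weighted_unifrac(
    table: CommunityTable, tree: PhyloTree, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac distances between all sample pairs of ``table``.

    Every taxon of the table must be a leaf of ``tree`` (extra tree
    leaves count as zero abundance); every sample must have a positive
    total. ``normalized=True`` (default) divides each pairwise distance
    by its own maximum attainable value, bounding it in [0, 1].
    """
    rel = table.relative_abundance()  # raises on zero-total samples
    lengths, masks = tree.edge_arrays(table.taxon_ids)
    # clade abundance per (edge, sample): sum of relative abundances of
    # the table taxa descending through that edge
    clade = masks.astype(float) @ rel.to_numpy()
    n = len(table.sample_ids)
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(clade[:, i][:, None] - clade[:, i + 1:])
        num = lengths @ diff
        if normalized:
            den = lengths @ (clade[:, i][:, None] + clade[:, i + 1:])
            with np.errstate(invalid="ignore", divide="ignore"):
                num = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        dist[i, i + 1:] = num
        dist[i + 1:, i] = num
    return DistanceMatrix(table.sample_ids, dist)
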