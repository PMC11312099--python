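"""Procrustes congruence between paired ordinations and leave-one-out Δt.

The congruence statistic between two sample-matched ordinations X and Y
is the symmetric Procrustes correlation

    t0 = sqrt(1 - m²) = trace Σ,

where Σ holds the singular values of X'Y after both configurations have
been column-centered and scaled to unit Frobenius norm. t0 ranges from 0
(no agreement under any rotation/reflection) to 1 (exact
superimposability up to translation, uniform scaling and orthogonal
transformation). Significance comes from PROTEST: the rows of Y are
permuted and t0 recomputed, with the add-one permutation p-value.

The leave-one-out procedure attributes congruence to taxonomic groups:
for each group at a chosen rank, its taxa are removed from both
communities, weighted UniFrac -> PCoA -> t0 is recomputed, and
Δt = t0' - t0 reported. Groups that carry the cross-community signal
give negative Δt (congruence drops without them); groups that mask it
give positive Δt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import weighted_unifrac
from .io import CommunityTable, PhyloTree, TaxonomyMap
from .ordination import pcoa

logger = logging.getLogger(__name__)

__all__ = ["ProcrustesResult", "LOOResult", "procrustes_t0", "protest",
           "leave_one_out_delta_t"]


@dataclass
class ProcrustesResult:
    t0: float
    m2: float
    rotation: np.ndarray
    scale: float
    p_value: float | None = None
    n_permutations: int = 0


def _prepare(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 2:
        raise ValueError("configurations must be 2-D (samples x axes)")
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"row (sample) counts differ: {x.shape[0]} vs {y.shape[0]}"
        )
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rows (samples)")
    # pad the narrower configuration with zero columns
    width = max(x.shape[1], y.shape[1])
    if x.shape[1] < width:
        x = np.hstack([x, np.zeros((x.shape[0], width - x.shape[1]))])
    if y.shape[1] < width:
        y = np.hstack([y, np.zeros((y.shape[0], width - y.shape[1]))])
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("degenerate configuration (all rows identical)")
    return xc / nx, yc / ny


def _trace_sigma(m: np.ndarray) -> float:
    return float(np.linalg.svd(m, compute_uv=False).sum())


def procrustes_t0(
    x: np.ndarray,
    y: np.ndarray,
    sample_ids_x: list[str] | None = None,
    sample_ids_y: list[str] | None = None,
) -> ProcrustesResult:
    """Symmetric Procrustes superimposition of two sample-matched matrices.

    Rows must correspond one-to-one in the same order; if sample id
    lists are supplied they are checked. Reflections are permitted in
    the optimal rotation (no determinant constraint).
    """
    if sample_ids_x is not None and sample_ids_y is not None:
        if list(sample_ids_x) != list(sample_ids_y):
            raise ValueError("sample id mismatch between configurations")
    xn, yn = _prepare(x, y)
    u, s, vt = np.linalg.svd(xn.T @ yn)
    t0 = float(s.sum())
    t0 = min(t0, 1.0)  # guard rounding at exact superimposability
    m2 = 1.0 - t0 * t0
    rotation = vt.T @ u.T  # applied to Y: Y @ rotation best matches X
    return ProcrustesResult(t0=t0, m2=m2, rotation=rotation, scale=t0)


def protest(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    sample_ids_x: list[str] | None = None,
    sample_ids_y: list[str] | None = None,
) -> ProcrustesResult:
    """PROTEST: permutation significance of the Procrustes t0.

    Permutes the row order of Y ``n_permutations`` times;
    p = (1 + #{t_perm >= t0}) / (n_permutations + 1), never exactly 0.
    Deterministic given ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    result = procrustes_t0(x, y, sample_ids_x, sample_ids_y)
    xn, yn = _prepare(x, y)
    rng = np.random.default_rng(seed)
    n = xn.shape[0]
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if _trace_sigma(xn.T @ yn[perm]) >= result.t0:
            exceed += 1
    result.p_value = (1 + exceed) / (n_permutations + 1)
    result.n_permutations = n_permutations
    return result


@dataclass
class LOOResult:
    """Baseline congruence plus the per-group leave-one-out table.

    ``table`` has one row per taxonomic group at the chosen rank with
    columns ``t0_prime, delta_t, n_taxa_removed, skipped``; skipped rows
    (whose removal empties a sample) carry NaN statistics.
    """

    baseline: ProcrustesResult
    table: pd.DataFrame
    rank: str


def _pipeline_t0(
    table_a: CommunityTable,
    table_b: CommunityTable,
    tree: PhyloTree,
    n_axes: int,
    normalized: bool,
) -> ProcrustesResult:
    ord_a = pcoa(weighted_unifrac(table_a, tree, normalized=normalized), n_axes)
    ord_b = pcoa(weighted_unifrac(table_b, tree, normalized=normalized), n_axes)
    return procrustes_t0(
        ord_a.coordinates, ord_b.coordinates, ord_a.sample_ids, ord_b.sample_ids
    )


def leave_one_out_delta_t(
    table_a: CommunityTable,
    table_b: CommunityTable,
    tree: PhyloTree,
    taxonomy: TaxonomyMap,
    rank: str = "phylum",
    n_axes: int = 2,
    normalized: bool = True,
    side: str = "both",
) -> LOOResult:
    """Per-group Δt = t0' - t0 after removing each group at ``rank``.

    Groups are taken over the union of taxa in the two tables. By
    default a group is removed from BOTH communities (``side="both"``);
    ``side="a"``/``side="b"`` restricts removal to one community.
    Relative abundances renormalize implicitly over the remaining taxa.
    A group whose removal leaves some sample with zero total in either
    table is skipped (flagged row, warning).
    """
    if side not in ("both", "a", "b"):
        raise ValueError(f"side must be 'both', 'a' or 'b', not {side!r}")
    if table_a.sample_ids != table_b.sample_ids:
        if len(table_a.sample_ids) != len(table_b.sample_ids):
            raise ValueError("tables have different sample counts")
        logger.info(
            "leave_one_out_delta_t: sample ids differ; using positional pairing"
        )
    baseline = _pipeline_t0(table_a, table_b, tree, n_axes, normalized)

    all_taxa = list(dict.fromkeys(table_a.taxon_ids + table_b.taxon_ids))
    groups = taxonomy.groups_at_rank(rank, all_taxa)
    rows = []
    for group in sorted(groups):
        members = set(groups[group])
        sub_a = table_a.drop_taxa(members) if side in ("both", "a") else table_a
        sub_b = table_b.drop_taxa(members) if side in ("both", "b") else table_b
        n_removed = (len(table_a.taxon_ids) - len(sub_a.taxon_ids)) + (
            len(table_b.taxon_ids) - len(sub_b.taxon_ids)
        )
        empties = (
            sub_a.shape[0] == 0
            or sub_b.shape[0] == 0
            or (sub_a.counts.sum(axis=0) == 0).any()
            or (sub_b.counts.sum(axis=0) == 0).any()
        )
        if empties:
            logger.warning(
                "leave_one_out_delta_t: removing %r empties a sample; skipped", group
            )
            rows.append({"taxon_group": group, "t0_prime": np.nan,
                         "delta_t": np.nan, "n_taxa_removed": n_removed,
                         "skipped": True})
            continue
        loo = _pipeline_t0(sub_a, sub_b, tree, n_axes, normalized)
        rows.append({"taxon_group": group, "t0_prime": loo.t0,
                     "delta_t": loo.t0 - baseline.t0,
                     "n_taxa_removed": n_removed, "skipped": False})
    table = pd.DataFrame(rows).set_index("taxon_group")
    return LOOResult(baseline=baseline, table=table, rank=rank)
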