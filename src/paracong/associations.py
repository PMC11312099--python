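"""Microbe-metabolite association screen and the differential-metabolite filter.

Each (taxon group, metabolite) pair is scored by Spearman's rank
correlation with significance from the Fisher-transform Z-test,

    z = arctanh(r) * sqrt(n - 3),  p = 2 * Phi(-|z|),

and annotated with the conventional heatmap stars: "**" for p < 0.01,
"*" for 0.01 <= p < 0.05, "" otherwise. Raw p-values are flagged by
default (matching the screen this reproduces); Benjamini-Hochberg
correction is available behind a flag.

The differential-metabolite filter retains rows with VIP > 1 (strict),
p < 0.05 (strict) and |log2FC| >= 1 (inclusive), the usual OPLS-DA
triple threshold; VIP values are consumed, not fitted, here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .io import CommunityTable, MetaboliteTable, TaxonomyMap

logger = logging.getLogger(__name__)

__all__ = [
    "spearman_z",
    "flag_for_p",
    "AssociationMatrix",
    "association_matrix",
    "screen_differential_metabolites",
]

_R_CLAMP = 1.0 - 1e-15


def spearman_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman correlation with two-sided Fisher-transform Z-test p-value.

    Midranks are used for ties. Requires equal lengths, n >= 4 and at
    least two distinct values per vector. |r| is clamped to 1 - 1e-15
    before arctanh so perfect monotone association yields a finite z
    and p indistinguishable from 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has no defined rank correlation")
    rx, ry = rankdata(x), rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(min(r, 1.0), -1.0)
    z = np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP)) * np.sqrt(n - 3)
    p = float(2.0 * norm.sf(abs(z)))
    return r, p


def flag_for_p(p: float) -> str:
    """Significance stars: '**' below 0.01, '*' below 0.05, else ''."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class AssociationMatrix:
    """(r, p, flag) per (taxon group, metabolite): three aligned DataFrames."""

    r: pd.DataFrame      # groups x metabolites
    p: pd.DataFrame
    flags: pd.DataFrame
    n_samples: int

    def long_format(self) -> pd.DataFrame:
        rows = []
        for g in self.r.index:
            for m in self.r.columns:
                rows.append({
                    "taxon_group": g, "metabolite": m,
                    "r": self.r.at[g, m], "p": self.p.at[g, m],
                    "flag": self.flags.at[g, m],
                })
        return pd.DataFrame(rows)


def _aggregate(table: CommunityTable, rank: str, taxonomy: TaxonomyMap) -> pd.DataFrame:
    groups = taxonomy.groups_at_rank(rank, table.taxon_ids)
    agg = {g: table.data.loc[members].sum(axis=0) for g, members in groups.items()}
    return pd.DataFrame(agg).T.loc[sorted(groups)]


def association_matrix(
    microbes: CommunityTable,
    metabolites: MetaboliteTable,
    rank: str | None = None,
    taxonomy: TaxonomyMap | None = None,
    correct: str = "none",
) -> AssociationMatrix:
    """Spearman+Z screen of every taxon group against every metabolite.

    Samples are aligned by id (order of the microbial table); at least 4
    shared samples are required. With ``rank`` given (taxonomy required)
    counts are summed within groups before converting to relative
    abundance. Constant features are skipped with a warning (NaN cells).
    ``correct="fdr_bh"`` replaces raw p-values with Benjamini-Hochberg
    adjusted ones before flagging.
    """
    if correct not in ("none", "fdr_bh"):
        raise ValueError(f"unknown correction {correct!r}")
    shared = [s for s in microbes.sample_ids if s in set(metabolites.sample_ids)]
    if len(shared) == 0:
        raise ValueError("no shared samples between tables")
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared sample(s); need >= 4")
    mic = microbes.select_samples(shared)
    met = metabolites.select_samples(shared)
    if rank is not None:
        if taxonomy is None:
            raise ValueError("rank aggregation requires a taxonomy")
        counts = _aggregate(mic, rank, taxonomy)
    else:
        counts = mic.data
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero microbial total in shared set")
    rel = counts / totals

    r = pd.DataFrame(np.nan, index=rel.index, columns=met.metabolite_ids)
    p = pd.DataFrame(np.nan, index=rel.index, columns=met.metabolite_ids)
    for g in rel.index:
        gx = rel.loc[g].to_numpy()
        if np.ptp(gx) == 0:
            logger.warning("skipping constant group %r", g)
            continue
        for m in met.metabolite_ids:
            my = met.data.loc[m].to_numpy()
            if np.ptp(my) == 0:
                continue
            r.at[g, m], p.at[g, m] = spearman_z(gx, my)
    constant_mets = [m for m in met.metabolite_ids
                     if np.ptp(met.data.loc[m].to_numpy()) == 0]
    if constant_mets:
        logger.warning("skipped constant metabolite(s): %s", constant_mets)
    if correct == "fdr_bh":
        from statsmodels.stats.multitest import multipletests

        flat = p.to_numpy().ravel()
        mask = ~np.isnan(flat)
        adjusted = flat.copy()
        if mask.any():
            adjusted[mask] = multipletests(flat[mask], method="fdr_bh")[1]
        p = pd.DataFrame(adjusted.reshape(p.shape), index=p.index, columns=p.columns)
    flags = p.map(lambda v: "" if np.isnan(v) else flag_for_p(v))
    return AssociationMatrix(r=r, p=p, flags=flags, n_samples=len(shared))


def screen_differential_metabolites(rows: pd.DataFrame) -> pd.DataFrame:
    """Retain rows with VIP > 1, p < 0.05 and |log2FC| >= 1 (order kept).

    Expects numeric columns ``VIP``, ``p`` and ``log2FC`` (names matched
    case-insensitively; ``p_value``/``pvalue`` accepted for ``p``).
    """
    colmap = {}
    lower = {c.lower(): c for c in rows.columns}
    for want, aliases in (("VIP", ("vip",)),
                          ("p", ("p", "p_value", "pvalue", "p-value")),
                          ("log2FC", ("log2fc", "log2_fc", "log2(fc)"))):
        for alias in aliases:
            if alias in lower:
                colmap[want] = lower[alias]
                break
        else:
            raise ValueError(f"missing column {want!r}")
    vip = pd.to_numeric(rows[colmap["VIP"]])
    p = pd.to_numeric(rows[colmap["p"]])
    fc = pd.to_numeric(rows[colmap["log2FC"]])
    passes = (vip > 1.0) & (p < 0.05) & (fc.abs() >= 1.0)
    return rows.loc[passes]
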