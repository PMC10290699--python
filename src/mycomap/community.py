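"""OTU count tables, normalization, and inter-group correlation.

The entry point of the mapping workflow is a samples x OTUs count table
from an ITS metabarcoding run.  Counts are rarefied to a common depth
(subsampling without replacement, the QIIME convention), aggregated to
taxonomic or trophic-guild groups through a user-supplied mapping, and
the groups' co-occurrence structure is summarized as a hierarchically
clustered Spearman rank-correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "AbundanceTable",
    "GroupMapping",
    "CorrelationMatrix",
    "rarefy",
    "aggregate",
    "richness",
    "spearman_matrix",
]

UNASSIGNED = "unassigned"


@dataclass
class AbundanceTable:
    """Samples x OTUs integer count matrix."""

    counts: pd.DataFrame  # index: sample ids, columns: OTU ids

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample or OTU ids")
        self.counts = self.counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @classmethod
    def read_tsv(cls, path) -> "AbundanceTable":
        """First column OTU id, remaining columns samples (transposed in)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.T)

    def write_tsv(self, path) -> None:
        self.counts.T.to_csv(path, sep="\t", index_label="otu_id")


@dataclass
class GroupMapping:
    """OTU -> label per level (genus, family, order, phylum, trophic_guild).

    ``levels[level][otu_id] = label``; OTUs absent from a level are
    unassigned there.
    """

    levels: dict[str, dict[str, str]] = field(default_factory=dict)

    @classmethod
    def read_tsv(cls, path) -> "GroupMapping":
        """Long-format TSV with columns otu_id, level, label."""
        df = pd.read_csv(path, sep="\t")
        levels: dict[str, dict[str, str]] = {}
        for _, row in df.iterrows():
            lvl = levels.setdefault(str(row["level"]), {})
            otu = str(row["otu_id"])
            if otu in lvl and lvl[otu] != str(row["label"]):
                raise ValueError(
                    f"OTU {otu!r} mapped to two labels at level {row['level']!r}"
                )
            lvl[otu] = str(row["label"])
        return cls(levels)

    def write_tsv(self, path) -> None:
        rows = [
            {"otu_id": otu, "level": lvl, "label": lab}
            for lvl, mapping in self.levels.items()
            for otu, lab in mapping.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class CorrelationMatrix:
    """Spearman rho/p between groups with a display order from clustering."""

    labels: list[str]
    rho: np.ndarray
    p: np.ndarray
    order: np.ndarray  # permutation of range(len(labels))

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        """rho with non-significant entries masked to NaN (diagonal kept)."""
        out = self.rho.copy()
        mask = ~(self.p < alpha)
        np.fill_diagonal(mask, False)
        out[mask] = np.nan
        return out

    def reordered(self) -> pd.DataFrame:
        idx = self.order
        return pd.DataFrame(
            self.rho[np.ix_(idx, idx)],
            index=[self.labels[i] for i in idx],
            columns=[self.labels[i] for i in idx],
        )


def rarefy(
    table: AbundanceTable, depth: int | None = None, seed: int = 0
) -> AbundanceTable:
    """Subsample every sample to a common read depth without replacement.

    ``depth=None`` uses the smallest sample total (normalizing to the
    sample with the fewest sequences).  Each sample's reads are drawn as
    one multivariate-hypergeometric realization, so expected rarefied
    counts are proportional to the original counts.
    """
    totals = table.sample_totals()
    if depth is None:
        depth = int(totals.min())
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    short = totals[totals < depth]
    if len(short):
        raise ValueError(
            f"samples with fewer than {depth} reads: {list(short.index)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for i, row in enumerate(table.counts.to_numpy()):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return AbundanceTable(
        pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    )


def aggregate(
    table: AbundanceTable, mapping: GroupMapping, level: str
) -> pd.DataFrame:
    """Sum OTU counts into group columns at the given mapping level.

    OTUs without a label at this level are pooled into ``"unassigned"``;
    total reads per sample are conserved.
    """
    if level not in mapping.levels or not mapping.levels[level]:
        raise ValueError(f"no mapping entries for level {level!r}")
    lookup = mapping.levels[level]
    groups = [lookup.get(otu, UNASSIGNED) for otu in table.otu_ids]
    return table.counts.T.groupby(pd.Index(groups, name=level)).sum().T


def richness(table: AbundanceTable) -> pd.Series:
    """Number of distinct OTUs detected (count > 0) per sample."""
    return (table.counts > 0).sum(axis=1)


def spearman_matrix(
    groups: pd.DataFrame,
    alpha: float = 0.05,
    adjust: str = "none",
    linkage_method: str = "complete",
) -> CorrelationMatrix:
    """Spearman correlation between group abundance profiles.

    rho uses midranks; two-sided p-values use the t approximation with
    n-2 degrees of freedom.  ``adjust="bh"`` applies Benjamini-Hochberg
    across the upper triangle.  The display order comes from
    agglomerative clustering on distance 1 - rho.  Zero-variance groups
    yield NaN rho/p for their pairs (undefined, not zero).
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 samples")
    if adjust not in ("none", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    m = groups.shape[1]
    with warnings.catch_warnings():
        # constant groups are a documented NaN outcome, not a user error
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, p = stats.spearmanr(groups.to_numpy(), axis=0)
    if m == 2:  # scipy collapses the 2-column case to scalars
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        pv = float(p)
        p = np.array([[0.0, pv], [pv, 0.0]])
    rho = np.asarray(rho, float)
    p = np.asarray(p, float)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    # constant columns: spearmanr propagates NaN, keep it that way
    if adjust == "bh":
        iu = np.triu_indices(m, k=1)
        flat = p[iu]
        ok = np.isfinite(flat)
        if ok.any():
            adj = np.full_like(flat, np.nan)
            adj[ok] = _bh_adjust(flat[ok])
            p = p.copy()
            p[iu] = adj
            p.T[iu] = adj
    order = _cluster_order(rho, linkage_method)
    return CorrelationMatrix(list(groups.columns), rho, p, order)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def _cluster_order(rho: np.ndarray, method: str) -> np.ndarray:
    m = rho.shape[0]
    if m <= 2:
        return np.arange(m)
    dist = 1.0 - rho
    dist = np.where(np.isfinite(dist), dist, 2.0)  # undefined pairs: max distance
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return leaves_list(linkage(squareform(dist, checks=False), method=method))
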