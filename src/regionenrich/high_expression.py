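"""Per-gene "highest expression" region sets.

For each gene the mean and standard deviation of its expression across all
regions are computed; a region belongs to the gene's highest-expression set
when its value strictly exceeds ``mean + z_high * sd`` (default
``z_high = 1.96``). Genes with constant expression (sd = 0) get an empty set
but remain part of the sampling universe.

With the sample (``ddof=1``) standard deviation, the largest attainable
standardised deviation on ``n`` values is ``(n - 1) / sqrt(n)``, so atlases
with five or fewer regions can never flag any region at the default
threshold; with ``ddof=0`` the bound is ``sqrt(n - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas_io import ExpressionAtlas

__all__ = [
    "GeneRegionStats",
    "HighExpressionIndex",
    "gene_region_stats",
    "high_expression_sets",
    "write_high_expression",
]


@dataclass(frozen=True)
class GeneRegionStats:
    """Per-gene mean and standard deviation of expression across regions."""

    genes: tuple[str, ...]
    mean: np.ndarray  # (n_genes,)
    sd: np.ndarray  # (n_genes,)
    ddof: int


@dataclass(frozen=True)
class HighExpressionIndex:
    """Boolean gene × region membership of the highest-expression sets.

    ``flags[i, j]`` is True when region ``j`` is in gene ``i``'s set. All atlas
    genes are retained, including those with an empty set: they stay in the
    sampling universe of the resampling null.
    """

    genes: tuple[str, ...]
    regions: tuple[str, ...]
    flags: np.ndarray  # bool, (n_genes, n_regions)
    z_high: float
    stats: GeneRegionStats

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def _gene_pos(self) -> dict[str, int]:
        cache = self.__dict__.get("__gene_pos")
        if cache is None:
            cache = {g: i for i, g in enumerate(self.genes)}
            object.__setattr__(self, "__gene_pos", cache)
        return cache

    def regions_for(self, gene: str) -> tuple[str, ...]:
        """Highest-expression set of one gene, in atlas region order."""
        row = self.flags[self._gene_pos[gene]]
        return tuple(r for r, f in zip(self.regions, row) if f)

    def n_flagged(self) -> np.ndarray:
        return self.flags.sum(axis=1)


def gene_region_stats(atlas: ExpressionAtlas, ddof: int = 1) -> GeneRegionStats:
    """Mean/SD of each gene's expression across all regions.

    Requires at least two regions (SD undefined otherwise).
    """
    if atlas.n_regions < 2:
        raise ValueError("at least two regions are required to compute a per-gene SD")
    mean = atlas.values.mean(axis=1)
    sd = atlas.values.std(axis=1, ddof=ddof)
    return GeneRegionStats(genes=atlas.genes, mean=mean, sd=sd, ddof=ddof)


def high_expression_sets(
    atlas: ExpressionAtlas, z_high: float = 1.96, ddof: int = 1
) -> HighExpressionIndex:
    """Compute all per-gene highest-expression region sets.

    A region is flagged iff its value strictly exceeds
    ``mean + z_high * sd`` for that gene; equality is not enough. Constant
    genes (sd = 0) therefore have empty sets.
    """
    if z_high <= 0:
        raise ValueError("z_high must be positive")
    stats = gene_region_stats(atlas, ddof=ddof)
    cutoff = stats.mean + z_high * stats.sd
    # sd = 0 means a constant row: the set is empty by definition, guarded
    # explicitly so float rounding of the mean cannot flag anything
    flags = (atlas.values > cutoff[:, None]) & (stats.sd > 0)[:, None]
    return HighExpressionIndex(
        genes=atlas.genes,
        regions=atlas.regions,
        flags=flags,
        z_high=float(z_high),
        stats=stats,
    )


def write_high_expression(index: HighExpressionIndex, path: str | Path) -> None:
    """Write one row per gene: mean, sd, set size, semicolon-joined regions."""
    rows = []
    for i, gene in enumerate(index.genes):
        flagged = [r for r, f in zip(index.regions, index.flags[i]) if f]
        rows.append(
            {
                "gene": gene,
                "mean": index.stats.mean[i],
                "sd": index.stats.sd[i],
                "n_flagged": len(flagged),
                "flagged_regions": ";".join(flagged),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
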