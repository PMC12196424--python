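"""Readers, writers and symbol resolution for expression atlases and gene lists.

Two tabular dialects are supported for the atlas:

* ``hpa_long`` — tab-separated long format with one row per (gene, region)
  observation and columns ``Gene``, ``Gene name``, ``Brain region``, ``nTPM``.
  Genes are keyed by the symbol column (``Gene name``), matched as-is after
  whitespace stripping; no alias or identifier mapping is attempted.
* ``wide`` — tab-separated matrix with genes as rows, regions as columns and a
  header row of region names.

Gene lists are plain text, one symbol per line; blank lines and ``#`` comments
are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AtlasFormatError",
    "AtlasValueError",
    "DuplicateEntryError",
    "GeneListError",
    "GeneResolutionError",
    "ExpressionAtlas",
    "GeneList",
    "read_atlas",
    "write_atlas",
    "read_gene_list",
    "write_gene_list",
    "resolve_genes",
]

#: Column names expected in the long dialect.
HPA_LONG_COLUMNS = ("Gene", "Gene name", "Brain region", "nTPM")


class AtlasFormatError(ValueError):
    """The file does not conform to the declared dialect (e.g. missing column)."""


class AtlasValueError(ValueError):
    """A cell value is invalid (non-numeric, negative, or non-finite)."""


class DuplicateEntryError(ValueError):
    """Duplicate (gene, region) observation in long format, or duplicate ids."""


class GeneListError(ValueError):
    """The gene-list file yields no usable symbols."""


class GeneResolutionError(ValueError):
    """No symbol of the user list matches the atlas."""


@dataclass(frozen=True)
class ExpressionAtlas:
    """A dense gene × region matrix of non-negative expression values (nTPM).

    Invariants enforced at construction: unique, non-empty gene and region
    identifiers; a finite, non-negative value for every (gene, region) cell.
    """

    genes: tuple[str, ...]
    regions: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_regions), float64

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(self.genes) == 0 or len(self.regions) == 0:
            raise AtlasFormatError("atlas must have at least one gene and one region")
        if any(not g for g in self.genes) or any(not r for r in self.regions):
            raise AtlasFormatError("empty gene or region identifier")
        if len(set(self.genes)) != len(self.genes):
            raise DuplicateEntryError("duplicate gene identifiers in atlas")
        if len(set(self.regions)) != len(self.regions):
            raise DuplicateEntryError("duplicate region identifiers in atlas")
        if values.shape != (len(self.genes), len(self.regions)):
            raise AtlasFormatError(
                f"value matrix shape {values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.regions)} regions"
            )
        if not np.all(np.isfinite(values)):
            raise AtlasValueError("atlas contains non-finite values")
        if np.any(values < 0):
            raise AtlasValueError("atlas contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def gene_index(self, gene: str) -> int:
        return self._gene_pos[gene]

    @property
    def _gene_pos(self) -> dict[str, int]:
        # cached lazily on the instance (frozen dataclass -> object.__setattr__)
        cache = self.__dict__.get("__gene_pos")
        if cache is None:
            cache = {g: i for i, g in enumerate(self.genes)}
            object.__setattr__(self, "__gene_pos", cache)
        return cache

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_pos

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.genes), columns=list(self.regions)
        )


@dataclass(frozen=True)
class GeneList:
    """An ordered, duplicate-free list of gene symbols with a provenance label."""

    symbols: tuple[str, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


def _pivot_long(df: pd.DataFrame, path: Path, on_incomplete: str) -> ExpressionAtlas:
    missing = [c for c in HPA_LONG_COLUMNS if c not in df.columns]
    if missing:
        raise AtlasFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    symbols = df["Gene name"].astype(str).str.strip()
    regions_col = df["Brain region"].astype(str).str.strip()

    raw = df["nTPM"]
    numeric = pd.to_numeric(raw, errors="coerce")
    bad = numeric.isna() & raw.notna()
    bad |= raw.isna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise AtlasValueError(f"{path}: non-numeric nTPM value at line {row}")
    neg = numeric < 0
    if neg.any():
        row = int(neg.idxmax()) + 2
        raise AtlasValueError(f"{path}: negative nTPM value at line {row}")

    pairs = pd.DataFrame({"gene": symbols, "region": regions_col, "value": numeric})
    dup = pairs.duplicated(subset=["gene", "region"])
    if dup.any():
        g = pairs.loc[dup.idxmax(), "gene"]
        r = pairs.loc[dup.idxmax(), "region"]
        raise DuplicateEntryError(f"{path}: duplicate (gene, region) entry ({g}, {r})")

    # first-appearance order for both axes
    gene_order = list(dict.fromkeys(pairs["gene"]))
    region_order = list(dict.fromkeys(pairs["region"]))
    wide = pairs.pivot(index="gene", columns="region", values="value")
    wide = wide.reindex(index=gene_order, columns=region_order)

    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        offenders = list(wide.index[incomplete])
        if on_incomplete == "error":
            raise AtlasFormatError(
                f"{path}: gene(s) without a value for every region: "
                f"{', '.join(offenders[:10])}"
                + (" ..." if len(offenders) > 10 else "")
            )
        logger.warning(
            "%s: dropping %d gene(s) with incomplete region coverage",
            path,
            len(offenders),
        )
        wide = wide.loc[~incomplete]
        if wide.empty:
            raise AtlasFormatError(f"{path}: no gene has complete region coverage")

    return ExpressionAtlas(
        genes=tuple(wide.index),
        regions=tuple(wide.columns),
        values=wide.to_numpy(dtype=float),
    )


def _read_wide(path: Path) -> ExpressionAtlas:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise AtlasFormatError(f"{path}: wide dialect needs at least one region column")
    genes = [str(g).strip() for g in df.index]
    regions = [str(r).strip() for r in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        bad_row = int(np.argmax(numeric.isna().any(axis=1).to_numpy())) + 2
        raise AtlasValueError(f"{path}: non-numeric value at line {bad_row}")
    return ExpressionAtlas(
        genes=tuple(genes), regions=tuple(regions), values=numeric.to_numpy(dtype=float)
    )


def read_atlas(
    path: str | Path,
    dialect: Literal["hpa_long", "wide"] = "hpa_long",
    on_incomplete: Literal["error", "drop"] = "error",
) -> ExpressionAtlas:
    """Read an expression atlas from a TSV file.

    Parameters
    ----------
    path:
        Input file; UTF-8, tab-separated, header row required.
    dialect:
        ``hpa_long`` (one row per gene/region observation) or ``wide``
        (genes × regions matrix).
    on_incomplete:
        In the long dialect, what to do with genes lacking a value for some
        observed region: ``error`` (strict, default) or ``drop`` (permissive,
        with a logged warning).
    """
    path = Path(path)
    if dialect == "hpa_long":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return _pivot_long(df, path, on_incomplete)
    if dialect == "wide":
        return _read_wide(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def write_atlas(atlas: ExpressionAtlas, path: str | Path) -> None:
    """Write the atlas in the wide dialect (round-trips bit-exactly)."""
    frame = atlas.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t")


def read_gene_list(path: str | Path, provenance: str | None = None) -> GeneList:
    """Read a plain-text gene list (one symbol per line).

    Blank lines and lines starting with ``#`` are ignored; surrounding
    whitespace is stripped; duplicates are collapsed with a logged warning;
    case is preserved as written.
    """
    path = Path(path)
    seen: dict[str, None] = {}
    n_dup = 0
    for line in path.read_text(encoding="utf-8").splitlines():
        symbol = line.strip()
        if not symbol or symbol.startswith("#"):
            continue
        if symbol in seen:
            n_dup += 1
            continue
        seen[symbol] = None
    if n_dup:
        logger.warning("%s: collapsed %d duplicate symbol(s)", path, n_dup)
    if not seen:
        raise GeneListError(f"{path}: no gene symbols found")
    return GeneList(
        symbols=tuple(seen), provenance=provenance if provenance is not None else str(path)
    )


def write_gene_list(symbols: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(symbols) + "\n", encoding="utf-8")


def resolve_genes(
    atlas: ExpressionAtlas, gene_list: GeneList
) -> tuple[GeneList, GeneList]:
    """Split a user list into symbols present in / absent from the atlas.

    Returns ``(resolved, missing)``; order follows the input list. The length
    of ``resolved`` is the list length ``X`` used by the resampling null.
    Raises :class:`GeneResolutionError` when nothing resolves.
    """
    resolved = tuple(s for s in gene_list.symbols if s in atlas)
    missing = tuple(s for s in gene_list.symbols if s not in atlas)
    logger.info(
        "resolved %d/%d symbols against the atlas (%d missing)",
        len(resolved),
        len(gene_list.symbols),
        len(missing),
    )
    if not resolved:
        raise GeneResolutionError("no gene symbol of the list matches the atlas")
    return (
        GeneList(symbols=resolved, provenance=gene_list.provenance),
        GeneList(symbols=missing, provenance=gene_list.provenance + " (unmatched)"),
    )
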