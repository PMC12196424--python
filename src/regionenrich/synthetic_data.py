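"""Synthetic expression atlases with planted region-specific programs.

Background expression is drawn per gene from a log-normal whose location and
scale are themselves sampled per gene, giving the heavy right skew typical of
nTPM data and gene-to-gene variation in level and dispersion. A program
multiplies the values of its member genes in its target regions by a constant
factor, so the flagging rule's scale invariance is exercised and planted
signal strength is controlled by a single knob.

The module doubles as the positive-control harness: feed a program's member
list through the pipeline and its target regions should come out significant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atlas_io import ExpressionAtlas, GeneList

__all__ = [
    "Program",
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_atlas",
    "generate_gene_list",
    "positive_control_spec",
    "write_truth",
]


@dataclass(frozen=True)
class Program:
    """A planted high-expression program: member genes × target regions."""

    region_ids: tuple[int, ...]
    n_genes: int
    effect_multiplier: float


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic atlas.

    ``mu_range``/``sigma_range`` bound the per-gene log-normal location and
    scale (sampled uniformly per gene). Program gene sets are disjoint and
    taken from the front of the gene roster.
    """

    n_genes: int
    n_regions: int
    programs: tuple[Program, ...] = ()
    mu_range: tuple[float, float] = (0.0, 2.0)
    sigma_range: tuple[float, float] = (0.3, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("invalid field n_genes: must be >= 1")
        if self.n_regions < 6:
            raise ValueError(
                "invalid field n_regions: must be >= 6 (the flagging rule "
                "cannot fire on five or fewer regions)"
            )
        if self.sigma_range[0] <= 0:
            raise ValueError("invalid field sigma_range: scale must be positive")
        total = 0
        for k, prog in enumerate(self.programs):
            if prog.effect_multiplier <= 1:
                raise ValueError(
                    f"invalid field programs[{k}].effect_multiplier: must be > 1"
                )
            if prog.n_genes < 1:
                raise ValueError(f"invalid field programs[{k}].n_genes: must be >= 1")
            if not prog.region_ids:
                raise ValueError(f"invalid field programs[{k}].region_ids: empty")
            if any(r < 0 or r >= self.n_regions for r in prog.region_ids):
                raise ValueError(
                    f"invalid field programs[{k}].region_ids: out of range"
                )
            total += prog.n_genes
        if total > self.n_genes:
            raise ValueError("invalid field programs: member counts exceed n_genes")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated atlas: program membership per gene."""

    programs: tuple[dict, ...]  # {"genes": [...], "regions": [...]}
    gene_label: dict[str, int]  # gene -> program idx, -1 for background

    @property
    def background_genes(self) -> tuple[str, ...]:
        return tuple(g for g, l in self.gene_label.items() if l == -1)

    def program_genes(self, k: int | None = None) -> tuple[str, ...]:
        if k is None:
            return tuple(g for g, l in self.gene_label.items() if l >= 0)
        return tuple(self.programs[k]["genes"])


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _region_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"R{i:0{width}d}" for i in range(1, n + 1)]


def generate_atlas(spec: SyntheticSpec) -> tuple[ExpressionAtlas, SyntheticTruth]:
    """Draw an atlas from the spec; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    regions = _region_names(spec.n_regions)

    mu = rng.uniform(*spec.mu_range, size=spec.n_genes)
    sigma = rng.uniform(*spec.sigma_range, size=spec.n_genes)
    values = rng.lognormal(
        mean=mu[:, None], sigma=sigma[:, None], size=(spec.n_genes, spec.n_regions)
    )

    gene_label = {g: -1 for g in genes}
    programs = []
    cursor = 0
    for k, prog in enumerate(spec.programs):
        members = genes[cursor : cursor + prog.n_genes]
        cursor += prog.n_genes
        cols = list(prog.region_ids)
        idx = [genes.index(m) for m in members]
        values[np.ix_(idx, cols)] *= prog.effect_multiplier
        for m in members:
            gene_label[m] = k
        programs.append(
            {"genes": list(members), "regions": [regions[c] for c in cols]}
        )

    atlas = ExpressionAtlas(genes=tuple(genes), regions=tuple(regions), values=values)
    truth = SyntheticTruth(programs=tuple(programs), gene_label=gene_label)
    return atlas, truth


def generate_gene_list(
    truth: SyntheticTruth,
    n_signal: int,
    n_background: int,
    seed: int = 0,
    program: int | None = None,
    provenance: str = "synthetic",
) -> GeneList:
    """A shuffled list of ``n_signal`` program genes + ``n_background`` others.

    ``program`` restricts the signal draw to one planted program; by default
    all program genes are eligible.
    """
    rng = np.random.default_rng(seed)
    signal_pool = list(truth.program_genes(program))
    background_pool = list(truth.background_genes)
    if n_signal > len(signal_pool):
        raise ValueError(
            f"requested {n_signal} signal genes but only {len(signal_pool)} available"
        )
    if n_background > len(background_pool):
        raise ValueError(
            f"requested {n_background} background genes but only "
            f"{len(background_pool)} available"
        )
    chosen = list(rng.choice(signal_pool, size=n_signal, replace=False)) + list(
        rng.choice(background_pool, size=n_background, replace=False)
    )
    rng.shuffle(chosen)
    return GeneList(symbols=tuple(str(s) for s in chosen), provenance=provenance)


def positive_control_spec(
    n_genes: int = 2000,
    n_regions: int = 50,
    n_program_genes: int = 40,
    effect_multiplier: float = 50.0,
    seed: int = 0,
) -> SyntheticSpec:
    """Three disjoint planted programs, each targeting its own region triple.

    Feeding each program's member list through the pipeline should flag only
    that program's regions — the positive-control validation experiment.
    """
    thirds = [
        (0, 1, 2),
        (n_regions // 3, n_regions // 3 + 1, n_regions // 3 + 2),
        (2 * n_regions // 3, 2 * n_regions // 3 + 1, 2 * n_regions // 3 + 2),
    ]
    return SyntheticSpec(
        n_genes=n_genes,
        n_regions=n_regions,
        programs=tuple(
            Program(region_ids=t, n_genes=n_program_genes, effect_multiplier=effect_multiplier)
            for t in thirds
        ),
        seed=seed,
    )


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "programs": list(truth.programs),
        "gene_label": truth.gene_label,
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
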