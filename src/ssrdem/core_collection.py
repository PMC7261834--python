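"""Core-collection selection by allele-coverage maximization.

The advanced maximization (M) strategy is a greedy set-cover heuristic over
locus-allele classes: at each step the accession covering the most
not-yet-covered alleles joins the core; ties go to the accession with higher
within-individual heterozygosity, then to the lower input index.  Selection
stops when every allele observed in the panel is covered, and a redundancy
pruning pass removes accessions whose alleles are fully covered by the rest.
Missing calls contribute no classes, so coverage is of observed alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, Partition

__all__ = ["CoreCollection", "build_core", "coverage_report"]


@dataclass
class CoreCollection:
    selected: tuple[str, ...]
    allele_coverage: float
    strategy: str = "advanced_m"


def _allele_sets(g: GenotypeMatrix) -> list[set]:
    """Locus-allele classes carried by each individual."""
    out = []
    for i in range(g.n_individuals):
        s = set()
        for l in range(g.n_loci):
            a, b = g.calls[i, l]
            if a != MISSING:
                s.add((l, int(a)))
                s.add((l, int(b)))
        out.append(s)
    return out


def build_core(
    g: GenotypeMatrix,
    strategy: str = "advanced_m",
    seed: int | None = None,
) -> CoreCollection:
    """Select a minimal-redundancy subset capturing all observed alleles.

    Deterministic under the default tie rule; ``seed`` is accepted for
    interface symmetry but unused by the default rule.
    """
    if strategy != "advanced_m":
        raise ValueError(f"unknown strategy {strategy!r}")
    sets = _allele_sets(g)
    universe = set().union(*sets) if sets else set()
    het = [
        float(np.mean((g.calls[i, :, 0] != g.calls[i, :, 1])
                      & (g.calls[i, :, 0] != MISSING)))
        for i in range(g.n_individuals)
    ]
    covered: set = set()
    chosen: list[int] = []
    remaining = list(range(g.n_individuals))
    while covered != universe:
        best = None
        for i in remaining:
            gain = len(sets[i] - covered)
            key = (gain, het[i], -i)
            if best is None or key > best[0]:
                best = (key, i)
        (gain, _, _), pick = best
        if gain == 0:  # cannot happen while universe uncovered, defensive
            break
        chosen.append(pick)
        covered |= sets[pick]
        remaining.remove(pick)
    # redundancy pruning: drop anyone whose alleles are covered by the rest
    pruned = list(chosen)
    for i in list(pruned):
        others = set().union(*(sets[j] for j in pruned if j != i)) if len(pruned) > 1 else set()
        if sets[i] <= others:
            pruned.remove(i)
    pruned.sort()
    selected = tuple(g.individuals[i] for i in pruned)
    cov_alleles = set().union(*(sets[i] for i in pruned)) if pruned else set()
    coverage = len(cov_alleles) / len(universe) if universe else 1.0
    return CoreCollection(selected=selected, allele_coverage=coverage)


def coverage_report(
    g: GenotypeMatrix,
    core: CoreCollection | tuple[str, ...],
    partitions: dict[str, Partition] | None = None,
) -> dict:
    """Coverage fraction, size fraction, and composition of a core subset.

    Returns a dict with ``coverage`` (fraction of the panel's distinct
    locus-allele classes present in the core), ``size_fraction_pct``
    (core size as a percentage of the panel), and a ``composition``
    DataFrame of counts per group for each supplied partition.
    """
    ids = core.selected if isinstance(core, CoreCollection) else tuple(core)
    pos = {ind: i for i, ind in enumerate(g.individuals)}
    unknown = [i for i in ids if i not in pos]
    if unknown:
        raise ValueError(f"core contains unknown identifiers: {unknown[:5]}")
    sets = _allele_sets(g)
    universe = set().union(*sets)
    core_alleles = set().union(*(sets[pos[i]] for i in ids)) if ids else set()
    comp = {}
    for name, part in (partitions or {}).items():
        counts = {grp: 0 for grp in part.groups}
        for i in ids:
            lab = part.labels.get(i)
            if lab is not None:
                counts[lab] = counts.get(lab, 0) + 1
        comp[name] = counts
    return dict(
        coverage=len(core_alleles) / len(universe) if universe else 1.0,
        size_fraction_pct=100.0 * len(ids) / g.n_individuals,
        n_core=len(ids),
        n_panel=g.n_individuals,
        composition={k: pd.Series(v) for k, v in comp.items()},
    )
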