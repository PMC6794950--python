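"""Barcoding-gap diagnostics and the local-gap (PWG) discrimination rate.

A *global* barcoding gap exists when the largest intraspecific distance falls
below the smallest interspecific one. The *local* criterion is per species:
discrimination succeeds when the species' smallest distance to any other
sample strictly exceeds its largest within-species distance (ties fail).
Species sampled once (singletons) are never counted, in numerator or
denominator, but stay in the matrix as potential nearest neighbours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .datamodel import InputError, SpeciesMap
from .distances import DistanceMatrix, PairPartition


@dataclass(frozen=True)
class GapHistogram:
    bin_width: float
    edges: np.ndarray  # len = n_bins + 1, half-open bins [e_i, e_{i+1})
    intra_counts: np.ndarray
    inter_counts: np.ndarray


def gap_histogram(partition: PairPartition, bin_width: float = 0.005) -> GapHistogram:
    """Bin both distance classes on one shared grid from 0 to the maximum."""
    if bin_width <= 0:
        raise InputError("bin_width must be positive")
    if not partition.intra and not partition.inter:
        raise InputError("empty partition")
    values = np.concatenate([partition.intra_values, partition.inter_values])
    top = float(values.max())
    n_bins = max(1, int(math.floor(top / bin_width)) + 1)
    edges = np.arange(n_bins + 1) * bin_width
    intra, _ = np.histogram(partition.intra_values, bins=edges)
    inter, _ = np.histogram(partition.inter_values, bins=edges)
    return GapHistogram(bin_width=bin_width, edges=edges,
                        intra_counts=intra, inter_counts=inter)


def write_histogram(hist: GapHistogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_start\tbin_end\tintra_n\tinter_n\n")
        for i in range(len(hist.intra_counts)):
            fh.write(
                f"{hist.edges[i]:.4f}\t{hist.edges[i + 1]:.4f}\t"
                f"{hist.intra_counts[i]}\t{hist.inter_counts[i]}\n"
            )


def global_gap_exists(partition: PairPartition) -> tuple[bool | None, float | None]:
    """(gap?, margin): margin = min(inter) - max(intra).

    Returns (None, None) when the intraspecific class is empty.
    """
    if not partition.inter:
        raise InputError("interspecific class is empty")
    if not partition.intra:
        return None, None
    margin = float(partition.inter_values.min() - partition.intra_values.max())
    return margin > 0, margin


@dataclass
class DiscriminationReport:
    """Per-individual discrimination accounting for one method and matrix."""

    method: str
    per_species: dict[str, bool]  # non-singleton species only
    per_individual: dict[str, bool] = field(default_factory=dict)
    n_success_individuals: int = 0
    n_eligible_individuals: int = 0

    @property
    def rate(self) -> float:
        if self.n_eligible_individuals == 0:
            raise InputError("no eligible individuals")
        return 100.0 * self.n_success_individuals / self.n_eligible_individuals


def _species_distance_classes(
    species: str, matrix: DistanceMatrix, species_map: SpeciesMap
) -> tuple[np.ndarray, np.ndarray]:
    members = sorted(species_map.mapping[species] & set(matrix.ids))
    others = [s for s in matrix.ids if s not in set(members)]
    idx = {s: i for i, s in enumerate(matrix.ids)}
    intra = [
        matrix.values[idx[a], idx[b]]
        for i, a in enumerate(members)
        for b in members[i + 1:]
    ]
    inter = [matrix.values[idx[a], idx[o]] for a in members for o in others]
    intra = np.array([d for d in intra if not math.isnan(d)])
    inter = np.array([d for d in inter if not math.isnan(d)])
    return intra, inter


def local_gap_success(
    species: str, matrix: DistanceMatrix, species_map: SpeciesMap
) -> bool:
    """Strict local barcoding gap for one multi-individual species."""
    present = species_map.mapping[species] & set(matrix.ids)
    if len(present) < 2:
        raise InputError(f"species {species!r} has < 2 individuals in matrix")
    intra, inter = _species_distance_classes(species, matrix, species_map)
    if intra.size == 0 or inter.size == 0:
        raise InputError(f"species {species!r}: no defined distances")
    return float(inter.min()) > float(intra.max())


def effective_species_map(matrix: DistanceMatrix, species_map: SpeciesMap) -> SpeciesMap:
    """Restrict the species map to samples present in the matrix.

    Species whose sampled individuals drop to one become singletons for this
    matrix (e.g. samples lacking a locus in a concatenation).
    """
    present = set(matrix.ids)
    mapping = {
        sp: frozenset(s & present)
        for sp, s in species_map.mapping.items()
        if s & present
    }
    return SpeciesMap(mapping)


def pwg_discrimination(
    matrix: DistanceMatrix, species_map: SpeciesMap
) -> DiscriminationReport:
    """Local-gap success aggregated to a per-individual rate.

    Every individual of a successful species counts as one success; eligible
    individuals are all individuals of species with >= 2 samples in the
    matrix.
    """
    smap = effective_species_map(matrix, species_map)
    per_species: dict[str, bool] = {}
    per_individual: dict[str, bool] = {}
    for sp in smap.species:
        if smap.is_singleton(sp):
            continue
        ok = local_gap_success(sp, matrix, smap)
        per_species[sp] = ok
        for sample in smap.mapping[sp]:
            per_individual[sample] = ok
    if not per_individual:
        raise InputError("no eligible individuals (all species singletons)")
    return DiscriminationReport(
        method="PWG",
        per_species=per_species,
        per_individual=per_individual,
        n_success_individuals=sum(per_individual.values()),
        n_eligible_individuals=len(per_individual),
    )


def write_species_report(
    report: DiscriminationReport, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("species\tsuccess\n")
        for sp in sorted(report.per_species):
            fh.write(f"{sp}\t{int(report.per_species[sp])}\n")
        fh.write(
            f"# {report.method}: {report.n_success_individuals}/"
            f"{report.n_eligible_individuals} = {report.rate:.2f}%\n"
        )
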