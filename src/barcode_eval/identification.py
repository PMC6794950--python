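"""Nearest-neighbour species identification: Best Match and Best Close Match.

Best Match assigns each query to the species of its closest non-self
sequence, regardless of how distant that is; ties (within a relative
tolerance) keep the whole tied species set. Best Close Match additionally
requires the best distance to fall within a threshold derived from the
intraspecific distance distribution (by default its 95th percentile), else
the query is "no match". Queries are the individuals of multi-individual
species; singletons remain in the reference set only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .datamodel import InputError, SpeciesMap
from .distances import DistanceMatrix, PairPartition
from .gap_analysis import effective_species_map

TIE_REL_TOL = 1e-9

CATEGORIES = ("correct", "ambiguous", "incorrect", "no_match")


@dataclass(frozen=True)
class QueryVerdict:
    query: str
    best_distance: float | None
    matched_species: frozenset[str]
    category: str

    def __post_init__(self) -> None:
        assert self.category in CATEGORIES
        assert self.matched_species or self.category == "no_match"


def _nearest(query: str, matrix: DistanceMatrix, species_map: SpeciesMap):
    idx = {s: i for i, s in enumerate(matrix.ids)}
    if query not in idx:
        raise InputError(f"query {query!r} not in matrix")
    qi = idx[query]
    dists = [
        (matrix.values[qi, idx[s]], s)
        for s in matrix.ids
        if s != query and not math.isnan(matrix.values[qi, idx[s]])
    ]
    if not dists:
        raise InputError(f"query {query!r}: all distances undefined")
    best = min(d for d, _ in dists)
    tol = TIE_REL_TOL * max(1.0, abs(best))
    tied = [s for d, s in dists if d <= best + tol]
    return best, tied


def best_match(
    query: str, matrix: DistanceMatrix, species_map: SpeciesMap
) -> QueryVerdict:
    """Classify one query by its closest non-self sequence(s)."""
    smap = effective_species_map(matrix, species_map)
    best, tied = _nearest(query, matrix, smap)
    q_species = smap.species_for(query)
    tied_species = frozenset(smap.species_for(s) for s in tied)
    if tied_species == {q_species}:
        category = "correct"
    elif q_species in tied_species:
        category = "ambiguous"
    else:
        category = "incorrect"
    return QueryVerdict(query, float(best), tied_species, category)


def intraspecific_threshold(
    partition: PairPartition, percentile: float = 95.0
) -> float:
    """Percentile (linear interpolation) of all intraspecific distances."""
    if not partition.intra:
        raise InputError("intraspecific class is empty")
    return float(np.percentile(partition.intra_values, percentile))


def best_close_match(
    query: str,
    matrix: DistanceMatrix,
    species_map: SpeciesMap,
    threshold: float,
) -> QueryVerdict:
    """Best Match, demoted to 'no_match' when the best distance exceeds the
    threshold."""
    if threshold < 0:
        raise InputError("threshold must be >= 0")
    verdict = best_match(query, matrix, species_map)
    if verdict.best_distance is not None and verdict.best_distance > threshold:
        return QueryVerdict(query, verdict.best_distance, frozenset(), "no_match")
    return verdict


def identify_all(
    matrix: DistanceMatrix,
    species_map: SpeciesMap,
    method: str = "bm",
    threshold: float | None = None,
) -> list[QueryVerdict]:
    """Run BM or BCM over every eligible query (non-singleton individuals)."""
    smap = effective_species_map(matrix, species_map)
    queries = sorted(smap.eligible_samples() & set(matrix.ids))
    if not queries:
        raise InputError("no eligible queries")
    if method == "bm":
        return [best_match(q, matrix, smap) for q in queries]
    if method == "bcm":
        if threshold is None:
            raise InputError("best close match needs a threshold")
        return [best_close_match(q, matrix, smap, threshold) for q in queries]
    raise InputError(f"unknown method {method!r}")


@dataclass(frozen=True)
class IdentificationSummary:
    n_queries: int
    counts: dict[str, int]
    percentages: dict[str, float]


def summarize_identification(
    verdicts: Sequence[QueryVerdict], species_map: SpeciesMap | None = None
) -> IdentificationSummary:
    """Category counts and percentages over the eligible queries."""
    if not verdicts:
        raise InputError("no verdicts to summarise")
    counts = {c: 0 for c in CATEGORIES}
    for v in verdicts:
        counts[v.category] += 1
    n = len(verdicts)
    percentages = {c: round(100.0 * k / n, 2) for c, k in counts.items()}
    return IdentificationSummary(n_queries=n, counts=counts, percentages=percentages)


def write_verdicts(verdicts: Iterable[QueryVerdict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tbest_distance\tmatched_species\tcategory\n")
        for v in verdicts:
            d = "NA" if v.best_distance is None else f"{v.best_distance:.4f}"
            sp = ",".join(sorted(v.matched_species)) or "-"
            fh.write(f"{v.query}\t{d}\t{sp}\t{v.category}\n")
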