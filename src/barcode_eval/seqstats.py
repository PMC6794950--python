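"""Alignment characteristics: variable sites, parsimony-informative sites,
indel (DIP-style) events, and length summaries.

Site classification follows the common MEGA/DnaSP convention: only the four
unambiguous bases A/C/G/T can establish variability; gaps, '?' and IUPAC
ambiguity codes are treated as missing at a site. An indel event is a maximal
run of columns over which exactly the same non-empty set of sequences is
gapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import InputError, LocusAlignment

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class AlignmentStats:
    locus: str
    n_species: int | None
    n_samples: int
    aligned_length: int
    ungapped_length_range: tuple[int, int]
    n_variable_sites: int
    pct_variable: float
    n_parsimony_informative: int
    pct_pi: float
    n_indel_events: int
    indel_length_range: tuple[int, int] | None

    def __post_init__(self) -> None:
        assert self.n_parsimony_informative <= self.n_variable_sites <= self.aligned_length
        assert (self.indel_length_range is not None) == (self.n_indel_events > 0)


def _scoped(alignment: LocusAlignment, scope: Iterable[str] | None) -> list[str]:
    """Sequences of the scoped samples (default: all)."""
    if scope is None:
        seqs = [r.sequence for r in alignment.records]
    else:
        keep = set(scope)
        seqs = [r.sequence for r in alignment.records if r.sample_id in keep]
    if not seqs:
        raise InputError("empty sample scope")
    return seqs


def _columns(seqs: list[str]):
    return zip(*seqs)


def count_variable_sites(
    alignment: LocusAlignment, scope: Iterable[str] | None = None
) -> int:
    """Columns where >= 2 distinct unambiguous bases occur."""
    seqs = _scoped(alignment, scope)
    n = 0
    for col in _columns(seqs):
        bases = {c for c in col if c in _BASES}
        if len(bases) >= 2:
            n += 1
    return n


def count_parsimony_informative(
    alignment: LocusAlignment, scope: Iterable[str] | None = None
) -> int:
    """Columns where >= 2 distinct unambiguous bases each occur >= 2 times."""
    seqs = _scoped(alignment, scope)
    n = 0
    for col in _columns(seqs):
        counts: dict[str, int] = {}
        for c in col:
            if c in _BASES:
                counts[c] = counts.get(c, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            n += 1
    return n


def count_indel_events(
    alignment: LocusAlignment, scope: Iterable[str] | None = None
) -> tuple[int, int | None, int | None]:
    """(n_events, min_len, max_len) of maximal same-gap-set column runs.

    Two adjacent gapped columns belong to one event iff the identical set of
    sequences is gapped in both; runs with different gapped-sequence sets or
    separated by a gap-free column are distinct events. Lengths in columns.
    """
    seqs = _scoped(alignment, scope)
    gap = np.array([[c == "-" for c in s] for s in seqs], dtype=bool)
    n_rows, n_cols = gap.shape
    events: list[int] = []
    prev_set: frozenset[int] | None = None
    run_len = 0
    for j in range(n_cols):
        cur = frozenset(np.flatnonzero(gap[:, j]).tolist())
        if not cur:
            cur = None  # type: ignore[assignment]
        if cur == prev_set and cur is not None:
            run_len += 1
        else:
            if prev_set is not None:
                events.append(run_len)
            run_len = 1 if cur is not None else 0
        prev_set = cur
    if prev_set is not None:
        events.append(run_len)
    if not events:
        return 0, None, None
    return len(events), min(events), max(events)


def alignment_stats(
    alignment: LocusAlignment,
    scope: Iterable[str] | None = None,
    n_species: int | None = None,
) -> AlignmentStats:
    """Aggregate the per-locus Table-style descriptors.

    Percentages are relative to aligned length, rounded to 2 decimals.
    """
    seqs = _scoped(alignment, scope)
    length = alignment.aligned_length
    ungapped = [sum(1 for c in s if c not in "-?") for s in seqs]
    n_var = count_variable_sites(alignment, scope)
    n_pi = count_parsimony_informative(alignment, scope)
    n_ind, lo, hi = count_indel_events(alignment, scope)
    return AlignmentStats(
        locus=alignment.locus,
        n_species=n_species,
        n_samples=len(seqs),
        aligned_length=length,
        ungapped_length_range=(min(ungapped), max(ungapped)),
        n_variable_sites=n_var,
        pct_variable=round(100.0 * n_var / length, 2),
        n_parsimony_informative=n_pi,
        pct_pi=round(100.0 * n_pi / length, 2),
        n_indel_events=n_ind,
        indel_length_range=None if n_ind == 0 else (lo, hi),
    )


def stats_table(
    stats: Mapping[str, AlignmentStats] | Iterable[AlignmentStats],
) -> pd.DataFrame:
    """One row per locus/combination, mirroring the familiar report layout."""
    if isinstance(stats, Mapping):
        stats = stats.values()
    rows = []
    for s in stats:
        rng = s.indel_length_range
        rows.append(
            {
                "locus": s.locus,
                "n_samples": s.n_samples,
                "aligned_length_bp": s.aligned_length,
                "sequence_length_bp": f"{s.ungapped_length_range[0]}-{s.ungapped_length_range[1]}",
                "n_parsimony_informative_sites": s.n_parsimony_informative,
                "pct_parsimony_informative": s.pct_pi,
                "n_variable_sites": s.n_variable_sites,
                "pct_variable": s.pct_variable,
                "n_indels": s.n_indel_events,
                "indel_length_range": "-" if rng is None else f"{rng[0]}-{rng[1]}",
            }
        )
    return pd.DataFrame(rows)
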