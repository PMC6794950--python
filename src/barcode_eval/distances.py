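"""Kimura 2-parameter distances with pairwise deletion.

For each sequence pair, columns in which either sequence carries a gap, '?'
or an IUPAC ambiguity code are deleted before counting. With transition
proportion P and transversion proportion Q over the remaining n sites,

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

The distance is undefined (flagged, not raised) when no sites remain or the
logarithm's argument leaves its domain (saturation). Undefined entries are
stored as NaN in the matrix and excluded from all downstream summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import InputError, LocusAlignment, SpeciesMap

# Base encoding: A=0, C=1, G=2, T=3; anything else (gap, ?, ambiguity) = 255.
_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i

_PURINES = (0, 2)  # A, G


def encode_sequence(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_alignment(alignment: LocusAlignment) -> np.ndarray:
    """(n_samples, n_columns) uint8 code matrix in record order."""
    return np.vstack([encode_sequence(r.sequence) for r in alignment.records])


@dataclass(frozen=True)
class PairComparison:
    n_sites: int
    n_transitions: int
    n_transversions: int
    P: float
    Q: float
    distance: float | None
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.distance is not None


def _k2p_from_counts(n: int, ts: int, tv: int) -> PairComparison:
    if n == 0:
        return PairComparison(0, 0, 0, float("nan"), float("nan"), None,
                              "no comparable sites")
    p, q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return PairComparison(n, ts, tv, p, q, None, "saturated (log domain)")
    # + 0.0 normalises IEEE negative zero for identical sequences
    return PairComparison(n, ts, tv, p, q, -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0)


def k2p_pair(seq_a: str, seq_b: str) -> PairComparison:
    """K2P comparison of two equal-length aligned sequences."""
    if len(seq_a) != len(seq_b):
        raise InputError("sequences differ in aligned length")
    a, b = encode_sequence(seq_a), encode_sequence(seq_b)
    valid = (a != 255) & (b != 255)
    a, b = a[valid], b[valid]
    diff = a != b
    same_class = (np.isin(a, _PURINES)) == (np.isin(b, _PURINES))
    ts = int(np.count_nonzero(diff & same_class))
    tv = int(np.count_nonzero(diff & ~same_class))
    return _k2p_from_counts(int(valid.sum()), ts, tv)


class DistanceMatrix:
    """Symmetric matrix of K2P distances; NaN marks undefined entries."""

    def __init__(self, ids: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(ids), len(ids)):
            raise InputError("matrix shape does not match id count")
        self.ids = list(ids)
        self.values = values
        self._index = {s: i for i, s in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{name}  {row}\n")


def k2p_counts_matrix(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_sites, transitions, transversions) matrices for all sample pairs.

    Uses one-hot matrix products so bootstrap replicates stay cheap.
    """
    onehot = np.stack([(codes == k) for k in range(4)]).astype(np.float32)
    valid = onehot.sum(axis=0)
    n = valid @ valid.T
    match = sum(x @ x.T for x in onehot)
    pur = onehot[0] + onehot[2]
    pyr = onehot[1] + onehot[3]
    same_class = pur @ pur.T + pyr @ pyr.T
    ts = same_class - match
    tv = n - same_class
    return (np.rint(n).astype(np.int64),
            np.rint(ts).astype(np.int64),
            np.rint(tv).astype(np.int64))


def k2p_matrix_from_codes(codes: np.ndarray) -> np.ndarray:
    """K2P distance values (NaN where undefined) from a code matrix."""
    n, ts, tv = k2p_counts_matrix(codes)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, ts / np.maximum(n, 1), np.nan)
        q = np.where(n > 0, tv / np.maximum(n, 1), np.nan)
        w1 = 1.0 - 2.0 * p - q
        w2 = 1.0 - 2.0 * q
        d = np.where((w1 > 0) & (w2 > 0), -0.5 * np.log(w1 * np.sqrt(np.abs(w2))), np.nan)
    d = d + 0.0  # drop IEEE negative zeros
    np.fill_diagonal(d, 0.0)
    return d


def distance_matrix(alignment: LocusAlignment) -> DistanceMatrix:
    """All pairwise K2P distances of an alignment."""
    if len(alignment) < 2:
        raise InputError("distance analysis needs >= 2 records")
    return DistanceMatrix(alignment.sample_ids, k2p_matrix_from_codes(encode_alignment(alignment)))


@dataclass
class PairPartition:
    """Defined pairwise distances split into intra- and inter-specific."""

    intra: list[tuple[str, str, float]]
    inter: list[tuple[str, str, float]]

    @property
    def intra_values(self) -> np.ndarray:
        return np.array([d for _, _, d in self.intra], dtype=float)

    @property
    def inter_values(self) -> np.ndarray:
        return np.array([d for _, _, d in self.inter], dtype=float)


def partition_distances(
    matrix: DistanceMatrix,
    species_map: SpeciesMap,
    outgroups: Iterable[str] = (),
) -> PairPartition:
    """Assign each defined pair to the intra- or inter-specific class.

    Samples not covered by the species map (e.g. outgroups) are skipped.
    """
    out = set(outgroups)
    sp_of: dict[str, str] = {}
    for sp, samples in species_map.mapping.items():
        for s in samples:
            sp_of[s] = sp
    intra, inter = [], []
    ids = matrix.ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            if a in out or b in out or a not in sp_of or b not in sp_of:
                continue
            d = matrix.values[i, j]
            if math.isnan(d):
                continue
            (intra if sp_of[a] == sp_of[b] else inter).append((a, b, float(d)))
    return PairPartition(intra=intra, inter=inter)


@dataclass(frozen=True)
class DistanceSummary:
    """The five headline distance parameters plus both class ranges."""

    mean_all: float
    mean_intra: float
    mean_inter: float
    max_intra: float
    min_inter: float
    range_intra: tuple[float, float]
    range_inter: tuple[float, float]
    intra_empty: bool = False


def summarize_distances(partition: PairPartition) -> DistanceSummary:
    if not partition.inter:
        raise InputError("interspecific class is empty")
    inter = partition.inter_values
    if partition.intra:
        intra = partition.intra_values
        intra_empty = False
    else:
        intra = np.array([0.0])
        intra_empty = True
    allv = (
        np.concatenate([partition.intra_values, inter])
        if partition.intra
        else inter
    )
    return DistanceSummary(
        mean_all=float(allv.mean()),
        mean_intra=0.0 if intra_empty else float(intra.mean()),
        mean_inter=float(inter.mean()),
        max_intra=0.0 if intra_empty else float(intra.max()),
        min_inter=float(inter.min()),
        range_intra=(float(intra.min()), float(intra.max())) if not intra_empty else (0.0, 0.0),
        range_inter=(float(inter.min()), float(inter.max())),
        intra_empty=intra_empty,
    )


def write_long_format(
    matrix: DistanceMatrix,
    species_map: SpeciesMap,
    path: str | Path,
) -> None:
    """Tab-separated pair list: sample_a, sample_b, class, distance."""
    part = partition_distances(matrix, species_map)
    with open(path, "w") as fh:
        fh.write("sample_a\tsample_b\tclass\td\n")
        for cls, pairs in (("intraspecific", part.intra), ("interspecific", part.inter)):
            for a, b, d in pairs:
                fh.write(f"{a}\t{b}\t{cls}\t{d:.4f}\n")
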