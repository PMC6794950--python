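import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from barcode_eval import (
    BarcodeRecord,
    LocusAlignment,
    build_species_map,
    generate_dataset,
    known_truth_config,
)


def make_alignment(seqs: dict[str, str], locus: str = "toy") -> LocusAlignment:
    """Alignment from {'Species|sample': sequence} labels."""
    records = []
    for label, seq in seqs.items():
        species, sample = label.rsplit("|", 1)
        records.append(
            BarcodeRecord(sample_id=sample, species=species, locus=locus,
                          sequence=seq)
        )
    return LocusAlignment(locus, records)


def random_alignment(rng: np.random.Generator, n: int, length: int,
                     n_species: int | None = None) -> LocusAlignment:
    """Random (unrelated-sequence) alignment with species labels."""
    if n_species is None:
        n_species = max(2, n // 2)
    seqs = {}
    for i in range(n):
        sp = f"sp{i % n_species:02d}"
        seq = "".join("ACGT"[k] for k in rng.integers(0, 4, size=length))
        seqs[f"{sp}|s{i:03d}"] = seq
    return make_alignment(seqs)


def related_alignment(rng: np.random.Generator, n: int, length: int,
                      n_species: int | None = None, sp_subs: int = 6,
                      ind_subs: int = 2) -> LocusAlignment:
    """Alignment of sequences mutated from one base sequence: species share
    sp_subs private substitutions, individuals add ind_subs more. Distances
    stay far from K2P saturation, unlike independent random sequences."""
    if n_species is None:
        n_species = max(2, n // 2)
    base = rng.integers(0, 4, size=length)
    sp_seqs: dict[str, np.ndarray] = {}
    seqs = {}
    for i in range(n):
        sp = f"sp{i % n_species:02d}"
        if sp not in sp_seqs:
            s = base.copy()
            pos = rng.choice(length, size=sp_subs, replace=False)
            s[pos] = (s[pos] + rng.integers(1, 4, size=sp_subs)) % 4
            sp_seqs[sp] = s
        seq = sp_seqs[sp].copy()
        pos = rng.choice(length, size=ind_subs, replace=False)
        seq[pos] = (seq[pos] + rng.integers(1, 4, size=ind_subs)) % 4
        seqs[f"{sp}|s{i:03d}"] = "".join("ACGT"[c] for c in seq)
    return make_alignment(seqs)


@pytest.fixture
def toy_two_species():
    """Two 2-sample species with a clean gap between them."""
    aln = make_alignment(
        {
            "A_a|1": "AAAAAAAAAACCCCCCCCCC",
            "A_a|2": "AAAAAAAAAACCCCCCCCCC",
            "B_b|3": "GGGGGAAAAACCCCCCCCCC",
            "B_b|4": "GGGGGAAAAACCCCCCCCCC",
        }
    )
    return aln, build_species_map(aln)


@pytest.fixture(scope="session")
def known_truth_dataset():
    """Zero-intraspecific-depth preset dataset: every method should be perfect."""
    return generate_dataset(known_truth_config(seed=20260924 % 2**31))


@pytest.fixture(scope="session")
def introgressed_dataset():
    """Same preset with one forced plastid capture on a sister pair."""
    return generate_dataset(known_truth_config(seed=20260924 % 2**31, introgression=True))
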