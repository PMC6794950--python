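"""Seeded simulator of multi-species, multi-locus aligned barcode datasets.

The generator emulates the structure of a genus-level barcoding study: a
pure-birth (Yule) species tree carrying 2-3 subgeneric clades; one to a few
individuals per species, singletons included; one haplotype genealogy shared
by all plastid loci and an independent one for the nuclear locus; sequences
evolved under the Kimura 2-parameter substitution process with per-locus
rate multipliers (the nuclear locus fastest); rectangular gap-coded indel
events on the fast loci; and optional chloroplast capture, in which the
samples of one species of a sister pair carry exact copies of the other
species' plastid haplotypes, producing cyto-nuclear discordance.

All randomness flows from one ``numpy`` generator seeded by the config, so
a fixed seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from .datamodel import BarcodeRecord, InputError, LocusAlignment

_GAP = np.uint8(4)
_ALPHA = np.array(list("ACGT-"), dtype="U1")

NUCLEAR, PLASTID = "nuclear", "plastid"


@dataclass(frozen=True)
class LocusConfig:
    name: str
    length: int
    rate: float  # substitution-rate multiplier relative to the species tree scale
    kappa: float = 2.0  # transition/transversion rate ratio alpha/beta
    inheritance: str = PLASTID
    indel_events_mean: float = 0.0
    indel_length_range: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.rate <= 0 or self.kappa <= 0:
            raise InputError("locus length, rate and kappa must be positive")
        if self.inheritance not in (NUCLEAR, PLASTID):
            raise InputError(f"unknown inheritance {self.inheritance!r}")


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int
    individuals: tuple[int, ...]  # per-species sample counts (may include 1s)
    loci: tuple[LocusConfig, ...]
    seed: int
    birth_rate: float = 1.0
    intra_depth: float = 1e-4  # mean within-species coalescent depth, subst/site
    tree_height: float | None = None  # rescale root depth to this, if set
    # lengthen every terminal branch equally until the closest species pair
    # sits at least this far apart (keeps the tree ultrametric and bounds the
    # deepest paths, unlike a whole-tree rescale)
    min_species_divergence: float | None = None
    introgression_prob: float = 0.0  # chloroplast capture per sister pair
    force_introgression: bool = False  # guarantee capture on one sister pair
    missing: dict = field(default_factory=dict)  # locus -> n samples to drop
    n_clades: int = 3

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise InputError("need >= 2 species")
        if len(self.individuals) != self.n_species:
            raise InputError("one individual count per species required")
        if min(self.individuals) < 1:
            raise InputError("individual counts must be >= 1")
        if self.birth_rate <= 0 or self.intra_depth < 0:
            raise InputError("birth_rate > 0 and intra_depth >= 0 required")
        if not 0.0 <= self.introgression_prob <= 1.0:
            raise InputError("introgression_prob must be a probability")
        if not self.loci:
            raise InputError("at least one locus required")


@dataclass
class TruthTable:
    """Ground truth emitted alongside the alignments."""

    samples: pd.DataFrame  # sample_id, species, clade, introgression_donor
    genealogies: dict[str, str]  # genome -> newick
    locus_genome: dict[str, str]  # locus name -> genome

    def write(self, path: str | Path) -> None:
        self.samples.to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    alignments: dict[str, LocusAlignment]
    truth: TruthTable

    def write(self, out_dir: str | Path) -> None:
        from .datamodel import write_locus_fasta

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, aln in self.alignments.items():
            write_locus_fasta(aln, out / f"{name}.fasta")
        self.truth.write(out / "truth_samples.tsv")
        for genome, newick in self.truth.genealogies.items():
            (out / f"genealogy_{genome}.nwk").write_text(newick + "\n")
        manifest = {
            "loci": [
                {"name": lc.name, "path": f"{lc.name}.fasta",
                 "inheritance": lc.inheritance}
                for lc in self.config.loci
            ],
            "seed": self.config.seed,
            "outgroup_samples": [],
        }
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(
    n_species: int,
    birth_rate: float,
    rng: np.random.Generator,
) -> dendropy.Tree:
    """Ultrametric pure-birth tree; leaves labelled sp01..spNN.

    The process starts from a single lineage, splits at total rate
    k*birth_rate, and runs one further exponential stretch after the last
    split so tips do not sit on a split; the root-depth expectation is
    (1/birth_rate) * sum_{k=2..n} 1/k.
    """
    if n_species < 2:
        raise InputError("need >= 2 species")
    tns = dendropy.TaxonNamespace()
    # active lineages: (parent_node_or_None, start_time)
    active: list[tuple[dendropy.Node | None, float]] = [(None, 0.0)]
    t = 0.0
    root: dendropy.Node | None = None
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(0, k))
        parent, start = active.pop(idx)
        node = dendropy.Node()
        if parent is None:
            root = node
        else:
            parent.add_child(node)
            node.edge.length = t - start
        active.append((node, t))
        active.append((node, t))
    t_end = t + rng.exponential(1.0 / (n_species * birth_rate))
    labels = [f"sp{i + 1:02d}" for i in range(n_species)]
    order = rng.permutation(n_species)
    for (parent, start), li in zip(active, order):
        leaf = dendropy.Node(taxon=tns.new_taxon(label=labels[li]))
        parent.add_child(leaf)
        leaf.edge.length = t_end - start
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    return tree


def _depth_of(node: dendropy.Node) -> float:
    d = 0.0
    while node.parent_node is not None:
        d += node.edge.length or 0.0
        node = node.parent_node
    return d


def root_depth(tree: dendropy.Tree) -> float:
    """Maximum leaf depth (== every leaf's depth on an ultrametric tree)."""
    return max(_depth_of(lf) for lf in tree.leaf_node_iter())


def _scale_tree(tree: dendropy.Tree, factor: float) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor


def _leaf_path_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda x: x.label)
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return [x.label for x in taxa], out


def _clade_labels(tree: dendropy.Tree, n_clades: int) -> dict[str, str]:
    """Assign subgeneric-clade labels by cutting the first splits of the tree."""
    clades: list[dendropy.Node] = list(tree.seed_node.child_nodes())
    while len(clades) < n_clades:
        big = max(
            (c for c in clades if not c.is_leaf()),
            key=lambda c: sum(1 for _ in c.leaf_iter()),
            default=None,
        )
        if big is None:
            break
        clades.remove(big)
        clades.extend(big.child_nodes())
    labels: dict[str, str] = {}
    for k, node in enumerate(clades):
        for lf in node.leaf_iter():
            labels[lf.taxon.label] = f"clade{k + 1}"
    return labels


# ---------------------------------------------------------------------------
# Genealogies over sampled individuals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntrogressionEvent:
    donor: str
    recipient: str
    genome: str = PLASTID


def _sister_pairs(tree: dendropy.Tree) -> list[tuple[str, str]]:
    pairs = []
    for node in tree.preorder_internal_node_iter():
        kids = node.child_nodes()
        if len(kids) == 2 and all(k.is_leaf() for k in kids):
            a, b = sorted(k.taxon.label for k in kids)
            pairs.append((a, b))
    return sorted(pairs)


def simulate_individual_genealogies(
    species_tree: dendropy.Tree,
    samples_by_species: dict[str, list[str]],
    intra_depth: float,
    rng: np.random.Generator,
    introgressions: Sequence[IntrogressionEvent] = (),
) -> dendropy.Tree:
    """Expand each species leaf into a caterpillar of sampled individuals.

    Within a species, the m individuals coalesce at m-1 depths drawn
    Exp(mean=intra_depth), truncated to the terminal branch. For each
    chloroplast-capture event, the recipient species' samples are detached
    and re-attached as zero-height sisters of the donor species' sample
    leaves (haplotype copies), cycling through donors when the recipient has
    more samples.
    """
    captured: dict[str, str] = {}  # recipient species -> donor species
    for ev in introgressions:
        captured[ev.recipient] = ev.donor

    tns = dendropy.TaxonNamespace()

    def clone(node: dendropy.Node) -> dendropy.Node:
        new = dendropy.Node()
        new.edge.length = node.edge.length
        if node.is_leaf():
            new.species_label = node.taxon.label  # type: ignore[attr-defined]
        for child in node.child_nodes():
            new.add_child(clone(child))
        return new

    root = clone(species_tree.seed_node)
    gene_tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    gene_tree.is_rooted = True

    def expand_leaf(leaf: dendropy.Node, sample_ids: list[str]) -> dict[str, dendropy.Node]:
        """Replace a species leaf by a sample caterpillar; returns sample leaves."""
        m = len(sample_ids)
        term = leaf.edge.length or 0.0
        out: dict[str, dendropy.Node] = {}
        if m == 1:
            leaf.taxon = tns.new_taxon(label=sample_ids[0])
            out[sample_ids[0]] = leaf
            return out
        heights = np.sort(
            np.minimum(rng.exponential(intra_depth, size=m - 1)
                       if intra_depth > 0 else np.zeros(m - 1),
                       0.99 * term if term > 0 else 0.0)
        )[::-1]
        leaf.edge.length = term - float(heights[0])
        current = leaf
        for k in range(m - 1):
            h = float(heights[k])
            lf = dendropy.Node(taxon=tns.new_taxon(label=sample_ids[k]))
            lf.edge.length = h
            current.add_child(lf)
            out[sample_ids[k]] = lf
            if k < m - 2:
                nxt = dendropy.Node()
                nxt.edge.length = h - float(heights[k + 1])
                current.add_child(nxt)
                current = nxt
            else:
                last = dendropy.Node(taxon=tns.new_taxon(label=sample_ids[m - 1]))
                last.edge.length = h
                current.add_child(last)
                out[sample_ids[m - 1]] = last
        return out

    sample_leaves: dict[str, dict[str, dendropy.Node]] = {}
    for leaf in list(gene_tree.leaf_node_iter()):
        sp = getattr(leaf, "species_label", None)
        if sp is None:
            continue
        if sp in captured:
            # recipient samples join the donor's genealogy instead
            continue
        sample_leaves[sp] = expand_leaf(leaf, samples_by_species[sp])

    for recipient, donor in captured.items():
        # drop the recipient's own lineage
        for leaf in list(gene_tree.leaf_node_iter()):
            if getattr(leaf, "species_label", None) == recipient:
                parent = leaf.parent_node
                parent.remove_child(leaf)
                # suppress the unifurcation left behind
                if len(parent.child_nodes()) == 1 and parent.parent_node is not None:
                    only = parent.child_nodes()[0]
                    gp = parent.parent_node
                    only.edge.length = (only.edge.length or 0.0) + (parent.edge.length or 0.0)
                    gp.remove_child(parent)
                    gp.add_child(only)
        donors = sorted(sample_leaves[donor])
        for k, sid in enumerate(samples_by_species[recipient]):
            host_leaf = sample_leaves[donor][donors[k % len(donors)]]
            # host leaf becomes an internal node carrying two identical haplotypes
            twin = dendropy.Node(taxon=tns.new_taxon(label=sid))
            twin.edge.length = 0.0
            host_copy = dendropy.Node(taxon=host_leaf.taxon)
            host_copy.edge.length = 0.0
            host_leaf.taxon = None
            host_leaf.add_child(host_copy)
            host_leaf.add_child(twin)
            sample_leaves[donor][host_copy.taxon.label] = host_copy
    return gene_tree


# ---------------------------------------------------------------------------
# Sequence evolution (K2P process) and indels
# ---------------------------------------------------------------------------

def _k2p_edge_probs(branch: float, kappa: float) -> tuple[float, float]:
    """Expected (P, Q) after a branch of the given length under K2P."""
    bt = branch / (kappa + 2.0)  # beta * t
    at = kappa * bt  # alpha * t
    q = 0.5 - 0.5 * np.exp(-4.0 * bt)
    p = 0.25 + 0.25 * np.exp(-4.0 * bt) - 0.5 * np.exp(-2.0 * (at + bt))
    return float(p), float(q)


def _mutate(seq: np.ndarray, branch: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    if branch <= 0:
        return seq.copy()
    p, q = _k2p_edge_probs(branch, kappa)
    u = rng.random(seq.size)
    child = seq.copy()
    ts = u < p
    child[ts] ^= 2  # A<->G, C<->T
    tv = (u >= p) & (u < p + q)
    flip = np.where(rng.random(seq.size) < 0.5, 1, 3)
    child[tv] ^= flip[tv].astype(np.uint8)
    return child


def evolve_sequences(
    locus_tree: dendropy.Tree,
    length: int,
    rate: float,
    kappa: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Leaf sequences (integer codes) under the K2P process along the tree.

    Branch lengths are multiplied by the locus rate; the root sequence is
    uniform over A/C/G/T.
    """
    root_seq = rng.integers(0, 4, size=length, dtype=np.uint8)
    out: dict[str, np.ndarray] = {}
    stack = [(locus_tree.seed_node, root_seq)]
    while stack:
        node, seq = stack.pop()
        for child in sorted(
            node.child_nodes(),
            key=lambda c: min(lf.taxon.label for lf in c.leaf_iter()),
        ):
            child_seq = _mutate(seq, (child.edge.length or 0.0) * rate, kappa, rng)
            if child.is_leaf():
                out[child.taxon.label] = child_seq
            else:
                stack.append((child, child_seq))
    return out


def _apply_indels(
    seqs: dict[str, np.ndarray],
    locus_tree: dendropy.Tree,
    cfg: LocusConfig,
    rng: np.random.Generator,
) -> None:
    """Gap-code Poisson-many indel events, each borne by one branch and
    shared by all its descendant samples."""
    n_events = int(rng.poisson(cfg.indel_events_mean))
    if n_events == 0:
        return
    edges = [
        node for node in locus_tree.preorder_node_iter()
        if node.parent_node is not None
    ]
    lo, hi = cfg.indel_length_range
    for _ in range(n_events):
        node = edges[int(rng.integers(0, len(edges)))]
        ln = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, max(1, cfg.length - ln)))
        for lf in node.leaf_iter():
            seqs[lf.taxon.label][start:start + ln] = _GAP


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_ALPHA[codes])


# ---------------------------------------------------------------------------
# Whole-dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generation path: species tree, genealogies, sequences."""
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("tree", "assign", "genealogy", "sequence", "indel", "introgression"),
            ss.spawn(6),
        )
    }

    sp_tree = simulate_species_tree(config.n_species, config.birth_rate, streams["tree"])
    if config.tree_height is not None:
        _scale_tree(sp_tree, config.tree_height / root_depth(sp_tree))
    if config.min_species_divergence is not None:
        _, paths = _leaf_path_matrix(sp_tree)
        iu = np.triu_indices(paths.shape[0], k=1)
        shortfall = config.min_species_divergence - float(paths[iu].min())
        if shortfall > 0:
            for lf in sp_tree.leaf_node_iter():
                lf.edge.length = (lf.edge.length or 0.0) + shortfall / 2.0
    clades = _clade_labels(sp_tree, config.n_clades)

    species = sorted(lf.taxon.label for lf in sp_tree.leaf_node_iter())
    pairs = _sister_pairs(sp_tree)

    # chloroplast capture decisions, before individuals are allotted, so a
    # forced event can be guaranteed two multi-individual species
    events: list[IntrogressionEvent] = []
    counts = sorted(config.individuals, reverse=True)
    alloc: dict[str, int] = {}
    if config.force_introgression:
        if not pairs:
            raise InputError("no sister species pair for forced introgression")
        donor, recipient = pairs[0]
        if len(counts) >= 2 and counts[1] >= 2:
            alloc[donor], alloc[recipient] = counts[0], counts[1]
            counts = counts[2:]
            events.append(IntrogressionEvent(donor=donor, recipient=recipient))
        else:
            raise InputError("forced introgression needs two counts >= 2")
    remaining = [sp for sp in species if sp not in alloc]
    perm = streams["assign"].permutation(len(remaining))
    for sp, ci in zip(remaining, perm):
        alloc[sp] = counts[ci]
    if config.introgression_prob > 0:
        for a, b in pairs:
            if any(e.donor in (a, b) or e.recipient in (a, b) for e in events):
                continue
            if alloc[a] >= 2 and alloc[b] >= 2 and (
                streams["introgression"].random() < config.introgression_prob
            ):
                events.append(IntrogressionEvent(donor=a, recipient=b))

    samples_by_species = {
        sp: [f"{sp}.{k + 1}" for k in range(alloc[sp])] for sp in species
    }

    genealogies = {
        NUCLEAR: simulate_individual_genealogies(
            sp_tree, samples_by_species, config.intra_depth,
            streams["genealogy"], introgressions=(),
        ),
        PLASTID: simulate_individual_genealogies(
            sp_tree, samples_by_species, config.intra_depth,
            streams["genealogy"], introgressions=events,
        ),
    }

    # samples dropped from loci that failed to sequence, per config.missing
    drop_cache: dict[int, list[str]] = {}

    def missing_samples(k: int) -> list[str]:
        if k not in drop_cache:
            shielded = {e.donor for e in events} | {e.recipient for e in events}
            candidates = [
                sp for sp in species
                if alloc[sp] >= k + 2 and sp not in shielded
            ]
            if not candidates:
                raise InputError("no species can lose samples for 'missing'")
            sp = candidates[-1]
            drop_cache[k] = samples_by_species[sp][-k:]
        return drop_cache[k]

    alignments: dict[str, LocusAlignment] = {}
    order = [s for sp in species for s in samples_by_species[sp]]
    for lc in config.loci:
        genome = lc.inheritance
        seqs = evolve_sequences(
            genealogies[genome], lc.length, lc.rate, lc.kappa, streams["sequence"]
        )
        _apply_indels(seqs, genealogies[genome], lc, streams["indel"])
        drop = set(missing_samples(config.missing[lc.name])) if lc.name in config.missing else set()
        records = [
            BarcodeRecord(
                sample_id=s,
                species=s.rsplit(".", 1)[0],
                locus=lc.name,
                sequence=_codes_to_str(seqs[s]),
            )
            for s in order
            if s not in drop
        ]
        alignments[lc.name] = LocusAlignment(lc.name, records)

    donor_of = {e.recipient: e.donor for e in events}
    rows = [
        {
            "sample_id": s,
            "species": sp,
            "clade": clades.get(sp, "clade1"),
            "introgression_donor": donor_of.get(sp, "-"),
        }
        for sp in species
        for s in samples_by_species[sp]
    ]
    truth = TruthTable(
        samples=pd.DataFrame(rows),
        genealogies={
            g: t.as_string(schema="newick").strip() for g, t in genealogies.items()
        },
        locus_genome={lc.name: lc.inheritance for lc in config.loci},
    )
    return SimulatedDataset(config=config, alignments=alignments, truth=truth)


# ---------------------------------------------------------------------------
# Study-shaped preset
# ---------------------------------------------------------------------------

def pulsatilla_like(seed: int, **overrides) -> SimulationConfig:
    """Config shaped like the Pulsatilla study: 19 species in 3 clades,
    52 samples with 9 singletons, four loci with strongly unequal rates
    (nuclear ITS fastest), indel-bearing trnH-psbA and ITS, and two samples
    of one species missing the rbcL and matK genes.

    Rate multipliers follow the ratio of the observed per-locus mean
    interspecific distances (roughly 1 : 1.8 : 1.7 : 9.2 for
    rbcL : matK : trnH-psbA : ITS); the tree height puts the slowest locus
    near the observed 0.003-0.004 mean interspecific distance.
    """
    cfg = dict(
        n_species=19,
        individuals=(5, 5, 5, 4, 4, 4, 4, 4, 4, 4, 1, 1, 1, 1, 1, 1, 1, 1, 1),
        loci=(
            LocusConfig("rbcL", 1207, rate=1.0, kappa=2.0, inheritance=PLASTID),
            LocusConfig("matK", 835, rate=1.8, kappa=2.0, inheritance=PLASTID),
            LocusConfig("trnH_psbA", 379, rate=1.7, kappa=2.0,
                        inheritance=PLASTID, indel_events_mean=11,
                        indel_length_range=(1, 25)),
            LocusConfig("ITS", 589, rate=9.2, kappa=2.0, inheritance=NUCLEAR,
                        indel_events_mean=5, indel_length_range=(1, 2)),
        ),
        seed=seed,
        birth_rate=1.0,
        tree_height=0.0035,
        intra_depth=1.5e-4,
        missing={"rbcL": 2, "matK": 2},
        n_clades=3,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def known_truth_config(seed: int, introgression: bool = False) -> SimulationConfig:
    """Preset variant with zero intraspecific depth and every species pair at
    least 0.05 substitutions/site apart, optionally with one forced
    chloroplast capture on a sister pair."""
    return pulsatilla_like(
        seed,
        intra_depth=0.002 if introgression else 0.0,
        min_species_divergence=0.05,
        force_introgression=introgression,
    )
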