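"""Synthetic sequence panels.

Two generators:

* :func:`generate_fixture` emits a deterministic 14-accession, 4-marker panel
  whose per-accession ungapped lengths and per-marker haplotype partitions
  realise a tabulated specification (packaged in ``data/fixture_tables.yaml``).
  The real study sequences are unpublished; only their length and
  haplotype-equality structure is on record, and that structure is exactly
  what the fixture reproduces.  Sequences are built from a seeded random base
  per marker; each haplotype class carries its own deterministic substitution
  window, and length differences are realised as terminal gaps so the panel
  doubles as a per-marker alignment without implementing MSA.

* :func:`simulate_panel` draws a hierarchical divergence simulation
  (genus -> species -> accession) with per-level substitution rates and a
  transition/transversion ratio, returning the true genealogy for
  tree-recovery experiments.  No indels, no recombination, no coalescent
  variance — divergence is placed deterministically down the hierarchy.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import yaml

from .distances import AlignedBlock
from .errors import DataValidationError
from .phylo import PhyloTree
from .seq_io import AccessionRecord, InfrataxonRank, MarkerDefinition, MarkerPanel

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureAccession:
    record: AccessionRecord
    lengths: Mapping[str, int]  # marker_id -> ungapped bp
    haplotypes: Mapping[str, str]  # marker_id -> class letter


@dataclass(frozen=True)
class FixtureSpec:
    """Lengths and haplotype-equality classes for a deterministic panel."""

    markers: tuple[str, ...]
    accessions: tuple[FixtureAccession, ...]
    min_class_divergence: int = 1

    def __post_init__(self) -> None:
        if self.min_class_divergence < 1:
            raise DataValidationError("min_class_divergence must be >= 1")
        for acc in self.accessions:
            for mid in self.markers:
                if mid not in acc.lengths or mid not in acc.haplotypes:
                    raise DataValidationError(
                        f"accession {acc.record.accession_id!r} lacks length or "
                        f"haplotype for marker {mid!r}"
                    )
                if acc.lengths[mid] < 1:
                    raise DataValidationError(
                        f"non-positive length for {acc.record.accession_id!r}/{mid!r}"
                    )


def load_fixture_spec(path: str | None = None) -> FixtureSpec:
    """Load a fixture specification; default is the packaged 14-accession panel."""
    if path is None:
        source = (
            importlib.resources.files("grassbarcode.data") / "fixture_tables.yaml"
        )
        raw = yaml.safe_load(source.read_text(encoding="utf-8"))
    else:
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
    markers = tuple(raw["markers"])
    accessions = []
    for entry in raw["accessions"]:
        record = AccessionRecord(
            accession_id=entry["id"],
            genus=entry["genus"],
            species=entry["species"],
            infrataxon=entry.get("infrataxon"),
            infrataxon_rank=InfrataxonRank(entry.get("infrataxon_rank", "none")),
        )
        accessions.append(
            FixtureAccession(
                record=record,
                lengths=dict(entry["lengths"]),
                haplotypes=dict(entry["haplotypes"]),
            )
        )
    return FixtureSpec(
        markers=markers,
        accessions=tuple(accessions),
        min_class_divergence=int(raw.get("min_class_divergence", 1)),
    )


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _substitute(base: str) -> str:
    """Deterministic single-base edit: next base in A->C->G->T->A order."""
    order = "ACGT"
    return order[(order.index(base) + 1) % 4]


def generate_fixture(
    spec: FixtureSpec | None = None, seed: int = 0
) -> tuple[MarkerPanel, dict[str, AlignedBlock]]:
    """Deterministic panel realising the spec's lengths and haplotype classes.

    Returns the panel (sequences carry terminal gaps out to each marker's
    common alignment length) and the per-marker aligned blocks.
    """
    if spec is None:
        spec = load_fixture_spec()
    records = [acc.record for acc in spec.accessions]
    markers = [
        MarkerDefinition(marker_id=mid, marker_index=i)
        for i, mid in enumerate(spec.markers, start=1)
    ]
    sequences: dict[tuple[str, str], str] = {}
    blocks: dict[str, AlignedBlock] = {}
    div = spec.min_class_divergence

    for m_idx, mid in enumerate(spec.markers, start=1):
        lengths = [acc.lengths[mid] for acc in spec.accessions]
        max_len, min_len = max(lengths), min(lengths)
        # class letters in canonical (first appearance) order
        letters: list[str] = []
        for acc in spec.accessions:
            letter = acc.haplotypes[mid]
            if letter not in letters:
                letters.append(letter)
        if len(letters) * div > min_len:
            raise DataValidationError(
                f"marker {mid!r}: {len(letters)} classes x divergence {div} exceed "
                f"the shortest sequence ({min_len} bp); classes would not separate"
            )
        rng = np.random.default_rng([seed, m_idx])
        base = _random_sequence(rng, max_len)
        class_core: dict[str, np.ndarray] = {}
        for c_idx, letter in enumerate(letters):
            core = base.copy()
            for k in range(div):
                pos = c_idx * div + k  # window inside the gap-free region
                core[pos] = _substitute(str(core[pos]))
            class_core[letter] = core
        marker_seqs: list[str] = []
        for acc in spec.accessions:
            length = acc.lengths[mid]
            core = class_core[acc.haplotypes[mid]]
            seq = "".join(core[:length]) + "-" * (max_len - length)
            sequences[(acc.record.accession_id, mid)] = seq
            marker_seqs.append(seq)
        blocks[mid] = AlignedBlock(
            accession_ids=tuple(acc.record.accession_id for acc in spec.accessions),
            sequences=tuple(marker_seqs),
        )

    panel = MarkerPanel(accessions=records, markers=markers, sequences=sequences)
    return panel, blocks


@dataclass(frozen=True)
class SimulationSpec:
    """Hierarchical divergence simulation parameters.

    Rates are per-site substitution probabilities on the branch leading to
    each level.  Defaults mirror the study's scale: 7 genera, four markers of
    study-like lengths, clear between-species divergence and none within
    species (conspecific accessions are labelled as cultivars).
    """

    n_genera: int = 7
    species_per_genus: int = 2
    accessions_per_species: int = 2
    marker_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"ITS": 700, "matK": 400, "rbcL": 572, "trnL-F": 460}
    )
    genus_rate: float = 0.05
    species_rate: float = 0.01
    accession_rate: float = 0.0
    tstv_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genera, self.species_per_genus, self.accessions_per_species) < 1:
            raise DataValidationError("all counts must be >= 1")
        if min(self.genus_rate, self.species_rate, self.accession_rate) < 0:
            raise DataValidationError("rates must be >= 0")
        if self.tstv_ratio <= 0:
            raise DataValidationError("tstv_ratio must be > 0")
        if not self.marker_lengths:
            raise DataValidationError("at least one marker required")


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _mutate(seq: np.ndarray, rate: float, kappa: float, rng: np.random.Generator):
    """Apply per-site substitutions at the given rate and ts/tv ratio."""
    out = seq.copy()
    if rate <= 0:
        return out
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for pos in hits:
        old = str(out[pos])
        if rng.random() < kappa / (kappa + 1.0):
            out[pos] = _TRANSITION[old]
        else:
            out[pos] = _TRANSVERSIONS[old][rng.integers(0, 2)]
    return out


def simulate_panel(spec: SimulationSpec) -> tuple[MarkerPanel, PhyloTree]:
    """Simulate a genus -> species -> accession panel plus its true genealogy."""
    rng = np.random.default_rng(spec.seed)
    records: list[AccessionRecord] = []
    leaf_ids: list[str] = []
    many_cultivars = spec.accessions_per_species > 1
    for g in range(1, spec.n_genera + 1):
        for s in range(1, spec.species_per_genus + 1):
            for a in range(1, spec.accessions_per_species + 1):
                aid = f"G{g}_S{s}_A{a}"
                records.append(
                    AccessionRecord(
                        accession_id=aid,
                        genus=f"Genus{g}",
                        species=f"species{g}_{s}",
                        infrataxon=f"cv{a}" if many_cultivars else None,
                        infrataxon_rank=(
                            InfrataxonRank.CULTIVAR
                            if many_cultivars
                            else InfrataxonRank.NONE
                        ),
                    )
                )
                leaf_ids.append(aid)

    markers = [
        MarkerDefinition(marker_id=mid, marker_index=i)
        for i, mid in enumerate(spec.marker_lengths, start=1)
    ]
    sequences: dict[tuple[str, str], str] = {}
    for mid in spec.marker_lengths:
        length = spec.marker_lengths[mid]
        root = _random_sequence(rng, length)
        for g in range(1, spec.n_genera + 1):
            genus_seq = _mutate(root, spec.genus_rate, spec.tstv_ratio, rng)
            for s in range(1, spec.species_per_genus + 1):
                species_seq = _mutate(genus_seq, spec.species_rate, spec.tstv_ratio, rng)
                for a in range(1, spec.accessions_per_species + 1):
                    acc_seq = _mutate(
                        species_seq, spec.accession_rate, spec.tstv_ratio, rng
                    )
                    sequences[(f"G{g}_S{s}_A{a}", mid)] = "".join(acc_seq)

    panel = MarkerPanel(accessions=records, markers=markers, sequences=sequences)
    return panel, _true_genealogy(spec)


def _true_genealogy(spec: SimulationSpec) -> PhyloTree:
    """The generating hierarchy as a tree, branch lengths = per-level rates."""
    tns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    for g in range(1, spec.n_genera + 1):
        genus_node = dendropy.Node()
        root.add_child(genus_node)
        genus_node.edge.length = spec.genus_rate
        for s in range(1, spec.species_per_genus + 1):
            species_node = dendropy.Node()
            genus_node.add_child(species_node)
            species_node.edge.length = spec.species_rate
            for a in range(1, spec.accessions_per_species + 1):
                leaf = dendropy.Node(taxon=tns.new_taxon(label=f"G{g}_S{s}_A{a}"))
                species_node.add_child(leaf)
                leaf.edge.length = spec.accession_rate
    tree = dendropy.Tree(seed_node=root, taxon_namespace=tns)
    tree.is_rooted = False
    return PhyloTree(tree=tree)
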