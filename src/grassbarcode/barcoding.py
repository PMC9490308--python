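"""Composite DNA identification codes and discrimination statistics.

Each accession's composite barcode combines the total concatenated ungapped
length over all markers (the ``L`` part, e.g. L2127 for a 4-marker panel) with
its per-marker haplotype labels (H1..HM).  Two accessions are distinguishable
by the combined barcode iff they differ in total length or in at least one
marker's haplotype class.

Discrimination statistics count distinct haplotype classes (single marker) or
distinct composite codes (combined) across a set of *terminal taxa* — the
units an identification system is meant to tell apart.  Here conspecific
cultivars form one terminal taxon (cultivar names do not split taxa), while
named varieties are distinct terminal taxa; this matches how barcode databases
treat infraspecific ranks.  Assignment success (correct assignment rate, CAR)
is 100 x distinct classes-or-codes / number of taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .errors import DataValidationError
from .haplotyping import HaplotypeAssignment
from .seq_io import InfrataxonRank, MarkerPanel


@dataclass(frozen=True)
class CompositeBarcode:
    """The multi-marker identification code of one accession."""

    accession_id: str = field(compare=False)
    total_length_bp: int
    marker_labels: tuple[str, ...]  # ordered by marker_index

    @property
    def code_string(self) -> str:
        """Machine rendering, e.g. ``L2127|H1.A|H2.A|H3.A|H4.A``."""
        parts = [f"L{self.total_length_bp}"]
        parts += [lbl.replace("^", ".") for lbl in self.marker_labels]
        return "|".join(parts)

    @property
    def key(self) -> tuple:
        return (self.total_length_bp, self.marker_labels)


Classifier = Union[HaplotypeAssignment, Sequence[CompositeBarcode]]


def build_barcode(
    panel: MarkerPanel,
    assignments: Sequence[HaplotypeAssignment],
    accession_id: str,
) -> CompositeBarcode:
    """Assemble one accession's composite code from the marker assignments."""
    ordered = sorted(assignments, key=lambda a: a.marker_index)
    labels = []
    for asg in ordered:
        if accession_id not in asg.accession_ids:
            raise DataValidationError(
                f"accession {accession_id!r} missing from the {asg.marker_id!r} "
                "haplotype assignment"
            )
        labels.append(asg.label_of(accession_id))
    total = sum(
        panel.ungapped_length(accession_id, asg.marker_id) for asg in ordered
    )
    return CompositeBarcode(
        accession_id=accession_id,
        total_length_bp=total,
        marker_labels=tuple(labels),
    )


def build_all_barcodes(
    panel: MarkerPanel, assignments: Sequence[HaplotypeAssignment]
) -> list[CompositeBarcode]:
    return [build_barcode(panel, assignments, aid) for aid in panel.accession_ids]


def _key_of(classifier: Classifier, accession_id: str):
    """The identity an accession carries under a marker or the combined code."""
    if isinstance(classifier, HaplotypeAssignment):
        return classifier.label_of(accession_id)
    for bc in classifier:
        if bc.accession_id == accession_id:
            return bc.key
    raise DataValidationError(f"no composite barcode for accession {accession_id!r}")


def resolve_count(
    classifier: Classifier, evaluation_units: Sequence[Iterable[str]]
) -> int:
    """Distinct haplotype classes / composite codes observed across the units.

    ``evaluation_units`` are disjoint groups of accessions regarded as the same
    terminal taxon; the count is taken over the union of their members.
    """
    units = [set(u) for u in evaluation_units]
    if any(not u for u in units):
        raise DataValidationError("evaluation units must be non-empty")
    seen: set[str] = set()
    for unit in units:
        overlap = seen & unit
        if overlap:
            raise DataValidationError(
                f"evaluation units overlap on: {', '.join(sorted(overlap))}"
            )
        seen |= unit
    return len({_key_of(classifier, aid) for aid in seen})


def assignment_success(
    classifier: Classifier, taxa: Sequence[Iterable[str]]
) -> float:
    """CAR: 100 x distinct classes/codes over the set / number of taxa.

    Reported to one decimal place, round-half-up (87.5 for 7 of 8 taxa).
    """
    if not taxa:
        raise DataValidationError("empty taxa list")
    distinct = resolve_count(classifier, taxa)
    pct = Decimal(100 * distinct) / Decimal(len(taxa))
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def terminal_taxa(
    panel: MarkerPanel, accession_ids: Iterable[str] | None = None
) -> dict[str, set[str]]:
    """Group accessions into terminal taxa, keyed by a display name.

    The key is genus + species + variety epithet where present; cultivar names
    are dropped, so conspecific cultivars fall into one taxon.
    """
    wanted = set(accession_ids) if accession_ids is not None else None
    taxa: dict[str, set[str]] = {}
    for acc in panel.accessions:
        if wanted is not None and acc.accession_id not in wanted:
            continue
        name = acc.binomial
        if acc.infrataxon_rank is InfrataxonRank.VARIETY:
            name += f" var. {acc.infrataxon}"
        taxa.setdefault(name, set()).add(acc.accession_id)
    return taxa


@dataclass(frozen=True)
class LevelStats:
    """Discrimination statistics over one evaluation set / unit definition."""

    n_units: int
    per_marker_resolved: Mapping[str, int]
    per_marker_assignment_success: Mapping[str, float]
    combined_resolved: int
    combined_assignment_success: float
    unresolved_groups: tuple[frozenset[str], ...]

    def to_dict(self) -> dict:
        return {
            "n_units": self.n_units,
            "per_marker_resolved": dict(self.per_marker_resolved),
            "per_marker_assignment_success": dict(self.per_marker_assignment_success),
            "combined_resolved": self.combined_resolved,
            "combined_assignment_success": self.combined_assignment_success,
            "unresolved_groups": [sorted(g) for g in self.unresolved_groups],
        }


@dataclass(frozen=True)
class DiscriminationReport:
    """Discrimination at three taxonomic depths.

    ``species_level`` spans the whole panel with terminal taxa as units;
    ``within_genus`` restricts to each genus (variety/subspecies resolution);
    ``within_species`` restricts to each multi-accession species with every
    accession its own unit (cultivar resolution).
    """

    species_level: LevelStats
    within_genus: Mapping[str, LevelStats]
    within_species: Mapping[str, LevelStats]

    # Convenience views of the headline (species-level) numbers
    @property
    def per_marker_resolved(self) -> Mapping[str, int]:
        return self.species_level.per_marker_resolved

    @property
    def per_marker_assignment_success(self) -> Mapping[str, float]:
        return self.species_level.per_marker_assignment_success

    @property
    def combined_resolved(self) -> int:
        return self.species_level.combined_resolved

    @property
    def combined_assignment_success(self) -> float:
        return self.species_level.combined_assignment_success

    @property
    def unresolved_groups(self) -> tuple[frozenset[str], ...]:
        return self.species_level.unresolved_groups

    def to_dict(self) -> dict:
        return {
            "species_level": self.species_level.to_dict(),
            "within_genus": {g: s.to_dict() for g, s in self.within_genus.items()},
            "within_species": {s: t.to_dict() for s, t in self.within_species.items()},
        }


def _level_stats(
    assignments: Sequence[HaplotypeAssignment],
    barcodes: Sequence[CompositeBarcode],
    units: Sequence[set[str]],
) -> LevelStats:
    members = sorted(set().union(*units))
    sub_barcodes = [bc for bc in barcodes if bc.accession_id in set(members)]
    per_resolved = {
        asg.marker_id: resolve_count(asg, units) for asg in assignments
    }
    per_success = {
        asg.marker_id: assignment_success(asg, units) for asg in assignments
    }
    by_code: dict[tuple, set[str]] = {}
    for bc in sub_barcodes:
        by_code.setdefault(bc.key, set()).add(bc.accession_id)
    unresolved = tuple(
        frozenset(group) for group in by_code.values() if len(group) > 1
    )
    return LevelStats(
        n_units=len(units),
        per_marker_resolved=per_resolved,
        per_marker_assignment_success=per_success,
        combined_resolved=resolve_count(sub_barcodes, units),
        combined_assignment_success=assignment_success(sub_barcodes, units),
        unresolved_groups=unresolved,
    )


def discrimination_report(
    panel: MarkerPanel, assignments: Sequence[HaplotypeAssignment]
) -> DiscriminationReport:
    """Full three-level discrimination report for a panel."""
    barcodes = build_all_barcodes(panel, assignments)

    species_units = list(terminal_taxa(panel).values())
    species_level = _level_stats(assignments, barcodes, species_units)

    within_genus: dict[str, LevelStats] = {}
    for genus in sorted({a.genus for a in panel.accessions}):
        ids = {a.accession_id for a in panel.accessions if a.genus == genus}
        if len(ids) < 2:
            continue
        units = list(terminal_taxa(panel, ids).values())
        within_genus[genus] = _level_stats(assignments, barcodes, units)

    within_species: dict[str, LevelStats] = {}
    for binomial in sorted({a.binomial for a in panel.accessions}):
        ids = {a.accession_id for a in panel.accessions if a.binomial == binomial}
        if len(ids) < 2:
            continue
        units = [{aid} for aid in sorted(ids)]
        within_species[binomial] = _level_stats(assignments, barcodes, units)

    return DiscriminationReport(
        species_level=species_level,
        within_genus=within_genus,
        within_species=within_species,
    )


def write_barcode_table(
    panel: MarkerPanel,
    assignments: Sequence[HaplotypeAssignment],
    path: str | Path,
) -> Path:
    """Tab-separated barcode database mirroring the per-accession code table."""
    ordered = sorted(assignments, key=lambda a: a.marker_index)
    marker_ids = [a.marker_id for a in ordered]
    header = (
        ["accession_id", "taxon"]
        + [f"length_{m}" for m in marker_ids]
        + ["length_total"]
        + [f"haplotype_{m}" for m in marker_ids]
        + ["barcode"]
    )
    lines = ["\t".join(header)]
    for acc in panel.accessions:
        bc = build_barcode(panel, ordered, acc.accession_id)
        name = acc.binomial
        if acc.infrataxon:
            sep = "var." if acc.infrataxon_rank is InfrataxonRank.VARIETY else "cv."
            name += f" {sep} {acc.infrataxon}"
        lengths = [str(panel.ungapped_length(acc.accession_id, m)) for m in marker_ids]
        row = (
            [acc.accession_id, name]
            + lengths
            + [str(bc.total_length_bp)]
            + list(bc.marker_labels)
            + [bc.code_string]
        )
        lines.append("\t".join(row))
    out = Path(path)
    out.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return out
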