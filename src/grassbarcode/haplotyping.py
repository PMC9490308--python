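"""Per-marker haplotype collapsing.

Accessions whose sequences are indistinguishable at a marker form one
haplotype class.  Following the convention of haplotype software operating on
alignments (DnaSP-style), alignment columns containing a gap in *any* sequence
are excluded before comparison, so sequences that differ only by indels — and
hence may differ in ungapped length — collapse into the same haplotype.  For
unaligned input (unequal sequence lengths, no meaningful columns) identity
falls back to exact equality of the ungapped uppercase strings.  Ambiguity
codes compare as literal characters in both regimes.

Classes are labelled ``H<k>^<letter>`` where ``k`` is the marker's position in
the composite code and letters run A, B, C, ... (then AA, AB, ...) in order of
first appearance under the panel's accession ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DataValidationError
from .seq_io import MarkerPanel


@dataclass(frozen=True)
class HaplotypeClass:
    """One identical-sequence class at a marker."""

    label: str
    member_accession_ids: frozenset[str]
    representative_sequence: str  # as stored in the panel (possibly gapped)
    length_bp: int  # ungapped length of the representative

    def __contains__(self, accession_id: str) -> bool:
        return accession_id in self.member_accession_ids


@dataclass(frozen=True)
class HaplotypeAssignment:
    """Partition of a panel's accessions into haplotype classes at one marker."""

    marker_id: str
    marker_index: int
    classes: tuple[HaplotypeClass, ...]

    @property
    def n_haplotypes(self) -> int:
        return len(self.classes)

    @property
    def accession_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for cls in self.classes:
            out |= cls.member_accession_ids
        return frozenset(out)

    def label_of(self, accession_id: str) -> str:
        return self.class_of(accession_id).label

    def class_of(self, accession_id: str) -> HaplotypeClass:
        for cls in self.classes:
            if accession_id in cls:
                return cls
        raise DataValidationError(
            f"accession {accession_id!r} has no haplotype at marker {self.marker_id!r}"
        )


def class_letter(i: int) -> str:
    """0 -> 'A', 25 -> 'Z', 26 -> 'AA', ... (spreadsheet-column style)."""
    letters = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


def haplotype_key(sequence: str, excluded_columns: frozenset[int] | None = None) -> str:
    """Comparison key for haplotype identity.

    With ``excluded_columns`` (aligned input) the key is the sequence restricted
    to the remaining columns; otherwise it is the ungapped sequence.
    """
    if excluded_columns is None:
        return sequence.replace("-", "")
    return "".join(c for i, c in enumerate(sequence) if i not in excluded_columns)


def gap_columns(sequences: Sequence[str]) -> frozenset[int]:
    """Columns (0-based) containing '-' in at least one of the aligned sequences."""
    cols: set[int] = set()
    for seq in sequences:
        cols.update(i for i, c in enumerate(seq) if c == "-")
    return frozenset(cols)


def collapse_haplotypes(panel: MarkerPanel, marker_id: str) -> HaplotypeAssignment:
    """Partition the panel's accessions into haplotype classes at one marker."""
    marker = next((m for m in panel.markers if m.marker_id == marker_id), None)
    if marker is None:
        raise DataValidationError(f"marker {marker_id!r} not in panel")
    seqs: dict[str, str] = {}
    for acc in panel.accessions:
        key = (acc.accession_id, marker_id)
        if key not in panel.sequences:
            raise DataValidationError(
                f"accession {acc.accession_id!r} has no sequence for marker "
                f"{marker_id!r}"
            )
        seqs[acc.accession_id] = panel.sequences[key]

    lengths = {len(s) for s in seqs.values()}
    excluded = gap_columns(list(seqs.values())) if len(lengths) == 1 else None

    classes: list[tuple[str, list[str]]] = []  # (key, member ids) in first-seen order
    index_of: dict[str, int] = {}
    for acc_id, seq in seqs.items():  # panel order
        key = haplotype_key(seq, excluded)
        if key in index_of:
            classes[index_of[key]][1].append(acc_id)
        else:
            index_of[key] = len(classes)
            classes.append((key, [acc_id]))

    built = tuple(
        HaplotypeClass(
            label=f"H{marker.marker_index}^{class_letter(i)}",
            member_accession_ids=frozenset(members),
            representative_sequence=seqs[members[0]],
            length_bp=len(seqs[members[0]].replace("-", "")),
        )
        for i, (_, members) in enumerate(classes)
    )
    return HaplotypeAssignment(
        marker_id=marker_id, marker_index=marker.marker_index, classes=built
    )


def count_haplotypes(
    assignment: HaplotypeAssignment, accession_subset: Iterable[str]
) -> int:
    """Number of distinct haplotype classes intersecting the subset."""
    subset = set(accession_subset)
    if not subset:
        raise DataValidationError("empty accession subset")
    unknown = subset - set(assignment.accession_ids)
    if unknown:
        raise DataValidationError(
            f"accession(s) not in assignment for marker {assignment.marker_id!r}: "
            f"{', '.join(sorted(unknown))}"
        )
    return sum(1 for cls in assignment.classes if cls.member_accession_ids & subset)


def collapse_all(panel: MarkerPanel) -> list[HaplotypeAssignment]:
    """One assignment per marker, in composite-code (marker_index) order."""
    return [
        collapse_haplotypes(panel, m.marker_id)
        for m in sorted(panel.markers, key=lambda m: m.marker_index)
    ]


def write_haplotype_table(
    assignments: Iterable[HaplotypeAssignment], path: str | Path
) -> Path:
    """Tab-separated haplotype table: marker, label, length_bp, members."""
    lines = ["marker\thaplotype\tlength_bp\tmembers"]
    for asg in assignments:
        for cls in asg.classes:
            members = ",".join(sorted(cls.member_accession_ids))
            lines.append(f"{asg.marker_id}\t{cls.label}\t{cls.length_bp}\t{members}")
    out = Path(path)
    out.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return out
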