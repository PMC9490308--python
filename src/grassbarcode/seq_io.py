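"""Sequence and taxonomy input/output.

The unit of analysis is the *accession* (a sampled germplasm entry) and the
central container is the :class:`MarkerPanel`, an accession x marker matrix of
DNA sequences.  One FASTA file per marker holds one record per accession; a
tab-separated taxonomy table supplies the genus / species / variety-or-cultivar
identity of each accession and fixes the accession ordering used everywhere
downstream (haplotype letters, table rows, tree leaf order).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataValidationError

#: IUPAC nucleotide codes plus the gap symbol; sequences are stored uppercase.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

TAXONOMY_COLUMNS = ("accession_id", "genus", "species", "infrataxon", "infrataxon_rank")


class InfrataxonRank(str, enum.Enum):
    """Rank of the below-species epithet, if any."""

    NONE = "none"
    VARIETY = "variety"
    CULTIVAR = "cultivar"


@dataclass(frozen=True)
class AccessionRecord:
    """One sampled plant entry with its taxonomic identity."""

    accession_id: str
    genus: str
    species: str
    infrataxon: str | None = None
    infrataxon_rank: InfrataxonRank = InfrataxonRank.NONE

    def __post_init__(self) -> None:
        has_infra = self.infrataxon is not None and self.infrataxon != ""
        if has_infra == (self.infrataxon_rank is InfrataxonRank.NONE):
            raise DataValidationError(
                f"accession {self.accession_id!r}: infrataxon "
                f"{self.infrataxon!r} inconsistent with rank "
                f"{self.infrataxon_rank.value!r}"
            )

    @property
    def binomial(self) -> str:
        return f"{self.genus} {self.species}"


@dataclass(frozen=True)
class MarkerDefinition:
    """A barcoding marker and its position in the composite code (H1..HM)."""

    marker_id: str
    marker_index: int  # 1-based position in the composite code


@dataclass
class MarkerPanel:
    """Accession x marker matrix of DNA sequences.

    ``sequences`` maps ``(accession_id, marker_id)`` to an uppercase DNA string
    over the IUPAC alphabet plus ``-``.  The matrix is complete: every cell is
    present (enforced on construction).
    """

    accessions: list[AccessionRecord]
    markers: list[MarkerDefinition]
    sequences: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [a.accession_id for a in self.accessions]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DataValidationError(f"duplicate accession_id(s): {', '.join(dup)}")
        idx = sorted(m.marker_index for m in self.markers)
        if idx != list(range(1, len(self.markers) + 1)):
            raise DataValidationError(
                f"marker_index values must be 1..{len(self.markers)}, got {idx}"
            )
        for acc in self.accessions:
            for mk in self.markers:
                key = (acc.accession_id, mk.marker_id)
                if key not in self.sequences:
                    raise DataValidationError(
                        f"missing sequence for accession {acc.accession_id!r}, "
                        f"marker {mk.marker_id!r}"
                    )

    @property
    def accession_ids(self) -> list[str]:
        return [a.accession_id for a in self.accessions]

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in sorted(self.markers, key=lambda m: m.marker_index)]

    def record(self, accession_id: str) -> AccessionRecord:
        for acc in self.accessions:
            if acc.accession_id == accession_id:
                return acc
        raise KeyError(accession_id)

    def sequence(self, accession_id: str, marker_id: str) -> str:
        return self.sequences[(accession_id, marker_id)]

    def ungapped_length(self, accession_id: str, marker_id: str) -> int:
        return len(self.sequence(accession_id, marker_id).replace("-", ""))


def clean_sequence(raw: str, *, context: str = "") -> str:
    """Uppercase, map U->T, and validate against the IUPAC+gap alphabet.

    ``context`` (file/record) prefixes the error message; bad characters are
    reported with their 1-based position.
    """
    seq = raw.upper().replace("U", "T")
    for pos, ch in enumerate(seq, start=1):
        if ch not in IUPAC_CHARS:
            where = f"{context}, " if context else ""
            raise DataValidationError(
                f"{where}position {pos}: character {ch!r} is not an IUPAC "
                "nucleotide code or '-'"
            )
    return seq


def read_taxonomy(taxonomy_path: str | Path) -> list[AccessionRecord]:
    """Read the tab-separated taxonomy table (header row required)."""
    path = Path(taxonomy_path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise DataValidationError(f"{path}: empty taxonomy file")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != TAXONOMY_COLUMNS:
        raise DataValidationError(
            f"{path}: expected header {list(TAXONOMY_COLUMNS)}, got {list(header)}"
        )
    records: list[AccessionRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(TAXONOMY_COLUMNS):
            raise DataValidationError(
                f"{path}:{lineno}: expected {len(TAXONOMY_COLUMNS)} columns, "
                f"got {len(parts)}"
            )
        acc_id, genus, species, infra, rank = (p.strip() for p in parts)
        records.append(
            AccessionRecord(
                accession_id=acc_id,
                genus=genus,
                species=species,
                infrataxon=infra or None,
                infrataxon_rank=InfrataxonRank(rank or "none"),
            )
        )
    if not records:
        raise DataValidationError(f"{path}: taxonomy table has no data rows")
    return records


def read_panel(
    fasta_paths: Mapping[str, str | Path], taxonomy_path: str | Path
) -> MarkerPanel:
    """Assemble a :class:`MarkerPanel` from per-marker FASTA files + taxonomy.

    FASTA record IDs are the join key and must match taxonomy ``accession_id``
    verbatim (description after the first whitespace is ignored).  Marker order
    in the composite code follows the iteration order of ``fasta_paths``.
    """
    accessions = read_taxonomy(taxonomy_path)
    wanted = {a.accession_id for a in accessions}
    markers = [
        MarkerDefinition(marker_id=mid, marker_index=i)
        for i, mid in enumerate(fasta_paths, start=1)
    ]
    sequences: dict[tuple[str, str], str] = {}
    for mid, fpath in fasta_paths.items():
        seen: set[str] = set()
        for rec in SeqIO.parse(str(fpath), "fasta"):
            if rec.id in seen:
                raise DataValidationError(
                    f"{fpath}: duplicate record ID {rec.id!r} for marker {mid!r}"
                )
            seen.add(rec.id)
            if rec.id not in wanted:
                raise DataValidationError(
                    f"{fpath}: record {rec.id!r} not listed in the taxonomy table"
                )
            sequences[(rec.id, mid)] = clean_sequence(
                str(rec.seq), context=f"{fpath}, record {rec.id!r}"
            )
        missing = sorted(wanted - seen)
        if missing:
            raise DataValidationError(
                f"accession(s) {', '.join(missing)} listed in the taxonomy table "
                f"but absent from the {mid!r} FASTA ({fpath})"
            )
    return MarkerPanel(accessions=accessions, markers=markers, sequences=sequences)


def write_panel(panel: MarkerPanel, out_dir: str | Path) -> set[Path]:
    """Write one FASTA per marker plus ``taxonomy.tsv``; inverse of read_panel."""
    if not panel.accessions:
        raise DataValidationError("cannot write an empty panel (0 accessions)")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: set[Path] = set()

    tax_path = out / "taxonomy.tsv"
    rows = ["\t".join(TAXONOMY_COLUMNS)]
    for acc in panel.accessions:
        rows.append(
            "\t".join(
                [
                    acc.accession_id,
                    acc.genus,
                    acc.species,
                    acc.infrataxon or "",
                    acc.infrataxon_rank.value,
                ]
            )
        )
    tax_path.write_text("\n".join(rows) + "\n", encoding="utf-8", newline="\n")
    written.add(tax_path)

    for mk in sorted(panel.markers, key=lambda m: m.marker_index):
        fpath = out / f"{_safe_filename(mk.marker_id)}.fasta"
        records = [
            SeqRecord(
                Seq(panel.sequence(acc.accession_id, mk.marker_id)),
                id=acc.accession_id,
                description="",
            )
            for acc in panel.accessions
        ]
        with open(fpath, "w", encoding="utf-8", newline="\n") as handle:
            SeqIO.write(records, handle, "fasta")
        written.add(fpath)
    return written


def marker_fasta_paths(panel: MarkerPanel, out_dir: str | Path) -> dict[str, Path]:
    """Paths write_panel uses for each marker, keyed by marker_id in code order."""
    out = Path(out_dir)
    return {
        mk.marker_id: out / f"{_safe_filename(mk.marker_id)}.fasta"
        for mk in sorted(panel.markers, key=lambda m: m.marker_index)
    }


def _safe_filename(marker_id: str) -> str:
    return "".join(c if c.isalnum() or c in "._" else "-" for c in marker_id)


def subset_panel(panel: MarkerPanel, accession_ids: Iterable[str]) -> MarkerPanel:
    """Restrict a panel to the given accessions, preserving panel order."""
    keep = set(accession_ids)
    unknown = keep - set(panel.accession_ids)
    if unknown:
        raise DataValidationError(f"unknown accession(s): {', '.join(sorted(unknown))}")
    accs = [a for a in panel.accessions if a.accession_id in keep]
    seqs = {
        (a.accession_id, m.marker_id): panel.sequence(a.accession_id, m.marker_id)
        for a in accs
        for m in panel.markers
    }
    return MarkerPanel(accessions=accs, markers=list(panel.markers), sequences=seqs)
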