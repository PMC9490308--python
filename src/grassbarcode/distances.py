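"""Pairwise evolutionary distances on aligned sequences.

Supported models: raw proportion of differing sites (p-distance), raw count of
differing sites (number of differences), and the Kimura two-parameter (K2P)
correction, optionally with gamma-distributed rate variation across sites.
All models use *pairwise deletion*: for each sequence pair, alignment sites
where either sequence carries a gap or a non-ACGT (ambiguous) character are
excluded before counting.

K2P separates transitions (A<->G, C<->T; proportion P) from transversions
(proportion Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

and, with gamma shape parameter a,

    d = a/2 [ (1 - 2P - Q)^(-1/a) + 1/2 (1 - 2Q)^(-1/a) - 3/2 ].

When 1 - 2P - Q <= 0 or 1 - 2Q <= 0 the correction diverges (saturation); the
pair is flagged undefined rather than clamped, and tree building refuses
matrices with undefined entries.

A gamma correction of a raw difference *count* is not mathematically
meaningful (the correction acts on per-site divergence); ``num_diff`` ignores
any gamma shape and says so here rather than silently transforming the count.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ComputationError, DataValidationError

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
UNAMBIGUOUS = frozenset("ACGT")


class DistanceModel(str, enum.Enum):
    P_DISTANCE = "p"
    NUM_DIFF = "num_diff"
    K2P = "k2p"
    K2P_GAMMA = "k2p_gamma"
    NUM_DIFF_GAMMA = "num_diff_gamma"  # gamma ignored for raw counts


@dataclass(frozen=True)
class AlignedBlock:
    """An equal-length (aligned) set of sequences for one marker."""

    accession_ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.accession_ids) != len(self.sequences):
            raise DataValidationError("accession_ids and sequences length mismatch")
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise DataValidationError("duplicate accession_ids in aligned block")
        if not self.sequences:
            raise DataValidationError("empty aligned block")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise DataValidationError(
                f"aligned sequences must share one length, got {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n(self) -> int:
        return len(self.sequences)

    def sequence(self, accession_id: str) -> str:
        return self.sequences[self.accession_ids.index(accession_id)]


@dataclass(frozen=True)
class PairSites:
    """Comparable-site summary of one sequence pair under pairwise deletion."""

    n: int  # comparable sites
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.n

    @property
    def Q(self) -> float:
        return self.transversions / self.n

    @property
    def num_diff(self) -> int:
        return self.transitions + self.transversions

    @property
    def p_distance(self) -> float:
        return self.num_diff / self.n


def pairwise_sites(a: str, b: str) -> PairSites:
    """Count comparable sites, transitions and transversions for one pair.

    Raises :class:`ComputationError` when no site is comparable (n = 0).
    """
    if len(a) != len(b):
        raise DataValidationError(
            f"sequences must be equal length, got {len(a)} and {len(b)}"
        )
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in UNAMBIGUOUS or y not in UNAMBIGUOUS:
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES and y in PURINES) or (x in PYRIMIDINES and y in PYRIMIDINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ComputationError("no comparable sites in pair (pairwise deletion)")
    return PairSites(n=n, transitions=ts, transversions=tv)


def k2p_distance(P: float, Q: float, gamma_shape: float | None = None) -> float:
    """Kimura two-parameter distance from transition/transversion proportions.

    Raises :class:`ComputationError` at saturation (log/power arguments <= 0).
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise ComputationError(
            f"K2P undefined (saturation): 1-2P-Q={w1:.4g}, 1-2Q={w2:.4g}"
        )
    if gamma_shape is None:
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    a = float(gamma_shape)
    if a <= 0:
        raise DataValidationError(f"gamma shape must be positive, got {a}")
    return (a / 2.0) * (w1 ** (-1.0 / a) + 0.5 * w2 ** (-1.0 / a) - 1.5)


def num_differences(a: str, b: str) -> int:
    """Count of comparable sites where the two sequences differ."""
    return pairwise_sites(a, b).num_diff


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair comparable-site counts.

    Undefined (saturated or incomparable) pairs hold NaN in ``values``.
    """

    accession_ids: tuple[str, ...]
    values: np.ndarray  # (n, n) float, NaN where undefined
    model: DistanceModel
    gamma_shape: float | None
    site_counts: np.ndarray  # (n, n) int, comparable sites per pair

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    @property
    def has_undefined(self) -> bool:
        return bool(np.isnan(self.values).any())

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if math.isnan(self.values[i, j]):
                    out.append((self.accession_ids[i], self.accession_ids[j]))
        return out

    def value(self, a: str, b: str) -> float:
        i = self.accession_ids.index(a)
        j = self.accession_ids.index(b)
        return float(self.values[i, j])


def _pair_distance(
    pair: PairSites, model: DistanceModel, gamma_shape: float | None
) -> float:
    if model is DistanceModel.P_DISTANCE:
        return pair.p_distance
    if model in (DistanceModel.NUM_DIFF, DistanceModel.NUM_DIFF_GAMMA):
        return float(pair.num_diff)
    if model is DistanceModel.K2P:
        return k2p_distance(pair.P, pair.Q)
    if model is DistanceModel.K2P_GAMMA:
        shape = 1.0 if gamma_shape is None else gamma_shape
        return k2p_distance(pair.P, pair.Q, gamma_shape=shape)
    raise DataValidationError(f"unknown model {model!r}")


def distance_matrix(
    block: AlignedBlock,
    model: DistanceModel | str = DistanceModel.K2P,
    gamma_shape: float | None = None,
) -> DistanceMatrix:
    """All-pairs distances on an aligned block; undefined pairs flagged NaN."""
    model = DistanceModel(model)
    if block.n < 2:
        raise DataValidationError("distance matrix requires at least 2 sequences")
    n = block.n
    values = np.zeros((n, n), dtype=float)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        counts[i, i] = sum(1 for c in block.sequences[i] if c in UNAMBIGUOUS)
        for j in range(i + 1, n):
            try:
                pair = pairwise_sites(block.sequences[i], block.sequences[j])
                d = _pair_distance(pair, model, gamma_shape)
                counts[i, j] = counts[j, i] = pair.n
            except ComputationError:
                d = math.nan
            values[i, j] = values[j, i] = d
    return DistanceMatrix(
        accession_ids=block.accession_ids,
        values=values,
        model=model,
        gamma_shape=(
            gamma_shape
            if model in (DistanceModel.K2P_GAMMA,)
            else None
        ),
        site_counts=counts,
    )


def write_phylip(matrix: DistanceMatrix, path: str | Path) -> Path:
    """PHYLIP-style square distance matrix (NaN written as 'NA')."""
    lines = [f"{matrix.n}"]
    for i, name in enumerate(matrix.accession_ids):
        vals = []
        for j in range(matrix.n):
            v = matrix.values[i, j]
            vals.append("NA" if math.isnan(v) else f"{v:.6f}")
        lines.append(f"{name}\t" + "\t".join(vals))
    out = Path(path)
    out.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return out


def write_long_format(matrix: DistanceMatrix, path: str | Path) -> Path:
    """Tab-separated long format: id_a, id_b, distance, comparable_sites."""
    lines = ["id_a\tid_b\tdistance\tcomparable_sites"]
    for i in range(matrix.n):
        for j in range(i + 1, matrix.n):
            v = matrix.values[i, j]
            val = "NA" if math.isnan(v) else f"{v:.6f}"
            lines.append(
                f"{matrix.accession_ids[i]}\t{matrix.accession_ids[j]}\t{val}\t"
                f"{matrix.site_counts[i, j]}"
            )
    out = Path(path)
    out.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return out


def block_from_sequences(
    accession_ids: Sequence[str], sequences: Sequence[str]
) -> AlignedBlock:
    return AlignedBlock(tuple(accession_ids), tuple(sequences))


def blocks_from_panel(panel) -> dict[str, AlignedBlock]:
    """Per-marker aligned blocks from a panel whose sequences are pre-aligned.

    Requires equal gapped lengths per marker (the panel stores alignments, as
    the fixture and simulator emit); raises otherwise.
    """
    out: dict[str, AlignedBlock] = {}
    ids = tuple(panel.accession_ids)
    for mid in panel.marker_ids:
        seqs = tuple(panel.sequence(aid, mid) for aid in ids)
        if len({len(s) for s in seqs}) != 1:
            raise DataValidationError(
                f"marker {mid!r}: sequences are not aligned (unequal lengths); "
                "provide a pre-aligned panel for distance/tree stages"
            )
        out[mid] = AlignedBlock(accession_ids=ids, sequences=seqs)
    return out
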