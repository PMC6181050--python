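"""Protein sequence handling: FASTA I/O, monoisotopic masses, carbon
counting and tryptic digestion.

All masses are monoisotopic and expressed in daltons.  Sequences are taken
to be *mature* polypeptides (transit peptides already removed), written in
the 20 canonical one-letter codes.  Isoleucine and leucine are kept as
distinct letters but share a residue mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "WATER",
    "PROTON",
    "RESIDUE_MASS",
    "RESIDUE_CARBONS",
    "MET_OXIDATION",
    "ProteinRecord",
    "Peptide",
    "read_fasta",
    "write_fasta",
    "carbon_count",
    "peptide_mono_mass",
    "digest",
]

# Monoisotopic constants (Da)
WATER = 18.010565
PROTON = 1.00727646
MET_OXIDATION = 15.994915

# Monoisotopic residue (amino-acid minus water) masses, Da.
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

# Carbon atoms per residue (identical for the free amino acid: the water
# lost on condensation carries no carbon).
RESIDUE_CARBONS = {
    "G": 2, "A": 3, "S": 3, "P": 5, "V": 5, "T": 4, "C": 3, "L": 6,
    "I": 6, "N": 4, "D": 4, "Q": 5, "K": 6, "E": 5, "M": 5, "H": 6,
    "F": 9, "R": 6, "Y": 9, "W": 11,
}

CANONICAL = frozenset(RESIDUE_MASS)


def _validate_sequence(sequence: str, context: str = "sequence") -> None:
    bad = sorted(set(sequence) - CANONICAL)
    if bad:
        raise ValueError(
            f"non-canonical residue(s) {','.join(bad)} in {context!r}"
        )


@dataclass(frozen=True)
class ProteinRecord:
    """A mature protein sequence with its database identifier."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.id!r}")
        _validate_sequence(self.sequence, self.id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide located in its parent protein.

    ``start``/``end`` are 1-based inclusive residue positions in the mature
    protein.  ``modifications`` is a tuple of ``(position, delta_da, name)``
    with 1-based positions inside the peptide.
    """

    protein_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int = 0
    modifications: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide positions inconsistent with sequence length")
        for pos, _delta, _name in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside peptide of length "
                    f"{len(self.sequence)}"
                )

    @property
    def mass(self) -> float:
        return peptide_mono_mass(
            self.sequence, [(p, d) for p, d, _ in self.modifications]
        )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA database into :class:`ProteinRecord` objects.

    The record id is the first whitespace-separated token of the header.
    Duplicate ids and non-canonical residues are rejected.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(entry.id, entry.description, seq))
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def carbon_count(sequence: str) -> int:
    """Total carbon atoms of the intact polypeptide.

    The condensation water contains no carbon, so the count is simply the
    sum over residue formulas; the empty sequence has zero carbons.
    """
    _validate_sequence(sequence)
    return sum(RESIDUE_CARBONS[aa] for aa in sequence)


def peptide_mono_mass(sequence: str, modifications=()) -> float:
    """Neutral monoisotopic mass of a (modified) peptide.

    ``modifications`` is an iterable of ``(position, delta_da)`` pairs with
    1-based positions inside the peptide.
    """
    _validate_sequence(sequence)
    mass = WATER + sum(RESIDUE_MASS[aa] for aa in sequence)
    for pos, delta in modifications:
        if not 1 <= pos <= len(sequence):
            raise ValueError(
                f"modification position {pos} outside peptide of length {len(sequence)}"
            )
        mass += delta
    return mass


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cuts between i and i+1.

    Trypsin cuts after K or R except when the next residue is P.
    """
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein: ProteinRecord,
    max_missed: int = 0,
    min_len: int = 1,
    max_len: int = 100,
) -> list[Peptide]:
    """Tryptic digestion with missed cleavages.

    Emits every peptide whose boundaries are valid cleavage sites (or the
    protein termini) and which contains at most ``max_missed`` internal
    uncut sites, filtered to ``min_len <= length <= max_len``.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    sites = cleavage_sites(seq)
    # segment boundaries: 0-based start indices of fully cleaved fragments
    bounds = [0] + [i + 1 for i in sites] + [len(seq)]
    peptides: list[Peptide] = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + max_missed + 2, len(bounds))):
            start, end = bounds[a], bounds[b]
            if not min_len <= end - start <= max_len:
                continue
            peptides.append(
                Peptide(
                    protein_id=protein.id,
                    start=start + 1,
                    end=end,
                    sequence=seq[start:end],
                    missed_cleavages=b - a - 1,
                )
            )
    return peptides
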