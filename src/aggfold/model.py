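"""Peptide sequences and residue-level physicochemical classification.

The package analyses short cationic antimicrobial peptides.  Everything
downstream (SASA decomposition, contact statistics, charge arithmetic) is
driven by two small pieces of information per residue: its identity and its
physicochemical class (hydrophobic / polar / charged).  This module owns
both.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

__all__ = [
    "PeptideSequence",
    "ResidueClassScheme",
    "parse_sequence",
    "read_fasta_sequence",
    "composition",
    "net_charge",
    "classify_residues",
    "default_class_scheme",
    "BOMBININ_H2",
    "STANDARD_AA",
    "THREE_LETTER",
    "ONE_LETTER",
]

STANDARD_AA: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

THREE_LETTER: dict[str, str] = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
ONE_LETTER: dict[str, str] = {v: k for k, v in THREE_LETTER.items()}

# Average side-chain masses in Da (residue mass minus the Gly backbone unit);
# used for mass-weighted compactness measures on the reduced representation.
SIDECHAIN_MASS: dict[str, float] = {
    "A": 15.03, "C": 47.10, "D": 59.04, "E": 73.07, "F": 91.13,
    "G": 1.01, "H": 81.10, "I": 57.11, "K": 72.13, "L": 57.11,
    "M": 75.15, "N": 58.06, "P": 42.08, "Q": 72.09, "R": 100.14,
    "S": 31.03, "T": 45.06, "V": 43.09, "W": 130.17, "Y": 107.13,
}

# Formal charges at neutral pH: Lys/Arg +1, Asp/Glu -1, His neutral.
_SIDECHAIN_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}


@dataclass(frozen=True)
class PeptideSequence:
    """An ordered peptide sequence of one-letter amino-acid codes."""

    residues: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise ValueError("a peptide sequence must contain at least one residue")
        for code in self.residues:
            if code not in STANDARD_AA:
                raise ValueError(
                    f"non-standard amino-acid code {code!r}; expected one of the "
                    "20 standard one-letter codes"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def __getitem__(self, i):
        return self.residues[i]

    def __str__(self) -> str:
        return "".join(self.residues)


def parse_sequence(text: str, name: str = "") -> PeptideSequence:
    """Parse a one-letter-code string (whitespace tolerated) into a sequence.

    Raises ``ValueError`` on empty input or the first non-standard code,
    naming the offending character.
    """
    cleaned = "".join(text.split()).upper()
    if not cleaned:
        raise ValueError("empty sequence")
    return PeptideSequence(tuple(cleaned), name=name)


def read_fasta_sequence(path: str | Path) -> PeptideSequence:
    """Read a single-record FASTA file into a :class:`PeptideSequence`."""
    from Bio import SeqIO

    record = SeqIO.read(str(path), "fasta")
    return parse_sequence(str(record.seq), name=record.id)


#: The 20-residue bombinin H2 antimicrobial peptide from Bombina variegata.
BOMBININ_H2 = parse_sequence("IIGPVLGLVGSALGGLLKKI", name="bombinin_H2")


def composition(seq: PeptideSequence) -> tuple[dict[str, int], dict[str, float]]:
    """Per-residue-type counts and fractions.

    Returns ``(counts, fractions)``; counts sum to ``len(seq)`` and
    fractions sum to 1.
    """
    counts = dict(Counter(seq.residues))
    n = len(seq)
    fractions = {aa: c / n for aa, c in counts.items()}
    return counts, fractions


def net_charge(seq: PeptideSequence) -> int:
    """Formal net charge at neutral pH, in elementary charges.

    Convention: Lys/Arg +1, Asp/Glu -1, His 0, free N-terminus +1, free
    C-terminus -1.  No pKa model — formal charges only.
    """
    side = sum(_SIDECHAIN_CHARGE.get(aa, 0) for aa in seq)
    return side + 1 - 1


class ResidueClassScheme:
    """Total mapping from residue code to {hydrophobic, polar, charged}.

    The default partition puts Gly and Pro with the hydrophobic residues:
    for Gly/Pro-rich peptides such as bombinin the burial of these residues
    accounts for essentially the whole hydrophobic-surface loss on
    aggregation, so grouping them with the aliphatics keeps the class-
    decomposed SASA interpretable.  Override via the constructor if a
    different partition is wanted.
    """

    CLASSES = ("hydrophobic", "polar", "charged")

    def __init__(self, mapping: Mapping[str, str]):
        missing = STANDARD_AA - set(mapping)
        if missing:
            raise ValueError(
                f"class scheme must cover all 20 standard residues; missing "
                f"{sorted(missing)}"
            )
        bad = {aa: cls for aa, cls in mapping.items() if cls not in self.CLASSES}
        if bad:
            raise ValueError(f"unknown residue classes: {bad}")
        self._mapping = dict(mapping)

    def __getitem__(self, code: str) -> str:
        return self._mapping[code]

    def classify(self, seq: PeptideSequence) -> tuple[str, ...]:
        return tuple(self._mapping[aa] for aa in seq)


def default_class_scheme() -> ResidueClassScheme:
    """Default hydrophobic / polar / charged partition (Gly, Pro hydrophobic)."""
    mapping: dict[str, str] = {}
    for aa in "KRDE":
        mapping[aa] = "charged"
    for aa in "STNQCYHW":
        mapping[aa] = "polar"
    for aa in "AVLIMFPG":
        mapping[aa] = "hydrophobic"
    return ResidueClassScheme(mapping)


def classify_residues(
    seq: PeptideSequence, scheme: ResidueClassScheme | None = None
) -> tuple[str, ...]:
    """One class label per residue, in sequence order."""
    if scheme is None:
        scheme = default_class_scheme()
    return scheme.classify(seq)
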