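"""Aligned marker sequences with ambiguity-aware state sets.

Characters are interpreted over the five-state alphabet {A, C, G, T, -}:
the gap is an alignable indel state (informative in ribosomal markers such
as 16S/ITS1/28S), IUPAC ambiguity codes expand to polymorphic subsets, and
``?``/``N`` mean complete uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

STATES = ("A", "C", "G", "T", "-")

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "U": frozenset("T"), "-": frozenset("-"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT-"), "?": frozenset("ACGT-"),
}


def state_set(char: str) -> frozenset[str]:
    """Expand one alignment character to its non-empty state set."""
    try:
        return IUPAC[char.upper()]
    except KeyError:
        raise ValueError(f"unknown alignment character {char!r}") from None


@dataclass
class AlignmentSet:
    """One marker's alignment plus the terminal-to-species map.

    Parameters
    ----------
    marker
        Marker name (16S, COI, ITS1, 28S, ...).
    sequences
        Terminal label -> aligned sequence string; all equal length.
    species_map
        Terminal label -> species label.  Every mapped terminal must be in
        the alignment.
    """

    marker: str
    sequences: dict[str, str]
    species_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"marker {self.marker}: unequal sequence lengths {sorted(lengths)}")
        missing = [t for t in self.species_map if t not in self.sequences]
        if missing:
            raise ValueError(f"marker {self.marker}: mapped terminals absent from alignment: {missing}")
        for term, seq in self.sequences.items():
            for ch in seq:
                if ch.upper() not in IUPAC:
                    raise ValueError(f"marker {self.marker}, terminal {term}: bad character {ch!r}")

    @property
    def terminals(self) -> list[str]:
        return list(self.sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def column(self, position: int) -> dict[str, frozenset[str]]:
        """State sets of one 0-based alignment column."""
        if not 0 <= position < self.length:
            raise IndexError(f"position {position} outside alignment of length {self.length}")
        return {t: state_set(s[position]) for t, s in self.sequences.items()}

    def species_terminals(self, species: str) -> list[str]:
        return [t for t, sp in self.species_map.items() if sp == species]

    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp in self.species_map.values():
            seen.setdefault(sp, None)
        return list(seen)

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        marker: str | None = None,
        species_map: dict[str, str] | str | Path | None = None,
    ) -> "AlignmentSet":
        """Read a FASTA alignment; species map from a dict or a two-column CSV
        (``terminal_id, species``)."""
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise ValueError(f"no sequences in {path}")
        if isinstance(species_map, (str, Path)):
            species_map = read_species_map(species_map)
        return cls(
            marker=marker or Path(path).stem,
            sequences=records,
            species_map=dict(species_map or {}),
        )

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for term, seq in self.sequences.items():
                fh.write(f">{term}\n{seq}\n")


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a ``terminal_id, species`` CSV."""
    df = pd.read_csv(path, dtype=str)
    if not {"terminal_id", "species"} <= set(df.columns):
        raise ValueError(f"species map {path} needs columns terminal_id, species")
    return dict(zip(df["terminal_id"], df["species"]))


def write_species_map(species_map: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"terminal_id": list(species_map), "species": list(species_map.values())}
    ).to_csv(path, index=False)
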