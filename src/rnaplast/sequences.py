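"""RNA sequence container and input normalization.

Sequences are normalized on construction: DNA thymine is converted to
uracil and case is folded to upper case, so downstream thermodynamic code
only ever sees the alphabet {A, C, G, U}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_RESIDUES = frozenset("ACGU")

#: Watson-Crick partners (wobble G:U deliberately excluded).
WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class SequenceError(ValueError):
    """Raised for malformed sequence input (illegal residues, empty sequence)."""


def normalize_residues(raw: str, *, label: str = "") -> str:
    """Uppercase, convert T to U, and validate the alphabet.

    Raises :class:`SequenceError` naming the first offending position if a
    non-ACGUT symbol remains after normalization.
    """
    s = raw.strip().upper().replace("T", "U")
    if not s:
        raise SequenceError(f"empty sequence{' for ' + label if label else ''}")
    for pos, ch in enumerate(s, start=1):
        if ch not in VALID_RESIDUES:
            where = f" in record '{label}'" if label else ""
            raise SequenceError(
                f"illegal residue {ch!r} at position {pos}{where}; "
                "expected A/C/G/U (T is accepted and converted to U)"
            )
    return s


@dataclass(frozen=True)
class RnaSequence:
    """An identified RNA sequence over {A, C, G, U}.

    Parameters
    ----------
    id : str
        Record label (FASTA id or a generated identifier).
    residues : str
        Sequence text; normalized (T->U, uppercased) and validated.
    """

    id: str
    residues: str = field()

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_residues(self.residues, label=self.id))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def reverse_complement(residues: str) -> str:
    """Watson-Crick reverse complement of an RNA string."""
    return "".join(WC_COMPLEMENT[b] for b in reversed(residues))
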