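"""Point-substitution specifications in one-letter notation (e.g. C40S)."""

from __future__ import annotations

from dataclasses import dataclass

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MutationSpec:
    """One substitution: wild-type letter, author residue number, mutant letter.

    Identity "substitutions" (wt == mut) are permitted as a degenerate case
    with ΔΔG defined as 0; saturation screens never enumerate them.
    """

    position: int
    wt: str
    mut: str

    def __post_init__(self) -> None:
        for letter, what in ((self.wt, "wild-type"), (self.mut, "mutant")):
            if letter not in AA_ALPHABET:
                raise ValueError(f"{what} letter {letter!r} is not a standard amino acid")
        if self.position < 1:
            raise ValueError("residue number must be positive")

    @classmethod
    def from_string(cls, text: str) -> "MutationSpec":
        """Parse notation like ``C40S``."""
        text = text.strip()
        if len(text) < 3 or not text[1:-1].isdigit():
            raise ValueError(f"cannot parse mutation {text!r}; expected e.g. 'C40S'")
        return cls(position=int(text[1:-1]), wt=text[0].upper(), mut=text[-1].upper())

    @property
    def is_identity(self) -> bool:
        return self.wt == self.mut

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"
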