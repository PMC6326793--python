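"""Degenerate-nucleotide motif patterns for 3'-UTR cis-elements.

The three element classes handled by the package are the polyadenylation
signal (PAS, canonical hexamer AATAAA in DNA sense), the cytoplasmic
polyadenylation element (CPE, a U-rich consensus written here in the DNA
alphabet as T4-5 A1-2 T) and the Pumilio-binding element (PBE, TGTANATA).
Patterns are plain IUPAC strings matched on the mRNA-sense strand only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "IUPAC",
    "MotifPattern",
    "default_patterns",
    "ELEMENT_CLASSES",
]

ELEMENT_CLASSES = ("PAS", "CPE", "PBE")

#: IUPAC nucleotide codes mapped to the set of concrete bases they stand for.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class MotifPattern:
    """A named degenerate-nucleotide pattern with an element class.

    Parameters
    ----------
    name:
        Short identifier, e.g. ``"PAS-canonical"``.
    element_class:
        One of ``"PAS"``, ``"CPE"``, ``"PBE"``.  PBE patterns are
        annotate-only: the rule engine records them but attaches no effect.
    pattern:
        IUPAC string over the mRNA sense strand, length >= 4.
    """

    name: str
    element_class: str
    pattern: str

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(
                f"element_class must be one of {ELEMENT_CLASSES}, "
                f"got {self.element_class!r}"
            )
        if len(self.pattern) < 4:
            raise ValueError(f"pattern {self.pattern!r} shorter than 4 nt")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"pattern {self.pattern!r} has non-IUPAC codes {sorted(bad)}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)

    def matches_at(self, sequence: str, pos: int) -> bool:
        """True if the pattern matches ``sequence[pos:pos+len]`` exactly."""
        if pos < 0 or pos + len(self.pattern) > len(sequence):
            return False
        return all(
            sequence[pos + i] in IUPAC[c] for i, c in enumerate(self.pattern)
        )

    def to_regex(self) -> re.Pattern[str]:
        """Compile to a lookahead regex that reports overlapping matches."""
        body = "".join(
            c if len(IUPAC[c]) == 1 else "[" + "".join(sorted(IUPAC[c])) + "]"
            for c in self.pattern
        )
        return re.compile(f"(?=({body}))")


def default_patterns(
    include_attaaa_variant: bool = False,
) -> list[MotifPattern]:
    """The default motif set.

    PAS defaults to the canonical AATAAA hexamer only; the common ATTAAA
    variant is shipped but disabled by default so that element counts on the
    packaged UTR architectures match the counts the reporter study worked
    with.  The CPE set is the T4-5 A1-2 T consensus family; the PBE is
    TGTANATA and is annotated but carries no rule-engine effect.
    """
    pats = [MotifPattern("PAS-canonical", "PAS", "AATAAA")]
    if include_attaaa_variant:
        pats.append(MotifPattern("PAS-ATTAAA", "PAS", "ATTAAA"))
    pats += [
        MotifPattern("CPE-TTTTAT", "CPE", "TTTTAT"),
        MotifPattern("CPE-TTTTAAT", "CPE", "TTTTAAT"),
        MotifPattern("CPE-TTTTTAT", "CPE", "TTTTTAT"),
        MotifPattern("CPE-TTTTTAAT", "CPE", "TTTTTAAT"),
        MotifPattern("PBE-TGTANATA", "PBE", "TGTANATA"),
    ]
    return pats
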