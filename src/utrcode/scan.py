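"""Scan 3'-UTR sequences into cis-element architectures.

A `UtrArchitecture` is the ordered set of PAS/CPE/PBE occurrences on one
UTR; it is the object the rule engine consumes.  Scanning is exhaustive on
the sense strand: every substring matching any active pattern is reported,
and overlapping matches of the same element class are merged into one
element spanning their union (the code counts discrete elements, not raw
pattern hits).  Labels (PAS1, CPE3, ...) are ordinals assigned 5'->3'
within each class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .motifs import ELEMENT_CLASSES, MotifPattern

__all__ = [
    "UtrRecord",
    "CisElement",
    "UtrArchitecture",
    "scan_motifs",
    "gap_distance",
    "build_architecture",
]


@dataclass(frozen=True)
class UtrRecord:
    """A 3'-UTR sequence, stored internally in the DNA alphabet (sense strand)."""

    id: str
    sequence: str
    source_alphabet: str = "DNA"  # "DNA" or "RNA" as provided on input

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        seq = self.sequence.upper().replace("U", "T")
        for off, ch in enumerate(seq):
            if ch not in "ACGTN":
                raise ValueError(
                    f"record {self.id!r}: non-nucleotide character {ch!r} at offset {off}"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CisElement:
    """One motif occurrence: 0-based half-open coordinates on the UTR."""

    element_class: str
    start: int
    end: int
    matched_seq: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(f"unknown element class {self.element_class!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def overlaps(self, other: "CisElement") -> bool:
        return self.start < other.end and other.start < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class UtrArchitecture:
    """An ordered, labeled, merged set of cis-elements on a UTR."""

    utr_id: str
    utr_length: int
    elements: tuple[CisElement, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for el in self.elements:
            if el.end > self.utr_length:
                raise ValueError(
                    f"{self.utr_id}: element [{el.start},{el.end}) outside UTR "
                    f"of length {self.utr_length}"
                )
        object.__setattr__(
            self, "elements", tuple(sorted(self.elements, key=lambda e: (e.start, e.end)))
        )

    def of_class(self, element_class: str) -> tuple[CisElement, ...]:
        return tuple(e for e in self.elements if e.element_class == element_class)

    @property
    def pas(self) -> tuple[CisElement, ...]:
        return self.of_class("PAS")

    @property
    def cpe(self) -> tuple[CisElement, ...]:
        return self.of_class("CPE")

    @property
    def pbe(self) -> tuple[CisElement, ...]:
        return self.of_class("PBE")

    def get(self, label: str) -> CisElement:
        for el in self.elements:
            if el.label == label:
                return el
        raise KeyError(f"{self.utr_id}: no element labeled {label!r}")

    def counts(self) -> dict[str, int]:
        return {c: len(self.of_class(c)) for c in ELEMENT_CLASSES}


def _merge_same_class(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of overlapping intervals (sorted input not required)."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _label(elements: list[CisElement]) -> list[CisElement]:
    """Assign 5'->3' ordinals per class (PAS1, PAS2, ... CPE1, ...)."""
    out: list[CisElement] = []
    counters = {c: 0 for c in ELEMENT_CLASSES}
    for el in sorted(elements, key=lambda e: (e.start, e.end)):
        counters[el.element_class] += 1
        out.append(replace(el, label=f"{el.element_class}{counters[el.element_class]}"))
    return out


def scan_motifs(
    record: UtrRecord, patterns: list[MotifPattern]
) -> list[CisElement]:
    """Find every pattern occurrence on the sense strand of ``record``.

    Overlapping matches of the same element class are merged into a single
    element spanning their union; cross-class overlaps are kept separate.
    Output is sorted by position with per-class ordinal labels and is a
    pure function of the input.
    """
    if not patterns:
        raise ValueError("patterns must be non-empty")
    seq = record.sequence
    by_class: dict[str, list[tuple[int, int]]] = {c: [] for c in ELEMENT_CLASSES}
    for pat in patterns:
        rx = pat.to_regex()
        for m in rx.finditer(seq):
            s = m.start()
            by_class[pat.element_class].append((s, s + len(pat)))
    elements = [
        CisElement(cls, s, e, matched_seq=seq[s:e])
        for cls, ivals in by_class.items()
        for s, e in _merge_same_class(ivals)
    ]
    return _label(elements)


def gap_distance(a: CisElement, b: CisElement) -> int:
    """Spacer length in nt strictly between two non-overlapping elements.

    Adjacent motifs have gap 0.  Symmetric in argument order; overlapping
    elements raise ``ValueError``.
    """
    if a.overlaps(b):
        raise ValueError(
            f"elements [{a.start},{a.end}) and [{b.start},{b.end}) overlap"
        )
    up, down = (a, b) if a.start < b.start else (b, a)
    return down.start - up.end


def build_architecture(
    record: UtrRecord, elements: list[CisElement]
) -> UtrArchitecture:
    """Assemble a sorted, labeled, merged architecture from scanned elements.

    Idempotent: feeding an architecture's elements back in reproduces it.
    """
    for el in elements:
        if el.end > len(record):
            raise ValueError(
                f"{record.id}: element [{el.start},{el.end}) outside sequence "
                f"of length {len(record)}"
            )
    merged: list[CisElement] = []
    for cls in ELEMENT_CLASSES:
        ivals = [(e.start, e.end) for e in elements if e.element_class == cls]
        merged += [
            CisElement(cls, s, e, matched_seq=record.sequence[s:e])
            for s, e in _merge_same_class(ivals)
        ]
    return UtrArchitecture(record.id, len(record), tuple(_label(merged)))
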