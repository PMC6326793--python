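"""In-silico reporter mutagenesis: element mutations, spacer deletions,
CPE insertions and distal truncations on UTR sequences.

Every edit operates on a (record, architecture) pair, rewrites the
sequence, rescans with the active motif set, and verifies that the result
is exactly the expected architecture: untouched elements keep their
classes, lengths and pairwise gaps, and no motif is gained or lost beyond
the edit itself.  Where a junction created by an edit would form an
emergent motif, the operation deterministically repairs the adjacent
background base (or shifts the deletion window) and re-verifies.

The packaged construct set (`enumerate_reporter_constructs`) rebuilds the
full reporter mutagenesis matrix for the Cpeb1, Btg4 and Cnot6l 3'-UTRs.
The exact substitution used for CPE mutations in the original experiments
is not published; the central-T->G scheme here is this module's own
deterministic, length-preserving reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .motifs import MotifPattern, default_patterns
from .scan import (
    CisElement,
    UtrArchitecture,
    UtrRecord,
    build_architecture,
    gap_distance,
    scan_motifs,
)

__all__ = [
    "EditOp",
    "ConstructSpec",
    "mutate_pas",
    "mutate_cpe",
    "delete_spacer",
    "insert_cpe",
    "truncate_distal",
    "delete_pbe",
    "apply_construct",
    "enumerate_reporter_constructs",
    "PAS_MUTANT",
    "INSERTED_CPE",
]

#: the PAS knockout substitution used throughout the reporter experiments
PAS_MUTANT = "AAGGAA"
#: canonical CPE heptamer used for insertions (one of the consensus variants)
INSERTED_CPE = "TTTTAAT"

EDIT_KINDS = (
    "MUTATE_PAS",
    "MUTATE_CPE",
    "DELETE_SPACER",
    "INSERT_CPE",
    "TRUNCATE_DISTAL",
    "DELETE_PBE",
)

#: fixed fallback substitutions (motif-free scrambles) per element length
_SCRAMBLE = {5: "GACGC", 6: "GACGCA", 7: "GACGCAG", 8: "GACGCAGC"}


@dataclass(frozen=True)
class EditOp:
    """One edit: kind, target label(s), and an integer parameter.

    ``param`` is the remaining gap for DELETE_SPACER, the gap downstream of
    the PAS for INSERT_CPE, and the retained length for TRUNCATE_DISTAL.
    """

    kind: str
    target: str | tuple[str, str] | None = None
    param: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in EDIT_KINDS:
            raise ValueError(f"unknown edit kind {self.kind!r}")


@dataclass(frozen=True)
class ConstructSpec:
    """A named reporter construct: a base UTR plus an ordered edit list."""

    name: str
    base: str
    edits: tuple[EditOp, ...] = field(default_factory=tuple)


def _rescan(
    record: UtrRecord, patterns: list[MotifPattern]
) -> UtrArchitecture:
    return build_architecture(record, scan_motifs(record, patterns))


def _coords(arch: UtrArchitecture) -> set[tuple[str, int, int]]:
    return {(e.element_class, e.start, e.end) for e in arch.elements}


def _expected_after(
    arch: UtrArchitecture,
    drop: CisElement | None = None,
    shift_from: int | None = None,
    shift_by: int = 0,
    add: tuple[str, int, int] | None = None,
) -> set[tuple[str, int, int]]:
    """Element coordinate set expected after an edit: optionally drop one
    element, rigidly shift everything at/after ``shift_from``, add one."""
    out: set[tuple[str, int, int]] = set()
    for el in arch.elements:
        if drop is not None and el == drop:
            continue
        s, e = el.start, el.end
        if shift_from is not None and s >= shift_from:
            s, e = s + shift_by, e + shift_by
        out.add((el.element_class, s, e))
    if add is not None:
        out.add(add)
    return out


def _verified(
    record: UtrRecord,
    patterns: list[MotifPattern],
    expected: set[tuple[str, int, int]],
    what: str,
) -> tuple[UtrRecord, UtrArchitecture]:
    arch = _rescan(record, patterns)
    if _coords(arch) != expected:
        raise ValueError(
            f"{record.id}: {what} produced an unexpected element set "
            f"{sorted(_coords(arch) ^ expected)}"
        )
    return record, arch


def _edited(record: UtrRecord, sequence: str) -> UtrRecord:
    return UtrRecord(id=record.id, sequence=sequence, source_alphabet=record.source_alphabet)


def _get_labeled(arch: UtrArchitecture, label: str, element_class: str) -> CisElement:
    el = arch.get(label)  # KeyError if absent
    if el.element_class != element_class:
        raise ValueError(f"{label} is a {el.element_class}, expected {element_class}")
    return el


def mutate_pas(
    record: UtrRecord,
    arch: UtrArchitecture,
    label: str,
    patterns: list[MotifPattern] | None = None,
) -> tuple[UtrRecord, UtrArchitecture]:
    """Knock out one PAS by the in-place hexamer substitution AATAAA->AAGGAA.

    Length-preserving; the rescan verifies the edited site matches no
    active pattern and every other element is untouched.
    """
    patterns = default_patterns() if patterns is None else patterns
    el = _get_labeled(arch, label, "PAS")
    if len(el) != len(PAS_MUTANT):
        raise ValueError(
            f"{label} spans {len(el)} nt (merged match?); cannot substitute hexamer"
        )
    seq = record.sequence[: el.start] + PAS_MUTANT + record.sequence[el.end :]
    return _verified(
        _edited(record, seq), patterns, _expected_after(arch, drop=el), f"mutate {label}"
    )


def mutate_cpe(
    record: UtrRecord,
    arch: UtrArchitecture,
    label: str,
    patterns: list[MotifPattern] | None = None,
) -> tuple[UtrRecord, UtrArchitecture]:
    """Knock out one CPE by T->G at its three central positions
    (length-preserving); falls back to a fixed scramble if the central
    substitution leaves or creates a motif."""
    patterns = default_patterns() if patterns is None else patterns
    el = _get_labeled(arch, label, "CPE")
    mid = (len(el) - 3) // 2
    core = el.matched_seq or record.sequence[el.start : el.end]
    central = "".join(
        ("G" if c == "T" else c) if mid <= i < mid + 3 else c
        for i, c in enumerate(core)
    )
    expected = _expected_after(arch, drop=el)
    for sub in (central, _SCRAMBLE.get(len(el))):
        if sub is None:
            continue
        seq = record.sequence[: el.start] + sub + record.sequence[el.end :]
        try:
            return _verified(_edited(record, seq), patterns, expected, f"mutate {label}")
        except ValueError:
            continue
    raise ValueError(f"{record.id}: no motif-free substitution found for {label}")


def delete_spacer(
    record: UtrRecord,
    arch: UtrArchitecture,
    upstream_label: str,
    downstream_label: str,
    remaining_gap: int,
    patterns: list[MotifPattern] | None = None,
) -> tuple[UtrRecord, UtrArchitecture]:
    """Shorten the element-free spacer between two motifs to ``remaining_gap``.

    Nucleotides are removed from the spacer midpoint outward (shifting the
    deletion window deterministically if a junction would form a motif);
    both motifs stay intact and all other pairwise gaps are preserved.
    """
    patterns = default_patterns() if patterns is None else patterns
    up, down = arch.get(upstream_label), arch.get(downstream_label)
    if up.start > down.start:
        up, down = down, up
    gap = gap_distance(up, down)
    if not (0 <= remaining_gap < gap):
        raise ValueError(
            f"remaining_gap {remaining_gap} not in [0, current gap {gap})"
        )
    for el in arch.elements:
        if el not in (up, down) and el.start >= up.end and el.end <= down.start:
            raise ValueError(
                f"spacer {upstream_label}..{downstream_label} contains {el.label}"
            )
    d = gap - remaining_gap
    center_off = (gap - d) // 2
    # try the centered window first, then shift outward one base at a time
    offsets = sorted(range(0, gap - d + 1), key=lambda o: (abs(o - center_off), o))
    for off in offsets:
        cut = up.end + off
        seq = record.sequence[:cut] + record.sequence[cut + d :]
        expected = _expected_after(arch, shift_from=down.start, shift_by=-d)
        try:
            return _verified(
                _edited(record, seq),
                patterns,
                expected,
                f"delete spacer {upstream_label}..{downstream_label}",
            )
        except ValueError:
            continue
    raise ValueError(
        f"{record.id}: every deletion window between {upstream_label} and "
        f"{downstream_label} creates or destroys a motif"
    )


def insert_cpe(
    record: UtrRecord,
    arch: UtrArchitecture,
    pas_label: str,
    gap: int,
    patterns: list[MotifPattern] | None = None,
    cpe_motif: str = INSERTED_CPE,
) -> tuple[UtrRecord, UtrArchitecture]:
    """Insert a canonical CPE so its spacer to the PAS equals ``gap`` nt.

    The UTR grows by the motif length; the rescan must show exactly one new
    CPE at the insertion site.  If a junction would extend or create a
    motif, the flanking background bases are deterministically normalized
    to C before giving up.
    """
    patterns = default_patterns() if patterns is None else patterns
    pas = _get_labeled(arch, pas_label, "PAS")
    pos = pas.end + gap
    if pos > len(record):
        raise ValueError(f"insertion site {pos} beyond UTR of length {len(record)}")
    for el in arch.elements:
        if el.start < pos < el.end:
            raise ValueError(f"insertion site {pos} falls inside {el.label}")
    expected = _expected_after(
        arch, shift_from=pos, shift_by=len(cpe_motif), add=("CPE", pos, pos + len(cpe_motif))
    )
    base_seq = record.sequence
    variants = [base_seq]
    if pos >= 1:
        variants.append(base_seq[: pos - 1] + "C" + base_seq[pos:])
    if pos < len(base_seq):
        variants.append(base_seq[:pos] + "C" + base_seq[pos + 1 :])
    if pos >= 1 and pos < len(base_seq):
        variants.append(base_seq[: pos - 1] + "C" + base_seq[pos] + "C" + base_seq[pos + 1 :])
    for var in variants:
        if len(var) != len(base_seq):  # guard: repairs are substitutions only
            continue
        seq = var[:pos] + cpe_motif + var[pos:]
        try:
            return _verified(
                _edited(record, seq), patterns, expected, f"insert CPE after {pas_label}"
            )
        except ValueError:
            continue
    raise ValueError(
        f"{record.id}: inserted CPE at gap {gap} after {pas_label} cannot be "
        "realized without an emergent motif"
    )


def truncate_distal(
    record: UtrRecord,
    arch: UtrArchitecture,
    retained_length: int,
    patterns: list[MotifPattern] | None = None,
) -> tuple[UtrRecord, UtrArchitecture]:
    """Keep only the 3'-most ``retained_length`` nt and rescan.

    Coordinates are re-based to the fragment; elements upstream of the cut
    (or straddling it) are lost.
    """
    patterns = default_patterns() if patterns is None else patterns
    if not (0 < retained_length <= len(record)):
        raise ValueError(
            f"retained_length {retained_length} out of range (UTR is {len(record)} nt)"
        )
    cut = len(record) - retained_length
    seq = record.sequence[cut:]
    expected = {
        (el.element_class, el.start - cut, el.end - cut)
        for el in arch.elements
        if el.start >= cut
    }
    return _verified(
        _edited(record, seq), patterns, expected, f"truncate to {retained_length} nt"
    )


def delete_pbe(
    record: UtrRecord,
    arch: UtrArchitecture,
    label: str = "PBE1",
    patterns: list[MotifPattern] | None = None,
) -> tuple[UtrRecord, UtrArchitecture]:
    """Delete a PBE outright (the UTR shrinks by the element length)."""
    patterns = default_patterns() if patterns is None else patterns
    el = _get_labeled(arch, label, "PBE")
    seq = record.sequence[: el.start] + record.sequence[el.end :]
    expected = _expected_after(arch, drop=el, shift_from=el.end, shift_by=-len(el))
    return _verified(_edited(record, seq), patterns, expected, f"delete {label}")


def _apply_one(
    record: UtrRecord,
    arch: UtrArchitecture,
    op: EditOp,
    patterns: list[MotifPattern],
) -> tuple[UtrRecord, UtrArchitecture]:
    if op.kind == "MUTATE_PAS":
        return mutate_pas(record, arch, str(op.target), patterns)
    if op.kind == "MUTATE_CPE":
        return mutate_cpe(record, arch, str(op.target), patterns)
    if op.kind == "DELETE_SPACER":
        up, down = op.target  # type: ignore[misc]
        return delete_spacer(record, arch, up, down, int(op.param), patterns)
    if op.kind == "INSERT_CPE":
        return insert_cpe(record, arch, str(op.target), int(op.param), patterns)
    if op.kind == "TRUNCATE_DISTAL":
        return truncate_distal(record, arch, int(op.param), patterns)
    return delete_pbe(record, arch, str(op.target), patterns)


def apply_construct(
    spec: ConstructSpec,
    fixtures,
    patterns: list[MotifPattern] | None = None,
) -> tuple[UtrRecord, UtrArchitecture, list[str]]:
    """Apply a construct's edits in order to its base fixture.

    ``fixtures`` is a ``FixtureSet`` (or any mapping-like object with
    ``__getitem__`` returning an object with ``record``/``architecture``).
    Returns the edited record, its rescanned architecture, and an edit log;
    a failing edit raises with its 1-based index.  Deterministic.
    """
    patterns = default_patterns() if patterns is None else patterns
    try:
        fx = fixtures[spec.base]
    except KeyError as exc:
        raise KeyError(f"construct {spec.name!r}: unknown base {spec.base!r}") from exc
    record, arch = fx.record, fx.architecture
    log: list[str] = [f"base {spec.base} ({len(record)} nt, {arch.counts()})"]
    for i, op in enumerate(spec.edits, start=1):
        try:
            record, arch = _apply_one(record, arch, op, patterns)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"construct {spec.name!r}, edit {i} ({op.kind}): {exc}") from exc
        log.append(f"edit {i}: {op.kind} {op.target or ''} {op.param if op.param is not None else ''}".strip())
    log.append("note: CPE/inserted-CPE substitutions are reconstructed, not published")
    return record, arch, log


def _mp(label: str) -> EditOp:
    return EditOp("MUTATE_PAS", label)


def _mc(label: str) -> EditOp:
    return EditOp("MUTATE_CPE", label)


def enumerate_reporter_constructs() -> list[ConstructSpec]:
    """The packaged reporter construct matrix for the three UTR fixtures.

    Element labels are positional and re-evaluated after each edit, so
    multi-element mutations list the highest ordinal first (mutating PAS1
    before PAS3 would relabel the survivors).  Constructs named after
    CPE-series panels that were assayed on a single-PAS backbone include
    those backbone PAS mutations in their edit lists.
    """
    c: list[ConstructSpec] = []
    add = lambda name, base, *edits: c.append(ConstructSpec(name, base, tuple(edits)))

    # --- Cpeb1: PAS series ---
    add("Cpeb1-WT", "Cpeb1")
    add("Cpeb1-ΔPAS3", "Cpeb1", _mp("PAS3"))
    add("Cpeb1-ΔPAS1", "Cpeb1", _mp("PAS1"))
    add("Cpeb1-ΔPAS2", "Cpeb1", _mp("PAS2"))
    add("Cpeb1-ΔPAS2/3", "Cpeb1", _mp("PAS3"), _mp("PAS2"))
    add("Cpeb1-ΔPAS1/2", "Cpeb1", _mp("PAS2"), _mp("PAS1"))
    add("Cpeb1-ΔPAS1/3", "Cpeb1", _mp("PAS3"), _mp("PAS1"))
    add("Cpeb1-ΔPAS1/2/3", "Cpeb1", _mp("PAS3"), _mp("PAS2"), _mp("PAS1"))
    # --- Cpeb1: CPE series (WT and PAS2-only backbones) ---
    add("Cpeb1-ΔCPE1-4", "Cpeb1", _mc("CPE4"), _mc("CPE3"), _mc("CPE2"), _mc("CPE1"))
    add(
        "Cpeb1-ΔPAS1/3+ΔCPE1-4",
        "Cpeb1",
        _mp("PAS3"), _mp("PAS1"), _mc("CPE4"), _mc("CPE3"), _mc("CPE2"), _mc("CPE1"),
    )
    add("Cpeb1-ΔCPE1/2", "Cpeb1", _mp("PAS3"), _mp("PAS1"), _mc("CPE2"), _mc("CPE1"))
    add("Cpeb1-ΔCPE2/4", "Cpeb1", _mp("PAS3"), _mp("PAS1"), _mc("CPE4"), _mc("CPE2"))
    add(
        "Cpeb1-ΔPAS2/3+ΔCPE1-4",
        "Cpeb1",
        _mp("PAS3"), _mp("PAS2"), _mc("CPE4"), _mc("CPE3"), _mc("CPE2"), _mc("CPE1"),
    )
    # --- Cpeb1: PAS1-CPE1 spacing series (PAS1-only backbone) ---
    for remaining in (50, 35, 15):
        add(
            f"Cpeb1-spacer-{remaining}",
            "Cpeb1",
            _mp("PAS3"), _mp("PAS2"),
            EditOp("DELETE_SPACER", ("PAS1", "CPE1"), remaining),
        )
    for gap in (35, 50):
        add(
            f"Cpeb1-CPE-insert-{gap}",
            "Cpeb1",
            _mp("PAS3"), _mp("PAS2"),
            EditOp("INSERT_CPE", "PAS1", gap),
        )
    add("Cpeb1-ΔPBE", "Cpeb1", EditOp("DELETE_PBE", "PBE1"))

    # --- Btg4: CPE dose/position series ---
    add("Btg4-WT", "Btg4")
    add("Btg4-ΔCPE1", "Btg4", _mc("CPE1"))
    add("Btg4-ΔCPE2", "Btg4", _mc("CPE2"))
    add("Btg4-ΔCPE3", "Btg4", _mc("CPE3"))
    add("Btg4-ΔCPE1/3", "Btg4", _mc("CPE3"), _mc("CPE1"))
    add("Btg4-ΔCPE1/2", "Btg4", _mc("CPE2"), _mc("CPE1"))
    add("Btg4-ΔCPE1/2/3", "Btg4", _mc("CPE3"), _mc("CPE2"), _mc("CPE1"))

    # --- Cnot6l: proximal/distal PAS series ---
    add("Cnot6l-WT", "Cnot6l")
    add("Cnot6l-ΔPAS1", "Cnot6l", _mp("PAS1"))
    add("Cnot6l-ΔPAS2", "Cnot6l", _mp("PAS2"))
    add("Cnot6l-ΔPAS1+ΔCPE4", "Cnot6l", _mc("CPE4"), _mp("PAS1"))
    add("Cnot6l-ΔPAS1+ΔCPE2/3", "Cnot6l", _mc("CPE3"), _mc("CPE2"), _mp("PAS1"))
    add("Cnot6l-truncated-402", "Cnot6l", EditOp("TRUNCATE_DISTAL", None, 402))

    names = [s.name for s in c]
    assert len(names) == len(set(names)), "construct names must be unique"
    return c
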