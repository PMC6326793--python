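"""Sequence and annotation input/output.

FASTA parsing goes through Biopython.  Element annotations are written as
BED6 (0-based half-open) or GFF3 (1-based inclusive); both writers are
inverses of the bundled readers, which is property-tested on the packaged
fixtures.  BED carries the UTR length in a leading ``#utr_length=`` comment
so that a round-trip restores the full architecture; GFF3 uses the standard
``##sequence-region`` pragma.
"""

from __future__ import annotations

import os

from Bio import SeqIO

from .scan import CisElement, UtrArchitecture, UtrRecord

__all__ = [
    "read_utr_fasta",
    "write_utr_fasta",
    "write_annotations",
    "read_annotations",
]

ANNOTATION_FORMATS = ("BED", "GFF3")


def read_utr_fasta(path: str | os.PathLike) -> list[UtrRecord]:
    """Read 3'-UTR sequences from FASTA, DNA or RNA alphabet.

    U is normalized to T and lowercase to uppercase; the alphabet seen on
    input is recorded per record.  Raises ``ValueError`` on an empty file or
    on non-nucleotide characters (the error names the record and offset).
    """
    records: list[UtrRecord] = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        raw = str(rec.seq).upper()
        alphabet = "RNA" if "U" in raw else "DNA"
        records.append(UtrRecord(id=rec.id, sequence=raw, source_alphabet=alphabet))
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def write_utr_fasta(records: list[UtrRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def write_annotations(
    arch: UtrArchitecture, format: str, path: str | os.PathLike
) -> None:
    """Write an architecture's elements as BED6 or GFF3.

    BED: 0-based half-open, element label in the name column (the element
    class is the label's alphabetic prefix).  GFF3: 1-based inclusive,
    element class in the type column, label in ``ID``/``Name`` attributes.
    """
    fmt = format.upper()
    if fmt not in ANNOTATION_FORMATS:
        raise ValueError(f"unknown annotation format {format!r}; use BED or GFF3")
    with open(path, "w") as fh:
        if fmt == "BED":
            fh.write(f"#utr_id={arch.utr_id} utr_length={arch.utr_length}\n")
            for el in arch.elements:
                fh.write(
                    f"{arch.utr_id}\t{el.start}\t{el.end}\t{el.label}\t0\t+\n"
                )
        else:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {arch.utr_id} 1 {arch.utr_length}\n")
            for el in arch.elements:
                attrs = f"ID={el.label};Name={el.label}"
                fh.write(
                    f"{arch.utr_id}\tutrcode\t{el.element_class}\t"
                    f"{el.start + 1}\t{el.end}\t.\t+\t.\t{attrs}\n"
                )


def _class_from_label(label: str) -> str:
    cls = label.rstrip("0123456789")
    return cls


def read_annotations(
    path: str | os.PathLike,
    format: str,
    record: UtrRecord | None = None,
    utr_length: int | None = None,
) -> UtrArchitecture:
    """Read a BED6/GFF3 file written by :func:`write_annotations`.

    ``record`` (if given) supplies the sequence so ``matched_seq`` can be
    restored; otherwise elements carry ``matched_seq=None``.  For BED the
    UTR length comes from the header comment unless ``utr_length`` is given.
    """
    fmt = format.upper()
    if fmt not in ANNOTATION_FORMATS:
        raise ValueError(f"unknown annotation format {format!r}; use BED or GFF3")
    utr_id: str | None = record.id if record else None
    length = len(record) if record else utr_length
    elements: list[CisElement] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if fmt == "BED":
                if line.startswith("#"):
                    for tok in line.lstrip("#").split():
                        key, _, val = tok.partition("=")
                        if key == "utr_length" and length is None:
                            length = int(val)
                        elif key == "utr_id" and utr_id is None:
                            utr_id = val
                    continue
                chrom, s, e, name = line.split("\t")[:4]
                start, end = int(s), int(e)
                label = name
            else:
                if line.startswith("##sequence-region"):
                    _, sid, _, send = line.split()
                    if length is None:
                        length = int(send)
                    if utr_id is None:
                        utr_id = sid
                    continue
                if line.startswith("#"):
                    continue
                cols = line.split("\t")
                chrom, _, ftype, s, e = cols[0], cols[1], cols[2], cols[3], cols[4]
                start, end = int(s) - 1, int(e)
                label = dict(
                    kv.split("=") for kv in cols[8].split(";") if "=" in kv
                ).get("ID", f"{ftype}?")
            utr_id = utr_id or chrom
            matched = record.sequence[start:end] if record else None
            elements.append(
                CisElement(
                    _class_from_label(label), start, end, matched_seq=matched, label=label
                )
            )
    if utr_id is None or length is None:
        raise ValueError(f"{path}: cannot determine UTR id/length")
    return UtrArchitecture(utr_id, length, tuple(elements))
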