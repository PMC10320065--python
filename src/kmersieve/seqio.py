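"""Streaming FASTA/FASTQ readers and writers with transparent gzip.

Every other module moves reads through these functions, so the contracts are
strict: streams are lazy (no full-file materialization), read/write
round-trips preserve id, sequence and quality, and paired files are combined
positionally with id-stem checking as a diagnostic. Sequences are upper-cased
on ingestion because all k-mer work is case-insensitive; original case is not
preserved.

Parsing is delegated to Biopython's low-level iterators
(:func:`Bio.SeqIO.FastaIO.SimpleFastaParser`,
:func:`Bio.SeqIO.QualityIO.FastqGeneralIterator`); writing is plain text.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import PairingError, SequenceFormatError

__all__ = [
    "SeqRecord",
    "read_records",
    "write_records",
    "pair_streams",
    "pair_stem",
]

_GZIP_MAGIC = b"\x1f\x8b"


@dataclass(frozen=True)
class SeqRecord:
    """One read: id token, optional description, sequence, optional quality."""

    read_id: str
    sequence: str
    quality: str | None = None
    description: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise SequenceFormatError(f"record {self.read_id!r} has empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise SequenceFormatError(
                f"record {self.read_id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    @property
    def header(self) -> str:
        return f"{self.read_id} {self.description}" if self.description else self.read_id


def pair_stem(read_id: str) -> str:
    """Pairing key for a read id: the id token minus a ``/1`` or ``/2`` suffix.

    Ids carrying mate information in a comment (``@id 1:N:0:...``) already
    share the id token, so only the suffix form needs stripping.
    """
    if read_id.endswith(("/1", "/2")):
        return read_id[:-2]
    return read_id


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _split_header(title: str) -> tuple[str, str]:
    parts = title.split(None, 1)
    return parts[0], (parts[1] if len(parts) > 1 else "")


def read_records(path: str | Path, format: str = "auto") -> Iterator[SeqRecord]:
    """Lazily yield :class:`SeqRecord` from a FASTA/FASTQ file, plain or .gz.

    With ``format="auto"`` the format is sniffed from the first byte
    (``>`` FASTA, ``@`` FASTQ). An empty file yields an empty stream.
    """
    handle = _open_text(path)
    try:
        if format == "auto":
            first = handle.read(1)
            if first == "":
                return
            handle.seek(0)
            if first == ">":
                format = "fasta"
            elif first == "@":
                format = "fastq"
            else:
                raise SequenceFormatError(
                    f"{path}: cannot sniff format from leading byte {first!r}"
                )
        if format == "fasta":
            for title, seq in SimpleFastaParser(handle):
                read_id, desc = _split_header(title)
                yield SeqRecord(read_id, seq.upper(), None, desc)
        elif format == "fastq":
            ordinal = 0
            try:
                for title, seq, qual in FastqGeneralIterator(handle):
                    ordinal += 1
                    read_id, desc = _split_header(title)
                    yield SeqRecord(read_id, seq.upper(), qual, desc)
            except ValueError as exc:  # Biopython signals truncation this way
                raise SequenceFormatError(
                    f"{path}: malformed FASTQ near record {ordinal + 1}: {exc}"
                ) from exc
        else:
            raise SequenceFormatError(f"unknown format {format!r}")
    finally:
        handle.close()


def write_records(
    records: Iterable[SeqRecord],
    path: str | Path,
    format: str = "auto",
    gzip_out: bool | None = None,
) -> int:
    """Write records in stream order; returns the number written.

    ``format="auto"`` infers from the file name (``.fastq``/``.fq`` vs
    ``.fasta``/``.fa``/``.fna``); gzip compression defaults to on for paths
    ending in ``.gz``. Writing FASTQ from records that carry no quality string
    is refused rather than fabricating qualities; FASTQ -> FASTA simply drops
    quality.
    """
    path = Path(path)
    if gzip_out is None:
        gzip_out = path.name.endswith(".gz")
    if format == "auto":
        stem = path.name[:-3] if path.name.endswith(".gz") else path.name
        if stem.endswith((".fastq", ".fq")):
            format = "fastq"
        elif stem.endswith((".fasta", ".fa", ".fna")):
            format = "fasta"
        else:
            raise SequenceFormatError(f"cannot infer output format from {path.name!r}")
    if format not in ("fasta", "fastq"):
        raise SequenceFormatError(f"unknown format {format!r}")

    opener = gzip.open if gzip_out else open
    count = 0
    with opener(path, "wt", encoding="utf-8") as handle:  # type: ignore[operator]
        for rec in records:
            if format == "fasta":
                handle.write(f">{rec.header}\n{rec.sequence}\n")
            else:
                if rec.quality is None:
                    raise SequenceFormatError(
                        f"record {rec.read_id!r} has no quality string; "
                        "cannot write FASTQ from FASTA input"
                    )
                handle.write(f"@{rec.header}\n{rec.sequence}\n+\n{rec.quality}\n")
            count += 1
    return count


def pair_streams(
    stream1: Iterable[SeqRecord],
    stream2: Iterable[SeqRecord],
    strict: bool = False,
) -> Iterator[tuple[SeqRecord, SeqRecord]]:
    """Zip two read streams positionally into mate pairs.

    Record *n* of file 1 is paired with record *n* of file 2. Id stems
    (:func:`pair_stem`) are compared as a diagnostic: a mismatch warns, or
    raises :class:`PairingError` when ``strict`` is set. Unequal stream
    lengths raise :class:`PairingError` at the first orphan record.
    """
    it1, it2 = iter(stream1), iter(stream2)
    n = 0
    sentinel = object()
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        n += 1
        if r1 is sentinel or r2 is sentinel:
            which = "file 1" if r1 is sentinel else "file 2"
            raise PairingError(f"{which} exhausted at pair {n}: unequal record counts")
        assert isinstance(r1, SeqRecord) and isinstance(r2, SeqRecord)
        if pair_stem(r1.read_id) != pair_stem(r2.read_id):
            msg = (
                f"pair {n}: id stems differ "
                f"({r1.read_id!r} vs {r2.read_id!r}); pairing positionally"
            )
            if strict:
                raise PairingError(msg)
            warnings.warn(msg, stacklevel=2)
        yield r1, r2
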