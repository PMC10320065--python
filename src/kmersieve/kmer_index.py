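"""Exact canonical-k-mer -> taxonomy-node index.

This is the reference database of the pipeline. Every k-mer occurring in any
reference genome is stored explicitly and mapped to a single taxonomy node:
the genome's own node if the k-mer is unique to one node, otherwise the
lowest common ancestor (LCA) of all nodes whose genomes contain it. These are
the assignment semantics of Kraken-style classifiers, implemented here as an
exact map (no minimizers, no subsampling, no probabilistic structures), which
keeps the classification math auditable at the cost of memory — appropriate
for curated contaminant panels rather than whole-RefSeq databases.

By default k-mers are canonicalized (the lexicographic minimum of a k-mer
and its reverse complement) so both strands of a genome index identically;
a flag disables this for strand-specific experiments. Windows containing any
non-ACGT character are skipped entirely; IUPAC codes are not expanded.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import ConfigError, IndexCompatibilityError, IndexFormatError
from .taxonomy import TaxonomyTree

__all__ = [
    "ReferenceGenome",
    "KmerIndex",
    "enumerate_kmers",
    "canonical_form",
    "reverse_complement",
    "build_index",
    "save_index",
    "load_index",
    "read_reference_manifest",
]

_ACGT = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_MAGIC = "#kmersieve-index"
_FORMAT_VERSION = 1


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an ACGT string."""
    return sequence.translate(_COMPLEMENT)[::-1]


def canonical_form(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Idempotent; raises :class:`ConfigError` on non-ACGT input.
    """
    if not _ACGT.issuperset(kmer):
        raise ConfigError(f"k-mer {kmer!r} contains non-ACGT characters")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def enumerate_kmers(sequence: str, k: int) -> list[str]:
    """All consecutive k-length windows of *sequence*, in order.

    Input is case-insensitive (output upper-case); any window containing a
    character outside ACGT is omitted. A sequence shorter than k yields an
    empty list. E.g. the 3-mers of ``"ATGG"`` are ``["ATG", "TGG"]``.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    seq = sequence.upper()
    out: list[str] = []
    last_bad = -1  # index of the most recent non-ACGT character
    for i, ch in enumerate(seq):
        if ch not in _ACGT:
            last_bad = i
        if i >= k - 1 and last_bad <= i - k:
            out.append(seq[i - k + 1 : i + 1])
    return out


@dataclass(frozen=True)
class ReferenceGenome:
    """A labelled reference: one or more sequences tied to a taxonomy node."""

    label: str
    node_id: int
    sequences: tuple[str, ...]

    def __post_init__(self):
        if not self.sequences or all(len(s) == 0 for s in self.sequences):
            raise ConfigError(f"reference {self.label!r} has no sequence data")


@dataclass
class KmerIndex:
    """Map from (canonical) k-mer to the taxonomy node it is assigned to."""

    k: int
    canonicalize: bool
    tree_fingerprint: str
    entries: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, kmer: str) -> int | None:
        """Node id for a raw k-mer window, or None if absent from the index."""
        if self.canonicalize:
            kmer = canonical_form(kmer)
        return self.entries.get(kmer)

    def check_tree(self, tree: TaxonomyTree) -> None:
        if tree.fingerprint() != self.tree_fingerprint:
            raise IndexCompatibilityError(
                "index was built against a different taxonomy "
                f"(fingerprint {self.tree_fingerprint[:12]}... != "
                f"{tree.fingerprint()[:12]}...)"
            )


def build_index(
    references: Sequence[ReferenceGenome],
    tree: TaxonomyTree,
    k: int = 35,
    canonicalize: bool = True,
) -> KmerIndex:
    """Build the exact k-mer index from labelled reference genomes.

    Each k-mer maps to the LCA of the nodes of all references containing it;
    a k-mer seen only under one node maps to that node. Multiple references
    may share a node id (multi-genome species): their k-mer sets union under
    that node before LCA logic applies, which the pairwise LCA fold handles
    naturally since ``lca(x, x) == x``.
    """
    if not references:
        raise ConfigError("no reference genomes supplied")
    for ref in references:
        if ref.node_id not in tree:
            raise IndexCompatibilityError(
                f"reference {ref.label!r} is labelled with node {ref.node_id}, "
                "absent from the taxonomy"
            )
    entries: dict[str, int] = {}
    for ref in references:
        seen: set[str] = set()
        for seq in ref.sequences:
            for kmer in enumerate_kmers(seq, k):
                seen.add(canonical_form(kmer) if canonicalize else kmer)
        for kmer in seen:
            current = entries.get(kmer)
            entries[kmer] = (
                ref.node_id if current is None else tree.lca((current, ref.node_id))
            )
    if not entries:
        warnings.warn(
            f"index is empty: k={k} exceeds every reference sequence length",
            stacklevel=2,
        )
    return KmerIndex(
        k=k,
        canonicalize=canonicalize,
        tree_fingerprint=tree.fingerprint(),
        entries=entries,
    )


def save_index(index: KmerIndex, path: str | Path) -> None:
    """Persist an index as a self-describing gzip-compressed text file.

    Entries are written in sorted order and the gzip header carries no
    timestamp, so identical indices produce byte-identical files.
    """
    path = Path(path)
    lines = [
        f"{_MAGIC} v{_FORMAT_VERSION}",
        f"k={index.k}",
        f"canonicalize={int(index.canonicalize)}",
        f"tree_fingerprint={index.tree_fingerprint}",
    ]
    lines.extend(f"{kmer}\t{index.entries[kmer]}" for kmer in sorted(index.entries))
    payload = ("\n".join(lines) + "\n").encode("utf-8")
    # gzip.compress with mtime=0 embeds neither timestamp nor filename
    path.write_bytes(gzip.compress(payload, mtime=0))


def load_index(path: str | Path, tree: TaxonomyTree | None = None) -> KmerIndex:
    """Load an index written by :func:`save_index`.

    When *tree* is given, the stored taxonomy fingerprint is verified and a
    mismatch raises :class:`IndexCompatibilityError`.
    """
    path = Path(path)
    try:
        with gzip.open(path, "rt", encoding="utf-8") as handle:
            header = handle.readline().rstrip("\n")
            if not header.startswith(_MAGIC):
                raise IndexFormatError(f"{path}: not a kmersieve index")
            meta: dict[str, str] = {}
            for _ in range(3):
                key, _, value = handle.readline().rstrip("\n").partition("=")
                meta[key] = value
            try:
                k = int(meta["k"])
                canonicalize = bool(int(meta["canonicalize"]))
                fingerprint = meta["tree_fingerprint"]
            except (KeyError, ValueError) as exc:
                raise IndexFormatError(f"{path}: corrupt index header") from exc
            entries: dict[str, int] = {}
            for lineno, line in enumerate(handle, start=5):
                line = line.rstrip("\n")
                if not line:
                    continue
                kmer, sep, node = line.partition("\t")
                if not sep or len(kmer) != k:
                    raise IndexFormatError(f"{path}: corrupt entry at line {lineno}")
                entries[kmer] = int(node)
    except (OSError, gzip.BadGzipFile) as exc:
        raise IndexFormatError(f"{path}: cannot read index file ({exc})") from exc
    index = KmerIndex(k, canonicalize, fingerprint, entries)
    if tree is not None:
        index.check_tree(tree)
    return index


def read_reference_manifest(
    manifest_path: str | Path,
) -> list[ReferenceGenome]:
    """Read a manifest TSV (columns: path, taxid[, label]) into references.

    FASTA paths are resolved relative to the manifest's directory; all
    sequences of one FASTA file become one :class:`ReferenceGenome`.
    """
    from .seqio import read_records  # local import to avoid cycle at import time

    manifest_path = Path(manifest_path)
    references: list[ReferenceGenome] = []
    for lineno, raw in enumerate(
        manifest_path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ConfigError(
                f"{manifest_path} line {lineno}: expected 'path<TAB>taxid[<TAB>label]'"
            )
        fasta = Path(fields[0])
        if not fasta.is_absolute():
            fasta = manifest_path.parent / fasta
        try:
            node_id = int(fields[1])
        except ValueError:
            raise ConfigError(
                f"{manifest_path} line {lineno}: non-integer taxid {fields[1]!r}"
            )
        label = fields[2] if len(fields) > 2 else fasta.name
        sequences = tuple(rec.sequence for rec in read_records(fasta))
        if not sequences:
            raise ConfigError(f"{fasta}: no sequences found")
        references.append(ReferenceGenome(label, node_id, sequences))
    if not references:
        raise ConfigError(f"{manifest_path}: no references listed")
    return references
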